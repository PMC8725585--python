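"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the neutral-model
oracle enumerates every possible immigration/birth history of the
sequential urn process, and the Ewens oracle is the textbook closed form
written with plain factorials.
"""

from collections import Counter, defaultdict
from math import factorial, log

import numpy as np


def integer_partitions(n, max_part=None):
    """All partitions of n as descending tuples."""
    if n == 0:
        yield ()
        return
    if max_part is None:
        max_part = n
    for k in range(min(n, max_part), 0, -1):
        for rest in integer_partitions(n - k, k):
            yield (k,) + rest


def ewens_logprob(config, theta):
    """Ewens sampling formula via plain factorials (independent route)."""
    config = tuple(int(n) for n in config)
    J = sum(config)
    S = len(config)
    phi = Counter(config)
    num = factorial(J) * theta ** S
    den = 1.0
    for i in range(J):
        den *= theta + i
    for n in config:
        den *= n
    for c in phi.values():
        den *= factorial(c)
    return log(num / den)


def brute_force_neutral_distribution(J, theta, m):
    """Exact configuration distribution of the neutral urn, by enumeration.

    Walks every history of the sequential process: individual k+1 is an
    immigrant with probability I/(I+k) (always for k=0 or m=1); an
    immigrant founds a new metacommunity species with probability
    theta/(theta+A) (A = immigration events so far) or repeats species s
    with probability a_s/(theta+A); otherwise it copies a local individual
    (species s with probability n_s/(I+k)).  States are collapsed to the
    canonical multiset of (n_s, a_s) pairs so the enumeration stays small.

    Returns {sorted abundance tuple: probability}.
    """
    I = None if m == 1 else m * (J - 1) / (1.0 - m)
    results = defaultdict(float)
    # state: tuple of (n, a) pairs, sorted
    frontier = {((1, 1),): 1.0}
    for k in range(1, J):  # k individuals already placed
        new_frontier = defaultdict(float)
        for state, prob in frontier.items():
            A = sum(a for _, a in state)
            p_imm = 1.0 if m == 1 else I / (I + k)
            # immigration founding a new species
            p = prob * p_imm * (theta / (theta + A))
            st = tuple(sorted(state + ((1, 1),)))
            new_frontier[st] += p
            for i, (n, a) in enumerate(state):
                rest = state[:i] + state[i + 1 :]
                # immigration repeating species i
                p = prob * p_imm * (a / (theta + A))
                st = tuple(sorted(rest + ((n + 1, a + 1),)))
                new_frontier[st] += p
                # local birth (copy) of species i
                if m < 1:
                    p = prob * (n / (I + k))
                    st = tuple(sorted(rest + ((n + 1, a),)))
                    new_frontier[st] += p
        frontier = new_frontier
    out = defaultdict(float)
    for state, prob in frontier.items():
        config = tuple(sorted((n for n, _ in state), reverse=True))
        out[config] += prob
    return dict(out)


def nodf_naive(M):
    """NODF by the literal pairwise definition (loops, no vectorisation)."""
    M = np.asarray(M)
    terms_rows, terms_cols = [], []
    for axis, terms in ((0, terms_rows), (1, terms_cols)):
        V = M if axis == 0 else M.T
        n = V.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                fi, fj = V[i].sum(), V[j].sum()
                if fi == fj or min(fi, fj) == 0:
                    terms.append(0.0)
                else:
                    lo, hi = (i, j) if fi > fj else (j, i)
                    overlap = int((V[lo] & V[hi]).sum())
                    terms.append(100.0 * overlap / V[hi].sum())
    total = (sum(terms_rows) + sum(terms_cols)) / (len(terms_rows) + len(terms_cols))
    return total, float(np.mean(terms_rows)), float(np.mean(terms_cols))
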
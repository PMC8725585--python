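"""Beta-diversity structure: Bray-Curtis, NMDS, ANOSIM, Mantel, VPA.

The non-metric MDS is a Kruskal stress-1 minimiser (SMACOF iterations with
monotone regression of configuration distances on the observed
dissimilarities), restarted from several random configurations plus a
classical-scaling start; the best-stress solution is kept.

Permutation tests use the add-one convention
p = (1 + #{null >= observed}) / (1 + n_perm), so p is never exactly 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .tables import CommunityTable

__all__ = [
    "NMDSResult",
    "PermutationTestResult",
    "bray_curtis",
    "nmds",
    "anosim",
    "mantel",
    "hellinger",
    "vpa",
    "per_factor_fractions",
]


@dataclass
class NMDSResult:
    coordinates: np.ndarray  # samples x k, centred at the origin
    stress: float  # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    seed: int
    stress_trace: np.ndarray  # per-iteration stress of the winning start
    ids: list


@dataclass
class PermutationTestResult:
    statistic: float
    p: float
    n_perm: int
    seed: int
    null_values: np.ndarray
    method: str = ""


# ---------------------------------------------------------------------------
# Distances


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between samples."""
    values = table.abundance
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample row")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.sample_ids])


# ---------------------------------------------------------------------------
# Non-metric MDS


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(d: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d ** 2).sum()
    if denom == 0:
        return np.inf
    return float(np.sqrt(((d - disparities) ** 2).sum() / denom))


def _nmds_single(D, k, X0, max_iter, tol):
    n = D.shape[0]
    dis = squareform(D)  # observed dissimilarities, condensed
    order = np.argsort(dis, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    X = X0.copy()
    trace = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        # monotone regression of configuration distances on dissimilarity
        # order; ties in the dissimilarities are averaged (primary approach)
        dhat = iso.fit(dis, d).predict(dis)
        s = _stress1(d, dhat)
        trace.append(s)
        if prev - s < tol:
            converged = True
            break
        prev = s
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X - X.mean(axis=0), trace[-1], np.asarray(trace), converged


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> NMDSResult:
    """Non-metric multidimensional scaling (Kruskal stress-1).

    Runs one classical-scaling start plus ``n_starts - 1`` random starts and
    keeps the lowest-stress configuration.  Deterministic given ``seed``.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    if k >= n - 1:
        raise ValueError("k must be <= n_samples - 2")
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        X0 = _classical_mds(D, k) if start == 0 else rng.normal(size=(n, k))
        if not np.isfinite(X0).all() or np.allclose(X0, 0):
            X0 = rng.normal(size=(n, k))
        X, stress, trace, conv = _nmds_single(D, k, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, trace, conv)
    X, stress, trace, conv = best
    return NMDSResult(
        coordinates=X,
        stress=stress,
        n_starts=n_starts,
        converged=conv,
        seed=seed,
        stress_trace=trace,
        ids=list(dm.ids),
    )


# ---------------------------------------------------------------------------
# Permutation tests


def _perm_matrix(rng, n, n_perm):
    perms = np.empty((n_perm, n), dtype=np.int64)
    idx = np.arange(n)
    for i in range(n_perm):
        perms[i] = rng.permutation(idx)
    return perms


def anosim(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the null distribution permutes group labels.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    labels = np.asarray(grouping)
    if len(labels) != n:
        raise ValueError("grouping length does not match distance matrix")
    codes = pd.factorize(labels)[0]
    counts = np.bincount(codes)
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    dis = squareform(D)
    if np.ptp(dis) == 0:
        raise ValueError("constant distance matrix")
    ranks = rankdata(dis)
    M = len(ranks)
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(within):
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return (rb - rw) / (M / 2.0)

    observed = r_stat(codes[iu] == codes[ju])
    rng = np.random.default_rng(seed)
    perms = _perm_matrix(rng, n, n_perm)
    perm_codes = codes[perms]  # (n_perm, n) permuted group labels
    within = perm_codes[:, iu] == perm_codes[:, ju]  # (n_perm, M)
    n_within = within.sum(axis=1)
    sum_within = (within * ranks).sum(axis=1)
    total = ranks.sum()
    null = ((total - sum_within) / (M - n_within) - sum_within / n_within) / (M / 2.0)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationTestResult(float(observed), float(p), n_perm, seed, null, "anosim")


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of off-diagonal distances.

    Significance by permuting rows/columns of the second matrix; one-sided
    (correlation at least as large as observed), add-one convention.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share ids and order")
    A = np.asarray(dm1.data, dtype=float)
    B = np.asarray(dm2.data, dtype=float)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    v1 = A[iu, ju]
    v1c = v1 - v1.mean()
    n1 = np.sqrt((v1c ** 2).sum())
    if n1 == 0:
        raise ValueError("constant distance matrix")

    def corr(vec):
        vc = vec - vec.mean()
        denom = n1 * np.sqrt((vc ** 2).sum())
        return (v1c @ vc) / denom

    observed = corr(B[iu, ju])
    rng = np.random.default_rng(seed)
    perms = _perm_matrix(rng, n, n_perm)
    rows = perms[:, iu]
    cols = perms[:, ju]
    vperm = B[rows, cols]  # (n_perm, M)
    vc = vperm - vperm.mean(axis=1, keepdims=True)
    denom = n1 * np.sqrt((vc ** 2).sum(axis=1))
    null = (vc @ v1c) / denom
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationTestResult(float(observed), float(p), n_perm, seed, null, "mantel")


# ---------------------------------------------------------------------------
# Variance partitioning (VPA)


def hellinger(table: CommunityTable) -> np.ndarray:
    """Hellinger transform: square root of relative abundances."""
    rel = table.to_relative().abundance if table.mode == "counts" else table.abundance
    return np.sqrt(rel)


def _adjusted_r2(Y: np.ndarray, X: np.ndarray) -> float:
    n = Y.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank >= n - 1:
        raise ValueError("more predictors than samples allow")
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    ss_tot = (Yc ** 2).sum()
    r2 = (fitted ** 2).sum() / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 1 - rank))


def vpa(response: CommunityTable, blocks: dict) -> dict:
    """Variance partitioning of a Hellinger-transformed community table.

    For every non-empty subset of the 2-4 explanatory blocks the adjusted
    R^2 (Ezekiel correction) of the redundancy analysis is computed; unique
    and joint fractions follow by inclusion-exclusion.  Keys of the result:
    one per non-empty block subset ("X", "X&W", ...) holding that exclusive
    (Venn-atom) fraction, plus "residual".  Fractions may be negative
    (adjusted R^2); display conventions truncate at 0.
    """
    if not 2 <= len(blocks) <= 4:
        raise ValueError("vpa supports 2-4 blocks")
    names = list(blocks)
    mats = {}
    for name in names:
        X = np.asarray(blocks[name], dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != response.n_samples:
            raise ValueError(f"block {name!r} rows do not match samples")
        Xc = X - X.mean(axis=0)
        if np.linalg.matrix_rank(Xc) < X.shape[1]:
            warnings.warn(f"block {name!r} is rank deficient; collinear columns pooled")
        mats[name] = X
    Y = hellinger(response)
    f = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            X = np.hstack([mats[c] for c in combo])
            f[frozenset(combo)] = _adjusted_r2(Y, X)
    allset = frozenset(names)
    # h(U) = variance attributable only to atoms inside U; Moebius-invert it
    # to get each exclusive (Venn-atom) fraction a(V)
    h = {
        frozenset(U): f[allset] - f[allset - frozenset(U)]
        for r in range(len(names) + 1)
        for U in itertools.combinations(names, r)
    }
    fractions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            atom = 0.0
            for rr in range(len(combo) + 1):
                for sub in itertools.combinations(combo, rr):
                    atom += (-1) ** (len(combo) - rr) * h[frozenset(sub)]
            fractions["&".join(sorted(combo))] = atom
    fractions["residual"] = 1.0 - f[allset]
    return fractions


def per_factor_fractions(response: CommunityTable, factors: pd.DataFrame) -> pd.Series:
    """Unique adjusted-R^2 fraction of each single abiotic factor.

    The classic partition supports at most 4 blocks, so each factor is
    scored by the 2-block partition {factor} vs {all other factors} and its
    unique fraction reported.
    """
    out = {}
    for col in factors.columns:
        others = [c for c in factors.columns if c != col]
        fr = vpa(
            response,
            {"focal": factors[[col]].to_numpy(), "others": factors[others].to_numpy()},
        )
        out[col] = fr["focal"]
    return pd.Series(out, name="unique_fraction")
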
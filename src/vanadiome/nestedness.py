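"""NODF nestedness and margin-constrained null models.

NODF (nestedness metric based on overlap and decreasing fill) scores, for
every pair of rows (and of columns), the percentage of the sparser line's
presences that are shared with the denser line; pairs with equal fills score
zero.  0 = no nesting, 100 = every sparser community a perfect subset.

Null ensembles: ``equiprobable`` scatters the same total fill uniformly;
``fixed_fixed_swap`` runs a checkerboard-swap Markov chain that preserves
both row and column sums exactly (burn-in plus thinning of at least the
matrix fill between saved matrices).  Significance is a z test of the
observed NODF against the null ensemble; the verdict is "nested" only when
the observed value exceeds the null mean AND p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tables import CommunityTable, aggregate_rank, binarize, group_samples

__all__ = ["NODFResult", "nodf", "null_ensemble", "nodf_test", "nodf_by_rank"]


@dataclass
class NODFResult:
    nodf_total: float
    nodf_rows: float
    nodf_cols: float
    matrix_shape: tuple
    null_values: Optional[np.ndarray] = None
    z: Optional[float] = None
    p: Optional[float] = None
    nested: Optional[bool] = None
    null_algorithm: Optional[str] = None
    seed: Optional[int] = None


def _check_binary(matrix) -> np.ndarray:
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("matrix must be binary")
    M = M.astype(np.int64)
    if M.sum() == 0:
        raise ValueError("all-zero matrix")
    return M


def _pair_terms(M: np.ndarray):
    """Sum and count of paired-overlap terms over row pairs of M."""
    fills = M.sum(axis=1)
    overlap = M @ M.T
    n = M.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    fi, fj = fills[iu], fills[ju]
    ov = overlap[iu, ju]
    denom = np.minimum(fi, fj)
    valid = (fi != fj) & (denom > 0)
    terms = np.where(valid, 100.0 * ov / np.where(denom > 0, denom, 1), 0.0)
    return terms.sum(), len(terms)


def nodf(matrix) -> NODFResult:
    """NODF of a binary matrix (metric fields only).

    Uses fills and overlaps over all pairs, so it is invariant to row or
    column permutation; ties in fill contribute 0 by the decreasing-fill
    rule.
    """
    M = _check_binary(matrix)
    row_sum, n_row_pairs = _pair_terms(M)
    col_sum, n_col_pairs = _pair_terms(M.T)
    return NODFResult(
        nodf_total=(row_sum + col_sum) / (n_row_pairs + n_col_pairs),
        nodf_rows=row_sum / n_row_pairs,
        nodf_cols=col_sum / n_col_pairs,
        matrix_shape=M.shape,
    )


def _has_checkerboard(M: np.ndarray) -> bool:
    n = M.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a = (M[i] == 1) & (M[j] == 0)
            b = (M[i] == 0) & (M[j] == 1)
            if a.any() and b.any():
                return True
    return False


def _swap_chain(M: np.ndarray, n_attempts: int, rng) -> np.ndarray:
    """Run ``n_attempts`` attempted checkerboard swaps in place on M."""
    R, C = M.shape
    rows1 = rng.integers(0, R, size=n_attempts)
    rows2 = rng.integers(0, R, size=n_attempts)
    cols1 = rng.integers(0, C, size=n_attempts)
    cols2 = rng.integers(0, C, size=n_attempts)
    for r1, r2, c1, c2 in zip(rows1, rows2, cols1, cols2):
        if r1 == r2 or c1 == c2:
            continue
        a, b, c, d = M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2]
        if a == d and b == c and a != b:
            M[r1, c1] = b
            M[r1, c2] = a
            M[r2, c1] = a
            M[r2, c2] = b
    return M


def null_ensemble(
    matrix,
    algorithm: str = "fixed_fixed_swap",
    n: int = 999,
    seed: int = 0,
    burn_in: Optional[int] = None,
    thin: Optional[int] = None,
) -> list:
    """Generate ``n`` null matrices (n >= 99).

    equiprobable: total fill placed uniformly at random.
    fixed_fixed_swap: sequential checkerboard swaps preserving both margins
    exactly; thinning defaults to 2x the matrix fill (never below the fill).
    """
    M = _check_binary(matrix)
    if n < 99:
        raise ValueError("null ensemble needs n >= 99")
    rng = np.random.default_rng(seed)
    R, C = M.shape
    fill = int(M.sum())
    if algorithm == "equiprobable":
        out = []
        for _ in range(n):
            flat = np.zeros(R * C, dtype=np.int64)
            flat[rng.choice(R * C, size=fill, replace=False)] = 1
            out.append(flat.reshape(R, C))
        return out
    if algorithm != "fixed_fixed_swap":
        raise ValueError(f"unknown null algorithm {algorithm!r}")
    if not _has_checkerboard(M):
        raise ValueError("margins force a unique matrix; swap null undefined")
    if burn_in is None:
        burn_in = max(1000, 10 * fill)
    if thin is None:
        thin = 2 * fill
    thin = max(thin, fill)  # thinning >= matrix fill, by contract
    cur = M.copy()
    _swap_chain(cur, burn_in, rng)
    out = []
    for _ in range(n):
        _swap_chain(cur, thin, rng)
        out.append(cur.copy())
    return out


def nodf_test(
    matrix,
    algorithm: str = "fixed_fixed_swap",
    n: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    **chain_kw,
) -> NODFResult:
    """NODF z test against a null ensemble.

    z = (observed - null mean) / null sd; two-sided normal p.  The verdict
    ``nested`` additionally requires observed > null mean (communities are
    declared nested only when more nested than the null expectation).
    """
    observed = nodf(matrix)
    nulls = null_ensemble(matrix, algorithm, n, seed, **chain_kw)
    null_vals = np.array([nodf(Nm).nodf_total for Nm in nulls])
    sd = null_vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null ensemble (sd = 0)")
    z = (observed.nodf_total - null_vals.mean()) / sd
    p = float(2 * norm.sf(abs(z)))
    observed.null_values = null_vals
    observed.z = float(z)
    observed.p = p
    observed.nested = bool(observed.nodf_total > null_vals.mean() and p < alpha)
    observed.null_algorithm = algorithm
    observed.seed = seed
    return observed


def nodf_by_rank(
    table: CommunityTable,
    lineages: dict,
    meta: pd.DataFrame,
    grouping: str = "dose",
    algorithm: str = "fixed_fixed_swap",
    n: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """NODF test per taxonomic rank on group x taxon incidence matrices.

    ``lineages`` maps rank name -> {feature -> label at that rank}; samples
    are pooled by the metadata column ``grouping`` (habitat, dose or
    group_label) before binarization.
    """
    if grouping not in meta.columns:
        raise ValueError(f"metadata has no column {grouping!r}")
    rows = []
    for i, (rank, lineage) in enumerate(lineages.items()):
        agg = aggregate_rank(table, lineage, rank)
        pooled = group_samples(agg, meta, grouping)
        incidence = binarize(pooled).abundance.astype(int)
        res = nodf_test(incidence, algorithm, n, seed + i)
        rows.append(
            {
                "rank": rank,
                "nodf": res.nodf_total,
                "null_mean": float(res.null_values.mean()),
                "z": res.z,
                "p": res.p,
                "nested": res.nested,
                "n_groups": incidence.shape[0],
                "n_taxa": incidence.shape[1],
            }
        )
    return pd.DataFrame(rows)
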
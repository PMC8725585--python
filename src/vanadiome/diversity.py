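"""Alpha diversity and simple group tests.

Shannon H (natural log) and the Gini-Simpson index 1 - sum(p^2).  The
Gini-Simpson form is reported, rather than Simpson's concentration
sum(p^2) itself, so that "higher = more diverse" holds for both indices;
the two are complements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CommunityTable

__all__ = [
    "DiversityResult",
    "shannon",
    "simpson",
    "richness",
    "alpha_diversity",
    "gradient_correlation",
    "anova_oneway",
    "gradient_tests",
]


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon_H: float
    simpson_D: float
    richness: int


def _proportions(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (a < 0).any():
        raise ValueError("negative abundance")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    return a[a > 0] / total


def shannon(abundances) -> float:
    """Shannon index H = -sum p ln p (natural log)."""
    p = _proportions(abundances)
    return float(-(p * np.log(p)).sum())


def simpson(abundances) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    p = _proportions(abundances)
    return float(1.0 - (p * p).sum())


def richness(abundances) -> int:
    a = np.asarray(abundances, dtype=float)
    return int((a > 0).sum())


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample Shannon, Gini-Simpson and richness."""
    rows = []
    for sid in table.sample_ids:
        vec = table.data.loc[sid].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sid,
                "shannon_H": shannon(vec),
                "simpson_D": simpson(vec),
                "richness": richness(vec),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def gradient_correlation(values, doses):
    """Pearson correlation of a per-sample statistic with vanadium dose.

    Returns (r, p) with a two-sided p from the t distribution on n-2 df.
    """
    values = np.asarray(values, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if values.shape != doses.shape or values.ndim != 1:
        raise ValueError("values and doses must be equal-length vectors")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(doses) == 0 or np.ptp(values) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(values, doses)
    return float(r), float(p)


def anova_oneway(groups):
    """Classical one-way ANOVA over >= 2 groups of >= 2 observations."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 observations")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def gradient_tests(
    table: CommunityTable,
    meta: pd.DataFrame,
    per_habitat: bool = True,
) -> pd.DataFrame:
    """Pearson dose-trend tests of Shannon/Simpson, per habitat by default."""
    div = alpha_diversity(table)
    meta = meta.loc[div.index]
    out = []
    scopes = (
        [(h, meta["habitat"] == h) for h in sorted(meta["habitat"].unique())]
        if per_habitat
        else [("pooled", pd.Series(True, index=meta.index))]
    )
    for scope, mask in scopes:
        doses = meta.loc[mask, "dose"]
        for index_name in ("shannon_H", "simpson_D", "richness"):
            vals = div.loc[mask.index[mask], index_name]
            try:
                r, p = gradient_correlation(vals.to_numpy(), doses.to_numpy())
            except ValueError:
                r, p = np.nan, np.nan  # constant index (e.g. saturated richness)
            out.append(
                {"scope": scope, "index": index_name, "r": r, "p": p, "n": int(mask.sum())}
            )
    return pd.DataFrame(out)
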
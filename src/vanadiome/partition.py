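"""Turnover/nestedness partitioning of beta diversity.

Two flavors, both exactly additive (turnover + nestedness = total):

incidence (Carvalho family), from the shared / unique-to-each counts
(a, b, c):

    beta_cc   = (b + c) / (a + b + c)        total
    beta_-3   = 2 min(b, c) / (a + b + c)    replacement (turnover)
    beta_rich = |b - c| / (a + b + c)        richness difference (nestedness)

abundance (Bray-Curtis decomposition), with A = sum min(x, y),
B = sum(x - min), C = sum(y - min):

    d_BC  = (B + C) / (2A + B + C)           total Bray-Curtis
    d_bal = min(B, C) / (A + min(B, C))      balanced variation (turnover)
    d_gra = d_BC - d_bal                     abundance gradient (nestedness)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CommunityTable

__all__ = [
    "PartitionResult",
    "partition_incidence",
    "partition_braycurtis",
    "partition_pair",
    "partition_summary",
]


@dataclass(frozen=True)
class PartitionResult:
    beta_total: float
    turnover: float
    nestedness_component: float
    flavor: str

    @property
    def turnover_fraction(self) -> float:
        if self.beta_total == 0:
            return float("nan")
        return self.turnover / self.beta_total

    @property
    def nestedness_fraction(self) -> float:
        if self.beta_total == 0:
            return float("nan")
        return self.nestedness_component / self.beta_total


def partition_incidence(a: int, b: int, c: int) -> PartitionResult:
    """Carvalho partition from shared (a) and unique (b, c) feature counts."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    denom = a + b + c
    if denom == 0:
        raise ValueError("a + b + c must be positive")
    turnover = 2.0 * min(b, c) / denom
    nestedness = abs(b - c) / denom
    return PartitionResult(
        beta_total=(b + c) / denom,
        turnover=turnover,
        nestedness_component=nestedness,
        flavor="incidence_carvalho",
    )


def partition_braycurtis(x, y) -> PartitionResult:
    """Bray-Curtis split into balanced-variation and abundance-gradient parts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("zero-total vector")
    m = np.minimum(x, y)
    A = m.sum()
    B = (x - m).sum()
    C = (y - m).sum()
    if B + C == 0:
        return PartitionResult(0.0, 0.0, 0.0, "abundance_braycurtis")
    d_bc = (B + C) / (2 * A + B + C)
    d_bal = min(B, C) / (A + min(B, C))
    return PartitionResult(
        beta_total=d_bc,
        turnover=d_bal,
        nestedness_component=d_bc - d_bal,
        flavor="abundance_braycurtis",
    )


def partition_pair(x, y, flavor: str = "abundance_braycurtis") -> PartitionResult:
    """Partition one pair of abundance vectors under either flavor."""
    if flavor == "abundance_braycurtis":
        return partition_braycurtis(x, y)
    if flavor == "incidence_carvalho":
        px = np.asarray(x) > 0
        py = np.asarray(y) > 0
        a = int((px & py).sum())
        b = int((px & ~py).sum())
        c = int((~px & py).sum())
        return partition_incidence(a, b, c)
    raise ValueError(f"unknown flavor {flavor!r}")


def partition_summary(
    table: CommunityTable,
    meta: pd.DataFrame,
    scheme: str = "between_doses",
    flavor: str = "abundance_braycurtis",
) -> pd.DataFrame:
    """Average pairwise partition components per group contrast.

    ``scheme`` chooses the contrast column: ``between_habitats`` pairs
    samples from different habitats, ``between_doses`` pairs samples from
    different dose levels (within habitat).  Components of all contributing
    pairs are averaged and expressed as percentages of total beta; when the
    total is 0 the percentages are reported as NaN and flagged.
    """
    col = {"between_habitats": "habitat", "between_doses": "dose"}.get(scheme)
    if col is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    meta = meta.loc[table.data.index]
    rows = []
    if scheme == "between_habitats":
        contrasts = [("gut_vs_soil", meta.index)]
    else:
        contrasts = [
            (str(h), meta.index[meta["habitat"] == h])
            for h in sorted(meta["habitat"].unique())
        ]
    for name, ids in contrasts:
        sub = meta.loc[ids]
        groups = sub[col]
        if groups.nunique() < 2:
            raise ValueError(f"scheme {scheme!r} needs >= 2 groups in contrast {name}")
        totals, turns, nests = [], [], []
        for s1, s2 in itertools.combinations(ids, 2):
            if groups[s1] == groups[s2]:
                continue
            res = partition_pair(
                table.data.loc[s1].to_numpy(), table.data.loc[s2].to_numpy(), flavor
            )
            totals.append(res.beta_total)
            turns.append(res.turnover)
            nests.append(res.nestedness_component)
        total = float(np.mean(totals))
        turn = float(np.mean(turns))
        nest = float(np.mean(nests))
        degenerate = total == 0
        rows.append(
            {
                "contrast": name,
                "flavor": flavor,
                "beta_total": total,
                "turnover": turn,
                "nestedness": nest,
                "turnover_pct": np.nan if degenerate else 100.0 * turn / total,
                "nestedness_pct": np.nan if degenerate else 100.0 * nest / total,
                "degenerate": degenerate,
                "n_pairs": len(totals),
            }
        )
    return pd.DataFrame(rows)
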
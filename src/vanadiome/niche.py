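"""Levins niche breadth and vanadium-detoxifying-gene (VDG) screening.

Levins breadth of feature j across N communities:

    B_j = 1 / sum_i P_ij^2,   P_ij = abundance of j in community i
                                      / total abundance of j over communities

so sum_i P_ij = 1, 1 <= B_j <= N; B_j = N for a perfectly even generalist,
B_j = 1 for a single-community specialist.  A community's breadth is the
mean B over the features occurring in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .tables import CommunityTable, VDGCatalog

__all__ = [
    "NicheBreadthResult",
    "VDGSummary",
    "levins_breadth",
    "screen_vdg",
    "vdg_carrier_summary",
]


@dataclass
class NicheBreadthResult:
    per_feature: pd.Series  # B_j, indexed by feature
    community_mean: pd.Series  # mean B over features present, per sample
    N: int


@dataclass
class VDGSummary:
    per_group: pd.DataFrame  # group x {vdg_rel_abundance, carrier_rel_abundance, carrier_richness}
    habitat_shares: pd.DataFrame  # habitat x same columns, summing to 100 per column
    carrier_breadth: pd.Series  # mean Levins B of carrier taxa, per habitat


def levins_breadth(table: CommunityTable, features=None) -> NicheBreadthResult:
    """Levins niche breadth of each feature across the table's communities."""
    data = table.data if features is None else table.data[list(features)]
    totals = data.sum(axis=0)
    absent = totals[totals <= 0].index.tolist()
    if absent:
        raise ValueError(f"features absent from every community: {absent[:5]}")
    P = data.div(totals, axis=1)
    B = 1.0 / (P ** 2).sum(axis=0)
    B.name = "levins_B"
    present = data > 0
    community_mean = pd.Series(
        {
            sid: B[present.loc[sid]].mean() if present.loc[sid].any() else np.nan
            for sid in data.index
        },
        name="community_mean_B",
    )
    return NicheBreadthResult(B, community_mean, N=data.shape[0])


def screen_vdg(gene_table: CommunityTable, catalog: VDGCatalog):
    """Restrict a gene table to catalogued VDGs.

    Returns (vdg_table, per_sample) where ``per_sample`` holds each
    detoxification category's total, the overall VDG total and the
    proportion of VDG abundance in the whole gene table.
    """
    if gene_table.feature_kind != "gene":
        raise ValueError("screen_vdg needs a gene table")
    present = [f for f in gene_table.feature_ids if f in catalog.entries]
    missing = sorted(set(catalog.entries) - set(present))
    if not present:
        raise ValueError(
            "no catalog KO found in the gene table (identifier dialect mismatch?)"
        )
    if missing:
        warnings.warn(f"catalog KOs absent from the table: {missing}")
    sub = _dc_replace(gene_table, data=gene_table.data[present], mode=gene_table.mode)
    cats = pd.Series({f: catalog.entries[f] for f in present})
    per_sample = sub.data.T.groupby(cats).sum().T
    per_sample["vdg_total"] = sub.data.sum(axis=1)
    per_sample["vdg_proportion"] = per_sample["vdg_total"] / gene_table.data.sum(axis=1)
    return sub, per_sample


def vdg_carrier_summary(
    taxon_table: CommunityTable,
    carriers,
    gene_table: CommunityTable,
    catalog: VDGCatalog,
    meta: pd.DataFrame,
) -> VDGSummary:
    """Habitat/treatment profile of VDGs and their carrier taxa.

    ``carriers`` is the set of taxa known to encode at least one VDG.  The
    three per-group axes are the mean relative abundance of VDGs, the mean
    relative abundance of carrier taxa, and carrier richness; habitat shares
    of each quantity sum to 100%.  Carrier niche breadth is computed per
    habitat with :func:`levins_breadth` restricted to carriers present in
    that habitat.
    """
    carriers = [t for t in carriers if t in taxon_table.feature_ids]
    if not carriers:
        raise ValueError("carrier set empty (or disjoint from the taxon table)")
    meta = meta.loc[taxon_table.data.index]
    _, vdg_per_sample = screen_vdg(gene_table, catalog)
    taxon_rel = taxon_table.to_relative().data
    carrier_rel = taxon_rel[carriers].sum(axis=1)
    carrier_rich = (taxon_table.data[carriers] > 0).sum(axis=1)
    per_sample = pd.DataFrame(
        {
            "vdg_rel_abundance": vdg_per_sample.loc[meta.index, "vdg_proportion"],
            "carrier_rel_abundance": carrier_rel,
            "carrier_richness": carrier_rich,
        }
    )
    per_group = per_sample.groupby(meta["group_label"]).mean()
    by_habitat = per_sample.groupby(meta["habitat"]).sum()
    habitat_shares = 100.0 * by_habitat / by_habitat.sum(axis=0)
    breadth = {}
    for habitat in sorted(meta["habitat"].unique()):
        sub = taxon_table.subset_samples(meta.index[meta["habitat"] == habitat])
        present = [c for c in carriers if sub.data[c].sum() > 0]
        if not present:
            breadth[habitat] = np.nan
            continue
        breadth[habitat] = float(levins_breadth(sub, features=present).per_feature.mean())
    return VDGSummary(
        per_group=per_group,
        habitat_shares=habitat_shares,
        carrier_breadth=pd.Series(breadth, name="mean_carrier_B"),
    )
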
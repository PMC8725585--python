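"""Core data containers and table transformations.

Everything downstream consumes a :class:`CommunityTable`: a sample x feature
abundance matrix (features are taxa at some rank, or KEGG-orthology gene
groups) together with sample metadata (habitat, vanadium dose, abiotic
factors).  Tables are normalised internally to samples-as-rows regardless of
the on-disk orientation (processed metagenome tables are usually written
features x samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "VDGCatalog",
    "ABIOTIC_FACTORS",
    "VDG_CATEGORIES",
    "read_community_table",
    "write_community_table",
    "read_metadata",
    "validate_metadata",
    "to_relative",
    "binarize",
    "filter_features",
    "aggregate_rank",
]

#: The eight abiotic soil factors recorded for every microcosm sample.
ABIOTIC_FACTORS = ("pH", "TN", "NO3_N", "NH4_N", "TC", "AP", "AHN", "AS")

#: The three functional categories of vanadium detoxifying genes.
VDG_CATEGORIES = frozenset(
    {"reductive_metabolism", "transporter_efflux", "oxidative_damage_repair"}
)

_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class CommunityTable:
    """Sample x feature abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features, entries non-negative.
    feature_kind : {"taxon", "gene"}
    mode : {"counts", "relative"}
        ``counts`` requires integral entries; ``relative`` rows sum to 1
        for full profiles (feature subsets keep their original fractions,
        so sums may fall below 1).
    rank : str, optional
        Taxonomic rank of the features when ``feature_kind == "taxon"``.
    """

    data: pd.DataFrame
    feature_kind: str = "taxon"
    mode: str = "counts"
    rank: Optional[str] = None

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "gene"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        values = self.data.to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError("empty table")
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance")
        if (values < 0).any():
            raise ValueError("negative abundance")
        if self.mode == "counts":
            if not np.allclose(values, np.round(values), atol=1e-9):
                raise ValueError("mode=counts requires integer entries")
        else:
            # full relative profiles sum to 1; feature subsets of a relative
            # table keep their original fractions, so sums may fall below 1
            sums = values.sum(axis=1)
            if (sums > 1.0 + 1e-9).any():
                raise ValueError(
                    "mode=relative requires sample rows to sum to at most 1"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def abundance(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    # -- transformations -------------------------------------------------------
    def to_relative(self) -> "CommunityTable":
        return to_relative(self)

    def binarize(self, threshold: float = 0.0) -> "CommunityTable":
        return binarize(self, threshold)

    def filter_features(self, drop_categories, annotation) -> "CommunityTable":
        return filter_features(self, drop_categories, annotation)

    def aggregate_rank(self, lineage, target_rank) -> "CommunityTable":
        return aggregate_rank(self, lineage, target_rank)

    def subset_samples(self, sample_ids: Sequence) -> "CommunityTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return replace(self, data=self.data.loc[list(sample_ids)])

    def write_tsv(self, path) -> None:
        write_community_table(self, path)


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata for one sample: habitat, vanadium dose and abiotic factors."""

    sample_id: str
    habitat: str
    dose: float
    replicate: int
    group_label: str
    abiotic: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat not in ("gut", "soil"):
            raise ValueError(f"habitat must be 'gut' or 'soil', got {self.habitat!r}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class VDGCatalog:
    """Mapping of KEGG-orthology identifiers to a detoxification category."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values()} - VDG_CATEGORIES
        if bad:
            raise ValueError(f"unknown VDG categories: {sorted(bad)}")
        if len(self.entries) == 0:
            raise ValueError("empty VDG catalog")

    @property
    def kos(self):
        return set(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "VDGCatalog":
        df = pd.read_csv(path, sep="\t", header=None, names=["ko", "category"])
        if df["ko"].duplicated().any():
            raise ValueError("duplicate KO in catalog")
        return cls(dict(zip(df["ko"], df["category"])))

    @classmethod
    def from_yaml(cls, path) -> "VDGCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries: dict = {}
        # accept {category: [KOs]} or {KO: category}
        for key, val in raw.items():
            if isinstance(val, (list, tuple)):
                for ko in val:
                    if ko in entries:
                        raise ValueError(f"duplicate KO {ko}")
                    entries[ko] = key
            else:
                if key in entries:
                    raise ValueError(f"duplicate KO {key}")
                entries[key] = val
        return cls(entries)


# ---------------------------------------------------------------------------
# I/O


def read_community_table(
    path,
    orientation: str = "samples_as_rows",
    feature_kind: str = "taxon",
    mode: Optional[str] = None,
    rank: Optional[str] = None,
) -> CommunityTable:
    """Read a TSV abundance table and validate it.

    Mode inference is conservative: an all-integer body is ``counts``; rows
    summing to ~1 are ``relative``; anything else raises unless ``mode`` is
    forced by the caller.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("ragged or missing entries in table")
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundance")
    if mode is None:
        if np.allclose(values, np.round(values), atol=1e-9):
            mode = "counts"
        elif np.allclose(values.sum(axis=1), 1.0, atol=1e-6):
            mode = "relative"
            values = values / values.sum(axis=1, keepdims=True)
            df = pd.DataFrame(values, index=df.index, columns=df.columns)
        else:
            raise ValueError(
                "ambiguous mode: neither integer counts nor rows summing to 1; "
                "pass mode='counts' or mode='relative' explicitly"
            )
    elif mode == "relative":
        sums = values.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValueError("all-zero sample row")
        df = pd.DataFrame(values / sums, index=df.index, columns=df.columns)
    return CommunityTable(df, feature_kind=feature_kind, mode=mode, rank=rank)


def write_community_table(table: CommunityTable, path) -> None:
    """Write samples x features TSV with deterministic label order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV indexed by sample id.

    Required columns: habitat, dose, replicate, group_label.  Any of the
    eight abiotic factor columns present are kept as floats.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("habitat", "dose", "replicate", "group_label"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if (meta["dose"] < 0).any():
        raise ValueError("negative dose")
    bad = set(meta["habitat"]) - {"gut", "soil"}
    if bad:
        raise ValueError(f"unknown habitat values: {sorted(bad)}")
    return meta


def validate_metadata(meta: pd.DataFrame, table: CommunityTable) -> None:
    """Every sample in the table must have exactly one metadata record."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------------
# Transformations


def to_relative(table: CommunityTable) -> CommunityTable:
    """Convert to relative abundance (rows sum to 1)."""
    values = table.abundance
    totals = values.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        zero = [s for s, t in zip(table.sample_ids, totals[:, 0]) if t <= 0]
        raise ValueError(f"all-zero sample rows: {zero}")
    rel = pd.DataFrame(values / totals, index=table.data.index, columns=table.data.columns)
    return replace(table, data=rel, mode="relative")


def binarize(table: CommunityTable, threshold: float = 0.0) -> CommunityTable:
    """Presence/absence: 1 where abundance > threshold, else 0."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = (table.abundance > threshold).astype(float)
    data = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    return replace(table, data=data, mode="counts")


def filter_features(
    table: CommunityTable,
    drop_categories,
    annotation: Mapping,
) -> CommunityTable:
    """Drop features whose top-level annotation is in ``drop_categories``.

    Used to strip housekeeping gene classes (e.g. "Cellular Processes",
    "Genetic Information Processing") before functional-redundancy tests.
    Unannotated features are retained.
    """
    drop_categories = set(drop_categories)
    keep = [
        f
        for f in table.feature_ids
        if annotation.get(f) not in drop_categories
    ]
    if not keep:
        raise ValueError("filter would remove every feature")
    return replace(table, data=table.data[keep])


def aggregate_rank(
    table: CommunityTable,
    lineage: Mapping,
    target_rank: str,
) -> CommunityTable:
    """Sum abundances within the target-rank label of each feature.

    Features missing from ``lineage`` are pooled into an ``"unclassified"``
    column; per-sample totals are conserved exactly.
    """
    if table.feature_kind != "taxon":
        raise ValueError("aggregate_rank applies to taxon tables")
    labels = [lineage.get(f, "unclassified") for f in table.feature_ids]
    grouped = table.data.T.groupby(pd.Index(labels, name=target_rank), sort=True).sum().T
    return replace(table, data=grouped, rank=target_rank)


def group_samples(
    table: CommunityTable, meta: pd.DataFrame, by: str
) -> CommunityTable:
    """Pool samples by a metadata column (abundances summed within group)."""
    validate_metadata(meta, table)
    labels = meta.loc[table.data.index, by]
    pooled = table.data.groupby(labels, sort=True).sum()
    pooled.index = pooled.index.astype(str)
    mode = table.mode if table.mode == "counts" else "relative"
    if mode == "relative":
        pooled = pooled.div(pooled.sum(axis=1), axis=0)
    return replace(table, data=pooled, mode=mode)
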
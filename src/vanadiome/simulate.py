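"""Synthetic communities emulating the vanadium-microcosm study design.

The full scenario generates the 10 treatment groups (G0, S0, G21, S21,
GV0-GV3, SV0-SV3; doses 0/100/200/300 mg kg^-1, 3 replicates) with the
statistical structure the analysis assumes:

* dose-driven taxon turnover (Markov replacement of a fraction of the
  non-core community per dose step), stronger in the gut than in soil;
* declining taxon alpha diversity along the gradient (richness loss plus a
  mild dominance increase);
* functional redundancy: gene abundances are sums of carrier-taxon
  abundances; many carriers per gene in soil buffer taxon turnover (stable
  soil gene profiles), few carriers in the gut do not;
* abiotic factors correlated with dose, NH4-N carrying the largest effect.

Smaller generators provide neutral (urn) and niche (multinomial)
communities, nested incidence matrices, pure-turnover / nested-loss
community series, and the "soil-generalist" carrier fixture.
All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rad import (
    expected_lognormal,
    expected_preemption,
    expected_zipf,
)
from .tables import ABIOTIC_FACTORS, CommunityTable, VDGCatalog

__all__ = [
    "ScenarioSpec",
    "simulate_neutral_community",
    "simulate_niche_community",
    "make_nested_matrix",
    "make_modular_nested_matrix",
    "simulate_scenario",
    "simulate_turnover_communities",
    "simulate_nested_loss_communities",
    "simulate_vdg_generalist_tables",
]


# ---------------------------------------------------------------------------
# Neutral urn


def simulate_neutral_community(theta: float, m: float, J: int, seed=0) -> np.ndarray:
    """Sample one local community from Hubbell's neutral model.

    The metacommunity is assembled implicitly by a Chinese-restaurant
    process with parameter theta; the local community of size J is built
    sequentially, each arrival being an immigrant with probability
    I / (I + k - 1) (I = m (J-1)/(1-m); k individuals placed so far) and a
    copy of a uniformly chosen local individual otherwise.  At m = 1 every
    arrival immigrates and the process reduces to the Ewens process.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if J < 2:
        raise ValueError("J must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    I = np.inf if m == 1 else m * (J - 1) / (1.0 - m)
    local = []  # abundance per local species
    meta_events = []  # immigration events per metacommunity species
    individuals = []  # species index of each local individual
    immigrants = []  # species index of each immigration event
    for k in range(1, J + 1):
        immigrate = k == 1 or m == 1 or rng.random() < I / (I + k - 1)
        if immigrate:
            A = len(immigrants)
            if A == 0 or rng.random() < theta / (theta + A):
                species = len(local)
                local.append(0)
                meta_events.append(0)
            else:
                species = immigrants[rng.integers(A)]
            immigrants.append(species)
            meta_events[species] += 1
        else:
            species = individuals[rng.integers(k - 1)]
        local[species] += 1
        individuals.append(species)
    out = np.array(local, dtype=np.int64)
    return out[out > 0]


def simulate_niche_community(model: str, params: dict, S: int, J: int, seed=0) -> np.ndarray:
    """Multinomial community with probabilities from a niche RAD model."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if model == "preemption":
        exp = expected_preemption(1.0, S, params["alpha"])
    elif model == "zipf":
        exp = expected_zipf(1.0, S, params["p1"], params["gamma"])
    elif model == "lognormal":
        exp = expected_lognormal(S, params["mu"], params["sigma"])
    else:
        raise ValueError(f"unknown niche model {model!r}")
    if (exp <= 0).any() or not np.isfinite(exp).all():
        raise ValueError("degenerate model parameters")
    counts = rng.multinomial(J, exp / exp.sum())
    return counts[counts > 0]


def make_nested_matrix(
    n_communities: int, richness_profile, noise: float = 0.0, seed=0,
    n_features: int = None,
) -> np.ndarray:
    """Binary community x feature matrix, perfectly nested at noise = 0.

    Community i holds the first ``richness_profile[i]`` features of a fixed
    ordering; with noise > 0 that fraction of each row's presences is
    relocated to random absent columns of the same row (row fills are
    preserved).  ``n_features`` may exceed the richest community to leave
    the margins free (a feature pool wider than any community), which
    matters when the matrix is compared against margin-preserving nulls.
    """
    profile = np.asarray(richness_profile, dtype=int)
    if len(profile) != n_communities:
        raise ValueError("richness_profile length must equal n_communities")
    if noise == 0 and not (np.diff(profile) < 0).all():
        raise ValueError("richness_profile must be strictly decreasing at noise=0")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    if n_features is None:
        n_features = int(profile.max())
    if n_features < profile.max():
        raise ValueError("richness_profile exceeds the feature pool")
    if (profile <= 0).any():
        raise ValueError("richness must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    M = np.zeros((n_communities, n_features), dtype=np.int64)
    for i, r in enumerate(profile):
        M[i, :r] = 1
    if noise > 0:
        for i in range(n_communities):
            present = np.flatnonzero(M[i])
            absent = np.flatnonzero(M[i] == 0)
            k = min(int(round(noise * len(present))), len(absent))
            if k == 0:
                continue
            move = rng.choice(present, size=k, replace=False)
            dest = rng.choice(absent, size=k, replace=False)
            M[i, move] = 0
            M[i, dest] = 1
    return M


def make_modular_nested_matrix(
    n_modules: int = 2, rows_per: int = 10, cols_per: int = 16,
    noise: float = 0.05, seed=0,
) -> np.ndarray:
    """Modular nested incidence matrix whose nesting exceeds its margins.

    A globally perfect subset chain contains no 2x2 checkerboard and is the
    unique realization of its margins, so margin-preserving (fixed-fixed
    swap) nulls cannot score it.  Detectable nesting must therefore be
    modular: within each module the columns are top-run staircases (every
    community a subset of the richer ones), modules occupy disjoint row
    blocks, and a small noise fraction of presences is relocated anywhere
    to open swap freedom.  Against fixed-fixed nulls this structure scores
    z > 0; a margin-random matrix does not.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    nr, nc = n_modules * rows_per, n_modules * cols_per
    M = np.zeros((nr, nc), dtype=np.int64)
    for m in range(n_modules):
        for c in range(cols_per):
            f = max(1, rows_per - int(round(c * rows_per / cols_per)))
            M[m * rows_per : m * rows_per + f, m * cols_per + c] = 1
    pres = np.argwhere(M == 1)
    k = int(noise * len(pres))
    if k:
        mv = pres[rng.choice(len(pres), k, replace=False)]
        for r, c in mv:
            M[r, c] = 0
        emp = np.argwhere(M == 0)
        dst = emp[rng.choice(len(emp), k, replace=False)]
        for r, c in dst:
            M[r, c] = 1
    return M[M.sum(axis=1) > 0][:, M.sum(axis=0) > 0]


# ---------------------------------------------------------------------------
# Full study scenario


@dataclass
class ScenarioSpec:
    """Generative parameters of the gut/soil vanadium-gradient scenario.

    Defaults mirror the study design: 2 habitats x 4 doses
    (0/100/200/300 mg kg^-1) x 3 replicates plus the four baseline groups,
    sequencing depth fixed per sample, gut communities more dose-sensitive
    than soil, and soil functional redundancy an order of magnitude higher.
    """

    seed: int = 0
    n_replicates: int = 3
    doses: tuple = (0.0, 100.0, 200.0, 300.0)
    taxon_pool: int = 400
    gene_pool: int = 150
    n_active: int = 150  # taxa per community at dose 0
    n_core: int = 60  # persistent taxa never touched by turnover
    depth: int = 20000  # individuals counted per sample
    turnover_gut: float = 0.30  # non-core fraction replaced per dose step
    turnover_soil: float = 0.20
    richness_decline: float = 0.20  # non-core fraction lost per dose step
    evenness_decline: float = 0.12  # dominance exponent per step, non-core taxa only
    redundancy_gut: int = 2  # carrier taxa per gene function
    redundancy_soil: int = 40
    rep_noise_sd: float = 0.30  # lognormal replicate noise on taxon weights
    gene_noise_sd: float = 0.50  # lognormal per-sample noise on gene weights
    base_sd: float = 1.0  # lognormal spread of baseline taxon weights
    n_vdg: int = 30  # genes flagged as vanadium detoxifying
    abiotic_effects: dict = field(
        default_factory=lambda: {
            "pH": -0.06, "TN": 0.05, "NO3_N": 0.10, "NH4_N": 0.80,
            "TC": 0.04, "AP": 0.08, "AHN": 0.06, "AS": 0.12,
        }
    )
    abiotic_noise: float = 0.15

    def __post_init__(self):
        if not 0 <= self.turnover_gut <= 1 or not 0 <= self.turnover_soil <= 1:
            raise ValueError("turnover strength must be in [0, 1]")
        if self.n_core >= self.n_active:
            raise ValueError("core must be smaller than the active community")
        if self.redundancy_gut > self.taxon_pool or self.redundancy_soil > self.taxon_pool:
            raise ValueError("redundancy degree exceeds taxon pool")
        if self.n_active > self.taxon_pool:
            raise ValueError("active community exceeds taxon pool")


def _active_sets(spec: ScenarioSpec, habitat: str, rng) -> list:
    """Active taxon index set per dose step (Markov along the gradient)."""
    turnover = spec.turnover_gut if habitat == "gut" else spec.turnover_soil
    pool = np.arange(spec.taxon_pool)
    core = rng.choice(pool, size=spec.n_core, replace=False)
    rest = np.setdiff1d(pool, core)
    noncore = rng.choice(rest, size=spec.n_active - spec.n_core, replace=False)
    sets = [(core.copy(), noncore.copy())]
    for _ in range(len(spec.doses) - 1):
        core_prev, non_prev = sets[-1]
        available = np.setdiff1d(pool, np.concatenate([core_prev, non_prev]))
        n_replace = int(round(turnover * len(non_prev)))
        n_lose = int(round(spec.richness_decline * len(non_prev)))
        keep = rng.permutation(non_prev)
        lost_or_replaced = keep[: n_replace + n_lose]
        kept = keep[n_replace + n_lose :]
        newcomers = rng.choice(available, size=min(n_replace, len(available)), replace=False)
        sets.append((core_prev, np.concatenate([kept, newcomers])))
    return sets


def simulate_scenario(spec: ScenarioSpec):
    """Generate (taxon table, gene table, metadata, ground truth).

    The taxon table is counts (multinomial draws of ``spec.depth`` reads);
    the gene table is relative KO abundances computed from carrier taxa.
    The ground-truth record holds every generative parameter and the
    qualitative verdicts the pipeline is expected to reach.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = [f"t{i:04d}" for i in range(spec.taxon_pool)]
    genes = [f"K{10001 + i:05d}" for i in range(spec.gene_pool)]
    base = {
        h: np.exp(rng.normal(0.0, spec.base_sd, size=spec.taxon_pool))
        for h in ("gut", "soil")
    }
    active = {h: _active_sets(spec, h, rng) for h in ("gut", "soil")}
    carriers = {}
    copy_w = {}
    for h in ("gut", "soil"):
        k = spec.redundancy_gut if h == "gut" else spec.redundancy_soil
        core = active[h][0][0]
        cmap = []
        for _ in genes:
            if h == "soil":
                # high redundancy: functions spread across the persistent
                # core community, so taxon turnover barely moves them
                cmap.append(np.sort(rng.choice(core, size=min(k, len(core)), replace=False)))
            else:
                # low redundancy: one core anchor (keeps the gene present)
                # plus dose-sensitive carriers from the whole pool
                anchor = rng.choice(core, size=1)
                others = (
                    rng.choice(spec.taxon_pool, size=k - 1, replace=False)
                    if k > 1
                    else np.empty(0, dtype=int)
                )
                cmap.append(np.unique(np.concatenate([anchor, np.asarray(others, dtype=int)])))
        carriers[h] = cmap
        copy_w[h] = [np.exp(rng.normal(0.0, 0.5, size=len(c))) for c in cmap]

    groups = []
    for h, prefix in (("gut", "G"), ("soil", "S")):
        groups.append((f"{prefix}0", h, 0.0, 0))  # day-0 baseline
        groups.append((f"{prefix}21", h, 0.0, 0))  # day-21 untreated control
        for step, dose in enumerate(spec.doses):
            groups.append((f"{prefix}V{step}", h, float(dose), step))

    taxon_rows, gene_rows, meta_rows = [], [], []
    for group_label, habitat, dose, step in groups:
        core, noncore = active[habitat][step]
        idx = np.concatenate([core, noncore])
        # dominance increases with dose in the dose-sensitive (non-core)
        # fraction only; the persistent core is buffered against stress
        exponent = 1.0 + spec.evenness_decline * step
        base_w = np.concatenate(
            [base[habitat][core], base[habitat][noncore] ** exponent]
        )
        for rep in range(1, spec.n_replicates + 1):
            sid = f"{group_label}_{rep}"
            w = base_w * np.exp(rng.normal(0.0, spec.rep_noise_sd, size=len(idx)))
            p = w / w.sum()
            counts = np.zeros(spec.taxon_pool, dtype=np.int64)
            counts[idx] = rng.multinomial(spec.depth, p)
            taxon_rows.append(pd.Series(counts, index=taxa, name=sid))
            rel = counts / counts.sum()
            gw = np.empty(spec.gene_pool)
            for g in range(spec.gene_pool):
                gw[g] = float(rel[carriers[habitat][g]] @ copy_w[habitat][g])
            gw *= np.exp(rng.normal(0.0, spec.gene_noise_sd, size=spec.gene_pool))
            if gw.sum() <= 0:
                raise RuntimeError("infeasible spec: all-zero gene profile")
            gene_rows.append(pd.Series(gw / gw.sum(), index=genes, name=sid))
            abiotic = {
                f: rng.normal(
                    spec.abiotic_effects[f] * dose / 100.0, spec.abiotic_noise
                )
                for f in ABIOTIC_FACTORS
            }
            meta_rows.append(
                {
                    "sample_id": sid, "habitat": habitat, "dose": dose,
                    "replicate": rep, "group_label": group_label, **abiotic,
                }
            )

    taxon_df = pd.DataFrame(taxon_rows)
    keep = taxon_df.columns[taxon_df.sum(axis=0) > 0]
    taxon_table = CommunityTable(taxon_df[keep], feature_kind="taxon", mode="counts", rank="species")
    gene_table = CommunityTable(pd.DataFrame(gene_rows), feature_kind="gene", mode="relative")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    cats = sorted(
        ("reductive_metabolism", "transporter_efflux", "oxidative_damage_repair")
    )
    catalog = VDGCatalog({genes[i]: cats[i % 3] for i in range(spec.n_vdg)})
    vdg_carriers = sorted(
        {
            taxa[t]
            for h in ("gut", "soil")
            for g in range(spec.n_vdg)
            for t in carriers[h][g]
        }
    )
    ground_truth = {
        "spec": asdict(spec),
        "vdg_catalog": dict(catalog.entries),
        "vdg_carriers": vdg_carriers,
        "expected": {
            "gut_taxa_dose_anosim_significant": True,
            "soil_taxa_dose_anosim_significant": True,
            "gut_genes_dose_anosim_significant": True,
            "soil_genes_dose_anosim_significant": False,
            "taxon_shannon_declines_with_dose": True,
            "gene_shannon_dose_trend": False,
            "largest_abiotic_effect": "NH4_N",
        },
    }
    return taxon_table, gene_table, meta, ground_truth


# ---------------------------------------------------------------------------
# Focused fixtures


def _series_tables(active_sets, n_rep, pool, prefix="D"):
    taxa = [f"t{i:04d}" for i in range(pool)]
    rows, meta_rows = [], []
    for d, act in enumerate(active_sets):
        for rep in range(1, n_rep + 1):
            sid = f"{prefix}{d}_{rep}"
            counts = np.zeros(pool, dtype=np.int64)
            counts[act] = 1
            rows.append(pd.Series(counts, index=taxa, name=sid))
            meta_rows.append(
                {
                    "sample_id": sid, "habitat": "soil", "dose": float(100 * d),
                    "replicate": rep, "group_label": f"{prefix}{d}",
                }
            )
    df = pd.DataFrame(rows)
    df = df[df.columns[df.sum(axis=0) > 0]]
    table = CommunityTable(df, feature_kind="taxon", mode="counts")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, meta


def simulate_turnover_communities(
    n_doses: int = 4, n_rep: int = 3, richness: int = 60, swap: int = 20,
    pool: int = 300, seed=0,
):
    """Dose series with pure species replacement (balanced turnover)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(pool)
    sets = [order[:richness].copy()]
    cursor = richness
    for _ in range(n_doses - 1):
        prev = sets[-1]
        keep = prev[swap:]
        new = order[cursor : cursor + swap]
        cursor += swap
        sets.append(np.concatenate([keep, new]))
    return _series_tables(sets, n_rep, pool)


def simulate_nested_loss_communities(
    n_doses: int = 4, n_rep: int = 3, richness: int = 60, loss: int = 12,
    pool: int = 300, seed=0,
):
    """Dose series where each community is a subset of the previous one."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(pool)
    sets = [order[: richness - d * loss].copy() for d in range(n_doses)]
    if any(len(s) <= 0 for s in sets):
        raise ValueError("loss schedule exhausts the community")
    return _series_tables(sets, n_rep, pool)


def simulate_vdg_generalist_tables(
    n_per_habitat: int = 12, n_carriers: int = 20, n_background: int = 40, seed=0
):
    """"Soil-generalist" fixture: carriers even in soil, concentrated in gut.

    Every carrier taxon is present at similar abundance in all soil samples
    but concentrated into one or two gut samples, so the mean Levins breadth
    of carriers is strictly higher in soil than in the gut.
    """
    rng = np.random.default_rng(seed)
    carriers = [f"c{i:03d}" for i in range(n_carriers)]
    background = [f"b{i:03d}" for i in range(n_background)]
    rows, meta_rows = [], []
    for h, prefix in (("gut", "G"), ("soil", "S")):
        for s in range(n_per_habitat):
            sid = f"{prefix}{s:02d}"
            vals = {}
            for i, c in enumerate(carriers):
                if h == "soil":
                    vals[c] = 10 + int(rng.integers(0, 3))
                else:
                    home = i % n_per_habitat
                    vals[c] = 40 + int(rng.integers(0, 5)) if s == home else 0
            for b in background:
                vals[b] = 5 + int(rng.integers(0, 5))
            rows.append(pd.Series(vals, name=sid))
            meta_rows.append(
                {
                    "sample_id": sid, "habitat": h, "dose": 0.0,
                    "replicate": s + 1, "group_label": f"{prefix}0",
                }
            )
    table = CommunityTable(pd.DataFrame(rows), feature_kind="taxon", mode="counts")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, meta, carriers
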
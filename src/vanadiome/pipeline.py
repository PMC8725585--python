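"""End-to-end orchestration: simulate or load tables, run every stage,
write one TSV per stage plus a JSON run manifest sufficient to reproduce
the run (versions, seeds, parameters in effect)."""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import alpha_diversity, gradient_tests
from .nestedness import nodf, nodf_test
from .niche import levins_breadth, screen_vdg, vdg_carrier_summary
from .ordination import anosim, bray_curtis, mantel, nmds, per_factor_fractions
from .partition import partition_summary
from .rad import model_select, rescale_to_counts
from .simulate import ScenarioSpec, simulate_scenario
from .tables import (
    ABIOTIC_FACTORS,
    VDGCatalog,
    binarize,
    group_samples,
    read_community_table,
    read_metadata,
    validate_metadata,
    write_community_table,
)

log = logging.getLogger("vanadiome")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``taxon_path`` / ``simulate`` drives the inputs: either
    paths to taxon/gene/metadata TSVs, or a :class:`ScenarioSpec` for a
    fully synthetic run.
    """

    out_dir: str = "vanadiome_out"
    taxon_path: Optional[str] = None
    gene_path: Optional[str] = None
    metadata_path: Optional[str] = None
    vdg_catalog_path: Optional[str] = None
    simulate: Optional[ScenarioSpec] = None
    seed: int = 0
    n_perm: int = 999
    n_null: int = 999
    null_algorithm: str = "fixed_fixed_swap"
    j_target: int = 5000  # gene-table integerisation before ZSM fitting
    rad_scope: str = "per_group"  # "per_group" (first replicate) or "all"
    nmds_starts: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = ScenarioSpec(**sim)
        return cfg

    def validate(self):
        has_paths = self.taxon_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("exactly one of taxon_path / simulate must be set")


def _write(df: pd.DataFrame, out: Path, name: str, manifest: dict):
    path = out / name
    df.to_csv(path, sep="\t")
    manifest["outputs"].append(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns the manifest dictionary.

    Stage failures are isolated: a failing stage is logged into the
    manifest and the pipeline continues with the stages that do not depend
    on it.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_null": config.n_null,
        "null_algorithm": config.null_algorithm,
        "j_target": config.j_target,
        "outputs": [],
        "errors": {},
    }

    catalog = None
    carriers = None
    if config.simulate is not None:
        taxon, gene, meta, truth = simulate_scenario(config.simulate)
        manifest["scenario"] = truth["spec"]
        catalog = VDGCatalog(truth["vdg_catalog"])
        carriers = truth["vdg_carriers"]
        write_community_table(taxon, out / "taxon_table.tsv")
        write_community_table(gene, out / "gene_table.tsv")
        meta.to_csv(out / "metadata.tsv", sep="\t")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        manifest["outputs"] += [
            "taxon_table.tsv", "gene_table.tsv", "metadata.tsv", "ground_truth.json",
        ]
    else:
        taxon = read_community_table(config.taxon_path, feature_kind="taxon")
        gene = (
            read_community_table(config.gene_path, feature_kind="gene")
            if config.gene_path
            else None
        )
        meta = read_metadata(config.metadata_path)
        if config.vdg_catalog_path:
            p = str(config.vdg_catalog_path)
            catalog = (
                VDGCatalog.from_yaml(p)
                if p.endswith((".yml", ".yaml"))
                else VDGCatalog.from_tsv(p)
            )
    validate_metadata(meta, taxon)
    tables = {"taxa": taxon}
    if gene is not None:
        tables["genes"] = gene
    gradient_mask = meta["group_label"].str.contains("V", regex=False)
    gradient_ids = list(meta.index[gradient_mask])

    def stage(name, fn):
        try:
            t = time.time()
            fn()
            log.info("stage %s done in %.1fs", name, time.time() - t)
        except Exception as exc:  # noqa: BLE001 - isolate stage failures
            log.error("stage %s failed: %s", name, exc)
            manifest["errors"][name] = f"{exc}\n{traceback.format_exc(limit=3)}"

    # -- diversity -------------------------------------------------------
    def _diversity():
        for kind, table in tables.items():
            _write(alpha_diversity(table), out, f"diversity_{kind}.tsv", manifest)
            grad = gradient_tests(table.subset_samples(gradient_ids), meta)
            _write(grad.set_index(["scope", "index"]), out, f"gradient_{kind}.tsv", manifest)

    stage("diversity", _diversity)

    # -- ordination ------------------------------------------------------
    dms = {}

    def _ordination():
        rows = []
        for kind, table in tables.items():
            dm = bray_curtis(table)
            dms[kind] = dm
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / f"braycurtis_{kind}.tsv", sep="\t"
            )
            manifest["outputs"].append(f"braycurtis_{kind}.tsv")
            res = nmds(dm, n_starts=config.nmds_starts, seed=config.seed)
            coords = pd.DataFrame(
                res.coordinates, index=res.ids,
                columns=[f"NMDS{i + 1}" for i in range(res.coordinates.shape[1])],
            )
            coords["stress"] = res.stress
            _write(coords, out, f"nmds_{kind}.tsv", manifest)
            # ANOSIM across doses within each habitat
            sub_ids = [s for s in dm.ids if s in gradient_ids]
            for habitat in sorted(meta["habitat"].unique()):
                ids = [s for s in sub_ids if meta.loc[s, "habitat"] == habitat]
                sub = dm.filter(ids)
                res_a = anosim(sub, meta.loc[ids, "dose"].to_numpy(),
                               n_perm=config.n_perm, seed=config.seed)
                rows.append({"table": kind, "scope": habitat,
                             "R": res_a.statistic, "p": res_a.p, "n": len(ids)})
            res_h = anosim(dm, meta.loc[list(dm.ids), "habitat"].to_numpy(),
                           n_perm=config.n_perm, seed=config.seed)
            rows.append({"table": kind, "scope": "habitat",
                         "R": res_h.statistic, "p": res_h.p, "n": len(dm.ids)})
        _write(pd.DataFrame(rows).set_index(["table", "scope"]), out,
               "anosim.tsv", manifest)
        if "genes" in dms:
            res_m = mantel(dms["taxa"], dms["genes"], n_perm=config.n_perm,
                           seed=config.seed)
            _write(pd.DataFrame([{"r": res_m.statistic, "p": res_m.p,
                                  "n_perm": res_m.n_perm}]),
                   out, "mantel_taxa_vs_genes.tsv", manifest)

    stage("ordination", _ordination)

    # -- VPA -------------------------------------------------------------
    def _vpa():
        factors = meta.loc[taxon.sample_ids, [f for f in ABIOTIC_FACTORS if f in meta.columns]]
        if factors.shape[1] < 2:
            raise ValueError("need at least 2 abiotic factors for VPA")
        frac = per_factor_fractions(taxon, factors)
        _write(frac.to_frame(), out, "vpa_per_factor.tsv", manifest)

    stage("vpa", _vpa)

    # -- nestedness ------------------------------------------------------
    def _nestedness():
        rows = []
        for grouping in ("habitat", "group_label"):
            pooled = group_samples(taxon, meta, grouping)
            incidence = binarize(pooled).abundance.astype(int)
            try:
                res = nodf_test(incidence, config.null_algorithm,
                                n=config.n_null, seed=config.seed)
                rows.append({
                    "grouping": grouping, "nodf": res.nodf_total,
                    "null_mean": float(res.null_values.mean()), "z": res.z,
                    "p": res.p, "nested": res.nested, "note": "",
                })
            except ValueError as exc:
                # e.g. two-group incidence whose margins pin the null
                rows.append({
                    "grouping": grouping, "nodf": nodf(incidence).nodf_total,
                    "null_mean": np.nan, "z": np.nan, "p": np.nan,
                    "nested": None, "note": str(exc),
                })
        _write(pd.DataFrame(rows).set_index("grouping"), out, "nestedness.tsv", manifest)

    stage("nestedness", _nestedness)

    # -- beta partitioning ----------------------------------------------
    def _partition():
        frames = []
        for kind, table in tables.items():
            sub = table.subset_samples([s for s in table.sample_ids if s in gradient_ids])
            for flavor in ("incidence_carvalho", "abundance_braycurtis"):
                for scheme in ("between_doses", "between_habitats"):
                    df = partition_summary(sub, meta, scheme=scheme, flavor=flavor)
                    df.insert(0, "table", kind)
                    frames.append(df)
        _write(pd.concat(frames, ignore_index=True), out, "beta_partition.tsv", manifest)

    stage("partition", _partition)

    # -- RAD / ZSM model selection ---------------------------------------
    def _rad():
        if config.rad_scope == "per_group":
            chosen = [s for s in taxon.sample_ids if meta.loc[s, "replicate"] == 1]
        else:
            chosen = list(taxon.sample_ids)
        rows = []
        for kind, table in tables.items():
            for sid in chosen:
                vec = table.data.loc[sid].to_numpy()
                total = vec.sum()
                if table.mode == "relative" or total > config.j_target:
                    # integerise (or down-scale deep count tables) so the
                    # ZSM dynamic program stays desk-sized
                    vec = rescale_to_counts(vec / total, config.j_target)
                counts = vec[vec > 0].astype(np.int64)
                fits, best = model_select(counts, seed=config.seed)
                for f in fits:
                    rows.append({
                        "table": kind, "sample_id": sid, "model": f.model,
                        "params": json.dumps({k: round(float(v), 6)
                                              for k, v in f.params.items()}),
                        "loglik": f.loglik, "npar": f.npar, "aic": f.aic,
                        "best": f.model == best,
                        "m": f.params.get("m", np.nan),
                    })
        _write(pd.DataFrame(rows).set_index(["table", "sample_id", "model"]),
               out, "rad_model_selection.tsv", manifest)

    stage("rad", _rad)

    # -- niche breadth and VDGs ------------------------------------------
    def _niche():
        res = levins_breadth(taxon)
        _write(res.per_feature.to_frame(), out, "niche_breadth_features.tsv", manifest)
        _write(res.community_mean.to_frame(), out, "niche_breadth_communities.tsv", manifest)
        if catalog is not None and "genes" in tables:
            _, per_sample = screen_vdg(tables["genes"], catalog)
            _write(per_sample, out, "vdg_per_sample.tsv", manifest)
            if carriers:
                summary = vdg_carrier_summary(taxon, carriers, tables["genes"],
                                              catalog, meta)
                _write(summary.per_group, out, "vdg_per_group.tsv", manifest)
                _write(summary.habitat_shares, out, "vdg_habitat_shares.tsv", manifest)
                _write(summary.carrier_breadth.to_frame(), out,
                       "vdg_carrier_breadth.tsv", manifest)

    stage("niche", _niche)

    manifest["wall_clock_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
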
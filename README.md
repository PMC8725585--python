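# vanadiome

Community-assembly analysis for earthworm-gut and soil metagenomes under a
vanadium gradient — and, more generally, for any sample × feature abundance
tables (taxa at a chosen rank, or KEGG-orthology gene groups) collected
along a stress gradient in two habitats.

The package asks the questions a microbial ecologist asks of such a design:

* **Alpha diversity** — do Shannon *H* = −Σ pᵢ ln pᵢ and Gini-Simpson
  *D* = 1 − Σ pᵢ² decline along the dose gradient (Pearson tests,
  per habitat)?
* **Beta diversity** — Bray-Curtis distances, non-metric MDS (Kruskal
  stress-1), ANOSIM and Mantel permutation tests, and variance partitioning
  (partial RDA with Ezekiel-adjusted R²) over abiotic factors.
* **Nestedness** — NODF (nestedness metric based on overlap and decreasing
  fill, 0–100) with margin-preserving checkerboard-swap or equiprobable
  null ensembles and a one-directional z-test verdict.
* **Turnover vs nestedness** — exact additive partitions of beta diversity:
  the Carvalho incidence family (β_cc = β₋₃ + β_rich) and the Bray-Curtis
  decomposition into balanced variation and abundance gradient.
* **Community assembly** — rank-abundance models (brokenstick, niche
  preemption, lognormal, Zipf) fitted by Poisson likelihood, and the
  zero-sum multinomial (ZSM) neutral model fitted by the **exact Etienne
  sampling formula** for P(D | θ, m, J), all compared on
  AIC = −2 log L + 2 npar.  The migration rate *m* (with immigration
  parameter I = m(J−1)/(1−m); m = 1 means no dispersal limitation) is the
  headline estimate.
* **Niche breadth and detoxifying genes** — Levins breadth
  B = 1/Σᵢ P²ᵢⱼ (1 = single-habitat specialist, N = perfectly even
  generalist), and screening of vanadium-detoxifying genes (VDGs: reductive
  metabolism, transporter/efflux, oxidative-damage repair) with habitat
  shares and carrier-taxon breadth contrasts.

Processed abundance tables for such experiments are rarely available, so a
first-class synthetic generator (`vanadiome.simulate`) emulates
the microcosm design — 12 treatment groups (G0, S0, G21, S21, GV0–GV3,
SV0–SV3), doses 0/100/200/300 mg kg⁻¹, 3 replicates — including
dose-driven taxon turnover, declining alpha diversity, and the
functional-redundancy contrast between habitats. Every statistical claim in
the test suite is checked against that generator or an independent oracle.

## Worked example

```python
from vanadiome import (ScenarioSpec, simulate_scenario, bray_curtis,
                       anosim, fit_zsm, rescale_to_counts)
from vanadiome.diversity import gradient_tests

taxon, gene, meta, truth = simulate_scenario(ScenarioSpec(seed=42))
grad = [s for s in meta.index if "V" in meta.loc[s, "group_label"]]
soil = [s for s in grad if meta.loc[s, "habitat"] == "soil"]

res_t = anosim(bray_curtis(taxon.subset_samples(soil)), meta.loc[soil, "dose"],
               n_perm=999, seed=0)
res_g = anosim(bray_curtis(gene.subset_samples(soil)), meta.loc[soil, "dose"],
               n_perm=999, seed=0)
print(f"soil taxa  ANOSIM R = {res_t.statistic:.3f}, p = {res_t.p:.3f}")
print(f"soil genes ANOSIM R = {res_g.statistic:.3f}, p = {res_g.p:.3f}")
```

```
soil taxa  ANOSIM R = 1.000, p = 0.001
soil genes ANOSIM R = -0.145, p = 0.883
```

Taxonomic composition is strongly structured by dose while the gene
profiles are not — the functional-redundancy signature of the soil habitat.
The alpha-diversity gradient tests show the accompanying diversity loss in
both habitats:

```python
print(gradient_tests(taxon.subset_samples(grad), meta).to_string(index=False))
```

```
scope     index         r            p  n
  gut shannon_H -0.964587 4.132942e-07 12
  gut simpson_D -0.847587 4.985754e-04 12
  gut  richness -0.995712 1.133840e-11 12
 soil shannon_H -0.811127 1.365406e-03 12
 soil simpson_D -0.640989 2.469782e-02 12
 soil  richness -0.995712 1.133840e-11 12
```

Fitting the neutral model to one gene profile (integerised to J = 2000 by
largest-remainder rounding):

```python
counts = rescale_to_counts(gene.data.loc["SV2_1"].to_numpy(), 2000)
print(fit_zsm(counts[counts > 0], seed=0).summary())
```

```
Zero-sum multinomial (neutral) fit
----------------------------------
J (community size)    2000
S (species observed)  150
theta                 72.92
m (migration rate)    0.09497
I (immigration)       209.8
log-likelihood        -153.9495
AIC                   311.8990
converged             True
```

A migration rate well below 1 indicates dispersal limitation; model
selection (`vanadiome.rad.model_select`) compares this AIC with the four
niche-theory models.

## Command line

Every stage is also a subcommand of the `vanadiome` CLI:

```bash
vanadiome simulate --seed 1 --out sim/
vanadiome diversity --table sim/taxon_table.tsv --metadata sim/metadata.tsv
vanadiome anosim --table sim/taxon_table.tsv --metadata sim/metadata.tsv --group-by habitat
vanadiome radfit --table sim/taxon_table.tsv --sample GV0_1 --j-target 2000
vanadiome all --seed 1 --out run/          # full pipeline + JSON manifest
```

`vanadiome all` writes one TSV per stage and a `manifest.json` recording
every seed and parameter, sufficient to reproduce the run byte-for-byte.

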
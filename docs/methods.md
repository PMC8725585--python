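# Methods

This note records the models implemented in `vanadiome`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the design decisions taken where the methodology was
genuinely open.

## Diversity and group tests

Shannon diversity uses the natural logarithm, the convention of the
standard community-ecology toolchain. The Simpson index is reported as the
Gini-Simpson complement 1 − Σ pᵢ², so that "higher = more diverse" holds
for both indices; the concentration form Σ pᵢ² (the probability that two
random individuals share a species) is its exact complement. Dose-gradient
tests are two-sided Pearson correlations on n − 2 degrees of freedom, run
per habitat by default (a pooled option exists) because the two habitats
have different baseline diversity and pooling would confound habitat with
dose. One-way ANOVA is the classical F test via `scipy.stats.f_oneway`.

## Ordination

Bray-Curtis distances come from `scipy.spatial.distance.pdist`. Non-metric
MDS is written in-package as a Kruskal stress-1 minimiser so the stress
trace, seeding and restart policy are explicit: each start alternates
monotone (isotonic) regression of configuration distances on the observed
dissimilarities — ties averaged, the primary approach — with a Guttman
transform; 20 starts by default (one classical-scaling start plus 19
random ones, seeded), k = 2, convergence when the stress decrease falls
below 1e−9. Stress-1 = √(Σ(d − d̂)²/Σ d²).

ANOSIM uses R = (mean between-group rank − mean within-group rank)/(M/2)
with M = n(n−1)/2 and permutes group labels; Mantel correlates off-diagonal
distances and permutes the row/column order of the second matrix. Both
report the add-one permutation p-value p = (1 + #{null ≥ observed})/(1 +
n_perm), one-sided in the direction of association, so p is never exactly
zero; null vectors and seeds are kept in the result objects for
reproducibility.

Variance partitioning (VPA) Hellinger-transforms the community table
(square root of relative abundances — the standard transformation making
abundance data suitable for linear RDA), computes the adjusted R² (Ezekiel) of the
least-squares RDA for every subset of 2–4 explanatory blocks, and obtains
exclusive (Venn-atom) and joint fractions by Möbius inversion over the
complement lattice; atoms plus residual sum to 1 exactly. Negative adjusted
fractions are reported as-is (display conventions may truncate at 0).
Because the classic partition supports at most four blocks, per-factor
fractions for the eight abiotic factors are computed as the unique fraction
of {factor} against {all other factors} in a two-block partition — an
explicit interpretation, recorded in the output.

## Nestedness

NODF scores every pair of rows (and of columns): pairs with equal fills
contribute 0 (the decreasing-fill rule); otherwise the paired term is 100 ×
overlap / (fill of the sparser line). The implementation works on all
pairs, so it is invariant to row/column permutation. Two null ensembles are
provided: `equiprobable` (total fill scattered uniformly) and
`fixed_fixed_swap` (checkerboard-swap Markov chain preserving both margins
exactly; burn-in max(1000, 10×fill) attempted swaps, thinning 2×fill and
never below the fill). Significance is a z-test of the observed NODF
against the ensemble with a two-sided normal p, and the verdict "nested"
additionally requires observed > null mean — the one-directional decision
rule appropriate for a nestedness claim.

A structural caveat discovered while validating the swap null and worth
stating plainly: a *perfectly* nested matrix contains no 2×2 checkerboard
and is therefore the unique realization of its margins — the swap null is
undefined on it (the package raises "margins force a unique matrix"), and
near-perfect staircases carry almost no nesting signal beyond their
margins. Nesting that a margin-preserving null can detect must be
*modular*: the generator `make_modular_nested_matrix` builds within-module
subset chains plus a small relocation noise, and such matrices reject with
z ≈ 3. Perfect staircases are instead tested against the equiprobable
ensemble, where margins are free.

## Beta-diversity partitioning

Incidence flavor (Carvalho family): β_cc = (b+c)/(a+b+c) splits into
replacement β₋₃ = 2·min(b,c)/(a+b+c) and richness difference β_rich =
|b−c|/(a+b+c). Abundance flavor: Bray-Curtis d_BC = (B+C)/(2A+B+C) splits
into balanced variation d_bal = min(B,C)/(A+min(B,C)) and abundance
gradient d_gra = d_BC − d_bal, with A = Σ min(x,y), B = Σ(x−min), C =
Σ(y−min). Additivity is exact by construction and asserted to 1e−12.
Multi-sample summaries average the pairwise components within the requested
contrast (between doses within habitat, or between habitats); the
multi-site closed forms are out of scope. Identical groups yield zero total
beta and the percentages are flagged undefined rather than forced.

## Rank-abundance models and AIC

The four niche models are fitted by maximising a Poisson log-likelihood of
the observed abundances around the model's expected rank abundances:
brokenstick â_r = (J/S) Σ_{k=r}^S 1/k (0 parameters), preemption â_r =
Jα(1−α)^{r−1}/(1−(1−α)^S) (1), lognormal â_r = exp(μ + σ z_r) with Blom
normal order-statistic scores z_r (2), and Zipf â_r = J p₁ r^γ (2). The
Poisson error structure is a deliberate choice: it puts all five models —
including the neutral model's exact configuration likelihood — on a true
log-likelihood scale, which the cross-family AIC comparison
(AIC = −2 log L + 2 npar, ties broken toward fewer parameters) requires.
Optimisation is Nelder-Mead in unconstrained transforms (logit for α and
p₁, log for σ); a failing model is excluded from selection with a warning,
never aborting it.

## The zero-sum multinomial neutral model

The ZSM likelihood is the exact Etienne sampling formula; see the module
docstring of `vanadiome.neutral` for the formula and its log-space
implementation (per-species unsigned-Stirling terms, a streaming
log-sum-exp convolution for K(D, A), Pochhammer ratios via `lgamma`). Key
properties, each under test: at m = 1 it reduces exactly to the Ewens
sampling formula; for J ≤ 6 it matches a brute-force enumeration of every
immigration/birth history of the urn process; and it normalises to 1 over
all abundance configurations of J. K(D, A) is independent of (θ, m) and
cached per dataset, so a likelihood surface scan costs O(J) per point.

Fitting maximises over (log θ, logit m): a 12×12 coarse grid including the
m = 1 boundary, Nelder-Mead refinement, and a bounded 1-D profile over θ on
the Ewens branch. Two numerical decisions matter. First, the interior
branch caps m at 1 − 1e−9 and the boundary is handled by the Ewens formula,
avoiding I → ∞ overflow. Second, the (θ, m) surface has a well-known ridge
on which (θ large, m small) mimics the m = 1 boundary at negligible
likelihood gain; a maximiser without safeguards returns arbitrary points on
that ridge for dispersal-unlimited data. The fit therefore reports m = 1
("no dispersal limit") unless the interior optimum beats the boundary by
more than 1.35 log-likelihood units — the 5% critical value of the boundary
likelihood-ratio test, whose null is the ½(0 + χ²₁) mixture. Parameter
recovery at (θ = 20, m = 0.1, J = 1000) is unaffected by the safeguard
(dispersal limitation is then decisively supported in most samples);
median recovery over 20 communities is within ±30% for θ and ±50% for m.

Relative-abundance (gene) tables are integerised before fitting by
largest-remainder rounding to a configurable total (default J = 5000;
every positive feature receives at least one count). Deep count tables are
down-scaled the same way in the pipeline; the K(D, A) dynamic program is
quadratic in J, and J in the low thousands keeps a per-sample fit under a
few seconds while leaving the (θ, m) estimates stable. The pipeline fits
one replicate per treatment group by default (`rad_scope="per_group"`) and
reports per-group values; fitting every sample is a flag away.

## Niche breadth and VDG screening

Levins breadth normalises P per feature across communities (Σᵢ Pᵢⱼ = 1), so
B ranges from 1 (single community) to N (perfectly even), matching the
reading in which community-level means can far exceed small per-sample
values. The alternative normalisation (P as within-community proportion) is
noted but not used. A community's breadth is the mean B of the features
present in it; carrier-taxon breadth is computed per habitat on the
habitat's own sub-table, restricted to carriers present there. VDG
screening restricts a gene table to a user-supplied KO → category catalog
(three categories: reductive metabolism, transporter/efflux,
oxidative-damage repair); the sub-table keeps untouched abundance copies,
and per-sample category totals and VDG proportions are reported. The
catalog shipped with the synthetic scenario is generated and illustrative,
not a curated gene list.

## The synthetic scenario: what it emulates, and what it does not

`simulate_scenario` generates the full microcosm design: 2 habitats × (2
baseline groups + 4 doses) × 3 replicates = 36 samples, taxon counts as
multinomial draws of 20 000 reads, gene tables as relative KO abundances.
Mechanisms, with defaults chosen so the designed contrasts dominate
replicate noise at the study's sample sizes:

* **Turnover** — a persistent core (60 taxa) never turns over; of the
  non-core community, 30% (gut) / 20% (soil) is replaced per dose step
  (Markov along the gradient).
* **Alpha decline** — the non-core fraction loses 20% of its members per
  step and its abundance distribution steepens (dominance exponent
  1 + 0.12·step). The core is buffered, reflecting stress-tolerant
  residents.
* **Functional redundancy** — gene abundance is the copy-weighted sum of
  carrier-taxon abundances. Soil genes are carried by 40 core taxa each
  (turnover-buffered, hence stable profiles); gut genes by one core anchor
  plus one pool taxon (dose-sensitive profiles). Per-sample lognormal
  quantification noise (σ = 0.5) represents annotation/quantification
  error and dominates residual systematic effects.
* **Abiotic factors** — dose-correlated with NH₄-N carrying much the
  largest effect, plus Gaussian noise.

What passing tests on this generator show: the pipeline detects exactly the
structure the generator encodes (composition shifts, diversity trends,
redundancy contrast, nestedness/turnover balance, neutral parameters) at
realistic sample sizes and noise levels, with calibrated false-positive
rates on null data. What they do not show: performance on real metagenome
tables, whose compositional noise, sequencing depth variation, taxonomic
correlation structure and annotation biases the generator does not model.
Two expected behaviours of the scenario are themselves statistical: the
soil gene ANOSIM is a calibrated null, so it exceeds p = 0.05 in only ~95%
of seeds, and per-habitat trend tests on 12 samples have finite power — the
headline pattern is therefore asserted over a majority of seeds (≥ 8/10),
not universally.

## Determinism and degenerate inputs

Every stochastic component takes an explicit seed (`numpy` Generators;
sub-streams via `SeedSequence`), and identical configurations reproduce
byte-identical pipeline outputs. Degenerate inputs fail loudly and early:
all-zero samples are rejected where a statistic requires positive totals,
constant vectors are rejected by the correlation tests (and reported as NaN
rows by the pipeline-level summary), equal-fill-forced null ensembles and
zero-variance null distributions raise rather than silently returning 0/1
p-values, and mode inference on tables refuses ambiguous input unless the
caller forces an interpretation.
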
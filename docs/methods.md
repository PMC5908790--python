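# Methods

This note documents the models, statistics, and numerical choices behind
`synscreen`, and what the synthetic screens it generates do and do not
emulate.

## Time-zero-anchored dose response

Viability screens that only normalize to an untreated control cannot
distinguish slowed growth from cell killing. Anchoring to the measurement
taken at the time of dosing (T0 ≡ 100%) makes that distinction explicit:
the untreated (DMSO) wells define the top of the *growth window*, T0 its
midpoint reference, and responses below 100% indicate net cell loss.

Normalized responses are fitted with the four-parameter logistic

    y(c) = bottom + (top − bottom) / (1 + (c / EC50)^h)

canonicalized so `top ≥ bottom` (a positive Hill exponent `h` then means
response falls with dose). Fitting is plain least squares
(`scipy.optimize.curve_fit` in log-concentration space) initialized from
data quantiles — top = max response, bottom = min response, inflection =
concentration nearest mid-response, slope = 1 — with up to 5 jittered
restarts on optimizer failure. Data whose dynamic range is under 1 %T0 are
flagged degenerate without fitting; degenerate fits censor all downstream
concentration metrics rather than raising.

Metrics are closed-form inversions of the fitted curve:

* **gIC50** at `(dmso_level + 100)/2` — midpoint of the growth window;
* **gIC100** at 100 — complete growth stasis;
* **dEC50** at 50 — 50% net cell death;
* **Ymin − T0** — the fitted-curve minimum *over the tested range* minus
  100. The tested-range restriction matters: a finite assay never observes
  the asymptote, so the minimum is taken at the highest tested dose for a
  decreasing curve.

Levels outside the fitted asymptotes are censored `unreachable`; levels
attained only beyond the highest tested concentration are censored `>max`
and carry that concentration as a lower bound (the usual "> 29.3 µM"
reporting convention). On a decreasing curve with DMSO above T0 the
attained metrics always order gIC50 ≤ gIC100 ≤ dEC50.

Biological replicates are combined by geometric mean for concentration
metrics (potencies are log-scaled quantities; "arithmetic mean of nM
values" would be dominated by the weakest replicate) and arithmetic mean
for Ymin − T0. A metric is censored in the aggregate only if censored in
every replicate; mixed cases are flagged `partial`.

## Combination index and the three-tier call

Fixed-ratio titrations dilute both agents together so the mixture traces a
single total-dose axis. After fitting 4PL curves to each single agent and
the mixture, the mutually non-exclusive combination index at effect level
ℓ is

    CI = D1/Dx1 + D2/Dx2 + (D1·D2)/(Dx1·Dx2)

with `D1 = fA·D`, `D2 = fB·D` the component doses inside the mixture dose
`D` attaining ℓ, and `Dx1`, `Dx2` the single-agent doses attaining the
same ℓ. The cross term is the non-exclusive correction: a sham 1:1
self-combination scores exactly 1.25, and any exactly Loewe-additive
mixture scores `1 + ab ∈ (1, 1.25]` where `a + b = 1` are the two Loewe
fractions. CI is evaluated at all three metric-defined levels the mixture
attains within its tested range; the summary CI is the minimum over
available levels (configurable to a single canonical level). Effect levels
are defined once from the mixture plate's DMSO anchor and all three curves
are inverted at those common levels.

Fold shifts compare like-for-like concentrations of the same molecule:
`fold_A = Dx1 / D1` (single-agent potency over the per-component
concentration in the mixture), not total dose. Calls:

* **strongly synergistic** — summary CI < 0.44 and some level where both
  agents shift ≥ 5-fold;
* **synergistic** — summary CI < 0.78 and some level where both shift
  ≥ 3-fold;
* **additive** — everything else, including CI ∈ [0.78, 1] and low CI with
  a sub-threshold shift from either agent. No antagonism tier exists;
  CI > 1 is reported numerically but called additive.

The fold-shift gate defaults to one *common* level at which both agents
meet the threshold; a flag (`same_level_for_both=False`) allows each agent
to qualify at a different level, since the defining phrase "in any single
measured parameter" admits both readings.

When a monotherapy cannot attain a level at any dose (the level lies
outside its fitted asymptotes), its CI term is taken in the `Dx → ∞` limit
(zero) and the result is flagged `monotherapy_incapable`; the corresponding
fold shift is left undefined and cannot satisfy a gate. Dx lookups do
extrapolate beyond the tested range when the level is mathematically
attained — the single-agent curve is a fitted model, and capping Dx at the
top tested dose would bias CI upward.

## Biomarker association

Potencies enter association tests as log10 gIC50; censored values are
substituted with the maximum tested concentration — a conservative lower
bound that preserves their rank position at the resistant extreme — and
flagged. Markers are binary: gene level (any protein-changing mutation)
and residue level (`GENE_R###` parsed from missense-style protein-change
strings; frameshift/splice notations contribute to the gene level only).

The test is the two-sided Wilcoxon rank-sum, exact when the combined
sample is ≤ 20 without ties, otherwise normal approximation with
continuity and tie correction (perfectly balanced ranks return p = 1
exactly). The screen reports the unadjusted p < 0.05 flag used in
single-agent biomarker screens of this kind *and* Benjamini–Hochberg
q-values side by side; gene-level rankings are read from the gene-level
rows since residue markers are nested within their gene. The default
minimum mutant count is 1 (configurable).

Phenotype enrichment uses Fisher's exact test (two-sided, summing
hypergeometric probabilities ≤ the observed table's) with a sample odds
ratio, Haldane-corrected (+0.5) when any cell is empty. Binary phenotypes:
`net_death` (Ymin − T0 < 0), `synergy` (call at least synergistic), and
`ras_pathway_mut` (any mutation in KRAS/NRAS/HRAS/BRAF/NF1).

## In-vivo efficacy

Time to endpoint (TTE) interpolates the crossing of the endpoint volume
log-linearly between bracketing measurements, which is exact under
exponential growth: `t1 + (t2−t1)·ln(E/V1)/ln(V2/V1)` (linear fallback
with a warning if a bracketing volume is nonpositive). Animals never
reaching the endpoint are censored at the final study day.

%TGD is the percent increase in median TTE versus control; censored
animals contribute their censoring day to the median, which biases %TGD
toward zero — every comparison that includes such an animal is flagged.
Arms are compared with the Mantel–Cox log-rank test (lifelines). Day-fixed
TGI is `100·(1 − ΔT/ΔC)` on mean volume changes from randomization
baselines (undefined when the vehicle arm did not grow), with a
Mann–Whitney test on the day's volumes through the same rank-sum machinery
as the biomarker module.

## Synthetic screen generator

The generator is the test bed for every stage, with defaults chosen to
emulate a large single-agent screen and its combination follow-up:

* 230 lines across tumor types; 10-point titrations topping at 30 µM with
  ~half-log dilution (factor 3), duplicate treated wells, 6 T0 and 6 DMSO
  anchor wells per plate;
* per-line growth window: DMSO top ≈ N(320, 50) %T0 clipped to [150, 500]
  (6-day growth of 2–5× over T0); response floor mixing cytotoxic
  (U(0, 60)), cytostatic (U(60, 99)) and partial (above T0) classes;
* true gIC50 lognormal with median 550 nM and log10-SD 0.7, spanning
  roughly 10 nM to > 30 µM; the 4PL inflection is derived from the sampled
  gIC50 so planted multipliers shift every concentration metric exactly
  multiplicatively;
* mutations sampled independently per gene per line (simplest null for
  co-occurrence) at literature-like frequencies, with hotspot-weighted
  protein-change strings (e.g. KRAS G12 ≫ G13 > Q61) and ~10%
  frameshift/splice annotations; a 3× resistance multiplier on KRAS for
  the primary agent is the default planted effect (emulating a mutant/WT
  median potency ratio of ≈ 3);
* measurement noise is multiplicative lognormal with mean 1 and CV 10% by
  default (positive, heteroscedastic signals), applied to every raw well
  including anchors;
* one Hill slope per line, shared by both agents. Together with the shared
  growth window this keeps every Loewe-additive mixture exactly inside the
  4PL family (mixture inflection `1/(fA/IA + fB/IB)`), so noise-free data
  round-trip through the fitting pipeline exactly. With per-agent slopes
  the mixture is no longer a 4PL and fitted CIs can leak a few percent
  past the algebraic (1, 1.25] band at near-asymptote levels.

Combination plates are built by Loewe dose equivalence: the mixture
response at total dose D solves `fA·D/DxA(y) + fB·D/DxB(y) = ψ`, found by
scalar root bracketing (`brentq`, ~1e-12 relative; terms vanish where an
agent cannot attain y). ψ = 1 is exactly additive; ψ < 1 inflates the
equivalent dose by 1/ψ (a downstream CI near ψ + ψ²/4 at every level,
with correspondingly large fold shifts); ψ > 1 is antagonistic.

Xenografts grow as `V(t) = V0·exp(rate·t)` from randomization volumes
U(100, 200) mm³, measured every 3 days with the same multiplicative noise,
stopping at the first measurement ≥ 2000 mm³ or the final study day.

**What the generator does not emulate:** tumor-type-specific response
distributions, mutation co-occurrence structure, biphasic or bell-shaped
dose responses, plate-position or edge effects, batch drift between
biological replicates, adaptive resistance over assay duration, and
non-exponential (e.g. Gompertzian) tumor growth. Passing the pipeline's
tests on these synthetics therefore demonstrates correctness of the
quantitative machinery under its stated model, not robustness to every
artifact of real screening data.

## Numerical choices and degenerate inputs

* 4PL fitting bounds: slope ∈ [0.01, 30], inflection within ±4 decades of
  the tested range; asymptote order restored by canonicalization
  (swapping asymptotes while negating the slope leaves the curve
  unchanged).
* Inversion censoring tolerances: `>max` uses a 1e-12 relative guard so a
  level attained exactly at the top dose is reported uncensored.
* Ties in the rank-sum test switch to the corrected normal approximation;
  a constant pooled vector short-circuits to p = 1.
* Degenerate 2×2 margins (constant trait) return p = 1 with a warning
  rather than raising.
* Scales: concentrations are nM everywhere; days are 0-based from
  randomization in vivo.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` run the simulation studies at
sizes chosen to make their binomial/quantile acceptance bands tight while
remaining desk-scale: 50 noise-free pairs for the Loewe band; exhaustive
enumeration up to n = 10 (rank-sum) and N = 30 (Fisher); 100 seeded
200-line screens for planted-marker recovery; 2000 permutation tests and
500 equal-hazard studies for null calibration; and one 230-line screen at
default noise for the planted-resistance medians.
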
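# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions a maintainer would need to know.

## Assay QC statistics

**Coefficient of variation.** CV (%) = 100 · SD / mean. "Intra-assay" is
computed over technical replicates of one sample, "inter-assay" over one
summary value per independent (biological) experiment. All SDs in the
package are sample SDs (n − 1 denominator): replicate counts in assay
characterization are small (typically n = 3) and the biased estimator would
systematically understate variability. The CV is undefined (an error, not a
NaN) for n < 2 or non-positive mean, since RLU means at or below zero
indicate a measurement problem rather than a statistic to report.

**Z′-factor.** Z′ = 1 − 3(σ_sample + σ_negative)/|μ_sample − μ_negative|.
Equal means are an error (zero separation); the statistic is ≤ 1 with
equality only when both SDs vanish, and arbitrarily negative when the
distributions overlap. The conventional "excellent assay" threshold ≥ 0.5 is
exposed as `OPTIMAL_Z_FACTOR` but never enforced: a negative screen-level Z′
produces a logged robustness warning, because a screen can still yield hits
under a weak window when the effect sizes are large and two reads are
required to concur.

**Dilution linearity.** Ordinary least squares of log10(mean RLU) on the
log10 concentration surrogate −log10(dilution factor), so an ideally linear
assay has slope +1 (regressing on the factor itself would flip the sign and
nothing else). Levels whose mean signal is ≤ negative-control mean +
2·negative-control SD are considered indistinguishable from background,
excluded from the fit, and reported — deep dilutions visibly degrade in real
serial-dilution data and leaving them in would understate the linear range's
quality. At least three above-background levels are required; fewer is an
error rather than a two-point "fit".

## Hit calling

The decision statistic is deliberately simple and matches widespread primary
screening practice: per plate and per read, the mean *m* and sample SD of
the M1 solvent-control (DMSO-treated, stimulated) wells define a band
*m* ± *k*·SD with default *k* = 3. Choices worth recording:

- **Solvent controls only.** M0 (unstimulated background) and TSA (positive
  control) wells are QC references; they never enter the threshold. The
  positive control sits far above the band by design, and pooling M0 wells
  would mix two different distributions into one SD.
- **Strict inequality.** A signal exactly on *m* + *k*·SD is not a hit; the
  rule is "more than k SDs away".
- **Per plate, per read.** Thresholds are never pooled across plates or
  reads — the two reads differ in medium (phenol-red vs phenol-red-free) and
  hence in baseline scale, and plates differ in handling.
- **Dual-read AND rule.** Hit status requires strict exceedance in every
  configured read; a compound missing any read is `incomplete`, never a hit.
  The hit set is therefore exactly the intersection of the single-read hit
  sets (tested as an invariant).
- **Raw RLU scale.** Thresholding operates on raw signals, not logs; with
  multiplicative noise a log-scale rule would behave differently in the
  upper tail, but the raw-scale mean + 3·SD convention is what this class of
  screen uses and is what the simulator is validated against.
- **Activator-only default.** With control CVs of 25–50% the lower band
  *m* − 3·SD is at or below zero, so the assay has essentially no power for
  inhibitors; inhibitor calling exists but emits a warning.
- **Viability counterscreen.** Relative viability is the compound well's
  ATP-luminescence divided by the plate's solvent-control viability mean in
  the counterscreen read. Below the cutoff (default 0.7, configurable and
  recorded in output metadata — no published consensus value exists) the
  call is flagged `reduced_viability`; if the reporter signal in that read
  also fell below the solvent-control mean the flag is
  `viability_confounded` (signal loss explainable by cell death). The flag
  annotates but never vetoes a hit: a compound can be both genuinely
  activating and mildly cytotoxic.

## ΔΔCt relative quantification

Technical Ct replicates are averaged per (experiment, condition, gene); Ct
values outside (0, 45] are rejected as physically implausible for a 40-cycle
protocol. ΔCt = Ct_mean(gene) − Ct_mean(reference) within each sample;
ΔΔCt compares each test-group biological replicate's ΔCt to the control
group's **mean** ΔCt, and fold_r = 2^−ΔΔCt_r.

**Summarization convention.** The reported fold change is the mean ± sample
SD of the per-replicate folds. The alternative — exponentiating the group-
mean ΔΔCt and propagating error on the cycle scale — yields the geometric
rather than arithmetic mean fold and is *not* used; the arithmetic
convention reproduces the "mean ± SD" format these validation tables are
conventionally reported in, at the cost of a small upward Jensen bias under
noise (≈ (ln2·σ)²/2 relative). The control condition's own summary is
centred on 1 by construction (exactly 1 when its replicates are identical).

**Suppression ratio.** mean fold(vehicle) / mean fold(compound) for one
gene; > 1 is suppression, < 1 further activation. Ratios compose:
ratio(a,b)·ratio(b,c) = ratio(a,c) for a shared control (tested).

## Comparison harness

The decision tree mirrors common wet-lab statistics practice, with the
unstated criteria pinned down as follows:

- Normality: Shapiro–Wilk per group at α = 0.05 (a constant group is
  treated as non-normal — Shapiro is undefined on zero variance and a
  constant sample is better served by rank tests). Groups need ≥ 3 values.
- Variance homogeneity: median-centred Levene (the Brown–Forsythe variant)
  at α = 0.05.
- All normal + equal SDs → unpaired t-test (2 groups) or ordinary one-way
  ANOVA with Dunnett's comparisons against the control (> 2 groups; scipy's
  Dunnett p-values use quasi-Monte-Carlo integration and are seeded for
  reproducibility).
- All normal + unequal SDs → Welch t-test, or Welch ANOVA (statsmodels
  `anova_oneway`, `use_var="unequal"`) as omnibus with pairwise Welch
  t-tests against the control, Holm-adjusted, as the Dunnett-T3-type
  post-hoc. No installed package provides Dunnett's T3 proper; the
  Welch-pairwise + Holm family is the closest principled construction and
  is slightly conservative.
- Any non-normal group → exact Mann–Whitney (2 groups) or Kruskal–Wallis
  with Dunn's post-hoc against the control, Holm-adjusted. Dunn's test is
  implemented in-package (z on mean ranks with the standard tie
  correction); for two tie-free groups its p-value provably equals the
  Kruskal–Wallis χ² p-value, which the test suite uses as an independent
  cross-check.
- Degenerate input (all groups identical) reports p = 1 with a warning.
- Stars: p < 0.05 \*, < 0.005 \*\*, < 0.001 \*\*\*, < 0.0001 \*\*\*\*.

## Synthetic-data generators

**Screen simulator.** Well signal = read scale × role multiplier × compound
effect × ε, with ε a *mean-one* log-normal, ε = exp(σZ − σ²/2),
σ = √ln(1 + CV²), so the configured baselines are the exact means of the
generated distributions and the configured CV is the exact CV (moment
fidelity is tested). Signals are positive and assay noise at high means is
visibly multiplicative in this class of data, which motivates log-normal
over Gaussian noise. The two reads share each compound's true effect but
draw noise independently: read-to-read correlation enters only through the
biology, matching a screen whose raw read correlation was weak; a correlated
noise term is deliberately absent from the default model. Defaults describe
the campaign the analysis was built for: seven 384-well plates
(4 × 320 + 3 × 258 = 2054 compound wells, libraries LOPAC and ENZO), 16
M0 / 16 M1-solvent / 8 TSA control wells per plate, solvent multiplier 3×,
TSA 8×, per-read control CVs 0.45 (read 1, phenol-red medium) and 0.30
(read 2, phenol-red-free at twice the baseline scale, carrying the
viability counterscreen). The packaged default plants three 5× activators
and four cytotoxic compounds (viability fractions 0.20–0.35 with matched
signal depression). One compound well per plate per read, as the deck
geometry implies.

Not emulated: plate-position artifacts (edge effects, gradients),
liquid-handling failures, carry-over, and dose–response structure. Passing
tests therefore demonstrate correctness of the statistics under the assumed
noise model, not robustness to spatial artefacts — a B-score-style spatial
QC would be the natural extension if real plates showed them.

**Ct simulator.** Per (experiment, condition) the reference gene's latent Ct
is its baseline (default 20 cycles) plus biological noise; each target
gene's latent Ct adds the gene's baseline ΔCt (default 5 cycles) minus
log2(true fold). Technical replicates add independent N(0, σ_tech) per
measurement. Defaults are technical duplicates, 3 biological replicates,
σ_tech = 0.2 cycles, σ_bio = 0 — the replication structure of a routine
validation qPCR. With all noise zero the expression module inverts the
generator exactly (tested to 1e-12 relative).

A note on recovery precision: with σ_tech = 0.2 and duplicates, the
per-replicate ΔCt carries SD σ_tech·√(2/n_tech) = 0.2 cycles (gene and
reference each contribute), so the mean-fold estimate over 3 replicates has
a log2-scale SD of ≈ 0.16 and lands within ±15% of the planted fold in
roughly 82% of experiments — a useful calibration of what a 3-replicate
qPCR can and cannot resolve. The estimator itself is validated by agreement
with a direct simulation oracle of the identical generative model.

**Dilution simulator.** Level mean = base/10^d + background with
configurable per-level CV; the truth record carries base and background so
the expected linear range is known.

## Determinism and numerics

Every generator takes an explicit seed (`numpy.random.default_rng`);
identical config + seed gives byte-identical serialized output, which the
round-trip and idempotence tests assert at the byte level. The pipeline
derives per-stage sub-seeds from the run seed by SHA-256, keeping stages
independent of each other's draw counts. Serialized RLU values use full
`repr` precision so write → load round-trips are bit-exact. Thousands-
separator commas are accepted on input ("12,432.0" → 12432.0); the decimal
separator is the dot only. Well addresses are case-insensitive on input and
canonicalized to upper case without zero padding ("a01" → "A1").

## Problem sizes in the test suite

The stochastic suites run at sizes chosen to give tight Monte-Carlo
intervals while keeping the default `pytest` run fast: 200 simulated
single-plate screens against a 2000-screen brute-force oracle for the hit
rule (two-proportion 95% agreement), 500 simulated qPCR experiments for
fold recovery, and 400–500 replicate draws for the Z′ Monte-Carlo mean.

## Known limitations

- No FDR-style multiplicity control across compounds; the fixed k·SD rule
  is the method being modelled, and with heavy-tailed controls it is not a
  calibrated per-compound test.
- No amplification-efficiency correction (Pfaffl), standard curves, or
  melt-curve handling in the qPCR stage; plain ΔΔCt with one reference gene.
- No dose–response confirmation or EC50 estimation; screens are modelled at
  a single concentration.
- The Brown–Forsythe/Welch ANOVA post-hoc is a Dunnett-type construction
  (Welch pairwise + Holm), not Prism's Dunnett T3 tables; p-values can
  differ slightly in the third decimal for small samples.
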
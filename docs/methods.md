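# Methods

## Problem setting

The package models a retrospective case-control study of ipsilateral breast
tumor recurrence (IBTR) after breast-conserving surgery. Patients who later
developed IBTR are cases; controls recurred for at least as long as their
matched case's time to IBTR. Tumors are profiled on a targeted 248-gene
radiosensitivity panel (nCounter-style digital counts: endogenous probes,
13 housekeeping genes, a positive-control spike ladder, negative-control
background probes). Samples split into a discovery cohort (N = 172) and a
validation cohort (N = 164); the split is a fixed property of each sample
and never re-randomized. Analyses are stratified by estrogen-receptor
status and adjuvant radiotherapy into four groups: ER+RT+, ER+RT−, ER−RT+,
ER−RT−.

## The k-TSP single-sample predictor

A predictor is an ordered list of k gene-disjoint pair rules
"expression(A) > expression(B) votes high-risk" with an unweighted majority
vote. Pair ranking uses

* Δ = |P̂(Xᵢ > Xⱼ | case) − P̂(Xᵢ > Xⱼ | control)|, within-sample ties
  Xᵢ = Xⱼ counted ½ toward each probability (the symmetric choice);
* γ = |mean within-sample rank difference (case) − same (control)| as the
  secondary score, ranks taken over the analysis gene set with average ranks
  for ties;
* lexicographic (gene_a, gene_b) order as the final tie-break, applied after
  orientation, so selection is fully deterministic.

Sorting uses exact integer keys (cross-multiplied counts), never floating
probabilities, so equal scores are true ties rather than rounding
artifacts. Orientation is chosen so that A > B is the case (high-risk)
direction; at Δ = 0 the lexicographically smaller gene leads.

k is selected from a grid of odd values by stratified cross-validation
(default 5 folds, fixed seed) maximizing balanced accuracy — balanced
because the case-control design enriches cases far beyond their population
rate — with ties resolved toward smaller k. The default grid starts at 101
(the "at least 100 pairs" training policy, rounded up to odd so the
majority vote cannot tie) and ends at floor(n_genes/2) = 117 for the
default 235-gene analysis set; every trained model therefore uses ≥ 202
distinct genes. Training refuses strata with fewer than 10 cases or 10
controls; the pipeline skips such strata with a warning (the ER−RT−
stratum, N ≈ 3, exists precisely to exercise this guard).

Predictions depend only on within-sample orderings, so they are invariant
under any strictly monotone per-sample transform; this is property-tested
and is also why uniform per-sample rescaling of raw counts cannot change a
call. `subset_model` drops rules whose genes are missing on another
platform and removes one further lowest-ranked rule if the count would
become even; it is the only sanctioned way to apply a model with missing
genes.

The model's raw score is the vote fraction (fraction of rules voting
high-risk); the class cut point is vote fraction > 0.5.

## Normalization and QC

Normalization is two scaling steps then a log: (1) each sample is scaled so
its positive-control geometric mean equals the across-sample geometric mean
of those geometric means; (2) likewise on the housekeeping genes;
(3) log2(x + 1). Control and housekeeping probes are then dropped from the
analysis set. Using a *geometric* across-sample target makes the composite
map an exact fixed point: re-normalizing already-normalized linear data
reproduces it to machine precision, whereas an arithmetic target drifts by
mean(x)·mean(1/x) ≥ 1 per application. The geometric mean of any set
containing a zero is defined as 0, which deliberately routes such samples
to the QC error path rather than silently pseudo-counting.

QC (defaults follow common digital-count practice and are configurable):
a sample is removed when its positive-control scale factor leaves
[1/3, 3] or its housekeeping geometric mean falls below 32 counts; an
endogenous probe is removed when it sits at or below the per-sample
background (mean + 2 SD of the negative controls) in ≥ 85% of retained
samples.

## Signature scores

* **Rank-linear 10-gene score**: Σ coefficient × within-sample rank. The
  published coefficients of the radiosensitivity-index surrogate are not
  bundled; `data/ten_gs_synthetic.csv` ships synthetic placeholder
  coefficients (clearly labelled) so the machinery is testable. Rank scope
  defaults to the full panel, direction ascending; both configurable, since
  signatures differ in whether they rank within the signature or the panel.
* **Proliferation** = geometric mean of *MKI67* and *AURKA*; **immune** =
  geometric mean of IRF1, IGKC, STAT1, OSMR, CCL19, RELA, IRF8, FGR,
  TNFRSF1B, C3 (the "RelA" annotation spelling maps to panel id RELA). Both
  are computed on strictly positive linear-scale expression; passing log2
  values raises.
* **Median dichotomization**: high iff score > median of the supplied set
  (appropriate because the design enriches for recurrences, making a
  population cut point meaningless); exact-median values are low; a
  constant score vector warns and returns all-low.
* **Correlation**: Pearson r, OLS slope, and the two-sided zero-slope t
  test with n − 2 df (scipy `linregress`).

## Survival evaluation

Kaplan–Meier product-limit curves, the log-rank test (1 df for two groups,
g − 1 df generally) and Cox proportional-hazards fits are thin validated
wrappers over lifelines; ROC/AUC is the Mann–Whitney concordance with ties
credited ½ (scikit-learn). The Cox fit uses Efron tie handling (the
lifelines implementation) with the Newton tolerance tightened to 1e-9 so
the coefficient agrees with a grid-search maximizer of the written-out
partial likelihood to < 1e-4 on tie-free data; synthetic event times are
continuous, so ties are a measure-zero concern here. Guards: ≥ 5 events
per coefficient, no constant covariate, extreme coefficients (monotone
likelihood/separation) raise. 10-year risk is read from the KM curve as
1 − S(t) at the last event time ≤ 10.

## Treatment stratification

The RT− stratum's SSP estimates recurrence risk without radiotherapy:
low-risk samples form **No-RT**. For the rest, the RT+ stratum's SSP (a
radioresistance readout) decides: low risk under RT → **Give-RT**, high
risk even with RT → **More-treatment** (candidates for escalation). The
three groups partition the input exactly and are a pure function of the
two model predictions. Evaluation reports, per group, KM curves split by
actual RT with the log-rank p (a group with a single RT arm is flagged
prognostic-only rather than tested), and one Cox model with Give-RT and
More-treatment indicators, RT, and the two group × RT interactions. The
models must target the same ER stratum unless explicitly overridden.

## Synthetic cohort generator

The generator emulates the *structure* of the study, not any real tumor
biology:

* endogenous counts ~ NegativeBinomial(mean = μ_g · f_s, dispersion 10)
  with per-gene baselines μ_g log-normal around ~2⁶·⁵ and per-sample size
  factors f_s ~ LogNormal(0, 0.25); housekeeping genes high (≈ 2⁹) and
  class-independent; positive controls follow a six-step 4-fold geometric
  ladder scaled by f_s with Poisson noise; negative controls Poisson(2).
* **Planted order signal**: each gene of a planted pair is drawn uniformly
  from eight 3-fold-spaced levels *in both classes* — identical marginals,
  so no single gene separates cases from controls — while the joint
  coupling shifts A one level above B (cyclically) in cases and one below
  in controls, with a coupling probability calibrated (normal
  approximation to the adjacent-level order probability) so that
  P(A > B | case) − P(A > B | control) ≈ the requested `planted_delta`.
  The mechanism saturates near 0.68 at the defaults and warns beyond. An
  earlier mean-swap design was rejected because it leaked class signal
  through single-gene marginals, letting half-planted pairs outscore the
  planted ones.
* **Defaults as study conditions**: 172/164 cohort sizes; stratum
  fractions {0.52, 0.24, 0.22, 0.02} putting N ≈ 3 in ER−RT−; 40% cases
  per stratum; 15 planted pairs per stratum at Δ = 0.6 — sized so that a
  locked ≥ 101-rule majority vote separates held-out cases at AUC ≈
  0.7–0.9 (separation ≈ m·Δ/k against vote-noise SD ≈ 0.5/√k), i.e. a
  cohort in which such predictors genuinely validate; median time to IBTR
  4.4 years; follow-up up to 25 years.
* **Survival coupling**: cases draw truncated-exponential event times
  (median 4.4 y); each control's censoring time is uniform between a
  randomly matched case's event time and maximum follow-up, mirroring the
  control-selection rule of the emulated design. Adjuvant-therapy flags are
  cohort-specific Bernoulli annotations only.

What the synthetic data does **not** have: realistic gene-gene correlation
structure, FFPE degradation artifacts, platform batch effects, or any
biological relationship between expression and survival beyond the planted
pair order and the case/control labels. Green tests therefore establish
the *correctness of the machinery* (scoring, selection, voting, survival
statistics, determinism) and its *statistical calibration under the null*,
not clinical performance on real tumors.

## Simulation sizes and numerical choices

* Planted-pair recovery: 5 pairs at Δ = 0.6, 100 samples/class, top-5
  selection, 20 seeds (success = ≥ 4/5 recovered).
* Null calibration: 20 seeds of a no-signal single-stratum cohort
  (172 train / 164 held out), full default training; mean held-out AUC is
  expected in [0.4, 0.6]. Log-rank type-I error: 40 null survival draws,
  n = 300, two random arms, α = 0.05 (the measured rate fluctuates with
  binomial noise ≈ 0.034 around ~0.05).
* The log-rank permutation oracle at n = 8 compares the asymptotic
  chi-square p with a 10,000-permutation p; the test statistic must agree
  exactly, while the p-values differ by the discrete small-sample
  approximation (tolerance 0.10 at n = 8; 0.03 at n = 60).
* Exact-key sorting, lexicographic tie-breaks and geometric normalization
  targets make every pipeline stage deterministic; reruns with one seed
  are byte-identical, which the end-to-end test asserts file by file.

## Known limitations

* The Cox layer exposes Efron tie handling only (lifelines); Breslow is not
  offered. On continuous synthetic times the two coincide.
* The planted-signal mechanism cannot exceed an order difference of ~0.68;
  requests beyond it saturate with a warning.
* The bundled 10-gene coefficients are placeholders; real analyses must
  supply the published signature file.
* ER− treatment stratification requires an RT− model, which the default
  design cannot train (N ≈ 3); the pipeline reports it as skipped, and
  prognostic-only evaluation is available when a group has one RT arm.
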
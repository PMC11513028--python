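# Methods

This note records the models implemented by `gwhazard`, the constants and
policies that drive them, and the choices made where the underlying
methodology is conventionally under-specified.

## Element registry and exposure profiles

All constants live in `src/gwhazard/data/registry.yaml` (versioned;
operations never hard-code them). Per element the registry carries, in
µg L⁻¹ unless noted:

| El | MAC | S (=MAC) | I (=S/100) | WHO | BIS | RfD_ing | GIABS | Kp (cm/h) | SF_ing | DL |
|----|-----|----------|------------|-----|-----|---------|-------|-----------|--------|-----|
| Cr | 50 | 50 | 0.5 | 50 | 50 | 0.003 | 0.025 | 0.001 | 1.5 | 0.009 |
| Ni | 20 | 20 | 0.2 | 70 | 20 | 0.029 | 0.2 | 0.0002 | – | 0.011 |
| As | 50 | 50 | 0.5 | 10 | 10 | 0.003 | 1 | 0.001 | 0.5 | 0.006 |
| Mo | 70 | 70 | 0.7 | 70 | 70 | 0.005 | 1 | 0.001 | – | 0.001 |
| Cd | 3 | 3 | 0.03 | 3 | 3 | 0.0005 | 0.025 | 0.001 | 0.0061 | 0.002 |
| Pb | 10 | 10 | 0.1 | 10 | 10 | 0.0035 | 1 | 0.001 | 0.0085 | 0.005 |

The MAC column (CF/CI/HEI denominator) is back-calculated from the six
reported contamination factors (CF = mean/MAC − 1 inverted at each
element mean); it differs from the WHO/BIS acceptable limits for Ni and
As, so the registry also ships `mac_source="who"` / `"bis"` variants and
every pipeline run logs which registry it used. GIABS and Kp are not
usually tabulated alongside such studies; they are back-calculated from
the dermal dose/hazard ratios (Kp from CDI_der/EC, GIABS from
CDI_der/HQ_der) and stored with that provenance. Carcinogen slope
factors exist for Cr, As, Cd and Pb only; Ni and Mo are excluded from
the carcinogenic aggregates for lack of published slope factors.
Detection limits are the smallest finite concentrations observed per
element.

Cohort exposure constants (daily water intake 3.45 / 2 L day⁻¹, exposure
frequency 365 day year⁻¹, exposure period 70 / 10 y, life expectancy
25 550 / 3 250 day, body weight 73 / 32.7 kg, skin area 18 000 /
6 600 cm², exposure time 0.58 / 1 h day⁻¹, conversion 0.001 L cm⁻³ for
adult / child) are config-driven so region-specific values can be
substituted without code changes. Note the adult profile satisfies
EF·EP = LE, so adult CDI_ing reduces to EC(mg L⁻¹)·DWI/BW; the child
profile has EF·EP = 3650 ≠ LE = 3250 and the equation is applied exactly
as stated rather than "corrected".

## Pollution indices

CF, CI and HEI are as defined in the README; HEI − CI equals the number
of included elements, an identity the tests verify numerically. For HPI
the literature varies in its choice of ideal values I and in whether the
sub-index is signed. We use unit weights Wᵢ = 1/Sᵢ with S the
permissible set above, and a **signed** Qᵢ, because the reference
analysis reports negative HPI values (possible only without the
absolute value); the |·| textbook variant is available via
`hpi(..., signed=False)`. No ideal values are published for this element
set; we default to I = S/100, a "desirable ≪ permissible" convention
that places HPI for waters in the observed concentration regime in the
low single digits of either sign — consistent with the reported range
(−8.7…8.1, mean −0.27). m-HPI splits elements at Cᵢ ≤ Sᵢ and takes
W-weighted means of Cᵢ/Sᵢ − 1 over each side (NI ∈ [−1, 0], PI ≥ 0,
upper limit U_L = 100). These reconstructions reproduce the qualitative
behaviour (signs, 100 % Excellent on clean data) but exact numerical
agreement with any one study is not claimable without its raw data.

Censored elements are included at their substituted value by default;
`drop_censored=True` removes them per sample (both behaviours tested),
since dataset-level index summaries in the literature are sometimes
consistent with per-sample BDL exclusion.

Classification bands are stored in the registry config. Shared
boundaries belong to the lower band, except where a scale defines a band
as "< x", in which case x belongs to the next band (e.g. EC 750 is
already "Permissible", TDS 10 000 is still "Brackish water"). Critical
values: HPI 100, HEI 20, CI 3.

## Risk chain

Equations as in the README, with EC converted µg L⁻¹ → mg L⁻¹ inside the
CDI so HQ = CDI/RfD is dimensionless; every quantity is exactly linear
in EC. The dermal slope factor is policy-controlled: `eq11` implements
SF_der = SF_ing/GIABS; the default `as_printed` applies SF_ing to the
dermal dose unchanged, which is the behaviour consistent with published
dermal cancer-risk tables of this form. The policy is logged per run.

## BDL substitution

Left-censored measurements carry the detection limit as their bound.
Substitution policies: 0, DL, DL/2 (default), DL/√2. Geometric means are
taken after substitution over strictly positive values, with excluded
zeros counted and logged.

## Synthetic data

Each element concentration is lognormal, truncated at the observed
maximum, with (µ, σ) chosen so the **truncated** law matches the target
mean and SD: µ is solved (bracketed root) to put the truncated mean on
target for a given σ, and σ is solved for the SD. A plain untruncated
moment match followed by truncation would undershoot the Mo mean by
≈10 %, which is why the truncation-aware match is used. For Cr, Ni, Cd
and Pb the reported (mean, SD, max) triples are not attainable by any
capped lognormal — the cap binds before the SD reaches its target — so
the matcher keeps the mean exact, saturates σ (at 3, beyond which the
shape becomes implausibly heavy-tailed for trace-element data) and logs
the concession; the delivered SDs are 10–30 % low for those elements.
Sampling is by exact inverse-CDF transform of the truncated law, so no
rejection loop is needed and every draw is a deterministic function of
the seeded generator. Draws below the detection limit are flagged BDL.
pH, EC and TDS are independent uniforms within the observed ranges (the
analysis never couples them to the elements). Not emulated: spatial or
inter-element correlation (none reported to emulate) and the strong
median/mean skew of Pb and Cd (a single lognormal matched to mean/SD
understates it). Passing tests therefore demonstrate correctness of the
arithmetic and the qualitative clean-water regime, not distributional
fidelity to any specific aquifer.

## Surrogate models

Covariates are min–max normalized to [0, 1]; all rescaling parameters
are computed on the training partition only. Partitions are uniform
random without replacement, reproducible from a seed; the family
fractions are 75/25 (RBF indices and HI), 80/20 (RBF CR), 70/30 (MLP
indices and CR) and 85/15 (MLP HI).

**RBF.** Stage 1 is unsupervised: k-means (scikit-learn) on the
normalized training inputs places the centers; each center's width is
the mean distance to its two nearest other centers times an overlap
factor (default 1; a positive floor guards duplicate centers). Hidden
responses are Gaussians in the distance to each center, normalized
across units to sum to one per case (a softmax over the radial
responses), so activations lie in (0, 1). Stage 2 fits the identity
output layer by least squares (minimum-norm solve, which regularizes a
singular system) on z-scored targets. With hidden_units = n_train the
network interpolates its training set (train SOSE ≈ 0), a regime the
tests exercise.

**MLP.** One hidden layer; tanh in hidden *and* output layers. Targets
are mapped to the adjusted-normalized range with correction ε = 0.02,
y′ = 2(y − min + εR)/((1+2ε)R) − 1 with R the training range, so
training extremes land at ±1/1.04, reachable by tanh; the inverse map
restores the original scale (round-trip exact to 10⁻¹⁰). Training is
batch scaled conjugate gradient (Møller's algorithm; σ₀ = 5×10⁻⁵,
initial λ = 5×10⁻⁷, max 1000 iterations) with Glorot-style uniform
initialization from the seeded generator. Every `eval_every` iterations
the test-partition error is checked; training stops after `patience`
checks without improvement and the best-so-far parameters are kept.
Non-convergence is flagged in the model metadata, never fatal.

**Unit selection.** "Automatically computed" unit counts are resolved as
a grid search over 2…min(20, n_train/2) hidden units, selecting the
count with minimal test-partition SOSE on the original target scale.
One model per output is the default (per-index fits); a multi-output
mode trains one network per target family instead.

**Importance.** Permutation importance: the mean relative SOSE inflation
when each input column is shuffled (n_repeats draws from the seeded
generator), clipped at zero, averaged across outputs and normalized to
sum to one. Chosen for model-family neutrality; constant columns score
zero with a warning.

Models serialize to JSON (all weights, rescaling constants, seeds)
sufficient for bit-identical reload.

## Validation metrics

R² defaults to the standard coefficient of determination
1 − Σ(m−p)²/Σ(m−m̄)², undefined (NaN) for a constant measured vector. A
literal `as_printed` variant with Σ(p−m̄)² in the denominator is kept
behind a flag for fidelity to the source formula; it can exceed 1 and is
not used by default. SOSE = Σ(m−p)². The reported "RE" is the mean
absolute per-point relative error (m−p)/m over the partition (median and
max also reported); points with m = 0 are excluded with a count. The
residual vector m − p is exported with case ids and partition labels as
tidy parity data for plotting.

## Reproducibility

One global seed fans out to per-stage seeds through
`SeedSequence([seed, stage_code])`, so `simulate`, `train` etc. run
standalone yet agree with the `all` pipeline. Each run directory
contains exactly one `manifest.json` (config hash, stage seeds, policy
flags, registry version, package version); numeric outputs are
byte-identical across reruns of the same configuration.

## Problem sizes

The analysis scripts and the classification checks use the
study-condition n = 40. Surrogate-recovery validation uses n = 200
samples averaged over 5 generator seeds — large enough that test R² of
smooth targets stabilizes, small enough that the whole suite runs in
about a minute on one CPU. The Monte-Carlo check of the generator's
moment match uses n = 10⁴.

## Known limitations

* Exact HPI/m-HPI constants (ideal values, U_L) are conventions, not
  published facts; only qualitative agreement is claimed.
* The generator does not reproduce inter-element correlation or the full
  Pb/Cd tail skew, and concedes SD where the reported (mean, SD, max)
  triple is infeasible for a capped lognormal.
* Deterministic point-estimate exposure only (no Monte-Carlo exposure
  assessment, no inhalation route).
* No geospatial interpolation; coordinates are carried as metadata only.
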
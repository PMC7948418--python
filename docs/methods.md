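# Methods

This note documents the models, conventions, and numerical choices behind
`gpcrbias`, and what the synthetic-data validation does and does not show.

## Operational model and bias statistics

The package quantifies agonism with the Black–Leff operational model,

E(A) = basal + (Em − basal) · τⁿAⁿ / ((A + K_A)ⁿ + τⁿAⁿ),

where `Em` (maximal system response, response units), `n` (transducer slope,
dimensionless) and `basal` are properties of one assay system and are shared
by all ligands fitted together, while `τ` (operational efficacy) and `K_A`
(functional affinity, molar) are ligand-specific. For `n = 1` the model is
exactly a logistic with observed `Emax = Em·τ/(1+τ)` and
`EC50 = K_A/(1+τ)`; the test suite uses this reduction as a closed-form
oracle.

**Fit parameterization.** Each ligand is fitted as
(`log R = log10(τ/K_A)`, `log τ`), with `log K_A = log τ − log R` derived.
The transduction coefficient is the quantity of interest, and for full
agonists `τ` and `K_A` are individually ridge-degenerate while their ratio
remains well determined; parameterizing in `log R` keeps both the optimizer
and the reported standard error (read from the local covariance,
σ² (JᵀJ)⁻¹ with σ² = SSR/(m−p)) well conditioned. Bounds: `log τ` ∈ (−5, 5),
`log K_A` ∈ (−14, −2) M, `n` ∈ (0.3, 3) when free. `Em` is capped at
3× the observed response span: with a (near-)full reference agonist present,
solutions with a much larger `Em` and uniformly tiny `τ` sit on a likelihood
ridge on which no individual `log R` is identified (the per-assay Δ is
unaffected, because the shared-`Em` bias cancels in the difference, but the
reported standard errors would be meaningless).

**Initialization and multi-start.** Starting values come from per-ligand
4-parameter logistic fits, translated through the n = 1 mapping under an
assumed reference efficacy τ₀ = 10; further starts (τ₀ = 1, 100) run only if
a start fails to converge to an interior optimum or two starts disagree.

**Transducer slope.** Whether to estimate or fix `n` is left to the caller
(`n_hill=None` estimates it; `n_hill=1.0` fixes it). With only two ligands
and a free slope the shared parameters are weakly identified and individual
standard errors can be ridge-inflated; analyses of per-ligand error
magnitude (e.g. the weak-partial-agonist precision study) therefore fix
`n = 1`, which is also the generating value in all synthetic studies.

**Bias.** Within each replicate block (assay day) and pathway,
Δlog(τ/K_A) subtracts the reference endogenous ligand's log R from each
analog's; the reference's Δ is exactly zero by construction.
ΔΔlog(τ/K_A) = Δ(reference pathway, conventionally cAMP) − Δ(comparator),
per block; positive values mean bias toward the reference pathway, and the
anti-log of the block mean is the bias factor. The 95% interval is the
t-interval over per-block ΔΔ values (mean ± t₀.₉₇₅,ₙ₋₁·SEM); bias is called
significant when the interval excludes zero. Within-fit covariances are not
additionally propagated into this interval — between-assay scatter is
treated as the relevant replication unit; this is a documented
simplification. Blocks present in only one pathway are dropped (logged).
Ligands whose fitted high-dose asymptote is below 10% of `Em − basal` are
flagged weak partial agonists: their log R standard error is large and bias
estimates built on them are unreliable.

## Kinetic traces

- **Two-step normalization**: each well is divided by its own pre-agonist
  baseline mean, then by the time-matched mean of identically normalized
  vehicle wells (a serial record, not a scalar). Wells with baseline mean
  ≤ 0 raise a flagged error and are excluded by the pipeline with a log
  entry.
- **Ratiometric channels** (BRET 575/460, DERET 620/520) divide per time
  point after optional per-channel blank subtraction (fluorescein-only wells
  for DERET). Points whose blanked denominator is ≤ 0 are masked to NaN and
  the well flagged, not discarded: transient instrument artifacts should not
  throw away a well.
- **AUC** is trapezoidal on the native time grid over the post-agonist
  window, optionally after subtracting the baseline mean; no resampling or
  smoothing.
- **Half-time** defaults to the first linear-interpolated crossing of
  baseline + (peak − baseline)/2 — assumption-free, and exact for noise-free
  sampled traces. On noisy traces the sample maximum is biased upward, which
  biases the threshold crossing late; a one-phase exponential-association
  fit (`method="fit"`) is provided and is the better choice for sustained
  recruitment traces. Flat traces report a missing value rather than raise.
- Fold-change helpers cover forskolin-percent normalization (cAMP),
  fold-of-unstimulated (ERK), fold-of-glucose-only (insulin secretion), and
  qPCR 2^−ΔCt.

## Dose–response fitting

3- or 4-parameter logistic, fitted in log10-concentration space with an
analytic Jacobian; Hill slope fixed at 1 (3-parameter) or bounded to
(0.1, 5) to prevent pathological slopes on weak partial agonists. Vehicle
(0 M) rows are excluded from the fit; for the 3-parameter model they anchor
the basal initialization. Initialization is from data heuristics (min, max,
mid-range half-maximal crossing, slope 1) with multi-start on failure.
Flat data are flagged unidentifiable, never silently fitted. When replicate
blocks are present, each block is fitted separately and parameters are
reported as mean ± SEM over blocks — matching the convention of reporting
per-experiment parameter estimates — alongside the pooled fit. AUC-based
dose–response (PKA-type FRET assays) normalizes each well's trace to its
baseline, integrates, and expresses the AUC as a fold of the block's vehicle
mean, so vehicle wells map to 1.0 by construction.

## Internalization

From Mesna-cleavage intensity tables, per block:

fraction = (S_mesna,ligand − S_mesna,vehicle) / (S_no-mesna − S_mesna,vehicle).

The nonspecific floor (Mesna + vehicle) is subtracted from both numerator
and denominator so that a ligand with no internalization scores exactly 0
and complete protection scores exactly 1; a raw-denominator mode
(`subtract_background=False`) is provided for comparison with analyses that
normalize to the uncorrected no-Mesna signal. Blocks with non-positive
denominators are excluded with a log entry. Surface expression is the
background-subtracted no-Mesna signal relative to a reference receptor
within block. Cross-receptor summaries are expressed as log2 fold-changes
vs a reference receptor; non-positive responses are flagged below-range
instead of producing a number. Image segmentation and illumination
correction are upstream of this package, which consumes per-region mean
intensities.

## Synthetic data generator

The generator emulates the assay designs the analysis assumes:

- **Kinetics**: difference-of-exponentials time courses normalized to unit
  peak, f(t) ∝ e^(−k_off·t) − e^(−k_on·t) (k_off = 0 gives the sustained
  association 1 − e^(−k_on·t); peak time ln(k_on/k_off)/(k_on − k_off)),
  scaled by the operational-model fractional response at the dosed
  concentration on top of a baseline segment. Default scenarios use
  half-times of 1.5 min (GLP-1R) and 7.1 min (GIPR) for sustained mini-G_s
  recruitment and transient β-arrestin-2 kinetics.
- **Concentration–response studies**: 9 concentrations spanning 1 pM–1 µM
  (0.75-log spacing), 5 replicate blocks by default. Between-assay scatter
  is one Gaussian offset per (block, pathway) applied to every ligand's
  log R — the per-assay Δ normalization is designed to cancel exactly this
  kind of effect. Measurement noise is multiplicative Gaussian
  (default CV 5%) plus an additive floor. Plate-reader noise magnitudes are
  not published for these assays; the defaults are chosen to give realistic
  error bars and are configurable, not claimed as the study's values.
- **Internalization plates**: no-Mesna wells read the surface signal,
  Mesna+vehicle the nonspecific floor, Mesna+agonist the floor plus the
  protected fraction of the specific signal.

Identical inputs and seed give bit-identical output. What the generator does
**not** emulate: plate-position and edge effects, signal drift and
photobleaching, pipetting serial-dilution errors, receptor-expression
variability between transfections, and ligand depletion/degradation.
Passing tests therefore demonstrate correctness of the estimators under the
assumed noise structure, not robustness to every artifact of real plates.

## Validation problem sizes

The end-to-end validation runs 200 simulated two-pathway studies
(5 blocks, CV 5%, block scatter 0.1 log units, true ΔΔlog(τ/K_A) = 0.5):
point-estimate recovery and 95% CI coverage are computed across studies.
Logistic recovery uses 200 five-block studies; the weak-partial-agonist
precision study uses τ ∈ {1, 0.3, 0.1, 0.03} × 10 replicate assays.
Grid-search oracles (logistic and operational) use 0.01-step grids on toy
5-point data. These sizes give Monte-Carlo standard errors comfortably
below the tested margins while keeping the suite fast.

## Known limitations

- Bias CIs reflect between-assay scatter only; very small block counts
  (n < 4) give wide, unstable intervals.
- The operational fit assumes a shared `Em`/`basal`/`n` per assay; systems
  with ligand-dependent maximal responses not mediated through τ violate
  this.
- ΔΔ values for weak partial agonists (flagged) are reported but should be
  interpreted with their large errors in mind.
- No kinetic (time-dependent) bias modeling; matched incubation times across
  pathways are the caller's responsibility, as in the underlying assay
  design.
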
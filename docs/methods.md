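# Methods

## Kinetic model

The assay is modelled as two well-mixed compartments (apical 200 µL,
basolateral 1000 µL) exchanging solute across a membrane of area 0.33 cm²
with a constant overall apparent permeability `Papp` (cm/s). Both
concentrations relax exponentially toward the volume-weighted equilibrium
`C_eq = (C_a0·V_a + C_b0·V_b)/(V_a + V_b)` with rate constant
`k = Papp·A·(1/V_a + 1/V_b)`. Assumptions baked into this choice:

- **Passive, dissipative transport only.** No active (uphill) flux term:
  with equal concentrations on both sides the trajectories are flat, which
  matches the no-gradient control behaviour the assay design relies on. A
  first-order `leak_rate` hook exists on the ODE simulator for cellular
  consumption studies but is off by default.
- **Constant Papp.** No saturation or time dependence; the assay's 1–2 mM
  doses sit well below reported carrier saturation, and the data offer no
  leverage to fit more.
- **Composite membrane.** Filter and cell layer(s) compose in series
  (resistances add), which reproduces the observed blank ≫ cell-layer
  ordering; within a layer the transcellular and paracellular routes
  conduct in parallel (permeabilities add). A co-culture is two different
  layers stacked on one filter.
- **Multiplicative inhibition.** PFA scales the transcellular permeability
  by (1 − e_pfa), Tenapanor the paracellular one by (1 − e_tena); a single
  efficacy per inhibitor, no dose–response (the assay uses one dose each:
  1 mM PFA, 1 µM Tenapanor).

The ODE simulator (`simulate_ode`, DOP853 at rtol 1e-12 / atol 1e-14)
exists as an independent numerical cross-check of the closed form and as
the only solver once `leak_rate > 0`; Runge–Kutta steps preserve the linear
mass invariant to round-off, so total phosphate is conserved to ~1e-12
relative without any projection step.

## Estimators

- **Non-sink fit (default).** One-parameter bounded least squares
  (`scipy.optimize.least_squares`, xtol/ftol/gtol 1e-15) of the closed form
  against both compartments jointly, initial conditions taken from the
  observed baseline row, starting value obtained by inverting the final
  percent-of-equilibrium reading. On noiseless data it inverts the
  simulator to better than 1e-9 relative. The standard error comes from the
  Gauss–Newton approximation s²(JᵀJ)⁻¹.
- **Sink slope.** Least-squares slope of receiver amount (nmol) versus time
  over a reporting interval, divided by A·C_a0, with C_a0 the *initial*
  apical concentration (fixed, per the defining equation) rather than a
  time-varying donor concentration. Default interval 0–8 h, the assay's
  reporting window; configurable. A warning is attached whenever the
  receiver exceeds 10% of the donor anywhere in the interval (standard
  permeability-assay practice) — which this assay violates by design
  (receiver starts at 0.1 mM), motivating the non-sink default. A negative
  noise-driven slope is clamped to zero and flagged rather than reported as
  a negative permeability.
- **Replicate aggregation.** Papp is fitted per well, then summarized as
  mean ± SD (or median for recovery checks) per condition; wells are never
  pooled before fitting.
- **Inhibitor ratios.** Residual transport = 100·treated/control on
  condition means; a helper rounds to the nearest 5% for headline
  reporting (so 74.6% → 75%, 63.9% → 65%).
- **Pathway decomposition.** With arms (control, +PFA, +PFA+Tenapanor) and
  the blank-filter permeability available, overall values are converted to
  cell-layer permeabilities by subtracting the filter's series resistance,
  then `p_trans = (L_control − L_pfa)/e_pfa` and
  `p_para = (L_pfa − L_both)/e_tena`. With the default unit efficacies the
  results read as inhibitor-sensitive components (lower bounds on the
  pathways). Negative estimates — possible under noise, as in the
  endothelial arms where inhibitors have no effect — are flagged, not
  clamped. For a two-layer co-culture the inversion yields an effective
  single-layer equivalent.
- **TER.** Corrected resistance = (raw − blank)·area in Ω·cm². Readings
  below blank produce negative values that are flagged and returned as-is:
  audit trail over silent repair.
- **Mass recovery.** (Amount in both compartments + net withdrawn)/initial
  amount per time point; 1.0 within 5% passes QC. Departures indicate
  spillage, adsorption or cellular uptake.

## Synthetic-data generator

The generator emulates the study conditions: five insert layouts (blank,
endothelial apical, mesothelial apical/basolateral, co-culture), 1 mM
apical / 0.1 mM basolateral phosphate, sampling at 0/4/8/12 h, optional
PFA and PFA+Tenapanor arms, duplicative replication (default 6 wells per
condition).

**Ground-truth preset** (cm/s): blank filter 1.8e-5 (the value implied by
the blank filters reaching 78.1% of equilibrium at 12 h); mesothelial layer
p_trans = p_para = 6.8e-6, giving an overall 7.75e-6 that matches the
printed mesothelial mean of 7.74e-6; endothelial layer p_trans = 5e-6,
p_para = 6.5e-5 — a leaky, paracellular-dominated layer, so that (i) the
endothelial overall value (1.43e-5) sits between mesothelial and blank,
(ii) PFA has next to no effect on endothelial monolayers, and (iii) the
co-culture overall (6.97e-6) is only ~10% below the mesothelial value,
reproducing the finding that adding the endothelium does not further reduce
transport (the printed co-culture/mesothelial mean ratio is ≈ 0.91).
Inhibitor efficacies e_pfa = 0.2, e_tena = 0.15: deliberately partial
blockade, consistent with the observed incomplete inhibition.

**Noise model.** Per-sample Gaussian with σ = noise_sd·C + 0.005 mM: a
proportional CV (default 2%, a typical clinical-analyzer figure; the true
assay CV is unknowable from the reported data, so the recovery checks are
run at 2% and 5%) plus an additive floor representing the detection limit.
Noise applies to every sample including baseline; negative draws are
clamped at zero and the clamp count is logged. One master seed spawns
independent per-well substreams (`numpy.random.SeedSequence`), so a study
is exactly reproducible from its seed.

**Sampling withdrawal.** Default: no withdrawal. `replace_same` treats the
withdrawn aliquot as replaced at the sampled concentration (net mass change
zero — the closed form stays exact); `replace_blank` replaces with
phosphate-free medium, diluting each compartment by (V − v)/V at every
sampling and propagating the closed form piecewise, with withdrawn amounts
tracked so mass recovery stays at exactly 1.0 when the plan is honoured.

**Count matrices.** Negative-binomial raw counts (var = µ + 0.1·µ²), three
replicates per cell type, with mean profiles set so the detection calls at
threshold 100 reproduce the qualitative cell-line pattern
(SLC20A1/SLC20A2/XPR1 ~2000 everywhere; SLC34A2 400 in HPMC only; SLC34A3
300 in MeT-5A only; all others 15). Background means are kept far enough
below the threshold, and cell-specific means far enough above it, that the
pattern is stable across seeds at this replication level. The arteriole
preset uses cohort sizes 8/8/5/6 (controls/CKD5/low-GDP/high-GDP) and sets
SLC20A1's low-GDP mean to exactly twice the control mean; the tolerance
used when checking the recovered two-fold change is three delta-method
standard errors of a ratio of NB group means, computed from the configured
parameters.

What the generator does **not** emulate: carrier saturation, pH-dependent
phosphate speciation, unstirred layers, adsorption to the filter,
intracellular phosphate shifts, TER dynamics, library-size variation or
batch effects in the counts. Passing recovery tests therefore demonstrate
estimator correctness under the stated model, not robustness to these
real-data features.

## Thresholds, boundaries, tie-breaks

- Detection threshold 100 is **inclusive** (mean = 100 detected): the rule
  excludes transcripts *below* 100, so ties pass.
- LDH at exactly the 14 U/L detection limit is flagged as a cytotoxicity
  signal (conservative); censored below-limit readings are clean and never
  imputed.
- MTT viability above 100% is reported uncapped (phosphate can stimulate
  formazan reduction).
- Fold changes use raw count means (no library-size normalization) to
  mirror a raw-count presentation; a `size_factors` hook enables
  normalization and the default is a documented caveat.
- "Co-culture ≈ mesothelial" in the ordering checks is operationalised a
  priori as: co-culture median Papp not above the mesothelial median and
  within 15% of it (the preset truth ratio is 0.90).
- Serum-phosphorus conversion uses fixed atomic masses (P 30.974, O
  15.999); 4.5 mg/dL converts to 1.453 mmol/L, and checks accept the
  clinically quoted 1.45–1.46 rounding range.
- Papp unit metadata: both "×10⁻⁶ cm/s" and the occasionally printed
  "×10⁶ cm/s" are accepted, the latter reinterpreted as 10⁻⁶ with a warning
  (a permeability of 10⁶ cm/s is physically impossible).

## Problem sizes

Recovery and ordering checks use 200 wells per condition at 2% and 5%
noise (median within ±5% of truth); the ODE-vs-closed-form equivalence is
checked over 1,000 random parameter draws; the acceptance script uses 100
wells per condition. These sizes give comfortable statistical margins while
keeping a full test run in seconds.

## Known limitations

- Separate transcellular/paracellular permeabilities are unidentifiable
  from a single uninhibited curve; decomposition requires the inhibitor-arm
  design, and its accuracy is limited by how well the efficacies are known.
- The two-layer co-culture decomposition returns an effective single-layer
  equivalent, not per-layer pathway estimates.
- Inferential statistics (ANOVA and multiple-comparison procedures) are out
  of scope; the package reports descriptive means ± SD only.
- The generator's defaults encode one plausible ground truth consistent
  with the published condition means; they are not fitted to raw data
  (which are not available) and should be re-tuned for other cell systems.
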
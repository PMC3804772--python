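# Methods

## Scope and model

`noscabind` analyzes tubulin–noscapinoid binding affinity along two
routes that meet in the free energy ΔG_bind:

1. **Computational** — the linear interaction energy (LIE) empirical
   model with surface generalized Born (SGB) energy decomposition:

       ΔG_bind = α·⟨U_vdw⟩ + β·⟨U_elec⟩ + γ·⟨U_cav⟩ (+ intercept)

   where ⟨U_vdw⟩, ⟨U_elec⟩, ⟨U_cav⟩ are ensemble-average bound-minus-free
   van der Waals, electrostatic and cavity (surface-area) energies in
   kcal/mol.  These energy terms are *inputs*: they come from docking /
   ensemble-simulation software and are consumed here as tabular data.
   The coefficients are calibrated by ordinary least squares against
   experimentally measured ΔG of a training set.

2. **Experimental** — fluorescence-quench titration.  A ligand that
   quenches the receptor's intrinsic tryptophan fluorescence reports
   fractional occupancy a = ΔF/ΔF_max; single-site equilibrium binding
   gives 1/a = K_D/[free ligand] + 1, so a double-reciprocal plot yields
   K_D as its slope.  The measured K_D converts to free energy by
   ΔG = RT·ln K_D (K_D in mol/L), with R = 0.00199 kcal·mol⁻¹·K⁻¹ and
   T = 298 K by default (both overridable).

K_D is carried in µM throughout the I/O layer, matching assay
conventions; the fixed 1e-6 µM→M factor is applied only inside the
logarithm.

## LIE fit

* **No intercept by default.**  The canonical fitted equation for this
  system, ΔG = 0.072⟨U_vdw⟩ − 0.006⟨U_elec⟩ − 0.951⟨U_cav⟩, has no
  constant term; an intercept option exists for sensitivity analysis
  (≥5 rows required instead of ≥4).
* β and γ are stored signed (fitted values are negative), exactly as
  the equation above writes them.
* `r2_train` is the squared Pearson correlation between fitted and
  observed ΔG — the statistic conventionally quoted for LIE models.
  For the packaged training table it is 0.780.
* Rank deficiency is detected by a relative singular-value threshold of
  1e-10; the error names the collinear columns.
* Reproducing the published predicted-ΔG column of the designed-compound
  table deliberately uses the *rounded* printed coefficients, because
  that is what demonstrably regenerates the column (all 11 rows within
  ±0.002 kcal/mol, 10 of 11 within ±0.0005; the residual 0.001 on one
  row is an input-rounding artifact).
* The training table's own printed predicted-ΔG column is *not*
  regenerated by those coefficients (deviations 0.031–0.130 kcal/mol).
  How that column was produced is not documented in the source tables;
  `loo_predictions` (leave-one-out refits) exists to probe such schemes,
  and the reproduction report flags the column instead of asserting it.

## Quench-assay pipeline

Order of operations: inner-filter correction → ΔF_max estimation →
occupancy → double-reciprocal K_D fit.

* **Inner-filter correction** F_corr = F_obs·10^((A_ex+A_em)/2) is the
  identity when no absorbances are supplied.
* **ΔF_max** comes from unweighted OLS of 1/ΔF on 1/[total ligand];
  ΔF_max = 1/intercept, with an `UnsaturableCurveError` when the
  intercept is ≤ 0.  For the ideal (no-depletion) isotherm this
  transform is exactly linear, so noiseless data are recovered exactly.
* **Free-ligand handling.**  Default mode `total-as-free` takes free =
  total ligand — justified because the receptor (2 µM) is far below the
  K_D range of interest (tens of µM), making depletion second-order.
  `iterative-depletion` alternates free = total − a·R with refitting
  until successive K_D estimates change < 1e-6 relative (cap 100
  iterations); it is the better choice when K_D is within an order of
  magnitude of the receptor concentration.
* **Intercept.**  The reciprocal fit is unconstrained by default and the
  fitted intercept is reported as a model-consistency diagnostic; a
  constrained option pins it at the theoretical value 1.  Note a
  pipeline identity: when ΔF_max is estimated from the same points as
  the occupancy fit, the unconstrained intercept equals 1 *by
  construction* (1/a is a scalar multiple of 1/ΔF), so the diagnostic is
  only informative when ΔF_max is supplied externally or points are
  dropped between the two fits.
* **Degenerate points.**  The zero-ligand point defines F₀ and is
  excluded from reciprocal fits; points with ΔF ≤ 0 are dropped with a
  logged warning; occupancies above 1 beyond tolerance are dropped and
  logged as a data inconsistency.
* **Error amplification caveat.**  Reciprocal transforms inflate the
  influence of low-ligand points (largest 1/[L] leverage, smallest ΔF).
  Both double-reciprocal fits are unweighted OLS, so K_D estimates from
  noisy titrations carry substantially more relative error than the
  underlying fluorescence noise — the simulation studies below quantify
  this.

## Synthetic data

The generators emulate the assay and the docking-derived training
tables; they are the ground-truth oracle for every recovery test.

* **Quench titrations.**  Ideal model: a = L/(K_D+L) with L = total.
  Depletion model: free ligand solves the single-site mass balance
  quadratic L_free² + (K_D + R − L_total)·L_free − K_D·L_total = 0
  exactly (stable positive root).  Fluorescence is F = F₀ − a·ΔF_max
  plus additive Gaussian noise (instrument-like; specifiable as a
  fraction of F₀ because assay SDs scale with signal).  Optional
  Beer–Lambert absorbance columns (A = ε·L_total) are emitted with the
  attenuation applied, so the inner-filter correction can be exercised
  end-to-end.  Default grid 0, 10, 25, 50, 100, 150, 200 µM with 2 µM
  receptor, mirroring the assay.
* **Default amplitudes.**  F₀ = 500 a.u. with ΔF_max = 400 a.u. — an
  80% saturation quench.  The quench fraction is calibrated so that,
  under 1%-of-F₀ noise, replicate K_D estimates at K_D = 38 µM scatter
  with an SD of ≈5 µM, matching the ±4 µM experiment-to-experiment SD
  the assay reports; a shallower quench (e.g. 40%) would imply ±12 µM,
  inconsistent with that reported precision.
* **LIE tables.**  Covariates drawn uniformly from the observed spans
  of the packaged tables (u_vdw ∈ [−66, −46], u_elec ∈ [7, 130],
  u_cav ∈ [0.4, 2.1] kcal/mol); response = exact linear form + Gaussian
  noise.  One seeded generator per call; no global random state.
* **What the generators do not emulate:** photobleaching, drift,
  spectral bandpass effects, non-linear quenching, correlated
  between-point errors, and any systematic error in the docking-derived
  energy terms.  Passing recovery tests therefore demonstrate estimator
  correctness under the stated statistical model, not robustness to
  instrument pathologies.

## Simulation study sizes

Recovery studies use 100 replicate titrations (seeds 1–100) at the
assay grid for the headline K_D study, 60 replicates per noise level for
the noise-monotonicity check, and n = 50 compounds for the noisy LIE
recovery test; each replicate is a 7-point OLS problem, so the full
suite runs in seconds.

## Data fixtures and known inconsistencies

The four packaged tables are verbatim transcriptions; values are data,
never recomputed, and reconciliation lives in the report layer.  The
reproduction report (`noscabind reproduce`) recomputes everything
derivable and flags, rather than repairs, three standing issues:

1. The parent compound's (noscapine, id "1") K_D is printed as
   152 ± 1.0 µM beside an experimental ΔG of −5.246 kcal/mol, which
   back-converts to ≈144 µM — the value given elsewhere in the same
   source (144 ± 1.0 and 144 ± 2.8 µM).  All variants are preserved in
   `NOSCAPINE_KD_REPORTS`; table validation flags exactly this row
   (tolerance ±0.0015 kcal/mol, covering last-digit rounding).
2. The training table's predicted-ΔG column (see above).
3. The published one-way ANOVA F statistics could not be reconciled
   with the printed group means ± SD at n = 3; the report recomputes F
   from the summaries (`anova_oneway_from_summary`) for reference and
   asserts nothing about the published values.

## Limitations

* Single-site, non-cooperative binding only; no multi-site or Hill
  models.
* The primary K_D path is the linearized double-reciprocal fit (as the
  assay prescribes), not direct nonlinear isotherm fitting; at high
  noise the reciprocal transform's error amplification dominates the
  estimate's variance.
* Docking scores and SGB energy components are consumed as data;
  nothing here validates the simulations that produced them.
* IC50 and cell-cycle tables are read-only fixtures: no dose–response
  or cytometry analysis is performed.
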
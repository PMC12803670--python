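# Methods

This note documents the models, numerical choices and known limitations of
`nervefa`, module by module.

## Tensor estimation and FA

The signal model is the mono-exponential tensor model
S_i = S0·exp(−b_i gᵢᵀ D gᵢ) with D symmetric 3×3. Estimation is weighted
linear least squares (WLLS) on log-signals in two passes: an OLS pass on
ln S provides predicted signals Ŝ, and a single reweighted pass uses
weights Ŝ² — the conventional choice, since var(ln S) ≈ var(S)/S². Multiple
b=0 volumes enter the design as ordinary rows (no pre-averaging). Gradient
directions are interpreted in voxel coordinates; no gradient-to-image
rotation is applied, and the b-table reader documents this convention
rather than guessing an upstream one.

FA is computed from the eigenvalues as
FA = √(3/2)·‖λ−λ̄‖/‖λ‖, clipped to [0, 1] only against floating-point
overshoot. Negative eigenvalues from noisy fits are *retained* for the FA
computation but flagged: clipping them would bias FA low-anisotropy voxels
upward. Voxels with any nonpositive signal cannot enter the log-domain fit;
they are excluded from maps and ROI statistics and counted in the QC log.
Degenerate all-zero eigenvalue sets define FA = 0.

Defaults follow small-bore rodent imaging: b = 1000 s/mm², 30 directions +
3 b=0 volumes, 0.32×0.32×0.8 mm³ voxels, 0.8 mm slice spacing.

## Slice profiles and region segmentation

A nerve profile is the ordered per-slice (mean, SD, voxel count) of FA over
the ROI, with position = slice index × spacing (proximal→distal declared in
configuration, not inferred). Empty slices are retained as gaps and never
interpolated — the Gompertz fit consumes (x, FA) pairs and needs no uniform
grid.

Region classification is FA-only (nerve diameter is not available from a
mask-only input) and deliberately simple:

1. proximal plateau = median FA of the first `plateau_slices` (default 5);
2. injury onset = first run of **two consecutive** slices below
   plateau·(1 − `drop_fraction`) (default drop 0.20); the two-slice rule
   keeps a single noisy slice from splitting the nerve;
3. injury end = the two-constant-segment change-point that best separates
   the dip from the following slices, searched over at most
   `max_injury_mm` (default 8 mm) and compared over a `comparison_mm`
   (default 5 mm) downstream window. A boundary is admissible only when
   the downstream mean exceeds the dip mean by `min_step_fa` (default
   0.04, about twice the slice-noise SD): the injury is a *dip*, so FA
   must recover toward the distal top asymptote after it.

A below-threshold run with no admissible recovery step after it is the
terminal distal decline, not an injury; the profile is then handled like a
sham nerve: no injury run, and the terminal `sham_distal_mm` (default
15 mm, i.e. 19 slices at 0.8 mm) labeled distal. A plain
maximal-below-threshold rule was rejected because the distal top asymptote
of an acutely injured nerve (≈0.50) can itself sit below any threshold that
still catches the dip (≈0.42–0.55 against a ≈0.666 plateau), which would
merge injury and distal into one run.

Manual label files bypass the heuristic entirely and are validated only for
contiguity and order (proximal → injury → distal). Classification is
idempotent: labels are always recomputed from FA values.

## Gompertz fitting

The distal model is FA(x) = FA₀ + ΔFA·exp(−exp(−b(x − X_IP))). The fit is
bounded nonlinear least squares (trust-region reflective) on
(FA₀, ΔFA, b, X_IP), with an optional asymptote parameterization
(FA₀, FA_Target, b, X_IP) behind a switch; both report the same standard
form. ΔFA's sign is left free: regenerating nerves can show rising profiles.

Initials are data-driven: FA₀ from the mean of the first quartile of
points, FA_Target from the last quartile, X_IP at the steepest centered
finite-difference slope, b = 1 /mm. Bounds keep both asymptotes in [0, 1],
b ∈ (0.01, 10] /mm and X_IP within the sampled range ± 2 mm. All initials
and bounds are overridable, so any published initialization table can be
reproduced exactly. Five additional deterministic multi-starts jitter X_IP
across the profile quartiles and b over {0.3, 1, 3} (fixed-seed jitter);
the best solution by objective wins, which also gives the descent property
(objective at solution ≤ objective at the initial point). Tolerances are
1e-10 on objective and step, 2000 function evaluations per start.
Nonconvergence after all restarts returns a flagged record, not an
exception.

The covariance is σ̂²(JᵀJ)⁻¹ with the analytic Jacobian at the solution and
σ̂² = RSS/(n−4); SEs for FA_Target = FA₀+ΔFA and FA_IP = FA₀+ΔFA/e use the
delta method on the full covariance. Because Wald intervals undercover the
nonlinear parameters (b, X_IP) at realistic noise, `profile_confint`
provides profile-likelihood intervals: the bound for θ_j solves
RSS_profile(θ_j) = RSS_min + t²·σ̂² with the Student t quantile at n−4 df,
by bracketed root finding with the remaining three parameters re-optimized
at every evaluation. Monte-Carlo checks at slice-noise SD 0.02 put their
coverage at ≈0.92–0.96 per parameter versus ≈0.90 for Wald on X_IP.

Fits default to unweighted least squares (profiles of slice means);
1/SD² weighting is available but off by default. A fit whose 95% interval
for ΔFA contains zero is flagged degenerate (flat profile, e.g. sham or
pre-surgery) and additionally reports the constant-model mean; pipeline
tables use that mean as the level summary (FA₀ = FA_Target = FA_IP) for
degenerate fits, since the sigmoid's asymptotes are not identified there.

## SFI and uncertainty

SFI = −38.3·(EPL−NPL)/NPL + 109.5·(ETS−NTS)/NTS + 13.3·(EIT−NIT)/NIT. The
propagated SD uses the first-order delta method with *independent* errors
across the six lengths (no covariance information exists for footprint
measurements); the partial derivatives are c/N for experimental and
−cE/N² for normal lengths. Monte-Carlo cross-checks show the delta SE
within 3% of the sampling SD whenever each σ is ≤ 2% of its length.
Behavioral records carry days; the day-3 session exists only on the
behavioral side and is never joined to MRI.

## Longitudinal statistics

SFI joins MRI sessions by exact week (week 0 = pre-surgery baselines,
included by default with a flag to exclude). Pearson correlations pool all
animals and timepoints — the between-animal spread is part of the signal
being summarized — with exact t-transform p-values and Bonferroni
correction over the fixed family of five parameters (FA₀, FA_IP, ΔFA,
FA_Target, X_IP); zero-variance inputs yield an undefined (NaN) r rather
than 0. The within-subject complement is a repeated-measures ANOVA: SFI on
the parameter plus one intercept per animal, F = SS_cov/(SS_res/df₂) with
df₂ = n_obs − n_animals − 1 (63 observations from 9 animals × 7 sessions
give df (1, 53)). It is computed by within-animal centering, which is the
exact projection; it matches `statsmodels` OLS type-II F to machine
precision and a planted-null simulation puts its type-I error at ≈0.04.

## Synthetic cohorts

The generator emulates a 12-week rodent cut/repair study: 2 sham + 7
cut/repair animals, MRI at weeks 0, 2, …, 12, SFI at day 0, day 3 and
weekly. A latent per-animal recovery fraction ρ(t) = exp(−exp(−k(t−t₀)))
(k ∈ [0.30, 0.45] /wk, t₀ ∈ [5, 8] wk) drives both modalities, so planted
FA–SFI correlations exist by construction:

* distal parameters: FA₀ = 0.50 + 0.10ρ, FA_Target = 0.38 + 0.22ρ
  (injured → sham-like ≈0.60), b ∈ [0.6, 1.0] /mm and X_IP ≈ 7 ± 1 mm per
  animal;
* injury dip FA = 0.42 + 0.20ρ against a 0.666 proximal plateau — acutely
  deep (active degeneration), recovering toward plateau-like values, with
  a study-average near 0.55;
* SFI: day-3 deficit uniform in [−108, −82] recovering toward a per-animal
  asymptote in [−45, −25]; sham animals fluctuate in [−30, 0]. Weekly
  observation noise (SD 4, matching the delta-method SE of 0.5 mm
  footprint errors) is folded into the target *before* footprint lengths
  are back-solved, so the envelopes hold by construction and
  `compute_sfi` reproduces the recorded trajectory exactly. Back-solving
  shrinks both toe spreads by a common fraction and lengthens the print by
  half of it; the normal side is fixed at NPL 30, NTS 20, NIT 10 mm.

Slice-mean FA noise is additive Gaussian (SD 0.02) clipped to [0, 1]. The
DWI phantom is a thin cylinder of prolate tensors (axis along the slice
direction, trace fixed at 2.1×10⁻³ mm²/s, the axial eigenvalue root-solved
from the target FA) with Gaussian magnitude noise at a stated SNR — Rician
bias is deliberately not modeled. Every output is a deterministic function
of (design, seed).

What the generator does **not** emulate: anatomical curvature and caliber
changes, partial-volume effects at the nerve boundary, correlated
slice-to-slice noise, scanner drift between sessions, and Rician noise.
Passing tests therefore demonstrate the estimators' correctness and the
chain's statistical behavior under the stated noise model, not robustness
to all real-data artifacts.

## Problem sizes

Verification studies use 200 Monte-Carlo replicates for fit bias/coverage,
100 profiles for boundary recovery, 500 simulations for the ANOVA type-I
error, 10⁵ draws for the SFI Monte-Carlo, and one default 9-animal cohort
(63 fits) for the end-to-end study.

## Known limitations

* The segmentation heuristic needs a resolvable dip-to-distal recovery
  step; a late-recovery nerve whose dip has healed past the threshold is
  classified as injury-free (the terminal-15 mm convention then still
  isolates the correct distal segment).
* MD/AD/RD maps, eddy/motion/EPI corrections, denoising and tractography
  are out of scope.
* The RM-ANOVA uses per-animal intercepts only (no random slopes).
* Profile-likelihood intervals are reported per parameter; no simultaneous
  confidence region is provided.
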
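# nervefa

Gompertz-based fractional-anisotropy (FA) profilometry for monitoring
peripheral-nerve regeneration from diffusion MRI, with behavioral
validation against the sciatic functional index (SFI).

## The problem

After a nerve transection and surgical repair, axons distal to the injury
degenerate (Wallerian degeneration) and then slowly regrow toward the
target muscle. Diffusion tensor imaging tracks this process: FA — the
normalized dispersion of the diffusion-tensor eigenvalues, 0 for isotropic
to 1 for stick-like diffusion — falls where axonal structure is lost and
recovers as axons regenerate. Along an injured sciatic nerve the slice-wise
FA profile shows three regions: a high proximal plateau, a sharp dip at the
injury site, and a distal segment whose FA declines sigmoidally with
distance from the injury. `nervefa` models that distal decline with the
Gompertz function

    FA(x) = FA₀ + ΔFA · exp(−exp(−b · (x − X_IP)))

where x is distance (mm) along the distal segment, FA₀ is the top asymptote
near the injury, FA_Target = FA₀ + ΔFA the far asymptote, b (1/mm) the
slope, X_IP the inflection position and FA_IP = FA₀ + ΔFA/e the FA at the
inflection. The five derived quantities are compact biomarkers of distal
nerve state that can be followed over weeks and correlated with gait-based
recovery:

    SFI = −38.3·(EPL−NPL)/NPL + 109.5·(ETS−NTS)/NTS + 13.3·(EIT−NIT)/NIT

computed from six footprint lengths (print length, toe spread, intermediary
toe spread; experimental vs normal side), ≈0 healthy, ≈−100 fully impaired.

## What the package does

* `nervefa.tensor_model` — voxel-wise diffusion-tensor estimation from 4-D
  DWI (NIfTI + FSL-style bval/bvec) by two-pass weighted linear least
  squares on log-signals; FA maps with QC logging.
* `nervefa.profile` — slice-wise ROI FA statistics; automated
  proximal/injury/distal classification (threshold drop + change-point
  recovery step), with manual label files as first-class override; distal
  segment extraction.
* `nervefa.gompertz` — bounded nonlinear least-squares Gompertz fits with
  data-driven initials, deterministic multi-starts, Jacobian-based
  covariance, delta-method SEs for derived quantities, and
  profile-likelihood confidence intervals.
* `nervefa.behavior` — SFI and its delta-method uncertainty from
  per-measurement SDs.
* `nervefa.stats` — animal × week joining of SFI to MRI sessions, pooled
  Pearson correlations with Bonferroni correction (family of 5), and a
  repeated-measures ANOVA with the animal as error term
  (df = (1, n_obs − n_animals − 1)).
* `nervefa.synthetic` — synthetic cohorts (biweekly MRI weeks 0–12, weekly
  SFI plus a day-3 session; 2 sham + 7 cut/repair animals by default) with
  a latent per-animal recovery process linking FA and SFI, plus a DWI
  phantom generator, so the full chain is testable without any data
  download.
* `nervefa pipeline` CLI — `simulate`, `fit-tensor`, `profile`, `segment`,
  `fit-gompertz`, `sfi`, `stats`, `pipeline` subcommands.

## Worked example

```python
import numpy as np
from nervefa import GompertzParams, fit_gompertz, gompertz_eval
from nervefa.synthetic import simulate_distal_profile

truth = GompertzParams(fa0=0.55, dfa=-0.15, rate_b=0.8, x_ip=7.0)
distal = simulate_distal_profile(truth, n_slices=20, spacing=0.8,
                                 noise_sd=0.02, seed=1)
fit = fit_gompertz(distal)
print(f"FA0       = {fit.params.fa0:.3f} +/- {fit.derived.se['fa0']:.3f}")
print(f"FA_target = {fit.derived.fa_target:.3f} +/- {fit.derived.se['fa_target']:.3f}")
print(f"FA_ip     = {fit.derived.fa_ip:.3f}")
print(f"X_ip      = {fit.params.x_ip:.2f} mm")
```

prints

```
FA0       = 0.553 +/- 0.004
FA_target = 0.395 +/- 0.005
FA_ip     = 0.495
X_ip      = 7.15 mm
```

FA near the injury-side end of the distal segment sits at ≈0.55 and falls
to ≈0.40 toward the muscle, with the inflection ≈7 mm along the segment —
the fitted values recover the simulated truth within their standard
errors. Running the whole chain instead:

```sh
nervefa simulate --out cohort --seed 1
nervefa pipeline --cohort cohort --out results
```

writes per-fit Gompertz tables, SFI scores, the joined longitudinal table
and the correlation/ANOVA reports (e.g. pooled FA₀–SFI Pearson r ≈ 0.90
with Bonferroni-adjusted p ≪ 0.05, and an F(1, 53) ≈ 196 for FA₀ with 9
animals × 7 sessions).

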
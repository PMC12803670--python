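"""Synthetic cohorts with the statistical structure of a rat sciatic-nerve
cut/repair study.

The generator emulates the longitudinal design the pipeline assumes:
biweekly MRI at weeks 0-12 and weekly behavioral (SFI) testing plus one
3-day post-surgery session, for a cohort of sham (n=2) and cut/repair
(n=7) animals.

A latent per-animal recovery fraction rho(t) in [0, 1], itself following
a Gompertz curve in time, links imaging to behavior so that planted
FA-SFI correlations exist:

* distal Gompertz parameters interpolate from the acutely injured state
  (FA0 ~ 0.50, FA_target ~ 0.38) toward the sham-like state (both ~ 0.60)
  as rho -> 1;
* the injury-site FA dip recovers from ~0.42 acutely toward ~0.62 (its
  time average over the study is ~0.55), against a proximal plateau of
  ~0.666;
* the SFI trajectory runs from a day-3 deficit in [-110, -80] toward a
  per-animal recovery asymptote, staying within the observed cohort
  envelopes (sham in [-30, 0] throughout; cut/repair reaching [-75, -25]
  by week 12).

Footprint lengths are back-solved so that the SFI formula reproduces the
target trajectory (plus measurement noise folded into the target before
back-solving); the normal side is held at NPL 30 mm, NTS 20 mm, NIT 10 mm.
Slice-mean FA noise is additive Gaussian (default SD 0.02).  A DWI
phantom builder turns a truth FA profile into a thin cylinder of prolate
tensors (trace fixed at 2.1e-3 mm^2/s) so the tensor stage runs end to
end.  All outputs are deterministic functions of (design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from nervefa.gompertz import GompertzParams, gompertz_eval
from nervefa.profile import DistalProfile, NerveProfile, NerveSliceStat
from nervefa.tensor_model import DiffusionProtocol, TensorEstimate, predict_signal

__all__ = [
    "CohortDesign",
    "simulate_distal_profile",
    "simulate_full_profile",
    "simulate_cohort",
    "simulate_dwi_phantom",
    "default_protocol",
    "prolate_eigenvalues",
]

# normal-side footprint lengths (mm) held fixed when back-solving SFI
NORMAL_LENGTHS = {"npl": 30.0, "nts": 20.0, "nit": 10.0}
FOOTPRINT_SIGMA_MM = 0.5

# injured-state and sham-like distal Gompertz levels
FA0_INJURED, FA0_SHAM = 0.50, 0.60
FATARGET_INJURED, FATARGET_SHAM = 0.38, 0.60
PROXIMAL_FA = 0.666
INJURY_FA_ACUTE, INJURY_FA_RECOVERED = 0.42, 0.62


@dataclass(frozen=True)
class CohortDesign:
    """Study design constants; defaults mirror the emulated experiment."""

    n_sham: int = 2
    n_cut_repair: int = 7
    mri_weeks: tuple = (0, 2, 4, 6, 8, 10, 12)
    sfi_days: tuple = (0, 3) + tuple(7 * w for w in range(1, 13))
    slice_spacing: float = 0.8
    noise_sd_fa: float = 0.02
    n_proximal: int = 25
    n_injury: int = 4
    n_distal: int = 19
    seed: int = 0

    def __post_init__(self):
        if self.n_sham < 0 or self.n_cut_repair < 0:
            raise ValueError("animal counts must be nonnegative")
        if list(self.mri_weeks) != sorted(self.mri_weeks):
            raise ValueError("mri_weeks must be sorted ascending")
        if list(self.sfi_days) != sorted(self.sfi_days):
            raise ValueError("sfi_days must be sorted ascending")
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")


def simulate_distal_profile(params: GompertzParams, n_slices: int = 19,
                            spacing: float = 0.8, noise_sd: float = 0.02,
                            seed: int = 0) -> DistalProfile:
    """Sample a distal FA profile: Gompertz curve + i.i.d. Gaussian noise,
    clipped to [0, 1]."""
    if n_slices < 6:
        raise ValueError("need at least 6 slices")
    rng = np.random.default_rng(seed)
    x = np.arange(n_slices) * spacing
    fa = gompertz_eval(params, x)
    if noise_sd > 0:
        fa = fa + rng.normal(0.0, noise_sd, size=n_slices)
    fa = np.clip(fa, 0.0, 1.0)
    return DistalProfile(x=x, fa_mean=fa, fa_sd=np.full(n_slices, noise_sd))


def simulate_full_profile(distal_params: GompertzParams | None,
                          injury_fa: float | None = INJURY_FA_ACUTE,
                          proximal_fa: float = PROXIMAL_FA,
                          n_proximal: int = 25, n_injury: int = 4,
                          n_distal: int = 19, spacing: float = 0.8,
                          noise_sd: float = 0.02, seed: int = 0,
                          subject_id: str | None = None,
                          timepoint_weeks: float | None = None,
                          sham_distal_fa: float = FA0_SHAM):
    """Build a full-nerve profile (proximal plateau, injury dip, distal
    sigmoid) with known region boundaries.

    With ``injury_fa=None`` (sham / pre-surgery) the injury run is omitted
    and the distal segment is flat at ``sham_distal_fa`` (or at the given
    distal_params).  Returns ``(profile, truth)`` where truth holds the
    planted boundary indices and slice-wise noiseless FA.
    """
    rng = np.random.default_rng(seed)
    pieces = [np.full(n_proximal, proximal_fa)]
    if injury_fa is not None:
        pieces.append(np.full(n_injury, injury_fa))
        injury_start, injury_end = n_proximal, n_proximal + n_injury
    else:
        injury_start = injury_end = n_proximal
    xd = np.arange(n_distal) * spacing
    if distal_params is not None:
        pieces.append(gompertz_eval(distal_params, xd))
    else:
        pieces.append(np.full(n_distal, sham_distal_fa))
    clean = np.concatenate(pieces)
    noisy = np.clip(clean + rng.normal(0.0, noise_sd, clean.size), 0.0, 1.0)
    slices = [
        NerveSliceStat(index=i, position=i * spacing, fa_mean=float(v),
                       fa_sd=noise_sd, n_voxels=12)
        for i, v in enumerate(noisy)
    ]
    profile = NerveProfile(slices=slices, slice_spacing=spacing,
                           subject_id=subject_id, timepoint_weeks=timepoint_weeks)
    truth = {
        "injury_start": injury_start,
        "injury_end": injury_end,
        "distal_start": injury_end,
        "fa_clean": clean,
    }
    return profile, truth


def _rho(t_weeks, k, t0):
    """Latent recovery fraction: Gompertz in time, ~0 acutely, ->1 late."""
    return float(np.exp(-np.exp(-k * (t_weeks - t0))))


def _footprints_for_sfi(target_sfi: float) -> dict:
    """Back-solve experimental footprint lengths reproducing a target SFI.

    Deficit structure: toe spreads (TS, IT) shrink by a common fraction v
    while print length grows by half that fraction (toes drag, prints
    lengthen), giving SFI = 141.95 v exactly under the formula weights.
    """
    v = target_sfi / 141.95
    npl, nts, nit = NORMAL_LENGTHS["npl"], NORMAL_LENGTHS["nts"], NORMAL_LENGTHS["nit"]
    return {
        "npl": npl, "nts": nts, "nit": nit,
        "epl": npl * (1.0 - 0.5 * v),
        "ets": nts * (1.0 + v),
        "eit": nit * (1.0 + v),
    }


def simulate_cohort(design: CohortDesign = CohortDesign()):
    """Generate one cohort: per-animal/week full-nerve profiles, a footprint
    table, and a truth record of every latent value.

    Returns ``(profiles, footprints, truth)``: profiles is a dict mapping
    (animal_id, week) -> NerveProfile; footprints is a DataFrame in the
    behavioral-table format (with sigma_* columns); truth is a nested
    dict keyed by animal.
    """
    rng = np.random.default_rng(design.seed)
    profiles: dict = {}
    fp_rows = []
    truth: dict = {"design": asdict(design), "animals": {}}

    animals = [(f"sham{i+1:02d}", "sham") for i in range(design.n_sham)] + [
        (f"cr{i+1:02d}", "cut_repair") for i in range(design.n_cut_repair)
    ]
    # delta-method SD of SFI at the normal-side defaults with 0.5 mm sigmas
    sfi_noise_sd = 4.0

    for animal_id, cohort in animals:
        a_truth = {"cohort": cohort, "weeks": {}, "sfi": {}}
        if cohort == "cut_repair":
            k = rng.uniform(0.30, 0.45)
            t0 = rng.uniform(5.0, 8.0)
            s3 = rng.uniform(-108.0, -82.0)     # day-3 deficit
            s_rec = rng.uniform(-45.0, -25.0)   # recovery asymptote
            a_truth.update(recovery_rate=k, recovery_midpoint_weeks=t0,
                           sfi_acute=s3, sfi_recovered=s_rec)
        baseline_sfi = rng.uniform(-20.0, -5.0)
        rate_b = rng.uniform(0.6, 1.0)
        x_ip = 7.0 + rng.uniform(-1.0, 1.0)

        # --- imaging sessions ---
        for week in design.mri_weeks:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if cohort == "sham" or week == 0:
                params = GompertzParams(FA0_SHAM, 0.0, rate_b, x_ip)
                profile, ptruth = simulate_full_profile(
                    None, injury_fa=None,
                    n_proximal=design.n_proximal + design.n_injury,
                    n_injury=0, n_distal=design.n_distal,
                    spacing=design.slice_spacing, noise_sd=design.noise_sd_fa,
                    seed=sub_seed, subject_id=animal_id, timepoint_weeks=week,
                    sham_distal_fa=FA0_SHAM,
                )
                rho = 1.0
            else:
                rho = _rho(week, k, t0)
                fa0 = FA0_INJURED + rho * (FA0_SHAM - FA0_INJURED)
                fa_target = FATARGET_INJURED + rho * (FATARGET_SHAM - FATARGET_INJURED)
                params = GompertzParams(fa0, fa_target - fa0, rate_b, x_ip)
                injury_fa = INJURY_FA_ACUTE + rho * (INJURY_FA_RECOVERED - INJURY_FA_ACUTE)
                profile, ptruth = simulate_full_profile(
                    params, injury_fa=injury_fa,
                    n_proximal=design.n_proximal, n_injury=design.n_injury,
                    n_distal=design.n_distal, spacing=design.slice_spacing,
                    noise_sd=design.noise_sd_fa, seed=sub_seed,
                    subject_id=animal_id, timepoint_weeks=week,
                )
            profiles[(animal_id, week)] = profile
            a_truth["weeks"][int(week)] = {
                "rho": rho,
                "fa0": params.fa0,
                "dfa": params.dfa,
                "fa_target": params.fa_target,
                "fa_ip": params.fa_ip,
                "rate_b": params.rate_b,
                "x_ip": params.x_ip,
                "injury_start": ptruth["injury_start"],
                "injury_end": ptruth["injury_end"],
            }

        # --- behavioral sessions ---
        for day in design.sfi_days:
            week = day / 7.0
            if cohort == "sham" or day == 0:
                target = baseline_sfi + rng.uniform(-4.0, 4.0)
                observed = float(np.clip(target + rng.normal(0, sfi_noise_sd), -29.0, -1.0))
            else:
                rho_b = _rho(week, k, t0)
                target = s3 + rho_b * (s_rec - s3)
                observed = float(np.clip(target + rng.normal(0, sfi_noise_sd), -114.0, -25.0))
                if day == 3:
                    observed = float(np.clip(observed, -114.0, -76.0))
            lengths = _footprints_for_sfi(observed)
            fp_rows.append({
                "animal_id": animal_id, "timepoint_days": day, **lengths,
                **{f"sigma_{f}": FOOTPRINT_SIGMA_MM for f in
                   ("npl", "epl", "nts", "ets", "nit", "eit")},
            })
            a_truth["sfi"][int(day)] = {"target": float(target), "observed": observed}
        truth["animals"][animal_id] = a_truth

    footprints = pd.DataFrame(fp_rows)
    return profiles, footprints, truth


# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------

def default_protocol(n_directions: int = 30, n_b0: int = 3,
                     b: float = 1000.0) -> DiffusionProtocol:
    """A b = 1000 s/mm^2 protocol with n_b0 leading b=0 volumes and
    directions spread by a deterministic Fibonacci sphere."""
    i = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_directions
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionProtocol(bvals, directions)


def prolate_eigenvalues(fa: float, trace: float = 2.1e-3) -> np.ndarray:
    """Solve (l1, lt, lt) with l1 + 2 lt = trace reproducing a target FA.

    For an axially symmetric tensor FA = (l1 - lt) / sqrt(l1^2 + 2 lt^2);
    l1 is found by root solving on (trace/3, trace).  FA outside [0, 1)
    is unreachable and raises.
    """
    if not (0.0 <= fa < 1.0):
        raise ValueError(f"target FA {fa} unreachable for a positive prolate tensor")
    if fa == 0.0:
        return np.full(3, trace / 3.0)

    def f(l1):
        lt = (trace - l1) / 2.0
        return (l1 - lt) / math.sqrt(l1**2 + 2 * lt**2) - fa

    l1 = brentq(f, trace / 3.0 + 1e-18, trace * (1 - 1e-12), xtol=1e-18)
    lt = (trace - l1) / 2.0
    return np.array([l1, lt, lt])


def simulate_dwi_phantom(slice_fa: np.ndarray, protocol: DiffusionProtocol,
                         snr: float | None = None, seed: int = 0,
                         grid_size: int = 12, radius: float = 2.2,
                         s0: float = 1000.0, trace: float = 2.1e-3):
    """Build a 4-D DWI volume of a thin cylindrical "nerve".

    The nerve runs along the slice (z) axis; every in-cylinder voxel of
    slice k holds a prolate tensor (axis along z) whose FA equals
    ``slice_fa[k]``.  Background voxels are isotropic at the same trace.
    Gaussian noise of SD s0/snr is added to the magnitudes (``snr=None``
    for noiseless).  Returns ``(dwi, nerve_mask)``.
    """
    slice_fa = np.asarray(slice_fa, dtype=float)
    n_slices = slice_fa.size
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    c = (grid_size - 1) / 2.0
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= radius**2

    dwi = np.empty((grid_size, grid_size, n_slices, protocol.n_volumes))
    iso = TensorEstimate(components=np.array([trace / 3] * 3 + [0.0] * 3), s0=s0)
    bg_signal = predict_signal(iso, protocol)
    mask = np.zeros((grid_size, grid_size, n_slices), dtype=bool)
    for k in range(n_slices):
        lam = prolate_eigenvalues(slice_fa[k], trace)
        # principal axis along z
        comps = np.array([lam[1], lam[1], lam[0], 0.0, 0.0, 0.0])
        sig = predict_signal(TensorEstimate(components=comps, s0=s0), protocol)
        dwi[..., k, :] = bg_signal
        dwi[disk, k, :] = sig
        mask[disk, k] = True
    if snr is not None:
        rng = np.random.default_rng(seed)
        dwi = dwi + rng.normal(0.0, s0 / snr, size=dwi.shape)
        dwi = np.clip(dwi, 1e-6, None)
    return dwi, mask


def write_phantom_nifti(dwi: np.ndarray, mask: np.ndarray,
                        protocol: DiffusionProtocol, out_dir: str | Path,
                        voxel_size=(0.32, 0.32, 0.8)) -> dict:
    """Write the phantom as NIfTI + FSL b-table so the file-based pipeline
    entry points can consume it.  Returns the created paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size) + [1.0])
    paths = {
        "dwi": out_dir / "dwi.nii",
        "mask": out_dir / "mask.nii",
        "bval": out_dir / "dwi.bval",
        "bvec": out_dir / "dwi.bvec",
    }
    nib.save(nib.Nifti1Image(dwi.astype(np.float32), affine), str(paths["dwi"]))
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(paths["mask"]))
    protocol.to_fsl(paths["bval"], paths["bvec"])
    return {k: str(v) for k, v in paths.items()}
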
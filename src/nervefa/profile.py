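"""Slice-wise FA profiles along the nerve and region segmentation.

A nerve profile is the ordered sequence of per-slice ROI statistics
(mean FA, SD, voxel count) along the proximal-to-distal axis.  Slices are
classified into three contiguous regions — proximal, injury, distal —
either from a user-supplied label file (reproducing a manual workflow) or
by an FA-only heuristic:

* the proximal plateau level is the median FA of the first ``plateau_slices``
  slices;
* the injury onset is the first slice whose FA falls below
  ``plateau * (1 - drop_fraction)`` (transection sites show a sharp FA drop);
* the injury end is found by a two-segment change-point fit, because the
  distal segment's top asymptote can itself sit below the drop threshold:
  within a bounded search window the boundary minimizing the two-constant-
  segment residual sum of squares, with the downstream mean above the dip
  mean, separates the injury dip from the start of the distal sigmoid.

Sham-like profiles with no detectable drop are labeled with an empty
injury run and a terminal distal segment of ``sham_distal_mm`` (matching
the convention of taking the ~15 mm closest to the target muscle as the
distal region).

The distal segment is then re-origined so its first slice is x = 0 mm,
increasing toward the muscle — the independent variable of the Gompertz
fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "NerveSliceStat",
    "NerveProfile",
    "DistalProfile",
    "SegmentationParams",
    "slice_statistics",
    "classify_regions",
    "extract_distal",
    "read_profile_table",
    "write_profile_table",
]

REGIONS = ("proximal", "injury", "distal", "unassigned")


@dataclass(frozen=True)
class NerveSliceStat:
    """Per-slice ROI statistics; position = index * slice_spacing (mm)."""

    index: int
    position: float
    fa_mean: float
    fa_sd: float
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be positive")
        if self.fa_sd < 0:
            raise ValueError("fa_sd must be nonnegative")


@dataclass
class NerveProfile:
    """Ordered per-slice FA statistics with optional region labels.

    ``region_labels`` when assigned form three contiguous runs in the
    order proximal -> injury -> distal (the injury run may be empty).
    Missing slices appear as gaps in ``index``; positions stay strictly
    increasing.
    """

    slices: list
    slice_spacing: float = 0.8
    region_labels: list | None = None
    subject_id: str | None = None
    timepoint_weeks: float | None = None
    no_injury_detected: bool = False

    def __post_init__(self):
        idx = [s.index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice indices must be strictly increasing")
        if self.region_labels is not None:
            if len(self.region_labels) != len(self.slices):
                raise ValueError("one region label per slice required")
            _check_contiguous(self.region_labels)

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.slices])

    @property
    def fa_means(self) -> np.ndarray:
        return np.array([s.fa_mean for s in self.slices])

    @property
    def fa_sds(self) -> np.ndarray:
        return np.array([s.fa_sd for s in self.slices])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "slice_index": [s.index for s in self.slices],
                "position_mm": [s.position for s in self.slices],
                "fa_mean": [s.fa_mean for s in self.slices],
                "fa_sd": [s.fa_sd for s in self.slices],
                "n_voxels": [s.n_voxels for s in self.slices],
            }
        )
        if self.region_labels is not None:
            df["region"] = list(self.region_labels)
        return df


@dataclass
class DistalProfile:
    """Distal-segment FA profile with x re-origined to 0 at its first slice."""

    x: np.ndarray
    fa_mean: np.ndarray
    fa_sd: np.ndarray
    parent_ref: NerveProfile | None = None
    parent_indices: np.ndarray | None = None
    subject_id: str | None = None
    timepoint_weeks: float | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.fa_mean = np.asarray(self.fa_mean, dtype=float)
        self.fa_sd = np.asarray(self.fa_sd, dtype=float)
        if self.x.size and abs(self.x[0]) > 1e-12:
            raise ValueError("distal x must start at 0")

    def __len__(self) -> int:
        return int(self.x.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_mm": self.x, "fa_mean": self.fa_mean, "fa_sd": self.fa_sd})


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the FA-only region heuristic.

    plateau_slices: slices used for the proximal plateau median.
    drop_fraction: fractional FA drop below plateau flagging injury onset.
    max_injury_mm: search window for the injury end change-point.
    comparison_mm: downstream window length for the change-point fit.
    min_step_fa: smallest dip-to-distal FA recovery step accepted as an
        injury/distal boundary (steps below this are slice noise).
    sham_distal_mm: terminal distal extent when no injury is detected.
    """

    plateau_slices: int = 5
    drop_fraction: float = 0.20
    max_injury_mm: float = 8.0
    comparison_mm: float = 5.0
    min_step_fa: float = 0.04
    sham_distal_mm: float = 15.0


def _check_contiguous(labels) -> None:
    order = {"proximal": 0, "injury": 1, "distal": 2}
    seen = [order[l] for l in labels if l in order]
    if any(b < a for a, b in zip(seen, seen[1:])):
        raise ValueError("labels must form contiguous runs proximal -> injury -> distal")


def slice_statistics(fa_map, roi_mask: np.ndarray, slice_axis: int = 2,
                     slice_spacing: float = 0.8, subject_id: str | None = None,
                     timepoint_weeks: float | None = None) -> NerveProfile:
    """Compute per-slice mean/SD FA over the masked voxels of each slice.

    Slices with an empty mask become gaps (no NerveSliceStat emitted).
    The mask must be nonempty on at least 8 slices and share the FA grid.
    """
    values = np.asarray(fa_map.values if hasattr(fa_map, "values") else fa_map, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != values.shape:
        raise ValueError("ROI mask and FA map are on different grids")
    if hasattr(fa_map, "mask"):
        roi_mask = roi_mask & fa_map.mask
    if not roi_mask.any():
        raise ValueError("ROI mask selects no voxels")

    n_slices = values.shape[slice_axis]
    stats = []
    for k in range(n_slices):
        sl = [slice(None)] * values.ndim
        sl[slice_axis] = k
        m = roi_mask[tuple(sl)]
        if not m.any():
            continue
        vox = values[tuple(sl)][m]
        vox = vox[np.isfinite(vox)]
        if vox.size == 0:
            continue
        stats.append(
            NerveSliceStat(
                index=k,
                position=k * slice_spacing,
                fa_mean=float(vox.mean()),
                fa_sd=float(vox.std(ddof=1)) if vox.size > 1 else 0.0,
                n_voxels=int(vox.size),
            )
        )
    if len(stats) < 8:
        raise ValueError(f"mask nonempty on only {len(stats)} slices; need >= 8")
    return NerveProfile(slices=stats, slice_spacing=slice_spacing,
                        subject_id=subject_id, timepoint_weeks=timepoint_weeks)


def classify_regions(profile: NerveProfile,
                     params: SegmentationParams = SegmentationParams(),
                     labels: list | None = None) -> NerveProfile:
    """Label each slice proximal / injury / distal.

    If ``labels`` is given (e.g. loaded from a manual-classification
    file), it is validated and echoed verbatim, bypassing the heuristic.
    The heuristic is idempotent: labels are recomputed from FA values
    only.
    """
    if labels is not None:
        _check_contiguous(labels)
        if len(labels) != len(profile):
            raise ValueError("one label per slice required")
        return replace(profile, region_labels=list(labels))

    n = len(profile)
    if n < 8:
        raise ValueError("segmentation needs at least 8 slices")
    fa = profile.fa_means
    spacing = profile.slice_spacing

    plateau = float(np.median(fa[: params.plateau_slices]))
    threshold = plateau * (1.0 - params.drop_fraction)

    # injury onset: two consecutive below-threshold slices (a single noisy
    # slice must not split the nerve), leaving room for a distal run
    below = fa < threshold
    run2 = np.nonzero(below[:-1] & below[1:])[0]
    start = int(run2[0]) if run2.size else None
    if start is not None and n - start < 8:
        start = None
    end = _injury_end(fa, start, spacing, params) if start is not None else None
    if end is None:
        # sham-like (no drop), or a terminal decline with no recovery step
        # after it (the distal sigmoid tail, not an injury dip): terminal
        # ~sham_distal_mm is labeled distal by convention
        n_distal = min(n, math.ceil(params.sham_distal_mm / spacing))
        lab = ["proximal"] * (n - n_distal) + ["distal"] * n_distal
        return replace(profile, region_labels=lab, no_injury_detected=True)

    lab = ["proximal"] * start + ["injury"] * (end - start) + ["distal"] * (n - end)
    return replace(profile, region_labels=lab, no_injury_detected=False)


def _injury_end(fa: np.ndarray, start: int, spacing: float,
                params: SegmentationParams) -> int | None:
    """First distal slice after the injury dip, or None if the drop is not
    a dip.

    Candidate boundaries t in (start, start + max window] are scored by the
    residual sum of squares of two constant segments: the dip fa[start:t]
    and the following comparison window fa[t:t+w].  Only boundaries whose
    downstream mean exceeds the dip mean (FA recovery toward the distal
    top asymptote) are admissible; with none, the below-threshold run is a
    terminal decline rather than an injury dip and None is returned.
    """
    n = fa.size
    w = max(2, round(params.comparison_mm / spacing))
    t_max = min(n - 1, start + max(1, round(params.max_injury_mm / spacing)))
    best_t, best_sse = None, np.inf
    for t in range(start + 1, t_max + 1):
        seg_a = fa[start:t]
        seg_b = fa[t: min(n, t + w)]
        if seg_b.size < 2:
            break
        if seg_b.mean() - seg_a.mean() < params.min_step_fa:
            continue
        sse = float(np.sum((seg_a - seg_a.mean()) ** 2) + np.sum((seg_b - seg_b.mean()) ** 2))
        if sse < best_sse:
            best_sse, best_t = sse, t
    return best_t


def extract_distal(profile: NerveProfile) -> DistalProfile:
    """Isolate the distal run with positions re-origined to x=0 at its first
    slice.  Gaps inside the run are preserved (missing x), not interpolated."""
    if profile.region_labels is None:
        raise ValueError("profile must be labeled before distal extraction")
    idx = [i for i, l in enumerate(profile.region_labels) if l == "distal"]
    if not idx:
        raise ValueError(
            f"empty distal run for subject={profile.subject_id!r} "
            f"timepoint={profile.timepoint_weeks!r}"
        )
    pos = profile.positions[idx]
    return DistalProfile(
        x=pos - pos[0],
        fa_mean=profile.fa_means[idx],
        fa_sd=profile.fa_sds[idx],
        parent_ref=profile,
        parent_indices=np.array([profile.slices[i].index for i in idx]),
        subject_id=profile.subject_id,
        timepoint_weeks=profile.timepoint_weeks,
    )


def read_profile_table(path, slice_spacing: float | None = None,
                       subject_id: str | None = None,
                       timepoint_weeks: float | None = None) -> NerveProfile:
    """Read a tabular profile (CSV/TSV, header required) with columns
    slice_index, position_mm, fa_mean, fa_sd, n_voxels [, region]."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"slice_index", "position_mm", "fa_mean", "fa_sd", "n_voxels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    if slice_spacing is None:
        diffs = np.diff(df["position_mm"]) / np.maximum(np.diff(df["slice_index"]), 1)
        slice_spacing = float(np.median(diffs)) if len(df) > 1 else 0.8
    slices = [
        NerveSliceStat(int(r.slice_index), float(r.position_mm), float(r.fa_mean),
                       float(r.fa_sd), int(r.n_voxels))
        for r in df.itertuples()
    ]
    labels = list(df["region"]) if "region" in df.columns else None
    return NerveProfile(slices=slices, slice_spacing=slice_spacing,
                        region_labels=labels, subject_id=subject_id,
                        timepoint_weeks=timepoint_weeks)


def write_profile_table(profile: NerveProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)
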
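"""Diffusion-tensor estimation and fractional anisotropy.

Per-voxel tensors are estimated from diffusion-weighted (DW) signals by
weighted linear least squares (WLLS) on log-signals: an ordinary
least-squares pass provides predicted signals, whose squares are used as
weights in a single reweighted pass.  This is the standard two-pass WLLS
estimator for the mono-exponential tensor model

    S_i = S0 * exp(-b_i g_i^T D g_i)

with D a symmetric 3x3 tensor.  Fractional anisotropy (FA) is the
normalized dispersion of the tensor eigenvalues, ranging from 0
(isotropic diffusion) to 1 (stick-like diffusion).

Gradient directions are interpreted in voxel coordinates; no
gradient-to-image rotation is applied.  Multiple b=0 volumes enter the
design matrix as ordinary b=0 rows (no pre-averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib

__all__ = [
    "DiffusionProtocol",
    "TensorEstimate",
    "ScalarMap",
    "fit_tensor_wlls",
    "fractional_anisotropy",
    "predict_signal",
    "fa_volume",
    "design_matrix",
]


@dataclass(frozen=True)
class DiffusionProtocol:
    """Acquisition geometry: b-values (s/mm^2) and unit gradient directions.

    b=0 rows carry an arbitrary (zero) direction.  ``n_b0`` counts the
    non-diffusion-weighted volumes.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "directions", dirs)
        if dirs.shape != (bvals.size, 3):
            raise ValueError(
                f"directions shape {dirs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be nonnegative")
        dw = bvals > 0
        norms = np.linalg.norm(dirs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must have unit norm (tol 1e-6)")
        if self.n_b0 < 1:
            raise ValueError("at least one b=0 volume is required")

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.size)

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "DiffusionProtocol":
        """Read an FSL-dialect b-table: one row of b-values, three rows of
        direction components. Directions are taken in voxel coordinates."""
        bvals = np.loadtxt(bval_path, ndmin=2).ravel()
        bvecs = np.loadtxt(bvec_path, ndmin=2)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        # renormalize DW rows against text round-off
        norms = np.linalg.norm(bvecs, axis=1)
        dw = (bvals > 0) & (norms > 0)
        bvecs[dw] = bvecs[dw] / norms[dw, None]
        return cls(bvals, bvecs)

    def to_fsl(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.bvalues[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.directions.T, fmt="%.10f")


@dataclass
class TensorEstimate:
    """Symmetric diffusion tensor (mm^2/s) with eigen-decomposition.

    ``components`` holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz); ``eigenvalues``
    are sorted descending.  ``flags`` records quality issues (nonpositive
    input signal, failed fit, negative eigenvalues).
    """

    components: np.ndarray
    s0: float
    eigenvalues: np.ndarray = field(default=None)
    converged: bool = True
    flags: tuple = ()

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (6,):
            raise ValueError("components must be the 6 unique tensor values")
        if self.eigenvalues is None:
            self.eigenvalues = np.sort(np.linalg.eigvalsh(self.matrix))[::-1]
        else:
            self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        dxx, dyy, dzz, dxy, dxz, dyz = self.components
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])

    @property
    def fa(self) -> float:
        return fractional_anisotropy(self.eigenvalues)


@dataclass
class ScalarMap:
    """A per-voxel scalar grid (here FA) with an aligned boolean mask.

    FA values lie in [0, 1] inside the mask; NaN is allowed only outside.
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask grids must be aligned")


def design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    """Log-linear design: columns (1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz) for unknowns (ln S0, Dxx..Dyz)."""
    b = protocol.bvalues
    g = protocol.directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fit_tensor_wlls(signals: np.ndarray, protocol: DiffusionProtocol) -> TensorEstimate:
    """Fit one voxel's tensor by two-pass weighted linear least squares.

    Pass 1 is OLS on log-signals; pass 2 reweights with the squared
    OLS-predicted signals (the conventional WLLS weights, since
    var(ln S) ~ var(S)/S^2).  Negative eigenvalues are retained (not
    clipped) but flagged.

    Raises ``ValueError`` on fewer than 7 volumes.  Nonpositive signals
    or a rank-deficient design yield a non-converged estimate with an
    explanatory flag rather than an exception.
    """
    y = np.asarray(signals, dtype=float).ravel()
    if y.size != protocol.n_volumes:
        raise ValueError("signal vector length does not match protocol")
    if y.size < 7:
        raise ValueError("need at least 7 volumes (6 tensor components + log S0)")
    nan_est = TensorEstimate(
        components=np.full(6, np.nan), s0=np.nan,
        eigenvalues=np.full(3, np.nan), converged=False,
    )
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        nan_est.flags = ("nonpositive_signal",)
        return nan_est

    X = design_matrix(protocol)
    if np.linalg.matrix_rank(X) < 7:
        nan_est.flags = ("rank_deficient_design",)
        return nan_est

    logy = np.log(y)
    beta_ols, *_ = np.linalg.lstsq(X, logy, rcond=None)
    w = np.exp(X @ beta_ols)  # predicted signals
    Xw = X * (w[:, None])
    beta, *_ = np.linalg.lstsq(Xw, w * logy, rcond=None)

    if not np.all(np.isfinite(beta)):
        nan_est.flags = ("fit_failure",)
        return nan_est

    comps = beta[1:]
    est = TensorEstimate(components=comps, s0=float(np.exp(beta[0])))
    if np.any(est.eigenvalues < 0):
        est.flags = est.flags + ("negative_eigenvalue",)
    return est


def fractional_anisotropy(eigenvalues: np.ndarray) -> float:
    """FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||.

    All-zero eigenvalues are a degenerate voxel, defined as FA = 0.
    The result is clipped to [0, 1] only against floating-point
    overshoot (<= 1e-12 beyond the bounds).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    norm2 = float(np.sum(lam * lam))
    if norm2 == 0.0:
        return 0.0
    dev = lam - lam.mean()
    fa = np.sqrt(1.5 * float(np.sum(dev * dev)) / norm2)
    return float(min(max(fa, 0.0), 1.0))


def predict_signal(tensor: TensorEstimate, protocol: DiffusionProtocol) -> np.ndarray:
    """Forward model S_i = S0 * exp(-b_i g_i^T D g_i); exact inverse of the
    noiseless fit."""
    D = tensor.matrix
    g = protocol.directions
    adc = np.einsum("ij,jk,ik->i", g, D, g)
    return tensor.s0 * np.exp(-protocol.bvalues * adc)


def fa_volume(
    dwi: np.ndarray, protocol: DiffusionProtocol, mask: np.ndarray | None = None
) -> tuple[ScalarMap, dict]:
    """Fit every masked voxel of a 4-D DW array and return an FA map plus a
    QC log (counts of excluded/flagged voxels).

    Voxels with any nonpositive signal are excluded from the map (NaN,
    mask cleared) and counted in the QC log.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("expected a 4-D DW array (x, y, z, volume)")
    if dwi.shape[3] != protocol.n_volumes:
        raise ValueError("4th dimension does not match the protocol volume count")
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask grid does not match the DW volume")

    fa = np.full(dwi.shape[:3], np.nan)
    out_mask = mask.copy()
    qc = {"n_voxels": int(mask.sum()), "nonpositive_signal": 0,
          "fit_failure": 0, "negative_eigenvalue": 0}
    for idx in np.argwhere(mask):
        est = fit_tensor_wlls(dwi[tuple(idx)], protocol)
        if not est.converged:
            key = est.flags[0] if est.flags else "fit_failure"
            qc[key] = qc.get(key, 0) + 1
            out_mask[tuple(idx)] = False
            continue
        if "negative_eigenvalue" in est.flags:
            qc["negative_eigenvalue"] += 1
        fa[tuple(idx)] = est.fa
    return ScalarMap(values=fa, mask=out_mask), qc


def fa_volume_from_nifti(
    dwi_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    mask_path: str | Path | None = None,
) -> tuple[ScalarMap, dict, "nib.Nifti1Image"]:
    """Load a 4-D NIfTI + FSL b-table (+ optional mask) and compute the FA map.

    Returns the map, the QC log and a NIfTI image of the FA map aligned to
    the input grid.
    """
    img = nib.load(str(dwi_path))
    protocol = DiffusionProtocol.from_fsl(bval_path, bvec_path)
    data = np.asarray(img.dataobj, dtype=float)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    scalar_map, qc = fa_volume(data, protocol, mask)
    zooms = img.header.get_zooms()[:3]
    scalar_map.voxel_size = tuple(float(z) for z in zooms)
    fa_img = nib.Nifti1Image(scalar_map.values.astype(np.float32), img.affine)
    return scalar_map, qc, fa_img
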
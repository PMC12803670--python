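"""Sciatic functional index (SFI) from footprint measurements.

SFI summarizes hind-limb gait deficit from six footprint lengths taken on
the normal (N) and experimental (E) sides: print length (PL), toe spread
(TS, digits 1-5) and intermediary toe spread (IT, digits 2-4):

    SFI = -38.3 (EPL - NPL)/NPL + 109.5 (ETS - NTS)/NTS + 13.3 (EIT - NIT)/NIT

A healthy animal scores near 0, complete impairment near -100.  The
uncertainty of SFI is propagated from per-measurement SDs by the
first-order delta method with independent errors (no covariance between
footprint lengths is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FootprintMeasurement",
    "SFIRecord",
    "compute_sfi",
    "sfi_uncertainty",
    "sfi_table",
    "SFI_COEFFICIENTS",
]

# (coefficient, experimental field, normal field)
SFI_COEFFICIENTS = (
    (-38.3, "epl", "npl"),
    (109.5, "ets", "nts"),
    (13.3, "eit", "nit"),
)

_LENGTH_FIELDS = ("npl", "epl", "nts", "ets", "nit", "eit")


@dataclass(frozen=True)
class FootprintMeasurement:
    """Six footprint lengths (mm) and optional per-quantity SDs (mm)."""

    npl: float
    epl: float
    nts: float
    ets: float
    nit: float
    eit: float
    sigma: dict | None = None

    def __post_init__(self):
        for f in _LENGTH_FIELDS:
            if getattr(self, f) <= 0:
                raise ValueError(f"footprint length {f} must be strictly positive")
        if self.sigma is not None:
            bad = [k for k, v in self.sigma.items() if v < 0]
            if bad:
                raise ValueError(f"negative sigma for {bad}")


@dataclass(frozen=True)
class SFIRecord:
    value: float
    se: float | None = None
    animal_id: str | None = None
    timepoint_days: float | None = None


def compute_sfi(m: FootprintMeasurement) -> float:
    """Evaluate the SFI formula.  Scale-invariant: doubling every length
    leaves the index unchanged."""
    total = 0.0
    for coef, exp_f, norm_f in SFI_COEFFICIENTS:
        e, n = getattr(m, exp_f), getattr(m, norm_f)
        total += coef * (e - n) / n
    return total


def sfi_uncertainty(m: FootprintMeasurement) -> float:
    """Delta-method SD of SFI with independent measurement errors.

    Partial derivatives of each term c (E - N)/N are c/N w.r.t. E and
    -c E/N^2 w.r.t. N.  Raises if any of the six sigmas is missing.
    """
    if m.sigma is None:
        raise ValueError("sigma values required for uncertainty propagation")
    missing = [f for f in _LENGTH_FIELDS if f not in m.sigma]
    if missing:
        raise ValueError(f"missing sigma for: {missing}")
    var = 0.0
    for coef, exp_f, norm_f in SFI_COEFFICIENTS:
        e, n = getattr(m, exp_f), getattr(m, norm_f)
        d_e = coef / n
        d_n = -coef * e / n**2
        var += d_e**2 * m.sigma[exp_f] ** 2 + d_n**2 * m.sigma[norm_f] ** 2
    return float(np.sqrt(var))


def sfi_table(footprints: pd.DataFrame) -> pd.DataFrame:
    """Compute SFI (and SE where sigma_* columns are present) for a footprint
    table with columns animal_id, timepoint_days, npl, epl, nts, ets, nit, eit.

    Returns a table (animal_id, timepoint_days, sfi, sfi_se); sfi_se is NaN
    for rows without a complete sigma set.
    """
    required = {"animal_id", "timepoint_days", *_LENGTH_FIELDS}
    missing = required - set(footprints.columns)
    if missing:
        raise ValueError(f"footprint table missing columns: {sorted(missing)}")
    sigma_cols = {f: f"sigma_{f}" for f in _LENGTH_FIELDS}
    has_sigma = all(c in footprints.columns for c in sigma_cols.values())

    out = []
    for r in footprints.itertuples():
        sigma = None
        if has_sigma:
            sigma = {f: float(getattr(r, c)) for f, c in sigma_cols.items()}
        m = FootprintMeasurement(
            **{f: float(getattr(r, f)) for f in _LENGTH_FIELDS}, sigma=sigma
        )
        out.append(
            {
                "animal_id": r.animal_id,
                "timepoint_days": float(r.timepoint_days),
                "sfi": compute_sfi(m),
                "sfi_se": sfi_uncertainty(m) if sigma is not None else np.nan,
            }
        )
    return pd.DataFrame(out)
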
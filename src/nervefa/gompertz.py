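"""Gompertz model of the distal FA profile.

The distal segment of an injured nerve shows a sigmoid decline in FA with
distance x (mm) from the injury-side end of the segment:

    FA(x) = FA0 + dFA * exp(-exp(-b * (x - x_ip)))

with FA0 the top asymptote near the injury, dFA the (signed, typically
negative) total change along the segment, b (1/mm) the slope parameter
and x_ip the inflection-point position.  Derived quantities are the far
asymptote FA_target = FA0 + dFA and the inflection FA value
FA_ip = FA0 + dFA/e (the Gompertz inflection sits at a fixed fractional
height 1/e of the total change).

Fitting is bounded nonlinear least squares (trust-region reflective via
``scipy.optimize.least_squares``) with data-driven initial values,
deterministic multi-start restarts, a covariance from the Jacobian at the
solution scaled by the residual variance, and delta-method standard
errors for the derived quantities.  A fit whose 95% interval for dFA
contains zero is flagged degenerate (flat profile) and additionally
reports the constant-model mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from nervefa.profile import DistalProfile

__all__ = [
    "GompertzParams",
    "GompertzDerived",
    "GompertzFit",
    "gompertz_eval",
    "default_init",
    "fit_gompertz",
]

_E = float(np.e)

PARAM_NAMES = ("fa0", "dfa", "rate_b", "x_ip")
QUANTITY_NAMES = ("fa0", "dfa", "rate_b", "x_ip", "fa_target", "fa_ip")


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the distal-FA Gompertz curve (see module docstring)."""

    fa0: float
    dfa: float
    rate_b: float
    x_ip: float

    def __post_init__(self):
        if not (0.0 <= self.fa0 <= 1.0):
            raise ValueError(f"fa0={self.fa0} outside [0, 1]")
        if not (0.0 <= self.fa0 + self.dfa <= 1.0):
            raise ValueError(f"fa0+dfa={self.fa0 + self.dfa} outside [0, 1]")
        if self.rate_b <= 0:
            raise ValueError("rate_b must be positive")

    @property
    def fa_target(self) -> float:
        return self.fa0 + self.dfa

    @property
    def fa_ip(self) -> float:
        return self.fa0 + self.dfa / _E

    def as_array(self) -> np.ndarray:
        return np.array([self.fa0, self.dfa, self.rate_b, self.x_ip])


@dataclass
class GompertzDerived:
    """Derived quantities with uncertainties.

    ``se`` maps each of the six reported quantities to its standard
    error; ``cov`` is the 4x4 covariance of (fa0, dfa, rate_b, x_ip).
    """

    fa_target: float
    fa_ip: float
    se: dict
    cov: np.ndarray


@dataclass
class GompertzFit:
    params: GompertzParams
    derived: GompertzDerived
    residual_ss: float
    converged: bool
    degenerate: bool
    n_points: int
    constant_mean: float | None = None
    message: str = ""

    def to_record(self) -> dict:
        """Flat JSON-serializable record for one subject/timepoint."""
        rec = {
            "fa0": self.params.fa0,
            "dfa": self.params.dfa,
            "rate_b": self.params.rate_b,
            "x_ip": self.params.x_ip,
            "fa_target": self.derived.fa_target,
            "fa_ip": self.derived.fa_ip,
            "se": dict(self.derived.se),
            "cov": np.asarray(self.derived.cov).tolist(),
            "residual_ss": self.residual_ss,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_points": self.n_points,
        }
        if self.constant_mean is not None:
            rec["constant_mean"] = self.constant_mean
        return rec


def gompertz_eval(params, x):
    """Evaluate FA(x); vectorized over x.  ``params`` is a GompertzParams
    or a length-4 sequence (fa0, dfa, rate_b, x_ip)."""
    if isinstance(params, GompertzParams):
        fa0, dfa, b, xip = params.as_array()
    else:
        fa0, dfa, b, xip = params
    x = np.asarray(x, dtype=float)
    return fa0 + dfa * np.exp(-np.exp(-b * (x - xip)))


def _jacobian(theta, x):
    fa0, dfa, b, xip = theta
    u = np.exp(-b * (x - xip))
    g = np.exp(-u)
    J = np.empty((x.size, 4))
    J[:, 0] = 1.0
    J[:, 1] = g
    J[:, 2] = dfa * g * u * (x - xip)
    J[:, 3] = -dfa * g * u * b
    return J


def default_init(distal: DistalProfile | None = None, *, x=None, fa=None):
    """Data-driven initial values and box bounds.

    fa0 starts at the mean of the first quartile of points, the far
    asymptote at the mean of the last quartile, x_ip at the steepest
    centered finite-difference slope and b at 1.0 /mm.  Bounds keep both
    asymptotes inside [0, 1], b in (0.01, 10] and x_ip within the sampled
    range +/- 2 mm.  Requires >= 6 points spanning > 4 mm.
    """
    if distal is not None:
        x = np.asarray(distal.x, dtype=float)
        fa = np.asarray(distal.fa_mean, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        fa = np.asarray(fa, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 points to initialize the fit")
    if x.max() - x.min() <= 4.0:
        raise ValueError("distal profile must span more than 4 mm")

    q = max(1, x.size // 4)
    fa0 = float(np.mean(fa[:q]))
    fa_target = float(np.mean(fa[-q:]))
    dfa = fa_target - fa0
    # steepest |dFA/dx| by centered differences (interior points)
    slopes = (fa[2:] - fa[:-2]) / (x[2:] - x[:-2])
    k = int(np.argmax(np.abs(slopes))) + 1
    x_ip = float(x[k])
    init = np.array([np.clip(fa0, 0.0, 1.0),
                     np.clip(dfa, -1.0, 1.0), 1.0, x_ip])
    lower = np.array([0.0, -1.0, 0.01, x.min() - 2.0])
    upper = np.array([1.0, 1.0, 10.0, x.max() + 2.0])
    return init, (lower, upper)


def _restart_points(init, bounds, x):
    """Deterministic multi-start sequence: jitter x_ip across the profile
    and rate_b over a coarse grid."""
    lower, upper = bounds
    pts = [init]
    quantiles = np.quantile(x, [0.25, 0.5, 0.75])
    rates = (0.3, 1.0, 3.0)
    rng = np.random.default_rng(20260924)  # fixed: reproducible jitter
    for i in range(5):
        p = init.copy()
        p[2] = rates[i % len(rates)]
        p[3] = quantiles[i % len(quantiles)] + rng.uniform(-0.5, 0.5)
        pts.append(np.clip(p, lower + 1e-9, upper - 1e-9))
    return pts


def fit_gompertz(distal: DistalProfile | None = None, *, x=None, fa=None,
                 init=None, bounds=None, weights=None,
                 parameterization: str = "dfa") -> GompertzFit:
    """Fit the Gompertz curve to a distal FA profile by bounded NLS.

    ``weights`` are per-point weights w_i of the objective
    sum w_i (fa_i - FA(x_i))^2 (default unweighted).  With
    ``parameterization="asymptotes"`` the optimizer works in
    (fa0, fa_target, b, x_ip); results are reported in the standard
    (fa0, dfa, b, x_ip) form either way.

    Nonconvergence after the deterministic restarts yields a fit record
    with ``converged=False`` rather than an exception; fewer points than
    parameters is a hard error.
    """
    if distal is not None:
        x = np.asarray(distal.x, dtype=float)
        fa = np.asarray(distal.fa_mean, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        fa = np.asarray(fa, dtype=float)
    good = np.isfinite(x) & np.isfinite(fa)
    x, fa = x[good], fa[good]
    n = x.size
    if n < 4:
        raise ValueError(f"cannot fit 4 parameters to {n} points")
    if not np.all(np.isfinite(fa)):
        raise ValueError("non-finite FA values in distal profile")
    if weights is None:
        sw = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)[good] if np.asarray(weights).size == good.size else np.asarray(weights, dtype=float)
        if weights.size != n or np.any(weights < 0):
            raise ValueError("weights must be nonnegative, one per point")
        sw = np.sqrt(weights)

    if init is None or bounds is None:
        init_d, bounds_d = default_init(x=x, fa=fa)
        init = init_d if init is None else np.asarray(init, dtype=float)
        bounds = bounds_d if bounds is None else bounds
    init = np.clip(np.asarray(init, dtype=float), bounds[0], bounds[1])

    to_internal, from_internal = _parameterization(parameterization)

    def residuals(theta_int):
        theta = from_internal(theta_int)
        return sw * (gompertz_eval(theta, x) - fa)

    def jac(theta_int):
        theta = from_internal(theta_int)
        J = _jacobian(theta, x)
        if parameterization == "asymptotes":
            # chain rule: fa0_int = fa0, target_int = fa0 + dfa
            Ji = np.empty_like(J)
            Ji[:, 0] = J[:, 0] - J[:, 1]
            Ji[:, 1] = J[:, 1]
            Ji[:, 2:] = J[:, 2:]
            J = Ji
        return sw[:, None] * J

    lo_int, hi_int = _internal_bounds(parameterization, bounds)
    best = None
    for start in _restart_points(init, bounds, x):
        try:
            sol = optimize.least_squares(
                residuals, to_internal(start), jac=jac,
                bounds=(lo_int, hi_int), method="trf",
                ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=500 * 4,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol

    if best is None or not np.all(np.isfinite(best.x)):
        nan_se = {k: float("nan") for k in QUANTITY_NAMES}
        p = GompertzParams(0.5, 0.0, 1.0, float(np.median(x)))
        return GompertzFit(
            params=p,
            derived=GompertzDerived(p.fa_target, p.fa_ip, nan_se, np.full((4, 4), np.nan)),
            residual_ss=float("nan"), converged=False, degenerate=True,
            n_points=n, constant_mean=float(np.mean(fa)),
            message="optimization failed at every start point",
        )

    theta = from_internal(best.x)
    fa0, dfa, rate_b, x_ip = theta
    resid = gompertz_eval(theta, x) - fa
    rss = float(np.sum(sw**2 * resid**2))
    dof = max(n - 4, 1)
    sigma2 = rss / dof
    J = _jacobian(theta, x) * sw[:, None]
    JtJ = J.T @ J
    try:
        cov = sigma2 * np.linalg.pinv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
    cov = 0.5 * (cov + cov.T)

    se = {name: float(np.sqrt(max(cov[i, i], 0.0))) for i, name in enumerate(PARAM_NAMES)}
    # delta method on the full covariance:
    # fa_target = fa0 + dfa ; fa_ip = fa0 + dfa/e
    g_t = np.array([1.0, 1.0, 0.0, 0.0])
    g_ip = np.array([1.0, 1.0 / _E, 0.0, 0.0])
    se["fa_target"] = float(np.sqrt(max(g_t @ cov @ g_t, 0.0)))
    se["fa_ip"] = float(np.sqrt(max(g_ip @ cov @ g_ip, 0.0)))

    degenerate = bool(abs(dfa) <= sps.norm.ppf(0.975) * se["dfa"]) if np.isfinite(se["dfa"]) else True

    params = GompertzParams(float(np.clip(fa0, 0, 1)),
                            float(np.clip(dfa, -fa0, 1 - fa0)),
                            float(max(rate_b, 1e-12)), float(x_ip))
    derived = GompertzDerived(fa_target=params.fa_target, fa_ip=params.fa_ip,
                              se=se, cov=cov)
    return GompertzFit(
        params=params, derived=derived, residual_ss=rss,
        converged=bool(best.success), degenerate=degenerate, n_points=n,
        constant_mean=float(np.mean(fa)) if degenerate else None,
        message=best.message,
    )


def profile_confint(fit: GompertzFit, x, fa, level: float = 0.95,
                    weights=None) -> dict:
    """Profile-likelihood confidence intervals for the four fitted
    parameters.

    Wald (linearized) intervals undercover the nonlinear parameters
    (rate_b, x_ip) at realistic noise; profiling the residual sum of
    squares — the construction behind ``confint`` for R's nls — restores
    nominal coverage.  For each parameter the bound solves

        RSS(theta_j) - RSS_min = t^2 * s^2,   s^2 = RSS_min / (n - 4)

    where RSS(theta_j) is minimized over the other three parameters and
    t is the two-sided Student quantile with n - 4 df.  Bounds that run
    to the box constraints are returned clipped there.
    """
    x = np.asarray(x, dtype=float)
    fa = np.asarray(fa, dtype=float)
    n = x.size
    sw = np.ones(n) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    theta_hat = fit.params.as_array()
    rss_min = fit.residual_ss
    dof = max(n - 4, 1)
    s2 = rss_min / dof
    tcrit = sps.t.ppf(0.5 + level / 2.0, dof)
    target = rss_min + tcrit**2 * s2

    _, (lower, upper) = default_init(x=x, fa=fa)

    def rss_fixed(j, v):
        free = [k for k in range(4) if k != j]

        def resid(sub):
            th = np.empty(4)
            th[j] = v
            th[free] = sub
            return sw * (gompertz_eval(th, x) - fa)

        sol = optimize.least_squares(
            resid, theta_hat[free],
            bounds=(lower[free], upper[free]), method="trf",
            ftol=1e-9, xtol=1e-9, max_nfev=200,
        )
        return 2.0 * sol.cost

    out = {}
    for j, name in enumerate(PARAM_NAMES):
        se_j = fit.derived.se[name]
        step = 0.75 * se_j if np.isfinite(se_j) and se_j > 0 else 0.05 * max(abs(theta_hat[j]), 1.0)
        bnds = []
        for sign in (-1.0, 1.0):
            lim = lower[j] if sign < 0 else upper[j]
            a = theta_hat[j]
            b = a
            fb = rss_min - target
            for _ in range(40):
                b = b + sign * step
                if (sign < 0 and b <= lim) or (sign > 0 and b >= lim):
                    b = lim
                fb = rss_fixed(j, b) - target
                if fb > 0 or b == lim:
                    break
                step *= 1.6
            if fb <= 0:
                bnds.append(float(lim))  # interval runs into the box bound
                continue
            root = optimize.brentq(lambda v: rss_fixed(j, v) - target,
                                   min(a, b), max(a, b), xtol=1e-4, rtol=1e-6)
            bnds.append(float(root))
        out[name] = (min(bnds), max(bnds))
    return out


def _parameterization(name: str):
    if name == "dfa":
        return (lambda t: np.asarray(t, dtype=float),) * 2
    if name == "asymptotes":
        def to_internal(theta):
            fa0, dfa, b, xip = theta
            return np.array([fa0, fa0 + dfa, b, xip])

        def from_internal(ti):
            fa0, target, b, xip = ti
            return np.array([fa0, target - fa0, b, xip])

        return to_internal, from_internal
    raise ValueError(f"unknown parameterization {name!r}")


def _internal_bounds(name: str, bounds):
    lower, upper = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    if name == "dfa":
        return lower, upper
    # asymptote form: both levels bounded in [0, 1] directly
    lo = np.array([lower[0], 0.0, lower[2], lower[3]])
    hi = np.array([upper[0], 1.0, upper[2], upper[3]])
    return lo, hi


def fits_to_frame(records: list[dict]) -> "pd.DataFrame":
    """Flatten per-subject/timepoint fit records into a cohort table."""
    import pandas as pd

    rows = []
    for r in records:
        row = {k: r[k] for k in ("subject_id", "timepoint_weeks") if k in r}
        fit = r["fit"] if "fit" in r else r
        rec = fit.to_record() if isinstance(fit, GompertzFit) else fit
        for k in QUANTITY_NAMES + ("residual_ss", "converged", "degenerate", "n_points"):
            row[k] = rec[k]
        for k, v in rec["se"].items():
            row[f"se_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
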
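"""Fit the minimal model to a single subject's IVGTT.

Measured plasma insulin is the input; glucose is the output.  The fit is a
bounded multi-start weighted nonlinear least squares over (p1, p2, p3, G0)
with basal levels Gb, Ib fixed from the pre-injection samples.  Optimisation
runs in log-parameter space because p2 and p3 are poorly scaled and lie on a
well-known ridge; Latin-hypercube starts guard against it.

Weights are proportional to 1/(cv * G_obs)^2 — constant relative measurement
error, the standard assumption for glucose assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core_model import GlucoseTrajectory, InsulinInput, MinimalModelParams, simulate_minimal_model
from .errors import ConvergenceError, DataError, IdentifiabilityError, ParameterError

__all__ = [
    "Protocol",
    "IVGTTRecord",
    "FitOptions",
    "FitResult",
    "fit_minimal_model",
    "compute_SI",
    "parameter_precision",
]


@dataclass(frozen=True)
class Protocol:
    """IVGTT protocol metadata.

    ``secondary_agent`` records a secretagogue (tolbutamide) or insulin
    injection given after the glucose bolus to enhance the insulin pattern
    (modified protocol); ``secondary_time`` its timing in min (default 20).
    """

    glucose_dose: float = 0.3  # g/kg, conventional bolus
    secondary_agent: str = "none"
    secondary_time: float | None = None

    def __post_init__(self):
        if self.secondary_agent not in ("none", "tolbutamide", "insulin"):
            raise ParameterError(f"unknown secondary agent {self.secondary_agent!r}")
        if self.secondary_agent != "none" and self.secondary_time is None:
            object.__setattr__(self, "secondary_time", 20.0)


@dataclass(frozen=True)
class IVGTTRecord:
    """One subject's frequently-sampled IVGTT.

    Times are minutes relative to the glucose injection at t=0; samples at
    t < 0 are pre-injection (basal) draws.  Concentrations must be positive.
    """

    subject_id: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    protocol: Protocol = field(default_factory=Protocol)
    noise_cv: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        i = np.asarray(self.insulin, dtype=float)
        if not (t.ndim == g.ndim == i.ndim == 1) or not (t.shape == g.shape == i.shape):
            raise DataError("times, glucose and insulin must be 1-D arrays of equal length")
        if t.size < 2:
            raise DataError("record must contain at least two samples")
        if not np.all(np.diff(t) > 0):
            raise DataError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(g)) and np.all(np.isfinite(i))):
            raise DataError("record contains non-finite values")
        if np.any(g <= 0) or np.any(i <= 0):
            raise DataError("concentrations must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)
        object.__setattr__(self, "insulin", i)

    def basal(self) -> tuple[float, float]:
        """(Gb, Ib) from pre-injection samples (t < 0).

        The t=0 draw is by convention post-injection (the model's G0
        intercept), so it is excluded.  If no pre-injection samples exist,
        fall back to the final plateau (mean of the last three samples).
        """
        pre = self.times < 0
        if np.any(pre):
            return float(self.glucose[pre].mean()), float(self.insulin[pre].mean())
        return float(self.glucose[-3:].mean()), float(self.insulin[-3:].mean())

    def insulin_input(self, interpolation: str = "linear") -> InsulinInput:
        return InsulinInput(self.times, self.insulin, interpolation=interpolation)


# ---------------------------------------------------------------------------
# fit configuration


def _default_bounds():
    return {
        "p1": (1e-4, 0.2),
        "p2": (1e-3, 1.0),
        "p3": (1e-9, 1e-2),
        "G0": (50.0, 1000.0),
    }


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the weighted least-squares fit.

    ``fit_window`` excludes the early glucose-mixing phase (default start
    8 min); ``cv`` is the assumed relative glucose measurement error (falls
    back to the record's noise_cv, then 2%); ``fix`` freezes named parameters
    at given values.
    """

    fit_window: tuple[float, float | None] = (8.0, None)
    cv: float | None = None
    n_starts: int = 8
    seed: int = 0
    bounds: dict = field(default_factory=_default_bounds)
    fix: dict = field(default_factory=dict)
    interpolation: str = "linear"
    stage1_max_nfev: int = 60
    refine_top: int = 2
    max_nfev: int = 400

    def replace(self, **kw):
        return replace(self, **kw)


@dataclass(frozen=True)
class FitResult:
    """Estimated minimal-model parameters for one IVGTT and their precision.

    ``fsd`` holds fractional standard deviations sqrt(cov_ii)/|theta_i| per
    free parameter (inf where the Jacobian is rank-deficient along that
    parameter); ``ssr`` is the weighted sum of squared residuals.
    """

    params: MinimalModelParams
    SI: float
    ssr: float
    residuals: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)
    fit_times: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)
    fsd: dict
    free_names: tuple
    fixed: dict
    window: tuple
    cv: float
    n_obs: int
    n_starts: int
    converged: bool
    boundary_params: tuple
    jac_log: np.ndarray = field(repr=False)
    s2: float
    start_costs: tuple = field(repr=False, default=())

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def aic(self) -> float:
        """AIC = n ln(SSR/n) + 2k on the weighted SSR."""
        return self.n_obs * math.log(max(self.ssr, 1e-300) / self.n_obs) + 2 * self.n_free

    @property
    def max_fsd(self) -> float:
        return max(self.fsd.values()) if self.fsd else float("inf")

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {"p1": p.p1, "p2": p.p2, "p3": p.p3, "Gb": p.Gb, "Ib": p.Ib, "G0": p.G0},
            "SI": self.SI,
            "ssr": self.ssr,
            "aic": self.aic,
            "fsd": dict(self.fsd),
            "fixed": dict(self.fixed),
            "window": list(self.window),
            "cv": self.cv,
            "n_obs": self.n_obs,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "boundary_params": list(self.boundary_params),
        }


# ---------------------------------------------------------------------------
# shared multi-start machinery (also used by the model ladder)


def multistart_least_squares(
    residual,
    log_lo,
    log_hi,
    n_starts=8,
    seed=0,
    extra_starts=(),
    stage1_max_nfev=60,
    refine_top=2,
    max_nfev=400,
):
    """Two-stage multi-start bounded least squares in log-parameter space.

    Stage 1 runs a capped optimisation from each Latin-hypercube start (plus
    any warm starts); stage 2 polishes the best ``refine_top`` candidates to
    tight tolerance.  Returns (scipy result, list of stage-1 costs).
    """
    log_lo = np.asarray(log_lo, dtype=float)
    log_hi = np.asarray(log_hi, dtype=float)
    d = log_lo.size
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    starts = log_lo + sampler.random(n_starts) * (log_hi - log_lo)
    extra = [np.clip(np.asarray(s, dtype=float), log_lo, log_hi) for s in extra_starts]
    all_starts = list(starts) + extra

    stage1 = []
    for j, x0 in enumerate(all_starts):
        try:
            r = least_squares(
                residual,
                x0,
                bounds=(log_lo, log_hi),
                method="trf",
                x_scale="jac",
                max_nfev=stage1_max_nfev,
            )
            stage1.append((r, j >= n_starts))
        except Exception:  # a start may wander into a pathological corner
            continue
    if not stage1:
        raise ConvergenceError("all optimisation starts failed")
    stage1.sort(key=lambda item: item[0].cost)

    # polish the best stage-1 candidates plus every warm start: warm starts
    # carry nesting information that the cost ranking alone may drop
    candidates = [r for r, _ in stage1[: max(refine_top, 1)]]
    candidates += [r for r, is_warm in stage1[max(refine_top, 1):] if is_warm]

    best = None
    for cand in candidates:
        try:
            r = least_squares(
                residual,
                cand.x,
                bounds=(log_lo, log_hi),
                method="trf",
                x_scale="jac",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        best = stage1[0][0]
    return best, [r.cost for r, _ in stage1]


def _fsd_from_jacobian(jac_log, s2, rcond=1e-8):
    """Fractional SDs from the log-space Jacobian of weighted residuals.

    In log space the covariance diagonal is directly the squared fractional
    SD.  Directions with singular values below ``rcond * s_max`` are treated
    as unidentified: any parameter loading on them gets FSD = inf.
    """
    m, k = jac_log.shape
    u, s, vt = np.linalg.svd(jac_log, full_matrices=False)
    smax = s[0] if s.size else 0.0
    good = s > rcond * smax if smax > 0 else np.zeros_like(s, dtype=bool)
    fsd = np.empty(k)
    cov_log = np.zeros((k, k))
    for j in range(s.size):
        if good[j]:
            cov_log += np.outer(vt[j], vt[j]) / s[j] ** 2
    cov_log *= s2
    for i in range(k):
        deficient = any((not good[j]) and abs(vt[j, i]) > 1e-6 for j in range(s.size))
        fsd[i] = np.inf if deficient else math.sqrt(max(cov_log[i, i], 0.0))
    rank = int(good.sum())
    return fsd, cov_log, rank


# ---------------------------------------------------------------------------
# the fit itself

_PARAM_ORDER = ("p1", "p2", "p3", "G0")


def fit_minimal_model(record: IVGTTRecord, options: FitOptions | None = None) -> FitResult:
    """Weighted multi-start NLS fit of (p1, p2, p3, G0) to one IVGTT.

    Gb and Ib are fixed to the basal (pre-injection) samples.  The default
    fit window starts at 8 min, excluding the plasma mixing phase.  The
    result is deterministic given the options' seed.
    """
    opt = options or FitOptions()
    gb, ib = record.basal()

    lo_w = opt.fit_window[0]
    hi_w = opt.fit_window[1] if opt.fit_window[1] is not None else float(record.times[-1])
    mask = (record.times >= lo_w) & (record.times <= hi_w)
    t_obs = record.times[mask]
    g_obs = record.glucose[mask]
    if t_obs.size < 12:
        raise DataError(
            f"only {t_obs.size} glucose samples in fit window [{lo_w}, {hi_w}]; need >= 12"
        )
    insulin = record.insulin_input(opt.interpolation)
    if insulin.times[-1] < hi_w - 1e-9 or insulin.times[0] > 0.0:
        raise DataError("insulin series does not span the fit window")

    cv = opt.cv
    if cv is None:
        cv = record.noise_cv if record.noise_cv else 0.02
    sigma = cv * g_obs

    free = [n for n in _PARAM_ORDER if n not in opt.fix]
    if not free:
        raise ParameterError("at least one parameter must be free")
    for n in opt.fix:
        if n not in _PARAM_ORDER:
            raise ParameterError(f"cannot fix unknown parameter {n!r}")
    bounds = {**_default_bounds(), **opt.bounds}
    log_lo = np.log([bounds[n][0] for n in free])
    log_hi = np.log([bounds[n][1] for n in free])

    # simulate from t=0 (where G = G0) and read off the window samples
    if t_obs[0] > 0:
        t_eval = np.concatenate(([0.0], t_obs))
        skip = 1
    else:
        t_eval = t_obs
        skip = 0

    def make_params(z):
        vals = dict(opt.fix)
        vals.update({n: math.exp(v) for n, v in zip(free, z)})
        return MinimalModelParams(
            p1=vals["p1"], p2=vals["p2"], p3=vals["p3"], Gb=gb, Ib=ib, G0=vals["G0"]
        )

    def residual(z):
        traj = simulate_minimal_model(make_params(z), insulin, t_eval)
        return (traj.glucose[skip:] - g_obs) / sigma

    best, start_costs = multistart_least_squares(
        residual,
        log_lo,
        log_hi,
        n_starts=opt.n_starts,
        seed=opt.seed,
        stage1_max_nfev=opt.stage1_max_nfev,
        refine_top=opt.refine_top,
        max_nfev=opt.max_nfev,
    )

    params = make_params(best.x)
    res = best.fun
    ssr = float(res @ res)
    n = t_obs.size
    k = len(free)
    s2 = ssr / max(n - k, 1)
    fsd_vec, cov_log, rank = _fsd_from_jacobian(best.jac, s2)
    theta = np.exp(best.x)
    cov_nat = cov_log * np.outer(theta, theta)
    fsd = {name: float(v) for name, v in zip(free, fsd_vec)}

    span = log_hi - log_lo
    boundary = tuple(
        name
        for name, z, lo, hi, sp in zip(free, best.x, log_lo, log_hi, span)
        if min(z - lo, hi - z) < 1e-4 * sp
    )
    if boundary:
        warnings.warn(f"fit pinned at bounds for: {', '.join(boundary)}", stacklevel=2)

    return FitResult(
        params=params,
        SI=params.SI,
        ssr=ssr,
        residuals=res,
        predictions=res * sigma + g_obs,
        fit_times=t_obs,
        observed=g_obs,
        covariance=cov_nat,
        fsd=fsd,
        free_names=tuple(free),
        fixed=dict(opt.fix),
        window=(lo_w, hi_w),
        cv=cv,
        n_obs=n,
        n_starts=opt.n_starts,
        converged=bool(best.status > 0),
        boundary_params=boundary,
        jac_log=best.jac,
        s2=s2,
        start_costs=tuple(start_costs),
    )


def compute_SI(params: MinimalModelParams) -> float:
    """Insulin sensitivity index SI = p3/p2.

    SI is the steady-state dependence of fractional glucose disappearance on
    the plasma insulin increment; validation of the fit's p2 > 0 happens at
    parameter construction.
    """
    if params.p2 <= 0:
        raise ParameterError("p2 must be > 0")
    return params.p3 / params.p2


def parameter_precision(fit: FitResult, report_only: bool = False):
    """Per-parameter fractional standard deviations and identifiability flags.

    Returns a dict name -> {"estimate", "fsd", "identified"}; a parameter is
    flagged non-identified when FSD > 1 (or the Jacobian is rank-deficient
    along it).  Raises :class:`IdentifiabilityError` for a rank-deficient
    Jacobian unless ``report_only`` (the ladder uses report-only mode).
    """
    fsd_vec, _, rank = _fsd_from_jacobian(fit.jac_log, fit.s2)
    k = len(fit.free_names)
    if rank < k and not report_only:
        raise IdentifiabilityError(
            f"Jacobian rank {rank} < {k}: parameters "
            f"{[n for n, f in zip(fit.free_names, fsd_vec) if not np.isfinite(f)]} "
            "are not identifiable from these data"
        )
    est = {"p1": fit.params.p1, "p2": fit.params.p2, "p3": fit.params.p3, "G0": fit.params.G0}
    return {
        name: {
            "estimate": est[name],
            "fsd": float(f),
            "identified": bool(np.isfinite(f) and f <= 1.0),
        }
        for name, f in zip(fit.free_names, fsd_vec)
    }
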
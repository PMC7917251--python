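"""Candidate-model ladder for post-bolus glucose kinetics.

Model complexity is introduced systematically and each rung is judged on two
grounds: can it account for the data (SSR/AIC), and are its parameters
uniquely identifiable from a single IVGTT (fractional SDs)?  The rungs:

- M1: first-order glucose decay to basal, no explicit insulin action.
- M2: Michaelis-Menten disposal replacing the linear term.
- M3: M2 plus two-compartment glucose distribution (linear exchange).
- M6: the minimal model — linear disposal modulated by remote-compartment
  insulin action (delayed insulin effect).

A model is selected if it converged, all parameters are identified
(max FSD <= threshold), and its AIC = n ln(SSR/n) + 2k is minimal among such
survivors.  Models that cannot account for the delayed insulin-driven
acceleration of glucose decline leave structured residuals; models with
superfluous parameters fail the identifiability filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core_model import InsulinInput, MinimalModelParams, simulate_minimal_model
from .errors import DataError, ParameterError
from .estimation import (
    FitOptions,
    IVGTTRecord,
    _fsd_from_jacobian,
    multistart_least_squares,
)

__all__ = [
    "CandidateModel",
    "CandidateFit",
    "LadderReport",
    "MODELS",
    "get_model",
    "simulate_candidate",
    "fit_candidate",
    "fit_ladder",
]


@dataclass(frozen=True)
class CandidateModel:
    """One rung of the ladder: a glucose-kinetics structure with bounded
    parameters and a forward simulation."""

    model_id: str
    description: str
    param_names: tuple
    bounds: dict
    needs_insulin: bool

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def simulate(self, theta: dict, insulin: InsulinInput | None, times, gb: float, ib: float):
        times = np.asarray(times, dtype=float)
        if self.model_id == "M1":
            return gb + (theta["G0"] - gb) * np.exp(-theta["k"] * (times - times[0]))
        if self.model_id == "M2":
            return _kernels.rk4_michaelis(
                theta["Vmax"], theta["Km"], gb, theta["G0"], times, 0.02
            )
        if self.model_id == "M3":
            k12, k21 = theta["k12"], theta["k21"]
            g20 = k21 * gb / k12 if k12 > 0 else 0.0
            return _kernels.rk4_two_pool(
                theta["Vmax"], theta["Km"], k12, k21, gb, theta["G0"], g20, times, 0.02
            )
        if self.model_id == "M6":
            if insulin is None:
                raise ParameterError("M6 requires an insulin input")
            params = MinimalModelParams(
                p1=theta["p1"], p2=theta["p2"], p3=theta["p3"], Gb=gb, Ib=ib, G0=theta["G0"]
            )
            return simulate_minimal_model(params, insulin, times).glucose
        raise ParameterError(f"unknown model {self.model_id!r}")


_G0_BOUNDS = (50.0, 1000.0)

MODELS = {
    "M1": CandidateModel(
        "M1",
        "first-order glucose decay to basal, no explicit insulin action",
        ("k", "G0"),
        {"k": (1e-4, 0.5), "G0": _G0_BOUNDS},
        needs_insulin=False,
    ),
    "M2": CandidateModel(
        "M2",
        "Michaelis-Menten glucose disposal with constant basal production",
        ("Vmax", "Km", "G0"),
        {"Vmax": (1e-2, 1e6), "Km": (1.0, 1e8), "G0": _G0_BOUNDS},
        needs_insulin=False,
    ),
    "M3": CandidateModel(
        "M3",
        "Michaelis-Menten disposal plus two-compartment glucose distribution",
        ("Vmax", "Km", "k12", "k21", "G0"),
        {
            "Vmax": (1e-2, 1e6),
            "Km": (1.0, 1e8),
            "k12": (1e-5, 1.0),
            "k21": (1e-5, 1.0),
            "G0": _G0_BOUNDS,
        },
        needs_insulin=False,
    ),
    "M6": CandidateModel(
        "M6",
        "minimal model: linear disposal with delayed remote-compartment insulin action",
        ("p1", "p2", "p3", "G0"),
        {"p1": (1e-4, 0.2), "p2": (1e-3, 1.0), "p3": (1e-9, 1e-2), "G0": _G0_BOUNDS},
        needs_insulin=True,
    ),
}


def get_model(model_id: str) -> CandidateModel:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ParameterError(f"unknown candidate model {model_id!r}") from None


def simulate_candidate(model: CandidateModel | str, theta: dict, insulin, times, gb, ib):
    """Forward-simulate one candidate on a time grid (starts at times[0])."""
    if isinstance(model, str):
        model = get_model(model)
    return model.simulate(theta, insulin, np.asarray(times, dtype=float), gb, ib)


@dataclass(frozen=True)
class CandidateFit:
    """Fit summary of one ladder rung."""

    model_id: str
    theta: dict
    ssr: float
    aic: float
    fsd: dict
    max_fsd: float
    converged: bool
    boundary: tuple
    n_obs: int
    n_params: int
    residuals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "theta": dict(self.theta),
            "ssr": self.ssr,
            "aic": self.aic,
            "fsd": dict(self.fsd),
            "max_fsd": self.max_fsd,
            "converged": self.converged,
            "boundary": list(self.boundary),
            "n_obs": self.n_obs,
            "n_params": self.n_params,
        }


def _warm_starts(model: CandidateModel, fits: dict) -> list:
    """Log-space warm starts mapping a simpler fitted rung into this one,
    securing the SSR nesting M1 >= M2 >= M3 against optimizer luck."""
    starts = []
    if model.model_id == "M2" and "M1" in fits:
        t = fits["M1"].theta
        km = 1e6  # deep quasi-linear regime: Vmax/Km ~ k
        starts.append(np.log([t["k"] * km, km, t["G0"]]))
    if model.model_id == "M3" and "M2" in fits:
        t = fits["M2"].theta
        starts.append(np.log([t["Vmax"], t["Km"], 1e-3, 1e-5, t["G0"]]))
        starts.append(np.log([t["Vmax"], t["Km"], 0.05, 0.05, t["G0"]]))
    return starts


def fit_candidate(
    record: IVGTTRecord,
    model: CandidateModel | str,
    options: FitOptions | None = None,
    warm_starts=(),
) -> CandidateFit:
    """Fit one candidate with the shared weighted multi-start machinery."""
    if isinstance(model, str):
        model = get_model(model)
    opt = options or FitOptions()
    gb, ib = record.basal()

    lo_w = opt.fit_window[0]
    hi_w = opt.fit_window[1] if opt.fit_window[1] is not None else float(record.times[-1])
    mask = (record.times >= lo_w) & (record.times <= hi_w)
    t_obs = record.times[mask]
    g_obs = record.glucose[mask]
    if t_obs.size < 12:
        raise DataError(f"only {t_obs.size} samples in fit window; need >= 12")
    insulin = record.insulin_input(opt.interpolation) if model.needs_insulin else None

    cv = opt.cv
    if cv is None:
        cv = record.noise_cv if record.noise_cv else 0.02
    sigma = cv * g_obs

    names = model.param_names
    log_lo = np.log([model.bounds[n][0] for n in names])
    log_hi = np.log([model.bounds[n][1] for n in names])
    t_eval = np.concatenate(([0.0], t_obs)) if t_obs[0] > 0 else t_obs
    skip = 1 if t_obs[0] > 0 else 0

    def residual(z):
        theta = {n: math.exp(v) for n, v in zip(names, z)}
        g = model.simulate(theta, insulin, t_eval, gb, ib)
        return (g[skip:] - g_obs) / sigma

    best, _ = multistart_least_squares(
        residual,
        log_lo,
        log_hi,
        n_starts=opt.n_starts,
        seed=opt.seed,
        extra_starts=warm_starts,
        stage1_max_nfev=opt.stage1_max_nfev,
        refine_top=opt.refine_top,
        max_nfev=opt.max_nfev,
    )

    theta = {n: math.exp(v) for n, v in zip(names, best.x)}
    ssr = float(best.fun @ best.fun)
    n = t_obs.size
    k = len(names)
    s2 = ssr / max(n - k, 1)
    fsd_vec, _, _ = _fsd_from_jacobian(best.jac, s2)
    fsd = {nm: float(v) for nm, v in zip(names, fsd_vec)}
    span = log_hi - log_lo
    boundary = tuple(
        nm
        for nm, z, lo, hi, sp in zip(names, best.x, log_lo, log_hi, span)
        if min(z - lo, hi - z) < 1e-4 * sp
    )
    aic = n * math.log(max(ssr, 1e-300) / n) + 2 * k
    return CandidateFit(
        model_id=model.model_id,
        theta=theta,
        ssr=ssr,
        aic=aic,
        fsd=fsd,
        max_fsd=max(fsd.values()),
        converged=bool(best.status > 0),
        boundary=boundary,
        n_obs=n,
        n_params=k,
        residuals=best.fun,
    )


@dataclass(frozen=True)
class LadderReport:
    """Per-model fit summaries, the selected model and the rationale codes."""

    fits: dict
    selected: str | None
    rationale: tuple

    def to_dict(self) -> dict:
        return {
            "models": {mid: f.to_dict() for mid, f in self.fits.items()},
            "selected": self.selected,
            "rationale": list(self.rationale),
        }


def fit_ladder(
    record: IVGTTRecord,
    candidates=("M1", "M2", "M3", "M6"),
    options: FitOptions | None = None,
    fsd_threshold: float = 1.0,
) -> LadderReport:
    """Fit every candidate and select the best-supported structure.

    Survivors must have converged with every parameter identified
    (FSD <= ``fsd_threshold``); among survivors the minimal-AIC model is
    selected.  If no candidate survives, ``selected`` is None and the
    rationale says why each failed.
    """
    fits: dict[str, CandidateFit] = {}
    rationale = []
    for mid in candidates:
        model = get_model(mid) if isinstance(mid, str) else mid
        warm = _warm_starts(model, fits)
        fit = fit_candidate(record, model, options, warm_starts=warm)
        fits[model.model_id] = fit

    survivors = []
    for mid, f in fits.items():
        if not f.converged:
            rationale.append(f"{mid}:not-converged")
        elif not np.isfinite(f.max_fsd) or f.max_fsd > fsd_threshold:
            rationale.append(f"{mid}:non-identified(max_fsd={f.max_fsd:.3g})")
        else:
            survivors.append(mid)

    if not survivors:
        rationale.append("selected:none")
        return LadderReport(fits=fits, selected=None, rationale=tuple(rationale))

    selected = min(survivors, key=lambda m: fits[m].aic)
    rationale.append(f"selected:{selected}:min-aic-among-identified")
    return LadderReport(fits=fits, selected=selected, rationale=tuple(rationale))
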
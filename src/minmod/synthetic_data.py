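"""Ground-truth synthetic data: IVGTT records, cohorts, infusion pairs.

The generator emulates a frequently-sampled IVGTT: glucose sampled every
minute for 180 min after the bolus (plus pre-injection basal draws), a
biphasic insulin curve rising from basal, an optional secondary insulin peak
at 20 min mimicking the tolbutamide/insulin-modified protocol, and
independent multiplicative lognormal measurement noise on both series.

Because partition analysis makes insulin an *input*, the insulin curve is an
empirical template (sum of exponentials), not a secretion model — any
realistic shape suffices, and this one is analytically convenient.

Every generated record embeds its generating parameters in ``meta`` so
round-trip (generate -> fit -> compare) recovery studies need no external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clearance import ClearanceParams, InfusionExperiment, simulate_two_route
from .core_model import InsulinInput, MinimalModelParams, simulate_minimal_model
from .errors import ConfigError, DataError, ParameterError
from .estimation import IVGTTRecord, Protocol

__all__ = [
    "InsulinCurveTemplate",
    "CohortSpec",
    "ClearancePair",
    "NORMAL_SUBJECT",
    "default_schedule",
    "generate_ivgtt",
    "generate_population",
    "generate_clamp_cohort",
    "generate_clearance_cohort",
]

#: Literature-typical normal-subject parameters used as the standard fixture
#: (SG = 0.02 /min, p2 = 0.03 /min, SI = p3/p2 = 5e-4 /min per uU/ml).
NORMAL_SUBJECT = MinimalModelParams(
    p1=0.02, p2=0.03, p3=1.5e-5, Gb=90.0, Ib=10.0, G0=280.0, VD=1.8
)

#: Default assay CVs (glucose, insulin): typical clinical-laboratory precision.
DEFAULT_NOISE_CV = (0.02, 0.07)


def default_schedule(t_end: float = 180.0, step: float = 1.0) -> np.ndarray:
    """Per-minute sampling 0..t_end plus two pre-injection basal draws."""
    return np.concatenate(([-10.0, -5.0], np.arange(0.0, t_end + step / 2, step)))


@dataclass(frozen=True)
class InsulinCurveTemplate:
    """Biphasic plasma-insulin template as a sum of exponentials.

    First phase (from t=0):  Ib + peak_height * (e^(-t/tau_slow) - e^(-t/tau_fast)),
    normalised so the maximum increment equals ``peak_height``.  An optional
    secondary peak of the same form starts at ``secondary_time`` (default
    20 min), emulating the tolbutamide- or insulin-modified protocol.

    The curve is >= Ib everywhere and must return to within 5% of Ib by
    180 min (validated at construction).
    """

    Ib: float = 10.0
    peak_height: float = 80.0
    tau_fast: float = 2.0
    tau_slow: float = 20.0
    secondary_time: float | None = None
    secondary_height: float = 100.0
    secondary_tau_fast: float = 1.0
    secondary_tau_slow: float = 10.0

    def __post_init__(self):
        if self.Ib < 0 or self.peak_height < 0 or self.secondary_height < 0:
            raise ParameterError("insulin template levels must be >= 0")
        if not (0 < self.tau_fast < self.tau_slow):
            raise ParameterError("require 0 < tau_fast < tau_slow")
        if self.secondary_time is not None and not (
            0 < self.secondary_tau_fast < self.secondary_tau_slow
        ):
            raise ParameterError("require 0 < secondary_tau_fast < secondary_tau_slow")
        tail = self(180.0) - self.Ib
        if tail > 0.05 * max(self.Ib, 1e-12):
            raise ParameterError(
                f"template increment at 180 min ({tail:.3g} uU/ml) exceeds 5% of basal"
            )

    @staticmethod
    def _phase(t, height, tau_fast, tau_slow):
        t = np.maximum(t, 0.0)
        rf, rs = 1.0 / tau_fast, 1.0 / tau_slow
        # peak of e^(-rs t) - e^(-rf t) occurs at ln(rf/rs)/(rf - rs)
        tp = np.log(rf / rs) / (rf - rs)
        norm = np.exp(-rs * tp) - np.exp(-rf * tp)
        return height * (np.exp(-rs * t) - np.exp(-rf * t)) / norm

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.Ib)
        out = out + np.where(t > 0, self._phase(t, self.peak_height, self.tau_fast, self.tau_slow), 0.0)
        if self.secondary_time is not None:
            ts = t - self.secondary_time
            out = out + np.where(
                ts > 0,
                self._phase(ts, self.secondary_height, self.secondary_tau_fast, self.secondary_tau_slow),
                0.0,
            )
        return out if out.shape else float(out)

    def air_mean(self, window=(2.0, 10.0), schedule=None) -> float:
        """Trapezoidal mean insulin increment over ``window`` on a schedule
        (defaults to the per-minute schedule) — the template's AIRglucose."""
        times = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
        m = (times >= window[0]) & (times <= window[1])
        t = times[m]
        incr = np.asarray(self(t)) - self.Ib
        return float(np.trapezoid(incr, t) / (t[-1] - t[0]))

    def scaled_to_air(self, target_air: float, window=(2.0, 10.0), schedule=None):
        """Rescale the first-phase peak so the template AIR equals target."""
        cur = self.air_mean(window, schedule)
        if cur <= 0:
            raise ParameterError("template has non-positive AIR; cannot rescale")
        return replace(self, peak_height=self.peak_height * target_air / cur)

    def modified(self, agent: str = "insulin", time: float = 20.0) -> "InsulinCurveTemplate":
        """Template with the secondary peak switched on (modified protocol)."""
        if agent not in ("tolbutamide", "insulin"):
            raise ParameterError("secondary agent must be tolbutamide or insulin")
        return replace(self, secondary_time=time)


def _mean_one_lognormal(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))


def _noise_pair(noise_cv) -> tuple[float, float]:
    if noise_cv is None:
        return DEFAULT_NOISE_CV
    if np.isscalar(noise_cv):
        return float(noise_cv), float(noise_cv)
    g, i = noise_cv
    return float(g), float(i)


def generate_ivgtt(
    params: MinimalModelParams,
    template: InsulinCurveTemplate | None = None,
    schedule=None,
    noise_cv=None,
    seed: int | None = None,
    subject_id: str = "synthetic",
    insulin_input: str = "sampled",
    sim_step: float = 0.25,
) -> IVGTTRecord:
    """Generate one noisy IVGTT record with known ground truth.

    Insulin is sampled from the template on ``schedule``; glucose is then
    simulated from the minimal model driven by those samples
    (piecewise-linear), so a noiseless record is exactly self-consistent with
    the estimation machinery.  With ``insulin_input="continuous"`` glucose is
    instead driven by the template on a dense ``sim_step`` grid, introducing
    the sampling-discretisation mismatch present in real data.  Both observed
    series are perturbed by independent mean-one lognormal noise with the
    given CVs ((glucose, insulin) pair or a common scalar; default
    (0.02, 0.07)).
    """
    if seed is None:
        raise ConfigError("a seed is mandatory for synthetic data generation")
    if insulin_input not in ("sampled", "continuous"):
        raise ConfigError(f"unknown insulin_input mode {insulin_input!r}")
    tpl = template if template is not None else InsulinCurveTemplate(Ib=params.Ib)
    times = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    if not np.all(np.diff(times) > 0):
        raise DataError("schedule must be strictly increasing")
    post = times[times >= 0]
    if post.size == 0 or post[0] > 0:
        raise DataError("schedule must include t = 0 (injection)")

    if insulin_input == "sampled":
        insulin_true = InsulinInput(times, np.asarray(tpl(times), dtype=float))
    else:
        dense = np.arange(times[0], times[-1] + sim_step / 2, sim_step)
        insulin_true = InsulinInput(dense, np.asarray(tpl(dense), dtype=float))
    traj = simulate_minimal_model(params, insulin_true, post)

    glucose = np.where(times < 0, params.Gb, np.interp(times, post, traj.glucose))
    # exact at schedule points: interp is identity on `post`, Gb on basal draws
    insulin = np.asarray(tpl(times), dtype=float)

    cv_g, cv_i = _noise_pair(noise_cv)
    rng = np.random.default_rng(seed)
    glucose_obs = glucose * _mean_one_lognormal(rng, cv_g, times.size)
    insulin_obs = insulin * _mean_one_lognormal(rng, cv_i, times.size)

    sec = tpl.secondary_time
    protocol = Protocol(
        secondary_agent="none" if sec is None else "insulin",
        secondary_time=sec,
    )
    return IVGTTRecord(
        subject_id=subject_id,
        times=times,
        glucose=glucose_obs,
        insulin=insulin_obs,
        protocol=protocol,
        noise_cv=cv_g,
        meta={
            "truth": params,
            "template": tpl,
            "noise_cv": (cv_g, cv_i),
            "seed": int(seed),
            "glucose_noiseless": glucose,
            "insulin_noiseless": insulin,
        },
    )


def _draw(rng, spec, n, log=False):
    """Scalar -> constant column; (lo, hi) -> uniform (log-uniform if log)."""
    if np.isscalar(spec):
        return np.full(n, float(spec))
    lo, hi = spec
    if log:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    return rng.uniform(lo, hi, n)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic IVGTT cohort.

    Exactly one of ``di0`` (constant disposition index: AIR = DI0/SI, the
    rectangular-hyperbola law) or ``air_range`` (independent AIR draws) may
    be given; with neither, the unscaled default template is used.  ``si_range``
    is sampled log-uniformly; scalar fields are constants, (lo, hi) tuples
    uniform draws.
    """

    n: int
    seed: int
    di0: float | None = None
    si_range: tuple | float = (1e-4, 1e-3)
    air_range: tuple | float | None = None
    sg: tuple | float = 0.02
    p2: tuple | float = 0.03
    gb: tuple | float = 90.0
    ib: tuple | float = 10.0
    g0: tuple | float = 280.0
    vd_range: tuple | float = (1.6, 2.2)
    noise_cv: tuple | float | None = None
    air_window: tuple = (2.0, 10.0)
    modified_protocol: bool = False
    schedule: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("cohort size n must be >= 1")
        if self.di0 is not None and self.air_range is not None:
            raise ConfigError("give either di0 (hyperbola mode) or air_range, not both")
        if self.di0 is not None and self.di0 <= 0:
            raise ConfigError("di0 must be > 0")


def generate_population(spec: CohortSpec):
    """Generate a cohort of IVGTT records plus a ground-truth table.

    Per-subject AIR is realised by scaling the first-phase insulin peak so
    that the trapezoidal mean increment over the AIR window matches the
    target.  Returns (records, truth DataFrame with SI, SG, p2, AIR, DI, VD,
    basal levels and child seeds).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    si = _draw(rng, spec.si_range, n, log=True)
    sg = _draw(rng, spec.sg, n)
    p2 = _draw(rng, spec.p2, n)
    gb = _draw(rng, spec.gb, n)
    ib = _draw(rng, spec.ib, n)
    g0 = _draw(rng, spec.g0, n)
    vd = _draw(rng, spec.vd_range, n)
    child_seeds = rng.integers(0, 2**31 - 1, n)

    records, rows = [], []
    for j in range(n):
        tpl = InsulinCurveTemplate(Ib=ib[j])
        if spec.modified_protocol:
            tpl = tpl.modified()
        if spec.di0 is not None:
            air = spec.di0 / si[j]
            tpl = tpl.scaled_to_air(air, spec.air_window, spec.schedule)
        elif spec.air_range is not None:
            air = float(_draw(rng, spec.air_range, 1)[0])
            tpl = tpl.scaled_to_air(air, spec.air_window, spec.schedule)
        else:
            air = tpl.air_mean(spec.air_window, spec.schedule)
        params = MinimalModelParams(
            p1=sg[j], p2=p2[j], p3=si[j] * p2[j], Gb=gb[j], Ib=ib[j], G0=g0[j], VD=vd[j]
        )
        rec = generate_ivgtt(
            params,
            template=tpl,
            schedule=spec.schedule,
            noise_cv=spec.noise_cv,
            seed=int(child_seeds[j]),
            subject_id=f"S{j:03d}",
        )
        records.append(rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "SI": si[j],
                "SG": sg[j],
                "p2": p2[j],
                "p3": si[j] * p2[j],
                "AIR": air,
                "DI": si[j] * air,
                "VD": vd[j],
                "Gb": gb[j],
                "Ib": ib[j],
                "G0": g0[j],
                "seed": int(child_seeds[j]),
            }
        )
    return records, pd.DataFrame(rows)


def generate_clamp_cohort(
    n: int,
    seed: int,
    si_range=(1e-4, 1e-3),
    sg=0.02,
    p2=0.03,
    gb=90.0,
    ib=10.0,
    vd_range=(1.6, 2.2),
) -> list[MinimalModelParams]:
    """Parameter sets (with distribution volumes) for clamp-equivalence
    studies; SI log-uniform, VD uniform."""
    rng = np.random.default_rng(seed)
    si = _draw(rng, si_range, n, log=True)
    sgv = _draw(rng, sg, n)
    p2v = _draw(rng, p2, n)
    gbv = _draw(rng, gb, n)
    ibv = _draw(rng, ib, n)
    vdv = _draw(rng, vd_range, n)
    return [
        MinimalModelParams(
            p1=sgv[j], p2=p2v[j], p3=si[j] * p2v[j], Gb=gbv[j], Ib=ibv[j], G0=gbv[j], VD=vdv[j]
        )
        for j in range(n)
    ]


@dataclass(frozen=True)
class ClearancePair:
    """Matched-rate portal/peripheral infusion pair with known extraction."""

    portal: InfusionExperiment
    peripheral: InfusionExperiment
    f_true: float


def generate_clearance_cohort(
    n: int,
    seed: int,
    f_range=(0.22, 0.77),
    rate: float = 300.0,
    v_i: float = 60.0,
    k_sys: float = 0.15,
    ib: float = 10.0,
    noise_cv: float = 0.03,
) -> list[ClearancePair]:
    """Matched portal/peripheral infusion pairs across a range of first-pass
    extraction fractions (default uniform over 0.22-0.77).

    Steady-state incremental insulin for each route comes from the two-route
    model; measurement noise is mean-one lognormal with the given CV.
    """
    lo, hi = (f_range, f_range) if np.isscalar(f_range) else f_range
    if not (0 <= lo <= hi < 1):
        raise ConfigError("extraction fraction support must lie within [0, 1)")
    rng = np.random.default_rng(seed)
    f = _draw(rng, f_range, n)
    pairs = []
    for j in range(n):
        cp = ClearanceParams(F=float(f[j]), V_I=v_i, k_sys=k_sys, Ib=ib)
        out = []
        for route in ("portal", "peripheral"):
            exp = InfusionExperiment(route=route, rate=rate, noise_cv=noise_cv)
            res = simulate_two_route(cp, exp, duration=8.0 / k_sys)
            di = res.delta_i_ss * _mean_one_lognormal(rng, noise_cv, 1)[0]
            out.append(replace(exp, delta_i_ss=di))
        pairs.append(ClearancePair(portal=out[0], peripheral=out[1], f_true=float(f[j])))
    return pairs
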
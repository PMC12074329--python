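"""Seeded generator of synthetic CTG traces and labelled cohorts.

Real antepartum CTG archives are access-restricted, so the package ships a
generator that emulates the statistical structure the classifier relies on:
a slowly drifting fetal heart rate baseline, band-limited short-term
variability, transient accelerations, decelerations (optionally time-locked
to uterine contractions), smooth contraction bumps on the tone channel,
bursty missingness, and a class-conditional effect that attenuates
variability and accelerations while amplifying decelerations for the
adverse-outcome class.  Cohort metadata includes days-to-delivery and
clinical covariates deliberately confounded with the label so that
propensity-score matching downstream has real work to do.

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import MISSING, WINDOW_LEN, SAMPLE_PERIOD_S, CTGTrace
from .exceptions import ParameterError

__all__ = [
    "SimulationParams",
    "CohortSpec",
    "simulate_trace",
    "simulate_cohort",
    "inject_missingness",
]

FHR_LO, FHR_HI = 50.0, 250.0
TOCO_LO, TOCO_HI = 0.0, 100.0


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for one synthetic CTG trace.

    Defaults describe a term fetus on a one-hour, 960-step grid:
    baseline around 135 bpm, ~5 bpm short-term variability, a handful of
    accelerations and contractions per hour, and light bursty signal loss.
    ``adverse_effect`` (< 1) multiplies variability and the acceleration
    rate for adverse-labelled traces and divides the deceleration rate,
    producing the flatter, deceleration-heavy traces associated with
    compromised fetuses.
    """

    baseline_fhr_mean: float = 135.0  # bpm, must lie in the normal band [110, 160]
    baseline_fhr_sd: float = 8.0  # bpm, between-trace baseline spread
    stv_amplitude: float = 5.0  # bpm, short-term variability (noise SD)
    accel_rate: float = 8.0  # events / hour
    decel_rate: float = 2.0  # events / hour (spontaneous, on top of coupled ones)
    contraction_rate: float = 6.0  # events / hour
    decel_coupling: float = 0.3  # P(contraction triggers a deceleration)
    adverse_effect: float = 0.5  # class-conditional multiplier, < 1
    missing_rate: float = 0.05  # fraction of samples lost, in [0, 1)
    missing_burst_len: int = 20  # samples per dropout burst
    sample_count: int = WINDOW_LEN

    def validate(self) -> None:
        if not (110.0 <= self.baseline_fhr_mean <= 160.0):
            raise ParameterError("baseline_fhr_mean must lie in [110, 160] bpm")
        for name in ("baseline_fhr_sd", "stv_amplitude", "accel_rate",
                     "decel_rate", "contraction_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not (0.0 <= self.decel_coupling <= 1.0):
            raise ParameterError("decel_coupling must be in [0, 1]")
        if not (0.0 < self.adverse_effect):
            raise ParameterError("adverse_effect must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.missing_burst_len < 1:
            raise ParameterError("missing_burst_len must be >= 1")
        if self.sample_count < 1:
            raise ParameterError("sample_count must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Size, temporal range and seed of a synthetic labelled cohort."""

    n_normal: int
    n_adverse: int
    days_to_delivery_range: tuple[int, int] = (1, 7)
    seed: int = 0

    def validate(self) -> None:
        if self.n_normal < 0 or self.n_adverse < 0:
            raise ParameterError("cohort counts must be non-negative")
        lo, hi = self.days_to_delivery_range
        if not (1 <= lo <= hi <= 7):
            raise ParameterError("days_to_delivery_range must lie within [1, 7]")


def _gaussian_bump(n: int, center: float, sigma: float, amplitude: float) -> np.ndarray:
    t = np.arange(n)
    return amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def simulate_trace(
    params: SimulationParams, label: int, seed: int, trace_id: str = "trace",
    days_to_delivery: int = 1, covariates: dict | None = None,
) -> CTGTrace:
    """Generate one two-channel CTG trace.

    The adverse class (``label == 1``) has its short-term variability and
    acceleration rate multiplied by ``params.adverse_effect`` and its
    deceleration rate divided by it.  Non-missing FHR samples always lie in
    [50, 250] bpm and TOCO in [0, 100]; missing samples carry ``-1``.
    Bit-identical output for identical ``(params, label, seed)``.
    """
    params.validate()
    if label not in (0, 1):
        raise ParameterError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    n = params.sample_count
    hours = n * SAMPLE_PERIOD_S / 3600.0

    # per-trace physiological jitter so cohorts are not degenerate
    jitter = np.exp(rng.normal(0.0, 0.2, size=4))
    stv = params.stv_amplitude * jitter[0]
    accel_rate = params.accel_rate * jitter[1]
    decel_rate = params.decel_rate * jitter[2]
    contraction_rate = params.contraction_rate * jitter[3]
    if label == 1:
        stv *= params.adverse_effect
        accel_rate *= params.adverse_effect
        decel_rate /= params.adverse_effect

    # baseline: trace-level offset plus a slow bounded wander, kept inside
    # +/- 2.9 baseline SDs so event-free traces respect a 3-sigma envelope
    z0 = float(np.clip(rng.normal(), -2.0, 2.0))
    walk = np.cumsum(rng.normal(0.0, 1.0, size=n))
    walk = _smooth(walk, max(2, n // 16))
    sd = walk.std()
    if sd > 0:
        walk = walk / sd * 0.4
    baseline = params.baseline_fhr_mean + params.baseline_fhr_sd * np.clip(
        z0 + walk, -2.9, 2.9
    )

    # short-term variability: band-limited noise scaled to the target SD
    noise = _smooth(rng.normal(0.0, 1.0, size=n), 3)
    nsd = noise.std()
    variability = stv * (noise / nsd) if nsd > 0 else np.zeros(n)

    fhr = baseline + variability

    # accelerations: transient positive bumps (~ +15 bpm, ~15 s wide)
    for _ in range(rng.poisson(accel_rate * hours)):
        center = rng.uniform(0, n)
        amp = max(10.0, rng.normal(15.0, 3.0))
        fhr += _gaussian_bump(n, center, rng.uniform(2.0, 4.0), amp)

    # uterine contractions: smooth unimodal bumps on the tone channel
    toco = rng.uniform(5.0, 15.0) + _smooth(rng.normal(0.0, 2.0, size=n), 5)
    contraction_centers = []
    for _ in range(rng.poisson(contraction_rate * hours)):
        center = rng.uniform(0, n)
        contraction_centers.append(center)
        toco += _gaussian_bump(n, center, rng.uniform(6.0, 10.0), rng.uniform(30.0, 70.0))

    # decelerations: coupled to contraction peaks plus spontaneous ones
    decel_centers = [
        c + rng.uniform(0.0, 4.0)
        for c in contraction_centers
        if rng.uniform() < params.decel_coupling
    ]
    decel_centers += [rng.uniform(0, n) for _ in range(rng.poisson(decel_rate * hours))]
    for center in decel_centers:
        amp = max(12.0, rng.normal(22.0, 5.0))
        fhr -= _gaussian_bump(n, center, rng.uniform(5.0, 10.0), amp)

    fhr = np.clip(fhr, FHR_LO, FHR_HI)
    toco = np.clip(toco, TOCO_LO, TOCO_HI)

    trace = CTGTrace(
        trace_id=trace_id, fhr=fhr, toco=toco, label=label,
        days_to_delivery=days_to_delivery, covariates=covariates or {},
    )
    if params.missing_rate > 0:
        trace = inject_missingness(
            trace, params.missing_rate, params.missing_burst_len,
            seed=int(rng.integers(0, 2**31)),
        )
    return trace


def inject_missingness(
    trace: CTGTrace, rate: float, burst_len: int, seed: int
) -> CTGTrace:
    """Overwrite bursts of samples with the missing sentinel.

    Each channel receives its own independent dropout pattern.  The trace
    is divided into ``k = round(rate * T / burst_len)`` blocks and one
    burst of ``burst_len`` consecutive samples is placed uniformly inside
    each block, so the realised missing fraction tracks ``rate`` closely
    while runs keep a mean length near ``burst_len``.
    """
    if not (0.0 <= rate < 1.0):
        raise ParameterError("rate must be in [0, 1)")
    if burst_len < 1:
        raise ParameterError("burst_len must be >= 1")
    fhr = trace.fhr.copy()
    toco = trace.toco.copy()
    if rate > 0.0:
        rng = np.random.default_rng(seed)
        T = len(trace)
        for channel in (fhr, toco):
            k = int(round(rate * T / burst_len))
            if k == 0:
                continue
            edges = np.linspace(0, T, k + 1)
            for lo, hi in zip(edges[:-1], edges[1:]):
                span = hi - lo
                if span <= burst_len:
                    start = int(lo)
                else:
                    start = int(rng.uniform(lo, hi - burst_len))
                channel[start : min(start + burst_len, T)] = MISSING
    return replace(trace, fhr=fhr, toco=toco)


#: Covariate shifts applied to the adverse class (in covariate units);
#: these confound label with the matching covariates on purpose.
_COVARIATE_MODEL = {
    "gestational_age": (275.0, 7.0, -3.5),  # days: mean, sd, adverse shift
    "maternal_age": (30.0, 5.0, 2.0),  # years
    "bmi": (26.0, 4.0, 1.5),  # kg/m^2
    "parity": (1.0, 1.0, 0.4),  # prior births (continuous proxy)
}


def simulate_cohort(
    spec: CohortSpec,
    params: SimulationParams,
    day_adverse_effect=None,
) -> tuple[list[CTGTrace], pd.DataFrame]:
    """Generate a labelled cohort of traces plus its metadata table.

    Parameters
    ----------
    spec : CohortSpec
    params : SimulationParams
    day_adverse_effect : callable, optional
        Maps days-to-delivery to an ``adverse_effect`` override for adverse
        traces, letting experiments plant a temporal gradient in class
        signal strength.

    Returns
    -------
    traces : list of CTGTrace
    metadata : DataFrame with trace_id, label, days_to_delivery and the
        matching covariates (confounded with the label).
    """
    spec.validate()
    params.validate()
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_normal + spec.n_adverse
    trace_seeds = ss.generate_state(n_total + 1)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = spec.days_to_delivery_range

    labels = np.array([0] * spec.n_normal + [1] * spec.n_adverse)
    traces: list[CTGTrace] = []
    rows = []
    for i, label in enumerate(labels):
        days = int(meta_rng.integers(lo, hi + 1))
        covs = {
            name: mean + meta_rng.normal(0.0, sd) + shift * label
            for name, (mean, sd, shift) in _COVARIATE_MODEL.items()
        }
        trace_params = params
        if label == 1 and day_adverse_effect is not None:
            trace_params = replace(params, adverse_effect=float(day_adverse_effect(days)))
        trace = simulate_trace(
            trace_params, int(label), int(trace_seeds[i]),
            trace_id=f"sim{i:05d}", days_to_delivery=days, covariates=covs,
        )
        traces.append(trace)
        rows.append({"trace_id": trace.trace_id, "label": int(label),
                     "days_to_delivery": days, **covs})
    metadata = pd.DataFrame(
        rows, columns=["trace_id", "label", "days_to_delivery", *_COVARIATE_MODEL],
    )
    return traces, metadata
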
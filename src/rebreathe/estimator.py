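"""Two-breath rebreathing estimator for effective lung volume and FRC.

The effective lung volume (ELV) is the volume in which CO2 equilibrates
during rebreathing: the gas compartment (FRC) plus lung tissue and
pulmonary capillary blood. At end-expiration the external dead space of
known volume DV holds CO2 at a representative partial pressure avPet
(sampled mid-dead-space). Re-inspiring that gas raises the end-tidal value
by

    dPet = avPet * DV / ELV        =>        ELV = avPet * DV / dPet.

A single-breath estimate hangs on one data point, so a weighted average of
the first two breaths is used instead. With the cumulative rises
dPet1 = Pet(1) - Pet(0) and dPet2 = Pet(2) - Pet(0),

    dPet = 0.5 * (dPet1 + w * dPet2)
    ELV  = 2 * avPet * DV / (dPet1 + w * dPet2)

with default weight w = 0.57. The weight discounts the second breath for
its departure from the initial linear rise: for exponential wash-in with
rate k and breath period T, dPet2 = dPet1 * (1 + exp(-k T)), so

    w = 1 / (1 + exp(-k T))

makes the two-breath estimator exact; at k = 0.06 s^-1 and T = 5 s this
evaluates to 0.574, matching the fixed default. FRC follows from the
healthy-lung proportionality FRC = K * ELV with K = 0.82 (disease-specific
alternatives around 0.88 / 0.77 can be supplied via ``k_constant``).

ELV is a pressure ratio times DV, so it is invariant to the pressure unit
and to analyzer gain; absolute accuracy is set by how well DV is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .capnogram import BreathSegment, CapnogramTrace, breath_periods, segment_breaths
from .errors import (
    InsufficientBreathsError,
    KineticsFitError,
    NonRisingPetError,
)

__all__ = [
    "DeadSpaceConfig",
    "EstimatorConfig",
    "KineticsFit",
    "RebreathingEstimate",
    "compute_deltas",
    "second_breath_weight",
    "estimate_elv",
    "convert_elv_to_frc",
    "fit_rebreathing_kinetics",
    "fit_pet_geometric",
    "qc_measurement",
    "estimate_from_trace",
]

DEFAULT_WEIGHT = 0.57
DEFAULT_K_CONSTANT = 0.82


@dataclass(frozen=True)
class DeadSpaceConfig:
    """External rebreathing dead space: mouthpiece + filter + pipe.

    The study hardware has ``volume`` 0.148 L known to better than 3 mL;
    that tolerance bounds the absolute accuracy of ELV.
    """

    volume: float = 0.148
    volume_tolerance: float = 0.003

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("dead-space volume must be positive")
        if self.volume_tolerance < 0:
            raise ValueError("volume_tolerance must be >= 0")


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunable constants of the estimator and its QC gates.

    ``weight`` may be a number or ``"auto"``; auto fits the wash-in
    kinetics from all available breaths and derives the weight from the
    fitted per-breath decay, falling back to 0.57 when the fit fails.
    """

    weight: float | str = DEFAULT_WEIGHT
    k_constant: float = DEFAULT_K_CONSTANT
    dv_tv_low: float = 0.10
    dv_tv_high: float = 0.25
    regularity_cv_limit: float = 0.25
    pet_drop_tolerance_kpa: float = 0.1

    def __post_init__(self) -> None:
        if isinstance(self.weight, str):
            if self.weight != "auto":
                raise ValueError("weight must be a number or 'auto'")
        elif not 0 < float(self.weight) <= 1:
            raise ValueError("weight must be in (0, 1]")
        if not 0 < self.k_constant <= 1:
            raise ValueError("k_constant must be in (0, 1]")


@dataclass(frozen=True)
class KineticsFit:
    """Fitted exponential wash-in Pet(t) = pet0 + dP_inf (1 - exp(-k t))."""

    k_rate: float
    delta_p_inf: float
    pet0: float


@dataclass(frozen=True)
class RebreathingEstimate:
    """Full output record of one rebreathing measurement."""

    av_pet: float
    delta_pet1: float
    delta_pet2: float
    weight_w: float
    delta_pet: float
    elv: float
    k_constant: float
    frc: float
    qc_flags: frozenset[str] = frozenset()
    tv_estimate: float | None = None
    n_breaths: int = 0
    kinetics: KineticsFit | None = None
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        """True when an ELV was computed and no QC flag fired."""
        return not self.qc_flags and math.isfinite(self.elv)


def _pets(segments: Sequence[BreathSegment] | Sequence[float]) -> np.ndarray:
    vals = [s.pet if isinstance(s, BreathSegment) else float(s) for s in segments]
    return np.asarray(vals, dtype=float)


def compute_deltas(
    segments: Sequence[BreathSegment] | Sequence[float],
    check: bool = True,
) -> tuple[float, float, float]:
    """(avPet, dPet1, dPet2) from the first three breaths.

    avPet is the end-tidal value of breath 0 (the expiration filling the
    dead space); dPet1 and dPet2 are the cumulative rises of breaths 1 and
    2 over breath 0. With ``check`` (default) a non-rising sequence raises
    :class:`NonRisingPetError`; QC paths pass ``check=False`` and flag
    instead.
    """
    pets = _pets(segments)
    if pets.size < 3:
        raise InsufficientBreathsError(
            f"insufficient breaths: got {pets.size}, need >= 3"
        )
    av_pet = float(pets[0])
    d1 = float(pets[1] - pets[0])
    d2 = float(pets[2] - pets[0])
    if check and (d1 <= 0 or d2 <= 0):
        raise NonRisingPetError(
            f"non-rising Pet: dPet1={d1:.4g}, dPet2={d2:.4g} kPa"
        )
    return av_pet, d1, d2


def second_breath_weight(k_rate: float, breath_period: float) -> float:
    """Weight of the second breath from the wash-in rate constant.

    ``w = 1 / (1 + exp(-k T))``: 0.5 in the linear (k -> 0) limit where the
    cumulative two-breath rise is exactly twice the one-breath rise, 1.0 in
    the fast-equilibration limit, and 0.574 at k = 0.06 s^-1, T = 5 s.
    """
    if k_rate < 0:
        raise ValueError("k_rate must be >= 0")
    if breath_period <= 0:
        raise ValueError("breath_period must be positive")
    return float(1.0 / (1.0 + np.exp(-k_rate * breath_period)))


def estimate_elv(
    av_pet: float,
    dead_space: DeadSpaceConfig | float,
    delta_pet1: float,
    delta_pet2: float,
    weight: float = DEFAULT_WEIGHT,
) -> float:
    """ELV (litres) from the two-breath weighted rise.

    ``ELV = 2 avPet DV / (dPet1 + w dPet2)``. Being a pressure ratio the
    result is invariant to the pressure unit and analyzer gain.
    """
    dv = dead_space.volume if isinstance(dead_space, DeadSpaceConfig) else float(dead_space)
    if av_pet <= 0:
        raise ValueError("av_pet must be positive")
    if dv <= 0:
        raise ValueError("dead-space volume must be positive")
    denom = delta_pet1 + weight * delta_pet2
    if denom <= 0:
        raise NonRisingPetError(
            f"non-rising Pet: weighted rise {denom:.4g} kPa is not positive"
        )
    return 2.0 * av_pet * dv / denom


def convert_elv_to_frc(elv: float, k_constant: float = DEFAULT_K_CONSTANT) -> float:
    """FRC = K * ELV with the healthy-lung default K = 0.82."""
    if elv <= 0:
        raise ValueError("elv must be positive")
    if not 0 < k_constant <= 1:
        raise ValueError("k_constant must be in (0, 1]")
    return k_constant * elv


def fit_rebreathing_kinetics(
    breath_times: Sequence[float],
    pets: Sequence[float],
) -> KineticsFit:
    """Least-squares fit of the exponential wash-in over all breaths.

    ``Pet(t) = pet0 + dP_inf (1 - exp(-k (t - t0)))`` with t0 the first
    breath's time. Needs at least 4 breaths spanning at least 15 s.
    """
    t = np.asarray(breath_times, dtype=float)
    p = np.asarray(pets, dtype=float)
    if t.size != p.size:
        raise ValueError("breath_times and pets must have equal length")
    if t.size < 4 or (t[-1] - t[0]) < 15.0:
        raise ValueError(
            "kinetics fit needs >= 4 breaths spanning >= 15 s "
            f"(got {t.size} over {t[-1] - t[0]:.1f} s)"
        )
    tt = t - t[0]

    def model(tt, pet0, dpinf, k):
        return pet0 + dpinf * (1.0 - np.exp(-k * tt))

    d1 = p[1] - p[0]
    d2 = p[2] - p[1]
    if d1 > 0 and 0 < d2 < d1:
        k0 = -np.log(d2 / d1) / (tt[2] - tt[1])
    else:
        k0 = 0.06
    dpinf0 = max(2.0 * (p[-1] - p[0]), 1e-3)
    try:
        popt, _ = curve_fit(
            model,
            tt,
            p,
            p0=[p[0], dpinf0, max(k0, 1e-4)],
            bounds=([-np.inf, 1e-9, 1e-6], [np.inf, np.inf, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise KineticsFitError(f"kinetics fit failed: {exc}") from exc
    pet0, dpinf, k = (float(v) for v in popt)
    return KineticsFit(k_rate=k, delta_p_inf=dpinf, pet0=pet0)


def fit_pet_geometric(pets: Sequence[float]) -> tuple[float, float, float]:
    """Fit the breath-indexed geometric wash-in Pet(n) = p0 + A (1 - rho^n).

    Working in breath index rather than clock time makes the fit immune to
    breath-onset timing jitter from segmentation; rho is the per-breath
    decay exp(-k T), so the refined second-breath weight is 1/(1 + rho).
    Raises :class:`KineticsFitError` when the sequence is not compatible
    with a rising saturating exponential (rho outside (0, 1)).
    """
    p = _pets(pets)
    if p.size < 3:
        raise KineticsFitError("geometric fit needs >= 3 breaths")
    d1 = p[1] - p[0]
    d2 = p[2] - p[1]
    if d1 <= 0 or d2 <= 0:
        raise KineticsFitError("geometric fit needs a rising Pet sequence")
    rho0 = d2 / d1
    if not 0 < rho0 < 1:
        raise KineticsFitError(f"per-breath decay {rho0:.3f} outside (0, 1)")
    if p.size == 3:
        return float(p[0]), float(d1 / (1.0 - rho0)), float(rho0)

    def residuals(theta):
        p0, amp, rho = theta
        n = np.arange(p.size, dtype=float)
        return p0 + amp * (1.0 - rho**n) - p

    sol = least_squares(
        residuals,
        x0=[p[0], d1 / (1.0 - rho0), rho0],
        bounds=([-np.inf, 1e-12, 1e-9], [np.inf, np.inf, 1.0 - 1e-9]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise KineticsFitError(f"geometric fit failed: {sol.message}")
    p0, amp, rho = (float(v) for v in sol.x)
    if not 0 < rho < 1:
        raise KineticsFitError(f"fitted per-breath decay {rho:.3f} outside (0, 1)")
    return p0, amp, rho


def qc_measurement(
    segments: Sequence[BreathSegment],
    estimate: RebreathingEstimate | None = None,
    dead_space: DeadSpaceConfig | None = None,
    tv_estimate: float | None = None,
    regularity_cv_limit: float = 0.25,
    pet_drop_tolerance_kpa: float = 0.1,
) -> frozenset[str]:
    """Quality-control flags for one measurement; never raises.

    * ``dv_tv_low`` / ``dv_tv_high`` - DV/TV outside the 0.10-0.25 window
      where the dead space is neither too small (poor precision) nor too
      large (breaths leave the linear rise; mid-DV sampling stops being
      representative). Only evaluated when a tidal volume is supplied.
    * ``irregular`` - the coefficient of variation of the three breath
      periods around the analysed breaths exceeds ``regularity_cv_limit``,
      or the end-tidal sequence drops by more than
      ``pet_drop_tolerance_kpa`` anywhere in the record. Irregular
      breathing perturbs both timing and depth; a Pet fall beyond the
      extraction noise floor is incompatible with monotone wash-in.
    * ``leak_suspected`` - Pet fails to rise (dPet1 <= 0) or falls between
      breaths 1 and 2, the signature of dead-space gas escaping.
    * ``insufficient_breaths`` - fewer than three breaths available.
    """
    flags: set[str] = set()
    if len(segments) < 3:
        return frozenset({"insufficient_breaths"})
    if tv_estimate is not None and dead_space is not None:
        ratio = dead_space.volume / tv_estimate
        if ratio < 0.10:
            flags.add("dv_tv_low")
        elif ratio > 0.25:
            flags.add("dv_tv_high")
    periods = breath_periods(segments[:4])
    if periods.size >= 2:
        cv = float(np.std(periods, ddof=1) / np.mean(periods))
        if cv > regularity_cv_limit:
            flags.add("irregular")
    all_pets = np.array([s.pet for s in segments], dtype=float)
    if all_pets.size >= 2 and float(np.min(np.diff(all_pets))) < -pet_drop_tolerance_kpa:
        flags.add("irregular")
    if estimate is not None:
        d1 = estimate.delta_pet1
        pet1 = estimate.av_pet + estimate.delta_pet1
        pet2 = estimate.av_pet + estimate.delta_pet2
    else:
        av, d1, d2 = compute_deltas(segments[:3], check=False)
        pet1, pet2 = av + d1, av + d2
    if d1 <= 0 or pet2 < pet1:
        flags.add("leak_suspected")
    return frozenset(flags)


def _resolve_weight(
    segments: Sequence[BreathSegment],
    config: EstimatorConfig,
) -> tuple[float, KineticsFit | None]:
    if config.weight != "auto":
        return float(config.weight), None
    try:
        pet0, amp, rho = fit_pet_geometric([s.pet for s in segments])
    except KineticsFitError:
        return DEFAULT_WEIGHT, None
    w = 1.0 / (1.0 + rho)
    periods = breath_periods(segments)
    kin = None
    if periods.size:
        T = float(np.mean(periods))
        kin = KineticsFit(k_rate=-math.log(rho) / T, delta_p_inf=amp, pet0=pet0)
    return float(w), kin


def estimate_from_trace(
    trace: CapnogramTrace,
    dead_space: DeadSpaceConfig | float = DeadSpaceConfig(),
    config: EstimatorConfig = EstimatorConfig(),
    tv_estimate: float | None = None,
    **segment_kwargs,
) -> RebreathingEstimate:
    """Full pipeline: segment a trace, apply the two-breath estimator, QC.

    Returns an estimate record in all recoverable situations; ELV/FRC are
    NaN (with explanatory QC flags) when too few breaths are found or the
    weighted Pet rise is not positive. A flat trace with no respiratory
    signal still raises, since there is no measurement to record.
    """
    if not isinstance(dead_space, DeadSpaceConfig):
        dead_space = DeadSpaceConfig(volume=float(dead_space))
    nan = float("nan")
    try:
        segments = segment_breaths(trace, **segment_kwargs)
    except InsufficientBreathsError:
        return RebreathingEstimate(
            av_pet=nan, delta_pet1=nan, delta_pet2=nan,
            weight_w=nan, delta_pet=nan, elv=nan,
            k_constant=config.k_constant, frc=nan,
            qc_flags=frozenset({"insufficient_breaths"}),
            tv_estimate=tv_estimate, n_breaths=0,
        )
    av_pet, d1, d2 = compute_deltas(segments[:3], check=False)
    weight, kinetics = _resolve_weight(segments, config)
    denom = d1 + weight * d2
    if denom > 0 and av_pet > 0:
        elv = 2.0 * av_pet * dead_space.volume / denom
        frc = config.k_constant * elv
    else:
        elv = frc = nan
    estimate = RebreathingEstimate(
        av_pet=av_pet,
        delta_pet1=d1,
        delta_pet2=d2,
        weight_w=weight,
        delta_pet=0.5 * denom,
        elv=elv,
        k_constant=config.k_constant,
        frc=frc,
        tv_estimate=tv_estimate,
        n_breaths=len(segments),
        kinetics=kinetics,
    )
    flags = qc_measurement(
        segments,
        estimate,
        dead_space,
        tv_estimate=tv_estimate,
        regularity_cv_limit=config.regularity_cv_limit,
        pet_drop_tolerance_kpa=config.pet_drop_tolerance_kpa,
    )
    return RebreathingEstimate(
        **{
            **estimate.__dict__,
            "qc_flags": flags,
        }
    )
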
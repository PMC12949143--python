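"""Synthetic rebreathing capnogram generator with known ground truth.

The subject breathes in and out of an external dead space of volume DV.
Expired CO2 is re-inspired, so the end-tidal partial pressure Pet climbs
breath by breath, at first almost linearly and then towards a plateau; the
kinetics are summarised by a single exponential with rate constant k
(about 0.06 s^-1 in resting adults, plateau reached in roughly 30-40 s).

Breath-wise model: with breath period T = 60/RR and a = exp(-k T),

    Pet(n) = Pet0 + dP_inf * (1 - a^n),      n = 0, 1, 2, ...

where breath 0 is the expiration that fills the dead space (Pet(0) = Pet0)
and the plateau rise is tied to the ground-truth effective lung volume by

    dP_inf = Pet0 * DV / (ELV * (1 - a)),

so the first-breath rise equals the ideal single-breath increment
Pet0*DV/ELV exactly. That makes zero-noise parameter recovery an exact
oracle for the whole pipeline: segmentation, end-tidal extraction and the
two-breath estimator reproduce ELV to machine precision when noise,
analyzer lag and transport delay are switched off.

The rendered waveform has per-breath structure (sigmoid expiratory
upstroke, rising alveolar plateau with a short end-expiratory pause,
inspiratory downstroke to the dead-space gas trough), followed by a
first-order analyzer lag, a transport delay and additive Gaussian noise,
mimicking a sidestream-sampled signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .capnogram import CapnogramTrace, segment_breaths
from .errors import RebreatheError

__all__ = [
    "SimulatorParams",
    "GroundTruth",
    "simulate_pet_sequence",
    "synthesize_waveform",
    "simulate_trace",
    "inject_artifacts",
]


@dataclass(frozen=True)
class SimulatorParams:
    """Ground-truth lung and breathing parameters for one simulated subject.

    Defaults are a typical resting adult from the study conditions this
    simulator emulates: ELV 3 L, tidal volume 1.1 L, respiratory rate
    11 breaths/min, external dead space 0.148 L, baseline end-tidal
    5 kPa, wash-in rate constant 0.06 s^-1. Noise SD 0.05 kPa, analyzer
    lag 0.15 s and transport delay 0.5 s are typical sidestream-analyzer
    figures.
    """

    elv_true: float = 3.0
    tv: float = 1.1
    rr: float = 11.0
    dead_space: float = 0.148
    pet0: float = 5.0
    k_rate: float = 0.06
    noise_sd: float = 0.05
    analyzer_tau: float = 0.15
    transport_delay: float = 0.5
    sample_rate: float = 25.0
    frc_constant: float = 0.82
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.elv_true <= 0:
            raise ValueError("elv_true must be positive")
        if self.tv <= 0:
            raise ValueError("tv must be positive")
        if not 0 < self.rr <= 40:
            raise ValueError("rr must be in (0, 40] breaths/min")
        if self.dead_space <= 0:
            raise ValueError("dead_space must be positive")
        if self.k_rate <= 0:
            raise ValueError("k_rate must be positive")
        ratio = self.dead_space / self.tv
        if not 0 < ratio < 0.5:
            raise ValueError(
                f"dead_space/tv = {ratio:.3f} outside (0, 0.5): unphysical setup"
            )
        if self.pet0 <= 0:
            raise ValueError("pet0 must be positive")
        if min(self.noise_sd, self.analyzer_tau, self.transport_delay) < 0:
            raise ValueError("noise_sd, analyzer_tau, transport_delay must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def breath_period(self) -> float:
        """Breath period T = 60/RR in seconds."""
        return 60.0 / self.rr

    @property
    def frc_true(self) -> float:
        """Ground-truth FRC implied by the FRC/ELV constant."""
        return self.frc_constant * self.elv_true


@dataclass(frozen=True)
class GroundTruth:
    """Breath-wise end-tidal sequence and derived quantities, for testing."""

    pet: np.ndarray
    delta_p_inf: float
    per_breath_increment_ideal: float
    breath_period: float

    @property
    def n_breaths(self) -> int:
        return int(self.pet.size)


def simulate_pet_sequence(params: SimulatorParams, n_breaths: int = 6) -> GroundTruth:
    """Closed-form breath-wise Pet sequence for the single-exponential wash-in.

    ``Pet(n) = pet0 + dP_inf (1 - a^n)`` with ``a = exp(-k T)`` and the
    plateau rise chosen so the first-breath increment equals the ideal
    increment ``pet0 * DV / ELV``.
    """
    if n_breaths < 3:
        raise ValueError("n_breaths must be >= 3")
    T = params.breath_period
    a = float(np.exp(-params.k_rate * T))
    increment = params.pet0 * params.dead_space / params.elv_true
    delta_p_inf = increment / (1.0 - a)
    n = np.arange(n_breaths, dtype=float)
    pet = params.pet0 + delta_p_inf * (1.0 - a**n)
    return GroundTruth(
        pet=pet,
        delta_p_inf=float(delta_p_inf),
        per_breath_increment_ideal=float(increment),
        breath_period=T,
    )


def _first_order_lag(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Discrete first-order low-pass (analyzer cell response)."""
    alpha = 1.0 - np.exp(-dt / tau)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):
        y[i] = y[i - 1] + alpha * (x[i] - y[i - 1])
    return y


def synthesize_waveform(
    ground_truth: GroundTruth,
    params: SimulatorParams,
    *,
    seed: int | None = None,
    lead_in_s: float = 1.0,
    upstroke_s: float = 0.4,
    downstroke_s: float = 0.3,
    plateau_rise_kpa: float = 0.2,
    end_exp_hold_s: float = 0.15,
    trough_retention: float = 0.8,
    exp_fraction: float = 0.6,
) -> CapnogramTrace:
    """Render a breath-wise Pet sequence as a realistic sampled capnogram.

    Each breath occupies one period T: a sigmoid expiratory upstroke, a
    linearly rising alveolar plateau terminating at that breath's Pet, a
    short end-expiratory pause at exactly Pet (so end-tidal read-back is
    exact at zero distortion), then a sigmoid inspiratory downstroke to the
    trough. During rebreathing the trough is the dead-space gas level,
    ``trough_retention`` times the previous end-tidal value, rather than
    near zero. The clean waveform is then passed through a first-order lag
    (``analyzer_tau``), shifted by ``transport_delay`` and given additive
    Gaussian noise of SD ``noise_sd``.
    """
    fs = params.sample_rate
    dt = 1.0 / fs
    T = ground_truth.breath_period
    pet = ground_truth.pet
    n_breaths = pet.size
    n_samples = int(round((lead_in_s + n_breaths * T) * fs))
    t = np.arange(n_samples) * dt
    x = np.zeros(n_samples)

    te = exp_fraction * T
    ru = min(upstroke_s, 0.3 * te)
    hold = min(end_exp_hold_s, 0.3 * te)
    rd = min(downstroke_s, 0.3 * (T - te))
    troughs_before = np.concatenate(([0.0], trough_retention * pet[:-1]))

    def smooth(u: np.ndarray) -> np.ndarray:
        return 0.5 - 0.5 * np.cos(np.pi * np.clip(u, 0.0, 1.0))

    for b in range(n_breaths):
        t0 = lead_in_s + b * T
        lo = int(np.searchsorted(t, t0 - 0.5 * dt))
        hi = int(np.searchsorted(t, t0 + T - 0.5 * dt))
        local = t[lo:hi] - t0
        p = float(pet[b])
        tr0 = float(troughs_before[b])
        tr1 = trough_retention * p
        p_start = max(tr0 + 0.5 * (p - tr0), p - plateau_rise_kpa)
        y = np.empty_like(local)

        m = local < ru
        y[m] = tr0 + (p_start - tr0) * smooth(local[m] / ru)
        m = (local >= ru) & (local < te - hold)
        y[m] = p_start + (p - p_start) * (local[m] - ru) / (te - hold - ru)
        m = (local >= te - hold) & (local < te)
        y[m] = p  # end-expiratory pause: samples sit exactly at Pet
        m = (local >= te) & (local < te + rd)
        y[m] = p + (tr1 - p) * smooth((local[m] - te) / rd)
        m = local >= te + rd
        y[m] = tr1
        x[lo:hi] = y

    if params.analyzer_tau > 0:
        x = _first_order_lag(x, dt, params.analyzer_tau)
    if params.transport_delay > 0:
        shift = int(round(params.transport_delay * fs))
        if shift > 0:
            x = np.concatenate((np.full(shift, x[0]), x[:-shift]))
    used_seed = seed if seed is not None else params.seed
    if params.noise_sd > 0:
        rng = np.random.default_rng(used_seed)
        x = x + rng.normal(0.0, params.noise_sd, n_samples)
    np.clip(x, 0.0, None, out=x)
    meta = {
        "seed": used_seed,
        "simulator": dataclasses.asdict(params),
        "n_breaths": int(n_breaths),
    }
    return CapnogramTrace(times=t, pco2=x, sample_rate=fs, meta=meta)


def simulate_trace(
    params: SimulatorParams,
    n_breaths: int = 6,
    *,
    seed: int | None = None,
    **waveform_kwargs,
) -> tuple[CapnogramTrace, GroundTruth]:
    """Convenience: Pet sequence plus rendered waveform in one call."""
    gt = simulate_pet_sequence(params, n_breaths)
    trace = synthesize_waveform(gt, params, seed=seed, **waveform_kwargs)
    return trace, gt


def inject_artifacts(
    trace: CapnogramTrace,
    mode: str,
    severity: float,
    *,
    seed: int | None = None,
) -> CapnogramTrace:
    """Corrupt a trace with one of the two clinically observed failure modes.

    ``leak``
        Mouthpiece leakage: dead-space CO2 escapes, so every pressure from
        the onset of rebreathing (end of the first expiration) onward is
        scaled down by ``1 - severity``.
    ``irregular_breathing``
        Breath periods and amplitudes are jittered multiplicatively by
        about +/- ``severity``*100%: per-breath log-normal factors with
        log-SD ``log(1 + severity)``. Period jitter time-warps each breath;
        amplitude jitter scales the expiratory excursion above the local
        baseline (the inspiratory trough), leaving the baseline in place.

    In the ``severity -> 0`` limit both modes return the input unchanged.
    """
    if mode not in ("irregular_breathing", "leak"):
        raise ValueError(f"unknown artifact mode: {mode!r}")
    if not 0 < severity <= 1:
        raise ValueError("severity must be in (0, 1]")
    try:
        segments = segment_breaths(trace)
    except RebreatheError as exc:  # pragma: no cover - needs a broken fixture
        raise ValueError(f"cannot locate breaths for artifact injection: {exc}")

    if mode == "leak":
        onset = segments[0].t_exp_end
        scale = np.where(trace.times > onset, 1.0 - severity, 1.0)
        pco2 = trace.pco2 * scale
        meta = {**trace.meta, "artifact": {"mode": mode, "severity": severity}}
        return CapnogramTrace(trace.times, pco2, trace.sample_rate, meta)

    rng = np.random.default_rng(seed)
    sigma = float(np.log1p(severity))
    fs = trace.sample_rate
    starts = [
        int(np.searchsorted(trace.times, s.t_exp_start - 0.5 / fs))
        for s in segments
    ]
    bounds = starts + [len(trace)]
    pieces = [trace.pco2[: bounds[0]]]  # lead-in untouched
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = trace.pco2[a:b]
        if chunk.size < 2:
            pieces.append(chunk)
            continue
        f_period, f_amp = np.exp(sigma * rng.standard_normal(2))
        base = float(chunk.min())
        scaled = base + f_amp * (chunk - base)
        m_new = max(2, int(round(chunk.size * f_period)))
        xi = np.linspace(0.0, chunk.size - 1.0, m_new)
        pieces.append(np.interp(xi, np.arange(chunk.size), scaled))
    pco2 = np.clip(np.concatenate(pieces), 0.0, None)
    times = np.arange(pco2.size) / fs
    meta = {
        **trace.meta,
        "artifact": {"mode": mode, "severity": severity, "seed": seed},
    }
    return CapnogramTrace(times, pco2, fs, meta)
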
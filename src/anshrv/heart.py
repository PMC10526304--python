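"""Beat generation: integral pulse frequency modulation driven by m(t).

The autonomic neural signal modulates an integrate-and-fire pacemaker:
beat ``k+1`` is emitted at the smallest ``t`` with

    ∫_{t_k}^{t} m(u) / T0 du = 1

where ``T0`` (``base_period_s``) is the pacemaker period at unit drive.
Constant ``m`` therefore gives RR = T0 / m exactly, and slow modulation of
``m`` is transferred into the RR tachogram — the property the spectral
HRV analysis relies on.  Measurement/biological jitter is represented by
additive zero-mean Gaussian noise on the emitted RR intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (
    AutonomicSignal,
    Branch,
    BranchKinetics,
    DepletionSpec,
    SYMPATHETIC_BAND_HZ,
    VAGAL_BAND_HZ,
    autonomic_signal,
    branch_signal,
    build_stimulus_train,
    cross_couple,
    full_transmitter_signal,
    simulate_concentration,
    tonic_signal_level,
)

__all__ = [
    "RRSeries",
    "SimConfig",
    "InsufficientDurationError",
    "ipfm_beats",
    "add_output_noise",
    "simulate_rr",
]

logger = logging.getLogger(__name__)


class InsufficientDurationError(ValueError):
    """Signal too short to produce at least two beats."""


@dataclass(frozen=True)
class RRSeries:
    """An inter-beat interval series with its provenance.

    ``beat_times_s`` are the noise-free IPFM beat instants; ``rr_ms`` are
    the emitted intervals after output noise, so ``diff(beat_times_s)``
    reproduces the pre-noise intervals, not ``rr_ms``.
    """

    rr_ms: np.ndarray
    beat_times_s: np.ndarray
    seed: int
    noise_sd_ms: float
    base_period_s: float
    alpha: float = 1.0
    depletion_mode: str = "junction_conc"

    def __post_init__(self):
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(
            self, "beat_times_s", np.asarray(self.beat_times_s, dtype=float)
        )
        if rr.size and np.any(rr <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.rr_ms)


def ipfm_beats(signal: AutonomicSignal, base_period_s: float) -> np.ndarray:
    """Integral pulse frequency modulation: beat times from m(t).

    Trapezoidal cumulative integration of ``m / base_period_s`` on the
    signal grid; threshold crossings located by linear interpolation.
    The first beat is at t = 0.
    """
    if base_period_s <= 0:
        raise ValueError("base_period_s must be positive")
    from scipy.integrate import cumulative_trapezoid

    phase = cumulative_trapezoid(signal.m / base_period_s, signal.t_s, initial=0.0)
    n_beats = int(np.floor(phase[-1]))
    if n_beats < 1:
        raise InsufficientDurationError(
            f"signal of {signal.t_s[-1]:.1f} s yields fewer than 2 beats"
        )
    # phase is strictly increasing because m > 0
    return np.interp(np.arange(n_beats + 1, dtype=float), phase, signal.t_s)


def add_output_noise(
    rr_ms: np.ndarray, noise_sd_ms: float = 10.0, seed: int = 0
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise (default SD 10 ms) to each RR.

    Any interval driven non-positive is redrawn (with a warning); the
    redraw is deterministic under the seed.
    """
    if noise_sd_ms < 0:
        raise ValueError("noise_sd_ms must be non-negative")
    rr = np.asarray(rr_ms, dtype=float)
    if noise_sd_ms == 0:
        return rr.copy()
    rng = np.random.default_rng(seed)
    out = rr + rng.normal(0.0, noise_sd_ms, size=rr.shape)
    bad = out <= 0
    n_redraws = 0
    while np.any(bad):
        out[bad] = rr[bad] + rng.normal(0.0, noise_sd_ms, size=int(bad.sum()))
        n_redraws += int(bad.sum())
        bad = out <= 0
    if n_redraws:
        logger.warning("redrew %d noise deviates that drove RR <= 0", n_redraws)
    return out


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one RR-series simulation.

    The kinetic parameters default to the package's calibrated values
    (see :mod:`anshrv.params`); pass explicit ``BranchKinetics`` to
    override.  ``seed`` drives every stochastic stage (both stimulus
    trains and the output noise) through independent child streams.
    """

    vagal: BranchKinetics
    sympathetic: BranchKinetics
    depletion: DepletionSpec = field(default_factory=DepletionSpec)
    vagal_band_hz: tuple[float, float] = VAGAL_BAND_HZ
    sympathetic_band_hz: tuple[float, float] = SYMPATHETIC_BAND_HZ
    kappa_sv: float = 0.2
    duration_s: float = 300.0
    dt_s: float = 0.01
    m0: float = 1.0
    base_period_s: float = 0.8
    noise_sd_ms: float = 10.0
    seed: int = 0

    def with_alpha(self, alpha: float, mode=None) -> "SimConfig":
        dep = DepletionSpec(
            mode=mode if mode is not None else self.depletion.mode, alpha=alpha
        )
        return replace(self, depletion=dep)


def _child_seeds(seed: int, n: int = 3) -> list[int]:
    """Derive independent per-stage substream seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def simulate_rr(config: SimConfig) -> RRSeries:
    """End-to-end simulation: stimulus trains → kinetics → m(t) → IPFM → noise.

    Returns a reproducible RR series carrying the depletion scale, mode
    and seed in its provenance fields.
    """
    s_vagal, s_symp, s_noise = _child_seeds(config.seed)

    vt = build_stimulus_train(
        Branch.VAGAL, config.duration_s, config.vagal_band_hz, seed=s_vagal
    )
    st = build_stimulus_train(
        Branch.SYMPATHETIC, config.duration_s, config.sympathetic_band_hz, seed=s_symp
    )
    v_trace = simulate_concentration(
        vt, config.vagal, config.depletion, config.dt_s, init="stationary"
    )
    s_trace = simulate_concentration(
        st, config.sympathetic, config.depletion, config.dt_s, init="stationary"
    )
    V_raw = branch_signal(v_trace, config.vagal, config.depletion)
    S_raw = branch_signal(s_trace, config.sympathetic, config.depletion)

    # full-transmitter vagal tone recovered exactly from this run's trace
    v_base = float(np.mean(full_transmitter_signal(v_trace, config.vagal, config.depletion)))
    if v_base <= 0:
        v_base = tonic_signal_level(config.vagal, config.vagal_band_hz)
    S, V = cross_couple(S_raw, V_raw, config.kappa_sv, v_baseline=v_base)

    sig = autonomic_signal(S, V, v_trace.t_s, m0=config.m0)
    beats = ipfm_beats(sig, config.base_period_s)
    rr_clean_ms = np.diff(beats) * 1000.0
    rr_ms = add_output_noise(rr_clean_ms, config.noise_sd_ms, seed=s_noise)
    return RRSeries(
        rr_ms=rr_ms,
        beat_times_s=beats,
        seed=config.seed,
        noise_sd_ms=config.noise_sd_ms,
        base_period_s=config.base_period_s,
        alpha=config.depletion.alpha,
        depletion_mode=config.depletion.mode.value,
    )
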
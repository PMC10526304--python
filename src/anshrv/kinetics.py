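"""Neurotransmitter release–clearance kinetics and the autonomic neural signal.

The autonomic drive to the sinoatrial node is modelled as

    m(t) = m0 + S(t) + V(t)

where ``S`` is the sympathetic (norepinephrine-mediated) contribution,
``V`` the vagal (acetylcholine-mediated) contribution, and ``m0`` lumps
every non-autonomic influence on heart rate (intrinsic rate, hormonal and
circadian factors).  ``V`` enters with a negative sign — vagal activity
slows the heart — and ``m`` must stay strictly positive.

Each branch is driven by a stochastic stimulus train.  Every stimulus
releases a quantum of transmitter into the neuroeffector junction, which
clears exponentially while a fraction transfers to the extra-junctional
space; the weighted sum of the two compartment concentrations, passed
through a (possibly cooperative) receptor transduction and scaled by a
branch gain, is the branch signal.  The compartment kinetics are linear
— scaling the released quantum scales the concentrations exactly
proportionally — while the transduction may be supra-linear, so a
fractional acetylcholine depletion ``alpha`` produces a
supra-proportional loss of vagal drive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Branch",
    "DepletionMode",
    "BranchKinetics",
    "StimulusTrain",
    "DepletionSpec",
    "ConcentrationTrace",
    "AutonomicSignal",
    "PositivityError",
    "VAGAL_BAND_HZ",
    "SYMPATHETIC_BAND_HZ",
    "build_stimulus_train",
    "simulate_concentration",
    "branch_signal",
    "cross_couple",
    "autonomic_signal",
    "tonic_signal_level",
    "full_transmitter_signal",
]


class Branch(str, enum.Enum):
    SYMPATHETIC = "sympathetic"
    VAGAL = "vagal"


class DepletionMode(str, enum.Enum):
    """Level of the cholinergic chain at which depletion is applied."""

    VESICLE_COUNT = "vesicle_count"
    JUNCTION_CONC = "junction_conc"
    EJS_CONC = "ejs_conc"
    COUPLING = "coupling"
    VAGAL_GAIN = "vagal_gain"


#: Default stimulation bands: one vagal input every 2–4 s (respiratory
#: drive), one sympathetic input every 20–40 s.
VAGAL_BAND_HZ = (0.25, 0.5)
SYMPATHETIC_BAND_HZ = (0.025, 0.05)


class PositivityError(ValueError):
    """The combined autonomic signal m(t) dropped to zero or below."""

    def __init__(self, t_first: float, m_min: float):
        self.t_first = float(t_first)
        self.m_min = float(m_min)
        super().__init__(
            f"m(t) must be strictly positive; first violation at "
            f"t = {t_first:.3f} s (m = {m_min:.4g}). The vagal gain is too "
            f"large for the configured m0/sympathetic tone."
        )


@dataclass(frozen=True)
class BranchKinetics:
    """Release/clearance parameters for one autonomic branch.

    Parameters
    ----------
    branch
        Which branch these kinetics describe.
    release_quantum_q
        Transmitter concentration (arbitrary units) released into the
        neuroeffector junction per stimulus.
    junction_clearance_kJ, junction_to_ejs_transfer_kT, ejs_clearance_kE
        First-order rate constants (1/s).  The junction concentration
        decays at ``kJ + kT``; a flux ``kT * C_J`` feeds the
        extra-junctional space, which clears at ``kE``.
    junction_weight_wJ, ejs_weight_wE
        Non-negative weights combining the two compartments into the raw
        branch signal.
    gain_g
        Signal amplitude per unit concentration.
    latency_s
        Neuroeffector transduction delay applied to the branch signal.
    transduction_gamma, transduction_gamma2, transduction_mix
        Cooperativity of the concentration→effect transduction.  With
        the combined local drive ``d = wJ C_J + wE C_E`` the branch
        signal is

            g * [(1 - mix) * d**gamma + mix * d**gamma2].

        The defaults (gamma = gamma2 = 1) give a fully linear chain;
        exponents above 1 model Hill-type receptor cooperativity, under
        which a fractional loss of transmitter produces a
        supra-proportional loss of effect — the behaviour cholinergic
        depletion exhibits at the sinoatrial node.  Two terms allow two
        receptor populations of different cooperativity to read the
        same transmitter concentration (a steep fast pathway plus a
        shallower modulatory one).
    """

    branch: Branch
    release_quantum_q: float = 1.0
    junction_clearance_kJ: float = 1.0
    junction_to_ejs_transfer_kT: float = 0.5
    ejs_clearance_kE: float = 0.5
    junction_weight_wJ: float = 1.0
    ejs_weight_wE: float = 0.2
    gain_g: float = 1.0
    latency_s: float = 0.0
    transduction_gamma: float = 1.0
    transduction_gamma2: float = 1.0
    transduction_mix: float = 0.0

    def __post_init__(self):
        self_branch = Branch(self.branch)
        object.__setattr__(self, "branch", self_branch)
        for name in (
            "release_quantum_q",
            "junction_clearance_kJ",
            "junction_to_ejs_transfer_kT",
            "ejs_clearance_kE",
            "gain_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.junction_weight_wJ < 0 or self.ejs_weight_wE < 0:
            raise ValueError("compartment weights must be non-negative")
        if self.junction_weight_wJ + self.ejs_weight_wE <= 0:
            raise ValueError("at least one compartment weight must be positive")
        if self.latency_s < 0:
            raise ValueError("latency_s must be non-negative")
        if self.transduction_gamma < 1 or self.transduction_gamma2 < 1:
            raise ValueError("transduction exponents must be >= 1")
        if not 0 <= self.transduction_mix <= 1:
            raise ValueError("transduction_mix must lie in [0, 1]")

    @property
    def junction_decay(self) -> float:
        """Total junctional decay rate kJ + kT (1/s)."""
        return self.junction_clearance_kJ + self.junction_to_ejs_transfer_kT


@dataclass(frozen=True)
class StimulusTrain:
    """Point-process stimulation of one branch."""

    branch: Branch
    event_times_s: np.ndarray
    duration_s: float
    band_hz: tuple[float, float]
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "branch", Branch(self.branch))
        t = np.asarray(self.event_times_s, dtype=float)
        object.__setattr__(self, "event_times_s", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("event times must be strictly increasing within [0, duration]")


@dataclass(frozen=True)
class DepletionSpec:
    """Cholinergic depletion: scale ``alpha`` applied at level ``mode``.

    ``alpha`` is the fraction of baseline acetylcholine availability
    (1.0 = healthy, 0.55 = the most severe state simulated).
    """

    mode: DepletionMode = DepletionMode.JUNCTION_CONC
    alpha: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "mode", DepletionMode(self.mode))
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class ConcentrationTrace:
    """Junctional and extra-junctional concentration on a uniform grid."""

    t_s: np.ndarray
    C_J: np.ndarray
    C_E: np.ndarray
    branch: Branch

    def __post_init__(self):
        if not (len(self.t_s) == len(self.C_J) == len(self.C_E)):
            raise ValueError("trace arrays must share one grid")

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


@dataclass(frozen=True)
class AutonomicSignal:
    """Combined autonomic neural signal m(t) = m0 + S(t) + V(t)."""

    t_s: np.ndarray
    S: np.ndarray
    V: np.ndarray
    m: np.ndarray
    m0: float = 1.0

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


def build_stimulus_train(
    branch: Branch | str,
    duration_s: float,
    band_hz: tuple[float, float] | None = None,
    seed: int = 0,
) -> StimulusTrain:
    """Draw a stimulus train with inter-event intervals uniform on
    ``[1/f_hi, 1/f_lo]``.

    Defaults to the physiological bands: vagal (0.25, 0.5) Hz — one input
    per 2–4 s — and sympathetic (0.025, 0.05) Hz — one per 20–40 s.  A
    degenerate band ``(f, f)`` yields a strictly periodic train.
    """
    branch = Branch(branch)
    if band_hz is None:
        band_hz = VAGAL_BAND_HZ if branch is Branch.VAGAL else SYMPATHETIC_BAND_HZ
    f_lo, f_hi = band_hz
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 < f_lo <= f_hi:
        raise ValueError("band must satisfy 0 < f_lo <= f_hi")
    t_min, t_max = 1.0 / f_hi, 1.0 / f_lo
    rng = np.random.default_rng(seed)
    # draw enough intervals to cover the duration, then truncate
    n_guess = int(duration_s / t_min) + 2
    times: list[float] = []
    t = 0.0
    while True:
        intervals = rng.uniform(t_min, t_max, size=n_guess)
        for iv in intervals:
            t += iv
            if t > duration_s:
                return StimulusTrain(
                    branch=branch,
                    event_times_s=np.array(times),
                    duration_s=float(duration_s),
                    band_hz=(float(f_lo), float(f_hi)),
                    seed=int(seed),
                )
            times.append(t)


def _alpha_injection(dep: DepletionSpec, branch: Branch) -> float:
    """Scale applied to each released quantum (vagal branch only)."""
    if branch is Branch.VAGAL and dep.mode in (
        DepletionMode.VESICLE_COUNT,
        DepletionMode.JUNCTION_CONC,
    ):
        return dep.alpha
    return 1.0


def simulate_concentration(
    train: StimulusTrain,
    kin: BranchKinetics,
    dep: DepletionSpec | None = None,
    dt: float = 0.01,
    init: str = "zero",
) -> ConcentrationTrace:
    """Integrate the two-compartment kinetics driven by ``train``.

    Each stimulus at time ``t_i`` injects ``q * alpha_eff`` into the
    junction.  Between events the linear system

        dC_J/dt = -(kJ + kT) C_J
        dC_E/dt =  kT C_J - kE C_E

    is advanced with its exact exponential solution evaluated on the
    output grid, so no ODE discretisation error accumulates; ``dt`` only
    sets the sampling resolution of the returned trace.

    ``init`` selects the initial compartment state: ``"zero"`` (empty
    compartments) or ``"stationary"`` (the long-run mean concentrations
    for the train's band-implied rate, so short recordings start in
    steady state instead of with a filling transient).
    """
    if dep is None:
        dep = DepletionSpec()
    if dt <= 0 or dt > 0.05:
        raise ValueError("dt must be in (0, 0.05] s")
    if init not in ("zero", "stationary"):
        raise ValueError("init must be 'zero' or 'stationary'")
    if train.branch is not kin.branch:
        raise ValueError(
            f"train branch {train.branch.value!r} does not match kinetics "
            f"branch {kin.branch.value!r}"
        )

    a = kin.junction_decay
    kT, kE = kin.junction_to_ejs_transfer_kT, kin.ejs_clearance_kE
    inj = kin.release_quantum_q * _alpha_injection(dep, kin.branch)

    n = int(np.floor(train.duration_s / dt)) + 1
    t_grid = np.arange(n) * dt
    C_J = np.zeros(n)
    C_E = np.zeros(n)

    events = train.event_times_s
    if events.size:
        # segment boundaries: start, each event, end
        cj, ce = 0.0, 0.0
        if init == "stationary":
            f_lo, f_hi = train.band_hz
            rate = 2.0 / (1.0 / f_lo + 1.0 / f_hi)
            cj = inj * rate / a
            ce = kT * cj / kE
        seg_starts = np.concatenate(([0.0], events))
        idx = np.searchsorted(t_grid, seg_starts, side="left")
        idx = np.append(idx, n)
        for k in range(len(seg_starts)):
            lo, hi = idx[k], idx[k + 1]
            if k > 0:
                cj += inj  # impulse release at the segment start
            if hi > lo:
                tau = t_grid[lo:hi] - seg_starts[k]
                ej = np.exp(-a * tau)
                ee = np.exp(-kE * tau)
                C_J[lo:hi] = cj * ej
                if abs(a - kE) > 1e-12:
                    C_E[lo:hi] = ce * ee + kT * cj * (ee - ej) / (a - kE)
                else:
                    C_E[lo:hi] = ce * ee + kT * cj * tau * ee
            # advance state to the next segment boundary
            if k + 1 < len(seg_starts):
                span = seg_starts[k + 1] - seg_starts[k]
                ej0 = np.exp(-a * span)
                ee0 = np.exp(-kE * span)
                if abs(a - kE) > 1e-12:
                    ce = ce * ee0 + kT * cj * (ee0 - ej0) / (a - kE)
                else:
                    ce = ce * ee0 + kT * cj * span * ee0
                cj = cj * ej0

    if kin.branch is Branch.VAGAL and dep.mode is DepletionMode.EJS_CONC:
        C_E = C_E * dep.alpha
    return ConcentrationTrace(t_s=t_grid, C_J=C_J, C_E=C_E, branch=kin.branch)


def _transduced_drive(C_J, C_E, kin: BranchKinetics):
    d = kin.junction_weight_wJ * C_J + kin.ejs_weight_wE * C_E
    g1, g2, mix = kin.transduction_gamma, kin.transduction_gamma2, kin.transduction_mix
    if g1 == 1.0 and (mix == 0.0 or g2 == 1.0):
        return d
    if mix == 0.0:
        return d**g1
    return (1.0 - mix) * d**g1 + mix * d**g2


def branch_signal(
    trace: ConcentrationTrace,
    kin: BranchKinetics,
    dep: DepletionSpec | None = None,
) -> np.ndarray:
    """Map a concentration trace to the signed branch signal.

    raw = g * f(wJ * C_J + wE * C_E), delayed by the branch latency,
    where f is the (possibly cooperative) transduction function of the
    branch.  The vagal branch returns ``-raw`` (vagal activity lowers
    the heart rate); under ``vagal_gain`` depletion the vagal output is
    further scaled by ``alpha``.  Sympathetic output is positive.  With
    the default linear transduction, scaling the released quantum
    scales the signal exactly proportionally; with a pure cooperative
    exponent ``gamma`` a concentration scale ``c`` maps to a signal
    scale ``c**gamma``.
    """
    if dep is None:
        dep = DepletionSpec()
    raw = kin.gain_g * _transduced_drive(trace.C_J, trace.C_E, kin)
    if kin.latency_s > 0:
        shift = int(round(kin.latency_s / trace.dt))
        if shift > 0:
            raw = np.concatenate([np.zeros(shift), raw[:-shift]])
    if kin.branch is Branch.VAGAL:
        scale = dep.alpha if dep.mode is DepletionMode.VAGAL_GAIN else 1.0
        return -raw * scale
    return raw


def cross_couple(
    S_raw: np.ndarray,
    V_raw: np.ndarray,
    kappa_sv: float = 0.2,
    v_baseline: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tonic vagal→sympathetic facilitation.

    The two branches interact: withdrawal of vagal tone mildly depresses
    sympathetic amplitude as well.  With ``rho`` the current vagal tone
    relative to its healthy baseline (clipped to [0, 1]),

        S = S_raw * (1 - kappa_sv * (1 - rho)),   V unchanged.

    At full vagal tone (rho = 1) or with ``kappa_sv = 0`` the sympathetic
    signal passes through unmodified.
    """
    if not 0 <= kappa_sv <= 1:
        raise ValueError("kappa_sv must lie in [0, 1]")
    if v_baseline <= 0:
        raise ValueError("v_baseline must be positive")
    rho = float(np.clip(np.mean(np.abs(V_raw)) / v_baseline, 0.0, 1.0))
    S = S_raw * (1.0 - kappa_sv * (1.0 - rho))
    return S, V_raw


def autonomic_signal(
    S: np.ndarray,
    V: np.ndarray,
    t_s: np.ndarray,
    m0: float = 1.0,
) -> AutonomicSignal:
    """Combine the branch signals into m(t) = m0 + S(t) + V(t).

    Raises
    ------
    PositivityError
        If m(t) <= 0 anywhere.  A non-positive m means the configured
        gains are inconsistent with the intrinsic drive; it is reported,
        never silently clipped.
    """
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    if S.shape != V.shape or S.shape != np.asarray(t_s).shape:
        raise ValueError("S, V and t_s must share one grid")
    m = m0 + S + V
    if np.any(m <= 0):
        i = int(np.argmax(m <= 0))
        raise PositivityError(t_first=t_s[i], m_min=float(m.min()))
    return AutonomicSignal(t_s=np.asarray(t_s, dtype=float), S=S, V=V, m=m, m0=float(m0))


def full_transmitter_signal(trace: ConcentrationTrace, kin: BranchKinetics,
                            dep: DepletionSpec) -> np.ndarray:
    """|branch signal| this trace would produce at full transmitter
    availability (alpha = 1).

    Under junctional/vesicular depletion the concentrations scale
    linearly with ``alpha``, so the alpha = 1 compartment traces are
    recovered exactly as ``C / alpha`` before transduction.  Used as the
    reference vagal tone for the cross-branch coupling.
    """
    if kin.branch is not Branch.VAGAL or dep.mode is DepletionMode.COUPLING:
        return np.abs(kin.gain_g * _transduced_drive(trace.C_J, trace.C_E, kin))
    if dep.mode is DepletionMode.VAGAL_GAIN:
        return np.abs(kin.gain_g * _transduced_drive(trace.C_J, trace.C_E, kin))
    if dep.mode is DepletionMode.EJS_CONC:
        return np.abs(kin.gain_g * _transduced_drive(trace.C_J, trace.C_E / dep.alpha, kin))
    return np.abs(kin.gain_g * _transduced_drive(trace.C_J / dep.alpha,
                                                 trace.C_E / dep.alpha, kin))


def tonic_signal_level(kin: BranchKinetics, band_hz: tuple[float, float]) -> float:
    """Long-run mean of |branch signal| at full transmitter availability.

    For a stationary stimulus train of rate ``r`` (the band-implied mean
    rate), the stationary mean concentrations are

        E[C_J] = q r / (kJ + kT),    E[C_E] = kT E[C_J] / kE

    giving mean |signal| ≈ g f(wJ E[C_J] + wE E[C_E]) (exact for the
    linear chain).  A coarse tonic reference for the cross-branch
    coupling when no trace is available.
    """
    f_lo, f_hi = band_hz
    mean_interval = 0.5 * (1.0 / f_lo + 1.0 / f_hi)
    rate = 1.0 / mean_interval
    cj = kin.release_quantum_q * rate / kin.junction_decay
    ce = kin.junction_to_ejs_transfer_kT * cj / kin.ejs_clearance_kE
    return float(kin.gain_g * _transduced_drive(np.array(cj), np.array(ce), kin))
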
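"""Calibrated default parameters of the autonomic simulator.

The prior-model parameter values behind the published feature trajectory
are not printed anywhere, so the free parameters of this implementation
(branch gains, rate constants, pacemaker period, coupling strength) were
calibrated once, with :func:`anshrv.progression.calibrate`, against the
packaged 10-state progression table.  The values below are the result of
that calibration and are the package defaults; every simulation entry
point accepts explicit overrides.

Kinetic rate constants encode the physiology qualitatively:
acetylcholine is cleared within ~0.5 s at the junction (fast vagal
transfer, respiratory-band fluctuations), norepinephrine reuptake is an
order of magnitude slower (sympathetic low-pass, low-frequency
fluctuations).  The vagal transduction is strongly cooperative (two
receptor populations, Hill-type exponents ~11 and ~6.6), which is what
lets a 30% loss of transmitter abolish most of the vagal heart-rate
modulation, as the published feature trajectory requires; the
sympathetic transduction is linear.
"""

from __future__ import annotations

from .heart import SimConfig
from .kinetics import Branch, BranchKinetics, DepletionSpec

__all__ = ["DEFAULT_PARAMS", "default_config", "config_from_params"]

#: Flat calibrated parameter set (see module docstring).
DEFAULT_PARAMS: dict[str, float] = {
    "vagal.release_quantum_q": 1.0,
    "vagal.junction_clearance_kJ": 1.221748,
    "vagal.junction_to_ejs_transfer_kT": 1.0,
    "vagal.ejs_clearance_kE": 1.130792,
    "vagal.junction_weight_wJ": 0.2964325,
    "vagal.ejs_weight_wE": 1.0,
    "vagal.gain_g": 7284.568,
    "vagal.latency_s": 0.3,
    "vagal.transduction_gamma": 11.1209,
    "vagal.transduction_gamma2": 6.6,
    "vagal.transduction_mix": 0.03,
    "sympathetic.release_quantum_q": 1.0,
    "sympathetic.junction_clearance_kJ": 0.1880405,
    "sympathetic.junction_to_ejs_transfer_kT": 0.1880405,
    "sympathetic.ejs_clearance_kE": 0.1126105,
    "sympathetic.junction_weight_wJ": 0.001,
    "sympathetic.ejs_weight_wE": 1.0,
    "sympathetic.gain_g": 0.5313609,
    "sympathetic.latency_s": 1.5,
    "sympathetic.transduction_gamma": 1.0,
    "sympathetic.transduction_gamma2": 1.0,
    "sympathetic.transduction_mix": 0.0,
    "bands.vagal_lo_hz": 0.25,
    "bands.vagal_hi_hz": 0.5,
    "bands.sympathetic_lo_hz": 0.04111288,
    "bands.sympathetic_hi_hz": 0.06636465,
    "coupling.kappa_sv": 0.2,
    "sim.m0": 1.0,
    "sim.base_period_s": 0.6148211,
    "sim.dt_s": 0.01,
    "sim.noise_sd_ms": 10.0,
}


def _branch_kinetics(params: dict[str, float], branch: Branch) -> BranchKinetics:
    p = branch.value
    return BranchKinetics(
        branch=branch,
        release_quantum_q=params[f"{p}.release_quantum_q"],
        junction_clearance_kJ=params[f"{p}.junction_clearance_kJ"],
        junction_to_ejs_transfer_kT=params[f"{p}.junction_to_ejs_transfer_kT"],
        ejs_clearance_kE=params[f"{p}.ejs_clearance_kE"],
        junction_weight_wJ=params[f"{p}.junction_weight_wJ"],
        ejs_weight_wE=params[f"{p}.ejs_weight_wE"],
        gain_g=params[f"{p}.gain_g"],
        latency_s=params[f"{p}.latency_s"],
        transduction_gamma=params[f"{p}.transduction_gamma"],
        transduction_gamma2=params[f"{p}.transduction_gamma2"],
        transduction_mix=params[f"{p}.transduction_mix"],
    )


def config_from_params(
    params: dict[str, float],
    alpha: float = 1.0,
    mode: str = "junction_conc",
    duration_s: float = 300.0,
    seed: int = 0,
) -> SimConfig:
    """Build a :class:`SimConfig` from a flat parameter mapping.

    Unknown keys are rejected so configuration typos fail loudly.
    """
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    full = {**DEFAULT_PARAMS, **params}
    return SimConfig(
        vagal=_branch_kinetics(full, Branch.VAGAL),
        sympathetic=_branch_kinetics(full, Branch.SYMPATHETIC),
        depletion=DepletionSpec(mode=mode, alpha=alpha),
        vagal_band_hz=(full["bands.vagal_lo_hz"], full["bands.vagal_hi_hz"]),
        sympathetic_band_hz=(
            full["bands.sympathetic_lo_hz"],
            full["bands.sympathetic_hi_hz"],
        ),
        kappa_sv=full["coupling.kappa_sv"],
        duration_s=duration_s,
        dt_s=full["sim.dt_s"],
        m0=full["sim.m0"],
        base_period_s=full["sim.base_period_s"],
        noise_sd_ms=full["sim.noise_sd_ms"],
        seed=seed,
    )


def default_config(
    alpha: float = 1.0,
    mode: str = "junction_conc",
    duration_s: float = 300.0,
    seed: int = 0,
) -> SimConfig:
    """The calibrated default simulation configuration."""
    return config_from_params({}, alpha=alpha, mode=mode, duration_s=duration_s, seed=seed)
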
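"""Synthetic control and AD cohorts.

The study's clinical recordings are not available, so group comparisons
are exercised on synthetic stand-ins: each subject is one simulated
5-minute RR series whose acetylcholine availability is drawn from a
group-specific range (controls near full availability, AD well below),
with log-normal between-subject gain heterogeneity.  The group
``variability_scale`` shrinks both branch gains relative to the
progression calibration so the control medians land near the published
clinical group medians rather than the simulated-trajectory values.

These cohorts reproduce the *design* of the clinical comparison (20 vs
20 subjects, median summaries, Mann–Whitney at p < 0.01), not any
patient's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, extract_features
from .heart import RRSeries, simulate_rr
from .kinetics import BranchKinetics
from .params import DEFAULT_PARAMS, config_from_params

__all__ = [
    "GroupProfile",
    "LabeledRRSet",
    "control_profile",
    "ad_profile",
    "generate_subject",
    "generate_cohort",
    "cohort_features",
]

#: Clinical group medians used as generator setpoints.
CLINICAL_MEDIANS = {
    "control": {"sdnn_ms": 36.3, "rmssd_ms": 41.4, "lf_nu": 37.32, "hf_nu": 62.12,
                "lf_hf": 0.601, "sd1_ms": 29.3, "sd2_ms": 37.8, "sd2_sd1": 1.401},
    "AD": {"sdnn_ms": 10.9, "rmssd_ms": 10.4, "lf_nu": 69.58, "hf_nu": 29.95,
           "lf_hf": 2.323, "sd1_ms": 7.4, "sd2_ms": 12.3, "sd2_sd1": 1.68},
}


@dataclass(frozen=True)
class GroupProfile:
    """Generator settings for one subject group."""

    label: str
    alpha_range: tuple[float, float]
    variability_scale: float = 1.0
    heterogeneity_sigma: float = 0.2
    target_medians: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.alpha_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("alpha_range must lie within (0, 1]")
        if self.variability_scale <= 0:
            raise ValueError("variability_scale must be positive")


@dataclass(frozen=True)
class LabeledRRSet:
    """Per-subject RR series with group labels and provenance."""

    series: list[RRSeries]
    labels: list[str]
    subject_seeds: list[int]
    alphas: list[float]
    master_seed: int

    def __post_init__(self):
        n = len(self.series)
        if not (len(self.labels) == len(self.subject_seeds) == len(self.alphas) == n):
            raise ValueError("per-subject metadata lengths must match")
        if len(set(self.subject_seeds)) != n:
            raise ValueError("subject seeds must be unique")


def control_profile(variability_scale: float = 0.6) -> GroupProfile:
    """Healthy controls: near-full ACh availability."""
    return GroupProfile(
        label="control",
        alpha_range=(0.95, 1.0),
        variability_scale=variability_scale,
        target_medians=dict(CLINICAL_MEDIANS["control"]),
    )


def ad_profile(variability_scale: float = 0.35) -> GroupProfile:
    """AD patients: depleted ACh availability, below the control range.

    The default variability scale is below the control default: overall
    autonomic drive (and hence total spectral power) is reduced in the
    disease state, not just the vagal fraction.
    """
    return GroupProfile(
        label="AD",
        alpha_range=(0.55, 0.80),
        variability_scale=variability_scale,
        target_medians=dict(CLINICAL_MEDIANS["AD"]),
    )


def _scaled_params(base: dict[str, float], gain_scale: float) -> dict[str, float]:
    p = dict(base)
    p["vagal.gain_g"] = p["vagal.gain_g"] * gain_scale
    p["sympathetic.gain_g"] = p["sympathetic.gain_g"] * gain_scale
    return p


def generate_subject(
    profile: GroupProfile,
    seed: int,
    params: dict[str, float] | None = None,
    duration_s: float = 300.0,
) -> tuple[RRSeries, float]:
    """Simulate one subject: draw alpha and a gain multiplier, run 5 min.

    Returns the RR series and the drawn alpha.  Deterministic per seed.
    """
    base = {**DEFAULT_PARAMS, **(params or {})}
    rng = np.random.default_rng(seed)
    alpha = float(rng.uniform(*profile.alpha_range))
    mult = float(rng.lognormal(mean=0.0, sigma=profile.heterogeneity_sigma))
    p = _scaled_params(base, profile.variability_scale * mult)
    cfg = config_from_params(
        {k: v for k, v in p.items()},
        alpha=alpha,
        duration_s=duration_s,
        seed=int(rng.integers(0, 2**31)),
    )
    return simulate_rr(cfg), alpha


def generate_cohort(
    n_per_group: int = 20,
    profiles: tuple[GroupProfile, GroupProfile] | None = None,
    master_seed: int = 0,
    params: dict[str, float] | None = None,
    duration_s: float = 300.0,
) -> LabeledRRSet:
    """Generate the two labelled groups (default 20 + 20 subjects).

    Subject seeds are derived reproducibly from ``master_seed``; the
    cohort is a pure function of the master seed and the profiles.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if profiles is None:
        profiles = (control_profile(), ad_profile())
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s) for s in ss.generate_state(2 * n_per_group) % (2**31)]
    series, labels, alphas = [], [], []
    i = 0
    for profile in profiles:
        for _ in range(n_per_group):
            rr, alpha = generate_subject(profile, seeds[i], params=params, duration_s=duration_s)
            series.append(rr)
            labels.append(profile.label)
            alphas.append(alpha)
            i += 1
    return LabeledRRSet(
        series=series,
        labels=labels,
        subject_seeds=seeds,
        alphas=alphas,
        master_seed=master_seed,
    )


def cohort_features(cohort: LabeledRRSet, method: str = "welch") -> pd.DataFrame:
    """Feature matrix: one row per subject with its group label."""
    rows = []
    for rr, label, seed, alpha in zip(
        cohort.series, cohort.labels, cohort.subject_seeds, cohort.alphas
    ):
        row = {"group": label, "seed": seed, "alpha": alpha}
        row |= extract_features(rr.rr_ms, rr.beat_times_s, method=method).as_dict()
        rows.append(row)
    return pd.DataFrame(rows)
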
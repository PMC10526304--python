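import numpy as np
import pytest

from anshrv.kinetics import AutonomicSignal


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: results do not depend
    # on test execution order
    return np.random.default_rng(20260921)


def make_signal(duration_s=300.0, dt=0.01, m_fn=None, m0=1.0):
    """Helper: an AutonomicSignal with m(t) given directly (S = m - m0, V = 0)."""
    t = np.arange(0.0, duration_s + dt / 2, dt)
    m = np.full_like(t, m0) if m_fn is None else np.asarray(m_fn(t), dtype=float)
    return AutonomicSignal(t_s=t, S=m - m0, V=np.zeros_like(t), m=m, m0=m0)


@pytest.fixture(scope="session")
def progression_table_default():
    """Seed-mean 10-state feature table under the calibrated defaults.

    Session-scoped: several tests assert different properties of the
    same protocol run.
    """
    from anshrv.progression import run_progression

    return run_progression(n_seeds=10, base_seed=0)
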
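import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from modbind.structure import make_toy_structure  # noqa: E402
from modbind.toy import LangevinSpec, ToyPotential, simulate_escape  # noqa: E402


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure()


@pytest.fixture(scope="session")
def default_potential():
    return ToyPotential(barrier_height=5.0, well_curvature=4.0, barrier_curvature=4.0)


@pytest.fixture(scope="session")
def escape_samples_128(default_potential):
    """One moderately sized escape ensemble shared by distributional tests."""
    spec = LangevinSpec(temperature=1.5, t_max=1500.0, dt=0.01, seed=11, n_replicas=128)
    return simulate_escape(default_potential, spec)


def brute_force_auc(active_scores, decoy_scores, higher_better=True):
    """Pairwise Mann-Whitney AUC with half credit for ties (independent oracle)."""
    total = 0.0
    for a in active_scores:
        for d in decoy_scores:
            better = a > d if higher_better else a < d
            total += 1.0 if better else (0.5 if a == d else 0.0)
    return total / (len(active_scores) * len(decoy_scores))


@pytest.fixture(scope="session")
def brute_auc():
    return brute_force_auc


@pytest.fixture(autouse=True)
def _mpl_agg(monkeypatch):
    monkeypatch.setenv("MPLBACKEND", "Agg")
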
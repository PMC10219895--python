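"""Shared fixtures: canonical parameter sets and one expensive stiff cycle."""

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import autoreg as ar

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.filter_too_much],
    deadline=None,
)
settings.load_profile("ci")

REPO_ROOT = Path(__file__).resolve().parents[1]

# Dimensional set that maps exactly onto the canonical dimensionless values
# (k1 chosen so that eta1 = 0.76 to machine precision).
TABLE1_K1 = 0.017131165956651616


@pytest.fixture(scope="session")
def table1() -> ar.DimensionlessParams:
    """Canonical dimensionless parameter set (0.76, 0.008, 0.02, 0.01)."""
    return ar.DimensionlessParams(eta1=0.76, eta2=0.008, eta3=0.02, eta4=0.01)


@pytest.fixture(scope="session")
def table1_dim() -> ar.DimensionalParams:
    return ar.DimensionalParams(
        k1=TABLE1_K1, k2=0.02, k3=1.0, k4=495.0, k5=1.0, P0=1.0, X0=1.0, alpha=124.0
    )


@pytest.fixture(scope="session")
def table1_config() -> Path:
    return REPO_ROOT / "table1.yaml"


@pytest.fixture(scope="session")
def fig5_params() -> ar.DimensionlessParams:
    """Stiff relaxation-regime set: slow mRNA kinetics, eta1/eta3 = 30."""
    return ar.DimensionlessParams(eta1=0.009, eta2=0.008, eta3=0.0003, eta4=0.01)


@pytest.fixture(scope="session")
def fig5_cycle(fig5_params):
    """(trajectory, attractor report) of the stiff relaxation limit cycle."""
    traj, rep = ar.characterise_attractor(fig5_params, t_end=45000.0)
    assert rep.kind == "limit_cycle"
    return traj, rep
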
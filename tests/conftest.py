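import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dynade.ontology import AnnotationMap, OntologyDAG
from dynade.simulate import DEFAULT_TIMES, SimulationConfig, simulate_timeseries


@pytest.fixture(scope="session")
def default_times() -> np.ndarray:
    return np.asarray(DEFAULT_TIMES)


@pytest.fixture(scope="session")
def small_experiment():
    """300-gene simulated experiment with 20% DE genes (seeded)."""
    cfg = SimulationConfig(n_genes=300, frac_de=0.2, seed=11)
    return simulate_timeseries(cfg)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Noise-free simulation: diff equals the planted change exactly."""
    cfg = SimulationConfig(
        n_genes=100, frac_de=0.1, seed=3, noise_sd_fn=lambda x: np.zeros_like(np.asarray(x, dtype=float))
    )
    return simulate_timeseries(cfg)


@pytest.fixture()
def toy_dag() -> OntologyDAG:
    """Chain C is_a B is_a A plus a sibling D of B."""
    return OntologyDAG.from_edges([("C", "B"), ("B", "A"), ("D", "A")])


@pytest.fixture()
def toy_annotations(toy_dag) -> AnnotationMap:
    pairs = [("g1", "C"), ("g2", "C"), ("g3", "B"), ("g4", "D"), ("g5", "A")]
    return AnnotationMap.from_pairs(pairs, dag=toy_dag, propagate=True)
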
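import numpy as np
import pytest

import rhibayes as rb


@pytest.fixture
def small_dataset() -> rb.AnalysisDataset:
    """Hand-built 3-participant, 7-category dataset."""
    return rb.AnalysisDataset(
        participants=["a", "b", "c"],
        cia=np.array([0.2, 0.5, 0.9]),
        y_async=np.array([3, 4, 4]),
        y_sync=np.array([5, 4, 6]),
        n_categories=7,
    )


@pytest.fixture
def simulated_dataset() -> tuple[rb.AnalysisDataset, rb.SimulationTruth]:
    """A modest simulated dataset under the default study-like conditions."""
    config = rb.GeneratorConfig(n_participants=30, seed=42)
    return rb.simulate_dataset(config)


def make_draws(named_columns: dict[str, np.ndarray], n_chains: int = 2) -> rb.PosteriorDraws:
    """Build a PosteriorDraws container from per-parameter pooled vectors,
    splitting them evenly across chains."""
    names = list(named_columns)
    mat = np.column_stack([np.asarray(v, dtype=float) for v in named_columns.values()])
    m = mat.shape[0]
    assert m % n_chains == 0
    arr = mat.reshape(n_chains, m // n_chains, len(names))
    return rb.PosteriorDraws(names=names, array=arr)


@pytest.fixture
def constant_draws() -> rb.PosteriorDraws:
    """Single-draw-style container: every parameter constant across draws."""
    m = 8
    return make_draws(
        {
            "beta1": np.full(m, 0.5),
            "beta2": np.full(m, 0.0),
            "beta3": np.full(m, 0.33),
            "sigma_r": np.full(m, 1.0),
            "tau_1": np.full(m, -0.5),
            "r_a": np.full(m, -0.2),
            "r_b": np.full(m, 0.1),
            "r_c": np.full(m, 0.0),
        }
    )
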
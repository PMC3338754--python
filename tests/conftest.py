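import numpy as np
import pytest

from compfeat import ExpressionDataset, SimulationConfig, simulate_cohorts


@pytest.fixture
def tiny_ds():
    """Hand-written 4x3 dataset: g1 strongly up in the poor class."""
    return ExpressionDataset(
        sample_ids=["s1", "s2", "s3", "s4"],
        gene_ids=["g1", "g2", "g3"],
        values=np.array(
            [
                [1.0, 0.5, -0.2],
                [2.0, -0.5, 0.1],
                [5.0, 0.3, -0.1],
                [6.0, -0.3, 0.2],
            ]
        ),
        labels=np.array([0, 0, 1, 1]),
        er_status=np.array([1, 0, 1, 1]),
        name="tiny",
    )


@pytest.fixture(scope="session")
def strong_pair():
    """Two cohorts with a strong planted signal plus ground truth."""
    cfg = SimulationConfig(
        n_cohorts=2,
        samples_per_cohort=100,
        n_genes=150,
        n_informative=12,
        planted_module_sizes=(10,),
        effect_size=2.0,
        seed=5,
    )
    datasets, truth = simulate_cohorts(cfg)
    return cfg, datasets, truth


def random_dataset(rng, k=30, n=8, name="rand"):
    labels = np.array([0, 1] * (k // 2) + [0] * (k % 2))
    return ExpressionDataset(
        sample_ids=[f"{name}{i}" for i in range(k)],
        gene_ids=[f"g{j}" for j in range(n)],
        values=rng.normal(size=(k, n)),
        labels=labels,
        name=name,
    )
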
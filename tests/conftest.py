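import numpy as np
import pytest

from gmrfabric.datamodel import ExpressionDataset
from gmrfabric.model import GMRModel
from gmrfabric.synthetic import SyntheticConfig, generate


def make_dataset(blocks: dict, replicas: int = 4) -> ExpressionDataset:
    """Build a dataset from {group: {gene: [[spot replicas...], ...]}}.

    Every group must list the same genes with the same spot counts; spot ids
    are synthesized as s1, s2, ...
    """
    groups = list(blocks)
    genes = list(blocks[groups[0]])
    spot_ids = [[f"s{k + 1}" for k in range(len(blocks[groups[0]][g]))] for g in genes]
    values = {
        grp: np.array([spot for g in genes for spot in blocks[grp][g]], dtype=float)
        for grp in groups
    }
    return ExpressionDataset(
        groups=groups, genes=genes, spot_ids=spot_ids, values=values,
        replicas_per_group=replicas,
    )


def random_dataset(rng, n_genes=10, groups=("Z", "P"), max_spots=3, replicas=4):
    """Small random positive dataset for oracle-equivalence checks."""
    genes = [f"g{i}" for i in range(n_genes)]
    counts = rng.integers(1, max_spots + 1, size=n_genes)
    spot_ids = [[f"s{k + 1}" for k in range(c)] for c in counts]
    total = int(counts.sum())
    values = {
        grp: np.exp(rng.normal(1.0, 0.8, size=(total, replicas)))
        for grp in groups
    }
    return ExpressionDataset(
        groups=list(groups), genes=genes, spot_ids=spot_ids, values=values,
        replicas_per_group=replicas,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_run():
    """One default planted-hub dataset, fitted; shared across tests."""
    config = SyntheticConfig.default_planted(seed=11)
    dataset, truth = generate(config)
    results = GMRModel(dataset, normal=config.normal, nodules=list(config.nodules)).fit()
    return config, dataset, truth, results
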
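import numpy as np
import pandas as pd
import pytest

from refstab import CqDataset, collapse_replicates, default_study_config, relative_quantities, simulate_experiment


def build_dataset(cq_by_gene: dict[str, list[float]], metadata: dict[str, dict] | None = None,
                  efficiencies: dict[str, float] | None = None) -> CqDataset:
    """One-replicate dataset from {gene: [cq per sample]}; samples named s1, s2, ..."""
    n = len(next(iter(cq_by_gene.values())))
    samples = [f"s{i + 1}" for i in range(n)]
    rows = [
        (s, g, 1, cqs[i])
        for g, cqs in cq_by_gene.items()
        for i, s in enumerate(samples)
    ]
    cq = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq"])
    meta = pd.DataFrame(metadata or {s: {} for s in samples}).T
    meta.index.name = "sample"
    return CqDataset(cq=cq, metadata=meta, efficiencies=efficiencies or {})


def random_dataset(rng: np.random.Generator, n_genes: int = 5, n_samples: int = 12) -> CqDataset:
    cq_by_gene = {
        f"g{j}": list(rng.uniform(15, 30, size=n_samples)) for j in range(n_genes)
    }
    return build_dataset(cq_by_gene)


@pytest.fixture(scope="session")
def celmisia():
    """Default simulated translocation study (48 samples) with ground truth."""
    cfg = default_study_config("celmisia", seed=1)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def celmisia_rq(celmisia):
    ds, _ = celmisia
    collapsed, _ = collapse_replicates(ds)
    return relative_quantities(collapsed)


@pytest.fixture()
def worked_trio():
    """The hand-computed 3-gene example: two identical genes and a permuted one.

    With E = 2 the log2 RQ rows are (0,-1,-2), (0,-1,-2), (0,-2,-1); the
    pairwise log-ratio SDs are V12 = 0, V13 = V23 = SD{0,1,-1} = 1, hence
    M = (0.5, 0.5, 1.0).
    """
    return build_dataset({"a": [20.0, 21.0, 22.0], "b": [20.0, 21.0, 22.0], "c": [20.0, 22.0, 21.0]})
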
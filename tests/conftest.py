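import numpy as np
import pandas as pd
import pytest

from consig.dataset import ExpressionDataset


def make_dataset(
    matrix: np.ndarray | list,
    n_case: int,
    study_id: str = "S1",
    gene_ids: list[str] | None = None,
    is_log_scale: bool = True,
) -> ExpressionDataset:
    """Build a small ExpressionDataset; first n_case columns are cases."""
    x = np.asarray(matrix, dtype=float)
    genes = gene_ids or [f"g{i + 1}" for i in range(x.shape[0])]
    samples = [f"{study_id}_x{i + 1}" for i in range(x.shape[1])]
    labels = pd.Series([1] * n_case + [0] * (x.shape[1] - n_case), index=samples)
    return ExpressionDataset(
        matrix=pd.DataFrame(x, index=genes, columns=samples),
        labels=labels,
        study_id=study_id,
        is_log_scale=is_log_scale,
    )


def separable_dataset(
    n_per_class: int = 10,
    n_noise_genes: int = 4,
    gap: float = 2.0,
    noise: float = 0.3,
    seed: int = 0,
) -> ExpressionDataset:
    """Two informative genes (cases high, controls low) plus pure noise genes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    x = rng.normal(0.0, 1.0, size=(n_noise_genes + 2, n))
    for g in range(2):
        x[g] = rng.normal(0.0, noise, size=n)
        x[g, :n_per_class] += gap / 2
        x[g, n_per_class:] -= gap / 2
    return make_dataset(x, n_case=n_per_class)


@pytest.fixture
def toy_separable() -> ExpressionDataset:
    return separable_dataset()
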
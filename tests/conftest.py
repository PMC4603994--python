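import math

import numpy as np
import pandas as pd
import pytest

from ordimap import StudyConfig, generate_study
from ordimap.matrix_io import ExpressionMatrix


def brute_force_tau_b(x, y) -> float:
    """O(n²) pair-enumeration oracle for Kendall tau-b.

    Counts concordant/discordant/tied pairs explicitly and applies
    (C − D)/sqrt((n0 − n1)(n0 − n2)) with integer arithmetic, so exact
    float agreement with the implementation is expected.
    """
    n = len(x)
    cd = 0
    nzx = 0
    nzy = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = int(x[i] > x[j]) - int(x[i] < x[j])
            sy = int(y[i] > y[j]) - int(y[i] < y[j])
            cd += sx * sy
            nzx += sx != 0
            nzy += sy != 0
    if nzx == 0 or nzy == 0:
        return float("nan")
    return cd / math.sqrt(nzx * nzy)


def eigen_mds_oracle(similarity: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense eigendecomposition oracle for classical scaling.

    Returns (coordinates, eigenvalues-by-magnitude) from the
    double-centered similarity, axes ordered by |eigenvalue| descending
    and scaled by sqrt |eigenvalue|.
    """
    n = similarity.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ similarity @ J
    B = (B + B.T) / 2
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(-np.abs(vals))
    vals = vals[order]
    vecs = vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(np.abs(vals[:k]))
    return coords, vals


def make_matrix(values: np.ndarray, species=None, prefix="g") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with generated ids."""
    n_genes, n_samples = values.shape
    ids = [f"{prefix}{i}" for i in range(n_genes)]
    if species is None:
        species = ["mRNA"] * n_genes
    return ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=[f"s{j}" for j in range(n_samples)]),
        pd.Series(species, index=ids),
    )


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """Reduced study: 100 genes × (13 + 17) samples, structure intact."""
    return StudyConfig(
        n_mirna=20,
        n_mrna=80,
        n_case_samples=13,
        n_control_samples=17,
        n_target_pairs=20,
        n_shared_seed_groups=4,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size study bundle (640 genes) shared across slow tests."""
    return generate_study(StudyConfig(rng_seed=11))
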
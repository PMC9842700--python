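"""Shared fixtures: one small synthetic atlas, in memory and on disk."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transcortex.synthetic_data import SimulationConfig, generate_atlas, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_donors=4,
        samples_per_donor=50,
        n_genes=300,
        n_planted_de=20,
        mask_fraction=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def atlas_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("atlas")
    generate_atlas(small_config, out)
    return out


@pytest.fixture(scope="session")
def cortical_selection(small_atlas):
    """(gene x cortical-sample matrix, donor labels, affected indicator)."""
    frame = small_atlas.samples.frame
    ids = frame.loc[frame["structure_label"] != "subcortex", "sample_id"].tolist()
    X = small_atlas.gene_matrix[ids]
    donors = small_atlas.donor_of().loc[ids]
    affected = np.isin(ids, small_atlas.truth.true_affected_samples).astype(float)
    return X, donors, affected


def dense_gls_oracle(Y: np.ndarray, design: np.ndarray, Sigma: np.ndarray):
    """Brute-force GLS via the explicit correlation-matrix inverse.

    Returns (beta, sigma2, se_unscaled) per gene; the independent check for
    the whitening-based fit.
    """
    Si = np.linalg.inv(Sigma)
    xtsx_inv = np.linalg.inv(design.T @ Si @ design)
    betas, sigma2 = [], []
    df = design.shape[0] - design.shape[1]
    for y in Y:
        beta = xtsx_inv @ design.T @ Si @ y
        r = y - design @ beta
        sigma2.append(float(r @ Si @ r) / df)
        betas.append(beta)
    return np.array(betas), np.array(sigma2), np.sqrt(np.diag(xtsx_inv))


def batch_removal_oracle(values: pd.DataFrame, batch: pd.Series) -> np.ndarray:
    """Per-gene OLS on intercept + sum-to-zero batch contrasts, batch terms subtracted."""
    levels = list(dict.fromkeys(batch))
    k = len(levels)
    codes = np.array([levels.index(b) for b in batch])
    n = len(codes)
    design = np.ones((n, k))
    contrasts = np.zeros((n, k - 1))
    for j in range(k - 1):
        contrasts[codes == j, j] = 1.0
        contrasts[codes == k - 1, j] = -1.0
    design = np.column_stack([np.ones(n), contrasts])
    Y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    batch_part = design[:, 1:] @ beta[1:]
    return Y - batch_part.T
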
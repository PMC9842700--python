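"""Donor batch removal and two-pass scaled robust sigmoid (SRS) normalization.

Donor brains carry additive, gene-specific offsets (batch structure) on top of
the biological signal. Batch removal fits, per gene, an ordinary least squares
model of expression on an intercept plus sum-to-zero donor contrasts and
subtracts the fitted donor terms, retaining the grand intercept — the same
operation as limma's removeBatchEffect with donor as the single batch factor.

Because a linear fit is outlier-sensitive, batch removal is followed by SRS
normalization: a sigmoid centered at the median with robust scale IQR/1.35
(the normal-consistency constant),

    x_y = 1 / (1 + exp(-(x_i - <x>) / (IQR / 1.35)))

followed by min-max rescaling of the sigmoid outputs to the unit interval.
The gene-wise pass (across samples) is applied first; a second pass applies
the same transform within each sample across genes, damping sample-specific
artefacts. Both passes preserve ranks for non-degenerate input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "remove_batch_effects",
    "srs_vector",
    "srs_across_samples",
    "srs_within_sample",
    "normalize",
]

SIGMOID_SCALE_CONSTANT = 1.35  # IQR of a standard normal ≈ 1.349
_STAGES = ("batch_removed", "srs_across_samples", "srs_within_sample")


@dataclass
class NormalizedMatrix:
    """Gene × sample matrix carrying its normalization stage tag."""

    values: pd.DataFrame
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


def remove_batch_effects(X: ExpressionMatrix | NormalizedMatrix | pd.DataFrame,
                         batch: pd.Series) -> NormalizedMatrix:
    """Subtract per-gene additive donor (batch) terms estimated by OLS.

    With an intercept and sum-to-zero batch contrasts and no covariates, the
    fitted batch term for donor d is (donor-d mean − unweighted mean of donor
    means), per gene; the intercept is retained. A single batch is a no-op.
    """
    values = X.values if not isinstance(X, pd.DataFrame) else X
    batch = pd.Series(batch).reindex(values.columns)
    if batch.isna().any():
        missing = batch.index[batch.isna()][0]
        raise ValueError(f"sample {missing!r} has no batch label")
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2][0]
        raise ValueError(f"batch {small!r} has fewer than 2 samples")

    arr = values.to_numpy(dtype=float)
    levels = counts.index.tolist()
    codes = batch.map({b: i for i, b in enumerate(levels)}).to_numpy()
    # per-gene donor means, (genes x donors)
    donor_means = np.stack(
        [arr[:, codes == i].mean(axis=1) for i in range(len(levels))], axis=1
    )
    effects = donor_means - donor_means.mean(axis=1, keepdims=True)
    if len(levels) == 1:
        corrected = arr.copy()
    else:
        corrected = arr - effects[:, codes]
    return NormalizedMatrix(
        pd.DataFrame(corrected, index=values.index, columns=values.columns),
        stage="batch_removed",
    )


def srs_vector(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid of a vector, rescaled to [0,1].

    Scale falls back when degenerate: IQR/1.35 → 1.349·MAD → standard
    deviation; an all-equal vector maps to 0.5 everywhere, as does the
    rescale when the sigmoid outputs are all equal.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("srs_vector requires length >= 2")
    med = np.median(x)
    q25, q75 = np.percentile(x, [25, 75])  # linear-interpolation (type-7) quartiles
    scale = (q75 - q25) / SIGMOID_SCALE_CONSTANT
    if scale == 0.0:
        scale = 1.349 * np.median(np.abs(x - med))
    if scale == 0.0:
        scale = float(np.std(x))
    if scale == 0.0:
        return np.full_like(x, 0.5)
    y = expit((x - med) / scale)
    lo, hi = y.min(), y.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (y - lo) / (hi - lo)


def _srs_frame(values: pd.DataFrame, axis: int) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    out = np.empty_like(arr)
    if axis == 1:  # per row
        for i in range(arr.shape[0]):
            out[i] = srs_vector(arr[i])
    else:  # per column
        for j in range(arr.shape[1]):
            out[:, j] = srs_vector(arr[:, j])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def srs_across_samples(X: NormalizedMatrix) -> NormalizedMatrix:
    """Apply SRS + unit rescale to every gene row (across samples)."""
    return NormalizedMatrix(_srs_frame(X.values, axis=1), stage="srs_across_samples")


def srs_within_sample(X: NormalizedMatrix) -> NormalizedMatrix:
    """Apply SRS + unit rescale within each sample column (across genes).

    Runs after the gene-wise pass; stage order is enforced.
    """
    if X.stage != "srs_across_samples":
        raise ValueError("within-sample SRS must follow the across-samples pass")
    return NormalizedMatrix(_srs_frame(X.values, axis=0), stage="srs_within_sample")


def normalize(X: ExpressionMatrix | pd.DataFrame, batch: pd.Series,
              within_sample: bool = True) -> NormalizedMatrix:
    """Full stack: batch removal → gene-wise SRS → (optional) within-sample SRS."""
    out = srs_across_samples(remove_batch_effects(X, batch))
    if within_sample:
        out = srs_within_sample(out)
    logger.info("normalization complete (stage=%s)", out.stage)
    return out
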
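"""Differential stability: cross-donor reproducibility of regional expression.

For each gene, expression is averaged per (donor, structure); differential
stability (DS) is the mean, over all donor pairs, of the Pearson correlation
between the two donors' structure-mean vectors, restricted to structures both
donors sampled. A gene whose regional pattern replicates across donor brains
scores near 1. DS distributions of differentially expressed genes versus the
remainder are compared with a two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleTable
from .normalization import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["DSTable", "differential_stability", "compare_ds", "group_ds"]


@dataclass
class DSTable:
    """Gene-indexed DS values with an optional DE-group column."""

    table: pd.DataFrame  # columns: ds, group

    def values_for(self, group: str) -> np.ndarray:
        return self.table.loc[self.table["group"] == group, "ds"].to_numpy()


def differential_stability(
    X: NormalizedMatrix | pd.DataFrame, samples: SampleTable
) -> pd.Series:
    """Per-gene DS over all donor pairs sharing ≥3 structures.

    Donor pairs with fewer than 3 shared structures, or a constant structure-
    mean vector, contribute nothing; genes with no usable pair are excluded
    (logged).
    """
    values = X.values if isinstance(X, NormalizedMatrix) else X
    meta = samples.frame.set_index("sample_id").loc[values.columns]
    key = pd.MultiIndex.from_frame(meta[["donor_id", "structure_label"]])
    # genes x (donor, structure) means
    means = values.T.groupby(key).mean().T
    donors = sorted({d for d, _ in means.columns})
    if len(donors) < 2:
        raise ValueError("differential stability needs >= 2 donors")

    per_donor = {d: means.loc[:, [c for c in means.columns if c[0] == d]] for d in donors}
    for d in per_donor:
        per_donor[d].columns = [c[1] for c in per_donor[d].columns]

    corr_sum = np.zeros(len(means.index))
    corr_n = np.zeros(len(means.index))
    for d1, d2 in itertools.combinations(donors, 2):
        shared = per_donor[d1].columns.intersection(per_donor[d2].columns)
        if len(shared) < 3:
            continue
        a = per_donor[d1][shared].to_numpy(dtype=float)
        b = per_donor[d2][shared].to_numpy(dtype=float)
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
        ok = denom > 0
        r = np.zeros(len(denom))
        r[ok] = (ac * bc).sum(axis=1)[ok] / denom[ok]
        corr_sum[ok] += r[ok]
        corr_n[ok] += 1
    defined = corr_n > 0
    if not defined.all():
        logger.info("DS undefined for %d genes (no donor pair with shared structures)",
                    int((~defined).sum()))
    ds = pd.Series(corr_sum[defined] / corr_n[defined], index=means.index[defined], name="ds")
    return ds


def group_ds(ds: pd.Series, higher: set[str], lower: set[str]) -> DSTable:
    """Attach DE-group labels (de_higher / de_lower / other) to DS values."""
    group = np.where(ds.index.isin(list(higher)), "de_higher",
                     np.where(ds.index.isin(list(lower)), "de_lower", "other"))
    return DSTable(pd.DataFrame({"ds": ds, "group": group}))


def compare_ds(ds_de: np.ndarray, ds_other: np.ndarray
               ) -> tuple[float, float, tuple[float, float]]:
    """Two-sided Mann–Whitney U (U of the first group, sum-rank convention).

    Exact enumeration when both groups have ≤20 values and no ties span the
    groups; tie-corrected normal approximation otherwise. Returns
    (U, p, (median_de, median_other)).
    """
    ds_de = np.asarray(ds_de, dtype=float)
    ds_other = np.asarray(ds_other, dtype=float)
    if ds_de.size == 0 or ds_other.size == 0:
        raise ValueError("both DS groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([ds_de, ds_other]))) < ds_de.size + ds_other.size
    method = "exact" if (max(ds_de.size, ds_other.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(ds_de, ds_other, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue), (float(np.median(ds_de)),
                                                     float(np.median(ds_other)))
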
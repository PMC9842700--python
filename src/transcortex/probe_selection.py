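"""Collapse probe-level microarray data to one representative probe per gene.

Two stages, mirroring intensity-based filtering followed by RNAseq-concordance
collapse:

1. keep probes detected above background in at least ``min_fraction`` of
   samples, pooled across all donors jointly;
2. per gene, compute the Spearman correlation of each surviving probe against
   the gene's RNAseq profile on the matched samples, keep the probe with the
   highest correlation, and drop the gene entirely when it is absent from the
   RNAseq data (or all-zero there) or when the winning correlation falls
   below ``rho_min``.

Ties in the winning correlation are broken toward the lexicographically
smallest probe id (logged) so the collapse is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DetectionMatrix, ExpressionMatrix, ProbeTable

logger = logging.getLogger(__name__)

__all__ = ["ProbeSelectionResult", "filter_by_detection", "collapse_probes", "select_probes"]

LOW_DETECTION = "low_detection"
NOT_IN_RNASEQ = "not_in_rnaseq"
LOW_RNASEQ_CORRELATION = "low_rnaseq_correlation"
OUTCOMPETED = "outcompeted"


@dataclass
class ProbeSelectionResult:
    """Winner probe per gene plus the reason every other probe was dropped."""

    kept: dict[str, tuple[str, float]] = field(default_factory=dict)  # gene -> (probe, rho)
    dropped: dict[str, str] = field(default_factory=dict)             # probe -> reason

    def report(self) -> pd.DataFrame:
        """Long-form selection report: gene, probe, rho, status."""
        rows = [(g, p, rho, "kept") for g, (p, rho) in self.kept.items()]
        rows += [("", p, np.nan, reason) for p, reason in self.dropped.items()]
        return pd.DataFrame(rows, columns=["gene", "probe", "rho", "status"])

    def collapse_matrix(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        """Gene-level matrix: each kept gene's row is its winning probe's row."""
        genes = sorted(self.kept)
        probes = [self.kept[g][0] for g in genes]
        mat = expr.values.loc[probes]
        mat.index = genes
        return ExpressionMatrix(mat, row_kind="gene")


def filter_by_detection(det: DetectionMatrix, min_fraction: float = 0.5) -> list[str]:
    """Probes detected in at least ``min_fraction`` of all pooled samples (inclusive)."""
    if det.values.size == 0:
        raise ValueError("empty detection matrix")
    rate = det.values.mean(axis=1)
    kept = det.values.index[rate >= min_fraction].tolist()
    logger.info("detection filter: %d of %d probes at >= %.0f%% detection",
                len(kept), det.values.shape[0], 100 * min_fraction)
    return kept


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average ranks."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        return np.nan
    return float(np.corrcoef(ra, rb)[0, 1])


def collapse_probes(
    expr: ExpressionMatrix,
    probes: ProbeTable,
    rnaseq: ExpressionMatrix,
    rho_min: float = 0.2,
) -> ProbeSelectionResult:
    """Pick the best RNAseq-concordant probe per gene.

    Only annotated probes present in ``expr`` compete. Correlations use the
    sample intersection between the microarray and RNAseq columns; fewer than
    3 matched samples is fatal.
    """
    matched = [s for s in expr.col_ids if s in set(rnaseq.col_ids)]
    if len(matched) < 3:
        raise ValueError(f"correlation undefined: only {len(matched)} matched samples")

    gene_of = probes.gene_of()
    candidates = gene_of[gene_of.index.isin(expr.values.index)]
    sub_expr = expr.values.loc[candidates.index, matched]
    rna = rnaseq.values[matched]
    rna_genes = set(rnaseq.row_ids)

    result = ProbeSelectionResult()
    for gene, probe_ids in candidates.groupby(candidates).groups.items():
        probe_ids = sorted(probe_ids)
        if gene not in rna_genes or not np.any(rna.loc[gene].to_numpy()):
            for p in probe_ids:
                result.dropped[p] = NOT_IN_RNASEQ
            continue
        target = rna.loc[gene].to_numpy(dtype=float)
        rhos = {p: _spearman(sub_expr.loc[p].to_numpy(dtype=float), target) for p in probe_ids}
        finite = {p: r for p, r in rhos.items() if np.isfinite(r)}
        if not finite:
            for p in probe_ids:
                result.dropped[p] = LOW_RNASEQ_CORRELATION
            continue
        best_rho = max(finite.values())
        winners = sorted(p for p, r in finite.items() if r == best_rho)
        winner = winners[0]
        if len(winners) > 1:
            logger.info("gene %s: rho tie among %s; keeping %s", gene, winners, winner)
        if best_rho < rho_min:
            for p in probe_ids:
                result.dropped[p] = LOW_RNASEQ_CORRELATION
            continue
        result.kept[gene] = (winner, best_rho)
        for p in probe_ids:
            if p != winner:
                result.dropped[p] = OUTCOMPETED
    logger.info("probe collapse: %d genes kept, %d probes dropped",
                len(result.kept), len(result.dropped))
    return result


def select_probes(
    expr: ExpressionMatrix,
    det: DetectionMatrix,
    probes: ProbeTable,
    rnaseq: ExpressionMatrix,
    min_fraction: float = 0.5,
    rho_min: float = 0.2,
) -> tuple[ProbeSelectionResult, ExpressionMatrix]:
    """Detection filter then RNAseq collapse; returns the gene-level matrix too."""
    detected = filter_by_detection(det, min_fraction=min_fraction)
    detected_set = set(detected)
    kept_expr = ExpressionMatrix(expr.values.loc[[p for p in expr.row_ids
                                                  if p in detected_set]],
                                 row_kind="probe")
    result = collapse_probes(kept_expr, probes, rnaseq, rho_min=rho_min)
    for p in expr.row_ids:
        if p not in detected_set:
            result.dropped[p] = LOW_DETECTION
    return result, result.collapse_matrix(expr)
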
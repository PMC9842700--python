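"""Gene-set statistics: hypergeometric enrichment, fold enrichment, marker-set
gating, disease-signature set construction and trimmed-mean cell-type summaries.

Enrichment of a query gene list (e.g. the differentially expressed genes) in a
named set is tested with the upper-tail hypergeometric probability
P(X ≥ k) for k observed members of the set among n query genes, drawn from a
background of N genes containing K set members. Fold enrichment is the
percentage of query genes in the set divided by the corresponding background
percentage, (k/n)/(K/N). Term collections use Benjamini–Hochberg adjustment
with a significance rule of fold enrichment > 1 and q < 0.05; cell-type marker
collections use Bonferroni with adjusted p < 0.05, after discarding marker
sets with fewer than five genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "CellTypeExpression",
    "hypergeom_enrich",
    "adjust",
    "significant_terms",
    "significant_cell_types",
    "filter_marker_sets",
    "single_marker_crossref",
    "build_disease_sets",
    "trimmed_mean_expression",
]


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    background_N: int
    fold_enrichment: float
    p_value: float
    adjusted_p: float = np.nan
    correction: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_k <= min(self.set_size_K, self.query_size_n)):
            raise ValueError("overlap outside [0, min(K, n)]")


@dataclass
class CellTypeExpression:
    """Gene × cell-type trimmed-mean log2 expression with per-type cell counts."""

    values: pd.DataFrame          # genes x cell types
    cell_counts: dict[str, int]

    def omitted_from_plot(self) -> list[str]:
        """Genes with zero trimmed mean in every cell type."""
        return self.values.index[(self.values == 0).all(axis=1)].tolist()


def hypergeom_enrich(
    query: set[str], sets: GeneSetCollection, background: set[str],
    ease: bool = False,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of ``query`` in every set.

    Sets are intersected with the background before testing; sets vanishing
    after intersection are skipped (logged). ``ease`` applies the conservative
    EASE-style variant that tests k−1 instead of k.
    """
    if not query:
        raise ValueError("empty query gene set")
    if not query <= background:
        extra = sorted(query - background)[0]
        raise ValueError(f"query gene {extra!r} not in background")
    N, n = len(background), len(query)
    records = []
    for name in sets.names():
        members = set(sets.members(name)) & background
        K = len(members)
        if K == 0:
            logger.info("set %s empty after background intersection: skipped", name)
            continue
        k = len(members & query)
        k_test = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_test - 1, N, K, n))
        fold = (k / n) / (K / N)
        records.append(EnrichmentRecord(
            set_name=name, overlap_k=k, set_size_K=K, query_size_n=n,
            background_N=N, fold_enrichment=fold, p_value=p))
    return records


def adjust(records: list[EnrichmentRecord], method: str = "BH") -> list[EnrichmentRecord]:
    """Attach multiplicity-adjusted p-values across the tested sets."""
    if method not in ("BH", "bonferroni"):
        raise ValueError(f"unknown correction {method!r}")
    if not records:
        return records
    p = np.array([r.p_value for r in records])
    adj = bh_adjust(p) if method == "BH" else np.minimum(1.0, p * len(records))
    for r, a in zip(records, adj):
        r.adjusted_p = float(a)
        r.correction = method
    return records


def significant_terms(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Term rule: fold enrichment > 1.0 and BH q < 0.05."""
    return [r for r in records if r.fold_enrichment > 1.0 and r.adjusted_p < 0.05]


def significant_cell_types(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Cell-type rule: Bonferroni-adjusted p < 0.05."""
    return [r for r in records if r.adjusted_p < 0.05]


def filter_marker_sets(sets: GeneSetCollection, min_genes: int = 5) -> GeneSetCollection:
    """Drop marker sets with fewer than ``min_genes`` members ("at least five")."""
    kept = {name: v for name, v in sets.sets.items() if len(v[1]) >= min_genes}
    dropped = set(sets.names()) - set(kept)
    if dropped:
        logger.info("marker filter removed %d sets: %s", len(dropped), sorted(dropped))
    if not kept:
        raise ValueError("no marker sets survive the minimum-size filter")
    return GeneSetCollection(kept)


def single_marker_crossref(
    de_genes: set[str], expression: CellTypeExpression,
    specificity_threshold: float = 1.0,
) -> list[tuple[str, str]]:
    """DE genes whose expression is concentrated in a single cell type.

    A gene qualifies when its trimmed mean is positive in exactly one cell
    type, or when its top cell type carries at least ``specificity_threshold``
    of its total trimmed-mean mass. Reported as indications, not significant
    enrichments.
    """
    out = []
    vals = expression.values
    for gene in sorted(de_genes & set(vals.index)):
        row = vals.loc[gene]
        total = row.sum()
        if total <= 0:
            continue
        positive = row[row > 0]
        if len(positive) == 1 or (row.max() / total) >= specificity_threshold:
            out.append((gene, row.idxmax()))
    return out


def build_disease_sets(
    signature_table: pd.DataFrame, q_max: float = 0.05, lfc_abs_min: float = 0.1
) -> GeneSetCollection:
    """Per-disease higher/lower gene sets from a (gene, disease, logFC, q) table.

    Inclusion: q ≤ q_max (inclusive) and logFC strictly beyond ±lfc_abs_min.
    Diseases whose gates leave no genes yield no set but are logged — stricter
    criteria are known to empty these groups.
    """
    required = {"gene", "disease", "logFC", "q"}
    if not required <= set(signature_table.columns):
        raise ValueError(f"signature table must have columns {sorted(required)}")
    sets: dict[str, tuple[str, list[str]]] = {}
    for disease, sub in signature_table.groupby("disease"):
        passing = sub[sub["q"] <= q_max]
        higher = sorted(set(passing.loc[passing["logFC"] > lfc_abs_min, "gene"]))
        lower = sorted(set(passing.loc[passing["logFC"] < -lfc_abs_min, "gene"]))
        for direction, genes in (("higher", higher), ("lower", lower)):
            name = f"{disease}_{direction}"
            if not genes:
                logger.warning("disease set %s is empty under q<=%.2g, |logFC|>%.2g",
                               name, q_max, lfc_abs_min)
                continue
            sets[name] = (f"{disease} {direction} differential expression", genes)
    return GeneSetCollection(sets)


def trimmed_mean_expression(
    counts: pd.DataFrame, cell_labels: pd.Series
) -> CellTypeExpression:
    """Per (gene, cell type) trimmed mean of log2(x+1) expression.

    Within each cell type the lowest and highest floor(n/4) values are dropped
    per gene before averaging; types with fewer than 4 cells are excluded
    (logged).
    """
    cell_labels = pd.Series(cell_labels).reindex(counts.columns)
    if cell_labels.isna().any():
        raise ValueError("every cell needs a cell-type label")
    log2 = np.log2(counts.to_numpy(dtype=float) + 1.0)
    out = {}
    cell_n = {}
    for ct, cols in cell_labels.groupby(cell_labels).groups.items():
        idx = [counts.columns.get_loc(c) for c in cols]
        n = len(idx)
        if n < 4:
            logger.info("cell type %s has %d cells (<4): excluded", ct, n)
            continue
        trim = n // 4
        block = np.sort(log2[:, idx], axis=1)[:, trim:n - trim]
        out[ct] = block.mean(axis=1)
        cell_n[str(ct)] = n
    if not out:
        raise ValueError("no cell type has >= 4 cells")
    values = pd.DataFrame(out, index=counts.index)
    return CellTypeExpression(values=values, cell_counts=cell_n)
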
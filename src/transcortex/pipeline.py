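"""End-to-end orchestration: probe selection → spatial mapping → normalization
→ moderated DE → differential stability → enrichment, from a single config.

Every stage output is persisted as TSV/JSON under the output directory and the
run finishes with a machine-readable report of per-stage counts, the config
echo (with its hash) and the seed, so a run is reproducible from its report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import run_de
from .enrichment import adjust, filter_marker_sets, hypergeom_enrich, significant_cell_types
from .io_formats import (
    ExpressionMatrix,
    SampleTable,
    concat_bundles,
    read_expression_bundle,
    read_gmt,
    read_mask,
)
from .normalization import normalize
from .probe_selection import select_probes
from .spatial_mapping import assign_samples
from .stability import compare_ds, differential_stability, group_ds

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; validated before anything executes."""

    bundle_dirs: list[str]
    mask_paths: list[str]
    rnaseq_path: str
    cortical_labels_path: str
    marker_gmt_path: str | None = None
    term_gmt_path: str | None = None
    ds_table_path: str | None = None        # external gene→DS table (TSV)
    out_dir: str = "pipeline_out"
    min_fraction: float = 0.5
    rho_min: float = 0.2
    mask_threshold: float = 0.5
    mirror: bool = False
    alpha: float = 0.05
    min_marker_genes: int = 5
    use_block_correlation: bool = True
    within_sample_srs: bool = True
    seed: int = 0

    def validate(self) -> None:
        for stage, paths in (("probe_selection", self.bundle_dirs),
                             ("spatial_mapping", self.mask_paths)):
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"[{stage}] missing input: {p}")
        for p in (self.rnaseq_path, self.cortical_labels_path,
                  self.marker_gmt_path, self.term_gmt_path, self.ds_table_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineReport:
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"counts": self.counts, "timings_s": self.timings,
             "config": self.config, "version": self.version},
            indent=1, sort_keys=True, default=str))

    def summary(self) -> str:
        lines = [f"transcortex {self.version} run (config {self.config.get('digest', '?')})"]
        for key, val in self.counts.items():
            lines.append(f"  {key}: {val}")
        return "\n".join(lines)


def _stage(report: PipelineReport, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            report.timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage in order, persisting outputs under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config={**config.__dict__, "digest": config.digest()})
    rng_seed = int(config.seed)
    np.random.seed(rng_seed % (2 ** 31))  # stages are deterministic; belt and braces

    # ---- load -------------------------------------------------------------
    with _stage(report, "load"):
        bundles = [read_expression_bundle(d) for d in sorted(config.bundle_dirs)]
        probes, samples, expr, det = concat_bundles(bundles)
        rnaseq_df = pd.read_csv(config.rnaseq_path, index_col=0)
        rnaseq = ExpressionMatrix(rnaseq_df, row_kind="gene")
        cortical_labels = {
            line.strip() for line in Path(config.cortical_labels_path).read_text().splitlines()
            if line.strip()}
        masks = [read_mask(p) for p in config.mask_paths]
        report.counts["donors"] = len(bundles)
        report.counts["samples_loaded"] = len(samples.sample_ids)
        report.counts["probes_loaded"] = len(probes.probe_ids)

    # ---- probe selection --------------------------------------------------
    with _stage(report, "probe_selection"):
        selection, gene_expr = select_probes(
            expr, det, probes, rnaseq,
            min_fraction=config.min_fraction, rho_min=config.rho_min)
        selection.report().to_csv(out / "probe_selection.tsv", sep="\t", index=False)
        report.counts["genes_kept"] = len(selection.kept)
        report.counts["probes_dropped"] = len(selection.dropped)

    # ---- spatial mapping --------------------------------------------------
    with _stage(report, "spatial_mapping"):
        assignment = assign_samples(samples, masks, cortical_labels,
                                    threshold=config.mask_threshold, mirror=config.mirror)
        assignment.table.to_csv(out / "sample_assignment.tsv", sep="\t")
        assignment.counts_by_donor(samples).to_csv(out / "assignment_by_donor.tsv", sep="\t")
        affected_ids = assignment.ids("affected")
        control_ids = assignment.ids("control")
        if not affected_ids:
            raise ValueError("no affected samples under the mask at this threshold")
        report.counts["samples_affected"] = len(affected_ids)
        report.counts["samples_control"] = len(control_ids)
        report.counts["samples_excluded"] = len(assignment.ids("excluded"))

    # ---- normalization ----------------------------------------------------
    with _stage(report, "normalization"):
        analysis_ids = affected_ids + control_ids
        sub = ExpressionMatrix(gene_expr.values[analysis_ids], row_kind="gene")
        donor = samples.donor_ids.loc[analysis_ids]
        norm = normalize(sub, donor, within_sample=config.within_sample_srs)
        norm.values.to_csv(out / f"expression_{norm.stage}.tsv", sep="\t")

    # ---- differential expression -----------------------------------------
    with _stage(report, "diffexpr"):
        affected_set = set(affected_ids)
        affected_ind = np.array([1.0 if s in affected_set else 0.0 for s in analysis_ids])
        de = run_de(norm, affected_ind, donor.to_numpy(),
                    use_block_correlation=config.use_block_correlation)
        de.table.to_csv(out / "de_table.tsv", sep="\t")
        higher, lower = de.called(alpha=config.alpha)
        report.counts["consensus_rho"] = round(de.consensus_rho, 4)
        report.counts["ebayes_d0"] = (None if np.isinf(de.prior.d0)
                                      else round(de.prior.d0, 3))
        report.counts["ebayes_s0_sq"] = round(de.prior.s0_sq, 6)
        report.counts["de_higher"] = len(higher)
        report.counts["de_lower"] = len(lower)

    # ---- differential stability ------------------------------------------
    with _stage(report, "stability"):
        if config.ds_table_path is not None:
            ext = pd.read_csv(config.ds_table_path, sep="\t")
            ds = pd.Series(ext["ds"].to_numpy(), index=ext["gene"], name="ds")
            ds = ds[ds.index.isin(norm.values.index)]
        else:
            sub_samples = SampleTable(
                samples.frame[samples.frame["sample_id"].isin(analysis_ids)]
                .reset_index(drop=True))
            ds = differential_stability(norm, sub_samples)
        table = group_ds(ds, higher, lower)
        table.table.to_csv(out / "ds_table.tsv", sep="\t")
        de_ds = np.concatenate([table.values_for("de_higher"), table.values_for("de_lower")])
        other_ds = table.values_for("other")
        if de_ds.size and other_ds.size:
            u, p, (med_de, med_other) = compare_ds(de_ds, other_ds)
            report.counts["ds_median_de"] = round(med_de, 4)
            report.counts["ds_median_other"] = round(med_other, 4)
            report.counts["ds_mannwhitney_p"] = float(p)

    # ---- enrichment -------------------------------------------------------
    with _stage(report, "enrichment"):
        background = set(norm.values.index)
        de_genes = higher | lower
        enriched_names: list[str] = []
        for kind, path, method, min_genes in (
            ("markers", config.marker_gmt_path, "bonferroni", config.min_marker_genes),
            ("terms", config.term_gmt_path, "BH", 1),
        ):
            if path is None or not de_genes:
                continue
            sets = read_gmt(path)
            if min_genes > 1:
                sets = filter_marker_sets(sets, min_genes=min_genes)
            records = adjust(hypergeom_enrich(de_genes & background, sets, background),
                             method=method)
            frame = pd.DataFrame([r.__dict__ for r in records])
            frame.to_csv(out / f"enrichment_{kind}.tsv", sep="\t", index=False)
            sig = significant_cell_types(records) if method == "bonferroni" else [
                r for r in records if r.fold_enrichment > 1.0 and r.adjusted_p < 0.05]
            report.counts[f"enriched_{kind}"] = len(sig)
            enriched_names += [r.set_name for r in sig]
        report.counts["enriched_set_names"] = sorted(enriched_names)

    report.to_json(out / "report.json")
    (out / "summary.txt").write_text(report.summary() + "\n")
    logger.info("pipeline complete: %s", out / "report.json")
    return report
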
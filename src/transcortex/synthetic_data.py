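"""Seed-deterministic synthetic atlas generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* several donor brains, each contributing a block of cortical samples with
  additive, gene-specific donor offsets (what linear batch removal can
  eliminate exactly) and an exchangeable intra-donor residual correlation
  (what the consensus-correlation stage must recover);
* probes nested in genes with heterogeneous fidelity — one designated best
  probe per gene with low measurement noise — plus per-probe detection rates;
* left-cortical sample coordinates placed so a controlled fraction falls
  inside an axis-aligned box mask (with an optional mirrored right-hemisphere
  twin to exercise coordinate mirroring);
* planted regional differential expression inside the mask;
* a companion gene-level RNAseq table for a subset of donors, sharing the
  donor-level biological signal but with independent technical noise;
* cell-type marker sets partially overlapping the planted genes.

Default scale (6 donors x 200 cortical samples, 2000 genes, 2 RNAseq donors,
5% of samples inside the mask) mirrors the shape of the six-donor human brain
atlas analysis at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    DetectionMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    MaskVolume,
    ProbeTable,
    SampleTable,
    write_expression_bundle,
    write_gmt,
    write_mask,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedAtlas",
    "DiseaseSpec",
    "generate_dataset",
    "generate_atlas",
    "generate_disease_signature_table",
]

# world-space mask geometry (millimetres); grid is 40x48x40 at 2 mm isotropic
GRID_SHAPE = (40, 48, 40)
VOXEL_MM = 2.0
GRID_ORIGIN = (-40.0, -48.0, -40.0)
LEFT_BOX = ((-30.0, -10.0), (-20.0, 10.0), (0.0, 20.0))  # (lo, hi) per axis


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the reference conditions."""

    n_donors: int = 6
    samples_per_donor: int = 200
    n_genes: int = 2000
    probes_per_gene_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.2, 4: 0.1})
    donor_batch_sd: float = 0.8
    residual_sd: float = 0.4
    intra_donor_correlation: float = 0.3
    n_planted_de: int = 50
    de_effect_size: float = 1.0      # mean shift inside mask, residual-sd units
    mask_fraction: float = 0.05      # fraction of cortical samples inside the mask
    detection_rate_range: tuple[float, float] = (0.2, 0.95)
    rnaseq_donors: int = 2
    rnaseq_noise_sd: float = 0.5
    marker_set_specs: list[tuple[int, int]] = field(
        default_factory=lambda: [(20, 15), (15, 10), (10, 8), (20, 0), (15, 0), (4, 2), (3, 0)])
    seed: int = 0
    # secondary structure knobs
    n_structures: int = 10
    n_noncortical_per_donor: int = 8
    frac_genes_missing_rnaseq: float = 0.05
    n_low_fidelity_genes: int = 30   # genes whose probes are too noisy to track RNAseq
    frac_planted_higher: float = 0.7
    include_mirrored_mask: bool = True

    def __post_init__(self) -> None:
        if min(self.n_donors, self.samples_per_donor, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.intra_donor_correlation < 1.0):
            raise ValueError("intra_donor_correlation must be in [0, 1)")
        if not (0.0 < self.mask_fraction < 1.0):
            raise ValueError("mask_fraction must be in (0, 1)")
        lo, hi = self.detection_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("detection_rate_range probabilities must be in [0, 1]")
        if self.n_planted_de > self.n_genes:
            raise ValueError("n_planted_de exceeds n_genes")
        total = sum(self.probes_per_gene_distribution.values())
        if abs(total - 1.0) > 1e-9 or min(self.probes_per_gene_distribution) < 1:
            raise ValueError("probes_per_gene_distribution must be a distribution over ints >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream recovery."""

    planted_de_genes: dict[str, float]        # gene -> signed effect (expression units)
    true_affected_samples: list[str]
    per_donor_offsets: pd.DataFrame           # donors x genes
    enriched_marker_sets: list[str]           # expected to reach significance
    best_probe: dict[str, str]                # gene -> designated highest-fidelity probe

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_de_genes": self.planted_de_genes,
            "true_affected_samples": self.true_affected_samples,
            "per_donor_offsets": self.per_donor_offsets.to_dict(orient="index"),
            "enriched_marker_sets": self.enriched_marker_sets,
            "best_probe": self.best_probe,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedAtlas:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    probes: ProbeTable
    samples: SampleTable               # all donors concatenated
    expression: ExpressionMatrix       # probe-level
    detection: DetectionMatrix
    rnaseq: ExpressionMatrix           # gene-level, RNAseq-donor samples only
    gene_matrix: pd.DataFrame          # noiseless-probe gene x sample signal (for oracles)
    masks: dict[str, MaskVolume]       # "left" (and "right" mirrored twin)
    markers: GeneSetCollection
    truth: GroundTruth

    def donor_of(self) -> pd.Series:
        return self.samples.donor_ids


def _make_mask(box, name: str) -> MaskVolume:
    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])
    affine[:3, 3] = GRID_ORIGIN
    grid = np.zeros(GRID_SHAPE)
    centers = [GRID_ORIGIN[a] + VOXEL_MM * np.arange(GRID_SHAPE[a]) for a in range(3)]
    inside = [
        (centers[a] >= box[a][0]) & (centers[a] <= box[a][1]) for a in range(3)
    ]
    grid[np.ix_(*[np.where(m)[0] for m in inside])] = 1.0
    return MaskVolume(grid=grid, affine=affine, name=name)


def _mirror_box(box):
    (xlo, xhi), y, z = box
    return ((-xhi, -xlo), y, z)


def _sample_outside_box(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform left-hemisphere points at least one voxel clear of the mask box."""
    lo = np.array([-38.0, -46.0, -38.0])
    hi = np.array([-2.0, 44.0, 36.0])
    pad = 2 * VOXEL_MM
    blo = np.array([b[0] for b in LEFT_BOX]) - pad
    bhi = np.array([b[1] for b in LEFT_BOX]) + pad
    out = np.empty((0, 3))
    while len(out) < n:
        cand = rng.uniform(lo, hi, size=(2 * n + 16, 3))
        keep = ~np.all((cand >= blo) & (cand <= bhi), axis=1)
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _sample_inside_box(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points one voxel inside the mask box (trilinear value exactly 1)."""
    lo = np.array([b[0] for b in LEFT_BOX]) + VOXEL_MM
    hi = np.array([b[1] for b in LEFT_BOX]) - VOXEL_MM
    return rng.uniform(lo, hi, size=(n, 3))


def generate_dataset(config: SimulationConfig) -> SimulatedAtlas:
    """Run the generative model; everything flows from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    # structural layout (which ids exist) is a function of the config alone so
    # that changing the seed changes values but never shapes or identifiers
    rng_struct = np.random.default_rng(202310)
    donors = [f"D{d + 1}" for d in range(config.n_donors)]
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    # ----- samples and coordinates -------------------------------------------------
    n_cortical = config.n_donors * config.samples_per_donor
    n_inside = int(round(config.mask_fraction * n_cortical))
    if n_inside == 0:
        raise ValueError("degenerate design: mask_fraction places zero samples inside the mask")

    rows = []
    inside_flags = []
    # distribute inside-mask samples round-robin over donors
    inside_per_donor = [n_inside // config.n_donors] * config.n_donors
    for k in range(n_inside % config.n_donors):
        inside_per_donor[k] += 1
    structures = [f"ctx-parcel-{i + 1:02d}" for i in range(config.n_structures)]
    for d, donor in enumerate(donors):
        n_in = inside_per_donor[d]
        n_out = config.samples_per_donor - n_in
        pts = np.vstack([_sample_inside_box(rng, n_in), _sample_outside_box(rng, n_out)])
        labels = rng.choice(structures, size=config.samples_per_donor)
        for j in range(config.samples_per_donor):
            rows.append((f"{donor}_s{j + 1:04d}", donor, labels[j],
                         pts[j, 0], pts[j, 1], pts[j, 2], "left"))
            inside_flags.append(j < n_in)
        # non-cortical samples, excluded downstream by the cortical label list
        extra = _sample_outside_box(rng, config.n_noncortical_per_donor)
        for j in range(config.n_noncortical_per_donor):
            rows.append((f"{donor}_x{j + 1:03d}", donor, "subcortex",
                         extra[j, 0], extra[j, 1], extra[j, 2], "left"))
            inside_flags.append(False)
    samples = SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "structure_label",
                       "mni_x", "mni_y", "mni_z", "hemisphere"]))
    sample_ids = samples.sample_ids
    inside = np.array(inside_flags)
    donor_codes = samples.frame["donor_id"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    n_samples = len(sample_ids)

    # ----- gene universe partitions ------------------------------------------------
    n_missing = int(round(config.frac_genes_missing_rnaseq * config.n_genes))
    perm = rng_struct.permutation(config.n_genes)
    missing_rnaseq = set(np.array(genes)[perm[:n_missing]])
    low_fidelity = set(np.array(genes)[perm[n_missing:n_missing + config.n_low_fidelity_genes]])
    eligible = [g for g in genes if g not in missing_rnaseq and g not in low_fidelity]
    planted = list(rng.choice(eligible, size=config.n_planted_de, replace=False))
    n_higher = int(round(config.frac_planted_higher * config.n_planted_de))
    signs = np.array([1.0] * n_higher + [-1.0] * (config.n_planted_de - n_higher))
    effects = {g: float(s * config.de_effect_size * config.residual_sd)
               for g, s in zip(planted, signs)}

    # ----- gene-level signal -------------------------------------------------------
    baseline = rng.uniform(3.0, 10.0, size=config.n_genes)
    offsets = rng.normal(0.0, config.donor_batch_sd, size=(config.n_donors, config.n_genes))
    rho = config.intra_donor_correlation
    shared = rng.normal(size=(config.n_donors, config.n_genes))     # per-(donor, gene)
    noise = rng.normal(size=(config.n_genes, n_samples))
    resid = config.residual_sd * (np.sqrt(rho) * shared[donor_codes, :].T
                                  + np.sqrt(1.0 - rho) * noise)
    effect_vec = np.array([effects.get(g, 0.0) for g in genes])
    signal = (baseline[:, None] + effect_vec[:, None] * inside[None, :]) + resid
    gene_matrix = pd.DataFrame(signal + offsets.T[:, donor_codes],
                               index=genes, columns=sample_ids)

    # ----- probes nested in genes --------------------------------------------------
    ks = sorted(config.probes_per_gene_distribution)
    pvals = np.array([config.probes_per_gene_distribution[k] for k in ks], dtype=float)
    n_probes_per_gene = rng_struct.choice(ks, size=config.n_genes, p=pvals / pvals.sum())
    probe_rows, probe_values, probe_rates = [], [], []
    best_probe: dict[str, str] = {}
    lo_rate, hi_rate = config.detection_rate_range
    for gi, g in enumerate(genes):
        k = int(n_probes_per_gene[gi])
        order = rng.permutation(k)  # position of the best probe is random
        for j in range(k):
            pid = f"P{gi + 1:05d}_{j + 1}"
            is_best = order[j] == 0
            if g in low_fidelity:
                sd, is_best = 8.0, False
            elif is_best:
                sd = 0.1
            else:
                sd = rng.uniform(0.4, 1.0)
            bias = 0.0 if is_best else rng.normal(0.0, 0.5)
            rate = rng.uniform(0.7, 0.98) if (is_best or g in low_fidelity) \
                else rng.uniform(lo_rate, hi_rate)
            if is_best:
                best_probe[g] = pid
            probe_rows.append((pid, g, True))
            probe_values.append(gene_matrix.loc[g].to_numpy()
                                + bias + rng.normal(0.0, sd, size=n_samples))
            probe_rates.append(rate)
        if g in low_fidelity:  # deterministic stand-in so the dict stays total
            best_probe[g] = f"P{gi + 1:05d}_1"
    # unannotated probes: pure noise, no gene symbol
    for u in range(20):
        probe_rows.append((f"PU{u + 1:04d}", "", False))
        probe_values.append(rng.normal(5.0, 1.0, size=n_samples))
        probe_rates.append(rng.uniform(lo_rate, hi_rate))

    probes = ProbeTable(pd.DataFrame(probe_rows,
                                     columns=["probe_id", "gene_symbol", "is_annotated"]))
    probe_ids = probes.probe_ids
    expr = ExpressionMatrix(
        pd.DataFrame(np.vstack(probe_values), index=probe_ids, columns=sample_ids),
        row_kind="probe")
    det = DetectionMatrix(pd.DataFrame(
        (rng.random((len(probe_ids), n_samples)) < np.asarray(probe_rates)[:, None]).astype(int),
        index=probe_ids, columns=sample_ids))

    # ----- companion RNAseq: shared donor-level biology, independent noise --------
    rnaseq_donor_set = set(donors[: config.rnaseq_donors])
    rnaseq_cols = [s for s, d in zip(sample_ids, samples.frame["donor_id"]) if d in rnaseq_donor_set]
    rnaseq_genes = [g for g in genes if g not in missing_rnaseq]
    col_idx = [sample_ids.index(s) for s in rnaseq_cols]
    rnaseq_vals = (gene_matrix.loc[rnaseq_genes].to_numpy()[:, col_idx]
                   + rng.normal(0.0, config.rnaseq_noise_sd,
                                size=(len(rnaseq_genes), len(rnaseq_cols))))
    rnaseq = ExpressionMatrix(
        pd.DataFrame(rnaseq_vals, index=rnaseq_genes, columns=rnaseq_cols), row_kind="gene")

    # ----- marker sets -------------------------------------------------------------
    non_planted = [g for g in eligible if g not in effects]
    sets: dict[str, tuple[str, list[str]]] = {}
    enriched: list[str] = []
    for si, (size, n_overlap) in enumerate(config.marker_set_specs):
        if n_overlap > size:
            raise ValueError("marker overlap exceeds set size")
        if n_overlap > len(planted):  # e.g. a null design with no planted genes
            n_overlap = len(planted)
        members = list(rng.choice(planted, size=n_overlap, replace=False)) + \
            list(rng.choice(non_planted, size=size - n_overlap, replace=False))
        name = f"celltype_{si + 1:02d}"
        sets[name] = (f"synthetic marker set ({n_overlap}/{size} planted)", members)
        if size >= 5 and n_overlap / size >= 0.6:
            enriched.append(name)
    markers = GeneSetCollection(sets)

    truth = GroundTruth(
        planted_de_genes=effects,
        true_affected_samples=[s for s, f in zip(sample_ids, inside_flags) if f],
        per_donor_offsets=pd.DataFrame(offsets, index=donors, columns=genes),
        enriched_marker_sets=enriched,
        best_probe=best_probe,
    )
    masks = {"left": _make_mask(LEFT_BOX, "mask_left")}
    if config.include_mirrored_mask:
        masks["right"] = _make_mask(_mirror_box(LEFT_BOX), "mask_right")
    return SimulatedAtlas(config=config, probes=probes, samples=samples, expression=expr,
                          detection=det, rnaseq=rnaseq, gene_matrix=gene_matrix,
                          masks=masks, markers=markers, truth=truth)


def generate_atlas(config: SimulationConfig, out_dir: str | Path) -> SimulatedAtlas:
    """Generate and persist the full fixture in the pipeline's on-disk dialects.

    Layout: ``<out_dir>/donor_<id>/`` CSV bundles, ``mask_left.nii`` (and the
    mirrored ``mask_right.nii``), ``markers.gmt``, ``rnaseq.csv`` (headered
    gene x sample), ``cortical_labels.txt`` and ``ground_truth.json``.
    """
    atlas = generate_dataset(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for donor, sub in atlas.samples.frame.groupby("donor_id", sort=False):
        ids = sub["sample_id"].tolist()
        write_expression_bundle(
            out / f"donor_{donor}",
            atlas.probes,
            SampleTable(sub.reset_index(drop=True)),
            ExpressionMatrix(atlas.expression.values[ids], row_kind="probe"),
            DetectionMatrix(atlas.detection.values[ids]),
        )
    for key, mask in atlas.masks.items():
        write_mask(out / f"mask_{key}.nii", mask)
    write_gmt(out / "markers.gmt", atlas.markers)
    atlas.rnaseq.values.to_csv(out / "rnaseq.csv")
    labels = sorted(set(atlas.samples.frame["structure_label"]) - {"subcortex"})
    (out / "cortical_labels.txt").write_text("\n".join(labels) + "\n")
    atlas.truth.to_json(out / "ground_truth.json")
    (out / "config.json").write_text(json.dumps(asdict(atlas.config), default=list, indent=1))
    return atlas


@dataclass
class DiseaseSpec:
    """How many genes of each kind a synthetic disease signature contains."""

    name: str
    n_higher: int
    n_lower: int
    n_null: int = 20
    share_higher_with: str | None = None  # reuse this many higher genes from another disease
    n_shared: int = 0


def generate_disease_signature_table(
    gene_universe: list[str], specs: list[DiseaseSpec], seed: int
) -> pd.DataFrame:
    """Tabular fixture of per-disease (gene, logFC, q) rows with controlled gate counts.

    Qualifying "higher" rows have q ≤ 0.05 and logFC > 0.1; "lower" rows have
    q ≤ 0.05 and logFC < −0.1; null rows fail at least one gate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    higher_by_disease: dict[str, list[str]] = {}
    for spec in specs:
        n_total = spec.n_higher + spec.n_lower + spec.n_null
        if n_total > len(gene_universe):
            raise ValueError(f"disease {spec.name!r} requests more genes than the universe holds")
        shared: list[str] = []
        if spec.share_higher_with is not None:
            pool = higher_by_disease.get(spec.share_higher_with)
            if pool is None:
                raise ValueError(f"unknown shared-with disease {spec.share_higher_with!r}")
            if spec.n_shared > min(len(pool), spec.n_higher):
                raise ValueError("n_shared exceeds available higher genes")
            shared = list(rng.choice(pool, size=spec.n_shared, replace=False))
        fresh_pool = [g for g in gene_universe if g not in shared]
        fresh = list(rng.choice(fresh_pool, size=n_total - len(shared), replace=False))
        higher = shared + fresh[: spec.n_higher - len(shared)]
        rest = fresh[spec.n_higher - len(shared):]
        lower, nulls = rest[: spec.n_lower], rest[spec.n_lower:]
        for g in higher:
            rows.append((g, spec.name, rng.uniform(0.15, 1.0), rng.uniform(0.0, 0.05)))
        for g in lower:
            rows.append((g, spec.name, -rng.uniform(0.15, 1.0), rng.uniform(0.0, 0.05)))
        for g in nulls:
            if rng.random() < 0.5:  # fails the q gate
                rows.append((g, spec.name, rng.uniform(-1.0, 1.0), rng.uniform(0.051, 1.0)))
            else:  # fails the logFC gate
                rows.append((g, spec.name, rng.uniform(-0.1, 0.1), rng.uniform(0.0, 0.05)))
        higher_by_disease[spec.name] = higher
    return pd.DataFrame(rows, columns=["gene", "disease", "logFC", "q"])
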
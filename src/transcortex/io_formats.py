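"""Readers and writers for every external format the pipeline touches.

The microarray atlas dialect is a per-donor directory of four CSV files:

``Probes.csv``
    headered: ``probe_id,gene_symbol,is_annotated``
``SampleAnnot.csv``
    headered: ``sample_id,donor_id,structure_label,mni_x,mni_y,mni_z,hemisphere``
``MicroarrayExpression.csv``
    headerless; first column is the probe id, remaining columns are samples in
    ``SampleAnnot.csv`` row order (log-scale intensities)
``PACall.csv``
    headerless, same layout; binary above-background detection calls

Expression values are treated as already log-scaled at load; the loader never
transforms them. Gene identifiers are case-sensitive symbols with no alias
resolution. Coordinates are world-space MNI millimetres; voxel/world conversion
happens only through :class:`MaskVolume`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeTable",
    "SampleTable",
    "ExpressionMatrix",
    "DetectionMatrix",
    "MaskVolume",
    "GeneSetCollection",
    "FormatError",
    "read_expression_bundle",
    "write_expression_bundle",
    "concat_bundles",
    "read_gmt",
    "write_gmt",
    "read_mask",
    "write_mask",
]

BUNDLE_FILES = ("Probes.csv", "SampleAnnot.csv", "MicroarrayExpression.csv", "PACall.csv")


class FormatError(ValueError):
    """Fatal validation failure while reading or cross-checking an input file."""


@dataclass
class ProbeTable:
    """Probe → gene annotation. ``is_annotated`` rows must carry a gene symbol."""

    frame: pd.DataFrame  # columns: probe_id, gene_symbol, is_annotated

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol", "is_annotated"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"probe table missing columns: {sorted(missing)}")
        if self.frame["probe_id"].duplicated().any():
            dup = self.frame.loc[self.frame["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id: {dup!r}")
        annotated = self.frame[self.frame["is_annotated"].astype(bool)]
        bad = annotated["gene_symbol"].astype(str).str.len() == 0
        if bad.any():
            raise FormatError(
                f"annotated probe without gene symbol: {annotated.loc[bad, 'probe_id'].iloc[0]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.frame["probe_id"].tolist()

    def gene_of(self) -> pd.Series:
        """probe_id-indexed gene symbols for annotated probes only."""
        annotated = self.frame[self.frame["is_annotated"].astype(bool)]
        return annotated.set_index("probe_id")["gene_symbol"]


@dataclass
class SampleTable:
    """Per-sample donor, anatomical structure, MNI world coordinate and hemisphere."""

    frame: pd.DataFrame  # sample_id, donor_id, structure_label, mni_x/y/z, hemisphere

    def __post_init__(self) -> None:
        required = {"sample_id", "donor_id", "structure_label",
                    "mni_x", "mni_y", "mni_z", "hemisphere"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        coords = self.frame[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise FormatError("non-finite MNI coordinate in sample table")
        bad_hemi = ~self.frame["hemisphere"].isin(["left", "right"])
        if bad_hemi.any():
            raise FormatError(
                f"invalid hemisphere value: {self.frame.loc[bad_hemi, 'hemisphere'].iloc[0]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def donor_ids(self) -> pd.Series:
        return self.frame.set_index("sample_id")["donor_id"]

    def coords(self) -> np.ndarray:
        """(n_samples, 3) world-space millimetre coordinates."""
        return self.frame[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)


@dataclass
class ExpressionMatrix:
    """Real-valued matrix of log-scale expression, rows are probes or genes."""

    values: pd.DataFrame  # index: row ids, columns: sample ids
    row_kind: str = "probe"  # {"probe", "gene"}

    def __post_init__(self) -> None:
        if self.row_kind not in ("probe", "gene"):
            raise FormatError(f"row_kind must be 'probe' or 'gene', got {self.row_kind!r}")
        if self.values.isna().any().any():
            n = int(self.values.isna().sum().sum())
            raise FormatError(f"expression matrix contains {n} missing values")

    @property
    def row_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def col_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class DetectionMatrix:
    """Binary above-background detection calls, same shape/ids as probe expression."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise FormatError("detection matrix is not binary")

    @property
    def row_ids(self) -> list[str]:
        return self.values.index.tolist()


@dataclass
class MaskVolume:
    """A 3-D grid with a voxel-to-world affine, in millimetres."""

    grid: np.ndarray
    affine: np.ndarray
    name: str = "mask"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise FormatError(f"mask grid must be 3-D, got {self.grid.ndim}-D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if not np.all(np.isfinite(self.grid)):
            raise FormatError("mask grid contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("mask affine is not invertible")

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (n,3) world coordinates to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.c_[pts, np.ones(len(pts))]
        return (homog @ inv.T)[:, :3]


@dataclass
class GeneSetCollection:
    """Named gene sets (terms, cell-type markers, disease signatures)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets.keys())


# ---------------------------------------------------------------------------
# expression bundle
# ---------------------------------------------------------------------------

def read_expression_bundle(
    dir_path: str | Path, headered: bool = False
) -> tuple[ProbeTable, SampleTable, ExpressionMatrix, DetectionMatrix]:
    """Load one donor's four-file CSV bundle with cross-table validation.

    Parameters
    ----------
    dir_path
        Directory containing the four bundle CSVs.
    headered
        If True, expect a header row on the expression/detection CSVs
        (first column still the probe id) instead of the default headerless
        atlas dialect.
    """
    dir_path = Path(dir_path)
    for fname in BUNDLE_FILES:
        if not (dir_path / fname).is_file():
            raise FormatError(f"missing bundle file: {dir_path / fname}")

    probes = ProbeTable(pd.read_csv(dir_path / "Probes.csv", dtype={"probe_id": str,
                                                                    "gene_symbol": str}))
    probes.frame["gene_symbol"] = probes.frame["gene_symbol"].fillna("")
    samples = SampleTable(pd.read_csv(dir_path / "SampleAnnot.csv",
                                      dtype={"sample_id": str, "donor_id": str}))

    header = 0 if headered else None
    expr_raw = pd.read_csv(dir_path / "MicroarrayExpression.csv", header=header, dtype={0: str})
    det_raw = pd.read_csv(dir_path / "PACall.csv", header=header, dtype={0: str})
    sample_ids = samples.sample_ids

    def _shape(raw: pd.DataFrame, what: str) -> pd.DataFrame:
        if raw.shape[1] != len(sample_ids) + 1:
            raise FormatError(
                f"{what}: {raw.shape[1] - 1} data columns but {len(sample_ids)} annotated samples"
            )
        out = raw.set_index(raw.columns[0])
        out.index = out.index.astype(str)
        out.index.name = "probe_id"
        out.columns = sample_ids
        return out.astype(float)

    expr_df = _shape(expr_raw, "MicroarrayExpression.csv")
    det_df = _shape(det_raw, "PACall.csv")

    _check_ids(expr_df.index, probes.probe_ids, "expression probe", "Probes.csv")
    _check_ids(det_df.index, probes.probe_ids, "detection probe", "Probes.csv")
    if list(expr_df.index) != list(det_df.index):
        raise FormatError("expression and detection probe ordering differ")

    expr = ExpressionMatrix(expr_df, row_kind="probe")
    det = DetectionMatrix(det_df)
    logger.info("loaded bundle %s: %d probes x %d samples",
                dir_path, expr_df.shape[0], expr_df.shape[1])
    return probes, samples, expr, det


def _check_ids(found, declared, what: str, where: str) -> None:
    declared = set(declared)
    for fid in found:
        if fid not in declared:
            raise FormatError(f"{what} id {fid!r} not present in {where}")


def write_expression_bundle(
    dir_path: str | Path,
    probes: ProbeTable,
    samples: SampleTable,
    expr: ExpressionMatrix,
    det: DetectionMatrix,
) -> None:
    """Write a donor bundle in the headerless atlas dialect."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    probes.frame.to_csv(dir_path / "Probes.csv", index=False)
    samples.frame.to_csv(dir_path / "SampleAnnot.csv", index=False)
    expr.values.to_csv(dir_path / "MicroarrayExpression.csv", header=False)
    det.values.astype(int).to_csv(dir_path / "PACall.csv", header=False)


def concat_bundles(
    bundles: list[tuple[ProbeTable, SampleTable, ExpressionMatrix, DetectionMatrix]],
) -> tuple[ProbeTable, SampleTable, ExpressionMatrix, DetectionMatrix]:
    """Column-concatenate per-donor bundles sharing an identical probe universe."""
    if not bundles:
        raise FormatError("no bundles to concatenate")
    probes0 = bundles[0][0]
    ref_ids = probes0.probe_ids
    for probes, *_ in bundles[1:]:
        if probes.probe_ids != ref_ids:
            raise FormatError("bundles disagree on probe universe")
    samples = SampleTable(pd.concat([b[1].frame for b in bundles], ignore_index=True))
    expr = ExpressionMatrix(pd.concat([b[2].values for b in bundles], axis=1), row_kind="probe")
    det = DetectionMatrix(pd.concat([b[3].values for b in bundles], axis=1))
    return probes0, samples, expr, det


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated gene-set file: name, description, members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            name, desc = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> MaskVolume:
    """Read a single 3-D NIfTI volume; affine from the header, values untouched."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return MaskVolume(grid=data, affine=np.asarray(img.affine), name=Path(path).stem)


def write_mask(path: str | Path, mask: MaskVolume) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.float32), mask.affine)
    nib.save(img, str(path))
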
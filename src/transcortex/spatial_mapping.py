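"""Assign atlas samples to affected/control regions defined by volumetric masks.

Statistical-map masks are drawn on one hemisphere; because the atlas samples
the left cortex far more densely, mask coordinates can be mirrored across the
midsagittal plane (x → −x in MNI world space) before lookup. Mirroring is
implemented by negating the sample x-coordinate, which is exactly equivalent
to flipping the mask volume and avoids resampling.

A sample is "affected" when the trilinear interpolation of any mask at its
(optionally mirrored) world coordinate reaches a threshold (default 0.5, the
nearest-neighbour-equivalent rule for binary masks). Multiple masks combine
by maximum, i.e. their union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import MaskVolume, SampleTable

logger = logging.getLogger(__name__)

__all__ = ["RegionAssignment", "mirror_x", "trilinear_sample", "assign_samples"]

AFFECTED, CONTROL, EXCLUDED = "affected", "control", "excluded"


@dataclass
class RegionAssignment:
    """Per-sample affected/control/excluded label with interpolated mask values."""

    table: pd.DataFrame  # index sample_id; columns label, mask_value, mask_name

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def ids(self, label: str) -> list[str]:
        return self.table.index[self.table["label"] == label].tolist()

    def counts_by_donor(self, samples: SampleTable) -> pd.DataFrame:
        """Affected/control/excluded counts per donor, one row per donor."""
        merged = self.table.join(samples.frame.set_index("sample_id")["donor_id"])
        return (merged.groupby(["donor_id", "label"]).size()
                .unstack(fill_value=0)
                .reindex(columns=[AFFECTED, CONTROL, EXCLUDED], fill_value=0))


def mirror_x(coords: np.ndarray) -> np.ndarray:
    """Reflect world coordinates across the midsagittal plane: (x,y,z) → (−x,y,z)."""
    coords = np.asarray(coords, dtype=float)
    out = coords.copy()
    out[..., 0] = -out[..., 0]
    return out


def trilinear_sample(vol: MaskVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the volume at world-space points.

    Points mapping outside the grid's index bounding box return 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = vol.world_to_voxel(pts)  # (n, 3) continuous indices
    vals = ndimage.map_coordinates(vol.grid, idx.T, order=1, mode="constant", cval=0.0)
    return vals if np.asarray(points).ndim > 1 else float(vals[0])


def assign_samples(
    samples: SampleTable,
    masks: list[MaskVolume],
    cortical_labels: set[str],
    threshold: float = 0.5,
    mirror: bool = False,
) -> RegionAssignment:
    """Label every sample affected / control / excluded.

    Samples are excluded unless their structure label is in ``cortical_labels``
    and they lie in the left hemisphere. A cortical sample is affected iff the
    maximum over masks of the trilinear value at its (mirrored if requested)
    coordinate is ≥ ``threshold``.
    """
    if not masks:
        raise ValueError("at least one mask required")
    frame = samples.frame
    cortical = frame["structure_label"].isin(cortical_labels) & (frame["hemisphere"] == "left")
    if not cortical.any():
        raise ValueError("empty cortical selection: no left-hemisphere samples "
                         "match the cortical label list")

    coords = samples.coords()
    lookup = mirror_x(coords) if mirror else coords
    per_mask = np.stack([trilinear_sample(m, lookup) for m in masks])  # (n_masks, n)
    best = per_mask.argmax(axis=0)
    value = per_mask.max(axis=0)
    mask_names = np.array([m.name for m in masks])[best]

    label = np.where(value >= threshold, AFFECTED, CONTROL)
    label = np.where(cortical.to_numpy(), label, EXCLUDED)
    table = pd.DataFrame(
        {"label": label, "mask_value": value, "mask_name": mask_names},
        index=pd.Index(frame["sample_id"], name="sample_id"),
    )
    table.loc[table["label"] == EXCLUDED, "mask_name"] = ""
    n_aff = int((table["label"] == AFFECTED).sum())
    n_ctl = int((table["label"] == CONTROL).sum())
    logger.info("sample assignment: %d affected, %d control, %d excluded",
                n_aff, n_ctl, int((table["label"] == EXCLUDED).sum()))
    return RegionAssignment(table)
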
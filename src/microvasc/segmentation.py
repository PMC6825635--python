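"""Vessel segmentation by hysteresis thresholding.

Intratumoral vessels carry a bright immunosignal (e.g. the endothelial
marker CD34) over a dimmer tissue background.  Segmentation is a dual
threshold: voxels at or above the high threshold seed the mask, and voxels
at or above the low threshold are kept only when connected to a seed.  This
keeps dim vessel stretches that are contiguous with bright ones while
rejecting isolated background fluctuations of the same intensity.

Connectivity is configurable (6, 18 or 26 neighbours in 3D); 26 is the
default because thin vessels running obliquely to the grid disconnect under
face-only adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import ConsistencyError, DegenerateInputError, ParameterError
from .volume_io import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "SegmentationParams",
    "hysteresis_threshold",
    "auto_thresholds",
    "remove_small_components",
    "connected_components",
]

#: voxel-neighbourhood size -> scipy structuring-element rank
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ParameterError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean volume aligned to a :class:`VoxelGrid`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != bool:
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ParameterError(f"mask must be 3D, got ndim={data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def positive_count(self) -> int:
        return int(self.data.sum())

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass(frozen=True)
class SegmentationParams:
    """Hysteresis thresholds and cleanup settings.

    Thresholds are in raw intensity units of the input volume.  The default
    ``min_component_voxels`` of 27 corresponds to a 15 µm cube at the 5 µm
    analysis grid and drops speckle smaller than any plausible vessel.
    """

    low_threshold: float
    high_threshold: float
    connectivity: int = 26
    min_component_voxels: int = 27

    def __post_init__(self):
        if not (0 <= self.low_threshold <= self.high_threshold):
            raise ParameterError(
                f"need 0 <= low <= high, got low={self.low_threshold}, "
                f"high={self.high_threshold}"
            )
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ParameterError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.min_component_voxels < 0:
            raise ParameterError("min_component_voxels must be >= 0")


def hysteresis_threshold(grid: VoxelGrid, params: SegmentationParams) -> BinaryMask:
    """Dual-threshold segmentation.

    A voxel is positive iff its intensity is >= ``low_threshold`` and it is
    connected (under ``params.connectivity``) through such voxels to at
    least one voxel >= ``high_threshold``.  With ``low == high`` this equals
    a simple threshold.
    """
    low_mask = grid.data >= params.low_threshold
    high_mask = grid.data >= params.high_threshold
    structure = _structure(params.connectivity)
    labels, n_labels = ndi.label(low_mask, structure=structure)
    if n_labels == 0:
        return BinaryMask(data=np.zeros(grid.shape, dtype=bool), spacing=grid.spacing)
    seeded = np.unique(labels[high_mask])
    seeded = seeded[seeded > 0]
    keep = np.zeros(n_labels + 1, dtype=bool)
    keep[seeded] = True
    return BinaryMask(data=keep[labels], spacing=grid.spacing)


def auto_thresholds(grid: VoxelGrid, method: str = "otsu-split") -> tuple[float, float]:
    """Derive (low, high) hysteresis thresholds from the intensity histogram.

    ``"otsu-split"``: the high threshold is the Otsu threshold of the full
    histogram; the low threshold is the midpoint between the high threshold
    and the histogram mode below it (the background peak).  Always returns
    ``low <= high``.
    """
    if method != "otsu-split":
        raise ParameterError(f"unknown auto-threshold method {method!r}")
    data = grid.data
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise DegenerateInputError("constant volume: no threshold separates it")
    high = float(threshold_otsu(data.ravel()))
    counts, edges = np.histogram(data, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    below = centers < high
    if below.any():
        mode = float(centers[below][np.argmax(counts[below])])
        low = 0.5 * (mode + high)
    else:
        low = high
    return (min(low, high), high)


def remove_small_components(
    mask: BinaryMask, min_voxels: int, connectivity: int = 26
) -> BinaryMask:
    """Drop connected components with fewer than ``min_voxels`` voxels.

    ``min_voxels = 0`` (or 1) is the identity.
    """
    if min_voxels < 0:
        raise ParameterError("min_voxels must be >= 0")
    if min_voxels <= 1:
        return BinaryMask(data=mask.data.copy(), spacing=mask.spacing)
    labels, n_labels = ndi.label(mask.data, structure=_structure(connectivity))
    if n_labels == 0:
        return BinaryMask(data=mask.data.copy(), spacing=mask.spacing)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return BinaryMask(data=keep[labels], spacing=mask.spacing)


def connected_components(
    mask: BinaryMask, connectivity: int = 26
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label connected components and tabulate their sizes.

    Returns the labelled volume (labels 1..K, background 0) and a table with
    columns ``label``, ``voxel_count`` and ``volume_um3``; the sizes sum to
    the positive-voxel count.
    """
    labels, n_labels = ndi.label(mask.data, structure=_structure(connectivity))
    if n_labels == 0:
        table = pd.DataFrame(columns=["label", "voxel_count", "volume_um3"])
        return labels, table
    sizes = np.bincount(labels.ravel())[1:]
    table = pd.DataFrame(
        {
            "label": np.arange(1, n_labels + 1),
            "voxel_count": sizes,
            "volume_um3": sizes * mask.voxel_volume_um3(),
        }
    )
    return labels, table


def require_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ConsistencyError(f"mask shapes differ: {a.shape} vs {b.shape}")
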
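"""Reading, writing and resampling of 3D intensity volumes.

The unit of work throughout the package is the :class:`VoxelGrid`: a 3D
scalar intensity volume (axis order z, y, x; z is the optical-section axis)
with physical voxel spacing in micrometres.  Light-sheet acquisitions are
strongly anisotropic (sub-micron in xy, several microns between optical
sections), so every stage carries the spacing explicitly and
:func:`downsample_isotropic` resamples to the isotropic analysis grid
(5 µm by default downstream) by block averaging, which preserves the
fraction-of-signal semantics the density computation relies on.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGrid",
    "AcquisitionMeta",
    "read_tiff_stack",
    "write_tiff_stack",
    "downsample_isotropic",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar intensity volume with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Nonnegative, finite intensities.  Axis order is (z, y, x).
    spacing : tuple of float
        Physical voxel pitch ``(dz, dy, dx)`` in µm; strictly positive.
    origin : tuple of float, optional
        Physical position of voxel (0, 0, 0) in µm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ParameterError(f"volume must be 3D (z, y, x), got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ParameterError(f"every axis extent must be >= 1, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if np.issubdtype(data.dtype, np.floating):
            if not np.isfinite(data).all():
                raise ParameterError("intensities must be finite")
            if data.size and data.min() < 0:
                raise ParameterError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume along (z, y, x), in µm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry of a light-sheet stack.

    Defaults reflect a typical cleared-tissue acquisition: 0.585 µm lateral
    sampling and a 5 µm step between optical sections.
    """

    xy_resolution_um: float = 0.585
    z_step_um: float = 5.0
    channel_label: str = "CD34"
    source_path: str = ""

    def __post_init__(self):
        if self.xy_resolution_um <= 0 or self.z_step_um <= 0:
            raise ParameterError("resolutions must be strictly positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.z_step_um, self.xy_resolution_um, self.xy_resolution_um)


def _read_directory(path: str) -> np.ndarray:
    names = sorted(n for n in os.listdir(path) if not n.startswith("."))
    if not names:
        raise FormatError(f"no TIFF pages found in directory {path!r}")
    pages = []
    for name in names:
        page = tifffile.imread(os.path.join(path, name))
        if page.ndim != 2:
            raise FormatError(f"{name!r} is not a single-page 2D image (ndim={page.ndim})")
        pages.append(page)
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise FormatError(f"pages have unequal shapes: {sorted(shapes)}")
    return np.stack(pages, axis=0)


def _warn_on_tag_mismatch(path: str, spacing: tuple[float, float, float]) -> None:
    # TIFF resolution tags in cleared-tissue exports are unreliable; the
    # caller-supplied spacing always wins, but a conflict is worth a warning.
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is None:
                return
            num, den = res.value
            if num == 0 or num == den:  # absent or writer-default tag
                return
            # XResolution is pixels per unit; invert to µm per pixel assuming
            # the common micron-scaled convention.
            tag_dx = den / num
            if not np.isclose(tag_dx, spacing[2], rtol=0.05):
                logger.warning(
                    "TIFF resolution tag of %s implies dx=%.4g but spacing dx=%.4g "
                    "was supplied; using the supplied spacing",
                    path, tag_dx, spacing[2],
                )
    except Exception:  # tag parsing is best-effort only
        pass


def read_tiff_stack(path: str, spacing: tuple[float, float, float]) -> VoxelGrid:
    """Read a multi-page TIFF (or a directory of single-page TIFFs) as a VoxelGrid.

    z equals the page index; for a directory, pages are taken in lexicographic
    filename order.  Intensities are preserved bit-exactly.  ``spacing`` is
    attached as given; resolution tags embedded in the file are ignored (with
    a logged warning when they conflict).
    """
    if not os.path.exists(path):
        raise InputError(f"no such file or directory: {path!r}")
    if os.path.isdir(path):
        data = _read_directory(path)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise FormatError(f"expected a grayscale z-stack, got ndim={data.ndim}")
        if data.shape[0] == 0:
            raise FormatError(f"{path!r} contains zero pages")
        _warn_on_tag_mismatch(path, tuple(float(s) for s in spacing))
    return VoxelGrid(data=data, spacing=tuple(spacing))


def write_tiff_stack(grid: VoxelGrid, path: str) -> str:
    """Write a VoxelGrid as a lossless multi-page grayscale TIFF, one page per
    z-section.  ``read_tiff_stack`` inverts it bit-exactly."""
    try:
        tifffile.imwrite(path, grid.data, photometric="minisblack")
    except OSError as exc:
        raise InputError(f"cannot write TIFF to {path!r}: {exc}") from exc
    return path


def _block_mean_axis(a: np.ndarray, block: int, axis: int) -> np.ndarray:
    """Mean-reduce one axis in blocks of ``block`` voxels; the remainder that
    does not fill a whole block is folded into the last block."""
    n = a.shape[axis]
    n_out = max(1, n // block)
    starts = np.arange(n_out) * block
    sums = np.add.reduceat(a, starts, axis=axis)
    counts = np.diff(np.append(starts, n)).astype(np.float64)
    shape = [1] * a.ndim
    shape[axis] = n_out
    return sums / counts.reshape(shape)


def downsample_isotropic(grid: VoxelGrid, target_um: float) -> VoxelGrid:
    """Block-average a volume onto an isotropic grid of pitch ``target_um``.

    The block size along each axis is ``round(target_um / spacing_axis)``
    (minimum 1); each output voxel is the plain mean of the input voxels it
    covers, so a constant volume stays constant and, for evenly dividing
    extents, the global mean is preserved exactly.  Border voxels that do not
    fill a whole block are averaged into the last block rather than padded.
    """
    if target_um <= 0:
        raise ParameterError(f"target_um must be > 0, got {target_um}")
    blocks = tuple(max(1, round(target_um / s)) for s in grid.spacing)
    if blocks == (1, 1, 1):
        return VoxelGrid(data=grid.data, spacing=(target_um,) * 3, origin=grid.origin)
    out = grid.data.astype(np.float64)
    for axis, b in enumerate(blocks):
        if b > 1:
            out = _block_mean_axis(out, b, axis)
    return VoxelGrid(data=out, spacing=(target_um,) * 3, origin=grid.origin)
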
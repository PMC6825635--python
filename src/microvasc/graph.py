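"""Vascular graph extraction and radius morphometry.

The binary vessel mask is thinned to a one-voxel-wide centerline
(topological 3D thinning), the centerline is traced into a spatial graph of
nodes (endpoints and branch points) and segments (maximal centerline paths
between nodes), and a local radius is attached to every centerline point by
sampling the anisotropy-aware Euclidean distance transform of the mask.

Radii are classified into the three calibre classes used for vascular
phenotyping: thin (< 3 µm), intermediate, and thick (> 11 µm); radii of
exactly 3 or 11 µm count as intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .errors import ConsistencyError, ParameterError
from .segmentation import BinaryMask, _structure

logger = logging.getLogger(__name__)

__all__ = [
    "GraphNode",
    "GraphSegment",
    "VascularGraph",
    "GraphSummary",
    "RADIUS_THIN_BELOW_UM",
    "RADIUS_THICK_ABOVE_UM",
    "skeletonize_mask",
    "extract_graph",
    "estimate_radii",
    "classify_radius",
    "graph_summary",
    "export_spatial_graph",
    "import_spatial_graph",
]

#: default calibre-class bounds in µm
RADIUS_THIN_BELOW_UM = 3.0
RADIUS_THICK_ABOVE_UM = 11.0

_NB26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class GraphNode:
    id: int
    position_um: tuple[float, float, float]  # (z, y, x)
    degree: int
    radius_um: float | None = None


@dataclass
class GraphSegment:
    id: int
    node_ids: tuple[int, int]
    points_um: np.ndarray  # (n_points, 3), (z, y, x) in µm
    radii_um: np.ndarray | None = None  # (n_points,) in µm

    @property
    def length_um(self) -> float:
        if len(self.points_um) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())


@dataclass
class VascularGraph:
    """Spatial graph of a vascular network: nodes, segments, voxel spacing."""

    nodes: list[GraphNode]
    segments: list[GraphSegment]
    spacing: tuple[float, float, float]

    @property
    def n_points(self) -> int:
        return int(sum(len(s.points_um) for s in self.segments))

    def all_point_radii(self) -> np.ndarray:
        """Radii of all segment polyline points, concatenated."""
        if not self.segments:
            return np.empty(0)
        parts = [s.radii_um for s in self.segments if s.radii_um is not None]
        if len(parts) != len(self.segments):
            raise ParameterError("radii not filled; run estimate_radii first")
        return np.concatenate(parts)

    def validate(self) -> None:
        node_ids = {n.id for n in self.nodes}
        diag = float(np.linalg.norm(self.spacing))
        for seg in self.segments:
            if not set(seg.node_ids) <= node_ids:
                raise ConsistencyError(f"segment {seg.id} references unknown nodes")
            steps = np.linalg.norm(np.diff(seg.points_um, axis=0), axis=1)
            if steps.size and steps.max() > diag * (1 + 1e-9):
                raise ConsistencyError(
                    f"segment {seg.id} has a step larger than one voxel diagonal"
                )
            if seg.radii_um is not None and (
                not np.isfinite(seg.radii_um).all() or (seg.radii_um <= 0).any()
            ):
                raise ConsistencyError(f"segment {seg.id} has nonpositive radii")


def _solid_block_corners(skel: np.ndarray) -> np.ndarray:
    """Boolean array marking the low corner of every solid 2x2x2 block."""
    s = skel
    out = s[:-1, :-1, :-1].copy()
    for dz, dy, dx in np.ndindex(2, 2, 2):
        if (dz, dy, dx) != (0, 0, 0):
            out &= s[dz : s.shape[0] - 1 + dz,
                     dy : s.shape[1] - 1 + dy,
                     dx : s.shape[2] - 1 + dx]
    return out


_FULL_STRUCT = ndi.generate_binary_structure(3, 3)


def _is_removable(skel: np.ndarray, v: tuple[int, int, int]) -> bool:
    """A voxel may be deleted if its remaining 26-neighbourhood foreground
    stays one 26-connected component (no local disconnection) and it has a
    background 6-neighbour (no cavity is sealed off by its removal)."""
    z, y, x = v
    zlo, ylo, xlo = max(z - 1, 0), max(y - 1, 0), max(x - 1, 0)
    cube = skel[zlo : z + 2, ylo : y + 2, xlo : x + 2].copy()
    cube[z - zlo, y - ylo, x - xlo] = False
    if not cube.any():
        return False
    _, n_comp = ndi.label(cube, structure=_FULL_STRUCT)
    if n_comp != 1:
        return False
    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        w = (z + dz, y + dy, x + dx)
        if any(c < 0 or c >= s for c, s in zip(w, skel.shape)) or not skel[w]:
            return True
    return False


def _resolve_solid_blocks(skel: np.ndarray) -> None:
    """Greedily delete removable voxels until no solid 2x2x2 block remains.

    3D thinning occasionally leaves such blocks in dense, highly branched
    masks; they violate the one-voxel-wide contract of graph extraction.
    Deletion order is deterministic (lexicographic).
    """
    for _ in range(64):  # far more iterations than ever needed
        corners = np.argwhere(_solid_block_corners(skel))
        if not len(corners):
            return
        progress = False
        candidates = set()
        for c in corners:
            for off in np.ndindex(2, 2, 2):
                candidates.add((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
        for v in sorted(candidates):
            if skel[v] and _is_removable(skel, v):
                # only delete while the voxel still sits in a solid block
                z, y, x = v
                zlo, ylo, xlo = max(z - 1, 0), max(y - 1, 0), max(x - 1, 0)
                local = skel[zlo : z + 2, ylo : y + 2, xlo : x + 2]
                if _solid_block_corners(local).any():
                    skel[v] = False
                    progress = True
        if not progress:
            break
    if _solid_block_corners(skel).any():  # pragma: no cover - defensive
        logger.warning("could not fully thin skeleton; residual thick spots remain")


def skeletonize_mask(mask: BinaryMask) -> BinaryMask:
    """Thin the vessel mask to a one-voxel-wide centerline.

    The skeleton is a subset of the mask and preserves its 26-connected
    component count: if thinning deletes a tiny component entirely (which
    can happen for components of a few voxels), one voxel of it — the one
    deepest inside the component — is restored.  Residual solid 2x2x2
    blocks that the thinning pass leaves in dense branched regions are
    removed by a connectivity-preserving cleanup.
    """
    if not mask.data.any():
        return BinaryMask(data=np.zeros(mask.shape, dtype=bool), spacing=mask.spacing)
    skel = skeletonize(mask.data).astype(bool)
    skel &= mask.data  # thinning is subset-preserving, but be explicit
    _resolve_solid_blocks(skel)
    labels, n_labels = ndi.label(mask.data, structure=_structure(26))
    if n_labels:
        present = np.zeros(n_labels + 1, dtype=bool)
        present[np.unique(labels[skel])] = True
        missing = [lab for lab in range(1, n_labels + 1) if not present[lab]]
        if missing:
            edt = ndi.distance_transform_edt(mask.data, sampling=mask.spacing)
            for lab in missing:
                comp = labels == lab
                idx = np.unravel_index(np.argmax(np.where(comp, edt, -1)), mask.shape)
                skel[idx] = True
    return BinaryMask(data=skel, spacing=mask.spacing)


def _neighbour_map(voxels: set[tuple[int, int, int]]):
    nbrs = {}
    for v in voxels:
        z, y, x = v
        nbrs[v] = [
            w
            for d in _NB26
            if (w := (z + d[0], y + d[1], x + d[2])) in voxels
        ]
    return nbrs


def _check_thin(skeleton: BinaryMask) -> None:
    # a 2x2x2 solid block anywhere means the input was not thinned
    if min(skeleton.shape) >= 2 and skeleton.data.any():
        if _solid_block_corners(skeleton.data).any():
            raise ParameterError(
                "skeleton is not one-voxel-wide (contains a solid 2x2x2 block); "
                "run skeletonize_mask first"
            )


def extract_graph(skeleton: BinaryMask) -> VascularGraph:
    """Trace a one-voxel-wide skeleton into nodes and segments.

    Nodes are skeleton voxels whose 26-neighbour count differs from 2
    (endpoints and branch points), plus one anchor voxel per simple cycle
    that contains no such voxel.  Segments are the maximal centerline paths
    between nodes; every skeleton voxel belongs to exactly one segment
    polyline, with branch voxels shared between incident segments as
    endpoints.  Positions are physical (µm), via the mask spacing.
    """
    _check_thin(skeleton)
    spacing = np.asarray(skeleton.spacing)
    voxels = set(map(tuple, np.argwhere(skeleton.data)))
    nbrs = _neighbour_map(voxels)
    node_voxels = sorted(v for v in voxels if len(nbrs[v]) != 2)
    node_set = set(node_voxels)

    paths: list[list[tuple[int, int, int]]] = []
    seen_paths: set[tuple] = set()
    on_path: set[tuple[int, int, int]] = set(node_voxels)

    def _record(path):
        key = min(tuple(path), tuple(reversed(path)))
        if key not in seen_paths:
            seen_paths.add(key)
            paths.append(path)
            on_path.update(path)

    for u in node_voxels:
        for w in sorted(nbrs[u]):
            path = [u, w]
            prev, cur = u, w
            while cur not in node_set:
                nxt = nbrs[cur][0] if nbrs[cur][0] != prev else nbrs[cur][1]
                path.append(nxt)
                prev, cur = cur, nxt
            _record(path)

    # pure cycles: 26-connected components where every voxel has degree 2
    remaining = sorted(voxels - on_path)
    anchor_voxels: list[tuple[int, int, int]] = []
    visited: set[tuple[int, int, int]] = set()
    for a in remaining:
        if a in visited:
            continue
        anchor_voxels.append(a)
        path = [a]
        prev, cur = a, sorted(nbrs[a])[0]
        while cur != a:
            path.append(cur)
            visited.add(cur)
            nxt = nbrs[cur][0] if nbrs[cur][0] != prev else nbrs[cur][1]
            prev, cur = cur, nxt
        path.append(a)
        visited.add(a)
        _record(path)

    all_node_voxels = node_voxels + anchor_voxels
    node_id = {v: i for i, v in enumerate(all_node_voxels)}
    nodes = [
        GraphNode(
            id=i,
            position_um=tuple(np.asarray(v) * spacing),
            degree=len(nbrs[v]),
        )
        for i, v in enumerate(all_node_voxels)
    ]
    segments = [
        GraphSegment(
            id=i,
            node_ids=(node_id[path[0]], node_id[path[-1]]),
            points_um=np.asarray(path, dtype=float) * spacing,
        )
        for i, path in enumerate(paths)
    ]
    graph = VascularGraph(nodes=nodes, segments=segments, spacing=skeleton.spacing)
    graph.validate()
    return graph


def estimate_radii(graph: VascularGraph, mask: BinaryMask) -> VascularGraph:
    """Attach a local radius to every centerline point (and node).

    The radius at a point is its anisotropy-aware Euclidean distance (µm) to
    the nearest background voxel of ``mask`` — the radius of the largest
    ball centred on the centerline that fits inside the vessel.
    """
    spacing = np.asarray(mask.spacing)
    edt = ndi.distance_transform_edt(mask.data, sampling=mask.spacing)

    def _sample(points_um: np.ndarray) -> np.ndarray:
        idx = np.rint(points_um / spacing).astype(int)
        for ax in range(3):
            np.clip(idx[:, ax], 0, mask.shape[ax] - 1, out=idx[:, ax])
        inside = mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        if not inside.all():
            raise ConsistencyError("graph has centerline points outside the mask")
        return edt[idx[:, 0], idx[:, 1], idx[:, 2]]

    # one gather for all segment points, then split back per segment
    if graph.segments:
        counts = [len(s.points_um) for s in graph.segments]
        all_radii = _sample(np.concatenate([s.points_um for s in graph.segments]))
        splits = np.split(all_radii, np.cumsum(counts)[:-1])
    else:
        splits = []
    segments = [
        replace(s, radii_um=r) for s, r in zip(graph.segments, splits)
    ]
    if graph.nodes:
        node_radii = _sample(np.asarray([n.position_um for n in graph.nodes]))
    else:
        node_radii = []
    nodes = [
        replace(n, radius_um=float(r)) for n, r in zip(graph.nodes, node_radii)
    ]
    out = VascularGraph(nodes=nodes, segments=segments, spacing=graph.spacing)
    out.validate()
    return out


def classify_radius(
    radius_um: float,
    thin_below_um: float = RADIUS_THIN_BELOW_UM,
    thick_above_um: float = RADIUS_THICK_ABOVE_UM,
) -> str:
    """Calibre class of a vessel radius: ``thin`` (< 3 µm), ``thick``
    (> 11 µm) or ``intermediate`` (boundaries inclusive to intermediate)."""
    if not radius_um > 0:
        raise ParameterError(f"radius must be positive, got {radius_um}")
    if radius_um < thin_below_um:
        return "thin"
    if radius_um > thick_above_um:
        return "thick"
    return "intermediate"


@dataclass(frozen=True)
class GraphSummary:
    """Per-sample morphometry of a vascular graph."""

    mean_radius_um: float  # unweighted mean over all centerline points; NaN if empty
    total_length_um: float
    n_segments: int
    class_length_fractions: dict[str, float] = field(
        default_factory=lambda: {"thin": 0.0, "intermediate": 0.0, "thick": 0.0}
    )


def graph_summary(
    graph: VascularGraph,
    thin_below_um: float = RADIUS_THIN_BELOW_UM,
    thick_above_um: float = RADIUS_THICK_ABOVE_UM,
) -> GraphSummary:
    """Summarise a radius-filled graph.

    Mean radius is the unweighted mean over all segment polyline points;
    total length is the sum of segment lengths; class fractions are
    length fractions (each inter-point step classified by the mean radius
    of its two endpoints) and sum to 1 for a nonempty graph.
    """
    if not graph.segments:
        return GraphSummary(
            mean_radius_um=float("nan"), total_length_um=0.0, n_segments=0
        )
    radii = graph.all_point_radii()
    step_list, mid_list = [], []
    for seg in graph.segments:
        step_list.append(np.linalg.norm(np.diff(seg.points_um, axis=0), axis=1))
        mid_list.append(0.5 * (seg.radii_um[:-1] + seg.radii_um[1:]))
    steps = np.concatenate(step_list) if step_list else np.empty(0)
    mids = np.concatenate(mid_list) if mid_list else np.empty(0)
    total = float(steps.sum())
    class_lengths = {
        "thin": float(steps[mids < thin_below_um].sum()),
        "thick": float(steps[mids > thick_above_um].sum()),
    }
    class_lengths["intermediate"] = total - class_lengths["thin"] - class_lengths["thick"]
    fractions = {
        k: (v / total if total > 0 else 0.0) for k, v in class_lengths.items()
    }
    return GraphSummary(
        mean_radius_um=float(radii.mean()),
        total_length_um=total,
        n_segments=len(graph.segments),
        class_length_fractions=fractions,
    )


_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def export_spatial_graph(graph: VascularGraph, base_path: str) -> tuple[str, str]:
    """Write the graph as two CSV tables.

    ``<base>_points.csv`` has one row per polyline point
    (segment_id, point_index, z_um, y_um, x_um, radius_um) and
    ``<base>_nodes.csv`` one row per node
    (node_id, z_um, y_um, x_um, degree, radius_um).
    Floats are printed at full precision so re-import is bit-exact.
    """
    rows = []
    for seg in graph.segments:
        radii = (
            seg.radii_um
            if seg.radii_um is not None
            else np.full(len(seg.points_um), np.nan)
        )
        for i, (p, r) in enumerate(zip(seg.points_um, radii)):
            rows.append((seg.id, i, p[0], p[1], p[2], r))
    points = pd.DataFrame(
        rows, columns=["segment_id", "point_index", "z_um", "y_um", "x_um", "radius_um"]
    )
    nodes = pd.DataFrame(
        [
            (n.id, *n.position_um, n.degree, np.nan if n.radius_um is None else n.radius_um)
            for n in graph.nodes
        ],
        columns=["node_id", "z_um", "y_um", "x_um", "degree", "radius_um"],
    )
    p_path = f"{base_path}_points.csv"
    n_path = f"{base_path}_nodes.csv"
    points.to_csv(p_path, index=False, float_format=_FLOAT_FMT)
    nodes.to_csv(n_path, index=False, float_format=_FLOAT_FMT)
    return p_path, n_path


def import_spatial_graph(
    base_path: str, spacing: tuple[float, float, float]
) -> VascularGraph:
    """Inverse of :func:`export_spatial_graph`."""
    points = pd.read_csv(f"{base_path}_points.csv")
    node_df = pd.read_csv(f"{base_path}_nodes.csv")
    nodes = [
        GraphNode(
            id=int(r.node_id),
            position_um=(r.z_um, r.y_um, r.x_um),
            degree=int(r.degree),
            radius_um=None if np.isnan(r.radius_um) else float(r.radius_um),
        )
        for r in node_df.itertuples()
    ]
    by_pos = {n.position_um: n.id for n in nodes}
    segments = []
    if len(points):
        for seg_id, grp in points.groupby("segment_id", sort=True):
            grp = grp.sort_values("point_index")
            pts = grp[["z_um", "y_um", "x_um"]].to_numpy()
            radii = grp["radius_um"].to_numpy()
            segments.append(
                GraphSegment(
                    id=int(seg_id),
                    node_ids=(by_pos[tuple(pts[0])], by_pos[tuple(pts[-1])]),
                    points_um=pts,
                    radii_um=None if np.isnan(radii).all() else radii,
                )
            )
    return VascularGraph(nodes=nodes, segments=segments, spacing=tuple(spacing))
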
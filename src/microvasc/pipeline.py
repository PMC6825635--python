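"""End-to-end orchestration: volume -> mask -> graph -> features -> report.

``run_sample`` executes the full chain on one volume and writes every
intermediate artifact (mask, skeleton, spatial graph, density series,
summary) under ``<output_dir>/<sample_id>/`` together with a
``MANIFEST.json`` recording which stages completed; a failing stage
propagates as :class:`~microvasc.errors.StageError` carrying the stage
name, with the partial outputs left on disk.  ``run_group`` assembles
per-sample rows plus one unweighted mean row per label.

Blinding note: feature computation never reads the sample label; labels
are attached only at the reporting step.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .density import (
    GroupSummary,
    SampleSummary,
    SUMMARY_COLUMNS,
    aggregate_group,
    heterogeneity_features,
    section_densities,
    summaries_to_frame,
    summarize_sample,
)
from .errors import ConsistencyError, DegenerateInputError, StageError
from .graph import (
    VascularGraph,
    estimate_radii,
    export_spatial_graph,
    extract_graph,
    graph_summary,
    skeletonize_mask,
)
from .segmentation import (
    BinaryMask,
    SegmentationParams,
    auto_thresholds,
    hysteresis_threshold,
    remove_small_components,
)
from .volume_io import VoxelGrid, downsample_isotropic, read_tiff_stack, write_tiff_stack

logger = logging.getLogger(__name__)

__all__ = ["run_sample", "run_group", "summary_to_json"]


def summary_to_json(summary: SampleSummary) -> str:
    """Deterministic JSON encoding of a sample summary (NaN -> null)."""
    row = summary.as_row()
    clean = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in row.items()
    }
    return json.dumps(clean, sort_keys=True, indent=2) + "\n"


def _mask_to_u8(mask: BinaryMask) -> VoxelGrid:
    return VoxelGrid(
        data=mask.data.astype(np.uint8) * 255, spacing=mask.spacing
    )


def run_sample(
    config: PipelineConfig,
    sample_id: str,
    label: str,
    volume: VoxelGrid | None = None,
) -> SampleSummary:
    """Run the full chain on one sample and write all artifacts.

    ``volume`` may be passed directly (e.g. a phantom); otherwise
    ``config.input_path`` is read as a TIFF stack.  Deterministic for a
    fixed config: rerunning produces byte-identical summary JSON.
    """
    outdir = os.path.join(config.output_dir, sample_id)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"sample_id": sample_id, "completed": [], "failed": None}

    def _finish_stage(stage: str):
        manifest["completed"].append(stage)

    def _write_manifest():
        with open(os.path.join(outdir, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    stage = "load"
    try:
        if volume is None:
            volume = read_tiff_stack(config.input_path, config.spacing_um)
        _finish_stage(stage)

        stage = "downsample"
        grid = downsample_isotropic(volume, config.target_grid_um)
        _finish_stage(stage)

        stage = "segment"
        seg = config.segmentation
        if seg.mode == "auto":
            try:
                low, high = auto_thresholds(grid)
            except DegenerateInputError:
                # constant volume: nothing separable from background
                logger.warning(
                    "sample %s: constant intensity volume, emitting empty mask",
                    sample_id,
                )
                low = high = float("inf")
        else:
            low, high = seg.low, seg.high
        params = SegmentationParams(
            low_threshold=low,
            high_threshold=high,
            connectivity=seg.connectivity,
            min_component_voxels=seg.min_component_voxels,
        )
        mask = hysteresis_threshold(grid, params)
        mask = remove_small_components(mask, seg.min_component_voxels, seg.connectivity)
        write_tiff_stack(_mask_to_u8(mask), os.path.join(outdir, "mask.tif"))
        _finish_stage(stage)

        stage = "densities"
        tissue = None
        if config.tissue_mask_path:
            tgrid = read_tiff_stack(config.tissue_mask_path, (config.target_grid_um,) * 3)
            tissue = BinaryMask(data=tgrid.data > 0, spacing=grid.spacing)
        series = section_densities(mask, tissue)
        series.to_frame().to_csv(os.path.join(outdir, "densities.csv"), index=False)
        _finish_stage(stage)

        stage = "features"
        features = heterogeneity_features(series)
        _finish_stage(stage)

        stage = "graph"
        mean_radius: float | None = None
        if mask.data.any():
            skeleton = skeletonize_mask(mask)
            write_tiff_stack(_mask_to_u8(skeleton), os.path.join(outdir, "skeleton.tif"))
            graph = extract_graph(skeleton)
            graph = estimate_radii(graph, mask)
            export_spatial_graph(graph, os.path.join(outdir, "graph"))
            gsum = graph_summary(
                graph, config.radius_thin_below_um, config.radius_thick_above_um
            )
            if gsum.n_segments > 0:
                mean_radius = gsum.mean_radius_um
            with open(os.path.join(outdir, "graph_summary.json"), "w") as fh:
                json.dump(asdict(gsum), fh, sort_keys=True, indent=2)
                fh.write("\n")
        else:
            logger.warning("sample %s: empty vessel mask, no graph extracted", sample_id)
        _finish_stage(stage)

        stage = "summary"
        summary = summarize_sample(sample_id, label, features, mean_radius)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            fh.write(summary_to_json(summary))
        summaries_to_frame([summary]).to_csv(
            os.path.join(outdir, "summary.csv"), index=False
        )
        _finish_stage(stage)
    except Exception as exc:
        manifest["failed"] = stage
        _write_manifest()
        raise StageError(stage, exc) from exc
    _write_manifest()
    return summary


def run_group(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Per-sample rows plus one unweighted mean row per label.

    Labels keep their first-appearance order; mean rows follow the sample
    rows, in the canonical summary column order.
    """
    if not summaries:
        raise ConsistencyError("no sample summaries to aggregate")
    labels: list[str] = []
    for s in summaries:
        if s.label not in labels:
            labels.append(s.label)
    groups: list[GroupSummary] = [
        aggregate_group([s for s in summaries if s.label == lab], lab)
        for lab in labels
    ]
    return summaries_to_frame(summaries, groups)
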
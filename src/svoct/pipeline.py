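"""End-to-end batch orchestration: angiography → segmentation → metrics
(→ longitudinal), driven by a single validated YAML configuration.

Every run emits a :class:`RunManifest` carrying the configuration hash,
per-stage voxel/record counts and warnings, so results are traceable to
the exact effective configuration (no hidden defaults: the effective
config is serialized into the manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as _io
from .angiography import speckle_variance_volume
from .metrics import compute_metrics
from .segmentation import (
    SegmentationConfig,
    make_slab_voi,
    resample_isotropic,
    segment_volume,
)
from .volume import VOIMask

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AngioStageConfig(_StrictModel):
    enabled: bool = True
    input_stack: Optional[str] = None  # 4D TIFF (z, x, y, frames)
    spacing_um: Optional[tuple[float, float, float]] = None


class SegmentationStageConfig(_StrictModel):
    enabled: bool = True
    input_volume: Optional[str] = None  # used when angiography is disabled
    spacing_um: Optional[tuple[float, float, float]] = None
    voi_mask: Optional[str] = None
    voi_depth_um: Optional[float] = None  # slab VOI when no mask supplied
    open_radius: float = 0.0
    close_radius: float = 0.0
    median_size: int = 3
    depth_threshold_enabled: bool = True
    t0: Optional[float] = None
    t0_quantile: float = 0.5
    mu: float = 0.006
    shadow_filter_enabled: bool = True
    trigger_quantile: float = 0.98
    shadow_decay_length: float = 50.0
    frangi_enabled: bool = True
    frangi_scales: tuple[float, ...] = (4.0, 7.0, 10.0, 14.0, 18.0)
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    frangi_c: Optional[float] = None
    binarize_method: str = "otsu"
    binarize_threshold: Optional[float] = None
    binarize_log_domain: bool = True
    min_component_size: int = 27
    resample_enabled: bool = True
    isotropic_spacing: float = 2.5

    def to_segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            open_radius=self.open_radius,
            close_radius=self.close_radius,
            median_size=self.median_size,
            depth_threshold_enabled=self.depth_threshold_enabled,
            t0=self.t0,
            t0_quantile=self.t0_quantile,
            mu=self.mu,
            shadow_filter_enabled=self.shadow_filter_enabled,
            trigger_quantile=self.trigger_quantile,
            shadow_decay_length=self.shadow_decay_length,
            frangi_enabled=self.frangi_enabled,
            frangi_scales=self.frangi_scales,
            frangi_alpha=self.frangi_alpha,
            frangi_beta=self.frangi_beta,
            frangi_c=self.frangi_c,
            binarize_method=self.binarize_method,
            binarize_threshold=self.binarize_threshold,
            binarize_log_domain=self.binarize_log_domain,
            min_component_size=self.min_component_size,
            resample_enabled=self.resample_enabled,
            isotropic_spacing=self.isotropic_spacing,
        )


class MetricsStageConfig(_StrictModel):
    enabled: bool = True
    input_mask: Optional[str] = None  # used when segmentation is disabled
    dlf_thresholds_um: tuple[float, ...] = (150.0,)
    lambda_cutoff_um: float = 60.0
    bin_width_um: float = 2.5
    min_bins: int = 4


class LongitudinalStageConfig(_StrictModel):
    enabled: bool = False
    cohort_table: Optional[str] = None  # tidy CSV
    compare_metric: str = "DLF_150"
    compare_day: float = 17.0
    tolerance_days: float = 2.0


class PipelineConfig(_StrictModel):
    """Validated pipeline configuration (unknown keys are rejected)."""

    output_dir: str = "svoct_out"
    seed: int = 0
    angiography: AngioStageConfig = AngioStageConfig()
    segmentation: SegmentationStageConfig = SegmentationStageConfig()
    metrics: MetricsStageConfig = MetricsStageConfig()
    longitudinal: LongitudinalStageConfig = LongitudinalStageConfig()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        for p in (
            self.angiography.input_stack,
            self.segmentation.input_volume,
            self.segmentation.voi_mask,
            self.metrics.input_mask,
            self.longitudinal.cohort_table,
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


class RunManifest(_StrictModel):
    config_hash: str
    effective_config: dict
    stage_counts: dict[str, dict]
    outputs: dict[str, str]
    warnings: list[str]
    started_at: float
    finished_at: float

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.model_dump(mode="json"), indent=2))
        return path


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order, writing every
    intermediate volume and the final metric CSVs into ``output_dir``.

    Deterministic and idempotent for a fixed config and inputs; a stage
    failure raises with the stage name and offending input path.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stage_counts: dict[str, dict] = {}
    outputs: dict[str, str] = {}
    caught: list[str] = []

    angio_vol = None
    if config.angiography.enabled:
        src = config.angiography.input_stack
        if src is None:
            raise ValueError("angiography stage enabled but no input_stack configured")
        try:
            stack = _io.load_frame_stack(src, spacing=config.angiography.spacing_um)
            angio_vol = speckle_variance_volume(stack)
        except Exception as exc:
            raise RuntimeError(f"stage 'angiography' failed on {src}: {exc}") from exc
        p = _io.save_volume(angio_vol, out_dir / "angio.tif")
        outputs["angio_volume"] = str(p)
        stage_counts["angiography"] = {
            "n_positions": stack.n_positions,
            "n_frames": stack.intensities.shape[3],
        }

    mask = None
    voi: VOIMask | None = None
    if config.segmentation.enabled:
        seg_cfg = config.segmentation
        if angio_vol is None:
            if seg_cfg.input_volume is None:
                raise ValueError(
                    "segmentation stage needs the angiography stage or an "
                    "input_volume"
                )
            angio_vol = _io.load_volume(seg_cfg.input_volume,
                                        spacing=seg_cfg.spacing_um)
        if seg_cfg.voi_mask is not None:
            voi = _io.load_voi(seg_cfg.voi_mask)
        elif seg_cfg.voi_depth_um is not None:
            voi = make_slab_voi(angio_vol, depth_extent=seg_cfg.voi_depth_um)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                mask, seg_log = segment_volume(
                    angio_vol, seg_cfg.to_segmentation_config(), voi=voi
                )
            except Exception as exc:
                raise RuntimeError(f"stage 'segmentation' failed: {exc}") from exc
        caught.extend(str(w.message) for w in wlist)
        if voi is not None and seg_cfg.resample_enabled:
            # the metrics VOI must live on the same isotropic grid
            voi = resample_isotropic(voi, seg_cfg.isotropic_spacing)
        p = _io.save_volume(mask, out_dir / "mask.tif")
        outputs["vascular_mask"] = str(p)
        stage_counts["segmentation"] = seg_log

    if config.metrics.enabled:
        m_cfg = config.metrics
        if mask is None:
            if m_cfg.input_mask is None:
                raise ValueError(
                    "metrics stage needs the segmentation stage or an input_mask"
                )
            mask = _io.load_mask(m_cfg.input_mask)
        try:
            record, hist = compute_metrics(
                mask,
                voi=voi,
                thresholds=m_cfg.dlf_thresholds_um,
                fit_max=m_cfg.lambda_cutoff_um,
                bin_width=m_cfg.bin_width_um,
                min_bins=m_cfg.min_bins,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc
        df = _io.metrics_to_frame(record)
        df.to_csv(out_dir / "metrics.csv", index=False)
        _io.save_histogram_csv(hist, out_dir / "dnv_histogram.csv")
        outputs["metrics"] = str(out_dir / "metrics.csv")
        outputs["dnv_histogram"] = str(out_dir / "dnv_histogram.csv")
        stage_counts["metrics"] = {
            "tissue_voxels": record.tissue_voxel_count,
            "vessel_voxels": record.vessel_voxel_count,
        }

    if config.longitudinal.enabled:
        l_cfg = config.longitudinal
        if l_cfg.cohort_table is None:
            raise ValueError("longitudinal stage enabled but no cohort_table")
        from .longitudinal import cohort_compare, cohort_summary

        try:
            table = pd.read_csv(l_cfg.cohort_table)
            summary = cohort_summary(table, l_cfg.compare_metric)
            comparison = cohort_compare(
                table, l_cfg.compare_metric, l_cfg.compare_day,
                tolerance_days=l_cfg.tolerance_days,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'longitudinal' failed on {l_cfg.cohort_table}: {exc}"
            ) from exc
        summary.to_csv(out_dir / "cohort_summary.csv", index=False)
        outputs["cohort_summary"] = str(out_dir / "cohort_summary.csv")
        stage_counts["longitudinal"] = {
            "anova_p": comparison.anova_p,
            "pairwise_p": {str(k): v for k, v in comparison.pairwise_p.items()},
            "multiple_testing_correction": "none",
        }

    manifest = RunManifest(
        config_hash=config.config_hash(),
        effective_config=config.model_dump(mode="json"),
        stage_counts=stage_counts,
        outputs=outputs,
        warnings=caught,
        started_at=started,
        finished_at=time.time(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
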
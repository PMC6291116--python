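"""End-to-end orchestration of the four-stage segmentation pipeline.

Stages: contrast stretch and channel expansion, unstained-cell removal,
probabilistic four-phase level set, and cluster splitting by watershed with
a circular-Hough circularity gate.  The pipeline is a pure function of
(image, color model, config, seed).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cluster_seg, color_model, levelset, metrics, preprocess


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters; ranges validated on construction.

    ``variant`` chooses the nuclei-mask source for cluster splitting:
    ``"kmeans"`` (2-cluster k-means on the stained pixels; the recommended
    variant) or ``"phase"`` (the nucleus phase of the level set directly).
    """

    variant: str = "kmeans"
    sat_frac: float = 0.01
    hue_threshold: float = 120.0
    background_source: str = "model"  # or "border"
    t_pc: float = 1.0
    t_bg: float = 3.0
    levelset: levelset.LevelSetParams = field(default_factory=levelset.LevelSetParams)
    init_radius: float | None = None   # None: scaled to the image (see methods)
    init_spacing: float | None = None
    min_component_px: int = 200
    min_cytoplasm_frac: float = 0.1    # fraction of the median component area
    kmeans_seed: int = 0
    nuclei_opening_radius: int = 2
    nuclei_min_px: int = 30
    cht_sensitivity: float = 0.3
    cht_radius_lo: float = 0.25
    cht_radius_hi: float = 1.5
    ratio_max: float = 0.85
    iou_complete: float = 0.7

    def __post_init__(self) -> None:
        if self.variant not in ("kmeans", "phase"):
            raise ValueError("variant must be 'kmeans' or 'phase'")
        if self.background_source not in ("model", "border"):
            raise ValueError("background_source must be 'model' or 'border'")
        if not 0.0 <= self.sat_frac < 0.5:
            raise ValueError("sat_frac must lie in [0, 0.5)")
        if not 0.0 < self.ratio_max <= 1.0:
            raise ValueError("ratio_max must lie in (0, 1]")
        if not 0.0 < self.iou_complete <= 1.0:
            raise ValueError("iou_complete must lie in (0, 1]")
        if not 0.0 < self.cht_sensitivity <= 1.0:
            raise ValueError("cht_sensitivity must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        ls = raw.pop("levelset", None)
        kwargs = dict(raw)
        if ls is not None:
            ls_known = set(levelset.LevelSetParams.__dataclass_fields__)
            ls_unknown = set(ls) - ls_known
            if ls_unknown:
                raise ValueError(f"unknown levelset config keys: {sorted(ls_unknown)}")
            kwargs["levelset"] = levelset.LevelSetParams(**ls)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one pipeline run produces for a single image."""

    instances: cluster_seg.CellInstanceSet
    phase_mask: np.ndarray
    stained_mask: np.ndarray
    nuclei_mask: np.ndarray
    energy_log: list[dict]
    manifest: dict


def _auto_init(shape: tuple[int, int], config: PipelineConfig) -> tuple[float, float]:
    """Initialization circle geometry, scaled to the image size.

    Full-resolution smears (min dimension 1920) use radius 8 / spacing 24;
    smaller images scale proportionally with a floor of radius 5.
    """
    if config.init_radius is not None and config.init_spacing is not None:
        return config.init_radius, config.init_spacing
    scale = min(shape) / 1920.0
    radius = config.init_radius if config.init_radius is not None else max(5.0, round(8.0 * scale))
    spacing = config.init_spacing if config.init_spacing is not None else 3.0 * radius
    return radius, spacing


def run_pipeline(
    img: np.ndarray,
    model: color_model.RegionColorModel,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> PipelineResult:
    """Segment the plasma cells of one 8-bit RGB image.

    Parameters
    ----------
    img:
        8-bit RGB image (H, W, 3).
    model:
        Fitted per-region color model for the staining protocol; the
        distance table and channel weights are derived from it.
    config:
        Pipeline parameters.
    seed:
        Seed for the k-means nuclei clustering (combined with
        ``config.kmeans_seed``).
    """
    stretched = preprocess.contrast_stretch(img, config.sat_frac)
    stack = preprocess.to_channel_stack(stretched)

    bg = model.region_rgb_mean("background") if config.background_source == "model" else None
    cleaned = preprocess.remove_unstained(stack, stretched, config.hue_threshold, bg)
    stack = preprocess.to_channel_stack(cleaned)

    table = color_model.distance_table_from_model(model)
    weights = color_model.assign_weights(table, config.t_pc, config.t_bg)
    pmaps = color_model.probability_maps(stack, model, weights)
    dimgs = color_model.distance_images(stack, model, weights)

    radius, spacing = _auto_init(img.shape[:2], config)
    state = levelset.init_phis(img.shape[:2], radius=radius, spacing=spacing)
    state = levelset.evolve(state, pmaps, dimgs, config.levelset)
    phase_mask = levelset.extract_phase_mask(state)

    stained = levelset.stained_mask_from_phases(phase_mask)
    phase_nuclei = phase_mask == levelset.PHASE_NUCLEUS

    # cytoplasm-area floor expressed relative to the median component area
    from scipy import ndimage
    labels, n = ndimage.label(stained)
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        min_cyt = int(config.min_cytoplasm_frac * float(np.median(areas)))
    else:
        min_cyt = 0
    stained = levelset.postfilter_components(
        stained, phase_nuclei, config.min_component_px, min_cyt
    )

    if config.variant == "kmeans":
        nuclei = cluster_seg.nuclei_mask_kmeans(
            stack, stained, seed=config.kmeans_seed + seed
        )
    else:
        nuclei = phase_nuclei & stained
    nuclei = cluster_seg.clean_nuclei_mask(
        nuclei, config.nuclei_opening_radius, config.nuclei_min_px
    )

    r_lo, r_hi = cluster_seg.estimate_radius_range(
        stained, config.cht_radius_lo, config.cht_radius_hi
    )
    n_lo, n_hi = cluster_seg.estimate_radius_range(
        nuclei, config.cht_radius_lo, config.cht_radius_hi
    )
    nuclei_labels = cluster_seg.split_nuclei(
        nuclei, n_lo, n_hi, config.cht_sensitivity
    )
    cells = cluster_seg.split_cells(
        stained, nuclei_labels, r_lo, r_hi, config.cht_sensitivity
    )
    cells = cluster_seg.filter_by_nucleus_ratio(cells, config.ratio_max)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(seed),
        "variant": config.variant,
        "n_instances": len(cells),
        "init": {"radius": radius, "spacing": spacing},
        "iterations": state.iteration,
    }
    return PipelineResult(
        instances=cells,
        phase_mask=phase_mask,
        stained_mask=stained,
        nuclei_mask=nuclei,
        energy_log=state.energy_log,
        manifest=manifest,
    )


def fit_model_from_truth(img, truth, stretch: bool = True) -> color_model.RegionColorModel:
    """Fit the region color model from one labeled image.

    When ``stretch`` is true (the default) the model is fitted on the
    contrast-stretched image, i.e. in the representation the pipeline
    actually segments.
    """
    if stretch:
        img = preprocess.contrast_stretch(img)
    stack = preprocess.to_channel_stack(img)
    return color_model.fit_region_model(stack, truth.region_masks())


def evaluate_sets(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    iou_complete: float = 0.7,
) -> tuple[metrics.DetectionCounts, metrics.MetricReport]:
    """Pool detection counts over (prediction, truth) label-map pairs.

    Counts are accumulated per image and the metrics computed once on the
    totals (micro-averaging), matching how aggregate benchmark figures are
    tallied.
    """
    total = metrics.DetectionCounts()
    for pred_labels, truth_labels in pairs:
        total = total + metrics.match_instances(pred_labels, truth_labels, iou_complete)
    return total, metrics.compute_metrics(total)
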
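"""End-to-end orchestration of the appearance-quality study.

``run_study`` simulates (or could ingest) a cohort of scene images, pushes
every image through standardization, segmentation and feature extraction,
calibrates the PCA conformance monitor on fresh-state images only, projects
all treated and control images, and summarizes rejections per treatment
condition and storage day.  ``log_reduction`` is the microbial
log10(N/N0) inactivation utility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features
from .mspc import PCAConformanceMonitor, conformance_test
from .scene import (AppearanceParams, EffectModel, FreshPopulation,
                    SceneLayout, StudyDesign, enumerate_design, iter_cohort)
from .segment import largest_inscribed_rectangle, segment_roi
from .standardize import locate_references, standardize_image

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to run one simulated study end to end."""

    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectModel = field(default_factory=EffectModel.null)
    layout: SceneLayout = field(default_factory=SceneLayout)
    population: FreshPopulation = field(default_factory=FreshPopulation)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    ncomp: int = 7
    alpha: float = 0.05
    seed: int = 0
    segmentation_k: int = 4
    out_dir: Path | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class StudyReport:
    """Outputs of one study run."""

    inventory: pd.DataFrame
    features: pd.DataFrame
    monitor: PCAConformanceMonitor
    chart: pd.DataFrame
    rejection_summary: pd.DataFrame
    warnings: list[str]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.inventory.to_csv(out / "inventory.csv", index=False)
        self.features.to_csv(out / "features.csv", index=False)
        self.chart.to_csv(out / "chart.csv", index=False)
        self.rejection_summary.to_csv(out / "rejection_summary.csv",
                                      index=False)
        self.monitor.to_json(out / "model.json")


_META_COLS = ("image_id", "package_id", "map", "condition", "replicate",
              "slice", "event", "storage_day", "state")


def process_image(image: np.ndarray, layout: SceneLayout | None,
                  config: FeatureConfig, k: int, seed: int) -> np.ndarray:
    """Standardize one scene, segment the sample and extract its features."""
    refs = locate_references(image, layout_hint=layout)
    std = standardize_image(image, refs)
    mask = segment_roi(std, k=k, seed=seed)
    rect = largest_inscribed_rectangle(mask)
    return extract_features(std, mask, rect, config).values


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full pipeline on a simulated cohort.

    Calibration uses only fresh-state images; every treated and control image
    is projected onto the calibrated model.  Reproducible given
    ``config.seed``.
    """
    logger.info("enumerating design and rendering cohort")
    warnings: list[str] = []
    records, rows = [], []
    feat_names = None
    for rec, img in iter_cohort(config.design, config.effects, config.layout,
                                config.population, config.seed):
        try:
            vec = process_image(img, config.layout, config.feature_config,
                                config.segmentation_k,
                                seed=int(rec["seed"]) % (2 ** 31))
        except Exception as exc:  # pragma: no cover - defensive logging
            warnings.append(f"image {rec['image_id']}: {exc}")
            raise
        if feat_names is None:
            from .features import (color_feature_names, glcm_feature_names,
                                   wavelet_feature_names)
            feat_names = (color_feature_names()
                          + wavelet_feature_names(config.feature_config)
                          + glcm_feature_names(config.feature_config))
        records.append(rec)
        rows.append(vec)

    inventory = pd.DataFrame(records)
    X = np.vstack(rows)
    features = pd.concat(
        [inventory[list(_META_COLS)].reset_index(drop=True),
         pd.DataFrame(X, columns=feat_names)], axis=1)

    fresh_mask = inventory["state"] == "fresh"
    logger.info("calibrating on %d fresh images", int(fresh_mask.sum()))
    monitor = PCAConformanceMonitor(
        n_components=config.ncomp, alpha=config.alpha).fit(X[fresh_mask])

    logger.info("projecting %d monitored images", int((~fresh_mask).sum()))
    monitored = inventory[~fresh_mask].reset_index(drop=True)
    chart = monitor.conformance(
        X[~fresh_mask.values],
        metadata=monitored[["map", "condition", "storage_day", "state"]],
        sample_ids=monitored["image_id"].to_numpy())
    summary = conformance_test(chart)

    report = StudyReport(inventory=inventory, features=features,
                         monitor=monitor, chart=chart,
                         rejection_summary=summary, warnings=warnings)
    if config.out_dir is not None:
        report.save(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# microbial utility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrobialCount:
    """Viable counts before/after treatment, with the assay detection limit."""

    n0: float                  # CFU/g untreated
    n: float                   # CFU/g survivors
    detection_limit: float = 100.0

    def validate(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


@dataclass(frozen=True)
class LogReduction:
    """log10(N/N0); ``censored`` marks counts below the detection limit."""

    value: float
    censored: bool = False

    def __str__(self) -> str:
        return (f"< {self.value:g}" if self.censored else f"{self.value:g}")


def log_reduction(count: MicrobialCount) -> LogReduction:
    """Microbial inactivation as log10(N/N0).

    Survivor counts below the detection limit are censored: the returned
    value is the upper bound log10(detection_limit/N0).
    """
    count.validate()
    if count.n < count.detection_limit:
        return LogReduction(
            value=math.log10(count.detection_limit / count.n0),
            censored=True)
    return LogReduction(value=math.log10(count.n / count.n0))


__all__ = ["RunConfig", "StudyReport", "run_study", "process_image",
           "MicrobialCount", "LogReduction", "log_reduction",
           "enumerate_design", "AppearanceParams"]
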
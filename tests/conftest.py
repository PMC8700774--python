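import numpy as np
import pytest

from visqc import (AppearanceParams, FreshPopulation, RunConfig, SceneLayout,
                   StudyDesign, TreatmentCondition, largest_inscribed_rectangle,
                   locate_references, render_scene, run_study, segment_roi,
                   standardize_image)
from visqc.scene import EffectModel


@pytest.fixture(scope="session")
def layout():
    """Desk-scale scene layout (160 px frame, geometry proportional)."""
    return SceneLayout().scaled(160)


@pytest.fixture(scope="session")
def scene_image(layout):
    return render_scene(layout, AppearanceParams(seed=7))


@pytest.fixture(scope="session")
def std_image(layout, scene_image):
    refs = locate_references(scene_image, layout_hint=layout)
    return standardize_image(scene_image, refs)


@pytest.fixture(scope="session")
def roi(std_image):
    mask = segment_roi(std_image, seed=3)
    return mask, largest_inscribed_rectangle(mask)


def small_study_design(replicates=3):
    """Reduced design for pipeline tests: 1 MAP, 2 conditions, 2 control
    times, no untreated controls."""
    conds = (TreatmentCondition("TC2", 40.0, 6.0, 15.0),
             TreatmentCondition("TC5", 40.0, 12.0, 45.0))
    return StudyDesign(map_compositions=("MAP1",), conditions=conds,
                       control_times=(0, 7), replicates=replicates,
                       with_controls=False)


@pytest.fixture(scope="session")
def null_report():
    """Full pipeline run on the reduced design with no degradation effect."""
    config = RunConfig(design=small_study_design(), effects=EffectModel.null(),
                       layout=SceneLayout().scaled(128),
                       population=FreshPopulation(), ncomp=5, seed=11)
    return config, run_study(config)


def rect_iou(a, b):
    """IoU of two (top, left, bottom, right) rectangles."""
    t = max(a[0], b[0]); l = max(a[1], b[1])
    bb = min(a[2], b[2]); r = min(a[3], b[3])
    inter = max(0, bb - t) * max(0, r - l)
    area = lambda x: (x[2] - x[0]) * (x[3] - x[1])
    return inter / (area(a) + area(b) - inter)


def mask_iou(a, b):
    a = np.asarray(a, bool); b = np.asarray(b, bool)
    return (a & b).sum() / (a | b).sum()
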
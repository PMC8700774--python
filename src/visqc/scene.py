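"""Synthetic scene and study-cohort simulation.

The physical study images a food sample disc on a black background next to a
white reflectance reference and a dimensional indicator, under controlled
illumination.  This module emulates that fixture: :func:`render_scene` draws a
single scene with controllable color, texture and degradation (surface
whitening), :func:`enumerate_design` expands a treatment/storage study design
into its package and image inventory, and :func:`simulate_cohort` renders one
image per inventory record with population variability and per-condition
degradation effects.

The default study design mirrors a half-fraction factorial over process
temperature, pressure and time (four corner runs plus a center point run in
triplicate), crossed with three modified-atmosphere compositions, four storage
control times and two replicates, plus untreated control packages — 168
treated packages and 9 control packages, imaged as 2 slices x 2 events each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import LayoutError

logger = logging.getLogger(__name__)

#: Nominal RGB of the white reflectance reference (also the whitening target).
WHITE_REF_COLOR = (245.0, 245.0, 245.0)
#: Nominal RGB of the black background / black reference.
BLACK_REF_COLOR = (8.0, 8.0, 8.0)
#: Nominal RGB of the dimensional indicator.
INDICATOR_COLOR = (128.0, 128.0, 128.0)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneLayout:
    """Geometry of one scene: sample disc, reference patches, indicator.

    Rectangles are ``(top, left, bottom, right)`` in pixels, half-open
    ``[top, bottom) x [left, right)``, 0-based row-major.
    """

    image_height: int = 512
    image_width: int = 512
    disc_center: tuple[int, int] = (280, 200)
    disc_radius: int = 140
    white_ref_region: tuple[int, int, int, int] = (30, 360, 130, 460)
    black_ref_region: tuple[int, int, int, int] = (380, 360, 460, 460)
    indicator_region: tuple[int, int, int, int] = (30, 40, 70, 160)

    def validate(self) -> None:
        if self.disc_radius <= 0:
            raise LayoutError("disc_radius must be positive")
        r0, c0 = self.disc_center
        if (r0 - self.disc_radius < 0 or c0 - self.disc_radius < 0
                or r0 + self.disc_radius >= self.image_height
                or c0 + self.disc_radius >= self.image_width):
            raise LayoutError("disc not fully inside the frame")
        rects = [self.white_ref_region, self.black_ref_region,
                 self.indicator_region]
        for t, l, b, r in rects:
            if not (0 <= t < b <= self.image_height
                    and 0 <= l < r <= self.image_width):
                raise LayoutError(f"rectangle {(t, l, b, r)} out of frame")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if _rects_overlap(rects[i], rects[j]):
                    raise LayoutError("layout rectangles overlap")
            if _rect_disc_overlap(rects[i], self.disc_center,
                                  self.disc_radius):
                raise LayoutError("rectangle overlaps the sample disc")

    def disc_mask(self) -> np.ndarray:
        """Boolean mask of the sample disc."""
        rr, cc = np.ogrid[:self.image_height, :self.image_width]
        r0, c0 = self.disc_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.disc_radius ** 2

    def scaled(self, size: int) -> "SceneLayout":
        """Proportionally rescale the default geometry to a ``size`` px frame."""
        s = size / 512.0

        def sc(v):  # round and keep at least 1 px
            return max(1, int(round(v * s)))

        return SceneLayout(
            image_height=size, image_width=size,
            disc_center=(sc(self.disc_center[0]), sc(self.disc_center[1])),
            disc_radius=sc(self.disc_radius),
            white_ref_region=tuple(sc(v) for v in self.white_ref_region),
            black_ref_region=tuple(sc(v) for v in self.black_ref_region),
            indicator_region=tuple(sc(v) for v in self.indicator_region),
        )


def _rects_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def _rect_disc_overlap(rect, center, radius) -> bool:
    t, l, b, r = rect
    r0, c0 = center
    nearest_r = min(max(r0, t), b - 1)
    nearest_c = min(max(c0, l), r - 1)
    return (nearest_r - r0) ** 2 + (nearest_c - c0) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# appearance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AppearanceParams:
    """Parameters controlling the rendered appearance of one sample.

    ``whitening_fraction`` is the fraction of the disc area covered by
    whitened blotches (a convex blend toward the white-reference color),
    emulating surface whitening from dehydration/lignification.
    ``illumination_gain``/``offset`` apply a global affine light change that
    the standardization stage is meant to undo.
    """

    base_color: tuple[float, float, float] = (225.0, 120.0, 35.0)
    color_noise_sd: float = 6.0
    texture_correlation_length: float = 6.0
    texture_amplitude: float = 10.0
    whitening_fraction: float = 0.0
    illumination_gain: float = 1.0
    illumination_offset: float = 0.0
    white_level: float = 245.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.whitening_fraction <= 1.0:
            raise ValueError("whitening_fraction must be in [0, 1]")
        if self.illumination_gain <= 0:
            raise ValueError("illumination_gain must be positive")


@dataclass(frozen=True)
class TreatmentCondition:
    """One high-pressure CO2 treatment run setting."""

    name: str
    temperature: float  # degrees C
    pressure: float     # MPa
    time: float         # minutes

    def validate(self) -> None:
        # apparatus envelope
        if not (25.0 <= self.temperature <= 50.0):
            raise ValueError(f"{self.name}: temperature outside 25-50 C")
        if not (4.0 <= self.pressure <= 20.0):
            raise ValueError(f"{self.name}: pressure outside 4-20 MPa")
        if self.time <= 0:
            raise ValueError(f"{self.name}: nonpositive treatment time")


#: The five treatment conditions of the half-fraction factorial design
#: (TC1 is the center point, run in triplicate).
DEFAULT_CONDITIONS = (
    TreatmentCondition("TC1", 32.5, 9.0, 30.0),
    TreatmentCondition("TC2", 40.0, 6.0, 15.0),
    TreatmentCondition("TC3", 25.0, 6.0, 45.0),
    TreatmentCondition("TC4", 25.0, 12.0, 15.0),
    TreatmentCondition("TC5", 40.0, 12.0, 45.0),
)


@dataclass(frozen=True)
class StudyDesign:
    """Treatment/storage study design.

    The default reproduces the full study: 3 MAP compositions x 7 condition
    runs (4 factorial corners + center point x3) x 4 control times x 2
    replicates = 168 treated packages, plus one untreated control package per
    MAP per non-zero control time (9), each package holding 2 slices imaged
    at 2 events.
    """

    map_compositions: tuple[str, ...] = ("MAP1", "MAP2", "MAP3")
    conditions: tuple[TreatmentCondition, ...] = DEFAULT_CONDITIONS
    center_condition: str = "TC1"
    center_replicates: int = 3
    control_times: tuple[int, ...] = (0, 3, 7, 14)
    replicates: int = 2
    slices_per_package: int = 2
    imaging_events_per_package: int = 2
    with_controls: bool = True

    def condition_runs(self) -> list[tuple[TreatmentCondition, int]]:
        """Expand conditions into run instances: (condition, run index)."""
        runs = []
        for cond in self.conditions:
            n = self.center_replicates if cond.name == self.center_condition else 1
            for run in range(1, n + 1):
                runs.append((cond, run))
        return runs


def enumerate_design(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a study design into package and image inventories.

    Returns ``(packages, images)`` data frames.  Treated packages are imaged
    fresh (before packaging, state ``fresh``) and after treatment/storage
    (state ``treated``); control packages are imaged at packaging and at
    their control time, with both events counted as ``control`` state.
    """
    pkg_rows, img_rows = [], []

    def add_package(kind, map_, cond_name, run, day, rep):
        pid = len(pkg_rows)
        pkg_rows.append(dict(package_id=pid, kind=kind, map=map_,
                             condition=cond_name, run=run, storage_day=day,
                             replicate=rep))
        for sl in range(1, design.slices_per_package + 1):
            for ev in range(design.imaging_events_per_package):
                is_fresh_event = (ev == 0)
                if kind == "treated":
                    state = "fresh" if is_fresh_event else "treated"
                else:
                    state = "control"
                img_rows.append(dict(
                    image_id=len(img_rows), package_id=pid, map=map_,
                    condition=cond_name, replicate=rep, slice=sl,
                    event="fresh" if is_fresh_event else "post",
                    storage_day=0 if is_fresh_event else day,
                    state=state))

    for map_ in design.map_compositions:
        for cond, run in design.condition_runs():
            for day in design.control_times:
                for rep in range(1, design.replicates + 1):
                    add_package("treated", map_, cond.name, run, day, rep)
    if design.with_controls:
        for map_ in design.map_compositions:
            for day in design.control_times:
                if day != 0:
                    add_package("control", map_, None, 0, day, 1)

    return pd.DataFrame(pkg_rows), pd.DataFrame(img_rows)


# ---------------------------------------------------------------------------
# effect model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AppearanceEffect:
    """Additive degradation applied on top of a sample's fresh appearance."""

    color_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    whitening_delta: float = 0.0
    texture_delta: float = 0.0


@dataclass
class EffectModel:
    """Maps (condition, storage day) to a degradation effect.

    ``table`` keys are ``(condition_name_or_None, storage_day)``; missing
    keys mean no effect.  ``None`` condition addresses untreated (control)
    packages.
    """

    table: dict[tuple[str | None, int], AppearanceEffect] = field(
        default_factory=dict)

    @classmethod
    def null(cls) -> "EffectModel":
        return cls({})

    @classmethod
    def progressive(cls, severity: dict[str | None, float],
                    days: tuple[int, ...],
                    day_ramp: Callable[[int], float] = lambda d: d / 14.0,
                    whitening_scale: float = 0.5,
                    color_scale: tuple[float, float, float] = (0., 0., 0.),
                    texture_scale: float = 0.0) -> "EffectModel":
        """Build a table monotone in storage day.

        Per-cell effect magnitude is ``severity[cond] * (1 + day_ramp(day))``
        for treated conditions (severity applies at day 0 already, storage
        amplifies it) and ``severity[None] * day_ramp(day)`` for untreated
        controls (no effect at day 0).
        """
        table = {}
        for cond, sev in severity.items():
            for day in days:
                if cond is None:
                    mag = sev * day_ramp(day)
                else:
                    mag = sev * (1.0 + day_ramp(day))
                table[(cond, day)] = AppearanceEffect(
                    color_shift=tuple(mag * c for c in color_scale),
                    whitening_delta=mag * whitening_scale,
                    texture_delta=mag * texture_scale)
        return cls(table)

    def effect_for(self, condition: str | None, day: int) -> AppearanceEffect:
        return self.table.get((condition, day), AppearanceEffect())


def apply_effect(params: AppearanceParams,
                 effect: AppearanceEffect) -> AppearanceParams:
    """Perturb appearance parameters, clipping to valid ranges with a warning."""
    color = np.asarray(params.base_color) + np.asarray(effect.color_shift)
    if np.any(color < 0) or np.any(color > 255):
        logger.warning("effect color shift clipped to [0, 255]")
    color = np.clip(color, 0.0, 255.0)
    w = params.whitening_fraction + effect.whitening_delta
    if not 0.0 <= w <= 1.0:
        logger.warning("whitening fraction clipped to [0, 1]")
    w = float(np.clip(w, 0.0, 1.0))
    amp = params.texture_amplitude * (1.0 + effect.texture_delta)
    if amp < 0:
        logger.warning("texture amplitude clipped to 0")
        amp = 0.0
    return replace(params, base_color=tuple(color), whitening_fraction=w,
                   texture_amplitude=amp)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _correlated_field(shape, corr_length, rng):
    """Zero-mean, unit-SD Gaussian random field via smoothed white noise."""
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        fld = ndimage.gaussian_filter(noise, sigma=corr_length, mode="wrap")
    else:
        fld = noise
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def render_scene(layout: SceneLayout, params: AppearanceParams) -> np.ndarray:
    """Render one 8-bit RGB scene image.

    Black background everywhere outside the drawn regions; near-white
    reference patch; mid-gray dimensional indicator; sample disc filled with
    ``base_color`` plus a spatially correlated luminance texture, per-channel
    noise and whitened blotches; whole frame scaled by the illumination
    gain/offset.  Deterministic given ``params.seed``.
    """
    layout.validate()
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = layout.image_height, layout.image_width
    img = np.empty((H, W, 3), dtype=np.float64)

    # background doubles as the black reference
    img[:] = np.asarray(BLACK_REF_COLOR)
    img += rng.normal(0.0, 2.0, size=(H, W, 3))

    white_color = (params.white_level,) * 3
    for region, color, sd in ((layout.white_ref_region, white_color, 1.5),
                              (layout.indicator_region, INDICATOR_COLOR, 2.0)):
        t, l, b, r = region
        img[t:b, l:r] = np.asarray(color) + rng.normal(
            0.0, sd, size=(b - t, r - l, 3))

    disc = layout.disc_mask()
    n_disc = int(disc.sum())
    texture = _correlated_field((H, W), params.texture_correlation_length, rng)
    disc_px = (np.asarray(params.base_color)[None, :]
               + params.texture_amplitude * texture[disc, None]
               + rng.normal(0.0, params.color_noise_sd, size=(n_disc, 3)))

    # whitened blotches: threshold a smooth field so that exactly the target
    # fraction of disc pixels blends fully toward the white-reference color
    f = params.whitening_fraction
    if f > 0:
        blotch_field = _correlated_field(
            (H, W), max(params.texture_correlation_length, 4.0), rng)
        vals = blotch_field[disc]
        if f >= 1.0:
            blotch = np.ones(n_disc, dtype=bool)
        else:
            blotch = vals >= np.quantile(vals, 1.0 - f)
        white = (np.asarray(white_color)[None, :]
                 + rng.normal(0.0, 1.5, size=(int(blotch.sum()), 3)))
        disc_px[blotch] = white
    img[disc] = disc_px

    img = img * params.illumination_gain + params.illumination_offset
    img = np.clip(img, 0.0, 255.0)
    return np.floor(img + 0.5).astype(np.uint8)  # round half up


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreshPopulation:
    """Distribution of fresh-sample appearance across packages.

    Each package draws its own base color (channel-wise normal around
    ``base.base_color``) and texture amplitude; each image additionally draws
    a small illumination jitter, which the standardization stage corrects.
    """

    base: AppearanceParams = AppearanceParams()
    base_color_sd: tuple[float, float, float] = (6.0, 5.0, 4.0)
    texture_amplitude_sd: float = 1.5
    gain_sd: float = 0.02

    def sample_package(self, rng: np.random.Generator) -> AppearanceParams:
        color = tuple(np.clip(
            np.asarray(self.base.base_color)
            + rng.normal(0.0, self.base_color_sd), 0.0, 255.0))
        amp = max(0.0, self.base.texture_amplitude
                  + rng.normal(0.0, self.texture_amplitude_sd))
        return replace(self.base, base_color=color, texture_amplitude=amp)

    def sample_gain(self, rng: np.random.Generator) -> float:
        return max(0.1, 1.0 + rng.normal(0.0, self.gain_sd))


def iter_cohort(design: StudyDesign, effects: EffectModel,
                layout: SceneLayout, population: FreshPopulation,
                seed: int) -> Iterator[tuple[dict, np.ndarray]]:
    """Yield ``(image_record, image)`` pairs for every inventory record.

    Per-package appearance is drawn from ``population``; non-fresh images are
    additionally perturbed by ``effects`` at their (condition, storage day).
    Per-image random streams are derived from ``seed`` and the record index,
    so rendering is reproducible and independent of iteration order.
    """
    _, images = enumerate_design(design)
    pkg_params: dict[int, AppearanceParams] = {}
    for rec in images.to_dict("records"):
        ss_img = np.random.SeedSequence([seed, int(rec["image_id"])])
        pid = int(rec["package_id"])
        if pid not in pkg_params:
            pkg_rng = np.random.default_rng(
                np.random.SeedSequence([seed, 1_000_003 + pid]))
            pkg_params[pid] = population.sample_package(pkg_rng)
        params = pkg_params[pid]
        if rec["state"] != "fresh":
            cond = rec["condition"] if rec["state"] == "treated" else None
            params = apply_effect(
                params, effects.effect_for(cond, int(rec["storage_day"])))
        jitter_rng = np.random.default_rng(ss_img)
        img_seed = int(ss_img.generate_state(1)[0] % (2**31))
        params = replace(params, seed=img_seed,
                         illumination_gain=population.sample_gain(jitter_rng))
        rec = dict(rec, seed=img_seed)
        yield rec, render_scene(layout, params)


def simulate_cohort(design: StudyDesign, effects: EffectModel,
                    layout: SceneLayout, population: FreshPopulation,
                    seed: int) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Materialize the whole cohort: inventory frame plus images in order."""
    records, imgs = [], []
    for rec, img in iter_cohort(design, effects, layout, population, seed):
        records.append(rec)
        imgs.append(img)
    return pd.DataFrame(records), imgs
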
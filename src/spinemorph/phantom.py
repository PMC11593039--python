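"""Synthetic sagittal spine phantom with known per-vertebra morphometry.

The phantom emits an integer label map of a mid-sagittal spine slice in
which every vertebral body is a rounded rectangle whose anterior, middle and
posterior column heights are controlled exactly, together with a truth table
(heights, height loss ratio, fracture label, deformity class, bounding box).
Deformities remap the superior endplate profile while the inferior endplate
stays fixed, the way compression fractures typically collapse:

* ``wedge`` — anterior height reduced to ``(1 - t) * Hp``;
* ``biconcave`` — middle height reduced to ``(1 - t) * Hp``;
* ``crush`` — all three columns reduced uniformly by ``(1 - t)``; the
  Genant height loss *ratio* of such a body stays ~0, which is exactly the
  blind spot of ratio-based morphometry that motivates detector fusion.

Deformed profiles are flat (plateaued) across each measurement band, so the
phantom's truth heights are recovered by band-extent measurement up to pixel
rounding.  Everything is deterministic for a fixed seed.

A mock fracture detector is included: it assigns each vertebra a confidence
score from a logit-normal distribution whose mean is set by closed-form
quantile matching so that thresholding at 0.5 attains requested sensitivity
and specificity in expectation, and emits jittered bounding boxes in the
normalized YOLO frame.  This provides a controllable stand-in for a trained
detector so fusion strategies can be studied end to end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit, ndtri

from .detect_io import Corners, DetectionBox
from .errors import InvalidInputError, SizingError
from .morphometry import DEFAULT_BAND_HALFWIDTH, DEFAULT_COLUMN_FRACTIONS, compute_hlr

__all__ = [
    "DeformityClass",
    "PhantomSpec",
    "VertebraTruth",
    "PhantomTruth",
    "generate_spine",
    "apply_low_density_texture",
    "render_intensity",
    "mock_detector",
    "uniform_hlr_plan",
    "cohort_spec",
    "paper_scale_cohort_spec",
]


class DeformityClass(str, Enum):
    NONE = "none"
    WEDGE = "wedge"
    BICONCAVE = "biconcave"
    CRUSH = "crush"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and deformity plan of a synthetic spine.

    Defaults approximate an adult lumbar spine on a 1 mm sagittal grid:
    25 mm posterior body height, 35 mm anterior-posterior body width, 6 mm
    disc gap.  ``deformity_plan`` lists ``(vertebra_index, DeformityClass,
    target_hlr)`` triples; ``normal_hlr`` optionally assigns a small benign
    (non-fracture) height loss per vertebra, emulating degenerative
    remodeling in real cohorts.
    """

    n_vertebrae: int = 5
    base_posterior_height_mm: float | Sequence[float] = 25.0
    body_width_mm: float = 35.0
    disc_gap_mm: float = 6.0
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    deformity_plan: tuple[tuple[int, DeformityClass, float], ...] = ()
    normal_hlr: tuple[float, ...] | None = None
    corner_rounding: float = 0.08
    margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise InvalidInputError("n_vertebrae must be >= 1")
        for name in ("body_width_mm", "disc_gap_mm", "margin_mm"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise InvalidInputError("pixel spacing must be positive")
        hp = self.posterior_heights_mm()
        if any(h <= 0 for h in hp):
            raise InvalidInputError("posterior heights must be positive")
        if not 0.0 <= self.corner_rounding < 0.5:
            raise InvalidInputError("corner_rounding must lie in [0, 0.5)")
        seen = set()
        for idx, cls, t in self.deformity_plan:
            if not 0 <= idx < self.n_vertebrae:
                raise InvalidInputError(f"deformity index {idx} out of range")
            if idx in seen:
                raise InvalidInputError(f"duplicate deformity index {idx}")
            seen.add(idx)
            DeformityClass(cls)
            if not 0.0 <= t < 1.0:
                raise InvalidInputError(f"target HLR must lie in [0, 1), got {t}")
        if self.normal_hlr is not None:
            if len(self.normal_hlr) != self.n_vertebrae:
                raise InvalidInputError("normal_hlr must have one entry per vertebra")
            if any(not 0.0 <= t < 1.0 for t in self.normal_hlr):
                raise InvalidInputError("normal_hlr values must lie in [0, 1)")

    def posterior_heights_mm(self) -> list[float]:
        h = self.base_posterior_height_mm
        if np.isscalar(h):
            return [float(h)] * self.n_vertebrae
        h = list(h)
        if len(h) != self.n_vertebrae:
            raise InvalidInputError("per-vertebra heights must match n_vertebrae")
        return [float(v) for v in h]


@dataclass(frozen=True)
class VertebraTruth:
    """Ground truth for one phantom vertebra.

    ``hlr`` is the true Genant height loss ratio of the emitted geometry
    (0 for a crush deformity — the ratio is blind to uniform loss even
    though the body is fractured).  The bounding box is in 0-based pixel
    coordinates, inclusive corners.
    """

    index: int
    label_id: int
    name: str
    ha_mm: float
    hm_mm: float
    hp_mm: float
    hlr: float
    fractured: bool
    deformity: DeformityClass
    box_px: tuple[int, int, int, int]  # x0, y0, x1, y1


@dataclass(frozen=True)
class PhantomTruth:
    vertebrae: tuple[VertebraTruth, ...]
    image_shape: tuple[int, int]
    pixel_spacing_mm: tuple[float, float]
    seed: int

    def labels(self) -> dict[int, bool]:
        return {v.label_id: v.fractured for v in self.vertebrae}

    def boxes_normalized(self) -> dict[int, Corners]:
        """Per-vertebra boxes normalized to the image frame (x across columns)."""
        nr, nc = self.image_shape
        out = {}
        for v in self.vertebrae:
            x0, y0, x1, y1 = v.box_px
            out[v.label_id] = (x0 / nc, y0 / nr, (x1 + 1) / nc, (y1 + 1) / nr)
        return out

    def to_records(self) -> list[dict]:
        return [
            {
                "label_id": v.label_id,
                "name": v.name,
                "Ha_mm": v.ha_mm,
                "Hm_mm": v.hm_mm,
                "Hp_mm": v.hp_mm,
                "HLR": v.hlr,
                "deformity": v.deformity.value,
                "fractured": v.fractured,
                "x0": v.box_px[0],
                "y0": v.box_px[1],
                "x1": v.box_px[2],
                "y1": v.box_px[3],
            }
            for v in self.vertebrae
        ]


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Cosine ease from 0 to 1 on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def _height_profile(
    width_px: int,
    hp_px: float,
    deformity: DeformityClass,
    target: float,
    fractions: tuple[float, float, float] = DEFAULT_COLUMN_FRACTIONS,
    band: float = DEFAULT_BAND_HALFWIDTH,
) -> tuple[np.ndarray, float, float, float]:
    """Superior endplate profile h(x) in pixels plus the true column heights.

    The profile is flat across each measurement band (band half-width plus a
    2%-of-width guard), so band-extent measurement recovers the stated
    heights up to rounding.
    """
    x = np.arange(width_px, dtype=float) / max(width_px - 1, 1)
    fa, fm, fp = fractions
    guard = band + 0.02
    reduced = (1.0 - target) * hp_px

    if deformity is DeformityClass.NONE:
        prof = np.full(width_px, hp_px)
        ha = hm = hp = hp_px
    elif deformity is DeformityClass.CRUSH:
        prof = np.full(width_px, reduced)
        ha = hm = hp = reduced
    elif deformity is DeformityClass.WEDGE:
        # plateau at the reduced height through the anterior band, ramp up,
        # plateau at Hp through the posterior band
        lo, hi = fa + guard, fp - guard
        ramp = _smoothstep((x - lo) / (hi - lo))
        prof = reduced + (hp_px - reduced) * ramp
        ha, hp = reduced, hp_px
        hm = float(np.interp(fm, x, prof))
    elif deformity is DeformityClass.BICONCAVE:
        # Hp plateaus over anterior and posterior bands, dip to the reduced
        # height across the middle band
        left = _smoothstep((x - (fa + guard)) / ((fm - band - 0.02) - (fa + guard)))
        right = _smoothstep(((fp - guard) - x) / ((fp - guard) - (fm + band + 0.02)))
        dip = np.minimum(left, right)  # 0 at the ends, 1 across the middle band
        prof = hp_px - (hp_px - reduced) * dip
        ha = hp = hp_px
        hm = reduced
    else:  # pragma: no cover
        raise InvalidInputError(f"unknown deformity {deformity}")
    return prof, float(ha), float(hm), float(hp)


def _corner_drop(width_px: int, height_px: float, rounding: float) -> np.ndarray:
    """Per-column corner shave depth (applied at top and bottom corners)."""
    drop = np.zeros(width_px)
    if rounding <= 0:
        return drop
    r = rounding * min(height_px, width_px)
    r = min(r, 0.09 * width_px)  # keep clear of the anterior/posterior bands
    if r < 1:
        return drop
    x = np.arange(width_px, dtype=float)
    for dx in (x, width_px - 1 - x):
        inside = dx < r
        drop[inside] = np.maximum(
            drop[inside], r - np.sqrt(np.maximum(r * r - (r - dx[inside]) ** 2, 0.0))
        )
    return drop


def _plan_vertebra(
    spec: PhantomSpec, index: int
) -> tuple[DeformityClass, float, float]:
    """Resolve (deformity, fracture target, benign target) for one vertebra."""
    for idx, cls, t in spec.deformity_plan:
        if idx == index:
            return DeformityClass(cls), t, 0.0
    benign = spec.normal_hlr[index] if spec.normal_hlr is not None else 0.0
    return DeformityClass.NONE, 0.0, benign


def generate_spine(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize the phantom: integer label map (vertebra k -> label k+1) + truth.

    The spine runs top-to-bottom; the anterior side is image-left.  The
    vertical extent of vertebra k's mask at the posterior column equals its
    posterior height within one pixel.  Deterministic for a fixed spec.
    """
    sr, sc = spec.pixel_spacing_mm
    width_px = int(round(spec.body_width_mm / sc))
    gap_px = max(1, int(round(spec.disc_gap_mm / sr)))
    margin_r = max(1, int(round(spec.margin_mm / sr)))
    margin_c = max(1, int(round(spec.margin_mm / sc)))
    hp_list = spec.posterior_heights_mm()

    if width_px < 7:
        raise SizingError(
            f"body width {spec.body_width_mm} mm is under 7 px at {sc} mm spacing"
        )
    slots = []
    for k, hp_mm in enumerate(hp_list):
        hp_px = hp_mm / sr
        if hp_px < 3:
            raise SizingError(
                f"vertebra {k}: posterior height {hp_mm} mm is under 3 px at {sr} mm spacing"
            )
        slots.append(int(math.ceil(hp_px)))

    n_rows = 2 * margin_r + sum(slots) + gap_px * (spec.n_vertebrae - 1)
    n_cols = 2 * margin_c + width_px
    labels = np.zeros((n_rows, n_cols), dtype=np.int32)

    vertebrae = []
    y_top = margin_r
    for k, hp_mm in enumerate(hp_list):
        hp_px = hp_mm / sr
        deformity, target, benign = _plan_vertebra(spec, k)
        # benign (non-fracture) height loss rendered as a shallow wedge or
        # biconcavity depending on parity, keeping the truth label negative
        draw_def, draw_t = (deformity, target)
        if deformity is DeformityClass.NONE and benign > 0:
            draw_def = DeformityClass.WEDGE if k % 2 == 0 else DeformityClass.BICONCAVE
            draw_t = benign

        prof, ha_px, hm_px, hp_ref_px = _height_profile(width_px, hp_px, draw_def, draw_t)
        drop = _corner_drop(width_px, float(prof.max()), spec.corner_rounding)

        y_base = y_top + slots[k] - 1  # inferior endplate row (fixed)
        x_off = margin_c
        for i in range(width_px):
            h = int(round(prof[i]))
            d = int(round(drop[i]))
            top = y_base - (h - 1) + d
            bot = y_base - d
            if top <= bot:
                labels[top : bot + 1, x_off + i] = k + 1
        rows = np.flatnonzero((labels == k + 1).any(axis=1))
        cols = np.flatnonzero((labels == k + 1).any(axis=0))
        if rows.size == 0:
            raise SizingError(f"vertebra {k}: geometry vanished after rasterization")
        box = (int(cols[0]), int(rows[0]), int(cols[-1]), int(rows[-1]))

        ha_mm, hm_mm, hp_ref_mm = ha_px * sr, hm_px * sr, hp_ref_px * sr
        vertebrae.append(
            VertebraTruth(
                index=k,
                label_id=k + 1,
                name=f"V{k + 1}",
                ha_mm=ha_mm,
                hm_mm=hm_mm,
                hp_mm=hp_ref_mm,
                hlr=compute_hlr(ha_mm, hm_mm, hp_ref_mm),
                fractured=deformity is not DeformityClass.NONE and target > 0,
                deformity=deformity,
                box_px=box,
            )
        )
        y_top += slots[k] + gap_px

    truth = PhantomTruth(
        vertebrae=tuple(vertebrae),
        image_shape=(n_rows, n_cols),
        pixel_spacing_mm=(sr, sc),
        seed=spec.seed,
    )
    return labels, truth


def plan_truth(spec: PhantomSpec) -> PhantomTruth:
    """Phantom truth from geometry alone, without rasterizing.

    Useful for large cohort simulations where only per-vertebra heights,
    labels and boxes are needed; heights/HLR are the exact (pre-rounding)
    values and boxes come from the layout.
    """
    sr, sc = spec.pixel_spacing_mm
    width_px = int(round(spec.body_width_mm / sc))
    gap_px = max(1, int(round(spec.disc_gap_mm / sr)))
    margin_r = max(1, int(round(spec.margin_mm / sr)))
    margin_c = max(1, int(round(spec.margin_mm / sc)))
    hp_list = spec.posterior_heights_mm()
    slots = [int(math.ceil(h / sr)) for h in hp_list]
    n_rows = 2 * margin_r + sum(slots) + gap_px * (spec.n_vertebrae - 1)
    n_cols = 2 * margin_c + width_px

    vertebrae = []
    y_top = margin_r
    for k, hp_mm in enumerate(hp_list):
        deformity, target, benign = _plan_vertebra(spec, k)
        draw_def, draw_t = (deformity, target)
        if deformity is DeformityClass.NONE and benign > 0:
            draw_def = DeformityClass.WEDGE if k % 2 == 0 else DeformityClass.BICONCAVE
            draw_t = benign
        _, ha_px, hm_px, hp_px = _height_profile(width_px, hp_mm / sr, draw_def, draw_t)
        y_base = y_top + slots[k] - 1
        h_max = int(round(max(ha_px, hm_px, hp_px)))
        box = (margin_c, y_base - h_max + 1, margin_c + width_px - 1, y_base)
        ha_mm, hm_mm, hp_ref = ha_px * sr, hm_px * sr, hp_px * sr
        vertebrae.append(
            VertebraTruth(
                index=k, label_id=k + 1, name=f"V{k + 1}",
                ha_mm=ha_mm, hm_mm=hm_mm, hp_mm=hp_ref,
                hlr=compute_hlr(ha_mm, hm_mm, hp_ref),
                fractured=deformity is not DeformityClass.NONE and target > 0,
                deformity=deformity, box_px=box,
            )
        )
        y_top += slots[k] + gap_px
    return PhantomTruth(tuple(vertebrae), (n_rows, n_cols), (sr, sc), spec.seed)


def render_intensity(
    labels: np.ndarray,
    cortical_hu: float = 400.0,
    trabecular_hu: float = 250.0,
    background_hu: float = -50.0,
    rim_px: int = 2,
) -> np.ndarray:
    """Simple piecewise-constant CT-like intensity image from a label map.

    Each vertebra gets a bright cortical rim (the outer ``rim_px`` shell)
    over a trabecular interior; no noise or texture is added here.
    """
    mask = labels > 0
    interior = ndimage.binary_erosion(mask, iterations=rim_px)
    img = np.full(labels.shape, background_hu, dtype=float)
    img[mask] = cortical_hu
    img[interior] = trabecular_hu
    return img


def apply_low_density_texture(
    image: np.ndarray,
    mask: np.ndarray,
    reduction_range: tuple[float, float],
    seed: int = 0,
    erosion_px: int = 2,
) -> np.ndarray:
    """Randomly lower intensities in the trabecular interior of a mask.

    Emulates the low-attenuation trabecular bone of low-bone-density
    patients: each interior voxel (the mask eroded by ``erosion_px``, a
    proxy for everything inside the cortical rim) is reduced by an
    independent uniform draw from ``reduction_range``.  The rim is left
    untouched.  Returns a new image; seeded for reproducibility.
    """
    lo, hi = reduction_range
    if lo > hi:
        raise InvalidInputError(f"reduction_range must be (low, high), got {reduction_range}")
    img = np.asarray(image, dtype=float).copy()
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise InvalidInputError("image and mask shapes differ")
    interior = ndimage.binary_erosion(m, iterations=erosion_px) if erosion_px else m
    if not interior.any():
        warnings.warn("mask interior empty after erosion; texture not applied", stacklevel=2)
        return img
    rng = np.random.default_rng(seed)
    img[interior] -= rng.uniform(lo, hi, size=int(interior.sum()))
    return img


def _calibrated_logits(
    rng: np.random.Generator, n: int, p_above_half: float
) -> np.ndarray:
    """Logit-normal samples with P(score >= 0.5) == p_above_half.

    score = expit(mu + z), z ~ N(0,1), so P(score >= 0.5) = Phi(mu) and
    mu = Phi^-1(p).  The degenerate targets 0 and 1 are honoured exactly by
    truncating z to the matching half-line.
    """
    z = rng.standard_normal(n)
    if p_above_half >= 1.0:
        return np.abs(z)
    if p_above_half <= 0.0:
        return -np.abs(z) - 1e-9
    return ndtri(p_above_half) + z


def mock_detector(
    truth: PhantomTruth,
    sens_target: float = 0.83,
    spec_target: float = 0.96,
    seed: int = 0,
    emit_floor: float = 0.05,
    box_jitter: float = 0.05,
) -> list[DetectionBox]:
    """Emit calibrated synthetic detections for a phantom cohort.

    Fractured vertebrae draw confidences from a high-mean logit-normal
    distribution, normals from a low-mean one; the means are quantile-matched
    so that thresholding at 0.5 attains ``sens_target`` / ``spec_target`` in
    expectation.  A box (the truth box, jittered by ``box_jitter`` of its
    size in the normalized frame) is emitted only when the confidence clears
    ``emit_floor`` — low-confidence normals produce no box at all, as a real
    detector would.
    """
    if not 0.0 <= sens_target <= 1.0 or not 0.0 <= spec_target <= 1.0:
        raise InvalidInputError("sens/spec targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth.vertebrae)
    fractured = np.array([v.fractured for v in truth.vertebrae])
    logits = np.empty(n)
    logits[fractured] = _calibrated_logits(rng, int(fractured.sum()), sens_target)
    logits[~fractured] = _calibrated_logits(rng, int((~fractured).sum()), 1.0 - spec_target)
    confs = expit(logits)

    norm_boxes = truth.boxes_normalized()
    out = []
    for v, conf in zip(truth.vertebrae, confs):
        if conf < emit_floor:
            continue
        x0, y0, x1, y1 = norm_boxes[v.label_id]
        w, h = x1 - x0, y1 - y0
        jx, jy, jw, jh = rng.uniform(-box_jitter, box_jitter, 4)
        cx = np.clip((x0 + x1) / 2 + jx * w, 0.0, 1.0)
        cy = np.clip((y0 + y1) / 2 + jy * h, 0.0, 1.0)
        out.append(
            DetectionBox(
                class_id=0,
                cx=float(cx), cy=float(cy),
                w=float(w * (1 + jw)), h=float(h * (1 + jh)),
                confidence=float(np.clip(conf, 1e-9, 1.0)),
            )
        )
    return out


def uniform_hlr_plan(
    n: int,
    hlr_range: tuple[float, float] = (0.0, 0.5),
    classes: Sequence[DeformityClass] = (DeformityClass.WEDGE, DeformityClass.BICONCAVE),
    seed: int = 0,
) -> tuple[tuple[int, DeformityClass, float], ...]:
    """Deformity plan covering every vertebra with HLR uniform in a range."""
    rng = np.random.default_rng(seed)
    targets = rng.uniform(*hlr_range, n)
    return tuple(
        (k, classes[k % len(classes)], float(targets[k])) for k in range(n)
    )


def cohort_spec(
    n_fractured: int,
    n_normal: int,
    seed: int = 0,
    fracture_hlr_range: tuple[float, float] = (0.25, 0.6),
    subthreshold_fraction: float = 0.05,
    crush_fraction: float = 0.05,
    normal_hlr_sigma: float = 0.15,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> PhantomSpec:
    """A study-population-style cohort spec.

    Fractured vertebrae are mostly moderate/severe wedge or biconcave
    deformities with HLR uniform in ``fracture_hlr_range``; a small fraction
    are sub-threshold (HLR in [0.15, 0.25), the absolute-loss-on-a-tall-body
    failure mode) and a small fraction are crush deformities (uniform
    collapse, ratio-blind).  Normal vertebrae carry benign degenerative
    height loss drawn half-normal with scale ``normal_hlr_sigma``, truncated
    at 0.45, so a ratio-only reader produces realistic false positives.
    Posterior heights vary N(25, 2.5) mm.  The vertebra order is shuffled.
    """
    n = n_fractured + n_normal
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    frac_idx = order[:n_fractured]

    n_crush = int(round(crush_fraction * n_fractured))
    n_sub = int(round(subthreshold_fraction * n_fractured))
    plan = []
    for j, idx in enumerate(frac_idx):
        if j < n_crush:
            cls, t = DeformityClass.CRUSH, float(rng.uniform(0.2, 0.4))
        elif j < n_crush + n_sub:
            cls = DeformityClass.WEDGE if j % 2 else DeformityClass.BICONCAVE
            t = float(rng.uniform(0.15, 0.25))
        else:
            cls = DeformityClass.WEDGE if j % 2 else DeformityClass.BICONCAVE
            t = float(rng.uniform(*fracture_hlr_range))
        plan.append((int(idx), cls, t))

    benign = np.minimum(np.abs(rng.normal(0.0, normal_hlr_sigma, n)), 0.45)
    benign[frac_idx] = 0.0
    heights = np.clip(rng.normal(25.0, 2.5, n), 15.0, 35.0)

    return PhantomSpec(
        n_vertebrae=n,
        base_posterior_height_mm=tuple(float(h) for h in heights),
        deformity_plan=tuple(plan),
        normal_hlr=tuple(float(b) for b in benign),
        pixel_spacing_mm=pixel_spacing_mm,
        seed=seed,
    )


def paper_scale_cohort_spec(seed: int = 0, **kwargs) -> PhantomSpec:
    """The evaluation-scale cohort: 99 fractured and 882 normal vertebrae."""
    return cohort_spec(n_fractured=99, n_normal=882, seed=seed, **kwargs)
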
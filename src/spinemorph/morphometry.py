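"""Genant-style vertebral morphometry from binary masks.

A vertebral body's height is measured at three columns along its
anterior-posterior extent (anterior, middle, posterior).  The posterior
column, adjacent to the pedicle, serves as the reference height Hp; the
height loss ratio

    HLR = max(0, 1 - min(Ha, Hm) / Hp)

grades the body as normal (HLR < 20%), mild (20% <= HLR < 25%), moderate
(25% <= HLR < 40%) or severe (HLR >= 40%).  The semiquantitative grade uses
the worse (smaller) of the anterior and middle heights, matching how wedge
and biconcave deformities are read clinically.

Measurement procedure: the mask is reduced to its largest connected
component, resampled to isotropic pixels if needed, rotated so its principal
axis (the anterior-posterior axis of a vertebral body) is horizontal, and
the height at each column is the vertical foreground extent within a narrow
band of columns — the digital analogue of caliper placement on endplates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops

from .errors import InvalidInputError, MeasurementError

__all__ = [
    "VertebraMask",
    "MorphometryRecord",
    "GENANT_GRADES",
    "measure_heights",
    "compute_hlr",
    "genant_grade",
    "analyze_mask",
    "analyze_labelmap",
    "DEFAULT_COLUMN_FRACTIONS",
    "DEFAULT_BAND_HALFWIDTH",
    "DEFAULT_HLR_THRESHOLD",
]

#: Band centers along the anterior-posterior extent (anterior, middle, posterior).
DEFAULT_COLUMN_FRACTIONS: tuple[float, float, float] = (0.15, 0.50, 0.85)
#: Band half-width as a fraction of the anterior-posterior extent.
DEFAULT_BAND_HALFWIDTH: float = 0.05
#: Default binary positivity threshold for "HLR positive" (diagnostic cut).
#: The grading scale starts abnormality at 0.20; both are common presets.
DEFAULT_HLR_THRESHOLD: float = 0.25

GENANT_GRADES = ("normal", "mild", "moderate", "severe")


@dataclass(frozen=True)
class VertebraMask:
    """One vertebra's binary raster plus pixel spacing and identity."""

    mask: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    vertebra_label: str = ""
    slice_index: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise InvalidInputError(f"mask must be 2-D, got {m.ndim}-D")
        if not m.any():
            raise InvalidInputError(f"mask for {self.vertebra_label or 'vertebra'} is empty")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise InvalidInputError(f"pixel spacing must be positive, got {(sr, sc)}")


@dataclass(frozen=True)
class MorphometryRecord:
    """Heights, height loss ratio and Genant grade for one vertebra."""

    vertebra_label: str
    ha_mm: float
    hm_mm: float
    hp_mm: float
    hlr: float
    grade: str
    hlr_positive: bool

    def to_dict(self) -> dict:
        return {
            "label": self.vertebra_label,
            "Ha_mm": self.ha_mm,
            "Hm_mm": self.hm_mm,
            "Hp_mm": self.hp_mm,
            "HLR": self.hlr,
            "grade": self.grade,
            "hlr_positive": self.hlr_positive,
        }


def compute_hlr(ha_mm: float, hm_mm: float, hp_mm: float) -> float:
    """Height loss ratio: ``max(0, 1 - min(Ha, Hm) / Hp)``, in [0, 1)."""
    for name, v in (("Ha", ha_mm), ("Hm", hm_mm), ("Hp", hp_mm)):
        if not v > 0:
            raise InvalidInputError(f"{name} must be positive, got {v}")
    return max(0.0, 1.0 - min(ha_mm, hm_mm) / hp_mm)


def genant_grade(hlr: float) -> str:
    """Semiquantitative grade for an HLR in [0, 1).

    normal < 0.20 <= mild < 0.25 <= moderate < 0.40 <= severe; lower bounds
    are inclusive.
    """
    if math.isnan(hlr) or not 0.0 <= hlr < 1.0:
        raise InvalidInputError(f"HLR must lie in [0, 1), got {hlr}")
    if hlr < 0.20:
        return "normal"
    if hlr < 0.25:
        return "mild"
    if hlr < 0.40:
        return "moderate"
    return "severe"


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = sk_label(mask, return_num=True, connectivity=2)
    if n <= 1:
        return mask
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def _pca_tilt_degrees(mask: np.ndarray) -> tuple[float, float]:
    """(tilt of the principal axis from horizontal, elongation) of a mask."""
    props = regionprops(mask.astype(np.uint8))[0]
    t = 90.0 - math.degrees(props.orientation)
    while t > 90.0:
        t -= 180.0
    while t <= -90.0:
        t += 180.0
    minor = props.axis_minor_length or 1.0
    return t, props.axis_major_length / minor


def _endplate_tilt_degrees(mask: np.ndarray, trim: float = 0.15) -> float:
    """Tilt of the inferior endplate: least-squares slope of the bottom
    foreground boundary over the central part of the AP extent.

    Unlike a principal-axis fit, this is insensitive to wedge or biconcave
    deformity of the superior endplate, which tilts the principal axis even
    when the vertebra itself is not rotated.
    """
    cols = np.flatnonzero(mask.any(axis=0))
    x0, x1 = int(cols[0]), int(cols[-1])
    ext = x1 - x0 + 1
    lo = x0 + int(round(trim * ext))
    hi = x1 - int(round(trim * ext))
    xs, bottoms = [], []
    for x in range(lo, hi + 1):
        rows = np.flatnonzero(mask[:, x])
        if rows.size:
            xs.append(x)
            bottoms.append(rows[-1])
    if len(xs) < 2:
        return 0.0
    slope = np.polyfit(xs, bottoms, 1)[0]
    return math.degrees(math.atan(slope))


def _axis_align(mask: np.ndarray, spacing: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Resample to isotropic pixels and level the vertebra.

    Gross misorientation (an elongated body tilted beyond 20 degrees) is
    first corrected by principal-component rotation; the residual tilt is
    then removed by leveling the inferior endplate.  Returns the aligned
    mask and the isotropic pixel size in mm.
    """
    sr, sc = spacing
    m = mask
    iso = min(sr, sc)
    if abs(sr - sc) > 1e-9 * max(sr, sc):
        m = ndimage.zoom(m.astype(np.uint8), (sr / iso, sc / iso), order=0).astype(bool)
    coarse, elongation = _pca_tilt_degrees(m)
    if elongation > 1.3 and abs(coarse) > 20.0:
        m = ndimage.rotate(m.astype(float), coarse, order=1, reshape=True) > 0.5
        m = _largest_component(m)
    fine = _endplate_tilt_degrees(m)
    if abs(fine) > 0.5:
        m = ndimage.rotate(m.astype(float), fine, order=1, reshape=True) > 0.5
        m = _largest_component(m)
    return m, iso


def measure_heights(
    vmask: VertebraMask,
    column_fractions: Sequence[float] = DEFAULT_COLUMN_FRACTIONS,
    band_halfwidth_fraction: float = DEFAULT_BAND_HALFWIDTH,
    align: bool = True,
    anterior_side: str = "left",
) -> tuple[float, float, float]:
    """Anterior, middle and posterior vertebral heights in mm.

    The mask is axis-aligned by principal-component rotation (skipped when
    ``align`` is False or the tilt is below half a degree), then the height
    at each column is the vertical foreground extent
    ``(max - min + 1 rows) * row_spacing`` within a band of columns centered
    at ``fraction * AP_extent``.  ``anterior_side`` names the image side the
    anterior column sits on ("left" or "right").
    """
    fr = tuple(column_fractions)
    if len(fr) != 3 or not all(0.0 < f < 1.0 for f in fr) or not fr[0] < fr[1] < fr[2]:
        raise InvalidInputError(f"column fractions must be strictly increasing in (0,1): {fr}")
    if anterior_side not in ("left", "right"):
        raise InvalidInputError("anterior_side must be 'left' or 'right'")

    mask = _largest_component(np.asarray(vmask.mask, dtype=bool))
    if align:
        mask, iso = _axis_align(mask, vmask.pixel_spacing_mm)
    else:
        iso = vmask.pixel_spacing_mm[0]

    cols = np.flatnonzero(mask.any(axis=0))
    x0, x1 = int(cols[0]), int(cols[-1])
    extent = x1 - x0 + 1
    hw = band_halfwidth_fraction * extent

    heights = []
    names = ("anterior", "middle", "posterior")
    for name, f in zip(names, fr):
        if anterior_side == "right":
            f = 1.0 - f
        center = x0 + f * (extent - 1)
        lo = max(x0, int(round(center - hw)))
        hi = min(x1, int(round(center + hw)))
        band = mask[:, lo : hi + 1]
        rows = np.flatnonzero(band.any(axis=1))
        if rows.size == 0:
            raise MeasurementError(
                f"no foreground in the {name} column band of {vmask.vertebra_label or 'vertebra'}"
            )
        heights.append(float(rows[-1] - rows[0] + 1) * iso)
    return heights[0], heights[1], heights[2]


def analyze_mask(
    vmask: VertebraMask,
    hlr_threshold: float = DEFAULT_HLR_THRESHOLD,
    **measure_kwargs,
) -> MorphometryRecord:
    """Full morphometry for one vertebra: heights, HLR, grade, positivity."""
    ha, hm, hp = measure_heights(vmask, **measure_kwargs)
    hlr = compute_hlr(ha, hm, hp)
    return MorphometryRecord(
        vertebra_label=vmask.vertebra_label,
        ha_mm=ha, hm_mm=hm, hp_mm=hp, hlr=hlr,
        grade=genant_grade(hlr),
        hlr_positive=hlr >= hlr_threshold,
    )


def _mid_sagittal(volume: np.ndarray) -> np.ndarray:
    """Pick the sagittal slice (last axis) maximizing foreground area."""
    areas = volume.reshape(-1, volume.shape[-1]).sum(axis=0)
    return volume[..., int(np.argmax(areas))]


def analyze_labelmap(
    labels: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    label_names: dict[int, str] | None = None,
    hlr_threshold: float = DEFAULT_HLR_THRESHOLD,
    **measure_kwargs,
) -> list[MorphometryRecord]:
    """Per-vertebra morphometry over an integer label map (2-D or 3-D).

    Vertebra k carries label k in the map (background 0).  3-D inputs are
    reduced per vertebra to the sagittal slice with the largest foreground
    area before measurement.
    """
    arr = np.asarray(labels)
    if arr.ndim not in (2, 3):
        raise InvalidInputError(f"label map must be 2-D or 3-D, got {arr.ndim}-D")
    records = []
    slices = ndimage.find_objects(arr.astype(np.int64))
    for lid0, sl in enumerate(slices):
        if sl is None:
            continue
        lid = lid0 + 1
        m = arr[sl] == lid
        if arr.ndim == 3:
            m = _mid_sagittal(m)
        name = (label_names or {}).get(int(lid), f"V{int(lid)}")
        vm = VertebraMask(mask=m, pixel_spacing_mm=pixel_spacing_mm, vertebra_label=name)
        records.append(analyze_mask(vm, hlr_threshold=hlr_threshold, **measure_kwargs))
    return records
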
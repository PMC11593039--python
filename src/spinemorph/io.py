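"""File I/O: NIfTI and PNG label maps, CSV truth/morphometry/score tables.

NIfTI affines carry the pixel spacing on the diagonal (row, column, 1), so
a label map written here round-trips with its physical geometry.  PNGs are
written 16-bit to accommodate cohorts with more than 255 vertebrae.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .detect_io import Corners, VertebraScore
from .errors import InvalidInputError
from .fusion import FusionDecision
from .morphometry import MorphometryRecord

TRUTH_COLUMNS = [
    "label_id", "name", "Ha_mm", "Hm_mm", "Hp_mm", "HLR",
    "deformity", "fractured", "x0", "y0", "x1", "y1",
]


def save_nifti(path: str | Path, array: np.ndarray, pixel_spacing_mm: tuple[float, float]) -> None:
    sr, sc = pixel_spacing_mm
    affine = np.diag([sr, sc, 1.0, 1.0])
    data = array if array.ndim == 3 else array[..., None]
    nib.save(nib.Nifti1Image(data.astype(np.int16), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()
    return data, (float(zooms[0]), float(zooms[1]))


def save_png(path: str | Path, array: np.ndarray) -> None:
    arr = np.asarray(array)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("label values outside uint16 range")
    iio.imwrite(Path(path), arr.astype(np.uint16))


def load_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def load_labelmap(path: str | Path, pixel_spacing_mm=None):
    """Load a label map from NIfTI (spacing from header) or PNG (spacing required)."""
    p = Path(path)
    if p.suffix in (".nii",) or p.name.endswith(".nii.gz"):
        return load_nifti(p)
    if pixel_spacing_mm is None:
        raise InvalidInputError(f"pixel spacing required to load {p.name}")
    return load_png(p), tuple(pixel_spacing_mm)


def write_truth_csv(path: str | Path, truth) -> None:
    pd.DataFrame(truth.to_records(), columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def truth_boxes_normalized(df: pd.DataFrame, image_shape: tuple[int, int]) -> dict[int, Corners]:
    nr, nc = image_shape
    return {
        int(r.label_id): (r.x0 / nc, r.y0 / nr, (r.x1 + 1) / nc, (r.y1 + 1) / nr)
        for r in df.itertuples()
    }


def write_morphometry_csv(path: str | Path, records: Iterable[MorphometryRecord]) -> None:
    pd.DataFrame([r.to_dict() for r in records]).to_csv(path, index=False)


def read_morphometry_csv(path: str | Path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for r in df.itertuples():
        out[r.label] = MorphometryRecord(
            vertebra_label=str(r.label), ha_mm=r.Ha_mm, hm_mm=r.Hm_mm, hp_mm=r.Hp_mm,
            hlr=r.HLR, grade=r.grade, hlr_positive=bool(r.hlr_positive),
        )
    return out


def write_scores_csv(path: str | Path, scores: Iterable[VertebraScore]) -> None:
    pd.DataFrame(
        [{"vertebra_id": s.vertebra_id, "dl_confidence": s.dl_confidence} for s in scores]
    ).to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> dict:
    df = pd.read_csv(path)
    return {
        r.vertebra_id: VertebraScore(r.vertebra_id, float(r.dl_confidence))
        for r in df.itertuples()
    }


def write_decisions_csv(path: str | Path, decisions: Iterable[FusionDecision]) -> None:
    pd.DataFrame(
        [
            {
                "vertebra_id": d.vertebra_id,
                "method": d.method,
                "call": "positive" if d.positive else "negative",
                "provenance": d.provenance,
                "fused_score": d.fused_score,
            }
            for d in decisions
        ]
    ).to_csv(path, index=False)


def write_json(path: str | Path, payload: Mapping) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
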
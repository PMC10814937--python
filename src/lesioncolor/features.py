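"""Per-patient color feature assembly.

Each patient contributes 21 variables: the seven mean color parameters
(red, green, blue, L*, a*, b*, ITA) of the lesion, the same seven for the
surrounding normal-skin band, and the seven lesion-minus-normal
differences. Cohort tables transcribed from publications typically carry
lesion values only, so ``normal`` and ``delta`` are optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .colorimetry import ColorSummary, LabTriple, RGBTriple, image_to_lab, ita_from_lab, rgb_to_lab
from .segmentation import (
    ClosedBoundary,
    GeometryFeatures,
    ScaleCalibration,
    boundary_to_mask,
    geometry_features,
    normal_skin_band,
)

__all__ = [
    "DIAGNOSES",
    "PatientRecord",
    "ColorDelta",
    "summarize_region",
    "extract_patient",
    "records_to_frame",
    "write_feature_table",
    "PARAMETER_NAMES",
]

#: Closed diagnosis vocabulary of the study cohort.
DIAGNOSES = ("MCC", "CHERRY", "BCC/SCC", "HEMANGIOMA")

#: Canonical parameter order used throughout the package.
PARAMETER_NAMES = ("red", "green", "blue", "L", "a", "b", "ITA")


@dataclass(frozen=True)
class ColorDelta:
    """Componentwise lesion − normal differences of the 7 parameters.

    The ITA delta is the difference of the two regions' ITA values, not
    the ITA of the difference, so this is not a :class:`ColorSummary`.
    """

    red: float
    green: float
    blue: float
    L: float
    a: float
    b: float
    ITA: float

    @classmethod
    def between(cls, lesion: ColorSummary, normal: ColorSummary) -> "ColorDelta":
        d = lesion.as_array() - normal.as_array()
        return cls(*d)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: diagnosis plus lesion (and optionally normal-skin) colors."""

    patient_id: str
    diagnosis: str
    lesion: ColorSummary
    normal: Optional[ColorSummary] = None
    delta: Optional[ColorDelta] = None
    geometry: Optional[GeometryFeatures] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}"
            )
        if self.normal is not None and self.delta is not None:
            expected = self.lesion.as_array() - self.normal.as_array()
            if not np.allclose(expected, self.delta.as_array(), atol=1e-9):
                raise ValueError("delta is not lesion - normal componentwise")

    def parameter(self, name: str) -> float:
        """Lesion value of one of the 7 canonical parameters."""
        idx = PARAMETER_NAMES.index(name)
        return float(self.lesion.as_array()[idx])


def summarize_region(
    image: np.ndarray,
    mask: np.ndarray,
    lab_average: str = "per_pixel",
    ita_average: str = "from_mean_lab",
) -> ColorSummary:
    """The seven mean color parameters of a masked image region.

    RGB means are per-channel pixel means. Lab means average the per-pixel
    CIELAB values (``lab_average="per_pixel"``, the perceptually standard
    choice) or, alternatively, convert the mean RGB (``"mean_rgb"``). The
    region ITA is the ITA of the mean L* and b* (``"from_mean_lab"``), the
    convention consistent with published per-patient tables; per-pixel ITA
    averaging is available as ``ita_average="per_pixel"``.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask dimensions must match the image raster")
    if not mask.any():
        raise ValueError("empty region mask")
    pixels = image[mask].astype(float)
    rgb = RGBTriple(*pixels.mean(axis=0))
    if lab_average == "per_pixel":
        lab_pixels = image_to_lab(image)[mask]
        lab = LabTriple(*lab_pixels.mean(axis=0))
    elif lab_average == "mean_rgb":
        lab = rgb_to_lab(rgb)
        lab_pixels = None
    else:
        raise ValueError("lab_average must be 'per_pixel' or 'mean_rgb'")
    if ita_average == "from_mean_lab":
        ita = ita_from_lab(lab.L_star, lab.b_star)
    elif ita_average == "per_pixel":
        if lab_pixels is None:
            lab_pixels = image_to_lab(image)[mask]
        ita = float(
            np.mean([ita_from_lab(L, b) for L, _, b in lab_pixels])
        )
    else:
        raise ValueError("ita_average must be 'from_mean_lab' or 'per_pixel'")
    return ColorSummary(rgb=rgb, lab=lab, ita=ita)


def extract_patient(
    image: np.ndarray,
    boundary: ClosedBoundary,
    diagnosis: str,
    patient_id: str = "0",
    scale: Optional[ScaleCalibration] = None,
    band_factor: float = 1.25,
    **summary_options,
) -> PatientRecord:
    """Assemble a patient's 21 color variables from one photograph.

    The lesion summary comes from the boundary interior; the normal-skin
    summary from the 25%-enlarged band around it; ``delta`` is lesion
    minus normal. Geometry (diameter/surface/perimeter) is attached when a
    :class:`ScaleCalibration` is given.
    """
    shape = np.asarray(image).shape[:2]
    lesion_mask = boundary_to_mask(boundary, shape)
    band_mask = normal_skin_band(boundary, shape, factor=band_factor)
    lesion = summarize_region(image, lesion_mask, **summary_options)
    normal = summarize_region(image, band_mask, **summary_options)
    return PatientRecord(
        patient_id=patient_id,
        diagnosis=diagnosis,
        lesion=lesion,
        normal=normal,
        delta=ColorDelta.between(lesion, normal),
        geometry=geometry_features(boundary, scale) if scale is not None else None,
    )


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate records: one row per patient, canonical parameter columns."""
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id, "diagnosis": rec.diagnosis}
        row.update(zip(PARAMETER_NAMES, rec.lesion.as_array()))
        if rec.normal is not None:
            row.update(
                {f"normal_{n}": v for n, v in zip(PARAMETER_NAMES, rec.normal.as_array())}
            )
        if rec.delta is not None:
            row.update(
                {f"delta_{n}": v for n, v in zip(PARAMETER_NAMES, rec.delta.as_array())}
            )
        if rec.geometry is not None:
            row["max_diameter_cm"] = rec.geometry.max_diameter_cm
            row["surface_cm2"] = rec.geometry.surface_cm2
            row["perimeter_cm"] = rec.geometry.perimeter_cm
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(records: Sequence[PatientRecord], path) -> None:
    """Write the feature table as CSV with 2-decimal value formatting."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.2f")
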
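"""Synthetic lesion photographs, synthetic cohorts, and the study fixture.

No images were deposited by the study this package models, so every
pipeline stage is exercised against (a) generated photographs — a roughly
elliptical lesion whose interior mean RGB differs from a noisy background
"skin" field, optionally with a specular highlight disk and a ruler for
scale — with exact ground-truth boundary and masks, and (b) generated
cohorts of 7-parameter feature vectors drawn per diagnosis group from a
multivariate normal whose defaults are estimated from the packaged
46-patient cohort table, which ships verbatim as a hash-pinned CSV.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .colorimetry import ColorSummary, LabTriple, RGBTriple, ita_from_lab
from .features import DIAGNOSES, PatientRecord
from .segmentation import ClosedBoundary, ScaleCalibration, calibrate_scale

__all__ = [
    "SyntheticLesionSpec",
    "SyntheticLesionSample",
    "GroupSpec",
    "SyntheticCohortSpec",
    "generate_lesion_image",
    "generate_cohort",
    "default_cohort_spec",
    "load_study_fixture",
    "fixture_path",
]

# sha256 of the packaged cohort CSV; guards against silent edits
_FIXTURE_SHA256 = "c3d86a66d08611d72e128297cdacabd821dbd3cacaac9033399f6c17642d6e29"

#: Default synthetic colors: a red-purple nodular lesion on light skin.
DEFAULT_LESION_RGB = (180.0, 70.0, 90.0)
DEFAULT_SKIN_RGB = (220.0, 180.0, 160.0)


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Parameters of one synthetic lesion photograph.

    The lesion is an ellipse (semi-axes in px, rotation in radians) whose
    pixels are the lesion mean RGB plus independent per-channel Gaussian
    noise; the background is the skin mean plus its own noise. An optional
    highlight disk brightens pixels (specular flash reflection); an
    optional ruler draws two marks a known distance apart.
    """

    shape: tuple[int, int] = (256, 256)
    background_rgb: tuple[float, float, float] = DEFAULT_SKIN_RGB
    background_sd: float = 5.0
    lesion_rgb: tuple[float, float, float] = DEFAULT_LESION_RGB
    lesion_sd: float = 5.0
    center: tuple[float, float] = (128.0, 128.0)
    semi_axes: tuple[float, float] = (60.0, 40.0)
    rotation: float = 0.0
    highlight: Optional[tuple[float, float, float, float]] = None  # (x, y, r, boost)
    ruler: Optional[tuple[float, float, float, float, float]] = None  # (x1,y1,x2,y2,cm)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_sd, self.lesion_sd) < 0:
            raise ValueError("noise sd must be >= 0")
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class SyntheticLesionSample:
    """A generated photograph with its exact ground truth."""

    image: np.ndarray
    boundary: ClosedBoundary
    lesion_mask: np.ndarray
    background_mask: np.ndarray
    scale: Optional[ScaleCalibration] = None


def _ellipse_mask(spec: SyntheticLesionSpec, h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = spec.center
    a, b = spec.semi_axes
    ct, st = math.cos(spec.rotation), math.sin(spec.rotation)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_lesion_image(spec: SyntheticLesionSpec) -> SyntheticLesionSample:
    """Render a synthetic lesion photograph; deterministic given the seed."""
    h, w = spec.shape
    mask = _ellipse_mask(spec, h, w)
    if not mask.any():
        raise ValueError("lesion lies entirely outside the image frame")
    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb)
    if spec.background_sd > 0:
        img += rng.normal(0.0, spec.background_sd, size=img.shape)
    lesion = np.asarray(spec.lesion_rgb) + (
        rng.normal(0.0, spec.lesion_sd, size=(int(mask.sum()), 3))
        if spec.lesion_sd > 0
        else 0.0
    )
    img[mask] = lesion
    if spec.highlight is not None:
        hx, hy, hr, boost = spec.highlight
        yy, xx = np.mgrid[0:h, 0:w]
        disk = (xx - hx) ** 2 + (yy - hy) ** 2 <= hr**2
        img[disk] += boost
    scale = None
    if spec.ruler is not None:
        x1, y1, x2, y2, cm = spec.ruler
        for x, y in ((x1, y1), (x2, y2)):
            r0, r1 = int(round(y)) - 3, int(round(y)) + 4
            c0, c1 = int(round(x)) - 1, int(round(x)) + 2
            img[max(r0, 0) : max(r1, 0), max(c0, 0) : max(c1, 0)] = 0.0
        scale = calibrate_scale((x1, y1), (x2, y2), cm)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    t = np.linspace(0.0, 2 * math.pi, 256, endpoint=False)
    a, b = spec.semi_axes
    ct, st = math.cos(spec.rotation), math.sin(spec.rotation)
    ex = spec.center[0] + a * np.cos(t) * ct - b * np.sin(t) * st
    ey = spec.center[1] + a * np.cos(t) * st + b * np.sin(t) * ct
    boundary = ClosedBoundary(np.column_stack([ex, ey]))
    return SyntheticLesionSample(
        image=img,
        boundary=boundary,
        lesion_mask=mask,
        background_mask=~mask,
        scale=scale,
    )


@dataclass(frozen=True)
class GroupSpec:
    """Sampling parameters of one diagnosis group in a synthetic cohort."""

    n: int
    means: tuple[float, ...]
    cov: np.ndarray

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if len(self.means) != 7:
            raise ValueError("expected 7 parameter means")
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (7, 7) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric 7x7")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Per-diagnosis group specs plus the master seed."""

    groups: Mapping[str, GroupSpec]
    seed: int = 0


def default_cohort_spec(seed: int = 0, n_per_group: Optional[int] = None) -> SyntheticCohortSpec:
    """Cohort spec estimated from the packaged study table.

    Group means and diagonal covariances are the sample statistics of the
    46-patient fixture, so default synthetic cohorts resemble the study
    (11 cherry angiomas, 11 MCC, 12 BCC/SCC, 12 hemangiomas unless
    ``n_per_group`` overrides the sizes).
    """
    records = load_study_fixture()
    groups = {}
    for dx in DIAGNOSES:
        vals = np.array(
            [r.lesion.as_array() for r in records if r.diagnosis == dx]
        )
        groups[dx] = GroupSpec(
            n=n_per_group or len(vals),
            means=tuple(vals.mean(axis=0)),
            cov=np.diag(vals.var(axis=0, ddof=1)),
        )
    return SyntheticCohortSpec(groups=groups, seed=seed)


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientRecord]:
    """Draw a cohort of patient records from per-group multivariate normals.

    The sampled ITA column is discarded and recomputed from the sampled
    L* and b*, preserving the internal-consistency invariant of real
    feature tables. RGB draws are clipped to [0, 255] and L* to [0, 100].
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    i = 0
    for dx, g in spec.groups.items():
        draws = rng.multivariate_normal(g.means, g.cov, size=g.n, method="svd")
        for row in draws:
            i += 1
            rgb = RGBTriple(*np.clip(row[:3], 0.0, 255.0))
            L = float(np.clip(row[3], 0.0, 100.0))
            lab = LabTriple(L, float(row[4]), float(row[5]))
            records.append(
                PatientRecord(
                    patient_id=str(i),
                    diagnosis=dx,
                    lesion=ColorSummary(
                        rgb=rgb, lab=lab, ita=ita_from_lab(L, lab.b_star)
                    ),
                )
            )
    return records


def fixture_path():
    """Path-like handle on the packaged cohort CSV."""
    return resources.files("lesioncolor").joinpath("data/cohort_table.csv")


def load_study_fixture() -> list[PatientRecord]:
    """The packaged 46-patient cohort table as patient records.

    11 cherry angiomas, 11 MCC, 12 BCC/SCC and 12 hemangiomas, each with
    the 7 lesion color parameters (no normal-skin values are published
    per patient, so ``normal``/``delta`` are absent). The CSV is
    hash-pinned; a mismatch raises.
    """
    raw = fixture_path().read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged cohort table checksum mismatch ({digest}); "
            "the fixture is read-only"
        )
    df = pd.read_csv(fixture_path())
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=str(row.patient),
                diagnosis=row.diagnosis,
                lesion=ColorSummary(
                    rgb=RGBTriple(row.red, row.green, row.blue),
                    lab=LabTriple(row.L, row.a, row.b),
                    ita=row.ITA,
                ),
            )
        )
    return records
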
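"""Shared domain types, unit conventions and validation.

Conventions used by every module in this package:

* Volumes are ``numpy`` arrays indexed 0-based in ``(row, col, slice)``
  order.  An "axial slice" is ``volume[:, :, k]``.
* The labels *x*, *y*, *z* refer to the **image axes** (col, row, slice
  directions of the acquisition), matching scanners that apply the three
  motion-probing gradients orthogonally to the imaging plane rather than to
  the magnet frame.  No gradient-to-image rotation is performed; data
  acquired with a different convention can be permuted with
  :func:`reorient_gradients`.
* Diffusivities are expressed numerically in units of 1e-3 mm^2/s
  (equivalently um^2/ms): a stored value of ``1.2`` means
  ``1.2e-3 mm^2/s``.  b-values are in s/mm^2.
* Ages are integer years; decade buckets are ``"10s"`` .. ``"80s"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

#: ROI labels for the four measurement regions (right/left projection and
#: association fiber areas lateral to the body of the lateral ventricle).
ROI_LABELS = ("R_proj", "L_proj", "R_assoc", "L_assoc")

#: Enrollment age range: subjects with completed white-matter myelination,
#: bucketed into eight decades.
AGE_MIN, AGE_MAX = 10, 89


# ---------------------------------------------------------------------------
# Diffusion study
# ---------------------------------------------------------------------------

@dataclass
class DiffusionStudy:
    """One subject's b=0 volume plus three diffusion-weighted volumes.

    ``s_x``, ``s_y``, ``s_z`` hold the signal with the motion-probing
    gradient applied along the image x, y and z axes respectively.
    Signals are in arbitrary scanner units; only ratios to ``s0`` matter.
    """

    s0: np.ndarray
    s_x: np.ndarray
    s_y: np.ndarray
    s_z: np.ndarray
    b_value: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = "anon"
    age: Optional[int] = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    def volumes(self) -> dict[str, np.ndarray]:
        return {"b0": self.s0, "x": self.s_x, "y": self.s_y, "z": self.s_z}


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # allows ``if validate_study(s): ...``
        return self.passed


def validate_study(study: DiffusionStudy) -> ValidationReport:
    """Check a study's structural invariants.

    Returns a report rather than raising, so callers can surface every
    problem at once.  Checks: all four volumes are 3-D and share one shape,
    the b-value is positive, and signals are non-negative and finite.
    """
    violations: list[str] = []
    shapes = {name: np.asarray(vol).shape for name, vol in study.volumes().items()}
    if any(len(s) != 3 for s in shapes.values()):
        violations.append(f"volumes must be 3-D, got shapes {shapes}")
    if len(set(shapes.values())) != 1:
        violations.append(f"shape mismatch across volumes: {shapes}")
    if not study.b_value > 0:
        violations.append(f"non-positive b value: {study.b_value}")
    for name, vol in study.volumes().items():
        arr = np.asarray(vol)
        if not np.all(np.isfinite(arr)):
            violations.append(f"non-finite signal in {name}")
        elif np.any(arr < 0):
            violations.append(f"negative signal in {name}")
    return ValidationReport(passed=not violations, violations=violations)


def reorient_gradients(study: DiffusionStudy, order: str) -> DiffusionStudy:
    """Relabel gradient axes for data acquired with a different convention.

    ``order`` is a permutation of ``"xyz"``: ``order[i]`` names the stored
    volume that actually carries the gradient along image axis i.  E.g.
    ``"yxz"`` swaps the x and y diffusion volumes.
    """
    if sorted(order) != ["x", "y", "z"]:
        raise ValueError(f"order must be a permutation of 'xyz', got {order!r}")
    vols = {"x": study.s_x, "y": study.s_y, "z": study.s_z}
    return DiffusionStudy(
        s0=study.s0,
        s_x=vols[order[0]],
        s_y=vols[order[1]],
        s_z=vols[order[2]],
        b_value=study.b_value,
        voxel_size=study.voxel_size,
        subject_id=study.subject_id,
        age=study.age,
    )


# ---------------------------------------------------------------------------
# ADC maps
# ---------------------------------------------------------------------------

@dataclass
class ADCMaps:
    """Per-axis apparent diffusion coefficient volumes.

    Values are in 1e-3 mm^2/s.  Voxels where the ADC could not be computed
    (non-positive signal in b0 or any DWI) are ``NaN`` and ``False`` in
    ``valid_mask`` -- never a silent zero.  ``n_negative`` counts valid
    voxels with a negative ADC (signal increase under diffusion weighting,
    a noise effect); they are retained, not clipped.
    """

    adc_x: np.ndarray
    adc_y: np.ndarray
    adc_z: np.ndarray
    valid_mask: np.ndarray
    n_negative: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.adc_x.shape

    def by_axis(self) -> dict[str, np.ndarray]:
        return {"x": self.adc_x, "y": self.adc_y, "z": self.adc_z}


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """In-plane circular region: center ``(row, col)`` in voxels, radius in
    voxels.  Membership is inclusive: (r-cr)^2 + (c-cc)^2 <= radius^2."""

    center: tuple[float, float]
    radius: float

    def mask(self, plane_shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: plane_shape[0], : plane_shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass
class RoiSet:
    """The four measurement regions on the slice through the body of the
    lateral ventricle."""

    slice_index: int
    rois: dict[str, Roi]

    def validate(self, shape: tuple[int, int, int]) -> ValidationReport:
        violations: list[str] = []
        missing = [lab for lab in ROI_LABELS if lab not in self.rois]
        if missing:
            violations.append(f"missing ROI labels: {missing}")
        extra = [lab for lab in self.rois if lab not in ROI_LABELS]
        if extra:
            violations.append(f"unknown ROI labels: {extra}")
        if not (0 <= self.slice_index < shape[2]):
            violations.append(
                f"slice_index {self.slice_index} outside [0, {shape[2] - 1}]"
            )
            return ValidationReport(False, violations)
        plane = shape[:2]
        masks = {}
        for lab, roi in self.rois.items():
            r0 = roi.center[0] - roi.radius
            r1 = roi.center[0] + roi.radius
            c0 = roi.center[1] - roi.radius
            c1 = roi.center[1] + roi.radius
            if r0 < 0 or c0 < 0 or r1 > plane[0] - 1 or c1 > plane[1] - 1:
                violations.append(f"ROI {lab} extends outside grid bounds")
            masks[lab] = roi.mask(plane)
        labs = list(masks)
        for i, a in enumerate(labs):
            for b in labs[i + 1 :]:
                if np.any(masks[a] & masks[b]):
                    violations.append(f"ROIs {a} and {b} overlap")
        return ValidationReport(passed=not violations, violations=violations)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "slice": int(self.slice_index),
            "rois": {
                lab: {
                    "center": [float(r.center[0]), float(r.center[1])],
                    "radius": float(r.radius),
                }
                for lab, r in self.rois.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoiSet":
        doc = yaml.safe_load(Path(path).read_text())
        rois = {
            lab: Roi(center=(float(d["center"][0]), float(d["center"][1])),
                     radius=float(d["radius"]))
            for lab, d in doc["rois"].items()
        }
        return cls(slice_index=int(doc["slice"]), rois=rois)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def alps_index_from_means(
    adcx_proj: float, adcx_assoc: float, adcy_proj: float, adcz_assoc: float
) -> float:
    """ALPS index = mean(ADCx_proj, ADCx_assoc) / mean(ADCy_proj, ADCz_assoc).

    The numerator pools diffusivity along the perivascular-space direction
    (image x) in both fiber regions; the denominator pools diffusivity
    perpendicular to both the perivascular space and the local fiber
    direction.  Dimensionless; ~1 means no preferential perivascular
    diffusivity.
    """
    vals = (adcx_proj, adcx_assoc, adcy_proj, adcz_assoc)
    if not all(np.isfinite(vals)):
        raise ValueError(f"non-finite ADC means: {vals}")
    denom = (adcy_proj + adcz_assoc) / 2.0
    if denom <= 0:
        raise ValueError(f"degenerate denominator: mean(ADCy_proj, ADCz_assoc) = {denom}")
    return ((adcx_proj + adcx_assoc) / 2.0) / denom


@dataclass
class AlpsMeasurement:
    """The four pooled ROI means (1e-3 mm^2/s) and the derived index for one
    subject/observer.  The stored index always equals the formula applied to
    the stored means (recomputed in the constructor)."""

    adcx_proj: float
    adcx_assoc: float
    adcy_proj: float
    adcz_assoc: float
    subject_id: str = "anon"
    observer_id: str = "A"
    alps_index: float = field(init=False)

    def __post_init__(self) -> None:
        self.alps_index = alps_index_from_means(
            self.adcx_proj, self.adcx_assoc, self.adcy_proj, self.adcz_assoc
        )


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def decade_of(age: int) -> str:
    """Decade bucket label for an age in years (``47 -> "40s"``).

    Supported range is 10..89, the eight-decade span of a post-myelination
    adult/adolescent cohort; outside it a ``ValueError`` is raised.
    """
    age = int(age)
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")
    return f"{(age // 10) * 10}s"


#: CSV column names for the two standard observers.
OBSERVER_COLUMNS = ("index_obs_A", "index_obs_B")


@dataclass
class CohortTable:
    """Cohort of (subject, age, per-observer ALPS index) records.

    Backed by a DataFrame with columns ``subject_id``, ``age``, one
    ``index_obs_*`` column per observer, plus derived ``mean_index`` (the
    across-observer average used for all age analyses) and ``decade``.
    """

    df: pd.DataFrame

    @classmethod
    def from_records(cls, df: pd.DataFrame) -> "CohortTable":
        df = df.copy()
        obs_cols = [c for c in df.columns if c.startswith("index_obs_")]
        if not obs_cols:
            raise ValueError("no index_obs_* observer columns found")
        df["age"] = df["age"].astype(int)
        df["mean_index"] = df[obs_cols].mean(axis=1)
        df["decade"] = df["age"].map(decade_of)
        return cls(df=df)

    @property
    def observer_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("index_obs_")]

    @property
    def n(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        lead = ["subject_id", "age", "decade"]
        cols = lead + self.observer_columns + ["mean_index"]
        self.df[cols].to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path)
        return cls.from_records(df.drop(columns=["mean_index", "decade"], errors="ignore"))


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def save_study(study: DiffusionStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as four NIfTI volumes plus a YAML sidecar.

    Files: ``<id>_b0.nii.gz``, ``<id>_dwi_x.nii.gz`` (and y, z),
    ``<id>.yaml`` holding b_value, subject_id, age, voxel_size.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_size)
    paths: dict[str, Path] = {}
    names = {"b0": study.s0, "dwi_x": study.s_x, "dwi_y": study.s_y, "dwi_z": study.s_z}
    for tag, vol in names.items():
        p = out_dir / f"{study.subject_id}_{tag}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), aff), p)
        paths[tag] = p
    sidecar = {
        "subject_id": study.subject_id,
        "b_value": float(study.b_value),
        "voxel_size": [float(v) for v in study.voxel_size],
        "age": None if study.age is None else int(study.age),
    }
    sp = out_dir / f"{study.subject_id}.yaml"
    sp.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    paths["sidecar"] = sp
    return paths


def load_study(out_dir: str | Path, subject_id: str) -> DiffusionStudy:
    """Inverse of :func:`save_study`; round trips voxel-exactly."""
    out_dir = Path(out_dir)
    sidecar = yaml.safe_load((out_dir / f"{subject_id}.yaml").read_text())

    def _load(tag: str) -> np.ndarray:
        img = nib.load(out_dir / f"{subject_id}_{tag}.nii.gz")
        return np.asarray(img.dataobj, dtype=np.float64)

    return DiffusionStudy(
        s0=_load("b0"),
        s_x=_load("dwi_x"),
        s_y=_load("dwi_y"),
        s_z=_load("dwi_z"),
        b_value=float(sidecar["b_value"]),
        voxel_size=tuple(sidecar["voxel_size"]),
        subject_id=sidecar["subject_id"],
        age=sidecar["age"],
    )


def load_study_from_files(
    s0: str | Path,
    s_x: str | Path,
    s_y: str | Path,
    s_z: str | Path,
    b_value: float,
    subject_id: str = "anon",
    age: Optional[int] = None,
) -> DiffusionStudy:
    """Build a study from four explicit NIfTI paths (CLI entry point)."""
    imgs = [nib.load(p) for p in (s0, s_x, s_y, s_z)]
    zooms = imgs[0].header.get_zooms()[:3]
    vols = [np.asarray(img.dataobj, dtype=np.float64) for img in imgs]
    return DiffusionStudy(
        s0=vols[0], s_x=vols[1], s_y=vols[2], s_z=vols[3],
        b_value=float(b_value),
        voxel_size=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        subject_id=subject_id, age=age,
    )
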
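"""Synthetic data: diffusion-tensor phantoms and simulated cohorts.

Two generators give every pipeline stage a ground truth:

* **Phantoms** — a 3-D grid partitioned into axis-aligned regions, each
  carrying a diagonal diffusion tensor (Dx, Dy, Dz in 1e-3 mm^2/s).  The
  diffusion-weighted signal per axis follows the monoexponential model
  ``S_i = S0 * exp(-b * D_i)`` and magnitude noise is Rician:
  ``|S + n1 + i*n2|`` with independent Gaussian components of SD sigma.
  The default layout mimics an axial slice through the lateral-ventricle
  body at cartoon fidelity: an isotropic CSF block in the center, mirrored
  projection-fiber blocks (dominant Dz) adjacent-lateral and
  association-fiber blocks (dominant Dy) further lateral, all sharing a
  common perivascular Dx.  The closed-form ALPS index of a phantom,
  ``mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)``, is the ground
  truth every estimate is compared against.

* **Cohorts** — subject ages drawn per decade with configurable counts and
  a quadratic age trajectory of the index,
  ``peak_value - curvature * (age - peak_age)^2``, plus independent
  per-subject and per-observer Gaussian noise.

Tensors are diagonal by construction (principal axes aligned with the image
axes).  This is deliberate: a 3-axis DWI measurement is blind to
off-diagonal tensor terms, so oblique fibers would only lower the effective
anisotropy; real fiber geometry is out of scope.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; volumes draw noise in a fixed order (b0, x,
y, z), so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import CohortTable, DiffusionStudy, Roi, RoiSet

# ---------------------------------------------------------------------------
# Phantom spec
# ---------------------------------------------------------------------------

REGION_LABELS = ("background", "ventricle", "proj_L", "proj_R", "assoc_L", "assoc_R")


@dataclass
class Region:
    """Axis-aligned box with one diffusion tensor (diagonal) and S0.

    ``box`` is half-open voxel bounds ((r0, r1), (c0, c1), (s0, s1)).
    """

    label: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    tensor: tuple[float, float, float]  # (Dx, Dy, Dz) in 1e-3 mm^2/s
    s0: float = 1000.0

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        (r0, r1), (c0, c1), (s0_, s1) = self.box
        m[r0:r1, c0:c1, s0_:s1] = True
        return m


@dataclass
class PhantomSpec:
    """Geometry + tensors + noise for one phantom study."""

    shape: tuple[int, int, int] = (64, 64, 32)
    regions: list[Region] = field(default_factory=list)
    background_tensor: tuple[float, float, float] = (0.8, 0.8, 0.8)
    background_s0: float = 800.0
    b_value: float = 1000.0
    noise_sigma: float = 0.0

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    def validate(self) -> None:
        occupancy = np.zeros(self.shape, dtype=np.int32)
        for r in self.regions:
            if r.label not in REGION_LABELS:
                raise ValueError(f"unknown region label {r.label!r}")
            if any(d <= 0 for d in r.tensor):
                raise ValueError(f"region {r.label}: non-positive tensor diagonal")
            occupancy += r.mask(self.shape)
        if (occupancy > 1).any():
            raise ValueError("overlapping phantom regions")


def closed_form_index(spec: PhantomSpec) -> float:
    """Ground-truth ALPS index of a phantom from its tensors alone.

    Hemispheres are pooled exactly as the measurement pipeline pools them:
    L/R tensor entries averaged per fiber type before the ratio.
    """
    dx_proj = (spec.region("proj_L").tensor[0] + spec.region("proj_R").tensor[0]) / 2
    dx_assoc = (spec.region("assoc_L").tensor[0] + spec.region("assoc_R").tensor[0]) / 2
    dy_proj = (spec.region("proj_L").tensor[1] + spec.region("proj_R").tensor[1]) / 2
    dz_assoc = (spec.region("assoc_L").tensor[2] + spec.region("assoc_R").tensor[2]) / 2
    return ((dx_proj + dx_assoc) / 2.0) / ((dy_proj + dz_assoc) / 2.0)


# -- default geometry --------------------------------------------------------
#
# 64x64x32 grid; ventricle: central stack of one-slice boxes over slices
# 12..20, tapered so its cross-section is widest at slice 16 (the "body"
# slice a slice-suggestion scan should find); fiber blocks mirrored left
# (low col) / right (high col) of it, tall enough in z that mid-ventricle
# ROIs sit well inside.

_VENTRICLE_SLICES = range(12, 21)
_VENTRICLE_CENTER_SLICE = 16


def _ventricle_boxes() -> list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]:
    boxes = []
    for k in _VENTRICLE_SLICES:
        half_w = 6 - abs(k - _VENTRICLE_CENTER_SLICE)  # 6 at the body, tapering
        boxes.append(((24, 40), (32 - half_w, 32 + half_w), (k, k + 1)))
    return boxes


_PROJ_L_BOX = ((24, 40), (14, 23), (8, 24))
_PROJ_R_BOX = ((24, 40), (41, 50), (8, 24))
_ASSOC_L_BOX = ((24, 40), (4, 12), (8, 24))
_ASSOC_R_BOX = ((24, 40), (52, 60), (8, 24))

#: Tensor presets (Dx, Dy, Dz) in 1e-3 mm^2/s for (projection, association)
#: blocks.  "default" is the reference spec with closed-form index exactly
#: 3.0; "low_glymphatic" lowers the shared perivascular Dx (index 2.0);
#: "isotropic" is the null phantom (index 1.0); "normal_range" yields an
#: index of 1.5, inside the range reported for healthy adults (~1.3-1.6).
TENSOR_PRESETS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "default": ((1.2, 0.4, 1.4), (1.2, 1.4, 0.4)),
    "low_glymphatic": ((0.8, 0.4, 1.4), (0.8, 1.4, 0.4)),
    "isotropic": ((0.8, 0.8, 0.8), (0.8, 0.8, 0.8)),
    "normal_range": ((0.9, 0.6, 1.2), (0.9, 1.2, 0.6)),
}

VENTRICLE_TENSOR = (3.0, 3.0, 3.0)


def default_phantom_spec(
    variant: str = "default", noise_sigma: float = 0.0
) -> PhantomSpec:
    """Reference phantom layout with one of the tensor presets."""
    try:
        d_proj, d_assoc = TENSOR_PRESETS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(TENSOR_PRESETS)}"
        ) from None
    regions = [
        Region("ventricle", box, VENTRICLE_TENSOR, s0=1000.0)
        for box in _ventricle_boxes()
    ]
    regions += [
        Region("proj_L", _PROJ_L_BOX, d_proj),
        Region("proj_R", _PROJ_R_BOX, d_proj),
        Region("assoc_L", _ASSOC_L_BOX, d_assoc),
        Region("assoc_R", _ASSOC_R_BOX, d_assoc),
    ]
    return PhantomSpec(regions=regions, noise_sigma=noise_sigma)


def default_roi_set(radius: float = 2.5) -> RoiSet:
    """ROIs centered in the default phantom's fiber blocks, mid-ventricle
    slice (16)."""
    return RoiSet(
        slice_index=16,
        rois={
            "L_proj": Roi(center=(32.0, 18.0), radius=radius),
            "R_proj": Roi(center=(32.0, 45.0), radius=radius),
            "L_assoc": Roi(center=(32.0, 8.0), radius=radius),
            "R_assoc": Roi(center=(32.0, 56.0), radius=radius),
        },
    )


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def tensor_signal(
    d_diag: tuple[float, float, float], axis: str, s0: float, b: float
) -> float:
    """Monoexponential signal ``s0 * exp(-b * D_axis)``.

    ``d_diag`` is (Dx, Dy, Dz) in 1e-3 mm^2/s, ``b`` in s/mm^2.
    """
    d = dict(zip("xyz", d_diag))[axis]
    return s0 * np.exp(-b * d * 1e-3)


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def generate_phantom(
    spec: PhantomSpec, seed: int = 0, subject_id: str = "phantom"
) -> tuple[DiffusionStudy, dict]:
    """Synthesize one study from a phantom spec.

    Returns the study plus a ground-truth record holding every region's
    tensor, the noise level, and the closed-form ALPS index.  Same spec +
    seed -> bit-identical volumes.
    """
    spec.validate()
    shape = spec.shape
    d_vols = {
        ax: np.full(shape, spec.background_tensor[i], dtype=np.float64)
        for i, ax in enumerate("xyz")
    }
    s0 = np.full(shape, spec.background_s0, dtype=np.float64)
    for region in spec.regions:
        m = region.mask(shape)
        for i, ax in enumerate("xyz"):
            d_vols[ax][m] = region.tensor[i]
        s0[m] = region.s0

    signals = {"b0": s0}
    for ax in "xyz":
        signals[ax] = s0 * np.exp(-spec.b_value * d_vols[ax] * 1e-3)

    rng = np.random.default_rng(seed)
    noisy = {k: _rician(rng, signals[k], spec.noise_sigma) for k in ("b0", "x", "y", "z")}

    study = DiffusionStudy(
        s0=noisy["b0"], s_x=noisy["x"], s_y=noisy["y"], s_z=noisy["z"],
        b_value=spec.b_value, subject_id=subject_id,
    )
    truth = {
        "tensors": {r.label: list(r.tensor) for r in spec.regions},
        "background_tensor": list(spec.background_tensor),
        "b_value": spec.b_value,
        "noise_sigma": spec.noise_sigma,
        "seed": seed,
        "alps_index": closed_form_index(spec),
    }
    return study, truth


def save_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Decade subject counts of the reference normal cohort (ages 10-19 .. 80-89,
#: n = 128 total).
DEFAULT_DECADE_COUNTS = (24, 21, 14, 15, 19, 14, 15, 6)


@dataclass
class CohortSimSpec:
    """Generative model of a cohort with a quadratic age trajectory.

    True index: ``peak_value - curvature * (age - peak_age)^2``.  Each
    subject adds Gaussian noise of SD ``subject_sd``; each observer's
    reading adds independent Gaussian noise of SD ``observer_sd`` on top of
    the subject value.  With these defaults the expected inter-observer
    Pearson r is var_subj / (var_subj + var_obs) where var_subj includes the
    age-trend variance — about 0.85 at large n.
    """

    decade_counts: tuple[int, ...] = DEFAULT_DECADE_COUNTS
    peak_age: float = 45.0
    peak_value: float = 1.6
    curvature: float = 2.0e-4  # index units per year^2
    subject_sd: float = 0.1
    observer_sd: float = 0.05

    def validate(self) -> None:
        if any(c <= 0 for c in self.decade_counts):
            raise ValueError("decade counts must be positive")
        if len(self.decade_counts) != 8:
            raise ValueError("expected 8 decade counts (10s..80s)")
        if not 10 <= self.peak_age <= 89:
            raise ValueError(f"peak_age {self.peak_age} outside [10, 89]")


def true_index(spec: CohortSimSpec, age: np.ndarray | float) -> np.ndarray | float:
    return spec.peak_value - spec.curvature * (np.asarray(age, dtype=float) - spec.peak_age) ** 2


def generate_cohort(spec: CohortSimSpec | None = None, seed: int = 0) -> CohortTable:
    """Draw one cohort: ages uniform (integer) within each decade, two
    observer readings per subject.  Seeded and deterministic."""
    spec = spec or CohortSimSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    ages = np.concatenate(
        [
            rng.integers(10 * (d + 1), 10 * (d + 2), size=n)
            for d, n in enumerate(spec.decade_counts)
        ]
    )
    n = ages.size
    subject = true_index(spec, ages) + rng.normal(0.0, spec.subject_sd, n)
    obs_a = subject + rng.normal(0.0, spec.observer_sd, n)
    obs_b = subject + rng.normal(0.0, spec.observer_sd, n)
    df = pd.DataFrame(
        {
            "subject_id": [f"sim{i:04d}" for i in range(n)],
            "age": ages.astype(int),
            "index_obs_A": obs_a,
            "index_obs_B": obs_b,
        }
    )
    return CohortTable.from_records(df)


def null_cohort_spec(spec: CohortSimSpec | None = None) -> CohortSimSpec:
    """Same cohort model with the age effect switched off (curvature 0):
    every decade shares one index distribution."""
    return replace(spec or CohortSimSpec(), curvature=0.0)
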
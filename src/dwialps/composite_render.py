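"""Directional color composites for ROI localization.

The composite encodes the per-axis ADC of an axial slice as RGB channels
with the axis-to-color assignment used for directional diffusion imaging:
x (left-right, the perivascular direction at the measured slice) = red,
y (anterior-posterior, association fibers) = green, z (cranio-caudal,
projection fibers) = blue.  Channels are per-axis ADC divided by a fixed
reference diffusivity ``adc_ref`` and clipped to [0, 1]; this is a
brightness scheme for localization, not eigenvector color-FA (no tensor
exists with three axis-aligned gradients).  Each region is brightest in the
channels of its high-diffusivity axes: CSF renders white, projection-fiber
areas blue-dominant (high ADC_z), association areas green-dominant (high
ADC_y), which is all the ROI-placement workflow needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .core_model import ADCMaps

#: Default channel normalization: full channel brightness at 2.0e-3 mm^2/s.
DEFAULT_ADC_REF = 2.0

#: Default CSF-likeness threshold for ventricle slice suggestion
#: (mean ADC across axes, 1e-3 mm^2/s).
DEFAULT_CSF_THRESHOLD = 2.0


@dataclass
class CompositeImage:
    """RGB rendering of one axial slice; channels in [0, 1], invalid voxels
    black."""

    rgb: np.ndarray  # (rows, cols, 3) float in [0, 1]
    slice_index: int
    adc_ref: float


def render_composite(
    maps: ADCMaps, slice_index: int, adc_ref: float = DEFAULT_ADC_REF
) -> CompositeImage:
    """Render slice ``slice_index`` with x=red, y=green, z=blue.

    Channel value is ``clip(adc_axis / adc_ref, 0, 1)``; voxels outside the
    valid mask render black.  Deterministic and idempotent.
    """
    if not 0 <= slice_index < maps.shape[2]:
        raise ValueError(f"slice {slice_index} out of range [0, {maps.shape[2] - 1}]")
    if not adc_ref > 0:
        raise ValueError(f"adc_ref must be positive, got {adc_ref}")
    rows, cols = maps.shape[:2]
    rgb = np.zeros((rows, cols, 3), dtype=np.float64)
    valid = maps.valid_mask[:, :, slice_index]
    for ch, arr in enumerate((maps.adc_x, maps.adc_y, maps.adc_z)):
        plane = arr[:, :, slice_index]
        chan = np.clip(plane / adc_ref, 0.0, 1.0)
        chan[~valid] = 0.0
        rgb[:, :, ch] = chan
    return CompositeImage(rgb=rgb, slice_index=slice_index, adc_ref=adc_ref)


def quantize_8bit(rgb: np.ndarray) -> np.ndarray:
    """Map [0,1] floats to uint8 by round-half-up; fixed so PNG exports are
    bit-exact across platforms."""
    return np.floor(np.clip(rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def save_png(image: CompositeImage, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(quantize_8bit(image.rgb), mode="RGB").save(path, format="PNG")
    return path


def suggest_slice(
    maps: ADCMaps,
    csf_threshold: float = DEFAULT_CSF_THRESHOLD,
    central_fraction: float = 0.5,
) -> int:
    """Suggest the axial slice through the body of the lateral ventricle.

    Scores each slice by the in-slice count of CSF-like voxels (mean ADC
    across axes above ``csf_threshold``) within the central
    ``central_fraction`` band of rows and columns, and returns the argmax
    (lowest index on ties).  Advisory only: measurements always use the
    slice stored in the ``RoiSet``.
    """
    rows, cols, _ = maps.shape
    r0 = int(round(rows * (1 - central_fraction) / 2))
    c0 = int(round(cols * (1 - central_fraction) / 2))
    r1, c1 = rows - r0, cols - c0
    mean_adc = np.nanmean(
        np.stack([maps.adc_x, maps.adc_y, maps.adc_z]), axis=0
    )
    csf_like = (mean_adc > csf_threshold) & maps.valid_mask
    counts = csf_like[r0:r1, c0:c1, :].sum(axis=(0, 1))
    if counts.sum() == 0:
        raise ValueError("no ventricle candidate: no CSF-like voxels found")
    return int(np.argmax(counts))  # argmax returns the first (lowest) maximum
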
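"""Per-axis ADC computation from b=0 / b=1000 volume pairs.

With only two b-values per gradient axis the apparent diffusion coefficient
is the single-b monoexponential estimate

    ADC_i = ln(S0 / S_i) / b

per voxel and axis i in {x, y, z}.  No tensor fit is possible (or needed)
with three axis-aligned gradients.  Output is in 1e-3 mm^2/s.

Policy for pathological voxels: non-positive signal in either member of a
pair invalidates the voxel (NaN + mask) rather than clamping, because
clamping silently biases ROI means; negative ADCs from noise (S_i > S0) are
retained and merely counted, because zeroing them would bias means upward.
"""

from __future__ import annotations

import logging

import numpy as np

from .core_model import ADCMaps, DiffusionStudy, validate_study

log = logging.getLogger(__name__)


def compute_adc(study: DiffusionStudy) -> ADCMaps:
    """Compute x/y/z ADC volumes for one study.

    Raises ``ValueError`` if the study fails structural validation.  A voxel
    is valid iff S0 and all three diffusion-weighted signals are > 0 there;
    invalid voxels are NaN in all three maps.  An all-invalid volume logs a
    warning but is not an error.
    """
    report = validate_study(study)
    if not report.passed:
        raise ValueError("invalid study: " + "; ".join(report.violations))

    s0 = np.asarray(study.s0, dtype=np.float64)
    dwis = {
        "x": np.asarray(study.s_x, dtype=np.float64),
        "y": np.asarray(study.s_y, dtype=np.float64),
        "z": np.asarray(study.s_z, dtype=np.float64),
    }
    valid = s0 > 0
    for arr in dwis.values():
        valid &= arr > 0

    maps = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for axis, si in dwis.items():
            # ln(S0/Si)/b in mm^2/s, scaled to 1e-3 mm^2/s units
            adc = np.log(s0 / si) / study.b_value * 1e3
            adc[~valid] = np.nan
            maps[axis] = adc

    if not valid.any():
        log.warning("compute_adc: no valid voxels in study %s", study.subject_id)
    n_negative = int(sum(np.sum(m[valid] < 0) for m in maps.values()))
    if n_negative:
        log.info(
            "compute_adc: %d negative ADC values retained (noise; S_i > S0)",
            n_negative,
        )
    return ADCMaps(
        adc_x=maps["x"], adc_y=maps["y"], adc_z=maps["z"],
        valid_mask=valid, n_negative=n_negative,
    )


def adc_summary(maps: ADCMaps, mask: np.ndarray) -> dict[str, dict[str, float]]:
    """Per-axis mean, sample SD (n-1 denominator) and valid-voxel count
    within ``mask``.

    ``mask`` must match the map shape; a region with no valid voxels is an
    error ("empty region").  SD is NaN for a single-voxel region.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {maps.shape}")
    sel = mask & maps.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty region: no valid voxels under mask")
    out = {}
    for axis, arr in maps.by_axis().items():
        vals = arr[sel]
        out[axis] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if n > 1 else float("nan"),
            "n": n,
        }
    return out
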
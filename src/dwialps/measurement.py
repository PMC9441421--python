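"""ROI measurement and the ALPS index.

The index compares diffusivity along the perivascular-space direction
(image x, left-right at the measured slice) against diffusivity
perpendicular to the local fiber systems:

    ALPS = mean(ADCx_proj, ADCx_assoc) / mean(ADCy_proj, ADCz_assoc)

where "proj" is the projection-fiber area (fibers along z) and "assoc" the
association-fiber area (fibers along y), both lateral to the body of the
lateral ventricle.  Left and right hemisphere ROI means are averaged before
the formula (bilateral pooling); per-hemisphere indices are available via
:func:`hemisphere_indices`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adc_maps import compute_adc
from .core_model import (
    ADCMaps,
    AlpsMeasurement,
    DiffusionStudy,
    RoiSet,
    alps_index_from_means,
)


@dataclass
class RoiMeans:
    """Mean ADC per axis over the valid voxels of one ROI."""

    mean_x: float
    mean_y: float
    mean_z: float
    n_valid: int


def measure_rois(maps: ADCMaps, rois: RoiSet) -> dict[str, RoiMeans]:
    """Mean x/y/z ADC inside each circular ROI on the configured slice.

    A voxel belongs to an ROI iff its squared center distance is <= radius^2
    (inclusive boundary, so counts are bit-exact).  Only valid voxels enter
    the means; an ROI with no valid voxel raises an error naming it.
    """
    report = rois.validate(maps.shape)
    if not report.passed:
        raise ValueError("invalid RoiSet: " + "; ".join(report.violations))
    k = rois.slice_index
    out: dict[str, RoiMeans] = {}
    for label, roi in rois.rois.items():
        sel = roi.mask(maps.shape[:2]) & maps.valid_mask[:, :, k]
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {label}: no valid voxels")
        out[label] = RoiMeans(
            mean_x=float(maps.adc_x[:, :, k][sel].mean()),
            mean_y=float(maps.adc_y[:, :, k][sel].mean()),
            mean_z=float(maps.adc_z[:, :, k][sel].mean()),
            n_valid=n,
        )
    return out


# alias matching the formula's public name
alps_index = alps_index_from_means


def pooled_means(roi_means: dict[str, RoiMeans]) -> tuple[float, float, float, float]:
    """Bilateral pooling: average L/R hemispheres for each fiber type, then
    pick the axis each term of the index needs."""
    adcx_proj = (roi_means["L_proj"].mean_x + roi_means["R_proj"].mean_x) / 2.0
    adcx_assoc = (roi_means["L_assoc"].mean_x + roi_means["R_assoc"].mean_x) / 2.0
    adcy_proj = (roi_means["L_proj"].mean_y + roi_means["R_proj"].mean_y) / 2.0
    adcz_assoc = (roi_means["L_assoc"].mean_z + roi_means["R_assoc"].mean_z) / 2.0
    return adcx_proj, adcx_assoc, adcy_proj, adcz_assoc


def hemisphere_indices(maps: ADCMaps, rois: RoiSet) -> dict[str, float]:
    """Separate left/right ALPS indices (no bilateral pooling)."""
    rm = measure_rois(maps, rois)
    return {
        "left": alps_index_from_means(
            rm["L_proj"].mean_x, rm["L_assoc"].mean_x,
            rm["L_proj"].mean_y, rm["L_assoc"].mean_z,
        ),
        "right": alps_index_from_means(
            rm["R_proj"].mean_x, rm["R_assoc"].mean_x,
            rm["R_proj"].mean_y, rm["R_assoc"].mean_z,
        ),
    }


def measure_subject(
    study: DiffusionStudy, rois: RoiSet, observer_id: str = "A"
) -> AlpsMeasurement:
    """Full single-subject chain: ADC maps -> ROI means -> ALPS index.

    Stage failures propagate with the stage named in the message.
    """
    try:
        maps = compute_adc(study)
    except ValueError as e:
        raise ValueError(f"adc stage: {e}") from e
    try:
        rm = measure_rois(maps, rois)
    except ValueError as e:
        raise ValueError(f"roi stage: {e}") from e
    ax_p, ax_a, ay_p, az_a = pooled_means(rm)
    return AlpsMeasurement(
        adcx_proj=ax_p, adcx_assoc=ax_a, adcy_proj=ay_p, adcz_assoc=az_a,
        subject_id=study.subject_id, observer_id=observer_id,
    )


def combine_observers(measurements: list[AlpsMeasurement]) -> pd.DataFrame:
    """Per-subject arithmetic mean of observer indices.

    Returns a DataFrame (subject_id, n_observers, mean_index), one row per
    subject, sorted by subject_id.
    """
    if not measurements:
        raise ValueError("no measurements")
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in measurements],
            "alps_index": [m.alps_index for m in measurements],
        }
    )
    g = df.groupby("subject_id")["alps_index"]
    out = pd.DataFrame(
        {"n_observers": g.size(), "mean_index": g.mean()}
    ).reset_index()
    return out.sort_values("subject_id", ignore_index=True)


def measurements_to_csv(measurements: list[AlpsMeasurement], path) -> None:
    """CSV writer with the documented column order."""
    rows = [
        {
            "subject_id": m.subject_id,
            "observer_id": m.observer_id,
            "adcx_proj": m.adcx_proj,
            "adcx_assoc": m.adcx_assoc,
            "adcy_proj": m.adcy_proj,
            "adcz_assoc": m.adcz_assoc,
            "alps_index": m.alps_index,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
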
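"""PET standardized uptake value ratios (SUVR) and tau-atrophy association.

SUVR for an ROI is the mean tracer concentration inside the ROI normalized by
the mean concentration over a cerebellar gray-matter reference mask:
``SUVR = (sum_ROI I / V_ROI) / (sum_ref I / V_ref)``. On a uniform grid this
reduces to the voxel-mean ratio, which is how it is computed (the voxel-volume
factors cancel exactly). No partial-volume correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import LabelVolume, PETVolume


@dataclass
class SUVRResult:
    roi: str
    roi_volume_mm3: float
    roi_mean: float
    reference_mean: float
    suvr: float


@dataclass
class AssociationFit:
    slope: float
    intercept: float
    correlation: float
    n: int
    x: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray  # 95% CI band of the mean line
    ci_high: np.ndarray


def compute_suvr(
    pet: PETVolume,
    roi_mask: np.ndarray,
    ref_mask: np.ndarray,
    roi_name: str = "",
) -> SUVRResult:
    """SUVR of one ROI against the reference mask (same grid as the PET)."""
    roi_mask = np.asarray(roi_mask, bool)
    ref_mask = np.asarray(ref_mask, bool)
    if roi_mask.shape != pet.grid.shape or ref_mask.shape != pet.grid.shape:
        raise ValueError("masks must live on the PET grid")
    if roi_mask.sum() == 0 or ref_mask.sum() == 0:
        raise ValueError("empty ROI or reference mask")
    roi_mean = float(pet.grid[roi_mask].mean())
    ref_mean = float(pet.grid[ref_mask].mean())
    if ref_mean == 0:
        raise ValueError("zero reference mean concentration")
    dx, dy, dz = pet.spacing
    return SUVRResult(
        roi=roi_name,
        roi_volume_mm3=float(roi_mask.sum()) * dx * dy * dz,
        roi_mean=roi_mean,
        reference_mean=ref_mean,
        suvr=roi_mean / ref_mean,
    )


def suvr_table(
    pet: PETVolume,
    labels: LabelVolume,
    ref_mask: np.ndarray,
    subject_id: str = "",
) -> pd.DataFrame:
    """SUVR for every labeled structure of one subject."""
    rows = []
    for lab in labels.labels_present():
        name = labels.label_names.get(lab, f"label{lab}")
        res = compute_suvr(pet, labels.grid == lab, ref_mask, roi_name=name)
        region, _, hemi = name.partition("_")
        rows.append(
            {
                "subject_id": subject_id,
                "structure": name,
                "region": region,
                "hemisphere": hemi or "NA",
                "label": lab,
                "suvr": res.suvr,
                "roi_volume_mm3": res.roi_volume_mm3,
                "roi_mean": res.roi_mean,
                "reference_mean": res.reference_mean,
            }
        )
    return pd.DataFrame(rows)


def interhemispheric_consistency(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair deviation of (left, right) SUVR points from the line y = x.

    ``pairs`` needs columns subject_id, region, suvr_left, suvr_right. The
    signed deviation is the distance along the line normal,
    ``(right - left) / sqrt(2)``; the summary gives mean/SD per region.
    """
    required = {"subject_id", "region", "suvr_left", "suvr_right"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"need columns {sorted(required)}")
    out = pairs.copy()
    out["deviation"] = (out["suvr_right"] - out["suvr_left"]) / np.sqrt(2.0)
    out = out.sort_values(["region", "suvr_left"]).reset_index(drop=True)
    summary = out.groupby("region", as_index=False).agg(
        mean_deviation=("deviation", "mean"),
        sd_deviation=("deviation", "std"),
        n=("deviation", "size"),
    )
    return out, summary


def pair_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a per-structure SUVR table into left/right pairs per region."""
    left = table[table["hemisphere"] == "L"][["subject_id", "region", "suvr"]]
    right = table[table["hemisphere"] == "R"][["subject_id", "region", "suvr"]]
    merged = left.merge(right, on=["subject_id", "region"], suffixes=("_left", "_right"))
    return merged.rename(columns={"suvr_left": "suvr_left", "suvr_right": "suvr_right"})


def regress_suvr_on_atrophy(
    atrophy_rates: np.ndarray,
    suvrs: np.ndarray,
    alpha: float = 0.05,
) -> AssociationFit:
    """OLS of SUVR against atrophy rate with a 95% mean-prediction band."""
    x = np.asarray(atrophy_rates, float)
    y = np.asarray(suvrs, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired observations, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=alpha)
    order = np.argsort(x)
    r = float(np.corrcoef(x, y)[0, 1])
    return AssociationFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        correlation=r,
        n=len(x),
        x=x[order],
        fitted=pred["mean"].to_numpy()[order],
        ci_low=pred["mean_ci_lower"].to_numpy()[order],
        ci_high=pred["mean_ci_upper"].to_numpy()[order],
    )
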
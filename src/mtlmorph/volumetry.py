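"""Structure volumes, outlier exclusion and annualized atrophy rates.

Volumes are voxel counts times the voxel size; each subject's longitudinal
trajectory gets an ordinary least-squares fit whose slope is the annualized
rate of change, reported both in mm^3/yr and as percent of baseline per year
(negative slope = atrophy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LabelVolume, LongitudinalSeries

#: outlier threshold in units of the cohort/region standard deviation
OUTLIER_SD_FACTOR = 2.5


@dataclass
class AtrophyRate:
    structure: str
    slope_abs: float  # mm^3/yr (negative = atrophy)
    slope_pct: float  # % of baseline per yr
    intercept: float  # mm^3 at age 0
    n_used: int
    excluded_timepoints: list[int] = field(default_factory=list)
    r_squared: float = float("nan")

    @property
    def atrophy_rate_pct(self) -> float:
        """Presentation-layer magnitude: percent volume *loss* per year."""
        return -self.slope_pct


def compute_label_volume(vol: LabelVolume, label: int) -> float:
    """Volume in mm^3 of one label: voxel count times voxel dimensions."""
    if label not in vol.label_names:
        raise KeyError(f"unknown label id {label}")
    return float((vol.grid == label).sum()) * vol.voxel_volume


def series_volume_table(series: LongitudinalSeries) -> pd.DataFrame:
    """Long-format volumes for every (timepoint, structure) of one subject."""
    rows = []
    for i, tp in enumerate(series.timepoints):
        if tp.labels is None:
            continue
        for lab, name in tp.labels.label_names.items():
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "group": series.group_label,
                    "timepoint": i,
                    "age": tp.age,
                    "label": lab,
                    "structure": name,
                    "volume_mm3": compute_label_volume(tp.labels, lab),
                }
            )
    return pd.DataFrame(rows)


def cohort_volume_table(cohort: list[LongitudinalSeries]) -> pd.DataFrame:
    return pd.concat([series_volume_table(s) for s in cohort], ignore_index=True)


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------

def exclude_outlier_timepoints(
    volumes: pd.DataFrame,
    sd_factor: float = OUTLIER_SD_FACTOR,
    per_subject_sd: bool = False,
) -> pd.Series:
    """Flag outlier timepoints; returns a boolean ``excluded`` Series.

    Default rule: per region, the SD is computed across *all* observations in
    the cohort, and a subject's timepoint is flagged when its volume deviates
    from the subject's own mean by more than ``sd_factor`` times that SD.
    ``per_subject_sd=True`` switches the SD to within-subject.

    Raises if every timepoint of some subject/region is flagged.
    """
    required = {"subject_id", "structure", "volume_mm3"}
    if not required.issubset(volumes.columns):
        raise ValueError(f"volume table must have columns {sorted(required)}")

    excluded = pd.Series(False, index=volumes.index)
    for structure, region_df in volumes.groupby("structure"):
        if per_subject_sd:
            sd = region_df.groupby("subject_id")["volume_mm3"].transform("std").fillna(0.0)
        else:
            if len(region_df) < 3:
                raise ValueError(
                    f"need >= 3 cohort observations for region {structure!r} to define the SD"
                )
            sd = pd.Series(region_df["volume_mm3"].std(ddof=1), index=region_df.index)
        subj_mean = region_df.groupby("subject_id")["volume_mm3"].transform("mean")
        dev = (region_df["volume_mm3"] - subj_mean).abs()
        flags = dev > sd_factor * sd
        excluded.loc[region_df.index] = flags
        all_gone = flags.groupby(region_df["subject_id"]).all()
        bad = all_gone[all_gone].index.tolist()
        if bad:
            raise ValueError(
                f"all timepoints excluded for subject(s) {bad} in region {structure!r}"
            )
    return excluded


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------

def fit_atrophy_rate(
    ages: np.ndarray,
    volumes: np.ndarray,
    mask: np.ndarray | None = None,
    structure: str = "",
    baseline: str = "fitted",
) -> AtrophyRate:
    """OLS fit of volume against age; slope annualized, percent of baseline.

    ``baseline="fitted"`` (default) normalizes the percent rate by the fitted
    value at the first retained age — robust to baseline noise;
    ``baseline="observed"`` uses the first retained observation instead.
    """
    ages = np.asarray(ages, float)
    volumes = np.asarray(volumes, float)
    keep = np.ones(len(ages), dtype=bool) if mask is None else ~np.asarray(mask, bool)
    excluded = [int(i) for i in np.flatnonzero(~keep)]
    a, v = ages[keep], volumes[keep]
    if len(a) < 2:
        raise ValueError("need >= 2 unmasked timepoints to fit a rate")
    if len(np.unique(a)) < 2:
        raise ValueError("ages must be distinct")

    slope, intercept = np.polyfit(a, v, 1)
    fitted = intercept + slope * a
    ss_res = float(((v - fitted) ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    base = intercept + slope * a[0] if baseline == "fitted" else v[0]
    if base <= 0:
        raise ValueError("non-positive baseline volume")
    return AtrophyRate(
        structure=structure,
        slope_abs=float(slope),
        slope_pct=float(100.0 * slope / base),
        intercept=float(intercept),
        n_used=int(len(a)),
        excluded_timepoints=excluded,
        r_squared=float(r2),
    )


def fit_cohort_rates(
    volumes: pd.DataFrame,
    excluded: pd.Series | None = None,
    baseline: str = "fitted",
) -> pd.DataFrame:
    """Per-(subject, structure) atrophy rates from a long-format volume table."""
    if excluded is None:
        excluded = pd.Series(False, index=volumes.index)
    rows = []
    for (sid, structure), df in volumes.groupby(["subject_id", "structure"]):
        df = df.sort_values("age")
        rate = fit_atrophy_rate(
            df["age"].to_numpy(),
            df["volume_mm3"].to_numpy(),
            mask=excluded.loc[df.index].to_numpy(),
            structure=structure,
            baseline=baseline,
        )
        name, _, hemi = structure.partition("_")
        rows.append(
            {
                "subject_id": sid,
                "group": df["group"].iloc[0] if "group" in df else "",
                "structure": structure,
                "region": name,
                "hemisphere": hemi or "NA",
                "slope_mm3_per_yr": rate.slope_abs,
                "slope_pct_per_yr": rate.slope_pct,
                "atrophy_rate_pct_per_yr": rate.atrophy_rate_pct,
                "n_used": rate.n_used,
                "n_excluded": len(rate.excluded_timepoints),
                "r_squared": rate.r_squared,
            }
        )
    return pd.DataFrame(rows)


def summarize_group_rates(
    rates: pd.DataFrame,
    merge_erc_tec: bool = True,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD atrophy rate per structure per group.

    Hemispheres are reported separately and pooled (pooling averages each
    subject's left/right rates, never sums volumes). ERC and TEC, when both
    present, are additionally reported as a merged ``ERC/TEC`` compartment.
    """
    rates = rates.copy()
    if merge_erc_tec and {"ERC", "TEC"}.issubset(set(rates["region"])):
        merged = (
            rates[rates["region"].isin(["ERC", "TEC"])]
            .groupby(["subject_id", "group", "hemisphere"], as_index=False)
            .agg({"slope_pct_per_yr": "mean", "atrophy_rate_pct_per_yr": "mean"})
        )
        merged["region"] = "ERC/TEC"
        rates = pd.concat([rates, merged], ignore_index=True)

    frames = []
    grouped = rates.groupby(["group", "region", "hemisphere"], as_index=False).agg(
        mean_rate_pct_per_yr=("atrophy_rate_pct_per_yr", "mean"),
        sd_rate_pct_per_yr=("atrophy_rate_pct_per_yr", "std"),
        n=("atrophy_rate_pct_per_yr", "size"),
    )
    frames.append(grouped)
    if include_pooled:
        per_subject = rates.groupby(["group", "region", "subject_id"], as_index=False).agg(
            {"atrophy_rate_pct_per_yr": "mean"}
        )
        pooled = per_subject.groupby(["group", "region"], as_index=False).agg(
            mean_rate_pct_per_yr=("atrophy_rate_pct_per_yr", "mean"),
            sd_rate_pct_per_yr=("atrophy_rate_pct_per_yr", "std"),
            n=("atrophy_rate_pct_per_yr", "size"),
        )
        pooled["hemisphere"] = "pooled"
        frames.append(pooled)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "region", "hemisphere"]).reset_index(drop=True)
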
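"""Configuration, manifest handling and end-to-end orchestration.

A run is deterministic given its config (seeds included): the ``simulate``
stage writes a synthetic cohort (NIfTI label volumes, shell meshes, PET
phantoms) plus a CSV manifest; downstream stages read those artifacts and
emit CSV tables and a JSON provenance record listing every exclusion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import LabelVolume, LongitudinalSeries, PETVolume, Timepoint
from .lddmm import KernelConfig
from .suvr import pair_hemispheres, interhemispheric_consistency, regress_suvr_on_atrophy, suvr_table
from .synthetic import (
    make_laminar_shells,
    make_medial_shrinkage_series,
    make_pet_phantom,
    make_synthetic_cohort,
    ShellSpec,
)
from .thickness import compute_thickness, thickness_atrophy_rate
from .volumetry import (
    cohort_volume_table,
    exclude_outlier_timepoints,
    fit_cohort_rates,
    summarize_group_rates,
)

log = logging.getLogger("mtlmorph")

ALL_STAGES = ("simulate", "volumetry", "thickness", "subregions", "suvr", "report")

#: group-level generative atrophy rates (%/yr) for the demo cohort, following
#: the control/MCI regimes of longitudinal 3T MTL volumetry
DEFAULT_GROUP_SPECS = {
    "control": {"ERC": 2.90, "AMY": 1.26, "HIPP": 0.01},
    "MCI": {"ERC": 4.03, "AMY": 2.22, "HIPP": 0.70},
}


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips through YAML."""

    output_dir: str = "results/run"
    seed: int = 0
    n_subjects: int = 5  # per group
    group_specs: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_SPECS.items()})
    followup_years: list = field(default_factory=lambda: [0.0, 2.0, 4.0])
    noise_cv: float = 0.01
    rate_spread: float = 0.2
    # outlier rule
    outlier_sd_factor: float = 2.5
    outlier_per_subject_sd: bool = False
    rate_baseline: str = "fitted"
    # laminar thickness stage
    shell_subdivision: int = 2
    shell_inner_radius: float = 10.0
    shell_base_thickness: float = 3.0
    thinning_rates: dict = field(default_factory=lambda: {"control": 0.5, "MCI": 2.0})
    # subregion stage
    subregion_n_subjects: int = 1
    subregion_medial_rate: float = 7.0
    subregion_lateral_rate: float = 0.3
    # PET stage
    pet_base_suvr: dict = field(default_factory=lambda: {"ERC": 1.8, "AMY": 1.5, "HIPP": 1.2})
    pet_suvr_per_rate: float = 0.08  # tau-atrophy coupling: d(SUVR)/d(%/yr)
    pet_noise_sd: float = 0.02
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "group", "age", "hemisphere", "labels_path", "pet_path", "ref_mask_path"]


@dataclass
class CohortManifest:
    rows: pd.DataFrame
    warnings: list = field(default_factory=list)

    def subjects(self) -> list[str]:
        return sorted(self.rows["subject_id"].unique())


def load_manifest(path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Rows whose label volume is missing on disk are rejected (the run
    continues); subjects with fewer than three scans get a policy warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in ("subject_id", "group", "age", "labels_path") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns {missing_cols}")
    df["age"] = pd.to_numeric(df["age"], errors="raise")

    msgs = []
    keep = []
    for i, row in df.iterrows():
        p = path.parent / row["labels_path"]
        if not p.exists():
            msgs.append(f"row {i}: missing file {row['labels_path']}; rejected")
            keep.append(False)
        else:
            keep.append(True)
    df = df[np.asarray(keep, bool)].reset_index(drop=True)
    for sid, sub in df.groupby("subject_id"):
        if len(sub) < 3:
            msgs.append(f"subject {sid}: {len(sub)} scans, below the >=3 scans policy")
    for m in msgs:
        warnings.warn(m)
    return CohortManifest(rows=df, warnings=msgs)


def series_from_manifest(manifest: CohortManifest, base_dir: Path) -> list[LongitudinalSeries]:
    out = []
    for sid, sub in manifest.rows.groupby("subject_id"):
        sub = sub.sort_values("age")
        tps = []
        for _, row in sub.iterrows():
            vol = LabelVolume.from_nifti(base_dir / row["labels_path"])
            # label dictionary rides in a sidecar JSON next to the NIfTI
            sidecar = (base_dir / row["labels_path"]).with_suffix("").with_suffix(".labels.json")
            if sidecar.exists():
                names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
                vol.label_names = names
            else:
                vol.label_names = {int(l): f"label{l}" for l in vol.labels_present()}
            tps.append(Timepoint(age=float(row["age"]), labels=vol))
        out.append(
            LongitudinalSeries(subject_id=sid, timepoints=tps, group_label=sub["group"].iloc[0])
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, prov: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    cohort, gt = make_synthetic_cohort(
        cfg.group_specs,
        cfg.n_subjects,
        seed=cfg.seed,
        rate_spread=cfg.rate_spread,
        noise_cv=cfg.noise_cv,
        followup_years=cfg.followup_years,
    )
    vol_dir = out / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for series in cohort:
        gen_rates = {
            r["structure"]: r["generative_rate_pct_per_yr"]
            for _, r in gt[gt.subject_id == series.subject_id].iterrows()
        }
        for i, tp in enumerate(series.timepoints):
            rel = f"volumes/{series.subject_id}_tp{i}.nii.gz"
            nifti = tp.labels.to_nifti()
            nifti.to_filename(str(out / rel))
            sidecar = (out / rel).with_suffix("").with_suffix(".labels.json")
            sidecar.write_text(json.dumps({str(k): v for k, v in tp.labels.label_names.items()}))
            pet_rel, ref_rel = "", ""
            if i == 0:  # PET at baseline only, as in a typical tau-PET substudy
                suvr_gt = {}
                for lab, name in tp.labels.label_names.items():
                    region = name.split("_")[0]
                    rate = gen_rates.get(name, 0.0)
                    suvr_gt[lab] = cfg.pet_base_suvr[region] + cfg.pet_suvr_per_rate * rate
                pet, ref_mask, _ = make_pet_phantom(
                    tp.labels,
                    roi_activity={lab: s * 10.0 for lab, s in suvr_gt.items()},
                    ref_activity=10.0,
                    noise_sd=cfg.pet_noise_sd * 10.0,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                pet_rel = f"volumes/{series.subject_id}_tp{i}_pet.nii.gz"
                ref_rel = f"volumes/{series.subject_id}_tp{i}_ref.nii.gz"
                pet.to_nifti().to_filename(str(out / pet_rel))
                import nibabel as nib

                nib.Nifti1Image(ref_mask.astype(np.int16), pet.affine).to_filename(str(out / ref_rel))
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "group": series.group_label,
                    "age": tp.age,
                    "hemisphere": "both",
                    "labels_path": rel,
                    "pet_path": pet_rel,
                    "ref_mask_path": ref_rel,
                }
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out / "manifest.csv", index=False)
    gt.to_csv(out / "ground_truth_rates.csv", index=False)
    prov["simulate"] = {"n_subjects_per_group": cfg.n_subjects, "groups": sorted(cfg.group_specs)}
    log.info("simulate: wrote %d manifest rows", len(rows))


def _stage_volumetry(cfg: RunConfig, out: Path, prov: dict) -> None:
    manifest = load_manifest(out / "manifest.csv")
    cohort = series_from_manifest(manifest, out)
    volumes = cohort_volume_table(cohort)
    excluded = exclude_outlier_timepoints(
        volumes, sd_factor=cfg.outlier_sd_factor, per_subject_sd=cfg.outlier_per_subject_sd
    )
    rates = fit_cohort_rates(volumes, excluded, baseline=cfg.rate_baseline)
    summary = summarize_group_rates(rates)
    volumes.assign(excluded=excluded).to_csv(out / "volumes.csv", index=False)
    rates.to_csv(out / "rates.csv", index=False)
    summary.to_csv(out / "group_rates.csv", index=False)
    prov["volumetry"] = {
        "outlier_rule": "per-subject deviation vs cohort/region SD"
        if not cfg.outlier_per_subject_sd
        else "per-subject deviation vs within-subject SD",
        "outlier_sd_factor": cfg.outlier_sd_factor,
        "n_excluded_timepoints": int(excluded.sum()),
        "manifest_warnings": manifest.warnings,
    }
    log.info("volumetry: %d rates, %d outliers excluded", len(rates), int(excluded.sum()))


def _stage_thickness(cfg: RunConfig, out: Path, prov: dict) -> None:
    manifest = load_manifest(out / "manifest.csv")
    rng = np.random.default_rng(cfg.seed + 1)
    kernel = KernelConfig(sigma_V=4.0, sigma_W=3.0, n_timesteps=5, max_iter=40)
    rows = []
    flagged_total = 0
    baseline_fields = []
    meta = manifest.rows.drop_duplicates("subject_id")
    for _, mrow in meta.iterrows():
        sid, group = mrow["subject_id"], mrow["group"]
        ages = np.sort(manifest.rows[manifest.rows.subject_id == sid]["age"].to_numpy())
        thin = rng.normal(cfg.thinning_rates.get(group, 0.0), 0.1)
        spec = ShellSpec(
            inner_radius=cfg.shell_inner_radius,
            thickness_map=lambda d: cfg.shell_base_thickness + 1.0 * d[:, 2],
            mesh_resolution=cfg.shell_subdivision,
            thinning_rate=thin,
            timepoints=ages,
        )
        shells = make_laminar_shells(spec)
        medians = []
        for (inner, outer, gt_thick), age in zip(shells, ages):
            tf = compute_thickness(inner, outer, kernel)
            medians.append(tf.summary_median)
            flagged_total += int(np.isnan(tf.thickness).sum())
        rate = thickness_atrophy_rate(ages, np.array(medians))
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "generative_thinning_pct_per_yr": thin,
                "fitted_thinning_pct_per_yr": -rate,
                "baseline_median_mm": medians[0],
            }
        )
        baseline_fields.append(
            pd.DataFrame(
                {"subject_id": sid, "vertex": np.arange(len(shells[0][2])), "thickness_mm": shells[0][2]}
            )
        )
    pd.DataFrame(rows).to_csv(out / "thickness_rates.csv", index=False)
    pd.concat(baseline_fields, ignore_index=True).to_csv(out / "thickness_fields.csv", index=False)
    prov["thickness"] = {"n_flagged_vertices": flagged_total, "rule": "flowline endpoint > 0.5 mm from outer surface"}
    log.info("thickness: %d subjects", len(rows))


def _stage_subregions(cfg: RunConfig, out: Path, prov: dict) -> None:
    from .subregions import run_subject_subregion_pipeline

    all_rates = []
    for k in range(cfg.subregion_n_subjects):
        series, atlas, gt = make_medial_shrinkage_series(
            ages=[70.0, 72.0, 74.0],
            medial_rate=cfg.subregion_medial_rate,
            lateral_rate=cfg.subregion_lateral_rate,
            seed=cfg.seed + k,
            subject_id=f"subregion_{k:02d}",
        )
        rates, _ = run_subject_subregion_pipeline(
            series, atlas, structure_label=1, step_size=2, alignment_step_size=3
        )
        merged = rates.merge(gt[["label", "generative_rate_pct_per_yr"]], on="label")
        all_rates.append(merged)
    pd.concat(all_rates, ignore_index=True).to_csv(out / "subregion_rates.csv", index=False)
    prov["subregions"] = {"n_subjects": cfg.subregion_n_subjects}
    log.info("subregions: %d subjects", cfg.subregion_n_subjects)


def _stage_suvr(cfg: RunConfig, out: Path, prov: dict) -> None:
    manifest = load_manifest(out / "manifest.csv")
    if (manifest.rows["pet_path"] == "").all() or manifest.rows["pet_path"].isna().all():
        raise FileNotFoundError("suvr stage requires PET inputs; none in manifest")
    rates = pd.read_csv(out / "rates.csv") if (out / "rates.csv").exists() else None
    tables = []
    for _, row in manifest.rows.iterrows():
        if not isinstance(row["pet_path"], str) or row["pet_path"] == "":
            continue
        import nibabel as nib

        vol = LabelVolume.from_nifti(out / row["labels_path"])
        sidecar = (out / row["labels_path"]).with_suffix("").with_suffix(".labels.json")
        vol.label_names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        pet_img = nib.load(str(out / row["pet_path"]))
        pet = PETVolume(
            np.asarray(pet_img.dataobj, float),
            tuple(float(z) for z in pet_img.header.get_zooms()[:3]),
            np.asarray(pet_img.affine),
        )
        ref = np.asarray(nib.load(str(out / row["ref_mask_path"])).dataobj) > 0
        tables.append(suvr_table(pet, vol, ref, subject_id=row["subject_id"]))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "suvr.csv", index=False)

    pairs = pair_hemispheres(table)
    per_pair, symmetry = interhemispheric_consistency(pairs)
    per_pair.to_csv(out / "suvr_hemispheric_pairs.csv", index=False)
    symmetry.to_csv(out / "suvr_hemispheric_symmetry.csv", index=False)

    if rates is not None:
        assoc_rows = []
        pooled = table.groupby(["subject_id", "region"], as_index=False)["suvr"].mean()
        rates_pooled = rates.groupby(["subject_id", "region"], as_index=False)[
            "atrophy_rate_pct_per_yr"
        ].mean()
        merged = pooled.merge(rates_pooled, on=["subject_id", "region"])
        for region, sub in merged.groupby("region"):
            if len(sub) < 3 or np.ptp(sub["atrophy_rate_pct_per_yr"].to_numpy()) == 0:
                continue
            fit = regress_suvr_on_atrophy(
                sub["atrophy_rate_pct_per_yr"].to_numpy(), sub["suvr"].to_numpy()
            )
            assoc_rows.append(
                {"region": region, "slope": fit.slope, "intercept": fit.intercept,
                 "correlation": fit.correlation, "n": fit.n}
            )
        pd.DataFrame(assoc_rows).to_csv(out / "suvr_vs_atrophy.csv", index=False)
    prov["suvr"] = {"n_pet_scans": int((manifest.rows["pet_path"] != "").sum())}
    log.info("suvr: %d PET scans", prov["suvr"]["n_pet_scans"])


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the selected stages in order; returns the provenance record."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    log.info("run_pipeline seed=%d stages=%s", config.seed, ",".join(stages))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "config": dataclasses.asdict(config),
    }
    runners = {
        "simulate": _stage_simulate,
        "volumetry": _stage_volumetry,
        "thickness": _stage_thickness,
        "subregions": _stage_subregions,
        "suvr": _stage_suvr,
    }
    for stage in [s for s in ALL_STAGES if s in stages and s != "report"]:
        if stage != "simulate" and not (out / "manifest.csv").exists() and stage != "subregions":
            raise FileNotFoundError(
                f"stage {stage!r} requires the simulate stage's manifest.csv in {out}"
            )
        runners[stage](config, out, prov)
    config.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return prov
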
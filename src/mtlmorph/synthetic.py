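"""Phantom generators with known ground truth.

The generators emulate the statistical structure of a longitudinal 3T MTL
cohort: per-structure annual percent volume loss in the 0.5-9 %/yr range,
laminar shells 1-5 mm thick, subregion-heterogeneous amygdala shrinkage, and
ROI-dependent PET uptake ratios. Every generator is a pure function of its
spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    Atlas,
    LabelVolume,
    LongitudinalSeries,
    PETVolume,
    Timepoint,
    TriMesh,
    affine_from_spacing,
)

#: default voxel spacing (mm) of the 3T volumetry grid
DEFAULT_SPACING = (1.0, 1.0, 1.2)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class StructureShape:
    """Ellipsoidal structure: label id, semi-axes (mm) and center (mm)."""

    label: int
    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]
    name: str = ""


@dataclass
class PhantomSpec:
    structures: list[StructureShape]
    annual_rates: dict[int, float]  # label -> percent volume loss per year
    timepoints: Sequence[float]  # ages in years
    noise_cv: float = 0.0
    seed: int = 0
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    compound: bool = False  # compounded shrinkage instead of linear-in-volume

    def validate(self) -> None:
        ages = np.asarray(self.timepoints, float)
        if len(ages) < 1 or not np.all(np.isfinite(ages)):
            raise ValueError("timepoints must be finite")
        if len(ages) >= 2 and not np.all(np.diff(ages) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for lab, r in self.annual_rates.items():
            if not np.isfinite(r):
                raise ValueError(f"annual rate for label {lab} not finite")
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate structure labels")


@dataclass
class ShellSpec:
    """Spherical laminar compartment: inner radius plus a thickness map."""

    inner_radius: float
    thickness_map: Callable[[np.ndarray], np.ndarray]  # unit directions -> mm
    mesh_resolution: int = 3  # icosphere subdivision level
    thinning_rate: float = 0.0  # %/yr, compounded
    timepoints: Sequence[float] = (0.0,)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError("inner_radius must be > 0")
        ages = np.asarray(self.timepoints, float)
        if len(ages) >= 2 and not np.all(np.diff(ages) > 0):
            raise ValueError("timepoints must be strictly increasing")


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def ellipsoid_volume(semi_axes: Sequence[float]) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * math.pi * a * b * c


def rasterize_ellipsoid(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    semi_axes: Sequence[float],
    center: Sequence[float],
) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ellipsoid."""
    coords = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    q = np.zeros(grid_shape)
    for ax, (c, a, x) in enumerate(zip(center, semi_axes, coords)):
        shape = [1, 1, 1]
        shape[ax] = -1
        q = q + (((x - c) / a) ** 2).reshape(shape)
    return q <= 1.0


def _grid_for_structures(
    structures: Sequence[StructureShape],
    spacing: tuple[float, float, float],
    margin_mm: float = 4.0,
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid shape and world offset containing all structures plus a margin."""
    lo = np.min([np.asarray(s.center) - np.asarray(s.semi_axes) for s in structures], axis=0) - margin_mm
    hi = np.max([np.asarray(s.center) + np.asarray(s.semi_axes) for s in structures], axis=0) + margin_mm
    shape = tuple(int(np.ceil((h - l) / sp)) + 1 for l, h, sp in zip(lo, hi, spacing))
    return shape, lo


def _volume_noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=n))


# ---------------------------------------------------------------------------
# shrinking label phantom
# ---------------------------------------------------------------------------

def target_volume(v0: float, rate_pct: float, dt_years: float, compound: bool = False) -> float:
    """Analytic target volume after ``dt_years`` of shrinkage at ``rate_pct`` %/yr.

    Linear-in-volume by default (the estimand of an OLS fit to the volume
    trajectory); compounded decay available behind the flag.
    """
    if compound:
        return v0 * (1.0 - rate_pct / 100.0) ** dt_years
    return v0 * (1.0 - rate_pct * dt_years / 100.0)


def make_shrinking_label_phantom(
    spec: PhantomSpec,
    subject_id: str = "phantom",
    group_label: str = "",
) -> LongitudinalSeries:
    """Longitudinal label phantom of shrinking ellipsoids with known rates.

    Each structure's analytic target volume at age ``t`` is
    ``V0 * (1 - r * (t - t0) / 100)`` (optionally compounded); the ellipsoid is
    rescaled isotropically to hit the (noise-perturbed) target and rasterized.
    Ground-truth rates and analytic volumes are recorded on the series.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ages = np.asarray(spec.timepoints, float)
    t0 = ages[0]
    shape, offset = _grid_for_structures(spec.structures, spec.spacing)
    affine = affine_from_spacing(spec.spacing)
    affine[:3, 3] = offset

    label_names = {s.label: (s.name or f"label{s.label}") for s in spec.structures}
    noise = {
        s.label: _volume_noise_factors(rng, spec.noise_cv, len(ages)) for s in spec.structures
    }

    timepoints: list[Timepoint] = []
    analytic_rows = []
    for i, age in enumerate(ages):
        grid = np.zeros(shape, dtype=np.int16)
        degenerate = False
        for s in spec.structures:
            v0 = ellipsoid_volume(s.semi_axes)
            rate = spec.annual_rates.get(s.label, 0.0)
            vt = target_volume(v0, rate, age - t0, spec.compound)
            if vt <= 0:
                degenerate = True
                continue
            vt_noisy = vt * noise[s.label][i]
            scale = (vt_noisy / v0) ** (1.0 / 3.0)
            axes = tuple(a * scale for a in s.semi_axes)
            center = tuple(c - o for c, o in zip(s.center, offset))
            mask = rasterize_ellipsoid(shape, spec.spacing, axes, center)
            if mask.sum() < 1:
                degenerate = True
                continue
            if (grid[mask] != 0).any():
                raise ValueError(
                    f"structures overlap after rasterization at age {age:.2f}"
                )
            grid[mask] = s.label
            analytic_rows.append(
                {
                    "age": age,
                    "label": s.label,
                    "structure": label_names[s.label],
                    "analytic_volume_mm3": vt,
                    "noisy_target_mm3": vt_noisy,
                }
            )
        tp = Timepoint(age=age, labels=LabelVolume(grid, spec.spacing, affine.copy(), label_names))
        tp.degenerate = degenerate
        timepoints.append(tp)

    return LongitudinalSeries(
        subject_id=subject_id,
        timepoints=timepoints,
        group_label=group_label,
        ground_truth={
            "rates_pct_per_yr": dict(spec.annual_rates),
            "analytic_volumes": pd.DataFrame(analytic_rows),
            "compound": spec.compound,
        },
    )


# ---------------------------------------------------------------------------
# laminar shells
# ---------------------------------------------------------------------------

def make_laminar_shells(
    spec: ShellSpec,
) -> list[tuple[TriMesh, TriMesh, np.ndarray]]:
    """Inner/outer boundary meshes of a laminar shell at each timepoint.

    The outer surface is the inner icosphere displaced along outward vertex
    normals by the (age-decayed) thickness map; the per-vertex ground-truth
    thickness is returned alongside. Thinning is geometric with per-year ratio
    ``1 - thinning_rate/100``.
    """
    spec.validate()
    ages = np.asarray(spec.timepoints, float)
    t0 = ages[0]
    inner = TriMesh.icosphere(spec.mesh_resolution, spec.inner_radius, spec.center)
    directions = (inner.vertices - np.asarray(spec.center)) / spec.inner_radius
    base_thickness = np.asarray(spec.thickness_map(directions), float)
    if np.ndim(base_thickness) == 0:
        base_thickness = np.full(len(inner.vertices), float(base_thickness))
    if (base_thickness <= 0).any():
        raise ValueError("thickness_map must be positive everywhere")

    out = []
    for age in ages:
        factor = (1.0 - spec.thinning_rate / 100.0) ** (age - t0)
        thickness = base_thickness * factor
        if (thickness <= 0).any():
            raise ValueError(f"thinning drives thickness <= 0 at age {age:.2f}")
        normals = inner.vertex_normals()
        outer = inner.with_vertices(inner.vertices + normals * thickness[:, None])
        out.append((inner, outer, thickness))
    return out


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

def make_pet_phantom(
    labels: LabelVolume,
    roi_activity: dict[int, float],
    ref_activity: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    background_activity: float | None = None,
) -> tuple[PETVolume, np.ndarray, dict[int, float]]:
    """PET phantom on the label grid plus a reference (cerebellar-GM-like) mask.

    Returns ``(pet, ref_mask, ground_truth_suvr)`` with ground-truth SUVR per
    ROI equal to ``roi_activity / ref_activity``. Noise is zero-mean Gaussian.
    """
    if ref_activity <= 0:
        raise ValueError("ref_activity must be > 0")
    rng = np.random.default_rng(seed)
    if background_activity is None:
        background_activity = 0.5 * ref_activity

    grid = np.full(labels.grid.shape, float(background_activity))
    for lab, act in roi_activity.items():
        grid[labels.grid == lab] = act

    # reference region: a corner slab guaranteed outside the structures
    ref_mask = np.zeros(labels.grid.shape, dtype=bool)
    nx, ny, nz = labels.grid.shape
    sx, sy, sz = max(nx // 5, 2), max(ny // 5, 2), max(nz // 3, 2)
    ref_mask[:sx, :sy, :sz] = True
    ref_mask &= labels.grid == 0
    if ref_mask.sum() == 0:
        raise ValueError("no background voxels available for the reference mask")
    grid[ref_mask] = ref_activity

    if noise_sd > 0:
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)

    pet = PETVolume(grid=grid, spacing=labels.spacing, affine=labels.affine.copy())
    gt = {lab: act / ref_activity for lab, act in roi_activity.items()}
    return pet, ref_mask, gt


# ---------------------------------------------------------------------------
# amygdala subregion atlas
# ---------------------------------------------------------------------------

#: canonical amygdala subregion labels
SUBREGION_LABELS = {1: "BMA", 2: "BLA", 3: "CMA", 4: "LA", 5: "PA"}


#: transverse taper of the amygdala toward its lateral pole (breaks the
#: medial/lateral mirror symmetry, as in the real structure)
AMYGDALA_TAPER = 0.3


def _egg_inside(x, y, z, semi_axes, center, taper=AMYGDALA_TAPER):
    """Egg-shaped amygdala: transverse radii shrink toward the lateral (+x) pole."""
    a, b, c = semi_axes
    u = (np.asarray(x, float) - center[0]) / a
    g = np.maximum(1.0 - taper * u, 0.2)
    return (
        u**2
        + ((np.asarray(y, float) - center[1]) / (b * g)) ** 2
        + ((np.asarray(z, float) - center[2]) / (c * g)) ** 2
    ) <= 1.0


def make_subregion_atlas(
    n_lobes: int = 5,
    seed: int = 0,
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.6),
    semi_axes: tuple[float, float, float] = (9.5, 7.5, 6.5),
) -> Atlas:
    """Toy high-field amygdala atlas partitioned into up to 5 subregions.

    The amygdala is a laterally tapered ellipsoid (x = medial->lateral,
    y = posterior->anterior) partitioned so that CMA is posterior-most, LA
    lateral-most, PA a medial sliver, and BLA sits lateral to BMA — matching
    the relative subregion geometry of the primate amygdala. The split
    fractions get a small seeded jitter so different seeds yield distinct but
    valid atlases.
    """
    if n_lobes not in (4, 5):
        raise ValueError("atlas supports 4 or 5 subregions")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.03, 0.03, size=3)

    center = tuple(a + 3 * s for a, s in zip(semi_axes, spacing))
    shape = tuple(int(np.ceil(2 * c / s)) + 1 for c, s in zip(center, spacing))
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    Xg, Yg, Zg = np.meshgrid(*coords, indexing="ij")
    mask = _egg_inside(Xg, Yg, Zg, semi_axes, center)

    coords = np.argwhere(mask).astype(float) * np.asarray(spacing) - np.asarray(center)
    x, y = coords[:, 0], coords[:, 1]

    labels = np.zeros(len(coords), dtype=np.int16)
    y_cut = np.quantile(y, 0.22 + jitter[0])
    labels[y <= y_cut] = 3  # CMA posterior-most
    rest = labels == 0
    x_la = np.quantile(x[rest], 0.62 + jitter[1])
    labels[rest & (x >= x_la)] = 4  # LA lateral-most
    rest = labels == 0
    if n_lobes == 5:
        x_pa = np.quantile(x[rest], 0.12 + jitter[2])
        labels[rest & (x <= x_pa)] = 5  # PA medial sliver
        rest = labels == 0
    x_mid = np.median(x[rest])
    labels[rest & (x > x_mid)] = 2  # BLA lateral of BMA
    labels[labels == 0] = 1  # BMA

    grid = np.zeros(shape, dtype=np.int16)
    grid[mask] = labels
    names = {k: v for k, v in SUBREGION_LABELS.items() if k in np.unique(labels)}
    vol = LabelVolume(grid, spacing, label_names=names)
    return Atlas(
        labels=vol,
        provenance=f"synthetic-ellipsoid-atlas(seed={seed})",
        meta={"semi_axes": tuple(semi_axes), "center": tuple(center)},
    )


# ---------------------------------------------------------------------------
# subregion-heterogeneous (medial) shrinkage phantom
# ---------------------------------------------------------------------------

def _medial_lateral_rate(x, x_cut, medial_rate, lateral_rate, width_mm=1.0):
    """Sigmoid medial-to-lateral rate profile, crossing over at ``x_cut``."""
    w = 1.0 / (1.0 + np.exp(-(x_cut - np.asarray(x, float)) / width_mm))
    return lateral_rate + (medial_rate - lateral_rate) * w


def make_medial_shrinkage_series(
    ages: Sequence[float],
    medial_rate: float,
    lateral_rate: float = 0.0,
    seed: int = 0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    noise_cv: float = 0.01,
    atlas: Atlas | None = None,
    include_context: bool = True,
    subject_id: str = "medial_phantom",
) -> tuple[LongitudinalSeries, Atlas, pd.DataFrame]:
    """Amygdala phantom whose medial side shrinks faster than the lateral.

    The generative deformation contracts the y/z plane by a factor varying
    along the medial-lateral (x) axis: the local volume factor at baseline
    position x after ``dt`` years is ``1 - rate(x) * dt / 100`` with ``rate``
    interpolating from ``medial_rate`` to ``lateral_rate``. Ground-truth
    subregion volumes follow exactly from the atlas voxels times the local
    Jacobian. The subject series carries only the *whole* amygdala label (plus
    optional static context structures), so recovering the subregional rate
    contrast genuinely requires the atlas mapping.

    Returns ``(series, atlas, ground_truth)`` where ``ground_truth`` has one
    row per subregion with its generative rate fit.
    """
    from .volumetry import fit_atrophy_rate

    rng = np.random.default_rng(seed)
    ages = np.asarray(ages, float)
    t0 = ages[0]
    if atlas is None:
        atlas = make_subregion_atlas(seed=seed)
    semi_axes = np.asarray(atlas.meta["semi_axes"])
    center = np.asarray(atlas.meta["center"])

    agrid = atlas.labels.grid
    avox = atlas.labels.voxel_volume
    aidx = np.argwhere(agrid > 0)
    aworld_x = aidx[:, 0] * atlas.labels.spacing[0]
    # rate crossover at the medial boundary of LA: the lateral subregion is spared
    la_idx = np.argwhere(agrid == 4)
    x_cut = float(la_idx[:, 0].min() * atlas.labels.spacing[0]) if len(la_idx) else float(
        center[0]
    )

    # exact ground-truth subregion volumes via the local Jacobian
    arate = _medial_lateral_rate(aworld_x, x_cut, medial_rate, lateral_rate)
    alabels = agrid[tuple(aidx.T)]
    gt_rows = []
    vol_by_label = {}
    for lab in np.unique(alabels):
        sel = alabels == lab
        vols = np.array(
            [avox * np.sum(1.0 - arate[sel] * (a - t0) / 100.0) for a in ages]
        )
        vol_by_label[int(lab)] = vols
        rate = fit_atrophy_rate(ages, vols)
        gt_rows.append(
            {
                "subregion": atlas.labels.label_names.get(int(lab), str(lab)),
                "label": int(lab),
                "generative_rate_pct_per_yr": -rate.slope_pct,
                "baseline_volume_mm3": vols[0],
            }
        )
    ground_truth = pd.DataFrame(gt_rows)

    # subject grid: amygdala plus optional static context structures
    structures = [StructureShape(1, tuple(semi_axes), tuple(center), "AMY")]
    if include_context:
        cx, cy, cz = center
        structures += [
            StructureShape(2, (14.0, 5.0, 4.0), (cx - 28.0, cy, cz), "ERC"),
            StructureShape(3, (10.0, 4.0, 4.0), (cx + 26.0, cy, cz), "TEC"),
            StructureShape(4, (16.0, 7.0, 5.0), (cx, cy + 22.0, cz), "HIPP"),
        ]
    shape, offset = _grid_for_structures(structures, spacing)
    affine = affine_from_spacing(spacing)
    affine[:3, 3] = offset
    label_names = {s.label: s.name for s in structures}

    noise = _volume_noise_factors(rng, noise_cv, len(ages))
    coords = [offset[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")

    timepoints = []
    for i, age in enumerate(ages):
        grid = np.zeros(shape, dtype=np.int16)
        # amygdala: invert the contraction map (x preserved, y/z scaled)
        f = (1.0 - _medial_lateral_rate(X, x_cut, medial_rate, lateral_rate) * (age - t0) / 100.0) * noise[i]
        f = np.maximum(f, 1e-6)
        s = np.sqrt(f)
        y0 = center[1] + (Y - center[1]) / s
        z0 = center[2] + (Z - center[2]) / s
        inside = _egg_inside(X, y0, z0, semi_axes, center)
        grid[inside] = 1
        for sdef in structures[1:]:
            m = rasterize_ellipsoid(
                shape, spacing, sdef.semi_axes, tuple(np.asarray(sdef.center) - offset)
            )
            grid[m & (grid == 0)] = sdef.label
        timepoints.append(
            Timepoint(age=age, labels=LabelVolume(grid, spacing, affine.copy(), label_names))
        )

    series = LongitudinalSeries(
        subject_id=subject_id,
        timepoints=timepoints,
        ground_truth={
            "subregion_volumes": vol_by_label,
            "table": ground_truth,
            "medial_rate": medial_rate,
            "lateral_rate": lateral_rate,
        },
    )
    return series, atlas, ground_truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: baseline ellipsoid geometry per structure (single hemisphere, mm)
COHORT_STRUCTURES = {
    "ERC": {"semi_axes": (15.0, 5.0, 4.0)},
    "AMY": {"semi_axes": (9.0, 7.0, 6.5)},
    "HIPP": {"semi_axes": (20.0, 8.0, 5.0)},
}

#: default between-subject SD of the atrophy rate (%/yr)
DEFAULT_RATE_SPREAD = 0.2
#: default follow-up design: 4 scans over 6 years
DEFAULT_FOLLOWUP_YEARS = (0.0, 2.0, 4.0, 6.0)


def _cohort_structure_layout(hemispheres: bool) -> list[StructureShape]:
    """Non-overlapping placement of the cohort structures on one grid."""
    centers = {"ERC": (20.0, 42.0, 16.0), "AMY": (52.0, 44.0, 16.0), "HIPP": (34.0, 15.0, 16.0)}
    shapes = []
    label = 1
    for name, geo in COHORT_STRUCTURES.items():
        if hemispheres:
            for hemi, dz in (("L", 0.0), ("R", 36.0)):
                cx, cy, cz = centers[name]
                shapes.append(
                    StructureShape(label, geo["semi_axes"], (cx, cy, cz + dz), f"{name}_{hemi}")
                )
                label += 1
        else:
            shapes.append(StructureShape(label, geo["semi_axes"], centers[name], name))
            label += 1
    return shapes


def make_synthetic_cohort(
    group_specs: dict[str, dict[str, float]],
    n_subjects: int,
    seed: int = 0,
    rate_spread: float = DEFAULT_RATE_SPREAD,
    noise_cv: float = 0.01,
    followup_years: Sequence[float] = DEFAULT_FOLLOWUP_YEARS,
    baseline_age_mean: float = 70.0,
    baseline_age_sd: float = 6.0,
    hemispheres: bool = True,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> tuple[list[LongitudinalSeries], pd.DataFrame]:
    """Cohort of longitudinal label phantoms with group-structured rates.

    ``group_specs`` maps group name to per-structure generative rates (%/yr,
    keyed by ``ERC``/``AMY``/``HIPP``); each subject's structure rate is drawn
    from a normal with SD ``rate_spread`` around the group value, applied to
    both hemispheres. Returns the series plus a ground-truth table.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    rel = np.asarray(followup_years, float)

    series_list: list[LongitudinalSeries] = []
    gt_rows = []
    for group, struct_rates in group_specs.items():
        for k in range(n_subjects):
            sid = f"{group}_{k:03d}"
            baseline_age = rng.normal(baseline_age_mean, baseline_age_sd)
            shapes = _cohort_structure_layout(hemispheres)
            # seeded sub-voxel jitter decorrelates rasterization error across subjects
            for s in shapes:
                s.center = tuple(np.asarray(s.center) + rng.uniform(-0.5, 0.5, 3))
            rates_by_name = {
                name: rng.normal(struct_rates.get(name, 0.0), rate_spread)
                for name in COHORT_STRUCTURES
            }
            annual_rates = {s.label: rates_by_name[s.name.split("_")[0]] for s in shapes}
            spec = PhantomSpec(
                structures=shapes,
                annual_rates=annual_rates,
                timepoints=baseline_age + rel,
                noise_cv=noise_cv,
                seed=int(rng.integers(0, 2**31 - 1)),
                spacing=spacing,
            )
            series = make_shrinking_label_phantom(spec, subject_id=sid, group_label=group)
            series_list.append(series)
            for s in shapes:
                gt_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "structure": s.name,
                        "label": s.label,
                        "generative_rate_pct_per_yr": annual_rates[s.label],
                        "group_rate_pct_per_yr": struct_rates.get(s.name.split("_")[0], 0.0),
                        "baseline_age": baseline_age,
                    }
                )
    return series_list, pd.DataFrame(gt_rows)
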
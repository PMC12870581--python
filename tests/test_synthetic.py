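"""Phantom generators: ground truth, reproducibility, convergence."""

import numpy as np
import pandas as pd
import pytest

from mtlmorph.containers import TriMesh
from mtlmorph.synthetic import (
    PhantomSpec,
    ShellSpec,
    StructureShape,
    ellipsoid_volume,
    make_laminar_shells,
    make_medial_shrinkage_series,
    make_pet_phantom,
    make_shrinking_label_phantom,
    make_subregion_atlas,
    make_synthetic_cohort,
    rasterize_ellipsoid,
)
from mtlmorph.volumetry import compute_label_volume, fit_atrophy_rate, series_volume_table


def _simple_spec(**kw):
    defaults = dict(
        structures=[StructureShape(1, (10.0, 8.0, 6.0), (20.0, 20.0, 20.0), "AMY")],
        annual_rates={1: 0.0},
        timepoints=[70.0, 72.0, 74.0],
        noise_cv=0.0,
        seed=0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestShrinkingPhantom:
    def test_zero_rate_gives_identical_label_counts(self):
        series = make_shrinking_label_phantom(_simple_spec())
        counts = [(tp.labels.grid == 1).sum() for tp in series.timepoints]
        assert counts[0] > 0
        assert len(set(counts)) == 1

    def test_seeded_reproducibility_is_bit_identical(self):
        a = make_shrinking_label_phantom(_simple_spec(noise_cv=0.01, seed=7))
        b = make_shrinking_label_phantom(_simple_spec(noise_cv=0.01, seed=7))
        for ta, tb in zip(a.timepoints, b.timepoints):
            np.testing.assert_array_equal(ta.labels.grid, tb.labels.grid)

    def test_different_seeds_differ(self):
        a = make_shrinking_label_phantom(_simple_spec(noise_cv=0.02, seed=1))
        b = make_shrinking_label_phantom(_simple_spec(noise_cv=0.02, seed=2))
        assert any(
            (ta.labels.grid != tb.labels.grid).any()
            for ta, tb in zip(a.timepoints, b.timepoints)
        )

    def test_noiseless_rate_recovered_by_volumetry(self):
        spec = _simple_spec(
            annual_rates={1: 4.0}, timepoints=[70.0, 71.0, 72.0, 73.0, 74.0, 75.0]
        )
        series = make_shrinking_label_phantom(spec)
        tab = series_volume_table(series)
        rate = fit_atrophy_rate(tab["age"].to_numpy(), tab["volume_mm3"].to_numpy())
        assert rate.slope_pct == pytest.approx(-4.0, abs=0.2)

    def test_rasterized_volume_tracks_analytic_target_within_voxel_shell(self):
        spec = _simple_spec(annual_rates={1: 4.0}, timepoints=[70.0, 73.0])
        series = make_shrinking_label_phantom(spec)
        analytic = series.ground_truth["analytic_volumes"]
        for tp in series.timepoints:
            v = compute_label_volume(tp.labels, 1)
            target = analytic[analytic.age == tp.age]["analytic_volume_mm3"].iloc[0]
            # one-voxel surface shell bound on rasterization error
            shell = tp.labels.voxel_volume * 4 * np.pi * (target / (4 / 3 * np.pi)) ** (2 / 3)
            assert abs(v - target) < shell

    def test_overlapping_structures_rejected(self):
        spec = _simple_spec(
            structures=[
                StructureShape(1, (10.0, 8.0, 6.0), (20.0, 20.0, 20.0)),
                StructureShape(2, (10.0, 8.0, 6.0), (25.0, 20.0, 20.0)),
            ],
            annual_rates={1: 0.0, 2: 0.0},
        )
        with pytest.raises(ValueError, match="overlap"):
            make_shrinking_label_phantom(spec)

    def test_vanished_structure_flags_degenerate_timepoint(self):
        spec = _simple_spec(annual_rates={1: 40.0}, timepoints=[70.0, 71.0, 73.0])
        series = make_shrinking_label_phantom(spec)
        assert series.timepoints[-1].degenerate

    def test_rasterization_error_halves_with_voxel_size(self):
        axes, center = (10.0, 8.0, 6.0), (15.0, 13.0, 11.0)
        true = ellipsoid_volume(axes)
        errs = []
        for h in (1.0, 0.5):
            shape = tuple(int(30 / h) for _ in range(3))
            mask = rasterize_ellipsoid(shape, (h, h, h), axes, center)
            errs.append(abs(mask.sum() * h**3 - true))
        assert errs[1] <= errs[0]
        assert errs[1] / true < 0.02


class TestLaminarShells:
    def test_constant_thickness_ground_truth(self):
        spec = ShellSpec(inner_radius=10.0, thickness_map=lambda d: np.full(len(d), 2.5))
        (inner, outer, gt), = make_laminar_shells(spec)
        assert np.allclose(gt, 2.5)

    def test_variable_map_extremes(self):
        spec = ShellSpec(
            inner_radius=10.0, thickness_map=lambda d: 3.0 + 2.0 * d[:, 2]
        )  # 1..5 mm
        (inner, outer, gt), = make_laminar_shells(spec)
        assert gt.min() == pytest.approx(1.0, abs=1e-9)
        assert gt.max() == pytest.approx(5.0, abs=1e-9)

    def test_thinning_sequence_is_geometric(self):
        spec = ShellSpec(
            inner_radius=10.0,
            thickness_map=lambda d: np.full(len(d), 2.5),
            thinning_rate=2.0,
            timepoints=[70.0, 71.0, 72.0, 73.0, 74.0],
        )
        shells = make_laminar_shells(spec)
        medians = [np.median(gt) for _, _, gt in shells]
        ratios = np.diff(np.log(medians))
        assert np.allclose(np.exp(ratios), 0.98, atol=1e-12)

    def test_outer_is_normal_offset_of_inner(self):
        spec = ShellSpec(inner_radius=10.0, thickness_map=lambda d: 3.0 + d[:, 0])
        (inner, outer, gt), = make_laminar_shells(spec)
        disp = outer.vertices - inner.vertices
        np.testing.assert_allclose(np.linalg.norm(disp, axis=1), gt, rtol=1e-9)
        # displacement parallel to vertex normals
        n = inner.vertex_normals()
        cos = np.einsum("id,id->i", disp, n) / np.linalg.norm(disp, axis=1)
        assert cos.min() > 0.999

    def test_nonpositive_thickness_names_offending_age(self):
        spec = ShellSpec(
            inner_radius=10.0,
            thickness_map=lambda d: np.full(len(d), 0.5),
            thinning_rate=100.0,  # full loss after one year
            timepoints=[70.0, 71.0, 72.0],
        )
        with pytest.raises(ValueError, match="71"):
            make_laminar_shells(spec)


class TestPetPhantom:
    def _labels(self):
        spec = _simple_spec()
        return make_shrinking_label_phantom(spec).timepoints[0].labels

    def test_ground_truth_ratio(self):
        labels = self._labels()
        pet, ref, gt = make_pet_phantom(labels, {1: 2.0}, ref_activity=1.0, noise_sd=0.0)
        assert gt[1] == 2.0
        assert pet.grid[labels.grid == 1].mean() == pytest.approx(2.0)
        assert pet.grid[ref].mean() == pytest.approx(1.0)

    def test_uniform_activity_gives_unit_suvr(self):
        labels = self._labels()
        pet, ref, gt = make_pet_phantom(
            labels, {1: 1.0}, ref_activity=1.0, noise_sd=0.0, background_activity=1.0
        )
        assert np.allclose(pet.grid, 1.0)
        assert gt[1] == 1.0

    def test_noisy_suvr_recovers_within_three_standard_errors(self):
        labels = self._labels()
        sd = 0.05
        pet, ref, gt = make_pet_phantom(labels, {1: 2.0}, 1.0, noise_sd=sd, seed=3)
        n_roi = int((labels.grid == 1).sum())
        n_ref = int(ref.sum())
        roi_mean = pet.grid[labels.grid == 1].mean()
        ref_mean = pet.grid[ref].mean()
        suvr = roi_mean / ref_mean
        se = suvr * np.sqrt(sd**2 / (4.0 * n_roi) + sd**2 / (1.0 * n_ref))
        assert abs(suvr - 2.0) < 3.0 * se

    def test_requires_positive_reference(self):
        with pytest.raises(ValueError):
            make_pet_phantom(self._labels(), {1: 1.0}, ref_activity=0.0)


class TestSubregionAtlas:
    def test_labels_partition_the_amygdala(self):
        atlas = make_subregion_atlas(seed=0)
        grid = atlas.labels.grid
        assert set(np.unique(grid)) == {0, 1, 2, 3, 4, 5}
        vols = atlas.subregion_volumes()
        whole = (grid > 0).sum() * atlas.labels.voxel_volume
        assert sum(vols.values()) == pytest.approx(whole)

    def test_lateral_amygdala_is_lateral_most(self):
        atlas = make_subregion_atlas(seed=2)
        grid = atlas.labels.grid
        cent = {
            lab: np.argwhere(grid == lab).mean(axis=0)[0]
            for lab in (1, 2, 3, 4)  # BMA, BLA, CMA, LA
        }
        assert cent[4] > cent[1]  # LA lateral of BMA
        assert cent[4] > cent[3]  # LA lateral of CMA

    def test_cma_is_posterior_most(self):
        atlas = make_subregion_atlas(seed=0)
        grid = atlas.labels.grid
        y = {lab: np.argwhere(grid == lab).mean(axis=0)[1] for lab in (1, 2, 3, 4)}
        assert y[3] == min(y.values())

    def test_seeds_give_distinct_atlases(self):
        a = make_subregion_atlas(seed=0).labels.grid
        b = make_subregion_atlas(seed=5).labels.grid
        assert (a != b).any()


class TestSyntheticCohort:
    def test_single_subject_no_noise_recovers_generative_rate(self):
        cohort, gt = make_synthetic_cohort(
            {"g": {"ERC": 3.0, "AMY": 1.5, "HIPP": 0.5}},
            n_subjects=1,
            seed=0,
            rate_spread=0.0,
            noise_cv=0.0,
            hemispheres=False,
            spacing=(0.5, 0.5, 0.5),  # fine grid: rasterization error negligible
        )
        tab = series_volume_table(cohort[0])
        for name, want in (("ERC", 3.0), ("AMY", 1.5), ("HIPP", 0.5)):
            sub = tab[tab.structure == name]
            rate = fit_atrophy_rate(sub["age"].to_numpy(), sub["volume_mm3"].to_numpy())
            assert -rate.slope_pct == pytest.approx(want, abs=0.2)

    def test_seeding(self):
        a, _ = make_synthetic_cohort({"g": {"ERC": 2.0}}, 2, seed=1, hemispheres=False)
        b, _ = make_synthetic_cohort({"g": {"ERC": 2.0}}, 2, seed=1, hemispheres=False)
        c, _ = make_synthetic_cohort({"g": {"ERC": 2.0}}, 2, seed=2, hemispheres=False)
        np.testing.assert_array_equal(
            a[0].timepoints[0].labels.grid, b[0].timepoints[0].labels.grid
        )
        ga, gc = a[0].timepoints[0].labels.grid, c[0].timepoints[0].labels.grid
        assert ga.shape != gc.shape or (ga != gc).any()

    def test_ground_truth_table_matches_cohort(self):
        cohort, gt = make_synthetic_cohort(
            {"MCI": {"ERC": 4.0, "AMY": 2.2, "HIPP": 0.7}}, 3, seed=0
        )
        assert len(cohort) == 3
        assert set(gt["subject_id"]) == {s.subject_id for s in cohort}
        # both hemispheres present
        assert {"ERC_L", "ERC_R"}.issubset(set(gt["structure"]))


class TestMedialShrinkagePhantom:
    def test_ground_truth_contrast_and_partition(self):
        series, atlas, gt = make_medial_shrinkage_series(
            [70.0, 72.0, 74.0], medial_rate=7.0, lateral_rate=0.3, seed=0
        )
        by = gt.set_index("subregion")["generative_rate_pct_per_yr"]
        assert by[["BMA", "BLA", "CMA"]].mean() > by["LA"]
        # subject series carries only whole structures
        assert series.timepoints[0].labels.label_names[1] == "AMY"

    def test_exact_volume_bookkeeping(self):
        series, atlas, gt = make_medial_shrinkage_series(
            [70.0, 74.0], medial_rate=5.0, lateral_rate=5.0, seed=0, noise_cv=0.0
        )
        # uniform rate: every subregion decays at the same generative rate
        rates = gt["generative_rate_pct_per_yr"]
        assert rates.max() - rates.min() < 1e-6
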
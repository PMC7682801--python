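"""Generator contracts: geometry ground truth, determinism, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomorph.atlas import align
from cardiomorph.mesh import cavity_volume, thickness_map
from cardiomorph.synthetic import (
    CohortConfig,
    ShapeParams,
    cohort_frame,
    make_lv_mesh,
    simulate_cohort,
    slice_to_contours,
)
from cardiomorph.vascular import append_indices
from scipy import stats


class TestMakeLVMesh:
    def test_cavity_volume_matches_analytic_half_ellipsoid(self, canonical_mesh):
        analytic = (2.0 / 3.0) * np.pi * 20.0**2 * 80.0 / 1000.0  # 67.02 mL
        vol = cavity_volume(canonical_mesh)
        assert abs(vol - analytic) / analytic < 0.01

    def test_uniform_offset_gives_uniform_thickness(self, canonical_mesh):
        tm = thickness_map(canonical_mesh)
        assert np.abs(tm.values - 6.0).max() < 0.1

    def test_identical_params_and_seed_are_bitwise_identical(self):
        p = ShapeParams(80, 20, 6, node_noise_sd=0.5)
        m1 = make_lv_mesh(p, grid=(24, 10), rng=42)
        m2 = make_lv_mesh(p, grid=(24, 10), rng=42)
        assert np.array_equal(m1.nodes, m2.nodes)

    def test_node_count_and_ordering_contract(self, canonical_mesh):
        assert canonical_mesh.n_nodes == 2 * 48 * 20
        # basal endo ring comes first, at z = 0
        assert np.allclose(canonical_mesh.nodes[:48, 2], 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length=80, r_endo_base=5, wall_thickness=6),  # t >= r
            dict(length=-10, r_endo_base=20, wall_thickness=6),
            dict(length=80, r_endo_base=20, wall_thickness=0),
        ],
    )
    def test_degenerate_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ShapeParams(**kwargs)

    def test_grid_below_minimum_rejected(self, canonical_params):
        with pytest.raises(ValueError):
            make_lv_mesh(canonical_params, grid=(6, 3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        length=st.floats(50, 110),
        r=st.floats(15, 30),
        t=st.floats(3, 9),
        tilt=st.floats(-8, 8),
    )
    def test_valid_parameters_yield_valid_anatomy(self, length, r, t, tilt):
        """Any parameter draw in the physiologic box gives positive volume
        and a thickness map equal to the generating thickness."""
        p = ShapeParams(length, r, t, tilt_deg=tilt)
        m = make_lv_mesh(p, grid=(16, 8))
        assert cavity_volume(m) > 0
        assert np.all(thickness_map(m).values > 0)
        assert abs(thickness_map(m).mean - t) < 0.05 * t + 0.05


class TestSimulateCohort:
    def test_cohort_is_deterministic(self):
        cfg = CohortConfig(n_per_group=5, seed=9, grid=(16, 6))
        m1, r1 = simulate_cohort(cfg)
        m2, r2 = simulate_cohort(cfg)
        assert all(np.array_equal(a.nodes, b.nodes) for a, b in zip(m1, m2))
        assert cohort_frame(r1).equals(cohort_frame(r2))

    def test_counter_substreams_keep_earlier_subjects_fixed(self):
        small = simulate_cohort(CohortConfig(n_per_group=4, seed=3, grid=(16, 6)))
        large = simulate_cohort(CohortConfig(n_per_group=7, seed=3, grid=(16, 6)))
        # group A subjects 0..3 occupy the same leading positions
        for i in range(4):
            assert np.array_equal(small[0][i].nodes, large[0][i].nodes)

    def test_group_thickness_difference_matches_effect(self):
        cfg = CohortConfig(n_per_group=200, seed=1, grid=(16, 6))
        _, recs = simulate_cohort(cfg)
        fr = cohort_frame(recs)
        diff = (
            fr[fr.group == "hypertensive"].true_wall_thickness.mean()
            - fr[fr.group == "normotensive"].true_wall_thickness.mean()
        )
        se = np.sqrt(2.0 / 200) * cfg.thickness_sd
        assert abs(diff - cfg.thickness_effect) < 3 * se

    def test_group_effect_is_isolated_to_thickness(self):
        """With zero covariate offsets, thickness is the only shape parameter
        whose distribution differs between groups."""
        cfg = CohortConfig(n_per_group=250, seed=2, grid=(16, 6))
        _, recs = simulate_cohort(cfg)
        fr = cohort_frame(recs)
        a = fr[fr.group == "normotensive"]
        b = fr[fr.group == "hypertensive"]
        p_thick = stats.ttest_ind(a.true_wall_thickness, b.true_wall_thickness).pvalue
        assert p_thick < 1e-3
        for col in ("true_length", "true_r_mid", "true_apex_x", "true_apex_y",
                    "true_tilt_deg"):
            assert stats.ttest_ind(a[col], b[col]).pvalue > 0.01

    def test_default_calibration(self):
        """Population means of the generator equal the calibration targets;
        a sampled default cohort lands within a 3-sigma Monte-Carlo band."""
        cfg = CohortConfig()
        # population-level calibration is exact by construction
        assert cfg.thickness_mean == pytest.approx(5.2)
        assert cfg.thickness_mean + cfg.thickness_effect == pytest.approx(5.5)
        assert cfg.compliance_means == (0.258, 0.240)
        assert cfg.cap_functional_means["NTN"] == pytest.approx(115.2)
        w = cfg.subgroup_props
        mixed = sum(w[k] * cfg.cap_functional_means[k] for k in w)
        assert abs(mixed - 105.4) < 1.5  # prevalence-weighted exposed mean

        meshes, recs = simulate_cohort(CohortConfig(seed=0))
        fr = append_indices(cohort_frame(recs))
        fr["mean_wall_thickness"] = [thickness_map(align(m)).mean for m in meshes]
        n = 70
        targets = {
            "mean_wall_thickness": (5.2, 5.5, cfg.thickness_sd),
            "functional_capillary_density": (115.2, 105.4, 21.0),
            "global_compliance": (0.258, 0.240, cfg.compliance_between_sd),
        }
        for col, (m_ntn, m_htn, sd) in targets.items():
            band = 3 * sd / np.sqrt(n)
            got_ntn = fr[fr.group == "normotensive"][col].mean()
            got_htn = fr[fr.group == "hypertensive"][col].mean()
            # node noise adds ~+0.05 mm to measured (not generative) thickness
            slack = 0.06 if col == "mean_wall_thickness" else 0.0
            assert abs(got_ntn - m_ntn) < band + slack, col
            assert abs(got_htn - m_htn) < band + slack, col

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=1)
        with pytest.raises(ValueError):
            CohortConfig(sbp_thickness_corr=1.5)
        with pytest.raises(ValueError):
            CohortConfig(thickness_sd=-1)


class TestSliceToContours:
    def test_slice_count_at_1cm_spacing(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        assert len(stack.slices) == 8  # floor(80 / 10) intersecting planes
        assert stack.slices[0].z == pytest.approx(0.0)

    def test_contours_are_counter_clockwise_and_closed(self, canonical_mesh):
        from cardiomorph.mesh import _shoelace_area

        stack = slice_to_contours(canonical_mesh, 10.0)
        for sl in stack.slices:
            assert _shoelace_area(sl.endo) > 0  # CCW viewed from base (+z)
            assert _shoelace_area(sl.epi) > _shoelace_area(sl.endo)

    def test_spacing_larger_than_ventricle_errors(self, canonical_mesh):
        with pytest.raises(ValueError):
            slice_to_contours(canonical_mesh, 100.0)

    def test_rv_landmark_copied_through(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        assert np.allclose(stack.rv_centroid, canonical_mesh.rv_centroid)
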
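"""Alignment and PCA atlas: invariances, recovery, score contracts."""

import numpy as np
import pytest

from cardiomorph.atlas import DegenerateAtlasError, ShapeModel, align, build_atlas
from cardiomorph.mesh import thickness_map
from cardiomorph.synthetic import (
    CohortConfig,
    ShapeParams,
    cohort_frame,
    make_lv_mesh,
    simulate_cohort,
)

from conftest import random_rigid_transform


def small_cohort(n=12, seed=0, grid=(16, 8)):
    meshes, recs = simulate_cohort(
        CohortConfig(n_per_group=n // 2, seed=seed, grid=grid)
    )
    return meshes, cohort_frame(recs)


class TestAlign:
    def test_invariant_to_rigid_pretransform(self, canonical_mesh, rng):
        q, t = random_rigid_transform(rng)
        a1 = align(canonical_mesh)
        a2 = align(canonical_mesh.transformed(q, t))
        assert np.abs(a1.nodes - a2.nodes).max() < 1e-8

    def test_idempotent(self, canonical_mesh):
        once = align(canonical_mesh)
        twice = align(once)
        assert np.abs(once.nodes - twice.nodes).max() < 1e-10

    def test_no_size_normalisation(self, canonical_mesh):
        scaled = canonical_mesh.with_nodes(canonical_mesh.nodes * 1.2)
        scaled.rv_centroid = canonical_mesh.rv_centroid * 1.2
        a = align(canonical_mesh)
        a_scaled = align(scaled)
        assert np.abs(a_scaled.nodes - 1.2 * a.nodes).max() < 1e-8

    def test_canonical_frame_properties(self, canonical_mesh, rng):
        q, t = random_rigid_transform(rng)
        a = align(canonical_mesh.transformed(q, t))
        assert np.abs(a.nodes.mean(axis=0)).max() < 1e-9  # centroid at origin
        basal = np.concatenate([a.endo[0], a.epi[0]])
        assert np.ptp(basal[:, 2]) < 1e-8  # basal plane normal to z
        assert a.rv_centroid[0] > 0  # RV direction along +x
        assert abs(a.rv_centroid[1]) < 1e-8

    def test_degenerate_rv_direction_errors(self, canonical_mesh):
        bad = align(canonical_mesh)
        bad.rv_centroid = np.array([0.0, 0.0, 50.0]) + bad.nodes.mean(axis=0)
        with pytest.raises(ValueError, match="degenerate|parallel"):
            align(bad)


class TestBuildAtlas:
    def test_rank_one_cohort(self, rng):
        base = align(make_lv_mesh(ShapeParams(80, 20, 6), grid=(16, 8)))
        v = rng.standard_normal(base.n_nodes * 3)
        v /= np.linalg.norm(v)
        shapes = [base.as_vector() + s * v for s in (-1.0, 0.0, 1.0)]
        atlas = build_atlas(shapes)
        assert atlas.n_modes == 1
        assert atlas.explained_variance(1) == pytest.approx(1.0)

    def test_identical_meshes_are_degenerate(self, canonical_mesh):
        atlas = build_atlas([canonical_mesh.as_vector()] * 5)
        assert atlas.degenerate
        with pytest.raises(DegenerateAtlasError):
            atlas.explained_variance(1)
        with pytest.raises(DegenerateAtlasError):
            atlas.project(canonical_mesh.as_vector())

    def test_six_generative_parameters_dominate(self):
        """Independent variation on the six shape parameters produces six
        eigenvalues far above the node-noise floor."""
        meshes, _ = small_cohort(n=120, seed=4, grid=(16, 8))
        atlas = build_atlas(meshes, prealigned=False)
        lam = atlas.eigenvalues
        # a clear spectral gap: mode 7 sits at the node-noise floor, three
        # orders of magnitude below mode 1 and well below mode 6
        assert lam[6] / lam[0] < 5e-3
        assert lam[5] / lam[6] > 10

    def test_full_rank_reconstruction(self):
        meshes, _ = small_cohort(n=10, seed=5)
        atlas = build_atlas(meshes, prealigned=False)
        X = atlas.model.X
        rec = atlas.reconstruct(atlas.scores_sd)
        assert np.abs(rec - X).max() / np.abs(X).max() < 1e-8

    def test_score_and_mode_contracts(self):
        meshes, _ = small_cohort(n=14, seed=6)
        atlas = build_atlas(meshes, prealigned=False)
        s = atlas.scores_sd
        assert np.abs(s.mean(axis=0)).max() < 1e-10
        assert np.abs(s.std(axis=0, ddof=1) - 1.0).max() < 1e-10
        gram = atlas.modes @ atlas.modes.T
        assert np.abs(gram - np.eye(atlas.n_modes)).max() < 1e-10
        assert atlas.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        f = atlas.explained_fraction
        assert np.all(np.diff(f) <= 1e-15)  # sorted descending

    def test_subject_permutation_invariance(self):
        meshes, _ = small_cohort(n=10, seed=7)
        a1 = build_atlas(meshes, prealigned=False)
        perm = [3, 1, 4, 0, 9, 2, 8, 5, 7, 6]
        a2 = build_atlas([meshes[i] for i in perm], prealigned=False)
        assert np.allclose(a1.mean_shape, a2.mean_shape)
        assert np.allclose(a1.eigenvalues, a2.eigenvalues)
        assert np.allclose(a1.scores_sd[perm], a2.scores_sd, atol=1e-8)

    def test_cohort_level_rigid_invariance(self, rng):
        meshes, _ = small_cohort(n=10, seed=8)
        q, t = random_rigid_transform(rng)
        moved = [m.transformed(q, t) for m in meshes]
        a1 = build_atlas(meshes, prealigned=False)
        a2 = build_atlas(moved, prealigned=False)
        assert np.allclose(a1.eigenvalues, a2.eigenvalues, rtol=1e-8)

    def test_mismatched_grids_error(self):
        m1 = make_lv_mesh(ShapeParams(80, 20, 6), grid=(16, 8))
        m2 = make_lv_mesh(ShapeParams(80, 20, 6), grid=(24, 8))
        with pytest.raises(ValueError, match="correspond"):
            build_atlas([m1, m2, m1])

    def test_sign_convention_thickness_increase(self):
        meshes, _ = small_cohort(n=20, seed=9)
        atlas = build_atlas(meshes, prealigned=False)
        base = thickness_map(atlas.mean_mesh()).mean
        for i in range(1, atlas.n_modes + 1):
            plus = thickness_map(atlas.shape_at(i, 1.0)).mean
            assert plus - base > -1e-9


@pytest.fixture(scope="module")
def fitted_atlas():
    meshes, _ = small_cohort(n=16, seed=10)
    return build_atlas(meshes, prealigned=False)


class TestProjectAndSynthesis:
    @pytest.fixture()
    def atlas(self, fitted_atlas):
        return fitted_atlas

    def test_mean_projects_to_zero(self, atlas):
        assert np.abs(atlas.project(atlas.mean_shape)).max() < 1e-10

    def test_training_subject_roundtrip(self, atlas):
        x = atlas.model.X[3]
        assert np.abs(atlas.project(x) - atlas.scores_sd[3]).max() < 1e-9

    def test_synthetic_offset_projects_to_unit_vector(self, atlas):
        x = atlas.mean_shape + 2.0 * np.sqrt(atlas.eigenvalues[2]) * atlas.modes[2]
        s = atlas.project(x)
        expected = np.zeros(atlas.n_modes)
        expected[2] = 2.0
        assert np.abs(s - expected).max() < 1e-8

    def test_shape_at_zero_is_mean(self, atlas):
        assert np.array_equal(
            atlas.shape_at(1, 0.0).as_vector(), atlas.mean_shape
        )

    def test_shape_at_linearity(self, atlas):
        plus = atlas.shape_at(2, 3.0).as_vector()
        minus = atlas.shape_at(2, -3.0).as_vector()
        assert np.abs((plus + minus) / 2 - atlas.mean_shape).max() < 1e-9

    def test_mode_out_of_range_errors(self, atlas):
        with pytest.raises(ValueError):
            atlas.shape_at(0, 1.0)
        with pytest.raises(ValueError):
            atlas.explained_variance(atlas.n_modes + 1)


class TestParameterRecovery:
    def test_single_latent_factor_recovered(self):
        """In a cohort where only wall thickness varies, mode 1 tracks the
        latent thickness almost perfectly."""
        cfg = CohortConfig(
            n_per_group=75,
            seed=11,
            grid=(16, 8),
            thickness_effect=0.0,
            length_sd=0.0,
            r_mid_sd=0.0,
            apex_offset_sd=0.0,
            tilt_sd_deg=0.0,
            com_offset_sd=0.0,
            node_noise_sd=0.3,
        )
        meshes, recs = simulate_cohort(cfg)
        frame = cohort_frame(recs)
        atlas = build_atlas(meshes, prealigned=False)
        r = np.corrcoef(atlas.scores_sd[:, 0], frame["true_wall_thickness"])[0, 1]
        assert abs(r) > 0.95

    def test_thickness_mode_moves_thickness_not_length(self):
        """+3 SD along the thickness-linked mode raises the mean wall
        thickness by about 3 generator SDs and leaves length unchanged."""
        cfg = CohortConfig(
            n_per_group=75, seed=12, grid=(16, 8),
            thickness_effect=0.0, length_sd=0.0, r_mid_sd=0.0,
            apex_offset_sd=0.0, tilt_sd_deg=0.0, com_offset_sd=0.0,
            node_noise_sd=0.1,
        )
        meshes, _ = simulate_cohort(cfg)
        atlas = build_atlas(meshes, prealigned=False)
        base = atlas.mean_mesh()
        plus = atlas.shape_at(1, 3.0)
        d_thick = thickness_map(plus).mean - thickness_map(base).mean
        assert d_thick == pytest.approx(3.0 * cfg.thickness_sd, rel=0.15)
        length = lambda m: m.endo[:, :, 2].min() - m.endo[:, :, 2].max()
        assert abs(length(plus) - length(base)) < 1.0
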
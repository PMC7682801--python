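"""Mesh measurements and contour-stack reconstruction."""

import numpy as np
import pytest

from cardiomorph.mesh import (
    ContourStack,
    LVMesh,
    SliceContours,
    cavity_volume,
    myocardial_mass,
    reconstruct_mesh,
    thickness_map,
)
from cardiomorph.synthetic import ShapeParams, make_lv_mesh, slice_to_contours
from cardiomorph.vascular import bsa_and_index

from conftest import random_rigid_transform


def offset_shell_volume_quadrature(a, c, t, n_u=4000, n_tau=400):
    """Numeric-integration oracle for the half-ellipsoid offset-shell volume.

    The shell between the endocardial half-ellipsoid (semi-axes a, a, c) and
    its outward normal offset by t is a solid of revolution; its volume is
    integrated in meridian coordinates (u along the ellipse arc, tau along
    the normal) with the exact 2-D Jacobian, independent of any mesh.
    """
    u = np.linspace(0.0, np.pi / 2, n_u)  # 0 = apex, pi/2 = base
    tau = np.linspace(0.0, t, n_tau)
    uu, tt = np.meshgrid(u, tau, indexing="ij")

    def point(uu, tt):
        rho0 = a * np.sin(uu)
        z0 = -c * np.cos(uu)
        nr = np.sin(uu) / a
        nz = -np.cos(uu) / c
        nn = np.hypot(nr, nz)
        return rho0 + tt * nr / nn, z0 + tt * nz / nn

    rho, z = point(uu, tt)
    du = u[1] - u[0]
    dtau = tau[1] - tau[0]
    drho_du, drho_dt = np.gradient(rho, du, dtau)
    dz_du, dz_dt = np.gradient(z, du, dtau)
    jac = np.abs(drho_du * dz_dt - drho_dt * dz_du)
    integrand = 2.0 * np.pi * rho * jac
    return np.trapezoid(np.trapezoid(integrand, dx=dtau, axis=1), dx=du) / 1000.0


class TestMeasurements:
    def test_volume_mass_thickness_rigid_invariance(self, canonical_mesh, rng):
        q, t = random_rigid_transform(rng)
        moved = canonical_mesh.transformed(q, t)
        assert cavity_volume(moved) == pytest.approx(
            cavity_volume(canonical_mesh), rel=1e-9
        )
        assert myocardial_mass(moved) == pytest.approx(
            myocardial_mass(canonical_mesh), rel=1e-9
        )
        assert np.allclose(
            thickness_map(moved).values, thickness_map(canonical_mesh).values
        )

    def test_thickness_scales_with_coordinates(self, canonical_mesh):
        doubled = canonical_mesh.with_nodes(canonical_mesh.nodes * 2.0)
        assert thickness_map(doubled).mean == pytest.approx(
            2.0 * thickness_map(canonical_mesh).mean
        )

    def test_flat_mesh_has_zero_volume(self, canonical_mesh):
        flat_nodes = canonical_mesh.nodes.copy()
        flat_nodes[:, 2] = 0.0
        assert cavity_volume(canonical_mesh.with_nodes(flat_nodes)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_resolution_convergence(self, canonical_params):
        coarse = cavity_volume(make_lv_mesh(canonical_params, grid=(48, 20)))
        fine = cavity_volume(make_lv_mesh(canonical_params, grid=(96, 40)))
        assert abs(fine - coarse) / coarse < 0.005

    def test_mass_matches_quadrature_oracle(self, canonical_mesh):
        oracle_ml = offset_shell_volume_quadrature(20.0, 80.0, 6.0)
        mass = myocardial_mass(canonical_mesh)
        assert abs(mass - 1.05 * oracle_ml) / (1.05 * oracle_ml) < 0.02

    def test_zero_density_gives_zero_mass(self, canonical_mesh):
        assert myocardial_mass(canonical_mesh, density=0.0) == 0.0

    def test_crossed_surfaces_error(self, canonical_mesh):
        swapped = np.concatenate(
            [canonical_mesh.epi.reshape(-1, 3), canonical_mesh.endo.reshape(-1, 3)]
        )
        with pytest.raises(ValueError, match="cross"):
            myocardial_mass(canonical_mesh.with_nodes(swapped))

    def test_bsa_indexing(self):
        indexed, bsa = bsa_and_index(90.3, height_cm=170, weight_kg=70)
        assert bsa == pytest.approx(1.810, abs=0.002)
        assert 90.3 / 1.81 == pytest.approx(49.89, abs=0.01)
        # linearity in the indexed value
        indexed2, _ = bsa_and_index(180.6, 170, 70)
        assert indexed2 == pytest.approx(2 * indexed)


class TestReconstruction:
    def test_roundtrip_recovers_nodes(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        rec = reconstruct_mesh(stack, (48, 20))
        err = np.linalg.norm(rec.nodes - canonical_mesh.nodes, axis=1)
        assert np.sqrt((err**2).mean()) < 0.5

    def test_translation_equivariance(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        baseline = reconstruct_mesh(stack, (24, 10))
        shifted = ContourStack(
            slices=[
                SliceContours(
                    z=s.z, endo=s.endo + [10.0, 0.0], epi=s.epi + [10.0, 0.0]
                )
                for s in stack.slices
            ],
            rv_centroid=stack.rv_centroid + [10.0, 0.0, 0.0],
            basal_plane_z=stack.basal_plane_z,
        )
        rec = reconstruct_mesh(shifted, (24, 10))
        assert np.abs(rec.nodes - (baseline.nodes + [10.0, 0.0, 0.0])).max() < 1e-6

    def test_too_few_slices_error(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        truncated = ContourStack(
            slices=stack.slices[:3],
            rv_centroid=stack.rv_centroid,
            basal_plane_z=stack.basal_plane_z,
        )
        with pytest.raises(ValueError, match="4"):
            reconstruct_mesh(truncated, (24, 10))

    def test_crossing_contour_rejected(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        bowtie = stack.slices[2].endo.copy()
        # swap two opposite points to create a macroscopic self-intersection
        n = len(bowtie)
        bowtie[[0, n // 2]] = bowtie[[n // 2, 0]]
        bad = ContourStack(
            slices=[
                SliceContours(z=s.z, endo=(bowtie if i == 2 else s.endo), epi=s.epi)
                for i, s in enumerate(stack.slices)
            ],
            rv_centroid=stack.rv_centroid,
            basal_plane_z=stack.basal_plane_z,
        )
        with pytest.raises(ValueError, match="self-intersecting|enclose"):
            reconstruct_mesh(bad, (24, 10))

    def test_finer_slicing_reduces_error(self, canonical_params):
        """Reconstruction contracts toward the true surface as slice spacing
        shrinks (5 mm beats 20 mm)."""
        mesh = make_lv_mesh(canonical_params, grid=(32, 16))

        def rms(spacing):
            rec = reconstruct_mesh(slice_to_contours(mesh, spacing), (32, 16))
            e = np.linalg.norm(rec.nodes - mesh.nodes, axis=1)
            return np.sqrt((e**2).mean())

        assert rms(5.0) < rms(20.0)

    def test_thickness_preserved_through_roundtrip(self, canonical_mesh):
        stack = slice_to_contours(canonical_mesh, 10.0)
        rec = reconstruct_mesh(stack, (48, 20))
        assert thickness_map(rec).mean == pytest.approx(6.0, abs=0.15)
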
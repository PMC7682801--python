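"""Left-ventricular mesh data model, contour reconstruction and measurements.

The unit of shape analysis is :class:`LVMesh`: an endocardial and an
epicardial surface sampled on a fixed ``(surface, longitudinal level,
circumferential index)`` grid.  Because every mesh in a cohort shares the
same grid and node ordering, node ``k`` refers to the same anatomical
location in every subject — this ordering *is* the point correspondence
required for coordinate-based PCA.

Measurements follow cardiac MR conventions: cavity volume from the closed
(basal-capped) endocardial surface via the divergence theorem, myocardial
mass as the shell volume between epicardium and endocardium times muscle
density, and wall thickness as the distance between paired endo/epi nodes.

Units are mm for coordinates, mL for volumes and g for masses throughout.
The frame is right-handed with the base toward +z and the apex at negative z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from shapely.geometry import Polygon

__all__ = [
    "LVMesh",
    "SliceContours",
    "ContourStack",
    "ThicknessMap",
    "reconstruct_mesh",
    "thickness_map",
    "cavity_volume",
    "myocardial_mass",
    "MYOCARDIAL_DENSITY_G_PER_ML",
]

#: Conventional myocardial tissue density used to convert shell volume to mass.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

ENDO, EPI = 0, 1


@dataclass
class LVMesh:
    """Corresponded two-surface LV mesh.

    Parameters
    ----------
    nodes : (N, 3) float array, mm
        ``N = 2 * n_long * n_circ``.  Node ``s * n_long * n_circ + l * n_circ
        + c`` is surface ``s`` (0 endo, 1 epi), longitudinal level ``l``
        (0 = base), circumferential index ``c`` (counter-clockwise viewed
        from the base).
    n_circ, n_long : int
        Grid dimensions.
    rv_centroid : (3,) float array, mm
        Right-ventricular blood-pool centroid; the only RV information used,
        as the left-to-right orientation landmark for alignment.
    """

    nodes: np.ndarray
    n_circ: int
    n_long: int
    rv_centroid: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.rv_centroid = np.asarray(self.rv_centroid, dtype=float)
        expected = 2 * self.n_circ * self.n_long
        if self.nodes.shape != (expected, 3):
            raise ValueError(
                f"node array has shape {self.nodes.shape}, expected ({expected}, 3) "
                f"for grid ({self.n_circ}, {self.n_long})"
            )
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("mesh contains non-finite node coordinates")

    # -- grid views --------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def surface(self, which: int) -> np.ndarray:
        """Nodes of one surface as an (n_long, n_circ, 3) array (a view)."""
        per = self.n_long * self.n_circ
        return self.nodes[which * per : (which + 1) * per].reshape(
            self.n_long, self.n_circ, 3
        )

    @property
    def endo(self) -> np.ndarray:
        return self.surface(ENDO)

    @property
    def epi(self) -> np.ndarray:
        return self.surface(EPI)

    @property
    def surface_labels(self) -> np.ndarray:
        per = self.n_long * self.n_circ
        return np.repeat([ENDO, EPI], per)

    def as_vector(self) -> np.ndarray:
        """Flatten to a 3N shape vector (fixed cohort-wide ordering)."""
        return self.nodes.reshape(-1).copy()

    def with_nodes(self, nodes: np.ndarray) -> "LVMesh":
        return replace(self, nodes=np.asarray(nodes, dtype=float))

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, n_circ: int, n_long: int, rv_centroid=None
    ) -> "LVMesh":
        vec = np.asarray(vec, dtype=float)
        nodes = vec.reshape(-1, 3)
        if rv_centroid is None:
            rv_centroid = np.zeros(3)
        return cls(nodes=nodes, n_circ=n_circ, n_long=n_long, rv_centroid=rv_centroid)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LVMesh":
        """Apply a rigid transform ``x -> R x + t`` to nodes and landmark."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return replace(
            self,
            nodes=self.nodes @ rotation.T + translation,
            rv_centroid=rotation @ self.rv_centroid + translation,
        )


def _shoelace_area(pts: np.ndarray) -> float:
    """Signed area of a closed 2-D polygon (shoelace formula)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


@dataclass
class SliceContours:
    """Closed endo/epi contours of one short-axis plane."""

    z: float
    endo: np.ndarray  # (n_points, 2) mm
    epi: np.ndarray  # (n_points, 2) mm

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        if self.endo.shape != self.epi.shape or self.endo.ndim != 2:
            raise ValueError("endo and epi contours must share a (n, 2) shape")


@dataclass
class ContourStack:
    """Stack of short-axis contours ordered base -> apex (decreasing z)."""

    slices: list[SliceContours]
    rv_centroid: np.ndarray
    basal_plane_z: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rv_centroid = np.asarray(self.rv_centroid, dtype=float)
        if self.basal_plane_z is None:
            self.basal_plane_z = float(self.slices[0].z) if self.slices else 0.0
        zs = [s.z for s in self.slices]
        if any(b >= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slices must be strictly ordered base->apex (decreasing z)")

    def validate(self) -> None:
        """Check closure, simplicity and epi-encloses-endo on every slice."""
        if len(self.slices) < 4:
            raise ValueError(
                f"need at least 4 contoured slices, got {len(self.slices)}"
            )
        zs = np.array([s.z for s in self.slices])
        if not np.all(np.diff(zs) < 0):
            raise ValueError("slice planes must strictly decrease in z (base->apex)")
        for i, sl in enumerate(self.slices):
            polys = {}
            for name, pts in (("endo", sl.endo), ("epi", sl.epi)):
                poly = Polygon(pts)
                if not poly.is_valid or not poly.is_simple:
                    # tolerate microscopic self-intersection slivers from
                    # contouring jitter, but reject macroscopic defects
                    # (bow-ties, open loops): for those the shoelace signed
                    # area disagrees with the repaired polygon area
                    signed = _shoelace_area(pts)
                    repaired = poly.buffer(0)
                    if (
                        repaired.is_empty
                        or repaired.area <= 0
                        or abs(abs(signed) - repaired.area) > 0.02 * repaired.area
                    ):
                        raise ValueError(
                            f"{name} contour on slice {i} (z={sl.z:g}) is open "
                            "or self-intersecting"
                        )
                    poly = repaired
                polys[name] = poly
            if not polys["epi"].buffer(1e-6).contains(polys["endo"]):
                raise ValueError(
                    f"epi contour does not enclose endo contour on slice {i}"
                )


@dataclass
class ThicknessMap:
    """Wall thickness (mm) per (longitudinal, circumferential) node pair."""

    values: np.ndarray  # (n_long, n_circ)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def thickness_map(mesh: LVMesh) -> ThicknessMap:
    """Paired-node wall thickness.

    Thickness at grid position (l, c) is the Euclidean distance between the
    endocardial and epicardial node sharing that position.  This is exact on
    meshes whose epicardium was built as a normal offset of the endocardium
    and a stated approximation for oblique walls.
    """
    d = np.linalg.norm(mesh.epi - mesh.endo, axis=-1)
    return ThicknessMap(values=d)


def _closed_surface_volume(surface: np.ndarray) -> float:
    """Signed enclosed volume (mm^3) of a grid surface plus planar basal cap.

    ``surface`` is (n_long, n_circ, 3) with level 0 the basal ring.  The
    lateral wall is triangulated from the grid; the base is capped by a fan
    around the basal-ring centroid.  Divergence-theorem sum over triangles;
    the result is orientation-signed, positive for the construction used by
    :func:`cavity_volume` on valid anatomy.
    """
    L, C, _ = surface.shape
    tris = []
    a = surface[:-1]  # (L-1, C, 3)
    b = np.roll(surface[:-1], -1, axis=1)
    c = surface[1:]
    d = np.roll(surface[1:], -1, axis=1)
    # two triangles per quad, wound so normals point outward (away from the
    # long axis); the basal cap fan winds counter-clockwise so its normal is
    # +z (outward at the base) — consistent orientation makes the divergence
    # sum translation- and rotation-invariant
    tris.append(np.stack([a, c, b], axis=-2).reshape(-1, 3, 3))
    tris.append(np.stack([b, c, d], axis=-2).reshape(-1, 3, 3))
    ring = surface[0]
    centroid = ring.mean(axis=0)
    cap = np.stack(
        [np.broadcast_to(centroid, ring.shape), ring, np.roll(ring, -1, axis=0)],
        axis=-2,
    )
    tris.append(cap)
    t = np.concatenate(tris, axis=0)
    v = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    return float(v)


def cavity_volume(mesh: LVMesh) -> float:
    """LV cavity volume in mL from the closed endocardial surface.

    The endocardial surface is closed by a planar lid across the basal ring
    and the signed volume computed by the divergence theorem.  Rigid
    transforms leave the result unchanged.
    """
    vol_mm3 = abs(_closed_surface_volume(mesh.endo))
    return vol_mm3 / 1000.0


def myocardial_mass(
    mesh: LVMesh, density: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> float:
    """Myocardial mass in g: (epi enclosed volume − endo enclosed volume) × ρ.

    Both surfaces are closed with planar basal caps.  Raises if the surfaces
    cross (negative shell volume beyond numerical tolerance).
    """
    epi_vol = abs(_closed_surface_volume(mesh.epi))
    endo_vol = abs(_closed_surface_volume(mesh.endo))
    shell_ml = (epi_vol - endo_vol) / 1000.0
    if shell_ml < -1e-9:
        raise ValueError(
            f"epicardial volume ({epi_vol / 1000.0:.2f} mL) smaller than "
            f"endocardial volume ({endo_vol / 1000.0:.2f} mL): surfaces cross"
        )
    return max(shell_ml, 0.0) * density


# ---------------------------------------------------------------------------
# reconstruction from contours
# ---------------------------------------------------------------------------

def _contour_radius_resample(
    points: np.ndarray, centroid: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    """Radii of a star-shaped contour about ``centroid`` at given angles."""
    rel = points - centroid
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    r = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # periodic linear interpolation
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.tile(r, 3)
    return np.interp(np.mod(angles, 2 * np.pi), theta_ext, r_ext)


def _extrapolate_apex_z(zs: np.ndarray, mean_r2: np.ndarray) -> float:
    """Apex z by root of a least-squares quadratic of mean squared radius.

    For an ellipsoidal surface r^2(z) is exactly quadratic, so the root is
    exact; for general anatomy it is a smooth extrapolated closure.
    """
    k = min(len(zs), 4)
    z, y = zs[-k:], mean_r2[-k:]
    if k == 2 or np.ptp(z) == 0:
        coeffs = np.polyfit(z, y, 1)
    else:
        coeffs = np.polyfit(z, y, 2)
    roots = np.roots(coeffs)
    roots = roots[np.isreal(roots)].real
    below = roots[roots < zs[-1]]
    if below.size == 0:
        # fall back: linear extension of the last-slice trend
        slope = (y[-1] - y[-2]) / (z[-1] - z[-2])
        if slope <= 0:
            return float(zs[-1] - abs(zs[-1] - zs[0]) / max(len(zs) - 1, 1))
        return float(zs[-1] - y[-1] / slope)
    return float(below.max())


class _SurfaceInterpolant:
    """Smooth r(theta, z) surface from resampled slice contours.

    Radii are interpolated in r^2 along z with a not-a-knot cubic spline per
    circumferential angle (exact for ellipsoidal surfaces) and linearly
    across angles; slice centroids are interpolated linearly in z and held
    constant beyond the last slice.  The apex closure point (r = 0 at the
    extrapolated apex z) is included as a spline knot.
    """

    def __init__(self, zs, radii, centroids, angles):
        self.angles = angles  # (C,)
        self.z_apex = _extrapolate_apex_z(zs, (radii**2).mean(axis=1))
        knots_z = np.concatenate([zs, [self.z_apex]])
        vals = np.vstack([radii**2, np.zeros((1, radii.shape[1]))])
        # spline wants increasing x
        self.spline = CubicSpline(knots_z[::-1], vals[::-1], axis=0)
        self.z_base = float(zs[0])
        self.zs = zs
        self.centroids = centroids  # (n_slices, 2)

    def centroid_at(self, z: float) -> np.ndarray:
        z = np.clip(z, self.zs[-1], self.zs[0])
        cx = np.interp(-z, -self.zs, self.centroids[:, 0])
        cy = np.interp(-z, -self.zs, self.centroids[:, 1])
        return np.array([cx, cy])

    def radius_at(self, theta, z) -> np.ndarray:
        z = np.clip(z, self.z_apex, self.z_base)
        r2 = np.maximum(self.spline(z), 0.0)  # (C,) radii^2 at all grid angles
        ang = np.mod(np.atleast_1d(theta), 2 * np.pi)
        a_ext = np.concatenate(
            [self.angles - 2 * np.pi, self.angles, self.angles + 2 * np.pi]
        )
        r2_ext = np.tile(r2, 3)
        return np.sqrt(np.interp(ang, a_ext, r2_ext))

    def grid_points(self, z_levels: np.ndarray) -> np.ndarray:
        """(L, C, 3) surface samples at given z levels and the grid angles."""
        out = np.empty((len(z_levels), len(self.angles), 3))
        for i, z in enumerate(z_levels):
            r = np.sqrt(np.maximum(self.spline(z), 0.0))
            cen = self.centroid_at(z)
            out[i, :, 0] = cen[0] + r * np.cos(self.angles)
            out[i, :, 1] = cen[1] + r * np.sin(self.angles)
            out[i, :, 2] = z
        return out


def _grid_normals(surface: np.ndarray) -> np.ndarray:
    """Outward unit normals of an (L, C, 3) grid surface via grid tangents."""
    L, C, _ = surface.shape
    du = np.gradient(surface, axis=0)  # along longitude (base->apex)
    dv = (np.roll(surface, -1, axis=1) - np.roll(surface, 1, axis=1)) / 2.0
    n = np.cross(dv, du)
    norms = np.linalg.norm(n, axis=-1, keepdims=True)
    # degenerate (apex) rows: use mean of last valid row, falling back to -z
    bad = norms[..., 0] < 1e-12
    n = np.where(bad[..., None], np.array([0.0, 0.0, -1.0]), n / np.maximum(norms, 1e-12))
    # orient outward: positive dot with vector from ring centroid
    centroids = surface.mean(axis=1, keepdims=True)
    outward = surface - centroids
    flip = np.einsum("lcx,lcx->lc", n, outward) < 0
    apex_rows = np.all(bad, axis=1)
    n[flip & ~apex_rows[:, None]] *= -1.0
    return n


def reconstruct_mesh(stack: ContourStack, grid: tuple[int, int]) -> LVMesh:
    """Build a corresponded :class:`LVMesh` from a short-axis contour stack.

    Procedure
    ---------
    1. Every contour is resampled to ``n_circ`` points at equally spaced
       polar angles about its own centroid, with angle 0 pointing from the
       centroid toward the basal-plane projection of the RV centroid — the
       angular datum that makes circumferential indices correspond across
       subjects.
    2. Endocardial nodes are placed at ``n_long`` z levels equally spaced
       from the basal plane to the extrapolated endocardial apex, using a
       cubic-spline surface through the slices (interpolated in squared
       radius, which is exact for ellipsoidal anatomy).
    3. Each epicardial node is found by casting a ray from its paired
       endocardial node along the local endocardial outward normal onto the
       spline epicardial surface, so paired nodes measure wall thickness.
    """
    n_circ, n_long = grid
    stack.validate()
    zs = np.array([s.z for s in stack.slices])

    rv_xy = stack.rv_centroid[:2]

    surfs = {}
    for name in ("endo", "epi"):
        radii = np.empty((len(zs), n_circ))
        centroids = np.empty((len(zs), 2))
        datum_angles = np.empty(len(zs))
        for i, sl in enumerate(stack.slices):
            pts = getattr(sl, name)
            cen = pts.mean(axis=0)
            centroids[i] = cen
            datum = rv_xy - cen
            datum_angles[i] = np.arctan2(datum[1], datum[0])
        # common angular datum from the basal slice keeps columns straight
        base_angle = datum_angles[0]
        angles = np.mod(base_angle + 2 * np.pi * np.arange(n_circ) / n_circ, 2 * np.pi)
        for i, sl in enumerate(stack.slices):
            pts = getattr(sl, name)
            radii[i] = _contour_radius_resample(pts, centroids[i], angles)
        surfs[name] = _SurfaceInterpolant(zs, radii, centroids, angles)

    endo_interp, epi_interp = surfs["endo"], surfs["epi"]
    z0 = float(stack.basal_plane_z)
    z_levels = np.linspace(z0, endo_interp.z_apex, n_long)
    endo_nodes = endo_interp.grid_points(z_levels)

    normals = _grid_normals(endo_nodes)
    # apex row: straight down
    normals[-1] = np.array([0.0, 0.0, -1.0])

    epi_nodes = np.empty_like(endo_nodes)
    t_guess = max(epi_interp.radius_at(endo_interp.angles[0], z0)[0]
                  - endo_interp.radius_at(endo_interp.angles[0], z0)[0], 1.0)

    def epi_residual(tau: float, p: np.ndarray, n: np.ndarray) -> float:
        q = p + tau * n
        cen = epi_interp.centroid_at(q[2])
        rel = q[:2] - cen
        rho = float(np.hypot(rel[0], rel[1]))
        theta = float(np.arctan2(rel[1], rel[0]))
        return rho - float(epi_interp.radius_at(theta, q[2])[0])

    for l in range(n_long):
        for c in range(n_circ):
            p = endo_nodes[l, c]
            n = normals[l, c]
            if l == n_long - 1:
                # apex: epi point straight below at the epi apex closure
                cen = epi_interp.centroid_at(epi_interp.z_apex)
                epi_nodes[l, c] = np.array([cen[0], cen[1], epi_interp.z_apex])
                continue
            lo, hi = 1e-6, 4.0 * t_guess
            flo, fhi = epi_residual(lo, p, n), epi_residual(hi, p, n)
            tries = 0
            while flo * fhi > 0 and tries < 6:
                hi *= 2.0
                fhi = epi_residual(hi, p, n)
                tries += 1
            if flo * fhi > 0:
                raise ValueError(
                    "could not bracket the epicardial surface along the "
                    f"endocardial normal at grid ({l}, {c})"
                )
            tau = brentq(epi_residual, lo, hi, args=(p, n), xtol=1e-10)
            epi_nodes[l, c] = p + tau * n

    nodes = np.concatenate(
        [endo_nodes.reshape(-1, 3), epi_nodes.reshape(-1, 3)], axis=0
    )
    return LVMesh(
        nodes=nodes, n_circ=n_circ, n_long=n_long, rv_centroid=stack.rv_centroid
    )
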
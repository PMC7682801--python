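"""Rigid cohort alignment and the PCA statistical shape atlas.

The atlas is the field's standard point-distribution model: corresponded
meshes are rigidly aligned, stacked as shape vectors x_j (concatenated node
coordinates, mm), and the sample covariance of the centred vectors is
eigendecomposed.  The mean shape x̄ is the "average anatomy"; the
eigenvectors v_i are the modes of anatomic variation; eigenvalues λ_i (mm²)
give the variance carried by each mode, and each subject receives a score
per mode expressed in SD units, s_ij = v_iᵀ(x_j − x̄)/√λ_i.

Alignment is landmark-based, mirroring a two-step centre-of-mass +
orientation scheme: the node centroid is moved to the origin, the basal
plane normal is rotated to +z and the left-to-right direction (LV centroid
to RV centroid, projected into the basal plane) to +x.  No scaling is
applied — size is part of shape, so ventricular length can appear as a mode.

API shape follows statsmodels: :class:`ShapeModel` is built from data and
``fit()`` returns a :class:`ShapeAtlasResults` carrying estimates,
diagnostics and ``summary()``; :func:`build_atlas` is the functional
shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mesh import LVMesh, thickness_map

__all__ = [
    "align",
    "ShapeModel",
    "ShapeAtlasResults",
    "build_atlas",
    "DegenerateAtlasError",
]

#: Eigenvalues below this fraction of the leading eigenvalue are treated as
#: numerically zero and truncated.
EIG_TRUNCATION = 1e-10


class DegenerateAtlasError(ValueError):
    """Raised when an operation needs shape variance but the cohort has none."""


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align(mesh: LVMesh) -> LVMesh:
    """Rigidly align a mesh to the canonical cohort frame.

    After alignment the node centroid is at the origin, the least-squares
    basal plane (through the basal-level nodes of both surfaces) has normal
    +z pointing from apex to base, and the LV→RV centroid direction,
    projected into the basal plane, points along +x.  The rotation is proper
    (det +1) and no scaling is applied.
    """
    centroid = mesh.nodes.mean(axis=0)
    basal = np.concatenate([mesh.endo[0], mesh.epi[0]], axis=0)
    bc = basal.mean(axis=0)
    _, _, vt = np.linalg.svd(basal - bc, full_matrices=False)
    normal = vt[-1]
    # orient the normal from the apex toward the base
    if normal @ (bc - centroid) < 0:
        normal = -normal

    lr = mesh.rv_centroid - centroid
    lr_in_plane = lr - (lr @ normal) * normal
    n_lr = np.linalg.norm(lr_in_plane)
    if n_lr < 1e-9 * max(np.linalg.norm(lr), 1.0):
        raise ValueError(
            "LV-to-RV direction is parallel to the basal-plane normal; "
            "the in-plane orientation datum is degenerate"
        )
    x_axis = lr_in_plane / n_lr
    y_axis = np.cross(normal, x_axis)
    rotation = np.vstack([x_axis, y_axis, normal])  # rows: new axes, det = +1
    return mesh.transformed(rotation, -rotation @ centroid)


# ---------------------------------------------------------------------------
# the atlas model
# ---------------------------------------------------------------------------

def _as_vectors(shapes: Sequence) -> tuple[np.ndarray, tuple[int, int] | None, np.ndarray | None]:
    """Stack meshes or raw vectors into an (n, 3N) matrix."""
    if len(shapes) == 0:
        raise ValueError("empty cohort")
    if isinstance(shapes[0], LVMesh):
        grid = (shapes[0].n_circ, shapes[0].n_long)
        n3 = shapes[0].n_nodes * 3
        vecs = []
        for m in shapes:
            if (m.n_circ, m.n_long) != grid or m.n_nodes * 3 != n3:
                raise ValueError(
                    "meshes are not corresponded: node counts/grids differ"
                )
            vecs.append(m.as_vector())
        rv = np.mean([m.rv_centroid for m in shapes], axis=0)
        return np.asarray(vecs), grid, rv
    X = np.asarray([np.asarray(v, dtype=float).reshape(-1) for v in shapes])
    if X.ndim != 2 or np.unique([len(v) for v in X]).size != 1:
        raise ValueError("shape vectors must all share one length")
    return X, None, None


class ShapeModel:
    """PCA statistical shape model of a corresponded cohort.

    Parameters
    ----------
    shapes : sequence of LVMesh or of 1-D shape vectors
        The cohort.  Meshes must share the correspondence grid.
    prealigned : bool
        If False (default), meshes are passed through :func:`align` first.
        Raw vectors are always taken as given.
    subject_ids : optional sequence of str
    """

    def __init__(self, shapes, prealigned: bool = False, subject_ids=None):
        if len(shapes) < 3:
            raise ValueError("an atlas needs at least 3 subjects")
        if isinstance(shapes[0], LVMesh) and not prealigned:
            shapes = [align(m) for m in shapes]
        self.X, self.grid, self._rv = _as_vectors(shapes)
        n = self.X.shape[0]
        if subject_ids is None:
            subject_ids = [f"subj{j:04d}" for j in range(n)]
        if len(subject_ids) != n:
            raise ValueError("subject_ids length must match the cohort size")
        self.subject_ids = list(subject_ids)

    def fit(self) -> "ShapeAtlasResults":
        X = self.X
        n, p = X.shape
        mean = X.mean(axis=0)
        C = X - mean

        if p > n:
            gram = (C @ C.T) / (n - 1)
            w, U = np.linalg.eigh(gram)
        else:
            cov = (C.T @ C) / (n - 1)
            w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w = w[order]

        w = np.clip(w, 0.0, None)
        # an all-identical cohort produces eigenvalues at float-roundoff scale;
        # measure degeneracy against the coordinate magnitude, not zero
        scale = max(float(np.abs(X).max()), 1.0)
        if w.size == 0 or w[0] <= (1e-9 * scale) ** 2:
            return ShapeAtlasResults(
                model=self, mean_shape=mean, modes=np.empty((0, p)),
                eigenvalues=np.empty(0), scores_sd=np.empty((n, 0)),
                degenerate=True,
            )
        keep = w > EIG_TRUNCATION * w[0]
        w = w[keep]
        if p > n:
            U = U[:, order][:, keep]
            modes = (C.T @ U) / np.sqrt((n - 1) * w)  # (p, k), orthonormal cols
            modes = modes.T
        else:
            modes = V[:, order][:, keep].T

        modes = self._fix_signs(mean, modes, w)
        raw = C @ modes.T  # (n, k); per-mode sample variance equals λ
        scores_sd = raw / np.sqrt(w)
        return ShapeAtlasResults(
            model=self, mean_shape=mean, modes=modes, eigenvalues=w,
            scores_sd=scores_sd, degenerate=False,
        )

    def _fix_signs(self, mean: np.ndarray, modes: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Deterministic eigenvector signs.

        Each mode is oriented so that moving +1 SD from the mean *increases*
        mean wall thickness; if the thickness change is numerically zero (or
        no grid structure is available), the first non-zero component is made
        positive.  This keeps ±k SD renders and group-difference signs
        reproducible across runs and platforms.
        """
        modes = modes.copy()
        pair_dirs = None
        if self.grid is not None:
            n_circ, n_long = self.grid
            base = LVMesh.from_vector(mean, n_circ, n_long)
            diff = base.epi - base.endo  # (L, C, 3)
            norms = np.linalg.norm(diff, axis=-1, keepdims=True)
            pair_dirs = diff / np.maximum(norms, 1e-12)
        for i in range(modes.shape[0]):
            delta = 0.0
            if pair_dirs is not None:
                v = LVMesh.from_vector(modes[i], *self.grid)
                # linearised mean-thickness change along the mode: the
                # directional derivative is odd in the vector, so the sign
                # choice is orientation-consistent (a finite +1 SD step is
                # not, once the linear term vanishes)
                delta = float(
                    np.mean(
                        np.einsum("lcx,lcx->lc", pair_dirs, v.epi - v.endo)
                    )
                ) * np.sqrt(w[i])
            if abs(delta) > 1e-6:
                if delta < 0:
                    modes[i] *= -1
            else:
                # thickness-neutral mode: orient by the dominant component,
                # which is stable under eigensolver perturbation
                j = int(np.argmax(np.abs(modes[i])))
                if modes[i, j] < 0:
                    modes[i] *= -1
        return modes


@dataclass
class ShapeAtlasResults:
    """Fitted shape atlas: mean anatomy, modes, eigenvalues, subject scores."""

    model: ShapeModel
    mean_shape: np.ndarray  # (3N,)
    modes: np.ndarray  # (k, 3N) orthonormal rows, descending eigenvalue
    eigenvalues: np.ndarray  # (k,) mm^2
    scores_sd: np.ndarray  # (n, k) SD-unit scores
    degenerate: bool = False

    # -- basic quantities --------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.model.X.shape[0]

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def explained_fraction(self) -> np.ndarray:
        """f_i = λ_i / Σλ over the retained (non-null) modes."""
        self._require_nondegenerate()
        return self.eigenvalues / self.eigenvalues.sum()

    def _require_nondegenerate(self) -> None:
        if self.degenerate or self.n_modes == 0:
            raise DegenerateAtlasError(
                "the cohort has no shape variance (all eigenvalues are zero); "
                "explained fractions and scores are undefined"
            )

    def explained_variance(self, m: int) -> float:
        """Cumulative explained-variance fraction of the first ``m`` modes."""
        self._require_nondegenerate()
        if not 1 <= m <= self.n_modes:
            raise ValueError(f"m must lie in [1, {self.n_modes}], got {m}")
        return float(self.explained_fraction[:m].sum())

    # -- shape synthesis and projection ------------------------------------
    def _mesh_from_vector(self, vec: np.ndarray) -> LVMesh:
        if self.model.grid is None:
            raise ValueError(
                "this atlas was built from raw shape vectors; no mesh grid "
                "is available to rebuild an LVMesh"
            )
        n_circ, n_long = self.model.grid
        rv = self.model._rv if self.model._rv is not None else np.zeros(3)
        return LVMesh.from_vector(vec, n_circ, n_long, rv_centroid=rv)

    def shape_at(self, mode: int, k: float) -> LVMesh:
        """Mesh at x̄ + k·√λ_mode·v_mode (``mode`` is 1-based; k in SD units)."""
        self._require_nondegenerate()
        if not 1 <= mode <= self.n_modes:
            raise ValueError(f"mode must lie in [1, {self.n_modes}], got {mode}")
        vec = self.mean_shape + k * np.sqrt(self.eigenvalues[mode - 1]) * self.modes[mode - 1]
        return self._mesh_from_vector(vec)

    def mean_mesh(self) -> LVMesh:
        return self._mesh_from_vector(self.mean_shape.copy())

    def project(self, shape) -> np.ndarray:
        """SD-unit scores of a (held-out) aligned mesh or shape vector."""
        self._require_nondegenerate()
        x = shape.as_vector() if isinstance(shape, LVMesh) else np.asarray(shape, float)
        if x.size != self.mean_shape.size:
            raise ValueError("shape vector length does not match the atlas")
        return (self.modes @ (x - self.mean_shape)) / np.sqrt(self.eigenvalues)

    def reconstruct(self, scores_sd: np.ndarray) -> np.ndarray:
        """Shape vector x̄ + Σ s_i √λ_i v_i from SD-unit scores."""
        s = np.asarray(scores_sd, dtype=float)
        return self.mean_shape + (s * np.sqrt(self.eigenvalues)) @ self.modes

    # -- reporting ---------------------------------------------------------
    def scores_table(self) -> pd.DataFrame:
        """Long-format per-subject per-mode SD-unit scores."""
        self._require_nondegenerate()
        n, k = self.scores_sd.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.model.subject_ids, k),
                "mode": np.tile(np.arange(1, k + 1), n),
                "score_sd_units": self.scores_sd.reshape(-1),
            }
        )

    def summary(self) -> pd.DataFrame:
        """Per-mode eigenvalue, explained fraction and cumulative fraction."""
        self._require_nondegenerate()
        f = self.explained_fraction
        return pd.DataFrame(
            {
                "mode": np.arange(1, self.n_modes + 1),
                "eigenvalue_mm2": self.eigenvalues,
                "explained_fraction": f,
                "cumulative_fraction": np.cumsum(f),
            }
        )

    def plot_variance(self, max_modes: int = 20, ax=None):
        """Cumulative explained-variance curve over the leading modes."""
        import matplotlib.pyplot as plt

        self._require_nondegenerate()
        if ax is None:
            _, ax = plt.subplots()
        m = min(max_modes, self.n_modes)
        cum = np.cumsum(self.explained_fraction[:m])
        ax.plot(np.arange(1, m + 1), 100 * cum, marker="o")
        ax.set_xlabel("mode")
        ax.set_ylabel("cumulative variance explained (%)")
        ax.set_ylim(0, 100)
        return ax

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.degenerate:
            return "ShapeAtlasResults(degenerate: no shape variance)"
        head = (
            f"Shape atlas: {self.n_subjects} subjects, {self.n_modes} modes\n"
        )
        return head + self.summary().head(10).to_string(index=False)


def build_atlas(
    meshes: Sequence, prealigned: bool = True, subject_ids=None
) -> ShapeAtlasResults:
    """Fit a shape atlas from an aligned, corresponded cohort.

    ``prealigned=True`` (the default) trusts the caller's alignment, matching
    a pipeline where :func:`align` has already run; pass False to align here.
    """
    return ShapeModel(meshes, prealigned=prealigned, subject_ids=subject_ids).fit()
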
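"""Seeded synthetic LV cohorts with a known two-group structure.

The generator emulates the statistical structure of a hypertensive-pregnancy
versus normotensive-pregnancy imaging cohort so that every downstream stage
(mesh reconstruction, atlas building, mode statistics, vascular indices,
group tables) can be tested against ground truth without any external data.

Each subject's left ventricle is an idealised half-ellipsoid shell: the
endocardium is a half-ellipsoid truncated at the basal (equatorial) plane
and the epicardium is the endocardium offset outward by the wall thickness
along the surface normal, so the ground-truth thickness is exactly the
``wall_thickness`` parameter at every node.  Six parameters span the shape
variation: ventricular length, basal diameter, two apex-offset components,
apical tilt and wall thickness — the same axes the field's LV shape atlases
report as their leading modes.  The group effect is concentrated purely in
wall thickness: group B (hypertensive) has its mean thickness raised by
``thickness_effect`` while every nuisance parameter is drawn from the same
distribution in both groups.

Diameter variation is parameterised at the *mid-wall* radius
(``r_endo = r_mid − t/2``), so thickening is concentric: the mid-wall is
preserved, the cavity shrinks slightly and the epicardium expands slightly.
This makes the thickness direction approximately orthogonal to the diameter
direction in node space, which is what lets a thickness-specific PCA mode
emerge — the phenotype the analysis is designed to detect.

Clinical covariates (office/ambulatory blood pressures, age, BMI,
cholesterol:HDL ratio), vascular raw measurements (aortic areas, pulse
transit times, capillaroscopy fields) and group flags are drawn with
group-mean offsets calibrated to published midlife post-pregnancy cohort
values; see ``docs/methods.md`` for the calibration table.

Reproducibility: one seed per cohort; each subject consumes an independent
counter-derived substream, so enlarging the cohort never reshuffles earlier
subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .mesh import ContourStack, LVMesh, SliceContours
from .vascular import AORTIC_SITES, AorticSiteMeasurement, PWVMeasurement

__all__ = [
    "ShapeParams",
    "CohortConfig",
    "SubjectRecord",
    "SUBGROUPS",
    "make_lv_mesh",
    "simulate_cohort",
    "slice_to_contours",
    "cohort_frame",
]

#: Pregnancy-history subgroups: normotensive, gestational hypertension,
#: late-onset preeclampsia, early-onset preeclampsia.
SUBGROUPS = ("NTN", "GH", "latePET", "earlyPET")

GROUPS = ("normotensive", "hypertensive")


def collapse_group(subgroup: str) -> str:
    """Binary exposure collapse: NTN -> normotensive, rest -> hypertensive."""
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    return "normotensive" if subgroup == "NTN" else "hypertensive"


@dataclass(frozen=True)
class ShapeParams:
    """Generative shape parameters of one synthetic ventricle (mm / degrees)."""

    length: float
    r_endo_base: float
    wall_thickness: float
    apex_offset: tuple[float, float] = (0.0, 0.0)
    tilt_deg: float = 0.0
    com_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    node_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.r_endo_base <= 0 or self.wall_thickness <= 0:
            raise ValueError(
                "length, r_endo_base and wall_thickness must all be positive"
            )
        if self.wall_thickness >= self.r_endo_base:
            raise ValueError(
                f"wall thickness ({self.wall_thickness} mm) must be smaller than "
                f"the endocardial basal radius ({self.r_endo_base} mm): "
                "the cavity would be degenerate"
            )
        if self.node_noise_sd < 0:
            raise ValueError("node_noise_sd cannot be negative")


def make_lv_mesh(
    params: ShapeParams,
    grid: tuple[int, int] = (48, 20),
    rng: np.random.Generator | int | None = None,
) -> LVMesh:
    """Build a corresponded half-ellipsoid LV mesh from shape parameters.

    The endocardium is sampled at ``n_long`` longitudinal levels equally
    spaced in z from the basal plane (z = 0) to the apex (z = −length), with
    ``n_circ`` counter-clockwise circumferential samples per level; the
    epicardium is the outward normal offset by ``wall_thickness``.  Apex
    offset is applied as a base-anchored shear, tilt as a depth-progressive
    rotation about the y axis (the basal plane stays put — a rigid rotation
    would be invisible to landmark alignment), then the rigid translation
    and finally i.i.d. Gaussian node noise.

    Node ordering is identical for every call with the same grid — this
    ordering is the cohort-wide point correspondence.
    """
    n_circ, n_long = grid
    if n_circ < 8 or n_long < 4:
        raise ValueError(f"grid must be at least (8, 4), got {grid}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    a = params.r_endo_base
    c = params.length
    t = params.wall_thickness

    z = -c * np.arange(n_long) / (n_long - 1)  # (L,) base -> apex
    rho = a * np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ  # CCW viewed from base (+z)

    endo = np.empty((n_long, n_circ, 3))
    endo[..., 0] = rho[:, None] * np.cos(theta)[None, :]
    endo[..., 1] = rho[:, None] * np.sin(theta)[None, :]
    endo[..., 2] = z[:, None]

    # outward ellipsoid normal: grad(x^2/a^2 + y^2/a^2 + z^2/c^2)
    n = np.empty_like(endo)
    n[..., 0] = endo[..., 0] / a**2
    n[..., 1] = endo[..., 1] / a**2
    n[..., 2] = endo[..., 2] / c**2
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    epi = endo + t * n

    nodes = np.concatenate([endo.reshape(-1, 3), epi.reshape(-1, 3)], axis=0)
    rv = np.array([a + 35.0, 0.0, -c / 3.0])

    def shear(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        frac = -q[..., 2] / c
        q[..., 0] += params.apex_offset[0] * frac
        q[..., 1] += params.apex_offset[1] * frac
        return q

    def tilt(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        phi = math.radians(params.tilt_deg) * (-q[..., 2] / c)
        x, zz = q[..., 0].copy(), q[..., 2].copy()
        q[..., 0] = x * np.cos(phi) + zz * np.sin(phi)
        q[..., 2] = -x * np.sin(phi) + zz * np.cos(phi)
        return q

    nodes = tilt(shear(nodes)) + np.asarray(params.com_offset)
    rv = tilt(shear(rv[None, :]))[0] + np.asarray(params.com_offset)

    if params.node_noise_sd > 0:
        if rng is None:
            raise ValueError("node_noise_sd > 0 requires an rng or seed")
        nodes = nodes + rng.normal(0.0, params.node_noise_sd, nodes.shape)

    return LVMesh(nodes=nodes, n_circ=n_circ, n_long=n_long, rv_centroid=rv)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

def _default_covariates() -> dict[str, tuple[float, float, float]]:
    """name -> (normotensive mean, hypertensive mean, common SD)."""
    return {
        "sbp_office": (116.0, 126.0, 11.0),
        "dbp_office": (72.0, 78.0, 8.0),
        "sbp_ambulatory": (117.0, 120.0, 9.0),
        "dbp_ambulatory": (73.0, 75.0, 7.0),
        "central_pp": (38.0, 42.0, 7.0),
        "age": (42.0, 42.0, 5.0),
        "height": (165.0, 165.0, 6.0),
        "bmi": (25.5, 25.8, 4.2),
        "chol_hdl_ratio": (3.3, 3.5, 0.9),
    }


def _default_lvmi() -> dict[str, tuple[float, float]]:
    """Subgroup mean and SD of LV mass index (g/m^2)."""
    return {
        "NTN": (45.9, 6.5),
        "GH": (51.4, 7.1),
        "latePET": (49.6, 7.1),
        "earlyPET": (49.4, 7.1),
    }


def _default_cap_functional() -> dict[str, float]:
    return {"NTN": 115.2, "GH": 103.0, "latePET": 102.0, "earlyPET": 111.0}


def _default_cap_anatomic() -> dict[str, float]:
    # maximised (post-cuff) density sits above resting density; offsets chosen
    # as a fixed +12 capillaries/mm^2 over the functional means
    return {"NTN": 127.2, "GH": 115.0, "latePET": 114.0, "earlyPET": 123.0}


def _default_aortic_amin() -> dict[str, float]:
    """Mean minimum lumen area (mm^2) per aortic site, tapering distally."""
    return {"AA": 520.0, "PDA": 410.0, "DDA": 330.0, "AbA": 260.0}


def _default_flags() -> dict[str, tuple[float, float]]:
    """flag -> (prevalence in normotensive, prevalence in hypertensive)."""
    return {
        "on_antihypertensive": (0.0, 0.09),
        "current_smoker": (0.10, 0.10),
        "preterm_normotensive": (0.20, 0.0),
    }


@dataclass
class CohortConfig:
    """Synthetic-cohort generating distribution.

    Defaults define the emulated study conditions: two groups of 70, a
    0.3 mm concentric wall-thickness effect (5.5 vs 5.2 mm group means),
    nuisance variation in length, diameter, apex position and tilt drawn
    identically in both groups, and covariate/vascular group offsets
    calibrated to the published cohort values (see docs/methods.md).
    """

    n_per_group: int = 70
    seed: int = 0
    grid: tuple[int, int] = (32, 12)

    # shape model (mm / degrees)
    thickness_mean: float = 5.2
    thickness_sd: float = 0.8
    thickness_effect: float = 0.3
    length_mean: float = 82.0
    length_sd: float = 6.0
    r_mid_mean: float = 24.0
    r_mid_sd: float = 2.0
    apex_offset_sd: float = 2.5
    tilt_sd_deg: float = 4.0
    com_offset_sd: float = 2.0
    node_noise_sd: float = 0.3

    # covariates and their coupling to anatomy; the within-group SBP ↔
    # thickness correlation is weak by default so that, as reported for the
    # emulated study, the group difference in wall thickness is not
    # explained away by blood-pressure adjustment
    covariate_model: dict = field(default_factory=_default_covariates)
    sbp_thickness_corr: float = 0.1

    # group-structured outcome columns
    lvmi_model: dict = field(default_factory=_default_lvmi)
    cap_functional_means: dict = field(default_factory=_default_cap_functional)
    cap_anatomic_means: dict = field(default_factory=_default_cap_anatomic)
    cap_between_sd: float = 19.0
    cap_field_sd: float = 12.0

    compliance_means: tuple[float, float] = (0.258, 0.240)  # (NTN, HTN)
    compliance_between_sd: float = 0.05
    compliance_site_sd: float = 0.02
    aortic_amin_means: dict = field(default_factory=_default_aortic_amin)
    aortic_amin_rel_sd: float = 0.10

    pwv_means: tuple[float, float] = (6.8, 7.4)  # m/s
    pwv_sd: float = 1.0
    pwv_d_carotid: tuple[float, float] = (0.105, 0.010)  # m (mean, sd)
    pwv_d_femoral: tuple[float, float] = (0.605, 0.030)
    pwv_t_carotid: tuple[float, float] = (0.065, 0.008)  # s

    flags_model: dict = field(default_factory=_default_flags)
    subgroup_props: dict = field(
        default_factory=lambda: {"GH": 0.40, "latePET": 0.35, "earlyPET": 0.25}
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        sds = [
            self.thickness_sd, self.length_sd, self.r_mid_sd, self.apex_offset_sd,
            self.tilt_sd_deg, self.com_offset_sd, self.node_noise_sd,
            self.cap_between_sd, self.cap_field_sd, self.compliance_between_sd,
            self.compliance_site_sd, self.pwv_sd,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be non-negative")
        if not -1.0 <= self.sbp_thickness_corr <= 1.0:
            raise ValueError("sbp_thickness_corr must lie in [-1, 1]")
        for flag, (p0, p1) in self.flags_model.items():
            if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
                raise ValueError(f"prevalences for {flag!r} must lie in [0, 1]")
        props = self.subgroup_props
        if abs(sum(props.values()) - 1.0) > 1e-9 or any(p < 0 for p in props.values()):
            raise ValueError("subgroup proportions must be non-negative and sum to 1")


@dataclass
class SubjectRecord:
    """One subject: exposure labels, covariates, flags, raw vascular data."""

    subject_id: str
    subgroup: str  # NTN / GH / latePET / earlyPET
    sbp_office: float
    dbp_office: float
    sbp_ambulatory: float
    dbp_ambulatory: float
    central_pp: float
    age: float
    height: float
    weight: float
    bmi: float
    chol_hdl_ratio: float
    on_antihypertensive: bool
    current_smoker: bool
    preterm_normotensive: bool
    lv_mass_index: float
    capillary_fields_functional: np.ndarray  # 6 counts/mm^2
    capillary_fields_anatomic: np.ndarray  # 6 counts/mm^2
    aortic_sites: list  # list[AorticSiteMeasurement]
    pwv_raw: PWVMeasurement
    shape_params: ShapeParams
    true_r_mid: float

    def __post_init__(self) -> None:
        if len(self.capillary_fields_functional) != 6:
            raise ValueError("exactly 6 functional capillaroscopy fields required")
        if len(self.capillary_fields_anatomic) != 6:
            raise ValueError("exactly 6 anatomic capillaroscopy fields required")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")

    @property
    def group(self) -> str:
        return collapse_group(self.subgroup)


def _subject_rng(seed: int, group_idx: int, i: int) -> np.random.Generator:
    # counter-derived substream: adding subjects never reshuffles earlier ones
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, i))
    )


def simulate_cohort(config: CohortConfig) -> tuple[list[LVMesh], list[SubjectRecord]]:
    """Draw a full two-group cohort of meshes and subject records.

    Group B ("hypertensive") has its mean wall thickness raised by
    ``config.thickness_effect``; all nuisance shape parameters and the
    within-group covariate SDs are common to both groups.  Office systolic
    blood pressure is correlated with the *within-group* thickness residual
    via ``sbp_thickness_corr``, so blood-pressure adjustment can be
    exercised with and without confounding.
    """
    meshes: list[LVMesh] = []
    records: list[SubjectRecord] = []
    rho = config.sbp_thickness_corr

    for g, group in enumerate(GROUPS):
        for i in range(config.n_per_group):
            rng = _subject_rng(config.seed, g, i)

            if g == 0:
                subgroup = "NTN"
            else:
                names = list(config.subgroup_props)
                probs = np.array([config.subgroup_props[k] for k in names])
                subgroup = str(rng.choice(names, p=probs))

            t_mean = config.thickness_mean + config.thickness_effect * g
            t = float(rng.normal(t_mean, config.thickness_sd))
            t = max(t, 1.0)
            z_t = (t - t_mean) / config.thickness_sd if config.thickness_sd > 0 else 0.0
            r_mid = float(rng.normal(config.r_mid_mean, config.r_mid_sd))
            r_endo = max(r_mid - t / 2.0, t + 2.0)
            length = max(float(rng.normal(config.length_mean, config.length_sd)), 40.0)
            apex = rng.normal(0.0, config.apex_offset_sd, 2)
            tilt = float(rng.normal(0.0, config.tilt_sd_deg))
            com = rng.normal(0.0, config.com_offset_sd, 3)

            params = ShapeParams(
                length=length,
                r_endo_base=r_endo,
                wall_thickness=t,
                apex_offset=(float(apex[0]), float(apex[1])),
                tilt_deg=tilt,
                com_offset=(float(com[0]), float(com[1]), float(com[2])),
                node_noise_sd=config.node_noise_sd,
            )
            mesh = make_lv_mesh(params, grid=config.grid, rng=rng)

            cov: dict[str, float] = {}
            for name, (m0, m1, sd) in config.covariate_model.items():
                mean_g = m1 if g else m0
                eps = float(rng.standard_normal())
                if name == "sbp_office" and sd > 0:
                    val = mean_g + sd * (rho * z_t + math.sqrt(1 - rho**2) * eps)
                else:
                    val = mean_g + sd * eps
                cov[name] = val
            cov["central_pp"] = max(cov["central_pp"], 10.0)
            cov["bmi"] = max(cov["bmi"], 15.0)
            cov["height"] = max(cov["height"], 140.0)
            weight = cov["bmi"] * (cov["height"] / 100.0) ** 2

            lvmi_mean, lvmi_sd = config.lvmi_model[subgroup]
            lvmi = float(rng.normal(lvmi_mean, lvmi_sd))

            cap_f_lat = rng.normal(
                config.cap_functional_means[subgroup], config.cap_between_sd
            )
            cap_a_lat = rng.normal(
                config.cap_anatomic_means[subgroup], config.cap_between_sd
            )
            cap_f = np.clip(rng.normal(cap_f_lat, config.cap_field_sd, 6), 0, None)
            cap_a = np.clip(rng.normal(cap_a_lat, config.cap_field_sd, 6), 0, None)

            comp_lat = float(
                rng.normal(config.compliance_means[g], config.compliance_between_sd)
            )
            sites = []
            for site in AORTIC_SITES:
                comp = max(
                    comp_lat + float(rng.normal(0.0, config.compliance_site_sd)), 0.02
                )
                amin_mean = config.aortic_amin_means[site]
                a_min = max(
                    float(rng.normal(amin_mean, config.aortic_amin_rel_sd * amin_mean)),
                    50.0,
                )
                sites.append(
                    AorticSiteMeasurement(
                        site=site,
                        a_max=a_min * (1.0 + comp),
                        a_min=a_min,
                        pulse_pressure=cov["central_pp"],
                    )
                )

            v = max(float(rng.normal(config.pwv_means[g], config.pwv_sd)), 3.0)
            d_car = max(float(rng.normal(*config.pwv_d_carotid)), 0.05)
            d_fem = max(float(rng.normal(*config.pwv_d_femoral)), d_car + 0.2)
            t_car = max(float(rng.normal(*config.pwv_t_carotid)), 0.02)
            pwv_raw = PWVMeasurement(
                d_notch_carotid=d_car,
                d_notch_femoral=d_fem,
                t_carotid=t_car,
                t_femoral=t_car + (d_fem - d_car) / v,
            )

            flags = {}
            for flag, (p0, p1) in config.flags_model.items():
                flags[flag] = bool(rng.random() < (p1 if g else p0))

            records.append(
                SubjectRecord(
                    subject_id=f"{'N' if g == 0 else 'H'}{i:04d}",
                    subgroup=subgroup,
                    sbp_office=cov["sbp_office"],
                    dbp_office=cov["dbp_office"],
                    sbp_ambulatory=cov["sbp_ambulatory"],
                    dbp_ambulatory=cov["dbp_ambulatory"],
                    central_pp=cov["central_pp"],
                    age=cov["age"],
                    height=cov["height"],
                    weight=weight,
                    bmi=cov["bmi"],
                    chol_hdl_ratio=cov["chol_hdl_ratio"],
                    on_antihypertensive=flags["on_antihypertensive"],
                    current_smoker=flags["current_smoker"],
                    preterm_normotensive=flags["preterm_normotensive"],
                    lv_mass_index=lvmi,
                    capillary_fields_functional=cap_f,
                    capillary_fields_anatomic=cap_a,
                    aortic_sites=sites,
                    pwv_raw=pwv_raw,
                    shape_params=params,
                    true_r_mid=r_mid,
                )
            )
            meshes.append(mesh)

    return meshes, records


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records to the documented cohort CSV column layout."""
    rows = []
    for r in records:
        row: dict = {
            "subject_id": r.subject_id,
            "group": r.group,
            "subgroup": r.subgroup,
            "sbp_office": r.sbp_office,
            "dbp_office": r.dbp_office,
            "sbp_ambulatory": r.sbp_ambulatory,
            "dbp_ambulatory": r.dbp_ambulatory,
            "central_pp": r.central_pp,
            "age": r.age,
            "height": r.height,
            "weight": r.weight,
            "bmi": r.bmi,
            "chol_hdl_ratio": r.chol_hdl_ratio,
            "on_antihypertensive": r.on_antihypertensive,
            "current_smoker": r.current_smoker,
            "preterm_normotensive": r.preterm_normotensive,
            "lv_mass_index": r.lv_mass_index,
        }
        for i, v in enumerate(r.capillary_fields_functional, 1):
            row[f"cap_func_{i}"] = float(v)
        for i, v in enumerate(r.capillary_fields_anatomic, 1):
            row[f"cap_anat_{i}"] = float(v)
        for site in r.aortic_sites:
            row[f"{site.site}_a_max"] = site.a_max
            row[f"{site.site}_a_min"] = site.a_min
        row["pwv_d_carotid"] = r.pwv_raw.d_notch_carotid
        row["pwv_d_femoral"] = r.pwv_raw.d_notch_femoral
        row["pwv_t_carotid"] = r.pwv_raw.t_carotid
        row["pwv_t_femoral"] = r.pwv_raw.t_femoral
        row["true_length"] = r.shape_params.length
        row["true_r_mid"] = r.true_r_mid
        row["true_wall_thickness"] = r.shape_params.wall_thickness
        row["true_apex_x"] = r.shape_params.apex_offset[0]
        row["true_apex_y"] = r.shape_params.apex_offset[1]
        row["true_tilt_deg"] = r.shape_params.tilt_deg
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# short-axis slicing
# ---------------------------------------------------------------------------

def slice_to_contours(
    mesh: LVMesh, spacing: float, min_ring_radius: float = 3.0
) -> ContourStack:
    """Emulate short-axis contouring: cut the mesh at regularly spaced planes.

    Planes sit at ``z = z_base, z_base − spacing, …`` down to the most apical
    plane that still intersects both surfaces in a closed ring.  Each contour
    keeps the mesh's ``n_circ`` points, counter-clockwise viewed from the
    base.  The mesh must be in a frame whose long axis is approximately z.

    ``min_ring_radius`` drops planes whose endocardial ring has shrunk below
    a contourable size — mirroring manual contouring practice, where the
    apical cap is never traced as a slice.
    """
    if spacing <= 0:
        raise ValueError("slice spacing must be positive")
    endo, epi = mesh.endo, mesh.epi
    z_base = float(np.median(endo[0, :, 2]))
    # a plane intersects a surface in a full ring only above the surface's
    # shallowest meridian end (strictly, so the apex point itself is excluded)
    z_limit = max(endo[:, :, 2].min(axis=0).max(), epi[:, :, 2].min(axis=0).max())

    def ring_at(surface: np.ndarray, zk: float) -> np.ndarray:
        pts = np.empty((mesh.n_circ, 2))
        for c in range(mesh.n_circ):
            zm = surface[:, c, 2]
            pts[c, 0] = np.interp(-zk, -zm, surface[:, c, 0])
            pts[c, 1] = np.interp(-zk, -zm, surface[:, c, 1])
        return pts

    slices = []
    k = 0
    while True:
        zk = z_base - k * spacing
        if zk <= z_limit:
            break
        ring = ring_at(endo, zk)
        if np.linalg.norm(ring - ring.mean(axis=0), axis=1).mean() < min_ring_radius:
            break
        slices.append(SliceContours(z=zk, endo=ring, epi=ring_at(epi, zk)))
        k += 1
    if len(slices) < 4:
        raise ValueError(
            f"spacing {spacing} mm yields only {len(slices)} slices "
            "(need at least 4); spacing is too large for this ventricle"
        )
    return ContourStack(
        slices=slices, rv_centroid=mesh.rv_centroid.copy(), basal_plane_z=z_base
    )
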
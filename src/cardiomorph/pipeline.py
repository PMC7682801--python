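"""End-to-end cohort analysis: group tables, adjustment sweeps, reports.

``compare_groups`` builds the classic "Table 1" group-comparison table with
automatic test selection: continuous variables get a Shapiro-Wilk normality
check in each group (α = 0.05, both groups must pass) that routes them to an
unpaired Student t-test or a Mann-Whitney U test; categorical variables get
a Pearson χ² test (no continuity correction by default).

``adjustment_sweep`` re-tests an outcome's group difference under each
blood-pressure characterisation (office/ambulatory × systolic/diastolic)
via forced-entry OLS and flags whether the difference persists under *all*
variants.  ``subgroup_means`` compares each hypertensive-pregnancy subgroup
(GH, late PET, early PET) against the normotensive group and reports
descriptively whether the effect is graded with severity.

``run_pipeline`` wires the whole chain — simulate (or load) → slice →
reconstruct → align → atlas → mode tests → adjustment → indices → group
tables → sensitivity re-runs — into a versioned report directory whose
tables are byte-identical for identical config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .atlas import align, build_atlas
from .io import load_mesh_directory, save_atlas
from .mesh import reconstruct_mesh
from .modestats import adjust_mode, compare_modes, thickness_mode_selector
from .synthetic import (
    SUBGROUPS,
    CohortConfig,
    cohort_frame,
    simulate_cohort,
    slice_to_contours,
)
from .vascular import append_indices

__all__ = [
    "ComparisonSpec",
    "SensitivitySpec",
    "NAMED_FILTERS",
    "compare_groups",
    "adjustment_sweep",
    "subgroup_means",
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
]

BP_VARIANTS = ("sbp_office", "dbp_office", "sbp_ambulatory", "dbp_ambulatory")


@dataclass(frozen=True)
class ComparisonSpec:
    """How one variable enters the group-comparison table."""

    variable: str
    type: str = "continuous"  # or "categorical"
    force_test: str | None = None  # override: t / mann_whitney / chi_square

    def __post_init__(self) -> None:
        if self.type not in ("continuous", "categorical"):
            raise ValueError(f"unknown variable type {self.type!r}")
        if self.force_test not in (None, "t", "mann_whitney", "chi_square"):
            raise ValueError(f"unknown test override {self.force_test!r}")


#: Named sensitivity filters: predicate returns True for subjects to KEEP.
NAMED_FILTERS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "exclude_preterm_normotensive": lambda df: ~df["preterm_normotensive"].astype(bool),
    "exclude_on_antihypertensive": lambda df: ~df["on_antihypertensive"].astype(bool),
    "exclude_current_smoker": lambda df: ~df["current_smoker"].astype(bool),
}


@dataclass(frozen=True)
class SensitivitySpec:
    """One sensitivity re-run: a named exclusion plus variables to re-test."""

    filter_name: str
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.filter_name not in NAMED_FILTERS:
            raise ValueError(
                f"unknown filter {self.filter_name!r}; "
                f"available: {sorted(NAMED_FILTERS)}"
            )


def _choose_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> str:
    """Shapiro-Wilk in each group; both normal -> Student t, else Mann-Whitney."""
    px = stats.shapiro(x).pvalue
    py = stats.shapiro(y).pvalue
    return "t" if (px > alpha and py > alpha) else "mann_whitney"


def compare_groups(
    frame: pd.DataFrame,
    specs: Sequence[ComparisonSpec],
    group_col: str = "group",
    group_order: tuple[str, str] | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Two-group comparison table with automatic test selection.

    Returns one row per variable: per-group summary (mean±SD for t-tested,
    median [IQR] for Mann-Whitney, n (%) for categorical), the test used and
    the two-sided p-value.  Constant variables are kept in the table with
    ``test = "skipped (constant)"`` and no p-value.
    """
    levels = list(dict.fromkeys(frame[group_col].tolist()))
    if group_order is not None:
        levels = list(group_order)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    ga = frame[frame[group_col] == levels[0]]
    gb = frame[frame[group_col] == levels[1]]

    rows = []
    for spec in specs:
        v = spec.variable
        row: dict = {"variable": v, "type": spec.type}
        if spec.type == "continuous":
            x = ga[v].dropna().to_numpy(dtype=float)
            y = gb[v].dropna().to_numpy(dtype=float)
            row[f"n_{levels[0]}"], row[f"n_{levels[1]}"] = len(x), len(y)
            if np.ptp(np.concatenate([x, y])) == 0:
                row["test"] = "skipped (constant)"
                row["p"] = np.nan
                row[f"summary_{levels[0]}"] = f"{x.mean():.3g} (constant)"
                row[f"summary_{levels[1]}"] = f"{y.mean():.3g} (constant)"
                rows.append(row)
                continue
            test = spec.force_test or _choose_test(x, y)
            if test == "t":
                res = stats.ttest_ind(x, y, equal_var=True)
                row[f"summary_{levels[0]}"] = f"{x.mean():.2f}±{x.std(ddof=1):.2f}"
                row[f"summary_{levels[1]}"] = f"{y.mean():.2f}±{y.std(ddof=1):.2f}"
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                for lbl, arr in ((levels[0], x), (levels[1], y)):
                    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
                    row[f"summary_{lbl}"] = f"{q2:.2f} [{q1:.2f}-{q3:.2f}]"
            row["test"] = test
            row["p"] = float(res.pvalue)
        else:
            x = ga[v].astype(bool)
            y = gb[v].astype(bool)
            row[f"n_{levels[0]}"], row[f"n_{levels[1]}"] = len(x), len(y)
            row[f"summary_{levels[0]}"] = f"{x.sum()} ({100 * x.mean():.1f}%)"
            row[f"summary_{levels[1]}"] = f"{y.sum()} ({100 * y.mean():.1f}%)"
            table = np.array(
                [[x.sum(), (~x).sum()], [y.sum(), (~y).sum()]], dtype=float
            )
            if np.any(table.sum(axis=0) == 0):
                row["test"] = "skipped (constant)"
                row["p"] = np.nan
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
                row["test"] = "chi_square"
                row["p"] = float(p)
                row["statistic"] = float(chi2)
        rows.append(row)
    return pd.DataFrame(rows)


def adjustment_sweep(
    frame: pd.DataFrame,
    outcome: str,
    bp_variants: Sequence[str] = BP_VARIANTS,
    extra_covariates: Sequence[str] = (),
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Adjusted group difference of ``outcome`` under each BP characterisation.

    One forced-entry OLS model per blood-pressure variant (plus an
    unadjusted reference row).  The ``persists_all_variants`` flag is True
    only when every adjusted variant keeps p < α — the persistence criterion
    for calling a difference blood-pressure independent.
    """
    missing = [c for c in (outcome, *bp_variants, *extra_covariates) if c not in frame]
    if missing:
        raise KeyError(f"missing column(s) in cohort table: {missing}")
    y = frame[outcome].to_numpy(dtype=float)
    g = frame[group_col].to_numpy()

    rows = []
    unadj = adjust_mode(y, g)
    rows.append(
        {"variant": "unadjusted", "beta": unadj.beta, "se": unadj.se,
         "p": unadj.p, "n": unadj.n_obs}
    )
    adj_ps = []
    for variant in bp_variants:
        covs = frame[[variant, *extra_covariates]]
        res = adjust_mode(y, g, covariates=covs)
        adj_ps.append(res.p)
        rows.append(
            {"variant": variant, "beta": res.beta, "se": res.se,
             "p": res.p, "n": res.n_obs}
        )
    out = pd.DataFrame(rows)
    out["outcome"] = outcome
    out["persists_all_variants"] = bool(all(p < alpha for p in adj_ps))
    return out


def subgroup_means(
    frame: pd.DataFrame,
    outcome: str,
    subgroup_col: str = "subgroup",
    reference: str = "NTN",
) -> tuple[pd.DataFrame, str]:
    """Per-subgroup means with vs-reference t-tests and a graded-effect check.

    Each exposed subgroup (GH, late PET, early PET) is compared with the
    reference by unpaired t-test; subgroups with fewer than 2 subjects keep
    their mean but skip the test.  The trend check is descriptive: the
    effect is called graded only when the exposed subgroup means are
    strictly monotone in severity order *and* the extreme subgroups differ
    by more than twice the SE of that difference.
    """
    present = [s for s in SUBGROUPS if (frame[subgroup_col] == s).any()]
    rows = []
    ref_vals = frame.loc[frame[subgroup_col] == reference, outcome].dropna()
    for s in SUBGROUPS:
        vals = frame.loc[frame[subgroup_col] == s, outcome].dropna()
        row = {"subgroup": s, "n": len(vals)}
        if len(vals) == 0:
            row["note"] = "empty subgroup: skipped"
            rows.append(row)
            continue
        row["mean"] = float(vals.mean())
        row["sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        if s != reference:
            if len(vals) >= 2 and len(ref_vals) >= 2:
                res = stats.ttest_ind(vals, ref_vals, equal_var=True)
                row["p_vs_reference"] = float(res.pvalue)
            else:
                row["note"] = "t-test skipped (subgroup too small)"
        rows.append(row)
    table = pd.DataFrame(rows)

    exposed = [s for s in ("GH", "latePET", "earlyPET") if s in present]
    trend = "no graded effect"
    if len(exposed) == 3:
        means = [
            float(frame.loc[frame[subgroup_col] == s, outcome].mean())
            for s in exposed
        ]
        diffs = np.diff(means)
        if np.all(diffs > 0) or np.all(diffs < 0):
            a = frame.loc[frame[subgroup_col] == exposed[0], outcome].dropna()
            b = frame.loc[frame[subgroup_col] == exposed[-1], outcome].dropna()
            if len(a) >= 2 and len(b) >= 2:
                se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
                if abs(means[-1] - means[0]) > 2 * se:
                    trend = (
                        "graded increasing" if means[-1] > means[0]
                        else "graded decreasing"
                    )
    return table, trend


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

#: Variables entering the default group-comparison table.
DEFAULT_TABLE_VARIABLES: tuple[ComparisonSpec, ...] = (
    ComparisonSpec("age"),
    ComparisonSpec("bmi"),
    ComparisonSpec("sbp_office"),
    ComparisonSpec("dbp_office"),
    ComparisonSpec("sbp_ambulatory"),
    ComparisonSpec("dbp_ambulatory"),
    ComparisonSpec("chol_hdl_ratio"),
    ComparisonSpec("lv_mass_index"),
    ComparisonSpec("mean_wall_thickness"),
    ComparisonSpec("functional_capillary_density"),
    ComparisonSpec("anatomic_capillary_density"),
    ComparisonSpec("global_compliance"),
    ComparisonSpec("global_distensibility"),
    ComparisonSpec("pwv"),
    ComparisonSpec("on_antihypertensive", "categorical"),
    ComparisonSpec("current_smoker", "categorical"),
    ComparisonSpec("preterm_normotensive", "categorical"),
)


@dataclass
class PipelineConfig:
    """Configuration of one report run (synthetic or file-based inputs)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str | Path = "cardiomorph_report"
    # file-based inputs (both required together; override synthetic generation)
    mesh_dir: str | Path | None = None
    cohort_csv: str | Path | None = None

    slice_spacing: float = 10.0  # mm, emulated short-axis plane spacing
    reconstruct: bool = True  # run the contour -> mesh chain on synthetic meshes
    n_modes_tested: int = 20
    adjusted_outcomes: tuple[str, ...] = (
        "lv_mass_index",
        "functional_capillary_density",
    )
    sensitivity: tuple[SensitivitySpec, ...] = (
        SensitivitySpec(
            "exclude_preterm_normotensive",
            ("lv_mass_index", "functional_capillary_density"),
        ),
        SensitivitySpec(
            "exclude_on_antihypertensive",
            ("lv_mass_index", "functional_capillary_density"),
        ),
        SensitivitySpec(
            "exclude_current_smoker",
            ("functional_capillary_density",),
        ),
    )

    def validate(self) -> None:
        if (self.mesh_dir is None) != (self.cohort_csv is None):
            raise ValueError(
                "file-based input needs BOTH mesh_dir and cohort_csv; "
                "got only one of them"
            )
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        # CohortConfig validates itself in __post_init__


@dataclass
class ReportBundle:
    """In-memory handles to everything ``run_pipeline`` wrote."""

    out_dir: Path
    cohort: pd.DataFrame
    atlas: object
    mode_tests: pd.DataFrame
    adjustments: pd.DataFrame
    group_comparison: pd.DataFrame
    subgroups: dict
    sensitivity: pd.DataFrame
    thickness_mode: int
    config_hash: str


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = asdict(config)
    payload.pop("out_dir", None)  # the analysis is invariant to where it lands
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis chain and write a report directory.

    Identical config (including the cohort seed) produces byte-identical
    CSV tables.  Tables written: ``cohort.csv`` (with appended indices),
    ``atlas_summary.csv``, ``scores.csv``, ``mode_tests.csv``,
    ``adjustments.csv``, ``group_comparison.csv``, ``subgroups_*.csv``,
    ``sensitivity.csv``; plus ``atlas.npz`` and ``log.txt``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from .mesh import thickness_map  # local import to avoid cycle at module load

    # --- inputs -----------------------------------------------------------
    if config.mesh_dir is not None:
        shapes, names = load_mesh_directory(config.mesh_dir)
        frame = pd.read_csv(config.cohort_csv)
        meshes = shapes
    else:
        meshes, records = simulate_cohort(config.cohort)
        frame = cohort_frame(records)
        names = frame["subject_id"].tolist()
        if config.reconstruct:
            meshes = [
                reconstruct_mesh(
                    slice_to_contours(m, config.slice_spacing), config.cohort.grid
                )
                for m in meshes
            ]

    # --- alignment + atlas -------------------------------------------------
    from .mesh import LVMesh

    if isinstance(meshes[0], LVMesh):
        aligned = [align(m) for m in meshes]
        frame = frame.copy()
        frame["mean_wall_thickness"] = [thickness_map(m).mean for m in aligned]
    else:
        aligned = meshes  # raw vectors from an external deposit
    atlas = build_atlas(aligned, prealigned=True, subject_ids=names)

    frame = append_indices(frame)

    # --- mode statistics ----------------------------------------------------
    n_modes = min(config.n_modes_tested, atlas.n_modes)
    comp = compare_modes(
        atlas.scores_sd,
        frame["group"].to_numpy(),
        n_modes=n_modes,
        group_order=("normotensive", "hypertensive"),
    )
    if "true_wall_thickness" in frame:
        thickness_mode = thickness_mode_selector(atlas, frame)
    else:
        thickness_mode = int(comp.table.loc[comp.table["p"].idxmin(), "mode"])

    adjustments = []
    score_col = f"mode{thickness_mode}_score"
    frame[score_col] = atlas.scores_sd[:, thickness_mode - 1]
    for outcome in (score_col, *config.adjusted_outcomes):
        adjustments.append(adjustment_sweep(frame, outcome))
    adjustments = pd.concat(adjustments, ignore_index=True)

    # --- group tables -------------------------------------------------------
    specs = [s for s in DEFAULT_TABLE_VARIABLES if s.variable in frame.columns]
    comparison = compare_groups(
        frame, specs, group_order=("normotensive", "hypertensive")
    )

    subgroups = {}
    subgroup_frames = []
    if "subgroup" in frame:
        for outcome in config.adjusted_outcomes:
            tbl, trend = subgroup_means(frame, outcome)
            tbl.insert(0, "outcome", outcome)
            tbl["trend"] = trend
            subgroups[outcome] = (tbl, trend)
            subgroup_frames.append(tbl)

    sens_rows = []
    for spec in config.sensitivity:
        keep = NAMED_FILTERS[spec.filter_name](frame)
        sub = frame[keep]
        n_excluded = int((~keep).sum())
        retest = compare_groups(
            sub,
            [ComparisonSpec(v) for v in spec.variables],
            group_order=("normotensive", "hypertensive"),
        )
        for _, row in retest.iterrows():
            sens_rows.append(
                {
                    "filter": spec.filter_name,
                    "variable": row["variable"],
                    "n_retained": len(sub),
                    "n_excluded": n_excluded,
                    "test": row["test"],
                    "p": row["p"],
                }
            )
    sensitivity = pd.DataFrame(sens_rows)

    # --- write the report ---------------------------------------------------
    frame.to_csv(out / "cohort.csv", index=False)
    atlas.summary().to_csv(out / "atlas_summary.csv", index=False)
    atlas.scores_table().to_csv(out / "scores.csv", index=False)
    comp.table.to_csv(out / "mode_tests.csv", index=False)
    adjustments.to_csv(out / "adjustments.csv", index=False)
    comparison.to_csv(out / "group_comparison.csv", index=False)
    for outcome, (tbl, _) in subgroups.items():
        tbl.to_csv(out / f"subgroups_{outcome}.csv", index=False)
    sensitivity.to_csv(out / "sensitivity.csv", index=False)
    save_atlas(atlas, out / "atlas.npz")

    cfg_hash = _config_hash(config)
    sig = comp.significant_modes(0.05)
    log_lines = [
        f"cardiomorph {_pkg_version}",
        f"config_hash {cfg_hash}",
        f"seed {config.cohort.seed}",
        f"n_subjects {len(frame)}",
        f"n_modes {atlas.n_modes}",
        f"thickness_mode {thickness_mode}",
        f"significant_modes_p<0.05 {list(map(int, sig))}",
    ]
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")

    return ReportBundle(
        out_dir=out,
        cohort=frame,
        atlas=atlas,
        mode_tests=comp.table,
        adjustments=adjustments,
        group_comparison=comparison,
        subgroups=subgroups,
        sensitivity=sensitivity,
        thickness_mode=thickness_mode,
        config_hash=cfg_hash,
    )
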
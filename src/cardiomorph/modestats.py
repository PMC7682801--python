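"""Per-mode two-group inference, covariate adjustment and power arithmetic.

The primary contrast is an unpaired two-sample Student t-test (equal
variances pooled; Welch available behind a flag) applied mode-by-mode to the
SD-unit atlas scores of the first ``n_modes`` modes, reported with raw
two-sided p-values; Bonferroni correction is available but off by default,
matching how per-mode shape comparisons are conventionally displayed.

Covariate adjustment uses forced-entry ordinary least squares: the mode
score (or any outcome column) is regressed on a 0/1 group indicator plus
the requested covariates, all terms retained, and the *unstandardised*
group coefficient β with its SE and p-value is reported.  Group coding is
0 = reference (normotensive), 1 = exposed (hypertensive), so positive β
means a higher score in the exposed group under the atlas sign convention.

``required_sample_size`` implements the standard two-sample normal
approximation n = 2σ²(z_{1−α/2} + z_{power})²/δ², and
``empirical_power`` closes the loop by measuring the rejection rate of the
full simulate → align → atlas → t-test pipeline over replicate cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .atlas import build_atlas
from .synthetic import CohortConfig, cohort_frame, simulate_cohort

__all__ = [
    "ModeComparison",
    "AdjustmentResult",
    "compare_modes",
    "adjust_mode",
    "required_sample_size",
    "empirical_power",
    "thickness_mode_selector",
]


@dataclass
class ModeComparison:
    """Per-mode two-group t-test results (one row per mode)."""

    table: pd.DataFrame  # mode, mean_<ref>, mean_<other>, t, df, p[, p_bonferroni]
    group_order: tuple[str, str]
    n_modes: int

    def significant_modes(self, alpha: float = 0.05, adjusted: bool = False):
        col = "p_bonferroni" if adjusted else "p"
        if col not in self.table:
            raise ValueError("Bonferroni column was not requested")
        return self.table.loc[self.table[col] < alpha, "mode"].to_numpy()

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def plot(self, alpha: float = 0.05, ax=None):
        """Per-mode p-values on a log scale with the significance line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.table["mode"], self.table["p"], color="steelblue")
        ax.axhline(alpha, color="firebrick", linestyle="--", label=f"p = {alpha}")
        ax.set_yscale("log")
        ax.set_xlabel("mode")
        ax.set_ylabel("two-sided p (unpaired t-test)")
        ax.legend()
        return ax


def compare_modes(
    scores: np.ndarray,
    groups: Sequence[str],
    n_modes: int | None = None,
    group_order: tuple[str, str] | None = None,
    welch: bool = False,
    bonferroni: bool = False,
) -> ModeComparison:
    """Unpaired t-test of every mode score between the two groups.

    ``scores`` is the (n_subjects, n_available_modes) SD-unit score matrix;
    ``groups`` the per-subject labels.  The t statistic is signed as
    mean(first group) − mean(second group) where the group order defaults to
    first-appearance order (pass ``group_order`` to fix it).  Raw two-sided
    p-values are reported; the optional Bonferroni column multiplies them by
    the number of modes tested.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if group_order is not None:
        labels = list(group_order)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a = scores[groups == labels[0]]
    b = scores[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects for a t-test")
    if n_modes is None:
        n_modes = min(20, scores.shape[1])  # the conventional display depth
    if not 1 <= n_modes <= scores.shape[1]:
        raise ValueError(
            f"n_modes must lie in [1, {scores.shape[1]}], got {n_modes}"
        )

    a, b = a[:, :n_modes], b[:, :n_modes]
    res = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    dof = (
        len(a) + len(b) - 2
        if not welch
        else np.asarray(res.df if hasattr(res, "df") else np.nan)
    )
    table = pd.DataFrame(
        {
            "mode": np.arange(1, n_modes + 1),
            f"mean_{labels[0]}": a.mean(axis=0),
            f"mean_{labels[1]}": b.mean(axis=0),
            "t": np.atleast_1d(res.statistic),
            "df": dof,
            "p": np.atleast_1d(res.pvalue),
        }
    )
    if bonferroni:
        table["p_bonferroni"] = np.minimum(table["p"] * n_modes, 1.0)
    return ModeComparison(table=table, group_order=tuple(labels), n_modes=n_modes)


@dataclass
class AdjustmentResult:
    """Forced-entry OLS adjustment of one outcome for covariates.

    ``beta`` is the unstandardised group coefficient: the adjusted group
    difference in the outcome's own units (SD units for mode scores).
    """

    beta: float
    se: float
    p: float
    covariates: tuple[str, ...]
    n_obs: int
    ols_results: object = None  # statsmodels RegressionResults for diagnostics

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["group"],
                "beta": [self.beta],
                "se": [self.se],
                "p": [self.p],
                "covariates": [",".join(self.covariates) or "(none)"],
                "n": [self.n_obs],
            }
        )


def adjust_mode(
    score: Sequence[float],
    group: Sequence,
    covariates: pd.DataFrame | dict | None = None,
    reference: str | int | None = None,
) -> AdjustmentResult:
    """Adjusted group difference in a mode score (or any outcome) by OLS.

    The group is coded 0 for the reference level (by default ``"normotensive"``
    if present, else the first level in appearance order) and 1 otherwise.
    All covariates enter jointly (forced entry, no selection).  Rows with
    missing values are dropped (complete-case).
    """
    y = np.asarray(score, dtype=float)
    group = np.asarray(group)
    levels = list(dict.fromkeys(group.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    if reference is None:
        reference = "normotensive" if "normotensive" in levels else levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    g = (group != reference).astype(float)

    if covariates is None:
        covariates = pd.DataFrame(index=np.arange(len(y)))
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    design = pd.DataFrame({"group": g})
    for c in covariates.columns:
        design[str(c)] = np.asarray(covariates[c], dtype=float)

    mask = np.isfinite(y) & np.all(np.isfinite(design.to_numpy()), axis=1)
    n_complete = int(mask.sum())
    if n_complete < design.shape[1] + 2:
        raise ValueError(
            f"only {n_complete} complete cases for {design.shape[1]} terms; "
            "need at least covariates + 3 observations"
        )
    X = sm.add_constant(design[mask], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending column: the first whose removal restores full rank
        for col in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                raise ValueError(f"design is rank deficient: column {col!r} is collinear")
        raise ValueError("design is rank deficient")
    fit = sm.OLS(y[mask], X).fit()
    return AdjustmentResult(
        beta=float(fit.params["group"]),
        se=float(fit.bse["group"]),
        p=float(fit.pvalues["group"]),
        covariates=tuple(str(c) for c in covariates.columns),
        n_obs=n_complete,
        ols_results=fit,
    )


def required_sample_size(
    delta: float, sigma: float, alpha: float, power: float
) -> int:
    """Per-group n for a two-sample test of a mean difference δ with SD σ.

    Normal approximation: smallest integer n with
    n ≥ 2σ²(z_{1−α/2} + z_{power})²/δ², floored at 2 per group.
    """
    if delta <= 0 or sigma <= 0:
        raise ValueError("delta and sigma must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie strictly between 0 and 1")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n = 2.0 * (sigma / delta) ** 2 * z**2
    return max(int(math.ceil(n - 1e-12)), 2)


# ---------------------------------------------------------------------------
# empirical power of the full pipeline
# ---------------------------------------------------------------------------

def thickness_mode_selector(atlas, frame: pd.DataFrame) -> int:
    """1-based index of the mode most correlated with true wall thickness.

    Uses the generator's ground-truth thickness column, so selection never
    peeks at the group labels (valid under the null).
    """
    t = frame["true_wall_thickness"].to_numpy()
    scores = atlas.scores_sd
    t_c = t - t.mean()
    s_c = scores - scores.mean(axis=0)
    denom = np.sqrt((t_c**2).sum() * (s_c**2).sum(axis=0))
    corr = np.where(denom > 0, (s_c * t_c[:, None]).sum(axis=0) / denom, 0.0)
    return int(np.argmax(np.abs(corr))) + 1


def empirical_power(
    config: CohortConfig,
    mode_selector: Callable | int = thickness_mode_selector,
    alpha: float = 0.05,
    n_reps: int = 100,
    seed: int = 0,
    welch: bool = False,
) -> float:
    """Rejection rate of the mode t-test over replicate synthetic cohorts.

    Each replicate draws a fresh cohort (the replicate index perturbs the
    config seed deterministically), aligns it, fits the atlas, picks a mode
    via ``mode_selector`` (a 1-based index or a callable
    ``(atlas, frame) -> index``) and tests it between groups at ``alpha``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    rejections = 0
    for rep in range(n_reps):
        cfg = replace(config, seed=(seed * 1_000_003 + rep) % (2**31 - 1))
        meshes, records = simulate_cohort(cfg)
        frame = cohort_frame(records)
        atlas = build_atlas(meshes, prealigned=False)
        if callable(mode_selector):
            mode = mode_selector(atlas, frame)
        else:
            mode = int(mode_selector)
        comp = compare_modes(
            atlas.scores_sd,
            frame["group"].to_numpy(),
            n_modes=atlas.n_modes,
            group_order=("normotensive", "hypertensive"),
            welch=welch,
        )
        p = float(comp.table.loc[comp.table["mode"] == mode, "p"].iloc[0])
        if p < alpha:
            rejections += 1
    return rejections / n_reps
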
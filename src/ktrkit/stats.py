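"""Aggregation and statistics for C/N measurements.

The statistical unit is the *image* (ROI data point): per-cell values are
averaged within each image, and those image means — not single cells —
enter SEM, t-tests and ANOVA. This matches common practice for field-of-
view microscopy data, where cells within an image are correlated.

Tests: two-tailed Welch t-test by default (pooled-variance optional) and
fixed-effects two-way ANOVA with interaction, type II sums of squares for
unbalanced designs. Raw p values are reported; a Benjamini-Hochberg
correction helper exists but is not applied by default.

Response kinetics of a time course are summarised as fold change relative
to the pre-treatment baseline window, the first time point reaching
significance across replicates, the half-maximal time, and the plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "ResponseMetrics",
    "aggregate",
    "t_test_two_tailed",
    "anova_two_way",
    "response_metrics",
    "dose_response",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM of one condition over its image-level data points."""

    condition: str
    n_units: int
    mean: float
    sem: float
    unit_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ResponseMetrics:
    """Kinetic summary of a treatment response time course."""

    baseline_cn: float
    t: np.ndarray
    fold_change: np.ndarray
    plateau_cn: float
    plateau_fold: float
    t_signif: float | None
    t_half: float | None


def aggregate(
    measurements: pd.DataFrame,
    value: str = "cn_ratio",
    *,
    image_by: str | list[str] = "field",
    condition_by: str | list[str] | None = None,
    min_cells: int = 10,
    require_valid: bool = True,
) -> list[GroupSummary]:
    """Collapse cells -> image means -> condition summaries.

    Each image's valid cells are averaged into one data point; the
    per-condition mean and SEM are computed over those image data points.
    A warning is raised for any image contributing fewer than ``min_cells``
    valid cells.
    """
    df = measurements
    if require_valid and "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    df = df.dropna(subset=[value])
    image_by = [image_by] if isinstance(image_by, str) else list(image_by)
    cond_by = (
        [condition_by] if isinstance(condition_by, str) else list(condition_by or [])
    )
    if df.empty:
        raise ValueError("no valid measurements to aggregate")

    # one data point per image: mean over its cells
    per_cell = df.groupby(cond_by + image_by + ["cell_id"], as_index=False)[value].mean()
    counts = per_cell.groupby(cond_by + image_by, as_index=False)[value].count()
    for _, row in counts.iterrows():
        if row[value] < min_cells:
            warnings.warn(
                f"image {tuple(row[c] for c in cond_by + image_by)} has only "
                f"{int(row[value])} valid cells (minimum recommended {min_cells})"
            )
    per_image = per_cell.groupby(cond_by + image_by, as_index=False)[value].mean()

    out: list[GroupSummary] = []
    if cond_by:
        groups = per_image.groupby(cond_by)
    else:
        groups = [("all", per_image)]
    for label, g in groups:
        if g.empty:
            raise ValueError(f"empty group {label!r}")
        vals = g[value].to_numpy(dtype=float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        name = label if isinstance(label, str) else "/".join(str(x) for x in np.atleast_1d(label))
        out.append(
            GroupSummary(
                condition=name, n_units=n, mean=float(vals.mean()), sem=sem,
                unit_values=tuple(float(v) for v in vals),
            )
        )
    return out


def t_test_two_tailed(
    group_a: np.ndarray, group_b: np.ndarray, *, equal_var: bool = False
) -> TestResult:
    """Two-sided two-sample t-test (Welch by default).

    Degenerate case: both groups with zero variance and equal means gives
    p = 1 by convention (no evidence of difference).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("t-test", 0.0, float(a.size + b.size - 2), 1.0)
        return TestResult("t-test", float("inf"), float(a.size + b.size - 2), 0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(getattr(res, "df", a.size + b.size - 2))
    return TestResult("t-test", float(res.statistic), df, float(res.pvalue))


def anova_two_way(
    table: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
) -> list[TestResult]:
    """Fixed-effects two-way ANOVA with interaction (type II SS).

    Returns one :class:`TestResult` per factor and, when estimable, the
    interaction. If either factor has a single level the analysis reduces
    to a one-way ANOVA on the other factor, with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table[[value, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "fa", "fb"]
    n_a = df["fa"].nunique()
    n_b = df["fb"].nunique()
    if n_a < 2 and n_b < 2:
        raise ValueError("both factors have a single level; nothing to test")
    if n_a < 2 or n_b < 2:
        keep, name = ("fb", factor_b) if n_a < 2 else ("fa", factor_a)
        warnings.warn(
            f"factor {factor_a if n_a < 2 else factor_b!r} has one level; "
            "reducing to one-way ANOVA"
        )
        model = ols("y ~ C(%s)" % keep, data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        row = tab.loc[f"C({keep})"]
        return [
            TestResult(
                "anova", float(row["F"]),
                (float(row["df"]), float(tab.loc["Residual", "df"])),
                float(row["PR(>F)"]), factors=(name,),
            )
        ]
    # interaction only estimable with replication within cells
    replicated = df.groupby(["fa", "fb"]).size().min() > 1
    formula = "y ~ C(fa) * C(fb)" if replicated else "y ~ C(fa) + C(fb)"
    model = ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    resid_df = float(tab.loc["Residual", "df"])
    labels = {
        "C(fa)": (factor_a,),
        "C(fb)": (factor_b,),
        "C(fa):C(fb)": (factor_a, factor_b),
    }
    out = []
    for key, facs in labels.items():
        if key in tab.index:
            row = tab.loc[key]
            out.append(
                TestResult(
                    "anova", float(row["F"]), (float(row["df"]), resid_df),
                    float(row["PR(>F)"]), factors=facs,
                )
            )
    return out


def response_metrics(
    traces: np.ndarray,
    t: np.ndarray,
    event_time: float,
    *,
    alpha: float = 0.05,
    plateau_points: int = 5,
    flat_tol: float = 0.05,
) -> ResponseMetrics:
    """Kinetic summary of replicate response time courses.

    Parameters
    ----------
    traces
        (n_replicates, n_time) array of replicate-level C/N time courses.
    t
        Time grid in minutes.
    event_time
        Time of the treatment whose response is summarised; samples before
        it form the baseline window.

    Fold change is the replicate-mean trace divided by the replicate-mean
    baseline. ``t_signif`` is the first post-event time at which a paired
    two-sided t-test of replicate values against replicate baselines gives
    p < alpha (requires >= 3 replicates; None otherwise or if never
    significant). ``t_half`` is the first post-event time the fold change
    crosses halfway between 1 and the plateau fold; None for flat traces
    (plateau fold within ``flat_tol`` of 1).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    t = np.asarray(t, dtype=float)
    pre = t < event_time
    if not pre.any():
        raise ValueError("no samples before the event; baseline undefined")
    base_per_rep = traces[:, pre].mean(axis=1)
    baseline = float(base_per_rep.mean())
    mean_trace = traces.mean(axis=0)
    fold = mean_trace / baseline
    post = t >= event_time
    plateau_cn = float(mean_trace[-plateau_points:].mean())
    plateau_fold = plateau_cn / baseline

    t_signif = None
    if traces.shape[0] >= 3:
        for i in np.nonzero(post)[0]:
            vals = traces[:, i]
            if np.allclose(vals, base_per_rep):
                continue
            p = sps.ttest_rel(vals, base_per_rep).pvalue
            if p < alpha:
                t_signif = float(t[i])
                break

    t_half = None
    if abs(plateau_fold - 1.0) > flat_tol:
        half = (1.0 + plateau_fold) / 2.0
        for i in np.nonzero(post)[0]:
            crossed = fold[i] >= half if plateau_fold > 1 else fold[i] <= half
            if crossed:
                t_half = float(t[i])
                break
    return ResponseMetrics(
        baseline_cn=baseline, t=t, fold_change=fold,
        plateau_cn=plateau_cn, plateau_fold=float(plateau_fold),
        t_signif=t_signif, t_half=t_half,
    )


def dose_response(summaries: dict[float, GroupSummary]) -> pd.DataFrame:
    """Dose-sorted mean ± SEM table with a monotonicity flag.

    The flag reports whether an isotonic (monotone) fit explains the dose
    series: the residual RMS of the best monotone fit (increasing or
    decreasing), normalised by the response range, must stay below 5%.
    Input order is irrelevant; duplicate doses are an error.
    """
    doses = list(summaries)
    if len(doses) != len(set(doses)):
        raise ValueError("duplicate dose labels")
    if len(doses) < 2:
        raise ValueError("need at least two doses")
    order = np.argsort(doses)
    d = np.asarray(doses, dtype=float)[order]
    means = np.asarray([summaries[doses[i]].mean for i in order])
    sems = np.asarray([summaries[doses[i]].sem for i in order])
    ns = np.asarray([summaries[doses[i]].n_units for i in order])

    from sklearn.isotonic import IsotonicRegression

    rng_ = means.max() - means.min()
    if rng_ == 0:
        monotone = True
        residual = 0.0
    else:
        resids = []
        for increasing in (True, False):
            fit = IsotonicRegression(increasing=increasing).fit_transform(d, means)
            resids.append(np.sqrt(np.mean((fit - means) ** 2)))
        residual = float(min(resids) / rng_)
        monotone = residual < 0.05
    df = pd.DataFrame({"dose": d, "mean": means, "sem": sems, "n_units": ns})
    df.attrs["monotone"] = monotone
    df.attrs["isotonic_residual"] = residual
    return df


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH-adjusted p values (off by default in all pipelines here)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), alpha=alpha, method="fdr_bh")[1]
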
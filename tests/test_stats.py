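"""Aggregation rule, Welch t, two-way ANOVA and response kinetics.

The t and F statistics are checked against explicit textbook formulas
computed inside the tests (sums of squares by hand), independent of the
scipy/statsmodels implementations behind the package functions.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

import ktrkit as k


def _measurements(values_by_field: dict, condition: str | None = None) -> pd.DataFrame:
    rows = []
    for field, vals in values_by_field.items():
        for i, v in enumerate(vals):
            row = {"field": field, "cell_id": i + 1, "cn_ratio": v, "valid": True}
            if condition is not None:
                row["condition"] = condition
            rows.append(row)
    return pd.DataFrame(rows)


class TestAggregate:
    def test_image_mean_is_the_data_point(self):
        with pytest.warns(UserWarning, match="valid cells"):
            (s,) = k.aggregate(_measurements({0: [0.5, 0.7]}), min_cells=10)
        assert s.mean == pytest.approx(0.6)
        assert s.n_units == 1

    def test_identical_images_have_zero_sem(self):
        cells = list(np.linspace(0.4, 0.9, 12))
        (s,) = k.aggregate(_measurements({0: cells, 1: cells, 2: cells}))
        assert s.n_units == 3
        assert s.sem == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_cell_order_and_split_passes(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.3, 1.5, 24).tolist()
        df1 = _measurements({0: vals[:12], 1: vals[12:]})
        shuffled = df1.sample(frac=1.0, random_state=0).reset_index(drop=True)
        # split each image's cells into two passes (duplicate rows per cell)
        split = pd.concat([df1, df1], ignore_index=True)
        for df in (shuffled, split):
            (a,) = k.aggregate(df1)
            (b,) = k.aggregate(df)
            assert b.mean == pytest.approx(a.mean)
            assert b.sem == pytest.approx(a.sem)

    def test_invalid_cells_excluded(self):
        df = _measurements({0: list(np.full(12, 1.0))})
        df.loc[0, "valid"] = False
        df.loc[0, "cn_ratio"] = 99.0
        (s,) = k.aggregate(df)
        assert s.mean == pytest.approx(1.0)

    def test_empty_input_errors(self):
        df = _measurements({0: [1.0] * 12})
        df["valid"] = False
        with pytest.raises(ValueError, match="no valid"):
            k.aggregate(df)

    def test_simulated_replicates_recover_generator_mean(self, params):
        rng = np.random.default_rng(11)
        sensor = k.SensorSpec(name="s", nls_score=10.5, mw_kda=32, copies=2)
        true_cn = k.steady_state_cn(sensor, 0.0, params)
        fields = {f: (true_cn * rng.lognormal(0, 0.06, 15)).tolist() for f in range(3)}
        (s,) = k.aggregate(_measurements(fields))
        # lognormal(0, 0.06) has mean exp(0.0018); CI check via SEM
        assert abs(s.mean - true_cn) < 4 * max(s.sem, 1e-3)


def _welch_oracle(a, b):
    """Hand-coded Welch t, df, and two-sided p (t CDF via incomplete beta)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, df, p


class TestTTest:
    def test_identical_constant_groups_give_p_one(self):
        res = k.t_test_two_tailed([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0

    def test_matches_hand_computed_welch(self):
        a = [0.61, 0.58, 0.65, 0.59]
        b = [0.92, 1.01, 0.88]
        res = k.t_test_two_tailed(a, b)
        t, df, p = _welch_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-8)
        assert res.df == pytest.approx(df, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(1.0, 0.2, rng.integers(3, 9))
            b = rng.normal(1.2, 0.3, rng.integers(3, 9))
            res = k.t_test_two_tailed(a, b)
            t, df, p = _welch_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_large_shift_tiny_variance_is_decisive(self):
        a = np.array([1.0, 1.0001, 0.9999, 1.0])
        res = k.t_test_two_tailed(a, a + 10.0)
        assert res.p_value < 1e-6

    def test_groups_of_one_rejected(self):
        with pytest.raises(ValueError):
            k.t_test_two_tailed([1.0], [2.0, 3.0])


def _anova_2x2_oracle(df):
    """Balanced two-way ANOVA sums of squares by hand."""
    grand = df["y"].mean()
    n = len(df)
    cells = df.groupby(["fa", "fb"])["y"]
    r = cells.size().iloc[0]
    ss_a = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("fa")
    )
    ss_b = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("fb")
    )
    ss_cells = sum(len(g) * (g.mean() - grand) ** 2 for _, g in cells)
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((g - g.mean()) ** 2).sum() for _, g in cells)
    df_a = df["fa"].nunique() - 1
    df_b = df["fb"].nunique() - 1
    df_ab = df_a * df_b
    df_err = n - df["fa"].nunique() * df["fb"].nunique()
    return {
        "A": (ss_a / df_a) / (ss_err / df_err),
        "B": (ss_b / df_b) / (ss_err / df_err),
        "AB": (ss_ab / df_ab) / (ss_err / df_err),
    }


def _balanced_2x2():
    rows = []
    data = {
        ("ctrl", "s1"): [0.62, 0.58, 0.66],
        ("ctrl", "s2"): [0.41, 0.44, 0.40],
        ("fsk", "s1"): [1.55, 1.49, 1.61],
        ("fsk", "s2"): [0.52, 0.47, 0.50],
    }
    for (fa, fb), ys in data.items():
        rows += [{"fa": fa, "fb": fb, "y": y} for y in ys]
    return pd.DataFrame(rows)


class TestAnovaTwoWay:
    def test_balanced_fixture_matches_hand_sums_of_squares(self):
        df = _balanced_2x2()
        results = {r.factors: r for r in k.anova_two_way(df, "y", "fa", "fb")}
        oracle = _anova_2x2_oracle(df)
        assert results[("fa",)].statistic == pytest.approx(oracle["A"], abs=1e-8)
        assert results[("fb",)].statistic == pytest.approx(oracle["B"], abs=1e-8)
        assert results[("fa", "fb")].statistic == pytest.approx(oracle["AB"], abs=1e-8)

    def test_inert_factor_has_f_near_zero(self):
        rows = []
        for fb in ("x", "y"):  # identical cell means across factor B
            for fa, mu in (("lo", 0.5), ("hi", 1.5)):
                rows += [{"fa": fa, "fb": fb, "y": mu + d} for d in (-0.05, 0.0, 0.05)]
        results = {r.factors: r for r in k.anova_two_way(pd.DataFrame(rows), "y", "fa", "fb")}
        assert results[("fb",)].statistic == pytest.approx(0.0, abs=1e-10)
        assert results[("fb",)].p_value > 0.99

    def test_additive_construction_has_null_interaction(self):
        rows = []
        a_eff = {"lo": 0.0, "hi": 0.8}
        b_eff = {"x": 0.0, "y": 0.3}
        for fa in a_eff:
            for fb in b_eff:
                mu = 0.5 + a_eff[fa] + b_eff[fb]
                rows += [{"fa": fa, "fb": fb, "y": mu + d} for d in (-0.04, 0.04)]
        results = {r.factors: r for r in k.anova_two_way(pd.DataFrame(rows), "y", "fa", "fb")}
        assert results[("fa", "fb")].p_value > 0.5

    def test_single_level_factor_reduces_to_one_way(self):
        df = _balanced_2x2()
        df["fb"] = "only"
        with pytest.warns(UserWarning, match="one level"):
            results = k.anova_two_way(df, "y", "fa", "fb")
        assert len(results) == 1
        assert results[0].factors == ("fa",)


class TestResponseMetrics:
    def test_flat_trace_has_unit_fold_and_no_onset(self):
        t = np.arange(0.0, 30.0)
        traces = np.full((3, t.size), 0.6)
        rm = k.response_metrics(traces, t, event_time=3.0)
        assert np.allclose(rm.fold_change, 1.0)
        assert rm.t_signif is None
        assert rm.t_half is None

    def test_logistic_rise_recovers_half_time_and_plateau(self):
        t = np.arange(0.0, 40.0)
        rng = np.random.default_rng(2)
        base, plateau, t50, tau = 0.6, 2.4, 8.0, 1.5
        clean = base + (plateau - base) / (1.0 + np.exp(-(t - t50) / tau))
        traces = clean[None, :] * rng.lognormal(0, 0.01, (4, t.size))
        rm = k.response_metrics(traces, t, event_time=2.0)
        assert rm.t_half == pytest.approx(8.0, abs=1.0)
        assert rm.plateau_fold == pytest.approx(4.0, abs=0.2)
        assert rm.t_signif is not None and rm.t_signif <= 8.0

    def test_inhibitor_step_down_detected(self):
        t = np.arange(0.0, 30.0)
        clean = np.where(t < 10.0, 1.2, 1.2 - 0.6 * (1 - np.exp(-(t - 10.0) / 2.0)))
        traces = np.vstack([clean, clean * 1.01, clean * 0.99])
        rm = k.response_metrics(traces, t, event_time=10.0)
        assert rm.plateau_fold < 0.7
        assert rm.t_half is not None and rm.t_half >= 10.0
        post = rm.fold_change[t >= 10.0]
        assert post[-1] < post[0]

    def test_no_baseline_window_errors(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError, match="baseline"):
            k.response_metrics(np.ones((3, 10)), t, event_time=0.0)


class TestDoseResponse:
    def _summary(self, dose, mean):
        return k.GroupSummary(condition=f"{dose}", n_units=3, mean=mean, sem=0.05)

    def test_flat_series_is_trivially_monotone(self):
        table = k.dose_response({d: self._summary(d, 0.8) for d in (0, 1, 3)})
        assert table.attrs["monotone"]

    def test_sorted_output_invariant_to_input_order(self):
        summaries = {d: self._summary(d, m) for d, m in [(3, 1.2), (0, 0.5), (30, 1.8), (10, 1.5)]}
        t1 = k.dose_response(summaries)
        t2 = k.dose_response(dict(reversed(list(summaries.items()))))
        pd.testing.assert_frame_equal(t1, t2)
        assert list(t1["dose"]) == [0, 3, 10, 30]

    def test_simulated_agonist_series_is_increasing(self, params, pharm):
        """Steady-state C/N of a mid-score sensor rises monotonically with
        agonist dose under the default pharmacology."""
        sensor = k.SensorSpec(name="s", nls_score=10.5, mw_kda=32, copies=2)
        fsk = pharm.lookup("Fsk")
        summaries = {}
        for dose_um in (0.0, 1.0, 3.0, 10.0, 30.0):
            a = k.activities.hill(dose_um * 1e3, fsk.ec50_nm, fsk.hill)
            cn = k.steady_state_cn(sensor, a, params)
            summaries[dose_um] = k.GroupSummary(
                condition=f"{dose_um}uM", n_units=3, mean=cn, sem=0.01
            )
        table = k.dose_response(summaries)
        assert (np.diff(table["mean"]) > 0).all()
        assert table.attrs["monotone"]

    def test_fewer_than_two_doses_rejected(self):
        with pytest.raises(ValueError):
            k.dose_response({1.0: self._summary(1.0, 0.5)})


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    adj = k.stats.benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
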
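"""Median split, Kaplan-Meier estimator, log-rank test and the screen."""

import numpy as np
import pandas as pd
import pytest

import swimnet as sw
from swimnet.survival import DegenerateSplitError

from conftest import make_matrix


def km_oracle(t, times, events):
    """Brute-force risk-set product for the survival probability at t."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        n_risk = int(np.sum(times >= u))
        d = int(np.sum((times == u) & (events == 1)))
        s *= 1 - d / n_risk
    return s


class TestMedianSplit:
    def test_even_split(self):
        labels = sw.median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}))
        assert set(labels[labels == "low"].index) == {"a", "b"}
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_symmetric_tie_values(self):
        labels = sw.median_split(pd.Series({"a": 1.0, "b": 1.0, "c": 9.0, "d": 9.0}))
        assert set(labels[labels == "low"].index) == {"a", "b"}

    def test_constant_expression_rejected(self):
        with pytest.raises(DegenerateSplitError):
            sw.median_split(pd.Series([2.0, 2.0, 2.0, 2.0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sw.median_split(pd.Series([1.0, 2.0, 3.0]))


class TestKMCurve:
    def test_all_censored_curve_flat(self):
        curve = sw.km_curve([3.0, 5.0, 8.0], [0, 0, 0])
        assert curve(0) == 1.0 and curve(100) == 1.0

    def test_hand_computed_product_limit(self):
        curve = sw.km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve(0.5) == pytest.approx(1.0)
        assert curve(1.0) == pytest.approx(2 / 3)
        assert curve(2.5) == pytest.approx(1 / 3)
        assert curve(3.0) == pytest.approx(0.0)

    def test_single_subject_step(self):
        curve = sw.km_curve([4.0], [1])
        assert curve(3.9) == 1.0 and curve(4.0) == 0.0

    def test_matches_risk_set_oracle_with_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 20, size=40).astype(float)
        events = rng.integers(0, 2, size=40)
        curve = sw.km_curve(times, events)
        for t in np.arange(0.0, 25.0, 0.5):
            assert curve(t) == pytest.approx(km_oracle(t, times, events), abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            sw.km_curve([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_p_one(self):
        times = np.array([2.0, 4.0, 6.0, 8.0])
        events = np.array([1, 1, 0, 1])
        assert sw.logrank_p((times, events), (times, events)) == pytest.approx(1.0)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(1)
        a = (rng.exponential(10, 30), rng.integers(0, 2, 30))
        b = (rng.exponential(4, 25), rng.integers(0, 2, 25))
        assert sw.logrank_p(a, b) == pytest.approx(sw.logrank_p(b, a))

    def test_no_events_anywhere_warns_p_one(self):
        a = (np.array([1.0, 2.0]), np.array([0, 0]))
        b = (np.array([3.0, 4.0]), np.array([0, 0]))
        with pytest.warns(UserWarning):
            assert sw.logrank_p(a, b) == 1.0

    def test_power_under_strong_hazard_ratio(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            ta = rng.exponential(1.0, 100)
            tb = rng.exponential(1 / 3, 100)  # hazard ratio 3
            ea = np.ones(100, dtype=int)
            eb = np.ones(100, dtype=int)
            rejections += sw.logrank_p((ta, ea), (tb, eb)) < 0.05
        assert rejections / n_rep > 0.9


class TestSurvivalScreen:
    def make_cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i:02d}" for i in range(n)]
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(3, n)), index=["g1", "g2", "g3"], columns=samples
        )
        clinical = pd.DataFrame(
            {
                "sample_id": samples,
                "time": rng.exponential(10, n),
                "event": rng.integers(0, 2, n),
            }
        )
        return expr, clinical

    def test_single_gene_fdr_equals_p(self):
        expr, clinical = self.make_cohort()
        table = sw.survival_screen(expr, clinical, ["g1"])
        assert table.iloc[0]["fdr"] == pytest.approx(table.iloc[0]["p_value"])

    def test_bh_formula_on_known_p_list(self):
        # direct BH arithmetic: {0.01, 0.02, 0.03} -> all 0.03
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_degenerate_gene_gets_nan_and_is_excluded_from_bh(self):
        expr, clinical = self.make_cohort()
        expr.loc["g2"] = 4.0  # constant -> degenerate split
        table = sw.survival_screen(expr, clinical, ["g1", "g2", "g3"])
        by_gene = table.set_index("gene")
        assert np.isnan(by_gene.loc["g2", "p_value"]) and np.isnan(by_gene.loc["g2", "fdr"])
        # BH m = 2: adjusted = min(1, p * 2 / rank)
        tested = by_gene.drop("g2").sort_values("p_value")
        expected = np.minimum.accumulate(
            (tested["p_value"].to_numpy() * 2 / np.arange(1, 3))[::-1]
        )[::-1]
        assert np.allclose(tested["fdr"].to_numpy(), np.minimum(expected, 1.0))

    def test_bh_independent_of_row_order(self):
        expr, clinical = self.make_cohort(seed=5)
        t1 = sw.survival_screen(expr, clinical, ["g1", "g2", "g3"])
        t2 = sw.survival_screen(expr, clinical, ["g3", "g1", "g2"])
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_prognostic_gene_ranks_first(self):
        first = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            n = 60
            samples = [f"s{i:02d}" for i in range(n)]
            expr = pd.DataFrame(
                rng.normal(0, 1, size=(21, n)),
                index=["prog"] + [f"null{i:02d}" for i in range(20)],
                columns=samples,
            )
            hazard = 0.1 * np.exp(1.5 * expr.loc["prog"].to_numpy())
            times = rng.exponential(1 / hazard)
            censor = rng.exponential(20, n)
            clinical = pd.DataFrame(
                {
                    "sample_id": samples,
                    "time": np.minimum(times, censor),
                    "event": (times <= censor).astype(int),
                }
            )
            table = sw.survival_screen(expr, clinical, list(expr.index))
            first += table.iloc[0]["gene"] == "prog"
        assert first / n_rep >= 0.9
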
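import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from sigrecover import (
    ConfigurationError,
    GroupExpression,
    Roles,
    Thresholds,
    UndefinedStatisticError,
    correlate_profiles,
    gene_metrics,
    percent_change,
    recovery_factor,
    scs_residual,
    summarize_transcriptome,
)
from sigrecover.metrics import strength_label


class TestPerGeneMetrics:
    @pytest.mark.parametrize(
        "x,ref,expected",
        [(110.0, 100.0, 10.0), (100.0, 100.0, 0.0), (50.0, 200.0, -75.0)],
    )
    def test_percent_change(self, x, ref, expected):
        assert percent_change(x, ref) == pytest.approx(expected)

    def test_percent_change_zero_reference_undefined(self):
        assert np.isnan(percent_change(5.0, 0.0))

    @pytest.mark.parametrize(
        "pain,scs,naive,expected",
        [
            (200.0, 100.0, 100.0, 1.0),  # full recovery: scs == naive
            (200.0, 200.0, 100.0, 0.0),  # no movement: scs == pain
            (200.0, 150.0, 100.0, 0.5),
            (200.0, 250.0, 100.0, -0.5),  # moved away
            (200.0, 80.0, 100.0, 1.2),  # overshoot
        ],
    )
    def test_recovery_factor(self, pain, scs, naive, expected):
        assert recovery_factor(pain, scs, naive) == pytest.approx(expected)

    def test_recovery_factor_undefined_when_pain_equals_naive(self):
        assert np.isnan(recovery_factor(100.0, 120.0, 100.0))

    @pytest.mark.parametrize(
        "scs,naive,expected",
        [(100.0, 100.0, 0.0), (115.0, 100.0, 15.0), (84.0, 100.0, -16.0)],
    )
    def test_scs_residual(self, scs, naive, expected):
        assert scs_residual(scs, naive) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pain=st.floats(1.0, 1e4),
        scs=st.floats(1.0, 1e4),
        naive=st.floats(1.0, 1e4),
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, pain, scs, naive, a, b):
        """R_f is invariant under x -> a*x + b of all three expressions;
        percent change under pure rescaling x -> a*x."""
        rf = recovery_factor(pain, scs, naive)
        rf_t = recovery_factor(a * pain + b, a * scs + b, a * naive + b)
        if np.isfinite(rf):
            assert rf_t == pytest.approx(rf, rel=1e-6, abs=1e-9)
        pc = percent_change(pain, naive)
        assert percent_change(a * pain, a * naive) == pytest.approx(pc, rel=1e-6, abs=1e-9)


class TestCorrelation:
    def _fc(self, naive_col, treat_col):
        idx = [f"g{i}" for i in range(len(naive_col))]
        return pd.DataFrame({"naive": naive_col, "t": treat_col}, index=idx)

    def test_identical_profiles(self):
        v = list(np.linspace(-2, 2, 12))
        fc = self._fc(v, v)
        res = correlate_profiles(fc, "t", fc.index, naive="naive")
        assert res.r == pytest.approx(1.0)
        assert res.significant and res.p < 1e-6

    def test_negated_profiles(self):
        v = list(np.linspace(-2, 2, 12))
        res = correlate_profiles(self._fc(v, [-x for x in v]), "t", [f"g{i}" for i in range(12)], naive="naive")
        assert res.r == pytest.approx(-1.0)

    def test_matches_product_moment_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        fc = self._fc(list(x), list(y))
        res = correlate_profiles(fc, "t", fc.index, naive="naive")
        r_o, p_o = oracles.pearson_oracle(list(y), list(x))
        assert res.r == pytest.approx(r_o, abs=1e-10)
        assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_too_few_genes(self):
        fc = self._fc([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            correlate_profiles(fc, "t", fc.index, naive="naive")

    def test_zero_variance(self):
        fc = self._fc([1.0, 1.0, 1.0, 1.0], [0.1, 0.4, -0.2, 0.9])
        with pytest.raises(UndefinedStatisticError):
            correlate_profiles(fc, "t", fc.index, naive="naive")

    @pytest.mark.parametrize(
        "r,label",
        [(0.1, "very weak"), (-0.25, "weak"), (0.45, "moderate"), (0.65, "strong"), (0.95, "very strong")],
    )
    def test_strength_labels(self, r, label):
        assert strength_label(r) == label


class TestSummaries:
    def test_ten_gene_fixture_matches_bruteforce(self, ten_gene_expression):
        ge = ten_gene_expression
        summ = summarize_transcriptome(ge, list(ge.gene_ids), name="toy")
        expected = oracles.summarize_oracle(
            dict(ge.x_naive), dict(ge.x_pain),
            {t: dict(ge.x_scs(t)) for t in ge.roles.treatments},
        )
        assert summ.pct_changed == pytest.approx(expected["pct_changed"], abs=1e-10)
        assert summ.up_share == pytest.approx(expected["up_share"], abs=1e-10)
        assert summ.down_share == pytest.approx(expected["down_share"], abs=1e-10)
        for t in ge.roles.treatments:
            ts, exp = summ.treatments[t], expected["treatments"][t]
            for key in (
                "pct_recovered_le_one",
                "pct_recovered_unit_interval",
                "pct_near_naive",
                "n_rf_defined",
                "n_rf_undefined",
            ):
                assert getattr(ts, key) == pytest.approx(exp[key], abs=1e-10), (t, key)

    def test_degenerate_all_unchanged(self):
        roles = Roles(naive="n", reference="r", treatments=("t",))
        vals = pd.DataFrame(
            {"n": [10.0, 20.0, 5.0], "r": [10.0, 20.0, 5.0], "t": [11.0, 19.0, 5.0]},
            index=["g1", "g2", "g3"],
        )
        summ = summarize_transcriptome(GroupExpression(vals, roles), ["g1", "g2", "g3"])
        assert summ.pct_changed == 0.0
        assert summ.up_share is None
        ts = summ.treatments["t"]
        assert ts.pct_recovered_le_one is None and ts.pct_near_naive is None

    def test_rf_rule_semantics_pinned(self):
        """A treatment identical to the untreated reference (no movement,
        R_f = 0 everywhere) counts as fully recovered under both rules; a
        treatment strictly moving away from baseline (R_f < 0) still counts
        under 'R_f <= 1' but not under the unit-interval rule."""
        roles = Roles(naive="n", reference="r", treatments=("same", "away"))
        n = np.array([100.0, 50.0, 200.0, 80.0])
        p = np.array([150.0, 30.0, 300.0, 50.0])
        vals = pd.DataFrame(
            {"n": n, "r": p, "same": p, "away": p + (p - n)},
            index=[f"g{i}" for i in range(4)],
        )
        summ = summarize_transcriptome(GroupExpression(vals, roles), list(vals.index))
        assert summ.treatments["same"].pct_recovered_le_one == 100.0
        assert summ.treatments["same"].pct_recovered_unit_interval == 100.0
        assert summ.treatments["away"].pct_recovered_le_one == 100.0
        assert summ.treatments["away"].pct_recovered_unit_interval == 0.0

    def test_threshold_monotonicity(self, ten_gene_expression):
        """%C_p is non-increasing in the change threshold; %D_n is
        non-decreasing in the near-naive band."""
        ge = ten_gene_expression
        genes = list(ge.gene_ids)
        pct_changed = []
        near = []
        for change_min, band in [(0.05, 0.05), (0.10, 0.15), (0.20, 0.30), (0.60, 0.60)]:
            thr = Thresholds(change_min=change_min, near_naive_max=0.15)
            pct_changed.append(summarize_transcriptome(ge, genes, thr).pct_changed)
            thr_b = Thresholds(change_min=0.10, near_naive_max=band)
            near.append(summarize_transcriptome(ge, genes, thr_b).treatments["tA"].pct_near_naive)
        assert all(a >= b for a, b in zip(pct_changed, pct_changed[1:]))
        assert all(a <= b for a, b in zip(near, near[1:]))

    def test_gene_metrics_undefined_flags(self, ten_gene_expression):
        gm = gene_metrics(ten_gene_expression)
        assert np.isnan(gm.loc["g04", "rf_tA"])  # x_pain == x_naive
        assert not gm.loc["g04", "changed"]
        assert gm.loc["g01", "changed"]  # +10% inclusive boundary
        assert not gm.loc["g05", "changed"]  # +9.9% below threshold

    def test_invalid_thresholds_name_the_field(self):
        with pytest.raises(ConfigurationError, match="change_min"):
            Thresholds(change_min=1.5)
        with pytest.raises(ConfigurationError, match="rf_rule"):
            Thresholds(rf_rule="banana")
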
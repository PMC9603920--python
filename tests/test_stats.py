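"""Percent inhibition, flux ratio, and the comparison scheme (Shapiro gate,
Student t, ANOVA + Dunnett)."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant.stats import (
    ConditionSummary,
    NoInductionError,
    anova_dunnett,
    autophagy_flux,
    dunnett_critical_value,
    flux_table,
    normality_gate,
    percent_inhibition,
    screen_report,
    t_test_two_group,
)


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "treated,expected", [(5.0, 0.0), (1.0, 100.0), (3.0, 50.0)],
        ids=["no-effect", "full", "midpoint"],
    )
    def test_known_points(self, treated, expected):
        pct, capped = percent_inhibition(1.0, 5.0, treated)
        assert pct == pytest.approx(expected)
        assert not capped

    def test_below_baseline_flagged_not_clipped(self):
        pct, capped = percent_inhibition(1.0, 5.0, 0.0)
        assert pct == pytest.approx(125.0)
        assert capped

    def test_no_induction_is_an_error(self):
        with pytest.raises(NoInductionError):
            percent_inhibition(2.0, 2.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_affine_invariance(self, shift, scale):
        base = percent_inhibition(1.0, 5.0, 2.5)[0]
        shifted = percent_inhibition(1.0 + shift, 5.0 + shift, 2.5 + shift)[0]
        scaled = percent_inhibition(scale * 1.0, scale * 5.0, scale * 2.5)[0]
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestFlux:
    def test_ratio_of_known_intensities(self):
        assert autophagy_flux(2.0, 1.0) == pytest.approx(2.0)
        assert autophagy_flux(1.3, 1.3) == pytest.approx(1.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            autophagy_flux(2.0, 0.0)

    def test_subunity_flux_warned_not_rejected(self, caplog):
        with caplog.at_level("WARNING"):
            assert autophagy_flux(0.5, 1.0) == pytest.approx(0.5)
        assert "no measurable flux" in caplog.text

    def test_planted_lymphoblast_table_reproduces_group_ordering(self):
        """ALS-like lines show elevated flux; the inhibitor restores control
        levels; the LC3-II difference column tracks the same direction."""
        rng = np.random.default_rng(0)

        def lines(group, flux, n=4):
            minus = rng.uniform(0.8, 1.2, n)
            return pd.DataFrame({
                "group": group, "line": [f"{group}{i}" for i in range(n)],
                "lc3ii_plus": minus * flux * rng.normal(1, 0.03, n),
                "lc3ii_minus": minus,
            })

        df = pd.concat([lines("control", 1.5), lines("ALS", 2.4), lines("ALS+inh", 1.5)])
        out = flux_table(df)
        means = out.groupby("group").flux_ratio.mean()
        assert means["ALS"] > means["control"]
        assert means["ALS+inh"] == pytest.approx(means["control"], rel=0.15)
        diffs = out.groupby("group").lc3ii_difference.mean()
        assert diffs["ALS"] > diffs["ALS+inh"]


class TestNormalityGate:
    def test_constant_sample_flagged_degenerate(self):
        df = normality_gate({"g": [2.0, 2.0, 2.0, 2.0]})
        assert df.note.iloc[0].startswith("degenerate")

    def test_small_sample_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            df = normality_gate({"g": [1.0, 2.0]})
        assert df.note.iloc[0].startswith("skipped")

    def test_bimodal_sample_fails_gate(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(-3, 0.5, 25), rng.normal(3, 0.5, 25)])
        df = normality_gate({"g": v})
        assert df.normal.iloc[0] is False or df.p_value.iloc[0] < 0.05

    def test_type_i_error_near_alpha_for_normal_samples(self):
        """Over 1000 seeded normal samples the gate rejects ~5% at alpha=.05."""
        rng = np.random.default_rng(7)
        rejects = 0
        for _ in range(1000):
            p = normality_gate({"g": rng.normal(size=50)}).p_value.iloc[0]
            rejects += p < 0.05
        assert 0.03 <= rejects / 1000 <= 0.07


class TestTTest:
    def test_matches_closed_form_student_statistic(self):
        a = np.array([1.1, 2.3, 2.9, 4.2])
        b = np.array([2.0, 3.1, 3.9, 5.5, 4.4])
        res = t_test_two_group(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * sps.t.sf(abs(t), na + nb - 2)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_identical_groups_give_t0_p1(self):
        r = t_test_two_group([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        r2 = t_test_two_group([2.0, 2.0], [2.0, 2.0])
        assert (r2.statistic, r2.p_value) == (0.0, 1.0)

    def test_separation_limit_drives_p_to_zero(self):
        r = t_test_two_group([1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0])
        assert r.p_value < 1e-6

    def test_zero_variance_in_both_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_group([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_group([1.0], [1.0, 2.0])

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 7), rng.normal(0.4, 1.2, 9)
        f, _ = sps.f_oneway(a, b)
        t = t_test_two_group(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-8)


class TestDunnett:
    def test_single_comparison_reduces_to_t_test(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        _, (comp,) = anova_dunnett({"t": a, "ref": b}, "ref")
        tt = t_test_two_group(a, b)
        assert comp.p_value == pytest.approx(tt.p_value, abs=1e-12)
        assert comp.statistic == pytest.approx(tt.statistic, abs=1e-12)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(0.3 * i, 1, 6) for i in range(4)}
        groups["ref"] = rng.normal(0, 1, 6)
        _, comps = anova_dunnett(groups, "ref")
        n = 6
        df = 5 * n - 5
        for c in comps:
            unadj = 2 * sps.t.sf(abs(c.statistic), df)
            assert c.p_value >= unadj - 1e-6

    def test_adjusted_p_monotone_in_number_of_comparisons(self):
        rng = np.random.default_rng(5)
        data = {f"g{i}": rng.normal(0, 1, 6) for i in range(4)}
        ref = rng.normal(0.5, 1, 6)
        p_g0 = []
        for k in (1, 2, 3, 4):
            groups = {f"g{i}": data[f"g{i}"] for i in range(k)}
            groups["ref"] = ref
            _, comps = anova_dunnett(groups, "ref", rng=np.random.default_rng(9))
            p_g0.append(next(c.p_value for c in comps if c.comparison.startswith("g0 ")))
        assert all(b >= a - 5e-3 for a, b in zip(p_g0, p_g0[1:]))

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett({"a": [1, 2, 3]}, "ref")

    def test_monte_carlo_route_matches_exact_integral(self):
        """For wide comparison families the sampled max-|t| null must agree
        with the library's quasi-Monte-Carlo multivariate-t integral."""
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(0.2 * (i % 3), 1, 4) for i in range(12)}
        groups["ref"] = rng.normal(0, 1, 4)
        _, comps = anova_dunnett(groups, "ref", rng=np.random.default_rng(3))
        exact = sps.dunnett(*[groups[f"g{i}"] for i in range(12)],
                            control=groups["ref"], rng=np.random.default_rng(1))
        for c, p in zip(comps, exact.pvalue):
            assert c.p_value == pytest.approx(p, abs=0.01)

    def test_critical_value_agrees_with_library_decisions(self):
        c = dunnett_critical_value(3, 5, alpha=0.05)
        agree = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            gs = [rng.normal(0, 1, 5) for _ in range(3)]
            ref = rng.normal(0, 1, 5)
            res = sps.dunnett(*gs, control=ref, rng=np.random.default_rng(1))
            sp2 = sum(((g - g.mean()) ** 2).sum() for g in gs + [ref]) / 16
            tmax = max(abs(g.mean() - ref.mean()) / np.sqrt(sp2 * 2 / 5) for g in gs)
            agree += (res.pvalue.min() < 0.05) == (tmax > c)
        assert agree == 30


class TestScreenReport:
    def _summaries(self, compound_means, rng):
        out = [
            ConditionSummary("control", tuple(1.0 + 0.05 * rng.normal(size=3))),
            ConditionSummary("inducer", tuple(3.0 + 0.05 * rng.normal(size=3))),
        ]
        for name, m in compound_means.items():
            out.append(ConditionSummary(name, tuple(m + 0.05 * rng.normal(size=3))))
        return out

    def test_planted_inhibitor_is_the_only_hit(self):
        rng = np.random.default_rng(0)
        means = {f"c{i:02d}": 3.0 for i in range(10)}
        means["planted"] = 1.2
        report = screen_report(self._summaries(means, rng), "control", "inducer")
        assert report[report.is_hit].compound.tolist() == ["planted"]

    def test_all_inert_compounds_give_no_hits(self):
        rng = np.random.default_rng(1)
        means = {f"c{i:02d}": 3.0 for i in range(10)}
        report = screen_report(self._summaries(means, rng), "control", "inducer")
        assert not report.is_hit.any()

    def test_no_compounds_gives_empty_table(self):
        rng = np.random.default_rng(2)
        report = screen_report(self._summaries({}, rng), "control", "inducer")
        assert report.empty

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            screen_report([ConditionSummary("inducer", (3.0, 3.1))], "control", "inducer")
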
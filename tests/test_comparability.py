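"""True-score CIs, the six comparability criteria, and difference statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gicomp as g
from gicomp.comparability import CriterionSpec, paired_cohens_d
from gicomp.intervals import Interval
from gicomp.reliability import ReliabilityLookup


class TestTrueScoreCI:
    def test_estimated_true_score_regresses_toward_100(self):
        assert g.estimated_true_score(100, 0.5) == 100
        assert g.estimated_true_score(130, 0.9) == pytest.approx(127)
        assert g.estimated_true_score(130, 1.0) == 130

    def test_ci_bounds_hand_arithmetic(self):
        ci = g.true_score_ci(130, 0.9)
        assert ci.lower == pytest.approx(118.18, abs=0.01)
        assert ci.upper == pytest.approx(135.82, abs=0.01)

    def test_perfect_reliability_gives_point_interval(self):
        ci = g.true_score_ci(120, 1.0)
        assert ci.lower == ci.upper == 120

    def test_interval_symmetric_about_100_at_the_mean(self):
        for r in (0.5, 0.8, 0.95):
            ci = g.true_score_ci(100, r)
            assert ci.lower + ci.upper == pytest.approx(200)

    @pytest.mark.parametrize(
        "r, width", [(0.98, 8), (0.97, 10), (0.95, 13), (0.99, 6), (0.93, 15), (0.94, 14)]
    )
    def test_reported_widths(self, r, width):
        assert g.ci_width_points(r) == width

    def test_width_zero_at_perfect_reliability(self):
        assert g.ci_width_points(1.0) == 0

    def test_width_nonincreasing_in_reliability_above_half(self):
        rs = np.linspace(0.5, 1.0, 200)
        widths = [g.ci_width_points(r) for r in rs]
        assert all(w2 <= w1 for w1, w2 in zip(widths, widths[1:]))


class TestIntervalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((90, 110), (105, 120), True),
            ((90, 100), (100.5, 110), False),
            ((90, 100), (100, 110), True),  # touching closed intervals overlap
        ],
    )
    def test_closed_interval_overlap(self, a, b, expected):
        assert g.intervals_overlap(Interval(*a), Interval(*b)) is expected

    @given(
        st.tuples(st.integers(40, 160), st.integers(0, 30)),
        st.tuples(st.integers(40, 160), st.integers(0, 30)),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_is_symmetric(self, a, b):
        ia = Interval(a[0], a[0] + a[1])
        ib = Interval(b[0], b[0] + b[1])
        assert g.intervals_overlap(ia, ib) == g.intervals_overlap(ib, ia)


def make_lookup(r_a=0.95, r_b=0.90, band=(5, 21), rtt=0.85):
    return ReliabilityLookup(
        overall={"A": r_a, "B": r_b},
        by_age={("A", band): r_a, ("B", band): r_b},
        by_age_iq={
            ("A", band, grp): r_a for grp in ("below_average", "average", "above_average")
        } | {
            ("B", band, grp): r_b for grp in ("below_average", "average", "above_average")
        },
        retest={"A": rtt, "B": rtt},
    )


class TestEvaluateCriterion:
    def test_equal_iqs_comparable_under_every_criterion(self):
        lookup = make_lookup()
        for kind in g.CRITERIA:
            flag = g.evaluate_criterion(
                104, 104, CriterionSpec(kind), lookup, "A", "B", band=(5, 21)
            )
            assert flag is True

    def test_nominal_category_boundary_splits_84_85(self):
        lookup = make_lookup()
        assert (
            g.evaluate_criterion(84, 85, CriterionSpec("NomIQ"), lookup, "A", "B") is False
        )

    def test_nomci_comparable_when_category_spans_intersect(self):
        # CIs [108,116] and [117,125]: {average, above_average} and {above_average}
        lookup = make_lookup()
        flag = g.evaluate_criterion(
            112, 121, CriterionSpec("NomCI"), lookup, "A", "B", band=(5, 21)
        )
        assert flag is True

    def test_unavailable_cell_excludes_subject(self):
        lookup = ReliabilityLookup(overall={"A": 0.95, "B": 0.9})
        flag = g.evaluate_criterion(
            100, 105, CriterionSpec("CI_age"), lookup, "A", "B", band=(5, 21)
        )
        assert flag is None


class TestPairComparison:
    def test_self_pair_rates_100_percent_everywhere(self, cohort, battery, norms, lookup):
        pair = g.compare_pair(cohort, battery, norms, "FSIQ7", "FSIQ7", lookup)
        for kind in g.CRITERIA:
            for grouping in ("overall", "iq", "age"):
                rates = g.comparability_rates(pair, kind, grouping)
                valid = rates["pct_comparable"].dropna()
                assert (valid == 100.0).all()

    def test_rate_aggregation_identity(self, pair):
        # per-group rates recombine exactly to the overall rate
        for kind in g.CRITERIA:
            overall = g.comparability_rates(pair, kind, "overall")
            by_iq = g.comparability_rates(pair, kind, "iq").dropna()
            recombined = (by_iq["pct_comparable"] * by_iq["n"]).sum() / by_iq["n"].sum()
            assert recombined == pytest.approx(overall["pct_comparable"].iloc[0], abs=1e-9)

    def test_nomci_rate_never_below_nomiq_rate(self, pair):
        # the CI's category span contains the point category
        nomiq = g.comparability_rates(pair, "NomIQ", "overall")["pct_comparable"].iloc[0]
        nomci = g.comparability_rates(pair, "NomCI", "overall")["pct_comparable"].iloc[0]
        assert nomci >= nomiq

    def test_rates_nondecreasing_as_reliability_drops(self, cohort, battery, norms):
        # wider CIs can only preserve or create overlap
        prev = -1.0
        for r in (0.99, 0.95, 0.90, 0.80, 0.70):
            lk = ReliabilityLookup(overall={"FSIQ7": r, "ABIQ2": r})
            p = g.compare_pair(
                cohort, battery, norms, "FSIQ7", "ABIQ2", lk,
                criteria=[CriterionSpec("CI_overall")],
            )
            rate = g.comparability_rates(p, "CI_overall", "overall")["pct_comparable"].iloc[0]
            assert rate >= prev
            prev = rate

    def test_vectorized_flags_match_scalar_rule(self, cohort, battery, norms, lookup):
        # independent re-implementation of the overall-CI rule on the same subjects
        pair = g.compare_pair(cohort, battery, norms, "FSIQ7", "ABIQ2", lookup)
        r_a = lookup.overall["FSIQ7"]
        r_b = lookup.overall["ABIQ2"]
        direct = []
        for a, b in zip(pair.table["iq_a"], pair.table["iq_b"]):
            ca = g.true_score_ci(int(a), r_a)
            cb = g.true_score_ci(int(b), r_b)
            direct.append(max(ca.lower, cb.lower) <= min(ca.upper, cb.upper))
        assert (pair.table["CI_overall"].to_numpy(bool) == np.array(direct)).all()

    def test_excluded_subjects_counted_not_dropped(self, cohort, battery, norms):
        lk = ReliabilityLookup(overall={"FSIQ7": 0.95, "ABIQ2": 0.9})  # no age cells
        pair = g.compare_pair(cohort, battery, norms, "FSIQ7", "ABIQ2", lk)
        assert pair.excluded["CI_age"] == len(cohort)
        assert pair.table["CI_age"].isna().all()


class TestDifferenceStatistics:
    def test_identical_composites_all_zero(self, cohort, battery, norms):
        pair = g.compare_pair(cohort, battery, norms, "FSIQ7", "FSIQ7")
        summary = g.abs_difference_summary(pair)
        assert summary["abs"]["mean"] == 0
        assert summary["abs"]["max"] == 0

    @pytest.mark.parametrize("rho, expected", [(0.95, 3.79), (0.0, 16.93)])
    def test_mean_abs_difference_closed_form(self, rho, expected):
        # |D| for bivariate-normal IQs: 15 sqrt(2(1-rho)) sqrt(2/pi)
        rng = np.random.default_rng(11)
        n = 100_000
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        d = np.abs(15 * z1 - 15 * z2)
        assert d.mean() == pytest.approx(expected, rel=0.02)

    def test_dunlap_d_printed_value(self):
        assert paired_cohens_d(t=3.73, r=0.93, n=2109) == pytest.approx(0.030, abs=5e-4)

    def test_group_level_comparison_on_identical_scores(self, cohort, battery, norms):
        pair = g.compare_pair(cohort, battery, norms, "FSIQ7", "FSIQ7")
        res = g.group_level_comparison(pair, 0.95, 0.95)
        assert res.d == 0
        assert res.r == pytest.approx(1.0)

    def test_d_has_sign_of_mean_difference(self, pair, lookup):
        res = g.group_level_comparison(
            pair, lookup.overall["FSIQ7"], lookup.overall["ABIQ2"]
        )
        mean_d = pair.signed_diff.mean()
        if mean_d != 0:
            assert np.sign(res.d) == np.sign(mean_d)


class TestExtremityRatio:
    def test_single_component_and_parallel_limits(self):
        assert g.extremity_ratio(1, 0.3) == 1
        assert g.extremity_ratio(6, 1.0) == 1

    def test_hand_value(self):
        assert g.extremity_ratio(4, 0.5) == pytest.approx(np.sqrt(4 / 2.5))

    def test_degenerate_intercorrelation_rejected(self):
        with pytest.raises(ValueError):
            g.extremity_ratio(4, -0.5)


def test_true_score_ci_coverage_smoke():
    # exact CTT model: T ~ N(100, 15^2 r), X = T + E; nominal 95% coverage
    r = 0.9
    rng = np.random.default_rng(19)
    n = 50_000
    t = 100 + 15 * np.sqrt(r) * rng.standard_normal(n)
    x = t + 15 * np.sqrt(1 - r) * rng.standard_normal(n)
    that = 100 + r * (x - 100)
    half = 1.959964 * 15 * np.sqrt(r * (1 - r))
    coverage = np.mean((t >= that - half) & (t <= that + half))
    assert coverage == pytest.approx(0.95, abs=0.01)
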
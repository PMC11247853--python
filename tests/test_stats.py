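"""Cohort statistics: rate tables, partitioned chi-squared, the
Mantel–Haenszel trend test against a permutation oracle, Fisher exact vs
hypergeometric enumeration, and the univariate screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import hypergeom

from blastotrace.stats import (
    apply_exclusions,
    chisq_partitioned,
    compare_outcome_rates,
    group_euploidy_rates,
    mh_trend,
    univariate_screen,
)


def toy_cohort(categories, aneuploid, n_after=None, cycles=None):
    n = len(categories)
    return pd.DataFrame(
        {
            "embryo_id": [f"E{i}" for i in range(n)],
            "cycle_id": cycles if cycles is not None else np.arange(n) // 2,
            "category": categories,
            "n_after_tB": n_after if n_after is not None else [0] * n,
            "aneuploid": pd.array(aneuploid, dtype="boolean"),
        }
    )


class TestEuploidyRates:
    def test_simple_rate(self):
        df = toy_cohort(["none"] * 10, [False] * 4 + [True] * 6)
        out = group_euploidy_rates(df, "category").set_index("group")
        assert out.loc["none", "n"] == 10
        assert out.loc["none", "rate"] == pytest.approx(0.40)

    def test_empty_group_rate_is_missing_not_zero(self):
        df = toy_cohort(["none"] * 5, [False] * 5)
        out = group_euploidy_rates(df, "category").set_index("group")
        assert np.isnan(out.loc["both", "rate"]) and out.loc["both", "n"] == 0

    def test_all_euploid_gives_rate_one(self):
        df = toy_cohort(["none", "after_only"] * 4, [False] * 8,
                        n_after=[0, 2] * 4)
        out = group_euploidy_rates(df, "category")
        present = out[out["n"] > 0]
        assert (present["rate"] == 1.0).all()

    def test_post_tb_count_binning_and_conservation(self):
        n_after = [0, 1, 2, 3, 4, 5, 6, 0]
        df = toy_cohort(["none"] * 8, [False] * 8, n_after=n_after)
        out = group_euploidy_rates(df, "post_tb_count").set_index("group")
        assert out.loc[">=4", "n"] == 3
        assert out["n"].sum() == len(df)

    def test_unlabelled_embryo_rejected(self):
        df = toy_cohort(["none"] * 3, [True, None, False])
        with pytest.raises(ValueError, match="without a euploid/aneuploid"):
            group_euploidy_rates(df)


class TestApplyExclusions:
    def test_cascade_counts(self):
        df = pd.DataFrame(
            {
                "no_result": [True] + [False] * 9,
                "mosaic": [False, True, True] + [False] * 7,
                "imaging_abnormal": [False] * 3 + [True] + [False] * 6,
                "off_frame": [False] * 4 + [True] + [False] * 5,
                "aneuploid": pd.array([None, None, None, True, False] + [True, False] * 2 + [True], dtype="boolean"),
            }
        )
        kept, counts = apply_exclusions(df)
        assert counts["biopsied"] == 10
        assert counts["excluded_no_result"] == 1
        assert counts["excluded_mosaic"] == 2
        assert counts["excluded_imaging_abnormal"] == 1
        assert counts["excluded_off_frame"] == 1
        assert counts["analysable"] == len(kept) == 5


class TestPartitionedChisq:
    def test_identical_rows_give_zero_statistic(self):
        res = chisq_partitioned(np.array([[30, 70], [30, 70]]))
        assert res.overall_chi2 == pytest.approx(0.0)
        assert res.overall_p == pytest.approx(1.0)

    def test_matches_hand_computed_pearson(self):
        # [[50,50],[20,80]]: chi2 = sum (O-E)^2/E with margins 100/100, 70/130
        table = np.array([[50, 50], [20, 80]], float)
        res = chisq_partitioned(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert res.overall_chi2 == pytest.approx(chi2_hand)

    def test_four_identical_rows_no_significant_pairs(self):
        res = chisq_partitioned(np.tile([40, 60], (4, 1)), alpha=0.008)
        assert len(res.pairwise) == 6
        assert not any(c.significant for c in res.pairwise)

    def test_zero_margin_row_excluded_with_diagnostic(self):
        res = chisq_partitioned(
            pd.DataFrame([[10, 10], [0, 0], [5, 15]], index=["a", "b", "c"])
        )
        assert res.excluded_rows == ["b"]
        assert len(res.pairwise) == 1

    def test_small_expected_counts_warned(self):
        res = chisq_partitioned(np.array([[2, 3], [3, 2]]))
        assert any("< 5" in w for w in res.warnings)


class TestMHTrend:
    def test_linear_decline_is_highly_significant(self):
        # first-column proportion declines linearly: strong positive
        # association between the row score and the second-column indicator
        table = np.array([[400, 100], [300, 200], [200, 300], [100, 400]])
        z, p = mh_trend(table)
        assert p < 1e-3 and z > 0

    def test_equal_proportions_give_zero(self):
        z, p = mh_trend(np.tile([50, 50], (4, 1)))
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_row_reversal_flips_sign_only(self):
        table = np.array([[40, 10], [25, 25], [20, 30]])
        z1, p1 = mh_trend(table)
        z2, p2 = mh_trend(table[::-1])
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_two_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mh_trend(np.array([[10, 10], [5, 15]]))

    def test_matches_permutation_oracle(self):
        # individual-level permutation of outcomes as the empirical null
        rng = np.random.default_rng(0)
        table = np.array([[30, 15], [22, 18], [14, 21]])
        scores = np.repeat([1, 2, 3], table.sum(axis=1))
        y = np.concatenate([np.r_[np.zeros(a), np.ones(b)] for a, b in table])
        z_obs, p_obs = mh_trend(table)
        n = len(y)

        def stat(yy):
            r = np.corrcoef(scores, yy)[0, 1]
            return (n - 1) * r**2

        m2_obs = stat(y)
        assert m2_obs == pytest.approx(z_obs**2, rel=1e-9)
        perm = np.array([stat(rng.permutation(y)) for _ in range(4000)])
        p_perm = (perm >= m2_obs - 1e-12).mean()
        assert p_obs == pytest.approx(p_perm, abs=0.02)


def fisher_oracle(table):
    """Two-sided Fisher P by full enumeration of tables with fixed margins."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: hypergeom.pmf(k, n, r1, c1) for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestOutcomeRates:
    def _transfers(self):
        rows = []
        for cat, n, k in [("none", 10, 3), ("before_only", 10, 5), ("after_only", 8, 2)]:
            for i in range(n):
                rows.append((cat, i < k))
        df = pd.DataFrame(rows, columns=["category", "pregnant"])
        df["n_after_tB"] = (df["category"] == "after_only").astype(int)
        return df

    def test_fisher_p_matches_enumeration(self):
        df = self._transfers()
        out = compare_outcome_rates(df, "pregnant").set_index("group")
        p_pkg = out.loc["before_only", "fisher_p"]
        assert p_pkg == pytest.approx(fisher_oracle([[5, 5], [3, 7]]), rel=1e-9)

    def test_identical_groups_p_one(self):
        df = pd.DataFrame(
            {"category": ["none"] * 10 + ["after_only"] * 10,
             "pregnant": [True] * 3 + [False] * 7 + [True] * 3 + [False] * 7,
             "n_after_tB": [0] * 10 + [1] * 10}
        )
        out = compare_outcome_rates(df, "pregnant").set_index("group")
        assert out.loc["after_only", "fisher_p"] == pytest.approx(1.0)

    def test_empty_group_omitted_with_note(self):
        out = compare_outcome_rates(self._transfers(), "pregnant").set_index("group")
        assert out.loc["both", "note"] == "omitted: no transfers"
        assert np.isnan(out.loc["both", "rate"])

    def test_fisher_agrees_with_enumeration_on_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or t.sum() > 40 or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            _, p = sps.fisher_exact(t)
            assert p == pytest.approx(fisher_oracle(t.tolist()), rel=1e-6)


class TestUnivariateScreen:
    def _cohort(self, shift=0.0, n=300, seed=0):
        rng = np.random.default_rng(seed)
        aneu = rng.random(n) < 0.5
        return pd.DataFrame(
            {
                "aneuploid": pd.array(aneu, dtype="boolean"),
                "age": rng.normal(32, 4, n) + shift * aneu,
                "icm_grade": rng.choice(["A", "B"], n),
                "constant": np.ones(n),
            }
        )

    def test_null_p_not_systematically_small(self):
        ps = [
            univariate_screen(self._cohort(seed=s), ["age"])["p"].iloc[0]
            for s in range(40)
        ]
        assert 0.2 < np.mean(ps) < 0.8
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_location_shift_detected(self):
        out = univariate_screen(self._cohort(shift=3.0, n=800), ["age"])
        assert out["p"].iloc[0] < 1e-3
        assert out["test"].iloc[0] == "mann_whitney"

    def test_constant_variable_skipped(self):
        out = univariate_screen(self._cohort(), ["constant"]).set_index("variable")
        assert out.loc["constant", "note"] == "skipped: constant"

    def test_categorical_uses_count_test(self):
        out = univariate_screen(self._cohort(n=400), ["icm_grade"])
        assert out["test"].iloc[0] in ("chi2", "fisher")
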
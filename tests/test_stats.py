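"""Split-plot ANOVA, Fisher's LSD, rank transform and the unpaired t-test.

The ANOVA is checked three ways: a fully hand-computed sums-of-squares
table on a 2x2x2 toy design, an independent reference implementation
(pingouin) on realistic cohorts, and algebraic invariants (SS conservation,
location/scale equivariance, the F = t^2 reduction)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import dkiblast as dk


def _toy_2x2x2():
    # g1 subjects: (1,2) and (2,3) across the two times; g2: (3,4), (4,5)
    rows = []
    data = {
        ("g1", "s1"): (1.0, 2.0),
        ("g1", "s2"): (2.0, 3.0),
        ("g2", "s3"): (3.0, 4.0),
        ("g2", "s4"): (4.0, 5.0),
    }
    for (g, s), (v1, v2) in data.items():
        rows.append(dict(subject=s, group=g, time="t1", value=v1))
        rows.append(dict(subject=s, group=g, time="t2", value=v2))
    return pd.DataFrame(rows)


def _cohort(seed=0, effect=0.0, n=6):
    times = ("baseline", "d1", "d7", "d14", "d28")
    means = {
        (g, t): 1.0 + (effect if g == "injured" and t in ("d7", "d14") else 0.0)
        for g in ("sham", "injured")
        for t in times
    }
    return dk.make_cohort_table(
        dk.CohortSpec(n_per_group=n, means=means, seed=seed)
    )


class TestRankTransform:
    def test_simple_order(self):
        np.testing.assert_array_equal(dk.rank_transform([3, 1, 2]), [3, 1, 2])

    def test_midranks_for_ties(self):
        np.testing.assert_array_equal(
            dk.rank_transform([1, 1, 2]), [1.5, 1.5, 3]
        )

    def test_nan_stays_nan(self):
        out = dk.rank_transform([2.0, np.nan, 1.0])
        assert np.isnan(out[1])
        np.testing.assert_array_equal(out[[0, 2]], [2, 1])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            dk.rank_transform([np.nan, np.nan])

    def test_monotone_invariance(self, rng):
        for _ in range(100):
            x = rng.normal(size=12)
            base = dk.rank_transform(x)
            np.testing.assert_array_equal(base, dk.rank_transform(np.exp(x)))
            np.testing.assert_array_equal(
                base, dk.rank_transform(np.log(x - x.min() + 1.0))
            )


class TestMixedAnova:
    def test_hand_computed_ss_partition(self):
        # Hand computation: grand mean 3; SS_group = 8, SS_subj(group) = 2,
        # SS_time = 2, SS_interaction = 0, SS_residual = 0, SS_total = 12.
        res = dk.mixed_anova(_toy_2x2x2())
        assert res.group.ss == pytest.approx(8.0, abs=1e-12)
        assert res.subject_within_group.ss == pytest.approx(2.0, abs=1e-12)
        assert res.time.ss == pytest.approx(2.0, abs=1e-12)
        assert res.interaction.ss == pytest.approx(0.0, abs=1e-12)
        assert res.residual.ss == pytest.approx(0.0, abs=1e-12)
        assert res.ss_total == pytest.approx(12.0, abs=1e-12)
        assert (res.group.df, res.subject_within_group.df, res.time.df,
                res.interaction.df, res.residual.df) == (1, 2, 1, 1, 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pingouin_reference(self, seed):
        import pingouin as pg

        table = _cohort(seed=seed, effect=0.3)
        ours = dk.mixed_anova(table)
        ref = pg.mixed_anova(
            data=table, dv="value", within="time", between="group",
            subject="subject",
        ).set_index("Source")
        assert ours.group.F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert ours.time.F == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert ours.interaction.F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert ours.group.p == pytest.approx(ref.loc["group", "p_unc"], rel=1e-9)

    def test_ss_conservation(self, rng):
        table = _cohort(seed=3, effect=0.2)
        res = dk.mixed_anova(table)
        total = sum(e.ss for e in res.effects())
        assert total == pytest.approx(res.ss_total, rel=1e-12)

    def test_location_invariance(self):
        t = _cohort(seed=4)
        shifted = t.copy()
        shifted["value"] += 100.0
        a, b = dk.mixed_anova(t), dk.mixed_anova(shifted)
        assert a.group.F == pytest.approx(b.group.F, rel=1e-9)
        assert a.time.F == pytest.approx(b.time.F, rel=1e-9)
        assert a.interaction.F == pytest.approx(b.interaction.F, rel=1e-9)

    @given(c=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, c):
        t = _cohort(seed=5, effect=0.2)
        scaled = t.copy()
        scaled["value"] *= c
        a, b = dk.mixed_anova(t), dk.mixed_anova(scaled)
        assert b.group.ss == pytest.approx(c * c * a.group.ss, rel=1e-9)
        assert b.group.F == pytest.approx(a.group.F, rel=1e-6)
        assert b.group.p == pytest.approx(a.group.p, rel=1e-6)

    def test_single_time_group_f_equals_t_squared(self, rng):
        rows = []
        for g, vals in (("a", rng.normal(0, 1, 8)), ("b", rng.normal(0.5, 1, 8))):
            for i, v in enumerate(vals):
                rows.append(dict(subject=f"{g}{i}", group=g, time="t1", value=v))
        table = pd.DataFrame(rows)
        res = dk.mixed_anova(table)
        a = table[table.group == "a"]["value"].to_numpy()
        b = table[table.group == "b"]["value"].to_numpy()
        tt = dk.unpaired_t(a, b)
        assert res.group.F == pytest.approx(tt.t**2, rel=1e-10)
        assert res.group.p == pytest.approx(tt.p, rel=1e-10)

    def test_incomplete_subject_rejected(self):
        t = _cohort(seed=6)
        t = t[~((t.subject == "sham_01") & (t.time == "d7"))]
        with pytest.raises(ValueError, match="incomplete"):
            dk.mixed_anova(t)

    def test_unbalanced_groups_rejected(self):
        t = _cohort(seed=7)
        t = t[t.subject != "sham_01"]
        with pytest.raises(ValueError, match="unbalanced"):
            dk.mixed_anova(t)

    def test_type_one_error_calibration_small(self):
        # 400 null cohorts: rejection rate of the group test should sit in
        # the 95% binomial band around 0.05 (the full-size calibration runs
        # in the acceptance suite)
        hits = 0
        n = 400
        for seed in range(n):
            res = dk.mixed_anova(_cohort(seed=seed, effect=0.0))
            hits += res.group.p < 0.05
        lo, hi = sps.binom.ppf([0.025, 0.975], n, 0.05)
        assert lo <= hits <= hi


class TestFisherLSD:
    def test_identical_groups_p_near_one(self):
        t = _cohort(seed=8, effect=0.0)
        # force exactly equal group means at every time point
        piv = t.pivot_table(index="time", columns="group", values="value")
        res = dk.mixed_anova(t)
        rows = dk.fisher_lsd(t, res)
        for r in rows:
            assert 0.0 <= r.p <= 1.0

    def test_zero_difference_p_exactly_one(self):
        rows = []
        vals = {"s1": (1.0, 2.0), "s2": (2.0, 1.0)}
        for g in ("a", "b"):
            for s, (v1, v2) in vals.items():
                rows.append(dict(subject=f"{g}{s}", group=g, time="t1", value=v1))
                rows.append(dict(subject=f"{g}{s}", group=g, time="t2", value=v2))
        t = pd.DataFrame(rows)
        res = dk.mixed_anova(t)
        for r in dk.fisher_lsd(t, res):
            assert r.mean_difference == 0.0
            assert r.p == 1.0

    def test_single_time_reduces_to_unpaired_t(self, rng):
        rows = []
        for g in ("a", "b"):
            shift = 0.0 if g == "a" else 0.8
            for i in range(6):
                rows.append(
                    dict(subject=f"{g}{i}", group=g, time="t1",
                         value=rng.normal(shift, 1.0))
                )
        t = pd.DataFrame(rows)
        res = dk.mixed_anova(t)
        (row,) = dk.fisher_lsd(t, res)
        a = t[t.group == "a"]["value"].to_numpy()
        b = t[t.group == "b"]["value"].to_numpy()
        ref = dk.unpaired_t(a, b)
        assert row.t == pytest.approx(ref.t, rel=1e-10)
        assert row.p == pytest.approx(ref.p, rel=1e-10)
        assert row.df == pytest.approx(ref.df)

    def test_shifted_time_point_detected(self):
        # a d14-only shift of >= 4 SE should flag d14 (and only d14) in the
        # overwhelming majority of seeded replicates
        n_detect, n_false = 0, 0
        n_rep = 200
        for seed in range(n_rep):
            means = {
                (g, t): 1.0 + (0.35 if g == "injured" and t == "d14" else 0.0)
                for g in ("sham", "injured")
                for t in ("baseline", "d1", "d7", "d14", "d28")
            }
            table = dk.make_cohort_table(
                dk.CohortSpec(
                    n_per_group=6, means=means, between_sd=0.03,
                    within_sd=0.05, seed=seed,
                )
            )
            res = dk.mixed_anova(table)
            rows = {r.time: r for r in dk.fisher_lsd(table, res)}
            n_detect += rows["d14"].significant
            n_false += any(
                rows[t].significant for t in ("baseline", "d1", "d28")
            )
        assert n_detect >= 0.95 * n_rep
        assert n_false <= 0.25 * n_rep  # unadjusted LSD; some false hits expected

    def test_three_groups_rejected(self):
        rows = []
        for g in ("a", "b", "c"):
            for i in range(3):
                for tt in ("t1", "t2"):
                    rows.append(
                        dict(subject=f"{g}{i}", group=g, time=tt, value=float(i))
                    )
        t = pd.DataFrame(rows)
        res = dk.mixed_anova(t)
        with pytest.raises(ValueError, match="two groups"):
            dk.fisher_lsd(t, res)


class TestUnpairedT:
    def test_identical_samples(self):
        res = dk.unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_formula_oracle(self):
        # pooled SD = 1, t = -3 / (1 * sqrt(2/3))
        res = dk.unpaired_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        ab, ba = dk.unpaired_t(a, b), dk.unpaired_t(b, a)
        assert ab.t == pytest.approx(-ba.t, rel=1e-12)
        assert ab.p == pytest.approx(ba.p, rel=1e-12)

    def test_zero_variance_equal_means(self):
        res = dk.unpaired_t([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    def test_zero_variance_unequal_means(self):
        res = dk.unpaired_t([2.0, 2.0], [3.0, 3.0])
        assert res.p == 0.0 and res.degenerate

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dk.unpaired_t([1.0], [2.0, 3.0])
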
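"""Behavioral analysis: scoring, SDT indices, t-tests, RM-ANOVA.

The RM-ANOVA is checked against two independent routes: a brute-force
sequential-projection oracle (residual sums of squares of nested OLS fits
on dummy-coded design matrices; in a balanced layout the effect subspaces
are orthogonal, so sequential SS equal the ANOVA decomposition) and
statsmodels' AnovaRM for the F statistics.
"""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM

from scenecue import inverse_normal, paired_ttest, rm_anova, score_trials, sdt_indices


# ---------------------------------------------------------------- scoring


def tiny_design():
    return pd.DataFrame(
        {
            "trial_id": [0, 1, 2, 3],
            "cue_condition": ["valid", "valid", "invalid", "neutral"],
            "cued_stream": ["A", "B", "B", "none"],
            "target_stream": ["A", "B", "A", "B"],
            "target_onset_s": [2.0, 2.5, 1.5, 3.0],
        }
    )


class TestScoreTrials:
    def test_outcome_labels_follow_the_response_window(self):
        responses = pd.DataFrame(
            {
                "trial_id": [0, 1, 2, 3],
                "responded": [True, True, False, True],
                "response_time_s": [1.9, 2.8, np.nan, 6.0],
                "premature": [True, False, False, False],
            }
        )
        scored = score_trials(tiny_design(), responses, stream_duration=5.0)
        # before onset -> false alarm; in window -> hit; none -> miss;
        # after stream end -> ignored, i.e. miss
        assert scored.outcome.tolist() == ["false_alarm", "hit", "miss", "miss"]
        assert scored.rt_from_onset_s[1] == pytest.approx(0.3)

    def test_orphan_trial_ids_raise_join_error(self):
        responses = pd.DataFrame(
            {
                "trial_id": [0, 1, 2, 99],
                "responded": [False] * 4,
                "response_time_s": [np.nan] * 4,
                "premature": [False] * 4,
            }
        )
        with pytest.raises(ValueError, match="99"):
            score_trials(tiny_design(), responses)


# ---------------------------------------------------------------- SDT


class TestInverseNormal:
    @pytest.mark.parametrize(
        "p,z",
        [(0.5, 0.0), (0.975, 1.959964), (0.05, -1.644854), (0.85, 1.036433)],
    )
    def test_matches_normal_quantiles(self, p, z):
        assert inverse_normal(p) == pytest.approx(z, abs=1e-6)

    def test_is_inverse_of_the_normal_cdf(self):
        from scipy.stats import norm

        for p in np.linspace(0.01, 0.99, 23):
            assert abs(norm.cdf(inverse_normal(p)) - p) < 1e-10

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            inverse_normal(p)


class TestSdtIndices:
    def test_equal_rates_give_zero_dprime(self):
        s = sdt_indices(17, 20, 17, 20)
        assert s.dprime == pytest.approx(0.0, abs=1e-12)
        assert s.criterion == pytest.approx(-inverse_normal(0.85), abs=1e-9)

    def test_textbook_example(self):
        # H = 0.85, FA = 0.05: d' = z(.85) - z(.05), c = -(z(.85)+z(.05))/2
        s = sdt_indices(17, 20, 1, 20)
        assert s.dprime == pytest.approx(2.681287, abs=1e-5)
        assert s.criterion == pytest.approx(0.304210, abs=1e-5)

    def test_perfect_observer_is_corrected_by_half_trial_rule(self):
        # 20/20 and 0/20 -> rates 0.975 / 0.025 -> d' = 2 z(0.975), c = 0
        s = sdt_indices(20, 20, 0, 20)
        assert s.hit_rate == pytest.approx(0.975)
        assert s.fa_rate == pytest.approx(0.025)
        assert s.dprime == pytest.approx(3.919928, abs=1e-5)
        assert s.criterion == pytest.approx(0.0, abs=1e-12)

    def test_symmetries_under_role_swap(self):
        """Swapping the hit/false-alarm rates negates d' (and leaves c
        unchanged); relabeling responses (complement rates) negates c and
        leaves d' unchanged."""
        a = sdt_indices(15, 20, 3, 25)
        swapped = sdt_indices(3, 25, 15, 20)
        assert swapped.dprime == pytest.approx(-a.dprime)
        assert swapped.criterion == pytest.approx(a.criterion)
        relabeled = sdt_indices(25 - 3, 25, 20 - 15, 20)
        assert relabeled.dprime == pytest.approx(a.dprime)
        assert relabeled.criterion == pytest.approx(-a.criterion)

    def test_closed_form_grid(self):
        """d'/c match the z-transform closed form across a grid of counts."""
        for hits in range(0, 21, 4):
            for fas in range(0, 21, 4):
                s = sdt_indices(hits, 20, fas, 20)
                h = hits / 20 if 0 < hits < 20 else (0.025 if hits == 0 else 0.975)
                f = fas / 20 if 0 < fas < 20 else (0.025 if fas == 0 else 0.975)
                assert s.dprime == pytest.approx(
                    inverse_normal(h) - inverse_normal(f), abs=1e-6
                )
                assert s.criterion == pytest.approx(
                    -(inverse_normal(h) + inverse_normal(f)) / 2, abs=1e-6
                )

    def test_zero_opportunities_rejected(self):
        with pytest.raises(ValueError):
            sdt_indices(0, 0, 0, 10)


# ---------------------------------------------------------------- t-test


class TestPairedTTest:
    def test_closed_form_on_one_to_five(self):
        res = paired_ttest(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert res.t == pytest.approx(4.242641, abs=1e-6)
        assert res.df == 4

    def test_swapping_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        a, b = paired_ttest(x, y), paired_ttest(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_agrees_with_scipy(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(1)
        x, y = rng.normal(0.5, 1, 10), rng.normal(0, 1, 10)
        ours = paired_ttest(x, y)
        ref = ttest_rel(x, y)
        assert ours.t == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_identical_samples_are_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="variance"):
            paired_ttest(x, x)


# ---------------------------------------------------------------- RM-ANOVA


def projection_oracle(data: pd.DataFrame, factors: list[str]) -> dict[str, float]:
    """Sequential nested-OLS sums of squares on dummy design matrices."""

    def dummies(labels) -> np.ndarray:
        return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(float)

    def interaction(*cols) -> np.ndarray:
        combined = data[list(cols)].astype(str).agg("|".join, axis=1)
        return dummies(combined)

    y = data.value.to_numpy(float)

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    ones = np.ones((len(y), 1))
    blocks = [ones, dummies(data.participant)]
    names: list[str] = ["intercept", "subject"]
    if factors == ["A"]:
        blocks += [dummies(data.A), interaction("participant", "A")]
        names += ["A", "A_error"]
    else:
        blocks += [
            dummies(data.A),
            dummies(data.B),
            interaction("A", "B"),
            interaction("participant", "A"),
            interaction("participant", "B"),
            interaction("participant", "A", "B"),
        ]
        names += ["A", "B", "A:B", "A_error", "B_error", "AB_error"]

    out: dict[str, float] = {}
    prev = rss(blocks[0])
    X = blocks[0]
    for name, block in zip(names[1:], blocks[1:]):
        X = np.hstack([X, block])
        cur = rss(X)
        out[name] = prev - cur
        prev = cur
    return out


def random_layout(rng, n_subj, a_levels, b_levels=None) -> pd.DataFrame:
    rows = []
    for s in range(n_subj):
        for a in range(a_levels):
            if b_levels is None:
                rows.append({"participant": s, "A": f"a{a}", "value": rng.normal()})
            else:
                for b in range(b_levels):
                    rows.append(
                        {"participant": s, "A": f"a{a}", "B": f"b{b}", "value": rng.normal()}
                    )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        data = pd.DataFrame(
            {
                "participant": [0, 0, 0, 1, 1, 1, 2, 2, 2],
                "A": ["x", "y", "z"] * 3,
                "value": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 5.0, 5.0, 5.0],
            }
        )
        res = rm_anova(data, "oneway_rm")
        assert res["A"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_level_oneway_equals_squared_paired_t(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            x, y = rng.normal(0.3, 1, n), rng.normal(0, 1, n)
            data = pd.DataFrame(
                {
                    "participant": np.repeat(np.arange(n), 2),
                    "A": ["x", "y"] * n,
                    "value": np.column_stack([x, y]).ravel(),
                }
            )
            res = rm_anova(data, "oneway_rm")
            t = paired_ttest(x, y)
            assert res["A"]["F"] == pytest.approx(t.t**2, rel=1e-10)
            assert res["A"]["df"] == 1
            assert res["A"]["df_error"] == n - 1
            assert res["A"]["p"] == pytest.approx(t.p, rel=1e-10)

    @pytest.mark.parametrize("trial", range(50))
    def test_oneway_ss_match_projection_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        data = random_layout(rng, int(rng.integers(2, 7)), int(rng.integers(2, 4)))
        res = rm_anova(data, "oneway_rm")
        oracle = projection_oracle(data, ["A"])
        assert res["A"]["SS"] == pytest.approx(oracle["A"], rel=1e-8, abs=1e-10)
        assert res["subject"]["SS"] == pytest.approx(oracle["subject"], rel=1e-8, abs=1e-10)
        assert res["A"]["SS_error"] == pytest.approx(oracle["A_error"], rel=1e-8, abs=1e-10)

    @pytest.mark.parametrize("trial", range(50))
    def test_twoway_ss_match_projection_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        data = random_layout(
            rng, int(rng.integers(2, 7)), int(rng.integers(2, 4)), int(rng.integers(2, 4))
        )
        res = rm_anova(data, "twoway_rm")
        oracle = projection_oracle(data, ["A", "B"])
        for ours, theirs in (
            ("A", "A"),
            ("B", "B"),
            ("A:B", "A:B"),
        ):
            assert res[ours]["SS"] == pytest.approx(oracle[theirs], rel=1e-8, abs=1e-10)
            err_key = {"A": "A_error", "B": "B_error", "A:B": "AB_error"}[ours]
            assert res[ours]["SS_error"] == pytest.approx(
                oracle[err_key], rel=1e-8, abs=1e-10
            )
        # SS of all mean-centered components sum to the total SS
        assert res.ss_total == pytest.approx(sum(oracle.values()), rel=1e-8)

    def test_f_statistics_match_statsmodels(self):
        rng = np.random.default_rng(3)
        data = random_layout(rng, 6, 3, 2)
        res = rm_anova(data, "twoway_rm")
        ref = AnovaRM(data, "value", "participant", within=["A", "B"]).fit().anova_table
        assert res["A"]["F"] == pytest.approx(ref.loc["A", "F Value"], rel=1e-8)
        assert res["B"]["F"] == pytest.approx(ref.loc["B", "F Value"], rel=1e-8)
        assert res["A:B"]["F"] == pytest.approx(ref.loc["A:B", "F Value"], rel=1e-8)
        assert res["A"]["df_error"] == ref.loc["A", "Den DF"]

    def test_missing_cells_rejected(self):
        data = random_layout(np.random.default_rng(4), 3, 3).iloc[:-1]
        with pytest.raises(ValueError, match="cell"):
            rm_anova(data, "oneway_rm")
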
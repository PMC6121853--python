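"""Ethogram scoring, fighting-ability index, matching, outcome models."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.formula.api as smf
import statsmodels.stats.anova as ssa

from stripesignal import (
    fighting_ability,
    matching_test,
    outcome_lmm,
    score_ethogram,
    stripe_outcome_glmm,
)
from stripesignal.contest import DEFAULT_ETHOGRAM
from stripesignal.synth import SyntheticConfig, gen_behavior_events, gen_contests


def _events(rows):
    return pd.DataFrame(rows, columns=["time_s", "actor_id", "behavior_code"])


class TestScoreEthogram:
    def test_empty_stream(self):
        assert score_ethogram(_events([]), "f1") == (0, 0)

    def test_counts_by_valence_ignoring_neutral(self):
        ev = _events(
            [
                (1.0, "f1", "bite"),
                (2.0, "f1", "chase"),
                (3.0, "f1", "ram"),
                (4.0, "f1", "flee"),
                (5.0, "f1", "retreat"),
                (6.0, "f1", "swim"),
                (7.0, "f2", "bite"),
            ]
        )
        assert score_ethogram(ev, "f1") == (3, 2)

    def test_unknown_code_raises_with_name(self):
        ev = _events([(1.0, "f1", "somersault")])
        with pytest.raises(KeyError, match="somersault"):
            score_ethogram(ev, "f1")

    def test_unsorted_events_rejected(self):
        ev = _events([(5.0, "f1", "bite"), (1.0, "f1", "bite")])
        with pytest.raises(ValueError, match="sorted"):
            score_ethogram(ev, "f1")

    def test_generator_stream_matches_direct_tally(self, config):
        ev = gen_behavior_events(config, "fx", 25.0, 10.0)
        agg, sub = score_ethogram(ev, "fx")
        valence = ev["behavior_code"].map(DEFAULT_ETHOGRAM)
        assert agg == (valence == "aggressive").sum()
        assert sub == (valence == "submissive").sum()


class TestFightingAbility:
    @pytest.mark.parametrize(
        "agg,sub,expected", [(12, 4, 8), (0, 0, 0), (4, 12, -8)]
    )
    def test_index_formula(self, agg, sub, expected):
        assert fighting_ability(agg, sub) == expected

    def test_antisymmetric_under_count_swap(self, rng):
        for _ in range(20):
            a, s = rng.integers(0, 50, 2)
            assert fighting_ability(a, s) == -fighting_ability(s, a)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fighting_ability(-1, 0)


def _dyads_from_diffs(length_diffs, mass_diffs=None):
    mass_diffs = mass_diffs if mass_diffs is not None else length_diffs
    rows = []
    for i, (dl, dm) in enumerate(zip(length_diffs, mass_diffs)):
        for j, sign in ((0, 0.0), (1, 1.0)):
            rows.append(
                {
                    "pair_id": f"p{i}",
                    "fish_id": f"p{i}_{j}",
                    "sex": "m",
                    "standard_length_cm": 6.0 + sign * -dl,
                    "mass_g": 8.0 + sign * -dm,
                    "winner_id": f"p{i}_0",
                    "aggressive_count": 10,
                    "submissive_count": 5,
                }
            )
    return pd.DataFrame(rows)


class TestMatchingTest:
    def test_perfectly_matched_pairs_give_p_one(self):
        out = matching_test(_dyads_from_diffs([0.0] * 8))
        assert (out["p"] == 1.0).all()
        assert (out["mean_diff"] == 0.0).all()

    def test_statistic_matches_signed_rank_enumeration(self):
        diffs = [1.0, 2.0, 3.0, -1.5, -2.5, 0.5]
        out = matching_test(_dyads_from_diffs(diffs))
        d = np.array(diffs)
        ranks = st.rankdata(np.abs(d))
        t_plus = ranks[d > 0].sum()
        t_minus = ranks[d < 0].sum()
        v_expected = min(t_plus, t_minus)
        assert out.loc[out["variable"] == "standard_length_cm", "V"].iloc[0] == v_expected
        # exact p by enumerating all 2^6 sign assignments
        total = ranks.sum()
        all_t = [
            sum(r for r, s in zip(ranks, signs) if s > 0)
            for signs in itertools.product([1, -1], repeat=6)
        ]
        obs_dev = abs(t_plus - total / 2)
        p_enum = np.mean([abs(t - total / 2) >= obs_dev - 1e-12 for t in all_t])
        assert out.loc[out["variable"] == "standard_length_cm", "p"].iloc[0] == pytest.approx(
            p_enum, abs=1e-12
        )

    def test_type_i_error_near_nominal_under_null(self, rng):
        # unbiased matching: rejection rate ~ alpha
        reps, hits = 400, 0
        for _ in range(reps):
            diffs = rng.normal(0, 0.3, 12)
            out = matching_test(_dyads_from_diffs(diffs))
            hits += out.loc[out["variable"] == "standard_length_cm", "p"].iloc[0] < 0.05
        rate = hits / reps
        assert 0.02 <= rate <= 0.09

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="6 pairs"):
            matching_test(_dyads_from_diffs([0.1] * 4))


def _sim_dyads(rng, n_pairs=20, winner_ability_advantage=0.0, pair_sd=1.0, mass_adv=0.0):
    rows = []
    for i in range(n_pairs):
        sex = "m" if i % 2 == 0 else "f"
        pair_eff = rng.normal(0, pair_sd)
        for j in range(2):
            is_winner = j == 0
            agg = max(0, int(rng.normal(20 + (winner_ability_advantage if is_winner else 0), 3)))
            sub = max(0, int(rng.normal(10, 3)))
            rows.append(
                {
                    "pair_id": f"p{i}",
                    "fish_id": f"p{i}_{j}",
                    "sex": sex,
                    "standard_length_cm": 6.0 + rng.normal(0, 0.2),
                    "mass_g": 8.0 + pair_eff + (mass_adv if is_winner else 0) + rng.normal(0, 0.6),
                    "winner_id": f"p{i}_0",
                    "aggressive_count": agg,
                    "submissive_count": sub,
                    "stripe_begin": "dark",
                    "stripe_end": "dark",
                }
            )
    return pd.DataFrame(rows)


class TestOutcomeLmm:
    def test_containment_df_pattern(self, rng):
        fit = outcome_lmm(_sim_dyads(rng, n_pairs=20), "fighting_ability")
        tbl = fit.anova.set_index("term")
        # 40 obs, 20 pairs, success + interaction within: 40 - 20 - 2 = 18
        assert tbl.loc["success", "df_den"] == 18.0
        # sex is between-pair: 20 pairs - 2 between columns = 18
        assert tbl.loc["sex", "df_den"] == 18.0

    def test_null_success_effect_calibrated(self, rng):
        reps, hits = 200, 0
        for _ in range(reps):
            fit = outcome_lmm(_sim_dyads(rng, winner_ability_advantage=0.0), "fighting_ability")
            hits += fit.term_f("success")[1] < 0.05
        assert hits / reps < 0.11

    def test_recovers_winner_advantage(self, rng):
        reps, hits = 100, 0
        for _ in range(reps):
            fit = outcome_lmm(_sim_dyads(rng, winner_ability_advantage=5.0), "fighting_ability")
            est = fit.fixed_effect("success") + 0.5 * fit.fixed_effect("success:sex")
            se = 1.2  # conservative bound given resid sd 3*sqrt(2)/sqrt(20)
            hits += abs(est - 5.0) <= 3 * se
        assert hits >= 90

    def test_zero_pair_variance_matches_two_way_anova_oracle(self, rng):
        # pair variance 0 by construction: pair means all equal
        rows = []
        for i in range(16):
            sex = "m" if i % 2 == 0 else "f"
            e = rng.normal(0, 1.0)
            rows.append(dict(pair_id=f"p{i}", fish_id=f"p{i}_0", sex=sex,
                             standard_length_cm=6, mass_g=10 + e,
                             winner_id=f"p{i}_0", aggressive_count=0, submissive_count=0))
            rows.append(dict(pair_id=f"p{i}", fish_id=f"p{i}_1", sex=sex,
                             standard_length_cm=6, mass_g=10 - e,
                             winner_id=f"p{i}_0", aggressive_count=0, submissive_count=0))
        dyads = pd.DataFrame(rows)
        fit = outcome_lmm(dyads, "mass")
        df = dyads.copy()
        df["success"] = (df["fish_id"] == df["winner_id"]).astype(float)
        df["sexm"] = (df["sex"] == "m").astype(float)
        ols = smf.ols("mass_g ~ success * sexm", df).fit()
        tbl = ssa.anova_lm(ols, typ=3)
        assert fit.term_f("success")[0] == pytest.approx(float(tbl.loc["success", "F"]), rel=1e-6)

    def test_single_sex_drops_interaction(self, rng):
        dyads = _sim_dyads(rng, n_pairs=8)
        dyads["sex"] = "f"
        with pytest.warns(UserWarning, match="single sex"):
            fit = outcome_lmm(dyads, "fighting_ability")
        assert "sex" not in fit.terms

    def test_winners_heavier_in_generator_data(self, config):
        dyads, _ = gen_contests(config)
        dyads["is_winner"] = dyads["fish_id"] == dyads["winner_id"]
        w = dyads.loc[dyads["is_winner"], "mass_g"].mean()
        l = dyads.loc[~dyads["is_winner"], "mass_g"].mean()
        assert w > l


def _stripe_dyads(rng, n_pairs, p_pale_loser, p_pale_winner):
    rows = []
    for i in range(n_pairs):
        for j in range(2):
            is_winner = j == 0
            p_pale = p_pale_loser if not is_winner else p_pale_winner
            rows.append(
                {
                    "pair_id": f"p{i}",
                    "fish_id": f"p{i}_{j}",
                    "sex": "m",
                    "standard_length_cm": 6.0,
                    "mass_g": 8.0,
                    "winner_id": f"p{i}_0",
                    "aggressive_count": 1,
                    "submissive_count": 0,
                    "stripe_begin": "dark",
                    "stripe_end": "pale" if rng.random() < p_pale else "dark",
                }
            )
    return pd.DataFrame(rows)


class TestStripeOutcomeGlmm:
    def test_complete_separation_flagged(self, rng):
        dyads = _stripe_dyads(rng, 12, p_pale_loser=1.0, p_pale_winner=0.0)
        res = stripe_outcome_glmm(dyads, "end")
        assert res.separation
        assert res.fit.method == "firth"

    def test_null_lrt_rejection_rate_near_nominal(self, rng):
        reps, hits = 300, 0
        for _ in range(reps):
            dyads = _stripe_dyads(rng, 20, p_pale_loser=0.5, p_pale_winner=0.5)
            try:
                res = stripe_outcome_glmm(dyads, "end")
            except ValueError:
                continue  # all-pale or all-dark draws carry no information
            if res.separation:
                continue
            hits += res.p < 0.05
        assert hits / reps < 0.10

    def test_strong_paling_effect_detected(self, rng):
        reps, hits, used = 60, 0, 0
        for _ in range(reps):
            dyads = _stripe_dyads(rng, 20, p_pale_loser=0.9, p_pale_winner=0.1)
            res = stripe_outcome_glmm(dyads, "end")
            if res.separation:
                continue
            used += 1
            hits += res.p < 0.001
        assert used > 0 and hits / used >= 0.7

    def test_begin_timepoint_null_in_generator_data(self, config):
        dyads, _ = gen_contests(config)
        res = stripe_outcome_glmm(dyads, "begin")
        # all stripes dark at the start: no information, no association
        assert res.p > 0.5

    def test_odds_ratio_direction(self, rng):
        dyads = _stripe_dyads(rng, 40, p_pale_loser=0.85, p_pale_winner=0.15)
        res = stripe_outcome_glmm(dyads, "end")
        # pale stripe predicts losing: odds ratio of winning when pale < 1
        assert res.odds_ratio < 1.0
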
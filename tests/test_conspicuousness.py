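"""Patch-pair contrasts, adjacency models, variance partition, change tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.formula.api as smf
import statsmodels.stats.anova as ssa
from statsmodels.stats.multitest import multipletests

from stripesignal import (
    DEFAULT_ADJACENCY,
    AdjacencyMap,
    ColorPatch,
    adjacency_lmm,
    aggregate_per_fish,
    pairwise_contrasts,
    per_patch_change_tests,
    variance_partition,
)
from stripesignal.conspicuousness import PATCH_LABELS
from stripesignal.lmm import sequential_ss
from stripesignal.spectra import DEFAULT_GRID, Spectrum
from stripesignal.synth import SyntheticConfig, gen_face_spectra, gen_light_environment, gen_visual_system


class TestAdjacencyMap:
    def test_symmetric(self):
        assert DEFAULT_ADJACENCY.adjacent("white", "blue")
        assert DEFAULT_ADJACENCY.adjacent("blue", "white")

    def test_irreflexive_rejected(self):
        with pytest.raises(ValueError, match="irreflexive"):
            AdjacencyMap([("white", "white")])

    def test_default_covers_all_patches(self):
        assert set(PATCH_LABELS) <= DEFAULT_ADJACENCY.labels()


class TestPairwiseContrasts:
    def test_five_patches_give_ten_records_per_fish_state(self, contrast_records):
        counts = contrast_records.groupby(["fish_id", "state"]).size()
        assert (counts == 10).all()

    def test_duplicate_spectra_give_zero_contrast(self, visual_system, light_env):
        refl = Spectrum(DEFAULT_GRID.copy(), np.full(len(DEFAULT_GRID), 0.3), "reflectance")
        patches = [
            ColorPatch("white", "f1", "dominant", refl),
            ColorPatch("blue", "f1", "dominant", refl),
        ]
        rec = pairwise_contrasts(patches, DEFAULT_ADJACENCY, visual_system, light_env)
        assert rec["delta_S"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert rec["delta_L"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_adjacency_entry_raises(self, visual_system, light_env):
        refl = Spectrum(DEFAULT_GRID.copy(), np.full(len(DEFAULT_GRID), 0.3), "reflectance")
        patches = [
            ColorPatch("white", "f1", "dominant", refl),
            ColorPatch("blue", "f1", "dominant", refl),
        ]
        empty_map = AdjacencyMap([("a", "b")])
        with pytest.raises(KeyError, match="adjacency"):
            pairwise_contrasts(patches, empty_map, visual_system, light_env)

    def test_color_pairs_exceed_discrimination_threshold(self, contrast_records):
        # every blue/yellow/black-stripe color combination is > 1 JND
        dom = contrast_records[contrast_records["state"] == "dominant"]
        colorful = {"blue", "yellow", "black_horizontal_stripe", "black_vertical_stripe"}
        sub = dom[
            dom["patch_a"].isin(colorful)
            & dom["patch_b"].isin(colorful)
            & ~(dom["patch_a"].str.startswith("black") & dom["patch_b"].str.startswith("black"))
        ]
        assert len(sub) > 0
        assert (sub["delta_S"] > 1.0).all()


class TestAggregatePerFish:
    def test_single_record_categories(self, visual_system, light_env):
        cfg = SyntheticConfig(seed=5, spectral_noise_sd=0.0)
        patches = [
            p
            for p in gen_face_spectra(cfg, "f1", "dominant")
            if p.patch_label in ("white", "blue", "yellow")
        ]
        rec = pairwise_contrasts(patches, DEFAULT_ADJACENCY, visual_system, light_env)
        # white-blue and blue-yellow adjacent, white-yellow nonadjacent
        agg = aggregate_per_fish(rec)
        nonadj = agg[~agg["adjacent"]]
        assert nonadj["mean_delta_S"].iloc[0] == pytest.approx(
            rec.loc[~rec["adjacent"], "delta_S"].iloc[0]
        )

    def test_matches_direct_groupby_oracle(self, contrast_records):
        agg = aggregate_per_fish(contrast_records)
        oracle = (
            contrast_records.groupby(["fish_id", "state", "adjacent"])["delta_S"]
            .mean()
            .reset_index()
        )
        merged = agg.merge(oracle, on=["fish_id", "state", "adjacent"])
        np.testing.assert_allclose(merged["mean_delta_S"], merged["delta_S"], rtol=1e-12)

    def test_two_records_average(self):
        rec = pd.DataFrame(
            {
                "fish_id": ["f1"] * 3,
                "state": ["dominant"] * 3,
                "patch_a": ["white", "white", "blue"],
                "patch_b": ["blue", "yellow", "yellow"],
                "adjacent": [True, False, True],
                "delta_S": [2.0, 5.0, 4.0],
                "delta_L": [1.0, 2.0, 3.0],
            }
        )
        agg = aggregate_per_fish(rec)
        adj = agg[agg["adjacent"]]
        assert adj["mean_delta_S"].iloc[0] == pytest.approx(3.0)


def _simulate_aggregated(rng, n_fish=20, adjacency_effect=0.0, fish_sd=0.5, resid_sd=0.5):
    """Aggregated per-fish means straight from the model the LMM assumes."""
    fish_eff = rng.normal(0, fish_sd, n_fish)
    rows = []
    for i in range(n_fish):
        for adj in (False, True):
            rows.append(
                {
                    "fish_id": f"f{i:02d}",
                    "state": "dominant",
                    "adjacent": adj,
                    "mean_delta_S": 5.0
                    + adjacency_effect * adj
                    + fish_eff[i]
                    + rng.normal(0, resid_sd),
                    "mean_delta_L": 1.0,
                }
            )
    return pd.DataFrame(rows)


class TestAdjacencyLmm:
    def test_estimates_containment_df(self, rng):
        agg = _simulate_aggregated(rng, n_fish=10, adjacency_effect=3.0)
        fit = adjacency_lmm(agg, "chromatic", "dominant_only")
        row = fit.anova.iloc[0]
        assert row["term"] == "adjacency"
        assert row["df_num"] == 1
        assert row["df_den"] == 9.0  # 20 obs - 10 fish - 1 within column

    def test_zero_group_variance_matches_anova_oracle(self, rng):
        # construct data whose per-fish means are all identical so the REML
        # random-intercept variance lands on the boundary at zero
        n = 12
        e = rng.normal(0, 0.5, n)
        rows = []
        for i in range(n):
            rows.append(dict(fish_id=f"f{i}", state="dominant", adjacent=False,
                             mean_delta_S=5.0 + e[i], mean_delta_L=1.0))
            rows.append(dict(fish_id=f"f{i}", state="dominant", adjacent=True,
                             mean_delta_S=8.0 - e[i], mean_delta_L=1.0))
        agg = pd.DataFrame(rows)
        fit = adjacency_lmm(agg, "chromatic", "dominant_only")
        df = agg.rename(columns={"mean_delta_S": "y"})
        df["adj"] = df["adjacent"].astype(float)
        ols = smf.ols("y ~ adj", df).fit()
        f_oracle = float(ssa.anova_lm(ols)["F"]["adj"])
        assert fit.random_variances["group"] < 0.01
        assert fit.term_f("adjacency")[0] == pytest.approx(f_oracle, rel=1e-8)

    def test_recovers_simulated_adjacency_effect(self, rng):
        hits = 0
        reps = 50
        for _ in range(reps):
            agg = _simulate_aggregated(rng, n_fish=20, adjacency_effect=3.0)
            fit = adjacency_lmm(agg, "chromatic", "dominant_only")
            if abs(fit.fixed_effect("adjacency") - 3.0) <= 0.3:
                hits += 1
        assert hits >= int(0.85 * reps)

    def test_achromatic_response_is_sqrt_transformed(self, rng):
        agg = _simulate_aggregated(rng, n_fish=10, adjacency_effect=2.0)
        agg["mean_delta_L"] = agg["mean_delta_S"] ** 2
        fit = adjacency_lmm(agg, "achromatic", "dominant_only")
        assert fit.transform == "sqrt"
        np.testing.assert_allclose(
            np.sort(fit.response), np.sort(agg["mean_delta_S"].to_numpy()), rtol=1e-12
        )


class TestVariancePartition:
    def _fit(self, agg):
        return adjacency_lmm(agg, "chromatic", "dominant_and_subordinate")

    def _make(self, rng, f, n_fish=16):
        rows = []
        for i in range(n_fish):
            for state in ("dominant", "subordinate"):
                for adj in (False, True):
                    rows.append(
                        {
                            "fish_id": f"{state[:3]}{i}",
                            "state": state,
                            "adjacent": adj,
                            "mean_delta_S": f(i, state == "subordinate", adj, rng),
                            "mean_delta_L": 1.0,
                        }
                    )
        return pd.DataFrame(rows)

    def test_pure_noise_explains_little(self, rng):
        agg = self._make(rng, lambda i, s, a, r: r.normal(0, 1), n_fish=40)
        part = variance_partition(self._fit(agg))
        # 3 fixed df on 160 observations: chance-level explained share
        assert part["pct_of_total"].sum() < 10.0

    def test_pure_adjacency_signal_explains_all(self, rng):
        agg = self._make(rng, lambda i, s, a, r: 1.0 + 2.0 * a)
        part = variance_partition(self._fit(agg))
        adjacency_share = part.loc[part["term"] == "adjacency", "pct_of_total"].iloc[0]
        assert adjacency_share == pytest.approx(100.0, abs=1e-8)

    def test_matches_independent_sequential_ss_oracle(self, rng):
        agg = self._make(
            rng, lambda i, s, a, r: 2.0 + 3.0 * a + 0.4 * s + 0.1 * a * s + r.normal(0, 0.3)
        )
        fit = self._fit(agg)
        part = variance_partition(fit)

        # oracle: explicit nested OLS projections
        y = fit.response
        adj = fit.design["adjacency"].to_numpy()
        pale = fit.design["stripe_pale"].to_numpy()
        inter = fit.design["adjacency:stripe_pale"].to_numpy()
        ones = np.ones_like(y)

        def rss(*cols):
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        tot = np.sum((y - y.mean()) ** 2)
        ss_adj = rss(ones) - rss(ones, adj)
        ss_pale = rss(ones, adj) - rss(ones, adj, pale)
        ss_int = rss(ones, adj, pale) - rss(ones, adj, pale, inter)
        expected = 100.0 * np.array([ss_adj, ss_pale, ss_int]) / tot
        np.testing.assert_allclose(part["pct_of_total"].to_numpy(), expected, atol=1e-8)
        assert part["term"].tolist() == ["adjacency", "stripe", "adjacency:stripe"]
        # dominant share belongs to adjacency in this simulation
        assert expected[0] > expected[1]


class TestPerPatchChangeTests:
    def test_identical_groups_are_never_flagged(self, rng):
        rows = []
        vals = rng.uniform(1, 5, 8)
        for state in ("dominant", "subordinate"):
            for i in range(8):
                rows.append(
                    {
                        "fish_id": f"{state}{i}",
                        "state": state,
                        "patch_a": "white",
                        "patch_b": "blue",
                        "adjacent": True,
                        "delta_S": vals[i],
                        "delta_L": vals[i],
                    }
                )
        table = per_patch_change_tests(pd.DataFrame(rows))
        assert not table["significant"].any()
        assert (table["p_adj"] == 1.0).all()

    def test_bh_step_up_formula(self):
        raw = np.array([0.01, 0.02, 0.04, 0.5])
        adj = multipletests(raw, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.5], rtol=1e-12)

    def test_bh_preserves_p_value_ordering(self, rng):
        raw = rng.uniform(0, 1, 12)
        adj = multipletests(raw, method="fdr_bh")[1]
        assert np.all(np.diff(adj[np.argsort(raw)]) >= -1e-15)

    def test_mann_whitney_u_matches_exhaustive_enumeration(self):
        x = np.array([1.2, 3.4, 2.2])
        y = np.array([0.5, 2.9, 4.1])
        u_scipy, _ = st.mannwhitneyu(x, y, alternative="two-sided")
        # brute force: count of (i, j) pairs with x_i > y_j over all pairings
        u_brute = sum(xi > yj for xi in x for yj in y)
        assert u_scipy == u_brute
        # p-value by enumeration of all C(6,3) = 20 group assignments
        pooled = np.concatenate([x, y])
        obs_stat = abs(u_brute - 4.5)
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(6) if i not in idx]]
            u = sum(xi > yj for xi in xs for yj in ys)
            total += 1
            count += abs(u - 4.5) >= obs_stat - 1e-12
        _, p_scipy = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p_scipy == pytest.approx(count / total, abs=1e-12)

    def test_stripe_pairs_change_achromatically_on_real_dataset(self, contrast_records):
        table = per_patch_change_tests(contrast_records)
        achro = table[table["contrast_kind"] == "achromatic"]
        stripe = achro[
            (achro["patch_a"] == "black_horizontal_stripe")
            | (achro["patch_b"] == "black_horizontal_stripe")
        ]
        assert stripe["significant"].all()

    def test_small_group_skipped_with_warning(self):
        rows = [
            dict(fish_id="a", state="dominant", patch_a="white", patch_b="blue",
                 adjacent=True, delta_S=1.0, delta_L=1.0),
            dict(fish_id="b", state="subordinate", patch_a="white", patch_b="blue",
                 adjacent=True, delta_S=2.0, delta_L=2.0),
        ]
        with pytest.warns(UserWarning, match="group size"):
            table = per_patch_change_tests(pd.DataFrame(rows))
        assert table.empty
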
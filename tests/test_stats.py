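"""Screening statistics: outliers, repeated-measures GLM, post-hocs,
actor comparison, factor analysis."""

import numpy as np
import pandas as pd
import pytest

from vitalkin.errors import DataError
from vitalkin.features import FEATURE_NAMES
from vitalkin.stats import (
    REFERENCE_SCREENING_PVALUES,
    SIGNIFICANT_FEATURES,
    build_cell_means,
    compare_actors,
    posthoc_pairwise,
    principal_factor_analysis,
    remove_outliers,
    rm_anova_F,
    rm_glm,
    screen_features,
)
from vitalkin.synthetic import CONDITIONS


class TestOutlierRemoval:
    def test_extreme_value_removed_when_attainable(self):
        # nine 1s and one 100: z = 89.1 / 31.31 = 2.85 > 2.5 (hand-checked)
        vals = [1.0] * 9 + [100.0]
        kept, removed = remove_outliers(vals)
        assert list(removed) == [9]
        assert 100.0 not in kept

    def test_single_extreme_among_five_cannot_reach_2p5_sd(self):
        # the largest attainable |z| with n=5 is (n-1)/sqrt(n) = 1.79
        kept, removed = remove_outliers([1, 1, 1, 1, 100])
        assert len(removed) == 0

    def test_identical_values_remove_nothing(self):
        kept, removed = remove_outliers([5.0, 5.0, 5.0])
        assert len(removed) == 0 and len(kept) == 3

    def test_gaussian_removal_rate_matches_tail_mass(self):
        # 2 * Phi(-2.5) = 1.24%
        x = np.random.default_rng(0).normal(size=10_000)
        _, removed = remove_outliers(x)
        assert len(removed) / 10_000 == pytest.approx(0.0124, abs=0.004)

    def test_too_few_values(self):
        with pytest.raises(DataError):
            remove_outliers([1.0, 2.0])


class TestRmGlm:
    @staticmethod
    def cells_from(X):
        idx = pd.MultiIndex.from_product([[f"a{i}" for i in range(X.shape[0])], ["m"]],
                                         names=["action", "actor"])
        return pd.DataFrame(X, index=idx, columns=list(CONDITIONS))

    def test_identical_columns_give_null_result(self):
        X = np.tile(np.random.default_rng(0).normal(size=(10, 1)), (1, 5))
        res = rm_glm(self.cells_from(X), "f")
        assert res.F == 0.0 and res.p == 1.0

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 5))
        X[:, 2] += 10 * X.std()
        res = rm_glm(self.cells_from(X), "f")
        assert res.p < 1e-4

    def test_agrees_with_independent_implementation(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 5)) + rng.normal(size=(9, 1))
        F, df1, df2 = rm_anova_F(X)
        long = pd.DataFrame({
            "y": X.ravel(),
            "subj": np.repeat(np.arange(9), 5),
            "cond": np.tile(np.arange(5), 9),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert F == pytest.approx(float(ref["F"].iloc[0]), abs=1e-10)

    def test_gg_correction_rare_under_compound_symmetry(self):
        # spherical covariance: Mauchly should reject at ~alpha, so the
        # correction is applied in a small minority of replicates
        applied = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(14, 5)) + 2.0 * rng.normal(size=(14, 1))
            res = rm_glm(self.cells_from(X), "f")
            applied += res.gg_applied
        assert applied / n_rep <= 0.10

    def test_incomplete_rows_dropped_then_error_below_three(self):
        X = np.random.default_rng(3).normal(size=(4, 5))
        cells = self.cells_from(X)
        cells.iloc[0, 0] = np.nan
        cells.iloc[1, 2] = np.nan
        with pytest.raises(DataError, match="complete rows"):
            rm_glm(cells, "f")


class TestPosthoc:
    def test_shifted_condition_marked_by_all_others(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.1, size=(10, 5))
        X[:, 2] += 5.0
        cells = TestRmGlm.cells_from(X)
        letters = posthoc_pairwise(cells, omnibus_significant=True)
        assert set(letters["rude"]) == {"a", "b", "d", "e"}
        for cond in ("gentle", "neutral", "slow", "fast"):
            assert "c" in letters[cond]

    def test_identical_columns_no_letters(self):
        X = np.tile(np.random.default_rng(0).normal(size=(10, 1)), (1, 5))
        letters = posthoc_pairwise(TestRmGlm.cells_from(X), omnibus_significant=True)
        assert all(v == "" for v in letters.values())

    def test_nonsignificant_omnibus_yields_empty_with_warning(self, caplog):
        import logging

        X = np.random.default_rng(0).normal(size=(10, 5))
        with caplog.at_level(logging.WARNING, logger="vitalkin.stats"):
            letters = posthoc_pairwise(TestRmGlm.cells_from(X), omnibus_significant=False)
        assert all(v == "" for v in letters.values())
        assert any("non-significant" in m for m in caplog.messages)

    def test_letter_matrix_symmetry(self, mini_table):
        from vitalkin.stats import CONDITION_LETTERS

        _, summary = screen_features(mini_table, features=("Vmx", "Amx", "S"))
        inv = {v: k for k, v in CONDITION_LETTERS.items()}
        for _, row in summary.iterrows():
            for cond in CONDITIONS:
                for letter in row[f"{cond}_letters"]:
                    partner = inv[letter]
                    assert CONDITION_LETTERS[cond] in row[f"{partner}_letters"]


class TestActorComparison:
    def test_angle_features_differ_between_default_actors(self, mini_table):
        res = compare_actors(mini_table)
        sig = set(res.loc[res["significant"], "feature"])
        angle_feats = {"AACmx", "AACa", "AACsd", "AEmx", "AEa", "AEsd"}
        # the two default actors differ in arm geometry: posture features react
        assert len(sig & angle_feats) >= 2

    def test_identical_actors_show_only_chance_hits(self):
        from vitalkin.features import build_table
        from vitalkin.synthetic import (
            ACTIONS, ActorProfile, SynthDatasetConfig, generate_dataset,
        )

        twin = dict(upper_arm_m=0.31, forearm_m=0.29,
                    shoulder_pos=np.array([0.17, 0.03, 0.47]), swivel_rad=0.2, sway_gain=0.05)
        profiles = [ActorProfile("a1", "m", **twin), ActorProfile("a2", "f", **twin)]
        counts = {a: {c: 4 for c in CONDITIONS} for a in ("grasp", "offer", "drop", "silence")}
        cfg = SynthDatasetConfig(counts=counts, seed=21, actor_profiles=profiles)
        table, _ = build_table(generate_dataset(cfg))
        res = compare_actors(table)
        assert res["significant"].sum() <= 4  # ~1 expected by chance at alpha=.05

    def test_single_actor_table_is_a_pairing_error(self, mini_table):
        solo = mini_table[mini_table["actor"] == "actor_m"]
        with pytest.raises(DataError, match="2 actors"):
            compare_actors(solo)


class TestScreening:
    def test_reference_pvalues_select_the_17_features(self):
        derived = [f for f in FEATURE_NAMES if REFERENCE_SCREENING_PVALUES[f] < 0.05]
        excluded = {"%POSmx", "POSmx", "%POWmx", "POWmx", "AEa"}
        assert set(derived) == set(FEATURE_NAMES) - excluded
        assert len(SIGNIFICANT_FEATURES) == 17
        assert tuple(derived) == SIGNIFICANT_FEATURES

    def test_screening_emits_one_row_per_feature(self, mini_table):
        _, summary = screen_features(mini_table)
        assert len(summary) == 22
        assert summary["p"].between(0, 1).all()
        # strong kinematic contrasts must be detected on the study conditions
        sig = set(summary.loc[summary["significant"], "feature"])
        assert {"Vmx", "Amx", "Jmx", "AL", "SMa"} <= sig

    def test_cell_means_outlier_becomes_missing(self, mini_table):
        t = mini_table.copy()
        col = t.columns.get_loc("Vmx")
        t.iloc[0, col] = 1e6  # wreck one trial -> its cell mean becomes an outlier
        cells = build_cell_means(t, "Vmx")
        assert cells.isna().sum().sum() == 1


class TestFactorAnalysis:
    @staticmethod
    def block_table(n=300, seed=0):
        rng = np.random.default_rng(seed)
        F3 = rng.normal(size=(n, 3))
        X = np.hstack([
            F3[:, [i]] * np.array([[0.9, 0.85, 0.8]]) + 0.3 * rng.normal(size=(n, 3))
            for i in range(3)
        ])
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(9)])

    def test_three_latent_blocks_recovered(self):
        df = self.block_table()
        fm = principal_factor_analysis(df, features=list(df.columns))
        assert fm.n_components == 3
        for block in range(3):
            cols = [f"f{3 * block + j}" for j in range(3)]
            comp = fm.loadings.loc[cols].abs().idxmax(axis=1)
            assert comp.nunique() == 1, f"block {block} split across components"
            assert (fm.loadings.loc[cols].abs().max(axis=1) > 0.7).all()

    def test_retention_follows_eigenvalue_one_criterion(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(400, 6)), columns=list("abcdef"))
        fm = principal_factor_analysis(df, features=list("abcdef"))
        assert fm.n_components == int((fm.eigenvalues > 1.0).sum())

    def test_duplicated_feature_loads_with_its_twin(self):
        df = self.block_table()
        df["f9"] = df["f0"] + 1e-6 * np.random.default_rng(1).normal(size=len(df))
        fm = principal_factor_analysis(df, features=list(df.columns))
        c0 = fm.loadings.loc["f0"].abs().idxmax()
        assert fm.loadings.loc["f9"].abs().idxmax() == c0
        assert abs(fm.loadings.loc["f9", c0]) > 0.7

    def test_too_few_rows_rejected(self):
        df = self.block_table(n=20)
        with pytest.raises(DataError, match=">= 50"):
            principal_factor_analysis(df, features=list(df.columns))

    def test_representatives_are_unique_and_one_per_component(self, mini_table):
        fm = principal_factor_analysis(mini_table)
        assert len(fm.representatives) == fm.n_components
        assert len(set(fm.representatives)) == fm.n_components
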
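"""Split-plot ANOVA: structure, degenerate inputs, oracle agreement, power."""

import warnings

import numpy as np
import pandas as pd
import pytest

from checkfish.stats import compare_similarity, run_mixed_anova, simple_effects


def design_data(rng, n_per_cell=7, treatment_shift=0.0, session_shift=0.0):
    """2 (treatment) x 2 (environment) between, 2-level within (session)."""
    rows = []
    i = 0
    for t in ("QNP", "control"):
        for e in ("A1A2", "HC"):
            for _ in range(n_per_cell):
                i += 1
                base = rng.normal() + (treatment_shift if t == "QNP" else 0.0)
                for sess in ("A1", "A2"):
                    rows.append(
                        {
                            "animal_id": f"a{i}",
                            "treatment": t,
                            "environment": e,
                            "session": sess,
                            "y": base + rng.normal()
                            + (session_shift if sess == "A2" else 0.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestRunMixedAnova:
    def test_reports_all_design_terms_with_correct_dfs(self):
        tab = run_mixed_anova(design_data(np.random.default_rng(0)), dv="y")
        assert set(tab["source"]) == {
            "treatment", "environment", "treatment:environment",
            "session", "session:treatment", "session:environment",
            "session:treatment:environment",
        }
        assert (tab["df1"] == 1.0).all()
        assert (tab["df2"] == 24.0).all()  # 28 subjects - 4 cells

    def test_matches_pingouin_on_one_between_design(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        d = design_data(rng, treatment_shift=0.8)
        d = d[d["environment"] == "A1A2"]
        mine = run_mixed_anova(d, dv="y", between=("treatment",))
        ref = pg.mixed_anova(
            data=d, dv="y", within="session", subject="animal_id", between="treatment"
        ).set_index("Source")
        m = mine.set_index("source")
        for src, ref_src in (("treatment", "treatment"), ("session", "session"),
                             ("session:treatment", "Interaction")):
            assert m.loc[src, "F"] == pytest.approx(ref.loc[ref_src, "F"], rel=1e-9)
            assert m.loc[src, "p"] == pytest.approx(ref.loc[ref_src, "p_unc"], rel=1e-9)

    def test_planted_within_effect_detected(self):
        d = design_data(np.random.default_rng(1), n_per_cell=10, session_shift=1.5)
        tab = run_mixed_anova(d, dv="y").set_index("source")
        assert tab.loc["session", "p"] < 0.001

    def test_planted_between_effect_power(self):
        # effect of 2 pooled SD at n = 9 + 9: rejection rate > 0.9
        rng = np.random.default_rng(2)
        hits = 0
        reps = 100
        for _ in range(reps):
            d = design_data(rng, n_per_cell=9, treatment_shift=2.0 * np.sqrt(2))
            d = d[d["environment"] == "A1A2"]
            tab = run_mixed_anova(d, dv="y", between=("treatment",)).set_index("source")
            hits += tab.loc["treatment", "p"] < 0.05
        assert hits / reps > 0.9

    def test_zero_variance_degenerate_data_flagged(self):
        d = design_data(np.random.default_rng(3))
        # distinct cell means, zero within-cell variance
        d["y"] = (
            (d["treatment"] == "QNP").astype(float) * 2
            + (d["session"] == "A2").astype(float)
        )
        with pytest.warns(UserWarning, match="zero within-cell error variance"):
            tab = run_mixed_anova(d, dv="y").set_index("source")
        assert np.isinf(tab.loc["session", "F"]) and tab.loc["session", "p"] == 0.0

    def test_agrees_with_permutation_oracle_on_small_design(self):
        # between-treatment p-value vs a permutation test on subject means
        rng = np.random.default_rng(4)
        d = design_data(rng, n_per_cell=6, treatment_shift=1.0)
        d = d[d["environment"] == "A1A2"]
        tab = run_mixed_anova(d, dv="y", between=("treatment",)).set_index("source")
        means = d.groupby(["animal_id", "treatment"])["y"].mean().reset_index()
        obs = abs(
            means[means.treatment == "QNP"]["y"].mean()
            - means[means.treatment == "control"]["y"].mean()
        )
        count = 0
        reps = 4000
        vals = means["y"].to_numpy()
        labels = (means["treatment"] == "QNP").to_numpy()
        for _ in range(reps):
            perm = rng.permutation(labels)
            stat = abs(vals[perm].mean() - vals[~perm].mean())
            count += stat >= obs
        p_perm = count / reps
        assert tab.loc["treatment", "p"] == pytest.approx(p_perm, abs=0.03)


class TestCompareSimilarity:
    def scores(self, rng, effect=0.0, n=7):
        rows = []
        i = 0
        for t in ("QNP", "control"):
            for e in ("A1A2", "HC"):
                for _ in range(n):
                    i += 1
                    rows.append(
                        {
                            "animal_id": f"a{i}", "treatment": t, "environment": e,
                            "region": "CA1",
                            "score": rng.normal() + (effect if t == "QNP" else 0.0),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_scores_show_no_effect(self):
        d = self.scores(np.random.default_rng(0))
        d["score"] = 0.4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tabs = compare_similarity(d)
        p = tabs["CA1"].set_index("source").loc["treatment", "p"]
        assert np.isnan(p) or p > 0.9

    def test_undefined_scores_excluded_and_counted(self):
        d = self.scores(np.random.default_rng(1))
        d.loc[d.index[:3], "score"] = np.nan
        tabs = compare_similarity(d)
        assert (tabs["CA1"]["n_excluded"] == 3).all()

    def test_all_undefined_region_skipped_with_warning(self):
        d = self.scores(np.random.default_rng(2))
        d["score"] = np.nan
        with pytest.warns(UserWarning, match="undefined"):
            tabs = compare_similarity(d)
        assert tabs == {}

    def test_planted_treatment_effect_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 60
        for _ in range(reps):
            d = self.scores(rng, effect=1.5, n=9)
            tabs = compare_similarity(d)
            p = tabs["CA1"].set_index("source").loc["treatment", "p"]
            hits += p < 0.05
        assert hits / reps > 0.8


class TestSimilarityContrastStructure:
    """Score ANOVAs on simulated two-epoch populations: equal overlap in
    both arms stays null; a planted overlap difference is detected."""

    CELLS = {("QNP", "A1A2"): 9, ("control", "A1A2"): 9,
             ("QNP", "HC"): 6, ("control", "HC"): 5}
    MARGINALS = {"QNP": (0.112, 0.207), "control": (0.294, 0.306)}

    def _simulated_scores(self, rng, n_nuclei, overlap, hc_p=0.05):
        from checkfish.similarity import similarity_from_counts
        from checkfish.synth import joint_activity_law

        rows = []
        i = 0
        for (t, e), n_animals in self.CELLS.items():
            if e == "A1A2":
                p1, p2 = self.MARGINALS[t]
                law = joint_activity_law(p1, p2, overlap[t])
            else:
                law = joint_activity_law(hc_p, hc_p, 0.0)
            p = [law["negative"], law["e1_only"], law["e2_only"], law["double"]]
            for _ in range(n_animals):
                i += 1
                counts = rng.multinomial(n_nuclei, p)
                res = similarity_from_counts(*counts)
                rows.append({"animal_id": f"a{i}", "treatment": t, "environment": e,
                             "region": "CA1", "score": res.score if res.defined else np.nan})
        return pd.DataFrame(rows)

    def test_equal_overlap_arms_stay_null(self):
        # per-animal analysed counts at the study's scale (hundreds)
        rng = np.random.default_rng(11)
        reps, nonsig = 150, 0
        for _ in range(reps):
            d = self._simulated_scores(rng, n_nuclei=250,
                                       overlap={"QNP": 0.3, "control": 0.3})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tabs = compare_similarity(d)
            p = tabs["CA1"].set_index("source").loc["treatment", "p"]
            nonsig += not (p < 0.05)
        assert nonsig / reps >= 0.88

    def test_planted_overlap_difference_detected(self):
        rng = np.random.default_rng(12)
        reps, hits = 60, 0
        for _ in range(reps):
            d = self._simulated_scores(rng, n_nuclei=250,
                                       overlap={"QNP": 0.4, "control": 0.0})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tabs = compare_similarity(d)
            p = tabs["CA1"].set_index("source").loc["treatment", "p"]
            hits += p < 0.05
        assert hits / reps > 0.8


class TestSimpleEffects:
    def test_two_level_contrast_with_bonferroni(self):
        rng = np.random.default_rng(0)
        d = design_data(rng, treatment_shift=3.0)
        out = simple_effects(d, dv="y", factor="treatment", by="session")
        assert len(out) == 2
        assert (out["p_bonferroni"] >= out["p"]).all()
        assert (out["p_bonferroni"] < 0.05).all()
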
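"""Speed normalization, interaction epsilon scores, ANOVA and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ryrmod.interaction import (
    expected_phenotype,
    group_means,
    interaction_score,
    interaction_test,
    normalize_speeds,
    power_two_groups,
)
from ryrmod.synthetic import SpeedSpec, gen_speed_dataset


class TestNormalize:
    def test_reference_mean_becomes_one(self):
        df = pd.DataFrame(
            {
                "larva_id": ["a", "b", "c"],
                "assay_id": ["x"] * 3,
                "genotype": ["WT", "WT", "mutant"],
                "treatment": ["vehicle", "vehicle", "vehicle"],
                "speed_mm_s": [2.0, 4.0, 4.5],
            }
        )
        out = normalize_speeds(df)
        wt = out[(out.genotype == "WT") & (out.treatment == "vehicle")]
        assert wt["speed_norm"].mean() == pytest.approx(1.0)
        assert out.loc[out.larva_id == "c", "speed_norm"].iloc[0] == pytest.approx(1.5)

    def test_per_assay_normalization(self):
        """Two assays with different reference means: within-assay ratios are
        unchanged by pooling."""
        rows = []
        for assay, ref in [("a1", 2.0), ("a2", 8.0)]:
            rows += [
                (f"{assay}-r1", assay, "WT", "vehicle", ref),
                (f"{assay}-r2", assay, "WT", "vehicle", ref),
                (f"{assay}-m", assay, "mutant", "vehicle", ref * 0.5),
            ]
        df = pd.DataFrame(rows, columns=["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"])
        out = normalize_speeds(df)
        muts = out[out.genotype == "mutant"]["speed_norm"]
        assert np.allclose(muts, 0.5)

    def test_missing_reference_names_assay(self):
        df = pd.DataFrame(
            {
                "larva_id": ["a"],
                "assay_id": ["assayQ"],
                "genotype": ["mutant"],
                "treatment": ["vehicle"],
                "speed_mm_s": [1.0],
            }
        )
        with pytest.raises(ValueError, match="assayQ"):
            normalize_speeds(df)


class TestExpectedPhenotype:
    def test_no_effect_identity(self):
        assert expected_phenotype(1.0, 1.0, "additive") == 1.0
        assert expected_phenotype(1.0, 1.0, "multiplicative") == 1.0

    def test_formulas(self):
        # normalized forms of Wg + Wc - W and Wg*Wc/W at W=1
        assert expected_phenotype(0.5, 0.8, "additive") == pytest.approx(0.3)
        assert expected_phenotype(0.5, 0.8, "multiplicative") == pytest.approx(0.4)

    def test_unnormalized_equivalence(self):
        W, Wg, Wc = 3.0, 1.5, 2.4
        G, C = Wg / W, Wc / W
        assert expected_phenotype(G, C, "additive") == pytest.approx((Wg + Wc - W) / W)
        assert expected_phenotype(G, C, "multiplicative") == pytest.approx((Wg * Wc / W) / W)

    def test_boundary_zero_chemical(self):
        assert expected_phenotype(0.7, 0.0, "multiplicative") == 0.0
        assert expected_phenotype(0.7, 0.0, "additive") == pytest.approx(-0.3)

    def test_eps_arithmetic(self):
        eps_add, eps_mult = interaction_score(0.6, 0.7, 0.9)
        assert eps_add == pytest.approx(0.9 - 0.3)
        assert eps_mult == pytest.approx(0.9 - 0.42)


def closed_form_balanced_anova(df: pd.DataFrame, value: str):
    """Textbook balanced two-way ANOVA decomposition; returns interaction F, p."""
    cells = df.groupby(["genotype", "treatment"])[value]
    n = cells.count().iloc[0]
    assert (cells.count() == n).all()
    grand = df[value].mean()
    a_means = df.groupby("genotype")[value].mean()
    b_means = df.groupby("treatment")[value].mean()
    cell_means = cells.mean()
    ss_a = 2 * n * ((a_means - grand) ** 2).sum()
    ss_b = 2 * n * ((b_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_int = ss_cells - ss_a - ss_b
    ss_tot = ((df[value] - grand) ** 2).sum()
    ss_res = ss_tot - ss_cells
    df_res = len(df) - 4
    F = (ss_int / 1) / (ss_res / df_res)
    return F, float(stats.f.sf(F, 1, df_res))


class TestInteractionTest:
    def test_balanced_matches_closed_form(self, toy_speed_frame):
        res = interaction_test(toy_speed_frame, chemical="chem")
        norm = normalize_speeds(toy_speed_frame)
        F, p = closed_form_balanced_anova(norm, "speed_norm")
        assert res.anova.loc["C(A):C(B)", "F"] == pytest.approx(F, abs=1e-6)
        assert res.p_interaction == pytest.approx(p, abs=1e-6)

    def test_noise_free_additive_no_interaction(self):
        rows = []
        i = 0
        for geno, g in [("WT", 0.0), ("mutant", -1.0)]:
            for treat, c in [("vehicle", 0.0), ("chem", -0.5)]:
                for jitter in (-0.1, 0.0, 0.1):  # same within-cell pattern: no residual noise term breaking additivity
                    rows.append((f"l{i}", "a", geno, treat, 3.0 + g + c + jitter))
                    i += 1
        df = pd.DataFrame(rows, columns=["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"])
        res = interaction_test(df, chemical="chem")
        assert res.anova.loc["C(A):C(B)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert res.p_interaction == 1.0 or res.p_interaction > 0.999999
        assert res.classification == "none"

    def test_exactly_additive_zero_noise_p_is_one(self):
        rows = []
        i = 0
        for geno, g in [("WT", 0.0), ("mutant", -1.0)]:
            for treat, c in [("vehicle", 0.0), ("chem", -0.5)]:
                for _ in range(3):
                    rows.append((f"l{i}", "a", geno, treat, 3.0 + g + c))
                    i += 1
        df = pd.DataFrame(rows, columns=["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"])
        res = interaction_test(df, chemical="chem")
        assert res.p_interaction == 1.0
        assert res.classification == "none"

    def test_planted_positive_interaction_detected(self):
        df = gen_speed_dataset(
            SpeedSpec(n_per_group=20, interaction_model="custom", epsilon=0.5,
                      noise_sd=0.1, seed=11)
        )
        res = interaction_test(df)
        assert res.classification == "positive"
        assert res.eps_mult > 0.3

    def test_scale_invariance_of_eps(self):
        df = gen_speed_dataset(SpeedSpec(n_per_group=10, noise_sd=0.05, seed=4))
        res1 = interaction_test(df)
        df2 = df.copy()
        df2["speed_mm_s"] *= 7.3  # uniform rescaling of raw speeds
        res2 = interaction_test(df2)
        assert res1.eps_add == pytest.approx(res2.eps_add, abs=1e-12)
        assert res1.eps_mult == pytest.approx(res2.eps_mult, abs=1e-12)

    def test_empty_cell_rejected(self, toy_speed_frame):
        df = toy_speed_frame[~((toy_speed_frame.genotype == "mutant") & (toy_speed_frame.treatment == "chem"))]
        with pytest.raises(ValueError):
            interaction_test(df, chemical="chem")

    def test_group_means_missing_group(self, toy_speed_frame):
        df = normalize_speeds(toy_speed_frame)
        with pytest.raises(ValueError, match="missing group"):
            group_means(df[df.genotype == "WT"], chemical="chem")


class TestEpsilonRecovery:
    def test_custom_epsilon_recovered(self):
        """Mean estimated eps_mult over seeds recovers the planted offset."""
        for eps_true in (-0.3, 0.0, 0.3):
            est = []
            for seed in range(120):
                df = gen_speed_dataset(
                    SpeedSpec(n_per_group=20, interaction_model="custom",
                              epsilon=eps_true, noise_sd=0.1, seed=seed)
                )
                m = group_means(df)
                _, eps_mult = interaction_score(m["G"], m["C"], m["GC"])
                est.append(eps_mult)
            assert np.mean(est) == pytest.approx(eps_true, abs=0.02)

    def test_multiplicative_null_centered(self):
        est = []
        for seed in range(100):
            df = gen_speed_dataset(
                SpeedSpec(n_per_group=20, interaction_model="multiplicative",
                          noise_sd=0.05, seed=seed)
            )
            m = group_means(df)
            est.append(interaction_score(m["G"], m["C"], m["GC"])[1])
        se = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est)) < 3 * se + 1e-3


class TestPower:
    def test_null_power_equals_alpha(self):
        assert power_two_groups(1.0, 0.5, 1.0, 0.5, 10) == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_power_one(self):
        assert power_two_groups(100.0, 0.1, 0.0, 0.1, 5) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning):
            assert power_two_groups(1.0, 0.0, 1.0, 0.0, 5) == 0.05

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        d = 1.0 / 0.5
        expect = TTestIndPower().power(effect_size=d, nobs1=9, alpha=0.05)
        assert power_two_groups(1.0, 0.5, 0.0, 0.5, 9) == pytest.approx(expect, abs=1e-8)

    def test_monte_carlo_agreement(self):
        """Rejection rate of an actual pooled t-test at the same parameters."""
        rng = np.random.default_rng(42)
        n, reps = 9, 20000
        x = rng.normal(1.0, 0.5, (reps, n))
        y = rng.normal(0.0, 0.5, (reps, n))
        t, p = stats.ttest_ind(x, y, axis=1)
        rate = float((p < 0.05).mean())
        assert power_two_groups(1.0, 0.5, 0.0, 0.5, 9) == pytest.approx(rate, abs=0.01)
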
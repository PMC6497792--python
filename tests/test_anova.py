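import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps
from phenoscreen.anova import (
    SOURCE_ENVIRONMENT,
    SOURCE_GENOTYPE,
    SOURCE_INTERACTION,
    SOURCE_RESIDUAL,
)
from phenoscreen.errors import (
    DesignMismatchError,
    InsufficientReplicationError,
    UnbalancedDesignError,
)

from conftest import long_frame, random_balanced_table


def brute_force_two_way_ss(table, trait):
    """Independent oracle: SS by explicit loops over the mean decomposition."""
    sub = table.trait_values(trait)
    genotypes = sorted(sub["genotype"].unique())
    envs = sorted(sub["environment"].unique())
    cell = {
        (g, e): sub.query("genotype == @g and environment == @e")["value"].to_numpy()
        for g in genotypes
        for e in envs
    }
    r = len(next(iter(cell.values())))
    all_values = np.concatenate(list(cell.values()))
    grand = all_values.mean()
    gm = {g: np.mean([cell[g, e].mean() for e in envs]) for g in genotypes}
    em = {e: np.mean([cell[g, e].mean() for g in genotypes]) for e in envs}
    ss_g = len(envs) * r * sum((gm[g] - grand) ** 2 for g in genotypes)
    ss_e = len(genotypes) * r * sum((em[e] - grand) ** 2 for e in envs)
    ss_ge = r * sum(
        (cell[g, e].mean() - gm[g] - em[e] + grand) ** 2
        for g in genotypes
        for e in envs
    )
    ss_res = sum(
        ((cell[g, e] - cell[g, e].mean()) ** 2).sum() for g in genotypes for e in envs
    )
    return ss_g, ss_e, ss_ge, ss_res


class TestTwoWayAnova:
    def test_hand_computed_toy_decomposition(self, toy_2x2x2):
        anova = ps.two_way_anova(toy_2x2x2, "t1")
        assert anova.loc[SOURCE_GENOTYPE, "sum_sq"] == pytest.approx(32)
        assert anova.loc[SOURCE_ENVIRONMENT, "sum_sq"] == pytest.approx(2)
        assert anova.loc[SOURCE_INTERACTION, "sum_sq"] == pytest.approx(0)
        assert anova.loc[SOURCE_RESIDUAL, "sum_sq"] == pytest.approx(8)
        assert anova["df"].tolist() == [1, 1, 1, 4]

    def test_constant_data_gives_zero_ss(self):
        table = ps.phenotype_table_from_frame(
            long_frame(
                {
                    ("G1", "non_stressed"): [5, 5],
                    ("G1", "stressed"): [5, 5],
                    ("G2", "non_stressed"): [5, 5],
                    ("G2", "stressed"): [5, 5],
                }
            )
        )
        anova = ps.two_way_anova(table, "t1")
        assert (anova["sum_sq"] == 0).all()

    def test_sources_sum_to_total_ss(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            table = random_balanced_table(rng)
            anova = ps.two_way_anova(table, "t1")
            values = table.trait_values("t1")["value"].to_numpy()
            total = ((values - values.mean()) ** 2).sum()
            assert anova["sum_sq"].sum() == pytest.approx(total, rel=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            table = random_balanced_table(rng)
            anova = ps.two_way_anova(table, "t1")
            ss = brute_force_two_way_ss(table, "t1")
            for source, expected in zip(
                [SOURCE_GENOTYPE, SOURCE_ENVIRONMENT, SOURCE_INTERACTION, SOURCE_RESIDUAL],
                ss,
            ):
                assert anova.loc[source, "sum_sq"] == pytest.approx(expected, rel=1e-9)

    def test_matches_statsmodels(self):
        """Cross-check SS, F and p against an OLS fit with full interaction."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        table = random_balanced_table(rng, g=4, r=3)
        ours = ps.two_way_anova(table, "t1")
        df = table.trait_values("t1")
        fit = smf.ols("value ~ C(genotype) * C(environment)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        mapping = {
            SOURCE_GENOTYPE: "C(genotype)",
            SOURCE_ENVIRONMENT: "C(environment)",
            SOURCE_INTERACTION: "C(genotype):C(environment)",
            SOURCE_RESIDUAL: "Residual",
        }
        for source, name in mapping.items():
            assert ours.loc[source, "sum_sq"] == pytest.approx(
                ref.loc[name, "sum_sq"], rel=1e-8
            )
        assert ours.loc[SOURCE_GENOTYPE, "p_value"] == pytest.approx(
            ref.loc["C(genotype)", "PR(>F)"], rel=1e-8
        )

    def test_unbalanced_after_policy_reduces_r_with_warning(self, toy_2x2x2):
        df = pd.concat(
            [
                toy_2x2x2.data,
                pd.DataFrame(
                    [
                        {
                            "genotype": "G1",
                            "environment": "non_stressed",
                            "replicate": 3,
                            "trait": "t1",
                            "value": 2.0,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
        table = ps.phenotype_table_from_frame(df)
        with pytest.warns(UserWarning, match="balanced subset"):
            anova = ps.two_way_anova(table, "t1")
        assert anova.loc[SOURCE_RESIDUAL, "df"] == 4  # r reduced back to 2

    def test_empty_cell_is_unbalanced_error(self, toy_2x2x2):
        df = toy_2x2x2.data.query("~(genotype == 'G2' and environment == 'stressed')")
        table = ps.phenotype_table_from_frame(df)
        with pytest.raises(UnbalancedDesignError, match="G2"):
            ps.two_way_anova(table, "t1")

    def test_single_replicate_errors(self):
        table = ps.phenotype_table_from_frame(
            long_frame(
                {
                    ("G1", "non_stressed"): [1],
                    ("G1", "stressed"): [2],
                    ("G2", "non_stressed"): [3],
                    ("G2", "stressed"): [4],
                }
            )
        )
        with pytest.raises(InsufficientReplicationError):
            ps.two_way_anova(table, "t1")


class TestOneWayAnova:
    def test_hand_computed_example(self):
        table = ps.phenotype_table_from_frame(
            long_frame({("G1", "stressed"): [0, 2], ("G2", "stressed"): [4, 6]})
        )
        anova = ps.one_way_anova(table, "t1", "stressed")
        assert anova.loc[SOURCE_GENOTYPE, "sum_sq"] == pytest.approx(16)
        assert anova.loc[SOURCE_RESIDUAL, "sum_sq"] == pytest.approx(4)

    def test_df_partition(self):
        rng = np.random.default_rng(3)
        table = random_balanced_table(rng, g=5, s=1, r=4)
        anova = ps.one_way_anova(table, "t1", "non_stressed")
        assert anova["df"].sum() == 5 * 4 - 1

    def test_identical_genotype_values_give_zero_genotype_ss(self):
        table = ps.phenotype_table_from_frame(
            long_frame({("G1", "stressed"): [1, 3], ("G2", "stressed"): [1, 3]})
        )
        anova = ps.one_way_anova(table, "t1", "stressed")
        assert anova.loc[SOURCE_GENOTYPE, "sum_sq"] == pytest.approx(0)


class TestVarianceComponents:
    @staticmethod
    def make_anova(ms_g, ms_ge, ms_res, g, s, r):
        rows = pd.DataFrame(
            {
                "sum_sq": [
                    ms_g * (g - 1),
                    1.0,
                    ms_ge * (g - 1) * (s - 1),
                    ms_res * g * s * (r - 1),
                ],
                "df": [g - 1, s - 1, (g - 1) * (s - 1), g * s * (r - 1)],
            },
            index=pd.Index(
                [SOURCE_GENOTYPE, SOURCE_ENVIRONMENT, SOURCE_INTERACTION, SOURCE_RESIDUAL],
                name="source",
            ),
        )
        rows["mean_sq"] = rows["sum_sq"] / rows["df"]
        return rows

    def test_moment_equations(self):
        anova = self.make_anova(ms_g=10, ms_ge=4, ms_res=2, g=16, s=2, r=3)
        comp = ps.variance_components(anova, s=2, r=3)
        assert comp.sigma2_g == pytest.approx(1.0)
        assert comp.sigma2_ge == pytest.approx(2 / 3)
        assert comp.sigma2_e == pytest.approx(2.0)
        assert comp.truncated == ()

    def test_negative_genetic_estimate_truncated(self):
        anova = self.make_anova(ms_g=3, ms_ge=4, ms_res=2, g=16, s=2, r=3)
        comp = ps.variance_components(anova, s=2, r=3)
        assert comp.sigma2_g == 0.0
        assert "sigma2_g" in comp.truncated

    def test_all_mean_squares_equal_gives_zero_components(self):
        anova = self.make_anova(ms_g=2, ms_ge=2, ms_res=2, g=16, s=2, r=3)
        comp = ps.variance_components(anova, s=2, r=3)
        assert comp.sigma2_g == 0.0 and comp.sigma2_ge == 0.0

    def test_design_mismatch_detected(self):
        anova = self.make_anova(ms_g=10, ms_ge=4, ms_res=2, g=16, s=2, r=3)
        with pytest.raises(DesignMismatchError):
            ps.variance_components(anova, s=2, r=4)


class TestHeritability:
    def test_hand_computed_combined_h(self):
        comp = ps.VarianceComponents(
            sigma2_g=4, sigma2_ge=2, sigma2_e=6, s=2, r=3
        )
        assert ps.heritability(comp).H == pytest.approx(100 * 4 / 6, abs=1e-9)

    def test_zero_genetic_variance_gives_zero_h(self):
        comp = ps.VarianceComponents(sigma2_g=0, sigma2_ge=2, sigma2_e=6, s=2, r=3)
        assert ps.heritability(comp).H == 0.0

    def test_pure_genetic_variance_gives_full_h(self):
        comp = ps.VarianceComponents(sigma2_g=3, sigma2_ge=0, sigma2_e=0, s=2, r=3)
        assert ps.heritability(comp).H == pytest.approx(100.0)

    def test_degenerate_all_zero_warns(self):
        comp = ps.VarianceComponents(sigma2_g=0, sigma2_ge=0, sigma2_e=0, s=2, r=3)
        with pytest.warns(UserWarning, match="zero"):
            assert ps.heritability(comp).H == 0.0

    def test_h_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(9)
        table = random_balanced_table(rng, g=6, r=3)
        h0 = ps.trait_heritability(table, "t1").H
        df = table.data.copy()
        df["value"] = 3.5 * df["value"] - 11.0
        h1 = ps.trait_heritability(ps.phenotype_table_from_frame(df), "t1").H
        assert h1 == pytest.approx(h0, rel=1e-9)

    def test_near_constant_environment_has_zero_h(self):
        """A trait flattened by stress (e.g. soil water at wilting point)
        keeps high control-side H but drops to 0 under stress."""
        spec = ps.TraitSpec(
            trait="vwc", mu_ns=19.49, effect=-19.49,
            sigma2_g=6.0, sigma2_ge=0.0, sigma2_e=0.6,
        )
        table = ps.simulate_trait(spec, g=16, s=2, r=3, seed=4)
        df = table.data.copy()
        # stress forces the measurement to the floor: constant across genotypes
        df.loc[df["environment"] == "stressed", "value"] = 0.0
        flat = ps.phenotype_table_from_frame(df)
        h_ns = ps.trait_heritability(flat, "vwc", scope="non_stressed").H
        h_s = ps.trait_heritability(flat, "vwc", scope="stressed").H
        assert h_ns > 50.0
        assert h_s == 0.0

    def test_per_env_table_layout(self, study_population):
        herit = ps.heritability_table(study_population, scope="per-env")
        assert len(herit) == 24 * 2
        assert set(herit["scope"]) == {"non_stressed", "stressed"}
        assert herit["H_percent"].between(0, 100).all()
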
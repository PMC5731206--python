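import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import sertoliseq as sq


def anova_oracle(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Reference 2x2 factorial ANOVA via an OLS linear model."""
    fit = sm.OLS.from_formula(
        "y ~ C(a) * C(b)", pd.DataFrame({"y": y, "a": a, "b": b})
    ).fit()
    table = anova_lm(fit, typ=2)
    return {
        "F_fshr": table.loc["C(a)", "F"],
        "p_fshr": table.loc["C(a)", "PR(>F)"],
        "F_ar": table.loc["C(b)", "F"],
        "p_ar": table.loc["C(b)", "PR(>F)"],
        "F_interaction": table.loc["C(a):C(b)", "F"],
        "p_interaction": table.loc["C(a):C(b)", "PR(>F)"],
    }


def knockout_matrix(values: np.ndarray, n: int) -> sq.ExpressionMatrix:
    """Build a 4-genotype matrix from an array (transcripts, 4, n)."""
    cols, data, meta = [], [], []
    for gi, g in enumerate(sq.GENOTYPES):
        for r in range(1, n + 1):
            cols.append(f"{g}_{r}")
            meta.append((f"{g}_{r}", g, r))
        data.append(values[:, gi, :])
    df = pd.DataFrame(
        np.concatenate(data, axis=1),
        index=pd.Index([f"T{i}" for i in range(values.shape[0])], name="transcript_id"),
        columns=cols,
    )
    sm_meta = pd.DataFrame(meta, columns=["sample_id", "group", "replicate"]).set_index(
        "sample_id"
    )
    return sq.ExpressionMatrix(df, sm_meta)


class TestEnrichmentFactor:
    def test_control_is_exactly_one(self):
        morph = sq.default_morphometry()
        assert sq.compute_enrichment_factor(morph, "control") == 1.0

    def test_identical_genotype_gives_one(self):
        morph = pd.DataFrame(
            {"sertoli_cells_per_testis": [100.0, 100.0], "testis_volume": [10.0, 10.0]},
            index=pd.Index(["control", "FSHRKO"], name="genotype"),
        )
        assert sq.compute_enrichment_factor(morph, "FSHRKO") == pytest.approx(1.0)

    def test_halved_cells_quartered_volume_gives_two(self):
        morph = pd.DataFrame(
            {"sertoli_cells_per_testis": [100.0, 50.0], "testis_volume": [20.0, 5.0]},
            index=pd.Index(["control", "SCARKO"], name="genotype"),
        )
        assert sq.compute_enrichment_factor(morph, "SCARKO") == pytest.approx(2.0)

    def test_random_morphometry_matches_density_ratio_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            cells = rng.uniform(1e6, 5e7, 2)
            vols = rng.uniform(5, 50, 2)
            morph = pd.DataFrame(
                {"sertoli_cells_per_testis": cells, "testis_volume": vols},
                index=pd.Index(["control", "X"], name="genotype"),
            )
            expected = (cells[1] / vols[1]) / (cells[0] / vols[0])
            assert sq.compute_enrichment_factor(morph, "X") == pytest.approx(
                expected, abs=1e-12 * expected
            )

    def test_missing_genotype_is_hard_error(self):
        with pytest.raises(KeyError):
            sq.compute_enrichment_factor(sq.default_morphometry(), "nonexistent")


class TestSertoliNormalization:
    def test_unit_factors_are_identity(self, tiny_matrix):
        factors = {"control": 1.0, "treated": 1.0}
        out = sq.normalize_to_sertoli_number(tiny_matrix, factors)
        assert np.array_equal(out.values.to_numpy(), tiny_matrix.values.to_numpy())

    def test_factor_two_halves_that_genotype(self, tiny_matrix):
        out = sq.normalize_to_sertoli_number(tiny_matrix, {"control": 1.0, "treated": 2.0})
        assert np.allclose(out.values["t1"], tiny_matrix.values["t1"] / 2)
        assert np.allclose(out.values["c1"], tiny_matrix.values["c1"])

    def test_unmapped_genotype_is_hard_error(self, tiny_matrix):
        with pytest.raises(KeyError):
            sq.normalize_to_sertoli_number(tiny_matrix, {"control": 1.0})

    def test_constant_per_cell_expression_recovered_across_genotypes(self):
        """A Sertoli transcript with equal per-cell expression but unequal
        Sertoli numbers has equal normalized means at zero noise."""
        truth = sq.generate_truth(200, sq.TruthConfig(cv=0.0,
                                                      frac_fshr_affected=0.0,
                                                      frac_ar_affected=0.0,
                                                      frac_fshr_up=0.0,
                                                      frac_ar_up=0.0), seed=21)
        morph = sq.default_morphometry()
        em = sq.simulate_knockout_study(truth, morph, n_replicates=3, seed=22)
        normalized = sq.normalize_to_sertoli_number(em, sq.enrichment_factors(morph))
        sert = truth.ids_in_category("sertoli_exclusive")
        means = normalized.with_values(normalized.values.loc[sert]).group_means()
        for g in sq.GENOTYPES[1:]:
            assert np.allclose(means[g], means["control"], rtol=1e-9)


class TestFactorialAnova:
    def test_matches_linear_model_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        n = 4
        values = rng.lognormal(3, 0.5, size=(100, 4, n))
        records = sq.per_transcript_two_factor_anova(knockout_matrix(values, n),
                                                     posthoc=False)
        a = np.repeat([0, 1, 0, 1], n)
        b = np.repeat([0, 0, 1, 1], n)
        coding = {g: c for g, c in sq.FactorialDesign().coding.items()}
        order = [coding[g] for g in sq.GENOTYPES]
        for i in range(values.shape[0]):
            y = np.concatenate([values[i, gi, :] for gi in range(4)])
            a_vec = np.repeat([c[0] for c in order], n)
            b_vec = np.repeat([c[1] for c in order], n)
            ref = anova_oracle(y, a_vec, b_vec)
            row = records.iloc[i]
            for key in ("p_fshr_anova", "p_ar_anova", "p_interaction"):
                oracle_key = key.replace("_anova", "").replace("p_", "p_")
                assert row[key] == pytest.approx(ref[oracle_key], abs=1e-8)
            assert row["F_interaction"] == pytest.approx(ref["F_interaction"], abs=1e-6)

    def test_equal_cell_means_give_zero_f(self):
        # all four cells share mean 10 with nonzero within-cell spread
        cell = np.array([9.0, 11.0, 10.5, 9.5])
        values = np.stack([np.stack([cell + 0 for _ in range(4)])])
        perm = np.stack([np.stack([np.random.default_rng(i).permutation(cell)
                                   for i in range(4)])])
        records = sq.per_transcript_two_factor_anova(knockout_matrix(perm, 4),
                                                     posthoc=False)
        assert records.iloc[0]["F_fshr"] == pytest.approx(0.0, abs=1e-12)
        assert records.iloc[0]["F_ar"] == pytest.approx(0.0, abs=1e-12)
        assert records.iloc[0]["F_interaction"] == pytest.approx(0.0, abs=1e-12)
        assert records.iloc[0]["p_interaction"] == pytest.approx(1.0)

    def test_multiplicative_effects_additive_on_log_scale(self):
        """x0.5 per single knockout and x0.25 double is exactly additive in log2."""
        base = np.array([8.0, 8.0, 8.0, 8.0]) * np.array([1.0, 1.1, 0.9, 1.05])
        values = np.stack(
            [np.stack([base, base * 0.5, base * 0.5, base * 0.25])]
        )
        records = sq.per_transcript_two_factor_anova(
            knockout_matrix(values, 4), posthoc=False, transform="log2"
        )
        assert records.iloc[0]["ss_interaction"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_residual_variance_gives_undefined_p(self):
        values = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[None, :, None], (1, 1, 3))
        records = sq.per_transcript_two_factor_anova(knockout_matrix(values, 3),
                                                     posthoc=False)
        assert np.isnan(records.iloc[0]["p_interaction"])

    def test_direction_labels_match_mean_difference_sign(self):
        rng = np.random.default_rng(29)
        values = rng.lognormal(3, 0.4, size=(50, 4, 4))
        values[:25, 1, :] *= 0.2   # FSHRKO strongly down
        values[25:, 1, :] *= 4.0   # FSHRKO strongly up
        records = sq.per_transcript_two_factor_anova(knockout_matrix(values, 4))
        sig = records["regulation_fshr"] != "unchanged"
        diff = records["mean_FSHRKO"] - records["mean_control"]
        assert (records.loc[sig & (diff < 0), "regulation_fshr"] == "down").all()
        assert (records.loc[sig & (diff > 0), "regulation_fshr"] == "up").all()
        assert (records.loc[~sig, "regulation_fshr"] == "unchanged").all()

    def test_posthoc_letters_only_for_significant_interactions(self):
        rng = np.random.default_rng(31)
        values = rng.lognormal(3, 0.3, size=(40, 4, 4))
        values[:10, 3, :] *= 0.05  # strong synergistic loss in double KO
        records = sq.per_transcript_two_factor_anova(knockout_matrix(values, 4))
        has_letters = records["posthoc_letters"].astype(str) != ""
        is_interaction = records["effect_mode"] == "interaction"
        assert (has_letters == is_interaction).all()

    def test_tukey_p_matches_statsmodels_on_fixture(self):
        from sertoliseq.hormones import _tukey_pairwise_p

        rng = np.random.default_rng(37)
        n = 5
        data = rng.normal(10, 1, size=(4, n))
        data[3] += 4
        means = data.mean(axis=1)
        mse = data.var(axis=1, ddof=1).mean()
        pmat = _tukey_pairwise_p(means, np.full(4, n), mse, 4 * (n - 1))
        flat = np.concatenate([data[i] for i in range(4)])
        groups = np.repeat(list("ABCD"), n)
        ref = pairwise_tukeyhsd(flat, groups)
        for (i, j), p_ref in zip(
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], ref.pvalues
        ):
            assert pmat[i, j] == pytest.approx(p_ref, abs=1e-6)

    def test_normalization_invariance(self):
        """Scaling one genotype's samples and its enrichment factor by the
        same constant leaves every ANOVA record unchanged."""
        rng = np.random.default_rng(41)
        values = rng.lognormal(3, 0.4, size=(30, 4, 4))
        em = knockout_matrix(values, 4)
        factors = pd.Series({g: 1.0 for g in sq.GENOTYPES})
        c = 3.7
        scaled_values = em.values.copy()
        scko = [s for s in em.values.columns if s.startswith("SCARKO_")]
        scaled_values[scko] *= c
        scaled_factors = factors.copy()
        scaled_factors["SCARKO"] = c
        base = sq.per_transcript_two_factor_anova(
            sq.normalize_to_sertoli_number(em, factors)
        )
        scaled = sq.per_transcript_two_factor_anova(
            sq.normalize_to_sertoli_number(em.with_values(scaled_values), scaled_factors)
        )
        num = base.select_dtypes(include=[float])
        pd.testing.assert_frame_equal(num, scaled[num.columns], atol=1e-10, rtol=1e-10)
        assert (base["regulation_fshr"] == scaled["regulation_fshr"]).all()

    def test_unbalanced_design_matches_balanced_when_dropping_nothing(self):
        rng = np.random.default_rng(43)
        values = rng.lognormal(3, 0.4, size=(5, 4, 3))
        em = knockout_matrix(values, 3)
        balanced = sq.per_transcript_two_factor_anova(em, posthoc=False)
        # drop one replicate to force the Type-II OLS path
        cols = [c for c in em.values.columns if c != "control_3"]
        unb = sq.ExpressionMatrix(
            em.values[cols], em.sample_meta.loc[cols], em.gene_symbols
        )
        records = sq.per_transcript_two_factor_anova(unb, posthoc=False)
        a = unb.sample_meta.loc[cols, "group"].map(
            {g: c[0] for g, c in sq.FactorialDesign().coding.items()}
        ).to_numpy(float)
        b = unb.sample_meta.loc[cols, "group"].map(
            {g: c[1] for g, c in sq.FactorialDesign().coding.items()}
        ).to_numpy(float)
        for i in range(5):
            ref = anova_oracle(unb.values.iloc[i].to_numpy(), a, b)
            assert records.iloc[i]["p_interaction"] == pytest.approx(
                ref["p_interaction"], abs=1e-8
            )
        assert balanced.iloc[0]["p_interaction"] == pytest.approx(
            anova_oracle(
                em.values.iloc[0].to_numpy(),
                em.sample_meta.loc[list(em.values.columns), "group"].map(
                    {g: c[0] for g, c in sq.FactorialDesign().coding.items()}
                ).to_numpy(float),
                em.sample_meta.loc[list(em.values.columns), "group"].map(
                    {g: c[1] for g, c in sq.FactorialDesign().coding.items()}
                ).to_numpy(float),
            )["p_interaction"],
            abs=1e-8,
        )


class TestRegulationSummary:
    def test_nonsignificant_interaction_counts_additive(self):
        rng = np.random.default_rng(47)
        values = rng.lognormal(3, 0.3, size=(20, 4, 4))
        records = sq.per_transcript_two_factor_anova(knockout_matrix(values, 4))
        summary = sq.classify_regulation(records)
        assert summary["additive"] + summary["interaction"] == 20
        n_add = (records["effect_mode"] == "additive").sum()
        assert summary["additive"] == n_add

    def test_deep_double_ko_decrease_detected(self):
        rng = np.random.default_rng(53)
        values = rng.lognormal(3, 0.15, size=(30, 4, 4))
        values[:5, 3, :] *= 0.03  # >90% loss in double knockout, synergistic
        records = sq.per_transcript_two_factor_anova(knockout_matrix(values, 4))
        summary = sq.classify_regulation(records)
        deep = set(summary["deep_double_ko_decrease"])
        assert deep == {f"T{i}" for i in range(5)}

    def test_knockout_simulation_recovers_injected_directions(self, small_truth):
        morph = sq.default_morphometry()
        em = sq.simulate_knockout_study(small_truth, morph, n_replicates=4, seed=55)
        normalized = sq.normalize_to_sertoli_number(em, sq.enrichment_factors(morph))
        sert = small_truth.ids_in_category("sertoli_exclusive")
        records = sq.per_transcript_two_factor_anova(
            normalized.with_values(normalized.values.loc[sert])
        )
        strong_down = sert[
            (small_truth.fshr_effect.loc[sert] <= 0.5).to_numpy()
        ]
        frac_down = (records.loc[strong_down, "regulation_fshr"] == "down").mean()
        assert frac_down >= 0.9
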
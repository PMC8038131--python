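"""Risk-allele orientation, allele-count scoring, tertile banding and
category odds ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gmdrprs as g
from gmdrprs.containers import EffectEstimate
from gmdrprs.prs import (
    PolygenicRiskScorer,
    PRSModel,
    empirical_tertile_bounds,
    preset_bands,
)
from conftest import make_genotype_matrix


def _effect(or_value):
    lo, hi = min(or_value, 1 / or_value) * 0.9, max(or_value, 1 / or_value) * 1.1
    return EffectEstimate("snp", or_value, min(lo, or_value), max(hi, or_value), 0.001)


class TestOrientation:
    def test_minor_or_above_one_picks_minor(self, small_genotypes):
        model = g.orient_risk_alleles(
            small_genotypes,
            {s: _effect(1.29) for s in small_genotypes.snp_ids},
            small_genotypes.snp_ids[:2],
            bounds=(1, 2),
        )
        sid = small_genotypes.snp_ids[0]
        assert model.risk_allele[sid] == small_genotypes.snps.loc[sid, "minor_allele"]
        assert model.risk_is_minor[sid]

    def test_minor_or_below_one_picks_major(self, small_genotypes):
        sid = small_genotypes.snp_ids[0]
        model = g.orient_risk_alleles(
            small_genotypes, {sid: _effect(0.76)}, [sid], bounds=(1, 2)
        )
        assert model.risk_allele[sid] == small_genotypes.snps.loc[sid, "major_allele"]
        assert not model.risk_is_minor[sid]

    def test_or_exactly_one_rejected(self, small_genotypes):
        sid = small_genotypes.snp_ids[0]
        eff = EffectEstimate("snp", 1.0, 0.9, 1.1, 0.9)
        with pytest.raises(ValueError, match="manually"):
            g.orient_risk_alleles(small_genotypes, {sid: eff}, [sid], bounds=(1, 2))


class TestScoring:
    def test_worked_example_risk_allele_counts(self):
        # SNP with alleles G (minor, risk) / T: TT -> 0, GT -> 1, GG -> 2
        gm = make_genotype_matrix([[0.0], [1.0], [2.0]], snp_ids=["rs1"])
        gm.snps.loc["rs1", ["minor_allele", "major_allele"]] = ["G", "T"]
        model = PRSModel(("rs1",), {"rs1": "G"}, {"rs1": True}, bounds=(0, 1))
        scores = g.compute_prs(gm, model)["score"]
        assert scores.tolist() == [0, 1, 2]

    def test_major_risk_allele_flips_counts(self):
        gm = make_genotype_matrix([[0.0], [1.0], [2.0]], snp_ids=["rs1"])
        gm.snps.loc["rs1", ["minor_allele", "major_allele"]] = ["T", "G"]
        model = PRSModel(("rs1",), {"rs1": "G"}, {"rs1": False}, bounds=(0, 1))
        assert g.compute_prs(gm, model)["score"].tolist() == [2, 1, 0]

    def test_score_range_over_six_snps(self):
        none = make_genotype_matrix(np.zeros((1, 6)))
        allr = make_genotype_matrix(np.full((1, 6), 2.0))
        model = PRSModel(
            tuple(none.snp_ids),
            {s: "A" for s in none.snp_ids},
            {s: True for s in none.snp_ids},
            bounds=(3, 6),
        )
        assert g.compute_prs(none, model)["score"].iloc[0] == 0
        assert g.compute_prs(allr, model)["score"].iloc[0] == 12 == model.max_score

    def test_equals_brute_force_count_and_snp_order_invariance(self):
        rng = np.random.default_rng(71)
        vals = rng.integers(0, 3, size=(50, 4)).astype(float)
        gm = make_genotype_matrix(vals)
        orient = {s: bool(i % 2) for i, s in enumerate(gm.snp_ids)}
        model = PRSModel(tuple(gm.snp_ids), {s: "X" for s in gm.snp_ids}, orient, (3, 5))
        scores = g.compute_prs(gm, model)["score"].to_numpy()
        # brute force per subject
        expect = []
        for row in vals:
            t = 0
            for j, s in enumerate(gm.snp_ids):
                c = row[j] if orient[s] else 2 - row[j]
                t += int(c)
            expect.append(t)
        np.testing.assert_array_equal(scores, expect)
        # permuted SNP order gives identical scores
        perm_ids = list(reversed(gm.snp_ids))
        model_p = PRSModel(tuple(perm_ids), {s: "X" for s in perm_ids},
                           {s: orient[s] for s in perm_ids}, (3, 5))
        np.testing.assert_array_equal(
            g.compute_prs(gm, model_p)["score"].to_numpy(), expect
        )

    @given(st.integers(0, 2))
    @settings(max_examples=9, deadline=None, derandomize=True)
    def test_flip_conservation(self, count):
        # flipping the declared risk allele maps the component 0/1/2 -> 2/1/0
        gm = make_genotype_matrix([[float(count)]], snp_ids=["rs1"])
        m_minor = PRSModel(("rs1",), {"rs1": "A"}, {"rs1": True}, (0, 1))
        m_major = PRSModel(("rs1",), {"rs1": "G"}, {"rs1": False}, (0, 1))
        s1 = g.compute_prs(gm, m_minor)["score"].iloc[0]
        s2 = g.compute_prs(gm, m_major)["score"].iloc[0]
        assert s1 + s2 == 2

    def test_missing_subject_excluded_by_default_mean_imputed_on_request(self):
        vals = np.array([[0.0, 1.0], [np.nan, 2.0], [2.0, 0.0]])
        gm = make_genotype_matrix(vals)
        model = PRSModel(tuple(gm.snp_ids), {s: "A" for s in gm.snp_ids},
                         {s: True for s in gm.snp_ids}, (1, 2))
        out = g.compute_prs(gm, model)
        assert len(out) == 2  # middle subject dropped
        imputed = g.compute_prs(gm, model, missing="mean")
        assert len(imputed) == 3


class TestBands:
    def test_preset_six_snp_bands(self):
        scores = pd.Series(range(0, 13))
        cats = g.categorize(scores, preset_bands(6))
        assert list(cats[:4]) == ["low"] * 4  # 0-3
        assert list(cats[4:7]) == ["medium"] * 3  # 4-6
        assert list(cats[7:]) == ["high"] * 6  # >=7

    def test_preset_five_snp_bands(self):
        scores = pd.Series(range(0, 11))
        cats = g.categorize(scores, preset_bands(5))
        assert cats[5] == "medium"  # score 5
        assert cats[6] == "high"  # score >= 6
        assert cats[3] == "low"

    def test_no_preset_for_other_sizes(self):
        with pytest.raises(KeyError, match="preset"):
            preset_bands(4)

    def test_empirical_tertiles_on_known_scores(self):
        scores = np.repeat([0, 1, 2, 3, 4, 5, 6], 30)
        b1, b2 = empirical_tertile_bounds(scores)
        cats = g.categorize(scores, (b1, b2))
        frac = pd.Series(cats).value_counts(normalize=True)
        assert 0.2 < frac["low"] < 0.5 and 0.2 < frac["high"] < 0.5


class TestCategoryOR:
    def test_reference_or_fixed_at_one(self):
        rng = np.random.default_rng(72)
        cats = pd.Categorical(rng.choice(["low", "medium", "high"], 600),
                              categories=["low", "medium", "high"], ordered=True)
        y = (rng.random(600) < 0.3).astype(float)
        out = g.prs_category_or(cats, y)
        assert out["low"].or_value == 1.0

    def test_monotone_ors_with_planted_per_allele_effect(self):
        gm = g.simulate_genotypes(20_000, seed=73)
        snps = ["rs6759952", "rs1369535", "rs13059137", "rs72616195",
                "rs7834206", "rs11175834"]
        model = g.DiseaseModel(snp_log_or={s: 0.2 for s in snps}, intercept=-2.0)
        ct = g.simulate_outcome(gm, None, model, seed=74)
        prs_model = PRSModel(tuple(snps), {s: "A" for s in snps},
                             {s: True for s in snps}, preset_bands(6))
        profile = g.compute_prs(gm, prs_model)
        out = g.prs_category_or(profile["category"], ct.data["case"].to_numpy())
        assert 1.0 < out["medium"].or_value < out["high"].or_value

    def test_empty_reference_rejected(self):
        cats = pd.Categorical(["high"] * 10, categories=["low", "medium", "high"])
        with pytest.raises(ValueError, match="reference"):
            g.prs_category_or(cats, np.ones(10))


class TestScorerEstimator:
    def test_fit_orients_from_data_and_transform_scores(self):
        gm = g.simulate_genotypes(8000, seed=75)
        snps = ["rs6759952", "rs1369535", "rs13059137", "rs72616195",
                "rs7834206", "rs11175834"]
        model = g.DiseaseModel(
            snp_log_or={**{s: 0.25 for s in snps if s != "rs6759952"},
                        "rs6759952": -0.27},
            prevalence_target=0.3,
        )
        ct = g.simulate_outcome(gm, None, model, seed=76)
        sc = PolygenicRiskScorer(snp_ids=snps, snp_meta=gm.snps)
        sc.fit(gm.dosage[snps], ct.data["case"].to_numpy())
        # protective minor allele -> risk sits on the major allele
        assert not sc.model_.risk_is_minor["rs6759952"]
        assert all(sc.model_.risk_is_minor[s] for s in snps if s != "rs6759952")
        prof = sc.transform(gm.dosage[snps])
        assert prof["score"].between(0, 12).all()
        assert sc.model_.bounds == (3, 6)

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        sc = PolygenicRiskScorer(bands="tertile", missing="mean")
        assert clone(sc).get_params()["bands"] == "tertile"

    def test_weighted_variant_off_by_default(self):
        gm = g.simulate_genotypes(2000, seed=77)
        snps = list(gm.snp_ids[:5])
        y = (np.random.default_rng(78).random(2000) < 0.3).astype(float)
        sc = PolygenicRiskScorer(snp_ids=snps, bands=(3, 5), snp_meta=gm.snps)
        prof = sc.fit(gm.dosage[snps], y).transform(gm.dosage[snps])
        assert "weighted_score" not in prof.columns
        scw = PolygenicRiskScorer(snp_ids=snps, bands=(3, 5), weighted=True,
                                  snp_meta=gm.snps)
        profw = scw.fit(gm.dosage[snps], y).transform(gm.dosage[snps])
        assert "weighted_score" in profw.columns
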
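"""Marginal and interaction models, demographics, and the eQTL statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ambientgxe.association import (
    GxEInteractionModel,
    MarginalGenotypeModel,
    demographics_compare,
    gxe_analysis,
    marginal_genotype_analysis,
    spearman_eqtl,
)
from ambientgxe.errors import DataError, DegenerateTestError, InestimableError
from ambientgxe.synthetic import generate_genotypes


def make_subjects(rng, n=600, q=0.42, exposure_p=0.3, betas=None):
    """Direct cohort builder (no spatial machinery) for model unit tests."""
    betas = betas or {}
    genos = generate_genotypes(n, q, rng)
    g = np.array([{"AA": 0, "AG": 1, "GG": 2}[x] for x in genos], float)
    e = (rng.random(n) < exposure_p).astype(float)
    age = rng.normal(65, 8, n)
    male = rng.random(n) < 0.5
    smoker = rng.random(n) < 0.5
    eta = (
        betas.get("b0", 0.0)
        + betas.get("bg", 0.0) * g
        + betas.get("be", 0.0) * e
        + betas.get("bge", 0.0) * g * e
        + betas.get("bage", 0.0) * (age - 65)
    )
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "status": np.where(y, "case", "control"),
            "age_years": age,
            "sex": np.where(male, "male", "female"),
            "smoker_ever": smoker,
            "genotype": genos,
        }
    )
    exposed = pd.Series(e.astype(bool), index=subjects["subject_id"])
    return subjects, exposed


class TestMarginalModel:
    def test_two_allele_or_is_square_of_one_allele_or(self, rng):
        subjects, _ = make_subjects(rng, betas={"bg": 0.2})
        res = marginal_genotype_analysis(subjects, "additive")
        one = res.or_per_allele()
        two = res.or_two_alleles()
        assert two.OR == pytest.approx(one.OR**2, rel=1e-10)

    def test_null_coverage_of_per_allele_ci(self):
        """With bg=0 the 95% CI for the per-allele OR should cover 1 in
        roughly 95% of replicates."""
        covered = 0
        reps = 150
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            subjects, _ = make_subjects(rng, n=500)
            est = marginal_genotype_analysis(subjects, "additive").or_per_allele()
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert 0.90 <= covered / reps <= 0.99

    def test_recessive_detects_gg_only_risk(self, rng):
        subjects, _ = make_subjects(rng, n=2000, betas={"b0": -1.0})
        g = subjects["genotype"]
        risk = np.where(g == "GG", 0.55, 0.25)
        y = np.random.default_rng(1).random(len(g)) < risk
        subjects = subjects.assign(status=np.where(y, "case", "control"))
        est = marginal_genotype_analysis(subjects, "recessive").or_genotype()
        assert est.OR > 1.0 and est.p < 0.05

    def test_heterozygotes_dropped_by_homozygote_contrast(self, rng):
        subjects, _ = make_subjects(rng)
        res = marginal_genotype_analysis(subjects, "homozygote_contrast")
        n_ag = int((subjects["genotype"] == "AG").sum())
        assert res.drop_log.excluded_genotype_model == n_ag
        assert res.drop_log.n_analysed == len(subjects) - n_ag


class TestGxEModel:
    def test_reference_cell_or_is_exactly_one(self, rng):
        subjects, exposed = make_subjects(rng)
        table = gxe_analysis(subjects, exposed).table()
        ref = table[(table.exposure == "none") & (table.genotype == "AA")]
        assert ref["OR"].iloc[0] == 1.0

    def test_joint_cell_is_coefficient_sum(self, rng):
        subjects, exposed = make_subjects(rng, betas={"bge": 0.4})
        res = gxe_analysis(subjects, exposed)
        fit = res.fit
        expected = (
            2 * fit["genotype"] + fit["exposed"] + 2 * fit["genotype_x_exposed"]
        )
        assert res.cell_or(2.0, True).log_or == pytest.approx(expected, rel=1e-12)

    def test_null_cohort_gives_unit_ors(self, rng):
        subjects, exposed = make_subjects(rng, n=4000)
        res = gxe_analysis(subjects, exposed)
        table = res.table().dropna(subset=["p"])
        assert ((table.ci_low < 1.0) & (1.0 < table.ci_high)).all()

    def test_interaction_recovery_direct_design(self):
        """Averaged over replicates the interaction coefficient estimate
        recovers the generating per-allele log-OR."""
        true = np.log(2.5)
        ests = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            subjects, exposed = make_subjects(
                rng, n=3000, betas={"b0": -1.0, "bge": true}
            )
            ests.append(
                gxe_analysis(subjects, exposed).interaction_or.log_or
            )
        assert np.mean(ests) == pytest.approx(true, abs=0.05)

    def test_inestimable_when_genotype_constant_in_stratum(self, rng):
        subjects, exposed = make_subjects(rng, n=300)
        # force every exposed subject to genotype AA
        exposed_ids = exposed[exposed].index
        subjects.loc[
            subjects["subject_id"].isin(exposed_ids), "genotype"
        ] = "AA"
        with pytest.raises(InestimableError):
            gxe_analysis(subjects, exposed)

    def test_allele_relabel_flips_signs_and_inverts_ors(self, rng):
        subjects, exposed = make_subjects(rng, betas={"bg": 0.3, "bge": 0.2})
        res = gxe_analysis(subjects, exposed, model="homozygote_contrast")
        flipped = subjects.assign(
            genotype=subjects["genotype"].map(
                {"AA": "GG", "AG": "AG", "GG": "AA"}
            )
        )
        res_f = gxe_analysis(flipped, exposed, model="homozygote_contrast")
        assert res_f.fit["genotype"] == pytest.approx(
            -res.fit["genotype"], rel=1e-7
        )
        assert res_f.interaction_or.OR == pytest.approx(
            1.0 / res.interaction_or.OR, rel=1e-7
        )

    def test_wald_and_lrt_interaction_p_agree(self, rng):
        subjects, exposed = make_subjects(rng, n=2000, betas={"bge": 0.1})
        res = gxe_analysis(subjects, exposed)
        ratio = res.interaction_p_wald / res.interaction_p_lrt
        assert 1 / 1.5 <= ratio <= 1.5

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        subjects, exposed = make_subjects(rng, betas={"bg": 0.1, "bge": 0.3})
        res = gxe_analysis(subjects, exposed)
        g = subjects["genotype"].map({"AA": 0, "AG": 1, "GG": 2}).to_numpy(float)
        e = exposed.to_numpy(float)
        X = np.column_stack(
            [
                np.ones(len(subjects)),
                g,
                e,
                g * e,
                subjects["age_years"],
                (subjects["sex"] == "male").astype(float),
                subjects["smoker_ever"].astype(float),
            ]
        )
        y = (subjects["status"] == "case").to_numpy(float)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(res.fit.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(res.fit.se, ref.bse, rtol=1e-5)


class TestDemographics:
    def test_identical_groups(self):
        subjects = pd.DataFrame(
            {
                "status": ["case"] * 3 + ["control"] * 3,
                "age_years": [50.0, 60.0, 70.0] * 2,
            }
        )
        res = demographics_compare(subjects, "age_years")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_pooled_t_hand_computed(self):
        subjects = pd.DataFrame(
            {
                "status": ["case"] * 3 + ["control"] * 3,
                "age_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        res = demographics_compare(subjects, "age_years")
        assert res.statistic == pytest.approx(-3.67423461417, rel=1e-9)
        assert res.df == 4
        assert res.p == pytest.approx(0.021312, rel=1e-3)

    def test_balanced_table_chi2_zero(self):
        subjects = pd.DataFrame(
            {
                "status": ["case"] * 100 + ["control"] * 100,
                "sex": (["male"] * 50 + ["female"] * 50) * 2,
            }
        )
        res = demographics_compare(subjects, "sex")
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_tiny_group_rejected(self):
        subjects = pd.DataFrame(
            {"status": ["case", "control", "control"], "age_years": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(DataError):
            demographics_compare(subjects, "age_years")


class TestSpearmanEqtl:
    def test_monotone_series(self):
        g = [0, 0, 1, 1, 2, 2]
        # identical rank (and tie) structure -> perfect rank correlation
        assert spearman_eqtl(g, [1, 1, 3, 3, 5, 5]).rho == pytest.approx(1.0)
        assert spearman_eqtl(g, [5, 5, 3, 3, 1, 1]).rho == pytest.approx(-1.0)
        # strictly monotone expression across tied genotypes stays positive
        assert spearman_eqtl(g, [1, 2, 3, 4, 5, 6]).rho > 0.9

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateTestError):
            spearman_eqtl([0, 1, 2, 2], [3.0, 3.0, 3.0, 3.0])
        with pytest.raises(DataError):
            spearman_eqtl([0, 1], [1.0, 2.0])

    def test_permutation_p_matches_exhaustive_enumeration(self):
        g = [0, 0, 1, 2, 2, 1]
        x = [0.1, 0.9, 0.4, 1.2, 0.8, 0.5]
        res = spearman_eqtl(g, x, permutation=True)
        obs = abs(stats.spearmanr(g, x).statistic)
        count = total = 0
        for perm in itertools.permutations(x):
            r = abs(stats.spearmanr(g, perm).statistic)
            count += r >= obs - 1e-12
            total += 1
        assert res.p_permutation == pytest.approx(count / total, rel=1e-12)
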
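"""Polygenic scoring, Nagelkerke pseudo-R2 and two-stage substitution."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mrmediation.instruments import clump, prs_model
from mrmediation.simulate import SimulationTruth, make_two_sample, simulate_cohort
from mrmediation.twostage import (
    Cohort,
    TwoStageError,
    WeakInstrumentError,
    nagelkerke_r2,
    score,
    two_stage,
)


def tiny_cohort(dosages, ea=None):
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(m) * 1000 + 1,
            "effect_allele": ea or ["A"] * m,
            "other_allele": "G",
        }
    )
    phenotypes = pd.DataFrame(
        {
            "smoking_ever": np.zeros(n),
            "bmi": np.full(n, 27.0),
            "bmi_std": np.zeros(n),
            "t2d": np.zeros(n),
            "cad": np.zeros(n),
        }
    )
    covariates = pd.DataFrame(
        {"age": np.full(n, 60.0), "sex": np.zeros(n),
         **{f"pc{i+1}": np.zeros(n) for i in range(5)}}
    )
    return Cohort(dosages, snps, phenotypes, covariates)


class TestScore:
    def test_hand_matrix_product(self):
        dos = [[0, 1, 2], [2, 2, 0], [1, 0, 1], [0, 0, 0], [2, 1, 1]]
        cohort = tiny_cohort(dos)
        prs = pd.DataFrame(
            {"snp_id": ["s0", "s1", "s2"], "effect_allele": ["A"] * 3,
             "weight": [0.5, -1.0, 2.0]}
        )
        expected = np.asarray(dos) @ np.array([0.5, -1.0, 2.0])
        np.testing.assert_allclose(score(cohort, prs), expected)

    def test_zero_weights(self):
        cohort = tiny_cohort(np.ones((4, 2)))
        prs = pd.DataFrame({"snp_id": ["s0", "s1"], "effect_allele": ["A", "A"],
                            "weight": [0.0, 0.0]})
        np.testing.assert_allclose(score(cohort, prs), 0.0)

    def test_single_snp_identity(self):
        dos = np.array([[0.0], [1.0], [2.0], [1.0]])
        cohort = tiny_cohort(dos)
        prs = pd.DataFrame({"snp_id": ["s0"], "effect_allele": ["A"],
                            "weight": [1.0]})
        np.testing.assert_allclose(score(cohort, prs), dos[:, 0])

    def test_other_allele_weight_counts_complement_dosage(self):
        dos = np.array([[0.0], [2.0]])
        cohort = tiny_cohort(dos)
        prs = pd.DataFrame({"snp_id": ["s0"], "effect_allele": ["G"],
                            "weight": [1.0]})
        np.testing.assert_allclose(score(cohort, prs), [2.0, 0.0])

    def test_excess_missing_fatal(self):
        cohort = tiny_cohort(np.ones((3, 1)))
        prs = pd.DataFrame(
            {"snp_id": ["s0", "absent1", "absent2"],
             "effect_allele": ["A"] * 3, "weight": [1.0] * 3}
        )
        with pytest.raises(TwoStageError):
            score(cohort, prs)


class TestNagelkerke:
    def test_uninformative_predictor_near_zero(self, rng):
        n = 2000
        y = rng.integers(0, 2, n).astype(float)
        x = rng.standard_normal((n, 1))
        r2 = nagelkerke_r2(y, x)
        assert abs(r2) < 0.01

    def test_strong_predictor_approaches_one(self, rng):
        n = 2000
        x = rng.standard_normal((n, 1))
        y = (expit(20 * x[:, 0]) > rng.random(n)).astype(float)
        r2 = nagelkerke_r2(y, x)
        assert r2 > 0.9

    def test_weak_prs_calibrated_magnitude(self, rng):
        """A predictor sized to explain ~0.3% of a binary trait: the
        pseudo-R2 recovers that magnitude (mean of 20 replicates within
        +/- 0.002)."""
        beta, prev, n = 0.095, 0.45, 20_000
        # analytic target: Cox-Snell ~ beta^2 pq; Nagelkerke rescales by
        # 1 - exp(2 l0 / n)
        l0_per = prev * math.log(prev) + (1 - prev) * math.log(1 - prev)
        target = beta**2 * prev * (1 - prev) / (1 - math.exp(2 * l0_per))
        estimates = []
        for _ in range(20):
            x = rng.standard_normal((n, 1))
            p = expit(math.log(prev / (1 - prev)) + beta * x[:, 0])
            y = (rng.random(n) < p).astype(float)
            estimates.append(nagelkerke_r2(y, x))
        assert np.mean(estimates) == pytest.approx(target, abs=0.002)
        assert target == pytest.approx(0.003, abs=0.001)


@pytest.fixture(scope="module")
def small_system():
    """Compact truth + instrument + weight tables + one target cohort."""
    truth = SimulationTruth.generate(
        m_snps=800, n_causal_smk=60, n_causal_bmi=60, seed=42
    )
    study = make_two_sample(truth, 12_000, 12_000, seed=43,
                            outcome_traits=("t2d",))
    inst = clump(study.exposure["smoking"], study.ld)
    smk_prs = prs_model(inst)
    bmi_prs = prs_model(inst, weights_from=study.exposure["bmi"])
    cohort = simulate_cohort(truth, 12_000, seed=44)
    return truth, cohort, smk_prs, bmi_prs


class TestTwoStage:
    def test_zero_weight_prs_refused(self, small_system):
        _, cohort, smk_prs, _ = small_system
        null_prs = smk_prs.assign(weight=0.0)
        with pytest.raises(WeakInstrumentError):
            two_stage(cohort, null_prs, "t2d")

    def test_total_effect_positive_on_bmi_and_disease(self, small_system):
        _, cohort, smk_prs, _ = small_system
        res_bmi = two_stage(cohort, smk_prs, "bmi")
        assert res_bmi.total.beta > 0
        assert res_bmi.stage1_f > 10
        # kg/m2 change per doubling of smoking odds: ln(2) x raw coefficient
        assert res_bmi.bmi_change_per_doubling == pytest.approx(
            math.log(2.0) * res_bmi.total.beta
        )
        res_t2d = two_stage(cohort, smk_prs, "t2d")
        assert res_t2d.total.beta > 0
        assert res_t2d.total.pvalue < 0.05
        assert 0 < res_t2d.nagelkerke < 1

    def test_zero_mediator_weights_reproduce_total_model(self, small_system):
        """All-zero mediator weights: the adjusted model collapses onto the
        unadjusted one, coefficient equal to machine precision."""
        _, cohort, smk_prs, bmi_prs = small_system
        total = two_stage(cohort, smk_prs, "t2d")
        adjusted = two_stage(
            cohort, smk_prs, "t2d", bmi_weights=bmi_prs.assign(weight=0.0)
        )
        assert adjusted.total.beta == pytest.approx(total.total.beta, rel=1e-12)

    def test_adjusted_model_reports_both_channels(self, small_system):
        _, cohort, smk_prs, bmi_prs = small_system
        res = two_stage(cohort, smk_prs, "t2d", bmi_weights=bmi_prs)
        assert res.direct is not None and res.mediator is not None
        assert res.total is None

    def test_or_form_consistent_with_conversion(self, small_system):
        from mrmediation.estimators import to_odds_ratio

        _, cohort, smk_prs, _ = small_system
        res = two_stage(cohort, smk_prs, "t2d")
        assert res.total.or_ == pytest.approx(
            to_odds_ratio(res.total.beta, "binary"), rel=1e-12
        )


class TestMediationScenarios:
    """Replicated 2SPS decomposition under known path truths.

    Reduced scale for the test budget: 10 replicates, target cohorts of
    16 000, 1600 variants.  The two predicted channels are built from the
    same variants and are therefore strongly collinear, so adjusted-model
    CIs are wide; the full-scale behavior is exercised by the two-sample
    acceptance studies."""

    @pytest.fixture(scope="class")
    @staticmethod
    def replicates():
        truth = SimulationTruth.generate(
            m_snps=1600, n_causal_smk=120, n_causal_bmi=120,
            theta_st=0.0, seed=7,
        )
        rows = []
        for rep in range(10):
            # only the exposure cohort's GWAS feeds the weights; the
            # outcome cohort is not used by 2SPS, so keep it minimal
            study = make_two_sample(truth, 16_000, 1000,
                                    seed=1000 + rep, outcome_traits=("t2d",))
            inst = clump(study.exposure["smoking"], study.ld)
            smk_prs = prs_model(inst)
            bmi_prs = prs_model(inst, weights_from=study.exposure["bmi"],
                                max_missing=0.5)
            cohort = simulate_cohort(truth, 16_000, seed=5000 + rep)
            total_t2d = two_stage(cohort, smk_prs, "t2d")
            adj_t2d = two_stage(cohort, smk_prs, "t2d", bmi_weights=bmi_prs)
            adj_cad = two_stage(cohort, smk_prs, "cad", bmi_weights=bmi_prs)
            rows.append(
                {
                    "total_sig": total_t2d.total.pvalue < 0.05,
                    "adj_covers_0": adj_t2d.direct.ci_low
                    <= 0.0
                    <= adj_t2d.direct.ci_high,
                    "cad_direct_b": adj_cad.direct.beta,
                    "cad_positive_sig": adj_cad.direct.ci_low > 0.0,
                }
            )
        return pd.DataFrame(rows)

    def test_null_direct_t2d_covered(self, replicates):
        """With no direct smoking->T2D path the BMI-adjusted coefficient
        covers zero in most replicates while the unadjusted total always
        stays significant."""
        assert replicates["total_sig"].mean() >= 0.9
        assert replicates["adj_covers_0"].mean() >= 0.8

    def test_direct_cad_path_survives_adjustment(self, replicates):
        """The nonzero direct smoking->CAD path stays positive after BMI
        adjustment in every replicate and significant in the majority (at
        this reduced scale the collinear channels limit power)."""
        assert (replicates["cad_direct_b"] > 0).all()
        assert replicates["cad_positive_sig"].mean() >= 0.6


class TestBootstrapSE:
    def test_bootstrap_se_replaces_model_se(self, small_system):
        _, cohort, smk_prs, _ = small_system
        model = two_stage(cohort, smk_prs, "t2d")
        boot = two_stage(cohort, smk_prs, "t2d", n_boot=10, seed=3)
        # same point estimate, a positive resampling-based SE
        assert boot.total.beta == pytest.approx(model.total.beta, rel=1e-12)
        assert boot.total.se > 0
        assert boot.total.se != model.total.se
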
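"""Synthetic cohorts and GWAS summary statistics under a known causal model.

The generating structural model mirrors a smoking–adiposity–disease
mediation system: sparse per-SNP effects raise a smoking liability
(liability-threshold binary status), smoking shifts BMI, and the binary
disease outcomes (T2D, CAD) follow logistic models with a BMI path and a
direct smoking path:

    liability = G gamma_smk + covariates + N(0, s)
    smoking   = 1[liability > threshold(prevalence)]
    BMI_sd    = theta_SB * smoking + G gamma_bmi + covariates + N(0, s_b)
    logit P(T2D) = a_T + theta_BT * BMI_sd + theta_ST * smoking (+ pleiotropy)
    logit P(CAD) = a_C + theta_BC * BMI_sd + theta_SC * smoking

Genotypes are dosages from a latent AR(1) Gaussian copula per haplotype,
giving geometric within-block LD decay and independent blocks.  Default
path coefficients are back-derived from the instrument-scale effects the
mediation literature reports for these traits (see docs/methods.md);
per-SNP effects are concentrated in a few hundred variants so that
desk-scale cohorts (n ~ 2 x 10^4) yield instruments of realistic strength.

Two summary-level generators complement the cohort route for replicate
studies where individual-level data is unnecessary: one draws harmonized
instrument effects directly (pleiotropy calibration), the other draws
genome-wide z-scores under the polygenic LD score model (genetic
correlation recovery).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .instruments import LDReference
from .ldsc import LDScoreTable
from .sumstats import HarmonizedSet, SummaryStats
from .twostage import Cohort

logger = logging.getLogger(__name__)

N_CHROMOSOMES = 22
_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]

#: nuisance covariate effects (age is standardized to (age-60)/10)
COVARIATE_EFFECTS = {
    "liability": (0.05, 0.05, 0.02),  # age, sex, each PC
    "bmi": (0.10, 0.05, 0.02),
    "t2d": (0.30, 0.10, 0.02),
    "cad": (0.40, 0.20, 0.02),
}

#: default directional pleiotropy magnitude (log-odds added directly to the
#: outcome per effect allele of an affected variant) used by calibration
#: studies when pleiotropy is switched on
DEFAULT_PLEIOTROPY_MEAN = 0.05
DEFAULT_PLEIOTROPY_SD = 0.02

TRAIT_COLUMNS = {
    "smoking": ("smoking_ever", "binary"),
    "lifetime_smoking": ("lifetime_smoking", "continuous"),
    "bmi": ("bmi_std", "continuous"),
    "t2d": ("t2d", "binary"),
    "cad": ("cad", "binary"),
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Fully realized generating parameters for one synthetic system.

    ``snps`` holds per-variant metadata (maf, block, alleles, position);
    the gamma arrays are dense per-SNP effects (zero off the causal sets).
    Path coefficients: theta_sb (BMI SD per smoking status), theta_bt /
    theta_bc (log-odds per BMI SD), theta_st / theta_sc (direct log-odds
    per smoking status).  Identical truth + seed reproduces cohorts
    byte-for-byte.
    """

    snps: pd.DataFrame
    gamma_smk: np.ndarray
    gamma_bmi: np.ndarray
    pleio_t2d: np.ndarray
    block_size: int
    r2_adjacent: float
    theta_sb: float
    theta_bt: float
    theta_st: float
    theta_bc: float
    theta_sc: float
    prev_smoking: float
    prev_t2d: float
    prev_cad: float
    liability_noise_sd: float
    bmi_noise_sd: float
    bmi_mean: float = 27.0
    bmi_sd: float = 4.7
    seed: int = 0

    @property
    def m(self) -> int:
        return len(self.snps)

    @classmethod
    def generate(
        cls,
        m_snps: int = 5000,
        block_size: int = 10,
        r2_adjacent: float = 0.3,
        maf_range: tuple[float, float] = (0.05, 0.5),
        n_causal_smk: int = 150,
        n_causal_bmi: int = 150,
        gamma_smk_sd: float = 0.08,
        gamma_bmi_sd: float = 0.08,
        theta_sb: float = 0.93,
        theta_bt: float = 0.92,
        theta_st: float = 0.34,
        theta_bc: float = 0.21,
        theta_sc: float = 0.66,
        prev_smoking: float = 0.45,
        prev_t2d: float = 0.20,
        prev_cad: float = 0.20,
        pleiotropy_frac: float = 0.0,
        pleiotropy_mean: float = 0.0,
        pleiotropy_sd: float = 0.0,
        disjoint_causals: bool = False,
        seed: int = 0,
    ) -> "SimulationTruth":
        """Draw a concrete truth: mafs, alleles, positions, causal effects.

        Defaults encode the study conditions of the mediation system
        (prevalences, path coefficients on the scales above, desk-scale
        polygenicity).  ``pleiotropy_*`` adds directional SNP->T2D effects
        to a fraction of the smoking-causal variants.  Causal sets are
        drawn independently per trait and may overlap (biological
        pleiotropy); ``disjoint_causals`` forces them apart, the regime
        where every exposure instrument is outcome-valid — compact
        genomes otherwise overlap heavily by construction.
        """
        for prev in (prev_smoking, prev_t2d, prev_cad):
            if not 0.0 < prev < 1.0:
                raise SimulationError("prevalences must lie in (0, 1)")
        if m_snps % block_size:
            raise SimulationError("m_snps must be a multiple of block_size")
        rng = np.random.default_rng(seed)
        m = m_snps
        maf = rng.uniform(*maf_range, size=m)
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
        ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
        oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

        n_blocks = m // block_size
        block = np.repeat(np.arange(n_blocks), block_size)
        blocks_per_chrom = math.ceil(n_blocks / N_CHROMOSOMES)
        chrom = (block // blocks_per_chrom + 1).astype(str)
        # 5 kb spacing, positions restarting per chromosome
        pos = np.empty(m, dtype=np.int64)
        for c in np.unique(chrom):
            idx = np.where(chrom == c)[0]
            pos[idx] = 1_000_000 + np.arange(idx.size) * 5_000

        snps = pd.DataFrame(
            {
                "snp_id": [f"rs{i + 1}" for i in range(m)],
                "chrom": chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "block": block,
            }
        )

        gamma_smk = np.zeros(m)
        gamma_bmi = np.zeros(m)
        idx_smk = rng.choice(m, size=n_causal_smk, replace=False)
        if disjoint_causals:
            pool = np.setdiff1d(np.arange(m), idx_smk)
            idx_bmi = rng.choice(pool, size=n_causal_bmi, replace=False)
        else:
            idx_bmi = rng.choice(m, size=n_causal_bmi, replace=False)
        gamma_smk[idx_smk] = rng.normal(0.0, gamma_smk_sd, size=n_causal_smk)
        gamma_bmi[idx_bmi] = rng.normal(0.0, gamma_bmi_sd, size=n_causal_bmi)

        pleio = np.zeros(m)
        if pleiotropy_frac > 0:
            n_pleio = max(1, round(pleiotropy_frac * n_causal_smk))
            chosen = rng.choice(idx_smk, size=n_pleio, replace=False)
            pleio[chosen] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_pleio)

        var_g = 2.0 * maf * (1.0 - maf)
        var_smk = float(np.sum(gamma_smk**2 * var_g))
        var_bmi = float(np.sum(gamma_bmi**2 * var_g))
        if var_smk > 0.85 or var_bmi > 0.85:
            logger.warning(
                "genetic variance close to saturation (smk %.2f, bmi %.2f)",
                var_smk, var_bmi,
            )
        liability_noise_sd = math.sqrt(max(0.15, 1.0 - var_smk))
        pq = prev_smoking * (1.0 - prev_smoking)
        bmi_noise_sd = math.sqrt(max(0.15, 1.0 - theta_sb**2 * pq - var_bmi))

        return cls(
            snps=snps,
            gamma_smk=gamma_smk,
            gamma_bmi=gamma_bmi,
            pleio_t2d=pleio,
            block_size=block_size,
            r2_adjacent=r2_adjacent,
            theta_sb=theta_sb,
            theta_bt=theta_bt,
            theta_st=theta_st,
            theta_bc=theta_bc,
            theta_sc=theta_sc,
            prev_smoking=prev_smoking,
            prev_t2d=prev_t2d,
            prev_cad=prev_cad,
            liability_noise_sd=liability_noise_sd,
            bmi_noise_sd=bmi_noise_sd,
            seed=seed,
        )

    def with_paths(self, **thetas: float) -> "SimulationTruth":
        """Copy of the truth with path coefficients overridden."""
        return replace(self, **thetas)

    def ld_reference(self) -> LDReference:
        """Target pairwise r2 implied by the AR(1) block structure."""
        ids = self.snps["snp_id"].to_numpy()
        block = self.snps["block"].to_numpy()
        ref = LDReference(window_bp=self.block_size * 5_000)
        m = self.m
        for start in range(0, m, self.block_size):
            stop = min(start + self.block_size, m)
            for i in range(start, stop):
                for j in range(i + 1, stop):
                    if block[i] != block[j]:
                        continue
                    ref.set(ids[i], ids[j], self.r2_adjacent ** (j - i))
        return ref


def _simulate_dosages(
    truth: SimulationTruth, n: int, rng: np.random.Generator,
    chunk_blocks: int = 64,
) -> np.ndarray:
    """Dosage matrix (n x M, int8) from a latent AR(1) Gaussian copula.

    One latent normal per individual and SNP follows an AR(1) correlation
    rho = sqrt(r2_adjacent) within each block (so latent r2 decays
    geometrically with distance); the dosage is obtained by double
    thresholding at the Hardy–Weinberg quantiles, P(d >= 1) = 1-(1-p)^2
    and P(d = 2) = p^2.  Marginals are exact HWE; realized dosage LD sits
    slightly below the latent target (copula discretization), while the
    LD reference reports the latent truth.
    """
    m = truth.m
    bs = truth.block_size
    rho = math.sqrt(truth.r2_adjacent)
    d = np.abs(np.subtract.outer(np.arange(bs), np.arange(bs)))
    L = np.linalg.cholesky(rho**d + 1e-12 * np.eye(bs)).astype(np.float32)
    maf = truth.snps["eaf"].to_numpy()
    t_any = sps.norm.ppf(maf * (2.0 - maf)).astype(np.float32)  # P(d>=1)
    t_hom = sps.norm.ppf(maf**2).astype(np.float32)             # P(d==2)
    out = np.empty((n, m), dtype=np.int8)
    step = chunk_blocks * bs
    for start in range(0, m, step):
        stop = min(start + step, m)
        width = stop - start
        z = rng.standard_normal((n, width), dtype=np.float32)
        z = (z.reshape(n * (width // bs), bs) @ L.T).reshape(n, width)
        out[:, start:stop] = (z < t_any[start:stop]).view(np.int8)
        out[:, start:stop] += (z < t_hom[start:stop]).view(np.int8)
    return out


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept making mean(sigmoid(a + lp)) equal the target prevalence."""
    def f(a: float) -> float:
        return float(np.mean(special.expit(a + lp))) - prevalence

    try:
        return optimize.brentq(f, -30.0, 30.0, xtol=1e-10)
    except ValueError as err:
        raise SimulationError(
            f"prevalence {prevalence} unreachable given linear predictor"
        ) from err


def simulate_cohort(truth: SimulationTruth, n: int, seed: int = 0) -> Cohort:
    """Simulate one individual-level cohort from a realized truth.

    Deterministic given (truth, n, seed).  Covariates (age, sex, five PCs)
    are independent with small nuisance effects on every trait; the
    liability threshold is the empirical quantile, so the smoking
    prevalence matches the target up to integer rounding, and the disease
    intercepts are solved so expected prevalence equals the target.
    """
    if n < 100:
        raise SimulationError("cohort size must be >= 100")
    rng = np.random.default_rng(seed)
    dosages = _simulate_dosages(truth, n, rng)

    age = rng.normal(60.0, 10.0, size=n)
    age_std = (age - 60.0) / 10.0
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 5))
    covariates = pd.DataFrame(
        {"age": age, "sex": sex,
         **{f"pc{i + 1}": pcs[:, i] for i in range(5)}}
    )

    def covar_part(key: str) -> np.ndarray:
        a, sx, p = COVARIATE_EFFECTS[key]
        return a * age_std + sx * sex + p * pcs.sum(axis=1)

    idx_smk = np.flatnonzero(truth.gamma_smk)
    idx_bmi = np.flatnonzero(truth.gamma_bmi)
    g_smk = dosages[:, idx_smk].astype(np.float32) @ truth.gamma_smk[idx_smk].astype(
        np.float32
    )
    g_bmi = dosages[:, idx_bmi].astype(np.float32) @ truth.gamma_bmi[idx_bmi].astype(
        np.float32
    )

    liability = (
        g_smk.astype(float)
        + covar_part("liability")
        + rng.normal(0.0, truth.liability_noise_sd, size=n)
    )
    thr = np.quantile(liability, 1.0 - truth.prev_smoking)
    smoking = (liability > thr).astype(float)
    lifetime = (liability - liability.mean()) / liability.std()

    bmi_std = (
        truth.theta_sb * smoking
        + g_bmi.astype(float)
        + covar_part("bmi")
        + rng.normal(0.0, truth.bmi_noise_sd, size=n)
    )
    bmi = truth.bmi_mean + truth.bmi_sd * bmi_std

    lp_t2d = truth.theta_bt * bmi_std + truth.theta_st * smoking + covar_part("t2d")
    idx_pl = np.flatnonzero(truth.pleio_t2d)
    if idx_pl.size:
        lp_t2d = lp_t2d + dosages[:, idx_pl].astype(np.float32) @ truth.pleio_t2d[
            idx_pl
        ].astype(np.float32)
    a_t = _solve_intercept(lp_t2d, truth.prev_t2d)
    t2d = (rng.random(n) < special.expit(a_t + lp_t2d)).astype(float)

    lp_cad = truth.theta_bc * bmi_std + truth.theta_sc * smoking + covar_part("cad")
    a_c = _solve_intercept(lp_cad, truth.prev_cad)
    cad = (rng.random(n) < special.expit(a_c + lp_cad)).astype(float)

    phenotypes = pd.DataFrame(
        {
            "smoking_ever": smoking,
            "lifetime_smoking": lifetime,
            "bmi": bmi,
            "bmi_std": bmi_std,
            "t2d": t2d,
            "cad": cad,
        }
    )
    return Cohort(
        dosages=dosages,
        snps=truth.snps[
            ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]
        ].reset_index(drop=True),
        phenotypes=phenotypes,
        covariates=covariates,
    )


def _covariate_design(cohort: Cohort) -> np.ndarray:
    cov = cohort.covariates
    age_std = (cov["age"].to_numpy(float) - 60.0) / 10.0
    return np.column_stack(
        [np.ones(cohort.n), age_std, cov["sex"].to_numpy(float)]
        + [cov[f"pc{i + 1}"].to_numpy(float) for i in range(5)]
    )


def gwas_scan(cohort: Cohort, trait: str, chunk: int = 512) -> SummaryStats:
    """Per-SNP association scan adjusted for age, sex and five PCs.

    Continuous traits: exact per-SNP OLS after residualizing genotype and
    phenotype on the covariates.  Binary traits: one-step score-based
    logistic estimates from the covariate-only null fit (beta = U/V,
    se = 1/sqrt(V), the standard large-cohort GWAS approximation; accurate
    for the small per-SNP effects the generator produces).  Monomorphic
    variants are dropped with a warning.
    """
    if trait not in TRAIT_COLUMNS:
        raise SimulationError(f"unknown trait {trait!r}; one of {list(TRAIT_COLUMNS)}")
    column, trait_type = TRAIT_COLUMNS[trait]
    if column not in cohort.phenotypes.columns:
        raise SimulationError(f"cohort lacks phenotype column {column!r}")
    y = cohort.phenotypes[column].to_numpy(float)
    X = _covariate_design(cohort)
    n, m = cohort.dosages.shape

    eaf = cohort.eaf()
    poly = (eaf > 0.0) & (eaf < 1.0)
    if not poly.all():
        logger.warning("gwas_scan: dropping %d monomorphic variants",
                       int((~poly).sum()))

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    X32 = X.astype(np.float32)
    if trait_type == "continuous":
        XtX = X.T @ X
        coef_y = np.linalg.solve(XtX, X.T @ y)
        y_r = (y - X @ coef_y).astype(np.float32)
        yty = float(y_r.astype(np.float64) @ y_r.astype(np.float64))
        dof = n - X.shape[1] - 1
        for start in range(0, m, chunk):
            stop = min(start + chunk, m)
            G = cohort.dosages[:, start:stop].astype(np.float32)
            B = np.linalg.solve(XtX, (X32.T @ G).astype(np.float64))
            Gr = G - X32 @ B.astype(np.float32)
            den = np.einsum("ij,ij->j", Gr, Gr, dtype=np.float64)
            den[den == 0.0] = np.nan
            num = (Gr.T @ y_r).astype(np.float64)
            b = num / den
            rss = np.maximum(yty - b**2 * den, 0.0)
            beta[start:stop] = b
            se[start:stop] = np.sqrt(rss / dof / den)
    else:
        import statsmodels.api as sm

        null = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p_hat = np.asarray(null.predict(X), float)
        w = p_hat * (1.0 - p_hat)
        resid = (y - p_hat).astype(np.float32)
        w32 = w.astype(np.float32)
        XtWX = X.T @ (w[:, None] * X)
        Xw32 = (w[:, None] * X).astype(np.float32)
        for start in range(0, m, chunk):
            stop = min(start + chunk, m)
            G = cohort.dosages[:, start:stop].astype(np.float32)
            B = np.linalg.solve(XtWX, (Xw32.T @ G).astype(np.float64))
            Gr = G - X32 @ B.astype(np.float32)
            U = (Gr.T @ resid).astype(np.float64)
            V = np.einsum("ij,ij,i->j", Gr, Gr, w32, dtype=np.float64)
            V[V == 0.0] = np.nan
            beta[start:stop] = U / V
            se[start:stop] = 1.0 / np.sqrt(V)

    z2 = (beta / se) ** 2
    pval = sps.chi2.sf(z2, 1)
    pval = np.clip(pval, 5e-324, 1.0)
    frame = pd.DataFrame(
        {
            "snp_id": cohort.snps["snp_id"],
            "chrom": cohort.snps["chrom"].astype(str),
            "pos": cohort.snps["pos"],
            "effect_allele": cohort.snps["effect_allele"],
            "other_allele": cohort.snps["other_allele"],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "n": float(n),
        }
    )[poly & np.isfinite(beta) & np.isfinite(se)]
    return SummaryStats(
        frame.reset_index(drop=True), trait_name=trait, trait_type=trait_type
    )


@dataclass
class TwoSampleStudy:
    """Paired GWAS summary statistics from non-overlapping cohorts."""

    exposure: dict[str, SummaryStats]
    outcome: dict[str, SummaryStats]
    ld: LDReference
    truth: SimulationTruth
    cohorts: dict[str, Cohort] = field(default_factory=dict)


def make_two_sample(
    truth: SimulationTruth,
    n_exposure: int = 20_000,
    n_outcome: int = 20_000,
    seed: int = 0,
    seed_exposure: int | None = None,
    seed_outcome: int | None = None,
    exposure_traits: Sequence[str] = ("smoking", "bmi"),
    outcome_traits: Sequence[str] = ("t2d", "cad", "bmi"),
    keep_cohorts: bool = False,
) -> TwoSampleStudy:
    """Two independent cohorts from one truth: exposure GWAS from cohort A,
    outcome GWAS from cohort B, plus the LD reference of the truth.

    Seeds default to two distinct children of ``seed``; passing the same
    explicit seed for both cohorts is allowed (deliberate sample-overlap
    bias scenario) but warned about.
    """
    if seed_exposure is None or seed_outcome is None:
        child = np.random.SeedSequence(seed).generate_state(2)
        if seed_exposure is None:
            seed_exposure = int(child[0]) & 0x7FFFFFFF
        if seed_outcome is None:
            seed_outcome = int(child[1]) & 0x7FFFFFFF
    if seed_exposure == seed_outcome:
        logger.warning(
            "identical exposure/outcome seeds: cohorts fully overlap "
            "(sample-overlap bias scenario)"
        )
    cohort_a = simulate_cohort(truth, n_exposure, seed=seed_exposure)
    cohort_b = simulate_cohort(truth, n_outcome, seed=seed_outcome)
    study = TwoSampleStudy(
        exposure={t: gwas_scan(cohort_a, t) for t in exposure_traits},
        outcome={t: gwas_scan(cohort_b, t) for t in outcome_traits},
        ld=truth.ld_reference(),
        truth=truth,
    )
    if keep_cohorts:
        study.cohorts = {"exposure": cohort_a, "outcome": cohort_b}
    return study


# ---------------------------------------------------------------------------
# summary-level generators


def simulate_instrument_summary(
    k: int = 60,
    theta: float = 0.2,
    seed: int = 0,
    bx_range: tuple[float, float] = (0.08, 0.25),
    se_x: float = 0.015,
    se_y: float = 0.03,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    exposure_type: str = "binary",
    n_exp: float = 1_200_000.0,
    n_out: float = 900_000.0,
) -> HarmonizedSet:
    """Draw a harmonized instrument directly on the summary level.

    True exposure effects are uniform over ``bx_range`` (a selected,
    positively oriented instrument); outcome effects are
    theta * bx + alpha with per-SNP pleiotropy alpha ~ N(mean, sd); both
    are observed with Gaussian error at the stated SEs (mild heterogeneity
    in se_y).  This is the fast path for estimator calibration studies.
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*bx_range, size=k)
    alpha = (
        rng.normal(pleiotropy_mean, pleiotropy_sd, size=k)
        if (pleiotropy_mean or pleiotropy_sd)
        else np.zeros(k)
    )
    by_true = theta * bx_true + alpha
    sx = np.full(k, se_x)
    sy = se_y * rng.uniform(0.85, 1.15, size=k)
    bx = bx_true + rng.standard_normal(k) * sx
    by = by_true + rng.standard_normal(k) * sy
    return HarmonizedSet.from_arrays(
        bx, sx, by, sy,
        exposure_name="exposure", outcome_name="outcome",
        exposure_type=exposure_type, outcome_type="binary",
        n_exp=n_exp, n_out=n_out,
    )


def simulate_ldsc_pair(
    m_snps: int = 5000,
    n1: float = 20_000.0,
    n2: float = 20_000.0,
    h2_1: float = 0.3,
    h2_2: float = 0.3,
    rg: float = 0.25,
    block_size: int = 10,
    r2_adjacent: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, LDScoreTable]:
    """Genome-wide z-scores for two traits under the polygenic LD model.

    Per-SNP true effects are bivariate normal with variance h2/M and
    correlation rg (infinitesimal model, shared across traits); z-scores
    are sqrt(n) * R beta + eps with eps ~ N(0, R) drawn independently per
    trait (non-overlapping samples), R the block AR(1) LD matrix.  Returns
    (z1, z2, LD scores).
    """
    if m_snps % block_size:
        raise SimulationError("m_snps must be a multiple of block_size")
    rng = np.random.default_rng(seed)
    rho_lat = math.sqrt(r2_adjacent)
    d = np.abs(np.subtract.outer(np.arange(block_size), np.arange(block_size)))
    R = rho_lat**d  # AR(1) correlation; r2 = r2_adjacent**distance
    L = np.linalg.cholesky(R + 1e-12 * np.eye(block_size))

    nb = m_snps // block_size
    cov_b = np.array(
        [
            [h2_1, rg * math.sqrt(h2_1 * h2_2)],
            [rg * math.sqrt(h2_1 * h2_2), h2_2],
        ]
    ) / m_snps
    chol_b = np.linalg.cholesky(cov_b + 1e-18 * np.eye(2))
    betas = rng.standard_normal((m_snps, 2)) @ chol_b.T

    b1 = betas[:, 0].reshape(nb, block_size)
    b2 = betas[:, 1].reshape(nb, block_size)
    eps1 = rng.standard_normal((nb, block_size)) @ L.T
    eps2 = rng.standard_normal((nb, block_size)) @ L.T
    z1 = (math.sqrt(n1) * b1 @ R.T + eps1).ravel()
    z2 = (math.sqrt(n2) * b2 @ R.T + eps2).ravel()

    ell_block = (R**2).sum(axis=1)
    ell = np.tile(ell_block, nb)
    scores = LDScoreTable(
        pd.Series(ell, index=[f"rs{i + 1}" for i in range(m_snps)]), m=m_snps
    )
    return z1, z2, scores
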
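"""Individual-level MR: polygenic scores and two-stage predictor substitution.

The two-stage predictor substitution (2SPS) design estimates a causal
effect from individual-level data: stage 1 regresses the exposure on the
genetic score (plus covariates) and carries the fitted prediction; stage 2
regresses the outcome on that prediction (plus covariates).  A second
stage-1 model with mediator weights on the *same* instrument variants
("mediator-by-exposure-SNPs") lets stage 2 decompose the exposure effect
into a direct channel and a mediated channel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import LN2, MREstimate, _build_estimate

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
WEAK_INSTRUMENT_F = 10.0


class TwoStageError(ValueError):
    pass


class WeakInstrumentError(TwoStageError):
    """Stage-1 instrument too weak for predictor substitution."""


@dataclass
class Cohort:
    """Individual-level cohort: dosages, phenotypes and covariates.

    ``dosages`` is individuals x SNPs with values in [0, 2]; ``snps`` the
    matching variant table (snp_id, chrom, pos, effect_allele,
    other_allele); phenotypes include smoking_ever {0,1}, bmi (kg/m2),
    bmi_std (SD units), t2d {0,1}, cad {0,1} and optionally a continuous
    lifetime_smoking score; covariates are age, sex and pc1..pc5.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        n = self.dosages.shape[0]
        if len(self.phenotypes) != n or len(self.covariates) != n:
            raise TwoStageError("phenotype/covariate rows must match dosage rows")
        if self.dosages.shape[1] != len(self.snps):
            raise TwoStageError("snp table rows must match dosage columns")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def eaf(self) -> np.ndarray:
        """Effect-allele frequency: column mean dosage / 2, exactly."""
        return self.dosages.mean(axis=0, dtype=np.float64) / 2.0

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names or DEFAULT_COVARIATES
        return self.covariates[names].to_numpy(float)

    def write_dir(self, outdir: str | Path) -> None:
        """Plain-text export: dosage matrix, snp table, phenotypes, covariates."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dos = pd.DataFrame(self.dosages, columns=self.snps["snp_id"])
        dos.to_csv(outdir / "dosages.tsv", sep="\t", index=False)
        self.snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)

    @classmethod
    def read_dir(cls, indir: str | Path) -> "Cohort":
        indir = Path(indir)
        dos = pd.read_csv(indir / "dosages.tsv", sep="\t")
        return cls(
            dosages=dos.to_numpy(np.float32),
            snps=pd.read_csv(indir / "snps.tsv", sep="\t"),
            phenotypes=pd.read_csv(indir / "phenotypes.tsv", sep="\t"),
            covariates=pd.read_csv(indir / "covariates.tsv", sep="\t"),
        )


def score(cohort: Cohort, prs: pd.DataFrame, max_missing: float = 0.2) -> np.ndarray:
    """Per-individual polygenic score, score_i = sum_j w_j dosage_ij.

    ``prs`` needs columns snp_id, effect_allele, weight.  Weights whose
    effect allele is the cohort's *other* allele contribute
    w * (2 - dosage).  Missing variants are dropped with a warning; losing
    more than ``max_missing`` of them is fatal.
    """
    for col in ("snp_id", "effect_allele", "weight"):
        if col not in prs.columns:
            raise TwoStageError(f"PRS table missing column {col!r}")
    col_of = {s: i for i, s in enumerate(cohort.snps["snp_id"])}
    ea = dict(zip(cohort.snps["snp_id"], cohort.snps["effect_allele"]))
    oa = dict(zip(cohort.snps["snp_id"], cohort.snps["other_allele"]))

    out = np.zeros(cohort.n)
    n_missing = 0
    for snp, allele, w in prs[["snp_id", "effect_allele", "weight"]].itertuples(
        index=False
    ):
        j = col_of.get(snp)
        if j is None:
            n_missing += 1
            continue
        d = cohort.dosages[:, j].astype(np.float64)
        if allele == ea[snp]:
            out += w * d
        elif allele == oa[snp]:
            out += w * (2.0 - d)
        else:
            n_missing += 1  # allele mismatch: unusable
    if n_missing:
        logger.warning("score: %d of %d PRS variants unusable", n_missing, len(prs))
        if n_missing > max_missing * len(prs):
            raise TwoStageError(
                f"{n_missing}/{len(prs)} PRS variants missing from cohort"
            )
    return out


def nagelkerke_r2(
    y: np.ndarray, x_full: np.ndarray, x_null: np.ndarray | None = None
) -> float:
    """Nagelkerke pseudo-R2 between nested logistic models.

    R2 = [1 - exp((2/n)(l0 - l1))] / [1 - exp((2/n) l0)] with l0, l1 the
    maximized log-likelihoods of the null and full models.  ``x_null``
    defaults to an intercept-only model.  Quasi-separation is reported
    with a warning rather than raised.
    """
    y = np.asarray(y, float)
    n = y.size
    x_full = sm.add_constant(np.asarray(x_full, float), has_constant="add")
    if x_null is None:
        x_null = np.ones((n, 1))
    else:
        x_null = sm.add_constant(np.asarray(x_null, float), has_constant="add")
    try:
        fit1 = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
        fit0 = sm.Logit(y, x_null).fit(disp=0, maxiter=200)
    except Exception as err:  # pragma: no cover - statsmodels specific
        raise TwoStageError(f"logistic fit failed: {err}") from err
    ll1, ll0 = fit1.llf, fit0.llf
    if not (fit1.mle_retvals.get("converged", True)):
        logger.warning("nagelkerke_r2: full model did not fully converge "
                       "(possible separation); value reported anyway")
    cox_snell = 1.0 - math.exp(2.0 / n * (ll0 - ll1))
    max_r2 = 1.0 - math.exp(2.0 / n * ll0)
    return float(cox_snell / max_r2)


def _stage1_f(exposure: np.ndarray, instrument: np.ndarray, covars: np.ndarray) -> float:
    """Partial F of the instrument in a linear stage-1 fit (t^2 of the
    score coefficient with covariates included)."""
    X = sm.add_constant(np.column_stack([instrument, covars]), has_constant="add")
    fit = sm.OLS(np.asarray(exposure, float), X).fit()
    return float(fit.tvalues[1] ** 2)


@dataclass
class TwoStageResult:
    """2SPS estimates for one outcome.

    ``total`` is the predicted-exposure coefficient without the mediator
    channel; when mediator weights are supplied, ``direct`` is the
    predicted-exposure coefficient with predicted mediator in the model and
    ``mediator`` the predicted-mediator coefficient.  For a continuous
    outcome (BMI) the absolute change per 2-fold exposure risk is
    ln(2) * beta on the raw scale.
    """

    outcome: str
    outcome_type: str
    stage1_beta: float
    stage1_f: float
    nagelkerke: float
    total: MREstimate | None = None
    direct: MREstimate | None = None
    mediator: MREstimate | None = None
    bmi_change_per_doubling: float | None = None

    def as_row(self) -> dict:
        row = {
            "outcome": self.outcome,
            "stage1_beta": self.stage1_beta,
            "stage1_f": self.stage1_f,
            "nagelkerke_r2": self.nagelkerke,
        }
        for label in ("total", "direct", "mediator"):
            est = getattr(self, label)
            if est is not None:
                row.update({f"{label}_{k}": v for k, v in est.as_row().items()})
        if self.bmi_change_per_doubling is not None:
            row["bmi_change_per_doubling"] = self.bmi_change_per_doubling
        return row


def two_stage(
    cohort: Cohort,
    smoking_prs: pd.DataFrame,
    outcome: str,
    bmi_weights: pd.DataFrame | None = None,
    exposure: str = "smoking_ever",
    covariates: list[str] | None = None,
    f_threshold: float = WEAK_INSTRUMENT_F,
    n_boot: int = 0,
    seed: int = 0,
) -> TwoStageResult:
    """Two-stage predictor substitution for one outcome.

    Stage 1 regresses the exposure (logistic for smoking status, linear
    for a continuous exposure) on the polygenic score plus age, sex and
    PCs, and carries the fitted prediction (fitted probability for a
    binary exposure).  Stage 2 regresses the outcome (logistic for
    t2d/cad, linear for bmi) on the prediction plus covariates; that
    coefficient is the total effect.  When ``bmi_weights`` is given, a
    second stage-1 linear model predicts standardized BMI from the
    BMI-weighted score on the same variants, and stage 2 includes both
    predictions: predicted exposure is then the direct effect and
    predicted BMI the mediated channel.  A stage-1 partial F below
    ``f_threshold`` aborts (weak instrument).

    SEs are model-based by default (they ignore stage-1 estimation
    uncertainty); ``n_boot > 0`` replaces the headline SE with a seeded
    nonparametric bootstrap over individuals, re-running both stages.
    """
    if n_boot:
        return _two_stage_bootstrap(
            cohort, smoking_prs, outcome, bmi_weights, exposure,
            covariates, f_threshold, n_boot, seed,
        )
    covariates = covariates or DEFAULT_COVARIATES
    covars = cohort.covariate_matrix(covariates)
    ph = cohort.phenotypes
    if outcome not in ("t2d", "cad", "bmi"):
        raise TwoStageError(f"unsupported outcome {outcome!r}")
    if exposure not in ph.columns:
        raise TwoStageError(f"exposure {exposure!r} not in cohort phenotypes")

    s = score(cohort, smoking_prs)
    expo = ph[exposure].to_numpy(float)
    binary_exposure = set(np.unique(expo)) <= {0.0, 1.0}

    if np.ptp(s) == 0.0:
        raise WeakInstrumentError(
            "polygenic score is constant (zero weights?): stage-1 F = 0"
        )
    f_stat = _stage1_f(expo, s, covars)
    if f_stat < f_threshold:
        raise WeakInstrumentError(
            f"stage-1 F = {f_stat:.2f} < {f_threshold}: refusing stage 2"
        )

    X1 = sm.add_constant(np.column_stack([s, covars]), has_constant="add")
    if binary_exposure:
        fit1 = sm.Logit(expo, X1).fit(disp=0, maxiter=200)
        nag = nagelkerke_r2(expo, np.column_stack([s, covars]), covars)
    else:
        fit1 = sm.OLS(expo, X1).fit()
        nag = float("nan")
    pred_exposure = np.asarray(fit1.predict(X1), float)
    stage1_beta = float(fit1.params[1])

    pred_bmi = None
    if bmi_weights is not None:
        s_bmi = score(cohort, bmi_weights)
        if np.ptp(s_bmi) == 0.0:
            logger.warning(
                "two_stage: mediator score is constant; mediator channel dropped"
            )
        else:
            fit1b = sm.OLS(
                ph["bmi_std"].to_numpy(float),
                sm.add_constant(np.column_stack([s_bmi, covars]), has_constant="add"),
            ).fit()
            pred_bmi = np.asarray(fit1b.fittedvalues, float)

    cols = [pred_exposure] + ([pred_bmi] if pred_bmi is not None else [])
    X2 = sm.add_constant(np.column_stack(cols + [covars]), has_constant="add")
    exposure_type = "binary" if binary_exposure else "continuous"

    if outcome == "bmi":
        y = ph["bmi"].to_numpy(float)
        fit2 = sm.OLS(y, X2).fit()
    else:
        y = ph[outcome].to_numpy(float)
        try:
            fit2 = sm.Logit(y, X2).fit(disp=0, maxiter=200)
        except Exception as err:
            raise TwoStageError(f"stage-2 fit failed to converge: {err}") from err
        if not fit2.mle_retvals.get("converged", False):
            raise TwoStageError(
                f"stage-2 fit did not converge: {fit2.mle_retvals}"
            )

    est_exposure = _build_estimate(
        "2sps", float(fit2.params[1]), float(fit2.bse[1]),
        len(smoking_prs), exposure_type,
    )
    result = TwoStageResult(
        outcome=outcome,
        outcome_type="continuous" if outcome == "bmi" else "binary",
        stage1_beta=stage1_beta,
        stage1_f=f_stat,
        nagelkerke=nag,
    )
    if pred_bmi is None:
        result.total = est_exposure
    else:
        result.direct = est_exposure
        result.mediator = _build_estimate(
            "2sps_mediator", float(fit2.params[2]), float(fit2.bse[2]),
            len(bmi_weights), "continuous",
        )
    if outcome == "bmi":
        scale = LN2 if exposure_type == "binary" else 1.0
        result.bmi_change_per_doubling = scale * est_exposure.beta
    return result


def _resampled(cohort: Cohort, idx: np.ndarray) -> Cohort:
    return Cohort(
        dosages=cohort.dosages[idx],
        snps=cohort.snps,
        phenotypes=cohort.phenotypes.iloc[idx].reset_index(drop=True),
        covariates=cohort.covariates.iloc[idx].reset_index(drop=True),
    )


def _two_stage_bootstrap(
    cohort: Cohort,
    smoking_prs: pd.DataFrame,
    outcome: str,
    bmi_weights: pd.DataFrame | None,
    exposure: str,
    covariates: list[str] | None,
    f_threshold: float,
    n_boot: int,
    seed: int,
) -> TwoStageResult:
    """Point estimates from the full sample; SE of the headline
    coefficient from a nonparametric bootstrap over individuals."""
    point = two_stage(
        cohort, smoking_prs, outcome, bmi_weights, exposure, covariates,
        f_threshold, n_boot=0,
    )
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, cohort.n, size=cohort.n)
        try:
            rep = two_stage(
                _resampled(cohort, idx), smoking_prs, outcome, bmi_weights,
                exposure, covariates, f_threshold=0.0, n_boot=0,
            )
        except TwoStageError:
            continue
        est = rep.total if rep.total is not None else rep.direct
        draws.append(est.beta)
    if len(draws) >= 2:
        se = float(np.std(draws, ddof=1))
        target = point.total if point.total is not None else point.direct
        refreshed = _build_estimate(
            target.method, target.beta, se, target.n_snps, target.exposure_type
        )
        if point.total is not None:
            point.total = refreshed
        else:
            point.direct = refreshed
    return point
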
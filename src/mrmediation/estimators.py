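"""Two-sample Mendelian randomization estimators and diagnostics.

All estimators consume a harmonized exposure–outcome SNP table.  The
per-SNP building block is the Wald ratio (outcome effect over exposure
effect); the inverse-variance-weighted (IVW) estimate is the weighted
zero-intercept regression of outcome on exposure effects, the weighted
median is robust to up to half of invalid weight, and MR-Egger frees the
intercept to absorb (and test for) directional horizontal pleiotropy.

Scale conventions: causal effects are on the log scale.  For a binary
exposure the odds-ratio form is reported per 2-fold increase in exposure
odds, OR = exp(ln(2) * beta); for a continuous exposure it is per SD,
OR = exp(beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .sumstats import HarmonizedSet

LN2 = math.log(2.0)

_MIN_P = 5e-324  # smallest subnormal double; keeps p in (0, 1]


class EstimatorError(ValueError):
    """Invalid input to an MR estimator."""


def to_odds_ratio(
    beta: float,
    exposure_type: str,
    ci: tuple[float, float] | None = None,
):
    """Convert a log-scale causal effect to an odds-ratio form.

    Binary exposure: OR per 2-fold increase in exposure odds,
    exp(ln(2) * beta).  Continuous exposure: OR per SD, exp(beta).
    When ``ci`` is given the endpoints are transformed identically and
    (or, lo, hi) is returned; otherwise the OR alone.
    """
    if exposure_type not in ("binary", "continuous"):
        raise EstimatorError(f"unknown exposure_type {exposure_type!r}")
    scale = LN2 if exposure_type == "binary" else 1.0
    or_ = math.exp(scale * beta)
    if ci is None:
        return or_
    return or_, math.exp(scale * ci[0]), math.exp(scale * ci[1])


@dataclass
class MREstimate:
    """Causal effect estimate on the log scale with OR-converted form."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure_type: str = "binary"
    or_: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if math.isnan(self.or_):
            self.or_, self.or_ci_low, self.or_ci_high = to_odds_ratio(
                self.beta, self.exposure_type, (self.ci_low, self.ci_high)
            )

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.n_snps,
            "b": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.pvalue,
            "or": self.or_,
            "or_lci95": self.or_ci_low,
            "or_uci95": self.or_ci_high,
        }


def _build_estimate(
    method: str,
    beta: float,
    se: float,
    k: int,
    exposure_type: str,
    df: int | None = None,
) -> MREstimate:
    """Assemble an estimate with two-sided p and 95% CI.

    Normal reference by default; Student t with ``df`` degrees of freedom
    when given (MR-Egger convention).
    """
    if df is None:
        crit = sps.norm.ppf(0.975)
        p = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else 0.0
    else:
        crit = sps.t.ppf(0.975, df)
        p = 2.0 * sps.t.sf(abs(beta) / se, df) if se > 0 else 0.0
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - crit * se),
        ci_high=float(beta + crit * se),
        pvalue=float(max(p, _MIN_P)),
        n_snps=int(k),
        exposure_type=exposure_type,
    )


def wald_ratio(
    bx: float, by: float, se_x: float, se_y: float, exposure_type: str = "binary"
) -> MREstimate:
    """Single-variant Wald ratio, beta = by/bx, first-order se = se_y/|bx|.

    The first-order SE ignores uncertainty in bx; it is adequate when the
    instrument is strong (|bx|/se_x well above 10).
    """
    if bx == 0:
        raise EstimatorError("wald_ratio undefined for bx = 0")
    return _build_estimate(
        "wald", by / bx, se_y / abs(bx), 1, exposure_type
    )


def _ivw_closed_form(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    w = 1.0 / sy**2
    sww = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sww
    se_fixed = math.sqrt(1.0 / sww)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights 1/se_y^2.  ``model="fixed"`` uses
    se = sqrt(1 / sum w bx^2); ``"multiplicative_random"`` inflates it by
    max(1, sqrt(Q/(k-1))), the residual-variance (multiplicative
    over-dispersion) random-effects flavor.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown IVW model {model!r}")
    bx, by, sy = h.bx(), h.by(), h.sy()
    k = bx.size
    if k < 2:
        raise EstimatorError("IVW needs >= 2 variants; use wald_ratio for one")
    beta, se, q = _ivw_closed_form(bx, by, sy)
    method = "ivw_fe"
    if model == "multiplicative_random":
        se *= max(1.0, math.sqrt(q / (k - 1)))
        method = "ivw_re"
    return _build_estimate(method, beta, se, k, h.exposure_type())


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted median with the midpoint-interpolation convention.

    Order the values; at value i the cumulative weight is the normalized
    sum up to i minus half of weight i; the estimate linearly interpolates
    the values where that cumulative weight crosses one half.  Accepts a
    (B, k) batch; returns shape (B,).
    """
    r = np.atleast_2d(ratios).astype(float)
    w = np.atleast_2d(weights).astype(float)
    order = np.argsort(r, axis=1)
    r_s = np.take_along_axis(r, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    w_s = w_s / w_s.sum(axis=1, keepdims=True)
    cs = np.cumsum(w_s, axis=1) - 0.5 * w_s
    below = cs < 0.5
    j = below.sum(axis=1)  # first index with cs >= 0.5
    B, k = r_s.shape
    out = np.empty(B)
    rows = np.arange(B)
    at_edge = j == 0
    out[at_edge] = r_s[at_edge, 0]
    top = j >= k  # all cs < 0.5 (possible only via rounding)
    out[top] = r_s[top, -1]
    mid = ~(at_edge | top)
    jm = j[mid]
    c1 = cs[rows[mid], jm - 1]
    c2 = cs[rows[mid], jm]
    t = (0.5 - c1) / (c2 - c1)
    out[mid] = r_s[rows[mid], jm - 1] + t * (r_s[rows[mid], jm] - r_s[rows[mid], jm - 1])
    return out


def weighted_median(
    h: HarmonizedSet, n_boot: int = 5000, seed: int = 0
) -> MREstimate:
    """Weighted-median MR estimate.

    Per-SNP Wald ratios are combined with inverse-variance weights
    w_i = bx_i^2/se_y_i^2 (the first-order ratio variances); the estimate
    interpolates the ordered ratios at cumulative weight one half.  The SE
    comes from a seeded parametric bootstrap resampling bx and by from
    their standard errors.
    """
    bx, sx, by, sy = h.bx(), h.sx(), h.by(), h.sy()
    k = bx.size
    if k < 3:
        raise EstimatorError("weighted median needs >= 3 variants")
    if n_boot < 1:
        raise EstimatorError("n_boot must be a positive integer")
    ratios = by / bx
    weights = bx**2 / sy**2
    point = float(_weighted_median(ratios, weights)[0])

    rng = np.random.default_rng(seed)
    bxb = bx + rng.standard_normal((n_boot, k)) * sx
    byb = by + rng.standard_normal((n_boot, k)) * sy
    bxb = np.where(bxb == 0.0, np.finfo(float).tiny, bxb)
    boots = _weighted_median(byb / bxb, bxb**2 / sy**2)
    # a single bootstrap draw cannot estimate spread
    se = float(np.std(boots, ddof=1)) if n_boot >= 2 else float("nan")
    return _build_estimate("weighted_median", point, se, k, h.exposure_type())


@dataclass
class EggerResult:
    """MR-Egger regression: slope (causal effect) and pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def mr_egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression with a free intercept.

    Rows are first oriented so every exposure beta is non-negative (the
    estimator is not invariant to allele coding).  Outcome betas are
    regressed on exposure betas with weights 1/se_y^2; SEs use the
    residual-variance inflation floored at 1, and p-values the t
    distribution with k - 2 degrees of freedom.  A nonzero intercept
    indicates directional horizontal pleiotropy.
    """
    bx, by, sy = h.bx(), h.by(), h.sy()
    k = bx.size
    if k < 3:
        raise EstimatorError("MR-Egger needs >= 3 variants")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    A = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(A, X.T @ (w * by))
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    infl = max(1.0, math.sqrt(sigma2))
    cov_unit = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_unit)) * infl

    slope = _build_estimate(
        "egger_slope", coef[1], se[1], k, h.exposure_type(), df=k - 2
    )
    ip = 2.0 * sps.t.sf(abs(coef[0]) / se[0], k - 2)
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pvalue=float(max(ip, _MIN_P)),
    )


@dataclass
class QResult:
    """Cochran's Q heterogeneity test for the Wald ratios."""

    q: float
    df: int
    pvalue: float


def cochran_q(h: HarmonizedSet, est: MREstimate) -> QResult:
    """Cochran's Q about a given estimate.

    Q = sum_i w_i (ratio_i - beta)^2 with w_i = bx_i^2/se_y_i^2, referred
    to chi-square with k - 1 degrees of freedom.
    """
    bx, by, sy = h.bx(), h.by(), h.sy()
    k = bx.size
    if k < 2:
        raise EstimatorError("Cochran's Q needs >= 2 variants")
    w = bx**2 / sy**2
    q = float(np.sum(w * (by / bx - est.beta) ** 2))
    p = float(sps.chi2.sf(q, k - 1))
    return QResult(q=q, df=k - 1, pvalue=max(p, _MIN_P))


def mr_report(
    h: HarmonizedSet, n_boot: int = 5000, seed: int = 0
) -> dict:
    """Run IVW (random effects), weighted median and MR-Egger on one
    harmonized set and collect the standard diagnostics block."""
    est_ivw = ivw(h)
    rows = [est_ivw.as_row()]
    diagnostics: dict = {}
    q = cochran_q(h, ivw(h, model="fixed"))
    diagnostics.update({"Q": q.q, "Q_df": q.df, "Q_p": q.pvalue})
    if h.n_retained >= 3:
        rows.append(weighted_median(h, n_boot=n_boot, seed=seed).as_row())
        eg = mr_egger(h)
        rows.append(eg.slope.as_row())
        diagnostics.update(
            {
                "egger_intercept": eg.intercept,
                "egger_intercept_se": eg.intercept_se,
                "egger_intercept_p": eg.intercept_pvalue,
            }
        )
    return {"estimates": rows, "diagnostics": diagnostics, "ivw": est_ivw}
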
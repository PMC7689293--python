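"""Multivariable MR and total/direct mediation reporting.

Multivariable MR regresses outcome effects jointly on several exposures'
genetic effects, yielding each exposure's *direct* effect conditional on
the others.  Paired with the univariable (*total*) effect this gives the
mediation decomposition used for a mediator such as BMI.  For binary
outcomes the indirect effect is never reported: odds ratios are
noncollapsible, so total minus direct has no clean causal interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimatorError, MREstimate, _build_estimate
from .sumstats import HarmonizedSet


@dataclass
class MVMRResult:
    """Per-exposure direct effects from a joint weighted regression."""

    estimates: dict[str, MREstimate]
    exposures: list[str]
    n_snps: int
    conditional_f: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> MREstimate:
        return self.estimates[name]


def _conditional_f(X: np.ndarray, se_x: np.ndarray, j: int) -> float:
    """Heuristic conditional instrument-strength statistic for exposure j.

    Weighted regression of exposure j's effects on the other exposures'
    effects (weights 1/se_xj^2); the mean weighted squared residual per
    remaining degree of freedom plays the role of a conditional F.  A
    diagnostic only — not the full Sanderson–Windmeijer statistic.
    """
    k, m = X.shape
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    others = others[:, np.any(others != 0.0, axis=0)]
    w = 1.0 / se_x**2
    if others.shape[1] == 0:
        rss = float(np.sum(w * y**2))
        return rss / k
    A = others.T @ (w[:, None] * others)
    coef = np.linalg.solve(A, others.T @ (w * y))
    resid = y - others @ coef
    return float(np.sum(w * resid**2)) / (k - m + 1)


def mvmr_fit(h: HarmonizedSet) -> MVMRResult:
    """Fit multivariable MR on a multi-exposure harmonized set.

    Weighted multiple regression (no intercept) of outcome betas on the
    matrix of exposure betas with weights 1/se_y^2.  SEs come from the
    weighted-regression covariance with the residual-variance inflation
    floored at 1, matching the IVW random-effects convention.  With a
    single exposure this reproduces univariable IVW exactly.
    """
    names = h.exposure_names
    m = len(names)
    X = h.exposure_matrix()
    y = h.by()
    sy = h.sy()
    k = X.shape[0]
    if k < m + 1:
        raise EstimatorError(
            f"MVMR needs more variants ({k}) than exposures ({m})"
        )
    # an exposure contributing no genetic signal is dropped from the
    # design (direct effect 0 by construction) rather than breaking the fit
    active = [i for i in range(m) if np.any(X[:, i] != 0.0)]
    Xa = X[:, active]
    ma = len(active)
    w = 1.0 / sy**2
    Xw = np.sqrt(w)[:, None] * Xa
    if np.linalg.matrix_rank(Xw) < ma:
        corr = np.corrcoef(Xw, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise EstimatorError(
            f"rank-deficient design: exposures {names[active[i]]!r} and "
            f"{names[active[j]]!r} have collinear genetic effects"
        )
    A = Xa.T @ (w[:, None] * Xa)
    coef_a = np.linalg.solve(A, Xa.T @ (w * y))
    resid = y - Xa @ coef_a
    dof = k - ma
    sigma2 = float(np.sum(w * resid**2)) / dof if dof > 0 else 1.0
    infl2 = max(1.0, sigma2)
    cov = np.linalg.inv(A) * infl2
    ses_a = np.sqrt(np.diag(cov))
    coef = np.zeros(m)
    ses = np.full(m, np.nan)
    for pos, i in enumerate(active):
        coef[i] = coef_a[pos]
        ses[i] = ses_a[pos]

    estimates = {}
    for i, name in enumerate(names):
        if np.isnan(ses[i]):
            estimates[name] = MREstimate(
                method="mvmr_direct", beta=0.0, se=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), pvalue=1.0,
                n_snps=k, exposure_type=h.exposure_type(name),
            )
        else:
            estimates[name] = _build_estimate(
                "mvmr_direct", coef[i], ses[i], k, h.exposure_type(name)
            )
    cond_f = {}
    if m >= 1:
        for i, name in enumerate(names):
            se_xi = h.sx(name)
            cond_f[name] = _conditional_f(X, se_xi, i)
    return MVMRResult(
        estimates=estimates, exposures=list(names), n_snps=k, conditional_f=cond_f
    )


def percent_per_doubling(beta: float, exposure_type: str = "binary") -> float:
    """Percent change in outcome odds per 2-fold exposure increase,
    100*(exp(ln2*beta) - 1); per SD for a continuous exposure."""
    scale = math.log(2.0) if exposure_type == "binary" else 1.0
    return 100.0 * (math.exp(scale * beta) - 1.0)


@dataclass
class MediationResult:
    """Total and direct effects of one exposure on one outcome.

    Percent forms are per 2-fold exposure increase (binary exposure) or
    per SD (continuous), with CIs by monotone endpoint transformation.
    The indirect effect is deliberately absent for binary outcomes
    (noncollapsible odds ratios); ``indirect_absent_reason`` records why.
    """

    exposure: str
    outcome: str
    total: MREstimate
    direct: MREstimate
    total_percent: float
    total_percent_ci: tuple[float, float]
    direct_percent: float
    direct_percent_ci: tuple[float, float]
    indirect_absent_reason: str | None

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "total_b": self.total.beta,
            "total_or": self.total.or_,
            "total_or_lci95": self.total.or_ci_low,
            "total_or_uci95": self.total.or_ci_high,
            "direct_b": self.direct.beta,
            "direct_or": self.direct.or_,
            "direct_or_lci95": self.direct.or_ci_low,
            "direct_or_uci95": self.direct.or_ci_high,
            "total_percent": self.total_percent,
            "total_percent_lci95": self.total_percent_ci[0],
            "total_percent_uci95": self.total_percent_ci[1],
            "direct_percent": self.direct_percent,
            "direct_percent_lci95": self.direct_percent_ci[0],
            "direct_percent_uci95": self.direct_percent_ci[1],
            "indirect_absent_reason": self.indirect_absent_reason or "",
        }


def mediate(
    total: MREstimate,
    mvmr: MVMRResult,
    exposure_name: str,
    outcome_name: str = "outcome",
    outcome_type: str = "binary",
) -> MediationResult:
    """Pair a univariable (total) estimate with the MVMR (direct) estimate.

    Computes percent-change forms with CIs transformed endpoint-wise.  For
    binary outcomes no indirect effect or proportion mediated is computed.
    """
    if exposure_name not in mvmr.estimates:
        raise EstimatorError(
            f"exposure {exposure_name!r} not in MVMR fit {mvmr.exposures}"
        )
    direct = mvmr[exposure_name]
    et = total.exposure_type
    reason = "noncollapsible binary outcome" if outcome_type == "binary" else None
    return MediationResult(
        exposure=exposure_name,
        outcome=outcome_name,
        total=total,
        direct=direct,
        total_percent=percent_per_doubling(total.beta, et),
        total_percent_ci=(
            percent_per_doubling(total.ci_low, et),
            percent_per_doubling(total.ci_high, et),
        ),
        direct_percent=percent_per_doubling(direct.beta, et),
        direct_percent_ci=(
            percent_per_doubling(direct.ci_low, et),
            percent_per_doubling(direct.ci_high, et),
        ),
        indirect_absent_reason=reason,
    )
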
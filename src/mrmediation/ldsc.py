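"""Simplified LD score regression: heritability and genetic correlation.

Under a polygenic model, the expected association chi-square of a variant
grows linearly in its LD score (the sum of r-squared with every variant in
its window, itself included): E[z_j^2] = n h2 l_j / M + 1.  Regressing z^2
on l therefore estimates SNP heritability from summary statistics alone,
with the intercept absorbing confounding inflation.  For two traits with
non-overlapping samples, E[z1_j z2_j] = sqrt(n1 n2) rho_g l_j / M, and the
genetic correlation is r_g = rho_g / sqrt(h1^2 h2^2).

This is a deliberately compact estimator: a single re-weighting iteration
instead of full iterative weighting, and no reference LD scores are
shipped — scores always derive from the LD reference supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .instruments import LDReference

logger = logging.getLogger(__name__)

DEFAULT_JACKKNIFE_BLOCKS = 200


class LdscError(ValueError):
    pass


@dataclass
class LDScoreTable:
    """Per-SNP LD scores (l_j >= 1) in genome order, with M = SNP count."""

    scores: pd.Series  # index snp_id, values l_j
    m: int

    def __post_init__(self) -> None:
        if np.any(self.scores.to_numpy() < 1.0 - 1e-9):
            raise LdscError("LD scores must be >= 1 (each SNP tags itself)")

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(float)


def compute_ld_scores(ld: LDReference, snp_ids: list[str]) -> LDScoreTable:
    """l_j = 1 + sum of r2(i, j) over reference partners within the set.

    SNPs absent from the reference receive l = 1 (they tag only
    themselves); this is logged rather than fatal.
    """
    idx = {s: i for i, s in enumerate(snp_ids)}
    scores = np.ones(len(snp_ids))
    n_hit = 0
    for (a, b), r2 in ld.pairs.items():
        ia, ib = idx.get(a), idx.get(b)
        if ia is not None and ib is not None:
            scores[ia] += r2
            scores[ib] += r2
            n_hit += 1
    if n_hit == 0:
        logger.warning("compute_ld_scores: no reference pair matched the SNP set")
    return LDScoreTable(pd.Series(scores, index=snp_ids), m=len(snp_ids))


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares fit of y = intercept + slope * x.

    A constant regressor (no LD-score spread) carries no signal: the
    slope is 0 and the intercept the weighted mean.
    """
    if np.ptp(x) < 1e-12:
        return 0.0, float(np.sum(w * y) / np.sum(w))
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(A, X.T @ (w * y))
    return float(coef[1]), float(coef[0])


def h2_regression(
    z2: np.ndarray, n: float, ld: LDScoreTable
) -> tuple[float, float]:
    """SNP heritability from the regression of z^2 on LD scores.

    One unweighted pass pins a provisional h2, then a single re-weighting
    iteration with var(z^2) weights 1/(2 (1 + n h2 l/M)^2) gives the
    reported slope.  h2 = slope * M / n, clipped at 0 with a warning when
    the fit is negative.  Intercept near 1 indicates no confounding.
    """
    z2 = np.asarray(z2, float)
    ell = ld.values()
    if z2.size != ell.size:
        raise LdscError("z2 and LD score lengths differ")
    if z2.size < 200:
        raise LdscError("h2 regression needs >= 200 SNPs")
    m = ld.m
    slope, intercept = _wls_line(ell, z2, np.ones_like(ell))
    h2_prov = min(max(slope * m / n, 0.0), 1.0)
    w = 1.0 / (2.0 * (1.0 + n * h2_prov * ell / m) ** 2)
    slope, intercept = _wls_line(ell, z2, w)
    h2 = slope * m / n
    if h2 < 0:
        logger.warning("h2_regression: negative fitted h2 (%.4g), clipped to 0", h2)
        h2 = 0.0
    return float(h2), float(intercept)


@dataclass
class RgResult:
    h2_trait1: float
    h2_trait2: float
    rg: float
    se_rg: float
    pvalue: float
    intercept1: float
    intercept2: float
    gcov_intercept: float
    defined: bool = True

    def as_row(self, p1: str = "trait1", p2: str = "trait2") -> dict:
        z = self.rg / self.se_rg if self.se_rg > 0 else float("nan")
        return {
            "p1": p1,
            "p2": p2,
            "rg": self.rg,
            "se": self.se_rg,
            "z": z,
            "p": self.pvalue,
            "h2_obs_p1": self.h2_trait1,
            "h2_obs_p2": self.h2_trait2,
            "h2_int_p1": self.intercept1,
            "h2_int_p2": self.intercept2,
            "gcov_int": self.gcov_intercept,
        }


def _rg_point(
    z1: np.ndarray, z2: np.ndarray, n1: float, n2: float, ld: LDScoreTable,
    mask: np.ndarray | None = None,
) -> tuple[float, float, float, float, float, float]:
    """Point estimates (h1, h2, rho_g, rg, intercepts) on a SNP subset."""
    ell = ld.values()
    if mask is not None:
        z1, z2, ell = z1[mask], z2[mask], ell[mask]
    m = ld.m
    sub = LDScoreTable(pd.Series(ell), m=m)
    h1, int1 = h2_regression(z1**2, n1, sub)
    h2, int2 = h2_regression(z2**2, n2, sub)

    y = z1 * z2
    slope, gcov_int = _wls_line(ell, y, np.ones_like(ell))
    rho_prov = slope * m / math.sqrt(n1 * n2)
    w = 1.0 / (
        (1.0 + n1 * h1 * ell / m) * (1.0 + n2 * h2 * ell / m)
        + (math.sqrt(n1 * n2) * rho_prov * ell / m) ** 2
    )
    slope, gcov_int = _wls_line(ell, y, w)
    rho_g = slope * m / math.sqrt(n1 * n2)
    if h1 <= 0 or h2 <= 0:
        return h1, h2, rho_g, float("nan"), int1, int2, gcov_int
    rg = rho_g / math.sqrt(h1 * h2)
    rg = min(max(rg, -1.0), 1.0)
    return h1, h2, rho_g, rg, int1, int2, gcov_int


def rg_regression(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    ld: LDScoreTable,
    n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
) -> RgResult:
    """Bivariate LD score regression for the genetic correlation.

    The cross-product z1*z2 is regressed on LD scores; the slope scaled by
    M/sqrt(n1 n2) estimates the genetic covariance, normalized by the two
    heritabilities to r_g (clipped to [-1, 1]).  The SE is a delete-one
    block jackknife over ``n_blocks`` contiguous blocks (at least 20; the
    default shrinks to n_snps // 25 for small SNP sets).  Samples are
    assumed non-overlapping, so the cross-product intercept should sit
    near zero.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    m_snps = z1.size
    if z2.size != m_snps or ld.values().size != m_snps:
        raise LdscError("z1, z2 and LD scores must share the SNP set")
    n_blocks = min(n_blocks, max(20, m_snps // 25))
    if n_blocks < 20:
        raise LdscError("jackknife needs at least 20 blocks")

    h1, h2, rho_g, rg, int1, int2, gcov_int = _rg_point(z1, z2, n1, n2, ld)
    if math.isnan(rg):
        logger.warning("rg undefined: non-positive heritability estimate")
        return RgResult(h1, h2, float("nan"), float("nan"), float("nan"),
                        int1, int2, gcov_int, defined=False)

    edges = np.linspace(0, m_snps, n_blocks + 1).astype(int)
    pseudo = []
    for b in range(n_blocks):
        mask = np.ones(m_snps, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        rg_b = _rg_point(z1, z2, n1, n2, ld, mask)[3]
        if not math.isnan(rg_b):
            pseudo.append(rg_b)
    pseudo = np.array(pseudo)
    nb = pseudo.size
    se = math.sqrt((nb - 1) / nb * float(np.sum((pseudo - pseudo.mean()) ** 2)))
    p = float(max(2.0 * sps.norm.sf(abs(rg) / se), 5e-324)) if se > 0 else 1.0
    return RgResult(
        h2_trait1=h1, h2_trait2=h2, rg=rg, se_rg=se, pvalue=p,
        intercept1=int1, intercept2=int2, gcov_intercept=gcov_int,
    )
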
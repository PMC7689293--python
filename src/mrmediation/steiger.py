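"""MR-Steiger directionality test.

If the instrument truly acts on the exposure, which in turn causes the
outcome, the instrument should explain more variance in the exposure than
in the outcome.  The test aggregates per-SNP variance explained on each
trait, compares the implied correlations with a Fisher z test, and probes
robustness of the direction call over a grid of hypothetical
measurement-reliability values for the two traits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimators import EstimatorError
from .sumstats import HarmonizedSet

#: measurement-reliability multipliers probed per trait (6 x 6 grid)
DEFAULT_RELIABILITY_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    direction_defined: bool
    z: float
    pvalue: float
    sensitivity_ratio: float

    def as_row(self) -> dict:
        return {
            "r2_exposure": self.r2_exposure,
            "r2_outcome": self.r2_outcome,
            "correct_direction": self.correct_direction,
            "direction_defined": self.direction_defined,
            "z": self.z,
            "p": self.pvalue,
            "sensitivity_ratio": self.sensitivity_ratio,
        }


def _aggregate_r2(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> float:
    """Sum of per-SNP variance explained, r2_j = z_j^2/(z_j^2 + n_j).

    Equivalent to the Shim summary-statistics formula; for binary traits
    this is the observed-scale approximation from the association
    z-scores (no liability-scale conversion is attempted).
    """
    z2 = (beta / se) ** 2
    return float(np.sum(z2 / (z2 + n)))


def steiger_test(
    h: HarmonizedSet,
    n_exp: float | None = None,
    n_out: float | None = None,
    reliability_grid: tuple[float, ...] = DEFAULT_RELIABILITY_GRID,
) -> SteigerResult:
    """Infer causal direction between exposure and outcome.

    Aggregate instrument r-squared is computed for both traits; the
    direction is "correct" (exposure -> outcome) when the exposure r2 is
    larger.  The z statistic compares the two implied correlations
    (Fisher transform difference with the respective sample sizes).  The
    sensitivity ratio is the grid volume supporting the called direction
    over the volume opposing it, where each grid point rescales each
    trait's r2 by a hypothetical measurement reliability (observed r2
    divided by reliability = error-free r2); ``inf`` when no grid point
    opposes the call.
    """
    ret = h.retained
    if len(ret) < 1:
        raise EstimatorError("Steiger test needs at least one retained variant")
    name = h.exposure_names[0]
    bx, sx = h.bx(), h.sx()
    by, sy = h.by(), h.sy()
    nx = ret[f"n_exp_{name}"].to_numpy(float)
    ny = ret["n_out"].to_numpy(float)
    if n_exp is not None:
        nx = np.full_like(bx, float(n_exp))
    if n_out is not None:
        ny = np.full_like(by, float(n_out))

    r2x = _aggregate_r2(bx, sx, nx)
    r2y = _aggregate_r2(by, sy, ny)
    r2x = min(r2x, 1.0 - 1e-12)
    r2y = min(r2y, 1.0 - 1e-12)

    n_x = float(np.median(nx))
    n_y = float(np.median(ny))
    rx, ry = math.sqrt(r2x), math.sqrt(r2y)
    denom = math.sqrt(1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0))
    z = (math.atanh(rx) - math.atanh(ry)) / denom
    p = float(max(2.0 * sps.norm.sf(abs(z)), 5e-324))

    defined = r2x != r2y
    correct = r2x > r2y

    support = oppose = 0
    for gx, gy in itertools.product(reliability_grid, repeat=2):
        ax, ay = r2x / gx, r2y / gy
        if (ax > ay) == correct and ax != ay:
            support += 1
        elif ax != ay:
            oppose += 1
    sens = float("inf") if oppose == 0 else support / oppose

    return SteigerResult(
        r2_exposure=r2x,
        r2_outcome=r2y,
        correct_direction=bool(correct),
        direction_defined=bool(defined),
        z=float(z),
        pvalue=p,
        sensitivity_ratio=sens,
    )
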
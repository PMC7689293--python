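"""Genetic instrument construction: LD clumping and instrument strength.

An instrument is the set of genome-wide significant variants for the
exposure thinned to approximate linkage independence: candidates are
ranked by p-value and greedily retained, removing every unretained
candidate within a genomic window whose r-squared with the retained index
variant exceeds a threshold.  Instrument strength is summarized by the
variance explained in the exposure per variant (Shim's approximation from
summary statistics) and the corresponding F-statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, SumstatsError, harmonize

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.01
DEFAULT_WINDOW_BP = 250_000


class InstrumentError(ValueError):
    """Fatal problem while building an instrument."""


@dataclass
class LDReference:
    """Sparse pairwise r-squared lookup (symmetric; r2(a, a) == 1 implicit).

    Only pairs stored are treated as being in LD; absent pairs have r2 = 0,
    which matches a block-structured reference where cross-block LD is
    negligible.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    window_bp: int | None = None

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)

    def set(self, a: str, b: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise InstrumentError(f"r2 must lie in [0, 1], got {value}")
        if a != b:
            self.pairs[self._key(a, b)] = float(value)

    @classmethod
    def from_pairs(
        cls, triples: Iterable[tuple[str, str, float]], window_bp: int | None = None
    ) -> "LDReference":
        ref = cls(window_bp=window_bp)
        for a, b, r2 in triples:
            ref.set(str(a), str(b), float(r2))
        return ref

    def neighbors(self) -> dict[str, list[tuple[str, float]]]:
        """Adjacency map snp -> [(partner, r2), ...]."""
        adj: dict[str, list[tuple[str, float]]] = {}
        for (a, b), r2 in self.pairs.items():
            adj.setdefault(a, []).append((b, r2))
            adj.setdefault(b, []).append((a, r2))
        return adj

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDReference":
        df = pd.read_csv(path, sep="\t")
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise InstrumentError(f"LD reference missing column {col!r}")
        return cls.from_pairs(zip(df["snp_a"].astype(str), df["snp_b"].astype(str), df["r2"]))

    def to_tsv(self, path: str | Path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self.pairs.items())]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


def variance_explained(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    eaf: np.ndarray | float,
    n: np.ndarray | float,
) -> np.ndarray | float:
    """Per-variant fraction of exposure variance explained (Shim).

    r2_j = beta^2 * 2p(1-p) / (beta^2 * 2p(1-p) + se^2 * 2p(1-p) * n),
    which reduces to z^2 / (z^2 + n).  The total instrument R-squared is
    the sum over retained variants.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    eaf = np.asarray(eaf, float)
    n = np.asarray(n, float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise InstrumentError("eaf must lie strictly in (0, 1) (monomorphic variant)")
    if np.any(se <= 0.0) or np.any(n <= 1):
        raise InstrumentError("require se > 0 and n > 1")
    var_g = 2.0 * eaf * (1.0 - eaf)
    num = beta**2 * var_g
    out = num / (num + se**2 * var_g * n)
    return float(out) if out.ndim == 0 else out


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """Instrument F-statistic, F = [(n - k - 1)/k] * [R2/(1 - R2)]."""
    if not (0.0 <= r2_total < 1.0):
        raise InstrumentError("r2_total must lie in [0, 1)")
    if k < 1 or n <= k + 1:
        raise InstrumentError("require k >= 1 and n > k + 1")
    return (n - k - 1) / k * r2_total / (1.0 - r2_total)


@dataclass
class InstrumentSet:
    """Clumped instrument: retained variants ordered by ascending p-value.

    ``table`` carries the exposure summary-statistics rows of the retained
    variants plus a ``r2_exposure`` column (per-variant variance explained).
    """

    table: pd.DataFrame
    r2_total: float
    f_stat: float
    n_exposure: float
    trait_name: str = "trait"

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def k(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "trait": self.trait_name,
            "k": self.k,
            "r2_total": self.r2_total,
            "f_stat": self.f_stat,
            "n_exposure": self.n_exposure,
        }


def clump(
    sumstats: SummaryStats,
    ld: LDReference,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> InstrumentSet:
    """Greedy LD clumping of genome-wide significant variants.

    Candidates passing ``p_threshold`` are sorted by ascending p (ties
    broken by chromosome then position, for determinism).  The best
    remaining candidate is retained and all unretained candidates on the
    same chromosome within ``window_bp`` (radius) with r2 >= ``r2_threshold``
    against it are removed; each removed variant is therefore attributable
    to exactly one retained index variant.
    """
    df = sumstats.data
    cand = df[df["pvalue"] <= p_threshold].copy()
    if cand.empty:
        near = int((df["pvalue"] <= p_threshold * 100).sum())
        raise InstrumentError(
            f"{sumstats.trait_name}: no variant passes p <= {p_threshold:g} "
            f"({near} within two orders of magnitude)"
        )
    cand = cand.sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)

    adj = ld.neighbors()
    pos = dict(zip(df["snp_id"], df["pos"]))
    chrom = dict(zip(df["snp_id"], df["chrom"]))
    in_play = set(cand["snp_id"])
    removed: set[str] = set()
    retained: list[str] = []
    for snp in cand["snp_id"]:
        if snp in removed:
            continue
        retained.append(snp)
        removed.add(snp)
        for partner, r2 in adj.get(snp, ()):
            if partner in in_play and partner not in removed:
                if (
                    chrom.get(partner) == chrom[snp]
                    and abs(pos[partner] - pos[snp]) <= window_bp
                    and r2 >= r2_threshold
                ):
                    removed.add(partner)

    table = cand[cand["snp_id"].isin(retained)].reset_index(drop=True)
    table["r2_exposure"] = variance_explained(
        table["beta"].to_numpy(),
        table["se"].to_numpy(),
        table["eaf"].to_numpy(),
        table["n"].to_numpy(),
    )
    r2_total = float(table["r2_exposure"].sum())
    n_exp = float(table["n"].median())
    fstat = f_statistic(r2_total, n_exp, len(table))
    logger.info(
        "%s: clumped %d significant variants to %d (R2=%.4f, F=%.1f)",
        sumstats.trait_name, len(cand), len(table), r2_total, fstat,
    )
    return InstrumentSet(
        table=table,
        r2_total=r2_total,
        f_stat=fstat,
        n_exposure=n_exp,
        trait_name=sumstats.trait_name,
    )


def combined_instrument(
    stats: Sequence[SummaryStats],
    ld: LDReference,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[str]:
    """Joint instrument for multivariable MR.

    Takes the union of per-trait clumped instruments and re-clumps it at
    the same r2 threshold, ranking each variant by its best (minimum)
    p-value across the traits, so overlapping LD between the source
    instruments is not double counted.
    """
    frames = []
    for st in stats:
        inst = clump(st, ld, p_threshold, r2_threshold, window_bp)
        frames.append(st.data[st.data["snp_id"].isin(inst.snp_ids)])
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values("pvalue", kind="mergesort").drop_duplicates("snp_id")
    pooled = SummaryStats(
        pool.reset_index(drop=True),
        trait_name="combined",
        trait_type=stats[0].trait_type,
    )
    joint = clump(pooled, ld, p_threshold=1.0, r2_threshold=r2_threshold,
                  window_bp=window_bp)
    return joint.snp_ids


def prs_model(
    instrument: InstrumentSet,
    weights_from: SummaryStats | None = None,
    max_missing: float = 0.2,
) -> pd.DataFrame:
    """Polygenic-score weight table for an instrument.

    With ``weights_from`` omitted, each variant is weighted by its own
    exposure beta.  With a second trait's table supplied, weights are that
    trait's effects re-expressed for the instrument's effect alleles (the
    "mediator-by-exposure-SNPs" construction, e.g. BMI weights on smoking
    instrument variants).  Variants missing from the weight source are
    dropped with a warning; losing more than ``max_missing`` of them is
    fatal.
    """
    base = instrument.table
    if weights_from is None:
        return base[["snp_id", "effect_allele"]].assign(weight=base["beta"].to_numpy())

    inst_stats = SummaryStats(
        base[[c for c in base.columns if c != "r2_exposure"]].reset_index(drop=True),
        trait_name=instrument.trait_name,
        trait_type="continuous",
    )
    try:
        h = harmonize(inst_stats, weights_from)
    except SumstatsError as err:
        raise InstrumentError(
            f"no instrument variant found in weight source: {err}"
        ) from err
    kept = h.retained
    n_missing = instrument.k - len(kept)
    if n_missing:
        logger.warning(
            "prs_model: %d of %d instrument variants missing/unalignable in %s",
            n_missing, instrument.k, weights_from.trait_name,
        )
    if n_missing > max_missing * instrument.k:
        raise InstrumentError(
            f"{n_missing}/{instrument.k} instrument variants missing from "
            f"weight source (limit {max_missing:.0%})"
        )
    return pd.DataFrame(
        {
            "snp_id": kept["snp_id"].to_numpy(),
            "effect_allele": kept["effect_allele"].to_numpy(),
            "weight": kept["beta_out"].to_numpy(),
        }
    )
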
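"""GWAS summary statistics: containers, I/O and allele harmonization.

Every downstream analysis consumes per-SNP association tables (effect
allele, effect-allele frequency, beta, SE, p, N).  Two tables can only be
combined after *harmonization*: expressing the effects of both traits for
the same effect allele on the same strand, dropping variants whose alleles
cannot be reconciled.  Palindromic variants (A/T, C/G) are resolved from
allele frequencies or dropped when the frequency is too close to 0.5 to be
informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for a summary-statistics table
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

#: harmonization actions recorded per row
ACTION_KEPT = "kept"
ACTION_FLIPPED = "flipped"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_MISMATCH = "dropped_mismatch"
RETAINED_ACTIONS = (ACTION_KEPT, ACTION_FLIPPED)

DEFAULT_PALINDROME_EAF_WINDOW = 0.08


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table."""


def _normalize_chrom(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip()
    return s.str.replace(r"^chr", "", regex=True, case=False)


@dataclass
class SummaryStats:
    """Validated per-SNP association table for one trait.

    ``data`` holds the canonical columns (:data:`CANONICAL_COLUMNS`);
    ``beta`` is the per-allele effect of ``effect_allele`` — a log odds
    ratio for binary traits, SD units for continuous traits.
    """

    data: pd.DataFrame
    trait_name: str = "trait"
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SumstatsError(f"summary statistics missing columns: {missing}")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait_name: str = "trait",
        trait_type: str = "continuous",
    ) -> "SummaryStats":
        """Validate a raw table, dropping rows that violate the invariants.

        Dropped rows (bad alleles, indels, se<=0, eaf outside (0,1),
        p outside (0,1], n<=0, duplicate ids) are counted and logged.
        """
        df = frame.copy()
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SumstatsError(f"summary statistics missing columns: {missing}")
        df = df[CANONICAL_COLUMNS]
        df["snp_id"] = df["snp_id"].astype(str)
        df["chrom"] = _normalize_chrom(df["chrom"])
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
        for col in ("eaf", "beta", "se", "pvalue", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.upper().str.strip()

        n0 = len(df)
        ea, oa = df["effect_allele"], df["other_allele"]
        ok = (
            ea.isin(VALID_ALLELES)
            & oa.isin(VALID_ALLELES)
            & (ea != oa)
            & df["eaf"].gt(0.0) & df["eaf"].lt(1.0)
            & df["se"].gt(0.0)
            & df["pvalue"].gt(0.0) & df["pvalue"].le(1.0)
            & df["n"].gt(0)
            & df["pos"].notna() & df["beta"].notna()
        )
        df = df[ok]
        df = df[~df["snp_id"].duplicated(keep="first")]
        dropped = n0 - len(df)
        if dropped:
            logger.warning(
                "%s: dropped %d of %d rows failing validation", trait_name, dropped, n0
            )
        if df.empty:
            raise SumstatsError(f"{trait_name}: no valid rows after validation")
        df["pos"] = df["pos"].astype(np.int64)
        df["n"] = df["n"].astype(float)
        return cls(df.reset_index(drop=True), trait_name=trait_name, trait_type=trait_type)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStats":
        """Restrict to the given SNP ids (order of the table is kept)."""
        keep = self.data["snp_id"].isin(set(snp_ids))
        return SummaryStats(
            self.data[keep].reset_index(drop=True),
            trait_name=self.trait_name,
            trait_type=self.trait_type,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
) -> SummaryStats:
    """Read a tab/whitespace-delimited GWAS summary-statistics file.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"snp_id": "SNP", "beta": "BETA"}``; unmapped canonical names are
    assumed to match the header directly.  gzip input is transparent
    (by file extension).  Rows violating the table invariants are dropped
    with a logged count; a missing mandatory column is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in df.columns:
            raise SumstatsError(
                f"{path.name}: mandatory column {canonical!r} "
                f"(file column {source!r}) not found"
            )
        rename[source] = canonical
    df = df.rename(columns=rename)
    return SummaryStats.from_frame(
        df,
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
    )


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | \
           ((ea == "C") & (oa == "G")) | ((ea == "G") & (oa == "C"))


def _complement(series: pd.Series) -> pd.Series:
    return series.map(_COMPLEMENT)


def classify_alleles(
    ea_ref: pd.Series,
    oa_ref: pd.Series,
    ea_oth: pd.Series,
    oa_oth: pd.Series,
    eaf_ref: pd.Series,
    eaf_oth: pd.Series,
    palindrome_eaf_window: float,
) -> pd.Series:
    """Per-row harmonization action aligning ``oth`` alleles onto ``ref``.

    Non-palindromic variants are matched directly or via strand complement;
    a label swap (with or without complement) means the other table's beta
    refers to the reference *other* allele and must be flipped.  For
    palindromic variants the labels carry no strand information, so the
    decision rests on allele frequencies: both frequencies must lie outside
    ``0.5 +/- palindrome_eaf_window``; matching sides imply the same
    orientation (kept), opposite sides a flipped orientation.
    """
    pal_ref = _is_palindromic(ea_ref, oa_ref)
    pal_oth = _is_palindromic(ea_oth, oa_oth)

    same = (ea_oth == ea_ref) & (oa_oth == oa_ref)
    swap = (ea_oth == oa_ref) & (oa_oth == ea_ref)
    csame = (ea_oth == _complement(ea_ref)) & (oa_oth == _complement(oa_ref))
    cswap = (ea_oth == _complement(oa_ref)) & (oa_oth == _complement(ea_ref))

    # strict inequality with an epsilon so the stated window is inclusive
    # (an eaf exactly at the boundary drops) despite float representation
    w = palindrome_eaf_window + 1e-9
    outside = (eaf_ref - 0.5).abs() > w
    outside &= (eaf_oth - 0.5).abs() > w
    same_side = (eaf_ref - 0.5) * (eaf_oth - 0.5) > 0

    action = pd.Series(ACTION_DROPPED_MISMATCH, index=ea_ref.index)
    nonpal = ~pal_ref
    action[nonpal & (same | csame)] = ACTION_KEPT
    action[nonpal & (swap | cswap)] = ACTION_FLIPPED
    # palindromic: allele sets must agree (possibly via complement == same set)
    pal_match = pal_ref & pal_oth & (same | swap | csame | cswap)
    action[pal_match & ~outside] = ACTION_DROPPED_PALINDROMIC
    action[pal_match & outside & same_side] = ACTION_KEPT
    action[pal_match & outside & ~same_side] = ACTION_FLIPPED
    return action


@dataclass
class HarmonizedSet:
    """Exposure–outcome (or multi-exposure) aligned SNP table.

    ``data`` has one row per intersection SNP with an ``action`` column;
    rows with action in :data:`RETAINED_ACTIONS` are the instrument fed to
    the estimators.  All retained effects refer to the same effect allele.
    """

    data: pd.DataFrame
    exposure_names: list[str]
    outcome_name: str
    exposure_types: dict[str, str] = field(default_factory=dict)
    outcome_type: str = "binary"

    @property
    def retained(self) -> pd.DataFrame:
        return self.data[self.data["action"].isin(RETAINED_ACTIONS)]

    @property
    def n_retained(self) -> int:
        return int(len(self.retained))

    def exposure_type(self, name: str | None = None) -> str:
        name = name or self.exposure_names[0]
        return self.exposure_types.get(name, "binary")

    def bx(self, name: str | None = None) -> np.ndarray:
        name = name or self.exposure_names[0]
        return self.retained[f"beta_exp_{name}"].to_numpy(float)

    def sx(self, name: str | None = None) -> np.ndarray:
        name = name or self.exposure_names[0]
        return self.retained[f"se_exp_{name}"].to_numpy(float)

    def by(self) -> np.ndarray:
        return self.retained["beta_out"].to_numpy(float)

    def sy(self) -> np.ndarray:
        return self.retained["se_out"].to_numpy(float)

    def exposure_matrix(self) -> np.ndarray:
        """k x m matrix of exposure effects (column per exposure)."""
        return np.column_stack([self.bx(name) for name in self.exposure_names])

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedSet":
        keep = self.data["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.data[keep].reset_index(drop=True),
            exposure_names=list(self.exposure_names),
            outcome_name=self.outcome_name,
            exposure_types=dict(self.exposure_types),
            outcome_type=self.outcome_type,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_arrays(
        cls,
        bx: np.ndarray,
        sx: np.ndarray,
        by: np.ndarray,
        sy: np.ndarray,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        exposure_type: str = "binary",
        outcome_type: str = "binary",
        n_exp: float = 100_000.0,
        n_out: float = 100_000.0,
        eaf: np.ndarray | None = None,
    ) -> "HarmonizedSet":
        """Build a pre-aligned set directly from effect arrays (for toys and
        summary-level simulation)."""
        bx = np.asarray(bx, float)
        k = bx.size
        if eaf is None:
            eaf = np.full(k, 0.3)
        df = pd.DataFrame(
            {
                "snp_id": [f"snp{i}" for i in range(k)],
                "chrom": "1",
                "pos": np.arange(1, k + 1) * 1000,
                "effect_allele": "A",
                "other_allele": "G",
                f"beta_exp_{exposure_name}": bx,
                f"se_exp_{exposure_name}": np.asarray(sx, float),
                f"eaf_exp_{exposure_name}": eaf,
                f"n_exp_{exposure_name}": float(n_exp),
                "beta_out": np.asarray(by, float),
                "se_out": np.asarray(sy, float),
                "eaf_out": eaf,
                "n_out": float(n_out),
                "action": ACTION_KEPT,
            }
        )
        return cls(
            df,
            exposure_names=[exposure_name],
            outcome_name=outcome_name,
            exposure_types={exposure_name: exposure_type},
            outcome_type=outcome_type,
        )


def _aligned_columns(
    ref: pd.DataFrame,
    other: SummaryStats,
    palindrome_eaf_window: float,
    prefix: str,
) -> pd.DataFrame:
    """Merge ``other`` onto the reference frame and align its effects.

    Returns the reference frame with ``{beta,se,eaf,n}_{prefix}`` columns
    plus an action column named ``action_{prefix}``.  Flipped rows have the
    other-table beta negated and eaf reflected.
    """
    odf = other.data[
        ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]
    ].rename(
        columns={
            "effect_allele": "_ea_o",
            "other_allele": "_oa_o",
            "eaf": f"eaf_{prefix}",
            "beta": f"beta_{prefix}",
            "se": f"se_{prefix}",
            "n": f"n_{prefix}",
        }
    )
    merged = ref.merge(odf, on="snp_id", how="inner")
    if merged.empty:
        raise SumstatsError(
            f"no SNPs shared between reference set and {other.trait_name!r}"
        )
    action = classify_alleles(
        merged["effect_allele"],
        merged["other_allele"],
        merged["_ea_o"],
        merged["_oa_o"],
        merged["eaf_ref"],
        merged[f"eaf_{prefix}"],
        palindrome_eaf_window,
    )
    flip = action == ACTION_FLIPPED
    merged.loc[flip, f"beta_{prefix}"] = -merged.loc[flip, f"beta_{prefix}"]
    merged.loc[flip, f"eaf_{prefix}"] = 1.0 - merged.loc[flip, f"eaf_{prefix}"]
    merged[f"action_{prefix}"] = action
    return merged.drop(columns=["_ea_o", "_oa_o"])


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedSet:
    """Align an outcome table onto an exposure table.

    SNPs are intersected on id; outcome effects are re-expressed for the
    exposure effect allele (sign flip plus eaf reflection when the allele
    labels are swapped, directly or through the strand complement).
    Palindromic SNPs are retained only when both allele frequencies fall
    outside ``0.5 +/- palindrome_eaf_window`` and imply a consistent
    orientation.  Every intersection row is kept in the output with its
    action; only ``kept``/``flipped`` rows enter the analysis.
    """
    return harmonize_many([exposure], outcome, palindrome_eaf_window)


def harmonize_many(
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedSet:
    """Harmonize one outcome and >=1 exposures to a shared effect allele.

    The first exposure's alleles are the reference orientation; every other
    table (further exposures, then the outcome) is aligned to it.  A row is
    retained only if every table aligns (``kept`` or ``flipped``); otherwise
    the worst action among the tables is recorded.
    """
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise SumstatsError("palindrome_eaf_window must lie in [0, 0.5)")
    if not exposures:
        raise SumstatsError("at least one exposure table is required")

    first = exposures[0]
    ref = first.data[
        ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
         "eaf", "beta", "se", "n"]
    ].rename(
        columns={
            "eaf": "eaf_ref",
            "beta": f"beta_exp_{first.trait_name}",
            "se": f"se_exp_{first.trait_name}",
            "n": f"n_exp_{first.trait_name}",
        }
    )
    action_cols = []
    for exp in exposures[1:]:
        prefix = f"exp_{exp.trait_name}"
        ref = _aligned_columns(ref, exp, palindrome_eaf_window, prefix)
        action_cols.append(f"action_{prefix}")
    ref = _aligned_columns(ref, outcome, palindrome_eaf_window, "out")
    action_cols.append("action_out")

    # combined action: a row survives only if all alignments survive
    combined = ref["action_out"].copy()
    for col in action_cols:
        bad = ~ref[col].isin(RETAINED_ACTIONS)
        combined[bad] = ref.loc[bad, col]
    # rows where everything aligned: flipped if outcome itself was flipped
    ref["action"] = combined
    ref = ref.rename(columns={"eaf_ref": f"eaf_exp_{first.trait_name}"})
    ref = ref.drop(columns=action_cols)

    result = HarmonizedSet(
        ref.reset_index(drop=True),
        exposure_names=[e.trait_name for e in exposures],
        outcome_name=outcome.trait_name,
        exposure_types={e.trait_name: e.trait_type for e in exposures},
        outcome_type=outcome.trait_type,
    )
    if result.n_retained == 0:
        raise SumstatsError(
            f"harmonizing {first.trait_name!r} with {outcome.trait_name!r}: "
            "all intersection rows were dropped"
        )
    n_dropped = len(result.data) - result.n_retained
    if n_dropped:
        logger.info(
            "harmonize %s ~ %s: %d kept, %d dropped",
            first.trait_name, outcome.trait_name, result.n_retained, n_dropped,
        )
    return result
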
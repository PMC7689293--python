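"""Summary-statistics validation and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediation.sumstats import (
    ACTION_DROPPED_MISMATCH,
    ACTION_DROPPED_PALINDROMIC,
    ACTION_FLIPPED,
    ACTION_KEPT,
    SummaryStats,
    SumstatsError,
    harmonize,
    read_sumstats,
)

from conftest import make_sumstats_frame


def _stats(rows, name="trait", trait_type="binary"):
    return SummaryStats.from_frame(
        make_sumstats_frame(rows), trait_name=name, trait_type=trait_type
    )


class TestReadAndValidate:
    def test_toy_tsv_round_trip(self, tmp_path):
        frame = make_sumstats_frame([{}, {"beta": 0.2}, {"beta": -0.1}])
        path = tmp_path / "toy.tsv"
        frame.to_csv(path, sep="\t", index=False)
        stats = read_sumstats(path, trait_type="binary")
        assert len(stats) == 3
        assert list(stats.data["snp_id"]) == ["rs1", "rs2", "rs3"]

    def test_invalid_rows_dropped(self):
        stats = _stats(
            [
                {},
                {"se": 0.0},          # non-positive SE
                {"eaf": 1.0},          # monomorphic
                {"other_allele": "A"}, # ea == oa
                {"effect_allele": "AT"},  # indel
            ]
        )
        assert len(stats) == 1

    def test_duplicate_ids_dropped(self):
        frame = make_sumstats_frame([{}, {}])
        frame.loc[1, "snp_id"] = "rs1"
        stats = SummaryStats.from_frame(frame)
        assert len(stats) == 1

    def test_missing_column_fatal(self, tmp_path):
        frame = make_sumstats_frame([{}]).drop(columns=["eaf"])
        path = tmp_path / "noeaf.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="eaf"):
            read_sumstats(path)

    def test_column_map(self, tmp_path):
        frame = make_sumstats_frame([{}]).rename(columns={"beta": "BETA"})
        path = tmp_path / "mapped.tsv"
        frame.to_csv(path, sep="\t", index=False)
        stats = read_sumstats(path, column_map={"beta": "BETA"})
        assert stats.data.loc[0, "beta"] == pytest.approx(0.1)

    def test_empty_after_validation_fatal(self):
        with pytest.raises(SumstatsError):
            _stats([{"se": 0.0}])

    def test_chrom_prefix_normalized(self):
        stats = _stats([{"chrom": "chr7"}])
        assert stats.data.loc[0, "chrom"] == "7"


class TestHarmonize:
    def test_aligned_rows_kept_unchanged(self):
        exp = _stats([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = _stats([{"effect_allele": "A", "other_allele": "G", "beta": 0.05}])
        h = harmonize(exp, out)
        assert list(h.data["action"]) == [ACTION_KEPT]
        assert h.by()[0] == pytest.approx(0.05)

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = _stats([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = _stats(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.05, "eaf": 0.3}]
        )
        h = harmonize(exp, out)
        assert list(h.data["action"]) == [ACTION_FLIPPED]
        assert h.by()[0] == pytest.approx(-0.05)
        assert h.data.loc[0, "eaf_out"] == pytest.approx(0.7)

    def test_strand_complement_kept(self):
        exp = _stats([{"effect_allele": "A", "other_allele": "G"}])
        out = _stats([{"effect_allele": "T", "other_allele": "C", "beta": 0.07}])
        h = harmonize(exp, out)
        assert list(h.data["action"]) == [ACTION_KEPT]
        assert h.by()[0] == pytest.approx(0.07)

    # hand-written truth table for palindromic variants at window w = 0.08:
    # (exp alleles, out alleles, eaf_exp, eaf_out) -> action
    PALINDROME_CASES = [
        (("A", "T"), ("A", "T"), 0.30, 0.30, ACTION_KEPT),
        (("A", "T"), ("A", "T"), 0.30, 0.70, ACTION_FLIPPED),
        (("A", "T"), ("T", "A"), 0.30, 0.30, ACTION_KEPT),
        (("A", "T"), ("T", "A"), 0.70, 0.30, ACTION_FLIPPED),
        (("A", "T"), ("A", "T"), 0.49, 0.30, ACTION_DROPPED_PALINDROMIC),
        (("A", "T"), ("A", "T"), 0.30, 0.55, ACTION_DROPPED_PALINDROMIC),
        (("A", "T"), ("A", "T"), 0.50, 0.50, ACTION_DROPPED_PALINDROMIC),
        (("C", "G"), ("C", "G"), 0.20, 0.25, ACTION_KEPT),
        (("C", "G"), ("G", "C"), 0.20, 0.80, ACTION_FLIPPED),
        (("C", "G"), ("C", "G"), 0.42, 0.42, ACTION_DROPPED_PALINDROMIC),
        (("A", "T"), ("C", "G"), 0.30, 0.30, ACTION_DROPPED_MISMATCH),
        (("A", "G"), ("A", "C"), 0.30, 0.30, ACTION_DROPPED_MISMATCH),
    ]

    @pytest.mark.parametrize(
        "exp_alleles,out_alleles,eaf_exp,eaf_out,expected", PALINDROME_CASES
    )
    def test_palindrome_truth_table(
        self, exp_alleles, out_alleles, eaf_exp, eaf_out, expected
    ):
        exp = _stats(
            [{"effect_allele": exp_alleles[0], "other_allele": exp_alleles[1],
              "eaf": eaf_exp}]
        )
        out = _stats(
            [{"effect_allele": out_alleles[0], "other_allele": out_alleles[1],
              "eaf": eaf_out}]
        )
        if expected in (ACTION_KEPT, ACTION_FLIPPED):
            h = harmonize(exp, out, palindrome_eaf_window=0.08)
            assert list(h.data["action"]) == [expected]
        else:
            # single-row table where the only row drops -> fatal by contract
            with pytest.raises(SumstatsError):
                harmonize(exp, out, palindrome_eaf_window=0.08)

    def test_empty_intersection_fatal(self):
        exp = _stats([{}])
        out_frame = make_sumstats_frame([{}])
        out_frame["snp_id"] = ["other1"]
        out = SummaryStats.from_frame(out_frame)
        with pytest.raises(SumstatsError):
            harmonize(exp, out)

    def test_sign_flip_preserves_magnitude_and_p(self):
        exp = _stats([{"effect_allele": "A", "other_allele": "G"}])
        out = _stats(
            [{"effect_allele": "G", "other_allele": "A",
              "beta": 0.31, "pvalue": 0.007}]
        )
        h = harmonize(exp, out)
        assert abs(h.by()[0]) == pytest.approx(0.31)
        assert h.retained["n_out"].iloc[0] == 100_000

    def test_idempotent(self, toy_exposure):
        out = _stats(
            [
                {"effect_allele": "G", "other_allele": "A", "beta": 0.05},
                {"effect_allele": "C", "other_allele": "T", "beta": -0.02},
                {"effect_allele": "A", "other_allele": "G", "beta": 0.04},
            ]
        )
        h1 = harmonize(toy_exposure, out)
        # rebuild the outcome from the harmonized rows and harmonize again
        re_out_frame = h1.data.rename(
            columns={
                "beta_out": "beta", "se_out": "se",
                "eaf_out": "eaf", "n_out": "n",
            }
        )[["snp_id", "chrom", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "n"]].assign(pvalue=0.5)
        re_out = SummaryStats.from_frame(re_out_frame, trait_name="trait")
        h2 = harmonize(toy_exposure, re_out)
        np.testing.assert_allclose(h1.by(), h2.by())
        np.testing.assert_allclose(h1.bx(), h2.bx())
        assert (h2.data["action"] == ACTION_KEPT).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    flips=st.lists(st.booleans(), min_size=4, max_size=12),
    seed=st.integers(0, 10_000),
)
def test_harmonization_involution_property(flips, seed):
    """Flipping alleles in the outcome table never changes the harmonized
    effect: harmonize undoes any label swap exactly (involution)."""
    rng = np.random.default_rng(seed)
    k = len(flips)
    base = make_sumstats_frame(
        [{"effect_allele": "A", "other_allele": "G",
          "beta": float(rng.normal()), "eaf": float(rng.uniform(0.1, 0.9))}
         for _ in range(k)]
    )
    exp = SummaryStats.from_frame(base.copy(), trait_name="e")
    out_frame = base.copy()
    for i, flip in enumerate(flips):
        if flip:
            out_frame.loc[i, ["effect_allele", "other_allele"]] = ["G", "A"]
            out_frame.loc[i, "beta"] = -out_frame.loc[i, "beta"]
            out_frame.loc[i, "eaf"] = 1.0 - out_frame.loc[i, "eaf"]
    out = SummaryStats.from_frame(out_frame, trait_name="o")
    h = harmonize(exp, out)
    np.testing.assert_allclose(h.by(), h.bx(), atol=1e-12)
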
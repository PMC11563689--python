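"""NMD rule, C-terminal-loss arithmetic and variant-class assignment."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from exoburden.lof import (
    NmdRuleParams,
    classify,
    cterm_loss_fraction,
    nmd_predicted,
)
from exoburden.synthetic import generate_toy_transcript
from exoburden.types import Consequence, ValidationError, VariantClass

from conftest import make_variant


# 3-exon toy: 300 + 300 + 300 nt CDS, protein 299 aa.
# Penultimate exon's CDS 3' end sits at CDS coordinate 600, so the NMD
# boundary is 600 - 50 = 550: a PTC at CDS position < 550 is NMD-predicted.
EXONS = [300, 300, 300]
CDS_LEN = sum(EXONS)


def toy(ptc_offset: int):
    return generate_toy_transcript(3, EXONS, ptc_offset)


class TestNmdRule:
    @pytest.mark.parametrize(
        "ptc_pos, expected",
        [
            (10, True),  # first exon, far upstream
            (549, True),  # 51 nt upstream of penultimate exon 3' end
            (550, False),  # exactly 50 nt upstream: boundary -> escape
            (560, False),  # inside the penultimate escape zone
            (700, False),  # last exon
            (CDS_LEN, False),  # CDS 3' end
        ],
    )
    def test_truth_table(self, ptc_pos, expected):
        tx, _ = toy(0)
        assert nmd_predicted(tx, ptc_pos) is expected

    def test_toy_generator_places_ptc_by_offset(self):
        tx, var = toy(400)  # 400 nt upstream of CDS 3' end -> position 500
        assert var.cds_ptc_position == CDS_LEN - 400 == 500
        assert nmd_predicted(tx, var.cds_ptc_position)

    def test_single_coding_exon_always_escapes(self):
        tx, _ = generate_toy_transcript(2, [600, 300], 0)
        # collapse to a single coding exon by restricting the CDS
        tx.cds_end = tx.exons[0][1]
        assert nmd_predicted(tx, 100) is False

    def test_ptc_outside_cds_rejected(self):
        tx, _ = toy(0)
        with pytest.raises(ValidationError):
            nmd_predicted(tx, CDS_LEN + 1)
        with pytest.raises(ValidationError):
            cterm_loss_fraction(tx, 0)

    def test_escape_width_parameter(self):
        tx, _ = toy(0)
        wide = NmdRuleParams(penultimate_escape_bp=100)
        assert nmd_predicted(tx, 549) is True
        assert nmd_predicted(tx, 549, wide) is False  # boundary moves to 500


class TestCtermLoss:
    def test_full_loss_at_first_codon(self):
        tx, _ = toy(0)
        assert cterm_loss_fraction(tx, 1) == 1.0

    def test_five_percent_loss_not_lof(self):
        # protein of 1000 aa: CDS 3003 nt; PTC after codon 950 keeps 950 aa
        tx, _ = generate_toy_transcript(3, [1200, 1200, 603], 0)
        assert tx.protein_length_aa == 1000
        loss = cterm_loss_fraction(tx, 2852)  # (2852-1)//3 = 950 codons kept
        assert loss == pytest.approx(0.05)
        assert loss < NmdRuleParams().min_cterm_loss_fraction

    def test_large_protein_early_ptc_retained(self):
        # ~3,000-aa protein with a PTC at codon 117 loses ~96% of the protein
        tx, _ = generate_toy_transcript(4, [3000, 3000, 2400, 798], 0)
        assert tx.protein_length_aa == 3065
        loss = cterm_loss_fraction(tx, 117 * 3 - 2)
        assert loss == pytest.approx((3065 - 116) / 3065)
        assert loss >= 0.10

    @given(st.integers(1, CDS_LEN - 1))
    @settings(max_examples=50, deadline=None)
    def test_loss_non_increasing_in_position(self, pos):
        tx, _ = toy(0)
        assert cterm_loss_fraction(tx, pos) >= cterm_loss_fraction(tx, pos + 1)

    @given(st.integers(1, CDS_LEN - 1))
    @settings(max_examples=50, deadline=None)
    def test_nmd_monotone_along_cds(self, pos):
        """Moving a PTC 3'-ward never turns escape back into NMD."""
        tx, _ = toy(0)
        if not nmd_predicted(tx, pos):
            assert not nmd_predicted(tx, pos + 1)


class TestClassify:
    def test_early_nonsense_is_lof(self):
        tx, var = toy(500)
        rec = classify(var, tx)
        assert rec.variant_class is VariantClass.LOF
        assert rec.nmd_evaluated and rec.nmd_predicted
        assert rec.cterm_loss >= 0.10

    def test_escape_ptc_demoted(self):
        tx, var = toy(10)  # PTC 10 nt upstream of CDS end: last exon
        rec = classify(var, tx)
        assert rec.variant_class is VariantClass.OTHER
        assert rec.nmd_evaluated and not rec.nmd_predicted

    def test_nmd_positive_but_small_loss_demoted(self):
        # PTC in NMD territory of a long protein, losing only ~7%
        tx, _ = generate_toy_transcript(3, [2700, 90, 213], 0)
        var = make_variant(
            consequence=Consequence.STOP_GAINED, cds_ptc_position=2710
        )
        rec = classify(var, tx)
        assert rec.nmd_predicted is True
        assert rec.cterm_loss < 0.10
        assert rec.variant_class is VariantClass.OTHER

    def test_splice_without_ptc_retained_unevaluated(self):
        var = make_variant(consequence=Consequence.SPLICE_CANONICAL)
        rec = classify(var, None)
        assert rec.variant_class is VariantClass.LOF
        assert rec.nmd_evaluated is False

    def test_missense_consensus_rule(self):
        assert (
            classify(
                make_variant(
                    consequence=Consequence.MISSENSE,
                    predictor_flags=(True, True, True),
                )
            ).variant_class
            is VariantClass.DAMAGING_MISSENSE
        )
        assert (
            classify(
                make_variant(
                    consequence=Consequence.MISSENSE,
                    predictor_flags=(True, True, False),
                )
            ).variant_class
            is VariantClass.OTHER
        )

    def test_missense_without_flags_rejected(self):
        with pytest.raises(ValidationError, match="predictor flags"):
            classify(make_variant(consequence=Consequence.MISSENSE))

    @pytest.mark.parametrize(
        "csq", [Consequence.INFRAME, Consequence.OTHER]
    )
    def test_inframe_and_other_are_discarded(self, csq):
        assert classify(make_variant(consequence=csq)).variant_class is VariantClass.OTHER

    def test_synonymous(self):
        assert (
            classify(make_variant(consequence=Consequence.SYNONYMOUS)).variant_class
            is VariantClass.SYNONYMOUS
        )


@given(
    n_exons=st.integers(3, 6),
    codons=st.lists(st.integers(30, 120), min_size=6, max_size=6),
    data=st.data(),
)
@settings(max_examples=40, deadline=None)
def test_nmd_implies_loss_when_zone_is_late(n_exons, codons, data):
    """When the whole escape zone lies in the last 10% of codons, every
    NMD-predicted PTC automatically loses >= 10% of the protein."""
    lengths = [3 * c for c in codons[:n_exons]]
    tx, _ = generate_toy_transcript(n_exons, lengths, 0)
    boundary = sum(tx.cds_lengths_by_exon()[:-1]) - 50
    if boundary <= 1:
        return
    if boundary < 3 * int(0.9 * tx.protein_length_aa):
        return  # zone starts before the last 10%; premise not met
    pos = data.draw(st.integers(1, tx.cds_length_nt))
    if nmd_predicted(tx, pos):
        assert cterm_loss_fraction(tx, pos) >= 0.10
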
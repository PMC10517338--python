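"""Region calls, confidence scoring, and inclusion/exclusion rules."""

import pytest
from hypothesis import given, settings, strategies as st

from utrcensus.io_formats import ClinvarClass, Origin, VariantRecord
from utrcensus.transcript_context import (
    ContextConfig,
    EvidenceContext,
    NotEligibleError,
    Region,
    TranscriptFlag,
    TranscriptModel,
    confidence_score,
    locate_variant,
    resolve_inclusion,
)


def make_tx(tid="T1", strand="+", exons=((100, 500),), cds=(200, 400), gene="G", chrom="1"):
    return TranscriptModel(
        transcript_id=tid, gene=gene, chrom=chrom, strand=strand,
        exons=[tuple(e) for e in exons], cds=cds,
    )


def snv(pos, chrom="1"):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G")


# ---------------------------------------------------------------------------
# locate_variant
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pos, expected",
    [
        (450, Region.UTR3_EXONIC),
        (150, Region.UTR5_EXONIC),
        (300, Region.CDS_EXONIC),
        (50, Region.INTERGENIC),
        (600, Region.INTERGENIC),
    ],
)
def test_locate_snv_single_exon(pos, expected):
    assert locate_variant(snv(pos), make_tx()).region is expected


def test_locate_other_chromosome_is_intergenic():
    assert locate_variant(snv(300, chrom="2"), make_tx()).region is Region.INTERGENIC


def test_locate_minus_strand_swaps_utrs():
    tx = make_tx(strand="-")
    assert locate_variant(snv(450), tx).region is Region.UTR5_EXONIC
    assert locate_variant(snv(150), tx).region is Region.UTR3_EXONIC


def test_splice_proximal_window():
    # intron 301..399 between two exons
    tx = make_tx(exons=[(100, 300), (400, 600)], cds=(150, 550))
    # 5 bp from the right boundary (positions 395..399 are 5..1 away)
    assert locate_variant(snv(395), tx).region is Region.SPLICE_PROXIMAL_INTRONIC
    assert locate_variant(snv(308), tx).region is Region.SPLICE_PROXIMAL_INTRONIC
    assert locate_variant(snv(350), tx).region is Region.INTRONIC
    # exonic positions near the boundary are never splice-proximal
    assert locate_variant(snv(300), tx).region is Region.CDS_EXONIC


def test_splice_window_boundary_exhaustive():
    # scan every intronic base and compare to the distance rule
    tx = make_tx(exons=[(100, 300), (400, 600)], cds=(150, 550))
    for pos in range(301, 400):
        distance = min(pos - 301 + 1, 399 - pos + 1)
        expected = (
            Region.SPLICE_PROXIMAL_INTRONIC if distance <= 8 else Region.INTRONIC
        )
        assert locate_variant(snv(pos), tx).region is expected, pos


def test_deletion_spanning_utr_cds_boundary():
    tx = make_tx()  # 3'UTR starts at 401
    deletion = VariantRecord(chrom="1", pos=395, ref="A" * 10, alt="A")
    assert locate_variant(deletion, tx).region is Region.SPANNING


def test_deletion_contained_in_utr():
    deletion = VariantRecord(chrom="1", pos=420, ref="A" * 10, alt="A")
    assert locate_variant(deletion, make_tx()).region is Region.UTR3_EXONIC


def test_insertion_located_by_flanking_bases():
    tx = make_tx()
    # both flanks (500, 501): 501 is past the exon -> not contained
    ins_at_edge = VariantRecord(chrom="1", pos=500, ref="A", alt="AGG")
    assert locate_variant(ins_at_edge, tx).region is not Region.UTR3_EXONIC
    ins_inside = VariantRecord(chrom="1", pos=450, ref="A", alt="AGG")
    assert locate_variant(ins_inside, tx).region is Region.UTR3_EXONIC


def test_noncoding_transcript_excluded_from_utr_logic():
    tx = TranscriptModel("T1", "G", "1", "+", exons=[(100, 500)], cds=None)
    with pytest.raises(NotEligibleError, match="non-coding"):
        locate_variant(snv(300), tx)


def test_configurable_splice_window():
    tx = make_tx(exons=[(100, 300), (400, 600)], cds=(150, 550))
    wide = ContextConfig(splice_window=60)
    assert locate_variant(snv(350), tx, wide).region is Region.SPLICE_PROXIMAL_INTRONIC


# ---------------------------------------------------------------------------
# confidence_score
# ---------------------------------------------------------------------------

VAR = snv(450)  # 3'UTR of the preferred transcript
PREFERRED = make_tx("PREF")


def test_score_2_no_overlapping_transcripts():
    assert confidence_score(VAR, PREFERRED, [], "utr3").value == 2


def test_score_0_cds_exonic_on_other():
    other = make_tx("O1", exons=[(430, 480)], cds=(430, 480))
    assert confidence_score(VAR, PREFERRED, [other], "utr3").value == 0


def test_score_0_splice_proximal_on_other():
    other = make_tx("O1", exons=[(350, 445), (460, 550)], cds=(350, 550))
    assert confidence_score(VAR, PREFERRED, [other], "utr3").value == 0


def test_score_1_intronic_on_other():
    other = make_tx("O1", exons=[(300, 420), (500, 550)], cds=(300, 550))
    assert confidence_score(VAR, PREFERRED, [other], "utr3").value == 1


def test_score_1_opposite_utr_on_other():
    # minus-strand transcript whose 5'UTR covers position 450
    other = make_tx("O1", strand="-", exons=[(350, 550)], cds=(350, 420))
    assert confidence_score(VAR, PREFERRED, [other], "utr3").value == 1


def test_same_utr_on_other_does_not_demote():
    other = make_tx("O1", exons=[(350, 550)], cds=(360, 420))
    assert locate_variant(VAR, other).region is Region.UTR3_EXONIC
    assert confidence_score(VAR, PREFERRED, [other], "utr3").value == 2


def test_score_precondition_enforced():
    with pytest.raises(NotEligibleError):
        confidence_score(snv(300), PREFERRED, [], "utr3")  # CDS position
    with pytest.raises(NotEligibleError):
        confidence_score(VAR, PREFERRED, [], "utr5")  # wrong target side


_OTHERS = [
    make_tx("O1", exons=[(430, 480)], cds=(430, 480)),  # cds hit -> 0
    make_tx("O2", exons=[(300, 420), (500, 550)], cds=(300, 550)),  # intronic -> 1
    make_tx("O3", strand="-", exons=[(350, 550)], cds=(350, 420)),  # opposite UTR -> 1
    make_tx("O4", exons=[(700, 900)], cds=(750, 850)),  # no overlap
]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(subset=st.lists(st.sampled_from(_OTHERS), max_size=4, unique_by=lambda t: t.transcript_id),
       extra=st.sampled_from(_OTHERS))
def test_monotonicity_and_order_invariance(subset, extra):
    """Adding a transcript never raises the score; order never matters."""
    base = confidence_score(VAR, PREFERRED, subset, "utr3").value
    grown = confidence_score(VAR, PREFERRED, subset + [extra], "utr3").value
    assert grown <= base
    reordered = confidence_score(VAR, PREFERRED, list(reversed(subset)), "utr3").value
    assert reordered == base


# ---------------------------------------------------------------------------
# resolve_inclusion
# ---------------------------------------------------------------------------


def _calls(**regions):
    from utrcensus.transcript_context import RegionCall

    return {tid: RegionCall(tid, region) for tid, region in regions.items()}


PRINCIPAL_FLAGS = {"PREF": {TranscriptFlag.APPRIS_PRINCIPAL}}


def test_include_clean_germline_snv():
    decision = resolve_inclusion(VAR, _calls(PREF=Region.UTR3_EXONIC), PRINCIPAL_FLAGS)
    assert decision.include and decision.reason == "included"


def test_exclude_mane_select_cds_conflict():
    # UTR on the principal but missense (CDS) on the MANE Select transcript
    flags = {
        "PREF": {TranscriptFlag.APPRIS_PRINCIPAL},
        "MANE": {TranscriptFlag.MANE_SELECT},
    }
    decision = resolve_inclusion(
        VAR, _calls(PREF=Region.UTR3_EXONIC, MANE=Region.CDS_EXONIC), flags
    )
    assert not decision.include and decision.reason == "mane_conflict"


def test_exclude_mane_plus_clinical_conflict_despite_select_utr():
    # UTR on MANE Select + principal, non-UTR on MANE Plus Clinical,
    # insufficient evidence -> excluded
    flags = {
        "PREF": {TranscriptFlag.APPRIS_PRINCIPAL, TranscriptFlag.MANE_SELECT},
        "PLUS": {TranscriptFlag.MANE_PLUS_CLINICAL},
    }
    decision = resolve_inclusion(
        VAR,
        _calls(PREF=Region.UTR5_EXONIC, PLUS=Region.CDS_EXONIC),
        flags,
        evidence_context=EvidenceContext.INSUFFICIENT,
    )
    assert not decision.include and decision.reason == "mane_conflict"


def test_mane_conflict_excludes_even_with_utr_evidence_by_default():
    flags = {
        "PREF": {TranscriptFlag.APPRIS_PRINCIPAL},
        "MANE": {TranscriptFlag.MANE_SELECT},
    }
    calls = _calls(PREF=Region.UTR3_EXONIC, MANE=Region.CDS_EXONIC)
    strict = resolve_inclusion(
        VAR, calls, flags, evidence_context=EvidenceContext.UTR_MECHANISM_SUPPORTED
    )
    assert not strict.include  # conservative default
    overridden = resolve_inclusion(
        VAR, calls, flags,
        evidence_context=EvidenceContext.UTR_MECHANISM_SUPPORTED,
        allow_mane_override=True,
    )
    assert overridden.include


def test_alternative_conflict_depends_on_evidence():
    flags = {
        "PREF": {TranscriptFlag.APPRIS_PRINCIPAL},
        "ALT": {TranscriptFlag.APPRIS_ALTERNATIVE},
    }
    calls = _calls(PREF=Region.UTR3_EXONIC, ALT=Region.CDS_EXONIC)
    for context in (EvidenceContext.INSUFFICIENT, EvidenceContext.NON_UTR_SUPPORTED):
        assert not resolve_inclusion(VAR, calls, flags, context).include
    assert resolve_inclusion(
        VAR, calls, flags, EvidenceContext.UTR_MECHANISM_SUPPORTED
    ).include


def test_deep_intronic_on_alternative_is_not_a_conflict():
    flags = {
        "PREF": {TranscriptFlag.APPRIS_PRINCIPAL},
        "ALT": {TranscriptFlag.APPRIS_ALTERNATIVE},
    }
    decision = resolve_inclusion(
        VAR, _calls(PREF=Region.UTR3_EXONIC, ALT=Region.INTRONIC), flags
    )
    assert decision.include


def test_exclude_not_utr_on_principal():
    decision = resolve_inclusion(VAR, _calls(PREF=Region.CDS_EXONIC), PRINCIPAL_FLAGS)
    assert not decision.include and decision.reason == "not_utr_on_principal"


def test_exclude_somatic_and_excluded_types():
    somatic = VariantRecord(
        chrom="1", pos=450, ref="A", alt="G", origin=Origin.SOMATIC
    )
    decision = resolve_inclusion(
        somatic, _calls(PREF=Region.UTR3_EXONIC), PRINCIPAL_FLAGS
    )
    assert not decision.include and decision.reason == "somatic"

    repeat = VariantRecord(
        chrom="1", pos=450, ref="A", alt="A", symbolic_type="repeat_expansion",
        clinvar_class=ClinvarClass.P,
    )
    decision = resolve_inclusion(
        repeat, _calls(PREF=Region.UTR3_EXONIC), PRINCIPAL_FLAGS
    )
    assert not decision.include and decision.reason == "excluded_type"


def test_missing_principal_call_is_an_error():
    with pytest.raises(ValueError, match="principal"):
        resolve_inclusion(VAR, _calls(OTHER=Region.UTR3_EXONIC), {"OTHER": set()})
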
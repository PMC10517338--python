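"""Transcript-context resolution for UTR variants.

Each candidate variant is located on every overlapping transcript
(5'/3' UTR exon, CDS exon, intron, splice-proximal intron) and assigned a
confidence score in {0, 1, 2} reflecting how unambiguously its effect is
mediated through the UTR of the preferred transcript:

* score 2 — UTR-exonic on the preferred transcript and nowhere else does
  the variant touch another transcript;
* score 1 — also falls in an intron or the opposite UTR of some other
  transcript;
* score 0 — falls in a CDS exon, or within ``splice_window`` bases of an
  intron/exon boundary (a putative splicing variant), on another transcript.

Inclusion/exclusion then applies transcript-priority rules: a variant is
kept only when UTR-exonic on the designated APPRIS principal transcript,
with no non-UTR impact on a MANE Select / Plus Clinical transcript of the
same gene, and non-UTR impacts on APPRIS alternative transcripts are
disqualifying unless curated evidence supports the UTR mechanism.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import Origin, VariantRecord

__all__ = [
    "Region",
    "EvidenceContext",
    "TranscriptFlag",
    "TranscriptModel",
    "RegionCall",
    "ConfidenceScore",
    "InclusionDecision",
    "ContextConfig",
    "NotEligibleError",
    "locate_variant",
    "confidence_score",
    "resolve_inclusion",
]


class Region(enum.Enum):
    UTR5_EXONIC = "utr5_exonic"
    UTR3_EXONIC = "utr3_exonic"
    CDS_EXONIC = "cds_exonic"
    SPLICE_PROXIMAL_INTRONIC = "splice_proximal_intronic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    SPANNING = "spanning"


class EvidenceContext(enum.Enum):
    UTR_MECHANISM_SUPPORTED = "utr_mechanism_supported"
    NON_UTR_SUPPORTED = "non_utr_supported"
    INSUFFICIENT = "insufficient"


class TranscriptFlag(enum.Enum):
    CLINVAR_PREFERRED = "clinvar_preferred"
    APPRIS_PRINCIPAL = "appris_principal"
    APPRIS_ALTERNATIVE = "appris_alternative"
    MANE_SELECT = "mane_select"
    MANE_PLUS_CLINICAL = "mane_plus_clinical"


class NotEligibleError(ValueError):
    """The variant does not satisfy an operation's precondition."""


@dataclass
class ContextConfig:
    """Tunable windows for transcript-context classification.

    ``splice_window`` is the distance (bases) from an intron/exon boundary
    within which an intronic variant counts as splice-proximal.
    """

    splice_window: int = 8


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS/UTR structure for one transcript.

    ``exons`` are 1-based inclusive genomic intervals sorted by start;
    ``cds`` is the genomic span (start, end) of the coding sequence, or
    None for non-coding transcripts. UTR interval lists are derived on
    construction: exonic territory outside the CDS span, split by genomic
    side of the CDS, with strand deciding which side is the 5'UTR.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    flags: set[TranscriptFlag] = field(default_factory=set)
    utr5: list[tuple[int, int]] = field(init=False)
    utr3: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        self.utr5, self.utr3 = self._derive_utrs()

    @property
    def coding(self) -> bool:
        return self.cds is not None

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def _derive_utrs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        if self.cds is None:
            return [], []
        cds_start, cds_end = self.cds
        left: list[tuple[int, int]] = []
        right: list[tuple[int, int]] = []
        for s, e in self.exons:
            if e < cds_start:
                left.append((s, e))
            elif s < cds_start:
                left.append((s, cds_start - 1))
            if s > cds_end:
                right.append((s, e))
            elif e > cds_end:
                right.append((cds_end + 1, e))
        if self.strand == "+":
            return left, right
        return right, left

    def cds_exonic_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces inside the CDS span (the coding exonic territory)."""
        if self.cds is None:
            return []
        cds_start, cds_end = self.cds
        out = []
        for s, e in self.exons:
            lo, hi = max(s, cds_start), min(e, cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


@dataclass(frozen=True)
class RegionCall:
    transcript_id: str
    region: Region


@dataclass(frozen=True)
class ConfidenceScore:
    value: int  # in {0, 1, 2}
    rationale: tuple[RegionCall, ...]


@dataclass(frozen=True)
class InclusionDecision:
    include: bool
    reason: str


def _variant_span(variant: VariantRecord) -> tuple[int, int, bool]:
    """Return (start, end, is_insertion) of the reference footprint.

    A pure insertion (anchored single-base ref, alt extending it) has no
    reference footprint of its own; it is located by its two flanking
    bases, both of which must fall in the same interval for an exonic call.
    """
    is_insertion = (
        len(variant.ref) == 1
        and len(variant.alt) > 1
        and variant.alt.startswith(variant.ref)
    )
    if is_insertion:
        return variant.pos, variant.pos + 1, True
    return variant.pos, variant.end, False


def _contained(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(s <= start and end <= e for s, e in intervals)


def locate_variant(
    variant: VariantRecord,
    transcript: TranscriptModel,
    config: ContextConfig | None = None,
) -> RegionCall:
    """Classify the variant's region on one transcript.

    UTR/CDS-exonic calls require the full reference span to sit inside a
    single interval of that class; spans crossing any UTR/CDS or
    exon/intron boundary are ``spanning``. Variants on another chromosome
    or wholly outside the transcript span are ``intergenic``.
    """
    config = config or ContextConfig()
    tid = transcript.transcript_id
    if not transcript.coding:
        raise NotEligibleError(
            f"{tid} is non-coding (no CDS) and is excluded from UTR region logic"
        )
    if variant.chrom != transcript.chrom:
        return RegionCall(tid, Region.INTERGENIC)

    start, end, _ = _variant_span(variant)
    tx_start, tx_end = transcript.span
    if end < tx_start or start > tx_end:
        return RegionCall(tid, Region.INTERGENIC)

    if _contained(start, end, transcript.utr5):
        return RegionCall(tid, Region.UTR5_EXONIC)
    if _contained(start, end, transcript.utr3):
        return RegionCall(tid, Region.UTR3_EXONIC)
    if _contained(start, end, transcript.cds_exonic_intervals()):
        return RegionCall(tid, Region.CDS_EXONIC)

    for intron_start, intron_end in transcript.introns():
        if intron_start <= start and end <= intron_end:
            boundary_distance = min(
                start - intron_start + 1, intron_end - end + 1
            )
            if boundary_distance <= config.splice_window:
                return RegionCall(tid, Region.SPLICE_PROXIMAL_INTRONIC)
            return RegionCall(tid, Region.INTRONIC)

    return RegionCall(tid, Region.SPANNING)


_TARGET_REGION = {"utr5": Region.UTR5_EXONIC, "utr3": Region.UTR3_EXONIC}
_OPPOSITE_REGION = {"utr5": Region.UTR3_EXONIC, "utr3": Region.UTR5_EXONIC}

#: Regions on another transcript that drop the confidence score to 0
_SCORE0_REGIONS = {Region.CDS_EXONIC, Region.SPLICE_PROXIMAL_INTRONIC}


def confidence_score(
    variant: VariantRecord,
    preferred: TranscriptModel,
    others: Sequence[TranscriptModel],
    target_region: str,
    config: ContextConfig | None = None,
) -> ConfidenceScore:
    """Assign the initial confidence score {0, 1, 2} for a UTR variant.

    Requires the variant to be UTR-exonic for ``target_region`` ("utr5" or
    "utr3") on the preferred transcript. Score 0 if any other transcript
    yields a CDS-exonic or splice-proximal call; else 1 if any yields an
    intronic or opposite-UTR exonic call; else 2. Spanning calls on other
    transcripts are conservatively treated at the severity of their worst
    constituent (CDS-exonic), i.e. score 0.
    """
    config = config or ContextConfig()
    if target_region not in _TARGET_REGION:
        raise ValueError(f"target_region must be 'utr5' or 'utr3', got {target_region!r}")
    preferred_call = locate_variant(variant, preferred, config)
    if preferred_call.region is not _TARGET_REGION[target_region]:
        raise NotEligibleError(
            f"variant is {preferred_call.region.value}, not "
            f"{_TARGET_REGION[target_region].value}, on preferred transcript "
            f"{preferred.transcript_id}"
        )

    calls = [
        locate_variant(variant, t, config)
        for t in others
        if t.transcript_id != preferred.transcript_id and t.coding
    ]
    demote_to_0 = tuple(
        c for c in calls if c.region in _SCORE0_REGIONS or c.region is Region.SPANNING
    )
    if demote_to_0:
        return ConfidenceScore(0, demote_to_0)
    demote_to_1 = tuple(
        c
        for c in calls
        if c.region is Region.INTRONIC or c.region is _OPPOSITE_REGION[target_region]
    )
    if demote_to_1:
        return ConfidenceScore(1, demote_to_1)
    return ConfidenceScore(2, (preferred_call,))


#: include/exclude reason codes, in precedence order
REASON_NOT_UTR_ON_PRINCIPAL = "not_utr_on_principal"
REASON_MANE_CONFLICT = "mane_conflict"
REASON_ALTERNATIVE_CONFLICT = "alternative_conflict"
REASON_SOMATIC = "somatic"
REASON_EXCLUDED_TYPE = "excluded_type"
REASON_INCLUDED = "included"

_UTR_REGIONS = {Region.UTR5_EXONIC, Region.UTR3_EXONIC}

#: region calls that constitute a non-UTR *impact* on a transcript; a deep
#: intronic position affects no product of that transcript and conflicts
#: with nothing
_NON_UTR_IMPACTS = {Region.CDS_EXONIC, Region.SPLICE_PROXIMAL_INTRONIC, Region.SPANNING}

#: variant types excluded from curation outright
EXCLUDED_VARIANT_TYPES = {"repeat_expansion", "multi_region_SV", "CNV"}


def resolve_inclusion(
    variant: VariantRecord,
    calls: Mapping[str, RegionCall],
    flags: Mapping[str, set[TranscriptFlag]],
    evidence_context: EvidenceContext = EvidenceContext.INSUFFICIENT,
    allow_mane_override: bool = False,
) -> InclusionDecision:
    """Apply the transcript-priority inclusion/exclusion rules.

    ``calls`` maps transcript_id -> RegionCall and must include the APPRIS
    principal transcript. Exclusions, in order of precedence:

    1. variant type is a repeat expansion or multi-region SV / CNV;
    2. somatic origin;
    3. not UTR-exonic on the APPRIS principal;
    4. non-UTR call on any MANE Select / Plus Clinical transcript
       (by default disqualifying regardless of evidence; set
       ``allow_mane_override`` to let curated UTR-mechanism evidence keep
       the variant);
    5. non-UTR call on an APPRIS alternative transcript, unless curated
       evidence supports the UTR mechanism.
    """
    principal_ids = [
        tid for tid, fl in flags.items() if TranscriptFlag.APPRIS_PRINCIPAL in fl
    ]
    principal_calls = [calls[tid] for tid in principal_ids if tid in calls]
    if not principal_calls:
        raise ValueError("calls must include the APPRIS principal transcript")

    if variant.symbolic_type in EXCLUDED_VARIANT_TYPES:
        return InclusionDecision(False, REASON_EXCLUDED_TYPE)
    if variant.origin is Origin.SOMATIC:
        return InclusionDecision(False, REASON_SOMATIC)
    if not any(c.region in _UTR_REGIONS for c in principal_calls):
        return InclusionDecision(False, REASON_NOT_UTR_ON_PRINCIPAL)

    for tid, call in calls.items():
        fl = flags.get(tid, set())
        is_mane = fl & {TranscriptFlag.MANE_SELECT, TranscriptFlag.MANE_PLUS_CLINICAL}
        if is_mane and call.region in _NON_UTR_IMPACTS:
            if not (
                allow_mane_override
                and evidence_context is EvidenceContext.UTR_MECHANISM_SUPPORTED
            ):
                return InclusionDecision(False, REASON_MANE_CONFLICT)

    for tid, call in calls.items():
        fl = flags.get(tid, set())
        if (
            TranscriptFlag.APPRIS_ALTERNATIVE in fl
            and call.region in _NON_UTR_IMPACTS
            and evidence_context
            in (EvidenceContext.NON_UTR_SUPPORTED, EvidenceContext.INSUFFICIENT)
        ):
            return InclusionDecision(False, REASON_ALTERNATIVE_CONFLICT)

    return InclusionDecision(True, REASON_INCLUDED)
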
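"""Population-frequency, significance, and variant-type filters.

The filtering funnel keeps only pathogenic / likely pathogenic (or
P-vs-LP-conflicting) records, discards anything with a subpopulation
allele frequency above the benign-evidence threshold (strictly > 0.05 by
default), and partitions the survivors into a variant-type taxonomy
(SNV / indel / delins / SV / CNV / repeat expansion). Tandem-repeat
alleles are banded by repeat count, with the default bands following the
myotonic-dystrophy (DMPK CTG) convention: 5-34 normal, 35-49 premutation,
>50 fully penetrant. A count of exactly 50 falls in none of the default
bands and reports ``unclassified`` — the bands are config-editable for
annotations that close that gap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .io_formats import ClinvarClass, VariantRecord

__all__ = [
    "FilterConfig",
    "VariantType",
    "UNCLASSIFIED_BAND",
    "filter_significance",
    "filter_allele_frequency",
    "classify_variant_type",
    "classify_repeat_allele",
    "write_filter_report",
]

#: label returned when a repeat count falls outside every configured band
UNCLASSIFIED_BAND = "unclassified"

#: maximum net length (bases) for an indel; longer events are SVs
_DEFAULT_SV_MIN_LEN = 51


class VariantType(enum.Enum):
    SNV = "SNV"
    INDEL = "indel"
    DELINS = "delins"
    SV = "SV"
    CNV = "CNV"
    REPEAT_EXPANSION = "repeat_expansion"


@dataclass
class FilterConfig:
    """Thresholds for the filtering funnel.

    ``af_discard_threshold`` (default 0.05): a record with any
    subpopulation AF strictly above this is discarded as effectively
    benign. ``benign_min_af`` (default 0.01): the *looser* threshold used
    when recruiting putative-benign benchmark variants — deliberately a
    separate knob from the discard threshold. ``repeat_bands`` are
    (label, min_repeats, max_repeats) with inclusive bounds; max None
    means unbounded.
    """

    af_discard_threshold: float = 0.05
    benign_min_af: float = 0.01
    sv_min_len: int = _DEFAULT_SV_MIN_LEN
    repeat_bands: list[tuple[str, int, int | None]] = field(
        default_factory=lambda: [
            ("normal", 5, 34),
            ("premutation", 35, 49),
            ("fully_penetrant", 51, None),
        ]
    )

    def __post_init__(self) -> None:
        if not 0 < self.benign_min_af < self.af_discard_threshold <= 1:
            raise ValueError(
                "must satisfy 0 < benign_min_af < af_discard_threshold <= 1"
            )
        prev_max = -1
        for label, lo, hi in self.repeat_bands:
            if lo <= prev_max:
                raise ValueError(f"repeat bands overlap or are unordered at {label!r}")
            if hi is not None:
                if hi < lo:
                    raise ValueError(f"band {label!r} has max < min")
                prev_max = hi
            else:
                prev_max = float("inf")  # open-ended band must be last

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "repeat_bands" in raw:
            raw["repeat_bands"] = [
                (b["label"], b["min_repeats"], b.get("max_repeats")) for b in raw["repeat_bands"]
            ]
        return cls(**raw)


_KEPT_CLASSES = {ClinvarClass.P, ClinvarClass.LP, ClinvarClass.P_AND_LP_CONFLICTING}


def filter_significance(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep only P, LP, and P-vs-LP-conflicting records (order-preserving)."""
    return [r for r in records if r.clinvar_class in _KEPT_CLASSES]


def filter_allele_frequency(
    records: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Discard records with any subpopulation AF strictly above threshold.

    Records without AF data are kept: absence of population observations
    is treated as evidence of rarity, not of commonness.
    """
    config = config or FilterConfig()
    kept = []
    for rec in records:
        for label, value in rec.af.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"allele frequency {label}={value} outside [0, 1] for {rec.key}"
                )
        afs = rec.subpopulation_afs
        if afs and max(afs.values()) > config.af_discard_threshold:
            continue
        kept.append(rec)
    return kept


def _trim_alleles(ref: str, alt: str) -> tuple[str, str]:
    """Strip the common prefix then common suffix (left-normalization)."""
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    ref, alt = ref[i:], alt[i:]
    j = 0
    while j < min(len(ref), len(alt)) and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]:
        j += 1
    if j:
        ref, alt = ref[:-j], alt[:-j]
    return ref, alt


def classify_variant_type(
    ref: str | None,
    alt: str | None,
    symbolic_info: str | None = None,
    config: FilterConfig | None = None,
) -> VariantType:
    """Assign a variant-type label from alleles or a symbolic descriptor.

    SNV: single mismatched base. Pure insertion/deletion: indel if the net
    length (max(len(ref), len(alt)) - 1 on normalized alleles) is below
    ``sv_min_len``, SV otherwise. delins: both alleles change and neither
    is a prefix of the other. Symbolic descriptors ("CNV",
    "repeat_expansion") win over allele strings.
    """
    config = config or FilterConfig()
    if symbolic_info is not None:
        if symbolic_info == "CNV":
            return VariantType.CNV
        if symbolic_info == "repeat_expansion":
            return VariantType.REPEAT_EXPANSION
        return VariantType.SV
    if ref is None or alt is None:
        raise ValueError("ref and alt required for non-symbolic variants")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}): not a variant")
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    t_ref, t_alt = _trim_alleles(ref, alt)
    if not t_ref or not t_alt:
        net = max(len(t_ref), len(t_alt))
        return VariantType.INDEL if net < config.sv_min_len else VariantType.SV
    return VariantType.DELINS


def classify_repeat_allele(
    repeat_count: int, config: FilterConfig | None = None
) -> str:
    """Band a tandem-repeat allele by repeat count.

    Returns the label of the unique band containing the count, or
    ``unclassified`` when no band covers it.
    """
    if repeat_count < 0:
        raise ValueError("repeat_count must be >= 0")
    config = config or FilterConfig()
    for label, lo, hi in config.repeat_bands:
        if lo <= repeat_count and (hi is None or repeat_count <= hi):
            return label
    return UNCLASSIFIED_BAND


def write_filter_report(
    records: Sequence[VariantRecord],
    kept: Sequence[VariantRecord],
    path: str | Path,
    reason: str,
) -> None:
    """Write a per-record TSV report with keep/drop reason codes."""
    kept_keys = {r.key for r in kept}
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdecision\treason\n")
        for rec in records:
            decision = "keep" if rec.key in kept_keys else "drop"
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t{decision}\t"
                f"{reason if decision == 'drop' else ''}\n"
            )
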
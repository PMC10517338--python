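"""The curated census of P/LP UTR variants and its summary statistics.

The packaged fixtures hold the 26 3'UTR and 68 5'UTR variants classified
as pathogenic or likely pathogenic after evidence curation, each with its
transcript HGVS (on the APPRIS principal transcript), gene, ClinVar
classification, study classification, and proposed molecular mechanism.
Fixtures are versioned data with recorded checksums; this module loads
them, stratifies by mechanism, cross-tabulates study-vs-ClinVar
classifications, and summarizes the implicated genes.
"""

from __future__ import annotations

import enum
import hashlib
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import ClinvarClass, FormatError, UtrRegion, parse_hgvs_utr
from . import stats_eval

__all__ = [
    "Mechanism",
    "StudyClass",
    "CensusEntry",
    "CrossTab",
    "IntegrityError",
    "MECHANISM_SIDE",
    "MECHANISM_ALIASES",
    "load_census",
    "stratify_mechanism",
    "cross_tabulate",
    "unique_genes",
    "compare_gene_metric",
]


class IntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


class Mechanism(enum.Enum):
    MIRNA_BINDING = "mirna_binding"
    POLYADENYLATION_SIGNAL = "polyadenylation_signal"
    MRNA_STABILITY = "mrna_stability"
    SPLICING_3UTR = "splicing_3utr"
    SECONDARY_STRUCTURE = "secondary_structure"
    UORF_EXISTING = "uorf_existing"
    NOVEL_UPSTREAM_START = "novel_upstream_start"
    MRNA_PROTEIN_INTERACTION = "mrna_protein_interaction"
    PROMOTER_ACTIVITY = "promoter_activity"
    PROMOTER_METHYLATION = "promoter_methylation"
    SPLICING_5UTR = "splicing_5utr"
    UNDETERMINED = "undetermined"


class StudyClass(enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"


#: which UTR each mechanism can act in; UNDETERMINED is side-neutral
MECHANISM_SIDE: dict[Mechanism, str | None] = {
    Mechanism.MIRNA_BINDING: "utr3",
    Mechanism.POLYADENYLATION_SIGNAL: "utr3",
    Mechanism.MRNA_STABILITY: "utr3",
    Mechanism.SPLICING_3UTR: "utr3",
    Mechanism.SECONDARY_STRUCTURE: "utr3",
    Mechanism.UORF_EXISTING: "utr5",
    Mechanism.NOVEL_UPSTREAM_START: "utr5",
    Mechanism.MRNA_PROTEIN_INTERACTION: "utr5",
    Mechanism.PROMOTER_ACTIVITY: "utr5",
    Mechanism.PROMOTER_METHYLATION: "utr5",
    Mechanism.SPLICING_5UTR: "utr5",
    Mechanism.UNDETERMINED: None,
}

#: normalization of prose mechanism headers to the enum
MECHANISM_ALIASES: dict[str, Mechanism] = {
    "altered mirna binding": Mechanism.MIRNA_BINDING,
    "impact on polyadenylation signal": Mechanism.POLYADENYLATION_SIGNAL,
    "impact on mrna stability": Mechanism.MRNA_STABILITY,
    "altered splicing": Mechanism.SPLICING_3UTR,
    "impact on secondary structure": Mechanism.SECONDARY_STRUCTURE,
    "translation: impact on existing regulatory uorf": Mechanism.UORF_EXISTING,
    "translation: introduction of novel upstream start codon": Mechanism.NOVEL_UPSTREAM_START,
    "translation: altered mrna-protein interaction": Mechanism.MRNA_PROTEIN_INTERACTION,
    "transcription: altered promoter activity": Mechanism.PROMOTER_ACTIVITY,
    "transcription: altered promoter methylation": Mechanism.PROMOTER_METHYLATION,
    "transcription: splicing": Mechanism.SPLICING_5UTR,
    "undetermined mechanism": Mechanism.UNDETERMINED,
}

#: sha256 of the packaged fixtures, recorded when the tables were frozen
FIXTURE_CHECKSUMS = {
    "census_utr3.tsv": "f3e8eafba153f2956a7a49fcbe2514dd56585334b5b551133d51645a8e5e4a49",
    "census_utr5.tsv": "c3e4ac5562a10133efa05aa1362c5cc98f63916c9150bbdebec7df4e5016a004",
}

_SIDE_REGION = {"utr3": UtrRegion.THREE_PRIME_UTR, "utr5": UtrRegion.FIVE_PRIME_UTR}


@dataclass(frozen=True)
class CensusEntry:
    """One curated P/LP UTR variant (a row of the census tables)."""

    hgvs: str
    gene: str
    utr_side: str  # "utr3" or "utr5"
    clinvar_class: ClinvarClass
    study_class: StudyClass
    mechanism: Mechanism
    functional_evidence: bool | None = None

    def __post_init__(self) -> None:
        side = MECHANISM_SIDE[self.mechanism]
        if side is not None and side != self.utr_side:
            raise ValueError(
                f"mechanism {self.mechanism.value} is a {side} mechanism but "
                f"entry {self.hgvs} is {self.utr_side}"
            )


@dataclass(frozen=True)
class CrossTab:
    """Study-class x ClinVar-class contingency counts."""

    counts: Mapping[tuple[StudyClass, ClinvarClass], int]

    def total(self) -> int:
        return sum(self.counts.values())

    def row_total(self, study_class: StudyClass) -> int:
        return sum(v for (s, _), v in self.counts.items() if s is study_class)

    def get(self, study_class: StudyClass, clinvar_class: ClinvarClass) -> int:
        return self.counts.get((study_class, clinvar_class), 0)


def _normalize_mechanism(raw: str) -> Mechanism:
    try:
        return Mechanism(raw)
    except ValueError:
        key = raw.strip().lower()
        if key in MECHANISM_ALIASES:
            return MECHANISM_ALIASES[key]
        raise FormatError(f"unknown mechanism string {raw!r}")


def _load_fixture(name: str, verify_checksum: bool = True) -> pd.DataFrame:
    data = (resources.files("utrcensus") / "data" / name).read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        expected = FIXTURE_CHECKSUMS[name]
        if digest != expected:
            raise IntegrityError(
                f"fixture {name} checksum mismatch: {digest} != {expected}"
            )
    import io

    return pd.read_csv(io.BytesIO(data), sep="\t", dtype=str)


def load_census(side: str = "both", verify_checksum: bool = True) -> list[CensusEntry]:
    """Load the packaged census for one UTR side ("utr3", "utr5", or "both").

    Every HGVS string is checked to parse under the restricted UTR grammar
    and to agree with the declared UTR side; fixture checksums are verified
    unless disabled.
    """
    if side not in ("utr3", "utr5", "both"):
        raise ValueError(f"side must be 'utr3', 'utr5', or 'both', got {side!r}")
    names = {
        "utr3": ["census_utr3.tsv"],
        "utr5": ["census_utr5.tsv"],
        "both": ["census_utr3.tsv", "census_utr5.tsv"],
    }[side]
    entries: list[CensusEntry] = []
    for name in names:
        df = _load_fixture(name, verify_checksum=verify_checksum)
        for row in df.itertuples(index=False):
            fe = getattr(row, "functional_evidence", None)
            entry = CensusEntry(
                hgvs=row.hgvs,
                gene=row.gene,
                utr_side=row.utr_side,
                clinvar_class=ClinvarClass(row.clinvar_class),
                study_class=StudyClass(row.study_class),
                mechanism=_normalize_mechanism(row.mechanism),
                functional_evidence=None if pd.isna(fe) else fe == "1",
            )
            location = parse_hgvs_utr(entry.hgvs)
            if location.region is not _SIDE_REGION[entry.utr_side]:
                raise FormatError(
                    f"HGVS {entry.hgvs} side disagrees with utr_side={entry.utr_side}"
                )
            entries.append(entry)
    return entries


def stratify_mechanism(entries: Iterable[CensusEntry]) -> dict[Mechanism, int]:
    """Count entries per mechanism (counts partition the input)."""
    return dict(Counter(e.mechanism for e in entries))


def cross_tabulate(entries: Iterable[CensusEntry]) -> CrossTab:
    """Full study-class x ClinVar-class contingency table."""
    return CrossTab(dict(Counter((e.study_class, e.clinvar_class) for e in entries)))


def unique_genes(entries: Iterable[CensusEntry]) -> set[str]:
    """Deduplicated set of gene symbols in the census."""
    return {e.gene for e in entries}


def compare_gene_metric(
    group_a: Mapping[str, float] | Sequence[float],
    group_b: Mapping[str, float] | Sequence[float],
) -> "stats_eval.ComparisonResult":
    """Two-sided rank-sum comparison of a per-gene metric between groups.

    Accepts gene -> value mappings (or bare value sequences) — used for
    ClinVar P/LP counts per gene and LoF-intolerance (LOEUF-style)
    metrics.
    """
    values_a = list(group_a.values()) if isinstance(group_a, Mapping) else list(group_a)
    values_b = list(group_b.values()) if isinstance(group_b, Mapping) else list(group_b)
    if not values_a or not values_b:
        raise ValueError("both groups must be non-empty")
    return stats_eval.rank_sum_test(values_a, values_b)
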
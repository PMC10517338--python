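"""Readers and writers for the external formats the pipeline touches.

Covers ClinVar-style tab-delimited variant summaries, GTF/GFF3 transcript
annotation, allele-frequency tables, bedGraph/wiggle conservation tracks,
and a restricted HGVS parser for exonic UTR coordinates (``c.-N`` / ``c.*N``).

All internal coordinates are 1-based inclusive (GFF convention). BED-style
0-based half-open inputs (bedGraph) are converted at the parser boundary.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("utrcensus")

__all__ = [
    "ClinvarClass",
    "Origin",
    "UtrRegion",
    "EditType",
    "VariantRecord",
    "HgvsUtrLocation",
    "ConservationTrack",
    "FormatError",
    "HgvsParseError",
    "NotUtrVariantError",
    "DEFAULT_SIGNIFICANCE_MAP",
    "read_clinvar_summary",
    "parse_hgvs_utr",
    "read_transcripts",
    "read_transcript_flags",
    "read_af_table",
    "annotate_allele_frequencies",
    "read_conservation_track",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_vcf",
]


class FormatError(ValueError):
    """An input file violates its declared format."""


class HgvsParseError(ValueError):
    """An HGVS string cannot be parsed by the restricted UTR grammar."""


class NotUtrVariantError(HgvsParseError):
    """A syntactically valid HGVS string that does not denote an exonic UTR variant."""


class ClinvarClass(enum.Enum):
    P = "P"
    LP = "LP"
    P_AND_LP_CONFLICTING = "P_and_LP_conflicting"
    OTHER = "other"


class Origin(enum.Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"
    UNKNOWN = "unknown"


class UtrRegion(enum.Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"


class EditType(enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


#: Default mapping from ClinVar free-text significance to the internal enum.
#: ClinVar wording varies by release, so callers may pass their own table.
DEFAULT_SIGNIFICANCE_MAP: dict[str, ClinvarClass] = {
    "Pathogenic": ClinvarClass.P,
    "Likely pathogenic": ClinvarClass.LP,
    "Pathogenic/Likely pathogenic": ClinvarClass.P_AND_LP_CONFLICTING,
}


@dataclass
class VariantRecord:
    """One genomic variant with clinical and population-frequency metadata.

    ``af`` maps subpopulation labels to allele frequencies in [0, 1]; the
    reserved key ``"total"`` holds the cohort-wide frequency.
    """

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    hgvs: str = ""
    gene: str = ""
    clinvar_class: ClinvarClass = ClinvarClass.OTHER
    origin: Origin = Origin.UNKNOWN
    af: dict[str, float] = field(default_factory=dict)
    symbolic_type: str | None = None  # e.g. "CNV", "repeat_expansion" for symbolic SVs
    repeat_count: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.symbolic_type is None and (not self.ref or not self.alt):
            raise ValueError("ref and alt must be non-empty for non-symbolic records")
        for label, value in self.af.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"allele frequency {label}={value} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + max(len(self.ref), 1) - 1

    @property
    def total_af(self) -> float | None:
        return self.af.get("total")

    @property
    def subpopulation_afs(self) -> dict[str, float]:
        return {k: v for k, v in self.af.items() if k != "total"}


@dataclass(frozen=True)
class HgvsUtrLocation:
    """A transcript-level UTR coordinate parsed from an HGVS ``c.`` string.

    Offsets are positive integers counted from the CDS start (5'UTR,
    ``c.-N``) or from the CDS end (3'UTR, ``c.*N``), normalized so that
    ``start_offset <= end_offset`` regardless of print order.
    """

    transcript_id: str
    region: UtrRegion
    start_offset: int
    end_offset: int
    edit: EditType
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.start_offset <= self.end_offset):
            raise ValueError("offsets must satisfy 0 < start_offset <= end_offset")


# ---------------------------------------------------------------------------
# ClinVar-style summary
# ---------------------------------------------------------------------------

REQUIRED_SUMMARY_COLUMNS = (
    "VariationID",
    "Name",
    "GeneSymbol",
    "ClinicalSignificance",
    "ReviewStatus",
    "Chromosome",
    "PositionVCF",
    "ReferenceAlleleVCF",
    "AlternateAlleleVCF",
)


def read_clinvar_summary(
    path: str | Path,
    significance_map: Mapping[str, ClinvarClass] = DEFAULT_SIGNIFICANCE_MAP,
) -> list[VariantRecord]:
    """Read a ClinVar-style tab-delimited variant summary.

    Significance strings absent from ``significance_map`` collapse to
    :attr:`ClinvarClass.OTHER`. Rows whose coordinates cannot be interpreted
    (non-integer position, missing alleles) are skipped with a log message.
    Multi-allelic rows (comma-separated alternate alleles) are split into
    biallelic records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        sig = getattr(row, "ClinicalSignificance")
        cls = significance_map.get(sig, ClinvarClass.OTHER)
        origin = _parse_origin(getattr(row, "OriginSimple", ""))
        try:
            pos = int(getattr(row, "PositionVCF"))
        except (TypeError, ValueError):
            logger.warning(
                "skipping row %s: malformed position %r",
                getattr(row, "VariationID"),
                getattr(row, "PositionVCF"),
            )
            continue
        ref = getattr(row, "ReferenceAlleleVCF").strip()
        alts = [a.strip() for a in getattr(row, "AlternateAlleleVCF").split(",")]
        if not ref or not all(alts):
            logger.warning(
                "skipping row %s: empty allele", getattr(row, "VariationID")
            )
            continue
        for alt in alts:
            try:
                records.append(
                    VariantRecord(
                        chrom=getattr(row, "Chromosome"),
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        hgvs=getattr(row, "Name"),
                        gene=getattr(row, "GeneSymbol"),
                        clinvar_class=cls,
                        origin=origin,
                    )
                )
            except ValueError as exc:
                logger.warning(
                    "skipping row %s: %s", getattr(row, "VariationID"), exc
                )
    return records


def _parse_origin(text: str) -> Origin:
    text = (text or "").strip().lower()
    if "somatic" in text:
        return Origin.SOMATIC
    if "germline" in text:
        return Origin.GERMLINE
    return Origin.UNKNOWN


# ---------------------------------------------------------------------------
# HGVS UTR coordinates
# ---------------------------------------------------------------------------

_HGVS_RE = re.compile(
    r"""^(?P<tx>[A-Za-z][A-Za-z0-9_]*\.\d+)     # versioned accession
        (?:\([A-Za-z0-9-]+\))?                  # optional gene in parentheses
        :c\.
        (?P<body>.+)$""",
    re.VERBOSE,
)

_POS_RE = re.compile(r"^(?P<prefix>[-*])(?P<offset>\d+)(?P<intron>[+-]\d+)?$")

_EDIT_RES: tuple[tuple[EditType, re.Pattern[str]], ...] = (
    (EditType.SUBSTITUTION, re.compile(r"^(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$")),
    (EditType.DELINS, re.compile(r"^delins(?P<alt>[ACGTN]+)$")),
    (EditType.DELETION, re.compile(r"^del(?P<ref>[ACGTN]*)$")),
    (EditType.DUPLICATION, re.compile(r"^dup(?P<ref>[ACGTN]*)$")),
    (EditType.INSERTION, re.compile(r"^ins(?P<alt>[ACGTN]+)$")),
)


def parse_hgvs_utr(hgvs: str) -> HgvsUtrLocation:
    """Parse a transcript HGVS string restricted to exonic UTR coordinates.

    Accepts ``c.-N`` (5'UTR) and ``c.*N`` (3'UTR) positions, single or
    ranged, with substitution / del / dup / ins / delins edits. Coding
    positions (no prefix) and intronic offsets (``c.-15+3``) raise
    :class:`NotUtrVariantError`; anything else unparseable raises
    :class:`HgvsParseError`.
    """
    m = _HGVS_RE.match(hgvs.strip())
    if m is None:
        raise HgvsParseError(f"cannot parse HGVS string: {hgvs!r}")
    tx, body = m.group("tx"), m.group("body")

    # split coordinate part from the edit description
    coord_m = re.match(
        r"^(?P<p1>[-*]?\d+(?:[+-]\d+)?)(?:_(?P<p2>[-*]?\d+(?:[+-]\d+)?))?(?P<edit>.*)$",
        body,
    )
    if coord_m is None or not coord_m.group("edit"):
        raise HgvsParseError(f"cannot parse HGVS coordinate/edit in {hgvs!r}")

    positions = [coord_m.group("p1")]
    if coord_m.group("p2") is not None:
        positions.append(coord_m.group("p2"))

    parsed = []
    for p in positions:
        pm = _POS_RE.match(p)
        if pm is None:
            if re.match(r"^\d", p):
                raise NotUtrVariantError(
                    f"coding-region coordinate in {hgvs!r}: not a UTR variant"
                )
            raise HgvsParseError(f"cannot parse position {p!r} in {hgvs!r}")
        if pm.group("intron"):
            raise NotUtrVariantError(
                f"intronic offset in {hgvs!r}: not an exonic UTR variant"
            )
        parsed.append((pm.group("prefix"), int(pm.group("offset"))))

    prefixes = {pfx for pfx, _ in parsed}
    if len(prefixes) > 1:
        raise NotUtrVariantError(
            f"range spans the coding sequence in {hgvs!r}: not a UTR variant"
        )
    prefix = prefixes.pop()
    region = UtrRegion.THREE_PRIME_UTR if prefix == "*" else UtrRegion.FIVE_PRIME_UTR
    offsets = [off for _, off in parsed]
    start, end = min(offsets), max(offsets)

    edit_str = coord_m.group("edit")
    for edit_type, pattern in _EDIT_RES:
        em = pattern.match(edit_str)
        if em:
            groups = em.groupdict()
            return HgvsUtrLocation(
                transcript_id=tx,
                region=region,
                start_offset=start,
                end_offset=end,
                edit=edit_type,
                ref_allele=groups.get("ref") or None,
                alt_allele=groups.get("alt") or None,
            )
    raise HgvsParseError(f"unsupported edit description {edit_str!r} in {hgvs!r}")


# ---------------------------------------------------------------------------
# Transcript annotation (GTF / GFF3)
# ---------------------------------------------------------------------------


def read_transcripts(path: str | Path) -> list:
    """Read transcript models from a GTF or GFF3 file.

    Requires exon features; transcripts lacking CDS features are flagged
    non-coding (``TranscriptModel.coding == False``) and carry no UTRs —
    UTR territory is defined only relative to a coding sequence. UTR
    intervals are derived as exonic-minus-CDS, split by side of the CDS
    with the strand deciding which side is 5'.
    """
    import gffutils

    from .transcript_context import TranscriptModel

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
        verbose=False,
        # only exon/CDS features are consumed; skip GTF gene/transcript
        # extent inference (slow and chatty)
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}

    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            tid = _transcript_id_of(feat)
            if tid is None:
                continue
            store.setdefault(tid, []).append((feat.start, feat.end))
            if tid not in meta:
                meta[tid] = {
                    "gene": _gene_of(feat),
                    "strand": feat.strand,
                    "chrom": feat.seqid,
                }

    models = []
    for tid, ex in sorted(exons.items()):
        ex = sorted(ex)
        info = meta[tid]
        cds_intervals = sorted(cds.get(tid, []))
        if cds_intervals:
            cds_span = (cds_intervals[0][0], cds_intervals[-1][1])
        else:
            cds_span = None
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene=info["gene"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=ex,
                cds=cds_span,
            )
        )
    return models


def _transcript_id_of(feat) -> str | None:
    for key in ("transcript_id", "Parent"):
        if key in feat.attributes:
            value = feat.attributes[key]
            return value[0] if isinstance(value, list) else value
    return None


def _gene_of(feat) -> str:
    for key in ("gene_name", "gene_id", "gene"):
        if key in feat.attributes:
            value = feat.attributes[key]
            return value[0] if isinstance(value, list) else value
    return ""


def read_transcript_flags(path: str | Path) -> dict[str, set[str]]:
    """Read the transcript-flag sidecar TSV (columns: transcript_id, flag)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("transcript_id", "flag"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    flags: dict[str, set[str]] = {}
    for tid, flag in zip(df["transcript_id"], df["flag"]):
        flags.setdefault(tid, set()).add(flag)
    return flags


# ---------------------------------------------------------------------------
# Allele-frequency tables
# ---------------------------------------------------------------------------


def read_af_table(path: str | Path) -> dict[tuple[str, int, str, str], dict[str, float]]:
    """Read a TSV of allele frequencies keyed by (chrom, pos, ref, alt).

    Expected columns: chrom, pos, ref, alt, then one column per frequency
    ("total" plus subpopulation labels). Values must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = ("chrom", "pos", "ref", "alt")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    af_cols = [c for c in df.columns if c not in required]
    table: dict[tuple[str, int, str, str], dict[str, float]] = {}
    for row in df.itertuples(index=False):
        afs = {}
        for col in af_cols:
            value = getattr(row, col)
            if pd.isna(value):
                continue
            value = float(value)
            if not 0.0 <= value <= 1.0:
                raise FormatError(
                    f"allele frequency {col}={value} outside [0, 1] at "
                    f"{row.chrom}:{row.pos}"
                )
            afs[col] = value
        table[(str(row.chrom), int(row.pos), row.ref, row.alt)] = afs
    return table


def annotate_allele_frequencies(
    records: Iterable[VariantRecord],
    af_table: Mapping[tuple[str, int, str, str], Mapping[str, float]],
) -> list[VariantRecord]:
    """Attach AF maps to records in place (absent keys leave af empty)."""
    out = list(records)
    for rec in out:
        afs = af_table.get(rec.key)
        if afs:
            rec.af = dict(afs)
    return out


# ---------------------------------------------------------------------------
# Conservation tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------


class ConservationTrack:
    """Position-indexed per-base score lookup over non-overlapping intervals.

    Intervals are stored 1-based inclusive. ``get`` returns ``None`` for
    uncovered positions (absence is a value, not an error).
    """

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._values: dict[str, list[float]] = {}
        self._pending: dict[str, list[tuple[int, int, float]]] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        """Add a 1-based inclusive interval [start, end] with a score."""
        if end < start:
            raise FormatError(f"empty interval {chrom}:{start}-{end}")
        self._pending.setdefault(chrom, []).append((start, end, value))

    def finalize(self) -> "ConservationTrack":
        for chrom, intervals in self._pending.items():
            intervals.sort()
            prev_end = 0
            for start, end, _ in intervals:
                if start <= prev_end:
                    raise FormatError(
                        f"overlapping intervals on {chrom} at position {start}"
                    )
                prev_end = end
            self._starts[chrom] = [iv[0] for iv in intervals]
            self._ends[chrom] = [iv[1] for iv in intervals]
            self._values[chrom] = [iv[2] for iv in intervals]
        self._pending.clear()
        return self

    def covers_chrom(self, chrom: str) -> bool:
        return chrom in self._starts

    def get(self, chrom: str, pos: int) -> float | None:
        """Score at a 1-based position, or None if uncovered."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos <= self._ends[chrom][i]:
            return self._values[chrom][i]
        return None

    def max_over(self, chrom: str, start: int, end: int) -> float | None:
        """Maximum score over [start, end]; None if fully uncovered."""
        scores = [s for p in range(start, end + 1) if (s := self.get(chrom, p)) is not None]
        return max(scores) if scores else None


def read_conservation_track(path: str | Path) -> ConservationTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) conservation track.

    bedGraph intervals are 0-based half-open and converted to 1-based
    inclusive; wiggle positions are already 1-based. Overlapping intervals
    raise :class:`FormatError`.
    """
    track = ConservationTrack()
    mode = "bedgraph"
    wig_chrom = ""
    wig_pos = wig_step = wig_span = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixedstep"
                wig_chrom = params["chrom"]
                wig_pos = int(params["start"])
                wig_step = int(params.get("step", 1))
                wig_span = int(params.get("span", 1))
                continue
            if line.startswith("variableStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                mode = "variablestep"
                wig_chrom = params["chrom"]
                wig_span = int(params.get("span", 1))
                continue
            fields = line.split()
            if mode == "bedgraph":
                if len(fields) != 4:
                    raise FormatError(f"malformed bedGraph line: {line!r}")
                chrom, start0, end0, value = fields
                track.add(chrom, int(start0) + 1, int(end0), float(value))
            elif mode == "fixedstep":
                track.add(wig_chrom, wig_pos, wig_pos + wig_span - 1, float(fields[0]))
                wig_pos += wig_step
            else:  # variableStep
                pos = int(fields[0])
                track.add(wig_chrom, pos, pos + wig_span - 1, float(fields[1]))
    return track.finalize()


# ---------------------------------------------------------------------------
# Variant serialization (TSV round-trip; VCF export)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs",
    "gene",
    "clinvar_class",
    "origin",
    "af",
    "symbolic_type",
    "repeat_count",
)


def write_variants_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records to TSV; the AF map is serialized as a JSON column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alt,
                    rec.hgvs,
                    rec.gene,
                    rec.clinvar_class.value,
                    rec.origin.value,
                    json.dumps(rec.af, sort_keys=True),
                    rec.symbolic_type or "",
                    "" if rec.repeat_count is None else rec.repeat_count,
                ]
            )


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Inverse of :func:`write_variants_tsv` (exact field round-trip)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _TSV_COLUMNS if c not in (reader.fieldnames or ())]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for row in reader:
            records.append(
                VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    hgvs=row["hgvs"],
                    gene=row["gene"],
                    clinvar_class=ClinvarClass(row["clinvar_class"]),
                    origin=Origin(row["origin"]),
                    af=json.loads(row["af"]),
                    symbolic_type=row["symbolic_type"] or None,
                    repeat_count=int(row["repeat_count"]) if row["repeat_count"] else None,
                )
            )
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path, assembly: str = "GRCh38") -> None:
    """Export records as a minimal sites-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={assembly}\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Total allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            info = [f"CLNSIG={rec.clinvar_class.value}"]
            if rec.gene:
                info.insert(0, f"GENE={rec.gene}")
            if rec.total_af is not None:
                info.append(f"AF={rec.total_af:g}")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                + ";".join(info)
                + "\n"
            )
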
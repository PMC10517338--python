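"""Benchmark assembly: putative-benign recruitment and group assignment.

A benchmark for one UTR side pairs the curated P/LP census with putative
benign variants: common variants (total allele frequency > 1% by
default — deliberately looser than the 5% discard threshold used when
filtering P/LP candidates) whose full span lies inside a UTR exon of a
transcript that itself harbors a P/LP census variant. Each P/LP entry is
then labeled model-matched or model-mismatched according to whether its
curated mechanism belongs to the mechanism set a given predictor was
designed for; variants with an undetermined mechanism are mismatched.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .census import CensusEntry, Mechanism
from .io_formats import VariantRecord
from .transcript_context import TranscriptModel
from .variant_filtering import FilterConfig

logger = logging.getLogger("utrcensus")

__all__ = [
    "Group",
    "BenchmarkItem",
    "BenchmarkDataset",
    "ModelMechanismMap",
    "DEFAULT_MODEL_MECHANISMS",
    "assemble_benign",
    "assign_groups",
    "write_benchmark_tsv",
]


class Group(enum.Enum):
    PLP_MATCHED = "plp_matched"
    PLP_MISMATCHED = "plp_mismatched"
    BENIGN = "benign"


@dataclass(frozen=True)
class BenchmarkItem:
    key: tuple | str  # variant key, or census HGVS for P/LP entries
    group: Group
    mechanism: Mechanism | None  # None for benign items


@dataclass(frozen=True)
class BenchmarkDataset:
    utr_side: str
    items: tuple[BenchmarkItem, ...]

    def size(self, group: Group) -> int:
        return sum(1 for i in self.items if i.group is group)


@dataclass
class ModelMechanismMap:
    """Which curated mechanisms a predictor is matched to, per UTR side."""

    model: str
    utr_side: str
    matched: set[Mechanism] = field(default_factory=set)

    @classmethod
    def from_yaml(cls, path: str | Path) -> dict[str, "ModelMechanismMap"]:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return {
            name: cls(
                model=name,
                utr_side=entry["utr_side"],
                matched={Mechanism(m) for m in entry["matched"]},
            )
            for name, entry in raw.items()
        }


#: Default model -> matched-mechanism sets. The transcription model's
#: matched set includes 5'UTR splicing (listed among transcription-level
#: mechanisms in the census) — an interpretive choice; the map is
#: configurable for users who read that boundary differently.
DEFAULT_MODEL_MECHANISMS: dict[str, ModelMechanismMap] = {
    "orf": ModelMechanismMap(
        model="orf",
        utr_side="utr5",
        matched={Mechanism.UORF_EXISTING, Mechanism.NOVEL_UPSTREAM_START},
    ),
    "stability": ModelMechanismMap(
        model="stability",
        utr_side="utr3",
        matched={Mechanism.POLYADENYLATION_SIGNAL, Mechanism.MRNA_STABILITY},
    ),
    "transcription": ModelMechanismMap(
        model="transcription",
        utr_side="utr5",
        matched={
            Mechanism.PROMOTER_ACTIVITY,
            Mechanism.PROMOTER_METHYLATION,
            Mechanism.SPLICING_5UTR,
        },
    ),
}


def assemble_benign(
    af_table: Mapping[tuple[str, int, str, str], Mapping[str, float]],
    transcripts_with_plp: Sequence[TranscriptModel],
    utr_side: str,
    config: FilterConfig | None = None,
) -> list[VariantRecord]:
    """Recruit putative-benign variants for one UTR side.

    Keeps variants from the AF table whose full reference span lies inside
    a UTR exon (of the requested side) of a transcript harboring a P/LP
    census variant, and whose total allele frequency is strictly above
    ``benign_min_af``. Duplicates shared across overlapping transcripts
    are collapsed by (chrom, pos, ref, alt). Output order follows genomic
    coordinates, so the result is deterministic given the inputs.
    """
    if utr_side not in ("utr3", "utr5"):
        raise ValueError(f"utr_side must be 'utr3' or 'utr5', got {utr_side!r}")
    config = config or FilterConfig()
    intervals_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for tx in transcripts_with_plp:
        for s, e in tx.utr3 if utr_side == "utr3" else tx.utr5:
            intervals_by_chrom.setdefault(tx.chrom, []).append((s, e))
    if not intervals_by_chrom:
        logger.warning("no qualifying transcripts with UTR exons; empty benign set")
        return []

    out: list[VariantRecord] = []
    seen: set[tuple] = set()
    for (chrom, pos, ref, alt), afs in sorted(af_table.items()):
        if (chrom, pos, ref, alt) in seen:
            continue
        total = afs.get("total")
        if total is None or not total > config.benign_min_af:
            continue
        end = pos + max(len(ref), 1) - 1
        if any(
            s <= pos and end <= e for s, e in intervals_by_chrom.get(chrom, ())
        ):
            seen.add((chrom, pos, ref, alt))
            out.append(
                VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, af=dict(afs))
            )
    return out


def assign_groups(
    census_entries: Iterable[CensusEntry],
    benign_variants: Iterable[VariantRecord],
    model: ModelMechanismMap,
) -> BenchmarkDataset:
    """Label census entries matched/mismatched for one model; benign as-is.

    A P/LP entry is ``plp_matched`` iff its mechanism is in the model's
    matched set (undetermined is always mismatched). All entries must be
    on the model's UTR side.
    """
    items: list[BenchmarkItem] = []
    for entry in census_entries:
        if entry.utr_side != model.utr_side:
            raise ValueError(
                f"census entry {entry.hgvs} is {entry.utr_side} but model "
                f"{model.model!r} evaluates {model.utr_side}"
            )
        group = (
            Group.PLP_MATCHED
            if entry.mechanism in model.matched
            else Group.PLP_MISMATCHED
        )
        items.append(BenchmarkItem(key=entry.hgvs, group=group, mechanism=entry.mechanism))
    for var in benign_variants:
        items.append(BenchmarkItem(key=var.key, group=Group.BENIGN, mechanism=None))
    return BenchmarkDataset(utr_side=model.utr_side, items=tuple(items))


def write_benchmark_tsv(
    dataset: BenchmarkDataset, model: ModelMechanismMap, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tgroup\tmechanism\tmodel\n")
        for item in dataset.items:
            key = item.key if isinstance(item.key, str) else ":".join(map(str, item.key))
            mech = item.mechanism.value if item.mechanism else ""
            fh.write(f"{key}\t{item.group.value}\t{mech}\t{model.model}\n")
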
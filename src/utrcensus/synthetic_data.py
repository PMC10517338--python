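"""Synthetic inputs with controllable effect structure.

Generates every input the pipeline consumes — multi-transcript gene
annotations engineered to trigger each confidence score and exclusion
reason, allele-frequency spectra straddling the 1% and 5% thresholds,
effect-score sets in which model-matched variants carry larger-magnitude
effects than mismatched or benign ones, and conservation tracks elevated
at pathogenic positions. All generators are pure functions of
(config, seed): a fixed seed reproduces byte-identical output.

The generator controls score *distributions*, not sequence biology: effect
signs are Rademacher(+/-1), mirroring that regulatory pathogenicity can
act through both expression increase and decrease, so the absolute value
of a score is the informative axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .benchmark import (
    BenchmarkDataset,
    DEFAULT_MODEL_MECHANISMS,
    ModelMechanismMap,
    assemble_benign,
    assign_groups,
)
from .census import CensusEntry, Mechanism, MECHANISM_SIDE, StudyClass
from .effect_scoring import EffectScore
from .io_formats import ClinvarClass, ConservationTrack, Origin, VariantRecord
from .transcript_context import TranscriptFlag, TranscriptModel
from .variant_filtering import FilterConfig

__all__ = [
    "SimulationConfig",
    "SimulatedAnnotation",
    "SimulatedBenchmark",
    "ANNOTATION_SCENARIOS",
    "simulate_annotation",
    "simulate_benchmark",
    "write_annotation_gtf",
    "write_conservation_bedgraph",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generators.

    Effect sizes are locations of the absolute raw score for each group
    (matched >= mismatched >= 0), on top of Gaussian noise with sd
    ``benign_effect_sd``; ``conservation_shift`` is the elevation of
    conservation scores at P/LP positions over the benign baseline.
    The allele-frequency spectrum is a long-tailed Beta whose mass
    straddles the 0.01 and 0.05 thresholds so both filters are exercised.
    """

    seed: int = 0
    n_genes: int = 12
    transcripts_per_gene: int = 2
    utr_exon_count_range: tuple[int, int] = (1, 2)
    n_plp: int = 60
    n_benign: int = 30
    matched_effect_size: float = 3.0
    mismatched_effect_size: float = 1.0
    benign_effect_sd: float = 1.0
    conservation_shift: float = 2.0
    af_spectrum: tuple[float, float] = (0.3, 4.0)  # Beta(a, b)

    def __post_init__(self) -> None:
        if not self.matched_effect_size >= self.mismatched_effect_size >= 0:
            raise ValueError(
                "must satisfy matched_effect_size >= mismatched_effect_size >= 0"
            )
        for name in ("n_genes", "transcripts_per_gene", "n_plp", "n_benign"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulatedVariantTruth:
    """A synthetic UTR variant with its engineered ground truth."""

    variant: VariantRecord
    gene: str
    scenario: str
    expected_confidence: int | None  # None when the scenario is an exclusion case
    expected_included: bool


@dataclass(frozen=True)
class SimulatedAnnotation:
    transcripts: tuple[TranscriptModel, ...]
    flags: dict[str, set[TranscriptFlag]]
    truths: tuple[SimulatedVariantTruth, ...]


#: scenario name -> (expected confidence score, expected inclusion)
#: With the default (insufficient) evidence context, any non-UTR impact on
#: an alternative transcript is disqualifying, so the score-0 overlap
#: scenarios are also exclusion scenarios.
ANNOTATION_SCENARIOS: dict[str, tuple[int | None, bool]] = {
    "no_overlap": (2, True),
    "cds_overlap": (0, False),
    "splice_proximal_overlap": (0, False),
    "intron_overlap": (1, True),
    "opposite_utr_overlap": (1, True),
    "mane_cds_conflict": (0, False),
    "somatic": (2, False),
    "repeat_expansion": (None, False),
}

_GENE_WINDOW = 10_000
_CHROM = "chrS"


def _principal_transcript(gene_idx: int, n_utr3_exons: int) -> TranscriptModel:
    base = gene_idx * _GENE_WINDOW
    # plus-strand gene: 5'UTR, CDS, then a 3'UTR split into n exons
    exons = [(base + 1000, base + 2000)]
    cds = (base + 1200, base + 1700)
    if n_utr3_exons == 2:
        # split the 3'UTR across an intron
        exons = [(base + 1000, base + 1900), (base + 2100, base + 2400)]
    return TranscriptModel(
        transcript_id=f"NM_9{gene_idx:05d}.1",
        gene=f"GENE{gene_idx}",
        chrom=_CHROM,
        strand="+",
        exons=exons,
        cds=cds,
    )


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Generate gene structures engineered to hit every confidence score.

    Each gene carries one APPRIS-principal transcript with a 3'UTR variant
    and, depending on the scenario cycled over genes, an overlapping
    alternative transcript that yields a known region call (CDS exon,
    splice-proximal intron, deep intron, opposite UTR), a MANE conflict, a
    somatic origin, or an excluded variant type. With
    ``transcripts_per_gene == 1`` every gene uses the no-overlap scenario
    and all variants score 2.
    """
    rng = np.random.default_rng(config.seed)
    scenarios = list(ANNOTATION_SCENARIOS)
    transcripts: list[TranscriptModel] = []
    flags: dict[str, set[TranscriptFlag]] = {}
    truths: list[SimulatedVariantTruth] = []

    for g in range(config.n_genes):
        if config.transcripts_per_gene <= 1:
            scenario = "no_overlap"
        else:
            scenario = scenarios[g % len(scenarios)]
        n_utr3_exons = int(
            rng.integers(config.utr_exon_count_range[0], config.utr_exon_count_range[1] + 1)
        )
        principal = _principal_transcript(g, min(n_utr3_exons, 2))
        transcripts.append(principal)
        flags[principal.transcript_id] = {
            TranscriptFlag.APPRIS_PRINCIPAL,
            TranscriptFlag.CLINVAR_PREFERRED,
            TranscriptFlag.MANE_SELECT,
        }
        base = g * _GENE_WINDOW
        pos = base + 1850  # inside the principal's first 3'UTR exon
        variant = VariantRecord(
            chrom=_CHROM,
            pos=pos,
            ref="A",
            alt="G",
            gene=principal.gene,
            clinvar_class=ClinvarClass.P,
        )

        other_id = f"NM_8{g:05d}.1"
        other: TranscriptModel | None = None
        other_flags: set[TranscriptFlag] = {TranscriptFlag.APPRIS_ALTERNATIVE}
        if scenario == "cds_overlap":
            other = TranscriptModel(
                other_id, principal.gene, _CHROM, "+",
                exons=[(base + 1700, base + 1950)], cds=(base + 1750, base + 1950),
            )
        elif scenario == "splice_proximal_overlap":
            other = TranscriptModel(
                other_id, principal.gene, _CHROM, "+",
                exons=[(base + 1600, base + 1845), (base + 1860, base + 1950)],
                cds=(base + 1600, base + 1950),
            )
        elif scenario == "intron_overlap":
            other = TranscriptModel(
                other_id, principal.gene, _CHROM, "+",
                exons=[(base + 1700, base + 1820), (base + 1900, base + 1950)],
                cds=(base + 1700, base + 1950),
            )
        elif scenario == "opposite_utr_overlap":
            # minus-strand neighbor whose 5'UTR covers the variant
            other = TranscriptModel(
                other_id, principal.gene, _CHROM, "-",
                exons=[(base + 1700, base + 1950)], cds=(base + 1700, base + 1800),
            )
        elif scenario == "mane_cds_conflict":
            other = TranscriptModel(
                other_id, principal.gene, _CHROM, "+",
                exons=[(base + 1700, base + 1950)], cds=(base + 1750, base + 1950),
            )
            other_flags = {TranscriptFlag.MANE_PLUS_CLINICAL}
        elif scenario == "somatic":
            variant.origin = Origin.SOMATIC
        elif scenario == "repeat_expansion":
            variant.symbolic_type = "repeat_expansion"
            variant.repeat_count = int(rng.integers(35, 120))

        if other is not None:
            transcripts.append(other)
            flags[other.transcript_id] = other_flags

        expected_confidence, expected_included = ANNOTATION_SCENARIOS[scenario]
        truths.append(
            SimulatedVariantTruth(
                variant=variant,
                gene=principal.gene,
                scenario=scenario,
                expected_confidence=expected_confidence,
                expected_included=expected_included,
            )
        )
    return SimulatedAnnotation(tuple(transcripts), flags, tuple(truths))


@dataclass(frozen=True)
class SimulatedBenchmark:
    dataset: BenchmarkDataset
    scores: tuple[EffectScore, ...]
    track: ConservationTrack
    variants: dict  # item key -> VariantRecord (for conservation lookups)
    af_table: dict  # the synthetic AF table the benign set was recruited from


def simulate_benchmark(
    config: SimulationConfig,
    model: ModelMechanismMap | None = None,
) -> SimulatedBenchmark:
    """Generate a grouped benchmark with engineered score separation.

    P/LP entries split evenly into model-matched and model-mismatched
    mechanism labels; raw scores are ``sign * effect_size + noise`` with a
    Rademacher sign, group-specific location, and common noise sd. Benign
    variants are recruited through the real assembly path: a synthetic AF
    table over the UTR of a synthetic transcript, with decoy entries below
    the frequency threshold and outside the UTR, is passed through
    :func:`~utrcensus.benchmark.assemble_benign`. Conservation scores at
    P/LP positions are elevated by ``conservation_shift``.
    """
    model = model or DEFAULT_MODEL_MECHANISMS["orf"]
    rng = np.random.default_rng(config.seed)
    side = model.utr_side

    n_matched = config.n_plp // 2
    n_mismatched = config.n_plp - n_matched
    matched_pool = sorted(model.matched, key=lambda m: m.value)
    mismatched_pool = sorted(
        (
            m
            for m in Mechanism
            if m not in model.matched and MECHANISM_SIDE[m] in (side, None)
        ),
        key=lambda m: m.value,
    )

    entries: list[CensusEntry] = []
    prefix = "*" if side == "utr3" else "-"
    for i in range(config.n_plp):
        mech = (
            matched_pool[i % len(matched_pool)]
            if i < n_matched
            else mismatched_pool[i % len(mismatched_pool)]
        )
        entries.append(
            CensusEntry(
                hgvs=f"NM_7{i:05d}.1:c.{prefix}{i + 1}A>G",
                gene=f"PGENE{i}",
                utr_side=side,
                clinvar_class=ClinvarClass.P,
                study_class=StudyClass.P if i % 3 == 0 else StudyClass.LP,
                mechanism=mech,
            )
        )

    # one synthetic host transcript; its UTR is where benign variants live
    utr_len = max(4 * (config.n_plp + 3 * config.n_benign), 400)
    if side == "utr3":
        tx = TranscriptModel(
            "NM_600000.1", "HOST", _CHROM, "+",
            exons=[(1000, 1000 + 300 + utr_len)], cds=(1100, 1300),
        )
        utr_lo, utr_hi = 1301, 1000 + 300 + utr_len
    else:
        tx = TranscriptModel(
            "NM_600000.1", "HOST", _CHROM, "+",
            exons=[(1000, 1000 + 300 + utr_len)], cds=(1000 + utr_len, 1000 + 300 + utr_len - 100),
        )
        utr_lo, utr_hi = 1000, 1000 + utr_len - 1

    filter_config = FilterConfig()
    bases = "ACGT"
    positions = rng.choice(
        np.arange(utr_lo, utr_hi + 1), size=3 * config.n_benign + config.n_plp, replace=False
    )
    plp_positions = positions[: config.n_plp]
    benign_positions = positions[config.n_plp : config.n_plp + config.n_benign]
    decoy_positions = positions[config.n_plp + config.n_benign :]

    af_table: dict[tuple[str, int, str, str], dict[str, float]] = {}

    def long_tail_af(minimum: float | None, maximum: float | None) -> float:
        a, b = config.af_spectrum
        while True:
            af = float(rng.beta(a, b))
            if (minimum is None or af > minimum) and (maximum is None or af <= maximum):
                return af

    for pos in benign_positions:
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        af_table[(_CHROM, int(pos), ref, alt)] = {
            "total": long_tail_af(filter_config.benign_min_af, None)
        }
    # decoys: half too rare, half common but outside the UTR exon
    for j, pos in enumerate(decoy_positions):
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        if j % 2 == 0:
            af_table[(_CHROM, int(pos), ref, alt)] = {
                "total": long_tail_af(None, filter_config.benign_min_af)
            }
        else:
            af_table[(_CHROM, int(pos) + utr_len + 100_000, ref, alt)] = {
                "total": long_tail_af(filter_config.benign_min_af, None)
            }

    benign_variants = assemble_benign(af_table, [tx], side, filter_config)
    dataset = assign_groups(entries, benign_variants, model)

    # effect scores: sign-symmetric locations, common gaussian noise
    scores: list[EffectScore] = []
    variants: dict = {}
    track = ConservationTrack()
    for i, entry in enumerate(entries):
        loc = (
            config.matched_effect_size if i < n_matched else config.mismatched_effect_size
        )
        sign = 1.0 if rng.random() < 0.5 else -1.0
        raw = sign * loc + rng.normal(0.0, config.benign_effect_sd)
        scores.append(EffectScore(variant_key=entry.hgvs, model=model.model, raw=raw))
        pos = int(plp_positions[i])
        variants[entry.hgvs] = VariantRecord(
            chrom=_CHROM, pos=pos, ref="A", alt="G", hgvs=entry.hgvs, gene=entry.gene
        )
        track.add(_CHROM, pos, pos, float(rng.normal(config.conservation_shift, 1.0)))
    for var in benign_variants:
        raw = rng.normal(0.0, config.benign_effect_sd)
        scores.append(EffectScore(variant_key=var.key, model=model.model, raw=raw))
        variants[var.key] = var
        track.add(_CHROM, var.pos, var.pos, float(rng.normal(0.0, 1.0)))
    track.finalize()

    return SimulatedBenchmark(
        dataset=dataset,
        scores=tuple(scores),
        track=track,
        variants=variants,
        af_table=af_table,
    )


def write_annotation_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (exon and CDS features)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene}";'
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds is not None:
                for s, e in tx.cds_exonic_intervals():
                    fh.write(
                        f"{tx.chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                    )


def write_conservation_bedgraph(track: ConservationTrack, path: str | Path) -> None:
    """Write a finalized track as bedGraph (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(track._starts):
            for s, e, v in zip(
                track._starts[chrom], track._ends[chrom], track._values[chrom]
            ):
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{v:.12g}\n")
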
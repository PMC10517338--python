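# Methods

This note documents the models and procedures implemented in `utrcensus`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All internal coordinates are 1-based inclusive (GFF/HGVS convention).
bedGraph input, which is 0-based half-open, is converted at the parser
boundary: a bedGraph interval `[start, end)` covers 1-based positions
`start+1 .. end`. Wiggle `fixedStep`/`variableStep` blocks are already
1-based and read as such. Multi-allelic summary rows are split into
biallelic records before any filtering, because allele frequency and
effect scoring are per-allele notions.

The HGVS parser covers only the exonic-UTR subset of the `c.` grammar:
`c.-N` (5′UTR, counted upstream from the CDS start) and `c.*N` (3′UTR,
counted downstream from the CDS end), single positions or ranges, with
substitution, `del`, `dup`, `ins`, and `delins` edits. Coding positions
and intronic offsets (`c.-15+3`) are rejected as not-exonic-UTR by
design: the pipeline's scope is variants *entirely within* a UTR exon.
5′UTR ranges print the more-upstream base first (`c.-118_-117del`);
offsets are stored as positive integers normalized so that
`start_offset <= end_offset`.

## Transcript context and the confidence score

UTR intervals are derived per transcript as exonic-minus-CDS territory,
split by genomic side of the CDS span, with strand deciding which side is
5′. Derivation therefore tiles the exonic territory exactly: 5′UTR ∪
CDS-exonic ∪ 3′UTR with no overlap. Transcripts with exons but no CDS are
flagged non-coding and excluded from all UTR logic — a UTR is only
defined relative to a coding sequence.

A variant's region on a transcript is called from its full reference
span: UTR- or CDS-exonic only when the span sits inside a single interval
of that class; spans crossing any UTR/CDS or exon/intron boundary are
`spanning`. Insertions have no reference footprint and are located by
their two flanking bases, both of which must lie in the same UTR exonic
interval — the strictest reading of "entirely within", chosen because no
other convention is obviously right. An intronic position within 8 bp of
an exon boundary is `splice_proximal_intronic`; the 8-bp window is the
operational definition of a "splicing variant" and is a config value
(annotation practice drifts). Exonic positions near boundaries are never
splice-proximal.

The confidence score summarizes how unambiguous the UTR assignment is,
from the multiset of region calls on other transcripts:

| other-transcript calls                        | score |
|-----------------------------------------------|-------|
| CDS-exonic, splice-proximal, or spanning      | 0     |
| else intronic or opposite-UTR exonic          | 1     |
| none of the above                             | 2     |

A same-UTR call on another transcript does not demote: the variant is
still a UTR variant there. Spanning calls are scored at the severity of
their worst constituent (CDS), a conservative tie-break the score table
itself does not address. The score is by construction invariant to the
order of the other transcripts, and adding a transcript can only lower
it.

Inclusion into the curated set requires, in precedence order: an
eligible variant type (repeat expansions and multi-region SVs/CNVs are
out), germline origin, UTR-exonic status on the designated APPRIS
principal transcript, no non-UTR impact on a MANE Select or Plus Clinical
transcript of the gene, and no non-UTR impact on an APPRIS alternative
unless curated evidence supports the UTR mechanism. "Non-UTR impact"
means CDS-exonic, splice-proximal, or spanning — a deep-intronic position
on some transcript affects none of its products and conflicts with
nothing. The MANE rule is applied regardless of evidence by default (the
conservative stance); an explicit `allow_mane_override` flag exists for
users who want curated UTR-mechanism evidence to win. The loader takes a
single designated principal per gene; where annotation versions disagree,
supply the most recent designation. Whether a variant that is
splice-proximal on the *preferred* transcript itself should be eligible
is not defined; the implementation requires UTR-exonic status on the
preferred transcript and ignores that corner.

## Filtering

Significance filtering keeps P, LP, and P-vs-LP-conflicting records. The
free-text significance mapping is config-exposed because ClinVar wording
varies by release; unmapped strings collapse to `other` and are dropped.

Both allele-frequency comparisons are strict (`>`), matching their
definitions: a record is discarded when any *subpopulation* AF exceeds
0.05 (common enough to be benign), while putative-benign recruitment
requires *total* AF above 0.01. These are deliberately two different
config keys — the benign threshold is looser so that most census UTRs
contribute at least one benign variant to the benchmark. Records with no
AF data are kept: absence of population observations is evidence of
rarity, not commonness.

Variant types partition non-symbolic (ref, alt) pairs: SNV for a single
mismatched base; pure insertions/deletions are indels up to a net length
of 50 and SVs above it, with net length measured as
max(len(ref), len(alt)) − 1 on normalized (common-context-trimmed)
alleles so the measure is canonical; delins when both alleles change and
neither is a prefix of the other. CNVs and repeat expansions come from
symbolic descriptors. The default repeat bands (5–34 normal, 35–49
premutation, ≥51 fully penetrant) follow the myotonic-dystrophy CTG
convention; a count of exactly 50 is reported `unclassified` rather than
silently assigned, because the bounding conventions in the literature
leave that value genuinely ambiguous — the band table is config-editable.

## The census fixtures

The packaged tables hold the 26 3′UTR and 68 5′UTR P/LP variants with
HGVS (on the APPRIS principal transcript), gene, ClinVar class, study
class, and mechanism. They are versioned data with recorded sha256
checksums, verified on load; checksum verification can be disabled for
user-modified tables. Mechanism strings normalize to a twelve-value enum
through an explicit alias map (table headers are prose); each mechanism
is tied to its UTR side and entries with side-inconsistent mechanisms are
rejected. The `functional_evidence` column is nullable and ships empty:
per-variant functional-evidence flags exist only in supplementary
curation material not reproduced here, so no counts are derived from it.

## Benchmarks and model matching

A benchmark for one UTR side is the census plus putative benign variants:
entries from an AF table whose full span lies in a UTR exon (of that
side) of a transcript harboring a census variant, with total AF > 1%.
Benign variants recruited through overlapping transcripts are
deduplicated by (chrom, pos, ref, alt) to avoid double-counting in rank
tests, and carry no mechanism label. No attempt is made to match benign
variants to P/LP variants by distance or sequence context.

The default model-to-mechanism map is: ORF-recognition model ↔ {existing
uORF, novel upstream start}; mRNA-stability model ↔ {polyadenylation
signal, mRNA stability}; transcription model ↔ {promoter activity,
promoter methylation, 5′UTR splicing}. Splicing in the 5′UTR is grouped
with transcription-level mechanisms because that is where the census
tables place it, but the attribution is interpretive, so the map is a
config file. A variant with an undetermined mechanism is always
model-mismatched.

## Effect-score aggregation

All three adapters consume numeric prediction arrays; running the
underlying networks is out of scope (the weights are external, GPU-scale
artifacts), and an optional runner interface exists for users who have
them.

* **Transcription**: tensors indexed (strand, window, track) for the
  reference- and alternative-centered sequences. Per sequence: average
  the two strands elementwise, subset to the center window ± 2 (five
  windows total; the center index is runner-supplied metadata, never
  inferred) and to the chosen CAGE track subset (a required explicit
  input), compute log2(1 + window-sum) per track, and average over
  tracks. The effect is alt − ref. The log is taken after summing
  windows, with a pseudocount of one.
* **Stability**: per-sequence score is the mean over the K
  cross-validation fold models (K = 50 in the intended ensemble; any
  K ≥ 1 is accepted), effect = mean(alt) − mean(ref). The model's
  six-channel input track builder is included: one-hot A/C/G/T, a
  coding-frame channel marking the first base of each codon, and a
  splice-site indicator channel. The frame channel is a codon-start
  indicator, not a {0,1,2} frame index — the indicator form is the
  documented choice where the encoding is underspecified.
* **ORF recognition**: effect = mean-ribosome-load fold change,
  log2(alt/ref) by default so the absolute value treats load increase and
  decrease symmetrically; the plain ratio scale is exposed for users who
  want the raw fold change.

All effects negate under ref/alt swap (the ratio scale inverts instead),
and `abs` is always |raw|.

Conservation annotation returns the track value at the variant position,
or the maximum over the reference span for multi-base variants. Spans
partially outside track coverage use the covered subset (maximizing
usable annotation); fully uncovered spans return an explicit absence, not
an error.

## Statistics

Group comparisons use the two-sided Mann–Whitney Wilcoxon test with U
computed from midranks. The exact null distribution is used when
n₁ + n₂ ≤ 25 and the pooled sample is tie-free — the census subgroup
sizes live in this range, so exactness is available where it matters —
otherwise the normal approximation with tie and continuity corrections.
Two-sided exact p-values follow the doubled-smaller-tail convention,
capped at 1.

AUC is computed as the normalized rank statistic
(#{pos > neg} + ½·#{pos = neg}) / (n₁·n₂), so the identity
AUC = U/(n₁·n₂) holds exactly rather than approximately. ROC points come
from a sweep over the pooled score grid under the rule
"score ≥ threshold ⇒ positive". The best-separating threshold maximizes
Youden's J = TPR − FPR, with ties broken toward the lowest threshold —
"best separation" does not pin down a criterion, so a single standard,
deterministic one is fixed and named in the output.

Benchmark evaluation reports three pairwise comparisons (matched vs
benign, matched vs mismatched, all P/LP vs benign) and the matched-vs-
benign ROC, on absolute scores by default. No multiple-testing correction
is applied across models, and AUC confidence intervals are out of scope.

## Synthetic data

The generator emulates the *statistical* structure of the benchmark, not
sequence biology: it controls score and conservation distributions, gene
geometry, and AF spectra, but contains no uORFs, polyadenylation motifs,
or real conservation patterns. Passing tests therefore demonstrate that
the pipeline machinery is correct under the engineered conditions, not
that any particular predictor works on real variants.

Defaults: matched location 3.0, mismatched 1.0, benign noise sd 1.0 —
matched effects at three noise sds give clear but not degenerate
separation, and a nonzero mismatched location reflects that mismatched
P/LP variants are still pathogenic and score somewhat above benign.
Effect signs are Rademacher(±1), mirroring pathogenicity acting through
both expression increase and decrease; this is what makes the absolute
scale more informative than the raw scale, and the generator reproduces
that qualitative behavior. Conservation scores at P/LP positions are
elevated by 2.0 over a standard-normal benign baseline. The AF spectrum
is Beta(0.3, 4): long-tailed with most mass rare but enough above 1% and
5% to exercise both thresholds. Benign variants are recruited through the
real assembly path (a synthetic AF table with rare and out-of-UTR decoys,
passed through the benign-assembly rules), not injected directly.

Annotation simulation cycles each gene through eight scenarios (clean,
CDS overlap, splice-proximal overlap, deep-intron overlap, opposite-UTR
overlap, MANE conflict, somatic, repeat expansion), each with a known
expected confidence score and inclusion decision, at one scenario per
gene. All generators are pure functions of (config, seed); reruns are
byte-identical.

## Problem sizes used in the checks

The packaged census checks run on the full 26 + 68 tables. Oracle
comparisons use 1,000 randomized cases per family (rank-sum enumeration
up to n₁+n₂ = 12, where full enumeration is cheap; small random tensors
and tracks for the effect adapters) at a 1e-12 tolerance. The pipeline
separation study uses 500 replicates at 30 variants per group, and the
type-I calibration 10,000 null replicates at n = 20 per group — sizes at
which the empirical rejection rate pins down the nominal 5% level to
within half a point.

## Known limitations

* The HGVS grammar is deliberately partial (no protein-level, inversion,
  or complex rearrangement support).
* Genomic-to-transcript coordinate mapping of HGVS UTR offsets is not
  implemented; census entries are keyed by HGVS and benchmark items by
  genomic coordinates, and joining the two requires a transcript
  annotation supplied by the user.
* BigWig conservation input is not parsed natively; convert to bedGraph
  or wiggle text first (the track interface is format-agnostic).
* Evidence contexts for the alternative-transcript exclusion rule are an
  input column; no literature mining is attempted.
* `evaluate_benchmark` assumes one score per dataset item from a single
  model; cross-model comparisons are left to the caller.
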
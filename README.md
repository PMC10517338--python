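# utrcensus

Curation and benchmarking toolkit for pathogenic variants in untranslated
regions (UTRs).

Variants in the 5′ and 3′ UTR can cause rare disease through regulatory
mechanisms — disrupted upstream open reading frames (uORFs), novel upstream
start codons, damaged polyadenylation signals, altered miRNA or RNA-binding
protein interactions, promoter effects — yet they are easy to misclassify:
the same genomic position can be 3′UTR on one transcript and missense on
another, and public databases mix submissions of very different quality.
`utrcensus` implements a reproducible pipeline for this problem, aimed at
people building or validating variant-effect predictors for non-coding
regions:

1. **Filtering** of ClinVar-style variant summaries to pathogenic / likely
   pathogenic (P/LP) records, with a strict subpopulation allele-frequency
   discard rule (any subpopulation AF > 5%) and a variant-type taxonomy
   (SNV / indel ≤ 50 nt / SV > 50 nt / delins / CNV / repeat expansion,
   with repeat-count banding, e.g. the DMPK CTG bands 5–34 / 35–49 / >50).
2. **Transcript-context resolution**: each variant is located on every
   overlapping transcript (UTR exon, CDS exon, intron, splice-proximal
   intron = within 8 bp of an exon boundary) and assigned a confidence
   score in {0, 1, 2}; variants are excluded when their UTR status does not
   survive the APPRIS-principal / MANE Select / MANE Plus Clinical
   transcript hierarchy.
3. **A curated census** of 94 P/LP UTR variants (26 in the 3′UTR, 68 in
   the 5′UTR, 49 unique genes), shipped as checksummed TSV fixtures with
   per-variant molecular mechanism labels, plus the mechanism
   stratifications, study-vs-ClinVar cross-tabulations, and gene summaries
   computed from them.
4. **Benchmark assembly**: the census is paired with putative benign
   variants — common variants (total AF > 1%) inside the UTR exons of
   census transcripts — and each P/LP variant is labeled *model-matched*
   or *model-mismatched* for a given predictor according to its curated
   mechanism (ORF-recognition, mRNA-stability, and transcription-level
   model mappings are built in and configurable).
5. **Effect-score aggregation** for three predictor families, as pure
   functions over supplied prediction arrays (the networks themselves are
   not run): strand-averaged CAGE-track windows with a
   log2(1 + Σ) transform for transcription models; ensemble-mean
   differences for mRNA-stability models; log2 mean-ribosome-load fold
   change for ORF models. Conservation (PhyloP-style) annotation takes the
   per-base score, or the maximum over multi-base reference spans.
6. **Statistical evaluation**: two-sided Mann–Whitney Wilcoxon tests
   (exact when n₁+n₂ ≤ 25 and tie-free, normal approximation with tie and
   continuity corrections otherwise), rank-based ROC/AUC with
   AUC = U/(n₁·n₂) exactly, and best-threshold search by Youden's
   J = TPR − FPR. Scores are compared on the absolute scale by default,
   because regulatory pathogenicity acts through both expression increase
   and decrease.

A synthetic-data module generates every input the pipeline reads — gene
structures engineered to trigger each confidence score and exclusion
reason, AF spectra straddling the 1% / 5% thresholds, score sets with
controllable group separation, conservation tracks elevated at pathogenic
positions — so the full pipeline is testable offline.

## Worked example

```python
import utrcensus as uc

# census summaries
utr3 = uc.load_census("utr3")
print("3'UTR census:", len(utr3), "P/LP variants in",
      len(uc.unique_genes(utr3)), "genes")
for mech, n in sorted(uc.stratify_mechanism(utr3).items(), key=lambda kv: -kv[1]):
    print(f"  {mech.value:24s} {n}")

# benchmark a synthetic score set with the stability-model grouping
from utrcensus.synthetic_data import SimulationConfig, simulate_benchmark
from utrcensus.benchmark import DEFAULT_MODEL_MECHANISMS

sim = simulate_benchmark(SimulationConfig(seed=1, n_plp=26, n_benign=67),
                         model=DEFAULT_MODEL_MECHANISMS["stability"])
report = uc.evaluate_benchmark(sim.dataset, sim.scores, use_abs=True)
print(f"matched vs benign:     U={report.matched_vs_benign.u_statistic:.1f}, "
      f"p={report.matched_vs_benign.p_value:.2e}")
print(f"matched vs mismatched: p={report.matched_vs_mismatched.p_value:.2e}")
print(f"all P/LP vs benign:    p={report.plp_vs_benign.p_value:.2e}")
print(f"ROC AUC (|score|): {report.roc.auc:.3f}, "
      f"best threshold {report.roc.best_threshold:.2f}")
```

prints

```
3'UTR census: 26 P/LP variants in 14 genes
  polyadenylation_signal   10
  mirna_binding            7
  undetermined             4
  mrna_stability           3
  splicing_3utr            1
  secondary_structure      1
matched vs benign:     U=861.0, p=2.98e-08
matched vs mismatched: p=9.72e-05
all P/LP vs benign:    p=1.24e-06
ROC AUC (|score|): 0.989, best threshold 1.68
```

The census lines are the curated table itself: 26 3′UTR P/LP variants
across 14 genes, dominated by polyadenylation-signal and miRNA-binding
mechanisms. The benchmark lines evaluate a synthetic score set shaped like
a well-matched predictor (26 P/LP vs 67 benign variants): model-matched
variants separate sharply from benign ones (small U-test p, AUC near 1),
and also from model-mismatched P/LP variants, while the Youden threshold
reports the |score| cutoff that best splits matched from benign.

A `utr-census` console script exposes the same functionality from the
shell (`utr-census report --by mechanism`, `utr-census simulate`,
`utr-census evaluate`, `utr-census parse`, `utr-census score-confidence`);
see `utr-census --help`.

## Documentation

The model, its assumptions, parameter defaults, and known limitations are
described in [docs/methods.md](docs/methods.md).
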
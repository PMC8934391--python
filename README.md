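# srnatlas

A toolkit for sequence-level analysis of small RNA sequencing data across
tissues and biofluids. Instead of collapsing reads onto canonical miRNA or
small-RNA gene entries, every unique adapter-trimmed sequence — canonical
miRNAs, isomiRs, tRNA/Y RNA-derived fragments, piRNAs and fragments of
protein-coding transcripts — is quantified, classified for tissue
specificity, and traced into biofluids. The intended users are groups
designing or validating extracellular-RNA (exRNA) biomarker studies, who
need to know whether a candidate sequence is genuinely elevated in a tissue
of interest and whether it is detectable in plasma, urine, saliva or CSF.

## What it computes

**Unique-sequence quantification.** Adapter-trimmed reads are collapsed by
exact sequence into a counts table. Multi-mapping annotations are resolved
per sequence by a fixed biotype priority
(miRNA > YRNA > tRNA > piRNA > protein_coding > other); ties within a
biotype break lexicographically on the gene id.

**Detection filters.** Tissues: a sequence is kept if some source shows
> 25 reads in ≥ 2 of its 3 replicates. Biofluids: > 10 reads in > 50% of
samples. All inequalities strict; thresholds configurable.

**Median-of-ratios normalization.** For counts $c_{sj}$ (sequence $s$,
sample $j$), the reference is the row geometric mean
$r_s = (\prod_j c_{sj})^{1/m}$ over rows with no zero; the size factor is
$f_j = \mathrm{median}_s\, (c_{sj}/r_s)$ and normalized counts are
$n_{sj} = c_{sj}/f_j$.

**Tissue-elevation classification** (the Human Protein Atlas categories),
on replicate-averaged normalized expression $e_t$ with fold threshold $F$
(default 7; 5 is the HPA definitional value) and expression cutoff 1:

- *tissue-enriched*: $e_t > 1$ and $e_t \ge F \cdot \max_{u \ne t} e_u$;
- *group-enriched*: smallest group $G$ of 2–4 tissues with
  $\min_G e > 1$ and $\min_G e \ge F \cdot \max_{u \notin G} e_u$;
- *tissue-enhanced*: $e_t > 1$ and
  $e_t \ge F \cdot \mathrm{mean}_{u \ne t}\, e_u$, not meeting the above;
- otherwise *not elevated*.

The union of the first three categories is **tissue-elevated**.

**Biofluid attribution ("direct" tissue-of-origin).** Sequences detected in
a biofluid are intersected with each tissue's elevated set; each tissue
reports the number of detected elevated sequences, the sum of their mean
normalized counts, and that sum as a fraction of the total. A sequence
elevated in several tissues counts for each of them, so fractions sum to 1.

**Diversity and rarefaction.** Sequence diversity counts unique sequences
above a normalized-expression cutoff (10); gene diversity counts parent
genes after collapsing isoforms. Rarefaction is the exact hypergeometric
expectation of richness at depth $d$:
$E[S_d] = \sum_i \left(1 - \binom{N-n_i}{d}\big/\binom{N}{d}\right)$.

**Differential-expression annotation.** Externally computed (log2FC, p)
tables are BH-adjusted (α = 0.05) and joined to the elevation calls.

**Synthetic data.** A generator emulates the atlas structure — isomiR
families, log-normal baseline expression, planted tissue-elevated
sequences at a configurable fold, negative-binomial counts, biofluids as
weighted mixtures of tissue profiles — and emits the ground truth needed
to score recovery.

## Worked example

```python
from srnatlas import SimulationConfig, classify_sequence, TissueProfile
from srnatlas.datasets import gallbladder_trf_profile
from srnatlas.evaluation import run_tissue_pipeline, recovery_metrics

# A bundled cautionary example: a tRNA fragment whose expression in
# gallbladder is ~9.9x the runner-up tissue (ileum), hence classified
# gallbladder-enriched -- yet it is abundant in most solid tissues and
# a poor marker of tissue specificity in blood-derived fluids.
call = classify_sequence(
    TissueProfile("gallbladder-tRF", gallbladder_trf_profile()), fold=7
)
print(f"category={call.category} tissues={sorted(call.tissues)} "
      f"fold={call.fold_change:.2f}")

# End-to-end on synthetic data with planted ground truth.
sim = SimulationConfig(seed=1)       # 10 tissues x 3 replicates, fold-10 plants
matrix, truth, normalized, calls = run_tissue_pipeline(sim)
m = recovery_metrics(calls, truth)
print(f"{len(matrix.sequences)} sequences, {len(matrix.samples)} samples")
print(f"planted={m.n_planted} called_elevated={m.n_called} "
      f"sensitivity={m.sensitivity:.3f} precision={m.precision:.3f}")
```

prints

```
category=tissue_enriched tissues=['GALLBLADDER'] fold=9.88
308 sequences, 30 samples
planted=80 called_elevated=74 sensitivity=0.925 precision=1.000
```

The fold of 9.88 is the ratio of the gallbladder expression to the highest
remaining tissue; sensitivity is the fraction of planted elevated sequences
recovered with the right tissue, and precision the fraction of elevated
calls that were planted.

A CLI mirrors the library
(`srnatlas simulate | quantify | filter | normalize | enrich | attribute |
diversity | rarefy | annotate-de | report`); run `srnatlas --help`.

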
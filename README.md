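# dielkit

Dual-algorithm detection of diurnal/circadian rhythms in gene-expression
time courses, with circular phase statistics and cross-dataset comparison.

## The problem

Roughly a tenth of the expressed genome in a vertebrate tissue cycles with
the day/night cycle. A typical experiment samples a tissue every 4 h for
48 h (12 timepoints, ZT0–ZT44, where ZT0 is lights-on), producing an
expression matrix from which rhythmic transcripts must be identified,
their peak times (acrophases) estimated, and — for comparative studies —
the rhythmic gene sets of different tissues, life stages or species
measured against each other. dielkit is for computational biologists doing
exactly this: it implements the two complementary detector families used
in such surveys, the circular arithmetic that phases on a 24 h clock
require, and the set/phase comparison machinery, plus a synthetic-data
generator with known ground truth for validating the whole pipeline.

## Methods at the core

**Pattern matching (HAYSTACK-style).** A library of model waveforms —
five shapes (cosine, spike, box, rising and falling ramps) × 24 peak
phases at period 24 h — is fit to each gene by ordinary least squares.
With Pearson correlation r between gene *y* and best pattern *m*, a gene
is called rhythmic when

    r ≥ max(0.81, r*)        r* = top-q% permutation threshold

where r\* is the (100−q)th percentile (q = 5 by default) of best-pattern
correlations after shuffling each row's time labels. The winning
pattern's phase and shape annotate the call.

**Rank concordance (JTK_CYCLE-style).** For reference orderings derived
from cosines over a (period, lag) lattice — periods {20, 24, 28} h (the
4 h-grid-representable periods in 20–28 h), one lag per timepoint —
Kendall's S is

    S = Σ_{i<j} sgn(y_j − y_i) · sgn(ref_j − ref_i)

The null distribution of S is exact (generating-function convolution over
the reference's tie groups, the Jonckheere–Terpstra construction), the
test is two-sided on |S|, and p-values are Bonferroni-adjusted for the 18
(period, lag) combinations; calls require adjusted p < 0.05.

**Circular phase statistics.** Phases are averaged as mean directions of
unit vectors (so ZT2 and ZT22 average to ZT0, not ZT12); phase pairs
straddling dawn are linearised by adding 24 h to the smaller member of
any pair differing by more than 12 h before computing R²; circular
distances, agreement fractions within the sampling window, 1-D phase
histograms and 2-D phase contour grids are provided.

**Set comparison.** Venn partitions, the Tanimoto–Jaccard index
100·|A∩B|/|A∪B| (one decimal, half-up), similarity ranking of a query
set against a panel, and common-vs-specific binning over a gene × tissue
presence matrix. Transcript→gene and gene→ortholog collapsing merge
phases by circular mean.

## Worked example

Simulate a liver-like time course (500 genes, 11% rhythmic, noise SD
0.25 at amplitude 1) and run both detectors:

```python
from dielkit import (SyntheticSpec, generate_dataset, run_detection,
                     PipelineConfig, HaystackConfig)

spec = SyntheticSpec(n_genes=500, frac_rhythmic=0.11, noise_sd=0.25, seed=42)
tc, truth = generate_dataset(spec)
result = run_detection(tc, PipelineConfig(haystack=HaystackConfig(seed=42), seed=42))
print(result["report"])
```

prints (abridged):

```json
{
  "n_genes": 500,
  "haystack": {"n_calls": 59, "genome_fraction_pct": 11.8},
  "jtk":      {"n_calls": 48, "genome_fraction_pct": 9.6},
  "common": 37,
  "union": 70,
  "union_fraction_pct": 14.0
}
```

Of the 55 truly rhythmic genes, 50 are recovered by the union of the two
detectors; the 20 extra calls reflect the permutation rule's designed
top-5% admission rate on the 445 arrhythmic genes. Each detector alone
calls ~10–12% of the genes — the order of magnitude such surveys report —
and the intersection (37) is markedly smaller than either list, the
hallmark of the two algorithms' different sensitivities (the pattern
matcher favours spike/box shapes; the rank test admits 20 h and 28 h
periods).

The same stages are scriptable from a shell:

```sh
dielkit simulate --n-genes 500 --seed 42 --out tc.tsv
dielkit detect both --input tc.tsv --seed 42 --out calls.tsv
dielkit compare venn --a setA.txt --b setB.txt
```

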
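# scnanopipe

Whitelist-free analysis of high-throughput single-cell nanopore sequencing
of full-length cDNAs (10x-style droplet libraries read on long-read
platforms). Long reads carry ~5–15% sequencing error, which scrambles the
16-nt cell barcodes (CBs) and 12-nt unique molecular identifiers (UMIs)
that deconvolution depends on; most existing tools lean on matched
short-read data or a manufacturer barcode whitelist to compensate.
`scnanopipe` does neither: it calls true cells directly from the data,
collapses duplicate reads into error-corrected consensus molecules, and
computes same-cell gene expression, isoform composition, and
transcriptome-wide SNVs — phenotype and genotype from the same cells.

It is written for method developers and analysts who want an inspectable,
fully synthetic-testable implementation of this workflow: every stage can
be driven end to end by the built-in simulator with known ground truth,
with no external aligner or reference download.

## The algorithms

**Cell calling (knee anchoring + local refinement).** Let `X_i` be the
number of supporting reads of the CB at rank `i` (descending). The crude
anchor is the rank where the log–log rank curve drops fastest: per-rank
discrete derivatives

```
d_i = (log10 X_{i+1} − log10 X_i) / (log10(i+1) − log10 i)
```

are median-smoothed within 0.001-wide windows `w` of `log10 i`, and

```
Cr = round(10^(0.001 · w*)),   w* = argmax_w |median_i∈w d_i|
```

The anchor is then extended by 10% (`Cr2 = ceil(1.1·Cr)`) to rescue
low-read cells, CBs within 2 Levenshtein distances (LD) are merged
one-directionally into the CB with more supporting reads (`Cr3`), and
cells covering fewer than 300 genes (configurable) are removed after
quantification (`Cr4`).

**Molecule curation.** Per cell, reads aligning to the same locus (start
coordinates chained within 5 bp, same chromosome/strand) are clustered;
within a cluster, UMIs within 2 LD are merged toward the most-supported
UMI; each UMI group is collapsed into a consensus sequence by per-column
majority vote around the highest-quality backbone read.

**Quantification.** Gene counts are consensus-molecule (UMI) counts by
maximal exonic overlap; isoform counts are assigned by exon-chain
compatibility (every molecule junction must match a transcript junction
within ±10 nt, truncation-tolerant at the termini) and split uniformly
across compatible transcripts.

**SNVs.** Molecules are piled up against the reference (substitutions
only); an alternative allele needs ≥2 supporting consensus molecules;
variants seen in <1% of covered cells overall *and* <5% within every cell
type are removed as random errors; covered cells with no alternative
allele are wild-type (0/0), uncovered cells are missing (./.); variants
mutant in >90% of covered cells are labelled germline, the rest somatic.

**Statistics.** Differential combinations of isoforms (DCI): per gene, a
Pearson chi-square on the isoform × group aggregated molecule counts,
Benjamini–Hochberg corrected, flagged when adjusted p < 0.05 and some
isoform's cellular prevalence differs ≥10 points between groups; the most
dominant transcript (MDT) is reported per group. Differentially expanded
mutations (deMut): per locus, a 2×2 chi-square on (mutant, wild-type) ×
groups over covered cells, flagged when adjusted p < 0.05 and the
cellular-frequency difference exceeds 0.1.

## Worked example

Simulate a 30-cell experiment (3 cell types, 25 genes, planted isoform
switches and SNVs) and run the pipeline on its truth alignments:

```python
from scnanopipe import simulator, pipeline

sim = simulator.simulate_experiment(simulator.SimConfig(seed=7))
result = pipeline.run_pipeline(
    sim.reads, sim.truth.read_alignments, sim.genes, sim.genome,
    pipeline.PipelineConfig(min_genes=10),
)
```

Output of the summary printout:

```
reads: 5280  accepted: 5280
anchor: Cr=30 Cr2=33 Cr3=33 Cr4=30
cells: 30 (all planted: True)
molecules: 1719 (truth 1719)
gene matrix: (25, 30)  isoform matrix: (38, 30)
candidate SNVs: 3
  chr1:5859 C>G  mutant cells: 5  support: 31
  chr1:7988 C>G  mutant cells: 3  support: 5
  chr1:9727 G>T  mutant cells: 7  support: 16
```

Reading: the knee anchor lands at rank 30 (the 30 planted cells), the 10%
extension admits 3 ambient barcodes, which the gene-count filter removes
again (`Cr4=30`). All 1719 true molecules are recovered, and the three
planted SNVs are called at their planted loci (1-based positions shown)
with the correct carrier cells. With zero simulated errors the recovered
matrices equal the truth matrices exactly; with nanopore-like error rates
(2% substitutions, 1% indels in read bodies) the recovered gene × cell
counts rank-correlate with truth at Spearman ≈ 0.98–0.99.

The same stages are available as a CLI
(`scnanopipe simulate | nanoqc | scanner | assigner | curator |
expression | isoform | snv | dci | demut | run-all`), e.g.:

```bash
scnanopipe simulate --seed 7 -o simdir
scnanopipe run-all --fastq simdir/reads.fastq.gz \
    --alignments simdir/truth_alignments.tsv \
    --genome simdir/genome.fa --gtf simdir/genes.gtf \
    --min-genes 10 -o outdir
```

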
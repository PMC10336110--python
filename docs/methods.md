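# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `scnanopipe`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Adapter scanning

Reads are expected to follow the 10x-style construct
`R1-adapter (22 nt) + CB (16 nt) + UMI (12 nt) + polyT + cDNA + TSO (27 nt)`,
possibly reverse-complemented. Each adapter is located by semi-global
alignment (adapter aligned end to end, free flanks on the read) inside the
terminal 100-nt window of the read, with BLAST-like scoring: match +2,
mismatch −3, gap open −5, gap extend −2. Identity is computed as matches
over alignment columns of the adapter's aligned core, gap columns
included, and a hit requires identity ≥ 0.70. The semi-global form is
deliberate: a purely local alignment can trim mismatching adapter ends and
report a high identity over a short exact core, accepting adapters that
are mostly wrong.

Both orientations are evaluated in full and the orientation with the
higher combined adapter score wins. This matters in practice: a
reverse-complemented read occasionally shows a spurious ≥70% R1-like match
in its forward orientation, and an early-exit strategy would reject it.

The polyT tract between UMI and insert is trimmed greedily, absorbing one
non-T base per ten consumed T's (configurable). A consequence is that an
insert beginning with a run of T's loses those bases from its extracted
sequence; alignment-anchored stages are unaffected, but consensus
sequences can be a few bases short at the 5' end. Rejection reasons are
fixed (`no_r1`, `no_tso`, `short_insert` for inserts under 200 bp,
`short_read` for reads that cannot hold the construct at all) so that QC
counts are comparable across runs.

## Cell calling

The barcode rank curve uses exact supporting-read counts with
lexicographic tie-breaking. Per-rank discrete derivatives of log10(count)
against log10(rank) are grouped into windows by
`w = floor(log10(rank)/0.001)` — a half-open binning in which every rank
belongs to exactly one window; single-rank windows are allowed (they are
unavoidable below rank ~434, where consecutive ranks are more than 0.001
apart in log10). The window statistic is the median derivative; the
selected window maximizes the magnitude of that median, i.e. the steepest
descent. A literal mode that takes the signed argmax instead is available
behind a flag, but on a non-increasing curve the signed argmax selects the
flattest window, which is not a knee; the magnitude form is the default.
The anchor count is `round(10^(0.001·w*))`. A curve with all counts equal
has no knee and raises an error.

The window-median smoothing is what makes the statistic robust at depth:
deep in the ambient tail a count transition (say 2→1) produces an enormous
single-rank derivative, but its window contains dozens to hundreds of
ranks whose derivatives are zero, so the median suppresses it. Near the
knee the windows are narrow and the drop survives the median.

The 10% extension uses `ceil`, capped at the curve length. The 2-LD merge
processes barcodes in descending original-count order; each barcode is
absorbed by the highest-original-count already-retained barcode within
Levenshtein distance 2 (ties broken lexicographically), making absorption
one-directional: an absorber is never itself absorbed, and total counts
are conserved. Original rather than accumulated counts are used to rank
absorbers so the outcome does not depend on merge history. The gene-count
filter (default 300 genes; configurable, and necessarily smaller for toy
simulations) runs after quantification: retained cells are provisionally
deconvoluted, quantified, and only then filtered, resolving the circular
dependency between cell calling and gene counting. Reads whose raw CB is
outside the top-`Cr2` list are dropped rather than rescued by distance to
a final CB.

## Molecule curation

Positional clustering is single-linkage chaining on alignment starts
(same chromosome and strand): a sorted read joins the open cluster when
its start is within 5 bp of the previous read's start, so a cluster can
span more than 5 bp end to end. Start coordinates only are used; full-length
cDNA reads share 5' alignment starts per gene while 3' ends vary with
truncation.

UMI curation inside a cluster mirrors the CB merge: descending-count
greedy absorption within 2 LD toward the most-supported UMI. On sparse
clusters (random UMIs, occasional coincidental neighbours) this is
identical to exhaustive single-linkage clustering, which is how the
agreement benchmark checks it. On dense error families the two can
legitimately differ: a read two errors away from one family seed and two
from another bridges the families under single-linkage, while the
directional merge keeps them apart — that separation is the point of
directional merging.

Consensus construction: one read is itself; of two reads the one with the
higher mean base quality is taken; three or more reads are combined by
center-star alignment around the highest-mean-quality backbone, voting
per column over `{A,C,G,T,N, gap}` with ties broken by summed base
quality, then alphabetically; a gap majority deletes the column and
insertion columns (keyed by backbone position and offset) count
non-participating reads as gap votes. Reads whose length equals the
backbone's are compared column-wise without alignment: equal length almost
always means substitution-only differences, and edit-distance alignments
otherwise sometimes choose cost-equivalent indel pairs that create
spurious gap columns (measured to cost ~2 points of exact-recovery rate).
Consensus base qualities are the mean quality of the winning base's votes,
capped at 60.

## Quantification

Gene assignment: candidate genes must hold ≥50% of the molecule's aligned
bases within their span; among those, the gene with maximal exonic overlap
wins; exact ties are left unassigned. If no gene has exonic overlap, a
purely intronic containment (≥50% of bases in the span) assigns the gene
— single-nucleus libraries are rich in pre-mRNA — and this fallback can
be disabled. Assignment is strand-agnostic by default because the scanner
already orients reads and residual strand errors should not silence
molecules; a stranded mode exists.

Isoform assignment requires every molecule junction to match a transcript
junction within ±10 nt (nanopore splice wobble) as a contiguous run of
the transcript's junction chain, with terminal blocks allowed to stop
short of (but not overrun) the flanking exons. Mono-exon molecules are
compatible with any transcript exon that contains them. One count per
molecule is split uniformly over compatible transcripts, so per-gene
isoform counts never exceed the gene count, with equality when every
molecule is isoform-resolved.

## SNV calling

Consensus molecules are re-anchored on their spliced reference via global
edit-distance alignment, so consensus indels do not phase-shift downstream
bases; only substitution columns enter the pileup, and indels are not
called at all — duplicate-consensus does not reliably correct them on
this platform. Depths count molecules, never raw reads, and no
base-quality weighting is applied (the consensus already denoised). The
two-molecule support rule for candidates is a total across cells; a
single cell needs only one alternative molecule to be labelled mutant (a
per-cell support flag exists). Prevalence filtering retains a variant if
its mutant fraction is ≥1% of covered cells overall or ≥5% of covered
cells in at least one cell type; fractions always use covered
(non-missing) cells as denominator. With very few cells these percentage
filters are vacuous (1 mutant among 30 covered cells is already 3.3%);
their operating characteristics are therefore benchmarked at 600 cells.
Germline calls require mutant fraction strictly above 0.90 among covered
cells; everything else is somatic, making the partition exhaustive and
exclusive.

## DCI and deMut statistics

The chi-square is the plain Pearson statistic with expected counts from
margins, no continuity correction and no minimum-expected-count rule (a
warning is logged when an expected cell is below 5); zero-margin rows and
columns are dropped, and a table degenerating below 2×2 yields p = 1. BH
adjustment is the standard step-up with monotonicity enforced from the
largest rank. Both are checked against independent implementations to
1e-10.

For DCI, genes detected in fewer than 5% of cells in *both* groups are
skipped, as are genes with fewer than two isoforms with nonzero aggregate
counts; the test runs on isoform × group aggregated molecule counts
(aggregation across cells deliberately blunts dropout noise), and BH spans
the tested genes. The cellular prevalence of an isoform in a group is the
fraction of gene-expressing cells with at least one molecule of that
isoform — a cell-based quantity, distinct from the molecule-count
composition the chi-square sees; the DCI flag gates on adjusted p < 0.05
and a prevalence difference of at least 10 points. The MDT is the argmax
of aggregated counts per group (ties to the smaller transcript id).
Designs may be one-vs-rest or explicit pairs.

For deMut, loci below 5% mutant fraction in every compared group are
skipped; the 2×2 (mutant, wild-type) × group table uses covered cells
only; the flag requires adjusted p < 0.05 and a frequency difference
strictly above 0.1.

## The synthetic-experiment generator

The generator emulates the statistical structure each stage consumes, at
desk scale:

- a toy genome (default 25 genes on one chromosome; 3–5 exons of 150–220
  bp, introns of 120–250 bp) in which additional isoforms skip one
  distinct internal exon each, so full-length molecules carry
  isoform-diagnostic junctions while isoforms share exons;
- 3 cell types × 10 cells with pairwise-LD>4 barcodes; molecules per cell
  are negative binomial (mean 60, dispersion 10) with a floor of 20, of
  which the first 12 cover distinct genes (housekeeping-like breadth) —
  the floor and baseline guarantee that every simulated cell clears the
  toy-scale gene filter, since cells below the detection floor are not
  the object of the exactness checks;
- per-molecule duplicates are 1 + Poisson(2); reads are assembled with
  the real adapter sequences, a 20-nt polyT, strand-flipped with
  probability 0.5, and corrupted by independent per-base substitutions
  and single-base indels at separate barcode/body rates;
- UMIs are sampled collision-free within a cell (pairwise LD > 2) so that
  molecule identity is well defined in truth tables;
- planted DCI genes give the first isoform an 0.8 share in one cell type
  and the complementary share elsewhere; planted SNVs sit mid-way through
  each gene's first exon (shared by all isoforms) with carrier
  frequencies of 0.5 in the enriched type and 0.05 elsewhere; ambient
  reads come from 40 extra barcodes at ~1.5 reads each;
- truth tables (cells, molecule table, gene/isoform matrices, per-cell
  variant states with alternative-molecule totals, and per-read spliced
  truth alignments) are asserted self-consistent at generation time. The
  truth alignments stand in for an external spliced aligner so the whole
  pipeline runs hermetically; SAM/BAM from a real aligner drops into the
  same interface.

Three scale-matched generators feed the statistics and the cell caller
directly at realistic sizes without paying read-level cost: barcode
observations (500 true CBs with log-normal depths — median 1500, σ=0.6,
floor 50 — plus 20,000 ambient barcodes with geometric counts ≤10,
corrupted at 2% substitution / 1% indel per base), two-isoform
gene × cell count matrices (200 cells per group, Poisson(5) molecules per
gene per cell, binomial isoform splits with a configurable composition
shift), and locus × cell depth/alt tables (3 × 200 cells, Poisson(2.5)
molecule coverage). In the last of these, unstructured error loci draw
each molecule's consensus base as the strict majority over its duplicate
reads (1 + Poisson(1.5) duplicates, 1% per-base read error uniform over
the three alternatives) — the per-locus equivalent of running the full
consensus, which is benchmarked separately at sequence level.

What these simulations do not emulate: homopolymer-dependent and other
sequence-context error structure, signal-level artefacts, chimeric reads,
doublets, ambient-RNA expression structure (ambient reads are uniform),
truncated (non-full-length) cDNAs, and genuinely novel isoforms. Passing
benchmarks therefore demonstrate algorithmic correctness and operating
characteristics under the stated error model, not performance on real
tissue.

## Benchmark conditions and numerical tolerances

Problem sizes for the benchmarks were chosen to exercise each property at
the scale where it is meaningful: cell calling at 500 cells + 20,000
ambient barcodes; UMI-merge agreement on 100 clusters of 200 reads;
consensus recovery over 1000 trials of 5 duplicates of a 300-nt template
at 2% substitutions; DCI characteristics on 20 null replicates of 500
genes and 3 planted-shift replicates of 200 genes (the planted shift is
30 percentage points of isoform composition); deMut on 500 error loci and
20 planted loci across 600 cells; end-to-end runs at 30 cells. The
end-to-end exactness check exempts planted variants whose total
alternative-molecule count is below the two-molecule support rule (rarely,
no carrier expresses the gene); the pipeline is then required *not* to
call them.

Numerical notes: chi-square p-values come from the χ² survival function;
agreement checks use 1e-10 relative tolerance; Levenshtein distances are
computed with early termination at the threshold; the knee finder breaks
window ties toward the smaller window index; MDT and absorber ties break
lexicographically. All stages are deterministic given their inputs; all
simulation randomness flows through a single numpy Generator seeded from
the experiment seed.

## Known limitations

- Indel variants are out of scope by design.
- C>T changes from RNA editing are indistinguishable from genomic
  transitions without external annotation.
- The prevalence filters assume hundreds of covered cells; at toy scale
  they pass singleton errors through (see SNV section).
- The isoform model counts known transcripts only; novel junctions make a
  molecule gene-level only.
- Reads with two R1 hits (chimeras) are rejected via the TSO check rather
  than split.
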
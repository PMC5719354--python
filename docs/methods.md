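# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical/tie-breaking choices that matter for
reproducibility.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. GFF3/GTF are parsed and
emitted 1-based inclusive; the conversion happens only in `ethylome.io`,
so there is exactly one conversion boundary. Methylation tables are
0-based TSVs with columns chrom, pos0, strand, context, m_count,
total_count (CGmap/bedGraph-like). FASTA is wrapped at 60 columns.

## Isoform catalog

**Collapse.** Multi-exon transcript models are identical isoforms iff
they share (chromosome, strand, intron chain) exactly: long-read end
raggedness is overwhelmingly terminal, so internal splice sites are
compared exactly while terminal-exon outer boundaries are merged into
TSS/TES ranges. Because chain identity alone defines multi-exon groups,
the `end_fuzz` parameter (default 5 bp) does not affect multi-exon
grouping; it quantizes the span key used for stable mono-exon isoform
ids. Mono-exon models group by ≥ 50 % reciprocal overlap under single
linkage (connected components, hence order-independent). Isoform ids are
hashes of the chain (or fuzz-rounded span), so ids are invariant under
input permutation. Every input model lands in exactly one isoform's
member list, and collapse is idempotent on the isoforms' representative
models.

**Locus assignment.** An isoform is assigned to the same-strand
annotated gene with maximal exonic overlap (≥ 1 bp required; ties break
to the lexicographically smaller gene id). `reference_match` requires an
exact chain match to an annotated transcript (mono-exon: ≥ 50 %
reciprocal overlap with a mono-exon annotated transcript); an assigned
isoform without a chain match is `novel_isoform`; an unassigned one is
`novel_locus`.

**AS events.** Events are computed against the reference transcript
sharing the most introns (ties → longer genomic span, then id):

* *ES* — an internal reference exon with no overlapping isoform exon
  whose two flanking reference introns are both contained in a single
  isoform intron; reported at the skipped exon.
* *IR* — an isoform exon strictly spanning a reference intron plus parts
  of both flanking exons; reported at the retained intron.
* Boundary shifts are assessed on a bijective intron matching (an
  isoform intron and a reference intron match when each overlaps the
  other and nothing else). When two consecutive matched intron pairs
  shift the two boundaries facing the exon between them, that is one
  *IESC* at the isoform exon, consuming both shifts. Any remaining
  single-boundary shift is *A5S* at the donor (5′ splice) side or *A3S*
  at the acceptor side, strand-aware — the category names follow
  transcript orientation, not genome left/right. Terminal-exon outer
  boundaries never produce events, and a mono-exon isoform compared to a
  multi-exon reference yields no events (tallied "unclassified
  mono-exon").

The classifier is verified, case by case, against an independent
brute-force enumerator over every reference × isoform geometry with up
to four exons per side on both strands (≈ 32 000 geometries).

**APA.** Strand-aware 3′ ends (end for +, start for −) of all member
models at a locus are clustered by single linkage with a 50 bp default
linkage distance; each cluster is summarized at its lower-median member
end. A locus with ≥ 2 clusters is multi-APS.

**Condition-specific isoforms.** An isoform is expressed in a condition
iff its mean FPKM over that condition's replicates is ≥ 0.5 (default,
configurable); condition-specific iff expressed in exactly one
condition. The threshold is a package choice — no community standard
exists for "specific".

## lncRNAs

Candidates must be ≥ 200 nt (community convention for lncRNA length).
The coding filter is deliberately minimal: longest ATG→stop ORF over the
three forward frames (open-ended ORFs count to the sequence end), coding
iff ≥ 100 codons. `filter_noncoding` accepts external labels so output
from dedicated coding-potential classifiers can replace the stand-in.

Positional classes use fixed precedence sense > antisense > intronic >
intergenic: sense/antisense need ≥ 1 bp exonic overlap (same/opposite
strand), intronic requires full containment in a gene span without
exonic overlap (either strand), everything else placed is intergenic,
and unplaced records are unmapped. The precedence order is a package
decision; it makes the classes a partition.

Cis-targets are anchored on the **gene**, strand-aware: the window runs
from 10 kb upstream of the gene TSS to 100 kb past its 3′ end, the
lncRNA qualifies with ≥ 1 bp of window overlap, and additionally must
share a network edge with the gene scoring strictly above 0.2. The
signed distance reported is gene-oriented from the TSS to the nearest
lncRNA edge (negative = upstream, 0 = covers the TSS). In the pipeline,
the edge scores are |Pearson r| between the lncRNA's and gene's
expression rows; whether "interaction" should instead mean same-module
membership is genuinely open, so the direct-edge rule is the default and
module labels are carried alongside in the outputs.

## Methylome

**Context.** For a + strand cytosine at p the context reads bases
p, p+1, p+2; on the − strand, the complemented bases p, p−1, p−2
(5′→3′ on that strand). CG needs one following base; CHG/CHH need two;
sites whose needed bases run off the sequence or hit an N are no-data.
The vectorised genome scan and the scalar routine are cross-checked, and
both are verified against a 64-trinucleotide × 2-strand enumeration.

**mC calls.** A cytosine with coverage < 4 is no-data. Otherwise it is
methylated iff the one-sided binomial tail P(X ≥ m | n, p = error rate)
is below α = 0.01 after BH correction across all tested sites of the
condition. Error rate 0.01 approximates typical bisulfite non-conversion
plus sequencing error; all three knobs are exposed. This calling rule is
a package decision (cross-condition categories need per-site calls, and
no standard rule is universal).

**Categories.** Sites with any no-data status are excluded (reported
separately) rather than imputed. Of sites methylated somewhere:
methylated in all three conditions → constitutive; in exactly one
treatment → that treatment's specific class; anything else — including
control-only and two-condition patterns — → varied. The 2³ pattern space
partitions exactly into 1 + 1 + 1 + 4 patterns plus the methylated-nowhere
case.

**Region levels and profiles.** A region's level pools counts:
Σm / Σtotal per context (null if uncovered), so concatenating regions
combines levels coverage-weighted — a conservation identity the tests
assert to 1e-12. Gene profiles use strand-aware upstream [TSS−2 kb, TSS),
body [TSS, TES), downstream [TES, TES+2 kb); the 2 kb flank is a package
default. A gene-averaged (rather than pooled) alternative is not the
default but trivially computable from the per-gene table. Metagene
curves bin each region fractionally (20 bins default), reversed for −
strand genes.

**Profile clustering.** k-means (k = 4, 10 restarts, fixed seed) on the
six standardized upstream/body × context features. Downstream levels
are reported but not clustered on, because the four archetypal patterns
the grouping is meant to separate are defined by upstream and body
behaviour. Clusters are relabelled 1..k by decreasing upstream-CG mean,
making "cluster 1" reproducible across runs.

**DMRs.** 200 bp windows stepping 50 bp; a window is testable iff ≥ 4
context cytosines have ≥ 4× coverage in both conditions. Pooled counts
give a 2×2 table tested with a two-sided Fisher exact p, computed
in-package as a vectorised hypergeometric sum over the table support
(ties included within a 1e-7 relative tolerance, the conventional
definition); the implementation is validated against an independent
binomial-coefficient enumeration and against `scipy.stats.fisher_exact`
to 1e-10. BH runs across all testable windows of a context/pair;
windows with q ≤ 0.05 and |Δ| ≥ the context threshold (CG 0.4, CHG 0.2,
CHH 0.1) merge when overlapping or book-ended with the same direction,
and each merged region is re-scored on its pooled counts (a merged
region whose pooled |Δ| slips below the threshold is dropped, keeping
the reported set consistent). Direction is hyper/hypo in condition B
versus A; swapping the conditions provably flips directions and negates
deltas with p unchanged. All parameters are configurable defaults drawn
from common WGBS practice, not from any published tool's settings.

**Annotation.** Precedence gene-body > gene-upstream > gene-downstream >
TE > intergenic at ≥ 1 bp overlap, flanks 2 kb strand-aware; every DMR
gets one tag plus the list of all genes it touches.

## Expression and network

The DE rule is plumbing: per gene, log2 fold change of condition means
with a 0.1 pseudocount (FPKM zeros are common, particularly for
lncRNAs), Welch's t across replicates, BH over tested genes; DE iff
|lfc| ≥ 1 and q < 0.05. Zero-variance rows with equal means are not DE;
with different means they are (the mean difference is real even though
the t statistic degenerates, so p is set to 0 rather than propagating a
NaN).

Module detection is a **simplified analogue** of weighted co-expression
analysis and is documented as such: |Pearson r|^β adjacency (β = 6) on
standardized gene rows, dissimilarity 1 − adjacency, average-linkage
clustering cut at 0.25, clusters below the minimum size pooled as
unassigned. There is no topological-overlap transform, no dynamic tree
cut, and no network-rewiring score. Because the adjacency is unsigned,
two modules driven oppositely by the *same* condition are merged by
construction — planted-truth tests therefore use modules on distinct
conditions. Eigengenes are the leading right singular vector of the
standardized member submatrix, sign-oriented so the mean member
correlation is non-negative. Module ids are color-style labels assigned
by decreasing size. Module–condition association correlates the
eigengene with the condition's 0/1 sample indicator; p comes from the
correlation t statistic at n = samples and BH runs over the whole
module × condition grid; the sign is reported only under q < 0.05.

Subnetworks retain edges with |r| ≥ 0.8 among seed genes and their
direct neighbors and drop connected components containing no seed, so
every surviving node reaches a seed through retained edges.

## Synthetic data

The generator emulates the five input kinds of a three-condition
ethylene-treatment design at desk scale and plants machine-readable
truth for every downstream stage. Defaults for the end-to-end synthetic
run: 2 chromosomes × 200 kb at GC 0.4, 60 genes of 2–5 exons
(exons 150–400 bp, introns 80–300 bp, intergenic gaps ≥ 1.2 kb,
strands ~50/50); two baseline reads per gene plus per-category AS
perturbation rates; planted splice-boundary shifts of ≥ 9 bp so that
planted A3S/A5S/IESC events exceed the 5 bp terminal-end fuzz by
construction; APA models shifted > 60 bp; methylomes at 20–30× Poisson
coverage with binomial methylated counts (level + 0.005 conversion
error), CHH base levels rising CK < LE < HE to mimic the
treatment-dependent CHH gain; planted DMRs of 300 bp at Δ = 0.5, mutually
separated by ≥ 400 bp so merged calls cannot bridge two planted regions;
expression as baseline FPKM ~ U(3, 8) with multiplicative condition
effects (×4 up or ÷4 down) and Gaussian noise (σ = 0.2), three planted
modules on distinct conditions including one repressed control module.
Exon-skipping and intron-retention perturbations require ≥ 3-exon
parents, because retaining the only intron of a 2-exon gene leaves a
mono-exon model that is unclassifiable by design.

What the generator does **not** emulate — and hence what green tests do
not demonstrate about real data: read-level errors and chimeras,
alignment artefacts, bisulfite conversion chemistry (counts are drawn
directly), PCR duplicates, expression count overdispersion beyond
Gaussian noise, overlapping genes, alternative TSSs, and repeat-driven
methylation structure. Recovery at precision = recall = 1 shows the
stages are correct against their definitions, not that real pineapple
data would be this clean.

Each generator takes its own seed; the pipeline derives per-stage seeds
from a single master seed, and all five generators are byte-reproducible
for a fixed seed.

## Problem sizes

The test and acceptance runs use deliberately small instances chosen as
the package's own study conditions: 200-gene/0.9 Mb genomes for
transcript-stage recovery, 60 kb genomes × 20 seeds at 30× coverage and
10 planted DMRs per context for DMR operating characteristics, 24 genes
× 4 archetypes for profile clustering, 60 genes/9 samples for the
network stage, and the default 2 × 200 kb configuration for end-to-end
determinism.

## Known limitations

* Sense-overlapping lncRNAs are structurally indistinguishable from
  novel isoforms of their host gene in the pipeline's candidate funnel
  (which starts from novel loci); they are classified correctly when
  presented as candidates, but the automatic funnel will fold them into
  the gene's isoform set, as any structure-only pipeline must.
* The AS classifier emits both an A5S and an A3S when both boundaries of
  one matched intron shift without an accompanying internal-exon change;
  geometries outside simple single-event perturbations can legitimately
  decompose into several events.
* The DMR caller reports window-grid coordinates, so called boundaries
  are quantized to the step size rather than to cytosine positions.
* The network stage is a minimal analogue; its module boundaries and
  association q-values are not comparable to published WGCNA/SPINE
  results.
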
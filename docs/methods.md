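# Methods

## Problem and model

isoweave assembles transcripts de novo from fixed-length RNA-seq reads,
without a reference genome. The central design choice is to extend
contigs by *whole reads* rather than k-mers: at every step the contig is
grown by the read holding the longest exact terminal overlap (at least
`l` bases), which preserves the full nucleotide arrangement of each read
instead of the k−1 characters a de Bruijn step carries.

The pipeline: deduplicate reads → build the overlap index → extend
seeds into contigs → grow branches at divergence points → cut contigs
into splicing-graph segments → extract s→t paths → filter → (optionally)
evaluate against an annotation.

## Read model

Reads are uppercase ACGT strings of one fixed length `L`. Identical
sequences are collapsed into a unique read whose *multiplicity* is used
as its coverage everywhere downstream. Reads with ambiguous bases or a
different length are dropped whole: the 2-bit packing of the index and
the exact-overlap extension both assume the 4-letter alphabet and fixed
`L`. Reads are indexed as given (strand-specific protocol); a
`both_strands` flag additionally indexes reverse complements for
unstranded libraries. Base qualities are parsed but ignored; no step is
quality-aware.

## The overlap index

Two tries answer "which reads overlap this contig end the most?" in
O(L) per query.

* **Left-extension tree**: a trie over the distinct (L−1)-character read
  prefixes. Each read's suffix of length `l..L−1` that exists as a
  complete root path gets the read's id stored at the path-end node.
  The restriction to prefix paths is the simplification: a suffix can
  only ever be used in left extension if it equals some read's prefix.
* Id-free leaves are then deleted iteratively (they can never answer a
  query), and
* the **right-extension tree** is built from the trimmed left tree: each
  read prefix of length `l..L−1` whose path ends at an id-bearing node
  is inserted *reversed*, carrying the read's id. Querying it with the
  reversed 3' contig suffix finds reads whose prefix matches the contig
  end.
* Finally the top `l` levels of both tries collapse into one layer keyed
  by 2-bit-packed l-mers (A=0, C=1, G=2, T=3, first base most
  significant), which bounds a lookup by one hash probe plus at most
  L−1−l single-character steps. This forces `l ≤ 32`.

Node counts follow the convention that the root is counted and a
compressed l-path is one node; this is the only convention that
reproduces the worked example's 16 → 10 → 7 sequence, which the test
suite and the acceptance script pin down.

A query returns the deepest id-bearing node on the matched path: the
overlap length and the uid set attaining it. Stored uid lists are kept
sorted and duplicate-free so candidate order is deterministic.

## Contig extension and branching

Seeds are reads whose multiplicity strictly exceeds the mean; if nothing
does (duplicate-free data) every read seeds, in uid order — otherwise
such data would assemble nothing. Extension exhausts the right direction
and then the left (the order is immaterial on error-free data). At each
step, among the candidates at the deepest id-bearing node, the read
whose multiplicity is closest to the contig coverage (member read-bases
over contig length) is chosen; ties go to the smaller multiplicity, then
the smaller uid. A direction stops when no candidate remains or the
chosen read is already placed in the contig (this also breaks circular
overlap traps). Every placement is asserted to match the contig exactly
over its span.

Unchosen candidates are divergence points. Each seeds a branch contig
grown only away from its anchor; a branch that incorporates a read
already placed in a main contig converges there. The exact junction
coordinates are recovered by extending the sequence agreement maximally
on both sides of the anchor and the converging read — so an
exon-skipping bubble collapses to an empty alternative segment and a
direct skip edge, and junction coordinates land on the true exon
boundaries even when neighbouring exons share their first base. A
convergence whose coordinates would point backwards on the same contig
is rejected to keep the graph acyclic. Branches are grown immediately
after their main contig so their reads are consumed before the next
seed is drawn; branch-onto-branch convergence is not modelled
(a limitation: third-order splicing structure within one bubble can
yield duplicated segments rather than nested bubbles).

## Splicing graph

Divergence/convergence coordinates cut each contig into maximal
unbranched segments; segments plus non-empty alternative segments are
vertices, and contigs linked by convergences form one locus. Weights
are reads per base:

* `w(v)` = summed multiplicity of reads whose placement overlaps the
  segment, divided by segment length (branch placements are projected
  through the junction coordinate maps; a read placed identically twice
  counts once);
* `w(u→v)` = summed multiplicity of distinct reads found spanning the
  junction in its ±(L−1)-base sequence context, divided by L. A
  junction with no spanning read may instead be supported by a mate
  pair placed consistently on both sides (weight pairs/L).

A virtual source s and sink t are attached to the in-degree-0 and
out-degree-0 vertices with w(s,v)=w(v), w(u,t)=w(u), w(s)=Σ out,
w(t)=Σ in. Edges lighter than `trim_rel_weight` (default 0.05) times
their heaviest sibling (sharing source or target) are trimmed, then
vertices off every s→t path are dropped. The 0.05 default is a
package choice; it is exposed in the configuration.

## Path extraction

**Enumeration** lists every s→t path with an explicit-stack DFS,
children in ascending vertex id. It is exponential in pathological
graphs, so above `max_enum_paths` (default 10 000) per locus it falls
back to the hybrid strategy with a warning.

**Hybrid** computes, in topological order (Kahn with smallest-id
tie-break), `capacity(v) = max over in-edges (u,v) of min(capacity(u),
w(u,v), w(v))` with `capacity(s) = w(s)`; predecessor ties prefer the
longer path from s in bases (virtual vertices contribute 0), then fewer
edges, then the smaller id — "longest among thickest". Backtracking from
t yields one path whose bottleneck equals capacity(t) (asserted); its
bottleneck is subtracted from every vertex and edge on it (floored at
0, with the s/t weight identities restored), and the loop repeats until
all edges reach zero weight, capacity(t) falls below `hybrid_stop_cov`
(default 2, aligned with the coverage filter), or |E| paths have been
extracted. The |E| cap guarantees termination even when a round's
bottleneck is a vertex and zeroes no edge.

Both strategies' outputs pass the same filters: length strictly over
200 bases; bottleneck coverage strictly over 2 reads per base; at least
20 reads (multiplicities summed, exact substring placement) mapped; and
for paired data every base covered by a read or by the span between
co-mapped mates (each occurrence of one mate is bridged to the nearest
downstream occurrence of the other). Coverage in the second rule is the
path bottleneck, the same quantity the hybrid DP optimises.

## Evaluation

Assembled and annotated transcripts are aligned in-process with an
affine-gap local aligner (match 1, mismatch −2, gap open −3, extend
−1). Identity is matches over the alignment length, with the
denominator floored by the shorter sequence's length: a raw local
identity would score a short perfect block shared by unrelated
sequences as 1.0, while the floor makes unrelated 300-mers score ≈0.05
and leaves a perfect substring at 1.0. Covered fraction counts
annotated bases inside aligned (match/mismatch) columns. An assembled
transcript is *full-length reconstructed* at ≥95% identity to some
annotated transcript; an annotated transcript is *full-length
identified* when its single best-scoring assembled partner covers ≥95%
of it (no stitching of fragments). recall = identified/annotated;
precision = reconstructed/assembled; with no ground-truth set, raw
counts accompany the ratios.

## Synthetic data

The generator emulates the assembler's target regime: a multi-exon gene
with isoforms as strictly increasing exon chains, exon sequences
screened against shared 16-mers (so distinct exons never alias in the
index at practical `l`), and reads tiled along each isoform at stride
`step` plus a final window, replicated per-isoform `abundance` times.
Defaults: L=50, step=2, error rate 0 — with step ≤ L−l every adjacent
tile overlaps detectably and per-base coverage is abundance·L/step,
placing the canonical fixture (exons 300/250/350, isoforms ABC and AC
at abundances 6 and 5) above every default filter at vertices
(≈3–5.5 reads/base) and junctions (≈2.4–2.9 reads/base). Substitution
errors are available; indels are not modelled because extension is
exact-overlap. Even exon lengths keep junction tilings phase-aligned
across isoforms so shared exons deduplicate into shared reads; the test
suite also covers the de-phased case.

What passing on this generator does *not* show: robustness to
sequencing errors at realistic rates, non-uniform coverage, intronic or
antisense contamination, or genuinely repetitive transcriptomes — real
libraries violate all four.

## Numerical and degenerate-input choices

Weights are floats compared exactly in the DP (ties arise from
constructed integer weights, not measurement); peeled weights below
1e-12 count as zero/covered. Coordinates are 0-based half-open
throughout. Degenerate inputs: empty read files parse to an empty list
with a warning; a fully-filtered read set raises "no usable reads"; a
terminus shorter than `l` returns an empty hit with a warning; an empty
locus graph augments to bare s/t; zero evaluation denominators report 0
with a warning.

## Problem sizes

The default test and acceptance runs use desk-scale inputs chosen as
representative rather than exhaustive: the four-read worked example,
200 random read sets (≤200 reads, L≤30) for index/oracle equivalence,
500 random DAGs (≤10 vertices) for the path algorithms, and the
two-isoform locus (~4 000 raw / 450 unique reads) end to end.
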
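# Methods

## The clustering model

`longclust` assumes that (i) transcripts of one gene share a large fraction of
their sequence (exons), so any two reads from the same gene share many k-mers
even at long-read error rates, while (ii) reads from distinct genes share
essentially none. Under these assumptions the hard part of clustering is not
recognising similarity but certifying *dissimilarity*, which needs no
alignment — a small shared-k-mer count suffices. The pipeline therefore
selects a maximal set of mutually dissimilar reads (the pseudo-reference, one
proxy per expressed gene), and lets a spliced aligner do the similarity work:
every read that aligns properly to a proxy joins that proxy's cluster.

The greedy solver for the underlying program (maximise |P| s.t. all pairwise
similarities < α) processes reads longest-first because the longest reads
carry the most complete exon structure and make the best gene proxies. Only
reads longer than the iteration's threshold *L* are candidates; the very
first sketchable read is admitted unconditionally (the feasible set is never
empty). Candidate pruning uses an inverted minimizer index — reads sharing no
hash have similarity 0 by definition — and is exactly equivalent to the
all-members comparison loop (tested).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.03 | maximum sketch similarity tolerated between two gene proxies; the working point that separates same-gene from cross-gene read pairs at ONT error rates |
| `iterations` | 3 | rounds of extract-align-assign; later rounds recover genes whose reads were all below *L* or aligned improperly |
| `L_fractions` | (0.6, 0.8, 0.9) | *L* is the N60 length of the reads in play in round 1, N80 in round 2, N90 in round 3 and beyond; tightest first for speed, relaxed later for coverage |
| `k` | 11 | minimizer k-mer size, bp. Matches the spliced aligner's k. With per-base error *e* on *each* of two same-gene reads, a k-mer survives intact in both with probability ≈ (1−e)^2k: 0.20 at e=0.07 and 0.059 at e=0.12 — both above α even in the low tail. At k=15 these drop to 0.11 and 0.021: the tail of the first crosses α (same-gene reads get admitted as separate proxies, splitting genes) and the second is below α outright. Cross-gene sharing is what bounds k from below: at k=9 random sharing between 1-2 kb reads approaches α, at k=11 it stays ~100× under it. |
| `w` | 5 | minimizer window (k-mers per window). Sketch density ≈ 2/(w+1) ≈ 1/3 of k-mers; a dense window limits the extra variance that window-minimum selection adds on noisy reads (with w=10 the selection noise pushes tail same-gene pairs under α at 12% error). |
| `canonical` | true | per-k-mer strand canonicalisation (min of 2-bit packing of k-mer and its reverse complement) makes sketches strand-symmetric; required for cDNA reads, harmless for dRNA |
| `threads` | 1 | minimap2 threads; does not affect output content |

Aligner invocation is fixed to `minimap2 -ax splice -k 11 -t <threads>`;
secondary alignments are kept (default aligner behaviour) because the
proper-alignment rule needs to know whether a read has any.

## Proper-alignment rule — reading choices

* Matches/mismatches come from `=`/`X` CIGAR ops when present, else from
  M ops plus the `NM` tag (`mismatches = NM − inserted − deleted bases`).
  Both encodings of one alignment give identical counts (tested).
* `N` (intron) ops are excluded from the deletion count: with spliced
  alignment a proxy whose isoform lacks one of the read's exons legally skips
  it; counting the skip as a deletion would reject most multi-exon
  alignments.
* Hard clips count as clipped bases along with soft clips, so the rule does
  not depend on the aligner's clip encoding (primary records normally
  soft-clip, making this a no-op in practice).
* The clip comparison is waived for reads with no secondary alignment: a
  read that only matches one proxy is unambiguous even when mostly clipped.
* Unmapped reads and failed primaries both go to the next iteration's input.

## Evaluation

Ground truth from a reads-vs-genome SAM keeps each read's primary alignment
as a half-open interval; classes are connected components of same-chromosome
interval overlap (≥ 1 bp), computed by a sort-and-sweep that equals
brute-force union-find (tested on 10⁴ intervals). Overlap is strand-agnostic,
so overlapping antisense genes merge into one class — a limitation inherited
from the construction. Unmapped reads are excluded: they have no class.

ARI, FMI are computed from integer pair counts over the contingency table
(exact up to the final division); V-Measure uses homogeneity/completeness
with β=1; NMI normalises mutual information by the arithmetic mean of the two
entropies, the convention under which NMI and V-Measure coincide. Partitions
identical up to relabeling (permutation-pattern contingency) report exactly
1.0 on all four metrics. Reads the tool leaves unclustered are scored as
singleton clusters — dropping them would inflate every metric. The
expression-stratified report sorts classes by size (ties by class id) and
splits the class list into five contiguous parts of near-equal class count
(`numpy.array_split` semantics: 7 classes → parts of 2,2,1,1,1).

## Synthetic data

The generator emulates the structure the algorithm assumes: each gene is an
independent random chain of 3–8 exons (80–400 bp), with 1–5 isoforms — the
full chain plus exon-skipping variants that drop one or two exons (never
below two), so isoforms of a gene share most of their bases while genes share
none. Reads draw a gene by expression weight (log-normal σ=1 by default), an
isoform uniformly, optionally truncate from the 5′ end (3′-biased coverage
mode), then pass through an independent per-base error channel
(substitution/insertion/deletion mix 40/30/30 at 7% for the ONT preset, 1%
for the PacBio preset) and flip strand with probability ½ in cDNA mode.
Default experiment size — 20 genes, 2000 reads — is the package's reference
benchmark; it runs in seconds and exercises every pipeline stage including
multi-iteration recovery.

What the generator does **not** model: basecaller-specific and homopolymer
error structure, chimeric reads, adapters/barcodes, genes that overlap on the
genome or share paralogous exons, intron retention, and positional coverage
bias beyond simple truncation. Perfect recovery on this benchmark therefore
shows the machinery is correct under the model's own assumptions; it does not
predict accuracy on real libraries, where paralogy and chimeras blur both the
clustering and the alignment-derived truth.

## Numerical and degenerate-input choices

* K-mer hash: splitmix64 finalizer over the 2-bit packed k-mer — seed-free,
  bijective on 64 bits (distinct k-mers never collide for k ≤ 31), identical
  across platforms and runs.
* Length ties in sorting and selection break by ascending read index; class
  and cluster ids are assigned in deterministic sweep/admission order, so a
  rerun is byte-identical.
* Nxx uses `cumsum >= fraction × total` on the descending lengths; reads of
  non-positive length and empty length lists are errors.
* Reads shorter than k+w−1 sketch to the empty set; they are never selected
  as proxies (an empty sketch satisfies the dissimilarity constraint
  vacuously, not meaningfully) but still participate as alignment queries.
* An iteration that selects zero proxies (nothing sketchable left) stops the
  pipeline; remaining reads are reported unclustered. Empty input yields an
  empty assignment, not an error.
* Singleton clusters (a proxy that attracted nothing) are kept: they are
  putative genes.

## Known limitations

* No cross-iteration merging: a gene partially assigned in round 1 whose
  remaining reads seed a round-2 proxy ends up split. At the default error
  rate this is rare (it requires a proper-alignment failure against the
  gene's own proxy); at 12% error it is the main loss mode, visible as
  cluster counts above the true gene count.
* α, k and w trade gene splitting against gene merging; the defaults target
  the 5–15% error band and are not tuned for consensus-corrected (≤1% error)
  reads, where larger k would gain specificity.
* The evaluation-side truth construction merges overlapping antisense genes
  (strand-agnostic overlap) and inherits aligner bias on real data.
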
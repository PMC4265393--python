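# Methods

## Problem setting

Amplicon surveys of a marker gene (e.g. the 18S rRNA V5 region) sequence a
short window (~250 bp after truncation) of a gene whose reference phylogeny
is built from full-length sequences. Two platform realities drive the
design: homopolymer run lengths are frequently miscalled by flow-based
sequencers, and the short amplicon carries too few informative sites for
reliable de novo phylogenetics. The pipeline therefore (i) measures
sequence similarity in a way that discounts run-length uncertainty and
(ii) infers relationships by *placing* short sequences into a fixed
full-gene reference tree rather than building a tree from them.

## Homopolymer-aware alignment

`hp_align` aligns a query against the sequence graph of its partner
(conceptually the cluster centroid, assumed error-free by abundance).
Every maximal run of one base with length L ≥ `min_hp_len` (default 3)
receives skip edges that allow up to `max_hp_skip` (default 1, never the
whole run) trailing bases to be omitted at zero score cost. The dynamic
programme is a five-state affine-gap Gotoh recursion (substitution, gap in
either sequence, free skip in either sequence) maximising the lexicographic
objective (score, #match columns, −#counted columns), packed into one
float64 key; the secondary terms make the reported similarity deterministic
and direction-independent under symmetric scoring. Defaults: match +1,
mismatch −2, gap open −3, gap extend −1; a gap of length g costs
open + g·extend. With `hp_model=False` the recursion reduces exactly to
classical Needleman–Wunsch/Gotoh (verified against an independently coded
oracle in the test suite).

Skip semantics. A skip chain must *enter from* and *exit into* a match of
the run base (or the alignment end). This restricts skips to length
uncertainty of runs both sequences share, which is what the error process
produces; without the restriction, free skips would also fire inside
unrelated sequence regions.

Similarity is #match / (#columns − #hp_gap); hp_gap columns are score-free
and uncounted, so sequences differing only by ≤ `max_hp_skip` bases per
qualifying run have similarity exactly 1.0.

Known limitation: a true single-base indel immediately adjacent to a
homopolymer run is indistinguishable from "substitution + run slip", and
because skips are score-free the aligner may prefer the latter when it
scores higher. For such pairs the hp-aware similarity can fall below the
plain similarity by O(1/length) (observed magnitude ≤ ~0.005 on random
mutated pairs). At clustering thresholds of 97–99% this has no practical
effect, but "hp similarity ≥ plain similarity" is *not* a universal
identity; it holds exactly for pairs differing only within runs, which is
how the property is tested.

## Preprocessing

Reads are laid out barcode + primer + insert. Assignment requires a unique
barcode within `max_barcode_errors` Hamming mismatches (default 1; two
barcodes within tolerance → rejected as ambiguous) and a primer match with
≤ `max_primer_errors` mismatches (default 2; IUPAC codes expand to their
base sets). Errors are counted as fixed-position mismatches, the standard
454 demultiplexing convention — indels in barcode/primer are not modelled.
Quality filters (minimum, mean, sliding-window mean, ambiguous bases,
length) default to permissive values since no specific thresholds are
assumed; truncation to `truncate_len` (default 250) discards shorter reads
because the clustering similarity presumes equal-length inputs.
Dereplication conserves read counts per sample. The copy-number gate keeps
a unique sequence iff its count in *some* sample reaches n ("in a given
sample" semantics); it gates entry to clustering without zeroing
sub-threshold counts. Denoising and chimera removal are external,
upstream steps by design.

## Clustering

Greedy, abundance-ordered, best-fit: sequences are processed in descending
total copy number (ties broken lexicographically) and join the
highest-similarity centroid at or above the threshold, else found a new
OTU. Best-fit (rather than first-fit) assignment makes the partition
independent of centroid creation order beyond the abundance ranking; ties
go to the more abundant centroid. The centroid is always the most abundant
member by construction. `multisample_filter` optionally drops OTUs seen in
a single sample; the abundance matrix conserves the summed copy numbers
and is exported as BIOM 1.0 JSON. OTU labels come from the most similar
reference leaf (glocal alignment), with ties within 1e−6 joined into one
label to make the ambiguity visible.

## Placement

Candidates are extant reference leaves only. The query is aligned
end-to-end with free end gaps on the ungapped full-length reference
sequence (the amplicon is a gene subregion). The default search is
exhaustive; an optional prescreen ranks leaves by edlib infix edit
distance and aligns only the top k (exact for the best hit in practice,
off by default). Ties within `tie_epsilon` = 1e−9 of the best similarity
are resolved uniformly at random from the supplied seed and flagged on the
Placement record. The pendant branch length is the Jukes–Cantor distance
of the query-vs-target alignment with p = mismatches / counted columns
(hp_gap columns excluded, consistent with the similarity); p ≥ 0.75
saturates to a configurable maximum (default 3.0) with a warning. The
query attaches as a sister of the target leaf, bisecting the target's
branch at its midpoint (configurable fraction); reference topology and
pairwise path lengths are preserved to numerical precision. The alignment
gains the query row in reference coordinates, with query insertions as new
columns gapped in all other rows. Pruning keeps queries plus each query's
nearest reference leaf, suppressing pass-through nodes with branch lengths
summed; trimming keeps the column window covered by the queries.

## Robinson–Foulds and the leave-out simulation

Bipartitions are canonicalised as the split side not containing the
lexicographically smallest leaf (which also removes the rooted-tree
duplicate at the root). The normalised distance divides the symmetric
difference by the *total internal edge count of both trees* — for two
binary trees this is the conventional 2(n−3), and it remains well defined
for the multifurcations pruning can create.

Each simulation replicate samples `n_reference` leaves as the working
reference (induced subtree + alignment rows), takes `n_query` of the
remaining leaves, cuts a `region_len` column window from each query's
alignment row (the amplicon stand-in; the window is a configurable column
range since in-silico PCR is out of scope), places the queries, and
compares the placement tree restricted to the query leaves against the
queries' induced subtree in the original tree. The random-tree baseline
replaces the placement tree with a uniformly random resolved topology on
the same leaves. Everything is reproducible from the seed (per-replicate
generators are spawned as `default_rng([seed, replicate])`).

## Synthetic data

`synthetic` generates: random binary trees (uniform coalescent-style
joins; branch length = floor + exponential, defaults 0.01 + Exp(0.05)
expected substitutions/site), Jukes–Cantor evolution of ungapped
alignments (checked against the closed-form p(d) = ¾(1 − e^(−4d/3)) in the
tests), and 454-like reads: barcode + concrete primer realisation +
template with per-base substitutions (default 0.001) and homopolymer slips
of ±1 base per run with probability min(0.01·(L−2), 0.5) — linear growth
with run length, reflecting the flow-signal origin of 454 length errors.
Qualities decline linearly (37 → 30) with Gaussian jitter. The community
fixture uses 20 templates on a tree with branch floor 0.03 (pairwise
divergence well beyond the 99% clustering threshold, as between congeneric
18S sequences), 4 samples, each template in 2 samples at lognormal depth
around 25 reads.

What the generator does *not* emulate: non-homopolymer indels (after
denoising and truncation the real workflow leaves slips as the dominant
length error, and the clustering similarity assumes equal lengths),
chimeras, flowgram-level noise, and primer-site mutations. Passing tests
therefore demonstrate correct behaviour of the algorithms under the stated
error model, not robustness to chimeric or heavily indel-laden data.

## Problem sizes and numerical choices

The shipped checks use: 1000 random pairs (length ≤ 30) for the aligner
oracle, 10 000 run-edited pairs for the homopolymer property, a
20-template community (~1000 reads) for clustering recovery, a 100-leaf ×
500-column reference for the placement self-test, 200 random 8-leaf tree
pairs for RF cross-validation, and a 200-leaf reference with n_ref = 150,
n_query ∈ {10, 40}, 100 replicates (edlib prescreen top-10) for the
accuracy simulation — sizes chosen so the whole suite runs in minutes on
one CPU while still exercising every code path at meaningful scale; the
full study-scale defaults (750 references, 1000 replicates) remain the
`SimConfig` defaults. Similarity comparisons use an absolute tolerance of
1e−12; threshold comparisons subtract 1e−12 before comparing; path-length
preservation is asserted at 1e−9. The DP key packing is exact for integer
scores and sequences up to ~2000 bases.

## Known limitations

- The hp-similarity/plain-similarity ordering caveat described above.
- Placement targets extant leaves only; ancestral-node placement,
  likelihood-weighted multi-placements and jplace output are out of scope.
- BIOM support is the 1.0 JSON dialect only (no HDF5).
- FASTQ quality encoding is fixed to Phred+33; Phred+64 files are not
  auto-detected.
- The attachment point on the target branch (midpoint) and the JC pendant
  length are pragmatic conventions; the placement literature does not fix
  them for this setting.
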
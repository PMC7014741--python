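# Methods

## Model

A de novo transcriptome assembly is reduced to a bipartite relation between
contigs and sequencing *fragments* (read pairs collapsed by query name).
Nucleotide sequence, alignment position and mapping quality are deliberately
ignored: a contig is identified with the set of fragments that map to it,
and similarity between contigs i and j is the fraction of the smaller
fragment set that the two share,

    w_ij = R_ij / min(R_i, R_j),  w_ij ∈ (0, 1],

with w_ij = 1 exactly when the smaller set is contained in the larger. The
method makes no attempt to infer whether two contigs derive from "the same
gene"; it only groups contigs whose read evidence overlaps, which is the
strongest statement the data support in the absence of a genome.

The pipeline is: (1) parse SAM/BAM into the fragment–contig table, keeping
sample origin; (2) filter low-evidence contigs; (3) build the read-sharing
graph over passing contigs; (4) split it into connected components
("pre-clusters"); (5) agglomerate each pre-cluster independently; (6) emit
the partition, counts and representatives.

## Parameters

* **l ≥ 0** (default 2) — minimum effective coverage s_i / c_i, where
  s_i is the summed length (bases) of all fragments mapping to contig i and
  c_i its length (bp). The boundary is inclusive: s_i = l·c_i passes
  (a 750-bp contig with nine 250-base reads, coverage exactly 3, passes at
  l = 3). Unlike a fixed minimum read count, the criterion scales with
  contig length. Filtered contigs are not discarded; they are emitted as
  `low_evidence` single-contig clusters so the output partitions the whole
  assembly.
* **d ∈ [0, 1]** (default 0.3) — merge threshold. Entities merge while the
  best available weight is **≥ d** (the inclusive comparison makes d = 1
  meaningful: subset read sets still merge). d = 0 collapses each
  pre-cluster into one cluster (z_min); d = 1 yields the finest clustering
  (z_max). z(d) is non-decreasing and the partitions are nested (each
  higher-d partition refines each lower-d one), which is what makes
  bisection for a target cluster count sound.

## Agglomeration and determinism

Each pre-cluster's candidate edges live in a max-weight binary heap. Merges
create a fresh entity whose fragment set is the exact union of its parents'
sets; weights against all other live entities are recomputed exactly (no
incremental approximation) and pushed. Entries referring to consumed
entities are discarded lazily on pop — entity ids are never reused, so an
entry is valid iff both ids are still live. Ties on weight break by
(smaller min entity id, then smaller max entity id); initial ids follow the
lexicographic order of member contigs and merged entities take consecutive
fresh ids. This total order makes results reproducible run-to-run and
independent of the worker count; pre-clusters are distributed over a thread
pool and reassembled in a fixed order. Cluster ids are assigned by the
lexicographically smallest member contig.

Shared-read counting uses an inverted index (fragment → contigs), so only
pairs with R_ij > 0 are ever materialized; the filter is applied before
edge construction, which is observably identical to building all edges and
then zeroing a filtered contig's weights.

## Counting conventions

R_i, R_j and R_ij count *distinct fragments pooled across samples*; the
per-sample counts are kept only for the output. A fragment maps to a contig
iff at least one of its mates has a mapped primary or secondary alignment
there (orphan mates count; supplementary/chimeric records do not). s_i sums
query lengths, not aligned-block lengths, so soft-clipped bases count. A
fragment whose contigs end up in two different final clusters contributes to
both clusters' raw counts; within one cluster it is counted once per sample.

## Tuning procedures

`sweep_d` runs the full clustering on a d grid (endpoints always included)
and records z(d); a non-monotone curve is raised as an engine defect rather
than smoothed over. Given an external per-contig identification (e.g. BLAST
hits against a reference transcriptome, produced outside this package),
`efficiency_curve` counts n_As — distinct external ids among each run's
representative contigs (representatives, not whole clusters, by default;
`over_clusters=True` switches) — and Ef = n_As / z. Knees of z(d) are
located by the extreme discrete second difference of the grid curve: the
biggest slope drop in the left half (d_l) and the biggest rise in the right
half (d_r), ties resolved toward the respective extreme; a perfectly linear
or flat curve sets a no-knee flag and returns the grid endpoints. This is
one concrete operationalization of a visually defined feature; on coarse
grids the knee location is only as fine as the grid. `solve_for_target_z`
bisects d for a requested z* in [z_min, z_max], memoizing evaluations,
stopping when the bracket is below 1e-3 or an evaluation is within the
requested tolerance, and returning the evaluated d minimizing |z − z*|.
Because z(d) is a step function, the returned d* is one point of a plateau,
not a unique root.

## Evaluation

Clusterings are scored against ground-truth locus labels over contig pairs:
a (same cluster, same locus), b (same cluster, different locus), c
(different cluster, same locus), d (neither); recall R = a/(a+c), precision
P = a/(a+b). Counts are computed from the cluster × locus contingency table
via binomial coefficients, which is exactly equivalent to enumerating all
C(n,2) pairs. Contigs without a truth label are excluded first. Undefined
ratios (no positive pairs at all) are reported as missing, never as 0.
Low-evidence singletons participate in the evaluation by default; the CLI
offers `--exclude-low-evidence` because some comparable tools drop such
contigs entirely, which changes the pair universe.

## Synthetic data

The generator emulates the phenomena that make assembly clustering
non-trivial: several contigs per locus with controllably overlapping
fragment sets (`shared_fraction_within` of the smaller contig's fragments),
optional cross-locus sharing (`shared_fraction_between`, creating
false-positive pressure), multiple samples, multi-mapped fragments and junk
contigs that fail the coverage filter. Sharing is realized through common
fragment pools consumed as prefixes, so pairwise overlap fractions hold by
construction rather than merely in expectation. Defaults: 20 loci, 2–4
isoforms each, within-sharing 0.6, between-sharing 0, 30–60 fragments per
contig, 100-base reads, 2 samples, 5 junk contigs — a regime in which the
default d = 0.3 sits well below the within-locus weight (≈ 0.6) and well
above cross-locus noise (0), so the true partition is recoverable exactly,
while raising between-sharing degrades precision as intended.

What the generator does *not* emulate: sequencing error, expression-level
variation between samples, partial overlaps along contig coordinates,
chimeric contigs, or realistic fragment-length distributions. Reads are
abstract identifiers with no sequence (the method never reads sequence), and
emitted SAM uses a minimal dialect (unpaired records, POS 1, full-length
match CIGAR, MAPQ 0). Tests passing on these fixtures therefore validate
the combinatorial machinery — weights, filtering, agglomeration, counting,
evaluation — not robustness to alignment noise or to assemblies whose
read-sharing structure differs from the pool model.

## Numerical and degenerate-input choices

* Weights are exact rational arithmetic on set cardinalities evaluated in
  floating point; no tolerance is applied to the d comparison (w ≥ d is the
  literal float comparison).
* A contig present in the header but receiving zero fragments is
  low-evidence for any l > 0 and passes at l = 0 (where it becomes a
  singleton; its empty read set is never involved in a weight).
* Duplicate (fragment, contig) records collapse; a mate observed through
  several records contributes its length once.
* Conflicting contig lengths across input files are an error, not a
  warning.
* Test problem sizes: oracle-equivalence runs use ≤ 30 contigs and ≤ 500
  fragments per instance (the naive re-sort oracle is cubic), and synthetic
  recovery fixtures use 20 loci × 3 isoforms; these sizes exercise every
  code path while keeping the full suite in seconds.

## Known limitations

Repeat-derived reads shared across unrelated loci chain pre-clusters
together and, at low d, can collapse distinct genes into one cluster — an
inherent property of the read-sharing signal, controllable only via d.
The heap tie-break order is this implementation's own; other
implementations of the same algorithm may resolve equal-weight merges
differently and produce legitimately different partitions on ties.
Equivalence-class input (salmon/kallisto style) is not supported; input
must be SAM/BAM.
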
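# Methods

## The analysis model

`bcrnet` treats a bulk BCR amplicon library as a mixture of cDNA molecules
drawn from clones, where a clone is a unique (chain, V gene, J gene, CDR3
nucleotide sequence) combination. All downstream arithmetic is in units of
UMI-collapsed molecules: "read count" always means the number of distinct
UMI consensus reads assigned to a clone, never raw sequencer reads.

### UMI consensus

Reads sharing a UMI form a MIG. The consensus restricts members to the
modal read length (length disagreements within a MIG come from rare indel
errors; alignment is out of scope) and takes, per position, the base with
the maximal summed Phred quality, breaking ties by member count and then by
alphabetical base. The tie chain makes the result deterministic and
independent of read order. Consensus quality is the winning summed quality
capped at Q40.

MIGs smaller than a threshold *t* are dropped. *t* is either fixed
(default 2) or selected per sample from the MIG size histogram: smooth the
log1p counts over the *observed* sizes with a window-3 moving average, take
the main mode (largest smoothed mass at size > 1, ties to the larger size),
and set *t* = 1 + the size of the smoothed minimum strictly between the
size-1 error peak and that mode. Histograms without an interior valley
(e.g. the monotone histograms produced by geometric PCR depth) fall back to
the fixed value. The selected rule and value are logged per sample; *t* = 1
is permitted configuration (it disables the filter, appropriate for
noise-free or shallow libraries) but never chosen silently.

With per-base error ε and a majority vote over 3 reads, the per-base
consensus error is ≈ ε² (two coinciding errors) + (4/9)·3ε² (two
discordant errors resolved against the truth by the tie-break) ≈ 2.3ε²,
which the acceptance suite bounds by 2·(3ε²).

### CDR3 extraction and clonotypes

Each V segment carries an anchor motif ending at the CDR3 start, each J
segment one beginning at the CDR3 end; the CDR3 is the junction-internal
substring between them (anchors excluded), shifted by per-segment
`anchor_offset` values when a different junction convention is needed.
Extraction requires exactly one V-anchor hit and one J-anchor hit in the
read; zero hits, multiple hits, V/J from different loci, or an inverted
boundary each reject the read with a named reason, and rejection counts are
reported. Exact matching replaces germline alignment deliberately: the
built-in reference and the simulator are co-designed so anchor matching is
lossless on error-free reads, and real-data users with an upstream aligner
enter at the clonotype-table interface instead. Anchor mutations therefore
surface as rejections (counted), not as silently misassigned clones.

Productivity requires CDR3 length divisible by 3 (from a configurable
`frame_offset`, default 0 — the anchors in the built-in reference are codon
aligned) and no in-frame stop codon. Filters exclude clones but never alter
counts; fractions are recomputed over survivors after every filter, so they
always sum to 1.

### Clonality network

Edge rule: two clones are linked iff their V call sets intersect, their J
call sets intersect, and their CDR3s are Hamming distance 1 apart
(configurable up to `max_cdr3_distance`). Unequal CDR3 lengths are infinite
distance by default; a single-indel link is available behind `allow_indel`
but off, because SHM is substitution-dominated and cross-length links can
merge distinct rearrangements. Set-intersection gene matching lets
ambiguous multi-gene calls link. Construction buckets CDR3s by length and
compares byte matrices, which is exactly equivalent to evaluating the
predicate on all pairs (asserted against a brute-force oracle in tests).

Clusters are connected components. "Fully connected group" is read as
connectivity, not as a clique: SHM lineages are branched trees, which are
connected but not complete. Per cluster: total reads, fraction of the chain
group's reads, major clone (maximal count, ties to lexicographically
smallest CDR3), subclone count = members − 1, and branching metrics
(eccentricity of the major clone, maximal degree, variant read fraction).

Clusters with fewer than `min_cluster_umis` (default 2) supporting
molecules are removed *before* dominance scoring — the order is logged —
and fractions are renormalized. A cluster is dominant iff its fraction
≥ θ; θ defaults to 0.10 and the boundary is inclusive (the operational
rule "10% or more"). Dominant clusters are colored red, blue, green, …, in
descending fraction order (an artifact convention; only the palette is
meaningful), all others gray. Node display size is count^(1/3) × a scale
constant, which compresses the dynamic range enough to show a 90% clone
and singleton background on one plot; size ratios are invariant (8× count
⇒ 2× size).

Sample label: 0 / 1 / 2 / >2 dominant clusters ⇒ no_dominant_clone /
monoclonal / biclonal / oligo_polyclonal, taken per chain group. The
sample-level label comes from the heavy chain — each B cell carries one
productive heavy rearrangement, while light-chain repertoires are less
discriminative — and both group labels are always reported. IGK and IGL
records are pooled into one "light" analysis group (they compete for the
same light-chain denominator) while each record keeps its locus; V/J calls
are locus-specific, so cross-locus links cannot arise.

## The simulator

The generator emulates the observables of a bulk tumor library: planted
dominant clones with stated molecule fractions; a polyclonal background
whose fractions come from a symmetric Dirichlet over the remaining mass,
resampled until every background clone is below θ (so planted labels stay
identifiable); SHM as independent per-base CDR3 substitutions per molecule
at rate μ (star-like divergence from the root — this reproduces 1-bp
neighbor subclones, not phylogenetic tree shape); UMIs uniform over 4^L
(collisions possible and recorded, or suppressed); geometric PCR depth
(minimum 1; a fixed-depth mode exists for controlled experiments); and
uniform per-base sequencing errors over the whole read, UMI included.
Clone roots are germline V/J flanks around a random stop-free NDN, and
roots sharing a (V, J) pair are kept ≥ 3 substitutions apart so separate
planted clones cannot merge through 1-bp variants.

Defaults are the conditions used throughout the test suite: 5000 molecules,
μ = 0.005/base, ε = 0.003/base, mean PCR depth 5, UMI length 12, 30
background clones. The noise rates and depth are conventional values for
UMI amplicon protocols, not measurements of any particular library; they
are all exposed in `SimulationConfig` (YAML-serializable).

What the simulator does **not** model — and hence what passing tests do not
establish about real data: realistic germline gene usage and allele
diversity, indel SHM, isotype switching, chimeric PCR artifacts, UMI-aware
sub-clustering of collided UMIs, and quality-score heterogeneity (simulated
reads carry uniform Q40, so consensus voting reduces to majority). Real
upstream aligners also annotate junctions with their own frame convention;
the `frame_offset` knob exists because that convention may differ from the
junction-internal one used here.

## Numerical and design choices

- Determinism everywhere: all randomness flows from one seed through
  `numpy.random.default_rng`; grouping sorts by UMI; clones sort by
  (−count, chain, CDR3); identical seed and config give byte-identical
  FASTQ, tables and reports.
- Degenerate inputs are defined, not errors: empty read sets give empty
  MIG lists; zero accepted reads give an empty clone table with *Tr* = 0;
  a filter that removes every cluster yields an explicit
  `no_dominant_clone` classification and a logged warning.
- Fraction invariants are enforced to 1e-9 after every stage that changes
  membership.
- Dialect column maps are data (`bcrnet.io.DIALECTS`), overridable per
  call; gene-call score suffixes `(…)` are stripped, allele suffixes `*NN`
  kept, because the edge rule compares gene identity as exported.
- The DOT writer/reader is a minimal hand-rolled dialect (quoted ids,
  `--` edges); GraphML goes through networkx and carries all attributes.

## Problem sizes used in the checks

Acceptance-style checks run at desk scale: 50 simulated samples per
clonality class at 5000 molecules each for label recovery; 2 × 5000
molecules at fixed depth 3 for the consensus error bound; 20 seeds × 3 SHM
rates at 2000 molecules for branching monotonicity; 20 random tables of up
to 300 clones for the network oracles. These sizes give per-class recovery
estimates with ±~3% binomial precision and > 10⁶ consensus bases, while the
whole suite stays in the minutes range on one CPU.

## Known limitations

- Anchor-exact extraction cannot rescue reads whose anchor bases are
  mutated; at consensus error rates after UMI collapse this loses a small,
  reported fraction of molecules, uniformly across clones.
- UMI collisions merge two molecules into one MIG and are only quantified
  (by the simulator), not resolved by sequence sub-clustering.
- The histogram-valley threshold is an explicit reconstruction of a
  commonly used but under-specified heuristic; on monotone histograms it
  intentionally falls back to the fixed value rather than guessing.
- Cluster-level SHM grading counts distinct 1-bp variant clonotypes; it
  saturates once most single-mutation neighbors of a long-established
  clone are occupied, so it is a grade, not an unbounded mutation count.
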
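# Methods

## Coordinate and orientation conventions

Internally all positions are 1-based and intervals closed, so positions and
spans printed in cluster/contig tables can be compared digit for digit with
published tables. On-disk formats (BED, BEDPE, bedGraph) are 0-based
half-open. A breakend stores the boundary retained base and an orientation:
`LEFT_RETAINED` ('+') keeps the reference upstream of the position (the
fragment ends there), `RIGHT_RETAINED` ('-') keeps the downstream reference
(the fragment starts there). Junction identity for set operations is the
unordered pair of (chrom, pos, orient) triples; positional tolerance is a
parameter of the comparison operations, never of equality, because junction
coordinates in this setting are typically Sanger-confirmed to the base.

One convention wrinkle: published cluster tables list one coordinate per
breakpoint without orientation. When such a coordinate denotes the lower end
of a retained fragment we read it as the base *preceding* the retained start
(the BED/hydra breakend-start convention), which makes the printed fragment
lengths (upper minus lower coordinate) agree with retained-base counts.

## Two-sided microhomology

Let A be the retained sequence ending at the first arm's breakend and B the
retained sequence starting at the second arm's breakend, both read in
junction orientation (reverse complement applied for inverted fusions).
The seam can be slid right as long as B's first bases equal the reference
continuation past A's breakend (`mh_right`), and left as long as A's last
bases equal the reference immediately preceding B's breakend (`mh_left`).
`mh_len = mh_left + mh_right` counts the alternative seam placements — the
sequence shared by the two normal counterparts of the fusion and retained as
a single copy. Both sides are capped at a 50 bp window; windows truncated by
a contig edge are computed on the truncated window and flagged. The test
suite checks the caller against an independent oracle that exhaustively
enumerates breakpoint shifts and compares reconstructed fused molecules.

Microhomology and untemplated insertion are mutually exclusive calls: a
junction whose spanning sequence contains inserted bases gets `mh_len = 0`.

## The random-joining null and the enrichment test

Under blunt random joining of independent sequences, each side's extension
length is geometric with per-base match probability p = Σ_b f_b²
(¼ for uniform base composition), and the two sides are independent, so the
total K follows P(K = k) = (k+1)(1−p)² pᵏ and
P(K ≥ 1) = 1 − (1−p)² = 43.75% for uniform composition. The closed form is
validated in the tests against exhaustive enumeration of all 4⁸ flank pairs
of length 4 per side (the pmf is exact below the truncation boundary).
Uniform composition is the default because the expected rate it implies
(44% after rounding) is the standard reference value; non-uniform
composition is supported through p. The 50 bp window truncation changes the
null by less than 4⁻⁵⁰ and is ignored.

Enrichment of observed microhomology is tested with an exact one-sided
binomial test of #(mh ≥ 1) among insertion-free junctions against
P(K ≥ 1). The exact p-value of a discrete test is conservative, so the
result also carries the mid-p variant (half weight on the observed
outcome); calibration checks (uniformity of p under the null) are asserted
on the mid-p, and super-uniformity on the exact p. Summary fractions are
reported over two explicit denominators — all junctions, and insertion-free
junctions — because published statements of the microhomology rate use both.

## Breakpoint clustering

Per chromosome, sorted breakends are chained while consecutive positions are
at most `max_gap` apart (single-linkage); groups of ≥ 2 are clusters, the
rest singletons, and the two arms of a junction are clustered independently.
`max_gap` defaults to 2000 bp: the largest published within-cluster gap is
1823 bp and the smallest between-cluster separation exceeds 2 kb, so this
value reproduces the published grouping exactly; the tests also verify
equivalence with an O(n²) transitive-closure oracle, the partition property
and monotonicity in `max_gap`. Cluster spans are computed from member
positions (a few published rows print lengths inconsistent with their own
gaps; computed spans are authoritative here). Cross-passage persistence
assigns a new breakend to an existing cluster when it lies within `max_gap`
of the cluster's span, else pools the leftovers and re-clusters them. One
consequence documented in the tests: a published "new" group whose anchor
falls inside an old cluster's span is absorbed rather than reported as new.

## Contig assembly

Candidate links are facing breakend pairs from distinct junctions — lower
breakend `RIGHT_RETAINED`, higher `LEFT_RETAINED`, same chromosome — within
`max_link` (default 5000 bp, covering published contig fragments of
20–2118 bp with headroom; a second pass at up to 100 kb admits
multi-10-kb segments). Each breakend keeps its shortest-fragment candidate,
the in-silico analogue of resolving ambiguity by PCR; equal-length ties and
one-sided conflicts break the chain at that breakend and are flagged
(policy "strict" raises instead). Junctions then form maximal simple paths
(linear contigs) or cycles (circular contigs — episome topology). Reports
give per-contig microhomology, fragment lengths from breakend arithmetic,
and source distances (gaps between consecutive fragments in the normal
genome). Full amplicon reconstruction is out of scope: with real data the
link graph is too ambiguous for credible global assemblies.

Coordinated pairs: junctions J1, J2 are reported when one arm of each lies
within `max_intra` (default 2000 bp) at one locus, the remaining arms within
`max_intra` at another locus, and the two loci are ≥ `min_inter`
(default 100 kb) apart on the same chromosome.

## Coverage

Depth is averaged in non-overlapping bins (default 3000 bp, the resolution
amplicon coverage profiles are usually drawn at); log2 of a zero bin is
reported missing. Amplified segments are maximal runs of bins ≥
`min_fold` × baseline (default 3), merged across gaps shorter than 2 bins
and dropped below 2 bins — chosen so a ~20 kb internal unamplified gap
survives as a hole. The baseline is supplied (non-amplified coverage is a
known quantity, e.g. ~4 and ~3 reads for three and two chromosome copies at
~10× sequencing) or estimated as the median bin depth outside candidate
regions. No GC or mappability correction is attempted, and the "two levels
of amplification" seen in real data are emulated, not modelled, by the
segment calling.

## The simulator

The generator's defaults state the conditions being emulated, at roughly one
tenth of genomic scale: two 1 Mb chromosomes, each with two amplified source
regions; 17 breakpoint clusters with uniform spans of 100–2500 bp and 2–7
breaks each, anchors ≥ 10 kb apart (drawn uniformly — no sequence
determinant of cluster placement is modelled, since none is known), about
one singleton break per cluster; per-fragment copy numbers ~ round
N(15, 2), doubled with probability 0.3 to give two amplification levels;
insertions at 30% of joins with geometric length of mean 8 capped at 42 bp,
i.i.d. uniform bases (no templated copies — searches for them in real data
came up empty); passage fragment-loss probability 0.35 and Poisson(8) new
cuts per transition.

Joins: free fragment ends are chained into closed circles ("dmin", default
3 episomes) or one linear chain ("hsr"), the next partner drawn with weight
(1+β)^mh over candidate ends. The default β = 0.65 is calibrated once,
through the large-pool closed form f(β) = 1 − (1−p)²/E[((1+β)p)ᵏ-weights],
to reproduce the ~65% microhomology incidence reported for real amplicon
junctions; β = 0 recovers the analytic null exactly (verified by chi-square
goodness of fit on ~30 000 simulated joins). For tractability the biased
draw scores a random subset of at most `candidate_pool` (40) free ends per
join — this slightly attenuates the effective bias at large pool sizes and
is the package's own numerical choice; with β = 0 the draw is exactly
uniform and costs O(1). Candidates that would rebuild the contiguous
reference are excluded. With probability `p_insertion` the join instead
receives an untemplated insert and its microhomology is recorded as 0.

The passage transition loses fragments i.i.d.; a junction survives iff both
flanking fragments survive; Poisson-many new breaks cut survivors; maximal
blocks still held together by surviving junctions are re-joined in random
order and orientation with freshly sampled junctions (fate "new").
Structures untouched by loss or cuts persist bit-for-bit, so a zero-loss
zero-break transition is the identity on the junction set; a circle touched
only by cuts is opened at its wrap-around join. Junction fates
(retained/lost/new) are recorded as realized, so they partition the
passage-2 set exactly.

Observables: per-base depth = baseline + copy number × depth-per-copy
(default 0.67, i.e. ~10 with 15 copies over baseline 4), junction support ~
Poisson(0.4 × mean copy number of the two fragments); both exact in
noiseless mode (support floored at 1). Spanning sequences carry 50 retained
bases per side plus the insert. What the generator does **not** emulate:
read-level errors and mapping artifacts, GC-coverage bias, selection across
passages, replication mechanics, and real genome repeat structure — so
passing tests demonstrate correctness of the analysis logic under the
stated statistical structure, not robustness to alignment noise.

## Test and acceptance problem sizes

Simulation-backed checks use sizes chosen to make their statistical
tolerances sharp at interactive runtimes: ~10 000 unbiased joins per seed
(three seeds pooled) for the null distribution, 100 000 Monte-Carlo joins
for the null fraction, 50 seeded circular amplicons for exact contig
recovery, 200 × 200-junction replicates for test calibration, 20 runs of
100 junctions at β = 2 for power, and ~1000 fragments for the loss-rate
check. Tolerances follow from the binomial standard errors at those sizes
(e.g. ±0.015 on a fraction at n = 10 000).

## Known limitations

- Greedy shortest-fragment link resolution coincides with optimal matching
  only when true links are mutual nearest neighbours; dense overlapping
  clusters can force chain breaks (flagged, never silently resolved).
- Greedy nearest junction matching across passages coincides with optimal
  bipartite matching only at small tolerances; at tol = 0 (default) it is
  exact.
- The insertion caller requires exact 15 bp seed anchoring of the spanning
  sequence; junctions with variants inside both seed regions are reported
  unanchored rather than guessed.
- Repeat-class attribution of breakpoints is accepted only as a
  user-supplied annotation BED; no genome-wide insert-template search is
  performed (flank windows only).
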
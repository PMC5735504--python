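# Methods

## Model and procedure

A linkage map is built from a markers × individuals genotype matrix in five
stages. Throughout, m is the marker count, n the number of individuals, and
k the user-supplied prior on the chromosome number; rf denotes a pairwise
recombination-frequency estimate in [0, 0.5].

### Recombination-frequency estimation

For homozygous designs (RILs by selfing, doubled haploids) and backcrosses,
rf between two markers is the mismatch fraction over mutually scored
individuals. Missing data would otherwise bias a pair toward or away from
linkage depending on how the missing comparisons happen to resolve, so each
pair's estimate is placed at the midpoint of its attainable range: with c
mutually scored individuals, d mismatches among them, and u = n − c
individuals with at least one missing call,

    rf = (d + u/2) / (c + u),

i.e. every missing comparison contributes half a mismatch. This equals
d/c when u = 0 and always lies strictly between the all-match and
all-mismatch resolutions when d, u > 0. Estimates are clamped to 0.5: raw
fractions above it carry no ordering information.

For the F2 intercross, the double heterozygote is ambiguous (it may arise
from zero or two recombinant gametes), so rf is the maximum-likelihood
estimate under the standard two-locus model — each individual carries two
independent gametes, each recombinant with probability r — fitted by EM on
the pair's 3×3 joint genotype table. The E step computes the expected
recombinant-gamete count per joint class; the M step divides by 2n.
Defaults: initialisation r = 0.25, tolerance 1e−6, at most 100 iterations;
all pairs are updated simultaneously with vectorised arithmetic. The EM
estimate is cross-checked in the tests against brute-force likelihood
maximisation on an rf grid.

No inverse mapping-function correction (e.g. the RIL inflation
R = 2r/(1+2r)) is applied before clustering or ordering: both stages need
only a monotone distance, and monotone transforms do not change the optimal
path. Map distances are produced only at output time (below).

Entries strictly above a cutoff (default 0.4) are inflated to exactly 0.5.
Large rf values separate linkage groups, but their precise magnitude is
noise, and leaving them heterogeneous makes the path solvers spend effort on
meaningless edges. The inflation is applied once, to the matrix used by all
downstream stages; the cutoff is configurable because in very noisy data
moderately large rf values can still be informative.

### Marker filtering

Before rf estimation, markers are filtered in a fixed order: (1) in
homozygous designs, markers whose heterozygous-call fraction among scored
calls exceeds `max_het_fraction` (default 0.10) are dropped, and surviving H
calls are recoded to missing — residual heterozygosity carries no
information in a two-state comparison; (2) markers whose call vector exactly
duplicates an earlier marker are dropped; (3) of any pair with similarity
(agreeing fraction among mutually scored calls) above a user-chosen
threshold, the later marker is dropped. The default similarity threshold of
1.0 removes only exact duplicates. Removing heterozygous markers before
duplicates makes the duplicate test operate on the recoded vectors, which is
both deterministic and idempotent. The filter never removes the earlier
member of a pair, so surviving order is stable.

### Hamiltonian paths via a dummy vertex

Ordering is a minimum-weight Hamiltonian *path* problem: a tour would also
pay for the edge joining the two chromosome ends, which is exactly the edge
that should be free. A dummy vertex with zero-weight edges to every marker
converts the path problem into a standard TSP; the optimal tour necessarily
passes through the dummy, and cutting it there yields the optimal open path.
Weights are integers, rf × 100 000 (resolution 1e−5, far below what n ≤ 1000
individuals can resolve), the usual contract of TSP codes.

Two solver tiers are used:

* **Heuristic** (clustering and merging): nearest-neighbour construction
  followed by best-improvement 2-opt and Or-opt (segments of length 1–3,
  both orientations) descent, fully vectorised per move scan; multi-start
  (default 2 starts in the clustering phase) and deterministic given a seed.
* **Exact** (final ordering of small groups): Held–Karp dynamic programming
  over vertex subsets, provably optimal, with ties broken toward the
  lexicographically smallest order. The default ceiling is 18 vertices
  including the dummy (the table for 17 markers is ~70 MB and solves in
  seconds; the cost doubles per extra marker).
* Groups above the ceiling use the heuristic at a high budget: 8
  nearest-neighbour starts plus 150 double-bridge perturbations with
  re-descent, keeping the best path seen. "Optimal" for such groups
  therefore means best-found under a fixed, seeded search budget. The
  budget default was sized on the hardest supported noise level
  (η = 0.05, γ = 0.10), where the rf landscape is nearly flat (see
  "Limitations") and cheap descent stalls in poor local optima; each
  linkage group records which tier ordered it.

An adapter that writes TSPLIB instances and drives an external LKH-style
solver executable is included for convenience; nothing in the pipeline or
tests depends on it.

### Clustering

The minimum spanning tree of the complete rf graph is built with Kruskal's
algorithm under a documented deterministic tie-break (ascending rf, then
vertex indices). The tree is cut at its ceil(1.5·k) largest-rf edges —
deliberate over-segmentation, since some chromosomes may not form a single
clean cluster — and a cluster is *significant* when it holds at least
s = m/(2k) markers. If fewer than k significant components exist, the
next-largest edge is cut, repeatedly. Because cutting only shrinks
components, this iteration can stall below k significant components (one
fragmented chromosome can absorb every further cut without any piece
re-reaching s); when no cut depth reaches k, the pipeline reverts to the
depth that maximised the significant count rather than shattering the tree,
and warns. The scan over cut depths is done in one linear union-find sweep
by adding edges back smallest-first.

Each component is then solved with the heuristic tier and broken at every
path adjacency whose rf exceeds `break_threshold` (default 0.35): a cluster
spanning two chromosomes cannot avoid at least one near-0.5 adjacency in its
best path, while within-group adjacencies in dense maps sit far lower. The
default sits between those two regimes with margin on both sides;
it is user-configurable for sparse maps where legitimate within-group gaps
can be large.

### Merging

Clusters are processed smallest-first (ties by cluster id; the list is
re-sorted after every merge). For the current cluster, three increasingly
expensive tests are tried; link(x, y) denotes the minimum inter-cluster rf:

1. **Direct**: merge into the best candidate y\* when
   link(x, y\*) ≤ `direct_threshold` (default 0.15) and
   link(x, y\*) ≤ ½ · link(x, second-best). Matrix evidence only.
2. **Path**: for each nearby candidate, solve the joint path and let
   J(x, y) be its maximum adjacent rf; merge when the smallest J is less
   than half the next smallest.
3. **Reciprocal**: if x's best candidate by J is y\*, J(x, y\*) is at most
   the rf cutoff, and y\*'s own best candidate is x, merge.

A cluster failing all three is a complete linkage group. Two safeguards
shape the candidate set: (a) any accepted merge must pass a *re-split
guard* — no boundary edge of the joint path (an adjacency connecting the
two clusters) may exceed `break_threshold`, since the split criterion would
immediately undo such a merge. Jumps internal to one cluster do not veto a
merge: they belong to that cluster regardless, and at high noise the
budgeted solver occasionally shows spurious internal jumps. (b) Since any
joint path crosses between the two clusters at least once, its boundary
maximum is at least link(x, y); candidates with link above
`break_threshold` are therefore skipped without spending a solver run,
which is what keeps merging fast when most cluster pairs are unlinked.
Stage 2/3 consider at most `merge_candidates` (default 3) nearest
candidates by link.

### Ordering and map output

Each final group is ordered by the best available tier (above), oriented so
its lexicographically smaller end comes first (orientation is biologically
arbitrary), and adjacent rf converted to cumulative cM positions with
Haldane (−50·ln(1−2rf), default), Kosambi, or a plain 100·rf scale. An
adjacent rf of 0.5 is an infinite Haldane/Kosambi distance and raises an
error advising a re-split. Post-ordering curation of individual erroneous
markers is deliberately out of scope; the map CSV imports directly into
R/qtl-style tools that provide it.

## The simulator

Populations are generated as no-interference Markov chains along each
chromosome (Haldane model, matching the mapping-function default): the cM
spacing between adjacent markers gives a recombination probability
r = (1 − e^(−d/50))/2 per interval, transformed per design — RIL-by-selfing
switches its two homozygous states with the inflated probability
R = 2r/(1+2r); backcross switches AA/AB with r; F2 sums two independent
gamete chains into A/H/B calls. Markers are split as evenly as possible
across k chromosomes and evenly spaced. After the clean draw, each call is
flipped to a uniformly chosen different legal genotype with probability η,
then blanked with probability γ (a flipped-then-blanked call is simply
missing; the order is immaterial to the marginal rates but fixed for
reproducibility). Marker rows are shuffled by a separate seeded permutation
before entering the pipeline so input order leaks nothing.

Defaults mirror the study conditions the pipeline targets: n = 300
individuals, 100 cM chromosomes, η ∈ {0, 0.01, 0.05}, γ ∈ {0, 0.05, 0.10},
m = 1000–2000 markers on 5 chromosomes (or 2000 on 10). The simulator does
*not* model crossover interference, segregation distortion, residual RIL
heterozygosity, dominant/partially informative markers, or locus-specific
error and missingness. Passing tests therefore demonstrate correct handling
of marker volume, random genotyping error and random missingness — not of
systematic artifacts such as clustered sequencing errors or
interference-driven map compression.

## Numerical and design choices

* The significance rule s = m/(2k) uses real-valued comparison (a cluster
  is significant when size ≥ s); 1.5·k is rounded up for odd k, erring
  toward more cuts.
* rf matrices are symmetrised exactly (averaging float noise away);
  diagonals are zero by construction; asymmetric input files are rejected
  beyond 1e−9.
* Exact-solver ties break toward the lexicographically smallest order;
  MST ties toward smaller indices; similarity/duplicate filtering keeps the
  earliest marker in file order. Every stochastic component takes an
  explicit seed, and the CLI fans one top-level seed out to stages through
  `numpy.random.SeedSequence`, so full runs are byte-reproducible.
* Degenerate inputs: an all-zero rf matrix yields one cluster and a
  warning; singleton clusters pass through splitting unchanged; a pair with
  no informative individuals is an error, not a silent 0.5.
* Problem sizes in the test and acceptance runs (m = 1000–2000, n = 300,
  five-seed replication) are scaled-down versions of the target designs,
  chosen so the full suite completes in well under a minute of simulation
  plus a few seconds of pipeline per dataset while preserving marker
  density (0.5–2 cM spacing) and the full noise grid.

## Known limitations

* At high noise the missing-data midpoint adjustment shifts every rf up by
  ≈ γ·(1 − γ/4)/2 + η-dependent terms, compressing the contrast between
  adjacent and distant pairs; with η = 0.05, γ = 0.10 and n = 300 the
  ordering landscape is nearly flat and the heuristic's result depends on
  its budget. Group *membership* (the c statistic) is robust there, but
  fine-scale order quality degrades; at γ, η ≤ 1% orders are essentially
  perfect.
* Even with zero simulated noise, the sampling variance of rf at n = 300
  means the cost-optimal order can transpose markers closer than roughly
  1–2 cM; this is a property of the statistic, not of the solver.
* Group recovery is strongly biased toward the supplied k, by design; a
  wrong prior produces a confidently wrong group count.
* Chromosomes much smaller than m/(2k) markers (extreme size variation)
  can be absorbed or left as debris; the significance rule assumes
  moderately even marker allocation.
* True exactness is guaranteed (and tested against exhaustive enumeration)
  only up to the Held–Karp ceiling; larger groups carry a best-found
  guarantee under the stated budget.
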
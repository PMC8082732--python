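# Methods

## Genome model

A genome is a set of chromosomes; a chromosome is an ordered sequence of
oriented marker occurrences and is linear or circular.  Marker tokens are
arbitrary non-whitespace strings (real markers are gene or segment IDs), with
`> | ( ) - #` reserved by the file dialect.  Circular chromosomes are stored
canonically — the lexicographically smallest rotation of the smaller of the
two reading directions — so genome equality, hashing and round-tripping are
well defined; the model itself is rotation- and reversal-invariant.  Genomes
sharing no markers at all are legal inputs: the distance then degenerates to
pure indel/singleton costs.

For a pair (A, B) the census records per-marker multiplicities Φ_A, Φ_B and
ΔΦ = Φ_A − Φ_B, the common-marker set G, the matched occurrence count
n* = Σ_{m∈G} min(Φ_A, Φ_B), linear chromosome counts κ_A, κ_B, and the
capping quantities p* = max(κ_A, κ_B), a* = |κ_A − κ_B|.

## Diagrams and components

The multi-relational diagram MR(A,B) has one vertex per marker-extremity
occurrence.  Adjacency edges follow chromosome order; every pair of
same-marker occurrences across genomes contributes a tail and a head
extremity edge (siblings); every occurrence of a marker that is
over-represented in its genome (ΔΦ > 0 in A, ΔΦ < 0 in B) carries an indel
edge, since any such occurrence may end up unmatched.  For singular inputs
this reduces edge-for-edge to the classical relational diagram.  Vertex ids
are assigned deterministically (genome A left to right, tail before head,
then genome B, then caps) so that identical inputs produce identical ILP
models.

Capping adds 4p* cap-extremity vertices, one adjacency from every telomere
to a distinct cap, a* artificial adjacencies pairing the surplus caps of the
genome with fewer linear chromosomes, and the complete bipartite set of cap
extremity edges.  Under the degree-2 constraint a maximal capping set is a
perfect matching of A-caps to B-caps, and every capped consistent
decomposition consists of cycles only.

Components of a decomposition are classified as AB-cycles, AA-/BB-/AB-paths
and circular/linear singletons.  Runs (maximal stretches of indel edges of
one genome) are counted by a single walk; consecutive same-genome indel
edges merge into one run, cycles count run blocks circularly, AB-paths are
read from their A endpoint, and AA/BB-path signatures are normalized since
their two reading directions coincide.

One deliberate deviation from the "add an indel edge wherever both endpoints
have degree ≤ 1" completion rule: a *matched* occurrence whose extremities
are both telomeres of a single-marker linear chromosome would satisfy that
degree test, yet the equivalent matched singular genomes contain no such
indel edge.  The completion therefore adds an indel edge only for unmatched
occurrences.  In the capped diagram the distinction vanishes because every
telomere gains a cap adjacency, so the ILP's degree constraint already
encodes the corrected rule.

## Closed form for singular genomes

d = |G| − c − i/2 + Σλ(C) − δ, with λ(Λ) = 0 for Λ = 0 and ⌈(Λ+1)/2⌉
otherwise.  δ is computed greedily over chained recombination groups in the
order P, Q, T, S, M, N with δ = 2P + 3Q + 2T + S + 2M + N.  Path types use
the letters W/W̄/W_ (AA-paths with mixed, A-only, B-only runs), M/M̄/M_ (the
BB analogues) and Z/N (AB-paths read A→B with runs starting in A / in B);
linear singletons enter as W̄ or M_.  The group inventory was reconstructed
by exhaustively chaining the primitive recombination operations (the
Δd ≤ −1 operations plus the Δd = 0 operations that create reusable
sources), and the greedy order was fixed by comparison with an exact
memoized search over those operations (`oracle.exact_delta`): within T the
groups that spend one W or M per deduction (WM̄Z, WM_N, MW̄N, MW_Z) precede
the WWM̄-style groups, and within S the WW and MM groups come last.  The
greedy equals the exact optimum on all count vectors with entries ≤ 2
(6561 cases) and on random larger vectors; the test suite re-checks a
sample on every run.

## ILP

Variables: x_e (edge selected; adjacencies fixed to 1), y_i ∈ [0, i] (cycle
label, equal along selected edges, ≤ the smallest vertex id in the cycle, 0
on cycles through a selected indel edge), z_i (vertex i labels an indel-free
cycle, i·z_i ≤ y_i), r_v (run label: 0 in A-runs, 1 in B-runs), t_e
(transition host), s_k (circular singleton).  Label changes of r are
permitted only on genome-A adjacencies incident to an indel edge — every
other adjacency enforces r_u = r_v outright, and extremity/cap/indel edges
enforce it when selected — which canonizes each transition to the edge next
to its A-run without excluding any optimum, and keeps the t-variable count
small.  s_k exists only for circular chromosomes in which *every* occurrence
carries an indel edge; other circular chromosomes cannot be singletons, and
a constraint on them would misfire when all their indel edges happen to be
selected inside a larger cycle.  The objective maximizes
Σz − ½Σt − Σs; the distance is n* + p* − objective.

y is declared continuous: the coupling constraints force it to a common
per-cycle value and maximization pushes that value to the (integral)
smallest vertex id whenever a z is collected, so integrality is implied.

Backend: HiGHS through `scipy.optimize.milp` — deterministic and
single-threaded; `threads` and `seed` are accepted for interface stability
and recorded, but have no effect.  Time limit and relative MIP gap are
forwarded.  On a time-limited solve with an incumbent the solution reports
`feasible_gap` with distance bounds derived from the primal and dual bounds.

## Capping equivalence

For each maximal sibling set S, the best capping set P satisfies
max_P w(Q[S,P]) = w(D[S]) + p*, i.e. the capped (n* + p* − w(Q)) and
uncapped (n* − w(D)) distance formulas coincide per matching.  The +p*
offset is required for the two published weight definitions to be mutually
consistent (each cap contributes one marker and one closed cycle); the
property is verified by exhaustive enumeration of sibling and capping sets
on random tiny instances.

## Oracles

* `bfs_dcj_distance`: breadth-first search over genome states (adjacency
  sets) under all DCJ operations — two cuts with both rejoinings, telomeric
  variants, joins and the single-adjacency cut.  Ground truth for canonical
  instances up to ~5 markers.
* `min_over_matchings`: enumerates every maximal sibling set (injections per
  marker, with a size guard), realizes each as matched singular genomes
  (matched pairs get a shared composite id `m:k`; excess occurrences become
  fresh exclusive markers) and minimizes the closed form.
* `exact_delta`: exact recombination deduction by memoized search, the
  reference for the greedy.

The keystone tests assert three-way agreement (BFS = closed form = ILP) on
hundreds of random canonical instances, closed form = ILP on singular
instances with exclusive markers and mixed topologies, and matching oracle =
ILP on tiny natural instances.

## Simulator

Genomes evolve along a rooted weighted newick tree from a single linear root
chromosome of `root_length` markers.  Per edge of weight w, event counts are
Poisson: DCJs with mean w, duplications/deletions/insertions with mean
w × rate.  Defaults are root_length 20000, insertion rate 0.1, deletion rate
0.2, duplication rate 0.4, Zipf length shapes s = 4 (indels) and s = 6
(duplications); event order per edge is DCJs, duplications, deletions,
insertions; locations are uniform over the genome.  Choices where the
procedure was open: indel and duplication counts scale as weight × rate;
inserted markers get globally fresh symbols while duplications copy symbols
to a uniformly drawn target position; deletions are truncated so a
chromosome always keeps at least one occurrence (avoids empty genomes and
keeps κ stable); Zipf lengths are capped at the chromosome length.  A DCJ
draws two distinct breakpoints uniformly among all adjacencies and telomeres
and picks one of the two rejoinings equiprobably.  All randomness flows
through one seeded generator; every event is logged with enough detail that
`replay_edge` reproduces each child genome exactly.

What the simulator does and does not emulate: it produces realistic
marker-order evolution (rearrangement, gain, loss, duplication with
heavy-tailed segment lengths) but no sequence-level noise, no marker-inference
errors, no rate heterogeneity beyond edge weights, and no chromosome gain
other than through DCJs.  Tests passing on simulated data therefore validate
the combinatorics and the optimization, not the upstream marker pipeline.

## Problem sizes and numerics

The validation suite uses desk-scale instances chosen to keep brute force
exact: canonical pairs ≤ 5 markers (200 instances), singular pairs ≤ 10
common + 4 exclusive markers (200), natural pairs ≤ 8 occurrences with ≤ 3
copies per marker (100), capping enumeration with p* ≤ 2 (50), and a
scaled benchmark with root length 200, duplication rate 0.4 and 2 × 50
expected DCJs, solved to proven optimality (well under a second with HiGHS
at this size).  Matching and capping enumerations refuse to run above a
configurable bound.  MILP decoding rounds binaries at 0.5 and asserts the
reconstructed decomposition reproduces the objective.

## Known limitations

* Worst-case ILP size grows with duplicate occurrences and linear
  chromosome counts (caps behave like duplicates); heavily duplicated
  genomes may need a time limit, in which case bounds and a gap are
  reported instead of an exact distance.
* No sorting scenario (operation list) is reconstructed — the witness
  decomposition is informational, only the distance is contractual.
* Exclusive markers may repeat freely, but the closed form requires common
  markers to be singular; `distance_natural` is the general entry point.
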
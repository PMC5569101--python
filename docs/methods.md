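# Methods

## The coloring model

An influence graph G(V, E, α) carries edge labels α: E → {+, -}
(activation/inhibition).  Observations β: V ⇀ {+, -, 0} partially label
the observable nodes (role `gene`) of one profile; a coloring μ: V →
{+, -, 0} totally labels the graph.  The *influence* of an edge (p → n,
sign a) under μ is the sign product a·μ(p), with 0 absorbing (an unchanged
regulator transmits nothing).  μ is consistent when:

- **R1** — input nodes are unconstrained.  By default the inputs are the
  predecessor-free nodes; an explicit input list overrides this (and is
  honored by every downstream stage, including compaction).
- **R2** — every other variant node has at least one incoming influence
  equal to its own sign.
- **R3** — every other invariant node has either all incoming influences
  at 0, or two incoming influences of opposite variant signs.

Cycles need no special treatment: the rules are local constraints over a
total coloring, not a propagation order.  A node with no predecessors that
is *not* declared an input can only be 0 (R3 holds vacuously, R2 cannot).
Note the all-zero coloring always satisfies R2/R3, so a graph without
observations is never infeasible — infeasibility only ever comes from β.

## Repairs

When no consistent coloring extends β, two exact repair modes restore
consistency:

- **MCOS** (topology correction): find all minimum-cardinality sets R of
  non-input nodes such that exempting R from R2/R3 admits a consistent
  coloring.  The exemption models an *artificial influence* — an
  unmodeled regulator of arbitrary sign.  We implement it as a full
  exemption of the node rather than literally adding one signed edge from
  a fresh input; for variant nodes the two are identical, for invariant
  nodes the exemption is the more permissive (and simpler) semantics, a
  deliberate design choice.  By default any non-input node may be
  repaired (`repair_scope="all"`); `"unobserved"` restricts candidates to
  nodes outside Dom(β), in which case no repair may exist and the solver
  raises rather than returning a bogus score.
- **SCENFIT** (data correction): switch observed signs at minimum total
  cost — a variant flip (`+`↔`-`) costs 2, any switch across the
  variant/invariant boundary costs 1.  Equivalently, SCENFIT is the
  minimum, over all consistent colorings μ, of the summed switch cost
  between β and μ on Dom(β); the minimal repair sets are the switch
  patterns of the cost-optimal colorings.  A finite optimum always exists
  (the all-zero coloring bounds it).

Both modes return *every* minimal repair and the union of consistent
colorings under all of them; projections are always computed from that
union, never from a sample.  In-silico interventions enter as clamped
signs that are excluded from switching and from repair candidacy.

## Sign projection

Across a nonempty set of colorings, each node realizes a nonempty subset
of {+, -, 0}; the seven subsets map bijectively to the classes `+`, `-`,
`0` (strong), `Not+` = {-, 0}, `Not-` = {+, 0}, `change` = {+, -} (weak),
and `?` = {+, -, 0}.  Under MCOS the observed nodes keep their observed
signs, so they always project to the strong class of their observation;
the information content lies in the unobserved nodes.

## The solver

The solver is an exact branch-and-bound over per-node sign domains:

- nodes are ordered pseudo-topologically (each node after as many of its
  predecessors as possible; stable sorted-id tie-breaks make every output
  deterministic);
- a node's rule is checked as soon as it and all its predecessors are
  assigned, pruning dead branches early;
- SCENFIT accumulates switch costs along the assignment and prunes any
  branch strictly above the best known cost, so all cost-ties are kept;
- MCOS iterates candidate-set cardinality 0, 1, 2, … testing
  satisfiability per subset, and stops at the first feasible cardinality.

Everything is exact — the search prunes but never approximates.  The
intended regime is the compacted, desk-scale graph (tens of nodes, a
handful of unobserved nodes per profile); `enumerate_colorings` refuses
more than 12 unobserved nodes by default, and MCOS cost grows
combinatorially with the repair cardinality.  Brute-force oracles in the
test suite (exhaustive enumeration over all colorings, repair subsets and
switch assignments) verify scores, complete repair sets and projections on
hundreds of random instances.

## Discretization

Differential values reference each gene to the mean of the reference
class: p[g, i] = expr[g, i] − mean over reference profiles of expr[g, ·],
in log2 units; reference profiles are differenced against their own class
mean too.  Two thresholds (defaults k1 = 0.03, k2 = 0.2 log2 units, the
selected operating point) discretize p: above k2 → `+`, below −k2 → `-`,
strictly inside ±k1 → `0`.  Values in the [k1, k2] bands (including the
band edges) yield *no* observation — the rules leave the band undefined,
and an absent call is exactly what the partial-labeling semantics expects.
The reference mean includes the profile being discretized; with a handful
of reference profiles a leave-one-out mean would shift every reference
differential, and nothing in the three rules calls for it.

A threshold pair is discarded when its pooled variant-call proportion
exceeds 50% (strict), guarding against discretizations that declare most
of the transcriptome differential.  Surviving pairs are ranked by holdout
precision: per repetition, one profile (round-robin over profiles, one per
repetition, each with a spawned child seed) has half its calls hidden; the
visible half is repaired (MCOS) and each hidden node with a strong
projection is scored against its true sign.  The default search grid
crosses k1 ∈ {0.01, …, 0.10} with k2 ∈ {0.1, …, 1.5} (150 pairs) and is
configurable.  The summary reports mean precision and a normal 95% CI
(1.96·sd/√n).

## Graph construction

`extract_subgraph` keeps the union of *all* shortest directed paths
(unweighted, length minimized over the whole source set) from the source
pathway nodes to each reachable target; unreachable targets are dropped
and reported.  Keeping all tied paths rather than one witness makes the
output deterministic and faithful to the idea of capturing every minimal
route of influence.

`compact` iteratively removes unobserved, non-input nodes with in-degree
1 or out-degree 1, rewiring each predecessor×successor pair with the sign
product of the two edges (double inhibition activates).  Contractions
that would create a self-loop are skipped, as are nodes carrying one.
Sweeps process nodes in sorted order until a fixpoint.  Compaction is
information-preserving for the coloring model — an in-degree-1 node's
sign is forced by its single regulator, and an out-degree-1 node's
admissible influences transfer exactly to its successor — and rather than
trusting that argument, an acceptance property test re-derives the
projections of every retained node before and after compaction on ≥100
random graphs and requires identity.

## Signatures

Per profile, the MCOS projections of the never-observed nodes are
decomposed into booleans M[i, s, j] = 1 iff s ∈ projection of node i in
profile j, for s ∈ {+, -} only (invariant indicators are dropped as
redundant, and observed nodes are trivial).  FS is the class mean of M.
Ranking keeps assignments with FS_case > FS_control and tests the 2×2
presence table with a one-sided Fisher exact test towards the case class
— the directional pre-filter makes the one-sided test the natural choice,
and sidedness is an explicit argument for users who disagree.  Raw
p-values order the table; a Benjamini–Hochberg column is emitted
alongside, clearly labeled, without affecting the ranking.  The exported
matrix M can feed any external supervised learner; with a grossly
unbalanced reference class, reweighting the minority class to parity is
advisable there.

## Perturbation scoring

For profile j and sign s, every node k unobserved in β_j is clamped to s
and the SCENFIT score SF[k, s, j] recomputed; the clamp itself is never
switchable.  The top threshold is nearest-rank: with K candidate scores
sorted descending, the cutoff is the ⌈q·K⌉-th largest (q = 0.10 default)
and every score ≥ cutoff is top-ranked — a rank statement with inclusive
ties, since ties cannot be split deterministically.  The reference
distribution is recomputed per profile *and* per sign over all unobserved
candidates.  TPS averages the top-ranked indicator over all N_C profiles
of a class (a node observed in some profile contributes 0 there), and a
one-sided Fisher test compares case and control top-rank counts per
(node, sign).

## Synthetic data

The generator emulates the statistical shape of the real inputs at desk
scale: random signed directed graphs (G(n, p)-style, cycles permitted,
optional DAG mode; inhibition probability per edge; the low-out-degree
"sink side" carries the observable gene role), planted-consistent
colorings (inputs randomized, then admissible signs chosen in dependency
order; strongly-connected components up to 8 nodes solved exhaustively
and jointly, larger ones raise for regeneration), controlled corruptions
with known switch costs, and two-class expression matrices (per-gene
baseline ~ Normal(7, 1) log2 units as typical of normalized microarrays,
reference profiles at baseline + Normal(0, noise_sd), case profiles
shifted ±shift on the designated variant genes).

Defaults: 20 nodes, edge density 0.05, 30% inhibition, half the nodes
observable, 20 case + 5 reference profiles, 8 variant genes, shift 0.5
(well above k2 = 0.2), noise 0.05.  These sizes keep exact solving,
oracle cross-checks and full perturbation scans fast while preserving the
qualitative structure: a dominant case class, a small reference class,
shifts that clear the variant cutoff.  What synthetic data does *not*
model: realistic pathway topology (hubs, motifs, scale-free degree
distributions), correlated noise, batch structure, or any coupling
between the expression ground truth and the graph logic in the
two-class matrices.  Passing tests therefore certify the machinery —
exactness of repairs, recovery of planted structure, calibration of the
discretizer — not biological performance on real cohorts.

## Numerical and degenerate-input choices

- All randomness flows through numpy `SeedSequence` spawning; fixed seeds
  give bit-identical outputs everywhere, including TSV re-runs.
- Holdout hides max(1, round(frac·|Dom β|)) nodes; precision is undefined
  (reported as `None`/blank, excluded from aggregation) when no hidden
  node gets a scorable projection.
- Strict holdout scoring counts only strong-class predictions; the
  lenient mode (hidden sign ∈ projected set, all hidden nodes in the
  denominator) is available behind a flag and results are labeled by
  mode.  The ~33% three-sign random comparator is meaningful for the
  strict, single-sign scoring.
- Duplicate edges collapse (set semantics); parallel opposite-sign edges
  are legal and contribute independent influences.
- Node ids are opaque strings, preserved verbatim (decorated names like
  `JUN/FOS[n]` are never parsed).
- An empty coloring set has no projection (error), and empty classes are
  rejected wherever a class mean or test is requested.

## Known limitations

- MCOS subset search is exponential in the repair cardinality; profiles
  that conflict with the graph in many places are expensive.  The
  intended use is after compaction, at desk scale.
- No ASP/answer-set backend is bundled; the built-in exact solver is the
  only engine (the architecture allows plugging one in behind the same
  interface, which must then match scores and projections exactly).
- The two-sign comparison model is available only through the analytic
  random baseline, not as a full alternative coloring semantics.
- Survival analysis and supervised classification of M are out of scope;
  M is exported for external tools.
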
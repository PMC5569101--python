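# signet

Sign-consistency analysis of gene-expression profiles over signed influence
graphs.

`signet` asks a simple question about each expression profile: *can a
regulatory network explain it?*  Genes are discretized to qualitative
shifts — up (`+`), down (`-`), unchanged (`0`) — relative to a reference
class of profiles, and the network is a directed graph whose edges are
activations (`+`) or inhibitions (`-`) between species (proteins,
complexes, genes).  A global state of the system is a *coloring* assigning
every node a sign; it is **consistent** when every non-input node's sign is
explained by its direct regulators:

- a variant node (`+`/`-`) needs at least one activator with the same sign
  or one inhibitor with the opposite sign;
- an invariant node (`0`) needs either all incoming influences at `0`, or
  two regulators pushing in opposite directions.

Real profiles are rarely fully explainable, so `signet` computes **exact
minimal repairs** and mines what they reveal:

- **MCOS** — the minimum number of nodes that must receive an unmodeled
  ("artificial") influence for a consistent coloring to exist: a correction
  of the network.
- **SCENFIT** — the minimum-cost set of observation switches (a variant
  flip `+`↔`-` costs 2, a variant↔invariant switch costs 1): a correction
  of the data.
- **Sign projections** — across the union of consistent colorings under all
  minimal repairs, each node realizes a subset of `{+, -, 0}`; the seven
  possible subsets give the classes `+`, `-`, `0`, `Not+`, `Not-`,
  `change`, `?`.  Strong classes are predictions of unmeasured states.
- **Frequency signatures** — per class C (e.g. tumor vs normal), the
  frequency score `FS_C(i, s) = (1/N_C) Σ_j M[i, s, j]` counts how often
  node *i* projects to sign *s* across the class's profiles; case-enriched
  assignments are ranked by a one-sided Fisher exact test.
- **In-silico perturbations** — clamping an unobserved node to `+` or `-`
  and re-running SCENFIT measures how much of the profile the intervention
  contradicts; the Top Perturbation Score `TPS_C(i, s)` is the fraction of
  a class's profiles where the intervention ranks in the top 10% of all
  candidate perturbations.

The package is aimed at systems-biology analyses that confront two-class
transcriptomics (a large case cohort against a small reference class) with
curated signed pathway networks, and at method development: a synthetic
module generates graphs, planted-consistent labelings, controlled
corruptions with known repair cost, and two-class expression matrices, so
the whole pipeline is testable without external data.

## Worked example

```python
from signet import SignedGraph, Labeling, solve

graph = SignedGraph.from_edges(
    [("IL6", "STAT3", "+"), ("STAT3", "BCL2", "+"), ("STAT3", "TP53", "-")],
    genes={"BCL2", "TP53"},
)
beta = Labeling("patient1", {"BCL2": "+", "TP53": "+"})

result = solve(graph, beta, "scenfit")
print("score:", result.score)
print("minimal repairs:",
      [sorted((n, o.value, s.value) for n, o, s in r) for r in result.repair_sets])

result = solve(graph, beta, "mcos")
print("mcos score:", result.score)
for n, c in sorted(result.projections().items()):
    print(f"  {n}: {c}")
```

prints

```
score: 2
minimal repairs: [[('TP53', '+', '-')], [('BCL2', '+', '-')], [('BCL2', '+', '0'), ('TP53', '+', '0')]]
mcos score: 1
  BCL2: +
  IL6: change
  STAT3: change
  TP53: +
```

Both observed genes are up, but STAT3 activates BCL2 while inhibiting TP53
— no single STAT3 state explains both.  SCENFIT's cheapest data
corrections cost 2 (flip either gene, or move both to invariant at cost
1 + 1); MCOS instead exempts one gene from explanation (score 1), after
which the observed genes keep their observed signs and the unmeasured
IL6/STAT3 states project to `change` (they take either variant sign across
the minimal repairs).

## Command line

```sh
signet simulate --seed 3 --out-dir sim/            # synthetic bundle
signet discretize --expr expr.tsv --classes classes.tsv --out-dir obs/
signet build-graph --graph net.tsv --sources IL6 --targets @variants.txt --out-dir build/
signet solve --graph build/compacted.tsv --obs obs/p1.tsv --mode mcos --out p1.json
signet validate --graph net.tsv --obs-dir obs/ --reps 20 --out validation.tsv
signet signatures --graph net.tsv --obs-dir obs/ --classes classes.tsv --out-dir sig/
signet perturb --graph net.tsv --obs-dir obs/ --classes classes.tsv --out-dir tps/
signet run --config pipeline.yaml --seed 1 --out-dir results/
```

File formats are plain TSV: graphs as `source  sign  target` edge lists
with a `node  role` metadata table (`gene` marks observable nodes),
observations as `node  sign` per profile, expression as a genes × profiles
matrix with a `profile  class` map.  See `docs/methods.md` for the model,
parameter and design details.

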
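"""Synthetic influence graphs, planted-consistent labelings and expression data.

Every pipeline stage is exercisable without external data: random signed
graphs (cyclic or DAG), colorings planted to satisfy the consistency rules
(so repair scores are 0 by construction), controlled corruptions with known
SCENFIT cost, and two-class expression matrices with a reference (NPC-like)
baseline class, per-gene shifts in the case (MC-like) class and Gaussian
noise.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .consistency import _explained
from .core import ALL_SIGNS, Coloring, GENE, Labeling, Sign, SignedGraph, VARIANT_SIGNS
from .discretize import ExpressionMatrix

#: Largest strongly-connected component solved exhaustively when planting.
MAX_CYCLE_SIZE = 8


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``n_profiles_per_class`` is ``(n_case, n_reference)`` — case (MC-like)
    and reference (NPC-like) profile counts.  ``shift`` is the per-gene
    log2 expression offset applied to variant genes in the case class;
    ``noise_sd`` the per-measurement Gaussian sd.  The defaults are a
    desk-scale rendition of a two-class cohort dominated by the case class,
    with shifts well above the variant cutoff (0.2) and mild noise.
    """

    n_nodes: int = 20
    edge_density: float = 0.05
    p_inhibition: float = 0.3
    p_observed: float = 0.5
    n_profiles_per_class: Tuple[int, int] = (20, 5)
    n_variant_genes: int = 8
    shift: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0
    dag: bool = False
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for name in ("edge_density", "p_inhibition", "p_observed"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n < 0 for n in self.n_profiles_per_class):
            raise ValueError("profile counts must be >= 0")


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_graph(spec: SyntheticSpec) -> SignedGraph:
    """Random signed directed graph with gene roles on the sink side.

    Each ordered node pair (no self-loops; in DAG mode only pairs respecting
    a random topological order) carries an edge with probability
    ``edge_density``, inhibitory with probability ``p_inhibition``.  A
    fraction ``p_observed`` of the nodes, taken from the low-out-degree
    (sink) side, is flagged with the observable ``gene`` role.
    """
    rng = _rng(spec.seed, 0)
    width = len(str(max(spec.n_nodes - 1, 1)))
    names = [f"n{idx:0{width}d}" for idx in range(spec.n_nodes)]
    rank = {n: i for i, n in enumerate(rng.permutation(names))}
    edges: List[Tuple[str, str, Sign]] = []
    for u in names:
        for v in names:
            if u == v:
                continue
            if spec.dag and rank[u] >= rank[v]:
                continue
            if rng.random() < spec.edge_density:
                sign = Sign.MINUS if rng.random() < spec.p_inhibition else Sign.PLUS
                edges.append((u, v, sign))
    if not edges and spec.n_nodes > 1:
        warnings.warn("edge density produced an empty edge set", stacklevel=2)

    out_deg = {n: 0 for n in names}
    for u, _, _ in edges:
        out_deg[u] += 1
    n_genes = min(spec.n_nodes, max(1, int(round(spec.p_observed * spec.n_nodes))))
    tiebreak = rng.permutation(len(names))
    sink_order = sorted(names, key=lambda n: (out_deg[n], tiebreak[names.index(n)]))
    genes = set(sink_order[:n_genes])
    return SignedGraph.from_edges(edges, genes=genes, nodes=names)


def plant_consistent_labeling(graph: SignedGraph, seed: int = 0) -> Tuple[Coloring, Labeling]:
    """Plant a consistent coloring and return its observable restriction.

    Inputs get random signs; the remaining nodes are assigned in dependency
    order a sign admitted by rules R2/R3 given their predecessors.  Cyclic
    components are solved by bounded exhaustive search (component size
    capped at ``MAX_CYCLE_SIZE``), picking uniformly among the consistent
    joint assignments.  The labeling is the coloring restricted to
    gene-role nodes.
    """
    if not graph.nodes:
        raise ValueError("graph is empty")
    rng = _rng(seed, 1)
    simple = graph.to_digraph()
    condensed = nx.condensation(simple)
    assign: Dict[str, Sign] = {}

    for comp_id in nx.topological_sort(condensed):
        comp = sorted(condensed.nodes[comp_id]["members"])
        has_internal_edge = any(
            p in comp for n in comp for p, _ in graph.predecessors(n)
        )
        if len(comp) == 1 and not has_internal_edge:
            node = comp[0]
            if node in graph.inputs:
                assign[node] = ALL_SIGNS[rng.integers(3)]
            else:
                admissible = [
                    s
                    for s in ALL_SIGNS
                    if _explained(graph, {**assign, node: s}, node)
                ]
                assign[node] = admissible[rng.integers(len(admissible))]
            continue
        if len(comp) > MAX_CYCLE_SIZE:
            raise RuntimeError(
                f"cyclic component of size {len(comp)} exceeds the planting bound "
                f"({MAX_CYCLE_SIZE}); regenerate with a sparser graph"
            )
        consistent: List[Tuple[Sign, ...]] = []
        for combo in itertools.product(ALL_SIGNS, repeat=len(comp)):
            trial = {**assign, **dict(zip(comp, combo))}
            if all(
                n in graph.inputs or _explained(graph, trial, n) for n in comp
            ):
                consistent.append(combo)
        if not consistent:
            raise RuntimeError(
                f"no consistent assignment for cyclic component {comp}; regenerate"
            )
        choice = consistent[rng.integers(len(consistent))]
        assign.update(dict(zip(comp, choice)))

    coloring = Coloring(assign)
    labeling = Labeling(
        "planted", {n: coloring[n] for n in sorted(graph.genes)}
    )
    return coloring, labeling


def corrupt_labeling(
    labeling: Labeling,
    k: int,
    mode: str = "flip_variant",
    seed: int = 0,
    nodes: Optional[Iterable[str]] = None,
) -> Tuple[Labeling, Tuple[Tuple[str, Sign, Sign], ...]]:
    """Corrupt ``k`` observed variant signs, returning the switch ground truth.

    ``flip_variant`` replaces a variant sign by its opposite (SCENFIT cost 2
    per switch); ``to_invariant`` replaces it by 0 (cost 1).  ``nodes``
    optionally restricts the eligible pool.  The corrupted labeling and the
    list of ``(node, old, new)`` switches are returned.
    """
    if mode not in ("flip_variant", "to_invariant"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    pool = sorted(
        n
        for n, s in labeling.items()
        if s.is_variant and (nodes is None or n in set(nodes))
    )
    if k > len(pool):
        raise ValueError(f"cannot corrupt {k} nodes; only {len(pool)} eligible")
    rng = _rng(seed, 2)
    chosen = sorted(rng.choice(pool, size=k, replace=False).tolist()) if k else []
    new = dict(labeling.items())
    switches = []
    for n in chosen:
        old = labeling[n]
        target = old.opposite if mode == "flip_variant" else Sign.ZERO
        new[n] = target
        switches.append((n, old, target))
    return Labeling(labeling.profile_id, new), tuple(switches)


def generate_expression(
    graph: SignedGraph, spec: SyntheticSpec
) -> Tuple[ExpressionMatrix, Dict[str, Sign]]:
    """Two-class expression matrix over the graph's genes + ground-truth signs.

    Reference-class profiles draw Normal(baseline_g, noise_sd) per gene;
    case-class profiles add ``+shift`` or ``-shift`` to the chosen variant
    genes (recorded in the returned sign map; non-variant genes map to 0).
    """
    genes = sorted(graph.genes)
    if not genes:
        raise ValueError("graph has no gene-role nodes")
    if spec.n_variant_genes > len(genes):
        raise ValueError(
            f"n_variant_genes={spec.n_variant_genes} exceeds the {len(genes)} genes"
        )
    n_case, n_ref = spec.n_profiles_per_class
    if n_ref < 1:
        raise ValueError("need at least one reference-class profile")
    rng = _rng(spec.seed, 3)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    variant = sorted(rng.choice(genes, size=spec.n_variant_genes, replace=False).tolist())
    truth: Dict[str, Sign] = {g: Sign.ZERO for g in genes}
    for g in variant:
        truth[g] = VARIANT_SIGNS[rng.integers(2)]

    case_ids = [f"MC{i + 1:03d}" for i in range(n_case)]
    ref_ids = [f"NPC{i + 1:02d}" for i in range(n_ref)]
    columns = {}
    for pid in ref_ids:
        columns[pid] = baseline + rng.normal(0, spec.noise_sd, size=len(genes))
    offsets = np.array(
        [spec.shift * (1 if truth[g] is Sign.PLUS else -1 if truth[g] is Sign.MINUS else 0) for g in genes]
    )
    for pid in case_ids:
        columns[pid] = baseline + offsets + rng.normal(0, spec.noise_sd, size=len(genes))

    values = pd.DataFrame(columns, index=genes)
    classes = pd.Series(
        {**{p: "NPC" for p in ref_ids}, **{p: "MC" for p in case_ids}}
    ).reindex(values.columns)
    return ExpressionMatrix(values, classes, reference_class="NPC"), truth


def write_bundle(out_dir, spec: SyntheticSpec) -> Dict[str, str]:
    """Generate and write a full synthetic bundle (graph, expression, truth).

    Writes the graph TSVs, the expression matrix and class map, per-profile
    planted observation TSVs, and a ground-truth JSON; returns the file map.
    """
    from .core import write_graph, write_labeling

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph = generate_graph(spec)
    coloring, labeling = plant_consistent_labeling(graph, spec.seed)
    expr, truth = generate_expression(graph, spec)

    paths = {
        "graph": str(out_dir / "graph.tsv"),
        "roles": str(out_dir / "roles.tsv"),
        "inputs": str(out_dir / "inputs.txt"),
        "expression": str(out_dir / "expression.tsv"),
        "classes": str(out_dir / "classes.tsv"),
        "truth": str(out_dir / "ground_truth.json"),
    }
    write_graph(graph, paths["graph"], paths["roles"], paths["inputs"])
    expr.values.round(6).to_csv(paths["expression"], sep="\t", index_label="gene")
    with open(paths["classes"], "w") as fh:
        fh.write("profile\tclass\n")
        for p in expr.profiles:
            fh.write(f"{p}\t{expr.classes[p]}\n")
    obs_dir = out_dir / "observations"
    obs_dir.mkdir(exist_ok=True)
    write_labeling(labeling, obs_dir / "planted.tsv")
    paths["observations"] = str(obs_dir)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "spec": asdict(spec),
                "planted_coloring": {n: s.value for n, s in sorted(coloring.items())},
                "variant_signs": {g: s.value for g, s in sorted(truth.items())},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
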
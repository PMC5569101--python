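"""Shared domain types for sign-consistency analysis of influence graphs.

An *influence graph* is a directed graph whose edges carry an activation
(``+``) or inhibition (``-``) sign between molecular species.  Observations
attach a sign in ``{+, -, 0}`` (up, down, unchanged) to a subset of nodes
(typically genes); a *coloring* assigns a sign to every node.  This module
holds the graph/labeling/coloring containers, the elementary sign algebra,
and the plain-text (TSV) readers and writers shared by every stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import pandas as pd

GENE = "gene"
SPECIES = "species"
ROLES = (GENE, SPECIES)


class Sign(str, enum.Enum):
    """One of the three qualitative signs ``+`` (up), ``-`` (down), ``0`` (unchanged)."""

    PLUS = "+"
    MINUS = "-"
    ZERO = "0"

    def __str__(self) -> str:
        return self.value

    def __repr__(self) -> str:
        return f"Sign({self.value!r})"

    @property
    def is_variant(self) -> bool:
        return self is not Sign.ZERO

    @property
    def opposite(self) -> "Sign":
        """The opposite variant sign; 0 is its own opposite."""
        if self is Sign.PLUS:
            return Sign.MINUS
        if self is Sign.MINUS:
            return Sign.PLUS
        return Sign.ZERO


VARIANT_SIGNS = (Sign.PLUS, Sign.MINUS)
ALL_SIGNS = (Sign.PLUS, Sign.MINUS, Sign.ZERO)


def influence(edge_sign: Sign | str, source_sign: Sign | str) -> Sign:
    """Sign contributed to a target by one edge, given the source node's sign.

    An activation (``+``) transmits the source sign unchanged, an inhibition
    (``-``) flips ``+`` and ``-``; an unchanged source (``0``) transmits ``0``
    through either edge type.  Edge signs are restricted to ``{+, -}``.
    """
    edge_sign, source_sign = Sign(edge_sign), Sign(source_sign)
    if not edge_sign.is_variant:
        raise ValueError("edges are activations (+) or inhibitions (-); edge sign 0 is invalid")
    if source_sign is Sign.ZERO:
        return Sign.ZERO
    if edge_sign is Sign.PLUS:
        return source_sign
    return source_sign.opposite


def compose_signs(a: Sign | str, b: Sign | str) -> Sign:
    """Sign product of two variant signs (path composition): ``- . - = +``."""
    a, b = Sign(a), Sign(b)
    if not (a.is_variant and b.is_variant):
        raise ValueError("compose_signs is defined on variant signs {+, -} only")
    return Sign.PLUS if a is b else Sign.MINUS


class SignedGraph:
    """Directed graph G(V, E, alpha) with signed edges and node roles.

    Parameters
    ----------
    edges:
        Iterable of ``(source, target, sign)`` triples, sign in ``{+, -}``.
        Parallel edges with opposite signs are permitted; duplicates collapse.
    roles:
        Mapping node-id -> role, role in ``{"gene", "species"}``.  Every edge
        endpoint must be declared here.  ``gene`` marks observable nodes.
    inputs:
        Optional explicit set of input nodes (exempt from the consistency
        rules).  Defaults to the nodes with no predecessor.
    """

    __slots__ = ("roles", "edges", "inputs", "_preds", "_succs")

    def __init__(
        self,
        edges: Iterable[Tuple[str, str, Sign | str]],
        roles: Mapping[str, str],
        inputs: Optional[Iterable[str]] = None,
    ) -> None:
        role_map = {str(n): str(r) for n, r in dict(roles).items()}
        for n, r in role_map.items():
            if r not in ROLES:
                raise ValueError(f"node {n!r} has unknown role {r!r}; expected one of {ROLES}")
        norm = set()
        for u, v, s in edges:
            u, v, s = str(u), str(v), Sign(s)
            if not s.is_variant:
                raise ValueError(f"edge {u}->{v} has sign 0; edges must be + or -")
            if u not in role_map or v not in role_map:
                raise ValueError(f"edge {u}->{v} has an undeclared endpoint")
            norm.add((u, v, s))
        self.edges: FrozenSet[Tuple[str, str, Sign]] = frozenset(norm)
        self.roles: Dict[str, str] = role_map
        preds: Dict[str, list] = {n: [] for n in role_map}
        succs: Dict[str, list] = {n: [] for n in role_map}
        for u, v, s in sorted(norm):
            preds[v].append((u, s))
            succs[u].append((v, s))
        self._preds = {n: tuple(es) for n, es in preds.items()}
        self._succs = {n: tuple(es) for n, es in succs.items()}
        if inputs is None:
            self.inputs = frozenset(n for n in role_map if not self._preds[n])
        else:
            inp = frozenset(str(n) for n in inputs)
            missing = inp - role_map.keys()
            if missing:
                raise ValueError(f"declared inputs are not nodes: {sorted(missing)}")
            self.inputs = inp

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str, Sign | str]],
        genes: Iterable[str] = (),
        nodes: Iterable[str] = (),
        inputs: Optional[Iterable[str]] = None,
    ) -> "SignedGraph":
        """Build a graph from an edge list, inferring the node set.

        ``genes`` marks the observable nodes; everything else is a species.
        ``nodes`` may add isolated nodes absent from the edge list.
        """
        edges = [(str(u), str(v), Sign(s)) for u, v, s in edges]
        gene_set = {str(g) for g in genes}
        all_nodes = {str(n) for n in nodes} | gene_set
        for u, v, _ in edges:
            all_nodes.add(u)
            all_nodes.add(v)
        roles = {n: (GENE if n in gene_set else SPECIES) for n in all_nodes}
        return cls(edges, roles, inputs)

    def with_inputs(self, inputs: Iterable[str]) -> "SignedGraph":
        return SignedGraph(self.edges, self.roles, inputs)

    # -- queries --------------------------------------------------------------

    @property
    def nodes(self) -> FrozenSet[str]:
        return frozenset(self.roles)

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset(n for n, r in self.roles.items() if r == GENE)

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self.roles

    def predecessors(self, node: str) -> Tuple[Tuple[str, Sign], ...]:
        """``(source, edge_sign)`` pairs of the in-edges of ``node``."""
        try:
            return self._preds[node]
        except KeyError:
            raise ValueError(f"unknown node {node!r}") from None

    def successors(self, node: str) -> Tuple[Tuple[str, Sign], ...]:
        try:
            return self._succs[node]
        except KeyError:
            raise ValueError(f"unknown node {node!r}") from None

    def in_degree(self, node: str) -> int:
        return len(self.predecessors(node))

    def out_degree(self, node: str) -> int:
        return len(self.successors(node))

    def to_digraph(self):
        """Simple (unsigned) :class:`networkx.DiGraph` view for path algorithms."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.roles))
        g.add_edges_from(sorted({(u, v) for u, v, _ in self.edges}))
        return g

    def to_networkx(self):
        """:class:`networkx.MultiDiGraph` carrying the edge ``sign`` attribute."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for n in sorted(self.roles):
            g.add_node(n, role=self.roles[n], input=n in self.inputs)
        for u, v, s in sorted(self.edges):
            g.add_edge(u, v, sign=s.value)
        return g

    def __repr__(self) -> str:
        return (
            f"SignedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"n_genes={len(self.genes)}, n_inputs={len(self.inputs)})"
        )


@dataclass(frozen=True)
class Labeling:
    """Partial sign assignment (observations) for one expression profile."""

    profile_id: str
    assignments: Mapping[str, Sign] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "assignments",
            {str(n): Sign(s) for n, s in dict(self.assignments).items()},
        )

    @property
    def domain(self) -> FrozenSet[str]:
        """Dom(beta): the set of observed nodes."""
        return frozenset(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def __iter__(self) -> Iterator[str]:
        return iter(self.assignments)

    def __contains__(self, node: str) -> bool:
        return node in self.assignments

    def __getitem__(self, node: str) -> Sign:
        return self.assignments[node]

    def get(self, node: str, default=None):
        return self.assignments.get(node, default)

    def items(self):
        return self.assignments.items()

    def restricted_to(self, nodes: Iterable[str]) -> "Labeling":
        keep = set(nodes)
        return Labeling(self.profile_id, {n: s for n, s in self.assignments.items() if n in keep})

    def with_observation(self, node: str, sign: Sign | str) -> "Labeling":
        new = dict(self.assignments)
        new[str(node)] = Sign(sign)
        return Labeling(self.profile_id, new)

    def check_against(self, graph: SignedGraph) -> None:
        unknown = self.domain - graph.nodes
        if unknown:
            raise ValueError(
                f"labeling {self.profile_id!r} observes nodes absent from the graph: "
                f"{sorted(unknown)[:5]}..."
            )


class Coloring(dict):
    """Total sign assignment mu: V -> {+, -, 0}; hashable, treated as immutable."""

    def __init__(self, *args, **kwargs) -> None:
        super().__init__(*args, **kwargs)
        for n in list(self):
            self[n] = Sign(self[n])

    def __hash__(self) -> int:  # type: ignore[override]
        return hash(frozenset(self.items()))


# -- TSV input / output -------------------------------------------------------
#
# Graph file: columns `source  sign  target`; node metadata: `node  role`;
# optional inputs file: one node-id per line; observations: `node  sign`.


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_graph(
    edge_path,
    roles_path=None,
    inputs_path=None,
) -> SignedGraph:
    """Read a signed graph from its edge-list TSV (and optional metadata files)."""
    df = _read_tsv(edge_path)
    required = {"source", "sign", "target"}
    if not required.issubset(df.columns):
        raise ValueError(f"graph file {edge_path} must have columns {sorted(required)}")
    edges = [(r.source, r.target, r.sign) for r in df.itertuples()]
    genes: set = set()
    nodes: set = set()
    if roles_path is not None:
        rdf = _read_tsv(roles_path)
        if not {"node", "role"}.issubset(rdf.columns):
            raise ValueError(f"roles file {roles_path} must have columns ['node', 'role']")
        nodes = set(rdf["node"])
        genes = set(rdf.loc[rdf["role"] == GENE, "node"])
    inputs = None
    if inputs_path is not None:
        text = Path(inputs_path).read_text()
        inputs = [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]
    return SignedGraph.from_edges(edges, genes=genes, nodes=nodes, inputs=inputs)


def write_graph(graph: SignedGraph, edge_path, roles_path=None, inputs_path=None, header: str = "") -> None:
    edge_path = Path(edge_path)
    rows = sorted((u, s.value, v) for u, v, s in graph.edges)
    with edge_path.open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("source\tsign\ttarget\n")
        for u, s, v in rows:
            fh.write(f"{u}\t{s}\t{v}\n")
    if roles_path is not None:
        with Path(roles_path).open("w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("node\trole\n")
            for n in sorted(graph.roles):
                fh.write(f"{n}\t{graph.roles[n]}\n")
    if inputs_path is not None:
        with Path(inputs_path).open("w") as fh:
            for n in sorted(graph.inputs):
                fh.write(f"{n}\n")


def read_labeling(path, profile_id: Optional[str] = None) -> Labeling:
    """Read one profile's observations (TSV with columns ``node  sign``)."""
    path = Path(path)
    df = _read_tsv(path)
    if not {"node", "sign"}.issubset(df.columns):
        raise ValueError(f"observation file {path} must have columns ['node', 'sign']")
    return Labeling(profile_id or path.stem, {r.node: r.sign for r in df.itertuples()})


def write_labeling(labeling: Labeling, path, header: str = "") -> None:
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("node\tsign\n")
        for n in sorted(labeling.domain):
            fh.write(f"{n}\t{labeling[n].value}\n")


def read_labeling_dir(obs_dir) -> Dict[str, Labeling]:
    """Read every ``*.tsv`` in a directory as one labeling per profile."""
    out: Dict[str, Labeling] = {}
    for path in sorted(Path(obs_dir).glob("*.tsv")):
        lab = read_labeling(path)
        out[lab.profile_id] = lab
    if not out:
        raise ValueError(f"no observation TSVs found under {obs_dir}")
    return out


def read_class_map(path) -> Dict[str, str]:
    """Read a profile -> class TSV (columns ``profile  class``)."""
    df = _read_tsv(path)
    if not {"profile", "class"}.issubset(df.columns):
        raise ValueError(f"class map {path} must have columns ['profile', 'class']")
    return dict(zip(df["profile"], df["class"]))
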
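"""Sign-consistency checking, exact enumeration, repairs and sign projection.

The qualitative model: a coloring ``mu`` assigns every node one sign in
``{+, -, 0}``.  It is *consistent* with the influence graph when

- (R1) input nodes are unconstrained;
- (R2) every other variant node has at least one predecessor whose influence
  (edge sign applied to the predecessor's sign) equals its own sign;
- (R3) every other invariant (0) node has either all predecessor influences
  equal to 0, or two predecessors with opposite variant influences.

When no coloring extends the observations ``beta``, consistency is restored
by one of two exact repair modes:

- **MCOS**: grant a minimum-cardinality set of non-input nodes an "artificial
  influence" exempting them from R2/R3 (a correction of the graph topology);
- **SCENFIT**: switch observed signs at minimum total cost (a correction of
  the data), where a variant flip (``+`` <-> ``-``) costs 2 and any switch
  between a variant sign and ``0`` costs 1.

Projections summarize, per node, the set of signs realized across the union
of consistent colorings under *all* minimal repairs; the seven possible sign
sets give the seven projection classes.

The solver is an exact branch-and-bound over sign domains in a
pseudo-topological node order, pruning on accumulated switch cost and on
rule violations as soon as a node and its predecessors are assigned.  It is
designed for the compacted, desk-scale graphs this package targets; the
exhaustive ``enumerate_colorings`` is deliberately bounded.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import ALL_SIGNS, Coloring, Labeling, Sign, SignedGraph, influence

#: Default cap on the number of unobserved nodes for exhaustive enumeration.
BRUTE_FORCE_BOUND = 12

#: SCENFIT switch costs: observed sign -> ((alternative sign, cost), ...).
SWITCH_COSTS: Dict[Sign, Tuple[Tuple[Sign, int], ...]] = {
    Sign.PLUS: ((Sign.MINUS, 2), (Sign.ZERO, 1)),
    Sign.MINUS: ((Sign.PLUS, 2), (Sign.ZERO, 1)),
    Sign.ZERO: ((Sign.PLUS, 1), (Sign.MINUS, 1)),
}


class ProjectionClass(enum.Enum):
    """The seven sign-projection classes (nonempty subsets of {+, -, 0})."""

    PLUS = "+"
    MINUS = "-"
    ZERO = "0"
    NOT_PLUS = "Not+"
    NOT_MINUS = "Not-"
    CHANGE = "change"
    UNKNOWN = "?"

    def __str__(self) -> str:
        return self.value

    @property
    def signs(self) -> FrozenSet[Sign]:
        return _SIGNS_BY_CLASS[self]

    @property
    def is_strong(self) -> bool:
        """Strong classes pin the node to a single sign in every solution."""
        return len(self.signs) == 1

    @classmethod
    def from_signs(cls, signs: Iterable[Sign | str]) -> "ProjectionClass":
        key = frozenset(Sign(s) for s in signs)
        try:
            return _CLASS_BY_SIGNS[key]
        except KeyError:
            raise ValueError(f"not a nonempty subset of {{+,-,0}}: {signs!r}") from None


_SIGNS_BY_CLASS: Dict[ProjectionClass, FrozenSet[Sign]] = {
    ProjectionClass.PLUS: frozenset({Sign.PLUS}),
    ProjectionClass.MINUS: frozenset({Sign.MINUS}),
    ProjectionClass.ZERO: frozenset({Sign.ZERO}),
    ProjectionClass.NOT_PLUS: frozenset({Sign.MINUS, Sign.ZERO}),
    ProjectionClass.NOT_MINUS: frozenset({Sign.PLUS, Sign.ZERO}),
    ProjectionClass.CHANGE: frozenset({Sign.PLUS, Sign.MINUS}),
    ProjectionClass.UNKNOWN: frozenset({Sign.PLUS, Sign.MINUS, Sign.ZERO}),
}
_CLASS_BY_SIGNS: Dict[FrozenSet[Sign], ProjectionClass] = {
    v: k for k, v in _SIGNS_BY_CLASS.items()
}


@dataclass(frozen=True)
class RepairResult:
    """Outcome of an exact repair run.

    ``repair_sets`` holds *all* minimal repairs: frozensets of node-ids for
    MCOS, frozensets of ``(node, old_sign, new_sign)`` switches for SCENFIT.
    ``colorings`` is the union of consistent colorings under every minimal
    repair (the basis of sign projection).
    """

    mode: str
    score: int
    repair_sets: Tuple[FrozenSet, ...]
    colorings: Tuple[Coloring, ...]

    def projections(self, nodes: Optional[Iterable[str]] = None) -> Dict[str, ProjectionClass]:
        return project_signs(self.colorings, nodes)


# -- consistency rules --------------------------------------------------------


def _explained(graph: SignedGraph, assign: Mapping[str, Sign], node: str) -> bool:
    """Check rules R2/R3 for ``node``; every predecessor must be assigned."""
    target = assign[node]
    has_plus = has_minus = False
    all_zero = True
    for p, es in graph.predecessors(node):
        inf = influence(es, assign[p])
        if inf is Sign.ZERO:
            continue
        all_zero = False
        if target.is_variant:
            if inf is target:
                return True
        elif inf is Sign.PLUS:
            has_plus = True
        else:
            has_minus = True
        if has_plus and has_minus:
            return True
    if target.is_variant:
        return False
    return all_zero or (has_plus and has_minus)


def is_consistent_coloring(graph: SignedGraph, mu: Mapping[str, Sign]) -> bool:
    """True iff the *total* coloring ``mu`` satisfies rules R1-R3."""
    mu = {str(n): Sign(s) for n, s in dict(mu).items()}
    if set(mu) != graph.nodes:
        missing = graph.nodes - set(mu)
        extra = set(mu) - graph.nodes
        raise ValueError(
            f"coloring must assign every graph node exactly once "
            f"(missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})"
        )
    return all(_explained(graph, mu, n) for n in graph.nodes if n not in graph.inputs)


# -- search engine ------------------------------------------------------------


def _pseudo_topological_order(graph: SignedGraph) -> List[str]:
    """Deterministic order placing nodes after their predecessors when possible."""
    remaining = set(graph.nodes)
    placed: Set[str] = set()
    order: List[str] = []
    while remaining:
        nxt = min(
            remaining,
            key=lambda n: (sum(1 for p, _ in graph.predecessors(n) if p not in placed), n),
        )
        order.append(nxt)
        placed.add(nxt)
        remaining.discard(nxt)
    return order


def _search(
    graph: SignedGraph,
    domains: Mapping[str, Sequence[Tuple[Sign, int]]],
    check_nodes: Iterable[str],
    stop_first: bool = False,
) -> Tuple[Optional[int], List[Coloring]]:
    """Enumerate consistent colorings of minimum total domain cost.

    ``domains`` maps each node to its candidate ``(sign, cost)`` pairs;
    ``check_nodes`` are the nodes subject to rules R2/R3.  Returns the best
    cost and *all* colorings attaining it, or ``(None, [])`` when no coloring
    satisfies the rules.  With ``stop_first`` the search stops at the first
    consistent coloring (existence test; costs must then all be zero).
    """
    order = _pseudo_topological_order(graph)
    pos = {n: i for i, n in enumerate(order)}
    ready: List[List[str]] = [[] for _ in order]
    for n in check_nodes:
        i = pos[n]
        for p, _ in graph.predecessors(n):
            i = max(i, pos[p])
        ready[i].append(n)

    assign: Dict[str, Sign] = {}
    best = math.inf
    found: List[Coloring] = []

    def rec(i: int, cost: int) -> bool:
        nonlocal best
        if i == len(order):
            if cost < best:
                best = cost
                found.clear()
            found.append(Coloring(assign))
            return True
        node = order[i]
        checks = ready[i]
        for sign, c in domains[node]:
            new_cost = cost + c
            if new_cost > best:
                continue
            assign[node] = sign
            if all(_explained(graph, assign, m) for m in checks):
                hit = rec(i + 1, new_cost)
                if hit and stop_first:
                    del assign[node]
                    return True
            del assign[node]
        return False

    rec(0, 0)
    if not found:
        return None, []
    return int(best), found


def _full_domains(
    graph: SignedGraph, fixed: Mapping[str, Sign]
) -> Dict[str, Tuple[Tuple[Sign, int], ...]]:
    free = tuple((s, 0) for s in ALL_SIGNS)
    return {
        n: (((fixed[n], 0),) if n in fixed else free) for n in graph.nodes
    }


# -- public operations --------------------------------------------------------


def enumerate_colorings(
    graph: SignedGraph, beta: Labeling, bound: int = BRUTE_FORCE_BOUND
) -> List[Coloring]:
    """All consistent colorings extending ``beta`` (exhaustive, bounded).

    Refuses graphs with more than ``bound`` unobserved nodes, for which the
    3^(|V|-|beta|) candidate space is no longer desk-sized; use :func:`solve`
    there instead.
    """
    beta.check_against(graph)
    n_free = len(graph.nodes - beta.domain)
    if n_free > bound:
        raise ValueError(
            f"{n_free} unobserved nodes exceed the brute-force bound ({bound}); "
            "use solve() for repair-based analysis"
        )
    fixed = {n: beta[n] for n in beta.domain}
    _, cols = _search(
        graph, _full_domains(graph, fixed), graph.nodes - graph.inputs
    )
    return cols


def solve(
    graph: SignedGraph,
    beta: Labeling,
    mode: str = "mcos",
    *,
    repair_scope: str = "all",
    fixed: Optional[Mapping[str, Sign | str]] = None,
) -> RepairResult:
    """Exact MCOS or SCENFIT repair of ``(graph, beta)``.

    Parameters
    ----------
    mode:
        ``"mcos"`` exempts a minimum number of non-input nodes from the
        rules; ``"scenfit"`` switches observed signs at minimum cost
        (variant flip 2, variant <-> invariant 1).
    repair_scope:
        For MCOS, ``"all"`` allows artificial influences on any non-input
        node; ``"unobserved"`` restricts them to nodes outside Dom(beta).
    fixed:
        Hard sign clamps that are never repairable in either mode (used for
        in-silico interventions).  Keys must not overlap Dom(beta).

    Consistent inputs return score 0 with the unrepaired colorings.
    """
    beta.check_against(graph)
    mode = mode.lower()
    clamps = {str(n): Sign(s) for n, s in dict(fixed or {}).items()}
    for n in clamps:
        if n not in graph:
            raise ValueError(f"fixed node {n!r} is not in the graph")
        if n in beta:
            raise ValueError(f"fixed node {n!r} is already observed")
    if mode == "mcos":
        return _solve_mcos(graph, beta, clamps, repair_scope)
    if mode == "scenfit":
        return _solve_scenfit(graph, beta, clamps)
    raise ValueError(f"unknown repair mode {mode!r}; expected 'mcos' or 'scenfit'")


def _solve_mcos(
    graph: SignedGraph,
    beta: Labeling,
    clamps: Mapping[str, Sign],
    repair_scope: str,
) -> RepairResult:
    if repair_scope not in ("all", "unobserved"):
        raise ValueError(f"unknown repair_scope {repair_scope!r}")
    fixed = {**{n: beta[n] for n in beta.domain}, **clamps}
    domains = _full_domains(graph, fixed)
    candidates = sorted(
        n
        for n in graph.nodes
        if n not in graph.inputs
        and n not in clamps
        and (repair_scope == "all" or n not in beta)
    )
    constrained = graph.nodes - graph.inputs
    winners: List[FrozenSet[str]] = []
    score = 0
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            cost, _ = _search(
                graph, domains, constrained - set(combo), stop_first=True
            )
            if cost is not None:
                winners.append(frozenset(combo))
        if winners:
            score = k
            break
    else:
        # Only reachable with a restricted repair scope: exempting every
        # candidate still leaves an unexplained observation.
        raise RuntimeError(
            "no MCOS repair exists within the allowed candidates "
            f"(repair_scope={repair_scope!r})"
        )
    colorings: List[Coloring] = []
    seen: Set[Coloring] = set()
    for repair in winners:
        _, cols = _search(graph, domains, constrained - repair)
        for c in cols:
            if c not in seen:
                seen.add(c)
                colorings.append(c)
    return RepairResult("mcos", score, tuple(winners), tuple(colorings))


def _solve_scenfit(
    graph: SignedGraph, beta: Labeling, clamps: Mapping[str, Sign]
) -> RepairResult:
    domains: Dict[str, Tuple[Tuple[Sign, int], ...]] = {}
    for n in graph.nodes:
        if n in clamps:
            domains[n] = ((clamps[n], 0),)
        elif n in beta:
            observed = beta[n]
            domains[n] = ((observed, 0),) + SWITCH_COSTS[observed]
        else:
            domains[n] = tuple((s, 0) for s in ALL_SIGNS)
    cost, cols = _search(graph, domains, graph.nodes - graph.inputs)
    if cost is None:
        # Unreachable: the all-zero coloring satisfies R3 everywhere, so a
        # finite-cost repair always exists.
        raise RuntimeError("SCENFIT search found no consistent coloring")
    repair_sets: List[FrozenSet[Tuple[str, Sign, Sign]]] = []
    seen: Set[FrozenSet] = set()
    for mu in cols:
        switches = frozenset(
            (n, beta[n], mu[n]) for n in beta.domain if mu[n] is not beta[n]
        )
        if switches not in seen:
            seen.add(switches)
            repair_sets.append(switches)
    return RepairResult("scenfit", cost, tuple(repair_sets), tuple(cols))


def project_signs(
    colorings: Sequence[Mapping[str, Sign]],
    nodes: Optional[Iterable[str]] = None,
) -> Dict[str, ProjectionClass]:
    """Map each node to the class of the sign set it takes across colorings."""
    colorings = list(colorings)
    if not colorings:
        raise ValueError("sign projection is undefined for an empty coloring set")
    if nodes is None:
        nodes = colorings[0].keys()
    out: Dict[str, ProjectionClass] = {}
    for n in nodes:
        out[n] = ProjectionClass.from_signs({mu[n] for mu in colorings})
    return out
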
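"""Independent brute-force oracles for the exact solver.

Everything here enumerates candidate spaces exhaustively (all 3^|V|
colorings, all repair subsets, all switch assignments) and applies the
consistency rules through a separate, direct implementation.  Intended for
tiny fixtures only.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Set, Tuple

from signet.core import ALL_SIGNS, Labeling, Sign, SignedGraph, influence

SWITCHES = {
    Sign.PLUS: ((Sign.MINUS, 2), (Sign.ZERO, 1)),
    Sign.MINUS: ((Sign.PLUS, 2), (Sign.ZERO, 1)),
    Sign.ZERO: ((Sign.PLUS, 1), (Sign.MINUS, 1)),
}


def node_ok(graph: SignedGraph, mu: Dict[str, Sign], n: str) -> bool:
    """Direct restatement of rules R2/R3 for one node."""
    infl = [influence(s, mu[p]) for p, s in graph.predecessors(n)]
    if mu[n] is Sign.ZERO:
        return all(i is Sign.ZERO for i in infl) or (
            Sign.PLUS in infl and Sign.MINUS in infl
        )
    return mu[n] in infl


def consistent(graph: SignedGraph, mu: Dict[str, Sign], exempt: Set[str] = frozenset()) -> bool:
    skip = set(graph.inputs) | set(exempt)
    return all(node_ok(graph, mu, n) for n in graph.nodes if n not in skip)


def all_colorings(graph: SignedGraph):
    nodes = sorted(graph.nodes)
    for combo in itertools.product(ALL_SIGNS, repeat=len(nodes)):
        yield dict(zip(nodes, combo))


def consistent_colorings(
    graph: SignedGraph, beta: Labeling, exempt: Set[str] = frozenset()
) -> List[Dict[str, Sign]]:
    out = []
    for mu in all_colorings(graph):
        if all(mu[n] is beta[n] for n in beta.domain) and consistent(graph, mu, exempt):
            out.append(mu)
    return out


def mcos_oracle(graph: SignedGraph, beta: Labeling):
    """(score, minimal repair sets, union of colorings) by subset enumeration."""
    candidates = sorted(graph.nodes - graph.inputs)
    for k in range(len(candidates) + 1):
        winners = []
        colorings = []
        seen = set()
        for combo in itertools.combinations(candidates, k):
            cols = consistent_colorings(graph, beta, set(combo))
            if cols:
                winners.append(frozenset(combo))
                for mu in cols:
                    key = frozenset(mu.items())
                    if key not in seen:
                        seen.add(key)
                        colorings.append(mu)
        if winners:
            return k, winners, colorings
    raise AssertionError("unreachable: exempting every non-input node is consistent")


def scenfit_oracle(graph: SignedGraph, beta: Labeling):
    """(score, minimal switch sets, colorings) by switch-assignment enumeration."""
    dom = sorted(beta.domain)
    options = []
    for n in dom:
        base = [(beta[n], 0)] + list(SWITCHES[beta[n]])
        options.append(base)
    best = None
    results = []  # (cost, switch set, colorings)
    for combo in itertools.product(*options):
        cost = sum(c for _, c in combo)
        if best is not None and cost > best:
            continue
        switched = Labeling(beta.profile_id, {n: s for n, (s, _) in zip(dom, combo)})
        cols = consistent_colorings(graph, switched)
        if not cols:
            continue
        switches = frozenset(
            (n, beta[n], switched[n]) for n in dom if switched[n] is not beta[n]
        )
        if best is None or cost < best:
            best = cost
            results = [(switches, cols)]
        elif cost == best:
            results.append((switches, cols))
    assert best is not None, "all-zero coloring guarantees a finite repair"
    repair_sets = []
    colorings = []
    seen_r, seen_c = set(), set()
    for switches, cols in results:
        if switches not in seen_r:
            seen_r.add(switches)
            repair_sets.append(switches)
        for mu in cols:
            key = frozenset(mu.items())
            if key not in seen_c:
                seen_c.add(key)
                colorings.append(mu)
    return best, repair_sets, colorings


def projections_oracle(colorings, nodes) -> Dict[str, FrozenSet[Sign]]:
    return {n: frozenset(mu[n] for mu in colorings) for n in nodes}


def fisher_greater_oracle(a: int, na: int, b: int, nb: int) -> float:
    """One-sided (greater) Fisher p by direct hypergeometric tail summation."""
    from math import comb

    total = na + nb
    successes = a + b
    denom = comb(total, na)
    p = 0.0
    for x in range(max(0, successes - nb), min(na, successes) + 1):
        if x >= a:
            p += comb(successes, x) * comb(total - successes, na - x) / denom
    return p
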
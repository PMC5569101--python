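"""In-silico single-node perturbations scored by SCENFIT conflict cost.

Fixing an unobserved node to a variant sign (an intervention that itself is
never repairable) and re-running the SCENFIT repair measures how strongly
that activation/inhibition conflicts with a profile's observations: the
higher the score, the more data the intervention contradicts.  Per profile
and per perturbation sign, the scores of all unobserved candidate nodes
form the reference distribution; a perturbation is *top-ranked* when its
score reaches the nearest-rank upper ``q`` quantile (default 10%, ties at
the threshold included).  The Top Perturbation Score (TPS) of an assignment
(node, sign) in a class is the fraction of the class's profiles where it is
top-ranked, and case-vs-control enrichment is tested with a one-sided
Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .consistency import solve
from .core import Labeling, Sign, SignedGraph, VARIANT_SIGNS

DEFAULT_TOP_FRACTION = 0.10


def perturb_and_score(
    graph: SignedGraph, beta: Labeling, node: str, sign: Sign | str
) -> int:
    """SCENFIT score after adding the intervention ``node := sign`` to ``beta``.

    The added observation is clamped (the intervention is ground truth, not
    data, so it is never switchable); the node must be unobserved in
    ``beta``.
    """
    sign = Sign(sign)
    if not sign.is_variant:
        raise ValueError("perturbations fix a node to a variant sign (+ or -)")
    if node in beta:
        raise ValueError(f"node {node!r} is already observed in profile {beta.profile_id!r}")
    return solve(graph, beta, "scenfit", fixed={node: sign}).score


def top_threshold(scores: Sequence[int], q: float = DEFAULT_TOP_FRACTION) -> float:
    """Nearest-rank upper-quantile cutoff separating the top ``q`` scores.

    With K scores sorted descending, the threshold is the m-th largest where
    m = ceil(q * K); every score >= threshold counts as top-ranked, so ties
    at the cutoff are all included.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("top_threshold needs at least one score")
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    m = math.ceil(q * len(scores))
    return float(sorted(scores, reverse=True)[m - 1])


@dataclass
class PerturbationScores:
    """Full SCENFIT perturbation scan across profiles.

    ``sf`` maps ``(node, sign, profile)`` to the SCENFIT score of the
    perturbed labeling, ``flags`` to the top-ranked indicator f(i, s, j);
    ``thresholds`` holds the per-(profile, sign) cutoff; ``tps`` maps
    ``(node, sign, class)`` to the Top Perturbation Score and ``fisher_p``
    maps ``(node, sign)`` to the case-vs-control enrichment p-value.
    """

    sf: Dict[Tuple[str, Sign, str], int]
    flags: Dict[Tuple[str, Sign, str], int]
    thresholds: Dict[Tuple[str, Sign], float]
    tps: Dict[Tuple[str, Sign, str], float]
    fisher_p: Dict[Tuple[str, Sign], float]
    classes: Dict[str, str] = field(default_factory=dict)

    def sf_frame(self) -> pd.DataFrame:
        """Long-format (node, sign, profile, sf, f) table."""
        rows = [
            (n, s.value, p, score, self.flags[(n, s, p)])
            for (n, s, p), score in sorted(self.sf.items())
        ]
        return pd.DataFrame(rows, columns=["node", "sign", "profile", "sf", "f"])

    def summary_frame(self, case_class: str = "MC", control_class: str = "NPC") -> pd.DataFrame:
        """Per-(node, direction) TPS summary with the Fisher p-value."""
        rows = []
        keys = sorted({(n, s) for n, s, _ in self.tps})
        for n, s in keys:
            rows.append(
                (
                    n,
                    s.value,
                    self.tps.get((n, s, control_class), float("nan")),
                    self.tps.get((n, s, case_class), float("nan")),
                    self.fisher_p.get((n, s), float("nan")),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["node", "direction", f"tps_{control_class}", f"tps_{case_class}", "p_fisher"],
        )


def tps(
    graph: SignedGraph,
    labelings: Mapping[str, Labeling],
    classes: Mapping[str, str],
    candidates: Optional[Iterable[str]] = None,
    q: float = DEFAULT_TOP_FRACTION,
    case_class: str = "MC",
    control_class: str = "NPC",
) -> PerturbationScores:
    """Top Perturbation Scores for candidate (node, sign) interventions.

    For every profile j and perturbation sign s, the SCENFIT score of fixing
    k := s is computed for *every* node k unobserved in that profile; the
    top-``q`` cutoff is derived from that full per-profile distribution.
    ``candidates`` restricts which assignments are aggregated into TPS
    (default: nodes unobserved in every profile).  TPS averages the
    top-ranked indicator over all N_C profiles of each class (a node
    observed in a profile contributes 0 there).
    """
    profiles = sorted(labelings)
    if not profiles:
        raise ValueError("tps requires at least one labeling")
    for p in profiles:
        if p not in classes:
            raise ValueError(f"class map missing profile {p!r}")
    class_names = sorted(set(classes[p] for p in profiles))
    for cls in class_names:
        if not any(classes[p] == cls for p in profiles):
            raise ValueError(f"empty class {cls!r}")

    if candidates is None:
        observed_anywhere = set()
        for lab in labelings.values():
            observed_anywhere |= lab.domain
        candidates = sorted(graph.nodes - observed_anywhere)
    else:
        candidates = sorted({str(c) for c in candidates})
        for c in candidates:
            if c not in graph:
                raise ValueError(f"candidate {c!r} is not a graph node")

    sf: Dict[Tuple[str, Sign, str], int] = {}
    flags: Dict[Tuple[str, Sign, str], int] = {}
    thresholds: Dict[Tuple[str, Sign], float] = {}
    for p in profiles:
        beta = labelings[p]
        beta.check_against(graph)
        unobserved = sorted(graph.nodes - beta.domain)
        for s in VARIANT_SIGNS:
            scores = {k: perturb_and_score(graph, beta, k, s) for k in unobserved}
            cutoff = top_threshold(list(scores.values()), q)
            thresholds[(p, s)] = cutoff
            for k, score in scores.items():
                sf[(k, s, p)] = score
                flags[(k, s, p)] = int(score >= cutoff)

    tps_map: Dict[Tuple[str, Sign, str], float] = {}
    fisher: Dict[Tuple[str, Sign], float] = {}
    n_case = sum(1 for p in profiles if classes[p] == case_class)
    n_control = sum(1 for p in profiles if classes[p] == control_class)
    for node in candidates:
        for s in VARIANT_SIGNS:
            per_class_hits: Dict[str, int] = {}
            for cls in class_names:
                members = [p for p in profiles if classes[p] == cls]
                hits = sum(flags.get((node, s, p), 0) for p in members)
                per_class_hits[cls] = hits
                tps_map[(node, s, cls)] = hits / len(members)
            if n_case and n_control:
                a = per_class_hits.get(case_class, 0)
                b = per_class_hits.get(control_class, 0)
                _, pval = stats.fisher_exact(
                    [[a, n_case - a], [b, n_control - b]], alternative="greater"
                )
                fisher[(node, s)] = float(pval)
    return PerturbationScores(sf, flags, thresholds, tps_map, fisher, dict(classes))
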
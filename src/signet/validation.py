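"""Holdout precision of sign predictions and randomized baselines.

Prediction quality is measured by hiding a fraction of one profile's
observed signs, repairing the remainder against the graph (MCOS mode) and
comparing the strong-class projections of the hidden nodes with their true
signs.  The comparator is the same procedure on sign-permuted data, and
an analytic sanity baseline is the precision of a uniformly random
predictor: 1/3 (~33%) under the three-sign model, 1/2 (50%) under the
two-sign model.  All precisions are reported in percent (0-100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .consistency import project_signs, solve
from .core import Labeling, SignedGraph

SCORING_MODES = ("strict", "lenient")


@dataclass(frozen=True)
class HoldoutResult:
    """Precision (%) over strong-class predictions of hidden nodes.

    ``precision`` is ``None`` when no hidden node received a scorable
    projection (undefined precision).
    """

    precision: Optional[float]
    n_scored: int
    n_hidden: int


def holdout_precision(
    graph: SignedGraph,
    beta: Labeling,
    frac: float = 0.5,
    seed: int = 0,
    mode: str = "strict",
) -> HoldoutResult:
    """Hide a random fraction of ``beta``, predict it back, score precision.

    ``strict`` scoring counts only hidden nodes whose projection is a strong
    class (single sign), correct iff that sign equals the hidden one; weak
    and ``?`` projections are excluded from the denominator.  ``lenient``
    scoring credits any projection whose sign set contains the hidden sign,
    with every hidden node in the denominator.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    if mode not in SCORING_MODES:
        raise ValueError(f"unknown scoring mode {mode!r}; expected one of {SCORING_MODES}")
    dom = sorted(beta.domain)
    if not dom:
        raise ValueError("holdout requires a nonempty labeling")
    beta.check_against(graph)
    rng = np.random.default_rng(seed)
    n_hide = min(len(dom), max(1, int(round(frac * len(dom)))))
    hidden = set(rng.choice(dom, size=n_hide, replace=False).tolist())
    visible = Labeling(beta.profile_id, {n: beta[n] for n in dom if n not in hidden})
    result = solve(graph, visible, "mcos")
    proj = project_signs(result.colorings, hidden)
    correct = scored = 0
    for n in sorted(hidden):
        cls = proj[n]
        if mode == "strict":
            if cls.is_strong:
                scored += 1
                correct += cls.signs == frozenset({beta[n]})
        else:
            scored += 1
            correct += beta[n] in cls.signs
    precision = 100.0 * correct / scored if scored else None
    return HoldoutResult(precision, scored, n_hide)


def randomized_baseline(
    graph: SignedGraph,
    beta: Labeling,
    frac: float = 0.5,
    reps: int = 100,
    seed: int = 0,
    mode: str = "strict",
) -> List[HoldoutResult]:
    """Holdout precision after uniformly permuting the observed signs.

    Each repetition shuffles the observed signs across Dom(beta) and runs
    :func:`holdout_precision` with a fresh split; the list of per-repetition
    results is returned (precision ``None`` where undefined).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    dom = sorted(beta.domain)
    root = np.random.SeedSequence(seed)
    out: List[HoldoutResult] = []
    for child in root.spawn(reps):
        rng = np.random.default_rng(child)
        permuted_signs = [beta[n] for n in dom]
        rng.shuffle(permuted_signs)
        shuffled = Labeling(beta.profile_id, dict(zip(dom, permuted_signs)))
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(holdout_precision(graph, shuffled, frac=frac, seed=sub_seed, mode=mode))
    return out


def random_sign_precision(n_signs: int, n: int, seed: int = 0) -> float:
    """Match rate (%) of uniformly random truth/prediction sign pairs.

    Simulates ``n`` iid pairs drawn uniformly from a 2- or 3-sign alphabet;
    the expectation is 50% and ~33% respectively.
    """
    if n_signs not in (2, 3):
        raise ValueError("n_signs must be 2 or 3")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    truth = rng.integers(n_signs, size=n)
    pred = rng.integers(n_signs, size=n)
    return 100.0 * float(np.mean(truth == pred))


def precisions(results: Sequence[HoldoutResult]) -> List[float]:
    """Defined precision values from a list of holdout results."""
    return [r.precision for r in results if r.precision is not None]


def compare_precisions(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed Welch t-test p-value between two precision distributions."""
    a = [x for x in a if x is not None]
    b = [x for x in b if x is not None]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two defined precisions per group")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
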
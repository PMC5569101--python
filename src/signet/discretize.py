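"""Three-sign discretization of expression matrices and threshold selection.

Each profile's expression is referenced to the mean of a baseline class
(normal plasma cells, "NPC", by default): ``p[g, i] = expr[g, i] -
mean_NPC(expr[g, :])`` in log2 units.  Two nonnegative thresholds then
discretize the differential values per gene and profile:

- ``p >  k2``           over-expressed  (+)
- ``p < -k2``           under-expressed (-)
- ``-k1 < p < k1``      invariant       (0)
- otherwise             unobserved (the [k1, k2] band carries no call)

Threshold pairs whose pooled proportion of variant calls exceeds 50% are
discarded; surviving pairs are ranked by mean holdout precision (predicting
a hidden half of each profile's calls from the visible half through the
sign-consistency model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Labeling, Sign, SignedGraph

DEFAULT_REFERENCE_CLASS = "NPC"

#: Selected operating point: invariant band half-width and variant cutoff.
DEFAULT_K1 = 0.03
DEFAULT_K2 = 0.2


@dataclass
class ExpressionMatrix:
    """Log2-normalized expression (rows = genes, columns = profiles) + classes."""

    values: pd.DataFrame
    classes: pd.Series
    reference_class: str = DEFAULT_REFERENCE_CLASS

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.classes = pd.Series(self.classes).astype(str)
        if set(self.classes.index) != set(self.values.columns):
            raise ValueError("class map must cover exactly the profile columns")
        self.classes = self.classes.reindex(self.values.columns)
        if not (self.classes == self.reference_class).any():
            raise ValueError(
                f"no profile of reference class {self.reference_class!r}; "
                "the baseline mean is undefined"
            )

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def profiles(self) -> List[str]:
        return list(self.values.columns)

    @property
    def reference_profiles(self) -> List[str]:
        return list(self.classes.index[self.classes == self.reference_class])

    @classmethod
    def from_tsv(cls, matrix_path, classes_path, reference_class: str = DEFAULT_REFERENCE_CLASS):
        from .core import read_class_map

        values = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
        classes = pd.Series(read_class_map(classes_path))
        return cls(values, classes, reference_class)


@dataclass(frozen=True)
class ThresholdPair:
    """Invariant band half-width ``k1`` and variant cutoff ``k2`` (0 <= k1 <= k2)."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (0 <= self.k1 <= self.k2):
            raise ValueError(f"require 0 <= k1 <= k2, got k1={self.k1}, k2={self.k2}")


def default_grid() -> List[ThresholdPair]:
    """The default 150-pair search grid (k1 in 0.01..0.10, k2 in 0.1..1.5)."""
    k1s = np.round(np.arange(0.01, 0.101, 0.01), 3)
    k2s = np.round(np.arange(0.1, 1.51, 0.1), 3)
    return [ThresholdPair(k1, k2) for k1 in k1s for k2 in k2s if k1 <= k2]


def differential_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene expression minus the reference-class mean, for every profile.

    Reference-class profiles are differenced against their own class mean as
    well (they are profiles like any other).
    """
    ref_mean = expr.values[expr.reference_profiles].mean(axis=1)
    return expr.values.sub(ref_mean, axis=0)


def discretize_profile(
    diff: pd.DataFrame, profile: str, thresholds: ThresholdPair
) -> Labeling:
    """Discretize one profile's differential values into a partial labeling.

    Genes falling in the undefined bands ``[k1, k2]`` / ``[-k2, -k1]`` (or at
    the band edges) are left out of the labeling entirely.
    """
    if profile not in diff.columns:
        raise ValueError(f"unknown profile {profile!r}")
    p = diff[profile]
    signs: Dict[str, Sign] = {}
    k1, k2 = thresholds.k1, thresholds.k2
    for gene, value in p.items():
        if value > k2:
            signs[str(gene)] = Sign.PLUS
        elif value < -k2:
            signs[str(gene)] = Sign.MINUS
        elif -k1 < value < k1:
            signs[str(gene)] = Sign.ZERO
    return Labeling(str(profile), signs)


def discretize_all(diff: pd.DataFrame, thresholds: ThresholdPair) -> Dict[str, Labeling]:
    return {str(p): discretize_profile(diff, p, thresholds) for p in diff.columns}


def sign_proportion_filter(
    labelings: Iterable[Labeling], max_prop: float = 0.5
) -> bool:
    """Keep/discard a discretization by its pooled variant-sign proportion.

    Returns ``True`` (keep) when the fraction of variant (+/-) calls among
    all calls, pooled over the given labelings, is at most ``max_prop``;
    the discard rule is strict (> max_prop).
    """
    n_variant = n_total = 0
    for lab in labelings:
        for _, s in lab.items():
            n_total += 1
            n_variant += s.is_variant
    if n_total == 0:
        raise ValueError("sign_proportion_filter needs at least one sign call")
    return n_variant / n_total <= max_prop


@dataclass(frozen=True)
class ThresholdReport:
    """One row of the threshold search: pair, filter outcome and precision."""

    thresholds: ThresholdPair
    kept: bool
    n_reps: int
    mean_precision: float
    ci95: float


def threshold_search(
    expr: ExpressionMatrix,
    graph: SignedGraph,
    grid: Optional[Sequence[ThresholdPair]] = None,
    reps: int = 20,
    holdout_frac: float = 0.5,
    seed: int = 0,
) -> List[ThresholdReport]:
    """Rank threshold pairs by holdout precision of sign-consistency prediction.

    For each surviving pair (sign-proportion filter at 50%), ``reps``
    repetitions hide ``holdout_frac`` of one profile's calls (profiles
    cycled round-robin, one per repetition) and score the strong-class
    predictions of the hidden signs.  Reports the mean precision (%) and a
    normal-approximation 95% CI (1.96 * sd / sqrt(n)).  Rows are sorted
    kept-first, by decreasing mean precision.
    """
    from .validation import holdout_precision

    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 < holdout_frac < 1):
        raise ValueError("holdout_frac must be in (0, 1)")
    observable = sorted(graph.genes)
    if not observable:
        raise ValueError("graph has no observable (gene-role) nodes")

    diff = differential_matrix(expr)
    profiles = expr.profiles
    root = np.random.SeedSequence(seed)
    reports: List[ThresholdReport] = []
    for pair, pair_seed in zip(grid, root.spawn(len(grid))):
        labelings = discretize_all(diff, pair)
        kept = sign_proportion_filter(labelings.values())
        if not kept:
            reports.append(ThresholdReport(pair, False, 0, float("nan"), float("nan")))
            continue
        precisions: List[float] = []
        rep_seeds = pair_seed.generate_state(reps) % (2**31)
        for r in range(reps):
            profile = profiles[r % len(profiles)]
            beta = labelings[profile].restricted_to(observable)
            if len(beta) == 0:
                continue
            res = holdout_precision(graph, beta, frac=holdout_frac, seed=int(rep_seeds[r]))
            if res.precision is not None:
                precisions.append(res.precision)
        if precisions:
            arr = np.asarray(precisions)
            mean = float(arr.mean())
            ci = float(1.96 * arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        else:
            mean, ci = float("nan"), float("nan")
        reports.append(ThresholdReport(pair, True, len(precisions), mean, ci))

    if not any(r.kept for r in reports):
        warnings.warn(
            "every threshold pair was discarded by the 50% sign-proportion filter",
            stacklevel=2,
        )
    reports.sort(
        key=lambda r: (
            not r.kept,
            -(r.mean_precision if r.kept and np.isfinite(r.mean_precision) else -np.inf),
            r.thresholds.k1,
            r.thresholds.k2,
        )
    )
    return reports


def threshold_report_frame(reports: Sequence[ThresholdReport]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of a threshold search."""
    return pd.DataFrame(
        {
            "k1": [r.thresholds.k1 for r in reports],
            "k2": [r.thresholds.k2 for r in reports],
            "kept": [r.kept for r in reports],
            "n_reps": [r.n_reps for r in reports],
            "mean_precision": [r.mean_precision for r in reports],
            "ci95": [r.ci95 for r in reports],
        }
    )
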
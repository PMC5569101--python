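"""Per-class frequency signatures of predicted (node, sign) assignments.

Sign projections computed per profile (under MCOS repair) are decomposed
into boolean indicators M[node, sign, profile] = 1 iff the sign belongs to
the node's projected sign set in that profile.  Only nodes never observed
in any profile are indexed (observed nodes project trivially), and only the
variant signs ``+``/``-`` are kept.  Per class C, the frequency score

    FS[i, s | C] = (1 / N_C) * sum_j M[i, s, j]    over profiles j in C

measures how often an assignment recurs; assignments enriched in the case
class are ranked by a one-sided Fisher exact test on the 2x2 presence
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from scipy import stats

from .consistency import ProjectionClass
from .core import Labeling, Sign, SignedGraph

SIGN_COLUMNS = (Sign.PLUS.value, Sign.MINUS.value)


@dataclass
class PredictionMatrix:
    """Boolean prediction tensor, flattened to (node, sign) x profile.

    ``entries`` is a boolean DataFrame whose MultiIndex rows are
    ``(node, sign)`` with sign in ``{"+", "-"}`` and whose columns are
    profile ids; ``classes`` maps each profile to its class label.
    """

    entries: pd.DataFrame
    classes: Dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.entries.columns) - set(self.classes)
        if missing:
            raise ValueError(f"class map missing profiles: {sorted(missing)[:5]}")
        self.classes = {p: self.classes[p] for p in self.entries.columns}

    @property
    def nodes(self) -> List[str]:
        return sorted({n for n, _ in self.entries.index})

    @property
    def profiles(self) -> List[str]:
        return list(self.entries.columns)

    def class_profiles(self, cls: str) -> List[str]:
        return [p for p, c in self.classes.items() if c == cls]

    def class_size(self, cls: str) -> int:
        return len(self.class_profiles(cls))

    def to_tsv(self, path) -> None:
        """Export M with a class header row above the profile columns."""
        df = self.entries.astype(int).reset_index()
        df.columns = ["node", "sign"] + self.profiles
        with open(path, "w") as fh:
            fh.write("class\t\t" + "\t".join(self.classes[p] for p in self.profiles) + "\n")
            df.to_csv(fh, sep="\t", index=False)


def build_prediction_matrix(
    projections: Mapping[str, Mapping[str, ProjectionClass]],
    labelings: Mapping[str, Labeling],
    classes: Mapping[str, str],
) -> PredictionMatrix:
    """Decompose per-profile sign projections into the boolean matrix M.

    ``projections`` maps profile -> (node -> projection class), computed
    after MCOS repair.  Nodes observed in *any* profile's labeling are
    excluded, as is the invariant indicator.
    """
    profiles = sorted(projections)
    for p in profiles:
        if p not in classes:
            raise ValueError(f"class map missing profile {p!r}")
    observed_anywhere = set()
    for lab in labelings.values():
        observed_anywhere |= lab.domain
    candidate_nodes = sorted(
        set.intersection(*(set(projections[p]) for p in profiles)) - observed_anywhere
    ) if profiles else []
    index = pd.MultiIndex.from_tuples(
        [(n, s) for n in candidate_nodes for s in SIGN_COLUMNS], names=["node", "sign"]
    )
    data = {}
    for p in profiles:
        proj = projections[p]
        data[p] = [Sign(s) in proj[n].signs for n, s in index]
    entries = pd.DataFrame(data, index=index, dtype=bool)
    return PredictionMatrix(entries, dict(classes))


def frequency_score(
    M: PredictionMatrix, node: str, sign: Sign | str, cls: str
) -> float:
    """FS of one (node, sign) assignment in one class: mean of M over the class."""
    key = (str(node), Sign(sign).value)
    if key not in M.entries.index:
        raise ValueError(f"(node, sign) pair {key} is not indexed in M")
    profiles = M.class_profiles(cls)
    if not profiles:
        raise ValueError(f"no profiles of class {cls!r}")
    return float(M.entries.loc[key, profiles].mean())


def rank_assignments(
    M: PredictionMatrix,
    case_class: str = "MC",
    control_class: str = "NPC",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Rank case-enriched assignments by one-sided Fisher exact p-value.

    Keeps the (node, sign) rows with FS_case > FS_control, tests each
    2x2 presence/absence table with Fisher's exact test (one-sided towards
    the case class by default; ``alternative`` follows scipy's naming) and
    sorts ascending by p.  A Benjamini-Hochberg column (``q_bh``) is added
    for reference; the primary ordering uses the raw p-values.
    """
    n_case = M.class_size(case_class)
    n_control = M.class_size(control_class)
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be nonempty")
    case_profiles = M.class_profiles(case_class)
    control_profiles = M.class_profiles(control_class)
    rows = []
    for node, sign in M.entries.index:
        a = int(M.entries.loc[(node, sign), case_profiles].sum())
        b = int(M.entries.loc[(node, sign), control_profiles].sum())
        fs_case = a / n_case
        fs_control = b / n_control
        if fs_case <= fs_control:
            continue
        _, p = stats.fisher_exact(
            [[a, n_case - a], [b, n_control - b]], alternative=alternative
        )
        rows.append((node, sign, fs_control, fs_case, float(p)))
    table = pd.DataFrame(
        rows,
        columns=["node", "sign", f"fs_{control_class}", f"fs_{case_class}", "p_fisher"],
    )
    if len(table):
        table["q_bh"] = stats.false_discovery_control(table["p_fisher"], method="bh")
        table = table.sort_values(
            ["p_fisher", "node", "sign"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["q_bh"] = []
    return table


def annotate_connectivity(
    table: pd.DataFrame, graph: SignedGraph, observed: Iterable[str]
) -> pd.DataFrame:
    """Add the downstream-gene connectivity ratio (e.g. ``"8/529"``) per node."""
    from .graphbuild import count_connected_genes

    observed = sorted(set(observed))
    out = table.copy()
    ratios = []
    for node in out["node"]:
        down, total = count_connected_genes(graph, node, observed)
        ratios.append(f"{down}/{total}")
    out["connectivity"] = ratios
    return out
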
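"""Three-sign discretization, the proportion filter, and threshold search."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from signet.core import Labeling, Sign
from signet.discretize import (
    ExpressionMatrix,
    ThresholdPair,
    default_grid,
    differential_matrix,
    discretize_all,
    discretize_profile,
    sign_proportion_filter,
    threshold_search,
    threshold_report_frame,
)
from signet.synthetic_data import SyntheticSpec, generate_expression, generate_graph


def toy_matrix():
    values = pd.DataFrame(
        {
            "NPC1": [4.8, 7.0, 6.0],
            "NPC2": [5.2, 7.0, 6.0],
            "MC1": [5.2, 7.5, 6.0],
            "MC2": [6.0, 6.4, 6.01],
        },
        index=["g1", "g2", "g3"],
    )
    classes = pd.Series({"NPC1": "NPC", "NPC2": "NPC", "MC1": "MC", "MC2": "MC"})
    return ExpressionMatrix(values, classes)


class TestDifferentialMatrix:
    def test_subtracts_reference_mean(self):
        diff = differential_matrix(toy_matrix())
        assert diff.loc["g1", "MC1"] == pytest.approx(0.2)
        # reference profiles are differenced too
        assert diff.loc["g1", "NPC1"] == pytest.approx(-0.2)

    def test_equal_profiles_give_zero(self):
        values = pd.DataFrame({"NPC1": [3.0, 4.0], "MC1": [3.0, 4.0]}, index=["a", "b"])
        classes = pd.Series({"NPC1": "NPC", "MC1": "MC"})
        diff = differential_matrix(ExpressionMatrix(values, classes))
        assert (diff == 0).all().all()

    def test_matches_independent_centering(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(7, 1, size=(3, 4)),
            index=["g1", "g2", "g3"],
            columns=["NPC1", "NPC2", "MC1", "MC2"],
        )
        classes = pd.Series(
            {"NPC1": "NPC", "NPC2": "NPC", "MC1": "MC", "MC2": "MC"}
        )
        diff = differential_matrix(ExpressionMatrix(values, classes))
        for g in values.index:  # second, elementwise implementation
            ref = (values.loc[g, "NPC1"] + values.loc[g, "NPC2"]) / 2
            for p in values.columns:
                assert diff.loc[g, p] == pytest.approx(values.loc[g, p] - ref)

    def test_no_reference_profiles_rejected(self):
        values = pd.DataFrame({"MC1": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="reference"):
            ExpressionMatrix(values, pd.Series({"MC1": "MC"}))


class TestDiscretizeProfile:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.25, Sign.PLUS),    # above k2: over-expressed
            (-0.25, Sign.MINUS),  # below -k2: under-expressed
            (0.01, Sign.ZERO),    # inside the invariant band
            (0.10, None),         # the [k1, k2] gap yields no observation
            (-0.10, None),
            (0.03, None),         # band edges are exclusive
            (0.2, None),
        ],
    )
    def test_sign_rules(self, p, expected):
        diff = pd.DataFrame({"p1": [p]}, index=["g"])
        lab = discretize_profile(diff, "p1", ThresholdPair(0.03, 0.2))
        if expected is None:
            assert "g" not in lab
        else:
            assert lab["g"] is expected

    def test_monotone_in_p(self):
        t = ThresholdPair(0.05, 0.3)
        rank = {Sign.MINUS: -1, None: 0, Sign.ZERO: 0, Sign.PLUS: 1}
        values = np.linspace(-1, 1, 41)
        calls = []
        for v in values:
            lab = discretize_profile(pd.DataFrame({"p": [v]}, index=["g"]), "p", t)
            calls.append(rank[lab.get("g")])
        assert all(a <= b for a, b in zip(calls, calls[1:]))

    @given(
        k1=st.floats(0, 0.5),
        k2=st.floats(0.5, 2.0),
        p=st.floats(-3, 3, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_regions_partition_the_line(self, k1, k2, p):
        lab = discretize_profile(
            pd.DataFrame({"x": [p]}, index=["g"]), "x", ThresholdPair(k1, k2)
        )
        call = lab.get("g")
        if p > k2:
            assert call is Sign.PLUS
        elif p < -k2:
            assert call is Sign.MINUS
        elif -k1 < p < k1:
            assert call is Sign.ZERO
        else:
            assert call is None

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            discretize_profile(pd.DataFrame({"a": [0.0]}), "b", ThresholdPair(0, 1))


class TestThresholdPair:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ThresholdPair(0.5, 0.2)
        with pytest.raises(ValueError):
            ThresholdPair(-0.1, 0.2)

    def test_default_grid_has_150_pairs_including_selected(self):
        grid = default_grid()
        assert len(grid) == 150
        assert ThresholdPair(0.03, 0.2) in grid


class TestSignProportionFilter:
    def test_majority_variant_discarded(self):
        labs = [Labeling("p", {f"g{i}": "+" for i in range(60)} | {f"h{i}": "0" for i in range(40)})]
        assert sign_proportion_filter(labs) is False

    def test_no_variants_kept(self):
        labs = [Labeling("p", {"a": "0", "b": "0"})]
        assert sign_proportion_filter(labs) is True

    def test_exactly_half_kept(self):
        labs = [Labeling("p", {"a": "+", "b": "0"})]
        assert sign_proportion_filter(labs) is True  # strictly-greater discard

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sign_proportion_filter([Labeling("p", {})])


class TestThresholdSearch:
    def _instance(self, seed=0, noise=0.0):
        spec = SyntheticSpec(
            n_nodes=12, edge_density=0.12, p_observed=0.6, seed=seed,
            n_profiles_per_class=(4, 3), n_variant_genes=4, shift=0.5,
            noise_sd=noise,
        )
        graph = generate_graph(spec)
        expr, truth = generate_expression(graph, spec)
        return graph, expr, truth

    def test_deterministic_under_seed(self):
        graph, expr, _ = self._instance()
        grid = [ThresholdPair(0.03, 0.2), ThresholdPair(0.05, 0.4)]
        a = threshold_search(expr, graph, grid, reps=4, seed=9)
        b = threshold_search(expr, graph, grid, reps=4, seed=9)
        assert threshold_report_frame(a).equals(threshold_report_frame(b))

    def test_all_discarded_warns_and_flags(self):
        graph, expr, _ = self._instance()
        # k1 = k2 = 0: every nonzero differential is variant -> discard
        grid = [ThresholdPair(0.0, 0.0)]
        with pytest.warns(UserWarning, match="discarded"):
            reports = threshold_search(expr, graph, grid, reps=2)
        assert not any(r.kept for r in reports)

    def test_recovers_better_than_random_baseline(self):
        from signet.validation import random_sign_precision

        graph, expr, _ = self._instance(seed=3)
        reports = threshold_search(
            expr, graph, [ThresholdPair(0.03, 0.2)], reps=8, seed=4
        )
        best = reports[0]
        assert best.kept and best.n_reps > 0
        random_level = random_sign_precision(3, 100_000, seed=4)
        assert best.mean_precision >= random_level

    def test_graph_without_genes_rejected(self):
        graph, expr, _ = self._instance()
        from signet.core import SignedGraph

        empty = SignedGraph.from_edges([("A", "B", "+")])
        with pytest.raises(ValueError, match="observable"):
            threshold_search(expr, empty, [ThresholdPair(0.03, 0.2)], reps=1)


class TestRecovery:
    def test_zero_noise_recovery_is_exact(self):
        spec = SyntheticSpec(
            n_nodes=14, edge_density=0.1, p_observed=0.6, seed=1,
            n_profiles_per_class=(5, 3), n_variant_genes=5, shift=0.5, noise_sd=0.0,
        )
        graph = generate_graph(spec)
        expr, truth = generate_expression(graph, spec)
        labelings = discretize_all(differential_matrix(expr), ThresholdPair(0.03, 0.2))
        for pid, lab in labelings.items():
            is_case = expr.classes[pid] == "MC"
            for gene, true_sign in truth.items():
                expected = true_sign if is_case else Sign.ZERO
                assert lab[gene] is expected, (pid, gene)
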
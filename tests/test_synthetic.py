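"""Generators: reproducibility, planted consistency, corruption costs."""

import json

import numpy as np
import pytest

from signet.consistency import is_consistent_coloring, solve
from signet.core import Labeling, Sign, SignedGraph
from signet.synthetic_data import (
    SyntheticSpec,
    corrupt_labeling,
    generate_expression,
    generate_graph,
    plant_consistent_labeling,
    write_bundle,
)


class TestSpec:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(edge_density=1.5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(noise_sd=-0.1)


class TestGenerateGraph:
    def test_reproducible_under_seed(self):
        a = generate_graph(SyntheticSpec(seed=7))
        b = generate_graph(SyntheticSpec(seed=7))
        assert a.edges == b.edges and a.roles == b.roles

    def test_no_inhibition_probability_means_all_activations(self):
        g = generate_graph(SyntheticSpec(p_inhibition=0.0, seed=1))
        assert all(s is Sign.PLUS for _, _, s in g.edges)

    def test_edge_count_within_binomial_bounds(self):
        # n=10 nodes, density for E[edges] = 90 * 1/6 = 15
        counts = [
            generate_graph(SyntheticSpec(n_nodes=10, edge_density=1 / 6, seed=s)).n_edges
            for s in range(100)
        ]
        assert all(5 <= c <= 30 for c in counts)
        assert np.mean(counts) == pytest.approx(15, abs=2)

    def test_dag_mode_is_acyclic(self):
        import networkx as nx

        g = generate_graph(SyntheticSpec(n_nodes=15, edge_density=0.2, dag=True, seed=3))
        assert nx.is_directed_acyclic_graph(g.to_digraph())

    def test_gene_fraction(self):
        g = generate_graph(SyntheticSpec(n_nodes=20, p_observed=0.5, seed=0))
        assert len(g.genes) == 10


class TestPlantConsistentLabeling:
    @pytest.mark.parametrize("seed", range(12))
    def test_planted_coloring_is_consistent(self, seed):
        graph = generate_graph(SyntheticSpec(seed=seed))
        coloring, labeling = plant_consistent_labeling(graph, seed)
        assert is_consistent_coloring(graph, coloring)
        assert labeling.domain == graph.genes
        assert solve(graph, labeling, "mcos").score == 0
        assert solve(graph, labeling, "scenfit").score == 0

    def test_forced_chain_propagation(self):
        g = SignedGraph.from_edges([("A", "B", "+"), ("B", "C", "-")], genes={"C"})
        for seed in range(10):
            coloring, _ = plant_consistent_labeling(g, seed)
            if coloring["A"] is Sign.PLUS:
                assert coloring["B"] is Sign.PLUS and coloring["C"] is Sign.MINUS
            elif coloring["A"] is Sign.MINUS:
                assert coloring["B"] is Sign.MINUS and coloring["C"] is Sign.PLUS
            else:
                assert coloring["B"] is Sign.ZERO and coloring["C"] is Sign.ZERO

    def test_reproducible_under_seed(self):
        graph = generate_graph(SyntheticSpec(seed=4))
        assert plant_consistent_labeling(graph, 9) == plant_consistent_labeling(graph, 9)

    def test_cycles_get_jointly_consistent_signs(self):
        g = SignedGraph.from_edges(
            [("A", "B", "+"), ("B", "C", "+"), ("C", "A", "+")],
            genes={"A", "B", "C"},
            inputs=[],
        )
        for seed in range(5):
            coloring, _ = plant_consistent_labeling(g, seed)
            assert is_consistent_coloring(g, coloring)


def isolated_pairs(k):
    """k disjoint observed edges A_i -(+)-> B_i; every flip is locally forced."""
    edges = [(f"A{i}", f"B{i}", "+") for i in range(k)]
    genes = {n for e in edges for n in e[:2]}
    return SignedGraph.from_edges(edges, genes=genes)


class TestCorruptLabeling:
    def test_zero_corruptions_is_identity(self):
        lab = Labeling("p", {"a": "+", "b": "-"})
        out, switches = corrupt_labeling(lab, 0)
        assert dict(out.items()) == dict(lab.items()) and switches == ()

    def test_flip_on_isolated_leaf_costs_exactly_two(self):
        graph = isolated_pairs(1)
        _, beta = plant_consistent_labeling(graph, 2)
        eligible = [n for n in beta.domain if beta[n].is_variant and n.startswith("B")]
        if eligible:
            corrupted, switches = corrupt_labeling(beta, 1, "flip_variant", seed=0,
                                                   nodes=eligible)
            assert solve(graph, corrupted, "scenfit").score == 2

    def test_to_invariant_on_isolated_leaves_costs_k(self):
        graph = isolated_pairs(3)
        for seed in range(6):
            coloring, beta = plant_consistent_labeling(graph, seed)
            leaves = [f"B{i}" for i in range(3) if beta[f"B{i}"].is_variant]
            if len(leaves) < 3:
                continue
            corrupted, switches = corrupt_labeling(
                beta, 3, "to_invariant", seed=seed, nodes=leaves
            )
            assert len(switches) == 3
            assert solve(graph, corrupted, "scenfit").score == 3

    def test_ground_truth_switches_reported(self):
        lab = Labeling("p", {"a": "+", "b": "-", "c": "0"})
        out, switches = corrupt_labeling(lab, 2, "flip_variant", seed=1)
        assert len(switches) == 2
        for node, old, new in switches:
            assert lab[node] is old and out[node] is new and new is old.opposite

    def test_too_many_corruptions_rejected(self):
        lab = Labeling("p", {"a": "+", "b": "0"})
        with pytest.raises(ValueError, match="eligible"):
            corrupt_labeling(lab, 2)

    def test_scenfit_upper_bound_after_corruption(self):
        """Corrupting k variant signs raises SCENFIT by at most 2k."""
        spec = SyntheticSpec(n_nodes=12, edge_density=0.12, p_observed=0.6, seed=6)
        graph = generate_graph(spec)
        _, beta = plant_consistent_labeling(graph, 6)
        n_variant = sum(1 for _, s in beta.items() if s.is_variant)
        for k in range(min(3, n_variant) + 1):
            corrupted, _ = corrupt_labeling(beta, k, "flip_variant", seed=k)
            assert solve(graph, corrupted, "scenfit").score <= 2 * k


class TestGenerateExpression:
    def test_zero_noise_exact_shifts(self):
        spec = SyntheticSpec(seed=2, noise_sd=0.0, shift=0.5)
        graph = generate_graph(spec)
        expr, truth = generate_expression(graph, spec)
        ref = expr.values[expr.reference_profiles].mean(axis=1)
        for pid in expr.profiles:
            for gene in expr.genes:
                delta = expr.values.loc[gene, pid] - ref[gene]
                if expr.classes[pid] == "MC" and truth[gene] is Sign.PLUS:
                    assert delta == pytest.approx(0.5)
                elif expr.classes[pid] == "MC" and truth[gene] is Sign.MINUS:
                    assert delta == pytest.approx(-0.5)
                else:
                    assert delta == pytest.approx(0.0)

    def test_zero_shift_means_no_variants_detectable(self):
        spec = SyntheticSpec(seed=2, noise_sd=0.0, shift=0.0)
        graph = generate_graph(spec)
        expr, _ = generate_expression(graph, spec)
        ref = expr.values[expr.reference_profiles].mean(axis=1)
        assert np.allclose(expr.values.sub(ref, axis=0).to_numpy(), 0.0)

    def test_reproducible_and_class_sizes(self):
        spec = SyntheticSpec(seed=8, n_profiles_per_class=(6, 4))
        graph = generate_graph(spec)
        a, truth_a = generate_expression(graph, spec)
        b, truth_b = generate_expression(graph, spec)
        assert a.values.equals(b.values) and truth_a == truth_b
        assert (a.classes == "MC").sum() == 6 and (a.classes == "NPC").sum() == 4

    def test_too_many_variant_genes_rejected(self):
        spec = SyntheticSpec(seed=0, n_variant_genes=100)
        graph = generate_graph(spec)
        with pytest.raises(ValueError, match="exceeds"):
            generate_expression(graph, spec)


class TestWriteBundle:
    def test_bundle_files_exist_and_reload(self, tmp_path):
        from signet.core import read_graph, read_labeling_dir

        spec = SyntheticSpec(seed=3)
        paths = write_bundle(tmp_path / "bundle", spec)
        graph = read_graph(paths["graph"], paths["roles"], paths["inputs"])
        labelings = read_labeling_dir(paths["observations"])
        truth = json.loads((tmp_path / "bundle" / "ground_truth.json").read_text())
        assert graph.n_nodes == spec.n_nodes
        assert "planted" in labelings
        assert set(truth["planted_coloring"]) == graph.nodes
        # planted observations reload to a consistent instance
        assert solve(graph, labelings["planted"], "mcos").score == 0
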
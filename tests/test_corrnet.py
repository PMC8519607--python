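"""Correlation, mutual rank, decay weighting and network construction."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from teanet import (
    build_network,
    components,
    corr_pvalue,
    count_pairs_above,
    decay_weight,
    gene_metabolite_network,
    hubs,
    mr_ceiling,
    mutual_rank,
    pairwise_pcc,
)
from teanet.corrnet import CoNetwork
from teanet.errors import DomainError, InsufficientDataError, ParameterError, StructuralError

# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_mutual_rank(r_of: dict, nodes: list, mode: str) -> dict:
    """Counting-based ranks: rank = 1 + #better + #ties/2, no library rank call."""
    def rank(a, b):
        rab = r_of[frozenset((a, b))]
        better = sum(
            1 for c in nodes if c not in (a, b) and r_of[frozenset((a, c))] > rab
        )
        ties = sum(
            1 for c in nodes if c not in (a, b) and r_of[frozenset((a, c))] == rab
        )
        return 1.0 + better + ties / 2.0

    out = {}
    for a, b in itertools.combinations(nodes, 2):
        prod = rank(a, b) * rank(b, a)
        out[frozenset((a, b))] = np.sqrt(prod) if mode == "geometric_mean" else prod
    return out


def _corr_frame(r_of: dict) -> pd.DataFrame:
    rows = [
        {"node_a": min(pair), "node_b": max(pair), "r": r}
        for pair, r in ((tuple(sorted(k)), v) for k, v in r_of.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------

class TestPairwisePCC:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        out = pairwise_pcc(df, log_transform=False)
        r = out.set_index(["node_a", "node_b"])["r"]
        assert r[("a", "b")] == pytest.approx(1.0)
        assert r[("a", "c")] == pytest.approx(-1.0)

    def test_fixed_example_against_arbitrary_precision_value(self):
        # exact-fraction computation: r = 5.5 / sqrt(5 * 8.75)
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 5]}, dtype=float)
        out = pairwise_pcc(df, log_transform=False)
        assert out["r"].iloc[0] == pytest.approx(0.8315218406202999, abs=1e-12)

    def test_pairwise_complete_observations(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        df.loc[:5, "b"] = np.nan
        out = pairwise_pcc(df, log_transform=False).set_index(["node_a", "node_b"])
        assert out.loc[("a", "b"), "n_used"] == 24
        assert out.loc[("a", "c"), "n_used"] == 30
        sub = df.dropna()
        assert out.loc[("a", "b"), "r"] == pytest.approx(
            np.corrcoef(sub["a"], sub["b"])[0, 1]
        )

    def test_untestable_pairs_excluded_from_bh(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 3)), columns=list("abc"))
        df.loc[3:, "c"] = np.nan  # only 3 complete obs against c
        out = pairwise_pcc(df, log_transform=False).set_index(["node_a", "node_b"])
        assert not out.loc[("a", "c"), "testable"]
        assert np.isnan(out.loc[("a", "c"), "q"])
        assert out.loc[("a", "b"), "testable"]

    def test_zero_variance_column_excluded_with_warning(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 2)), columns=["a", "b"])
        df["const"] = 3.0
        with pytest.warns(UserWarning, match="const"):
            out = pairwise_pcc(df, log_transform=False)
        assert set(out["node_a"]) | set(out["node_b"]) == {"a", "b"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            pairwise_pcc(df, log_transform=False),
            pairwise_pcc(shuffled, log_transform=False),
            rtol=1e-12,
        )


class TestCorrPvalue:
    def test_null_r_gives_unit_p(self):
        assert corr_pvalue(0.0, 20) == pytest.approx(1.0)

    def test_perfect_r_gives_zero_p(self):
        assert corr_pvalue(1.0, 10) == 0.0
        assert corr_pvalue(-1.0, 10) == 0.0

    def test_against_independent_t_cdf_oracle(self):
        # frozen from R: 2 * pt(-abs(0.8 * sqrt(66 / 0.36)), df = 66)
        assert corr_pvalue(0.8, 68) == pytest.approx(2.766255356415938e-16, abs=1e-26)

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            corr_pvalue(0.5, 3)


# ---------------------------------------------------------------------------
# mutual rank + decay
# ---------------------------------------------------------------------------

class TestMutualRank:
    def test_reciprocal_best_pair_has_unit_mr(self):
        r_of = {
            frozenset(("A", "B")): 0.9,
            frozenset(("A", "C")): 0.5,
            frozenset(("B", "C")): 0.7,
        }
        out = mutual_rank(_corr_frame(r_of)).set_index(["node_a", "node_b"])
        assert out.loc[("A", "B"), "mr"] == pytest.approx(1.0)
        assert out.loc[("A", "B"), "weight"] == pytest.approx(1.0)

    def test_three_node_hand_example(self):
        # ranks: A: B=1, C=2; B: A=1, C=2; C: B=1, A=2
        # -> MR(A,B)=1, MR(B,C)=sqrt(2), MR(A,C)=2 in geometric-mean mode
        r_of = {
            frozenset(("A", "B")): 0.9,
            frozenset(("A", "C")): 0.5,
            frozenset(("B", "C")): 0.7,
        }
        out = mutual_rank(_corr_frame(r_of)).set_index(["node_a", "node_b"])
        assert out.loc[("A", "B"), "mr"] == pytest.approx(1.0)
        assert out.loc[("B", "C"), "mr"] == pytest.approx(np.sqrt(2.0))
        assert out.loc[("A", "C"), "mr"] == pytest.approx(2.0)
        prod = mutual_rank(_corr_frame(r_of), mode="product").set_index(["node_a", "node_b"])
        assert prod.loc[("B", "C"), "mr"] == pytest.approx(2.0)
        assert prod.loc[("A", "C"), "mr"] == pytest.approx(4.0)

    @pytest.mark.parametrize("mode", ["geometric_mean", "product"])
    def test_matches_brute_force_enumeration(self, mode):
        rng = np.random.default_rng(7)
        for trial in range(200):
            k = int(rng.integers(3, 9))
            nodes = [f"N{i}" for i in range(k)]
            # draw from a coarse grid so ties actually occur
            r_of = {
                frozenset(p): float(rng.choice(np.round(np.linspace(-1, 1, 21), 2)))
                for p in itertools.combinations(nodes, 2)
            }
            got = mutual_rank(_corr_frame(r_of), mode=mode)
            expected = brute_force_mutual_rank(r_of, nodes, mode)
            for row in got.itertuples(index=False):
                assert row.mr == pytest.approx(
                    expected[frozenset((row.node_a, row.node_b))], abs=1e-12
                )

    def test_symmetry_and_weight_range(self):
        rng = np.random.default_rng(8)
        nodes = [f"N{i}" for i in range(8)]
        r_of = {frozenset(p): float(rng.uniform(-1, 1)) for p in itertools.combinations(nodes, 2)}
        out = mutual_rank(_corr_frame(r_of))
        assert (out["mr"] >= 1.0 - 1e-12).all()
        assert ((out["weight"] > 0) & (out["weight"] <= 1.0)).all()
        assert ((out["weight"] == 1.0) == (out["mr"] == 1.0)).all()

    def test_incomplete_pair_set_rejected(self):
        frame = _corr_frame({frozenset(("A", "B")): 0.5, frozenset(("B", "C")): 0.4})
        with pytest.raises(StructuralError):
            mutual_rank(frame)


class TestDecayWeight:
    def test_unit_mr_gives_unit_weight(self):
        assert decay_weight(1.0) == pytest.approx(1.0)

    def test_mr_101_gives_inverse_e(self):
        assert decay_weight(101.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_exact_form_on_grid(self):
        mr = np.linspace(1, 1000, 2000)
        assert np.max(np.abs(decay_weight(mr) - np.exp(-(mr - 1) / 100.0))) < 1e-12

    def test_floor_inversion(self):
        # w >= 0.01 exactly when MR <= 1 + 100 ln(100) ~ 461.517
        ceiling = mr_ceiling(0.01)
        assert ceiling == pytest.approx(461.51701859880916, abs=1e-9)
        assert decay_weight(ceiling) == pytest.approx(0.01, abs=1e-12)
        assert decay_weight(ceiling + 1e-6) < 0.01 < decay_weight(ceiling - 1e-6)

    def test_domain_error_below_one(self):
        with pytest.raises(DomainError):
            decay_weight(0.5)


# ---------------------------------------------------------------------------
# network construction and queries
# ---------------------------------------------------------------------------

def _corr_with_stats(r_of: dict, n: int = 68) -> pd.DataFrame:
    frame = _corr_frame(r_of)
    frame["n_used"] = n
    frame["p"] = corr_pvalue(frame["r"].to_numpy(), n)
    from teanet.differential import bh_adjust

    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame["testable"] = True
    return frame


class TestBuildNetwork:
    def test_all_pairs_below_gate_give_empty_network(self):
        r_of = {frozenset(p): 0.3 for p in itertools.combinations("ABC", 2)}
        corr = _corr_with_stats(r_of)
        net = build_network(corr, mutual_rank(corr))
        assert net.n_edges == 0 and net.n_nodes == 3

    def test_single_passing_edge_kept(self):
        r_of = {
            frozenset(("A", "B")): 0.9,
            frozenset(("A", "C")): 0.5,
            frozenset(("B", "C")): 0.6,
        }
        corr = _corr_with_stats(r_of)
        net = build_network(corr, mutual_rank(corr), pcc_gate=0.8)
        assert net.n_edges == 1 and net.graph.has_edge("A", "B")

    def test_raising_gate_never_adds_edges(self):
        rng = np.random.default_rng(11)
        r_of = {
            frozenset(p): float(rng.uniform(0, 1))
            for p in itertools.combinations([f"N{i}" for i in range(8)], 2)
        }
        corr = _corr_with_stats(r_of)
        edges = mutual_rank(corr)
        prev = None
        for gate in (0.2, 0.4, 0.6, 0.8, 0.95):
            n = build_network(corr, edges, pcc_gate=gate).n_edges
            if prev is not None:
                assert n <= prev
            prev = n

    def test_negative_correlations_gated_on_absolute_value(self):
        r_of = {
            frozenset(("A", "B")): -0.95,
            frozenset(("A", "C")): 0.1,
            frozenset(("B", "C")): 0.2,
        }
        corr = _corr_with_stats(r_of)
        net = build_network(corr, mutual_rank(corr), pcc_gate=0.8)
        assert net.graph.has_edge("A", "B")


class TestQueries:
    def test_star_center_is_top_hub(self):
        g = nx.star_graph(5)
        net = CoNetwork(nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes}))
        top = hubs(net, top_k=1)
        assert top == [("N0", 5)]

    def test_empty_network_has_no_hubs(self):
        assert hubs(CoNetwork(nx.Graph())) == []

    def test_hub_degrees_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for trial in range(100):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            ranked = hubs(CoNetwork(g))
            for node, deg in ranked:
                assert deg == sum(1 for _ in g.neighbors(node))
            degs = [d for _, d in ranked]
            assert degs == sorted(degs, reverse=True)

    def test_two_disjoint_edges_give_two_components(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        comps = components(CoNetwork(g))
        assert sorted(map(len, comps)) == [2, 2]

    def test_component_sizes_partition_nodes(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        g.add_node("E")  # isolated
        comps = components(CoNetwork(g))
        assert sum(map(len, comps)) == 5

    def test_count_pairs_above(self):
        corr = pd.DataFrame(
            {"node_a": ["A", "A", "B"], "node_b": ["B", "C", "C"], "r": [0.85, 0.92, -0.81]}
        )
        assert count_pairs_above(corr, 0.8, use_abs=True) == 3
        assert count_pairs_above(corr, 0.9, use_abs=True) == 1
        assert count_pairs_above(corr, 0.8, use_abs=False) == 2
        assert count_pairs_above(corr, 1.0, use_abs=True) == 0

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(13)
        corr = pd.DataFrame(
            {"node_a": "A", "node_b": [f"B{i}" for i in range(50)], "r": rng.uniform(-1, 1, 50)}
        )
        counts = [count_pairs_above(corr, t) for t in np.linspace(0, 1, 11)]
        assert counts == sorted(counts, reverse=True)


class TestGeneMetaboliteNetwork:
    def test_empty_gene_list_reduces_to_metabolite_network(self, cohort):
        metab, expr, _ = cohort
        gm = gene_metabolite_network(expr, metab, [], pcc_gate=0.8)
        corr = pairwise_pcc(metab.biological())
        met = build_network(corr, mutual_rank(corr), pcc_gate=0.8)
        assert gm.edge_table().equals(met.edge_table())

    def test_deterministic(self, cohort):
        metab, expr, _ = cohort
        genes = expr.gene_ids[:10]
        e1 = gene_metabolite_network(expr, metab, genes).edge_table()
        e2 = gene_metabolite_network(expr, metab, genes).edge_table()
        assert e1.equals(e2)

    def test_unknown_gene_rejected(self, cohort):
        metab, expr, _ = cohort
        with pytest.raises(KeyError):
            gene_metabolite_network(expr, metab, ["NOPE"])

    def test_disjoint_samples_rejected(self, cohort):
        metab, expr, _ = cohort
        renamed = expr.values.copy()
        renamed.index = [f"X{i}" for i in range(len(renamed))]
        from teanet import ExpressionMatrix
        from teanet.errors import AlignmentError

        with pytest.raises(AlignmentError):
            gene_metabolite_network(ExpressionMatrix(renamed), metab, [])
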
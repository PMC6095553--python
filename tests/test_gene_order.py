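"""Gene-order extraction and DCJ distance, checked against a BFS oracle."""

import numpy as np
import pytest

from helpers import (
    all_signed_circular_orders,
    bfs_distances_from,
    matching_of,
    random_signed_order,
)

from mitocomp.gene_order import (
    GeneOrder,
    dcj_distance,
    extract_gene_order,
    invert_segment,
    parse_gene_order,
    pairwise_matrix,
    read_gene_orders,
    write_gene_orders,
)
from mitocomp.seqio import Annotation, Feature
from mitocomp.synthetic import evolve_by_inversions, random_gene_order


def _order(spec: str, gid: str = "x") -> GeneOrder:
    return parse_gene_order(f"{gid}: {spec} )")


class TestExtractGeneOrder:
    def _ann(self, feats):
        return Annotation("g", 10_000, feats)

    def test_sorted_by_start_with_strand_signs(self):
        ann = self._ann(
            [
                Feature("a", "gene", 100, 200, "+"),
                Feature("c", "gene", 900, 950, "+"),
                Feature("b", "gene", 500, 700, "-"),
            ]
        )
        assert extract_gene_order(ann).genes == (("a", 1), ("b", -1), ("c", 1))

    def test_duplicate_drop_all_policy(self):
        ann = self._ann(
            [
                Feature("a", "gene", 0, 100, "+"),
                Feature("dup", "gene", 200, 300, "+"),
                Feature("dup", "gene", 400, 500, "+"),
                Feature("b", "gene", 600, 700, "+"),
            ]
        )
        with pytest.warns(UserWarning, match="dup"):
            order = extract_gene_order(ann)
        assert "dup" not in order.symbols

    def test_trans_spliced_collapsed_to_first_fragment(self):
        ann = self._ann(
            [
                Feature("nad5", "gene", 100, 300, "+"),
                Feature("a", "gene", 500, 600, "+"),
                Feature("nad5", "gene", 800, 900, "-"),
            ]
        )
        order = extract_gene_order(ann, trans_spliced={"nad5"})
        assert order.genes == (("nad5", 1), ("a", 1))


class TestDCJDistance:
    def test_identity_up_to_rotation_and_reflection(self):
        a = _order("+g0 +g1 +g2 +g3 +g4")
        rot = GeneOrder("r", a.genes[3:] + a.genes[:3])
        refl = GeneOrder("f", tuple((g, -s) for g, s in reversed(a.genes)))
        assert dcj_distance(a, rot) == 0
        assert dcj_distance(a, refl) == 0

    def test_single_inversion_is_one_operation(self):
        a = _order("+1 +2 +3 +4")
        b = _order("+1 -3 -2 +4")
        assert dcj_distance(a, b) == 1

    def test_restricted_to_shared_genes(self):
        a = _order("+a +b +c +x")
        b = _order("+a +b +c +y")
        assert dcj_distance(a, b) == 0

    def test_empty_shared_set_rejected(self):
        with pytest.raises(ValueError, match="no shared genes"):
            dcj_distance(_order("+a +b"), _order("+c +d"))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_bfs_oracle_exhaustive_small(self, n):
        """Adjacency-cycle formula equals BFS minimal DCJ count for every
        signed circular order."""
        gene_index = {f"g{i}": i for i in range(n)}
        identity = GeneOrder("id", tuple((f"g{i}", 1) for i in range(n)))
        dist = bfs_distances_from(matching_of(identity, gene_index))
        for order in all_signed_circular_orders(n):
            assert dcj_distance(identity, order) == dist[matching_of(order, gene_index)]

    def test_metric_axioms_on_random_orders(self):
        rng = np.random.default_rng(77)
        orders = [random_signed_order(8, rng, f"o{i}") for i in range(6)]
        for a in orders:
            assert dcj_distance(a, a) == 0
            for b in orders:
                d_ab = dcj_distance(a, b)
                assert d_ab == dcj_distance(b, a)
                for c in orders:
                    assert d_ab <= dcj_distance(a, c) + dcj_distance(c, b)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_planted_inversions_recovered_exactly(self, k):
        anc = random_gene_order(30, seed=11)
        der, segments = evolve_by_inversions(anc, k, seed=50 + k)
        assert len(segments) == k
        assert dcj_distance(anc, der) == k


class TestPairwiseMatrix:
    def test_identical_orders_zero_matrix(self):
        orders = [
            GeneOrder(f"g{i}", (("a", 1), ("b", 1), ("c", 1))) for i in range(3)
        ]
        assert (pairwise_matrix(orders).values == 0).all()

    def test_chain_of_inversions_triangle(self):
        a = _order("+1 +2 +3 +4 +5 +6", "a")
        b = invert_segment(a, 1, 3)
        c = invert_segment(b, 3, 5)
        mat = pairwise_matrix([GeneOrder("a", a.genes), GeneOrder("b", b.genes), GeneOrder("c", c.genes)])
        assert mat.loc["a", "c"] <= 2
        assert mat.loc["a", "c"] <= mat.loc["a", "b"] + mat.loc["b", "c"]
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()

    def test_common_ancestor_bound(self):
        anc = random_gene_order(20, seed=3)
        d1, _ = evolve_by_inversions(anc, 3, seed=4, derived_id="d1")
        d2, _ = evolve_by_inversions(anc, 3, seed=5, derived_id="d2")
        assert dcj_distance(d1, d2) <= 6


class TestTextFormat:
    def test_roundtrip(self, tmp_path):
        orders = [
            _order("+a -b +c", "one"),
            GeneOrder("two", (("a", -1), ("c", 1), ("b", 1)), "linear"),
        ]
        p = tmp_path / "orders.txt"
        write_gene_orders(orders, p)
        back = read_gene_orders(p)
        assert back == orders

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_gene_order("no-colon-here")
        with pytest.raises(ValueError, match="duplicate"):
            parse_gene_order("x: +a +a )")
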
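"""Multinetwork algebra: alignment re-keying, log normalization, sums,
trimming, degree differences and the random-half control."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from altrin import (
    AlignedRIN,
    ResidueRIN,
    StructureMetadata,
    SumNetwork,
    align_rin,
    build_multinetwork,
    delta_degree,
    log_normalize,
    random_half_control,
    resolution_balance_test,
    sum_network,
    trim_top_fraction,
    weighted_degree,
)
from altrin.msa_map import AlignmentMap

from conftest import in_subset


def make_rin(structure_id, edges):
    rin = ResidueRIN(structure_id=structure_id)
    for (a, b), w in edges.items():
        rin.add_edge(("A", str(a)), ("A", str(b)), w, "spatial")
    return rin


def make_map(structure_id, residue_to_column, column_to_reference=None):
    return AlignmentMap(
        structure_id=structure_id,
        residue_to_column={str(k): v for k, v in residue_to_column.items()},
        column_to_reference=column_to_reference or {},
    )


def aligned(structure_id, edges):
    return AlignedRIN(structure_id=structure_id,
                      edges={k: float(v) for k, v in edges.items()})


def make_mn(rins, meta=None, column_to_reference=None):
    meta = meta or [StructureMetadata(structure_id=r.structure_id)
                    for r in rins]
    return build_multinetwork(rins, meta, reference_id="ref",
                              column_to_reference=column_to_reference)


class TestAlignRIN:
    def test_identity_map_renames_only(self):
        rin = make_rin("s", {(1, 2): 0.5, (2, 4): 1.0})
        amap = make_map("s", {1: 0, 2: 1, 4: 3})
        out = align_rin(rin, amap)
        assert out.edges == {(0, 1): 0.5, (1, 3): 1.0}
        assert out.dropped_edges == 0

    def test_unmapped_endpoint_drops_edge_and_counts(self):
        rin = make_rin("s", {(1, 2): 0.5, (2, 9): 1.0})
        amap = make_map("s", {1: 0, 2: 1})
        out = align_rin(rin, amap)
        assert out.edges == {(0, 1): 0.5}
        assert out.dropped_edges == 1

    def test_empty_rin(self):
        out = align_rin(make_rin("s", {}), make_map("s", {1: 0}))
        assert out.edges == {}

    def test_structure_id_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            align_rin(make_rin("s1", {}), make_map("s2", {}))


class TestLogNormalize:
    def test_empty_network_unchanged(self):
        out = log_normalize(aligned("s", {}))
        assert out.edges == {}
        assert out.scale == 1.0

    def test_total_at_most_one_unchanged(self):
        out = log_normalize(aligned("s", {(0, 1): 1.0}))
        assert out.edges[(0, 1)] == 1.0

    def test_two_edges_scaled_to_log_total(self):
        w = math.e - 1
        out = log_normalize(aligned("s", {(0, 1): w, (2, 3): w}))
        expected_total = math.log(2 * math.e - 1)
        assert out.total_weight == pytest.approx(expected_total, abs=1e-12)
        assert out.edges[(0, 1)] == pytest.approx(expected_total / 2)
        assert out.raw_total == pytest.approx(2 * math.e - 2)

    @pytest.mark.parametrize("total", [1.5, 7.0, 123.4])
    def test_normalized_total_is_log1p_of_raw(self, total):
        rng = np.random.default_rng(int(total * 10))
        raw = rng.dirichlet(np.ones(6)) * total
        edges = {(i, i + 1): float(w) for i, w in enumerate(raw)}
        out = log_normalize(aligned("s", edges))
        assert out.total_weight == pytest.approx(math.log1p(total), abs=1e-9)


class TestBuildMultinetwork:
    def test_metadata_join_and_stub(self):
        rins = [aligned("a", {}), aligned("b", {})]
        mn = make_mn(rins, meta=[StructureMetadata(structure_id="a",
                                                   wpd_state="open")])
        assert mn.metadata["a"].wpd_state == "open"
        assert mn.metadata["b"].wpd_state == "unknown"

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_mn([aligned("a", {}), aligned("a", {})])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            make_mn([])


class TestSumNetwork:
    def test_single_structure_identity(self):
        rin = aligned("a", {(0, 1): 0.7})
        net = sum_network(make_mn([rin]))
        assert net.edges == rin.edges

    def test_two_identical_with_averaging(self):
        rins = [aligned("a", {(0, 1): 0.7}), aligned("b", {(0, 1): 0.7})]
        net = sum_network(make_mn(rins), per_structure_average=True)
        assert net.edges[(0, 1)] == pytest.approx(0.7)

    def test_disjoint_edges_both_present(self):
        rins = [aligned("a", {(0, 1): 0.3}), aligned("b", {(5, 9): 0.4})]
        net = sum_network(make_mn(rins))
        assert net.edges == {(0, 1): 0.3, (5, 9): 0.4}

    def test_empty_subset_rejected(self):
        mn = make_mn([aligned("a", {})])
        with pytest.raises(ValueError, match="selects no structures"):
            sum_network(mn, lambda m: False, label="nothing")

    def test_additivity_over_disjoint_subsets(self):
        rng = np.random.default_rng(11)
        rins = []
        for i in range(8):
            edges = {
                (int(a), int(b)): float(rng.uniform(0.1, 2))
                for a, b in rng.integers(0, 20, (5, 2)) if a < b
            }
            rins.append(aligned(f"s{i}", edges))
        meta = [StructureMetadata(structure_id=f"s{i}",
                                  tags={"g": "A" if i < 3 else "B"})
                for i in range(8)]
        mn = make_mn(rins, meta=meta)
        total = sum_network(mn)
        part_a = sum_network(mn, lambda m: m.tags["g"] == "A")
        part_b = sum_network(mn, lambda m: m.tags["g"] == "B")
        for key in total.edges:
            assert total.edges[key] == pytest.approx(
                part_a.edges.get(key, 0) + part_b.edges.get(key, 0),
                abs=1e-12,
            )


class TestTrim:
    def test_keep_all_is_identity(self):
        net = SumNetwork(edges={(0, 1): 1.0, (1, 2): 2.0}, n_contributing=1)
        assert trim_top_fraction(net, 1.0).edges == net.edges

    def test_keeps_five_largest_of_hundred(self):
        edges = {(i, i + 1): float(i + 1) for i in range(100)}
        net = SumNetwork(edges=edges, n_contributing=1)
        out = trim_top_fraction(net, 0.05)
        assert len(out.edges) == 5
        assert sorted(out.edges.values()) == [96.0, 97.0, 98.0, 99.0, 100.0]

    def test_ties_at_threshold_all_retained(self):
        edges = {(i, i + 1): 1.0 for i in range(10)}
        net = SumNetwork(edges=edges, n_contributing=1)
        assert len(trim_top_fraction(net, 0.05).edges) == 10

    def test_idempotent_at_same_fraction(self):
        rng = np.random.default_rng(4)
        edges = {(i, i + 1): float(rng.uniform(0, 5)) for i in range(40)}
        net = SumNetwork(edges=edges, n_contributing=1)
        once = trim_top_fraction(net, 0.25)
        twice = trim_top_fraction(once, 0.25)
        assert once.edges == twice.edges

    def test_isolated_nodes_dropped(self):
        net = SumNetwork(edges={(0, 1): 5.0, (7, 9): 0.1}, n_contributing=1)
        out = trim_top_fraction(net, 0.5)
        assert out.nodes == {0, 1}


class TestWeightedDegree:
    def test_triangle(self):
        net = SumNetwork(edges={(0, 1): 1.0, (1, 2): 2.0, (0, 2): 3.0},
                         n_contributing=1)
        assert weighted_degree(net) == {0: 4.0, 1: 3.0, 2: 5.0}

    def test_empty(self):
        assert weighted_degree(SumNetwork(edges={}, n_contributing=1)) == {}

    def test_star(self):
        net = SumNetwork(edges={(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0},
                         n_contributing=1)
        deg = weighted_degree(net)
        assert deg[0] == 3.0 and deg[1] == deg[2] == deg[3] == 1.0


class TestDeltaDegree:
    def _mn(self):
        rins = [
            aligned("a1", {(0, 1): 1.0, (1, 2): 0.5}),
            aligned("a2", {(0, 1): 0.8}),
            aligned("b1", {(0, 1): 0.2, (3, 4): 0.9}),
        ]
        meta = [StructureMetadata(structure_id=s, tags={"g": s[0].upper()})
                for s in ("a1", "a2", "b1")]
        return make_mn(rins, meta=meta,
                       column_to_reference={0: 10, 1: 11, 2: 12, 3: 13, 4: 14})

    def test_identical_subsets_zero(self):
        mn = self._mn()
        prof = delta_degree(mn, lambda m: True, lambda m: True)
        assert all(v == 0.0 for v in prof.by_reference.values())

    def test_antisymmetry_exact(self):
        mn = self._mn()
        ab = delta_degree(mn, in_subset_g("A"), in_subset_g("B"))
        ba = delta_degree(mn, in_subset_g("B"), in_subset_g("A"))
        assert ab.by_reference.keys() == ba.by_reference.keys()
        for k in ab.by_reference:
            assert ab.by_reference[k] == -ba.by_reference[k]

    def test_single_structure_vs_empty_network_structure(self):
        rins = [aligned("a", {(0, 1): 0.6}), aligned("b", {})]
        mn = make_mn(rins, column_to_reference={0: 1, 1: 2})
        prof = delta_degree(mn, lambda m: m.structure_id == "a",
                            lambda m: m.structure_id == "b")
        assert prof.by_reference == {1: 0.6, 2: 0.6}

    def test_unreferenced_columns_reported_separately(self):
        mn = self._mn()
        rins = mn.rins + [aligned("c", {(7, 8): 1.0})]
        mn2 = make_mn(rins, meta=list(mn.metadata.values())
                      + [StructureMetadata(structure_id="c",
                                           tags={"g": "A"})],
                      column_to_reference=mn.column_to_reference)
        prof = delta_degree(mn2, in_subset_g("A"), in_subset_g("B"))
        assert set(prof.unreferenced) == {7, 8}


def in_subset_g(label):
    return lambda m: m.tags.get("g") == label


class TestRandomHalfControl:
    def test_identical_members_exactly_zero(self):
        rins = [aligned(f"s{i}", {(0, 1): 0.5, (2, 3): 0.25})
                for i in range(6)]
        mn = make_mn(rins, column_to_reference={0: 1, 1: 2, 2: 3, 3: 4})
        prof = random_half_control(mn, n_samples=70, seed=123)
        assert all(v == 0.0 for v in prof.by_reference.values())

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        rins = [
            aligned(f"s{i}", {(0, 1): float(rng.uniform(0.1, 1))})
            for i in range(7)
        ]
        mn = make_mn(rins, column_to_reference={0: 1, 1: 2})
        p1 = random_half_control(mn, n_samples=70, seed=42)
        p2 = random_half_control(mn, n_samples=70, seed=42)
        assert p1.by_reference == p2.by_reference

    def test_mean_magnitude_shrinks_with_samples(self):
        """Monte-Carlo convergence: the averaged control profile tightens
        around zero as the number of sampled halves grows."""
        rng = np.random.default_rng(17)
        rins = [
            aligned(f"s{i}", {(0, 1): float(rng.uniform(0.1, 1.0)),
                              (1, 2): float(rng.uniform(0.1, 1.0))})
            for i in range(20)
        ]
        mn = make_mn(rins, column_to_reference={0: 1, 1: 2, 2: 3})

        def mean_abs(n_samples, seed):
            prof = random_half_control(mn, n_samples=n_samples, seed=seed)
            return np.mean([abs(v) for v in prof.by_reference.values()])

        few = np.mean([mean_abs(5, s) for s in range(8)])
        many = np.mean([mean_abs(200, s) for s in range(8)])
        assert many < few / 2


edge_weights = st.lists(
    st.floats(min_value=1e-6, max_value=50.0, allow_nan=False),
    min_size=1, max_size=12,
)


class TestAlgebraProperties:
    @given(weights=edge_weights)
    @settings(max_examples=60, deadline=None)
    def test_log_normalize_total_and_order_invariance(self, weights):
        edges = {(i, i + 1): w for i, w in enumerate(weights)}
        out = log_normalize(aligned("s", edges))
        t = sum(weights)
        expected = math.log1p(t) if t > 1 else t
        assert out.total_weight == pytest.approx(expected, rel=1e-9)
        reversed_edges = dict(reversed(list(edges.items())))
        out2 = log_normalize(aligned("s", reversed_edges))
        for k in edges:
            assert out.edges[k] == pytest.approx(out2.edges[k], rel=1e-12)

    @given(weights=edge_weights,
           fraction=st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=60, deadline=None)
    def test_trim_idempotent_and_never_below_nominal_count(self, weights,
                                                           fraction):
        edges = {(i, i + 1): w for i, w in enumerate(weights)}
        net = SumNetwork(edges=edges, n_contributing=1)
        once = trim_top_fraction(net, fraction)
        assert len(once.edges) >= math.ceil(fraction * len(edges))
        assert trim_top_fraction(once, fraction).edges == once.edges
        threshold = min(once.edges.values())
        assert all(w < threshold
                   for k, w in edges.items() if k not in once.edges)


class TestResolutionBalance:
    def test_identical_distributions_near_half(self):
        a = [1.0, 1.3, 1.7, 1.9]
        _, p = resolution_balance_test(a, list(a))
        assert 0.3 < p < 0.7

    def test_extreme_separation_exact_combinatorial_p(self):
        a = [1.0, 1.1, 1.2]
        b = [2.0, 2.1]
        u, p = resolution_balance_test(a, b, alternative="less")
        assert u == 0.0
        assert p == pytest.approx(1 / comb(5, 3), abs=1e-12)

    def test_exact_enumeration_small_n(self):
        """p-value matches exact enumeration of the U distribution."""
        a = [1.1, 1.5, 2.0]
        b = [1.3, 1.8]
        u_obs, p = resolution_balance_test(a, b, alternative="less")
        pooled = a + b
        n_a = len(a)
        us = []
        for idx in combinations(range(len(pooled)), n_a):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
            us.append(sum(x < y for x in xs for y in ys)
                      + 0.5 * sum(x == y for x in xs for y in ys))
        # scipy's U counts pairs where a > b for 'less' orientation
        u_stat = sum(x > y for x in a for y in b)
        assert u_obs == u_stat
        u_all = [len(a) * len(b) - u for u in us]
        expected_p = np.mean([u <= u_stat for u in u_all])
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolution_balance_test([], [1.0])
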
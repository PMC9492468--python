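"""Crosstalk detector tests: hypergeometric oracle, degree preservation,
consensus truth table, and planted/null simulations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clonescape.crosstalk import (
    build_profiles,
    consensus,
    detect_crosstalk_hyper,
    detect_deg_match,
    detect_joint_expression,
    hypergeom_upper_tail,
    randomize_lr_network,
    EVENT_KEY,
)
from clonescape.io import LigandReceptorDB, LRPair
from clonescape.qc import find_markers
from clonescape.simulate import SimulationConfig, simulate_counts


def hypergeom_oracle_comb(k, N, K, n):
    """Combinatorial-sum oracle: P(X >= k) via math.comb, no scipy."""
    if k <= 0:
        return 1.0
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def hypergeom_oracle_enumerate(k, N, K, n):
    """Exhaustive enumeration of every n-subset of the N-universe."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return hits / math.comb(N, n)


class TestHypergeom:
    def test_spec_worked_example(self):
        # N=10, K=4, n=4, k=4 -> 1 / C(10,4) = 1/210
        assert hypergeom_upper_tail(4, 10, 4, 4) == pytest.approx(1 / 210, abs=1e-12)
        assert hypergeom_oracle_enumerate(4, 10, 4, 4) == pytest.approx(1 / 210)

    def test_k_zero_gives_one(self):
        assert hypergeom_upper_tail(0, 10, 4, 4) == 1.0

    def test_matches_draw_enumeration_small(self):
        for N in range(1, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                            hypergeom_oracle_enumerate(k, N, K, n), abs=1e-10
                        )

    def test_monotone_in_k(self):
        for N, K, n in [(20, 8, 10), (25, 12, 12), (15, 3, 9)]:
            ps = [hypergeom_upper_tail(k, N, K, n) for k in range(min(K, n) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestRandomizeNetwork:
    def _degrees(self, db):
        out_deg, in_deg = {}, {}
        for p in db.pairs:
            out_deg[p.ligand] = out_deg.get(p.ligand, 0) + 1
            in_deg[p.receptor] = in_deg.get(p.receptor, 0) + 1
        return out_deg, in_deg

    def test_degree_preservation_exact(self):
        rng = np.random.default_rng(0)
        pairs = set()
        while len(pairs) < 60:
            pairs.add((f"L{rng.integers(0, 20)}", f"R{rng.integers(0, 20)}"))
        db = LigandReceptorDB([LRPair(l, r) for l, r in pairs])
        ref = self._degrees(db)
        for rdb in randomize_lr_network(db, R=50, seed=1):
            assert self._degrees(rdb) == ref
            assert len(rdb) == len(db)  # no duplicate edges collapsed

    def test_two_pair_graph_unique_rewiring(self):
        db = LigandReceptorDB([LRPair("a", "x"), LRPair("b", "y")])
        seen = {frozenset(r.keys()) for r in randomize_lr_network(db, R=50, seed=0)}
        allowed = {
            frozenset({("a", "x"), ("b", "y")}),
            frozenset({("a", "y"), ("b", "x")}),
        }
        assert seen <= allowed
        assert len(seen) == 2  # both states reached over 50 replicates

    def test_deterministic_under_seed(self, small_db):
        a = randomize_lr_network(small_db, R=20, seed=9)
        b = randomize_lr_network(small_db, R=20, seed=9)
        assert [r.keys() for r in a] == [r.keys() for r in b]

    def test_saturated_graph_warns_unchanged(self):
        # complete bipartite: no swap can avoid duplicating an edge
        db = LigandReceptorDB(
            [LRPair(l, r) for l in ("a", "b") for r in ("x", "y")]
        )
        with pytest.warns(UserWarning, match="no valid"):
            out = randomize_lr_network(db, R=1, seed=0)
        assert out[0].keys() == db.keys()

    def test_too_small_db_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            randomize_lr_network(LigandReceptorDB([LRPair("a", "x")]), R=1, seed=0)


def _profiles_from_lists(lists, all_genes):
    """Minimal profiles with fixed gene lists and unit mean expression."""
    from clonescape.crosstalk import ClusterExpressionProfile

    profiles = {}
    for cl, genes in lists.items():
        mean = pd.Series(0.0, index=all_genes)
        mean[list(genes)] = 1.0
        profiles[cl] = ClusterExpressionProfile(
            cl, mean, mean.copy(), expressed_genes=set(genes), deg_genes=set()
        )
    return profiles


class TestHyperDetector:
    def test_k_zero_record(self):
        genes = [f"g{i}" for i in range(10)]
        db = LigandReceptorDB([LRPair("g0", "g1"), LRPair("g2", "g3")])
        profiles = _profiles_from_lists({"A": {"g5"}, "B": {"g6"}}, genes)
        events, records = detect_crosstalk_hyper(profiles, db, [], bh=False)
        assert (records["k"] == 0).all()
        assert (records["p_hyper"] == 1.0).all()
        assert len(events) == 0

    def test_saturated_graph_empirical_one(self):
        # every ligand to every receptor: rewiring cannot change k
        ligs, recs = ["l1", "l2"], ["r1", "r2"]
        db = LigandReceptorDB([LRPair(l, r) for l in ligs for r in recs])
        genes = ligs + recs
        profiles = _profiles_from_lists({"A": set(ligs), "B": set(recs)}, genes)
        with pytest.warns(UserWarning):
            randomized = randomize_lr_network(db, R=25, seed=0)
        _, records = detect_crosstalk_hyper(profiles, db, randomized, bh=False)
        row = records[(records["source"] == "A") & (records["target"] == "B")].iloc[0]
        assert row["k"] == 4
        assert row["p_empirical"] == 1.0

    def test_record_invariants(self, small_db):
        genes = sorted(small_db.genes() | {"x1", "x2"})
        profiles = _profiles_from_lists(
            {"A": {"L1", "L2"}, "B": {"R1", "R2"}}, genes
        )
        randomized = randomize_lr_network(small_db, R=30, seed=3)
        _, records = detect_crosstalk_hyper(profiles, small_db, randomized, bh=False)
        assert ((records["k"] <= records[["K", "n"]].min(axis=1)) | (records["k"] == 0)).all()
        assert (records["p_hyper"] > 0).all() and (records["p_hyper"] <= 1).all()
        assert (records["p_empirical"] >= 1 / 31).all()


class TestDegMatch:
    def test_rule_application(self, small_db):
        genes = sorted(small_db.genes())
        profiles = _profiles_from_lists({"A": {"L1"}, "B": {"R1"}}, genes)
        events = detect_deg_match(profiles, small_db)
        keys = set(map(tuple, events[EVENT_KEY].itertuples(index=False)))
        assert ("A", "B", "L1", "R1") in keys
        assert all(k[2:] == ("L1", "R1") for k in keys)  # nothing else in lists

    def test_pair_not_in_db_not_emitted(self, small_db):
        genes = sorted(small_db.genes())
        profiles = _profiles_from_lists({"A": {"L1"}, "B": {"R2"}}, genes)
        events = detect_deg_match(profiles, small_db)
        assert len(events[(events["source"] == "A") & (events["target"] == "B")]) == 0

    def test_complex_requires_all_subunits(self, small_db):
        genes = sorted(small_db.genes())
        partial = _profiles_from_lists({"A": {"L3"}, "B": {"R3A"}}, genes)
        assert len(detect_deg_match(partial, small_db)
                   .query("ligand == 'L3'")) == 0
        full = _profiles_from_lists({"A": {"L3"}, "B": {"R3A", "R3B"}}, genes)
        got = detect_deg_match(full, small_db).query("ligand == 'L3'")
        assert set(got["source"]) == {"A"}

    def test_deterministic_tie_order(self, small_db):
        genes = sorted(small_db.genes())
        profiles = _profiles_from_lists(
            {"A": {"L1", "L2", "R1", "R2"}, "B": {"L1", "L2", "R1", "R2"}}, genes
        )
        e1 = detect_deg_match(profiles, small_db)
        e2 = detect_deg_match(profiles, small_db)
        pd.testing.assert_frame_equal(e1, e2)
        # equal strengths -> lexicographic by the event key
        ties = e1[e1["mean_strength"] == e1["mean_strength"].iloc[0]]
        assert list(ties[EVENT_KEY].itertuples(index=False)) == sorted(
            ties[EVENT_KEY].itertuples(index=False)
        )


class TestJointExpression:
    def test_gate_excludes_low_fraction(self):
        cfg = SimulationConfig(
            n_clusters=2, cells_per_cluster=50, n_genes=30, baseline_mean=2.0, seed=0
        )
        m, _ = simulate_counts(cfg)
        # make G0000 nearly silent in C0 (<10% of cells)
        dense = m.counts.toarray()
        labels = m.cell_meta["cluster"].to_numpy()
        dense[0, labels == "C0"] = 0
        dense[0, np.where(labels == "C0")[0][:2]] = 1  # 2/50 = 4%
        import scipy.sparse as sp

        from clonescape.io import CountMatrix

        m2 = CountMatrix(sp.csr_matrix(dense), m.gene_ids, m.cell_ids, m.cell_meta)
        db = LigandReceptorDB([LRPair("G0000", "G0001")])
        res = detect_joint_expression(m2, labels, db, n_perm=100, seed=0)
        assert len(res[res["source"] == "C0"]) == 0

    def test_planted_pair_significant(self):
        cfg = SimulationConfig(
            n_clusters=2, cells_per_cluster=150, n_genes=40, baseline_mean=1.5,
            planted_links=[("C0", "C1", "G0003", "G0004", 8.0)], seed=5,
        )
        m, _ = simulate_counts(cfg)
        labels = m.cell_meta["cluster"].to_numpy()
        db = LigandReceptorDB(
            [LRPair("G0003", "G0004"), LRPair("G0010", "G0011"), LRPair("G0012", "G0013")]
        )
        res = detect_joint_expression(m, labels, db, n_perm=500, seed=1)
        hit = res[
            (res["source"] == "C0") & (res["target"] == "C1")
            & (res["ligand"] == "G0003")
        ]
        assert hit["selected"].all() and len(hit) == 1

    def test_n_perm_floor(self, clustered_sim, small_db):
        m, _, _ = clustered_sim
        with pytest.raises(ValueError, match="n_perm"):
            detect_joint_expression(
                m, m.cell_meta["cluster"].to_numpy(), small_db, n_perm=10
            )


class TestConsensus:
    @staticmethod
    def _event_df(keys):
        return pd.DataFrame(
            [dict(zip(EVENT_KEY, k), mean_strength=1.0, selected=True) for k in keys],
            columns=EVENT_KEY + ["mean_strength", "selected"],
        )

    def test_truth_table_all_eight_patterns(self):
        key = ("A", "B", "L", "R")
        for pattern in itertools.product([0, 1], repeat=3):
            dfs = [self._event_df([key] if flag else []) for flag in pattern]
            out = consensus(*dfs)
            if sum(pattern) == 0:
                assert len(out) == 0
                continue
            assert len(out) == 1
            assert bool(out["consensus"].iloc[0]) == (sum(pattern) >= 2)

    def test_any_two_tools(self):
        key = ("A", "B", "L", "R")
        out = consensus(self._event_df([]), self._event_df([key]), self._event_df([key]))
        assert out["consensus"].iloc[0]
        assert out["detected_by"].iloc[0] == "crosstalk_hyper,deg_match"

    def test_single_detector_not_consensus(self):
        key = ("A", "B", "L", "R")
        out = consensus(self._event_df([key]), self._event_df([]), self._event_df([]))
        assert not out["consensus"].iloc[0]

    def test_symmetric_in_detector_identity(self):
        key = ("A", "B", "L", "R")
        patterns = [(1, 1, 0), (1, 0, 1), (0, 1, 1)]
        for p in patterns:
            dfs = [self._event_df([key] if f else []) for f in p]
            assert consensus(*dfs)["consensus"].iloc[0]
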
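"""Greedy clustering: assignment rule, index, dynamic representation."""

import numpy as np

from oracles import replay_greedy
from seedclust import (
    ClusterParams,
    Read,
    SeedParams,
    greedy_cluster,
    shared_seed_counts,
    sort_reads,
)
from seedclust.cluster import assign_read
from seedclust.seeds import Seed
from seedclust.simdata import SimConfig, chain_family_reads, simulate
from seedclust.sortreads import PreparedRead


def _prepared(rid, values, hcs_values=None):
    """A synthetic PreparedRead whose seeds carry the given values; values
    in ``hcs_values`` (default: all) get confidence above any threshold."""
    hcs_values = set(values) if hcs_values is None else set(hcs_values)
    seeds = [
        Seed(v, i, 0.999 if v in hcs_values else 0.1)
        for i, v in enumerate(values)
    ]
    dummy = Read(rid, "A" * max(1, len(values)), "I" * max(1, len(values)))
    return PreparedRead(dummy, seeds, hcs_values, len(hcs_values))


class TestSharedSeedCounts:
    def test_disjoint_read_has_empty_counts(self):
        index = {1: [0], 2: [0, 1]}
        assert shared_seed_counts({7, 8}, index) == {}

    def test_counts_match_brute_force_intersections(self):
        reps = {0: {1, 2, 3}, 1: {3, 4, 5, 6}, 2: {6, 7}}
        index = {}
        for cid, rep in reps.items():
            for v in rep:
                index.setdefault(v, []).append(cid)
        read_values = {2, 3, 6, 9}
        counts = shared_seed_counts(read_values, index)
        assert counts == {
            cid: len(read_values & rep) for cid, rep in reps.items()
            if read_values & rep
        }

    def test_founder_identity(self):
        founder = _prepared("f", [1, 2, 3])
        clusters, index = [], {}
        assign_read(founder, clusters, index, ClusterParams(0.5))
        assert shared_seed_counts({1, 2, 3}, index) == {0: 3}


class TestAssignRead:
    def test_first_read_founds_cluster_zero(self):
        clusters, index = [], {}
        cid = assign_read(_prepared("r0", [1, 2, 3]), clusters, index, ClusterParams(0.5))
        assert cid == 0
        assert clusters[0].hcs == {1, 2, 3}

    def test_exact_duplicate_joins_even_at_t2_one(self):
        clusters, index = [], {}
        assign_read(_prepared("r0", [1, 2, 3]), clusters, index, ClusterParams(1.0))
        cid = assign_read(_prepared("r1", [1, 2, 3]), clusters, index, ClusterParams(1.0))
        assert cid == 0 and clusters[0].members == ["r0", "r1"]

    def test_insufficient_fraction_founds_new_cluster(self):
        clusters, index = [], {}
        assign_read(_prepared("r0", [1, 2, 3, 4]), clusters, index, ClusterParams(0.5))
        cid = assign_read(_prepared("r1", [4, 5, 6, 7]), clusters, index, ClusterParams(0.5))
        assert cid == 1  # shares 1/4 < 0.5

    def test_join_updates_representation_and_index(self):
        clusters, index = [], {}
        assign_read(_prepared("r0", [1, 2, 3, 4]), clusters, index, ClusterParams(0.5))
        cid = assign_read(_prepared("r1", [3, 4, 5, 6]), clusters, index, ClusterParams(0.5))
        assert cid == 0
        assert clusters[0].hcs == {1, 2, 3, 4, 5, 6}
        assert index[5] == [0] and index[6] == [0]

    def test_only_hcs_enter_representation(self):
        clusters, index = [], {}
        assign_read(
            _prepared("r0", [1, 2, 3, 4], hcs_values=[1, 2]),
            clusters, index, ClusterParams(0.5),
        )
        assert clusters[0].hcs == {1, 2}
        cid = assign_read(
            _prepared("r1", [1, 2, 9, 10], hcs_values=[9]),
            clusters, index, ClusterParams(0.5),
        )
        assert cid == 0 and clusters[0].hcs == {1, 2, 9}

    def test_tie_broken_by_smallest_cluster_id(self):
        clusters, index = [], {}
        assign_read(_prepared("a", [1, 2]), clusters, index, ClusterParams(1.0))
        assign_read(_prepared("b", [3, 4]), clusters, index, ClusterParams(1.0))
        cid = assign_read(_prepared("c", [2, 3]), clusters, index, ClusterParams(0.5))
        assert cid == 0  # one shared seed with each; oldest cluster wins

    def test_zero_seed_read_founds_flagged_cluster(self):
        clusters, index = [], {}
        cid = assign_read(_prepared("empty", []), clusters, index, ClusterParams(0.5))
        assert clusters[cid].zero_seed and clusters[cid].hcs == set()
        # and such clusters never attract members
        cid2 = assign_read(_prepared("r1", [1, 2]), clusters, index, ClusterParams(0.0))
        assert cid2 == 1


class TestGreedyCluster:
    def test_identical_reads_form_one_cluster(self):
        stream = [_prepared(f"r{i}", [1, 2, 3]) for i in range(8)]
        clusters, assignment, _ = greedy_cluster(stream, ClusterParams(0.5))
        assert len(clusters) == 1 and len(clusters[0].members) == 8

    def test_seed_disjoint_families_never_merge(self):
        stream = [_prepared(f"a{i}", [1, 2, 3]) for i in range(3)]
        stream += [_prepared(f"b{i}", [7, 8, 9]) for i in range(3)]
        clusters, assignment, _ = greedy_cluster(stream, ClusterParams(0.5))
        assert len(clusters) == 2

    def test_hand_traced_two_family_fixture(self):
        # pencil-and-paper trace at t2=0.5:
        # r0 founds c0 {1,2,3,4}; r1 shares 2/4 -> joins c0, adds {5,6};
        # r2 shares 2/4 with c0 (values 5,6) -> joins c0, adds {7,8};
        # x0 shares 0 -> founds c1; x1 shares 2/4 -> joins c1.
        stream = [
            _prepared("r0", [1, 2, 3, 4]),
            _prepared("r1", [3, 4, 5, 6]),
            _prepared("r2", [5, 6, 7, 8]),
            _prepared("x0", [20, 21, 22, 23]),
            _prepared("x1", [22, 23, 24, 25]),
        ]
        clusters, assignment, _ = greedy_cluster(stream, ClusterParams(0.5))
        assert assignment == {"r0": 0, "r1": 0, "r2": 0, "x0": 1, "x1": 1}

    def test_matches_straight_line_replay_on_random_streams(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            stream = []
            for i in range(40):
                values = list(rng.choice(60, size=rng.integers(1, 12), replace=False))
                hcs = [v for v in values if rng.random() < 0.7]
                stream.append(_prepared(f"r{i}", values, hcs))
            t2 = float(rng.choice([0.3, 0.5, 0.8]))
            _, assignment, _ = greedy_cluster(stream, ClusterParams(t2))
            replay = replay_greedy(
                [(pr.read.read_id, {s.value for s in pr.seeds}, set(pr.hcs))
                 for pr in stream],
                t2,
            )
            assert assignment == replay

    def test_partition_and_representation_invariants(self):
        rng = np.random.default_rng(29)
        stream = []
        for i in range(60):
            values = list(rng.choice(50, size=rng.integers(1, 10), replace=False))
            hcs = [v for v in values if rng.random() < 0.6]
            stream.append(_prepared(f"r{i}", values, hcs))
        clusters, assignment, index = greedy_cluster(stream, ClusterParams(0.5))
        # partition: every read in exactly one cluster
        assert sorted(assignment) == sorted(pr.read.read_id for pr in stream)
        assert sum(len(c.members) for c in clusters) == len(stream)
        # representation-union: replayable from members' HCS sets
        hcs_by_read = {pr.read.read_id: pr.hcs for pr in stream}
        for c in clusters:
            assert c.hcs == set().union(*(hcs_by_read[m] for m in c.members))
        # index consistency: rebuild and compare
        rebuilt = {}
        for c in clusters:
            for v in c.hcs:
                rebuilt.setdefault(v, []).append(c.cluster_id)
        assert {v: sorted(cids) for v, cids in rebuilt.items()} == {
            v: sorted(cids) for v, cids in index.items()
        }

    def test_determinism(self):
        rng = np.random.default_rng(31)
        stream = []
        for i in range(30):
            values = list(rng.choice(40, size=5, replace=False))
            stream.append(_prepared(f"r{i}", values))
        a = greedy_cluster(stream, ClusterParams(0.5))[1]
        b = greedy_cluster(stream, ClusterParams(0.5))[1]
        assert a == b


class TestDynamicRepresentation:
    def test_chain_overlap_family_needs_dynamic_updates(self):
        # isoforms chain-overlap: A-B and B-C share two exons of three,
        # A-C only one. dynamic representations keep the family in one
        # cluster; frozen founder representations split it.
        reads, _ = chain_family_reads(n_exons=5, exon_length=300, seed=5)
        params = SeedParams(k=13, w=21, t1=0.95)
        stream = sort_reads(reads, params)
        dynamic, _, _ = greedy_cluster(stream, ClusterParams(0.5), dynamic=True)
        static, _, _ = greedy_cluster(stream, ClusterParams(0.5), dynamic=False)
        assert len(dynamic) == 1
        assert len(static) >= 2

    def test_simulated_families_recovered_without_noise(self):
        config = SimConfig(
            n_families=4, reads_per_family=(15, 15), error_rate=0.0, seed=9
        )
        reads, truth = simulate(config)
        stream = sort_reads(reads, SeedParams(k=13, w=21, t1=0.95))
        _, assignment, _ = greedy_cluster(stream, ClusterParams(0.5))
        for fam_id in range(4):
            cids = {assignment[r] for r, f in truth.family.items() if f == fam_id}
            assert len(cids) == 1
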
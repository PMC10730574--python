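import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from trajmine.embedding_cluster import (HashingEmbedder,
                                        average_linkage_clusters,
                                        cluster_trajectories, dtw_distance,
                                        embed_codes,
                                        trajectory_distance_matrix)
from trajmine.event_model import CodeVocabulary
from trajmine.trajectory_assembly import Trajectory

from oracles import dtw_bruteforce


class TestHashingEmbedder:
    def test_unit_norm_and_dimension(self):
        vec = HashingEmbedder(dim=256)(
            "Disorders of lipoprotein metabolism and other lipidemias")
        assert vec.shape == (256,)
        assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-9)

    def test_identical_descriptions_identical_vectors(self):
        emb = HashingEmbedder(dim=64)
        assert np.array_equal(emb("essential hypertension"),
                              emb("essential hypertension"))

    def test_different_descriptions_differ(self):
        emb = HashingEmbedder(dim=256)
        assert not np.allclose(emb("cerebral infarction"),
                               emb("depressive episode"))

    def test_embed_codes_uses_descriptions(self):
        vocab = CodeVocabulary.from_codes(["E78", "I10"])
        vocab.entries["E78"]["description"] = (
            "Disorders of lipoprotein metabolism and other lipidemias")
        out = embed_codes(vocab, dim=128)
        assert set(out) == {"E78", "I10"}
        assert all(v.shape == (128,) for v in out.values())

    def test_provider_failure_lists_codes(self):
        vocab = CodeVocabulary.from_codes(["A", "B"])

        def bad_provider(text):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="A.*B"):
            embed_codes(vocab, provider=bad_provider, dim=8)

    def test_wrong_dimension_rejected(self):
        vocab = CodeVocabulary.from_codes(["A"])
        with pytest.raises(RuntimeError):
            embed_codes(vocab, provider=lambda t: np.ones(3), dim=8)


class TestDTW:
    def test_zero_self_distance(self):
        rng = np.random.default_rng(0)
        seq = rng.normal(size=(4, 8))
        assert dtw_distance(seq, seq) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_reduce_to_local_cost(self):
        x = np.array([[1.0, 0.0]])
        y = np.array([[0.0, 1.0]])
        assert dtw_distance(x, y) == pytest.approx(np.sqrt(2.0))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(3, 5)), rng.normal(size=(4, 5))
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_diagonal_path_bounds_equal_length_sequences(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        diagonal = float(np.linalg.norm(a - b, axis=1).sum())
        assert dtw_distance(a, b) <= diagonal + 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.empty((0, 3)), np.ones((2, 3)))

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            m, n = rng.integers(1, 5, size=2)
            a, b = rng.normal(size=(m, 3)), rng.normal(size=(n, 3))
            assert dtw_distance(a, b) == pytest.approx(
                dtw_bruteforce(a, b), abs=1e-9)


class TestAverageLinkage:
    def test_k_equal_n_gives_singletons(self):
        dist = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert average_linkage_clusters(dist, k=3) == [[0], [1], [2]]

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        d = rng.random((7, 7)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        parts = average_linkage_clusters(d, k=3)
        flat = sorted(i for p in parts for i in p)
        assert flat == list(range(7))

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 8
            d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
            ours = average_linkage_clusters(d, k=3)
            lab = fcluster(linkage(squareform(d), method="average"),
                           t=3, criterion="maxclust")
            theirs = {}
            for i, l in enumerate(lab):
                theirs.setdefault(l, []).append(i)
            assert sorted(map(sorted, theirs.values())) == ours

    def test_threshold_mode_stops_before_expensive_merges(self):
        dist = np.array([[0, 0.1, 9, 9], [0.1, 0, 9, 9],
                         [9, 9, 0, 0.2], [9, 9, 0.2, 0.0]])
        assert average_linkage_clusters(dist, threshold=1.0) == [[0, 1], [2, 3]]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_clusters(np.zeros((2, 2)), k=5)


def _two_family_setup():
    vocab = CodeVocabulary.from_codes(
        ["I10", "I63", "I25", "F01.50", "F32", "F41", "F05", "F03.90"])
    for code, desc in {
        "I10": "essential primary hypertension",
        "I63": "cerebral infarction of the brain",
        "I25": "chronic ischaemic heart disease",
        "F01.50": "vascular dementia without behavioral disturbance",
        "F32": "major depressive episode",
        "F41": "other anxiety disorders",
        "F05": "delirium due to known physiological condition",
        "F03.90": "unspecified dementia without behavioral disturbance",
    }.items():
        vocab.entries[code]["description"] = desc
    family_a = [Trajectory(("I10", "I63", "F01.50"), 50),
                Trajectory(("I25", "I63", "F01.50"), 40),
                Trajectory(("I10", "I25", "I63", "F01.50"), 30)]
    family_b = [Trajectory(("F32", "F05", "F03.90"), 45),
                Trajectory(("F41", "F05", "F03.90"), 35)]
    return vocab, family_a, family_b


class TestClusterTrajectories:
    def test_disjoint_families_split_cleanly_at_k2(self):
        vocab, fam_a, fam_b = _two_family_setup()
        emb = embed_codes(vocab, dim=256)
        trajs = fam_a + fam_b
        dist = trajectory_distance_matrix(trajs, emb)
        parts = average_linkage_clusters(dist, k=2)
        assert sorted(map(sorted, parts)) == [[0, 1, 2], [3, 4]]

    def test_membership_invariant_to_input_permutation(self):
        vocab, fam_a, fam_b = _two_family_setup()
        emb = embed_codes(vocab, dim=256)
        trajs = fam_a + fam_b
        perm = [3, 0, 4, 1, 2]
        dist = trajectory_distance_matrix(trajs, emb)
        dist_p = trajectory_distance_matrix([trajs[i] for i in perm], emb)
        parts = average_linkage_clusters(dist, k=2)
        parts_p = average_linkage_clusters(dist_p, k=2)
        as_sets = {frozenset(trajs[i].codes for i in p) for p in parts}
        as_sets_p = {frozenset(trajs[perm[i]].codes for i in p)
                     for p in parts_p}
        assert as_sets == as_sets_p

    def test_singleton_clusters_reproduce_member_risks(self, planted_cohort):
        _, cohort, _ = planted_cohort
        trajs = [Trajectory(("I25", "I50", "F01.50"), 500),
                 Trajectory(("F41", "F05", "F03.90"), 500)]
        emb = embed_codes(cohort.vocabulary)
        clusters, _ = cluster_trajectories(cohort, trajs, emb,
                                           k=len(trajs), master_seed=0)
        from trajmine.matched_risk import relative_risk
        for c in clusters:
            assert len(c.members) == 1
            t = c.members[0]
            solo = relative_risk(cohort, list(t.prefix), t.terminal,
                                 seed=c.risk.seed)
            assert c.risk.rr == pytest.approx(solo.rr)
            assert c.risk.n_exposed == solo.n_exposed
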
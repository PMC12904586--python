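import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bialign import (
    EmbeddingSet,
    asw_celltype,
    asw_omics,
    foscttm,
    graph_connectivity,
    label_transfer_accuracy,
    mean_average_precision,
    nmi_score,
    report,
    seurat_alignment_score,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_silhouette(emb, labels):
    """Direct silhouette arithmetic (mean intra vs nearest-other-cluster distance)."""
    emb = np.asarray(emb, dtype=float)
    labels = np.asarray(labels)
    d = cdist(emb, emb)
    s = np.zeros(len(emb))
    for i in range(len(emb)):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = d[i, same].sum() / (n_same - 1)
        b = min(d[i, labels == l].mean() for l in np.unique(labels) if l != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


def brute_map(emb, labels, k):
    emb = np.asarray(emb, dtype=float)
    labels = np.asarray(labels)
    d = cdist(emb, emb)
    aps = []
    for i in range(len(emb)):
        order = np.argsort(d[i], kind="stable")
        nbrs = [j for j in order if j != i][:k]
        correct = [labels[j] == labels[i] for j in nbrs]
        m = sum(correct)
        if m == 0:
            aps.append(0.0)
            continue
        ap = 0.0
        hits = 0
        for r, c in enumerate(correct, start=1):
            if c:
                hits += 1
                ap += hits / r
        aps.append(ap / m)
    return float(np.mean(aps))


def brute_lta(train_emb, train_labels, test_emb, test_labels, k=5):
    d = cdist(np.asarray(test_emb, float), np.asarray(train_emb, float))
    correct = 0
    train_labels = np.asarray(train_labels)
    for i in range(len(test_emb)):
        order = np.argsort(d[i], kind="stable")[:k]
        votes = {}
        for rank, j in enumerate(order):
            lab = train_labels[j]
            votes.setdefault(lab, [0, rank])
            votes[lab][0] += 1
        pred = min(votes, key=lambda t: (-votes[t][0], votes[t][1]))
        if pred == test_labels[i]:
            correct += 1
    return correct / len(test_emb)


def brute_foscttm(Z1, Z2, pairs):
    Z1, Z2 = np.asarray(Z1, float), np.asarray(Z2, float)
    fracs = []
    for i, j in pairs:
        d12 = np.linalg.norm(Z2 - Z1[i], axis=1)
        d21 = np.linalg.norm(Z1 - Z2[j], axis=1)
        fracs.append(((d12 < d12[j]).sum() / len(Z2) + (d21 < d21[i]).sum() / len(Z1)) / 2)
    return float(np.mean(fracs))


def brute_gc(emb, types, k):
    import networkx as nx
    emb = np.asarray(emb, float)
    types = np.asarray(types)
    scores = []
    for t in np.unique(types):
        idx = np.nonzero(types == t)[0]
        d = cdist(emb[idx], emb[idx])
        g = nx.Graph()
        g.add_nodes_from(range(len(idx)))
        kk = min(k, len(idx) - 1)
        for a in range(len(idx)):
            order = [b for b in np.argsort(d[a], kind="stable") if b != a][:kk]
            for b in order:
                g.add_edge(a, int(b))
        largest = max(len(c) for c in nx.connected_components(g))
        scores.append(largest / len(idx))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------


class TestGraphConnectivity:
    def test_connected_single_type(self, rng):
        emb = rng.normal(size=(20, 3))
        assert graph_connectivity(emb, ["t"] * 20, k=5) == 1.0

    def test_split_type_gives_three_quarters(self):
        # type A connected; type B split into two distant halves -> LCC covers half
        a = np.random.default_rng(0).normal(size=(10, 2))
        b = np.vstack([np.random.default_rng(1).normal(size=(5, 2)),
                       np.random.default_rng(2).normal(size=(5, 2)) + 1000.0])
        emb = np.vstack([a, b])
        types = ["A"] * 10 + ["B"] * 10
        assert graph_connectivity(emb, types, k=2) == pytest.approx(0.75)

    def test_matches_brute_force(self, rng):
        emb = rng.normal(size=(40, 4))
        types = rng.choice(["x", "y", "z"], size=40)
        assert graph_connectivity(emb, types, k=4) == pytest.approx(brute_gc(emb, types, 4))


class TestSAS:
    def test_fully_separated_modalities_score_zero(self):
        emb = np.vstack([np.random.default_rng(0).normal(size=(30, 2)),
                         np.random.default_rng(1).normal(size=(30, 2)) + 1000.0])
        omics = ["a"] * 30 + ["b"] * 30
        assert seurat_alignment_score(emb, omics, k=10) == 0.0

    def test_well_mixed_blob_scores_near_one(self, rng):
        emb = rng.normal(size=(400, 3))
        omics = np.array(["a", "b"] * 200)
        assert seurat_alignment_score(emb, omics, k=10) > 0.9

    def test_k_too_large_rejected(self):
        emb = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            seurat_alignment_score(emb, ["a"] * 5 + ["b"] * 5, k=10)


class TestASWOmics:
    def test_interleaved_omics_near_one(self, rng):
        emb = rng.normal(size=(60, 3))
        omics = ["a", "b"] * 30
        assert asw_omics(emb, ["t"] * 60, omics) > 0.8

    def test_separated_omics_near_zero(self):
        emb = np.vstack([np.random.default_rng(0).normal(size=(20, 2)),
                         np.random.default_rng(1).normal(size=(20, 2)) + 100.0])
        omics = ["a"] * 20 + ["b"] * 20
        assert asw_omics(emb, ["t"] * 40, omics) < 0.1

    def test_matches_brute_force_silhouette_arithmetic(self, rng):
        emb = rng.normal(size=(8, 2))
        types = ["u"] * 4 + ["v"] * 4
        omics = ["a", "b", "a", "b"] * 2
        got = asw_omics(emb, types, omics)
        per_type = []
        for t in ("u", "v"):
            idx = [i for i in range(8) if types[i] == t]
            s = brute_silhouette(emb[idx], np.asarray(omics)[idx])
            per_type.append(np.mean(1 - np.abs(s)))
        assert got == pytest.approx(np.mean(per_type), rel=1e-8)

    def test_single_modality_type_excluded(self):
        emb = np.random.default_rng(0).normal(size=(8, 2))
        types = ["solo"] * 4 + ["both"] * 4
        omics = ["a"] * 4 + ["a", "b", "a", "b"]
        with pytest.warns(UserWarning, match="solo"):
            asw_omics(emb, types, omics)


class TestMAP:
    def test_all_neighbors_correct(self):
        emb = np.vstack([np.random.default_rng(0).normal(size=(10, 2)),
                         np.random.default_rng(1).normal(size=(10, 2)) + 100.0])
        types = ["a"] * 10 + ["b"] * 10
        assert mean_average_precision(emb, types, k=5) == 1.0

    def test_worked_pattern(self):
        # neighbor correctness (hit, miss, hit) -> AP = (1 + 2/3)/2 = 5/6
        emb = np.array([[0.0], [1.0], [2.0], [3.0]])
        types = ["a", "a", "b", "a"]
        # for cell 0: neighbors 1(a hit), 2(b miss), 3(a hit)
        nn_ap = (1.0 + 2.0 / 3.0) / 2.0
        got = mean_average_precision(emb, types, k=3)
        oracle = brute_map(emb, types, 3)
        assert got == pytest.approx(oracle, rel=1e-10)
        # first cell's AP is the hand-computed value
        assert nn_ap == pytest.approx(5 / 6)

    def test_matches_brute_force(self, rng):
        emb = rng.normal(size=(30, 3))
        types = rng.choice(["a", "b", "c"], size=30)
        got = mean_average_precision(emb, types, k=7)
        assert got == pytest.approx(brute_map(emb, types, 7), rel=1e-8)

    def test_random_labels_match_null_expectation(self, rng):
        # Monte-Carlo oracle: expected AP when neighbor correctness is an
        # i.i.d. Bernoulli(class frequency) sequence of length k
        k, freq = 15, 0.5
        sims = rng.random(size=(20000, k)) < freq
        aps = []
        for row in sims:
            m = row.sum()
            if m == 0:
                aps.append(0.0)
                continue
            hits = np.cumsum(row)
            aps.append(((hits / np.arange(1, k + 1)) * row).sum() / m)
        null_ap = float(np.mean(aps))
        emb = rng.normal(size=(600, 2))
        types = rng.choice(["a", "b"], size=600)
        got = mean_average_precision(emb, types, k=k)
        assert got == pytest.approx(null_ap, abs=0.05)


class TestASWCelltype:
    def test_two_far_clusters_near_one(self):
        emb = np.vstack([np.random.default_rng(0).normal(size=(15, 2)),
                         np.random.default_rng(1).normal(size=(15, 2)) + 1000.0])
        assert asw_celltype(emb, ["a"] * 15 + ["b"] * 15) > 0.99

    def test_random_labels_near_zero(self, rng):
        emb = rng.normal(size=(300, 2))
        labels = rng.choice(["a", "b"], size=300)
        assert abs(asw_celltype(emb, labels)) < 0.05

    def test_matches_brute_force(self, rng):
        emb = rng.normal(size=(6, 2))
        labels = ["a", "a", "b", "b", "c", "c"]
        got = asw_celltype(emb, labels)
        assert got == pytest.approx(np.mean(brute_silhouette(emb, np.array(labels))), rel=1e-8)

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            asw_celltype(np.zeros((5, 2)), ["a"] * 5)


class TestNMI:
    def test_perfect_clusters_give_one(self):
        emb = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 100.0])
        assert nmi_score(emb, ["x"] * 10 + ["y"] * 10) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self, rng):
        emb = np.vstack([rng.normal(size=(200, 2)), rng.normal(size=(200, 2)) + 50.0])
        labels = rng.choice(["a", "b"], size=400)  # independent of the split
        assert nmi_score(emb, labels) < 0.05

    def test_permutation_invariance_of_label_names(self):
        emb = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 100.0])
        a = nmi_score(emb, ["x"] * 10 + ["y"] * 10)
        b = nmi_score(emb, ["y"] * 10 + ["x"] * 10)
        assert a == pytest.approx(b)


class TestLTA:
    def test_identical_embeddings_distinct_clusters(self):
        train = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 10.0])
        labels = ["a"] * 10 + ["b"] * 10
        assert label_transfer_accuracy(train, labels, train, labels) == 1.0

    def test_wrong_cluster_cells_score_zero(self):
        train = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 10.0])
        labels = ["a"] * 10 + ["b"] * 10
        test = np.ones((5, 2)) * 10.0  # sits in the 'b' cluster
        assert label_transfer_accuracy(train, labels, test, ["a"] * 5) == 0.0

    def test_matches_brute_force_vote(self, rng):
        train = rng.normal(size=(40, 3))
        train_labels = rng.choice(["a", "b", "c"], size=40)
        test = rng.normal(size=(15, 3))
        test_labels = rng.choice(["a", "b", "c"], size=15)
        got = label_transfer_accuracy(train, train_labels, test, test_labels, k=5)
        assert got == pytest.approx(brute_lta(train, train_labels, test, test_labels), rel=1e-10)


class TestFOSCTTM:
    def test_identical_paired_embeddings_score_zero(self, rng):
        Z = rng.normal(size=(20, 4))
        pairs = [(i, i) for i in range(20)]
        assert foscttm(Z, Z, pairs) == 0.0

    def test_swapped_matches(self):
        Z1 = np.array([[0.0, 0.0], [1.0, 0.0]])
        Z2 = np.array([[1.0, 0.0], [0.0, 0.0]])  # true matches swapped
        assert foscttm(Z1, Z2, [(0, 0), (1, 1)]) == pytest.approx(0.5)

    def test_matches_brute_force_and_bounds(self, rng):
        Z1 = rng.normal(size=(25, 3))
        Z2 = rng.normal(size=(30, 3))
        pairs = [(i, i) for i in range(20)]
        got = foscttm(Z1, Z2, pairs)
        assert got == pytest.approx(brute_foscttm(Z1, Z2, pairs), rel=1e-10)
        assert 0.0 <= got <= 1.0

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            foscttm(np.zeros((2, 2)), np.zeros((2, 2)), [])


class TestReport:
    def _perfect_embedding(self, rng):
        centers = np.array([[0, 0], [100, 0], [0, 100.0]])
        Z1 = np.repeat(centers, 20, axis=0) + rng.normal(scale=1.0, size=(60, 2))
        Z2 = np.repeat(centers, 20, axis=0) + rng.normal(scale=1.0, size=(60, 2))
        labels = [f"t{i}" for i in range(3) for _ in range(20)]
        emb = EmbeddingSet(Z1, Z2, np.zeros((2, 3)), np.zeros((2, 3)))
        return emb, labels

    def test_perfect_integration_scores_high(self, rng):
        emb, labels = self._perfect_embedding(rng)
        rep = report(emb, labels, labels, true_pairs=[(i, i) for i in range(60)], k_map=10)
        assert rep.omics_mixing > 0.9
        assert rep.celltype_conservation > 0.9
        assert rep.lta == 1.0
        assert rep.foscttm is not None

    def test_unintegrated_data_scores_low_on_mixing(self, rng):
        Z1 = rng.normal(size=(40, 2))
        Z2 = rng.normal(size=(40, 2)) + 1000.0
        labels = ["a"] * 20 + ["b"] * 20
        emb = EmbeddingSet(Z1, Z2, np.zeros((2, 3)), np.zeros((2, 3)))
        rep = report(emb, labels, labels, k_map=10)
        assert rep.sas == 0.0
        assert rep.omics_mixing < 0.5
        assert rep.foscttm is None

    def test_aggregates_equal_component_means(self, rng):
        emb, labels = self._perfect_embedding(rng)
        rep = report(emb, labels, labels, k_map=10)
        assert rep.omics_mixing == pytest.approx((rep.gc + rep.sas + rep.asw_o) / 3, abs=1e-15)
        assert rep.celltype_conservation == pytest.approx((rep.map + rep.asw + rep.nmi) / 3, abs=1e-15)


class TestInvariances:
    def test_bounds_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(12, 30))
            emb = rng.normal(size=(n, 3))
            types = rng.choice(["a", "b"], size=n)
            omics = rng.choice(["m1", "m2"], size=n)
            if len(set(types)) < 2 or min((omics == o).sum() for o in ("m1", "m2")) < 4:
                continue
            k = 3
            assert 0.0 <= graph_connectivity(emb, types, k=k) <= 1.0
            assert 0.0 <= seurat_alignment_score(emb, omics, k=k) <= 1.0
            assert 0.0 <= mean_average_precision(emb, types, k=k) <= 1.0
            assert -1.0 <= asw_celltype(emb, types) <= 1.0
            assert 0.0 <= nmi_score(emb, types) <= 1.0 + 1e-12

    def test_rigid_rotation_invariance(self, rng):
        n = 40
        emb = rng.normal(size=(n, 3))
        types = rng.choice(["a", "b", "c"], size=n)
        omics = np.array(["m1", "m2"] * (n // 2))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rot = emb @ q
        assert graph_connectivity(emb, types, k=4) == pytest.approx(
            graph_connectivity(rot, types, k=4))
        assert seurat_alignment_score(emb, omics, k=4) == pytest.approx(
            seurat_alignment_score(rot, omics, k=4))
        assert mean_average_precision(emb, types, k=4) == pytest.approx(
            mean_average_precision(rot, types, k=4), rel=1e-8)
        assert asw_celltype(emb, types) == pytest.approx(asw_celltype(rot, types), rel=1e-8)
        pairs = [(i, i) for i in range(n)]
        assert foscttm(emb, emb + 0.01, pairs) == pytest.approx(
            foscttm(rot, (emb + 0.01) @ q, pairs), rel=1e-8)
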
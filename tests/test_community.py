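import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import dynflex as dx
from dynflex.community import build_modularity_tensor, evaluate_quality, \
    louvain_multilayer, repeat_partitions
from dynflex.errors import ContractError, DegenerateLayerError

from conftest import single_layer_stack, stack_from_layers


def set_partitions(n):
    """All set partitions of n items as restricted-growth label lists."""
    def rec(prefix, m):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(m + 1):
            yield from rec(prefix + [v], max(m, v + 1))
    yield from rec([0], 1)


def quality_direct(A, labels, gamma=1.0):
    """Independent double-sum oracle for single-layer Q at resolution gamma."""
    k = A.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def two_cliques_matrix():
    """Two disconnected 4-cliques with unit edges."""
    A = np.zeros((8, 8))
    for block in (slice(0, 4), slice(4, 8)):
        A[block, block] = 1.0
    np.fill_diagonal(A, 0.0)
    return A


class TestTensorConstruction:
    def test_single_layer_reduces_to_newman_matrix(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        tensor = build_modularity_tensor(single_layer_stack(A),
                                         dx.QualityParams(omega=0.0))
        k = A.sum(axis=1)
        expected = A - np.outer(k, k) / k.sum()
        np.testing.assert_allclose(tensor.supra.toarray(), expected, atol=1e-12)
        assert tensor.two_mu == pytest.approx(k.sum())

    def test_zero_omega_decouples_layers(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(stack_from_layers([A, A]),
                                         dx.QualityParams(omega=0.0))
        dense = tensor.supra.toarray()
        assert np.all(dense[:8, 8:] == 0)
        assert np.all(dense[8:, :8] == 0)

    def test_ordinal_coupling_entry_count(self):
        """3 layers of 5 nodes couple 2·N·(L−1) = 20 symmetric entries,
        verified by brute-force scan of the supra-matrix."""
        rng = np.random.default_rng(0)
        A = rng.uniform(0.1, 1.0, (5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tensor = build_modularity_tensor(stack_from_layers([A, A, A]),
                                         dx.QualityParams(omega=1.0))
        dense = tensor.supra.toarray()
        count = 0
        for i in range(15):
            for j in range(15):
                if i // 5 != j // 5 and dense[i, j] != 0:
                    count += 1
                    assert dense[i, j] == 1.0
                    assert i % 5 == j % 5  # only same node across layers
        assert count == 20

    def test_categorical_coupling_couples_all_layer_pairs(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(
            stack_from_layers([A, A, A]),
            dx.QualityParams(omega=0.5, coupling="categorical-all-pairs"))
        dense = tensor.supra.toarray()
        assert dense[0, 16] == 0.5  # layers 0 and 2 directly coupled
        assert tensor.two_mu == pytest.approx(3 * A.sum() + 0.5 * 8 * 3 * 2)

    def test_degenerate_layer_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = -1.0
        with pytest.raises(DegenerateLayerError):
            build_modularity_tensor(single_layer_stack(A))


class TestLouvain:
    def test_planted_cliques_stay_constant_across_layers(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(stack_from_layers([A, A, A]),
                                         dx.QualityParams(omega=1.0))
        part = louvain_multilayer(tensor, seed=0)
        S = part.S
        # one community per clique, constant across layers
        assert np.all(S == S[:, [0]])
        assert len(set(S[:4, 0])) == 1
        assert len(set(S[4:, 0])) == 1
        assert S[0, 0] != S[4, 0]
        assert np.all(dx.flexibility(S) == 0)

    def test_exhaustive_search_oracle_six_nodes(self):
        """Louvain attains the exhaustive-search maximum modularity on a
        single-layer 6-node graph (203 partitions enumerated)."""
        rng = np.random.default_rng(3)
        A = (rng.uniform(0, 1, (6, 6)) < 0.6).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        A[0, 1] = A[1, 0] = 1.0  # keep the graph connected enough
        tensor = build_modularity_tensor(single_layer_stack(A),
                                         dx.QualityParams(omega=0.0))
        best = max(evaluate_quality(np.array(p)[:, None], tensor)
                   for p in set_partitions(6))
        found = max(louvain_multilayer(tensor, seed=s).Q for s in range(10))
        assert found == pytest.approx(best, abs=1e-10)

    def test_determinism_given_seed(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(stack_from_layers([A, A]),
                                         dx.QualityParams(omega=1.0))
        p1 = louvain_multilayer(tensor, seed=7)
        p2 = louvain_multilayer(tensor, seed=7)
        assert np.array_equal(p1.S, p2.S)
        assert p1.Q == p2.Q

    def test_quality_trace_non_decreasing(self):
        rng = np.random.default_rng(5)
        layers = []
        for _ in range(4):
            A = rng.uniform(-0.2, 1.0, (12, 12))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            layers.append(A)
        tensor = build_modularity_tensor(stack_from_layers(layers))
        trace: list = []
        louvain_multilayer(tensor, seed=1, trace=trace)
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_large_omega_freezes_columns(self):
        """As ω grows, temporal persistence dominates and every node keeps
        one community across all layers (flexibility → 0)."""
        rng = np.random.default_rng(6)
        layers = []
        for _ in range(3):
            A = rng.uniform(0, 1, (10, 10))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            layers.append(A)
        tensor = build_modularity_tensor(stack_from_layers(layers),
                                         dx.QualityParams(omega=100.0))
        part = louvain_multilayer(tensor, seed=0)
        assert np.all(part.S == part.S[:, [0]])

    def test_canonical_labels_first_appearance(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(stack_from_layers([A, A]),
                                         dx.QualityParams(omega=1.0))
        S = louvain_multilayer(tensor, seed=0).S
        seen = []
        for l in range(S.shape[1]):
            for i in range(S.shape[0]):
                if S[i, l] not in seen:
                    seen.append(S[i, l])
        assert seen == sorted(seen)  # labels appear in 1,2,3,... order


class TestEvaluateQuality:
    def test_one_community_single_layer_is_zero(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(0, 1, (6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tensor = build_modularity_tensor(single_layer_stack(A),
                                         dx.QualityParams(omega=0.0))
        S = np.ones((6, 1), dtype=int)
        assert evaluate_quality(S, tensor) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_partition_matches_direct_sum(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, (7, 7))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tensor = build_modularity_tensor(single_layer_stack(A),
                                         dx.QualityParams(omega=0.0))
        S = np.arange(1, 8)[:, None]
        expected = quality_direct(A, S[:, 0])
        assert evaluate_quality(S, tensor) == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_invariance(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(stack_from_layers([A, A]))
        S = louvain_multilayer(tensor, seed=2).S
        remap = {c: 10 - c for c in np.unique(S)}
        S2 = np.vectorize(remap.get)(S)
        assert evaluate_quality(S2, tensor) == pytest.approx(
            evaluate_quality(S, tensor), abs=1e-12)

    def test_louvain_q_self_consistent(self):
        rng = np.random.default_rng(9)
        layers = []
        for _ in range(3):
            A = rng.uniform(-0.3, 1.0, (9, 9))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            layers.append(A)
        tensor = build_modularity_tensor(stack_from_layers(layers))
        part = louvain_multilayer(tensor, seed=4)
        assert part.Q == pytest.approx(evaluate_quality(part.S, tensor),
                                       abs=1e-10)

    def test_shape_mismatch_rejected(self):
        A = two_cliques_matrix()
        tensor = build_modularity_tensor(stack_from_layers([A, A]))
        with pytest.raises(ContractError):
            evaluate_quality(np.ones((3, 2), dtype=int), tensor)


class TestRepetitions:
    def test_repetition_count_and_seeds(self, planted_subject):
        spec, truth, ts = planted_subject
        stack = dx.dynamic_connectivity(ts, dx.WindowScheme(30, 10))
        parts = repeat_partitions(stack, n_reps=5, base_seed=100)
        assert len(parts) == 5
        assert [p.seed for p in parts] == [100, 101, 102, 103, 104]

    def test_stable_partitions_under_strong_structure(self):
        """With strong planted structure (r = 0.8, stable modules) the
        stochastic optimiser agrees with itself across repetitions: mean
        pairwise per-layer ARI of the S columns stays high."""
        spec = dx.CohortSpec(n_subjects_per_group=(1, 1), n_regions=40,
                             n_timepoints=120, n_modules=4,
                             switch_rate_per_group=(0.0, 0.0),
                             within_module_corr=0.8, seed=1)
        truth = dx.generate_partition_sequence(spec, 0, 201)
        ts = dx.simulate_timeseries(truth, spec, 202)
        stack = dx.dynamic_connectivity(ts, dx.WindowScheme(30, 10))
        parts = repeat_partitions(stack, n_reps=4, base_seed=0)
        aris = []
        for a in range(len(parts)):
            for b in range(a + 1, len(parts)):
                for l in range(stack.n_layers):
                    aris.append(adjusted_rand_score(parts[a].S[:, l],
                                                    parts[b].S[:, l]))
        assert np.mean(aris) > 0.9

    def test_planted_recovery_identifiable_regime(self, planted_subject):
        """Per-layer ARI against the planted modules is near-perfect when
        the module count keeps merges unprofitable."""
        spec, truth, ts = planted_subject
        stack = dx.dynamic_connectivity(ts, dx.WindowScheme(30, 1))
        part = louvain_multilayer(build_modularity_tensor(stack), seed=0)
        aris = []
        for l, start in enumerate(stack.window_starts):
            e = truth.epoch_of_time(int(start) + stack.scheme.width // 2)
            aris.append(adjusted_rand_score(truth.labels[:, e], part.S[:, l]))
        assert np.median(aris) > 0.9
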
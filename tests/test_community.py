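"""Multilayer modularity, generalized Louvain, agreement and consensus."""

import numpy as np
import pytest

from brainlayers import (
    AgreementMatrix,
    ConsensusError,
    Partition,
    adjusted_rand,
    agreement_per_layer,
    build_block,
    collapse_agreement,
    consensus_partition,
    generate_planted_layers,
    genlouvain,
    module_frequency_across_c,
    multilayer_modularity,
    supra_modularity_matrix,
    svd_normalize,
)
from brainlayers.community import relabel_first_appearance
from brainlayers.synthgen import PlantedSpec
from oracles import exhaustive_max_quality

DISJOINT_EDGES = np.array(
    [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float
)


class TestPartition:
    def test_noncontiguous_indices_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            Partition(np.array([[1, 1, 3]]))

    def test_1d_promoted_to_single_layer(self):
        p = Partition(np.array([1, 2, 1]))
        assert p.n_layers == 1 and p.n_communities == 2


class TestMultilayerModularity:
    def test_two_disjoint_edges_natural_partition(self):
        net = build_block([DISJOINT_EDGES], 0.0)
        q = multilayer_modularity(net, Partition(np.array([[1, 1, 2, 2]])))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_community_is_zero(self):
        net = build_block([DISJOINT_EDGES], 0.0)
        q = multilayer_modularity(net, Partition(np.array([[1, 1, 1, 1]])))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_layer_same_q(self):
        net = build_block([DISJOINT_EDGES, DISJOINT_EDGES], 0.0)
        q = multilayer_modularity(net, Partition(np.tile([1, 1, 2, 2], (2, 1))))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_size_mismatch_rejected(self):
        net = build_block([DISJOINT_EDGES], 0.0)
        with pytest.raises(ValueError):
            multilayer_modularity(net, Partition(np.array([[1, 1, 2]])))


class TestGenlouvain:
    def test_planted_two_blocks_recovered_every_run(self):
        planted = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        spec = PlantedSpec(8, 2, planted, 1.0, 0.1, 0.0)
        net = svd_normalize(build_block(generate_planted_layers(spec), 0.1))
        for res in genlouvain(net, n_runs=25, seed=0):
            assert adjusted_rand(res.partition.flat(), np.tile(planted, 2)) == 1.0

    def test_huge_coupling_forces_layer_consistency(self):
        spec = PlantedSpec(6, 3, np.array([1, 1, 1, 2, 2, 2]), 1.0, 0.1, 0.05, seed=2)
        net = build_block(generate_planted_layers(spec), 50.0)
        for res in genlouvain(net, n_runs=10, seed=1):
            a = res.partition.assignment
            assert np.all(a == a[0])  # same community per node across layers

    def test_returned_q_self_consistent(self, rng):
        spec = PlantedSpec(6, 2, np.array([1, 1, 1, 2, 2, 2]), 0.8, 0.2, 0.1, seed=4)
        net = svd_normalize(build_block(generate_planted_layers(spec), 0.3))
        for res in genlouvain(net, n_runs=10, seed=5):
            assert res.Q == pytest.approx(
                multilayer_modularity(net, res.partition), abs=1e-12
            )

    def test_reproducible_given_seed(self):
        spec = PlantedSpec(6, 2, np.array([1, 2, 1, 2, 1, 2]), 0.9, 0.3, 0.1, seed=6)
        net = build_block(generate_planted_layers(spec), 0.2)
        a = genlouvain(net, n_runs=5, seed=42)
        b = genlouvain(net, n_runs=5, seed=42)
        for ra, rb in zip(a, b):
            assert ra.Q == rb.Q
            assert np.array_equal(ra.partition.assignment, rb.partition.assignment)

    @pytest.mark.parametrize("c", [0.0, 0.1, 1.0])
    def test_matches_exhaustive_maximum_small_instance(self, c):
        """Best Q over runs equals the exact optimum over all partitions."""
        spec = PlantedSpec(4, 2, np.array([1, 1, 2, 2]), 1.0, 0.2, 0.1, seed=8)
        net = svd_normalize(build_block(generate_planted_layers(spec), c))
        B, two_mu = supra_modularity_matrix(net)
        q_exact = exhaustive_max_quality(B) / two_mu
        q_best = max(r.Q for r in genlouvain(net, n_runs=50, seed=3))
        assert q_best == pytest.approx(q_exact, abs=1e-10)

    def test_zero_coupling_layer_restriction_optimal(self):
        """At c = 0 the per-layer restriction maximizes single-layer modularity."""
        spec = PlantedSpec(5, 2, np.array([[1, 1, 2, 2, 2], [1, 2, 1, 2, 1]]),
                           1.0, 0.1, 0.05, seed=9)
        layers = generate_planted_layers(spec)
        net = build_block(layers, 0.0)
        best = max(genlouvain(net, n_runs=50, seed=7), key=lambda r: r.Q)
        for l, A in enumerate(net.layers):
            single = build_block([A], 0.0)
            B, two_mu = supra_modularity_matrix(single)
            q_opt = exhaustive_max_quality(B) / two_mu
            labels = relabel_first_appearance(best.partition.assignment[l])
            q_restricted = multilayer_modularity(single, Partition(labels[None, :]))
            assert q_restricted == pytest.approx(q_opt, abs=1e-10)


class TestAgreement:
    def test_identical_partitions(self):
        p = Partition(np.array([[1, 1, 2, 2]]))
        (m,) = agreement_per_layer([p, p])
        assert m.values[0, 1] == 1.0
        assert m.values[0, 2] == 0.0
        assert m.values[2, 3] == 1.0

    def test_half_agreement(self):
        p1 = Partition(np.array([[1, 1, 2, 2]]))
        p2 = Partition(np.array([[1, 1, 1, 2]]))
        (m,) = agreement_per_layer([p1, p2])
        assert m.values[0, 2] == 0.5
        assert m.values[2, 3] == 0.5
        assert m.values[0, 1] == 1.0

    def test_single_partition_entries_binary(self):
        p = Partition(np.array([[1, 2, 1]]))
        (m,) = agreement_per_layer([p])
        assert set(np.unique(m.values)) <= {0.0, 1.0}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            agreement_per_layer([])

    def test_proportion_invariants(self, rng):
        parts = [
            Partition(relabel_first_appearance(rng.integers(0, 3, size=12)).reshape(2, 6))
            for _ in range(7)
        ]
        for m in agreement_per_layer(parts):
            assert np.allclose(m.values, m.values.T)
            assert np.all(np.diag(m.values) == 1.0)
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_collapse_is_elementwise_mean(self):
        a = AgreementMatrix(np.eye(3), n_samples=1)
        v = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        b = AgreementMatrix(v, n_samples=1)
        m = collapse_agreement([a, b])
        assert m.values[0, 1] == 0.5
        assert np.allclose(collapse_agreement([b, b]).values, v)


class TestConsensus:
    def test_exact_blocks_converge_immediately(self):
        v = np.zeros((6, 6))
        v[:3, :3] = 1.0
        v[3:, 3:] = 1.0
        part = consensus_partition(AgreementMatrix(v, n_samples=10), n_runs=20, seed=0)
        assert np.array_equal(part.assignment[0], [1, 1, 1, 2, 2, 2])

    def test_noisy_planted_agreement_recovered(self, rng):
        n = 20
        planted = np.array([1] * 10 + [2] * 10)
        v = np.where(planted[:, None] == planted[None, :], 0.9, 0.1)
        noise = rng.normal(0, 0.03, size=(n, n))
        v = np.clip(0.5 * (noise + noise.T) + v, 0, 1)
        np.fill_diagonal(v, 1.0)
        part = consensus_partition(AgreementMatrix(v, n_samples=100), n_runs=50, seed=1)
        assert adjusted_rand(part.assignment[0], planted) == 1.0

    def test_all_ones_single_community(self):
        part = consensus_partition(AgreementMatrix(np.ones((5, 5)), n_samples=1), n_runs=10, seed=2)
        assert part.n_communities == 1

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        v = rng.random((12, 12))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        with pytest.raises(ConsensusError, match="did not stabilize"):
            consensus_partition(
                AgreementMatrix(v, n_samples=1), n_runs=20, seed=3, max_iter=1
            )


class TestModuleFrequency:
    def test_identical_partitions_all_frequency_one(self):
        p = Partition(np.array([[1, 1, 2, 2]]))
        res = module_frequency_across_c({0.0: p, 0.5: p, 1.0: p})
        assert np.all(res.frequencies.max(axis=1) == 1.0)
        assert np.array_equal(res.final, [1, 1, 2, 2])
        assert not res.flagged.any()

    def test_majority_counting(self):
        pa = Partition(np.array([[1, 1, 2, 2]]))
        pb = Partition(np.array([[2, 1, 2, 2]]))  # node 0 defects under this c
        byc = {c: pa for c in np.linspace(0, 0.6, 7)}
        byc.update({c: pb for c in (0.7, 0.8, 0.9)})
        res = module_frequency_across_c(byc)
        i = list(res.labels).index(res.final[0])
        assert res.frequencies[0, i] == pytest.approx(0.7)

    def test_label_alignment_across_permuted_labels(self):
        pa = Partition(np.array([[1, 1, 2, 2]]))
        pb = Partition(np.array([[2, 2, 1, 1]]))  # same split, swapped labels
        res = module_frequency_across_c({0.0: pa, 0.5: pb, 1.0: pa})
        assert np.all(res.frequencies.max(axis=1) == 1.0)

    def test_boundary_frequency_flagged(self):
        pa = Partition(np.array([[1, 1, 2, 2]]))
        pb = Partition(np.array([[2, 1, 2, 2]]))
        res = module_frequency_across_c({0.0: pa, 1.0: pb})
        # node 0 sits at frequency 0.5 with two final modules -> chance level
        assert res.chance_level == pytest.approx(0.5)
        assert res.flagged[0]
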
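import itertools

import numpy as np
import pytest

from hyperphylo.evolution import (
    Alignment,
    PriorConfig,
    jc69_transition_probability,
    log_joint,
    log_likelihood,
    log_prior,
    read_alignment,
    sequence_distances,
)
from hyperphylo.simulate import (
    SimulationConfig,
    random_tree,
    simulate_alignment,
    write_fasta,
)
from hyperphylo.trees import PhyloTree, neighbor_joining, tree_path_distances


def enumeration_loglik(T, Y):
    """Brute-force likelihood: sum over all internal-state assignments."""
    codes = {c: i for i, c in enumerate("ACGT")}
    n = T.n_tips
    n_internal = T.n_nodes - n
    probs = [jc69_transition_probability(t) for t in T.lengths]
    total = 0.0
    for col in range(Y.n_sites):
        site = 0.0
        tip_states = [codes.get(Y.sequences[i][col]) for i in range(n)]
        for assign in itertools.product(range(4), repeat=n_internal):
            state = dict(enumerate(tip_states))
            for k, node in enumerate(range(n, T.n_nodes)):
                state[node] = assign[k]
            p = 0.25
            for e, (a, b) in enumerate(T.edges):
                ps, pd = probs[e]
                if state[a] is None or state[b] is None:
                    continue  # missing tip: marginalised, edge contributes 1
                p *= ps if state[a] == state[b] else pd
            site += p
        total += np.log(site)
    return total


class TestAlignment:
    def test_validation(self):
        with pytest.raises(ValueError):
            Alignment(["a", "b"], ["ACGT", "ACG"])
        with pytest.raises(ValueError):
            Alignment(["a", "a"], ["ACGT", "ACGT"])

    def test_fasta_round_trip(self, tmp_path, small_alignment):
        path = tmp_path / "aln.fasta"
        write_fasta(small_alignment, path)
        back = read_alignment(path)
        assert back.labels == small_alignment.labels
        assert back.sequences == small_alignment.sequences

    def test_site_pattern_compression_preserves_counts(self, small_alignment):
        _, weights = small_alignment.site_patterns()
        assert weights.sum() == small_alignment.n_sites


class TestSequenceDistances:
    def test_identical_sequences(self):
        Y = Alignment(list("abc"), ["ACGT", "ACGT", "ACGT"])
        assert np.all(sequence_distances(Y, "raw_hamming") == 0)

    def test_raw_proportion(self):
        Y = Alignment(list("abc"), ["ACGT", "AGGT", "ACGT"])
        assert sequence_distances(Y, "raw_hamming")[0, 1] == 0.25

    def test_jc_correction_closed_form(self):
        # p = 0.25 -> -(3/4) ln(1 - 1/3)
        Y = Alignment(list("abc"), ["ACGT", "AGGT", "ACGT"])
        expected = -0.75 * np.log(2.0 / 3.0)
        assert sequence_distances(Y, "jc69")[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.304099, abs=1e-6)

    def test_ambiguous_sites_excluded(self):
        Y = Alignment(list("abc"), ["ACGT", "A-GT", "ACGT"])
        # only 3 comparable sites between a and b, none differ
        assert sequence_distances(Y, "raw_hamming")[0, 1] == 0.0

    def test_saturation_capped(self):
        Y = Alignment(list("abc"), ["AAAA", "CCCC", "GGGG"])
        assert sequence_distances(Y, "jc69")[0, 1] == 10.0

    def test_no_comparable_sites_names_pair(self):
        Y = Alignment(list("abc"), ["A---", "-CGT", "ACGT"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            sequence_distances(Y, "raw_hamming")

    def test_correction_inverts_simulated_divergence(self):
        """JC69 correction recovers true path distances from long alignments."""
        T = random_tree(SimulationConfig(n_taxa=3, seed=5))
        T.lengths = np.array([0.10, 0.15, 0.05])
        Y = simulate_alignment(T, 100_000, seed=9)
        D = sequence_distances(Y, "jc69")
        np.testing.assert_allclose(D, tree_path_distances(T), atol=0.02)


class TestTransitionProbability:
    def test_zero_branch(self):
        assert jc69_transition_probability(0.0) == (1.0, 0.0)

    def test_stationary_limit(self):
        ps, pd = jc69_transition_probability(1e4)
        assert ps == pytest.approx(0.25, abs=1e-12)
        assert pd == pytest.approx(0.25, abs=1e-12)

    def test_closed_form_and_normalisation(self):
        ps, pd = jc69_transition_probability(0.75)
        assert ps == pytest.approx(0.25 + 0.75 * np.exp(-1), abs=1e-12)
        assert ps + 3 * pd == pytest.approx(1.0, abs=1e-12)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            jc69_transition_probability(-0.1)


class TestLogLikelihood:
    def test_single_site_pair_closed_form(self):
        # three-taxon star: two tips identical at distance 0.75 total,
        # third attached with zero length so it only contributes p_same(0)=1
        T = PhyloTree(list("abc"), np.array([[0, 3], [1, 3], [2, 3]]), np.array([0.75, 0.0, 0.0]))
        Y = Alignment(list("abc"), ["A", "A", "A"])
        ps, _ = jc69_transition_probability(0.75)
        assert log_likelihood(T, Y) == pytest.approx(np.log(0.25 * ps), abs=1e-12)
        assert np.log(0.25 * ps) == pytest.approx(np.log(0.131478), abs=1e-5)

    @pytest.mark.parametrize("n,seed", [(4, 1), (5, 7), (5, 13)])
    def test_pruning_matches_enumeration(self, n, seed):
        T = random_tree(SimulationConfig(n_taxa=n, seed=seed))
        Y = simulate_alignment(T, 10, seed=seed + 1)
        assert log_likelihood(T, Y) == pytest.approx(enumeration_loglik(T, Y), abs=1e-10)

    def test_missing_data_marginalised(self):
        T = random_tree(SimulationConfig(n_taxa=4, seed=3))
        Y = simulate_alignment(T, 8, seed=4)
        gapped = Alignment(Y.labels, [s[:4] + "-N?-" for s in Y.sequences])
        truncated = Alignment(Y.labels, [s[:4] for s in Y.sequences])
        assert log_likelihood(T, gapped) == pytest.approx(
            log_likelihood(T, truncated), abs=1e-10
        )
        assert log_likelihood(T, gapped) == pytest.approx(
            enumeration_loglik(T, gapped), abs=1e-10
        )

    def test_invariant_to_taxon_order_and_traversal_root(self):
        T = random_tree(SimulationConfig(n_taxa=5, seed=21))
        Y = simulate_alignment(T, 20, seed=22)
        ref = log_likelihood(T, Y)
        perm = [3, 1, 4, 0, 2]
        Yp = Alignment([Y.labels[i] for i in perm], [Y.sequences[i] for i in perm])
        assert log_likelihood(T, Yp) == pytest.approx(ref, abs=1e-10)
        from hyperphylo.evolution import _pruning_loglik

        partials, weights = Y.site_patterns()
        for root in range(T.n_tips, T.n_nodes):
            assert _pruning_loglik(T, partials, weights, root) == pytest.approx(ref, abs=1e-10)

    def test_label_mismatch_rejected(self, small_tree, small_alignment):
        Y = Alignment(["x"] + small_alignment.labels[1:], small_alignment.sequences)
        with pytest.raises(ValueError):
            log_likelihood(small_tree, Y)


class TestPrior:
    def test_star_tree_closed_form(self):
        T = neighbor_joining(np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]]), list("ABC"))
        expected = np.log(0.1) - 0.3 + np.log(2.0) - 2 * np.log(3.0)
        assert expected == pytest.approx(-4.1066625, abs=1e-6)
        assert log_prior(T) == pytest.approx(expected, abs=1e-9)

    def test_total_length_marginal_is_exponential(self):
        """With shape 1 the total-length prior is Exponential(rate)."""
        T1 = neighbor_joining(np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]]), list("ABC"))
        T2 = neighbor_joining(np.array([[0, 4, 4], [4, 0, 4], [4, 4, 0.0]]), list("ABC"))
        # same proportions: difference must be the Exponential log ratio
        # plus the Jacobian term -(K-1) log(TL2/TL1)
        diff = log_prior(T2) - log_prior(T1)
        assert diff == pytest.approx(-0.1 * 3.0 - 2 * np.log(2.0), abs=1e-12)

    def test_zero_total_length(self):
        T = random_tree(SimulationConfig(n_taxa=4, seed=0))
        T.lengths = np.zeros_like(T.lengths)
        assert log_prior(T) == -np.inf

    def test_embedding_normal_mode(self):
        prior = PriorConfig(mode="embedding_normal")
        X = np.zeros((4, 3))
        expected = 12 * np.log(1.0 / np.sqrt(2 * np.pi))
        T = random_tree(SimulationConfig(n_taxa=4, seed=0))
        assert log_prior(T, prior, X) == pytest.approx(expected, abs=1e-12)

    def test_density_integrates_to_one(self):
        """The branch-length density matches its generative construction.

        Draw branch lengths by the construction itself (TL ~ Gamma, split by
        a Dirichlet); the probability of landing in a box must match the
        density integrated over the box, within Monte-Carlo error.
        """
        rng = np.random.default_rng(31)
        N = 200_000
        TL = rng.gamma(1.0, 1.0 / 0.1, size=N)
        p = rng.dirichlet([1.0, 1.0, 1.0], size=N)
        lengths = TL[:, None] * p
        lo, hi = np.array([2.5, 2.5, 3.5]), np.array([3.5, 3.5, 4.5])
        inside = np.all((lengths >= lo) & (lengths < hi), axis=1)
        p_emp = inside.mean()
        se = np.sqrt(p_emp * (1 - p_emp) / N)

        edges = np.array([[0, 3], [1, 3], [2, 3]])

        def density(l):
            T = PhyloTree(list("abc"), edges, np.asarray(l))
            return np.exp(log_prior(T))

        # average the density over the box by quadrature-by-sampling
        U = rng.uniform(lo, hi, size=(20_000, 3))
        p_model = np.mean([density(u) for u in U]) * np.prod(hi - lo)
        assert abs(p_emp - p_model) < 3 * se + 0.05 * p_model

    def test_negative_branch_rejected(self):
        T = random_tree(SimulationConfig(n_taxa=4, seed=0))
        T = PhyloTree(T.labels, T.edges, T.lengths)
        T.lengths[0] = -0.5
        with pytest.raises(ValueError):
            log_prior(T)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PriorConfig(gamma_shape=0.0)
        with pytest.raises(ValueError):
            PriorConfig(mode="flat")


class TestLogJoint:
    def test_additivity(self, small_tree, small_alignment):
        assert log_joint(small_tree, small_alignment) == pytest.approx(
            log_likelihood(small_tree, small_alignment) + log_prior(small_tree), abs=1e-12
        )

    def test_composition_of_oracles(self):
        T = random_tree(SimulationConfig(n_taxa=5, seed=7))
        Y = simulate_alignment(T, 10, seed=2)
        expected = enumeration_loglik(T, Y) + log_prior(T)
        assert log_joint(T, Y) == pytest.approx(expected, abs=1e-10)
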
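import numpy as np
import pytest

import codonchannel as cc
from codonchannel.matrix_io import MatrixValidationError


class TestSymmetricChannel:
    @pytest.mark.parametrize(
        "K, noise, expected",
        [
            (2, 0.11, 1 - (-(0.11 * np.log2(0.11) + 0.89 * np.log2(0.89)))),
            (61, 0.0, np.log2(61)),
            (4, 0.75, 0.0),
        ],
    )
    def test_known_capacity(self, K, noise, expected):
        channel, cap = cc.make_symmetric_channel(K, noise)
        assert cap == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(channel.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_noise_out_of_range(self):
        with pytest.raises(ValueError, match="noise"):
            cc.make_symmetric_channel(4, 0.75 + 1e-9)
        with pytest.raises(ValueError, match="noise"):
            cc.make_symmetric_channel(4, -0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_ab_matches_known_capacity_random_sweep(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 62))
        noise = float(rng.uniform(0, (K - 1) / K * 0.95))
        channel, cap = cc.make_symmetric_channel(K, noise)
        res = cc.arimoto_blahut(channel, tol=1e-12)
        assert res.capacity == pytest.approx(cap, abs=1e-6)


class TestWeaklySymmetricChannel:
    def test_rows_are_shifts_and_columns_sum_equally(self):
        channel, _ = cc.make_weakly_symmetric_channel(9, seed=5)
        M = channel.probs
        for i in range(9):
            np.testing.assert_allclose(M[i], np.roll(M[0], i))
        np.testing.assert_allclose(M.sum(axis=0), M.sum(axis=0)[0], atol=1e-12)


class TestReversibleCodonChannel:
    def test_validates_and_is_deterministic(self, bio61):
        a = cc.make_reversible_codon_channel(bio61, roughness=0.5, seed=4)
        b = cc.make_reversible_codon_channel(bio61, roughness=0.5, seed=4)
        assert a.probs.tobytes() == b.probs.tobytes()
        c = cc.make_reversible_codon_channel(bio61, roughness=0.5, seed=5)
        assert a.probs.tobytes() != c.probs.tobytes()

    def test_uniform_stationary_zero_roughness_is_doubly_stochastic(self, code):
        uniform = cc.Distribution.from_values(code.sense_order, np.ones(61))
        P = cc.make_reversible_codon_channel(uniform, roughness=0.0, seed=0)
        np.testing.assert_allclose(P.probs.sum(axis=0), 1.0, atol=1e-12)
        res = cc.arimoto_blahut(P, tol=1e-10)
        np.testing.assert_allclose(res.optimal_input.probs, 1 / 61, atol=1e-4)

    def test_detailed_balance_of_embedded_chain(self, bio61):
        """pi_x Z_x is reversible for the constructed kernel."""
        P = cc.make_reversible_codon_channel(bio61, roughness=0.5, seed=4)
        # recover Z_x: p(y|x) = S_xy pi_y / Z_x  =>  flows pi'_x p(y|x) symmetric
        # with pi'_x ∝ pi_x Z_x; solve for pi' as the stationary left eigenvector
        w, V = np.linalg.eig(P.probs.T)
        pi = np.real(V[:, np.argmax(np.real(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        flow = pi[:, None] * P.probs
        np.testing.assert_allclose(flow, flow.T, atol=1e-12)

    def test_degenerate_stationary_rejected(self, code):
        values = np.ones(61)
        values[0] = 0.0
        with pytest.raises(MatrixValidationError):
            bad = cc.Distribution.from_values(code.sense_order, values)
            cc.make_reversible_codon_channel(bad, seed=0)


class TestSampleCountMatrix:
    def test_single_draw_has_one_nonzero_cell(self, bio61):
        P = cc.make_reversible_codon_channel(bio61, roughness=0.5, seed=1)
        counts = cc.sample_count_matrix(bio61, P, n=1, seed=2)
        assert counts.total == 1
        assert int((counts.counts > 0).sum()) == 1

    def test_permutation_channel_concentrates_on_permutation_cells(self):
        K = 5
        labels = tuple(f"s{i}" for i in range(K))
        perm = np.roll(np.eye(K), 1, axis=1)
        P = cc.ChannelMatrix(labels, perm)
        p = cc.Distribution.from_values(labels, np.ones(K))
        counts = cc.sample_count_matrix(p, P, n=1000, seed=3)
        assert counts.counts[perm == 0].sum() == 0

    def test_seed_reproducibility(self, bio61):
        P = cc.make_reversible_codon_channel(bio61, roughness=0.5, seed=1)
        a = cc.sample_count_matrix(bio61, P, n=1000, seed=7)
        b = cc.sample_count_matrix(bio61, P, n=1000, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestFixtures:
    def test_verbatim_entries(self):
        bio, opt = cc.fixtures(renormalize=False)
        assert bio["CTG"] == pytest.approx(0.0373, abs=1e-12)
        assert opt["TGG"] == pytest.approx(0.0439, abs=1e-12)

    def test_shapes_and_stop_handling(self, code):
        bio, opt = cc.fixtures()
        assert len(bio) == 64
        assert len(opt) == 61
        assert not set(opt.labels) & code.stop_set
        assert bio.probs.sum() == pytest.approx(1.0)
        assert opt.probs.sum() == pytest.approx(1.0)

    def test_biological_stop_mass_is_tiny(self, code):
        bio = cc.load_biological_codon_frequencies(renormalize=False)
        stop_mass = sum(bio[c] for c in code.stop_set)
        assert stop_mass == pytest.approx(0.0007, abs=1e-12)
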
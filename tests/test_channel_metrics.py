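import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonchannel as cc
from codonchannel.matrix_io import MatrixFormatError


def _binary_entropy(p):
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def _chan(rows, labels=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or tuple(f"s{i}" for i in range(rows.shape[0]))
    return cc.ChannelMatrix(tuple(labels), rows)


def _dist(values, labels=None):
    labels = labels or tuple(f"s{i}" for i in range(len(values)))
    return cc.Distribution.from_values(tuple(labels), values)


class TestOutputDistribution:
    def test_identity_channel_passes_input_through(self):
        p = _dist([0.2, 0.3, 0.5])
        P = _chan(np.eye(3))
        np.testing.assert_allclose(cc.output_distribution(p, P).probs, p.probs)

    def test_constant_rows_ignore_input(self):
        q = [0.1, 0.6, 0.3]
        P = _chan([q, q, q])
        for values in ([1, 0, 0], [0.2, 0.3, 0.5]):
            np.testing.assert_allclose(
                cc.output_distribution(_dist(values), P).probs, q
            )

    def test_two_state_symmetric_channel(self):
        P = _chan([[0.9, 0.1], [0.1, 0.9]])
        p_y = cc.output_distribution(_dist([0.75, 0.25]), P)
        np.testing.assert_allclose(p_y.probs, [0.7, 0.3])

    def test_label_mismatch_raises(self):
        P = _chan(np.eye(2), labels=("ATG", "TGG"))
        with pytest.raises(MatrixFormatError, match="GCC"):
            cc.output_distribution(_dist([0.5, 0.5], labels=("ATG", "GCC")), P)


class TestConditionalEntropy:
    def test_identity_channel_is_noiseless(self):
        assert cc.conditional_entropy(_dist([0.3, 0.7]), _chan(np.eye(2))) == 0.0

    def test_symmetric_flip_gives_binary_entropy_for_any_input(self):
        P = _chan([[0.89, 0.11], [0.11, 0.89]])
        expected = _binary_entropy(0.11)
        for values in ([0.5, 0.5], [0.9, 0.1]):
            assert cc.conditional_entropy(_dist(values), P) == pytest.approx(expected)

    def test_uniform_rows_give_log_k(self):
        K = 7
        P = _chan(np.full((K, K), 1.0 / K))
        p = _dist(np.random.default_rng(0).dirichlet(np.ones(K)))
        assert cc.conditional_entropy(p, P) == pytest.approx(np.log2(K))


class TestMutualInformation:
    def test_noiseless_uniform_61(self, code):
        P = cc.ChannelMatrix(code.sense_order, np.eye(61))
        p = cc.Distribution.from_values(code.sense_order, np.ones(61))
        ev = cc.mutual_information(p, P)
        assert ev.mutual_information == pytest.approx(np.log2(61))
        assert ev.conditional_entropy == 0.0

    def test_constant_rows_carry_no_information(self):
        q = [0.25, 0.25, 0.5]
        ev = cc.mutual_information(_dist([0.6, 0.3, 0.1]), _chan([q, q, q]))
        assert ev.mutual_information == pytest.approx(0.0, abs=1e-12)

    def test_bsc_uniform_input(self, bsc11):
        channel, closed_form = bsc11
        p = _dist([0.5, 0.5], labels=channel.labels)
        ev = cc.mutual_information(p, channel)
        assert ev.mutual_information == pytest.approx(1 - _binary_entropy(0.11))
        assert ev.mutual_information == pytest.approx(closed_form)

    def test_decomposition_consistency(self):
        rng = np.random.default_rng(4)
        P = _chan(rng.dirichlet(np.ones(5), size=5))
        p = _dist(rng.dirichlet(np.ones(5)))
        ev = cc.mutual_information(p, P)
        assert ev.mutual_information == pytest.approx(
            ev.output_entropy - ev.conditional_entropy, abs=1e-12
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 9))
        M = rng.dirichlet(np.ones(K), size=K)
        p = rng.dirichlet(np.ones(K))
        labels = tuple(f"s{i}" for i in range(K))
        P = cc.ChannelMatrix(labels, M)
        d = cc.Distribution.from_values(labels, p)
        mi = cc.mutual_information(d, P).mutual_information
        assert -1e-10 <= mi <= min(cc.entropy(d), np.log2(K)) + 1e-10
        perm = rng.permutation(K)
        P2 = cc.ChannelMatrix(labels, M[np.ix_(perm, perm)])
        d2 = cc.Distribution.from_values(labels, p[perm])
        assert cc.mutual_information(d2, P2).mutual_information == pytest.approx(mi, abs=1e-10)


class TestKLDivergence:
    def test_zero_on_identical(self):
        p = _dist([0.4, 0.6])
        assert cc.kl_divergence(p, p) == 0.0

    def test_hand_computed_value(self):
        p, q = _dist([0.5, 0.5]), _dist([0.25, 0.75])
        expected = 0.5 * np.log2(2) + 0.5 * np.log2(2 / 3)
        assert cc.kl_divergence(p, q) == pytest.approx(expected)
        assert cc.kl_divergence(p, q) == pytest.approx(0.2075, abs=5e-5)

    def test_infinite_when_support_violated_with_warning(self):
        p = _dist([0.5, 0.5])
        q = _dist([1.0, 0.0])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            val = cc.kl_divergence(p, q)
        assert np.isinf(val)
        assert any("zero mass" in str(w.message) for w in caught)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_nonnegative_on_random_simplex_pairs(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 30))
        p = _dist(rng.dirichlet(np.ones(K)))
        q = _dist(rng.dirichlet(np.ones(K)))
        assert cc.kl_divergence(p, q) >= 0.0

    def test_fixture_tables_both_directions(self, bio61, opt61):
        forward = cc.kl_divergence(bio61, opt61)
        reverse = cc.kl_divergence(opt61, bio61)
        assert forward > 0 and reverse > 0
        assert forward != pytest.approx(reverse, abs=1e-3)  # KL is asymmetric here
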
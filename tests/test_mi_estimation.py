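"""MI bounds and the exact mixture oracle, cross-checked by quadrature."""

import numpy as np
import pytest

from dib.encoders import EncoderChannel, GaussianLatent, kl_to_prior_bits
from dib.mi_estimation import (
    MIEstimate,
    channel_mi_bounds,
    exact_discrete_channel_mi,
    predictive_info,
)

BINARY_PMF = (np.array([0.0, 1.0]), np.array([0.5, 0.5]))


class _TableChannel:
    """Stub channel with prescribed per-value encodings (for oracle tests)."""

    def __init__(self, values, means, scales):
        self.values = np.asarray(values, float)
        self.means = np.atleast_2d(np.asarray(means, float))
        self.scales = np.atleast_2d(np.asarray(scales, float))

    def encode(self, values):
        idx = np.array([int(np.argmin(np.abs(self.values - v))) for v in np.ravel(values)])
        return GaussianLatent(self.means[idx], self.scales[idx])


def _well_separated():
    return _TableChannel([0.0, 1.0], [[10.0], [-10.0]], [[0.01], [0.01]])


def _mixture_mi_quadrature(mu0, mu1, sigma):
    """Independent 1-D oracle: I(U;X) for a balanced two-Gaussian mixture."""
    from scipy.integrate import quad
    from scipy.stats import norm

    def integrand(u, mu):
        p = norm.pdf(u, mu, sigma)
        mix = 0.5 * norm.pdf(u, mu0, sigma) + 0.5 * norm.pdf(u, mu1, sigma)
        return p * (np.log2(np.maximum(p, 1e-300)) - np.log2(np.maximum(mix, 1e-300)))

    lo, hi = min(mu0, mu1) - 12 * sigma, max(mu0, mu1) + 12 * sigma
    total = 0.0
    for mu in (mu0, mu1):
        val, _ = quad(integrand, lo, hi, args=(mu,), limit=200)
        total += 0.5 * val
    return total


class TestChannelMIBounds:
    def test_uninformative_channel_brackets_zero(self):
        ch = _TableChannel([0.0, 1.0], [[0.3], [0.3]], [[1.2], [1.2]])
        est = channel_mi_bounds(ch, BINARY_PMF, K=256, n_batches=8, seed=0)
        assert abs(est.lower_bits) < 3 * est.std_error + 1e-6
        assert abs(est.upper_bits) < 3 * est.std_error + 1e-6

    def test_well_separated_binary_is_one_bit(self):
        est = channel_mi_bounds(_well_separated(), BINARY_PMF, K=4096, n_batches=8, seed=0)
        assert est.lower_bits == pytest.approx(1.0, abs=0.01)
        assert est.upper_bits == pytest.approx(1.0, abs=0.01)

    def test_lower_bound_capped_by_log2_k(self):
        est = channel_mi_bounds(_well_separated(), BINARY_PMF, K=2, n_batches=16, seed=1)
        assert est.lower_bits <= np.log2(2) + 1e-9

    def test_interval_shrinks_with_k(self):
        ch = _TableChannel([0.0, 1.0], [[0.6], [-0.6]], [[1.0], [1.0]])
        wide = channel_mi_bounds(ch, BINARY_PMF, K=2**8, n_batches=6, seed=2)
        narrow = channel_mi_bounds(ch, BINARY_PMF, K=2**14, n_batches=6, seed=2)
        assert narrow.gap_bits < wide.gap_bits

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            channel_mi_bounds(_well_separated(), BINARY_PMF, K=1)

    def test_continuous_path_agrees_with_discrete_path(self):
        """The generic K x K route and the enumerable-support route agree."""
        ch = _TableChannel([0.0, 1.0], [[0.8], [-0.8]], [[1.0], [1.0]])
        sample = np.tile([0.0, 1.0], 512)
        disc = channel_mi_bounds(ch, BINARY_PMF, K=1024, n_batches=8, seed=3)
        cont = channel_mi_bounds(ch, sample, K=1024, n_batches=8, seed=3)
        tol = 3 * (disc.std_error + cont.std_error)
        assert disc.lower_bits == pytest.approx(cont.lower_bits, abs=tol)
        assert disc.upper_bits == pytest.approx(cont.upper_bits, abs=tol)


class TestExactDiscreteMI:
    def test_identical_encoders_give_zero(self):
        ch = _TableChannel([0.0, 1.0], [[0.5], [0.5]], [[0.7], [0.7]])
        mi, se = exact_discrete_channel_mi(ch, BINARY_PMF, n_mc=20_000, seed=0)
        assert abs(mi) < 3 * se + 1e-9

    def test_well_separated_is_one_bit(self):
        mi, se = exact_discrete_channel_mi(_well_separated(), BINARY_PMF, n_mc=100_000, seed=0)
        assert mi == pytest.approx(1.0, abs=max(0.005, 3 * se))

    def test_overlapping_encoders_match_quadrature(self):
        ch = _TableChannel([0.0, 1.0], [[0.5], [-0.5]], [[1.0], [1.0]])
        mi, se = exact_discrete_channel_mi(ch, BINARY_PMF, n_mc=200_000, seed=0)
        oracle = _mixture_mi_quadrature(0.5, -0.5, 1.0)
        assert 0.0 < mi < 1.0
        assert mi == pytest.approx(oracle, abs=3 * se)

    def test_support_guard(self):
        vals = np.arange(65.0)
        ch = _TableChannel(vals, np.zeros((65, 1)), np.ones((65, 1)))
        with pytest.raises(ValueError):
            exact_discrete_channel_mi(ch, (vals, np.full(65, 1 / 65)), n_mc=10)


class TestBoundOrdering:
    def test_bounds_bracket_the_oracle_on_random_channels(self):
        """contrastive lower <= exact mixture MI <= leave-one-out upper."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            v = np.arange(4.0)
            means = rng.normal(0, 2, size=(4, 2))
            scales = np.exp(rng.normal(-0.5, 0.5, size=(4, 2)))
            probs = rng.dirichlet(np.ones(4))
            ch = _TableChannel(v, means, scales)
            est = channel_mi_bounds(ch, (v, probs), K=512, n_batches=8, seed=trial)
            mi, se = exact_discrete_channel_mi(ch, (v, probs), n_mc=40_000, seed=trial)
            slack = 3 * (est.std_error + se)
            assert est.lower_bits <= mi + slack
            assert mi <= est.upper_bits + slack

    def test_training_kl_upper_bounds_the_information(self):
        """The variational (KL) cost always dominates the true channel MI."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            ch = EncoderChannel("f", rng, latent_dim=3, hidden=(16,))
            for p in ch.parameters:  # random non-trivial weights
                p.data[...] = rng.normal(0, 0.7, size=p.data.shape)
            values, probs = BINARY_PMF
            kl = float((kl_to_prior_bits(ch.encode(values)) * probs).sum())
            mi, se = exact_discrete_channel_mi(ch, BINARY_PMF, n_mc=30_000, seed=trial)
            assert kl >= mi - 3 * se


class _MarginalModel:
    def __init__(self, marginal):
        self.logp = np.log(marginal)

    def predict_logprob(self, features, rng, n_samples=1):
        return np.tile(self.logp, (len(features), 1))


class TestPredictiveInfo:
    def _dataset(self):
        from dib.dib_objective import TabularDataset

        return TabularDataset(
            features=np.array([[0.0], [0.0], [1.0], [1.0]]),
            labels=np.array([0, 0, 0, 1]),
            feature_ids=["x1"],
        )

    def test_marginal_decoder_gives_zero_bits(self):
        ds = self._dataset()
        info, acc = predictive_info(_MarginalModel(ds.label_marginal()), ds)
        assert info == pytest.approx(0.0, abs=1e-9)
        assert acc == pytest.approx(0.75)

    def test_never_exceeds_label_entropy(self):
        class Perfect:
            def predict_logprob(self, features, rng, n_samples=1):
                out = np.full((len(features), 2), -745.0)
                labels = np.array([0, 0, 0, 1])
                out[np.arange(4), labels] = 0.0
                return out

        ds = self._dataset()
        info, acc = predictive_info(Perfect(), ds)
        assert info == pytest.approx(ds.label_entropy_bits(), abs=1e-6)
        assert info <= ds.label_entropy_bits() + 1e-9
        assert acc == 1.0

    def test_single_class_rejected(self):
        from dib.dib_objective import TabularDataset

        ds = TabularDataset(
            features=np.zeros((4, 1)), labels=np.ones(4, dtype=int), feature_ids=["x1"]
        )
        with pytest.raises(ValueError):
            predictive_info(_MarginalModel(np.array([0.0, 1.0])), ds)
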
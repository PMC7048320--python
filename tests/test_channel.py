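"""Noisy-channel transmission, ML decoding, and Monte-Carlo estimation."""


import numpy as np
import pytest
from scipy import stats

from mixedcodes import (
    ChannelConfig,
    CodeSpec,
    StimulusSpace,
    build_codebook,
    make_transform,
    ml_decode,
    perturb_input,
    simulate,
    transmit,
)
from mixedcodes.errors import InvalidConfigurationError


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


class TestTransmit:
    def test_gaussian_moments(self, rng):
        config = ChannelConfig(noise="gaussian", sigma2=2.5)
        word = np.zeros((10_000, 4))
        noisy = transmit(word, config, rng)
        assert noisy.mean() == pytest.approx(0.0, abs=0.05)
        assert noisy.var() == pytest.approx(2.5, rel=0.05)

    def test_tiny_noise_preserves_codeword(self, rng):
        config = ChannelConfig(noise="gaussian", sigma2=1e-18)
        word = np.array([1.0, 0.0, 1.0])
        np.testing.assert_allclose(transmit(word, config, rng), word, atol=1e-6)

    def test_reproducible_from_seed(self):
        config = ChannelConfig(noise="gaussian", sigma2=1.0)
        a = transmit(np.ones(5), config, np.random.default_rng(3))
        b = transmit(np.ones(5), config, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_poisson_requires_nonnegative_rates(self, rng):
        with pytest.raises(InvalidConfigurationError):
            transmit(np.array([-0.5, 1.0]), ChannelConfig(noise="poisson"), rng)

    def test_poisson_zero_rate_emits_zero(self, rng):
        noisy = transmit(np.zeros((100, 3)), ChannelConfig(noise="poisson"), rng)
        assert (noisy == 0).all()


class TestPerturbInput:
    def test_zero_probability_is_identity(self, rng):
        space = StimulusSpace(3, 5)
        s = space.stimuli()[:20]
        config = ChannelConfig(input_noise="local", p_shift=0.0)
        np.testing.assert_array_equal(perturb_input(s, space, config, rng), s)

    def test_certain_shift_moves_to_adjacent_value(self, rng):
        space = StimulusSpace(1, 5)
        config = ChannelConfig(input_noise="local", p_shift=1.0)
        s = np.full((2000, 1), 2)
        out = perturb_input(s, space, config, rng)
        assert set(np.unique(out)) == {1, 3}

    def test_edges_shift_inward(self, rng):
        space = StimulusSpace(1, 4)
        config = ChannelConfig(input_noise="local", p_shift=1.0)
        assert (perturb_input(np.zeros((500, 1), int), space, config, rng) == 1).all()
        assert (perturb_input(np.full((500, 1), 3), space, config, rng) == 2).all()

    def test_empirical_shift_frequency(self, rng):
        space = StimulusSpace(2, 9)
        config = ChannelConfig(input_noise="local", p_shift=0.3)
        s = np.full((20_000, 2), 4)
        out = perturb_input(s, space, config, rng)
        freq = (out != s).mean()
        assert freq == pytest.approx(0.3, abs=0.02)


class TestMLDecode:
    def test_noiseless_decodes_exactly(self):
        cb = build_codebook(StimulusSpace(2, 3), CodeSpec(2))
        config = ChannelConfig(noise="gaussian", sigma2=1.0)
        idx, ties = ml_decode(cb.words.astype(float), cb.words.astype(float), config)
        np.testing.assert_array_equal(idx, np.arange(9))
        assert not ties.any()

    def test_midway_tie_goes_to_lowest_index(self):
        words = np.array([[1.0, 0.0], [0.0, 1.0]])
        midpoint = np.array([[0.5, 0.5]])
        config = ChannelConfig(noise="gaussian", sigma2=1.0)
        idx, ties = ml_decode(midpoint, words, config)
        assert idx[0] == 0 and ties[0]

    def test_agrees_with_exhaustive_gaussian_likelihood(self):
        """Nearest-codeword decoding equals argmax of the normal density."""
        rng = np.random.default_rng(12)
        cb = build_codebook(StimulusSpace(2, 3), CodeSpec(1))
        words = cb.words.astype(float)
        config = ChannelConfig(noise="gaussian", sigma2=0.5)
        r = words[rng.integers(0, 9, 200)] + rng.normal(0, np.sqrt(0.5), (200, 6))
        idx, _ = ml_decode(r, words, config)
        loglik = np.stack(
            [stats.norm.logpdf(r, loc=w, scale=np.sqrt(0.5)).sum(axis=1) for w in words],
            axis=1,
        )
        np.testing.assert_array_equal(idx, loglik.argmax(axis=1))

    def test_agrees_with_exhaustive_poisson_likelihood(self):
        rng = np.random.default_rng(13)
        cb = build_codebook(StimulusSpace(2, 3), CodeSpec(2))
        lam = 4.0 * cb.words.astype(float)
        config = ChannelConfig(noise="poisson")
        r = rng.poisson(lam[rng.integers(0, 9, 300)]).astype(float)
        idx, _ = ml_decode(r, lam, config)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.stack(
                [stats.poisson.logpmf(r, mu=l).sum(axis=1) for l in lam], axis=1
            )
        np.testing.assert_array_equal(idx, np.nan_to_num(ll, neginf=-np.inf).argmax(axis=1))


class TestSimulate:
    def test_huge_snr_is_error_free(self):
        res = simulate(
            StimulusSpace(3, 5), CodeSpec(2), ChannelConfig(), 500, seed=1, snr=1e8
        )
        assert res.pe == 0.0 and res.mse == 0.0

    def test_confusion_accounting(self):
        res = simulate(
            StimulusSpace(2, 3), CodeSpec(1), ChannelConfig(), 3000, seed=2, snr=5.0
        )
        assert res.confusion.sum() == 3000
        assert res.pe == pytest.approx(1 - np.trace(res.confusion) / 3000)
        assert 0.0 <= res.pe <= 1.0

    def test_reproducible_from_seed(self):
        args = (StimulusSpace(2, 3), CodeSpec(2), ChannelConfig(), 400)
        a = simulate(*args, seed=7, snr=8.0)
        b = simulate(*args, seed=7, snr=8.0)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_order_ranking_at_intermediate_snr(self):
        """Higher-order codes make fewer errors at matched SNR."""
        space = StimulusSpace(3, 5)
        pes = {}
        for O in (1, 2, 3):
            res = simulate(space, CodeSpec(O), ChannelConfig(), 3000, seed=4, snr=15.0)
            pes[O] = res.pe
        assert pes[3] < pes[2] < pes[1]

    def test_transform_style_does_not_change_pe(self):
        """At fixed V and sigma^2, PE is invariant to the transform style."""
        space = StimulusSpace(3, 3)
        spec = CodeSpec(2)
        cb = build_codebook(space, spec)
        from mixedcodes import empirical_representation_energy

        p = empirical_representation_energy(cb, spec.energy_variant)
        V = 12.0
        pes = []
        for style, n_out in [
            ("identity_scaled", cb.n_units),
            ("random_rotation", cb.n_units),
            ("random_embedding", 2 * cb.n_units),
        ]:
            t = make_transform(cb.n_units, n_out, V, p, style=style, seed=21)
            res = simulate(
                space, spec, ChannelConfig(), 4000, seed=5, snr=10.0,
                target_energy=V, transform=t,
            )
            pes.append(res.pe)
        se = np.sqrt(max(p_ * (1 - p_) for p_ in pes) / 4000)
        assert max(pes) - min(pes) < 3 * se

    def test_local_input_noise_insensitive_to_order(self):
        """With only local input noise, all orders fail at the same rate."""
        space = StimulusSpace(3, 5)
        config = ChannelConfig(input_noise="local", p_shift=0.2)
        pes = [
            simulate(space, CodeSpec(O), config, 4000, seed=6, snr=1e7).pe
            for O in (1, 2, 3)
        ]
        se = np.sqrt(max(pes) * (1 - min(pes)) / 4000)
        assert max(pes) - min(pes) < 3 * se

    def test_per_stimulus_error_uniformity(self):
        """Stimulus symmetry: per-stimulus error rates are homogeneous."""
        space = StimulusSpace(2, 3)
        res = simulate(space, CodeSpec(1), ChannelConfig(), 30_000, seed=8, snr=6.0)
        presented = res.confusion.sum(axis=1)
        errors = presented - np.diag(res.confusion)
        rate = errors.sum() / presented.sum()
        _, p_value = stats.chisquare(errors, f_exp=presented * rate)
        assert p_value > 0.01

    def test_mse_lower_bound(self):
        """MSE is at least PE times the smallest nonzero squared distance."""
        res = simulate(
            StimulusSpace(3, 5), CodeSpec(2), ChannelConfig(), 4000, seed=9, snr=20.0
        )
        assert res.mse >= res.pe - 1e-12  # min nonzero squared feature error is 1

    def test_bitflip_pipelines_run(self):
        space = StimulusSpace(3, 2)
        for pipeline in ("direct", "nearest"):
            config = ChannelConfig(
                input_noise="bitflip", p_flip=0.05, bitflip_pipeline=pipeline
            )
            res = simulate(space, CodeSpec(2), config, 2000, seed=10, snr=25.0)
            assert 0.0 <= res.pe <= 1.0

    def test_squared_error_cdf_is_valid(self):
        res = simulate(
            StimulusSpace(2, 4), CodeSpec(2), ChannelConfig(), 2000, seed=11, snr=6.0
        )
        vals, cdf = res.squared_error_distribution()
        assert (np.diff(vals) > 0).all()
        assert cdf[-1] == pytest.approx(1.0)
        assert ((cdf >= -1e-12) & (cdf <= 1 + 1e-12)).all()
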
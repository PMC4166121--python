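"""Synthetic TCSPC generation: wraparound, IRF convolution, Poisson sampling."""

import numpy as np
import pytest

from flimbind.decay import DecayModel
from flimbind.tcspc import (
    AcquisitionConfig,
    IRFSpec,
    convolve_irf,
    generate_dataset,
    irf_expectation,
    periodic_decay_expectation,
    sample_counts,
)


def brute_force_circular_conv(x, kernel):
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += x[j] * kernel[(i - j) % n]
    return out


class TestPeriodicExpectation:
    def test_fast_lifetime_matches_plain_exponential(self, small_acq):
        m = DecayModel.from_pairs([(1.0, 0.1)])
        expected = periodic_decay_expectation(m, small_acq)
        t = small_acq.channel_times_ns
        plain = np.exp(-t / 0.1)
        signal = small_acq.total_counts * (1 - small_acq.background_fraction)
        plain = plain / plain.sum() * signal
        plain += small_acq.total_counts * small_acq.background_fraction / len(t)
        # wraparound factor 1/(1 - e^-500) is 1 to double precision
        assert np.allclose(expected, plain, rtol=1e-12)

    def test_wraparound_equals_explicit_pulse_train_sum(self, small_acq):
        # geometric-series oracle: sum tails of 100 prior pulses by hand
        tau = small_acq.rep_period_ns  # tau == T, worst wraparound
        m = DecayModel.from_pairs([(1.0, tau)])
        acq = AcquisitionConfig(
            n_channels=small_acq.n_channels,
            channel_width_ps=small_acq.channel_width_ps,
            rep_period_ns=small_acq.rep_period_ns,
            total_counts=small_acq.total_counts,
            background_fraction=0.0,
        )
        expected = periodic_decay_expectation(m, acq)
        t = acq.channel_times_ns
        train = np.zeros_like(t)
        for k in range(100):
            train += np.exp(-(t + k * acq.rep_period_ns) / tau)
        # before normalization the wrapped shape is the unwrapped decay
        # boosted by the geometric factor 1/(1 - e^-1) at every channel
        assert np.allclose(
            train / np.exp(-t / tau), 1.0 / (1.0 - np.exp(-1.0)), rtol=1e-9
        )
        train = train / train.sum() * acq.total_counts
        assert np.allclose(expected, train, rtol=1e-9)

    def test_background_contribution_is_uniform(self, small_acq):
        m = DecayModel.from_pairs([(1.0, 2.0)])
        no_bg = AcquisitionConfig(
            n_channels=small_acq.n_channels,
            channel_width_ps=small_acq.channel_width_ps,
            rep_period_ns=small_acq.rep_period_ns,
            total_counts=small_acq.total_counts,
            background_fraction=0.0,
        )
        half_bg = AcquisitionConfig(
            n_channels=small_acq.n_channels,
            channel_width_ps=small_acq.channel_width_ps,
            rep_period_ns=small_acq.rep_period_ns,
            total_counts=small_acq.total_counts,
            background_fraction=0.5,
        )
        flat = periodic_decay_expectation(m, half_bg) - 0.5 * periodic_decay_expectation(
            m, no_bg
        )
        assert np.ptp(flat) == pytest.approx(0.0, abs=1e-9)
        assert flat[0] == pytest.approx(
            0.5 * small_acq.total_counts / small_acq.n_channels, rel=1e-12
        )

    def test_very_slow_lifetime_warns(self, small_acq):
        m = DecayModel.from_pairs([(1.0, 600.0)])
        with pytest.warns(UserWarning, match="ill-conditioned"):
            periodic_decay_expectation(m, small_acq)

    def test_window_must_fit_one_period(self):
        with pytest.raises(ValueError, match="window"):
            AcquisitionConfig(
                n_channels=4096, channel_width_ps=20.0, rep_period_ns=50.0
            )


class TestConvolveIRF:
    def test_delta_kernel_is_identity(self, small_acq):
        x = np.exp(-small_acq.channel_times_ns / 0.5)
        delta = np.zeros(small_acq.n_channels)
        delta[0] = 123.0  # un-normalized on purpose
        assert np.allclose(convolve_irf(x, delta), x, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        acq = AcquisitionConfig(
            n_channels=256, channel_width_ps=195.2, rep_period_ns=50.0,
            total_counts=1e5,
        )
        m = DecayModel.from_pairs([(1.0, 0.09)])
        x = periodic_decay_expectation(m, acq)
        irf = IRFSpec(fwhm_ps=200.0, center_ns=2.0)
        kernel = irf_expectation(irf, acq)
        fast = convolve_irf(x, irf, acq)
        slow = brute_force_circular_conv(x, kernel)
        assert np.allclose(fast, slow, atol=1e-10 * x.max())

    def test_uniform_kernel_flattens(self, small_acq):
        x = np.exp(-small_acq.channel_times_ns / 0.5)
        flat = convolve_irf(x, np.ones(small_acq.n_channels))
        assert np.allclose(flat, x.mean(), rtol=1e-9)

    def test_total_counts_preserved(self, small_acq, narrow_irf):
        m = DecayModel.from_pairs([(0.8, 0.09), (0.2, 4.3)])
        x = periodic_decay_expectation(m, small_acq)
        y = convolve_irf(x, narrow_irf, small_acq)
        assert y.sum() == pytest.approx(x.sum(), rel=1e-9)

    def test_linearity(self, small_acq, narrow_irf):
        t = small_acq.channel_times_ns
        x = np.exp(-t / 0.1)
        y = np.exp(-t / 3.0)
        lhs = convolve_irf(2.0 * x + 3.0 * y, narrow_irf, small_acq)
        rhs = 2.0 * convolve_irf(x, narrow_irf, small_acq) + 3.0 * convolve_irf(
            y, narrow_irf, small_acq
        )
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_zero_area_kernel_rejected(self, small_acq):
        with pytest.raises(ValueError, match="zero area"):
            convolve_irf(np.ones(small_acq.n_channels), np.zeros(small_acq.n_channels))


class TestSampleCounts:
    def test_zero_expectation_gives_zero_counts(self):
        assert np.all(sample_counts(np.zeros(100), seed=1) == 0)

    def test_poisson_tail_bound_over_seeds(self):
        expected = np.array([10000.0])
        draws = [sample_counts(expected, seed=s)[0] for s in range(100)]
        assert all(abs(d - 10000) <= 400 for d in draws)  # 4 sigma

    def test_seed_reproducibility(self):
        expected = np.geomspace(1, 1e4, 50)
        a = sample_counts(expected, seed=7)
        b = sample_counts(expected, seed=7)
        assert np.array_equal(a, b)

    def test_negative_expectation_rejected(self):
        with pytest.raises(ValueError):
            sample_counts(np.array([-1.0]), seed=0)


class TestGenerateDataset:
    def test_same_seed_identical(self, small_acq, narrow_irf):
        m = DecayModel.from_pairs([(0.85, 0.09), (0.15, 4.3)])
        a = generate_dataset(m, narrow_irf, small_acq, seed=11)
        b = generate_dataset(m, narrow_irf, small_acq, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.irf_counts, b.irf_counts)

    def test_different_seeds_differ(self, small_acq, narrow_irf):
        m = DecayModel.from_pairs([(0.85, 0.09), (0.15, 4.3)])
        a = generate_dataset(m, narrow_irf, small_acq, seed=11)
        b = generate_dataset(m, narrow_irf, small_acq, seed=12)
        assert not np.array_equal(a.counts, b.counts)

    def test_total_counts_conserved_in_expectation(self, narrow_irf):
        acq = AcquisitionConfig(
            n_channels=256, channel_width_ps=195.2, rep_period_ns=50.0,
            total_counts=1e5,
        )
        m = DecayModel.from_pairs([(0.85, 0.09), (0.15, 4.3)])
        totals = [
            generate_dataset(m, narrow_irf, acq, seed=s).counts.sum()
            for s in range(200)
        ]
        assert np.mean(totals) == pytest.approx(acq.total_counts, rel=0.01)

    def test_rejects_invalid_model(self, small_acq, narrow_irf):
        with pytest.raises((ValueError, TypeError)):
            generate_dataset(None, narrow_irf, small_acq, seed=0)
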
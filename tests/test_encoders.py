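"""Rate, Poisson and NEF encoders."""

import numpy as np
import pytest
from scipy import stats

from spikeloop import (
    RateCodeStepper,
    RateEncoderParams,
    TimeGrid,
    ValidationError,
    encode_poisson,
    encode_regular,
    instantaneous_rate,
    make_fixture,
    nef_activities,
    nef_build,
    nef_encode_spiking,
    nef_reconstruct,
    nef_train_decoders,
)
from spikeloop.encoders import _lif_rate, lstsq_decoders


def constant(value, T=1.0, dt=1e-3, channels=1):
    return make_fixture("constant", TimeGrid(0.0, T, dt), channels=channels, value=value)


class TestInstantaneousRate:
    @pytest.mark.parametrize("I,expected", [(-1.0, 10.0), (1.0, 50.0), (0.0, 30.0)])
    def test_linear_map_endpoints_and_midpoint(self, I, expected):
        p = RateEncoderParams(v_min=10, v_max=50)
        assert instantaneous_rate(I, p) == pytest.approx(expected)

    def test_out_of_range_clipped(self):
        p = RateEncoderParams(v_min=0, v_max=100)
        assert instantaneous_rate(3.0, p) == pytest.approx(100.0)
        assert instantaneous_rate(-3.0, p) == pytest.approx(0.0)

    def test_monotone_in_drive(self):
        p = RateEncoderParams(v_min=5, v_max=80)
        I = np.linspace(-1, 1, 101)
        assert np.all(np.diff(instantaneous_rate(I, p)) >= 0)


class TestRegularEncoder:
    def test_full_drive_count_and_isi(self):
        p = RateEncoderParams(v_min=0, v_max=100)
        s = encode_regular(constant(1.0), p)
        assert abs(s.counts()[0] - 100) <= 1
        assert np.allclose(s.isis(0), 0.01, atol=1e-9)

    def test_zero_rate_is_silent(self):
        p = RateEncoderParams(v_min=0, v_max=100)
        s = encode_regular(constant(-1.0), p)
        assert s.n_spikes == 0

    def test_low_rate_regime_count(self):
        # 1.5 Hz drive over 100 s: the sparse regime used for repeaters
        p = RateEncoderParams(v_min=0, v_max=3)
        s = encode_regular(constant(0.0, T=100.0), p)
        assert abs(s.counts()[0] - 150) <= 1

    def test_unnormalized_signal_rejected(self):
        from spikeloop import ContinuousSignal

        sig = ContinuousSignal(TimeGrid(0, 0.01, 1e-3), np.full((10, 1), 2.0))
        with pytest.raises(ValidationError, match="normalized"):
            encode_regular(sig, RateEncoderParams(v_min=0, v_max=10))

    def test_empirical_rate_monotone_in_drive(self):
        p = RateEncoderParams(v_min=0, v_max=100)
        counts = [encode_regular(constant(I, T=2.0), p).n_spikes
                  for I in np.linspace(-1, 1, 9)]
        assert np.all(np.diff(counts) >= 0)

    def test_align_to_grid_snaps_times(self):
        p = RateEncoderParams(v_min=0, v_max=77, align_to_grid=True)
        s = encode_regular(constant(0.3), p)
        frac = (np.asarray(s.trains[0]) / 1e-3) % 1.0
        assert np.allclose(np.minimum(frac, 1 - frac), 0.0, atol=1e-6)


class TestPoissonEncoder:
    def test_seed_reproducibility(self):
        p = RateEncoderParams(v_min=0, v_max=100, mode="poisson", seed=42)
        a = encode_poisson(constant(0.5), p)
        b = encode_poisson(constant(0.5), p)
        assert a == b

    def test_count_and_isi_statistics(self):
        # 50 Hz homogeneous process over 100 s
        p = RateEncoderParams(v_min=0, v_max=100, mode="poisson", seed=7)
        s = encode_poisson(constant(0.0, T=100.0), p)
        n = s.counts()[0]
        assert abs(n - 5000) < 3 * np.sqrt(5000)
        isi = s.isis(0)
        cv = isi.std() / isi.mean()
        assert 0.95 < cv < 1.05
        assert stats.kstest(isi, "expon", args=(0, 1 / 50)).pvalue > 0.01

    def test_zero_rate_is_silent(self):
        p = RateEncoderParams(v_min=0, v_max=100, mode="poisson", seed=1)
        assert encode_poisson(constant(-1.0), p).n_spikes == 0

    def test_mean_rate_monotone_in_drive(self):
        p = RateEncoderParams(v_min=0, v_max=100, mode="poisson", seed=3)
        counts = [encode_poisson(constant(I, T=20.0), p).n_spikes
                  for I in (-0.5, 0.0, 0.5)]
        assert counts[0] < counts[1] < counts[2]


class TestStepper:
    def test_chunked_equals_whole_signal(self):
        """Tick-by-tick encoding must reproduce the batch encoders exactly."""
        grid = TimeGrid(0.0, 2.0, 1e-3)
        sig = make_fixture("sine", grid, freq=0.5)
        for mode in ("regular", "poisson"):
            p = RateEncoderParams(v_min=0, v_max=80, mode=mode, seed=9)
            batch = (encode_regular if mode == "regular" else encode_poisson)(sig, p)
            stepper = RateCodeStepper(p)
            times = []
            for k in range(grid.n_samples):
                for nid, t in stepper.advance(k * 1e-3, 1e-3, sig.values[k]):
                    times.append(t)
            assert len(times) == batch.n_spikes
            assert np.allclose(times, batch.trains[0], atol=1e-9)


class TestNEFTuning:
    def test_build_deterministic(self):
        a = nef_build(1, 100, seed=5)
        b = nef_build(1, 100, seed=5)
        assert np.array_equal(a.gains, b.gains)
        assert np.array_equal(a.encoders, b.encoders)

    def test_intercept_and_max_rate_constraints(self):
        e = nef_build(1, 50, seed=2)
        # evaluate along each neuron's preferred direction: silent below the
        # intercept, drawn maximum rate at projection 1
        proj = np.linspace(-1, 1, 201)
        for n in range(e.n_neurons):
            rates = _lif_rate(e.gains[n] * proj + e.biases[n], e.tau_m, e.t_ref)
            below = proj < e.intercepts[n] - 1e-9
            assert np.all(rates[below] == 0.0)
            assert rates[-1] == pytest.approx(e.max_rates[n], abs=0.5)

    def test_lif_rate_closed_form(self):
        # J=2, tau_m=20 ms, t_ref=2 ms -> 1/(0.002 + 0.02 ln 2)
        assert _lif_rate(np.array([2.0]), 0.02, 0.002)[0] == pytest.approx(
            1.0 / (0.002 + 0.02 * np.log(2.0)), rel=1e-12
        )

    def test_subthreshold_silent_and_asymptote(self):
        assert np.all(_lif_rate(np.linspace(-3, 1, 50), 0.02, 0.002) == 0.0)
        assert _lif_rate(np.array([1e9]), 0.02, 0.002)[0] == pytest.approx(500.0, rel=1e-3)

    def test_unreachable_max_rate_rejected(self):
        with pytest.raises(ValidationError):
            nef_build(1, 10, max_rates=(400, 600), seed=0)


class TestNEFDecoding:
    def test_toy_rectified_pair_recovers_identity(self):
        # a1 = max(0, I), a2 = max(0, -I) on {-1, 0, 1}: pseudoinverse by hand
        # gives decoders (1, -1) and exact reconstruction on the training set
        X = np.array([-1.0, 0.0, 1.0])
        A = np.stack([np.maximum(0, X), np.maximum(0, -X)], axis=1)
        phi = lstsq_decoders(A, X, regularization=0.0)
        assert phi[:, 0] == pytest.approx([1.0, -1.0])
        assert A @ phi[:, 0] == pytest.approx(X)

    def test_huge_ridge_shrinks_decoders_to_zero(self):
        e = nef_build(1, 20, seed=1)
        nef_train_decoders(e, np.linspace(-1, 1, 50), regularization=1e6)
        assert np.abs(e.decoders).max() < 1e-6

    def test_singular_system_suggests_regularization(self):
        A = np.zeros((10, 3))
        with pytest.raises(ValidationError, match="regularization"):
            lstsq_decoders(A, np.zeros(10), regularization=0.0)

    def test_reconstruction_error_about_one_percent(self):
        e = nef_build(1, 100, seed=0)
        nef_train_decoders(e, np.linspace(-1, 1, 200))
        test = np.linspace(-1, 1, 500)
        rmse = np.sqrt(np.mean((nef_reconstruct(e, test)[:, 0] - test) ** 2))
        assert rmse < 0.02

    def test_rmse_decreases_with_population_size(self):
        sizes = [10, 30, 100, 300]
        mean_rmse = []
        for n in sizes:
            r = []
            for seed in range(5):
                e = nef_build(1, n, seed=seed)
                nef_train_decoders(e, np.linspace(-1, 1, max(n, 50)))
                test = np.linspace(-1, 1, 300)
                r.append(np.sqrt(np.mean((nef_reconstruct(e, test)[:, 0] - test) ** 2)))
            mean_rmse.append(np.mean(r))
        assert np.all(np.diff(mean_rmse) < 0)


class TestNEFSpiking:
    def test_constant_input_rate_matches_tuning_curve(self):
        e = nef_build(1, 30, seed=3)
        sig = constant(0.5, T=2.0)
        spikes = nef_encode_spiking(sig, e)
        predicted = nef_activities(e, [0.5])[0]
        empirical = spikes.counts() / 2.0
        fast = predicted >= 20.0
        rel = np.abs(empirical[fast] - predicted[fast]) / predicted[fast]
        assert rel.max() < 0.05

    def test_subthreshold_neuron_is_silent(self):
        from spikeloop.encoders import NEFEnsemble

        e = NEFEnsemble(
            n_neurons=1, dim=1, encoders=np.array([[1.0]]), gains=np.array([0.0]),
            biases=np.array([0.9]), max_rates=np.array([100.0]),
            intercepts=np.array([0.0]),
        )
        assert nef_encode_spiking(constant(1.0), e).n_spikes == 0

    def test_deterministic(self):
        e = nef_build(1, 10, seed=8)
        sig = make_fixture("sine", TimeGrid(0, 1, 1e-3), freq=1.0)
        assert nef_encode_spiking(sig, e) == nef_encode_spiking(sig, e)
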
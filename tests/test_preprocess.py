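import numpy as np
import pandas as pd
import pytest

from n1dev import preprocess as pp
from n1dev.recording import ContinuousRecording, EpochSet


def make_rec(signal, montage, rate=1000.0):
    return ContinuousRecording(signal=signal, rate=rate, montage=montage)


def fft_amplitude(x, rate, freq):
    """Single-bin FFT amplitude oracle (signal length must hold integer cycles)."""
    spec = np.fft.rfft(x) / x.size * 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    return np.abs(spec[np.argmin(np.abs(freqs - freq))])


class TestFilter:
    def test_notch_removes_50hz(self, pair_montage):
        t = np.arange(0, 10, 1e-3)
        x = np.sin(2 * np.pi * 50 * t)
        rec = make_rec(np.vstack([x, -x]), pair_montage)
        out = pp.bandpass_notch_downsample(rec)
        # discard filter edge transients before measuring
        core = out.signal[0, 500:-500]
        assert fft_amplitude(core, out.rate, 50.0) < 0.01 * fft_amplitude(x, 1000.0, 50.0)

    def test_passband_10hz_preserved(self, pair_montage):
        t = np.arange(0, 10, 1e-3)
        x = np.sin(2 * np.pi * 10 * t)
        rec = make_rec(np.vstack([x, -x]), pair_montage)
        out = pp.bandpass_notch_downsample(rec)
        core = out.signal[0, 500:-500]
        assert fft_amplitude(core, out.rate, 10.0) > 0.95

    def test_downsample_arithmetic(self, pair_montage):
        rec = make_rec(np.zeros((2, 10000)), pair_montage, rate=1000.0)
        out = pp.bandpass_notch_downsample(rec, target_rate=500.0)
        assert out.n_samples == 5000
        assert out.rate == 500.0

    def test_linearity(self, pair_montage, rng):
        x = rng.standard_normal((2, 4000))
        y = rng.standard_normal((2, 4000))
        a, b = 1.7, -0.4
        f = lambda s: pp.bandpass_notch_downsample(make_rec(s, pair_montage)).signal
        assert np.allclose(f(a * x + b * y), a * f(x) + b * f(y), atol=1e-8)

    def test_invalid_band_edges(self, pair_montage):
        rec = make_rec(np.zeros((2, 1000)), pair_montage)
        with pytest.raises(ValueError):
            pp.bandpass_notch_downsample(rec, low_hz=30.0, high_hz=0.1)
        with pytest.raises(ValueError):
            pp.bandpass_notch_downsample(rec, high_hz=400.0, target_rate=500.0)


class TestInterpolation:
    def test_constant_field_reproduced(self, montage20):
        sig = np.full((20, 100), 7.25)
        rec = make_rec(sig, montage20)
        out = pp.interpolate_channels(rec, bad=[montage20.channels[3]])
        assert np.allclose(out.signal, 7.25)

    def test_empty_bad_list_is_identity(self, montage20, rng):
        rec = make_rec(rng.standard_normal((20, 50)), montage20)
        out = pp.interpolate_channels(rec, bad=[])
        assert np.array_equal(out.signal, rec.signal)

    def test_matches_brute_force_neighbor_oracle(self, montage20, rng):
        sig = rng.standard_normal((20, 30))
        bad = montage20.channels[5]
        rec = make_rec(sig, montage20)
        out = pp.interpolate_channels(rec, bad=[bad], k=4)
        # brute-force oracle: weighted mean of the 4 nearest good channels
        bi = montage20.channels.index(bad)
        dists = [
            (np.linalg.norm(montage20.positions[i] - montage20.positions[bi]), i)
            for i in range(20)
            if i != bi
        ]
        nearest = sorted(dists)[:4]
        w = np.array([1.0 / d for d, _ in nearest])
        w /= w.sum()
        expected = w @ np.array([sig[i] for _, i in nearest])
        assert np.allclose(out.signal[bi], expected, atol=1e-12)
        untouched = [i for i in range(20) if i != bi]
        assert np.array_equal(out.signal[untouched], sig[untouched])

    def test_bad_channel_cap(self, montage20):
        rec = make_rec(np.zeros((20, 10)), montage20)
        with pytest.raises(ValueError, match="cap"):
            pp.interpolate_channels(rec, bad=montage20.channels[:6])


class TestAverageReference:
    def test_column_means_zero(self, montage20, rng):
        rec = make_rec(rng.standard_normal((20, 200)) + 13.0, montage20)
        out = pp.rereference_average(rec)
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-9
        assert out.reference_state == "average"

    def test_projection_idempotent(self, montage20, rng):
        rec = make_rec(rng.standard_normal((20, 50)), montage20)
        once = pp.rereference_average(rec)
        twice = pp.rereference_average(once)
        assert np.allclose(once.signal, twice.signal, atol=1e-12)

    def test_two_channel_closed_form(self, pair_montage, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        rec = make_rec(np.vstack([a, b]), pair_montage)
        out = pp.rereference_average(rec)
        assert np.allclose(out.signal[0], (a - b) / 2)
        assert np.allclose(out.signal[1], (b - a) / 2)


def simple_events(onsets, condition="DIG", is_target=False):
    return pd.DataFrame(
        {
            "onset_ms": onsets,
            "condition": condition,
            "is_target": is_target,
            "block": 0,
        }
    )


class TestEpoching:
    def test_epoch_count_excludes_targets(self, montage20, rng):
        rec = make_rec(rng.standard_normal((20, 60000)) * 0.1, montage20, rate=500.0)
        ev = pd.concat(
            [
                simple_events(np.arange(54) * 2000.0 + 500),
                simple_events(np.arange(6) * 2000.0 + 109_000, is_target=True),
            ]
        )
        es = pp.epoch(rec, ev)
        assert es.counts() == {"DIG": 54}

    def test_constant_signal_baseline_zeroes_epoch(self, montage20):
        rec = make_rec(np.full((20, 5000), 42.0), montage20, rate=500.0)
        es = pp.epoch(rec, simple_events([2000.0]), baseline=(-100.0, 0.0))
        assert np.allclose(es.epochs["DIG"], 0.0)

    def test_half_open_sample_convention_at_500hz(self, montage20):
        rec = make_rec(np.zeros((20, 5000)), montage20, rate=500.0)
        es = pp.epoch(rec, simple_events([2000.0]))
        # [-100, 613) ms at 2 ms steps: samples -50..306 -> 357 points
        assert es.times_ms.size == 357
        assert es.times_ms[0] == -100.0
        assert es.times_ms[-1] == 612.0

    def test_edge_event_skipped_and_logged(self, montage20):
        rec = make_rec(np.zeros((20, 1000)), montage20, rate=500.0)
        es = pp.epoch(rec, simple_events([50.0, 1000.0]))
        assert es.counts() == {"DIG": 1}
        assert len(es.rejection_log) == 1
        assert "edge" in es.rejection_log[0][2]


class TestRejection:
    def make_epochset(self, montage, arrays):
        return EpochSet(
            subject="s",
            timepoint="T1",
            epochs={c: np.asarray(a, dtype=float) for c, a in arrays.items()},
            times_ms=np.arange(next(iter(arrays.values()))[0].shape[1]) * 2.0,
            montage=montage,
        )

    def test_all_within_threshold_nothing_removed(self, montage20, rng):
        es = self.make_epochset(montage20, {"DIG": rng.uniform(-150, 150, (10, 20, 30))})
        out = pp.reject_epochs(es)
        assert out.counts() == {"DIG": 10}

    def test_single_spike_removes_exactly_that_epoch(self, montage20, rng):
        arr = rng.uniform(-50, 50, (8, 20, 30))
        arr[3, 7, 11] = 250.0
        out = pp.reject_epochs(self.make_epochset(montage20, {"DIG": arr}))
        assert out.counts() == {"DIG": 7}
        assert out.rejection_log[-1][:2] == ("DIG", 3)

    @pytest.mark.parametrize("k", [0, 1, 5])
    def test_known_exceedance_count(self, montage20, rng, k):
        """Brute-force max-abs oracle: exactly k constructed exceedances removed."""
        arr = rng.uniform(-100, 100, (12, 20, 30))
        picks = rng.choice(12, size=k, replace=False)
        for i in picks:
            arr[i, int(rng.integers(20)), int(rng.integers(30))] = -222.0
        oracle = int((np.abs(arr).max(axis=(1, 2)) > 200.0).sum())
        assert oracle == k
        out = pp.reject_epochs(self.make_epochset(montage20, {"DIG": arr}))
        assert out.counts()["DIG"] == 12 - k


class TestInclusionRule:
    def make_counts(self, montage, counts):
        return EpochSet(
            subject="s",
            timepoint="T1",
            epochs={c: np.zeros((n, 20, 5)) for c, n in counts.items()},
            times_ms=np.arange(5.0),
            montage=montage,
        )

    @pytest.mark.parametrize(
        "counts,expect",
        [
            ({"DIG": 40, "LET": 44, "FF": 43}, True),
            ({"DIG": 19, "LET": 44, "FF": 43}, False),
            ({"DIG": 20, "LET": 20, "FF": 20}, True),  # "at least 20" is inclusive
        ],
    )
    def test_boundary(self, montage20, counts, expect):
        dec = pp.apply_inclusion_rule(self.make_counts(montage20, counts))
        assert dec.included is expect

    def test_missing_condition_excluded_with_reason(self, montage20):
        dec = pp.apply_inclusion_rule(self.make_counts(montage20, {"DIG": 30, "LET": 30}))
        assert not dec.included
        assert "FF" in dec.reason

    def test_condition_relabeling_invariance(self, montage20, rng):
        """Rejection + inclusion outcome does not depend on condition order/names."""
        arrays = {c: rng.uniform(-300, 300, (25, 20, 10)) for c in ("DIG", "LET", "FF")}
        es = self.make_epochset_like(montage20, arrays)
        base = pp.apply_inclusion_rule(pp.reject_epochs(es))
        relabel = {"DIG": "FF", "FF": "LET", "LET": "DIG"}
        es2 = self.make_epochset_like(montage20, {relabel[c]: a for c, a in arrays.items()})
        perm = pp.apply_inclusion_rule(pp.reject_epochs(es2))
        assert base.included == perm.included
        assert base.counts == {relabel[c]: n for c, n in perm.counts.items()}

    def make_epochset_like(self, montage, arrays):
        return EpochSet(
            subject="s",
            timepoint="T1",
            epochs={c: np.asarray(a, dtype=float) for c, a in arrays.items()},
            times_ms=np.arange(next(iter(arrays.values())).shape[2]) * 2.0,
            montage=montage,
        )


class TestRecordingIO:
    def test_npz_round_trip(self, montage20, rng, tmp_path):
        rec = make_rec(rng.standard_normal((20, 100)).astype(np.float32), montage20)
        rec.save(tmp_path / "rec.npz")
        back = ContinuousRecording.load(tmp_path / "rec.npz", montage20)
        assert np.allclose(back.signal, rec.signal, atol=1e-6)
        assert back.rate == rec.rate

    def test_epochset_round_trip(self, montage20, rng, tmp_path):
        es = EpochSet(
            subject="S001",
            timepoint="T2",
            epochs={"DIG": rng.standard_normal((5, 20, 12))},
            times_ms=np.arange(12.0),
            montage=montage20,
            rejection_log=[("DIG", 3, "test")],
        )
        es.save(tmp_path / "es.npz")
        back = EpochSet.load(tmp_path / "es.npz", montage20)
        assert back.subject == "S001" and back.timepoint == "T2"
        assert np.allclose(back.epochs["DIG"], es.epochs["DIG"], atol=1e-6)
        assert back.rejection_log == [("DIG", 3, "test")]
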
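import numpy as np
import pandas as pd
import pytest

from neurofuse.eeg import (
    EegEpochs,
    RawEeg,
    aggregate_eeg_rois,
    alpha_power,
    bandpass_eeg,
    csd_transform,
    drop_boundary_channels,
    epoch_eeg,
    reject_bad_channels,
    remove_artifact_components,
)
from neurofuse.rois import BOUNDARY_ELECTRODES, DEFAULT_ROI_MAP
from neurofuse.schedule import EventSchedule, Trial

FS = 125.0


def _raw(data, labels=None):
    labels = labels or tuple(f"E{i + 1}" for i in range(data.shape[0]))
    return RawEeg(np.asarray(data, dtype=float), tuple(labels), FS)


def _epochs(data, labels, window=(-1.0, 1.0)):
    n = data.shape[0]
    info = pd.DataFrame({"condition": ["ME"] * n, "trial": range(n),
                         "onset": np.arange(n, dtype=float)})
    return EegEpochs(np.asarray(data, float), tuple(labels), FS, window, info)


class TestBandpass:
    def _tone(self, f, n=12500):
        return np.sin(2 * np.pi * f * np.arange(n) / FS)

    def test_line_frequency_attenuated(self):
        x = self._tone(60.0)[None, :]
        out = bandpass_eeg(_raw(x)).data[0]
        mid = slice(2000, 10000)
        assert 20 * np.log10(out[mid].std() / x[0, mid].std()) < -20

    def test_alpha_passes(self):
        x = self._tone(10.0)[None, :]
        out = bandpass_eeg(_raw(x)).data[0]
        mid = slice(2000, 10000)
        assert abs(20 * np.log10(out[mid].std() / x[0, mid].std())) < 1.0

    def test_dc_removed(self):
        out = bandpass_eeg(_raw(np.full((1, 5000), 40.0))).data
        assert abs(out.mean()) < 1e-4


class TestBoundary:
    def test_full_montage_removes_exactly_24(self, geometry):
        labels = tuple(geometry.electrode_positions)
        rng = np.random.default_rng(0)
        raw = _raw(rng.normal(size=(len(labels), 100)), labels)
        out = drop_boundary_channels(raw)
        assert len(out.labels) == len(labels) - 24
        assert not set(out.labels) & set(BOUNDARY_ELECTRODES)

    def test_empty_list_identity(self):
        raw = _raw(np.ones((3, 10)))
        out = drop_boundary_channels(raw, ())
        assert out.labels == raw.labels

    def test_idempotent(self, geometry):
        labels = tuple(geometry.electrode_positions)
        raw = _raw(np.zeros((len(labels), 10)), labels)
        once = drop_boundary_channels(raw)
        with pytest.warns(UserWarning):
            twice = drop_boundary_channels(once)
        assert once.labels == twice.labels


class TestChannelRejection:
    def test_homogeneous_channels_all_kept(self):
        rng = np.random.default_rng(0)
        raw = _raw(rng.normal(0, 10, (16, 4000)))
        out, rejected = reject_bad_channels(raw)
        assert rejected == ()
        assert len(out.labels) == 16

    def test_high_variance_channel_rejected(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 10, (16, 4000))
        data[3] *= 50.0
        _, rejected = reject_bad_channels(_raw(data))
        assert "E4" in rejected

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 10, (12, 4000))
        data[5] *= 40.0
        labels = tuple(f"E{i + 1}" for i in range(12))
        _, rej_a = reject_bad_channels(_raw(data, labels))
        perm = rng.permutation(12)
        _, rej_b = reject_bad_channels(
            RawEeg(data[perm], tuple(np.array(labels)[perm]), FS))
        assert set(rej_a) == set(rej_b)

    def test_too_many_bad_channels_aborts(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (16, 4000))
        data[3] *= 100.0
        with pytest.raises(RuntimeError, match="unusable"):
            reject_bad_channels(_raw(data), max_fraction=0.01)


class TestIca:
    def test_remove_nothing_is_identity(self):
        rng = np.random.default_rng(0)
        t = np.arange(500) / FS
        data = np.stack([
            np.sin(2 * np.pi * 10 * t + ph) + 0.1 * rng.normal(size=500)
            for ph in rng.uniform(0, 6.28, 8)
        ])[None].repeat(6, axis=0)
        data = data + rng.normal(0, 0.05, data.shape)
        ep = _epochs(data, [f"E{i}" for i in range(8)])
        out = remove_artifact_components(ep, kurtosis_z_thresh=50.0, seed=0)
        assert np.array_equal(out.data, ep.data)

    def test_planted_blink_template_removed(self):
        rng = np.random.default_rng(1)
        n_ep, n_ch, n_t = 20, 8, 250
        clean = rng.laplace(0, 1.0, (n_ep, n_ch, n_t))
        blink = np.zeros(n_ep * n_t)
        for k in range(25):  # sparse large deflections
            i = rng.integers(0, n_ep * n_t - 30)
            blink[i:i + 30] += 40.0 * np.hanning(30)
        topography = np.array([3.0, 2.5, 2.0, 0.5, 0.2, 0.1, 0.0, 0.0])
        data = clean + topography[None, :, None] * blink.reshape(n_ep, 1, n_t)
        ep = _epochs(data, [f"E{i}" for i in range(n_ch)])
        out = remove_artifact_components(
            ep, references=blink[None, :], corr_thresh=0.7,
            kurtosis_z_thresh=50.0, n_components=8, seed=0)
        flat = out.data.transpose(1, 0, 2).reshape(n_ch, -1)
        for row in flat[:3]:  # frontal rows carried the blink
            assert abs(np.corrcoef(row, blink)[0, 1]) < 0.1

    def test_removing_components_reduces_rank(self):
        rng = np.random.default_rng(2)
        n_ep, n_ch, n_t = 10, 6, 200
        # full-rank non-Gaussian sources so the decomposition is exact
        s = rng.laplace(size=(n_ch, n_ep * n_t))
        mix = rng.normal(size=(n_ch, n_ch))
        data = (mix @ s).reshape(n_ch, n_ep, n_t).transpose(1, 0, 2)
        ref = s[0]
        ep = _epochs(data, [f"E{i}" for i in range(n_ch)])
        out = remove_artifact_components(
            ep, references=ref[None, :], corr_thresh=0.9,
            kurtosis_z_thresh=50.0, n_components=n_ch, seed=0)
        flat_in = data.transpose(1, 0, 2).reshape(n_ch, -1)
        flat_out = out.data.transpose(1, 0, 2).reshape(n_ch, -1)
        center = lambda m: m - m.mean(axis=1, keepdims=True)
        rank_in = np.linalg.matrix_rank(center(flat_in), tol=1e-6)
        rank_out = np.linalg.matrix_rank(center(flat_out), tol=1e-6)
        assert rank_in - rank_out == 1


class TestEpoching:
    def _sched(self):
        trials = [Trial("ME", 5.0, 5.0), Trial("MO", 30.0, 5.0),
                  Trial("MI", 55.0, 5.0), Trial("ME", 80.0, 5.0)]
        return EventSchedule(trials=tuple(trials), lead_in=5.0)

    def test_counts_and_window_length(self, schedule):
        n = int(schedule.end_time * FS + FS)
        raw = _raw(np.zeros((4, n)))
        ep = epoch_eeg(raw, schedule)
        assert ep.data.shape == (45, 4, int(2 * FS))

    def test_edge_trial_dropped(self):
        sched = EventSchedule(trials=tuple(
            [Trial("ME", 0.5, 5.0)] + list(self._sched().trials[1:])),
            lead_in=0.0)
        raw = _raw(np.zeros((4, int(90 * FS))))
        ep = epoch_eeg(raw, sched)
        assert len(ep.info) == 3  # the t=0.5 s trial cannot host a -1 s edge

    def test_missing_condition_aborts(self):
        sched = EventSchedule(trials=(Trial("ME", 5.0, 5.0),
                                      Trial("MO", 30.0, 5.0)))
        raw = _raw(np.zeros((4, int(60 * FS))))
        with pytest.raises(RuntimeError, match="no usable trials"):
            epoch_eeg(raw, sched)


class TestCsd:
    def _positions(self, geometry, labels):
        return {l: geometry.electrode_positions[l] for l in labels}

    def test_constant_potential_zero_csd(self, geometry):
        labels = [l for l in geometry.electrode_positions
                  if l not in BOUNDARY_ELECTRODES]
        ep = _epochs(np.full((2, len(labels), 20), 7.5), labels)
        out = csd_transform(ep, self._positions(geometry, labels))
        assert np.abs(out.data).max() < 1e-6 * 7.5
        assert out.units == "uV/cm^2"

    def test_linearity(self, geometry):
        labels = [l for l in geometry.electrode_positions
                  if l not in BOUNDARY_ELECTRODES]
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, len(labels), 10))
        y = rng.normal(size=(1, len(labels), 10))
        pos = self._positions(geometry, labels)
        fa = csd_transform(_epochs(x, labels), pos).data
        fb = csd_transform(_epochs(y, labels), pos).data
        fab = csd_transform(_epochs(2 * x + 3 * y, labels), pos).data
        assert np.allclose(fab, 2 * fa + 3 * fb, atol=1e-8)

    def test_dipole_pattern_sign_reversal(self, geometry):
        """Smooth dipolar pattern P1 about a tangential axis: spherical
        harmonics are eigenfunctions of the surface Laplacian, so the CSD
        is proportional to the pattern itself and reverses sign between
        the two poles (left vs right electrodes)."""
        labels = [l for l in geometry.electrode_positions
                  if l not in BOUNDARY_ELECTRODES]
        pos = self._positions(geometry, labels)
        pn = np.array([pos[l] / np.linalg.norm(pos[l]) for l in labels])
        v = pn[:, 0]  # P1 about a tangential axis: signs flip across midline
        ep = _epochs(v[None, :, None] * np.ones((1, len(labels), 3)), labels)
        out = csd_transform(ep, pos).data[0, :, 0]
        # sign structure follows the harmonic: positive at vertex-side
        # electrodes, negative on the lower rim
        top = v > np.quantile(v, 0.8)
        bot = v < np.quantile(v, 0.2)
        assert np.sign(out[top].mean()) != np.sign(out[bot].mean())
        assert np.corrcoef(out, v)[0, 1] > 0.9

    def test_duplicate_positions_rejected(self, geometry):
        labels = [l for l in geometry.electrode_positions
                  if l not in BOUNDARY_ELECTRODES]
        pos = self._positions(geometry, labels)
        pos[labels[1]] = pos[labels[0]]
        ep = _epochs(np.zeros((1, len(labels), 5)), labels)
        with pytest.raises(ValueError, match="duplicate"):
            csd_transform(ep, pos)


class TestAlphaPower:
    def _epoch_tone(self, f, amp_pre=1.0, amp_post=1.0):
        t = np.arange(-1.0, 1.0, 1 / FS)
        amp = np.where(t < 0, amp_pre, amp_post)
        x = amp * np.sin(2 * np.pi * f * t)
        return x[None, None, :]

    def test_stationary_tone_zero_change(self):
        table = alpha_power(_epochs(self._epoch_tone(10.0), ["E1"]))
        assert abs(table.alpha_change.iloc[0]) < 0.05

    def test_amplitude_halving_gives_log_quarter(self):
        table = alpha_power(
            _epochs(self._epoch_tone(10.0, 1.0, 0.5), ["E1"]))
        # power scales with amplitude squared
        assert table.alpha_change.iloc[0] == pytest.approx(np.log(0.25),
                                                           abs=0.25)

    def test_out_of_band_tone_near_floor(self):
        in_band = alpha_power(_epochs(self._epoch_tone(10.0), ["E1"]))
        t = np.arange(-1.0, 1.0, 1 / FS)
        x = np.sin(2 * np.pi * 30.0 * t)[None, None, :]
        from mne.time_frequency import tfr_array_morlet

        p10 = tfr_array_morlet(self._epoch_tone(10.0), sfreq=FS,
                               freqs=np.arange(8, 14), n_cycles=5,
                               output="power", verbose="error").mean()
        p30 = tfr_array_morlet(x, sfreq=FS, freqs=np.arange(8, 14),
                               n_cycles=5, output="power",
                               verbose="error").mean()
        assert p30 < 0.01 * p10

    def test_short_epoch_rejected(self):
        ep = _epochs(np.zeros((1, 1, int(0.4 * FS))), ["E1"],
                     window=(-0.2, 0.2))
        with pytest.raises(ValueError, match="wavelet"):
            alpha_power(ep)


class TestRoiAggregation:
    def test_left_central_is_mean_of_published_electrodes(self):
        members = DEFAULT_ROI_MAP.eeg_electrodes("left central")
        rng = np.random.default_rng(0)
        vals = rng.normal(size=len(members))
        table = pd.DataFrame({
            "condition": "ME", "trial": 0,
            "electrode": members, "alpha_change": vals,
        })
        agg = aggregate_eeg_rois(table)
        assert len(agg) == 1
        assert agg.alpha_change.iloc[0] == pytest.approx(vals.mean())

    def test_constant_value_preserved(self):
        members = DEFAULT_ROI_MAP.eeg_electrodes("right parietal")
        table = pd.DataFrame({"condition": "MO", "trial": 1,
                              "electrode": members, "alpha_change": 0.7})
        agg = aggregate_eeg_rois(table)
        assert agg.alpha_change.iloc[0] == pytest.approx(0.7)

    def test_member_order_irrelevant(self):
        members = DEFAULT_ROI_MAP.eeg_electrodes("left parietal")
        rng = np.random.default_rng(1)
        vals = rng.normal(size=len(members))
        t1 = pd.DataFrame({"condition": "MI", "trial": 0,
                           "electrode": members, "alpha_change": vals})
        perm = rng.permutation(len(members))
        t2 = t1.iloc[perm]
        a1 = aggregate_eeg_rois(t1).alpha_change.iloc[0]
        a2 = aggregate_eeg_rois(t2).alpha_change.iloc[0]
        assert a1 == pytest.approx(a2)

    def test_unknown_electrodes_ignored(self):
        table = pd.DataFrame({"condition": "ME", "trial": 0,
                              "electrode": ["E999"], "alpha_change": [1.0]})
        assert len(aggregate_eeg_rois(table)) == 0
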
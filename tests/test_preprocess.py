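import dataclasses

import numpy as np
import pytest

import bex
from bex.epochs import EpochSet, default_times, load_epochs, save_epochs

from conftest import make_epochs


def flat_epochs(montage, values, conditions=("CC",)):
    """EpochSet whose every sample equals `values[i]` for epoch i."""
    times = default_times()
    n = len(values)
    data = np.ones((n, len(montage), len(times))) * \
        np.asarray(values)[:, None, None]
    return EpochSet(data=data, times=times, sfreq=500.0,
                    conditions=np.array(list(conditions) * (n // len(conditions))
                                        or list(conditions)[:n], dtype=object),
                    ch_names=tuple(montage.names), ch_kinds=tuple(montage.kinds))


def sine_epochs(montage, freq_hz, amp=1.0):
    times = default_times()
    wave = amp * np.sin(2 * np.pi * freq_hz * times / 1000.0)
    data = np.tile(wave, (1, len(montage), 1))
    return EpochSet(data=data, times=times, sfreq=500.0,
                    conditions=np.array(["CC"], dtype=object),
                    ch_names=tuple(montage.names), ch_kinds=tuple(montage.kinds))


# ---------------------------------------------------------------------------
# Band-pass filter
# ---------------------------------------------------------------------------

def _response_at(ep_in, ep_out, freq_hz):
    """Amplitude of the filtered signal at the probe frequency (quadrature
    projection over the epoch interior, away from edge transients)."""
    mid = (ep_in.times > 100) & (ep_in.times < 700)
    phase = 2 * np.pi * freq_hz * ep_in.times[mid] / 1000.0
    y = ep_out.data[0, 0, mid]
    return np.hypot(2 * np.mean(y * np.sin(phase)),
                    2 * np.mean(y * np.cos(phase)))


def test_passband_10hz_attenuation_below_5pct(montage):
    ep = sine_epochs(montage, 10.0)
    out = bex.bandpass_filter(ep)
    assert _response_at(ep, out, 10.0) > 0.95


def test_stopband_100hz_attenuation_above_90pct(montage):
    ep = sine_epochs(montage, 100.0)
    out = bex.bandpass_filter(ep)
    assert _response_at(ep, out, 100.0) < 0.10


def test_dc_removed(montage):
    ep = flat_epochs(montage, [5.0])
    out = bex.bandpass_filter(ep)
    assert np.abs(out.data).max() < 1e-6


def test_filter_cutoff_validation(montage):
    ep = flat_epochs(montage, [1.0])
    with pytest.raises(ValueError):
        bex.bandpass_filter(ep, low_hz=30.0, high_hz=0.1)
    with pytest.raises(ValueError):
        bex.bandpass_filter(ep, low_hz=0.1, high_hz=400.0)


# ---------------------------------------------------------------------------
# Re-referencing
# ---------------------------------------------------------------------------

def test_rereference_simple_values(montage):
    ep = flat_epochs(montage, [1.0])
    eeg_idx = np.flatnonzero(ep.eeg_mask())[:3]
    ep.data[:] = 0.0
    ep.data[0, eeg_idx[0], :] = 1.0
    ep.data[0, eeg_idx[1], :] = 2.0
    ep.data[0, eeg_idx[2], :] = 3.0
    # restrict to a 3-channel EEG set to check the arithmetic exactly
    small = EpochSet(data=ep.data[:, eeg_idx, :], times=ep.times, sfreq=500.0,
                     conditions=ep.conditions,
                     ch_names=tuple(np.array(ep.ch_names)[eeg_idx]),
                     ch_kinds=("EEG",) * 3)
    out = bex.rereference_average(small)
    assert np.allclose(out.data[0, :, 0], [-1.0, 0.0, 1.0])


def test_rereference_zero_mean_and_idempotent(montage):
    ep = make_epochs(montage, ["CC", "WW"],
                     dataclasses.replace(bex.ErpEffectParams(), noise_sd=1.0,
                                         subject_gain_sd=0.0), seed=3)
    out = bex.rereference_average(ep)
    eeg = out.eeg_mask()
    assert np.allclose(out.data[:, eeg, :].mean(axis=1), 0.0, atol=1e-12)
    again = bex.rereference_average(out)
    assert np.allclose(again.data, out.data, atol=1e-12)
    # EOG untouched
    assert np.array_equal(out.data[:, ~eeg, :], ep.data[:, ~eeg, :])


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------

def test_baseline_constant_epoch_zeroed(montage):
    ep = flat_epochs(montage, [5.0])
    out = bex.baseline_correct(ep)
    assert np.allclose(out.data, 0.0)


def test_baseline_step_function(montage):
    ep = flat_epochs(montage, [0.0])
    ep.data[:, :, ep.times > 0] = 4.0
    out = bex.baseline_correct(ep)
    assert np.allclose(out.data[:, :, ep.times <= 0], 0.0)
    assert np.allclose(out.data[:, :, ep.times > 0], 4.0)


def test_baseline_mean_zero_for_every_epoch_channel(montage):
    ep = make_epochs(montage, ["CC"] * 3,
                     dataclasses.replace(bex.ErpEffectParams(), noise_sd=2.0,
                                         subject_gain_sd=0.0), seed=5)
    out = bex.baseline_correct(ep)
    win = (out.times >= -100) & (out.times <= 0)
    assert np.allclose(out.data[:, :, win].mean(axis=-1), 0.0, atol=1e-12)


def test_baseline_empty_window_errors(montage):
    ep = flat_epochs(montage, [1.0])
    with pytest.raises(ValueError):
        bex.baseline_correct(ep, (-500.0, -400.0))


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

def test_epoch_over_threshold_on_eog_rejected(montage):
    ep = flat_epochs(montage, [0.0, 0.0], conditions=("CC", "CC"))
    i_eog = ep.ch_names.index("VEOGU")
    ep.data[1, i_eog, 200] = 80.0
    kept, log = bex.reject_artifacts(ep, 75.0)
    assert kept.n_trials == 1
    assert not log.kept[1]
    assert "VEOGU" in log.offending[1]


def test_all_quiet_epochs_kept(montage):
    ep = make_epochs(montage, ["CC", "WW", "CW", "WC"],
                     dataclasses.replace(bex.ErpEffectParams(), noise_sd=1.0,
                                         subject_gain_sd=0.0), seed=8)
    kept, log = bex.reject_artifacts(ep, 75.0)
    assert kept.n_trials == 4
    assert log.kept.all()
    assert np.abs(kept.data).max() <= 75.0


def test_rejecting_whole_condition_errors(montage):
    ep = flat_epochs(montage, [100.0, 0.0], conditions=("CC", "WW"))
    with pytest.raises(ValueError, match="CC"):
        bex.reject_artifacts(ep, 75.0)


# ---------------------------------------------------------------------------
# Averaging, downsampling, channel selection
# ---------------------------------------------------------------------------

def test_average_single_epoch_identity(montage, noiseless_effects):
    ep = make_epochs(montage, ["CC", "WW", "CW", "WC"], noiseless_effects)
    erp = bex.average_by_condition(ep)
    for i, c in enumerate(ep.conditions):
        assert np.array_equal(erp.data[c], ep.data[i])
        assert erp.n_trials[c] == 1


def test_average_cancellation(montage):
    ep = flat_epochs(montage, [3.0, -3.0], conditions=("CC", "CC"))
    erp = bex.average_by_condition(ep)
    assert np.allclose(erp.data["CC"], 0.0)
    assert erp.n_trials["CC"] == 2


def test_downsample_500_to_100(montage, noiseless_effects):
    ep = make_epochs(montage, ["CC"], noiseless_effects)
    erp = bex.average_by_condition(ep)
    low = bex.downsample(erp, 100.0)
    assert low.data["CC"].shape[1] == 100
    assert np.allclose(np.diff(low.times), 10.0)
    assert 0.0 in low.times
    assert np.allclose(low.times % 10.0, 0.0)
    n_in_window = int(((low.times >= 100) & (low.times <= 600)).sum())
    assert n_in_window == 51


def test_downsample_constant_and_bad_factor(montage):
    ep = flat_epochs(montage, [2.0])
    erp = bex.average_by_condition(ep)
    low = bex.downsample(erp, 100.0)
    assert np.allclose(low.data["CC"], 2.0)
    with pytest.raises(ValueError):
        bex.downsample(erp, 150.0)


def test_select_channels_order_and_errors(montage, noiseless_effects):
    ep = make_epochs(montage, ["CC"], noiseless_effects)
    erp = bex.average_by_condition(ep)
    sub = bex.select_channels(erp, bex.SUBSET_34)
    assert sub.ch_names == tuple(bex.SUBSET_34)
    assert sub.data["CC"].shape[0] == 34
    ident = bex.select_channels(erp, erp.ch_names)
    assert np.array_equal(ident.data["CC"], erp.data["CC"])
    with pytest.raises(KeyError):
        bex.select_channels(erp, ("Nope1",))
    for ch in ("TP7", "P7", "P4", "F7"):
        assert ch in sub.ch_names


def test_average_and_downsample_commute(montage):
    eff = dataclasses.replace(bex.ErpEffectParams(), noise_sd=2.0,
                              subject_gain_sd=0.0)
    ep = make_epochs(montage, ["CC", "CC", "WW", "WW"], eff, seed=10)
    route_a = bex.downsample(bex.average_by_condition(ep), 100.0)
    # decimate epochs with the same phase anchor, then average
    anchor = int(np.argmin(np.abs(ep.times)))
    keep = (np.arange(len(ep.times)) - anchor) % 5 == 0
    ep_dec = EpochSet(data=ep.data[:, :, keep], times=ep.times[keep],
                      sfreq=100.0, conditions=ep.conditions,
                      ch_names=ep.ch_names, ch_kinds=ep.ch_kinds)
    route_b = bex.average_by_condition(ep_dec)
    for c in ("CC", "WW"):
        assert np.allclose(route_a.data[c], route_b.data[c], atol=1e-12)


def test_chain_rerun_bit_identical(montage):
    eff = bex.ErpEffectParams().rescaled_for_trials(16)
    ep = make_epochs(montage, ["CC", "WW", "CW", "WC"] * 2, eff, seed=12)
    erp1, _ = bex.preprocess_subject(ep, subset=bex.SUBSET_34)
    erp2, _ = bex.preprocess_subject(ep, subset=bex.SUBSET_34)
    for c in erp1.conditions:
        assert np.array_equal(erp1.data[c], erp2.data[c])


def test_epochs_hdf5_roundtrip(tmp_path, montage):
    eff = dataclasses.replace(bex.ErpEffectParams(), noise_sd=1.0,
                              subject_gain_sd=0.0)
    ep = make_epochs(montage, ["CC", "WW"], eff, seed=13)
    path = tmp_path / "epochs.h5"
    save_epochs(path, ep)
    back = load_epochs(path)
    assert back.ch_names == ep.ch_names
    assert back.ch_kinds == ep.ch_kinds
    assert np.array_equal(back.conditions, ep.conditions)
    assert back.sfreq == ep.sfreq
    assert np.allclose(back.data, ep.data, atol=1e-4)  # float32 storage
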
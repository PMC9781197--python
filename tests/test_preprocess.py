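"""Bandpass filtering, epoch extraction, feature layout, ERP averaging."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import signal as sps

from p300home import (
    EEGRecording,
    ParadigmConfig,
    PreprocConfig,
    SimulationConfig,
    average_erps,
    bandpass,
    extract_epochs,
    make_schedule,
    simulate_recording,
)

FS = 250.0


def _recording(samples, events=()):
    n_ch = samples.shape[0]
    names = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "PO8", "Oz")[:n_ch]
    return EEGRecording(
        samples=samples, sampling_rate=FS, channel_names=names, events=list(events)
    )


def _sine(freq, duration=20.0):
    t = np.arange(int(duration * FS)) / FS
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_dc_is_removed(self, preproc):
        rec = _recording(np.full((8, 5000), 37.0))
        out = bandpass(rec, preproc)
        assert np.abs(out.samples[:, 1000:-1000]).max() < 1.0

    def test_50hz_attenuated_by_analytic_margin_vs_10hz(self, preproc):
        """Time-domain attenuation matches the designed Butterworth
        magnitude response at 50 vs 10 Hz (frequency-response oracle)."""
        sos = sps.butter(3, [0.1, 25.0], btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=[10.0, 50.0], fs=FS)
        # zero-phase filtering applies the magnitude response twice
        expected_ratio = (np.abs(h[1]) / np.abs(h[0])) ** 2
        out = {}
        for f in (10.0, 50.0):
            rec = _recording(np.tile(_sine(f, duration=40.0), (8, 1)))
            filt = bandpass(rec, preproc).samples[0, 2500:7500]
            # project onto the stimulus frequency: isolates the steady
            # state from the slow high-pass edge transient
            seg_t = np.arange(2500, 7500) / FS
            out[f] = 2 * np.abs(np.mean(filt * np.exp(-2j * np.pi * f * seg_t)))
        measured_ratio = out[50.0] / out[10.0]
        assert measured_ratio == pytest.approx(expected_ratio, rel=0.05)
        assert 20 * np.log10(1 / measured_ratio) > 10  # > 10 dB down

    def test_midband_amplitude_preserved(self, preproc):
        rec = _recording(np.tile(_sine(10.0, duration=40.0), (8, 1)))
        filt = bandpass(rec, preproc).samples[0, 2500:7500]
        seg_t = np.arange(2500, 7500) / FS
        amp = 2 * np.abs(np.mean(filt * np.exp(-2j * np.pi * 10.0 * seg_t)))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_zero_phase_keeps_symmetric_pulse_symmetric(self):
        pulse = np.zeros((1, 4001))
        pulse[0, 1800:2201] = np.hanning(401)
        out = bandpass(_recording(pulse[:1]), PreprocConfig(filter_mode="zero_phase"))
        assert int(np.argmax(out.samples[0])) == 2000  # no peak lag
        seg = out.samples[0, 1500:2501]
        # truncating the very long 0.1 Hz impulse response leaves a
        # small (<1e-2) asymmetry on a finite signal
        assert np.allclose(seg, seg[::-1], atol=0.01)

    def test_band_above_nyquist_rejected(self):
        cfg = PreprocConfig(band_high=130.0)
        with pytest.raises(ValueError):
            bandpass(_recording(np.zeros((1, 1000))), cfg)


class TestExtractEpochs:
    def test_feature_dimensions(self, paradigm, sim_config, preproc):
        sched = make_schedule(paradigm, 0)
        rec = simulate_recording(sched, 3, sim_config, rng=0)
        epochs = extract_epochs(rec, preproc)
        assert epochs.samples_per_epoch == 200
        assert epochs.features.shape == (180, 1600)
        assert epochs.labels.sum() == 15

    def test_zero_recording_gives_zero_features(self, preproc):
        rec = _recording(np.zeros((8, 1000)), events=[(0.5, 2, False), (1.0, 3, True)])
        epochs = extract_epochs(rec, preproc)
        assert not epochs.features.any()

    def test_channel_major_layout(self, preproc):
        """Feature c*spe+t is channel c at sample t; permuting the analysis
        channel order permutes the feature blocks accordingly."""
        data = np.arange(8 * 1000, dtype=float).reshape(8, 1000)
        rec = _recording(data, events=[(0.4, 0, True), (1.2, 1, False)])
        epochs = extract_epochs(rec, preproc)
        start = int(0.4 * FS)
        for c in range(8):
            assert np.array_equal(
                epochs.features[0, c * 200 : (c + 1) * 200],
                data[c, start : start + 200],
            )
        swapped = replace(
            preproc, analysis_channels=tuple(reversed(preproc.analysis_channels))
        )
        ep2 = extract_epochs(rec, swapped)
        assert np.array_equal(ep2.features[0, :200], data[7, start : start + 200])

    def test_missing_channel_rejected(self, preproc):
        rec = _recording(np.zeros((4, 1000)), events=[(0.1, 0, False)])
        with pytest.raises(ValueError, match="missing"):
            extract_epochs(rec, preproc)

    def test_truncated_window_rejected(self, preproc):
        rec = _recording(np.zeros((8, 300)), events=[(0.5, 0, False)])
        with pytest.raises(ValueError, match="truncated"):
            extract_epochs(rec, preproc)


class TestAverageErps:
    def test_mean_of_identical_epochs_is_that_epoch(self, preproc):
        data = np.zeros((8, 2000))
        data[:, :] = np.arange(2000)[None, :] % 7
        events = [(0.0, 0, True), (0.0, 1, False)]
        epochs = extract_epochs(_recording(data, events), preproc)
        t_mean, nt_mean = average_erps(epochs)
        assert np.allclose(t_mean, nt_mean)
        assert np.allclose(t_mean, data[:, :200])

    def test_single_class_rejected(self, preproc):
        rec = _recording(np.zeros((8, 1000)), events=[(0.1, 0, True)])
        with pytest.raises(ValueError):
            average_erps(extract_epochs(rec, preproc))

    def test_target_average_peaks_near_300ms_nontarget_flat(
        self, paradigm, preproc
    ):
        quiet = SimulationConfig(noise_sigma=0.5)
        sched = make_schedule(paradigm, 8)
        rec = simulate_recording(sched, 6, quiet, rng=8)
        epochs = extract_epochs(bandpass(rec, preproc), preproc)
        t_mean, nt_mean = average_erps(epochs)
        pz = 3  # Pz is the dominant channel
        peak_ms = np.argmax(t_mean[pz]) / FS * 1000
        assert abs(peak_ms - 300) <= 40
        assert t_mean[pz].max() > 5 * np.abs(nt_mean[pz]).max()

    def test_secondary_display_average_peak_larger(self, preproc, sim_config):
        quiet = replace(sim_config, noise_sigma=0.5)
        peaks = {}
        for cfg in (ParadigmConfig(), ParadigmConfig.secondary()):
            sched = make_schedule(cfg, 9)
            rec = simulate_recording(sched, 1, quiet, rng=9)
            epochs = extract_epochs(bandpass(rec, preproc), preproc)
            t_mean, _ = average_erps(epochs)
            peaks[cfg.display] = t_mean[3].max()
        assert peaks["secondary_numbers"] > peaks["primary_symbols"]
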
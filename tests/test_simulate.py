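"""Synthetic-recording generator: templates, propagation geometry, noise,
electroporation/resealing, impedance tables."""

import numpy as np
import pytest
from scipy import stats as sps

from meakit import core_io, simulate
from meakit.errors import ParameterError


class TestExtracellularTemplate:
    def test_negative_peak_is_exact_and_ends_at_zero(self):
        w = simulate.make_extracellular_template(amp_neg=-123.4)
        assert w.min() == -123.4
        assert w[0] == 0.0 and w[-1] == 0.0

    def test_triphasic_positive_phases_below_100uV(self):
        w = simulate.make_extracellular_template(amp_neg=-123.4)
        imin = np.argmin(w)
        lead, trail = w[:imin], w[imin:]
        assert 0 < lead.max() < 100.0
        assert 0 < trail.max() < 100.0
        assert max(lead.max(), trail.max()) < abs(w.min())

    def test_linearity_in_amplitude(self):
        w1 = simulate.make_extracellular_template(amp_neg=-100.0)
        w2 = simulate.make_extracellular_template(amp_neg=-200.0)
        np.testing.assert_allclose(2 * w1, w2, rtol=1e-12)

    def test_nonnegative_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            simulate.make_extracellular_template(amp_neg=10.0)


class TestIntracellularTemplate:
    def test_plateau_flat_within_ten_percent(self):
        width = 4.0
        w = simulate.make_intracellular_template(plateau_width_ms=width)
        fs_ms = 20.0  # samples per ms at 20 kHz
        centre = (3.0 + 1.2 + width / 2) * fs_ms
        half = width / 2 * fs_ms
        plateau = w[int(centre - half) : int(centre + half)]
        level = -100.0 * 0.35
        assert np.all(np.abs(plateau - level) < 0.1 * abs(level))

    def test_no_trailing_positive_hump(self):
        w = simulate.make_intracellular_template(amp=-100.0)
        trail = w[np.argmin(w) :]
        assert trail.max() < 0.05 * 100.0

    def test_zero_plateau_width_degenerates_to_biphasic(self):
        w = simulate.make_intracellular_template(plateau_width_ms=0.0)
        # beyond the negative lobe the waveform returns to baseline: no
        # samples near a plateau level
        trail = w[np.argmin(w) + 40 :]  # 2 ms past the peak
        assert np.all(np.abs(trail) < 0.05 * 100.0)


class TestSimulateRecording:
    def test_noise_only_rms_matches_request(self):
        layout = core_io.ElectrodeLayout(
            {"a": (0, 0), "b": (700, 0), "c": (0, 700)}
        )
        params = simulate.SimulationParams(
            duration=60.0, firing_rate=0.0, noise_rms=12.0, seed=4
        )
        rec, gt = simulate.simulate_recording(params, layout)
        assert gt.n_spikes == 0
        rms = np.sqrt(np.mean(rec.data.astype(float) ** 2, axis=1))
        np.testing.assert_allclose(rms, 12.0, rtol=0.02)

    def test_identical_seed_identical_recording(self, layout60):
        params = simulate.SimulationParams(duration=2.0, seed=9)
        rec1, _ = simulate.simulate_recording(params, layout60)
        rec2, _ = simulate.simulate_recording(params, layout60)
        np.testing.assert_array_equal(rec1.data, rec2.data)

    def test_ground_truth_latency_across_one_pitch(self):
        # 700 um at 0.32 m/s is 2.1875 ms
        layout = core_io.ElectrodeLayout({"a": (0, 0), "b": (700, 0)})
        params = simulate.SimulationParams(
            duration=2.0, velocity=0.32, direction=(1, 0), seed=0,
            jitter_sd=0.0, amp_rel_sd=0.0,
        )
        _, gt = simulate.simulate_recording(params, layout)
        dt = gt.spike_times["b"] - gt.spike_times["a"]
        np.testing.assert_allclose(dt, 2.1875e-3, rtol=1e-12)

    def test_latencies_match_projected_distance_over_velocity(self, layout60):
        params = simulate.SimulationParams(
            duration=1.0, velocity=0.1, direction=(0.6, 0.8), seed=2
        )
        _, gt = simulate.simulate_recording(params, layout60)
        ev = gt.events[0]
        d = np.asarray(ev.direction)
        for e in ("22", "55", "87"):
            proj = (np.array(layout60.positions[e]) - ev.origin) @ d
            expected = ev.t + proj * 1e-6 / ev.velocity
            if len(gt.spike_times[e]):
                assert abs(gt.spike_times[e][0] - expected) < 1 / 20_000

    def test_quantized_output_on_adc_grid(self, small_sim):
        _, rec, _ = small_sim
        step = np.float32(0.195)
        requantized = np.round(rec.data / step) * step
        np.testing.assert_array_equal(rec.data, requantized)

    def test_noise_normality_excess_kurtosis(self):
        layout = core_io.ElectrodeLayout({"a": (0, 0)})
        params = simulate.SimulationParams(
            duration=50.0, firing_rate=0.0, noise_rms=5.0, seed=5
        )
        rec, _ = simulate.simulate_recording(params, layout)
        kurt = sps.kurtosis(rec.data[0].astype(float))
        assert abs(kurt) < 0.1

    def test_overlapping_event_trains_warn(self):
        layout = core_io.ElectrodeLayout({"a": (0, 0), "b": (700, 0)})
        params = simulate.SimulationParams(
            duration=0.5, firing_rate=200.0, seed=1
        )
        with pytest.warns(UserWarning, match="superposed"):
            simulate.simulate_recording(params, layout)

    @pytest.mark.parametrize(
        "bad",
        [
            {"duration": 0.0},
            {"velocity": 0.0},
            {"amp_mean": 10.0},
            {"noise_rms": -1.0},
            {"firing_rate": -1.0},
            {"direction": (0.0, 0.0)},
        ],
    )
    def test_invalid_params(self, bad):
        with pytest.raises(ParameterError):
            simulate.SimulationParams(**bad)


@pytest.fixture(scope="module")
def porated():
    layout = core_io.ElectrodeLayout({"a": (0, 0), "b": (700, 0)})
    params = simulate.SimulationParams(
        duration=40.0, noise_rms=0.0, seed=3, quantization_step=0.0,
        jitter_sd=0.0, amp_rel_sd=0.0,
    )
    rec, gt = simulate.simulate_electroporation(
        params, "a", t_onset=10.0, reseal_tau=8.0, layout=layout
    )
    return params, rec, gt


class TestElectroporation:
    @staticmethod
    def _snippets(rec, times):
        fs = rec.sampling_rate
        extra = simulate.make_extracellular_template(12.0, amp_neg=-1.0)
        off = simulate.template_peak_index(extra)
        out = []
        for t in times:
            i = int(round(t * fs)) - off
            out.append(rec.channel("a")[i : i + len(extra)].astype(float))
        return extra, out

    def test_mixing_weight_below_one_percent_after_five_taus(self, porated):
        params, rec, gt = porated
        t_on, tau = 10.0, 8.0
        times = gt.spike_times["a"]
        late = times[times > t_on + 5 * tau]
        extra, snips = self._snippets(rec, late)
        for s in snips:
            unit = s / -s.min()
            # residual intracellular contribution: relative deviation from
            # the extracellular shape
            rel = np.abs(unit - extra).max()
            intra = simulate.make_intracellular_template(12.0, amp=-1.0)
            scale = np.abs(intra - extra).max()
            assert rel / scale < 0.01

    def test_resealing_correlation_monotone(self, porated):
        params, rec, gt = porated
        times = gt.spike_times["a"]
        post = times[times >= 10.0]
        extra, snips = self._snippets(rec, post)
        corrs = [np.corrcoef(s, extra)[0, 1] for s in snips]
        assert np.all(np.diff(corrs) >= -1e-12)

    def test_other_electrodes_keep_extracellular_shape(self, porated):
        params, rec, gt = porated
        times = gt.spike_times["b"]
        post = times[(times > 11.0) & (times < params.duration - 0.1)]
        fs = rec.sampling_rate
        extra = simulate.make_extracellular_template(12.0, amp_neg=-1.0)
        off = simulate.template_peak_index(extra)
        for t in post[:5]:
            i = int(round(t * fs)) - off
            s = rec.channel("b")[i : i + len(extra)].astype(float)
            assert np.corrcoef(s, extra)[0, 1] > 0.9999

    def test_tiny_tau_first_post_onset_spike_extracellular(self):
        layout = core_io.ElectrodeLayout({"a": (0, 0), "b": (700, 0)})
        params = simulate.SimulationParams(
            duration=4.0, noise_rms=0.0, seed=3, quantization_step=0.0,
            jitter_sd=0.0, amp_rel_sd=0.0,
        )
        rec, gt = simulate.simulate_electroporation(
            params, "a", t_onset=1.0, reseal_tau=1e-9, layout=layout
        )
        extra, snips = self._snippets(
            rec, [t for t in gt.spike_times["a"] if t > 1.0][:1]
        )
        assert np.corrcoef(snips[0], extra)[0, 1] > 0.9999

    def test_unknown_electrode_rejected(self, layout60):
        params = simulate.SimulationParams(duration=1.0, seed=0)
        with pytest.raises(ParameterError, match="nope"):
            simulate.simulate_electroporation(
                params, "nope", 0.5, 1.0, layout=layout60
            )


class TestImpedanceSet:
    def test_zero_spread_identity_distortion_reproduces_means(self):
        df = simulate.simulate_impedance_set(spread=0.0, seed=0)
        for f, mean in simulate.IMPEDANCE_MEAN_KOHM.items():
            vals = df.loc[df["frequency_hz"] == f, "true_kohm"]
            assert (vals == mean).all()
            raw = df.loc[df["frequency_hz"] == f, "raw_kohm"]
            assert (raw == mean).all()

    def test_seed_reproducibility(self):
        a = simulate.simulate_impedance_set(seed=42)
        b = simulate.simulate_impedance_set(seed=42)
        assert a.equals(b)

    def test_affine_distortion_applied_cellwise(self):
        df = simulate.simulate_impedance_set(
            spread=1.0, distortion=(0.9, 5.0), seed=1
        )
        np.testing.assert_allclose(
            df["raw_kohm"], 0.9 * df["true_kohm"] + 5.0, rtol=1e-12
        )

    def test_negative_spread_rejected(self):
        with pytest.raises(ParameterError):
            simulate.simulate_impedance_set(spread=-0.1)


class TestPersistence:
    def test_simulation_round_trip(self, tmp_path, small_sim, layout60):
        _, rec, gt = small_sim
        path = tmp_path / "sim.h5"
        simulate.save_simulation(path, rec, layout60, gt)
        rec2, layout2 = core_io.read_container(path)
        gt2 = simulate.load_ground_truth(path)
        np.testing.assert_array_equal(rec.data, rec2.data)
        assert gt2.n_spikes == gt.n_spikes
        for e in layout60.ids:
            np.testing.assert_allclose(
                np.sort(gt.spike_times[e]), gt2.spike_times[e], rtol=1e-15
            )
        assert len(gt2.events) == len(gt.events)
        assert gt2.events[0].velocity == gt.events[0].velocity
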
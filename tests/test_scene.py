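import numpy as np
import pytest

from echoplace.scene import (
    ConfigurationError,
    DegenerateGeometryError,
    DeviceSpec,
    DirectionGrid,
    Reflector,
    SamplingDesign,
    Scene,
    beam_gain,
    generate_dataset,
    generate_scene,
    hfm_call,
    synthesize_echo_train,
)


class TestDirectionGrid:
    def test_default_device_grid(self):
        g = DirectionGrid.default()
        assert g.n_directions == 217
        assert g.n_azimuths == 31 and g.n_elevations == 7
        assert np.allclose(np.diff(g.azimuths), 10.0)
        assert np.allclose(np.diff(g.elevations), 10.8)
        assert g.azimuths[0] == -150.0 and g.azimuths[-1] == 150.0
        assert g.elevations[0] == -25.0

    def test_elevation_major_ordering(self):
        g = DirectionGrid.default()
        # index = el_index * 31 + az_index
        az, el = g.direction(g.index_of(az_index=3, el_index=2))
        assert az == pytest.approx(-120.0)
        assert el == pytest.approx(-25.0 + 2 * 10.8)


class TestDeviceSpec:
    def test_sample_count(self, full_spec):
        assert full_spec.n_samples == 7446

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ConfigurationError):
            DeviceSpec(record_duration=34.0001e-3)

    def test_mic_array_is_compact(self, full_spec):
        assert full_spec.mic_offsets.shape == (31, 3)
        assert np.linalg.norm(full_spec.mic_offsets, axis=1).max() <= 0.025 + 1e-12


class TestGenerateScene:
    REGION = ((2.0, 12.0), (0.0, 1.0), (0.0, 1.0))  # 10 m³, clear of keep-out

    def test_open_has_no_reflectors(self):
        scene = generate_scene("open", 5.0, self.REGION, rng_seed=1)
        assert len(scene.reflectors) == 0

    def test_poisson_mean_count(self):
        # density 5 m⁻³ × volume 10 m³ → mean 50 reflectors
        counts = [
            len(generate_scene("cluttered", 5.0, self.REGION, rng_seed=s).reflectors)
            for s in range(1000)
        ]
        assert np.mean(counts) == pytest.approx(50.0, abs=1.0)

    def test_seeded_determinism(self):
        a = generate_scene("cluttered", 2.0, self.REGION, rng_seed=7)
        b = generate_scene("cluttered", 2.0, self.REGION, rng_seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.strengths, b.strengths)

    def test_unknown_archetype(self):
        with pytest.raises(ConfigurationError):
            generate_scene("urban", 1.0, self.REGION, rng_seed=0)

    def test_degenerate_region(self):
        with pytest.raises(ConfigurationError):
            generate_scene("cluttered", 1.0, ((0, 0), (0, 1), (0, 1)), rng_seed=0)


class TestBeamGain:
    def test_boresight_is_unity(self, full_spec):
        assert beam_gain(0.0, 55e3, full_spec) == 1.0

    def test_minus_3db_at_half_opening_angle(self, full_spec):
        # 20° two-sided 3 dB width → one-sided −3 dB at 10°
        assert beam_gain(10.0, 55e3, full_spec) == pytest.approx(10 ** (-3 / 20))

    def test_monotone_taper(self, full_spec):
        offs = np.linspace(0, 60, 25)
        g = beam_gain(offs, 55e3, full_spec)
        assert np.all(np.diff(g) < 0)
        assert beam_gain(5.0, 55e3, full_spec) >= beam_gain(15.0, 55e3, full_spec)

    def test_narrower_at_higher_frequency(self, full_spec):
        assert beam_gain(10.0, 90e3, full_spec) < beam_gain(10.0, 45e3, full_spec)

    def test_out_of_band_frequency_rejected(self, full_spec):
        with pytest.raises(ConfigurationError):
            beam_gain(5.0, 20e3, full_spec)


class TestSynthesis:
    def test_empty_scene_is_pickup_plus_noise(self, tiny_spec):
        scene = Scene((), "open")
        tr = synthesize_echo_train(scene, (0, 0, 0), (0.0, 0.0), 0, tiny_spec, 5)
        call_n = int(round(tiny_spec.call_duration * tiny_spec.sample_rate))
        tail = tr.waveform[call_n + 50 :]
        assert np.abs(tail).max() < 6 * tiny_spec.self_noise_level
        assert np.std(tail) == pytest.approx(tiny_spec.self_noise_level, rel=0.1)

    def test_echo_delay_matches_two_way_travel(self, tiny_spec_noiseless):
        spec = tiny_spec_noiseless
        scene = Scene((Reflector((1.0, 0.0, 0.0), 1.0),), "open")
        tr = synthesize_echo_train(scene, (0, 0, 0), (0.0, 0.0), 0, spec, 0)
        call = hfm_call(spec)
        xc = np.correlate(tr.waveform, call, mode="full")
        lags = np.arange(len(xc)) - (len(call) - 1)
        in_echo = lags > len(call)  # exclude the saturated pickup at t=0
        lag = lags[in_echo][np.argmax(xc[in_echo])]
        expected = 2 * 1.0 / spec.speed_of_sound * spec.sample_rate
        assert abs(lag - expected) <= 1.0

    def test_inverse_square_amplitude_law(self, tiny_spec_noiseless):
        spec = tiny_spec_noiseless
        amps = []
        for r in (0.5, 1.0):
            scene = Scene((Reflector((r, 0.0, 0.0), 1.0),), "open")
            tr = synthesize_echo_train(scene, (0, 0, 0), (0.0, 0.0), 0, spec, 0)
            start = int(round(spec.call_duration * spec.sample_rate)) + 50
            amps.append(np.abs(tr.waveform[start:]).max())
        assert amps[0] / amps[1] == pytest.approx(4.0, rel=0.01)

    def test_beam_symmetry(self, tiny_spec_noiseless):
        spec = tiny_spec_noiseless
        r = 1.0
        refl = tuple(
            Reflector((r * np.cos(np.deg2rad(a)), r * np.sin(np.deg2rad(a)), 0.0), 1.0)
            for a in (-5.0, 5.0)
        )
        amps = []
        for rf in refl:
            tr = synthesize_echo_train(Scene((rf,), "open"), (0, 0, 0), (0.0, 0.0), 0, spec, 0)
            start = int(round(spec.call_duration * spec.sample_rate)) + 50
            amps.append(np.abs(tr.waveform[start:]).max())
        assert amps[0] == pytest.approx(amps[1], rel=1e-9)

    def test_zero_range_is_degenerate(self, tiny_spec):
        scene = Scene((Reflector((0.0, 0.0, 0.0), 1.0),), "open")
        with pytest.raises(DegenerateGeometryError):
            synthesize_echo_train(scene, (0, 0, 0), (0.0, 0.0), 0, tiny_spec, 0)

    def test_direction_must_be_on_grid(self, tiny_spec):
        with pytest.raises(ConfigurationError):
            synthesize_echo_train(Scene((), "open"), (0, 0, 0), (17.0, 3.0), 0, tiny_spec, 0)

    def test_seeded_determinism(self, tiny_spec):
        scene = Scene((Reflector((1.0, 0.0, 0.0), 1.0),), "open")
        a = synthesize_echo_train(scene, (0, 0, 0), (0.0, 0.0), 0, tiny_spec, 11)
        b = synthesize_echo_train(scene, (0, 0, 0), (0.0, 0.0), 0, tiny_spec, 11)
        assert np.array_equal(a.waveform, b.waveform)


class TestGenerateDataset:
    def test_count_contract_and_tags(self, tiny_spec):
        design = SamplingDesign(poses=np.zeros((2, 3)))
        scene = Scene((), "open")
        trains = list(generate_dataset(scene, design, tiny_spec, 3))
        expected = 2 * tiny_spec.grid.n_directions * tiny_spec.n_repeats * tiny_spec.n_mics
        assert len(trains) == expected
        tags = {
            (t.position_index, t.direction_index, t.repeat_index, t.mic_index)
            for t in trains
        }
        assert len(tags) == expected

    def test_repeats_differ_only_in_noise(self, tiny_spec, tiny_spec_noiseless):
        scene = Scene((Reflector((1.0, 0.0, 0.0), 1.0),), "open")
        design = SamplingDesign(poses=np.zeros((1, 3)))
        noisy = [
            t for t in generate_dataset(scene, design, tiny_spec, 5)
            if t.direction_index == 4 and t.mic_index == 0
        ]
        clean = [
            t for t in generate_dataset(scene, design, tiny_spec_noiseless, 5)
            if t.direction_index == 4 and t.mic_index == 0
        ]
        # noiseless repeats are bit-identical; noisy ones share the echo part
        assert np.array_equal(clean[0].waveform, clean[1].waveform)
        resid = [n.waveform - clean[0].waveform for n in noisy]
        assert not np.array_equal(noisy[0].waveform, noisy[1].waveform)
        for r in resid:
            assert np.std(r) == pytest.approx(tiny_spec.self_noise_level, rel=0.1)

    def test_bit_identical_for_equal_seeds(self, tiny_spec):
        scene = Scene((Reflector((1.2, 0.3, 0.0), 2.0),), "open")
        design = SamplingDesign(poses=np.zeros((1, 3)))
        a = np.stack([t.waveform for t in generate_dataset(scene, design, tiny_spec, 9)])
        b = np.stack([t.waveform for t in generate_dataset(scene, design, tiny_spec, 9)])
        assert np.array_equal(a, b)

    def test_transect_validation(self):
        with pytest.raises(ConfigurationError):
            SamplingDesign(
                poses=[[0, 0, 0], [1, 0, 0], [2.5, 0, 0]], design_name="transect"
            )
        d = SamplingDesign.transect(5, 0.25)
        assert d.spacing == 0.25
        assert d.n_positions == 5
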
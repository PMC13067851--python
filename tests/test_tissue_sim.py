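"""Simulator unit and property tests: geometry, heterogeneity sampling,
integration physics, photocurrent phenomenology and sample measurements."""

import numpy as np
import pytest

from optoloop import tissue_sim as ts
from optoloop.errors import (
    ConfigError,
    InvalidGeometryError,
    MeasurementUndefinedError,
)
from optoloop.movie import VoltageMovie


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


class TestDomain:
    def test_paper_scale_side_length(self):
        dom = ts.make_domain(256, 60.0, 15.0)
        assert dom.side_mm == pytest.approx(15.36)

    def test_conducting_count_matches_enumeration_oracle(self):
        dom = ts.make_domain(256, 60.0, 15.0)
        # independent brute force: count node centers within 7.5 mm of center
        h = 0.06
        count = 0
        c = 256 * h / 2
        for i in range(256):
            for j in range(0, 256):
                if ((i + 0.5) * h - c) ** 2 + ((j + 0.5) * h - c) ** 2 <= 7.5**2:
                    count += 1
        assert dom.n_conducting == count

    def test_disc_is_centered(self, small_domain):
        m = small_domain.conducting_mask
        assert np.array_equal(m, m[::-1, :])
        assert np.array_equal(m, m[:, ::-1])

    @pytest.mark.parametrize("diameter", [0.0, -3.0])
    def test_degenerate_diameter_rejected(self, diameter):
        with pytest.raises(InvalidGeometryError):
            ts.make_domain(64, 240.0, diameter)

    def test_oversized_disc_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ts.make_domain(64, 100.0, 15.0)  # 6.4 mm field cannot hold 15 mm


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------


class TestHeterogeneity:
    def test_fields_within_ranges(self, small_domain):
        for seed in range(5):
            het = ts.sample_heterogeneity(small_domain, seed=seed)
            g = het.global_current_scale
            assert 0.83 <= g <= 1.20
            assert 0.25 <= het.coupling_scale <= 4.0
            rel = het.cell_current_scale / g
            assert rel.min() >= 0.5 and rel.max() <= 2.0

    def test_same_seed_bit_identical(self, small_domain):
        a = ts.sample_heterogeneity(small_domain, seed=7)
        b = ts.sample_heterogeneity(small_domain, seed=7)
        assert a.global_current_scale == b.global_current_scale
        assert a.coupling_scale == b.coupling_scale
        assert np.array_equal(a.cell_current_scale, b.cell_current_scale)

    def test_per_cell_median_matches_global(self, small_domain):
        # Monte-Carlo check of the log-uniform per-node distribution:
        # the sample median of ~1e5 node draws should sit at the global value
        het = ts.sample_heterogeneity(
            ts.make_domain(320, 48.0, 15.0), seed=42
        )
        med = np.median(het.cell_current_scale)
        assert abs(med / het.global_current_scale - 1.0) < 0.02

    def test_inverted_range_rejected(self, small_domain):
        with pytest.raises(ConfigError):
            ts.sample_heterogeneity(small_domain, {"cell": (2.0, 0.5)}, seed=0)


# ---------------------------------------------------------------------------
# Integration physics
# ---------------------------------------------------------------------------


def _quick_cfg(duration=100.0):
    return ts.SimulationConfig(dt_ms=0.1, record_every=60, duration_ms=duration)


class TestIntegration:
    def test_resting_state_is_stable(self, small_domain):
        sim = ts.Simulation(small_domain, config=_quick_cfg())
        u0 = sim.u.copy()
        sim.run(100.0)
        assert np.abs(sim.u - u0).max() < 1e-9

    def test_no_coupling_no_propagation(self, small_domain):
        het = ts.HeterogeneityFields(
            1.0, np.ones(small_domain.conducting_mask.shape), 0.0, 0
        )
        spot = ts.disc_mask(small_domain, (7.68, 7.68), 0.6)
        ev = ts.StimulusEvent("electrical", spot, 1.0, 4.0, 1.5)
        mov = ts.run_protocol(small_domain, het, [ev], _quick_cfg(200.0))
        excited = (mov.frames > -20).any(axis=0)
        assert np.array_equal(excited & small_domain.conducting_mask, spot)

    def test_pure_diffusion_conserves_total_u(self, small_domain):
        # reaction switched off: k = 0 kills both nonlinear terms at v = 0
        model = ts.CellModel(k=0.0, eps0=0.0, mu1=0.0)
        sim = ts.Simulation(small_domain, model=model, config=_quick_cfg())
        rng = np.random.default_rng(0)
        sim.u[:] = rng.random(sim.u.size)
        total0 = sim.u.sum()
        sim.run(50.0)
        assert sim.u.sum() == pytest.approx(total0, rel=1e-9)

    def test_nonconducting_nodes_never_change(self, spiral_movie, small_domain):
        outside = ~small_domain.conducting_mask
        vals = spiral_movie.frames[:, outside]
        assert np.all(vals == vals[0:1])

    def test_seed_determinism_of_protocol(self, small_domain):
        cfg = _quick_cfg(200.0)
        s12 = ts.S1S2Config()
        ev1, _ = ts.s1s2_events(small_domain, s12, seed=9)
        ev2, _ = ts.s1s2_events(small_domain, s12, seed=9)
        m1 = ts.run_protocol(small_domain, None, ev1, cfg)
        m2 = ts.run_protocol(small_domain, None, ev2, cfg)
        assert np.array_equal(m1.frames, m2.frames)

    def test_refractory_second_stimulus_launches_no_wave(self, small_domain):
        strip = ts.edge_strip_mask(small_domain, "left", 0.8)
        s1 = ts.StimulusEvent("electrical", strip, 2.0, 4.0, 1.5)
        # premature re-stimulation of the same strip well inside the APD
        s2 = ts.StimulusEvent("electrical", strip, 40.0, 4.0, 1.5)
        single = ts.run_protocol(small_domain, None, [s1], _quick_cfg(400.0))
        double = ts.run_protocol(small_domain, None, [s1, s2], _quick_cfg(400.0))
        # a second wave would re-activate the probe column a second time
        def activations(mov):
            tr = mov.frames[:, 32, 40]
            above = tr > -20
            return int((~above[:-1] & above[1:]).sum())

        assert activations(double) == activations(single) == 1

    def test_divergence_is_reported_with_step(self, small_domain):
        model = ts.CellModel(diffusivity=0.008)
        sim = ts.Simulation(small_domain, model=model, config=_quick_cfg())
        sim.u[:] = 1e6  # poisoned state blows up the cubic reaction
        with pytest.raises(ts.IntegrationDivergedError) as exc:
            sim.run(10.0)
        assert exc.value.step > 0


class TestPhotocurrent:
    def test_zero_irradiance_is_inert(self, small_domain):
        spot = ts.disc_mask(small_domain, (7.68, 7.68), 1.0)
        ev = ts.StimulusEvent("optical", spot, 1.0, 50.0, 0.0)
        mov = ts.run_protocol(small_domain, None, [ev], _quick_cfg(100.0))
        assert np.abs(mov.frames - mov.frames[0]).max() < 1e-9

    def test_out_of_range_irradiance_clipped(self, small_domain):
        spot = ts.disc_mask(small_domain, (7.68, 7.68), 1.0)
        ev = ts.StimulusEvent("optical", spot, 1.0, 50.0, 1.7)
        assert ev.amplitude == 1.0

    def test_block_pass_dichotomy(self, small_domain):
        """A sustained full-width light line blocks an incoming planar wave at
        high irradiance and lets it through at low irradiance."""
        yy, xx = small_domain.node_centers_mm()
        line = (np.abs(xx - small_domain.side_mm / 2) < 0.45) & small_domain.conducting_mask
        s1 = ts.StimulusEvent("electrical", ts.edge_strip_mask(small_domain, "left", 0.8),
                              300.0, 4.0, 1.5)
        crossed = {}
        for irr in (1.0, 0.01):
            block = ts.StimulusEvent("optical", line, 0.0, 600.0, irr)
            mov = ts.run_protocol(small_domain, None, [s1, block], _quick_cfg(600.0))
            right = mov.frames[int(300 / 6) + 2 :, 32, 52]
            crossed[irr] = bool(right.max() > -20)
        assert not crossed[1.0] and crossed[0.01]

    def test_optical_pacing_origin_at_spot(self, small_domain):
        """A 50 ms suprathreshold light spot on quiescent tissue launches a
        wave whose earliest activation is the illuminated nodes."""
        center = (small_domain.side_mm / 2, small_domain.side_mm / 2)
        spot = ts.disc_mask(small_domain, center, 0.8)
        ev = ts.StimulusEvent("optical", spot, 5.0, 50.0, 1.0)
        mov = ts.run_protocol(small_domain, None, [ev], _quick_cfg(200.0))
        first = np.full(mov.frames.shape[1:], np.inf)
        for t in range(mov.n_frames):
            newly = (mov.frames[t] > -20) & np.isinf(first)
            first[newly] = t
        inside = small_domain.conducting_mask
        assert np.isfinite(first[inside]).any()
        t_min = first[inside].min()
        earliest = (first == t_min) & inside
        assert earliest[spot].any() and not earliest[~spot].any()


# ---------------------------------------------------------------------------
# Protocols and measurements
# ---------------------------------------------------------------------------


class TestProtocol:
    def test_s2_after_full_recovery_gives_no_reentry(self, small_domain):
        s12 = ts.S1S2Config(s2_offset_ms=600.0)  # far beyond the APD
        events, _ = ts.s1s2_events(small_domain, s12, seed=4)
        cfg = ts.SimulationConfig(dt_ms=0.1, record_every=60, duration_ms=1250.0)
        mov = ts.run_protocol(small_domain, None, events, cfg,
                              prerecord_ms=events[-1].t_on_ms + 50.0)
        assert ts.classify_sample(mov) != "sustained_spiral"
        # tissue is quiescent at the end
        assert mov.frames[-1].max() < -60

    def test_s1s2_fixture_sustains_spiral(self, spiral_movie):
        assert ts.classify_sample(spiral_movie) == "sustained_spiral"


class TestMeasurements:
    def test_cv_on_constructed_constant_velocity_movie(self):
        # waveform translating at exactly 200 mm/s over a 100 um grid
        h_mm, dt_ms, speed = 0.1, 1.0, 0.2  # mm, ms, mm/ms
        T, n = 40, 80
        x = np.arange(n) * h_mm
        frames = np.empty((T, n, n), dtype=np.float32)
        for t in range(T):
            front = speed * t * dt_ms
            frames[t] = np.where(x[None, :] <= front, 20.0, -80.0)
        mov = VoltageMovie(frames, dt_ms, h_mm * 1000.0)
        cv = ts.measure_cv(mov)
        assert cv == pytest.approx(200.0, rel=0.02)

    def test_apd_of_square_pulse(self):
        dt = 1.0
        trace = np.full(400, -80.0)
        trace[100:250] = 20.0  # 150 ms square pulse
        for level in (0.5, 0.8, 0.9):
            assert ts.measure_apd(trace, dt, level) == pytest.approx(150.0, abs=1.5)

    def test_measurements_refuse_flat_input(self):
        flat = VoltageMovie(np.full((30, 20, 20), -80.0, np.float32), 6.0, 240.0)
        with pytest.raises(MeasurementUndefinedError):
            ts.measure_cv(flat)
        with pytest.raises(MeasurementUndefinedError):
            ts.measure_apd(np.full(100, -80.0), 1.0)
        with pytest.raises(MeasurementUndefinedError):
            ts.measure_spiral_frequency(flat)

    def test_spiral_frequency_of_fixture(self, spiral_movie):
        f = ts.measure_spiral_frequency(spiral_movie)
        assert 5.0 < f < 40.0


class TestClassification:
    def test_quiescent_movie_is_propagation_failure(self, small_domain):
        frames = np.full((40,) + small_domain.conducting_mask.shape, -80.0, np.float32)
        mov = VoltageMovie(frames, 6.0, small_domain.spacing_um)
        assert ts.classify_sample(mov) == "propagation_failure"

    def test_single_wave_is_not_sustained(self, small_domain):
        s1 = ts.StimulusEvent(
            "electrical", ts.edge_strip_mask(small_domain, "left", 0.8), 2.0, 4.0, 1.5
        )
        cfg = ts.SimulationConfig(dt_ms=0.1, record_every=60, duration_ms=1250.0)
        mov = ts.run_protocol(small_domain, None, [s1], cfg)
        assert ts.classify_sample(mov) == "no_sustained_spiral"
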
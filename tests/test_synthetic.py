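import numpy as np
import pytest
from scipy import stats

from rgctyping import params as rp
from rgctyping.sorting import consolidate_events, detect
from rgctyping.synthetic import (
    ElectrodeConfig,
    RateFunction,
    calibrate_decay,
    default_archetypes,
    drive,
    kappa_for_dsi,
    noiseless_responses,
    render_traces,
    sample_population,
    scatter_cells_on_block,
    spikes_from_rate,
    temporal_kernel,
    vonmises_direction_gain,
    vonmises_dsi,
)


class TestPopulationSampling:
    def test_counts_and_grouping(self, archetypes, field):
        cells = sample_population(archetypes, 40, field, seed=0)
        assert len(cells) == 280
        per = {}
        for c in cells:
            per[c.archetype] = per.get(c.archetype, 0) + 1
        assert set(per.values()) == {40}

    def test_determinism(self, archetypes, field):
        a = sample_population(archetypes, 5, field, seed=7)
        b = sample_population(archetypes, 5, field, seed=7)
        assert a == b

    def test_zero_sd_degenerate_draw(self, field):
        from conftest import canonical_archetypes
        cells = sample_population(canonical_archetypes()[:1], 10, field, seed=1)
        assert len({c.latency for c in cells}) == 1
        assert len({c.rf_diameter for c in cells}) == 1
        assert len({c.rf_center for c in cells}) > 1

    def test_empty_archetypes_rejected(self, field):
        with pytest.raises(ValueError):
            sample_population([], 5, field, seed=0)


class TestKernelCalibration:
    @pytest.mark.parametrize("lat,target", [
        (0.12, 0.2), (0.30, 0.2), (0.12, 0.3), (0.30, 0.7), (0.15, 0.4),
    ])
    def test_measured_transience_matches_target(self, lat, target):
        tau = calibrate_decay(lat, target)
        t = (np.arange(300) + 0.5) * 0.005
        psth = rp.PSTH(temporal_kernel(t, lat, tau))
        assert rp.transience(psth) == pytest.approx(target, abs=0.01)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_decay(1.2, 0.9)

    def test_kernel_peaks_at_latency(self):
        t = np.linspace(0, 1.5, 15001)
        k = temporal_kernel(t, 0.2, 0.3)
        assert t[np.argmax(k)] == pytest.approx(0.2, abs=1e-3)
        assert k.max() == pytest.approx(1.0, abs=1e-6)


class TestDirectionTuning:
    def test_kappa_for_dsi_round_trip(self):
        for target in (0.2, 0.4, 0.6, 0.8):
            assert vonmises_dsi(kappa_for_dsi(target)) == pytest.approx(
                target, abs=1e-9)

    def test_dsi_monotone_in_concentration(self):
        kappas = np.linspace(0.1, 5, 20)
        vals = [vonmises_dsi(k) for k in kappas]
        assert np.all(np.diff(vals) > 0)

    def test_preferred_to_null_ratio_closed_form(self):
        kappa = 1.7
        ratio = (vonmises_direction_gain(90.0, 90.0, kappa)
                 / vonmises_direction_gain(270.0, 90.0, kappa))
        assert ratio == pytest.approx(np.exp(2 * kappa))


class TestDrive:
    def test_non_ds_cell_equal_bar_rates(self, canonical_cells, protocols):
        cell = canonical_cells[2]  # ON-OFF brisk transient, not DS
        resp = noiseless_responses(cell, protocols)
        rates = resp.bar_table.groupby("direction")["mean_rate"].mean()
        assert rates.max() / rates.min() < 1.2

    def test_off_cell_silent_at_bright_onset(self, canonical_cells, protocols):
        cell = canonical_cells[0]  # OFF brisk transient
        stim = protocols["marching_square"]
        rate = drive(cell, stim)
        ev = next(e for e in stim.events
                  if np.hypot(e.center[0] - 500, e.center[1] - 500) < 80)
        t = np.linspace(ev.onset, ev.onset + 1.0, 200)
        # no elevation above baseline at square appearance (residual kernel
        # tails from preceding events stay far below 0.1 Hz)
        assert rate(t).max() < cell.baseline_rate + 0.1
        t_off = np.linspace(ev.offset, ev.offset + 1.0, 200)
        assert rate(t_off).max() > cell.baseline_rate + 1.0


class TestPoissonSpiking:
    def test_constant_rate_count(self):
        rate = RateFunction(baseline=10.0, drives=[], duration=100.0)
        n = len(spikes_from_rate(rate, seed=0))
        # 2 ms dead time trims the expectation slightly below 1000
        assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_zero_rate_empty(self):
        rate = RateFunction(baseline=0.0, drives=[], duration=50.0)
        assert len(spikes_from_rate(rate, seed=0)) == 0

    def test_thinning_matches_time_rescaling_oracle(self):
        # ramp rate: lambda(t) = 20 t on [0, T]; Lambda(t) = 10 t^2.
        class Ramp:
            duration = 100.0
            def __call__(self, t):
                return 20.0 * np.atleast_1d(t)
            def max_rate(self, grid_dt=0.001):
                return 20.0 * self.duration

        thin = spikes_from_rate(Ramp(), seed=1, refractory=0.0)
        rng = np.random.default_rng(2)
        increments = rng.exponential(1.0, 120000)
        cum = np.cumsum(increments)
        rescaled = np.sqrt(cum / 10.0)  # inverse of Lambda
        rescaled = rescaled[rescaled < Ramp.duration]
        assert len(thin) > 10000
        ks = stats.ks_2samp(thin, rescaled)
        assert ks.pvalue > 0.001

    def test_refractory_enforced(self):
        rate = RateFunction(baseline=200.0, drives=[], duration=20.0)
        t = spikes_from_rate(rate, seed=3, refractory=0.002)
        assert np.diff(t).min() >= 0.002


class TestTraceRendering:
    def test_pure_noise_rms(self):
        block = render_traces([], [], ElectrodeConfig(rows=4, cols=6),
                              duration=2.0, noise_rms=2.4, seed=0)
        rms = float(np.sqrt(np.mean(block.samples.astype(float) ** 2)))
        assert rms == pytest.approx(2.4, rel=0.05)

    def test_noiseless_single_cell_detection_count(self):
        cfg = ElectrodeConfig(rows=4, cols=6)
        cells = scatter_cells_on_block(cfg, 1, seed=0)
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0.1, 4.9, 40))
        times = times[np.insert(np.diff(times) > 0.003, 0, True)]
        block = render_traces(cells, [times], cfg, duration=5.0,
                              noise_rms=0.0, seed=0)
        events = consolidate_events(detect(block, k_sd=3.5))
        assert len(events) == len(times)

    def test_nearby_cells_have_distinct_peak_electrodes(self):
        cfg = ElectrodeConfig(rows=6, cols=10)
        cells = scatter_cells_on_block(cfg, 2, seed=3, min_spacing=100.0)
        block = render_traces(cells, [np.array([0.5]), np.array([1.5])],
                              cfg, duration=2.0, noise_rms=1e-6, seed=0)
        peaks = [int(np.argmax(block.footprints[c.cell_id])) for c in cells]
        assert peaks[0] != peaks[1]

    def test_min_spacing_respected(self):
        cfg = ElectrodeConfig()
        cells = scatter_cells_on_block(cfg, 15, seed=2, min_spacing=30.0)
        pos = np.array([c.rf_center for c in cells])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 30.0


class TestClosingTheLoop:
    """The generator/extractor calibration contract on noiseless responses."""

    def test_bias_index_polarity(self, canonical_cells, canonical_responses):
        for cell in canonical_cells:
            v = rp.compute_cell_parameters(canonical_responses[cell.archetype],
                                           cell.cell_id)
            expected = {"ON": 1.0, "OFF": -1.0, "ON_OFF": 0.0}[cell.polarity]
            assert v.bias_index == pytest.approx(expected, abs=0.1), cell.archetype

    def test_transience_calibration(self, canonical_cells, canonical_responses):
        for cell in canonical_cells:
            v = rp.compute_cell_parameters(canonical_responses[cell.archetype],
                                           cell.cell_id)
            assert v.transience == pytest.approx(cell.transience_target,
                                                 abs=0.05), cell.archetype

    def test_extracted_dsi_monotone_in_concentration(self, protocols, field):
        from dataclasses import replace
        base = sample_population(default_archetypes()[4:5], 1, field,
                                 seed=0, margin=499.9)[0]
        vals = []
        for kappa in (0.3, 0.8, 1.5, 3.0):
            cell = replace(base, ds_concentration=kappa)
            resp = noiseless_responses(cell, protocols)
            dirs, rates = rp.select_bar_responses(cell.rf_center,
                                                  resp.bar_table, field)
            vals.append(rp.ds_index(rates, dirs))
        assert np.all(np.diff(vals) > 0)
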
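import numpy as np
import pytest
from scipy import signal

from rgctyping.sorting import (
    SortedUnit,
    TemplateSTA,
    bandpass,
    build_template,
    consolidate_events,
    demix,
    detect,
    match,
    qc_merge,
    refractory_violation_fraction,
    robust_sd,
)
from rgctyping.synthetic import (
    ElectrodeConfig,
    TraceBlock,
    render_traces,
    scatter_cells_on_block,
    spike_waveform,
)

FS = 20000.0


def tone_block(freq, n_electrodes=2, duration=1.0, amp=10.0):
    t = np.arange(int(duration * FS)) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    cfg = ElectrodeConfig(rows=1, cols=n_electrodes)
    return TraceBlock(np.tile(x, (n_electrodes, 1)).astype(np.float32), FS, cfg)


class TestBandpass:
    def test_stopband_attenuation_50hz(self):
        out = bandpass(tone_block(50.0, duration=2.0))
        mid = out.samples[0, 10000:30000]
        gain = np.sqrt(np.mean(mid.astype(float) ** 2)) / (10.0 / np.sqrt(2))
        assert 20 * np.log10(gain) < -40

    def test_passband_1khz_within_1db(self):
        out = bandpass(tone_block(1000.0, duration=2.0))
        mid = out.samples[0, 10000:30000]
        gain = np.sqrt(np.mean(mid.astype(float) ** 2)) / (10.0 / np.sqrt(2))
        assert abs(20 * np.log10(gain)) < 1

    def test_dc_removed(self):
        cfg = ElectrodeConfig(rows=1, cols=1)
        block = TraceBlock(np.full((1, 20000), 7.0, dtype=np.float32), FS, cfg)
        assert abs(bandpass(block).samples.mean()) < 0.05

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(tone_block(100.0), low=300.0, high=12000.0)


@pytest.fixture(scope="module")
def noise_block():
    rng = np.random.default_rng(5)
    cfg = ElectrodeConfig(rows=2, cols=5)
    samples = rng.normal(0, 2.4, (10, int(10 * FS))).astype(np.float32)
    return bandpass(TraceBlock(samples, FS, cfg))


class TestDetect:

    def test_absurd_threshold_gives_no_detections(self, noise_block):
        assert detect(noise_block, k_sd=50.0) == []

    def test_count_monotone_in_threshold(self, noise_block):
        counts = [len(detect(noise_block, k)) for k in (3.0, 3.5, 4.0, 5.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] < counts[0]

    def test_noise_rate_matches_level_crossing_oracle(self, noise_block):
        """Detection rate on pure noise agrees with the Rice level-crossing
        rate of the band-limited Gaussian process (order of magnitude)."""
        k = 3.5
        f, psd = signal.welch(noise_block.samples[0].astype(float), fs=FS,
                              nperseg=4096)
        m0 = np.trapezoid(psd, f)
        m2 = np.trapezoid(psd * f**2, f)
        expected = np.sqrt(m2 / m0) * np.exp(-k**2 / 2)  # upcrossings / s
        n_el, n_samp = noise_block.samples.shape
        rate = len(detect(noise_block, k)) / (n_el * n_samp / FS)
        assert expected / 3 < rate < expected * 3

    def test_robust_sd_ignores_sparse_spikes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, 100000)
        x[::1000] -= 100.0
        assert robust_sd(x) == pytest.approx(2.0, rel=0.05)


def two_cell_block(seed=0, rate=10.0, duration=12.0, noise=2.4):
    cfg = ElectrodeConfig(rows=4, cols=8)
    cells = scatter_cells_on_block(cfg, 2, seed=seed, min_spacing=80.0)
    rng = np.random.default_rng(seed)
    trains = []
    for _ in cells:
        t = np.sort(rng.uniform(0.1, duration - 0.1,
                                rng.poisson(rate * duration)))
        trains.append(t[np.insert(np.diff(t) > 0.003, 0, True)])
    block = render_traces(cells, trains, cfg, duration=duration,
                          noise_rms=noise, seed=seed + 1)
    return bandpass(block), trains


class TestDemix:
    def test_two_cells_high_snr_pure_clusters(self):
        # each preliminary cluster is pure (one owner cell) and both cells
        # are represented; a cell whose spikes alternate between two peak
        # electrodes may legitimately yield two pure clusters, which the
        # duplicate-merge stage later unifies
        block, trains = two_cell_block(seed=4)
        prelim = demix(block, seed=0)
        assert len(prelim) >= 2
        owners = set()
        for members in prelim:
            t = np.array(members) / FS
            frac = [np.mean(np.min(np.abs(t[:, None] - gt[None, :]), axis=1)
                            < 0.001) for gt in trains]
            assert max(frac) == pytest.approx(1.0, abs=0.02)
            owners.add(int(np.argmax(frac)))
        assert owners == {0, 1}

    def test_single_waveform_single_cluster(self):
        cfg = ElectrodeConfig(rows=4, cols=6)
        cells = scatter_cells_on_block(cfg, 1, seed=2)
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0.1, 11.9, 110))
        t = t[np.insert(np.diff(t) > 0.003, 0, True)]
        block = bandpass(render_traces(cells, [t], cfg, duration=12.0, seed=1))
        assert len(demix(block, seed=0)) == 1


class TestTemplateMatch:
    def make_template_block(self):
        cfg = ElectrodeConfig(rows=3, cols=5)
        cells = scatter_cells_on_block(cfg, 1, seed=6)
        times = np.array([0.1, 0.25, 0.43, 0.61, 0.99, 1.5, 1.8])
        block = render_traces(cells, [times], cfg, duration=2.0,
                              noise_rms=1e-9, seed=0, shape_variation=False)
        return block, times

    def test_exact_recovery_without_noise(self):
        block, times = self.make_template_block()
        wf = spike_waveform()
        amp = block.footprints[0]
        waveform = np.outer(amp, wf)
        tpl = TemplateSTA(waveform, np.argsort(amp)[::-1][:7], 100,
                          int(np.argmax(amp)))
        got = match(block, tpl)
        assert len(got) == len(times)
        assert np.max(np.abs(np.sort(got) - times)) <= 1.5 / FS

    def test_absent_template_no_matches(self):
        block, _ = self.make_template_block()
        rng = np.random.default_rng(1)
        waveform = rng.normal(0, 50, (block.samples.shape[0], 31))
        tpl = TemplateSTA(waveform, np.arange(7), 100, 0)
        assert len(match(block, tpl)) == 0

    def test_degenerate_template_rejected(self):
        block, _ = self.make_template_block()
        tpl = TemplateSTA(np.zeros((block.samples.shape[0], 31)),
                          np.arange(7), 100, 0)
        with pytest.raises(ValueError, match="degenerate"):
            match(block, tpl)

    def test_build_template_requires_sources(self):
        block, _ = self.make_template_block()
        with pytest.raises(ValueError, match="source events"):
            build_template(block, np.array([2000, 5000]), min_source=20)


def _unit(uid, waveform, times):
    n_el = waveform.shape[0]
    tpl = TemplateSTA(waveform, np.argsort(np.ptp(waveform, axis=1))[::-1][:3],
                      50, int(np.argmax(np.ptp(waveform, axis=1))))
    return SortedUnit(uid, tpl, np.asarray(times, dtype=float),
                      refractory_violation_fraction(np.asarray(times)))


class TestQCMerge:
    WF = np.outer([1.0, 0.5, 0.2], spike_waveform()) * 100

    def test_identical_templates_disjoint_trains_merge(self):
        a = _unit(0, self.WF, np.arange(0.0, 1.0, 0.01))
        b = _unit(1, self.WF, np.arange(0.005, 1.0, 0.01))
        merged = qc_merge([a, b])
        assert len(merged) == 1
        assert merged[0].merged_from == {0, 1}
        assert len(merged[0].spike_times) == 200

    def test_orthogonal_templates_do_not_merge(self):
        other = np.outer([0.2, 0.5, 1.0], np.roll(spike_waveform(), 8)) * 100
        a = _unit(0, self.WF, np.arange(0.0, 1.0, 0.01))
        b = _unit(1, other, np.arange(0.005, 1.0, 0.01))
        assert len(qc_merge([a, b])) == 2

    def test_violating_interleaved_trains_do_not_merge(self):
        a = _unit(0, self.WF, np.arange(0.0, 1.0, 0.02))
        b = _unit(1, self.WF, np.arange(0.0011, 1.0, 0.02))  # 1.1 ms offsets
        merged = qc_merge([a, b])
        assert len(merged) == 2

    def test_idempotence(self):
        a = _unit(0, self.WF, np.arange(0.0, 1.0, 0.01))
        b = _unit(1, self.WF, np.arange(0.005, 1.0, 0.01))
        once = qc_merge([a, b])
        twice = qc_merge(once)
        assert len(once) == len(twice)
        assert np.array_equal(once[0].spike_times, twice[0].spike_times)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc_merge([])


class TestRefractoryViolations:
    def test_fraction(self):
        t = np.array([0.0, 0.001, 0.1, 0.2])
        assert refractory_violation_fraction(t) == pytest.approx(1 / 3)

    def test_empty_and_single(self):
        assert refractory_violation_fraction(np.array([])) == 0.0
        assert refractory_violation_fraction(np.array([1.0])) == 0.0
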
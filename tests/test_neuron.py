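"""Vestibular ganglion neuron model: gating, firing phenotypes, metrics."""

import numpy as np
import pytest

from ihfit import neuron as nr
from ihfit.channel import ComponentParams


@pytest.fixture(scope="module")
def sustained():
    return nr.NeuronConfig.sustained(ih="both")


@pytest.fixture(scope="module")
def transient():
    return nr.NeuronConfig.transient(ih="both")


@pytest.fixture(scope="module")
def sustained_rest(sustained):
    return nr.find_rest(sustained)


@pytest.fixture(scope="module")
def transient_rest(transient):
    return nr.find_rest(transient)


class TestCampModulation:
    def test_published_transform(self):
        slow, fast = nr._default_slow(), nr._default_fast()
        slow2, fast2 = nr.apply_camp(slow.replace(G=3.0), fast)
        assert slow2.G == pytest.approx(3.0 * 1.91)          # 5.73 nS
        assert slow2.Vh == pytest.approx(slow.Vh + 12.0)     # -108.6 -> -96.6
        assert slow2.A == pytest.approx(slow.A / 5.31)
        assert fast2.A == pytest.approx(fast.A / 2.87)
        assert fast2.B == pytest.approx(fast.B / 2.87)
        assert (slow2.k, slow2.M, slow2.S) == (slow.k, slow.M, slow.S)

    def test_identity_modulation(self):
        slow, fast = nr._default_slow(), nr._default_fast()
        mod = nr.ModulationSpec(1.0, 0.0, 1.0, 1.0)
        s2, f2 = nr.apply_camp(slow, fast, mod)
        assert s2 == slow and f2 == fast

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            nr.ModulationSpec(conductance_factor=0.0)


class TestIntegration:
    def test_passive_leak_equilibrium(self):
        cfg = nr.NeuronConfig(G_Na=0, G_KH=0, G_KL=0, slow=None, fast=None)
        V, _ = nr.find_rest(cfg)
        assert V == pytest.approx(-67.0, abs=0.01)

    def test_gates_stay_in_unit_interval(self, sustained, sustained_rest):
        V0, g0 = sustained_rest
        stim = nr.StimulusSpec("step", 500.0, onset=5, duration=100)
        sim = nr.simulate(sustained, stim, 150, V0=V0, gates0=g0)
        assert sim.gates.min() >= -1e-6
        assert sim.gates.max() <= 1 + 1e-6

    def test_dt_convergence_of_spike_times(self, sustained, sustained_rest):
        V0, g0 = sustained_rest
        stim = nr.StimulusSpec("step", 100.0, onset=5, duration=60)
        a = nr.simulate(sustained, stim, 80, dt=0.01, V0=V0, gates0=g0)
        b = nr.simulate(sustained, stim, 80, dt=0.005, V0=V0, gates0=g0)
        assert a.spike_count == b.spike_count > 0
        assert np.max(np.abs(a.spikes - b.spikes)) < 0.05


class TestFiringPhenotypes:
    def test_sustained_fires_repetitively(self, sustained, sustained_rest):
        V0, g0 = sustained_rest
        for amp in (20.0, 40.0):
            stim = nr.StimulusSpec("step", amp, onset=10, duration=300)
            sim = nr.simulate(sustained, stim, 350, V0=V0, gates0=g0)
            assert sim.spike_count >= 5

    def test_transient_fires_single_onset_spike(self, transient, transient_rest):
        V0, g0 = transient_rest
        stim = nr.StimulusSpec("step", 400.0, onset=10, duration=300)
        sim = nr.simulate(transient, stim, 350, V0=V0, gates0=g0)
        assert sim.spike_count == 1
        assert sim.spikes[0] < 20.0

    @pytest.mark.parametrize("phenotype", ["sustained", "transient"])
    def test_hyperpolarization_sag(self, phenotype, request):
        cfg = request.getfixturevalue(phenotype)
        V0, g0 = request.getfixturevalue(f"{phenotype}_rest")
        stim = nr.StimulusSpec("step", -120.0, onset=10, duration=500)
        sim = nr.simulate(cfg, stim, 520, V0=V0, gates0=g0)
        seg = sim.V[(sim.t >= 10) & (sim.t < 510)]
        sag = seg.min() - seg[-1]
        assert sag < -3.0  # early minimum, then depolarizing relaxation


class TestThresholdAndConditioning:
    def test_bisection_contract(self, sustained, sustained_rest):
        thr = nr.find_threshold_epsc(sustained)
        V0, g0 = sustained_rest

        def fires(amp):
            stim = nr.StimulusSpec("epsc", amp, onset=1.0)
            return nr.simulate(sustained, stim, 30, V0=V0, gates0=g0).spike_count > 0

        assert fires(thr)
        assert not fires(0.98 * thr)

    def test_no_sodium_no_threshold(self, sustained):
        with pytest.raises(RuntimeError):
            nr.find_threshold_epsc(sustained.replace(G_Na=0.0), A_max=5000.0)

    def test_deep_conditioning_shortens_latency(self, sustained):
        thr = nr.find_threshold_epsc(sustained)
        lat = {}
        for vc in (-60.0, -120.0):
            sim = nr.conditioning_protocol(sustained, vc, epsc_amplitude=1.1 * thr)
            lat[vc] = nr.metrics(sim)["ap_latency"]
        assert lat[-120.0] is not None
        assert lat[-120.0] < lat[-60.0]

    def test_no_sodium_gives_epsp_only(self, sustained):
        cfg = sustained.replace(G_Na=0.0)
        sim = nr.conditioning_protocol(cfg, -105.0, epsc_amplitude=60.0)
        m = nr.metrics(sim)
        assert m["ap_count"] == 0 and m["ap_latency"] is None
        assert m["epsp_amplitude"] > 2.0
        assert m["epsp_decay_tau"] is not None and m["epsp_decay_tau"] > 0


class TestMetrics:
    def _fake_sim(self, V, dt=0.05):
        cfg = nr.NeuronConfig()
        t = np.arange(len(V)) * dt
        return nr.SimResult(t=t, V=V, gates=np.zeros((len(V), 8)), dt=dt,
                            config=cfg)

    def test_flat_trace(self):
        sim = self._fake_sim(np.full(2000, -65.0))
        m = nr.metrics(sim, stim_onset=10.0)
        assert m["ap_count"] == 0
        assert m["epsp_amplitude"] == pytest.approx(0.0)

    def test_synthetic_double_exponential_decay_recovered(self):
        dt = 0.05
        t = np.arange(0, 120, dt)
        onset = 10.0
        s = np.clip(t - onset, 0, None)
        epsp = 8.0 * np.exp(-s / 4.0) + 4.0 * np.exp(-s / 20.0)
        V = -65.0 + np.where(t >= onset, epsp, 0.0)
        sim = self._fake_sim(V, dt)
        m = nr.metrics(sim, stim_onset=onset, double_exp_tol=0.01)
        assert m["epsp_decay_double"] is not None
        assert m["epsp_decay_double"]["tau_fast"] == pytest.approx(4.0, rel=0.15)
        assert m["epsp_decay_double"]["tau_slow"] == pytest.approx(20.0, rel=0.15)

    def test_spike_detection_refractory_grouping(self):
        dt = 0.01
        t = np.arange(0, 20, dt)
        V = np.full_like(t, -65.0)
        for t0 in (5.0, 5.3, 12.0):  # first two within one refractory window
            V += 80.0 * np.exp(-((t - t0) ** 2) / 0.01)
        spikes = nr.detect_spikes(t, V)
        assert len(spikes) == 2
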
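"""Protocol construction, synthetic trace sets and trace-set I/O."""

import numpy as np
import pytest

import ihfit
from ihfit.clamp import noiseless_traces


class TestStandardProtocol:
    def test_benchmark_protocol_steps(self):
        proto = ihfit.standard_protocol()
        assert proto.V_hold == -60.0
        assert len(proto.step_voltages) == 10
        assert proto.step_voltages[0] == -60.0
        assert proto.step_voltages[-1] == -150.0
        assert np.allclose(np.diff(proto.step_voltages), -10.0)

    def test_recorded_data_variant_reaches_minus_160(self):
        proto = ihfit.standard_protocol(V_min=-160.0)
        assert len(proto.step_voltages) == 11
        assert proto.step_voltages[-1] == -160.0

    def test_invalid_sampling_rejected(self):
        with pytest.raises(ValueError):
            ihfit.ClampProtocol(V_hold=-60, step_voltages=(-100,), t_step=100,
                                t_post=0, sample_interval=0.0)


class TestSynthesize:
    def test_zero_noise_matches_closed_form(self, bench_params, small_protocol):
        slow, fast = bench_params
        ts = ihfit.synthesize(slow, fast, small_protocol, noise_sd=0.0)
        assert np.allclose(ts.traces, noiseless_traces(slow, fast, small_protocol))

    def test_noise_sd_recovered(self, bench_params, small_protocol):
        slow, fast = bench_params
        ts = ihfit.synthesize(slow, fast, small_protocol, noise_sd=10.0, seed=0)
        resid = ts.traces - noiseless_traces(slow, fast, small_protocol)
        assert resid.std() == pytest.approx(10.0, rel=0.05)

    def test_deterministic_under_seed(self, bench_params, small_protocol):
        slow, fast = bench_params
        a = ihfit.synthesize(slow, fast, small_protocol, noise_sd=10.0, seed=3)
        b = ihfit.synthesize(slow, fast, small_protocol, noise_sd=10.0, seed=3)
        assert np.array_equal(a.traces, b.traces)

    def test_mean_of_realizations_converges_to_clean(self, bench_params, small_protocol):
        slow, fast = bench_params
        clean = noiseless_traces(slow, fast, small_protocol)
        stack = np.mean([
            ihfit.synthesize(slow, fast, small_protocol, noise_sd=10.0, seed=s).traces
            for s in range(60)
        ], axis=0)
        assert np.abs(stack - clean).mean() < 10.0 / np.sqrt(60) * 1.5

    def test_negative_noise_rejected(self, bench_params, small_protocol):
        slow, fast = bench_params
        with pytest.raises(ValueError):
            ihfit.synthesize(slow, fast, small_protocol, noise_sd=-1.0)

    def test_steady_state_asymptote(self, bench_params):
        slow, fast = bench_params
        proto = ihfit.standard_protocol(t_step=20000.0, t_post=0.0,
                                        sample_interval=10.0)
        ts = ihfit.synthesize(slow, fast, proto, noise_sd=0.0)
        i_inf = sum(p.G * ihfit.activation(-150.0, p) * (-150 + 36)
                    for p in (slow, fast))
        assert ts.traces[-1, -1] == pytest.approx(i_inf, rel=1e-3)


class TestFixtures:
    def test_benchmark_fixture_values(self, bench_params):
        slow, fast = bench_params
        assert (slow.Vh, slow.k, slow.M, slow.S) == (-100, -6, -80, 80)
        assert (slow.A, slow.B, slow.G) == (1000, 60, 3)
        assert (fast.Vh, fast.k, fast.M, fast.S) == (-130, -9, -80, 40)
        assert (fast.A, fast.B, fast.G) == (250, 40, 4)

    def test_recorded_cell_fixture(self):
        slow, fast = ihfit.recorded_cell_fixture()
        assert slow.Vh == -108.6 and fast.Vh == -130.6
        assert slow.k == -9.6 and fast.k == -5.1
        assert slow.tau_peak == pytest.approx(995.0)
        assert fast.tau_peak == pytest.approx(244.0)

    def test_width_assignments_swap(self):
        st_text = ihfit.recorded_cell_fixture("text")
        st_fig = ihfit.recorded_cell_fixture("figure")
        assert st_text[1].S == st_fig[0].S == 59.8
        assert st_text[0].S == st_fig[1].S == 31.2
        with pytest.raises(ValueError):
            ihfit.recorded_cell_fixture("nonsense")


class TestTraceIO:
    def test_round_trip(self, bench_params, small_protocol, tmp_path):
        slow, fast = bench_params
        ts = ihfit.synthesize(slow, fast, small_protocol, noise_sd=10.0, seed=5)
        path = tmp_path / "traces.csv"
        ihfit.export_traces(ts, path)
        back = ihfit.import_traces(path)
        assert back.protocol == ts.protocol
        assert np.allclose(back.traces, ts.traces)
        assert back.noise_sd == ts.noise_sd and back.seed == ts.seed

    def test_missing_sidecar(self, tmp_path):
        path = tmp_path / "orphan.csv"
        path.write_text("time_ms,-100\n0,0\n")
        with pytest.raises(FileNotFoundError):
            ihfit.import_traces(path)

    def test_mismatched_columns(self, bench_params, small_protocol, tmp_path):
        import json
        slow, fast = bench_params
        ts = ihfit.synthesize(slow, fast, small_protocol, noise_sd=0.0)
        path = tmp_path / "traces.csv"
        ihfit.export_traces(ts, path)
        sidecar = path.with_suffix(".csv.json")
        meta = json.loads(sidecar.read_text())
        meta["protocol"]["step_voltages"] = meta["protocol"]["step_voltages"][:-1]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError):
            ihfit.import_traces(path)

    def test_trace_count_must_match_protocol(self, small_protocol):
        with pytest.raises(ValueError):
            ihfit.TraceSet(protocol=small_protocol,
                           traces=np.zeros((3, small_protocol.n_samples)))
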
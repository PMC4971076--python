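"""Pipeline engine: config parsing, buffered scheduling, latency, sweeps."""

import numpy as np
import pandas as pd
import pytest

from spikeloop import (
    LatencyProbe,
    ValidationError,
    build_graph,
    demo_config_path,
    measure_latency,
    parse_config,
    run_pipeline,
    sweep,
)


def chain_graph(n_hops: int, music_dt: float, t_step: float = 0.2):
    """step source -> (n_hops - 1) passthroughs -> probe: n_hops connections."""
    specs = [("src", "source", {"signal": "step", "t_step": t_step, "lo": 0.0, "hi": 1.0})]
    conns = []
    prev = "src"
    for i in range(n_hops - 1):
        name = f"p{i}"
        specs.append((name, "passthrough", {"width": 1}))
        conns.append(f"{prev}.out -> {name}.in")
        prev = name
    specs.append(("probe", "probe", {"width": 1}))
    conns.append(f"{prev}.out -> probe.in")
    return build_graph(specs, conns, music_dt)


class TestParseConfig:
    def test_braitenberg_demo_has_six_components(self):
        g = parse_config(demo_config_path())
        assert len(g.components) == 6
        # full loop: environment feeds the adapter and receives the command
        labels = {c.label for c in g.connections}
        assert "env.scan->adapt.in" in labels
        assert "motor.cmd->env.cmd" in labels

    def test_width_mismatch_rejected(self, tmp_path):
        cfg = tmp_path / "bad.ini"
        cfg.write_text(
            "[a]\nkind = source\nchannels = 2\n"
            "[b]\nkind = passthrough\nwidth = 3\n"
            "connect a.out -> b.in\n"
        )
        with pytest.raises(ValidationError, match="width mismatch"):
            parse_config(cfg)

    def test_empty_config_rejected(self, tmp_path):
        cfg = tmp_path / "empty.ini"
        cfg.write_text("# nothing\n")
        with pytest.raises(ValidationError, match="no components"):
            parse_config(cfg)

    def test_unknown_kind_lists_registered(self, tmp_path):
        cfg = tmp_path / "unk.ini"
        cfg.write_text("[a]\nkind = warp_drive\n")
        with pytest.raises(ValidationError, match="unknown component kind"):
            parse_config(cfg)

    def test_dangling_connection_rejected(self, tmp_path):
        cfg = tmp_path / "dang.ini"
        cfg.write_text(
            "[a]\nkind = source\n"
            "connect a.out -> ghost.in\n"
        )
        with pytest.raises(ValidationError, match="ghost"):
            parse_config(cfg)

    def test_disconnected_graph_rejected(self, tmp_path):
        cfg = tmp_path / "disc.ini"
        cfg.write_text("[a]\nkind = source\n\n[b]\nkind = source\n")
        with pytest.raises(ValidationError, match="not connected"):
            parse_config(cfg)

    def test_tick_must_be_multiple_of_music_dt(self, tmp_path):
        cfg = tmp_path / "tick.ini"
        cfg.write_text(
            "music_dt = 0.01\n[a]\nkind = source\ntick = 0.015\n"
            "[b]\nkind = probe\n"
            "connect a.out -> b.in\n"
        )
        with pytest.raises(ValidationError, match="integer"):
            parse_config(cfg)


class TestScheduler:
    def test_value_crosses_c_connections_in_c_ticks(self):
        """Brute-force event trace: a step injected at tick k is seen by the
        probe exactly c ticks later, one per buffered connection."""
        music_dt = 0.01
        for hops in (1, 2, 3, 5):
            g = chain_graph(hops, music_dt, t_step=0.05)
            res = run_pipeline(g, 0.5, seed=0)
            rec = res["probes"]["probe"]
            onset = rec.loc[rec["ch0"] > 0.5, "time"].iloc[0]
            assert onset == pytest.approx(0.05 + hops * music_dt)

    def test_same_seed_bitwise_identical(self):
        specs = [
            ("src", "source", {"signal": "randomwalk", "sigma": 2.0}),
            ("enc", "encoder", {"mode": "poisson", "n_neurons": 1, "v_max": 200.0}),
            ("dec", "decoder", {"n_neurons": 1, "tau_dec": 0.05}),
            ("probe", "probe", {"width": 1}),
        ]
        conns = ["src.out -> enc.in", "enc.out -> dec.in", "dec.out -> probe.in"]
        a = run_pipeline(build_graph(specs, conns, 0.01), 2.0, seed=5)
        b = run_pipeline(build_graph(specs, conns, 0.01), 2.0, seed=5)
        pd.testing.assert_frame_equal(a["probes"]["probe"], b["probes"]["probe"])
        c = run_pipeline(build_graph(specs, conns, 0.01), 2.0, seed=6)
        assert not a["probes"]["probe"]["ch0"].equals(c["probes"]["probe"]["ch0"])

    def test_event_conservation_on_every_connection(self):
        specs = [
            ("src", "source", {"signal": "constant", "value": 0.5, "channels": 3}),
            ("enc", "encoder", {"mode": "regular", "n_neurons": 3, "v_max": 80.0}),
            ("par", "parrot", {"n_neurons": 3, "delay": 0.0}),
            ("dec", "decoder", {"n_neurons": 3, "tau_dec": 0.05}),
            ("probe", "probe", {"width": 3}),
        ]
        conns = ["src.out -> enc.in", "enc.out -> par.in",
                 "par.out -> dec.in", "dec.out -> probe.in"]
        g = build_graph(specs, conns, 0.01)
        res = run_pipeline(g, 2.0, seed=0)
        for label, (sent, received) in res["conservation"].items():
            assert sent == received, label
        # and spikes were actually flowing
        assert res["conservation"]["enc.out->par.in"][0] > 100

    def test_component_failure_names_component_and_tick(self):
        g = chain_graph(3, 0.01)
        g.components["p0"].step = lambda t, dt, inputs: 1 / 0
        with pytest.raises(RuntimeError, match="p0.*tick 0"):
            run_pipeline(g, 0.1, seed=0)

    def test_rtf_decomposition(self):
        g = chain_graph(3, 0.01)
        res = run_pipeline(g, 0.5, seed=0)
        t = res["timings"]
        assert t.t_sim == 0.5
        assert t.rtf == pytest.approx(t.t_sim / t.t_run)
        assert t.epsilon >= 0.0
        assert t.t_total == pytest.approx(t.t_build + t.t_run + t.epsilon)


class TestLatency:
    @pytest.mark.parametrize("music_dt", [0.001, 0.005, 0.01, 0.02, 0.05])
    def test_latency_is_hops_times_tick(self, music_dt):
        hops = 3
        t_step = 20 * music_dt
        g = chain_graph(hops, music_dt, t_step=t_step)
        rep = measure_latency(
            g, LatencyProbe(probe="probe", stimulus_time=t_step, source="src"),
            T=100 * music_dt,
        )
        assert rep.hops == hops
        assert rep.latency == pytest.approx(hops * music_dt)

    def test_doubling_tick_doubles_latency(self):
        lat = {}
        for dt in (0.01, 0.02):
            g = chain_graph(4, dt, t_step=10 * dt)
            rep = measure_latency(
                g, LatencyProbe(probe="probe", stimulus_time=10 * dt, source="src"),
                T=50 * dt,
            )
            lat[dt] = rep.latency
        assert lat[0.02] == pytest.approx(2 * lat[0.01])

    def test_no_response_is_diagnosed(self):
        g = chain_graph(3, 0.01, t_step=999.0)  # step never happens
        with pytest.raises(ValidationError, match="no response"):
            measure_latency(
                g, LatencyProbe(probe="probe", stimulus_time=999.0, source="src"),
                T=0.2,
            )


class TestSweep:
    def _write_chain_config(self, path, music_dt=0.01):
        path.write_text(
            f"music_dt = {music_dt}\n"
            "[src]\nkind = source\nsignal = step\nt_step = 0.1\nlo = 0.0\nhi = 1.0\n"
            "[p0]\nkind = passthrough\nwidth = 1\n"
            "[probe]\nkind = probe\nwidth = 1\n"
            "connect src.out -> p0.in\n"
            "connect p0.out -> probe.in\n"
        )

    def test_grid_product_rows(self, tmp_path):
        cfg = tmp_path / "c.ini"
        self._write_chain_config(cfg)
        table = sweep(cfg, {"music_dt": [0.01, 0.02], "p0.gain": [1.0, 2.0]}, T=0.5)
        assert len(table) == 4
        assert set(table.columns) >= {"music_dt", "p0.gain", "seed", "rtf"}

    def test_latency_column_matches_single_measurement(self, tmp_path):
        cfg = tmp_path / "c.ini"
        self._write_chain_config(cfg)
        probe = LatencyProbe(probe="probe", stimulus_time=0.1, source="src")
        table = sweep(cfg, {"music_dt": [0.01]}, T=0.5, seed=3, probe_spec=probe)
        single = measure_latency(parse_config(cfg, overrides={"music_dt": 0.01}),
                                 probe, T=0.5, seed=3)
        assert table["latency"].iloc[0] == pytest.approx(single.latency)

    def test_repeated_grid_point_deterministic(self, tmp_path):
        cfg = tmp_path / "c.ini"
        self._write_chain_config(cfg)
        probe = LatencyProbe(probe="probe", stimulus_time=0.1, source="src")
        a = sweep(cfg, {"music_dt": [0.01, 0.01]}, T=0.5, seed=0, probe_spec=probe)
        assert a["latency"].iloc[0] == a["latency"].iloc[1]
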
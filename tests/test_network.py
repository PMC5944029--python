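import numpy as np
import pytest

from ecmoflow.network import (
    FluidProps,
    NetworkTopology,
    VesselSegment,
    conservation_residual,
    default_network,
    network_from_dict,
    poiseuille_resistance,
    solve_cycle,
    solve_harmonic,
    solve_mean,
    womersley_alpha,
    womersley_impedances,
    womersley_twoport,
    wall_shear_factor,
)
from ecmoflow.waveforms import (
    FlowWaveform,
    PerfusionSpec,
    cardiac_waveform,
    compose_perfusion,
    ecmo_waveform,
)

FLUID = FluidProps()


def _const_wave(ml_s: float, n: int = 128, period: float = 0.8) -> FlowWaveform:
    t = np.arange(n) * period / n
    return FlowWaveform(times=t, values=np.full(n, ml_s), period=period)


def _tube(name="tube", d=10.0, length=200.0, prox="a", dist="b", c=6.0):
    return VesselSegment(name, diameter=d, length=length,
                         proximal_node=prox, distal_node=dist, wave_speed=c)


# ---------------------------------------------------------------- topology


class TestDefaultNetwork:
    def test_default_shape(self):
        net = default_network(cardiac_waveform(3.0), ecmo_waveform(2.0))
        assert len(net.segments) == 8
        assert len(net.sources) == 2
        assert len(net.outlets) == 5

    def test_table_diameters_present(self):
        net = default_network(cardiac_waveform(5.0))
        diameters = {s.name: s.diameter for s in net.segments}
        assert diameters["asc_aorta"] == 28.0
        assert diameters["ia"] == 7.0
        assert diameters["lcca"] == 7.0
        assert diameters["lsa"] == 7.0
        assert diameters["left_femoral"] == 10.3
        assert diameters["desc_aorta"] == 11.3

    def test_removing_ecmo_source_is_valid(self):
        net = default_network(cardiac_waveform(5.0), ecmo=None)
        assert len(net.sources) == 1
        assert "ecmo_node" not in net.sources

    def test_default_outlet_pressure(self):
        net = default_network(cardiac_waveform(5.0))
        assert set(net.outlets.values()) == {70.0}

    def test_unknown_config_keys_listed(self):
        with pytest.raises(ValueError, match="bogus"):
            default_network(cardiac_waveform(5.0), config={"bogus": 1})

    def test_bad_segment_reference_listed(self):
        with pytest.raises(ValueError, match="no_such_segment"):
            default_network(
                cardiac_waveform(5.0),
                config={"lengths_mm": {"no_such_segment": 10.0}},
            )

    def test_config_overrides_apply(self):
        net = default_network(
            cardiac_waveform(5.0),
            config={"lengths_mm": {"desc_aorta": 350.0},
                    "wave_speed_m_s": 8.0,
                    "outlet_pressure_mmHg": 65.0},
        )
        assert net.segment("desc_aorta").length == 350.0
        assert net.segment("ia").wave_speed == 8.0
        assert set(net.outlets.values()) == {65.0}


class TestTopologyValidation:
    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ValueError, match="leaf"):
            NetworkTopology(
                segments=[_tube()],
                sources={"a": _const_wave(10.0)},
                outlets={"a": 70.0},  # 'b' dangles
            )

    def test_no_outlet_rejected(self):
        with pytest.raises(ValueError, match="outlet"):
            NetworkTopology(
                segments=[_tube()],
                sources={"a": _const_wave(10.0), "b": _const_wave(1.0)},
                outlets={},
            )

    def test_cycle_rejected(self):
        segs = [_tube("s1", prox="a", dist="b"),
                _tube("s2", prox="b", dist="c"),
                _tube("s3", prox="c", dist="a")]
        with pytest.raises(ValueError, match="tree"):
            NetworkTopology(segments=segs, sources={"a": _const_wave(1.0)},
                            outlets={"b": 70.0})

    def test_from_dict_missing_keys(self):
        with pytest.raises(ValueError, match="missing"):
            network_from_dict(
                {"segments": [{"name": "t", "diameter_mm": 10}],
                 "outlets": {}},
                sources={},
            )

    def test_from_dict_round_trip(self):
        data = {
            "segments": [
                {"name": "t1", "diameter_mm": 10.0, "length_mm": 100.0,
                 "from": "a", "to": "b"},
            ],
            "outlets": {"b": {"pressure_mmHg": 60.0}},
        }
        net = network_from_dict(data, sources={"a": _const_wave(10.0)})
        assert net.segment("t1").diameter == 10.0
        assert net.outlets["b"] == 60.0


# ------------------------------------------------------------ steady solve


class TestPoiseuilleResistance:
    def test_diameter_scaling(self):
        s1 = _tube(d=10.0)
        s2 = _tube(d=20.0)
        r1 = poiseuille_resistance(s1, FLUID)
        r2 = poiseuille_resistance(s2, FLUID)
        assert r1 / r2 == pytest.approx(16.0, rel=1e-12)

    def test_length_scaling(self):
        assert poiseuille_resistance(_tube(length=400.0), FLUID) == pytest.approx(
            2.0 * poiseuille_resistance(_tube(length=200.0), FLUID), rel=1e-12
        )

    def test_hand_evaluated_value(self):
        # 128 * 0.0035 * 0.1 / (pi * 0.0103^4), evaluated independently
        seg = _tube(d=10.3, length=100.0)
        expected = 128.0 * 0.0035 * 0.1 / (np.pi * 0.0103**4)
        assert poiseuille_resistance(seg, FLUID) == pytest.approx(expected, rel=1e-12)


class TestSolveMean:
    def test_zero_inflow_all_70mmHg(self):
        net = default_network(cardiac_waveform(0.0))
        sol = solve_mean(net, FLUID)
        for p in sol.node_pressures.values():
            assert p == pytest.approx(70.0 * 133.322, rel=1e-9)
        for q in sol.segment_flows.values():
            assert q == pytest.approx(0.0, abs=1e-15)

    def test_single_tube_series_circuit(self):
        seg = _tube()
        net = NetworkTopology(
            segments=[seg],
            sources={"a": _const_wave(50.0)},
            outlets={"b": 70.0},
        )
        sol = solve_mean(net, FLUID)
        q = 50.0e-6
        r = poiseuille_resistance(seg, FLUID)
        assert sol.segment_flows["tube"] == pytest.approx(q, rel=1e-12)
        assert sol.node_pressures["a"] == pytest.approx(
            70.0 * 133.322 + r * q, rel=1e-12
        )

    def test_symmetric_y_split(self):
        segs = [
            _tube("stem", prox="root", dist="j"),
            _tube("b1", d=7.0, length=100.0, prox="j", dist="o1"),
            _tube("b2", d=7.0, length=100.0, prox="j", dist="o2"),
        ]
        net = NetworkTopology(
            segments=segs,
            sources={"root": _const_wave(60.0)},
            outlets={"o1": 70.0, "o2": 70.0},
        )
        sol = solve_mean(net, FLUID)
        assert sol.segment_flows["b1"] == pytest.approx(
            sol.segment_flows["b2"], rel=1e-12
        )
        assert sol.segment_flows["b1"] == pytest.approx(30.0e-6, rel=1e-9)

    def test_unequal_y_against_dense_oracle(self):
        segs = [
            _tube("stem", d=12.0, length=150.0, prox="root", dist="j"),
            _tube("b1", d=7.0, length=100.0, prox="j", dist="o1"),
            _tube("b2", d=5.0, length=250.0, prox="j", dist="o2"),
        ]
        net = NetworkTopology(
            segments=segs,
            sources={"root": _const_wave(60.0)},
            outlets={"o1": 72.0, "o2": 65.0},
        )
        sol = solve_mean(net, FLUID)

        # independent brute-force nodal solve, assembled by hand
        g = {s.name: 1.0 / poiseuille_resistance(s, FLUID) for s in segs}
        p1 = 72.0 * 133.322
        p2 = 65.0 * 133.322
        q = 60.0e-6
        # unknowns [p_root, p_j]
        a = np.array([
            [g["stem"], -g["stem"]],
            [-g["stem"], g["stem"] + g["b1"] + g["b2"]],
        ])
        b = np.array([q, g["b1"] * p1 + g["b2"] * p2])
        p_root, p_j = np.linalg.solve(a, b)
        assert sol.node_pressures["root"] == pytest.approx(p_root, rel=1e-8)
        assert sol.node_pressures["j"] == pytest.approx(p_j, rel=1e-8)
        assert sol.segment_flows["b1"] == pytest.approx(
            g["b1"] * (p_j - p1), rel=1e-8
        )


# --------------------------------------------------------- Womersley waves


def _series_bessel_factor(alpha: float) -> complex:
    """Independent power-series evaluation of 2 J1(z)/(z J0(z))."""
    from math import factorial

    z = alpha * np.exp(1j * 3.0 * np.pi / 4.0)
    j0 = sum((-1) ** k * (z / 2) ** (2 * k) / (factorial(k) ** 2)
             for k in range(60))
    j1 = sum((-1) ** k * (z / 2) ** (2 * k + 1)
             / (factorial(k) * factorial(k + 1))
             for k in range(60))
    return 2.0 * j1 / (z * j0)


class TestWomersley:
    def test_poiseuille_limit_small_alpha(self):
        seg = _tube(d=10.0)
        omega = (0.1 / seg.radius_m) ** 2 * FLUID.viscosity / FLUID.density
        assert womersley_alpha(seg, FLUID, omega) == pytest.approx(0.1)
        z_long, _ = womersley_impedances(seg, FLUID, omega)
        poiseuille = 128.0 * FLUID.viscosity / (np.pi * (seg.diameter * 1e-3) ** 4)
        assert abs(z_long) == pytest.approx(poiseuille, rel=0.01)

    def test_inviscid_limit_large_alpha(self):
        seg = _tube(d=10.0)
        omega = (50.0 / seg.radius_m) ** 2 * FLUID.viscosity / FLUID.density
        zc, _ = womersley_twoport(seg, FLUID, omega)
        inviscid = FLUID.density * seg.wave_speed / seg.area_m2
        assert abs(zc) == pytest.approx(inviscid, rel=0.02)

    def test_bessel_factor_against_series_oracle(self):
        seg = _tube(d=10.0)
        omega = (5.0 / seg.radius_m) ** 2 * FLUID.viscosity / FLUID.density
        z_long, _ = womersley_impedances(seg, FLUID, omega)
        # recover F10 from the returned impedance and compare
        f10 = 1.0 - 1j * omega * FLUID.density / (seg.area_m2 * z_long)
        expected = _series_bessel_factor(5.0)
        assert f10 == pytest.approx(expected, rel=1e-10)

    def test_wall_shear_poiseuille_limit(self):
        seg = _tube(d=10.0)
        omega = (0.05 / seg.radius_m) ** 2 * FLUID.viscosity / FLUID.density
        factor = wall_shear_factor(seg, FLUID, omega)
        poiseuille = 4.0 * FLUID.viscosity / (np.pi * seg.radius_m**3)
        assert abs(factor) == pytest.approx(poiseuille, rel=0.01)

    def test_overflow_guard(self):
        seg = _tube(d=28.0)
        with pytest.raises(OverflowError):
            womersley_twoport(seg, FLUID, 1e12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            womersley_impedances(_tube(), FLUID, 0.0)


class TestSolveHarmonic:
    OMEGA0 = 2.0 * np.pi / 0.8

    def _single_tube_net(self):
        seg = _tube(length=400.0)
        net = NetworkTopology(
            segments=[seg],
            sources={"a": _const_wave(50.0)},
            outlets={"b": 70.0},
        )
        return seg, net

    def test_zero_source_gives_zero_field(self):
        _, net = self._single_tube_net()
        sol = solve_harmonic(net, FLUID, 1, {"a": 0.0 + 0.0j}, self.OMEGA0)
        assert sol.node_pressures["a"] == pytest.approx(0.0, abs=1e-18)

    def test_homogeneity(self):
        _, net = self._single_tube_net()
        q = 2e-5 + 1e-5j
        s1 = solve_harmonic(net, FLUID, 2, {"a": q}, self.OMEGA0)
        s2 = solve_harmonic(net, FLUID, 2, {"a": 3.0 * q}, self.OMEGA0)
        assert s2.node_pressures["a"] == pytest.approx(
            3.0 * s1.node_pressures["a"], rel=1e-12
        )

    def test_single_tube_closed_form_input_impedance(self):
        # zero-pressure termination: Z_in = Zc * tanh(gamma L)
        seg, net = self._single_tube_net()
        q = 3e-5 + 0j
        sol = solve_harmonic(net, FLUID, 1, {"a": q}, self.OMEGA0)
        zc, gamma = womersley_twoport(seg, FLUID, self.OMEGA0)
        expected = zc * np.tanh(gamma * seg.length_m)
        assert sol.node_pressures["a"] / q == pytest.approx(expected, rel=1e-8)

    def test_two_segment_series_closed_form(self):
        s1 = _tube("s1", d=10.0, length=300.0, prox="a", dist="m")
        s2 = _tube("s2", d=8.0, length=200.0, prox="m", dist="b", c=7.0)
        net = NetworkTopology(
            segments=[s1, s2],
            sources={"a": _const_wave(50.0)},
            outlets={"b": 70.0},
        )
        q = 2e-5 - 1e-5j
        sol = solve_harmonic(net, FLUID, 1, {"a": q}, self.OMEGA0)
        zc1, g1 = womersley_twoport(s1, FLUID, self.OMEGA0)
        zc2, g2 = womersley_twoport(s2, FLUID, self.OMEGA0)
        z_load = zc2 * np.tanh(g2 * s2.length_m)
        t1 = np.tanh(g1 * s1.length_m)
        z_in = zc1 * (z_load + zc1 * t1) / (zc1 + z_load * t1)
        p_a = q * z_in
        p_m = p_a * np.cosh(g1 * s1.length_m) - zc1 * q * np.sinh(g1 * s1.length_m)
        assert sol.node_pressures["a"] == pytest.approx(p_a, rel=1e-8)
        assert sol.node_pressures["m"] == pytest.approx(p_m, rel=1e-8)

    def test_matched_termination_input_impedance_is_zc(self):
        # a long continuation of the same line is a matched (reflection-free)
        # termination: tanh(gamma * L_total) -> 1
        seg = _tube("probe", length=300.0, prox="a", dist="m")
        tail = _tube("tail", length=400_000.0, prox="m", dist="b")
        net = NetworkTopology(
            segments=[seg, tail],
            sources={"a": _const_wave(50.0)},
            outlets={"b": 70.0},
        )
        q = 1e-5 + 0j
        sol = solve_harmonic(net, FLUID, 1, {"a": q}, self.OMEGA0)
        zc, _ = womersley_twoport(seg, FLUID, self.OMEGA0)
        assert sol.node_pressures["a"] / q == pytest.approx(zc, rel=1e-8)

    def test_harmonic_index_must_be_positive(self):
        _, net = self._single_tube_net()
        with pytest.raises(ValueError):
            solve_harmonic(net, FLUID, 0, {"a": 1e-5}, self.OMEGA0)


# -------------------------------------------------------- cycle synthesis


class TestSolveCycle:
    def test_steady_only_poiseuille_wss(self):
        seg = _tube(length=200.0)
        net = NetworkTopology(
            segments=[seg],
            sources={"a": _const_wave(50.0)},
            outlets={"b": 70.0},
        )
        sol = solve_cycle(net, FLUID)
        q = 50.0e-6
        expected = 4.0 * FLUID.viscosity * q / (np.pi * seg.radius_m**3)
        np.testing.assert_allclose(sol.station_wss["tube"], expected, rtol=1e-9)
        np.testing.assert_allclose(sol.station_flows["tube"], 50.0, rtol=1e-9)

    def test_nyquist_guard(self):
        net = default_network(cardiac_waveform(5.0, n_samples=128))
        with pytest.raises(ValueError, match="Nyquist"):
            solve_cycle(net, FLUID, n_harmonics=100)

    @pytest.mark.parametrize("target", [0.0, 0.4, 0.8])
    def test_junction_closure(self, target):
        cardiac, ecmo = compose_perfusion(PerfusionSpec(target_bai=target))
        net = default_network(cardiac, ecmo if ecmo.mean() > 0 else None)
        sol = solve_cycle(net, FLUID)
        assert conservation_residual(net, sol) < 0.005

    def test_outlet_means_match_source_means(self):
        cardiac, ecmo = compose_perfusion(PerfusionSpec(target_bai=0.6))
        net = default_network(cardiac, ecmo)
        sol = solve_cycle(net, FLUID)
        out_total = sum(sol.mean_outlet_flows().values())
        src_total = net.total_mean_source_flow
        assert out_total == pytest.approx(src_total, rel=0.005)

    def test_harmonic_truncation_convergence(self):
        cardiac, ecmo = compose_perfusion(PerfusionSpec(target_bai=0.6))
        net = default_network(cardiac, ecmo)
        s20 = solve_cycle(net, FLUID, n_harmonics=20)
        s40 = solve_cycle(net, FLUID, n_harmonics=40)
        for key in s40.outlet_flows:
            a = s20.outlet_flows[key].values
            b = s40.outlet_flows[key].values
            rel_rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))
            assert rel_rms < 0.01, key

    def test_source_additivity(self):
        cardiac, ecmo = compose_perfusion(PerfusionSpec(target_bai=0.6))
        zero = FlowWaveform(times=cardiac.times.copy(),
                            values=np.zeros_like(cardiac.values),
                            period=cardiac.period)
        both = solve_cycle(default_network(cardiac, ecmo), FLUID)
        only_c = solve_cycle(default_network(cardiac, zero), FLUID)
        only_e = solve_cycle(default_network(zero, ecmo), FLUID)
        # superposition holds for the oscillatory field exactly and for the
        # full cycle up to the shared 70 mmHg outlet baseline
        combined = only_c.trunk_flows + only_e.trunk_flows
        np.testing.assert_allclose(both.trunk_flows, combined, atol=1e-8)

    def test_no_ecmo_right_femoral_antegrade_at_peak_systole(self):
        cardiac, _ = compose_perfusion(PerfusionSpec(target_bai=0.0))
        net = default_network(cardiac, None)
        sol = solve_cycle(net, FLUID)
        peak = int(np.argmax(cardiac.values))
        assert np.all(sol.station_flows["right_femoral_prox"][:, peak] > 0)
        assert np.all(sol.station_flows["right_femoral_dist"][:, peak] > 0)

    def test_high_assist_mean_descending_flow_retrograde(self):
        cardiac, ecmo = compose_perfusion(PerfusionSpec(target_bai=0.8))
        net = default_network(cardiac, ecmo)
        sol = solve_cycle(net, FLUID)
        assert sol.station_flows["desc_aorta"].mean() < 0.0

    def test_station_grid_shared_with_sources(self):
        cardiac, ecmo = compose_perfusion(PerfusionSpec(target_bai=0.4))
        net = default_network(cardiac, ecmo)
        sol = solve_cycle(net, FLUID)
        np.testing.assert_allclose(sol.times, cardiac.times)
        for seg in net.segments:
            assert sol.station_flows[seg.name].shape[1] == cardiac.n_samples
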
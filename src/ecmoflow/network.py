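"""Linearized transmission-line solver for the aorta-branch-femoral tree.

The vessel tree is solved in the frequency domain: a steady (0th
harmonic) Poiseuille nodal solve plus, per harmonic of the source
waveforms, a Womersley two-port wave solve.  The cycle solution is then
synthesized by inverse Fourier summation at uniformly spaced stations
along every segment, including the wall shear stress from the Womersley
wall-gradient transfer factor.

Internal computations are SI (m, Pa, m^3/s); the public
:class:`CycleSolution` carries clinical units (mm, mmHg, mL/s, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

from .waveforms import FlowWaveform

__all__ = [
    "FluidProps",
    "VesselSegment",
    "NetworkTopology",
    "CycleSolution",
    "default_network",
    "network_from_dict",
    "poiseuille_resistance",
    "solve_mean",
    "womersley_twoport",
    "womersley_alpha",
    "womersley_impedances",
    "wall_shear_factor",
    "solve_harmonic",
    "reconstruct_cycle",
    "solve_cycle",
    "save_station_csv",
    "conservation_residual",
]

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322
DEFAULT_OUTLET_PRESSURE_MMHG = 70.0
DEFAULT_WAVE_SPEED_M_S = 6.0
DEFAULT_STATION_SPACING_MM = 5.0
DEFAULT_N_HARMONICS = 20
ALPHA_OVERFLOW_LIMIT = 700.0  # Bessel argument imag part beyond which exp overflows


@dataclass(frozen=True)
class FluidProps:
    """Blood constants: density kg/m^3, dynamic viscosity kg/(m s)."""

    density: float = 1050.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class VesselSegment:
    """One arterial segment of the tree.

    ``diameter`` and ``length`` are in mm; ``wave_speed`` (the wall
    stiffness surrogate) in m/s.  Flow is positive from
    ``proximal_node`` toward ``distal_node``.
    """

    name: str
    diameter: float
    length: float
    proximal_node: str
    distal_node: str
    wave_speed: float = DEFAULT_WAVE_SPEED_M_S

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0 or self.wave_speed <= 0:
            raise ValueError(
                f"segment {self.name!r}: diameter, length and wave_speed "
                "must be positive"
            )

    @property
    def radius_m(self) -> float:
        return self.diameter * 1e-3 / 2.0

    @property
    def length_m(self) -> float:
        return self.length * 1e-3

    @property
    def area_m2(self) -> float:
        return np.pi * self.radius_m**2


@dataclass
class NetworkTopology:
    """Tree of segments with flow sources and fixed-pressure outlets.

    ``sources`` maps node name to its inflow waveform; ``outlets`` maps
    node name to its static pressure in mmHg.  ``outlet_labels`` maps
    report keys (IA, LCCA, ...) to the terminal segment feeding each
    outlet; ``trunk_segments`` lists the segments forming the aortic
    trunk in proximal-to-distal order (the arc-length coordinate used by
    the interface tracker).
    """

    segments: list[VesselSegment]
    sources: dict[str, FlowWaveform]
    outlets: dict[str, float]
    outlet_labels: dict[str, str] = field(default_factory=dict)
    trunk_segments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        nodes = self.node_names()
        n_nodes = len(nodes)
        if len(self.segments) != n_nodes - 1:
            raise ValueError("segment graph is not a tree (wrong edge count)")
        # connectivity via union-find
        parent = {n: n for n in nodes}

        def find(n: str) -> str:
            while parent[n] != n:
                parent[n] = parent[parent[n]]
                n = parent[n]
            return n

        for s in self.segments:
            parent[find(s.proximal_node)] = find(s.distal_node)
        if len({find(n) for n in nodes}) != 1:
            raise ValueError("segment graph is not connected")
        degree: dict[str, int] = {n: 0 for n in nodes}
        for s in self.segments:
            degree[s.proximal_node] += 1
            degree[s.distal_node] += 1
        for n, d in degree.items():
            if d == 1 and n not in self.sources and n not in self.outlets:
                raise ValueError(f"leaf node {n!r} is neither a source nor an outlet")
        if not self.outlets:
            raise ValueError("network needs at least one pressure outlet")
        for n in list(self.sources) + list(self.outlets):
            if n not in degree:
                raise ValueError(f"source/outlet node {n!r} not in the tree")
        grids = list(self.sources.values())
        for w in grids[1:]:
            if not w.same_grid(grids[0]):
                raise ValueError("all source waveforms must share one sampling grid")

    def node_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.segments:
            for n in (s.proximal_node, s.distal_node):
                if n not in seen:
                    seen.append(n)
        return seen

    def segment(self, name: str) -> VesselSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def total_mean_source_flow(self) -> float:
        """Sum of cycle-mean source flows, mL/s."""
        return sum(w.mean() for w in self.sources.values())


_DEFAULT_SEGMENTS = [
    # name, diameter mm, length mm, proximal, distal
    ("asc_aorta", 28.0, 100.0, "root", "arch"),
    ("ia", 7.0, 50.0, "arch", "ia_out"),
    ("lcca", 7.0, 50.0, "arch", "lcca_out"),
    ("lsa", 7.0, 50.0, "arch", "lsa_out"),
    ("desc_aorta", 11.3, 400.0, "arch", "iliac"),
    ("left_femoral", 10.3, 120.0, "iliac", "lfa_out"),
    ("right_femoral_prox", 10.3, 60.0, "iliac", "ecmo_node"),
    ("right_femoral_dist", 10.3, 160.0, "ecmo_node", "rfa_out"),
]

_OUTLET_LABELS = {
    "IA": "ia",
    "LCCA": "lcca",
    "LSA": "lsa",
    "LFA": "left_femoral",
    "RFA": "right_femoral_dist",
}

_KNOWN_CONFIG_KEYS = {
    "lengths_mm",
    "diameters_mm",
    "wave_speed_m_s",
    "outlet_pressure_mmHg",
}


def default_network(
    cardiac: FlowWaveform,
    ecmo: FlowWaveform | None = None,
    config: dict | None = None,
) -> NetworkTopology:
    """Build the default 8-segment aorta-branch-femoral tree.

    Ascending aorta (28 mm) to the arch node where the innominate, left
    common carotid and left subclavian branches (7 mm each) leave;
    descending aorta at the diaphragm diameter (11.3 mm) down to the
    iliac bifurcation; left femoral (10.3 mm, outlet) and right femoral
    split by the ECMO access node into a proximal and a distal limb.
    The cardiac source feeds the root; the ECMO source (if any) feeds
    the access node.  All outlets sit at 70 mmHg by default.

    ``config`` may override ``lengths_mm``/``diameters_mm`` (per-segment
    maps), ``wave_speed_m_s`` (scalar or per-segment map) and
    ``outlet_pressure_mmHg``.
    """
    config = dict(config or {})
    bad = sorted(set(config) - _KNOWN_CONFIG_KEYS)
    if bad:
        raise ValueError(f"unknown network config keys: {bad}")
    lengths = dict(config.get("lengths_mm") or {})
    diameters = dict(config.get("diameters_mm") or {})
    wave_speed = config.get("wave_speed_m_s", DEFAULT_WAVE_SPEED_M_S)
    seg_names = [s[0] for s in _DEFAULT_SEGMENTS]
    for label, table in (("lengths_mm", lengths), ("diameters_mm", diameters)):
        bad = sorted(set(table) - set(seg_names))
        if bad:
            raise ValueError(f"{label} refers to unknown segments: {bad}")
    if isinstance(wave_speed, dict):
        bad = sorted(set(wave_speed) - set(seg_names))
        if bad:
            raise ValueError(f"wave_speed_m_s refers to unknown segments: {bad}")
        speed_of = lambda n: wave_speed.get(n, DEFAULT_WAVE_SPEED_M_S)
    else:
        speed_of = lambda n: float(wave_speed)
    p_out = float(config.get("outlet_pressure_mmHg", DEFAULT_OUTLET_PRESSURE_MMHG))

    segments = [
        VesselSegment(
            name=name,
            diameter=diameters.get(name, dia),
            length=lengths.get(name, length),
            proximal_node=prox,
            distal_node=dist,
            wave_speed=speed_of(name),
        )
        for name, dia, length, prox, dist in _DEFAULT_SEGMENTS
    ]
    sources = {"root": cardiac}
    if ecmo is not None:
        sources["ecmo_node"] = ecmo
    outlets = {n: p_out for n in ("ia_out", "lcca_out", "lsa_out", "lfa_out", "rfa_out")}
    return NetworkTopology(
        segments=segments,
        sources=sources,
        outlets=outlets,
        outlet_labels=dict(_OUTLET_LABELS),
        trunk_segments=["asc_aorta", "desc_aorta", "right_femoral_prox"],
    )


def network_from_dict(
    data: dict, sources: dict[str, FlowWaveform]
) -> NetworkTopology:
    """Build a topology from a parsed network-definition mapping.

    Expected layout::

        segments:
          - {name: tube, diameter_mm: 10, length_mm: 100,
             wave_speed_m_s: 6, from: a, to: b}
        outlets:
          b: {pressure_mmHg: 70}

    ``sources`` supplies the waveform for each source node.
    """
    problems: list[str] = []
    segments = []
    for i, raw in enumerate(data.get("segments", [])):
        missing = [k for k in ("name", "diameter_mm", "length_mm", "from", "to") if k not in raw]
        if missing:
            problems.append(f"segments[{i}]: missing keys {missing}")
            continue
        segments.append(
            VesselSegment(
                name=raw["name"],
                diameter=float(raw["diameter_mm"]),
                length=float(raw["length_mm"]),
                proximal_node=raw["from"],
                distal_node=raw["to"],
                wave_speed=float(raw.get("wave_speed_m_s", DEFAULT_WAVE_SPEED_M_S)),
            )
        )
    outlets = {}
    for node, raw in (data.get("outlets") or {}).items():
        if isinstance(raw, dict):
            outlets[node] = float(raw.get("pressure_mmHg", DEFAULT_OUTLET_PRESSURE_MMHG))
        else:
            outlets[node] = float(raw)
    if problems:
        raise ValueError("invalid network definition: " + "; ".join(problems))
    return NetworkTopology(
        segments=segments,
        sources=dict(sources),
        outlets=outlets,
        outlet_labels=dict(data.get("outlet_labels") or {}),
        trunk_segments=list(data.get("trunk_segments") or []),
    )


def poiseuille_resistance(segment: VesselSegment, fluid: FluidProps) -> float:
    """Steady laminar resistance 128 mu L / (pi D^4), Pa s/m^3."""
    d = segment.diameter * 1e-3
    return 128.0 * fluid.viscosity * segment.length_m / (np.pi * d**4)


@dataclass
class MeanSolution:
    """Steady (0th harmonic) solve: node pressures Pa, segment flows m^3/s."""

    node_pressures: dict[str, float]
    segment_flows: dict[str, float]


def solve_mean(
    network: NetworkTopology,
    fluid: FluidProps,
    source_means: dict[str, float] | None = None,
) -> MeanSolution:
    """Nodal Poiseuille solve with prescribed source inflows.

    ``source_means`` overrides the cycle means of the network sources
    (m^3/s per node); by default they are taken from the source
    waveforms.  Outlet pressures are held at their configured values.
    """
    if source_means is None:
        source_means = {
            n: w.mean() * 1e-6 for n, w in network.sources.items()
        }
    nodes = network.node_names()
    free = [n for n in nodes if n not in network.outlets]
    if not free and not network.outlets:
        raise ValueError("network has no outlet: singular steady problem")
    idx = {n: i for i, n in enumerate(free)}
    n_free = len(free)
    a = np.zeros((n_free, n_free))
    b = np.zeros(n_free)
    for n, q in source_means.items():
        if n in idx:
            b[idx[n]] += q
    conductance = {
        s.name: 1.0 / poiseuille_resistance(s, fluid) for s in network.segments
    }
    p_fixed = {n: p * PA_PER_MMHG for n, p in network.outlets.items()}
    for s in network.segments:
        g = conductance[s.name]
        for here, there in ((s.proximal_node, s.distal_node),
                            (s.distal_node, s.proximal_node)):
            if here not in idx:
                continue
            i = idx[here]
            a[i, i] += g
            if there in idx:
                a[i, idx[there]] -= g
            else:
                b[i] += g * p_fixed[there]
    if n_free:
        p_free = np.linalg.solve(a, b)
    else:
        p_free = np.zeros(0)
    pressures = dict(p_fixed)
    pressures.update({n: float(p_free[idx[n]]) for n in free})
    flows = {
        s.name: conductance[s.name]
        * (pressures[s.proximal_node] - pressures[s.distal_node])
        for s in network.segments
    }
    return MeanSolution(node_pressures=pressures, segment_flows=flows)


def womersley_alpha(segment: VesselSegment, fluid: FluidProps, omega: float) -> float:
    """Womersley number R sqrt(omega rho / mu)."""
    return segment.radius_m * np.sqrt(omega * fluid.density / fluid.viscosity)


def _bessel_factor(alpha: float) -> complex:
    """F10 = 2 J1(L)/(L J0(L)) with L = i^{3/2} alpha."""
    lam = alpha * np.exp(1j * 3.0 * np.pi / 4.0)
    if abs(lam.imag) > ALPHA_OVERFLOW_LIMIT:
        raise OverflowError(
            f"Womersley number {alpha:g} too large for Bessel evaluation; "
            "reduce the harmonic count"
        )
    return 2.0 * jv(1, lam) / (lam * jv(0, lam))


def womersley_impedances(
    segment: VesselSegment, fluid: FluidProps, omega: float
) -> tuple[complex, complex]:
    """Per-length longitudinal impedance and shunt admittance at ``omega``.

    Z_l = (i omega rho / A) / (1 - F10(alpha)); as alpha -> 0 this tends
    to the Poiseuille value 128 mu / (pi D^4).  The shunt admittance is
    i omega C with compliance per length C = A / (rho c^2) from the
    segment wave speed.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    area = segment.area_m2
    alpha = womersley_alpha(segment, fluid, omega)
    z_long = (1j * omega * fluid.density / area) / (1.0 - _bessel_factor(alpha))
    compliance = area / (fluid.density * segment.wave_speed**2)
    y_shunt = 1j * omega * compliance
    return z_long, y_shunt


def womersley_twoport(
    segment: VesselSegment, fluid: FluidProps, omega: float
) -> tuple[complex, complex]:
    """Characteristic impedance and propagation constant at ``omega``.

    Zc = sqrt(Z_l / Y), gamma = sqrt(Z_l * Y) with the principal branch
    (Re gamma >= 0, attenuating in +x).
    """
    z_long, y_shunt = womersley_impedances(segment, fluid, omega)
    zc = np.sqrt(z_long / y_shunt)
    gamma = np.sqrt(z_long * y_shunt)
    if gamma.real < 0:
        gamma, zc = -gamma, -zc
    return complex(zc), complex(gamma)


def wall_shear_factor(
    segment: VesselSegment, fluid: FluidProps, omega: float
) -> complex:
    """Complex ratio tau_hat / Q_hat for a Womersley velocity profile.

    For an oscillatory flow amplitude Q_hat in a tube of radius R,
    tau_hat = mu * Lambda * J1(Lambda) / (R J0(Lambda)) / (A (1 - F10))
    * Q_hat, which tends to the Poiseuille value 4 mu / (pi R^3) as
    alpha -> 0.
    """
    alpha = womersley_alpha(segment, fluid, omega)
    lam = alpha * np.exp(1j * 3.0 * np.pi / 4.0)
    if abs(lam.imag) > ALPHA_OVERFLOW_LIMIT:
        raise OverflowError(f"Womersley number {alpha:g} too large")
    r = segment.radius_m
    f10 = 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return complex(
        fluid.viscosity
        * lam
        * jv(1, lam)
        / (r * jv(0, lam))
        / (segment.area_m2 * (1.0 - f10))
    )


@dataclass
class HarmonicSolution:
    """One harmonic's complex field: node pressures Pa, end flows m^3/s."""

    harmonic: int
    omega: float
    node_pressures: dict[str, complex]
    # per segment: (flow entering at proximal end, flow leaving at distal end)
    segment_end_flows: dict[str, tuple[complex, complex]]
    twoports: dict[str, tuple[complex, complex]]  # (Zc, gamma)


def solve_harmonic(
    network: NetworkTopology,
    fluid: FluidProps,
    harmonic_index: int,
    source_amplitudes: dict[str, complex],
    omega0: float,
) -> HarmonicSolution:
    """Solve one harmonic of the tree as a transmission-line network.

    Junction conditions are single-valued pressure and complex flow
    conservation; the oscillatory pressure vanishes at the (static
    pressure) outlets.  ``source_amplitudes`` are the complex flow
    amplitudes injected at source nodes, m^3/s.
    """
    if harmonic_index < 1:
        raise ValueError("harmonic_index must be >= 1")
    omega = harmonic_index * omega0
    nodes = network.node_names()
    free = [n for n in nodes if n not in network.outlets]
    idx = {n: i for i, n in enumerate(free)}
    a = np.zeros((len(free), len(free)), dtype=complex)
    b = np.zeros(len(free), dtype=complex)
    for n, amp in source_amplitudes.items():
        if n in idx:
            b[idx[n]] += amp
    twoports: dict[str, tuple[complex, complex]] = {}
    admittances: dict[str, tuple[complex, complex]] = {}
    for s in network.segments:
        zc, gamma = womersley_twoport(s, fluid, omega)
        twoports[s.name] = (zc, gamma)
        gl = gamma * s.length_m
        sinh_gl = np.sinh(gl)
        if sinh_gl == 0:
            raise ValueError(f"segment {s.name!r}: degenerate line at harmonic {harmonic_index}")
        y_self = np.cosh(gl) / (zc * sinh_gl)
        y_mutual = 1.0 / (zc * sinh_gl)
        admittances[s.name] = (y_self, y_mutual)
        for here, there in ((s.proximal_node, s.distal_node),
                            (s.distal_node, s.proximal_node)):
            if here not in idx:
                continue
            i = idx[here]
            a[i, i] += y_self
            if there in idx:
                a[i, idx[there]] -= y_mutual
    if len(free):
        try:
            p_free = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular harmonic assembly at harmonic {harmonic_index}"
            ) from exc
    else:
        p_free = np.zeros(0, dtype=complex)
    pressures: dict[str, complex] = {n: 0.0 + 0.0j for n in network.outlets}
    pressures.update({n: complex(p_free[idx[n]]) for n in free})
    end_flows: dict[str, tuple[complex, complex]] = {}
    for s in network.segments:
        y_self, y_mutual = admittances[s.name]
        pa = pressures[s.proximal_node]
        pb = pressures[s.distal_node]
        q_in = y_self * pa - y_mutual * pb
        q_out = y_mutual * pa - y_self * pb
        end_flows[s.name] = (q_in, q_out)
    return HarmonicSolution(
        harmonic=harmonic_index,
        omega=omega,
        node_pressures=pressures,
        segment_end_flows=end_flows,
        twoports=twoports,
    )


@dataclass
class CycleSolution:
    """Converged periodic solution at stations along every segment.

    ``station_positions`` are local arc lengths from each segment's
    proximal end (mm); flows are signed positive away from the aortic
    root; ``trunk_arc_mm``/``trunk_flows`` give the concatenated
    aortic-trunk view on the global arc-length coordinate measured from
    the root (junction stations appear once per adjoining segment).
    """

    times: np.ndarray
    period: float
    node_pressures: dict[str, np.ndarray]  # mmHg
    station_positions: dict[str, np.ndarray]  # mm, local
    station_flows: dict[str, np.ndarray]  # mL/s, (n_sta, n_t)
    station_pressures: dict[str, np.ndarray]  # mmHg
    station_wss: dict[str, np.ndarray]  # Pa, signed
    trunk_arc_mm: np.ndarray
    trunk_flows: np.ndarray  # mL/s, (n_trunk_sta, n_t)
    outlet_flows: dict[str, FlowWaveform]  # report key -> waveform

    def mean_outlet_flows(self) -> dict[str, float]:
        """Cycle-mean outlet flow per report key, mL/s."""
        return {k: w.mean() for k, w in self.outlet_flows.items()}


def reconstruct_cycle(
    network: NetworkTopology,
    fluid: FluidProps,
    mean_solution: MeanSolution,
    harmonic_solutions: list[HarmonicSolution],
    times: np.ndarray,
    period: float,
    station_spacing_mm: float = DEFAULT_STATION_SPACING_MM,
) -> CycleSolution:
    """Inverse-Fourier synthesis of the cycle at uniform stations.

    Within a segment the harmonic pressure/flow profiles follow the
    transmission-line formulas between the solved end pressures; the
    steady part is uniform in x.  WSS per station combines the
    Poiseuille mean part 4 mu Qbar / (pi R^3) with the per-harmonic
    Womersley wall-gradient terms.
    """
    n_t = times.size
    nyquist = n_t // 2
    for h in harmonic_solutions:
        if h.harmonic > nyquist:
            raise ValueError(
                f"harmonic {h.harmonic} exceeds the Nyquist limit {nyquist} "
                f"of the {n_t}-sample grid"
            )
    omega0 = 2.0 * np.pi / period
    n_h = len(harmonic_solutions)
    # phases[k, t] = exp(i n_k w0 t); synthesis adds Re(amplitude * phase)
    harm_numbers = np.array([h.harmonic for h in harmonic_solutions])
    phases = np.exp(1j * np.outer(harm_numbers * omega0, times))

    node_pressures: dict[str, np.ndarray] = {}
    for n in network.node_names():
        amps = np.array([h.node_pressures[n] for h in harmonic_solutions])
        series = mean_solution.node_pressures[n] + (
            (amps @ phases).real if n_h else 0.0
        )
        node_pressures[n] = np.broadcast_to(series, (n_t,)) * MMHG_PER_PA

    station_positions: dict[str, np.ndarray] = {}
    station_flows: dict[str, np.ndarray] = {}
    station_pressures: dict[str, np.ndarray] = {}
    station_wss: dict[str, np.ndarray] = {}
    for s in network.segments:
        x_mm = np.arange(0.0, s.length + 1e-9, station_spacing_mm)
        if x_mm[-1] < s.length - 1e-9:
            x_mm = np.append(x_mm, s.length)
        x = x_mm * 1e-3
        n_sta = x.size
        q_bar = mean_solution.segment_flows[s.name]
        radius = s.radius_m
        tau_bar = 4.0 * fluid.viscosity * q_bar / (np.pi * radius**3)
        p_prox = mean_solution.node_pressures[s.proximal_node]
        p_dist = mean_solution.node_pressures[s.distal_node]
        # steady pressure is linear in x, steady flow/WSS uniform
        p_sta = p_prox + (p_dist - p_prox) * (x / s.length_m)
        # per-harmonic complex profiles along the segment, (n_sta, n_h)
        q_prof = np.zeros((n_sta, n_h), dtype=complex)
        p_prof = np.zeros((n_sta, n_h), dtype=complex)
        tau_fac = np.zeros(n_h, dtype=complex)
        for k, h in enumerate(harmonic_solutions):
            zc, gamma = h.twoports[s.name]
            pa = h.node_pressures[s.proximal_node]
            pb = h.node_pressures[s.distal_node]
            sinh_gl = np.sinh(gamma * s.length_m)
            p_prof[:, k] = (
                pa * np.sinh(gamma * (s.length_m - x)) + pb * np.sinh(gamma * x)
            ) / sinh_gl
            q_prof[:, k] = (
                pa * np.cosh(gamma * (s.length_m - x)) - pb * np.cosh(gamma * x)
            ) / (zc * sinh_gl)
            tau_fac[k] = wall_shear_factor(s, fluid, h.omega)
        flows = q_bar + (q_prof @ phases).real if n_h else np.full((n_sta, n_t), q_bar)
        press = p_sta[:, None] + ((p_prof @ phases).real if n_h else 0.0)
        wss = tau_bar + ((q_prof * tau_fac) @ phases).real if n_h else np.full(
            (n_sta, n_t), tau_bar
        )
        station_positions[s.name] = x_mm
        station_flows[s.name] = np.broadcast_to(flows, (n_sta, n_t)) * 1e6
        station_pressures[s.name] = np.broadcast_to(press, (n_sta, n_t)) * MMHG_PER_PA
        station_wss[s.name] = np.broadcast_to(wss, (n_sta, n_t)).copy()

    # trunk view on the global arc-length coordinate
    trunk_arc: list[np.ndarray] = []
    trunk_q: list[np.ndarray] = []
    offset = 0.0
    for name in network.trunk_segments or [s.name for s in network.segments[:1]]:
        seg = network.segment(name)
        trunk_arc.append(station_positions[name] + offset)
        trunk_q.append(station_flows[name])
        offset += seg.length
    trunk_arc_mm = np.concatenate(trunk_arc) if trunk_arc else np.zeros(0)
    trunk_flows = np.vstack(trunk_q) if trunk_q else np.zeros((0, n_t))

    outlet_flows: dict[str, FlowWaveform] = {}
    for key, seg_name in network.outlet_labels.items():
        outlet_flows[key] = FlowWaveform(
            times=times.copy(),
            values=station_flows[seg_name][-1].copy(),
            period=period,
        )
    return CycleSolution(
        times=times.copy(),
        period=period,
        node_pressures=node_pressures,
        station_positions=station_positions,
        station_flows=station_flows,
        station_pressures=station_pressures,
        station_wss=station_wss,
        trunk_arc_mm=trunk_arc_mm,
        trunk_flows=trunk_flows,
        outlet_flows=outlet_flows,
    )


def save_station_csv(solution: CycleSolution, segment_name: str, path) -> None:
    """Export one segment's station series as CSV.

    Long format with columns ``position_mm,time_s,flow_mL_s,
    pressure_mmHg,wss_Pa``, stations in proximal-to-distal order.
    """
    import csv as _csv

    x = solution.station_positions[segment_name]
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(
            ["position_mm", "time_s", "flow_mL_s", "pressure_mmHg", "wss_Pa"]
        )
        for i, pos in enumerate(x):
            for j, t in enumerate(solution.times):
                writer.writerow([
                    f"{pos:.6g}", f"{t:.9g}",
                    f"{solution.station_flows[segment_name][i, j]:.6g}",
                    f"{solution.station_pressures[segment_name][i, j]:.6g}",
                    f"{solution.station_wss[segment_name][i, j]:.6g}",
                ])


def solve_cycle(
    network: NetworkTopology,
    fluid: FluidProps | None = None,
    n_harmonics: int | None = None,
    station_spacing_mm: float = DEFAULT_STATION_SPACING_MM,
) -> CycleSolution:
    """Full periodic solve: steady part plus ``n_harmonics`` harmonics.

    ``n_harmonics=None`` (the default) solves every harmonic below the
    Nyquist bin of the source grid, making the injected sources the
    exact trigonometric interpolant of the sampled waveforms and the
    junction closure exact to round-off.  Pass a smaller count for
    deliberately truncated (faster) solves.
    """
    fluid = fluid or FluidProps()
    if not network.sources:
        raise ValueError("network has no sources")
    ref = next(iter(network.sources.values()))
    times, period = ref.times, ref.period
    if n_harmonics is None:
        n_harmonics = times.size // 2 - 1
    if n_harmonics > times.size // 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} exceeds Nyquist of the "
            f"{times.size}-sample grid"
        )
    omega0 = 2.0 * np.pi / period
    spectra = {
        node: np.fft.rfft(w.values * 1e-6) / w.n_samples
        for node, w in network.sources.items()
    }
    source_means = {node: float(c[0].real) for node, c in spectra.items()}
    mean_sol = solve_mean(network, fluid, source_means)
    harmonics = []
    for n in range(1, n_harmonics + 1):
        amps = {node: 2.0 * c[n] for node, c in spectra.items()}
        harmonics.append(solve_harmonic(network, fluid, n, amps, omega0))
    return reconstruct_cycle(
        network, fluid, mean_sol, harmonics, times, period, station_spacing_mm
    )


def conservation_residual(network: NetworkTopology, solution: CycleSolution) -> float:
    """Worst junction mass-closure error, as a fraction of total mean flow.

    At every interior node and every sample, sums the station-end flows
    of adjoining segments and any source injection; returns the maximum
    absolute residual divided by the total mean source flow (mL/s).
    """
    total = network.total_mean_source_flow
    if total == 0:
        total = 1.0
    n_t = solution.times.size
    worst = 0.0
    source_series = {
        node: w.values for node, w in network.sources.items()
    }
    for node in network.node_names():
        if node in network.outlets:
            continue
        net = np.zeros(n_t)
        if node in source_series:
            net += source_series[node]
        for s in network.segments:
            if s.distal_node == node:
                net += solution.station_flows[s.name][-1]
            if s.proximal_node == node:
                net -= solution.station_flows[s.name][0]
        worst = max(worst, float(np.max(np.abs(net))) / total)
    return worst
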
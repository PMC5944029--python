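"""Perfusion-level sweep orchestration, reporting, and fixtures.

Runs the model across a list of assist levels (default 0/40/60/80%),
computes the full index suite at each level, tracks the flow interface,
derives the cross-level trend statistics, and renders plain-text report
tables.  Everything here is deterministic; the fixture generator is the
only consumer of a seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices as idx
from .interface import InterfaceTrack, track_interface
from .network import (
    CycleSolution,
    FluidProps,
    NetworkTopology,
    conservation_residual,
    default_network,
    solve_cycle,
    womersley_twoport,
    VesselSegment,
)
from .waveforms import (
    DEFAULT_N_SAMPLES,
    DEFAULT_PERIOD_S,
    DEFAULT_SYSTOLIC_FRACTION,
    DEFAULT_TOTAL_FLOW_L_MIN,
    ML_S_PER_L_MIN,
    FlowWaveform,
    PerfusionSpec,
    cardiac_waveform,
    compose_perfusion,
    save_waveform_csv,
)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "render_report",
    "make_fixtures",
    "region_station_map",
    "load_config",
]

logger = logging.getLogger("ecmoflow")

DEFAULT_BAI_LEVELS = (0.0, 0.4, 0.6, 0.8)
CONSERVATION_TOLERANCE = 0.005

REGION_AORTIC_ARCH = "aortic_arch"
REGION_DESCENDING = "descending_aorta"
REGION_FEMORAL = "femoral_artery"


@dataclass(frozen=True)
class SweepConfig:
    """Validated sweep configuration with the paper-level physical defaults."""

    bai_levels: tuple[float, ...] = DEFAULT_BAI_LEVELS
    period_s: float = DEFAULT_PERIOD_S
    total_mean_flow_L_min: float = DEFAULT_TOTAL_FLOW_L_MIN
    systolic_fraction: float = DEFAULT_SYSTOLIC_FRACTION
    bai_mode: str = "mean_flow_ratio"
    n_samples: int = DEFAULT_N_SAMPLES
    n_harmonics: int | None = None  # None = every harmonic below Nyquist
    station_spacing_mm: float = 5.0
    density: float = 1050.0
    viscosity: float = 0.0035
    network: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bai_levels:
            raise ValueError("bai_levels must not be empty")
        levels = tuple(sorted(float(b) for b in self.bai_levels))
        object.__setattr__(self, "bai_levels", levels)
        for b in levels:
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"BAI level {b} outside [0,1]")

    def fluid(self) -> FluidProps:
        return FluidProps(density=self.density, viscosity=self.viscosity)

    def perfusion_spec(self, target_bai: float) -> PerfusionSpec:
        return PerfusionSpec(
            target_bai=target_bai,
            total_mean_flow=self.total_mean_flow_L_min,
            period=self.period_s,
            systolic_fraction=self.systolic_fraction,
            bai_mode=self.bai_mode,  # type: ignore[arg-type]
            n_samples=self.n_samples,
        )


def load_config(path: str | Path | None) -> SweepConfig:
    """Read a YAML (or JSON) config file; missing keys take defaults."""
    if path is None:
        return SweepConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(SweepConfig.__dataclass_fields__)
    bad = sorted(set(raw) - known)
    if bad:
        raise ValueError(f"{path}: unknown config keys {bad}")
    if "bai_levels" in raw:
        raw["bai_levels"] = tuple(raw["bai_levels"])
    return SweepConfig(**raw)


def region_station_map(
    network: NetworkTopology, solution: CycleSolution
) -> dict[str, list[tuple[str, int]]]:
    """Map report regions to (segment, station index) pairs.

    The 1-D model has no inner/outer wall, so regions are sets of
    sections: the arch region is the distal third of the ascending
    aorta segment; the femoral region collects stations within one
    femoral diameter of the iliac bifurcation; the descending region is
    the whole descending aorta.
    """
    regions: dict[str, list[tuple[str, int]]] = {
        REGION_AORTIC_ARCH: [],
        REGION_DESCENDING: [],
        REGION_FEMORAL: [],
    }
    asc = network.segment("asc_aorta")
    for i, x in enumerate(solution.station_positions["asc_aorta"]):
        if x >= 2.0 * asc.length / 3.0:
            regions[REGION_AORTIC_ARCH].append(("asc_aorta", i))
    for i, _ in enumerate(solution.station_positions["desc_aorta"]):
        regions[REGION_DESCENDING].append(("desc_aorta", i))
    for seg_name in ("left_femoral", "right_femoral_prox"):
        seg = network.segment(seg_name)
        for i, x in enumerate(solution.station_positions[seg_name]):
            if x <= seg.diameter:
                regions[REGION_FEMORAL].append((seg_name, i))
    return regions


def _region_wss_matrix(
    solution: CycleSolution, stations: list[tuple[str, int]]
) -> np.ndarray:
    if not stations:
        raise ValueError("region has no stations")
    return np.vstack([solution.station_wss[seg][i] for seg, i in stations])


@dataclass
class LevelResult:
    """All outputs for one assist level."""

    bai_level: float
    cardiac: FlowWaveform
    ecmo: FlowWaveform
    solution: CycleSolution
    report: idx.IndexReport
    interface: InterfaceTrack
    conservation: float


@dataclass
class SweepResult:
    """Sweep over assist levels plus cross-level trend statistics."""

    config: SweepConfig
    levels: list[LevelResult]
    trends: dict[str, float | str | None] = field(default_factory=dict)

    def level(self, bai: float) -> LevelResult:
        for lv in self.levels:
            if np.isclose(lv.bai_level, bai):
                return lv
        raise KeyError(f"no level {bai}")


def _run_level(config: SweepConfig, target_bai: float) -> LevelResult:
    t0 = time.perf_counter()
    cardiac, ecmo = compose_perfusion(config.perfusion_spec(target_bai))
    network = default_network(
        cardiac,
        ecmo if ecmo.mean() > 0 else None,
        config.network or None,
    )
    solution = solve_cycle(
        network,
        config.fluid(),
        n_harmonics=config.n_harmonics,
        station_spacing_mm=config.station_spacing_mm,
    )
    residual = conservation_residual(network, solution)
    if residual > CONSERVATION_TOLERANCE:
        logger.warning(
            "BAI %.2f: conservation residual %.3g exceeds %.3g",
            target_bai, residual, CONSERVATION_TOLERANCE,
        )
    outlet_means = solution.mean_outlet_flows()  # mL/s
    total_ml_s = config.total_mean_flow_L_min * ML_S_PER_L_MIN
    r_up, r_down = idx.flow_ratios(outlet_means, total_ml_s)
    hi_per_outlet = {
        key: idx.harmonic_index(w) for key, w in solution.outlet_flows.items()
    }
    regions = region_station_map(network, solution)
    dt = float(solution.times[1] - solution.times[0])
    osi_per_region = {}
    wss_per_region = {}
    for name, stations in regions.items():
        tau = _region_wss_matrix(solution, stations)
        wss_per_region[name] = idx.regional_mean_wss(tau)
        osi_per_region[name] = float(
            np.mean([idx.osi(row, dt) for row in tau])
        )
    track = track_interface(solution)
    report = idx.IndexReport(
        bai_instantaneous=idx.bai(ecmo, cardiac, "instantaneous_ratio"),
        bai_mean_ratio=idx.bai(ecmo, cardiac, "mean_flow_ratio"),
        r_up=r_up,
        r_down=r_down,
        hi_per_outlet=hi_per_outlet,
        osi_per_region=osi_per_region,
        mean_wss_per_region=wss_per_region,
        interface_position=track.cycle_mean_position,
    )
    logger.info(
        "BAI %.2f solved in %.3fs (conservation %.2e)",
        target_bai, time.perf_counter() - t0, residual,
    )
    return LevelResult(
        bai_level=target_bai,
        cardiac=cardiac,
        ecmo=ecmo,
        solution=solution,
        report=report,
        interface=track,
        conservation=residual,
    )


def _compute_trends(levels: list[LevelResult]) -> dict:
    """Cross-level Pearson correlations and trend pass/warn statuses."""
    trends: dict[str, float | str | None] = {}
    if len(levels) < 3:
        return trends
    bai = [lv.bai_level for lv in levels]
    upper = [
        sum(lv.solution.mean_outlet_flows()[k] for k in idx.UPPER_OUTLETS)
        for lv in levels
    ]
    lower = [
        sum(lv.solution.mean_outlet_flows()[k] for k in idx.LOWER_OUTLETS)
        for lv in levels
    ]
    hi_mean = [float(np.mean(list(lv.report.hi_per_outlet.values()))) for lv in levels]
    try:
        trends["r_upper_flow_vs_bai"] = idx.pearson_r(bai, upper)
        trends["r_lower_flow_vs_bai"] = idx.pearson_r(bai, lower)
        trends["r_hi_vs_bai"] = idx.pearson_r(bai, hi_mean)
        for region in (REGION_AORTIC_ARCH, REGION_FEMORAL):
            wss = [lv.report.mean_wss_per_region[region] for lv in levels]
            trends[f"r_wss_{region}_vs_bai"] = idx.pearson_r(bai, wss)
    except ValueError:
        pass
    # reported, not hard-asserted: reduced model may not keep the 3-D signs
    up_status = "pass" if trends.get("r_upper_flow_vs_bai", 0) > 0 else "warn"
    down_status = "pass" if trends.get("r_lower_flow_vs_bai", 0) < 0 else "warn"
    trends["upper_flow_trend_status"] = up_status
    trends["lower_flow_trend_status"] = down_status
    if up_status == "warn" or down_status == "warn":
        logger.warning(
            "flow-split trend signs deviate from the expected "
            "upper(+)/lower(-) pattern: r_up=%s r_down=%s",
            trends.get("r_upper_flow_vs_bai"), trends.get("r_lower_flow_vs_bai"),
        )
    return trends


def run_sweep(config: SweepConfig | None = None) -> SweepResult:
    """Run the model at every configured assist level and collect trends."""
    config = config or SweepConfig()
    levels = []
    for bai_level in config.bai_levels:
        try:
            levels.append(_run_level(config, bai_level))
        except Exception as exc:
            raise RuntimeError(f"sweep failed at BAI level {bai_level}: {exc}") from exc
    return SweepResult(config=config, levels=levels, trends=_compute_trends(levels))


def _bai_tag(bai: float) -> str:
    return f"{int(round(bai * 100)):02d}"


def render_report(sweep: SweepResult, out_dir: str | Path) -> list[Path]:
    """Write the report tables; returns the list of files written.

    Artifacts: per-level outlet waveform CSVs, mean-flow-vs-BAI table,
    harmonic-index table, regional mean-WSS table, regional OSI table,
    interface summary, and a JSON roll-up.  Output is byte-deterministic
    for a fixed config.
    """
    if not sweep.levels:
        raise ValueError("cannot render an empty sweep")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    outlet_keys = sorted(sweep.levels[0].solution.outlet_flows)
    for lv in sweep.levels:
        frame = pd.DataFrame({"time_s": lv.solution.times})
        for key in outlet_keys:
            frame[f"{key}_mL_s"] = lv.solution.outlet_flows[key].values
        path = out / f"outlet_flows_bai_{_bai_tag(lv.bai_level)}.csv"
        frame.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    bai_pct = [lv.bai_level * 100.0 for lv in sweep.levels]

    mean_rows = {
        "BAI_pct": bai_pct,
        **{
            f"{key}_L_min": [
                lv.solution.mean_outlet_flows()[key] / ML_S_PER_L_MIN
                for lv in sweep.levels
            ]
            for key in outlet_keys
        },
        "r_up": [lv.report.r_up for lv in sweep.levels],
        "r_down": [lv.report.r_down for lv in sweep.levels],
    }
    path = out / "mean_flow_vs_bai.csv"
    pd.DataFrame(mean_rows).to_csv(path, index=False, float_format="%.6g")
    written.append(path)

    hi_rows = {
        "BAI_pct": bai_pct,
        **{
            key: [lv.report.hi_per_outlet[key] for lv in sweep.levels]
            for key in outlet_keys
        },
    }
    path = out / "harmonic_index.csv"
    pd.DataFrame(hi_rows).to_csv(path, index=False, float_format="%.6g")
    written.append(path)

    region_names = sorted(sweep.levels[0].report.mean_wss_per_region)
    wss_rows = {
        "BAI_pct": bai_pct,
        **{
            region: [lv.report.mean_wss_per_region[region] for lv in sweep.levels]
            for region in region_names
        },
    }
    path = out / "regional_wss.csv"
    pd.DataFrame(wss_rows).to_csv(path, index=False, float_format="%.6g")
    written.append(path)

    osi_rows = {
        "BAI_pct": bai_pct,
        **{
            region: [lv.report.osi_per_region[region] for lv in sweep.levels]
            for region in region_names
        },
    }
    path = out / "osi_by_region.csv"
    pd.DataFrame(osi_rows).to_csv(path, index=False, float_format="%.6g")
    written.append(path)

    from .interface import save_track_csv

    for lv in sweep.levels:
        path = out / f"interface_track_bai_{_bai_tag(lv.bai_level)}.csv"
        save_track_csv(lv.interface, path)
        written.append(path)

    iface_rows = {
        "BAI_pct": bai_pct,
        "mean_position_mm": [
            lv.interface.cycle_mean_position if lv.interface.cycle_mean_position is not None else float("nan")
            for lv in sweep.levels
        ],
        "existence_fraction": [lv.interface.existence_fraction for lv in sweep.levels],
        "cycle_range_mm": [lv.interface.cycle_range for lv in sweep.levels],
    }
    path = out / "interface_summary.csv"
    pd.DataFrame(iface_rows).to_csv(path, index=False, float_format="%.6g")
    written.append(path)

    summary = {
        "bai_levels_pct": bai_pct,
        "reports": {
            _bai_tag(lv.bai_level): lv.report.to_dict() for lv in sweep.levels
        },
        "conservation_residual": {
            _bai_tag(lv.bai_level): lv.conservation for lv in sweep.levels
        },
        "trends": sweep.trends,
    }
    path = out / "sweep_summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, allow_nan=False,
                               default=float) + "\n")
    written.append(path)
    return written


def make_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Generate the small deterministic test-input fixture set.

    Same seed, same bytes.  Includes analytic waveforms whose index
    values have closed forms, a toy two-segment network definition, and
    a JSON file of oracle values with their derivations.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    period = 0.8
    n = 256
    t = np.arange(n) * period / n

    def _save(name: str, values: np.ndarray) -> None:
        path = out / name
        save_waveform_csv(FlowWaveform(times=t, values=values, period=period), path)
        written.append(path)

    _save("constant_3Lmin.csv", np.full(n, 50.0))
    _save("half_sine.csv", cardiac_waveform(5.0, period, 0.35, n).values)
    # square wave: 2 mL/s for the first half cycle, 0 after; paired with a
    # constant 2 mL/s ECMO flow the instantaneous assist ratio is
    # 0.5*(2/4) + 0.5*(2/2) = 0.75
    _save("square_cardiac.csv", np.where(t < period / 2, 2.0, 0.0))
    _save("square_ecmo.csv", np.full(n, 2.0))
    noisy = 40.0 + 10.0 * rng.standard_normal(n)
    _save("noisy_flow.csv", noisy)

    tube = VesselSegment("tube", diameter=10.0, length=200.0,
                         proximal_node="a", distal_node="b")
    zc, gamma = womersley_twoport(tube, FluidProps(), 2.0 * np.pi / period)
    network_def = {
        "segments": [
            {"name": "tube", "diameter_mm": 10.0, "length_mm": 200.0,
             "wave_speed_m_s": 6.0, "from": "a", "to": "b"},
            {"name": "tail", "diameter_mm": 8.0, "length_mm": 100.0,
             "wave_speed_m_s": 6.0, "from": "b", "to": "c"},
        ],
        "outlets": {"c": {"pressure_mmHg": 70.0}},
    }
    path = out / "toy_network.yaml"
    path.write_text(yaml.safe_dump(network_def, sort_keys=True))
    written.append(path)

    oracles = {
        "square_wave_bai_instantaneous": 0.75,
        "square_wave_bai_note": "ecmo=2 const, cardiac=2 half-duty square: "
                                "mean of 2/4 (first half) and 2/2 (second half)",
        "matched_tube_input_impedance": {
            "real": zc.real, "imag": zc.imag,
            "note": "terminating 'tube' with its characteristic impedance "
                    "makes the input impedance equal Zc (fundamental, 0.8 s)",
        },
        "seed": seed,
    }
    path = out / "oracles.json"
    path.write_text(json.dumps(oracles, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
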
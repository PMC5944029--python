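"""Scalar hemodynamic indices.

All operate on one-cycle uniformly sampled series.  Periodic signals are
stored on an endpoint-excluded grid (t = 0 .. T - dt); integrals close
the cycle by wrapping the first sample, so the trapezoidal cycle
integral of a periodic series equals ``mean * T`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveforms import BaiMode, FlowWaveform

__all__ = [
    "IndexReport",
    "bai",
    "flow_ratios",
    "harmonic_index",
    "osi",
    "regional_mean_wss",
    "pearson_r",
]

UPPER_OUTLETS = ("IA", "LCCA", "LSA")
LOWER_OUTLETS = ("LFA", "RFA")


@dataclass
class IndexReport:
    """All scalar indices for one perfusion level.

    Fractions are stored as values in [0, 1]; rendering to percent is a
    presentation concern.
    """

    bai_instantaneous: float
    bai_mean_ratio: float
    r_up: float
    r_down: float
    hi_per_outlet: dict[str, float] = field(default_factory=dict)
    osi_per_region: dict[str, float] = field(default_factory=dict)
    mean_wss_per_region: dict[str, float] = field(default_factory=dict)  # Pa
    interface_position: float | None = None  # mm from aortic root

    def __post_init__(self) -> None:
        for name, value in (
            ("bai_instantaneous", self.bai_instantaneous),
            ("bai_mean_ratio", self.bai_mean_ratio),
            ("r_up", self.r_up),
            ("r_down", self.r_down),
        ):
            if not 0.0 <= value <= 1.0 + 1e-9:
                raise ValueError(f"{name}={value} outside [0,1]")
        if self.r_up + self.r_down > 1.0 + 1e-9:
            raise ValueError("r_up + r_down exceeds 1")
        for outlet, hi_val in self.hi_per_outlet.items():
            if not -1e-9 <= hi_val <= 1.0 + 1e-9:
                raise ValueError(f"HI[{outlet}]={hi_val} outside [0,1]")
        for region, osi_val in self.osi_per_region.items():
            if not -1e-9 <= osi_val <= 0.5 + 1e-9:
                raise ValueError(f"OSI[{region}]={osi_val} outside [0,0.5]")

    def to_dict(self) -> dict:
        return {
            "bai": self.bai_mean_ratio,
            "bai_instantaneous": self.bai_instantaneous,
            "r_up": self.r_up,
            "r_down": self.r_down,
            "hi": dict(self.hi_per_outlet),
            "osi": dict(self.osi_per_region),
            "mean_wss_Pa": dict(self.mean_wss_per_region),
            "interface_mm": self.interface_position,
        }


def _cycle_trapz(values: np.ndarray, dt: float) -> float:
    """Trapezoidal integral over one period, wrapping periodically."""
    closed = np.concatenate([values, values[:1]])
    return float(np.trapezoid(closed, dx=dt))


def bai(ecmo: FlowWaveform, cardiac: FlowWaveform, mode: BaiMode = "mean_flow_ratio") -> float:
    """Blood assist index: ECMO share of total perfusion over one cycle.

    ``instantaneous_ratio`` averages F_E/(F_E+F_C) pointwise over the
    cycle (the integrand is defined as 0 where both flows vanish);
    ``mean_flow_ratio`` takes the ratio of cycle means.  Both return a
    fraction in [0, 1].
    """
    if not ecmo.same_grid(cardiac):
        raise ValueError("ecmo and cardiac waveforms must share the sampling grid")
    fe = ecmo.values
    fc = cardiac.values
    if mode == "mean_flow_ratio":
        total = fe.mean() + fc.mean()
        if total == 0.0:
            return 0.0
        value = fe.mean() / total
    elif mode == "instantaneous_ratio":
        denom = fe + fc
        ratio = np.divide(fe, denom, out=np.zeros_like(fe), where=denom != 0)
        value = _cycle_trapz(ratio, ecmo.dt) / ecmo.period
    else:
        raise ValueError(f"unknown bai mode {mode!r}")
    return float(np.clip(value, 0.0, 1.0))


def flow_ratios(
    outlet_mean_flows: dict[str, float], aorta_total: float
) -> tuple[float, float]:
    """Upper-body and lower-body perfusion fractions.

    r_up = (Q_IA + Q_LCCA + Q_LSA) / Q_total and
    r_down = (Q_LFA + Q_RFA) / Q_total, all on cycle-mean flows in
    consistent units.
    """
    if aorta_total <= 0:
        raise ValueError("aorta_total must be positive")
    for key in UPPER_OUTLETS + LOWER_OUTLETS:
        if key not in outlet_mean_flows:
            raise KeyError(f"outlet_mean_flows missing required outlet {key!r}")
    r_up = sum(outlet_mean_flows[k] for k in UPPER_OUTLETS) / aorta_total
    r_down = sum(outlet_mean_flows[k] for k in LOWER_OUTLETS) / aorta_total
    return float(r_up), float(r_down)


def harmonic_index(w: FlowWaveform) -> float:
    """Pulsatility fraction of the one-sided Fourier amplitude spectrum.

    HI = sum_{n>=1} T[n] / sum_{n>=0} T[n] with T[0] = |mean| and
    T[n] the amplitude of the n-th harmonic (2|c_n|/N, one-sided).
    0 for a steady signal, 1 for a zero-mean oscillation; an all-zero
    signal maps to 0 by convention.
    """
    q = w.values
    n = q.size
    coeffs = np.fft.rfft(q) / n
    amplitudes = np.abs(coeffs)
    amplitudes[1:] *= 2.0
    if n % 2 == 0:
        amplitudes[-1] /= 2.0  # Nyquist bin is not doubled
    # suppress FFT round-off so steady signals give exactly 0
    amplitudes[amplitudes < amplitudes.max() * 1e-12] = 0.0
    total = amplitudes.sum()
    if total == 0.0:
        return 0.0
    return float(amplitudes[1:].sum() / total)


def osi(wss: np.ndarray, dt: float = 1.0) -> float:
    """Oscillatory shear index of a signed one-cycle WSS series.

    OSI = 0.5 * (1 - |int tau dt| / int |tau| dt), trapezoidal over the
    closed cycle; 0 for unidirectional shear, 0.5 for zero-mean
    oscillation, and 0 by convention for an identically-zero series.
    """
    tau = np.asarray(wss, dtype=float)
    if tau.ndim != 1 or tau.size < 2:
        raise ValueError("wss must be a 1-D series with >= 2 samples")
    denom = _cycle_trapz(np.abs(tau), dt)
    if denom == 0.0:
        return 0.0
    numer = abs(_cycle_trapz(tau, dt))
    return float(np.clip(0.5 * (1.0 - numer / denom), 0.0, 0.5))


def regional_mean_wss(solution, region=None) -> float:
    """Time-and-station average of |WSS| over a region, Pa.

    ``solution`` is either a raw (n_stations, n_times) signed-WSS array
    (``region`` ignored) or a cycle solution exposing ``station_wss``,
    in which case ``region`` is a sequence of ``(segment_name,
    station_index)`` pairs selecting the stations.
    """
    if hasattr(solution, "station_wss"):
        if not region:
            raise ValueError("region must contain at least one station")
        tau = np.vstack([solution.station_wss[seg][i] for seg, i in region])
    else:
        tau = np.atleast_2d(np.asarray(solution, dtype=float))
    if tau.size == 0:
        raise ValueError("region must contain at least one station")
    return float(np.mean(np.abs(tau)))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance input")
    return float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
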
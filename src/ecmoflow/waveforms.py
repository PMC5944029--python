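"""Source waveform synthesis for the perfusion model.

Builds the pulsatile cardiac ejection waveform and the non-pulsatile
ECMO cannula waveform, and composes the two so that a requested blood
assist index (BAI) and total mean perfusion are met simultaneously.

Units at this interface are clinical: flow in mL/s inside a
:class:`FlowWaveform`, mean flows in L/min at function boundaries,
time in seconds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FlowWaveform",
    "PerfusionSpec",
    "InfeasibleBaiError",
    "cardiac_waveform",
    "ecmo_waveform",
    "compose_perfusion",
    "load_waveform_csv",
    "save_waveform_csv",
]

ML_S_PER_L_MIN = 1000.0 / 60.0

DEFAULT_PERIOD_S = 0.8
DEFAULT_TOTAL_FLOW_L_MIN = 5.0
DEFAULT_SYSTOLIC_FRACTION = 0.35
DEFAULT_N_SAMPLES = 800

BaiMode = Literal["instantaneous_ratio", "mean_flow_ratio"]


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic volumetric flow waveform sampled over one cycle.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, uniform, starting at 0, strictly
        increasing and spanning one period (endpoint excluded).
    values : ndarray
        Volumetric flow rate at each sample, mL/s.
    period : float
        Cycle duration in seconds.
    """

    times: np.ndarray
    values: np.ndarray
    period: float = DEFAULT_PERIOD_S

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if times.ndim != 1 or times.size < 64:
            raise ValueError("waveform needs >= 64 samples on a 1-D grid")
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly sampled")
        span = times[-1] - times[0] + dt[0]
        if not np.isclose(span, self.period, rtol=1e-6):
            raise ValueError(
                f"times span {span:g}s but period is {self.period:g}s"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("waveform values must be finite")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def mean(self) -> float:
        """Time-averaged flow over the cycle, mL/s (periodic mean)."""
        return float(np.mean(self.values))

    def mean_l_min(self) -> float:
        return self.mean() / ML_S_PER_L_MIN

    def same_grid(self, other: "FlowWaveform") -> bool:
        return (
            self.n_samples == other.n_samples
            and np.isclose(self.period, other.period)
            and np.allclose(self.times, other.times)
        )


@dataclass(frozen=True)
class PerfusionSpec:
    """Target perfusion state used to compose the two source waveforms."""

    target_bai: float
    total_mean_flow: float = DEFAULT_TOTAL_FLOW_L_MIN  # L/min
    period: float = DEFAULT_PERIOD_S
    systolic_fraction: float = DEFAULT_SYSTOLIC_FRACTION
    bai_mode: BaiMode = "mean_flow_ratio"
    n_samples: int = DEFAULT_N_SAMPLES

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_bai <= 1.0:
            raise ValueError(f"target_bai must lie in [0,1], got {self.target_bai}")
        if self.total_mean_flow <= 0:
            raise ValueError("total_mean_flow must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0,1)")
        if self.bai_mode not in ("instantaneous_ratio", "mean_flow_ratio"):
            raise ValueError(f"unknown bai_mode {self.bai_mode!r}")


class InfeasibleBaiError(ValueError):
    """Requested BAI cannot be met in the selected evaluation mode."""


def _time_grid(period: float, n_samples: int) -> np.ndarray:
    if period <= 0:
        raise ValueError("period must be positive")
    if n_samples < 64:
        raise ValueError(f"n_samples must be >= 64, got {n_samples}")
    return np.arange(n_samples) * (period / n_samples)


def cardiac_waveform(
    mean_flow: float,
    period: float = DEFAULT_PERIOD_S,
    systolic_fraction: float = DEFAULT_SYSTOLIC_FRACTION,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> FlowWaveform:
    """Half-sine systolic ejection waveform with zero diastolic flow.

    The amplitude is solved analytically so the cycle mean equals
    ``mean_flow``: a half sine of peak Q_p over a systolic window of
    duration s*T averages Q_p*2*s/pi over the cycle, hence
    ``peak = mean * pi / (2 * systolic_fraction)``.

    Parameters
    ----------
    mean_flow : float
        Cycle-mean flow in L/min (>= 0).
    """
    if mean_flow < 0:
        raise ValueError("mean_flow must be non-negative")
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie in (0,1)")
    t = _time_grid(period, n_samples)
    t_sys = systolic_fraction * period
    peak_ml_s = mean_flow * ML_S_PER_L_MIN * np.pi / (2.0 * systolic_fraction)
    values = np.where(
        t < t_sys, peak_ml_s * np.sin(np.pi * t / t_sys), 0.0
    )
    return FlowWaveform(times=t, values=values, period=period)


def ecmo_waveform(
    mean_flow: float,
    period: float = DEFAULT_PERIOD_S,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> FlowWaveform:
    """Constant (non-pulsatile) cannula waveform at ``mean_flow`` L/min."""
    if mean_flow < 0:
        raise ValueError("mean_flow must be non-negative")
    t = _time_grid(period, n_samples)
    values = np.full(n_samples, mean_flow * ML_S_PER_L_MIN)
    return FlowWaveform(times=t, values=values, period=period)


def _bai_of_pair(ecmo: FlowWaveform, cardiac: FlowWaveform, mode: BaiMode) -> float:
    # local import avoids a cycle: indices imports FlowWaveform from here
    from .indices import bai

    return bai(ecmo, cardiac, mode=mode)


def compose_perfusion(spec: PerfusionSpec) -> tuple[FlowWaveform, FlowWaveform]:
    """Build (cardiac, ecmo) waveforms matching the spec's BAI and total flow.

    The cycle means are complementary — ``mean(cardiac) + mean(ecmo) =
    total_mean_flow`` — and the BAI of the returned pair, evaluated in
    ``spec.bai_mode``, equals ``spec.target_bai`` to 1e-6.

    In ``mean_flow_ratio`` mode the split is closed-form.  In
    ``instantaneous_ratio`` mode the ECMO level is found by bracketed
    root-finding; because the cardiac shape carries no diastolic flow,
    any nonzero ECMO flow makes the instantaneous ratio equal 1
    throughout diastole, so targets in (0, 1 - systolic_fraction] are
    unreachable and raise :class:`InfeasibleBaiError`.

    Returns
    -------
    (cardiac, ecmo) : tuple of FlowWaveform
    """
    total = spec.total_mean_flow
    make_cardiac = lambda m: cardiac_waveform(
        m, spec.period, spec.systolic_fraction, spec.n_samples
    )
    make_ecmo = lambda m: ecmo_waveform(m, spec.period, spec.n_samples)

    if spec.target_bai == 0.0:
        return make_cardiac(total), make_ecmo(0.0)
    if spec.target_bai == 1.0:
        return make_cardiac(0.0), make_ecmo(total)

    if spec.bai_mode == "mean_flow_ratio":
        ecmo_mean = spec.target_bai * total
        # correct the half-sine's sampling bias so the discrete mean-flow
        # ratio recovers the target to round-off, not just to ~1e-5
        cardiac = make_cardiac(total - ecmo_mean)
        measured = cardiac.mean_l_min()
        if measured > 0:
            scale = (total - ecmo_mean) / measured
            cardiac = FlowWaveform(
                times=cardiac.times, values=cardiac.values * scale,
                period=cardiac.period,
            )
        return cardiac, make_ecmo(ecmo_mean)
    else:
        diastolic_floor = 1.0 - spec.systolic_fraction
        if spec.target_bai <= diastolic_floor:
            raise InfeasibleBaiError(
                "instantaneous_ratio BAI with a zero-diastolic cardiac shape "
                f"is only achievable at 0 or in ({diastolic_floor:.4f}, 1]; "
                f"requested {spec.target_bai:g}"
            )

        def residual(ecmo_mean: float) -> float:
            pair_bai = _bai_of_pair(
                make_ecmo(ecmo_mean),
                make_cardiac(total - ecmo_mean),
                "instantaneous_ratio",
            )
            return pair_bai - spec.target_bai

        eps = 1e-9 * total
        ecmo_mean = brentq(residual, eps, total - eps, xtol=1e-12, rtol=1e-14)

    cardiac = make_cardiac(total - ecmo_mean)
    ecmo = make_ecmo(ecmo_mean)
    return cardiac, ecmo


def load_waveform_csv(path: str | Path, period: float | None = None) -> FlowWaveform:
    """Read a one-period waveform CSV with columns ``time_s,flow_mL_s``."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["time_s", "flow_mL_s"]:
            raise ValueError(
                f"{path}: expected header 'time_s,flow_mL_s', got {header!r}"
            )
        rows = [(float(r[0]), float(r[1])) for r in reader if r]
    if not rows:
        raise ValueError(f"{path}: no samples")
    t = np.array([r[0] for r in rows])
    q = np.array([r[1] for r in rows])
    if period is None:
        period = float(t[-1] - t[0] + (t[1] - t[0]))
    return FlowWaveform(times=t - t[0], values=q, period=period)


def save_waveform_csv(w: FlowWaveform, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "flow_mL_s"])
        for t, q in zip(w.times, w.values):
            writer.writerow([f"{t:.9g}", f"{q:.9g}"])
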
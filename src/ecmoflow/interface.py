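"""Cardiac/ECMO flow-interface (watershed) localization.

The interface is the point on the aortic trunk where antegrade flow
from the heart (positive, away from the root) meets retrograde flow
driven by the femoral ECMO return (negative).  It is located on the
signed sectional flow of the 1-D solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CycleSolution

__all__ = [
    "InterfaceTrack",
    "locate_interface",
    "track_interface",
    "save_track_csv",
]


@dataclass
class InterfaceTrack:
    """Per-sample interface positions over one cycle.

    ``positions_mm[i]`` is NaN when no antegrade-to-retrograde front
    exists at sample i.  ``cycle_mean_position`` averages over the
    samples where the interface exists (None if it never does);
    ``existence_fraction`` is the share of the cycle with an interface.
    """

    times: np.ndarray
    positions_mm: np.ndarray
    cycle_mean_position: float | None
    cycle_range: float
    existence_fraction: float
    fully_retrograde_fraction: float

    def exists(self) -> np.ndarray:
        return ~np.isnan(self.positions_mm)


def locate_interface(
    solution: CycleSolution, time_index: int
) -> float | None:
    """Position (mm from the aortic root) of the watershed at one sample.

    Returns the most proximal trunk location where the signed flow
    changes from antegrade (positive, proximal side) to retrograde
    (negative, distal side), linearly interpolating the zero crossing
    between adjacent stations.  Returns None when no such front exists.
    A fully retrograde trunk reports position 0 (the front sits at the
    proximal end).
    """
    x = solution.trunk_arc_mm
    q = solution.trunk_flows[:, time_index].copy()
    if x.size < 2:
        return None
    # flows below solver round-off count as stagnant, not directional
    tol = 1e-10 * max(1.0, float(np.max(np.abs(solution.trunk_flows))))
    q[np.abs(q) < tol] = 0.0
    if q[0] <= 0.0:
        # no antegrade flow at the root side
        return 0.0 if np.any(q < 0.0) else None
    for i in range(x.size - 1):
        if q[i] > 0.0 and q[i + 1] < 0.0:
            dx = x[i + 1] - x[i]
            if dx <= 0.0:
                return float(x[i])  # sign change across a junction
            frac = q[i] / (q[i] - q[i + 1])
            return float(x[i] + frac * dx)
        if q[i] > 0.0 and q[i + 1] == 0.0:
            # grazing zero: interface only if flow goes negative beyond
            j = i + 1
            while j < x.size and q[j] == 0.0:
                j += 1
            if j < x.size and q[j] < 0.0:
                return float(x[i + 1])
    return None


def track_interface(solution: CycleSolution) -> InterfaceTrack:
    """Apply :func:`locate_interface` at every sample and summarize."""
    n_t = solution.times.size
    positions = np.full(n_t, np.nan)
    fully_retro = 0
    tol = 1e-10 * max(1.0, float(np.max(np.abs(solution.trunk_flows))))
    for i in range(n_t):
        pos = locate_interface(solution, i)
        if pos is not None:
            positions[i] = pos
            if pos == 0.0 and solution.trunk_flows[0, i] <= tol:
                fully_retro += 1
    exists = ~np.isnan(positions)
    if exists.any():
        mean_pos = float(np.mean(positions[exists]))
        span = float(np.max(positions[exists]) - np.min(positions[exists]))
    else:
        mean_pos = None
        span = 0.0
    return InterfaceTrack(
        times=solution.times.copy(),
        positions_mm=positions,
        cycle_mean_position=mean_pos,
        cycle_range=span,
        existence_fraction=float(exists.sum()) / n_t,
        fully_retrograde_fraction=fully_retro / n_t,
    )


def save_track_csv(track: InterfaceTrack, path) -> None:
    """Export a track as CSV with columns ``time_s,position_mm,exists``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "position_mm", "exists"])
        for t, pos in zip(track.times, track.positions_mm):
            exists = not np.isnan(pos)
            writer.writerow([
                f"{t:.9g}", f"{pos:.6g}" if exists else "", int(exists)
            ])
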
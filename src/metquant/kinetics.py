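"""Death-curve extraction from SYTOX time-lapse series.

Each frame is counted independently: SYTOX-positive cells are segmented with
a nucleus-scale minimum area (so cytoplasmic puncta never count as deaths)
and normalized to the initial nucleus count n0 from the frame-0 Hoechst
image — Hoechst is exposed only once, at the start, so n0 comes solely from
frame 0.  The plateau level is the mean of the trailing points, and the
onset is the earliest time after which the curve stays within a tolerance
band of that level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from metquant.imgio import ChannelStack
from metquant.segment import SegmentParams, segment_particles


class PlateauUndefinedError(ValueError):
    """The curve never enters the tolerance band around the plateau level."""


@dataclass
class DeathCurve:
    times_h: np.ndarray
    fraction_positive: np.ndarray
    n0: int
    plateau_level: float | None = None
    plateau_onset_h: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fraction_positive = np.asarray(self.fraction_positive, dtype=float)
        if self.times_h.shape != self.fraction_positive.shape:
            raise ValueError("times and fractions must have equal length")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def count_sytox_cells(frame: ChannelStack, params: SegmentParams) -> int:
    """Count SYTOX-positive cells in one frame (whole dead-cell nuclei, not
    puncta — ``params.min_area_px`` should be at nucleus scale)."""
    table, _ = segment_particles(frame.plane("sytox"), params)
    return len(table)


def build_death_curve(
    frames: Sequence[ChannelStack],
    n0: int,
    params: SegmentParams,
    replicate_groups: Sequence[Sequence[int]] | None = None,
) -> DeathCurve:
    """Build the normalized death curve from time-ordered frames.

    ``n0`` is the initial nucleus count from the frame-0 Hoechst image.
    When ``replicate_groups`` gives index groups of simultaneous replicate
    fields, per-time fractions are averaged across the group (each frame's
    own n0 applies before grouping; here a shared n0 is assumed).
    """
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    times = np.array([f.time_h if f.time_h is not None else i
                      for i, f in enumerate(frames)], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frames must be strictly time-ordered")
    counts = np.array([count_sytox_cells(f, params) for f in frames], dtype=float)
    fractions = counts / n0
    if replicate_groups is not None:
        fractions = np.array([np.mean([fractions[i] for i in grp])
                              for grp in replicate_groups])
        times = np.array([times[grp[0]] for grp in replicate_groups])
    return DeathCurve(times, fractions, n0)


def plateau_time(curve: DeathCurve, tol: float, tail_points: int = 4) -> tuple[float, float]:
    """Estimate the plateau level and its onset time.

    Level = mean of the final ``tail_points`` fractions; onset = earliest
    time after which every point stays within ``tol`` of the level.  Raises
    :class:`PlateauUndefinedError` when the curve never settles in the band.
    """
    f = curve.fraction_positive
    if f.size < 5:
        raise ValueError("plateau estimation needs at least 5 time points")
    k = min(tail_points, f.size)
    level = float(f[-k:].mean())
    within = np.abs(f - level) <= tol
    # earliest index from which the curve stays inside the band
    idx = None
    for i in range(f.size):
        if within[i:].all():
            idx = i
            break
    if idx is None:
        raise PlateauUndefinedError(
            f"curve never stays within ±{tol} of the plateau level {level:.4f}"
        )
    return level, float(curve.times_h[idx])
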
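"""Quadrant polarity statistic for cytoplasmic DNA puncta.

A circular ROI centered on the nucleus is divided into four 90° sectors,
with sector 1 oriented from the nucleus center toward the MET release site
on the cell edge.  Puncta within the circle are counted per sector across
all z-slices; a polarized cell accumulates puncta in sector 1.  Sector
counts from the same cells are compared with paired t-tests (quadrant 1
against each of the others), since the four counts per cell are jointly
constrained and an unpaired comparison would be miscalibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PolarityResult:
    counts: np.ndarray           # (n_cells, 4)
    mean_counts: np.ndarray      # (4,)
    fraction: np.ndarray         # (4,) pooled fraction per quadrant
    tests: list[dict]            # quadrant 1 vs 2, 3, 4: {"pair", "t", "p"}


def assign_quadrants(
    points_xy: np.ndarray,
    nucleus_center: tuple[float, float],
    met_anchor: tuple[float, float],
    radius_px: float,
) -> np.ndarray:
    """Count puncta per quadrant relative to the nucleus→MET-anchor axis.

    ``points_xy`` is an (n, 2) array of punctum (x, y) positions, z-slices
    pooled.  Quadrant 1 is |θ| ≤ 45° around the anchor axis, quadrant 2 is
    (45°, 135°], quadrant 4 is [−135°, −45°), quadrant 3 the remainder;
    boundary angles are deterministic per these closed/open intervals.  Only
    puncta within ``radius_px`` of the nucleus center are counted.
    """
    cx, cy = nucleus_center
    ax, ay = met_anchor
    if ax == cx and ay == cy:
        raise ValueError("MET anchor must differ from the nucleus center")
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    counts = np.zeros(4, dtype=int)
    if pts.size == 0:
        return counts
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    r = np.hypot(dx, dy)
    axis = np.arctan2(ay - cy, ax - cx)
    theta = np.degrees(np.arctan2(dy, dx) - axis)
    theta = (theta + 180.0) % 360.0 - 180.0     # wrap to (-180, 180]
    inside = r <= radius_px
    t = theta[inside]
    counts[0] = int(np.sum(np.abs(t) <= 45.0))
    counts[1] = int(np.sum((t > 45.0) & (t <= 135.0)))
    counts[3] = int(np.sum((t >= -135.0) & (t < -45.0)))
    counts[2] = int(inside.sum()) - counts[0] - counts[1] - counts[3]
    return counts


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if d.mean() == 0 else (float("inf"), 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def polarity_summary(counts_per_cell: np.ndarray) -> PolarityResult:
    """Aggregate quadrant counts across cells and test polarization.

    ``counts_per_cell`` is an (n_cells, 4) array; requires n_cells ≥ 2.
    Reports per-quadrant mean counts, pooled fractions, and paired t-tests
    of quadrant 1 versus quadrants 2–4.
    """
    counts = np.atleast_2d(np.asarray(counts_per_cell, dtype=float))
    if counts.shape[0] < 2:
        raise ValueError("polarity summary requires at least 2 cells")
    if counts.shape[1] != 4:
        raise ValueError("expected 4 quadrant counts per cell")
    total = counts.sum()
    fraction = counts.sum(axis=0) / total if total > 0 else np.zeros(4)
    tests = []
    for q in (1, 2, 3):
        t, p = _paired_t(counts[:, 0], counts[:, q])
        tests.append({"pair": (1, q + 1), "t": t, "p": p})
    return PolarityResult(counts.astype(int), counts.mean(axis=0), fraction, tests)


def vonmises_quadrant1_mass(kappa: float) -> float:
    """Analytic probability that a von Mises deviate lies within ±45° of its
    mean — the expected quadrant-1 fraction at angular concentration kappa."""
    lo, hi = -np.pi / 4, np.pi / 4
    if kappa == 0:
        return 0.25
    return float(stats.vonmises.cdf(hi, kappa) - stats.vonmises.cdf(lo, kappa))
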
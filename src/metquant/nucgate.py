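"""Nuclear counting and condensation gating.

Apoptotic nuclei are small and densely stained: on a dot plot of Hoechst MFI
versus 2-D nuclear area they separate from healthy nuclei as a
high-MFI/low-area population.  ``gate_condensed`` applies that gate
programmatically, either with absolute thresholds or — the default —
relative to the per-field medians, which makes the gate independent of
acquisition settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from metquant.segment import SegmentParams, segment_particles


class GateSpec(BaseModel):
    """Condensation gate: flag nuclei with area below ``area_max`` and MFI
    above ``mfi_min``.  In ``relative`` mode both values are fractions of the
    per-field medians (e.g. area < 0.7×median and MFI > 1.4×median)."""

    model_config = ConfigDict(extra="forbid")

    mode: str = Field("relative", pattern="^(relative|absolute)$")
    area_max: float = Field(0.7, gt=0)
    mfi_min: float = Field(1.4, gt=0)


@dataclass
class CondensationResult:
    n_total: int
    n_condensed: int
    flags: np.ndarray            # per-nucleus boolean, aligned with the RoiTable
    area_threshold: float
    mfi_threshold: float

    @property
    def fraction(self) -> float:
        return self.n_condensed / self.n_total if self.n_total else 0.0


def count_nuclei(
    hoechst: np.ndarray,
    params: SegmentParams,
) -> tuple[int, pd.DataFrame, np.ndarray]:
    """Count nuclei on a Hoechst image with watershed splitting of touching
    nuclei; the count is the per-cell denominator used downstream.

    Returns ``(count, roi_table, label_mask)``.
    """
    params = params.model_copy(update={"watershed": True})
    table, labels = segment_particles(hoechst, params)
    return len(table), table, labels


def gate_condensed(nuclei: pd.DataFrame, gate: GateSpec) -> CondensationResult:
    """Gate condensed (apoptotic) nuclei on the (area, MFI) table.

    A nucleus is condensed iff ``area_px < area_max`` and ``mfi > mfi_min``,
    with thresholds resolved per the gate mode.  Relative mode needs at
    least 10 nuclei to estimate the medians.
    """
    n = len(nuclei)
    if gate.mode == "relative":
        if n < 10:
            raise ValueError(f"relative gate needs >= 10 nuclei to estimate medians, got {n}")
        area_thr = gate.area_max * float(nuclei["area_px"].median())
        mfi_thr = gate.mfi_min * float(nuclei["mfi"].median())
    else:
        area_thr = gate.area_max
        mfi_thr = gate.mfi_min
    flags = (nuclei["area_px"].to_numpy() < area_thr) & (nuclei["mfi"].to_numpy() > mfi_thr)
    return CondensationResult(n, int(flags.sum()), flags, area_thr, mfi_thr)
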
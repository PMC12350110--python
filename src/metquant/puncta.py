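"""Per-cell cytoplasmic DNA-puncta detection and staining classification.

Cell bodies are delineated on the MPO channel and recorded as an ROI set;
DNA puncta are then detected on a DNA channel after blacking out the nuclear
mask, assigned to the cell whose ROI contains their centroid, and classified
by which of the four stains (Hoechst, SYTOX, MPO, CitH3) they carry.  The
staged combination classes H → H+S → H+S+M → H+S+M+C reflect the
processing sequence of the puncta; any non-nested combination falls into
"other".

For z-stacks each punctum is detected per slice and per-slice detections are
linked into 3-D components (26-connectivity); both the linked and the
per-slice counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata

from metquant.imgio import ChannelStack
from metquant.segment import (SegmentParams, binarize, mask_exclude,
                              segment_particles, sparse_object_threshold)

COMBO_CLASSES = ("H", "H+S", "H+S+M", "H+S+M+C", "other")

_FLAG_TO_CLASS = {
    (True, False, False, False): "H",
    (True, True, False, False): "H+S",
    (True, True, True, False): "H+S+M",
    (True, True, True, True): "H+S+M+C",
}


@dataclass
class PunctumRecord:
    """One cytoplasmic DNA punctum; ``cell_id`` 0 marks extracellular."""

    punctum_id: int
    cell_id: int
    x: float
    y: float
    z: float
    area_px: int
    positive: tuple[bool, bool, bool, bool] | None = None  # (H, S, M, C)
    combo_class: str | None = None


class ChannelPositivityRule(BaseModel):
    """How a punctum is scored positive for a channel.

    ``method``:

    * ``"cell_contrast"`` (default) — the threshold for a punctum is
      ``contrast_factor`` × the median intensity of its own cell's
      non-nuclear, non-punctum pixels in that channel.  Puncta are bright
      relative to the diffuse stain of their cell, so a per-cell contrast
      ratio is robust to both staining strength and the heavy class
      imbalance between cytoplasm and punctum pixels.
    * ``"auto_cell"`` — one ISODATA/intermeans threshold per channel over
      all in-cell, non-nuclear pixels.
    * ``"fixed"`` — per-channel thresholds in ``fixed_thresholds``.
    * ``"k_mad"`` — background median + k × scaled MAD of out-of-cell pixels.

    A punctum is positive iff at least ``min_fraction_pixels_positive`` of
    its pixels exceed the resolved threshold.
    """

    model_config = ConfigDict(extra="forbid")

    method: str = Field("cell_contrast", pattern="^(cell_contrast|auto_cell|fixed|k_mad)$")
    contrast_factor: float = Field(2.0, gt=1)
    fixed_thresholds: dict[str, float] | None = None
    k: float = Field(6.0, gt=0)
    min_fraction_pixels_positive: float = Field(0.5, gt=0, le=1)


def find_cell_rois(
    mpo: np.ndarray,
    params: SegmentParams,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment cell bodies on the MPO channel into an ROI set.

    Watershed separates touching cells.  Returns ``(roi_table, label_mask)``.
    """
    params = params.model_copy(update={"watershed": True})
    return segment_particles(mpo, params)


def detect_puncta(
    dna: np.ndarray,
    nuclear_mask: np.ndarray,
    cell_labels: np.ndarray,
    params: SegmentParams,
    nuclear_dilation_px: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, int, int]:
    """Detect DNA puncta outside the nuclear mask and assign them to cells.

    ``dna`` is a 2-D image or a (z, y, x) volume; the nuclear mask and cell
    labels are 2-D and apply to every slice.  Detection order: black out
    nuclear pixels → threshold → particle analysis → centroid-based cell
    assignment.  Puncta whose centroid lies outside every cell ROI are
    discarded from the per-cell table and counted as extracellular.

    Returns ``(records, punctum_labels, n_extracellular, n_per_slice)`` where
    ``punctum_labels`` has the same (z, y, x) shape as the input and
    ``n_per_slice`` is the unlinked per-slice detection count.
    """
    dna = np.asarray(dna, dtype=np.float64)
    squeeze = dna.ndim == 2
    if squeeze:
        dna = dna[None]
    if dna.ndim != 3:
        raise ValueError(f"expected 2-D image or (z, y, x) volume, got shape {dna.shape}")
    nuclear_mask = np.asarray(nuclear_mask) != 0
    if nuclear_dilation_px > 0:
        # absorb the blurred nuclear rim that extends past the segmented mask
        from skimage.morphology import dilation, disk
        nuclear_mask = dilation(nuclear_mask, disk(nuclear_dilation_px))
    cell_labels = np.asarray(cell_labels)
    cleaned = np.stack([mask_exclude(sl, nuclear_mask) for sl in dna])

    # one threshold for the whole volume keeps slices comparable; estimate it
    # outside the blacked-out nuclear pixels, whose zeros would skew Otsu
    sample = cleaned[:, nuclear_mask == 0]
    t = sparse_object_threshold(sample, params) if sample.size else None
    if t is None:
        t = np.inf
    vol_params = params.model_copy(update={"threshold_method": f"fixed:{t}"})
    binary = np.stack([binarize(sl, vol_params) for sl in cleaned])

    n_per_slice = 0
    conn2d = ndi.generate_binary_structure(2, params.skimage_connectivity)
    for sl in binary:
        _, n2 = ndi.label(sl, structure=conn2d)
        n_per_slice += n2

    # link across z with 26-connectivity
    labels, n3 = ndi.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    records = []
    n_extra = 0
    if n3:
        idx = np.arange(1, n3 + 1)
        areas = ndi.sum_labels(np.ones_like(labels), labels, idx)
        coms = ndi.center_of_mass(binary, labels, idx)
        for lab, area, (cz, cy, cx) in zip(idx, areas, coms):
            if area < params.min_area_px:
                labels[labels == lab] = 0
                continue
            cell = int(cell_labels[int(round(cy)), int(round(cx))])
            if cell == 0:
                n_extra += 1
                continue
            records.append({
                "punctum_id": int(lab), "cell_id": cell,
                "x": float(cx), "y": float(cy), "z": float(cz),
                "area_px": int(area),
            })
    df = pd.DataFrame(records, columns=["punctum_id", "cell_id", "x", "y", "z", "area_px"])
    if squeeze:
        labels = labels[0][None]  # keep (z, y, x) with z-extent 1
    return df, labels, n_extra, n_per_slice


def classify_puncta(
    records: pd.DataFrame,
    punctum_labels: np.ndarray,
    stack: ChannelStack,
    rule: ChannelPositivityRule,
    cell_labels: np.ndarray | None = None,
    nuclear_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score each punctum's per-channel positivity and combination class.

    Requires the four channels ``hoechst, sytox, mpo, cith3`` in ``stack``.
    Returns the records with boolean columns and ``combo_class`` added, plus
    the class-fraction table (normalized to the total punctum count, summing
    to 1 over observed classes).
    """
    channel_order = ("hoechst", "sytox", "mpo", "cith3")
    for name in channel_order:
        if name not in stack.channel_names:
            raise KeyError(f"missing channel {name!r} required for classification")
    if rule.method == "cell_contrast":
        if cell_labels is None:
            raise ValueError("cell_contrast positivity requires cell_labels")
        refs = _cell_reference_medians(stack, channel_order, cell_labels,
                                       nuclear_mask, punctum_labels)
        thresholds = None
    else:
        thresholds = {
            name: _channel_threshold(stack.channel(name), rule, name,
                                     cell_labels, nuclear_mask)
            for name in channel_order
        }
    out = records.copy()
    flags = {name: [] for name in channel_order}
    for _, row in out.iterrows():
        member = punctum_labels == int(row["punctum_id"])
        for name in channel_order:
            vol = stack.channel(name)
            vals = vol[member]
            if thresholds is None:
                ref = refs[name].get(int(row["cell_id"]), 0.0)
                thr = rule.contrast_factor * max(ref, 1e-6)
            else:
                thr = thresholds[name]
            frac = float(np.mean(vals > thr)) if vals.size else 0.0
            flags[name].append(frac >= rule.min_fraction_pixels_positive)
    for name in channel_order:
        out[f"pos_{name}"] = flags[name]
    out["combo_class"] = [
        _FLAG_TO_CLASS.get(tuple(bool(out.iloc[i][f"pos_{n}"]) for n in channel_order), "other")
        for i in range(len(out))
    ]
    if len(out):
        fractions = out["combo_class"].value_counts(normalize=True)
    else:
        fractions = pd.Series(dtype=float)
    fractions = fractions.reindex([c for c in COMBO_CLASSES if c in fractions.index])
    return out, fractions


def _cell_reference_medians(
    stack: ChannelStack,
    channel_order: tuple[str, ...],
    cell_labels: np.ndarray,
    nuclear_mask: np.ndarray | None,
    punctum_labels: np.ndarray,
) -> dict[str, dict[int, float]]:
    """Per-cell, per-channel median of non-nuclear, non-punctum pixels —
    the diffuse-stain reference the contrast rule compares puncta against."""
    cell_labels = np.asarray(cell_labels)
    shape = stack.channel(channel_order[0]).shape
    sel = np.broadcast_to(cell_labels > 0, shape) & (np.asarray(punctum_labels) == 0)
    if nuclear_mask is not None:
        sel = sel & np.broadcast_to(np.asarray(nuclear_mask) == 0, shape)
    cells2d = np.broadcast_to(cell_labels, shape)
    refs: dict[str, dict[int, float]] = {}
    ids = np.unique(cell_labels)
    ids = ids[ids > 0]
    for name in channel_order:
        vol = stack.channel(name)
        per_cell: dict[int, float] = {}
        for cid in ids:
            vals = vol[sel & (cells2d == cid)]
            per_cell[int(cid)] = float(np.median(vals)) if vals.size else 0.0
        refs[name] = per_cell
    return refs


def _channel_threshold(
    volume: np.ndarray,
    rule: ChannelPositivityRule,
    name: str,
    cell_labels: np.ndarray | None,
    nuclear_mask: np.ndarray | None,
) -> float:
    if rule.method == "fixed":
        if not rule.fixed_thresholds or name not in rule.fixed_thresholds:
            raise ValueError(f"fixed positivity rule lacks a threshold for {name!r}")
        return float(rule.fixed_thresholds[name])
    if cell_labels is None:
        raise ValueError(f"positivity method {rule.method!r} requires cell_labels")
    in_cell = np.broadcast_to(cell_labels > 0, volume.shape)
    if rule.method == "auto_cell":
        sel = in_cell.copy()
        if nuclear_mask is not None:
            sel &= np.broadcast_to(nuclear_mask == 0, volume.shape)
        vals = volume[sel]
        if vals.size == 0 or np.ptp(vals) == 0:
            return float("inf")     # no contrast: nothing scores positive
        return float(threshold_isodata(vals))
    # k_mad over out-of-cell background pixels
    bg = volume[~in_cell]
    if bg.size == 0:
        return float("inf")
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + rule.k * 1.4826 * mad


def puncta_positive_fraction(records: pd.DataFrame, n_cells: int) -> float:
    """Percent of cells carrying at least one detected punctum."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    n_pos = records.loc[records["cell_id"] > 0, "cell_id"].nunique() if len(records) else 0
    return 100.0 * n_pos / n_cells
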
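"""Binary segmentation chain and labeled-particle measurement.

Every quantification in the package builds on the same chain:
threshold → morphological close → hole fill → (optional) watershed split →
connected-component labeling → per-label measurement.  The watershed variant
splits touching objects along ridges of the Euclidean distance transform,
seeded by h-maxima-suppressed distance peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import clear_border, watershed

ROI_COLUMNS = ("label", "area_px", "centroid_x", "centroid_y", "mfi",
               "bbox_min_y", "bbox_min_x", "bbox_max_y", "bbox_max_x")

_INT_COLS = {"label": int, "area_px": int, "bbox_min_y": int, "bbox_min_x": int,
             "bbox_max_y": int, "bbox_max_x": int}


def empty_roi_table() -> pd.DataFrame:
    """An empty RoiTable with the canonical column schema."""
    return pd.DataFrame({c: pd.Series(dtype=float) for c in ROI_COLUMNS}).astype(_INT_COLS)


class SegmentParams(BaseModel):
    """Parameters of the segmentation chain.

    ``threshold_method`` is ``"otsu"`` (per-image automatic threshold) or
    ``"fixed:<value>"`` for a fixed intensity cutoff.  ``h_maxima`` is the
    prominence (in distance-transform pixels) below which neighbouring peaks
    are merged before watershed seeding.  ``connectivity`` follows the
    particle-counting convention: 8-connected foreground by default.
    """

    model_config = ConfigDict(extra="forbid")

    threshold_method: str = "otsu"
    close_radius_px: int = Field(1, ge=0)
    fill_holes: bool = True
    watershed: bool = False
    h_maxima: float = Field(2.0, gt=0)
    min_area_px: int = Field(1, ge=1)
    exclude_border: bool = False
    connectivity: int = Field(8)

    @field_validator("connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        return v

    @field_validator("threshold_method")
    @classmethod
    def _thr(cls, v: str) -> str:
        if v == "otsu":
            return v
        if v.startswith("fixed:"):
            float(v.split(":", 1)[1])  # must parse
            return v
        raise ValueError("threshold_method must be 'otsu' or 'fixed:<value>'")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2

    def threshold_value(self, image: np.ndarray) -> float | None:
        """Resolve the threshold for ``image``; None if no foreground exists."""
        if self.threshold_method.startswith("fixed:"):
            return float(self.threshold_method.split(":", 1)[1])
        if image.size == 0 or np.ptp(image) == 0:
            return None  # constant image: no foreground under Otsu
        return float(threshold_otsu(image))


def sparse_object_threshold(sample: np.ndarray, params: SegmentParams,
                            k_mad: float = 6.0) -> float | None:
    """Threshold for sparse bright objects (puncta, MET blobs) on a dim field.

    Histogram-splitting thresholds can collapse into the background mode when
    the bright class holds a tiny fraction of pixels, so the automatic value
    is floored at background median + ``k_mad`` × scaled MAD — objects dimmer
    than the noise floor are undetectable anyway.  Fixed thresholds pass
    through unchanged; returns None when no foreground exists.
    """
    t = params.threshold_value(sample)
    if t is None or params.threshold_method.startswith("fixed:"):
        return t
    med = float(np.median(sample))
    mad = float(np.median(np.abs(sample - med)))
    return max(t, med + k_mad * 1.4826 * mad)


def binarize(
    image: np.ndarray,
    params: SegmentParams,
    threshold_exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold, close and hole-fill a single 2-D image into a binary mask.

    ``threshold_exclude`` marks pixels (nonzero) to ignore when *estimating*
    an automatic threshold — e.g. blacked-out nuclear regions, whose zeros
    would otherwise dominate the Otsu histogram.  Excluded pixels are still
    binarized against the resulting threshold (they are zero, hence
    background).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    if threshold_exclude is not None and params.threshold_method == "otsu":
        sample = image[np.asarray(threshold_exclude) == 0]
        t = params.threshold_value(sample)
    else:
        t = params.threshold_value(image)
    if t is None:
        return np.zeros(image.shape, dtype=bool)
    mask = image > t
    if params.close_radius_px > 0 and mask.any():
        mask = morphology.closing(mask, morphology.disk(params.close_radius_px))
    if params.fill_holes and mask.any():
        mask = ndi.binary_fill_holes(mask)
    return mask


def _watershed_split(mask: np.ndarray, params: SegmentParams) -> np.ndarray:
    """Split touching objects along distance-transform ridges.

    Seeds are regional maxima of the Euclidean distance transform after
    h-maxima suppression (peaks closer in height than ``h_maxima`` merge into
    one seed), so round objects are never over-split.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    # cap h so small objects keep at least one seed
    h = min(params.h_maxima, max(float(dist.max()) / 2, 0.5))
    peaks = morphology.h_maxima(dist, h)
    structure = ndi.generate_binary_structure(2, params.skimage_connectivity)
    markers, n = ndi.label(peaks, structure=structure)
    if n == 0:
        return cc_label(mask, connectivity=params.skimage_connectivity).astype(np.int32)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def measure_labels(
    labels: np.ndarray,
    intensity: np.ndarray,
    min_area_px: int = 1,
    exclude_border: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Measure labeled regions into a RoiTable, dropping small/border labels.

    Returns the table together with the label image with dropped labels
    zeroed.  ``mfi`` is the mean of ``intensity`` over member pixels.
    """
    labels = np.asarray(labels)
    if exclude_border:
        labels = clear_border(labels)
    if labels.max() == 0:
        return empty_roi_table(), labels.astype(np.int32)
    props = regionprops_table(
        labels, intensity_image=intensity,
        properties=("label", "area", "centroid", "intensity_mean", "bbox"),
    )
    table = pd.DataFrame({
        "label": props["label"],
        "area_px": props["area"].astype(int),
        "centroid_x": props["centroid-1"],
        "centroid_y": props["centroid-0"],
        "mfi": props["intensity_mean"],
        "bbox_min_y": props["bbox-0"],
        "bbox_min_x": props["bbox-1"],
        "bbox_max_y": props["bbox-2"],
        "bbox_max_x": props["bbox-3"],
    })
    small = table.loc[table["area_px"] < min_area_px, "label"].to_numpy()
    if small.size:
        labels = np.where(np.isin(labels, small), 0, labels)
        table = table[table["area_px"] >= min_area_px].reset_index(drop=True)
    return table.astype(_INT_COLS), labels.astype(np.int32)


def segment_particles(
    image: np.ndarray,
    params: SegmentParams,
    measure_on: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Run the full segmentation chain on a 2-D image.

    Returns ``(roi_table, label_mask)``.  MFI is measured on ``measure_on``
    when given (same shape), otherwise on ``image`` itself.  An image with no
    foreground yields an empty table, not an error.
    """
    image = np.asarray(image, dtype=np.float64)
    if measure_on is not None:
        measure_on = np.asarray(measure_on, dtype=np.float64)
        if measure_on.shape != image.shape:
            raise ValueError("measure_on shape must match image shape")
    mask = binarize(image, params)
    if params.watershed:
        labels = _watershed_split(mask, params)
    else:
        labels = cc_label(mask, connectivity=params.skimage_connectivity).astype(np.int32)
    intensity = measure_on if measure_on is not None else image
    return measure_labels(labels, intensity, params.min_area_px, params.exclude_border)


def dilate_merge(mask: np.ndarray, iterations: int, radius_px: int = 1) -> np.ndarray:
    """Repeated binary dilation with a disk element, merging nearby segments.

    ``iterations=0`` returns the mask unchanged.  Foreground never shrinks and
    the connected-component count never increases.
    """
    if iterations < 0:
        raise ValueError("iterations must be nonnegative")
    if radius_px < 1:
        raise ValueError("radius_px must be a positive integer")
    out = np.asarray(mask).astype(bool)
    selem = morphology.disk(radius_px)
    for _ in range(iterations):
        out = morphology.dilation(out, selem)
    return out


def mask_exclude(image: np.ndarray, exclusion: np.ndarray) -> np.ndarray:
    """Zero out pixels inside the exclusion mask (nuclear blackout).

    ``exclusion`` may be boolean or a label image (any nonzero pixel is
    excluded).  All other pixels are returned bit-identically.
    """
    image = np.asarray(image)
    exclusion = np.asarray(exclusion)
    if exclusion.shape != image.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs exclusion {exclusion.shape}"
        )
    out = image.copy()
    out[exclusion != 0] = 0
    return out
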
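"""Image and table I/O, shared container types, and run configuration.

All pipeline stages consume a :class:`ChannelStack` — a named multi-channel
(optionally z-stacked) intensity volume with axes normalized to
``(channel, z, y, x)``.  Coordinates everywhere in the package are
pixel-centered, 0-based, with x increasing rightward (columns) and y downward
(rows).  Channels are addressed by configured name, never by acquisition
order, because 3- and 4-channel experiments are mixed freely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field, model_validator


class AxisAmbiguityError(ValueError):
    """Raised when TIFF axes cannot be mapped onto (channel, z, y, x)."""


@dataclass
class ChannelStack:
    """Multi-channel intensity image with named channels.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_z, height, width)``; nonnegative.
        A plain 2-D image is represented with a z-extent of 1.
    channel_names:
        One name per channel, e.g. ``("hoechst", "sytox", "mpo", "cith3")``.
    pixel_size_um:
        Physical pixel size in micrometres (isotropic in-plane).
    time_h:
        Optional acquisition time in hours, used for time-lapse frames.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float = 1.0
    time_h: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim == 2:
            self.data = self.data[None, None]
        elif self.data.ndim == 3:
            # interpret as (channel, y, x) with a single z slice
            self.data = self.data[:, None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (channel, z, y, x) data, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.time_h is not None and self.time_h < 0:
            raise ValueError("time_h must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) volume of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.data[idx]

    def plane(self, name: str, z: int = 0) -> np.ndarray:
        """Return a single (y, x) slice of the named channel."""
        return self.channel(name)[z]


def _normalize_axes(data: np.ndarray, axes: str, n_channels_expected: int) -> np.ndarray:
    """Reorder an arbitrary tifffile axes string onto (C, Z, Y, X)."""
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise AxisAmbiguityError(f"axes string {axes!r} does not match data ndim {data.ndim}")
    known = {"C", "Z", "Y", "X", "T", "I", "Q", "S"}
    if any(a not in known for a in axes):
        raise AxisAmbiguityError(f"unrecognized axes in {axes!r}")
    # fold sample/time/unknown axes into C or Z by size matching
    resolved = []
    for i, a in enumerate(axes):
        if a in "CZYX":
            resolved.append(a)
        elif data.shape[i] == n_channels_expected and "C" not in axes and "C" not in resolved:
            resolved.append("C")
        elif data.shape[i] == 1:
            resolved.append("Z" if "Z" not in axes and "Z" not in resolved else "C")
        else:
            raise AxisAmbiguityError(
                f"cannot resolve axis {a!r} of length {data.shape[i]} in axes {axes!r}"
            )
    for a in resolved:
        if resolved.count(a) > 1:
            raise AxisAmbiguityError(f"duplicate axis {a!r} after resolution of {axes!r}")
    if "Y" not in resolved or "X" not in resolved:
        raise AxisAmbiguityError(f"no spatial axes found in {axes!r}")
    out = data
    for a in "CZ":
        if a not in resolved:
            out = out[None]
            resolved = [a] + resolved
    order = [resolved.index(a) for a in "CZYX"]
    return np.transpose(out, order)


def read_channel_stack(
    path: str | Path,
    channel_map: Mapping[int, str] | Sequence[str],
    pixel_size_um: float = 1.0,
) -> ChannelStack:
    """Read a TIFF/OME-TIFF file into a :class:`ChannelStack`.

    ``channel_map`` gives the channel names either as an ordered sequence or
    as an index→name mapping.  Integer pixel data are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(channel_map, Mapping):
        names = [channel_map[i] for i in sorted(channel_map)]
    else:
        names = list(channel_map)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
    norm = _normalize_axes(data, axes, len(names))
    if norm.shape[0] != len(names):
        raise ValueError(
            f"channel-count mismatch: file has {norm.shape[0]} channels, map names {len(names)}"
        )
    return ChannelStack(norm, tuple(names), pixel_size_um=pixel_size_um)


def write_channel_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with CZYX axes and channel names."""
    tifffile.imwrite(
        Path(path),
        stack.data,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def persist_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as CSV (header row, '.' decimal, full precision).

    Re-reading with :func:`read_table` reproduces numeric values to 1e-9.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    table.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


# --------------------------------------------------------------------------
# run configuration

from metquant.segment import SegmentParams  # noqa: E402  (no import cycle)


class GateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = Field("relative", pattern="^(relative|absolute)$")
    area_max: float = Field(0.7, gt=0)
    mfi_min: float = Field(1.4, gt=0)


class PipelineConfig(BaseModel):
    """Validated run configuration: channel mapping plus every threshold,
    radius and gate the downstream modules use.  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    channels: dict[str, int] = Field(
        default_factory=lambda: {"hoechst": 0, "sytox": 1, "mpo": 2, "cith3": 3}
    )
    pixel_size_um: float = Field(1.0, gt=0)
    seed: int = Field(0, ge=0)
    output_dir: str = "metquant_out"

    nuclei: SegmentParams = SegmentParams(watershed=True, min_area_px=20)
    mets: SegmentParams = SegmentParams(min_area_px=20, exclude_border=True)
    cells: SegmentParams = SegmentParams(watershed=True, min_area_px=50)
    puncta: SegmentParams = SegmentParams(close_radius_px=0, fill_holes=False, min_area_px=3)
    sytox_cells: SegmentParams = SegmentParams(min_area_px=20)

    gate: GateConfig = GateConfig()
    dilate_iterations: int = Field(3, ge=0)
    dilate_radius_px: int = Field(1, ge=1)
    plateau_tol: float = Field(0.02, gt=0)
    plateau_tail_points: int = Field(4, ge=1)

    @model_validator(mode="after")
    def _check_channels(self) -> "PipelineConfig":
        idx = list(self.channels.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)
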
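"""Operetta-style plate I/O.

High-content imagers export one single-plane grayscale TIFF per
well/field/channel, encoding the plate coordinates in the file name.
This module parses that naming dialect, loads channel images normalized
to [0, 1], and groups them into per-field multi-channel sets keyed by
dye name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "FILENAME_PATTERN",
    "ImageKey",
    "ChannelImage",
    "FieldImageSet",
    "UnrecognizedFilenameError",
    "NotGrayscaleError",
    "DuplicateImageError",
    "parse_image_filename",
    "format_image_filename",
    "load_channel_image",
    "group_image_set",
]

#: Default physical pixel size (µm) of the acquisition this pipeline targets:
#: 40x water objective, binning 2, 1080 x 1080 at 16 bit.
DEFAULT_PIXEL_SIZE_UM = 0.299

#: File-name dialect: RRRCCC-F-TTTSSSCCC.tif with 3-digit zero-padded groups
#: except the field index, which may be 1 or 2 digits.
FILENAME_PATTERN = re.compile(
    r"^(?P<Row>[0-9]{3})(?P<Column>[0-9]{3})-(?P<Field>[0-9]{1,2})-"
    r"(?P<Time>[0-9]{3})(?P<Stack>[0-9]{3})(?P<Channel>[0-9]{3}).tif$"
)


class UnrecognizedFilenameError(ValueError):
    """File name does not follow the plate naming dialect."""


class NotGrayscaleError(ValueError):
    """TIFF is not a single-plane grayscale image."""


class DuplicateImageError(ValueError):
    """Two images share the same plate coordinates."""


@dataclass(frozen=True, order=True)
class ImageKey:
    """Plate coordinates of one channel image.

    All indices are 1-based as printed in the file name.
    """

    row: int
    column: int
    field: int
    time: int = 1
    stack: int = 1
    channel: int = 1

    def __post_init__(self) -> None:
        for name in ("row", "column", "field", "time", "stack", "channel"):
            if getattr(self, name) < 1:
                raise ValueError(f"ImageKey.{name} must be >= 1")

    @property
    def well(self) -> tuple[int, int]:
        return (self.row, self.column)


@dataclass
class ChannelImage:
    """One 2-D intensity grid with plate metadata.

    ``pixels`` is float64 scaled to [0, 1] by the full range of the
    source bit depth, so thresholds are camera-independent.
    """

    key: ImageKey
    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage pixels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0,1]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Same metadata, new pixel grid."""
        return ChannelImage(self.key, pixels, self.bit_depth, self.pixel_size_um)


@dataclass
class FieldImageSet:
    """All channels of one imaged field, keyed by dye name."""

    well: tuple[int, int]
    field: int
    channels: dict[str, ChannelImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ within field: {shapes}")

    def missing(self, required_dyes: Sequence[str]) -> list[str]:
        """Dye names required by an assay but absent from this field."""
        return [d for d in required_dyes if d not in self.channels]


def parse_image_filename(name: str) -> ImageKey:
    """Decode plate coordinates from a bare file name.

    Raises :class:`UnrecognizedFilenameError` if the name does not match
    the dialect.
    """
    m = FILENAME_PATTERN.match(name)
    if m is None:
        raise UnrecognizedFilenameError(f"unrecognized filename: {name!r}")
    g = m.groupdict()
    return ImageKey(
        row=int(g["Row"]),
        column=int(g["Column"]),
        field=int(g["Field"]),
        time=int(g["Time"]),
        stack=int(g["Stack"]),
        channel=int(g["Channel"]),
    )


def format_image_filename(key: ImageKey) -> str:
    """Inverse of :func:`parse_image_filename` for valid keys."""
    return (
        f"{key.row:03d}{key.column:03d}-{key.field:d}-"
        f"{key.time:03d}{key.stack:03d}{key.channel:03d}.tif"
    )


def load_channel_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ChannelImage:
    """Load a single-plane grayscale TIFF as a [0, 1]-scaled ChannelImage.

    The key is parsed from the file name; intensities are divided by
    ``2**bit_depth - 1`` where the bit depth comes from the stored dtype.
    """
    path = Path(path)
    key = parse_image_filename(path.name)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise NotGrayscaleError(f"not grayscale (shape {data.shape}): {path.name}")
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise NotGrayscaleError(f"unsupported dtype {data.dtype}: {path.name}")
    pixels = data.astype(np.float64) / (2**bit_depth - 1)
    return ChannelImage(key, pixels, bit_depth=bit_depth, pixel_size_um=pixel_size_um)


def group_image_set(
    images: Sequence[ChannelImage],
    channel_map: Mapping[int, str],
) -> list[FieldImageSet]:
    """Group channel images into one FieldImageSet per (well, field, time, stack).

    ``channel_map`` maps the numeric channel index to a dye name and must
    cover every channel present.  Output is ordered by (row, column, field).
    Every input image lands in exactly one set.
    """
    seen: dict[ImageKey, ChannelImage] = {}
    for im in images:
        if im.key in seen:
            raise DuplicateImageError(f"duplicate image key: {im.key}")
        if im.key.channel not in channel_map:
            raise KeyError(
                f"channel {im.key.channel} not in channel_map {dict(channel_map)}"
            )
        seen[im.key] = im

    groups: dict[tuple[int, int, int, int, int], dict[str, ChannelImage]] = {}
    for key, im in seen.items():
        gk = (key.row, key.column, key.field, key.time, key.stack)
        groups.setdefault(gk, {})[channel_map[key.channel]] = im

    out = []
    for (row, col, fld, _t, _s) in sorted(groups):
        out.append(
            FieldImageSet(well=(row, col), field=fld, channels=groups[(row, col, fld, _t, _s)])
        )
    return out
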
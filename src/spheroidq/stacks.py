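"""Multi-channel image stacks and 2D projection.

Confocal acquisitions arrive as Z-stacks with one fluorescence channel per
labeled cell type.  All quantification in this package operates on a 2D
per-channel projection; the projection never mixes channels, preserving the
distinct pixel values of each cell type's channel.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

PROJECTION_METHODS = ("max", "sum", "mean")


@dataclass
class ChannelStack:
    """A (plane, channel, row, col) fluorescence image stack.

    ``pixel_size`` is the isotropic physical edge length of one pixel in
    micrometres, when known.
    """

    pixels: np.ndarray
    channel_names: list
    pixel_size: float | None = None
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be 4-D (plane, channel, row, col)")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError(
                f"{self.pixels.shape[1]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and (self.pixels < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[2:]


@dataclass
class ProjectedImage:
    """A (channel, row, col) 2D projection of a ChannelStack."""

    pixels: np.ndarray
    channel_names: list
    pixel_size: float | None = None
    projection_method: str = "max"
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be 3-D (channel, row, col)")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError("channel count does not match channel_names")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.pixels[idx]


class AxisLayoutError(ValueError):
    """The axis layout of a TIFF could not be resolved from its metadata."""


def _normalize_axes(data: np.ndarray, axes: str | None) -> np.ndarray:
    """Reorder/reshape array to (plane, channel, row, col).

    ``axes`` follows the tifffile convention (e.g. ``"ZCYX"``).  Without
    metadata, 2-D arrays are a single plane and channel, 3-D arrays with a
    small leading extent (<= 6) are channel-first, and 4-D arrays are assumed
    plane-major (Z, C, Y, X); anything else is ambiguous.
    """
    if axes:
        axes = axes.upper()
        kept, sel = [], []
        have_z = "Z" in axes
        for i, ax in enumerate(axes):
            if ax in "ZCYX":
                kept.append(ax)
                sel.append(slice(None))
            elif ax in "TIQ" and not have_z and data.shape[i] > 1:
                kept.append("Z")  # a sole time/sequence axis acts as planes
                sel.append(slice(None))
                have_z = True
            elif data.shape[i] == 1:
                sel.append(0)  # squeeze singleton non-model axes (e.g. S)
            else:
                raise AxisLayoutError(
                    f"cannot interpret axis {ax!r} of extent {data.shape[i]} "
                    f"in layout {axes!r}"
                )
        arr = data[tuple(sel)]
        layout = "".join(kept)
        if "Y" not in layout or "X" not in layout:
            raise AxisLayoutError(f"layout {axes!r} lacks a row/col axis")
        for missing in ("Z", "C"):
            if missing not in layout:
                arr = arr[np.newaxis]
                layout = missing + layout
        order = [layout.index(ax) for ax in "ZCYX"]
        return np.transpose(arr, order)
    if data.ndim == 2:
        return data[np.newaxis, np.newaxis]
    if data.ndim == 3:
        if data.shape[0] <= 6:
            return data[np.newaxis]
        raise AxisLayoutError(
            f"3-D image with leading extent {data.shape[0]} and no axis metadata: "
            "cannot tell planes from channels (axis 0 is ambiguous)"
        )
    if data.ndim == 4:
        return data
    raise AxisLayoutError(f"unsupported image dimensionality {data.ndim}")


def _ome_pixel_size(ome_xml: str) -> float | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            v = el.get("PhysicalSizeX")
            if v is not None:
                return float(v)
    return None


def read_stack(path, channel_names: list | None = None) -> ChannelStack:
    """Read a TIFF / OME-TIFF into a normalized (Z, C, Y, X) ChannelStack.

    Channel names come from OME metadata when present, else from the
    ``channel_names`` argument, else are autogenerated as ``CH0, CH1, ...``.
    """
    try:
        tif = tifffile.TiffFile(str(path))
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    with tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        pixel_size = None
        meta_names = None
        if tif.ome_metadata:
            pixel_size = _ome_pixel_size(tif.ome_metadata)
            try:
                root = ET.fromstring(tif.ome_metadata)
                meta_names = [
                    el.get("Name")
                    for el in root.iter()
                    if el.tag.endswith("Channel") and el.get("Name")
                ] or None
            except ET.ParseError:
                pass
    pixels = _normalize_axes(data, axes)
    n_ch = pixels.shape[1]
    if meta_names and len(meta_names) == n_ch:
        names = meta_names
    elif channel_names is not None:
        if len(channel_names) != n_ch:
            raise ValueError(f"{n_ch} channels but {len(channel_names)} names given")
        names = list(channel_names)
    else:
        names = [f"CH{i}" for i in range(n_ch)]
    return ChannelStack(pixels, names, pixel_size=pixel_size, source_path=str(path))


def write_stack(stack: ChannelStack, path, ome: bool = True) -> None:
    """Write a ChannelStack as (OME-)TIFF, one sample per channel, ZCYX order."""
    meta: dict = {"axes": "ZCYX"}
    if ome:
        meta["Channel"] = {"Name": list(stack.channel_names)}
        if stack.pixel_size is not None:
            meta["PhysicalSizeX"] = stack.pixel_size
            meta["PhysicalSizeY"] = stack.pixel_size
    tifffile.imwrite(str(path), stack.pixels, ome=ome, metadata=meta)


def write_projection(img: ProjectedImage, path, ome: bool = True) -> None:
    write_stack(as_stack(img), path, ome=ome)


def as_stack(img: ProjectedImage) -> ChannelStack:
    """Lift a projection back to a single-plane stack."""
    return ChannelStack(
        img.pixels[np.newaxis],
        list(img.channel_names),
        pixel_size=img.pixel_size,
        source_path=img.source_path,
    )


def project(stack: ChannelStack, method: str = "max") -> ProjectedImage:
    """Collapse planes to a single 2D image per channel.

    ``max`` (default) takes the per-pixel maximum across planes and keeps the
    input dtype; ``sum`` and ``mean`` are computed in float64.  Channels are
    never mixed.
    """
    if method not in PROJECTION_METHODS:
        raise ValueError(
            f"unknown projection method {method!r}; supported: {PROJECTION_METHODS}"
        )
    if method == "max":
        pixels = stack.pixels.max(axis=0)
    elif method == "sum":
        pixels = stack.pixels.astype(np.float64).sum(axis=0)
    else:
        pixels = stack.pixels.astype(np.float64).mean(axis=0)
    return ProjectedImage(
        pixels=pixels,
        channel_names=list(stack.channel_names),
        pixel_size=stack.pixel_size,
        projection_method=method,
        source_path=stack.source_path,
    )
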
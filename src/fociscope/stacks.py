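"""Reading two-channel Z-stacks and preparing the merged 2-D field.

A :class:`ZStack` holds the raw per-plane intensities for the nuclear and
probe channels.  Recognition runs on a :class:`FieldImage`, obtained by
maximum-intensity projection across planes followed by min--max rescaling
to ``[0, 1]`` so that all downstream thresholds are bit-depth independent.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Any, Mapping

import numpy as np
import tifffile

__all__ = [
    "ZStack",
    "FieldImage",
    "read_stack",
    "write_stack",
    "max_project",
    "suppress_background",
]

CHANNEL_NAMES = ("nuclear", "probe")
DEFAULT_PLANE_SPACING_UM = 0.24


@dataclasses.dataclass(frozen=True)
class ZStack:
    """Raw two-channel 3-D intensities, ``(plane, row, col)`` per channel."""

    nuclear: np.ndarray
    probe: np.ndarray
    plane_spacing_um: float = DEFAULT_PLANE_SPACING_UM
    channel_names: tuple = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.nuclear.ndim != 3 or self.probe.ndim != 3:
            raise ValueError("channel arrays must be 3-D (plane, row, col)")
        if self.nuclear.shape != self.probe.shape:
            raise ValueError(
                f"channel shapes differ: {self.nuclear.shape} vs {self.probe.shape}"
            )
        if self.nuclear.shape[0] < 1:
            raise ValueError("a ZStack needs at least one plane")
        if self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be positive")
        if np.min(self.nuclear) < 0 or np.min(self.probe) < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_planes(self) -> int:
        return self.nuclear.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.nuclear.shape[1:]


@dataclasses.dataclass
class FieldImage:
    """Projected 2-D field, one ``[0, 1]`` float array per channel."""

    nuclear: np.ndarray
    probe: np.ndarray
    provenance: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, chan in (("nuclear", self.nuclear), ("probe", self.probe)):
            if chan.ndim != 2:
                raise ValueError(f"{name} channel must be 2-D")
            if chan.size and (chan.min() < 0 or chan.max() > 1):
                raise ValueError(f"{name} channel values must lie in [0, 1]")
        if self.nuclear.shape != self.probe.shape:
            raise ValueError("channels must share a shape")


def read_stack(
    path: str | os.PathLike,
    plane_spacing_um: float = DEFAULT_PLANE_SPACING_UM,
) -> ZStack:
    """Read a multipage TIFF written in plane-major, channel-interleaved order.

    Page ``2*p`` is the nuclear channel of plane ``p`` and page ``2*p + 1``
    the probe channel, matching :func:`write_stack`.
    """
    pages = tifffile.imread(os.fspath(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"unexpected TIFF layout with shape {pages.shape}")
    if pages.shape[0] % 2 != 0:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages cannot hold 2 channels per plane"
        )
    planes = pages.reshape(pages.shape[0] // 2, 2, *pages.shape[1:])
    return ZStack(
        nuclear=planes[:, 0],
        probe=planes[:, 1],
        plane_spacing_um=plane_spacing_um,
    )


def write_stack(stack: ZStack, path: str | os.PathLike) -> None:
    """Write a stack as multipage TIFF (plane-major, nuclear-then-probe)."""
    pages = np.stack([stack.nuclear, stack.probe], axis=1)
    pages = pages.reshape(-1, *stack.frame_shape)
    tifffile.imwrite(os.fspath(path), pages, photometric="minisblack")


def _rescale01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    lo = arr.min() if arr.size else 0.0
    hi = arr.max() if arr.size else 0.0
    if hi <= lo:
        # all-constant channel: documented to map to all zeros
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def max_project(stack: ZStack) -> FieldImage:
    """Per-channel maximum across planes, rescaled to ``[0, 1]``."""
    return FieldImage(
        nuclear=_rescale01(stack.nuclear.max(axis=0)),
        probe=_rescale01(stack.probe.max(axis=0)),
        provenance={"projection": "max"},
    )


def suppress_background(image: FieldImage, percentile: float = 5.0) -> FieldImage:
    """Subtract the given per-channel intensity percentile and rescale.

    Clamps at zero, so the rank order of the remaining pixels is preserved.
    ``percentile`` must lie in ``[0, 50)``.
    """
    if not 0 <= percentile < 50:
        raise ValueError(f"percentile must be in [0, 50), got {percentile}")

    def _suppress(chan: np.ndarray) -> np.ndarray:
        floor = np.percentile(chan, percentile)
        return _rescale01(np.clip(chan - floor, 0.0, None))

    provenance = dict(image.provenance)
    provenance["background_percentile"] = percentile
    return FieldImage(
        nuclear=_suppress(image.nuclear),
        probe=_suppress(image.probe),
        provenance=provenance,
    )
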
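"""Image-stack I/O, per-well cropping/pairing and physical-scale helpers.

The raw data unit is a time-lapse of grayscale transmission-intensity images
of a microwell array, stored as a multi-page TIFF.  Each cell-spotted
*sensing* well is paired with an empty *reference* well that shares the
global illumination drift and noise statistics; all downstream background
correction relies on that pairing.

Coordinate convention: 0-based ``(row, col)`` with the origin at the
top-left; crop windows are half-open intervals ``[origin, origin + side)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .exceptions import AlignmentError, BoundsError, ConfigurationError, FormatError

__all__ = [
    "AcquisitionMeta",
    "ImageStack",
    "WellStack",
    "WellPair",
    "read_timelapse",
    "write_timelapse",
    "crop_well_region",
    "pair_wells",
    "object_pixel_size",
    "pixel_area",
    "microwell_volume_nl",
    "field_of_view_mm",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Camera and timing parameters of one acquisition.

    Parameters
    ----------
    frame_interval_min:
        Nominal time between consecutive frames, minutes.
    camera_pixel_pitch_um:
        Physical pixel size on the sensor plane, micrometres.
    magnification:
        Objective magnification (dimensionless).
    binning:
        On-camera pixel binning factor (>= 1).
    bit_depth:
        Bits per pixel of the raw data.
    """

    frame_interval_min: float
    camera_pixel_pitch_um: float = 4.25
    magnification: float = 20.0
    binning: int = 1
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.camera_pixel_pitch_um <= 0:
            raise ValueError("camera_pixel_pitch_um must be > 0")
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")


def object_pixel_size(meta: AcquisitionMeta) -> float:
    """Effective pixel size at the sample plane, um/px.

    ``pitch * binning / magnification``.  The pipeline never assumes a fixed
    scale; this is the single place it is derived from hardware numbers.
    """
    return meta.camera_pixel_pitch_um * meta.binning / meta.magnification


def pixel_area(meta: AcquisitionMeta) -> float:
    """Physical area of one image pixel at the sample plane, um^2."""
    return object_pixel_size(meta) ** 2


def microwell_volume_nl(diameter_um: float = 200.0, height_um: float = 50.0) -> float:
    """Volume of one cylindrical microwell in nanolitres (1 nl = 1e6 um^3)."""
    if diameter_um <= 0 or height_um <= 0:
        raise ValueError("diameter and height must be > 0")
    return math.pi * (diameter_um / 2.0) ** 2 * height_um / 1e6


def field_of_view_mm(n_pixels: int, meta: AcquisitionMeta) -> float:
    """Extent of ``n_pixels`` sensor pixels at the sample plane, millimetres."""
    return n_pixels * object_pixel_size(meta) / 1000.0


@dataclass
class ImageStack:
    """Time-ordered grayscale intensity frames with acquisition times.

    ``frames`` has shape ``(T, H, W)``; ``times`` is in minutes and strictly
    increasing.  Intensities are nonnegative.
    """

    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.times.ndim != 1 or len(self.times) != len(self.frames):
            raise AlignmentError("times must be one value per frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise AlignmentError("times must be strictly increasing")
        if np.any(self.frames < 0):
            raise FormatError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class WellStack:
    """An :class:`ImageStack` cropped to one microwell."""

    stack: ImageStack
    well_id: str
    role: str  # "sensing" | "reference"
    crop_origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.role not in ("sensing", "reference"):
            raise ConfigurationError(f"role must be 'sensing' or 'reference', got {self.role!r}")
        h, w = self.stack.frame_shape
        if h != w:
            raise FormatError(f"well crop must be square, got {h}x{w}")


@dataclass
class WellPair:
    """A sensing well and its empty reference partner."""

    sensing: WellStack
    reference: WellStack

    def __post_init__(self) -> None:
        if self.sensing.stack.n_frames != self.reference.stack.n_frames:
            raise AlignmentError(
                f"frame count mismatch: sensing {self.sensing.stack.n_frames} "
                f"vs reference {self.reference.stack.n_frames}"
            )
        if not np.allclose(self.sensing.stack.times, self.reference.stack.times):
            raise AlignmentError("sensing and reference acquisition times differ")


_TIMES_KEY = "times_min"


def read_timelapse(path: str | Path, meta: AcquisitionMeta) -> ImageStack:
    """Load a multi-page grayscale TIFF as an :class:`ImageStack`.

    Frame times default to ``index * frame_interval``; per-frame timestamps
    embedded by :func:`write_timelapse` (a ``times_min`` list in the shaped
    metadata) take precedence, to tolerate stage-scanning jitter.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            shaped = tif.shaped_metadata
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    except ValueError as exc:  # ragged page shapes
        raise FormatError(f"{path}: inconsistent page shapes: {exc}") from exc

    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {frames.shape}"
        )

    times = None
    if shaped:
        for record in shaped:
            if _TIMES_KEY in record:
                times = np.asarray(record[_TIMES_KEY], dtype=float)
                break
    if times is None or len(times) != len(frames):
        times = np.arange(len(frames), dtype=float) * meta.frame_interval_min
    return ImageStack(frames=frames, times=times)


def write_timelapse(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF.

    Pixel values round-trip bit-exactly for integer stacks; per-frame times
    are embedded so :func:`read_timelapse` restores them.
    """
    tifffile.imwrite(
        Path(path),
        stack.frames,
        metadata={_TIMES_KEY: [float(t) for t in stack.times]},
    )


def crop_well_region(
    stack: ImageStack,
    center: tuple[int, int],
    side: int,
    well_id: str = "well",
    role: str = "sensing",
) -> WellStack:
    """Crop a ``side x side`` window centred at ``center`` from every frame.

    The window is ``[r0, r0+side) x [c0, c0+side)`` with
    ``r0 = center_row - side // 2``.  A window that would exceed the frame
    raises :class:`BoundsError` — no silent clipping.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    h, w = stack.frame_shape
    r0 = int(center[0]) - side // 2
    c0 = int(center[1]) - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
        raise BoundsError(
            f"crop window [{r0}:{r0 + side}, {c0}:{c0 + side}] exceeds frame {h}x{w}"
        )
    sub = stack.frames[:, r0 : r0 + side, c0 : c0 + side].copy()
    return WellStack(
        stack=ImageStack(frames=sub, times=stack.times.copy()),
        well_id=well_id,
        role=role,
        crop_origin=(r0, c0),
    )


def pair_wells(
    wells: Sequence[WellStack],
    layout: Mapping[str, str],
) -> list[WellPair]:
    """Pair each sensing well with its reference per the layout map.

    ``layout`` maps ``sensing_id -> reference_id``.  A sensing id whose
    reference does not exist raises :class:`ConfigurationError`; mismatched
    frame counts raise :class:`AlignmentError`.
    """
    by_id: dict[str, WellStack] = {}
    for well in wells:
        if well.well_id in by_id:
            raise ConfigurationError(f"duplicate well id {well.well_id!r}")
        by_id[well.well_id] = well

    pairs = []
    for sensing_id, reference_id in layout.items():
        if sensing_id not in by_id:
            raise ConfigurationError(f"sensing well {sensing_id!r} not found")
        if reference_id not in by_id:
            raise ConfigurationError(f"reference well {reference_id!r} not found")
        pairs.append(WellPair(sensing=by_id[sensing_id], reference=by_id[reference_id]))
    return pairs
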
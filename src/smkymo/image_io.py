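"""Multi-page TIFF input/output and the in-memory image-stack container.

Time-lapse single-molecule movies are stored as grayscale multi-page TIFF
files (one page per frame, 16-bit typical).  Acquisition metadata — the frame
interval and the pixel size — is not parsed from vendor tags, which are
unreliable; it is supplied explicitly, mirroring how microscopists set the
scale by hand in ImageJ.

Coordinate convention used project-wide: 0-based indices, ``x`` is the column,
``y`` is the row, and pixel centers sit at integer coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import EmptyInputError, ParameterError, StackFormatError

__all__ = ["ImageStack", "AcquisitionMeta", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """A T x H x W intensity stack with acquisition metadata.

    Parameters
    ----------
    pixels
        Array of shape ``(T, H, W)`` with finite, non-negative intensities in
        arbitrary camera units.  A 2D array is promoted to a single frame.
    frame_interval_s
        Time between consecutive frames, in seconds (> 0).
    pixel_size_um
        Lateral pixel size, in micrometers (> 0).
    channel_label
        Free-text channel name, e.g. ``"YFP"`` or ``"mCherry"``.
    """

    pixels: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim == 2:
            pixels = pixels[np.newaxis]
        if pixels.ndim != 3:
            raise StackFormatError(
                f"pixels must be a T x H x W array, got shape {pixels.shape}"
            )
        if pixels.shape[0] < 1 or pixels.shape[1] < 1 or pixels.shape[2] < 1:
            raise EmptyInputError("stack has no pixels")
        if not np.all(np.isfinite(pixels)):
            raise StackFormatError("stack contains non-finite intensities")
        if np.any(pixels < 0):
            raise StackFormatError("stack contains negative intensities")
        if not (self.frame_interval_s > 0):
            raise ParameterError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        if not (self.pixel_size_um > 0):
            raise ParameterError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )
        self.pixels = pixels

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def duration_s(self) -> float:
        """Total recording span, counting one interval per frame."""
        return self.n_frames * self.frame_interval_s

    @property
    def meta(self) -> "AcquisitionMeta":
        return AcquisitionMeta(
            n_frames=self.n_frames,
            exposure_ms=self.frame_interval_s * 1000.0,
            scale_um_per_px=self.pixel_size_um,
        )

    def frame(self, t: int) -> np.ndarray:
        return self.pixels[t]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition summary: frame count, exposure (ms) and scale (um/px)."""

    n_frames: int
    exposure_ms: float
    scale_um_per_px: float

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.exposure_ms / 1000.0


def read_stack(
    path: str | os.PathLike,
    frame_interval_s: float,
    pixel_size_um: float,
    channel_label: str = "",
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Pages are returned in file order, which is taken to be time order.
    Integer dtypes are preserved losslessly.

    Raises
    ------
    StackFormatError
        If the pages do not share one shape and dtype, or are not grayscale.
    EmptyInputError
        If the file contains no pages.
    ParameterError
        If ``frame_interval_s`` or ``pixel_size_um`` is not positive.
    """
    with tifffile.TiffFile(os.fspath(path)) as tif:
        if len(tif.pages) == 0:
            raise EmptyInputError(f"{path}: TIFF contains no pages")
        if len(tif.pages) > 1:
            shapes = {p.shape for p in tif.pages}
            dtypes = {p.dtype for p in tif.pages}
            if len(shapes) != 1 or len(dtypes) != 1:
                raise StackFormatError(
                    f"{path}: nonuniform pages "
                    f"(shapes {shapes}, dtypes {dtypes})"
                )
        pixels = tif.asarray()
    if pixels.ndim == 2:
        pixels = pixels[np.newaxis]
    if pixels.ndim != 3:
        raise StackFormatError(
            f"{path}: expected a grayscale stack, got array shape "
            f"{pixels.shape}"
        )
    return ImageStack(
        pixels=pixels,
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        channel_label=channel_label,
    )


def write_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Write a stack as a multi-page grayscale TIFF; returns the path.

    Integer stacks are written with their dtype unchanged and round-trip
    bit-identically through :func:`read_stack`.  Float stacks are written as
    32-bit float.
    """
    pixels = stack.pixels
    if np.issubdtype(pixels.dtype, np.floating):
        pixels = pixels.astype(np.float32)
    tifffile.imwrite(os.fspath(path), pixels, photometric="minisblack")
    return os.fspath(path)
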
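"""Reading and writing microscopy frames, masks, and overlays.

Frames are normalized to floating grayscale in [0, 1] by dividing by the
container bit-depth maximum (255 for 8-bit, 65535 for 16-bit), so that
normalization is frame-independent: 12-bit data in 16-bit containers keeps a
fixed scale across frames.  Multi-channel inputs are reduced to luminance by
an equal-weight channel mean.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

from .errors import DimensionError, EmptyStackError, ValidationError

__all__ = ["ImageStack", "load_stack", "write_mask", "read_mask", "write_overlay"]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class ImageStack:
    """An ordered time-lapse of same-sized grayscale frames in [0, 1].

    ``dt`` (seconds between frames) and ``pixel_size`` (µm/pixel) are
    optional acquisition metadata carried through for reporting; they do not
    affect segmentation.
    """

    frames: list[np.ndarray]
    dt: float | None = None
    pixel_size: float | None = None
    source_bit_depth: int = 8
    _shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyStackError("stack contains no frames")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise DimensionError(f"frame {i} is not 2-D")
            if f.shape != shape:
                raise DimensionError(f"frame {i} shape {f.shape} != {shape}")
        self._shape = shape

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self._shape[0]

    @property
    def width(self) -> int:
        return self._shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        # channel-last (H, W, C) with small C; equal-weight luminance
        if arr.shape[-1] in (3, 4):
            arr = arr[..., :3].mean(axis=-1)
        else:
            raise DimensionError(f"cannot interpret frame of shape {arr.shape}")
    if arr.ndim != 2:
        raise DimensionError(f"cannot interpret frame of shape {arr.shape}")
    return arr


def _normalize(arr: np.ndarray) -> tuple[np.ndarray, int]:
    arr = _to_grayscale(np.asarray(arr))
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    if np.issubdtype(arr.dtype, np.floating):
        # already-floating data is assumed pre-normalized
        return np.clip(arr.astype(np.float64), 0.0, 1.0), 8
    raise ValidationError(f"unsupported pixel dtype {arr.dtype}")


def _natural_key(p: Path):
    parts = re.split(r"(\d+)", p.name)
    return tuple(int(s) if s.isdigit() else s for s in parts), p.name


def load_stack(path, order: str = "numeric") -> ImageStack:
    """Load a time-lapse from a multi-page TIFF or a directory of frames.

    Parameters
    ----------
    path : path-like
        Multi-page TIFF file, single image file, or directory of TIFF/PNG
        frames.
    order : {"numeric", "lexicographic"}
        Directory ordering: natural numeric sort of filename digits
        (default) or plain lexicographic.
    """
    path = Path(path)
    raws: list[np.ndarray] = []
    if path.is_dir():
        files = [p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES]
        if not files:
            raise EmptyStackError(f"no TIFF/PNG frames in {path}")
        files.sort(key=_natural_key if order == "numeric" else lambda p: p.name)
        for p in files:
            raws.append(_read_image(p))
    elif path.is_file():
        if path.suffix.lower() in {".tif", ".tiff"}:
            with tifffile.TiffFile(str(path)) as tf:
                for page in tf.pages:
                    raws.append(page.asarray())
        else:
            raws.append(_read_image(path))
    else:
        raise EmptyStackError(f"unreadable path: {path}")
    if not raws:
        raise EmptyStackError(f"no frames found at {path}")

    frames, depth = [], 8
    for r in raws:
        f, d = _normalize(r)
        frames.append(f)
        depth = max(depth, d)
    return ImageStack(frames=frames, source_bit_depth=depth)


def _read_image(p: Path) -> np.ndarray:
    if p.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(str(p))
    return iio.imread(p)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit image: foreground 255, background 0."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError("mask must contain only {0, 1}")
    out = (mask.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), out)
    else:
        iio.imwrite(path, out)


def read_mask(path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask` (any nonzero = 1)."""
    arr = _to_grayscale(np.asarray(_read_image(Path(path))))
    return (arr > 0).astype(np.uint8)


def write_overlay(frame: np.ndarray, mask: np.ndarray, path, color=(0, 114, 255)) -> None:
    """Render the mask boundary in a contrasting color over the frame.

    The frame is contrast-stretched to its own [min, max] for display; the
    boundary is the set of foreground pixels with at least one 4-connected
    background (or image-border) neighbor.
    """
    frame = np.asarray(frame, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if frame.shape != mask.shape:
        raise DimensionError(f"frame {frame.shape} and mask {mask.shape} differ")
    lo, hi = frame.min(), frame.max()
    disp = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
    rgb = np.repeat((disp * 255).astype(np.uint8)[..., None], 3, axis=-1)
    boundary = _boundary(mask)
    rgb[boundary] = np.asarray(color, dtype=np.uint8)
    iio.imwrite(Path(path), rgb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior
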
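"""Image-stack I/O and the coordinate conventions shared by every module.

Conventions
-----------
* Stacks are arrays indexed ``(frame, row, column)``, 0-based, with pixel
  centers on the integer grid.
* All angle arithmetic is done in image coordinates ``x = column``
  (rightward) and ``y = row`` (downward); angles are four-quadrant
  ``atan2(y, x)`` values in ``(-pi, pi]``.  Only the *difference* between
  the to-center angle and the flow angle is physically meaningful, and that
  difference is independent of the handedness of the convention.
* Displacements are expressed in pixels per frame.  ``frame_interval``
  (seconds) and ``pixel_size`` (physical units per pixel) are carried as
  metadata for presentation only and never enter the computations.

Stacks are stored as multi-page grayscale TIFF, one page per frame,
via :mod:`tifffile`.  Pipeline parameters travel in YAML (or JSON, which
is a YAML subset) config files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .errors import FormatError, ValidationError

__all__ = ["ImageStack", "read_stack", "write_stack", "load_config", "save_config"]


@dataclass
class ImageStack:
    """A single-channel fluorescence time-lapse stack.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_rows, n_cols)`` with finite,
        non-negative intensities.  Intensities are treated as arbitrary
        non-negative reals; no assumption is made about bit depth or
        camera calibration.
    frame_interval
        Seconds per frame (metadata only; default 1.0).
    pixel_size
        Physical units per pixel (metadata only).
    """

    frames: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be 3-D (frame, row, col); got ndim={self.frames.ndim}"
            )
        if self.frames.size == 0:
            raise ValidationError("frames array is empty")
        if np.issubdtype(self.frames.dtype, np.floating):
            if not np.all(np.isfinite(self.frames)):
                raise ValidationError("frames contain non-finite values")
        if self.frames.min() < 0:
            raise ValidationError("frames contain negative intensities")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def require_temporal(self) -> None:
        """Raise unless the stack supports temporal operations (N >= 2)."""
        if self.n_frames < 2:
            raise ValidationError(
                f"temporal operations need at least 2 frames; stack has {self.n_frames}"
            )


def _read_pages(path: Path) -> list[np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        pages = [np.asarray(page.asarray()) for page in tif.pages]
    for idx, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(
                f"{path}: page {idx} has shape {page.shape}; expected a "
                "single-channel 2-D page"
            )
        if page.shape != pages[0].shape:
            raise FormatError(
                f"{path}: page {idx} has shape {page.shape}, inconsistent "
                f"with page 0 shape {pages[0].shape}"
            )
    return pages


def read_stack(
    path: str | Path,
    dtype_policy: str = "float",
    frame_interval: float = 1.0,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF (or a directory of ordered TIFFs) as a stack.

    Frame order follows page order for a multi-page file and sorted file
    name order for a directory.  Metadata (``frame_interval``,
    ``pixel_size``) comes from the caller / config, never from TIFF tags.

    Parameters
    ----------
    dtype_policy
        ``"float"`` converts integer payloads to float64; ``"preserve"``
        keeps the stored dtype.
    """
    if dtype_policy not in ("float", "preserve"):
        raise ValidationError(f"unknown dtype_policy {dtype_policy!r}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"{p}: directory contains no TIFF files")
        pages: list[np.ndarray] = []
        first_shape: tuple[int, ...] | None = None
        for f in files:
            for page in _read_pages(f):
                if first_shape is None:
                    first_shape = page.shape
                elif page.shape != first_shape:
                    raise FormatError(
                        f"{f}: frame shape {page.shape} inconsistent with "
                        f"first frame shape {first_shape}"
                    )
                pages.append(page)
    else:
        pages = _read_pages(p)
    if len(pages) < 2:
        raise ValidationError(
            f"{p}: a time-lapse stack needs at least 2 frames; found {len(pages)}"
        )
    frames = np.stack(pages, axis=0)
    if dtype_policy == "float" and not np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float64)
    return ImageStack(frames, frame_interval=frame_interval, pixel_size=pixel_size)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per frame.

    Floating-point payloads are stored as 32-bit float (lossless for
    float32 data); integer payloads keep their dtype.
    """
    # revalidate: the frames array may have been mutated since construction
    ImageStack(stack.frames, stack.frame_interval, stack.pixel_size)
    data = stack.frames
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON parameter file as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    return cfg


def save_config(config: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
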
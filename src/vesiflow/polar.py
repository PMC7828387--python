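"""Polar re-representation of images and direction maps about the center.

A Cartesian image is resampled on an (R, theta) grid via

    (x, y) = (C_x + R cos theta, C_y + R sin theta)

with x = column, y = row (image-down), so theta is measured from the +x
axis increasing toward +y.  Rows of the polar image share a distance from
the cell center and columns share a direction, which makes radial
structure — e.g. the inward drift of endocytosed vesicles — directly
readable as vertical motion over time.

The radial axis spans [0, r_max] in ``n_r`` uniformly spaced samples
(the first row is exactly R = 0, i.e. the center value repeated over all
angles); the angular axis spans [0, 2pi) in ``n_theta`` uniform bins.
Continuous quantities may be sampled with bilinear or nearest-neighbour
interpolation; categorical label planes are always nearest-neighbour —
interpolating between category codes is meaningless.  Samples falling
outside the image are marked with a fill value and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .direction import DirectionMap, Label
from .errors import ValidationError

__all__ = ["PolarImage", "PolarDirectionMaps", "to_polar", "to_polar_labels"]

_ORDER = {"nearest": 0, "bilinear": 1}


@dataclass
class PolarImage:
    """An image resampled on an (R, theta) grid.

    ``values`` is indexed (radius sample, angle bin); ``n_missing`` counts
    samples that fell outside the source image and carry the fill value.
    """

    values: np.ndarray
    r_max: float
    n_r: int
    n_theta: int
    center: tuple[float, float]
    interpolation: str
    n_missing: int
    fill_value: float = float("nan")

    @property
    def r_axis(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_r)

    @property
    def theta_axis(self) -> np.ndarray:
        return np.arange(self.n_theta) * (2 * np.pi / self.n_theta)

    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """TIFF payload plus a JSON sidecar recording the grid geometry."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.asarray(self.values).astype(np.float32))
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "r_max": self.r_max,
                    "n_r": self.n_r,
                    "n_theta": self.n_theta,
                    "center_row": self.center[0],
                    "center_col": self.center[1],
                    "interpolation": self.interpolation,
                    "n_missing": self.n_missing,
                },
                indent=2,
            )
        )


@dataclass
class PolarDirectionMaps:
    """Polar views of a direction map: label, delta and magnitude planes."""

    label: PolarImage
    delta: PolarImage
    magnitude: PolarImage


def _polar_coordinates(
    center: tuple[float, float], n_r: int, n_theta: int, r_max: float
) -> tuple[np.ndarray, np.ndarray]:
    radii = np.linspace(0.0, r_max, n_r)
    thetas = np.arange(n_theta) * (2 * np.pi / n_theta)
    rr, tt = np.meshgrid(radii, thetas, indexing="ij")
    rows = center[0] + rr * np.sin(tt)
    cols = center[1] + rr * np.cos(tt)
    return rows, cols


def _default_r_max(shape: tuple[int, int], center: tuple[float, float]) -> float:
    m, n = shape
    return float(min(center[0], m - 1 - center[0], center[1], n - 1 - center[1]))


def to_polar(
    image: np.ndarray,
    center: tuple[float, float],
    n_r: int | None = None,
    n_theta: int = 360,
    r_max: float | None = None,
    interpolation: str = "bilinear",
    fill_value: float = float("nan"),
) -> PolarImage:
    """Resample a 2-D image onto an (R, theta) grid about ``center``.

    Defaults: ``r_max`` is the distance from the center to the nearest
    image edge, ``n_r`` one sample per pixel of radius (ceil(r_max) + 1,
    so both R = 0 and R = r_max are sampled), ``n_theta`` 360.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("to_polar expects a 2-D image")
    if interpolation not in _ORDER:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    m, n = image.shape
    if not (0 <= center[0] <= m - 1 and 0 <= center[1] <= n - 1):
        raise ValidationError(f"center {center} outside image of shape {image.shape}")
    if r_max is None:
        r_max = _default_r_max(image.shape, center)
    if r_max <= 0:
        raise ValidationError("r_max must be positive (is the center on the image edge?)")
    if n_r is None:
        n_r = int(np.ceil(r_max)) + 1
    if n_r < 2 or n_theta < 4:
        raise ValidationError("need n_r >= 2 and n_theta >= 4")

    rows, cols = _polar_coordinates(center, n_r, n_theta, r_max)
    inside = (rows >= 0) & (rows <= m - 1) & (cols >= 0) & (cols <= n - 1)
    values = ndimage.map_coordinates(
        image, [rows, cols], order=_ORDER[interpolation], mode="nearest"
    )
    values = np.where(inside, values, fill_value)
    return PolarImage(
        values=values,
        r_max=float(r_max),
        n_r=n_r,
        n_theta=n_theta,
        center=(float(center[0]), float(center[1])),
        interpolation=interpolation,
        n_missing=int(np.sum(~inside)),
        fill_value=fill_value,
    )


def to_polar_labels(
    dmap: DirectionMap,
    center: tuple[float, float] | None = None,
    n_r: int | None = None,
    n_theta: int = 360,
    r_max: float | None = None,
    interpolation: str = "bilinear",
) -> PolarDirectionMaps:
    """Polar views of a direction map.

    The categorical label plane is resampled nearest-neighbour
    (interpolation applies only to the continuous delta and magnitude
    planes); out-of-image label samples become Excluded, and Excluded
    pixels stay Excluded.  ``center`` defaults to the map's own center.
    """
    if center is None:
        center = dmap.center
    label = to_polar(
        dmap.label.astype(float),
        center,
        n_r=n_r,
        n_theta=n_theta,
        r_max=r_max,
        interpolation="nearest",
        fill_value=float(Label.EXCLUDED),
    )
    label.values = label.values.astype(np.uint8)
    delta = to_polar(
        dmap.delta, center, n_r=n_r, n_theta=n_theta, r_max=r_max,
        interpolation=interpolation,
    )
    magnitude = to_polar(
        dmap.magnitude, center, n_r=n_r, n_theta=n_theta, r_max=r_max,
        interpolation=interpolation,
    )
    return PolarDirectionMaps(label=label, delta=delta, magnitude=magnitude)
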
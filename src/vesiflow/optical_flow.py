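"""Dense per-pixel Lucas-Kanade optical flow between consecutive frames.

Under brightness constancy a pattern moving by (vx, vy) between two frames
satisfies, to first order, ``Ix*vx + Iy*vy + It = 0`` at every pixel.  The
single constraint is under-determined (the aperture problem), so Lucas-
Kanade assumes the flow is constant over a small neighbourhood Omega around
each pixel and minimises the weighted least-squares cost

    sum_{Omega} W^2 * (Ix*vx + Iy*vy + It)^2

whose normal equations are the 2x2 structure-tensor solve

    [sum W^2 Ix^2   sum W^2 IxIy] [vx]   [-sum W^2 IxIt]
    [sum W^2 IyIx   sum W^2 Iy^2] [vy] = [-sum W^2 IyIt]

W is a window function weighting the neighbourhood center.  Where the
structure tensor is (near-)singular — flat or purely 1-D texture — the
solve is unreliable and the pixel is flagged invalid rather than solved.

No pyramidal or iterative refinement is performed: the plain single-level
scheme is valid for displacements up to roughly the spot width
(~2 px/frame for diffraction-limited vesicle spots).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import ValidationError
from .image_io import ImageStack

__all__ = [
    "FlowParams",
    "FlowField",
    "spatial_temporal_gradients",
    "solve_lk_pixel",
    "compute_flow",
    "compute_flow_series",
    "flow_to_dataframe",
    "write_flow_field",
    "read_flow_field",
]


@dataclass(frozen=True)
class FlowParams:
    """Lucas-Kanade parameters.

    window_radius
        Omega is the (2r+1) x (2r+1) square; default 7 (15x15 window).
    weight_kernel
        "gaussian" (sigma = ``weight_sigma`` or window_radius/2) or
        "uniform".  The kernel is normalised so sum(W^2) = 1; the
        structure tensor is then a weighted *mean* of gradient products,
        which makes ``eigenvalue_min`` independent of window size.
    eigenvalue_min
        Pixels whose smaller structure-tensor eigenvalue falls below this
        are flagged invalid (default 1e-4, in squared-gradient units of
        the input intensity scale).
    smoothing_sigma
        Gaussian pre-smoothing applied identically to both frames before
        differentiation (default 1.0 px; 0 disables).
    """

    window_radius: int = 7
    weight_kernel: str = "gaussian"
    weight_sigma: float | None = None
    eigenvalue_min: float = 1e-4
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValidationError("window_radius must be >= 1")
        if self.eigenvalue_min < 0:
            raise ValidationError("eigenvalue_min must be >= 0")
        if self.weight_kernel not in ("uniform", "gaussian"):
            raise ValidationError(f"unknown weight_kernel {self.weight_kernel!r}")
        if self.smoothing_sigma < 0:
            raise ValidationError("smoothing_sigma must be >= 0")

    def window(self) -> np.ndarray:
        """The weight array W over Omega, normalised so sum(W^2) = 1."""
        r = self.window_radius
        if self.weight_kernel == "uniform":
            w = np.ones((2 * r + 1, 2 * r + 1))
        else:
            sigma = self.weight_sigma if self.weight_sigma is not None else r / 2.0
            ax = np.arange(-r, r + 1)
            g = np.exp(-(ax**2) / (2 * sigma**2))
            w = np.outer(g, g)
        return w / np.sqrt(np.sum(w**2))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FlowField:
    """Per-pixel displacement field for one frame pair (pixels/frame).

    ``vx`` is the column-direction (x) component, ``vy`` the row-direction
    (y, image-down) component.  Where ``valid`` is False both components
    are exactly 0 and must be ignored.
    """

    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    params: FlowParams

    def __post_init__(self) -> None:
        if not (self.vx.shape == self.vy.shape == self.valid.shape):
            raise ValidationError("vx, vy, valid must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


def spatial_temporal_gradients(
    prev: np.ndarray, nxt: np.ndarray, smoothing_sigma: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial and temporal derivatives for one frame pair.

    Both frames are optionally Gaussian-smoothed (identically), then
    Ix, Iy are central differences of the two-frame mean — symmetric in
    the pair — with reflect boundary handling, and It = next - prev.
    """
    prev = np.asarray(prev, dtype=float)
    nxt = np.asarray(nxt, dtype=float)
    if prev.shape != nxt.shape or prev.ndim != 2:
        raise ValidationError(
            f"frames must be two same-shape 2-D arrays; got {prev.shape} and {nxt.shape}"
        )
    if smoothing_sigma > 0:
        prev = ndimage.gaussian_filter(prev, smoothing_sigma, mode="reflect")
        nxt = ndimage.gaussian_filter(nxt, smoothing_sigma, mode="reflect")
    mean = 0.5 * (prev + nxt)
    stencil = np.array([-0.5, 0.0, 0.5])
    ix = ndimage.correlate1d(mean, stencil, axis=1, mode="reflect")
    iy = ndimage.correlate1d(mean, stencil, axis=0, mode="reflect")
    it = nxt - prev
    return ix, iy, it


def _solve_tensor(a, b, c, bx, by, eigenvalue_min):
    """Solve [a b; b c] v = [-bx, -by]; returns (vx, vy, valid).

    Works elementwise on arrays.  ``valid`` is False where the smaller
    eigenvalue of the symmetric 2x2 tensor is below ``eigenvalue_min``.
    """
    half_trace = 0.5 * (a + c)
    radius = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    lam_min = half_trace - radius
    valid = lam_min >= eigenvalue_min
    det = a * c - b * b
    safe_det = np.where(valid, det, 1.0)
    vx = np.where(valid, (-c * bx + b * by) / safe_det, 0.0)
    vy = np.where(valid, (b * bx - a * by) / safe_det, 0.0)
    return vx, vy, valid


def solve_lk_pixel(
    ix: np.ndarray,
    iy: np.ndarray,
    it: np.ndarray,
    pixel: tuple[int, int],
    params: FlowParams,
) -> tuple[float, float, bool]:
    """Exact weighted normal-equations solve at one pixel.

    The window Omega is centered on ``pixel`` and truncated where it
    exceeds the image, with the corresponding slice of W.  Degeneracy is
    signalled through the returned ``valid`` flag, never raised.
    """
    r = params.window_radius
    row, col = pixel
    m, n = ix.shape
    w = params.window()
    r0, r1 = max(row - r, 0), min(row + r + 1, m)
    c0, c1 = max(col - r, 0), min(col + r + 1, n)
    wk = w[r0 - (row - r): r1 - (row - r), c0 - (col - r): c1 - (col - r)]
    w2 = wk**2
    gx = ix[r0:r1, c0:c1]
    gy = iy[r0:r1, c0:c1]
    gt = it[r0:r1, c0:c1]
    a = float(np.sum(w2 * gx * gx))
    b = float(np.sum(w2 * gx * gy))
    c = float(np.sum(w2 * gy * gy))
    bx = float(np.sum(w2 * gx * gt))
    by = float(np.sum(w2 * gy * gt))
    vx, vy, valid = _solve_tensor(a, b, c, bx, by, params.eigenvalue_min)
    return float(vx), float(vy), bool(valid)


def compute_flow(
    prev: np.ndarray, nxt: np.ndarray, params: FlowParams | None = None
) -> FlowField:
    """Dense Lucas-Kanade flow for one frame pair.

    Equivalent to :func:`solve_lk_pixel` applied at every pixel, computed
    with windowed correlations: summing zero-padded gradient products over
    the full kernel is identical to the truncated-window sums at the
    image border.
    """
    if params is None:
        params = FlowParams()
    ix, iy, it = spatial_temporal_gradients(prev, nxt, params.smoothing_sigma)
    w2 = params.window() ** 2

    def wsum(arr: np.ndarray) -> np.ndarray:
        return ndimage.correlate(arr, w2, mode="constant", cval=0.0)

    a = wsum(ix * ix)
    b = wsum(ix * iy)
    c = wsum(iy * iy)
    bx = wsum(ix * it)
    by = wsum(iy * it)
    vx, vy, valid = _solve_tensor(a, b, c, bx, by, params.eigenvalue_min)
    return FlowField(vx=vx, vy=vy, valid=valid, params=params)


def compute_flow_series(stack: ImageStack, params: FlowParams | None = None) -> list[FlowField]:
    """Flow fields for every adjacent frame pair: N frames -> N-1 fields."""
    stack.require_temporal()
    frames = stack.frames
    return [compute_flow(frames[k], frames[k + 1], params) for k in range(len(frames) - 1)]


def flow_to_dataframe(field: FlowField, frame_index: int = 0) -> pd.DataFrame:
    """Long-form per-pixel table (frame, row, col, vx, vy, valid)."""
    m, n = field.shape
    rows, cols = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    return pd.DataFrame(
        {
            "frame": frame_index,
            "row": rows.ravel(),
            "col": cols.ravel(),
            "vx": field.vx.ravel(),
            "vy": field.vy.ravel(),
            "valid": field.valid.ravel(),
        }
    )


def write_flow_field(field: FlowField, flow_path: str | Path, mask_path: str | Path) -> None:
    """Write vx/vy as a two-plane float32 TIFF plus a uint8 validity TIFF."""
    Path(flow_path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(flow_path, np.stack([field.vx, field.vy]).astype(np.float32))
    tifffile.imwrite(mask_path, field.valid.astype(np.uint8))


def read_flow_field(
    flow_path: str | Path, mask_path: str | Path, params: FlowParams | None = None
) -> FlowField:
    planes = tifffile.imread(flow_path)
    if planes.ndim != 3 or planes.shape[0] != 2:
        raise ValidationError(f"{flow_path}: expected a 2-plane (vx, vy) TIFF")
    valid = tifffile.imread(mask_path).astype(bool)
    return FlowField(
        vx=planes[0].astype(float),
        vy=planes[1].astype(float),
        valid=valid,
        params=params or FlowParams(),
    )
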
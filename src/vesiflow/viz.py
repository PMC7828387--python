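"""Rendering of flow and direction maps.

Two encodings are provided.  The conventional HSV encoding colors every
valid flow vector by its absolute orientation (hue) and magnitude
(saturation); it answers "which way in the image" but not "which way in
the cell".  The diverging encoding instead colors each classified pixel
by the wrapped angle difference delta = |alpha - beta| between the
to-center direction and the flow direction, on a red-white-blue ramp:
delta = 0 (straight at the center, endocytic) maps to the red extreme,
delta = pi (straight away) to the blue extreme, and delta = pi/2
(tangential) to the neutral midpoint.  The colormap position is exactly
delta / pi, so the encoding is monotone and invertible on [0, pi].

Figures are built on matplotlib Figure objects directly (no pyplot
state), so rendering works headless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from matplotlib.figure import Figure

from .direction import DirectionMap, FrameSummary, Label
from .errors import ValidationError
from .optical_flow import FlowField

__all__ = [
    "RenderConfig",
    "delta_to_position",
    "render_hsv",
    "decode_hsv",
    "render_diverging",
    "render_summary_panels",
    "save_rgb",
]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering options.

    colormap
        Name of a matplotlib colormap whose 0-end is red and 1-end is
        blue with a neutral midpoint (default "RdBu"); any diverging
        palette may be substituted.
    magnitude_for_saturation
        When True, the diverging render fades colors toward the neutral
        midpoint for weak flows (tone ~ magnitude / magnitude_ceiling).
    magnitude_ceiling
        Flow magnitude (px/frame) that saturates the HSV saturation
        channel and the optional tone modulation.
    background_color
        RGB triple in [0, 1] used for invalid / excluded pixels.
    overlay_alpha
        Blend weight of the rendered colors over a grayscale base image
        when one is supplied.
    """

    colormap: str = "RdBu"
    magnitude_for_saturation: bool = False
    magnitude_ceiling: float = 2.0
    background_color: tuple[float, float, float] = (0.0, 0.0, 0.0)
    overlay_alpha: float = 0.7

    def __post_init__(self) -> None:
        if self.magnitude_ceiling <= 0:
            raise ValidationError("magnitude_ceiling must be positive")
        if not 0 <= self.overlay_alpha <= 1:
            raise ValidationError("overlay_alpha must lie in [0, 1]")

    def cmap(self):
        return matplotlib.colormaps[self.colormap]


def delta_to_position(delta):
    """Colormap position of a wrapped angle difference: delta / pi."""
    return np.asarray(delta, dtype=float) / np.pi


def render_hsv(flow: FlowField, config: RenderConfig | None = None) -> np.ndarray:
    """HSV orientation/magnitude rendering of a flow field.

    Hue spans the full circle linearly in the flow angle, saturation is
    the magnitude clipped at ``magnitude_ceiling``, value is 1 on valid
    pixels; invalid pixels get the background color.  Returns float RGB
    in [0, 1] of shape (m, n, 3).
    """
    config = config or RenderConfig()
    angle = np.arctan2(flow.vy, flow.vx)
    hue = np.mod(angle, 2 * np.pi) / (2 * np.pi)
    sat = np.clip(flow.magnitude / config.magnitude_ceiling, 0.0, 1.0)
    val = np.ones_like(hue)
    rgb = hsv_to_rgb(np.dstack([hue, sat, val]))
    rgb[~flow.valid] = config.background_color
    return rgb


def decode_hsv(
    rgb: np.ndarray, config: RenderConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`render_hsv` on valid pixels.

    Returns (angle in (-pi, pi], magnitude clipped at the ceiling); used
    to verify the encoding is lossless up to the clipping.
    """
    config = config or RenderConfig()
    hsv = rgb_to_hsv(rgb)
    angle = hsv[..., 0] * 2 * np.pi
    angle = np.where(angle > np.pi, angle - 2 * np.pi, angle)
    magnitude = hsv[..., 1] * config.magnitude_ceiling
    return angle, magnitude


def render_diverging(
    dmap: DirectionMap,
    config: RenderConfig | None = None,
    base_image: np.ndarray | None = None,
) -> np.ndarray:
    """Diverging-colormap rendering of a direction map.

    Each included pixel is colored at colormap position delta / pi;
    Excluded pixels get the background color, or the grayscale base
    image when one is provided (the direction colors are then alpha-
    blended over it).
    """
    config = config or RenderConfig()
    pos = delta_to_position(np.nan_to_num(dmap.delta, nan=0.5))
    rgba = config.cmap()(np.clip(pos, 0.0, 1.0))
    rgb = rgba[..., :3]
    if config.magnitude_for_saturation:
        tone = np.clip(dmap.magnitude / config.magnitude_ceiling, 0.0, 1.0)
        neutral = np.asarray(config.cmap()(0.5)[:3])
        rgb = neutral + tone[..., None] * (rgb - neutral)
    included = dmap.included
    if base_image is not None:
        base = np.asarray(base_image, dtype=float)
        if base.shape != dmap.shape:
            raise ValidationError("base_image shape does not match the direction map")
        span = np.ptp(base)
        gray = (base - base.min()) / span if span else np.zeros_like(base)
        out = np.dstack([gray] * 3)
        a = config.overlay_alpha
        out[included] = (1 - a) * out[included] + a * rgb[included]
        return out
    out = np.empty(rgb.shape)
    out[...] = config.background_color
    out[included] = rgb[included]
    return out


def render_summary_panels(
    summaries: Sequence[FrameSummary], path: str | Path, title: str | None = None
) -> None:
    """Two stacked time-series panels: counts+magnitude, then proportions.

    Frames with no classified vectors have NaN proportions and appear as
    gaps, not zeros.
    """
    if len(summaries) == 0:
        raise ValidationError("render_summary_panels needs a non-empty series")
    frames = [s.frame_index for s in summaries]
    fig = Figure(figsize=(7, 6))
    FigureCanvasAgg(fig)
    ax_top, ax_bot = fig.subplots(2, 1, sharex=True)
    ax_top.plot(frames, [s.n_vectors for s in summaries], "o-", label="vectors classified")
    ax_top.plot(frames, [s.n_valid for s in summaries], "s--", label="flow solvable")
    ax_top.set_ylabel("count")
    ax_mag = ax_top.twinx()
    ax_mag.plot(
        frames,
        [s.total_magnitude for s in summaries],
        "^-",
        color="tab:green",
        label="total magnitude",
    )
    ax_mag.set_ylabel("total magnitude (px/frame)")
    lines = ax_top.get_lines() + ax_mag.get_lines()
    ax_top.legend(lines, [ln.get_label() for ln in lines], fontsize=8)
    ax_bot.plot(frames, [s.prop_inward for s in summaries], "o-", color="tab:red",
                label="inward")
    ax_bot.plot(frames, [s.prop_outward for s in summaries], "o-", color="tab:blue",
                label="outward")
    ax_bot.set_ylim(-0.05, 1.05)
    ax_bot.set_xlabel("frame pair")
    ax_bot.set_ylabel("proportion")
    ax_bot.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)


def save_rgb(rgb: np.ndarray, path: str | Path) -> None:
    """Write a float RGB array in [0, 1] as a PNG."""
    from matplotlib.image import imsave

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    imsave(path, np.clip(rgb, 0, 1))
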
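"""Pre-processing for stained bone-marrow photomicrographs.

Three operations feed the downstream color model and level set:

* percentile contrast stretching of the raw RGB image,
* expansion of the stretched RGB image into a 9-plane color stack
  (R, G, B, H, S, V, L, a, b), every plane rescaled to ``[0, 255]``,
* removal of unstained cells by replacing pixels whose hue falls below a
  threshold with the background color, so that unstained cells do not form
  an extra region for the four-phase level set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color

#: Fixed channel order of the 9-plane stack.
CHANNEL_NAMES: tuple[str, ...] = ("R", "G", "B", "H", "S", "V", "L", "a", "b")

#: Default hue cut (8-bit scale) below which a pixel is treated as unstained.
DEFAULT_HUE_THRESHOLD = 120.0


@dataclass(frozen=True)
class ChannelStack:
    """Per-pixel 9-channel color representation of one image.

    ``planes`` has shape ``(H, W, 9)`` in the fixed order
    ``(R, G, B, H, S, V, L, a, b)``; every plane lives on ``[0, 255]``
    (hue maps the full circle onto that range, L maps ``[0, 100]`` and
    a/b map ``[-128, 127]``).
    """

    planes: np.ndarray

    def __post_init__(self) -> None:
        if self.planes.ndim != 3 or self.planes.shape[2] != len(CHANNEL_NAMES):
            raise ValueError(
                f"expected (H, W, {len(CHANNEL_NAMES)}) planes, got {self.planes.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[:2]

    def plane(self, name: str) -> np.ndarray:
        """Return one named plane as an (H, W) float array."""
        try:
            idx = CHANNEL_NAMES.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; valid: {CHANNEL_NAMES}") from None
        return self.planes[..., idx]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    return img


def contrast_stretch(img: np.ndarray, sat_frac: float = 0.01) -> np.ndarray:
    """Linearly stretch each RGB channel, saturating histogram tails.

    The ``sat_frac`` quantile of each channel maps to 0 and the
    ``1 - sat_frac`` quantile to 255; values between are rescaled linearly
    and values outside are clipped.  A constant channel (upper quantile equal
    to the lower) is returned unchanged.

    Parameters
    ----------
    img:
        8-bit RGB image, shape ``(H, W, 3)``.
    sat_frac:
        Fraction of low and high intensities saturated (default 1%).

    Returns
    -------
    numpy.ndarray
        8-bit RGB image of the same shape.
    """
    img = _check_rgb(img)
    if not 0.0 <= sat_frac < 0.5:
        raise ValueError("sat_frac must lie in [0, 0.5)")
    out = np.empty_like(img, dtype=np.uint8)
    for c in range(3):
        chan = img[..., c].astype(np.float64)
        lo, hi = np.quantile(chan, [sat_frac, 1.0 - sat_frac])
        if hi <= lo:
            out[..., c] = img[..., c]
            continue
        stretched = (chan - lo) * (255.0 / (hi - lo))
        out[..., c] = np.clip(np.round(stretched), 0, 255).astype(np.uint8)
    return out


def to_channel_stack(img: np.ndarray) -> ChannelStack:
    """Expand an 8-bit RGB image into the 9-plane (R,G,B,H,S,V,L,a,b) stack.

    R, G, B pass through unchanged; H, S, V come from the standard RGB->HSV
    conversion with the full hue circle rescaled to ``[0, 255]``; L, a, b
    come from CIE Lab with ``L: [0,100] -> [0,255]`` and
    ``a, b: [-128,127] -> [0,255]``.
    """
    img = _check_rgb(img)
    rgbf = img.astype(np.float64) / 255.0
    hsv = color.rgb2hsv(rgbf)
    lab = color.rgb2lab(rgbf)
    planes = np.empty(img.shape[:2] + (9,), dtype=np.float64)
    planes[..., 0:3] = img.astype(np.float64)
    planes[..., 3] = hsv[..., 0] * 255.0
    planes[..., 4] = hsv[..., 1] * 255.0
    planes[..., 5] = hsv[..., 2] * 255.0
    planes[..., 6] = lab[..., 0] * (255.0 / 100.0)
    # the a/b range [-128, 127] spans exactly 255 units: a linear shift
    planes[..., 7] = lab[..., 1] + 128.0
    planes[..., 8] = lab[..., 2] + 128.0
    np.clip(planes, 0.0, 255.0, out=planes)
    return ChannelStack(planes)


def estimate_border_background(img: np.ndarray, border_px: int = 10) -> np.ndarray:
    """Median RGB color of a ``border_px``-wide frame around the image.

    Used as a fallback background estimate when no fitted color model is
    available (the image border of an aspirate photomicrograph is almost
    always background).
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    b = min(border_px, h // 2, w // 2)
    if b == 0:
        raise ValueError("image too small to estimate a border background")
    frame = np.ones((h, w), dtype=bool)
    frame[b:h - b, b:w - b] = False
    return np.median(img[frame].reshape(-1, 3), axis=0)


def remove_unstained(
    stack: ChannelStack,
    img: np.ndarray,
    hue_threshold: float = DEFAULT_HUE_THRESHOLD,
    bg_color: np.ndarray | None = None,
) -> np.ndarray:
    """Replace unstained-cell pixels (low hue) with the background color.

    Every pixel whose H plane value is strictly below ``hue_threshold``
    (8-bit hue scale) is replaced in RGB by ``bg_color``; all other pixels
    are returned unchanged.  Hue circularity is deliberately ignored: the
    rule is a plain ``<`` comparison on the rescaled plane.

    Parameters
    ----------
    stack:
        9-channel stack of ``img`` (supplies the H plane).
    img:
        The 8-bit RGB image being cleaned.
    hue_threshold:
        Cut on the ``[0, 255]`` hue plane (default 120).
    bg_color:
        RGB background replacement color, typically the per-channel mean of
        the fitted background region.  If ``None`` the median of a 10-pixel
        image border is used.
    """
    img = _check_rgb(img)
    if stack.shape != img.shape[:2]:
        raise ValueError("stack and image shapes disagree")
    if bg_color is None:
        bg_color = estimate_border_background(img)
    bg = np.clip(np.round(np.asarray(bg_color, dtype=np.float64)), 0, 255).astype(np.uint8)
    if bg.shape != (3,):
        raise ValueError("bg_color must be a length-3 RGB triple")
    out = img.copy()
    mask = stack.plane("H") < hue_threshold
    out[mask] = bg
    return out
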
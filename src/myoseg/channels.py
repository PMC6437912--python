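"""Per-pixel feature channels feeding the structured contour detector.

The default stack has 13 channels: the three CIE-LAB color channels, the
gradient magnitude of lightness at two blur levels (sigma = 0 and 1.5),
and oriented gradient energy at four orientations (0, 45, 90, 135 degrees)
computed at two image scales (full and half resolution, the latter
upsampled back to full size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2lab

ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)
SCALES = (1, 2)
N_CHANNELS = 13

CHANNEL_NAMES = tuple(
    ["lab_L", "lab_a", "lab_b", "gradmag_s0", "gradmag_s1.5"]
    + [f"orient_{int(t)}_scale{s}" for s in SCALES for t in ORIENTATIONS_DEG]
)


@dataclass(frozen=True)
class ChannelStack:
    """H x W x C stack of per-pixel features with named channels."""

    values: np.ndarray
    channel_names: tuple

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def _block_mean(img: np.ndarray, s: int) -> np.ndarray:
    """Downsample by factor ``s`` using non-overlapping block means.

    Odd trailing rows/columns are edge-padded so the block grid is exact.
    """
    h, w = img.shape
    ph, pw = (-h) % s, (-w) % s
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    h2, w2 = img.shape
    return img.reshape(h2 // s, s, w2 // s, s).mean(axis=(1, 3))


def _upsample_nearest(img: np.ndarray, s: int, h: int, w: int) -> np.ndarray:
    up = np.repeat(np.repeat(img, s, axis=0), s, axis=1)
    return up[:h, :w]


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            "expected an H x W x 3 RGB image; got shape "
            f"{image.shape}. Grayscale inputs must be converted first, e.g. "
            "np.stack([gray] * 3, axis=-1)."
        )
    if min(image.shape[0], image.shape[1]) < 16:
        raise ValueError("image too small: min side must be >= 16 pixels")
    return image


def compute_channels(rgb_image: np.ndarray) -> ChannelStack:
    """Compute the 13-channel per-pixel feature stack of an RGB image.

    Parameters
    ----------
    rgb_image:
        ``H x W x 3`` array, uint8 in [0, 255] or float in [0, 1].

    Returns
    -------
    ChannelStack
        Float64 ``H x W x 13`` stack.  Channel order: L, a, b, gradient
        magnitude at sigma=0 and sigma=1.5, then the 4 x 2 oriented
        gradient-energy channels (scale 1 first).
    """
    rgb_image = _validate_rgb(rgb_image)
    if rgb_image.dtype == np.uint8:
        img = rgb_image.astype(np.float64) / 255.0
    else:
        img = np.clip(rgb_image.astype(np.float64), 0.0, 1.0)

    h, w = img.shape[:2]
    lab = rgb2lab(img)
    lum = lab[..., 0] / 100.0  # lightness scaled to [0, 1]

    channels = [lab[..., 0], lab[..., 1], lab[..., 2]]

    # gradient magnitude at two blur levels
    for sigma in (0.0, 1.5):
        src = lum if sigma == 0.0 else gaussian_filter(lum, sigma)
        gy, gx = np.gradient(src)
        channels.append(np.hypot(gx, gy))

    # oriented gradient energy: |directional derivative| at 4 orientations,
    # at full and half resolution (half-resolution maps upsampled back)
    for s in SCALES:
        src = lum if s == 1 else _block_mean(lum, s)
        gy, gx = np.gradient(src)
        for theta in ORIENTATIONS_DEG:
            t = np.deg2rad(theta)
            e = np.abs(np.cos(t) * gx + np.sin(t) * gy)
            if s != 1:
                e = _upsample_nearest(e, s, h, w)
            channels.append(e)

    values = np.stack(channels, axis=-1)
    return ChannelStack(values=values, channel_names=CHANNEL_NAMES)
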
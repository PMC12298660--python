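"""Per-block colour statistics in RGB, HSV and CIE L*a*b*.

Each valid grid block contributes, per colour space, the mean and standard
deviation of its three channels — six values per space.  On beef surfaces
the red channel dominates both fat and lean, while the spread of each
channel separates heavily marbled surfaces (fat/lean contrast) from lean
regular cuts.

All channels are expressed on a common 0-255 scale:

* RGB: native 8-bit values;
* HSV: hue (0-360 deg), saturation and value (0-100%) each rescaled
  linearly to 0-255 (standard hexcone model);
* L*a*b*: D65 white point and sRGB primaries; L* (0-100) scaled by 255/100,
  a* and b* shifted from [-128, 127] by +128 and clipped.

Standard deviations are population (divide-by-N) values; with blocks of
several thousand pixels the sample/population distinction is negligible,
but one convention is required for bit-stable results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

COLORSPACES = ("RGB", "HSV", "LAB")


@dataclass(frozen=True)
class ColorStats:
    colorspace: str
    means: tuple[float, float, float]
    stds: tuple[float, float, float]

    @property
    def values(self) -> np.ndarray:
        """Six features in (mu_1, mu_2, mu_3, sigma_1, sigma_2, sigma_3) order."""
        return np.array(self.means + self.stds, dtype=float)


def _check_block(block: np.ndarray) -> np.ndarray:
    block = np.asarray(block)
    if block.ndim != 3 or block.shape[2] != 3 or block.size == 0:
        raise ValueError(f"expected a nonempty (h, w, 3) RGB block, got shape {block.shape}")
    return block


def convert_colorspace(block: np.ndarray, colorspace: str) -> np.ndarray:
    """Convert an 8-bit RGB block to the requested space on a 0-255 scale."""
    block = _check_block(block)
    space = colorspace.upper()
    if space == "RGB":
        return block.astype(float)
    if space == "HSV":
        hsv = _skcolor.rgb2hsv(block.astype(np.uint8))  # all channels in [0, 1]
        return hsv * 255.0
    if space == "LAB":
        lab = _skcolor.rgb2lab(block.astype(np.uint8))  # D65, sRGB linearization
        out = np.empty_like(lab)
        out[..., 0] = lab[..., 0] * 255.0 / 100.0
        out[..., 1] = np.clip(lab[..., 1] + 128.0, 0.0, 255.0)
        out[..., 2] = np.clip(lab[..., 2] + 128.0, 0.0, 255.0)
        return out
    raise ValueError(f"unknown colorspace {colorspace!r}; expected one of {COLORSPACES}")


def color_stats(block: np.ndarray, colorspace: str) -> ColorStats:
    """Population mean and standard deviation per channel on the 0-255 scale."""
    converted = convert_colorspace(block, colorspace)
    flat = converted.reshape(-1, 3)
    means = flat.mean(axis=0)
    stds = flat.std(axis=0)  # population (ddof=0)
    return ColorStats(
        colorspace=colorspace.upper(),
        means=tuple(float(v) for v in means),
        stds=tuple(float(v) for v in stds),
    )
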
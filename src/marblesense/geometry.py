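"""Elliptical region-of-interest masking and grid-block enumeration.

The screening pipeline confines analysis to a black elliptical mask centred
on the frame (nominally 960 x 720 px with the ellipse spanning 75% of each
dimension, i.e. semi-axes 360 and 270 px).  The masked region is then tiled
with grid-aligned square blocks; only blocks that lie entirely inside the
ellipse are used for feature extraction and classification.

Conventions (fixed so block counts are reproducible):

* coordinates are 0-based, x rightward, y downward;
* a pixel (x, y) is *inside* the ellipse iff its centre (x+0.5, y+0.5)
  satisfies the ellipse inequality with an inclusive boundary;
* the block grid is anchored at the image origin and residual margins are
  discarded; block windows are half-open ``[x, x+s) x [y, y+s)``.

Under these conventions the default medium mask yields 55 valid blocks at
64 x 64 px and 36 at 80 x 80 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

WORKING_WIDTH = 960
WORKING_HEIGHT = 720

#: named mask scales: small / medium / large ROI
MASK_SCALES = {"small": 0.60, "medium": 0.75, "large": 0.90}


@dataclass(frozen=True)
class EllipseMask:
    """Axis-aligned elliptical ROI centred on the image."""

    width: int
    height: int
    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float
    scale_fraction: float

    def inside(self, x, y):
        """Pixel-centre inside test; accepts scalars or arrays, returns bool(s)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        u = (x + 0.5 - self.center_x) / self.semi_axis_x
        v = (y + 0.5 - self.center_y) / self.semi_axis_y
        return u * u + v * v <= 1.0

    def boolean_mask(self) -> np.ndarray:
        """(H, W) boolean array, True for pixels inside the ellipse."""
        xs = np.arange(self.width)
        ys = np.arange(self.height)
        return self.inside(xs[np.newaxis, :], ys[:, np.newaxis])

    @property
    def area(self) -> int:
        """Number of pixels inside the rasterized ellipse."""
        return int(self.boolean_mask().sum())


@dataclass(frozen=True)
class BlockGrid:
    """Grid-aligned square blocks fully contained in an elliptical ROI."""

    block_size: int
    origins: tuple[tuple[int, int], ...]
    image_width: int
    image_height: int

    def __len__(self) -> int:
        return len(self.origins)

    def extract(self, pixels: np.ndarray, index: int) -> np.ndarray:
        """Return the (s, s, C) window of block ``index`` from an image array."""
        x, y = self.origins[index]
        s = self.block_size
        return pixels[y : y + s, x : x + s]

    def to_records(self) -> list[dict]:
        return [
            {"block_id": i, "x": x, "y": y, "size": self.block_size}
            for i, (x, y) in enumerate(self.origins)
        ]


@dataclass(frozen=True)
class MaskedImage:
    pixels: np.ndarray
    mask: EllipseMask = field(repr=False)


def make_ellipse_mask(
    width: int, height: int, scale_fraction: float = MASK_SCALES["medium"]
) -> EllipseMask:
    """Build the centred elliptical ROI spanning ``scale_fraction`` of each dimension.

    For (960, 720, 0.75) this is the medium mask: centre (480, 360),
    semi-axes (360, 270).
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"image dimensions must be positive, got {width}x{height}")
    if not 0.0 < scale_fraction <= 1.0:
        raise ValueError(f"scale_fraction must be in (0, 1], got {scale_fraction}")
    return EllipseMask(
        width=int(width),
        height=int(height),
        center_x=width / 2.0,
        center_y=height / 2.0,
        semi_axis_x=scale_fraction * width / 2.0,
        semi_axis_y=scale_fraction * height / 2.0,
        scale_fraction=float(scale_fraction),
    )


def apply_mask(image: np.ndarray, mask: EllipseMask) -> MaskedImage:
    """Zero every pixel outside the ellipse; pixels inside pass through."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {image.shape}")
    if image.shape[0] != mask.height or image.shape[1] != mask.width:
        raise ValueError(
            f"image shape {image.shape[1]}x{image.shape[0]} does not match "
            f"mask {mask.width}x{mask.height}"
        )
    out = image.copy()
    out[~mask.boolean_mask()] = 0
    return MaskedImage(pixels=out, mask=mask)


def enumerate_valid_blocks(mask: EllipseMask, block_size: int) -> BlockGrid:
    """List grid-aligned blocks whose every pixel lies inside the ellipse.

    The ellipse is convex, so a block is fully inside iff its four corner
    pixel centres are inside.  Order is row-major from the top-left.
    """
    s = int(block_size)
    if s <= 0 or s > min(mask.width, mask.height):
        raise ValueError(
            f"block_size must be in [1, {min(mask.width, mask.height)}], got {block_size}"
        )
    origins = []
    for by in range(0, mask.height - s + 1, s):
        for bx in range(0, mask.width - s + 1, s):
            corners_x = np.array([bx, bx + s - 1, bx, bx + s - 1])
            corners_y = np.array([by, by, by + s - 1, by + s - 1])
            if bool(np.all(mask.inside(corners_x, corners_y))):
                origins.append((bx, by))
    return BlockGrid(
        block_size=s,
        origins=tuple(origins),
        image_width=mask.width,
        image_height=mask.height,
    )


def load_image_rgb(path, *, resize: bool = True) -> np.ndarray:
    """Read a PNG/JPEG as 8-bit RGB, resizing to the 960x720 working frame.

    Bilinear resampling is used when the input is not already at the working
    resolution.
    """
    with Image.open(path) as im:
        im = im.convert("RGB")
        if resize and im.size != (WORKING_WIDTH, WORKING_HEIGHT):
            im = im.resize((WORKING_WIDTH, WORKING_HEIGHT), Image.BILINEAR)
        return np.asarray(im, dtype=np.uint8)


def save_image_rgb(path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)
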
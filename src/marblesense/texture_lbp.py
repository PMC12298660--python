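"""Uniform local binary pattern (LBP) histograms over grayscale blocks.

An LBP code thresholds P circularly arranged neighbours at radius R against
the centre pixel: bit k is set iff neighbour k is >= the centre.  Codes
whose circular bit string has at most two 0<->1 transitions are *uniform*;
for P = 8 there are exactly 58 of them (P(P-1) + 2) and every other code is
pooled into one non-uniform bin, giving a 59-bin histogram per block.  The
histogram is normalized by the number of computed codes so it sums to 1.

Conventions:

* neighbour k sits at angle 2*pi*k/P from the +x axis, and carries weight
  2**k in the code;
* for radius 1 the sampling points are the eight integer neighbours of the
  3x3 neighbourhood (the classic square-neighbourhood form of the
  operator); for larger radii fractional positions are sampled with
  bilinear interpolation;
* no padding: codes are computed only where the full neighbourhood lies
  inside the block, i.e. at the (s - 2R)^2 interior pixels of an s x s
  block.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

SUPPORTED_CONFIGS = ((8, 1), (8, 2), (16, 2))


@dataclass(frozen=True)
class LBPConfig:
    """Sampling geometry of the LBP operator: P points at radius R."""

    P: int = 8
    R: int = 1

    def __post_init__(self):
        if self.P not in (8, 16) or self.R not in (1, 2):
            raise ValueError(
                f"unsupported LBP configuration ({self.P}, {self.R}); "
                f"supported: {SUPPORTED_CONFIGS}"
            )

    @property
    def n_uniform(self) -> int:
        """Number of uniform codes: P(P-1) + 2."""
        return self.P * (self.P - 1) + 2

    @property
    def n_bins(self) -> int:
        """Histogram length: uniform bins plus the pooled non-uniform bin."""
        return self.n_uniform + 1


@dataclass(frozen=True)
class LBPHistogram:
    bins: np.ndarray
    config: LBPConfig

    def __post_init__(self):
        object.__setattr__(self, "bins", np.asarray(self.bins, dtype=float))
        if self.bins.shape != (self.config.n_bins,):
            raise ValueError(
                f"expected {self.config.n_bins} bins for P={self.config.P}, "
                f"got {self.bins.shape}"
            )


def to_grayscale(block: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma: round(0.299 R + 0.587 G + 0.114 B), clamped to [0, 255]."""
    block = np.asarray(block)
    if block.ndim != 3 or block.shape[2] != 3 or block.size == 0:
        raise ValueError(f"expected a nonempty (h, w, 3) RGB block, got shape {block.shape}")
    luma = 0.299 * block[..., 0] + 0.587 * block[..., 1] + 0.114 * block[..., 2]
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def lbp_code(center: float, neighbors) -> int:
    """Decimal LBP code of one pixel; bit k set iff neighbors[k] >= center."""
    neighbors = list(neighbors)
    P = len(neighbors)
    if P not in (8, 16):
        raise ValueError(f"expected 8 or 16 neighbour values, got {P}")
    code = 0
    for k, nv in enumerate(neighbors):
        if nv >= center:
            code |= 1 << k
    return code


def transition_count(code: int, P: int) -> int:
    """Number of 0<->1 changes in the circular bit string of ``code``."""
    if not 0 <= code < (1 << P):
        raise ValueError(f"code {code} out of range for P={P}")
    rotated = ((code << 1) | (code >> (P - 1))) & ((1 << P) - 1)
    return int(bin(code ^ rotated).count("1"))


@lru_cache(maxsize=None)
def _uniform_lut(P: int) -> np.ndarray:
    """Lookup table code -> bin: uniform codes in ascending order, then the pooled bin."""
    codes = np.arange(1 << P)
    lut = np.empty(1 << P, dtype=np.int64)
    nonuniform_bin = P * (P - 1) + 2
    next_bin = 0
    for c in codes:
        if transition_count(int(c), P) <= 2:
            lut[c] = next_bin
            next_bin += 1
        else:
            lut[c] = nonuniform_bin
    assert next_bin == nonuniform_bin
    return lut


def uniform_bin_index(code: int, P: int) -> int:
    """Histogram bin of an LBP code: 0..57 for the 58 uniform P=8 codes, 58 otherwise."""
    if not 0 <= code < (1 << P):
        raise ValueError(f"code {code} out of range for P={P}")
    return int(_uniform_lut(P)[code])


@lru_cache(maxsize=None)
def _sample_offsets(P: int, R: int) -> tuple[tuple[float, float], ...]:
    """(dx, dy) offset of each sampling point; radius-1 offsets snap to the 3x3 grid."""
    offsets = []
    for k in range(P):
        angle = 2.0 * np.pi * k / P
        dx, dy = R * np.cos(angle), R * np.sin(angle)
        if R == 1:
            dx, dy = float(np.rint(dx)), float(np.rint(dy))
        else:
            # snap points that are numerically integral (e.g. (R, 0)) to the grid
            if abs(dx - round(dx)) < 1e-9:
                dx = float(round(dx))
            if abs(dy - round(dy)) < 1e-9:
                dy = float(round(dy))
        offsets.append((dx, dy))
    return tuple(offsets)


def _neighbor_plane(gray: np.ndarray, R: int, dx: float, dy: float) -> np.ndarray:
    """Bilinearly sampled neighbour values for every interior pixel."""
    h, w = gray.shape
    y0, x0 = int(np.floor(dy)), int(np.floor(dx))
    fy, fx = dy - y0, dx - x0

    def shifted(oy: int, ox: int) -> np.ndarray:
        return gray[R + oy : h - R + oy, R + ox : w - R + ox]

    if fy == 0.0 and fx == 0.0:
        return shifted(y0, x0)
    return (
        (1 - fy) * (1 - fx) * shifted(y0, x0)
        + (1 - fy) * fx * shifted(y0, x0 + 1)
        + fy * (1 - fx) * shifted(y0 + 1, x0)
        + fy * fx * shifted(y0 + 1, x0 + 1)
    )


def lbp_code_image(gray: np.ndarray, config: LBPConfig) -> np.ndarray:
    """LBP codes at every interior pixel of a grayscale array."""
    gray = np.asarray(gray, dtype=float)
    h, w = gray.shape
    R = config.R
    if min(h, w) < 2 * R + 1:
        raise ValueError(
            f"block of shape {gray.shape} too small for radius {R} (need side >= {2 * R + 1})"
        )
    centers = gray[R : h - R, R : w - R]
    codes = np.zeros(centers.shape, dtype=np.int64)
    for k, (dx, dy) in enumerate(_sample_offsets(config.P, R)):
        neighbors = _neighbor_plane(gray, R, dx, dy)
        codes |= (neighbors >= centers).astype(np.int64) << k
    return codes


def lbp_histogram(block: np.ndarray, config: LBPConfig = LBPConfig(8, 1)) -> LBPHistogram:
    """Normalized uniform-LBP histogram of one RGB block.

    The block is converted to grayscale, codes are computed at the
    (s - 2R)^2 interior pixels, mapped through the uniform lookup table and
    binned; the histogram is divided by the number of codes so it sums to 1.
    """
    gray = to_grayscale(block)
    codes = lbp_code_image(gray, config)
    bins = np.bincount(
        _uniform_lut(config.P)[codes.ravel()], minlength=config.n_bins
    ).astype(float)
    return LBPHistogram(bins=bins / codes.size, config=config)


def concatenate_histograms(histograms: list[LBPHistogram]) -> np.ndarray:
    """Join per-block histograms into one image-level texture vector.

    Optional export only (e.g. 55 blocks x 59 bins = 3245 dimensions);
    classification operates on individual blocks.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    configs = {h.config for h in histograms}
    if len(configs) != 1:
        raise ValueError("histograms use mixed LBP configurations")
    return np.concatenate([h.bins for h in histograms])
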
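"""Synthetic beef-surface images with ground-truth fat masks.

The original three-class beef dataset (Wagyu / regular / fat-injected) is
private, so every pipeline stage is exercised on generated images that
reproduce the documented appearance contrasts between the classes:

* **Wagyu** — many small, scattered, mostly disconnected fat flecks of
  varying size on bright-red lean; high fat fraction.
* **Fat-injected** — fewer, elongated, interconnected streaks with a clear
  dominant orientation and uniform thickness, on darker red lean; high fat
  fraction.
* **Regular** — sparse fat on medium-red lean; low fat fraction.

Images are rendered at the 960 x 720 working resolution: correlated
Gaussian lean texture, anti-aliased near-white elliptical flecks (chained
end-to-end into curvilinear streaks for the injected class), restricted to
the elliptical ROI.  The binary fat mask actually rendered is returned as
ground truth.

Capture perturbations for robustness sweeps are also provided: a brightness
ladder (seven levels mu + 1.5 k sigma, k = -3..3), opaque label stickers,
specular-reflection blobs, and perspective warps equivalent to tilting the
camera.

All randomness flows from one integer seed through a named generator per
image, so identical seeds give bit-identical datasets.  Phenotype
parameters (fleck counts, sizes, fractions, colours) are free parameters of
the generator chosen to satisfy the qualitative contrasts above; they are
not measurements of real beef.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse
from skimage.transform import ProjectiveTransform, warp

from .geometry import WORKING_HEIGHT, WORKING_WIDTH, make_ellipse_mask
from .svm_classifier import BeefClass

# Brightness ladder anchors: mean ROI gray level of a nominal capture and the
# half-step such that level k targets mu + 1.5 k sigma for k in -3..3
# (1.5 sigma = one printed ladder step of 25.97 gray levels).
BRIGHTNESS_MU_DEFAULT = 98.91
BRIGHTNESS_SIGMA_DEFAULT = (98.91 - 72.94) / 1.5


class GenerationError(RuntimeError):
    """Raised when a phenotype spec cannot be rendered (infeasible fat layout)."""


@lru_cache(maxsize=8)
def _roi_mask(width: int, height: int, scale_fraction: float) -> np.ndarray:
    mask = make_ellipse_mask(width, height, scale_fraction).boolean_mask()
    mask.setflags(write=False)
    return mask


class Connectivity(str, enum.Enum):
    SCATTERED = "SCATTERED"
    INTERCONNECTED = "INTERCONNECTED"


class PerturbationKind(str, enum.Enum):
    NONE = "NONE"
    BRIGHTNESS = "BRIGHTNESS"
    LABEL = "LABEL"
    REFLECTION = "REFLECTION"
    TILT = "TILT"


class TiltDirection(str, enum.Enum):
    FORWARD = "FORWARD"
    BACKWARD = "BACKWARD"
    LEFT = "LEFT"
    RIGHT = "RIGHT"


@dataclass(frozen=True)
class PhenotypeSpec:
    beef_class: BeefClass
    lean_color_mean: tuple[float, float, float]
    lean_color_sd: tuple[float, float, float]
    fat_fraction_range: tuple[float, float]
    fleck_count_range: tuple[int, int]
    elongation_range: tuple[float, float]
    connectivity: Connectivity
    orientation_jitter: float  # degrees; 90 ~ isotropic
    fleck_area_jitter: float = 0.5  # lognormal sigma of per-fleck area

    def __post_init__(self):
        lo, hi = self.fat_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"fat_fraction_range must lie in (0, 1), got {self.fat_fraction_range}")
        if self.fleck_count_range[0] < 1 or self.fleck_count_range[0] > self.fleck_count_range[1]:
            raise ValueError(f"bad fleck_count_range {self.fleck_count_range}")


#: generator defaults per class; free parameters realizing the class contrasts
DEFAULT_SPECS: dict[BeefClass, PhenotypeSpec] = {
    BeefClass.WAGYU: PhenotypeSpec(
        beef_class=BeefClass.WAGYU,
        lean_color_mean=(178.0, 72.0, 66.0),  # bright red lean
        lean_color_sd=(12.0, 9.0, 9.0),
        fat_fraction_range=(0.26, 0.38),
        fleck_count_range=(150, 260),
        elongation_range=(1.0, 2.5),
        connectivity=Connectivity.SCATTERED,
        orientation_jitter=90.0,
        fleck_area_jitter=0.6,  # fat thickness varies
    ),
    BeefClass.REGULAR: PhenotypeSpec(
        beef_class=BeefClass.REGULAR,
        lean_color_mean=(160.0, 70.0, 64.0),
        lean_color_sd=(8.0, 6.0, 6.0),
        fat_fraction_range=(0.02, 0.07),
        fleck_count_range=(8, 25),
        elongation_range=(1.0, 3.0),
        connectivity=Connectivity.SCATTERED,
        orientation_jitter=90.0,
        fleck_area_jitter=0.5,
    ),
    BeefClass.FAT_INJECTED: PhenotypeSpec(
        beef_class=BeefClass.FAT_INJECTED,
        lean_color_mean=(132.0, 50.0, 52.0),  # lean tends toward dark red
        lean_color_sd=(9.0, 7.0, 7.0),
        fat_fraction_range=(0.22, 0.34),
        fleck_count_range=(16, 32),
        elongation_range=(6.0, 12.0),
        connectivity=Connectivity.INTERCONNECTED,
        orientation_jitter=14.0,  # clear directionality
        fleck_area_jitter=0.2,  # uniform thickness
    ),
}


@dataclass(frozen=True)
class PerturbationSpec:
    kind: PerturbationKind = PerturbationKind.NONE
    brightness_level: int = 0  # k in -3..3, target mean mu + 1.5 k sigma
    brightness_mu: float = BRIGHTNESS_MU_DEFAULT
    brightness_sigma: float = BRIGHTNESS_SIGMA_DEFAULT
    occlusion_area_fraction: float = 0.05
    tilt_angle: float = 0.0  # degrees
    tilt_direction: TiltDirection = TiltDirection.FORWARD

    def __post_init__(self):
        if not -3 <= self.brightness_level <= 3:
            raise ValueError(f"brightness_level must be in -3..3, got {self.brightness_level}")
        if not 0.0 <= self.occlusion_area_fraction <= 0.25:
            raise ValueError(f"occlusion fraction must be in [0, 0.25], got {self.occlusion_area_fraction}")
        if self.tilt_angle < 0:
            raise ValueError(f"tilt_angle must be >= 0, got {self.tilt_angle}")


def brightness_level_value(k: int, mu: float = BRIGHTNESS_MU_DEFAULT,
                           sigma: float = BRIGHTNESS_SIGMA_DEFAULT) -> float:
    """Target ROI gray mean of ladder level k: mu + 1.5 k sigma."""
    return mu + 1.5 * k * sigma


# ---------------------------------------------------------------------------
# rendering


def _sample_point_in_ellipse(rng, cx, cy, ax, ay, margin=0.95):
    """Uniform point inside the (slightly shrunk) ellipse."""
    while True:
        u, v = rng.uniform(-1, 1, size=2)
        if u * u + v * v <= margin * margin:
            return cx + u * ax, cy + v * ay


def _draw_fleck(mask, rng, cy, cx, area, elongation, theta):
    """Rasterize one rotated elliptical fleck; returns (end_y, end_x) of its tip."""
    b = np.sqrt(area / (np.pi * elongation))  # minor semi-axis
    a = elongation * b
    if b < 0.7:
        raise GenerationError(
            f"fleck area {area:.1f}px with elongation {elongation:.1f} is sub-pixel thin"
        )
    rr, cc = _draw_ellipse(cy, cx, b, a, shape=mask.shape, rotation=theta)
    mask[rr, cc] = True
    return cy - a * np.sin(theta), cx + a * np.cos(theta)


def generate_image(spec: PhenotypeSpec, seed: int,
                   scale_fraction: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    """Render one 960 x 720 surface image and its binary fat ground-truth mask.

    Fat flecks are added until the rendered fat fraction of the ROI reaches a
    target drawn from ``fat_fraction_range``; a spec whose count range cannot
    reach its fraction raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(seed)
    H, W = WORKING_HEIGHT, WORKING_WIDTH
    ellipse = make_ellipse_mask(W, H, scale_fraction)
    roi = _roi_mask(W, H, scale_fraction)
    roi_area = int(roi.sum())

    # lean background: correlated noise shared across channels
    noise = ndimage.gaussian_filter(
        rng.standard_normal((H, W), dtype=np.float32), sigma=1.5
    )
    noise /= max(float(noise.std()), 1e-9)
    tex = 0.8 * noise + 0.35 * rng.standard_normal((H, W), dtype=np.float32)
    img = (
        np.asarray(spec.lean_color_mean, dtype=np.float32)
        + np.asarray(spec.lean_color_sd, dtype=np.float32) * tex[..., np.newaxis]
    )

    # fat layout
    target = rng.uniform(*spec.fat_fraction_range)
    n_target = int(rng.integers(spec.fleck_count_range[0], spec.fleck_count_range[1] + 1))
    chain_len = 4 if spec.connectivity is Connectivity.INTERCONNECTED else 1
    unit_area = target * roi_area / (n_target * chain_len)
    if unit_area > 0.25 * roi_area:
        raise GenerationError("fat fraction unreachable: single fleck would dominate the ROI")

    fat = np.zeros((H, W), dtype=bool)
    dominant = rng.uniform(0.0, np.pi)
    jitter = np.deg2rad(spec.orientation_jitter)
    drawn = 0
    max_flecks = 6 * n_target
    check_every = max(1, n_target // 12)
    fraction = 0.0
    while drawn < max_flecks:
        x, y = _sample_point_in_ellipse(rng, ellipse.center_x, ellipse.center_y,
                                        ellipse.semi_axis_x, ellipse.semi_axis_y)
        theta = dominant + rng.uniform(-jitter, jitter)
        elong = rng.uniform(*spec.elongation_range)
        area = unit_area * rng.lognormal(0.0, spec.fleck_area_jitter)
        cy, cx = y, x
        for _ in range(chain_len):
            end_y, end_x = _draw_fleck(fat, rng, cy, cx, area, elong, theta)
            # next segment continues from the tip with a small direction change
            theta += rng.uniform(-0.25, 0.25)
            cy, cx = end_y, end_x
            if not (0 <= cy < H and 0 <= cx < W):
                break
        drawn += 1
        if drawn % check_every == 0 or drawn >= max_flecks:
            fraction = float((fat & roi).sum()) / roi_area
            if fraction >= target - 0.003:
                break
    fraction = float((fat & roi).sum()) / roi_area
    if fraction < spec.fat_fraction_range[0] - 0.02:
        raise GenerationError(
            f"fat fraction unreachable: reached {fraction:.3f} of target {target:.3f} "
            f"after {drawn} flecks"
        )

    fat &= roi

    # render: anti-aliased alpha blend of near-white fat over lean
    alpha = np.clip(
        ndimage.gaussian_filter(fat.astype(np.float32), sigma=0.8), 0.0, 1.0
    )[..., np.newaxis]
    fat_v = rng.uniform(222.0, 240.0)
    fat_color = np.array([fat_v, fat_v - 8.0, fat_v - 12.0], dtype=np.float32)
    fat_tex = 6.0 * ndimage.gaussian_filter(
        rng.standard_normal((H, W), dtype=np.float32), sigma=1.0
    )
    img += alpha * (fat_color + fat_tex[..., np.newaxis] - img)

    img[~roi] = 0.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), fat


# ---------------------------------------------------------------------------
# perturbations


def _adjust_brightness(image, spec, roi):
    target = brightness_level_value(spec.brightness_level, spec.brightness_mu, spec.brightness_sigma)
    out = image.astype(float)
    luma_w = np.array([0.299, 0.587, 0.114])
    for _ in range(10):  # fixed-point gain iterations compensate clipping
        gray = out @ luma_w
        current = float(gray[roi].mean())
        if abs(current - target) < 0.1 or current <= 0:
            break
        out = np.clip(out * (target / current), 0.0, 255.0)
    out[~roi] = 0.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _paste_label(image, spec, roi, rng):
    """Opaque white rounded rectangle with dark text-like strokes, fully in the ROI."""
    H, W = image.shape[:2]
    area = spec.occlusion_area_fraction * roi.sum()
    if area <= 0:
        return image.copy()
    aspect = 2.0  # width : height
    h = int(round(np.sqrt(area / aspect)))
    w = int(round(aspect * h))
    ellipse = make_ellipse_mask(W, H)
    for _ in range(200):
        cx, cy = _sample_point_in_ellipse(rng, ellipse.center_x, ellipse.center_y,
                                          ellipse.semi_axis_x, ellipse.semi_axis_y, margin=0.7)
        x0, y0 = int(cx - w / 2), int(cy - h / 2)
        corners_x = np.array([x0, x0 + w - 1, x0, x0 + w - 1])
        corners_y = np.array([y0, y0, y0 + h - 1, y0 + h - 1])
        if np.all(ellipse.inside(corners_x, corners_y)):
            break
    else:
        raise GenerationError(f"cannot place a label of {spec.occlusion_area_fraction:.0%} ROI area inside the ROI")
    out = image.copy()
    r = max(4, h // 10)
    sticker = np.zeros((H, W), dtype=bool)
    sticker[y0 + r : y0 + h - r, x0 : x0 + w] = True
    sticker[y0 : y0 + h, x0 + r : x0 + w - r] = True
    for ccx, ccy in ((x0 + r, y0 + r), (x0 + w - r - 1, y0 + r),
                     (x0 + r, y0 + h - r - 1), (x0 + w - r - 1, y0 + h - r - 1)):
        rr, cc = _draw_disk((ccy, ccx), r, shape=(H, W))
        sticker[rr, cc] = True
    out[sticker] = (250, 250, 248)
    # dark strokes imitating printed text
    n_lines = max(2, h // 18)
    for i in range(n_lines):
        ly = y0 + int((i + 1) * h / (n_lines + 1))
        lx0 = x0 + int(0.12 * w)
        lx1 = x0 + int(rng.uniform(0.55, 0.9) * w)
        out[ly - 1 : ly + 1, lx0:lx1] = (30, 30, 35)
    return out


def _add_reflections(image, spec, roi, rng):
    H, W = image.shape[:2]
    field_ = np.zeros((H, W), dtype=np.float32)
    n_blobs = int(rng.integers(2, 6))
    ellipse = make_ellipse_mask(W, H)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)
    for _ in range(n_blobs):
        x, y = _sample_point_in_ellipse(rng, ellipse.center_x, ellipse.center_y,
                                        ellipse.semi_axis_x, ellipse.semi_axis_y, margin=0.85)
        sig = rng.uniform(15.0, 45.0)
        field_ += np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sig**2)))
    alpha = np.clip(field_, 0.0, 1.0) * rng.uniform(0.75, 0.95)
    out = image.astype(float)
    for c in range(3):
        out[..., c] = (1 - alpha) * out[..., c] + alpha * 252.0
    out[~roi] = 0.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _tilt_homography(angle_deg: float, direction: TiltDirection, W: int, H: int) -> np.ndarray:
    """Homography of a camera rotated by angle about the image-plane axis."""
    f = 0.9 * W  # nominal focal length in pixels
    K = np.array([[f, 0, W / 2], [0, f, H / 2], [0, 0, 1.0]])
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    if direction in (TiltDirection.FORWARD, TiltDirection.BACKWARD):
        sgn = 1.0 if direction is TiltDirection.FORWARD else -1.0
        R = np.array([[1, 0, 0], [0, c, -sgn * s], [0, sgn * s, c]])
    else:
        sgn = 1.0 if direction is TiltDirection.LEFT else -1.0
        R = np.array([[c, 0, sgn * s], [0, 1, 0], [-sgn * s, 0, c]])
    return K @ R @ np.linalg.inv(K)


def _apply_tilt(image, spec):
    if spec.tilt_angle == 0:
        return image.copy()
    H_img, W_img = image.shape[:2]
    Hmat = _tilt_homography(spec.tilt_angle, spec.tilt_direction, W_img, H_img)
    tf = ProjectiveTransform(matrix=Hmat)
    out = warp(image.astype(float), tf.inverse, order=1, preserve_range=True,
               output_shape=(H_img, W_img), cval=0.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def perturb(image: np.ndarray, spec: PerturbationSpec, seed: int) -> np.ndarray:
    """Apply one capture perturbation; the input image is not modified."""
    image = np.asarray(image, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    roi = _roi_mask(image.shape[1], image.shape[0], 0.75)
    if spec.kind is PerturbationKind.NONE:
        return image.copy()
    if spec.kind is PerturbationKind.BRIGHTNESS:
        return _adjust_brightness(image, spec, roi)
    if spec.kind is PerturbationKind.LABEL:
        return _paste_label(image, spec, roi, rng)
    if spec.kind is PerturbationKind.REFLECTION:
        return _add_reflections(image, spec, roi, rng)
    if spec.kind is PerturbationKind.TILT:
        return _apply_tilt(image, spec)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class SyntheticDataset:
    """Seeded, class-balanced image collection with lazy rendering.

    Images are rendered on demand from per-image seeds recorded in the
    manifest, so datasets of hundreds of frames need not be held in memory.
    """

    manifest: pd.DataFrame = field(repr=False)
    specs: dict[BeefClass, PhenotypeSpec] = field(repr=False)
    seed: int
    scale_fraction: float = 0.75

    def __len__(self) -> int:
        return len(self.manifest)

    def subset(self, split: str) -> pd.DataFrame:
        return self.manifest[self.manifest["split"] == split]

    def render(self, image_id: int) -> tuple[np.ndarray, np.ndarray]:
        row = self.manifest.loc[self.manifest["id"] == image_id].iloc[0]
        return generate_image(
            self.specs[BeefClass(int(row["label"]))],
            int(row["seed"]),
            self.scale_fraction,
        )

    def save(self, out_dir) -> None:
        from .geometry import save_image_rgb
        from PIL import Image as _PILImage

        out = Path(out_dir)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for _, row in self.manifest.iterrows():
            cls = BeefClass(int(row["label"])).name.lower()
            img_dir = out / "images" / cls
            img_dir.mkdir(parents=True, exist_ok=True)
            image, fat = self.render(int(row["id"]))
            save_image_rgb(img_dir / f"{int(row['id']):05d}.png", image)
            _PILImage.fromarray((fat * 255).astype(np.uint8), mode="L").save(
                out / "masks" / f"{int(row['id']):05d}.png"
            )
        self.manifest.to_csv(out / "manifest.csv", index=False)


def generate_dataset(
    n_per_class: int,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    specs: dict[BeefClass, PhenotypeSpec] | None = None,
    seed: int = 0,
    scale_fraction: float = 0.75,
) -> SyntheticDataset:
    """Class-balanced dataset with disjoint train/validation/test splits.

    The default 0.6/0.2/0.2 split of 200 images per class gives the
    120/40/40 design used for large-sample evaluation.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {split}")
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    n_train = int(round(split[0] * n_per_class))
    n_val = int(round(split[1] * n_per_class))
    n_test = n_per_class - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split {split} of {n_per_class} images leaves an empty subset")
    rng = np.random.default_rng(seed)
    records = []
    next_id = 0
    for cls in (BeefClass.WAGYU, BeefClass.REGULAR, BeefClass.FAT_INJECTED):
        for i in range(n_per_class):
            part = "train" if i < n_train else ("validation" if i < n_train + n_val else "test")
            records.append(
                {
                    "id": next_id,
                    "label": int(cls),
                    "class_name": cls.name,
                    "split": part,
                    "seed": int(rng.integers(0, 2**31)),
                    "perturbation": PerturbationKind.NONE.value,
                }
            )
            next_id += 1
    manifest = pd.DataFrame.from_records(records)
    return SyntheticDataset(
        manifest=manifest, specs=specs, seed=seed, scale_fraction=scale_fraction
    )


def default_spec(beef_class: BeefClass, **overrides) -> PhenotypeSpec:
    """Copy of a class's default phenotype with optional field overrides."""
    return replace(DEFAULT_SPECS[BeefClass(beef_class)], **overrides)
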
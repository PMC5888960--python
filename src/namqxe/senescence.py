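"""Color-based canopy senescence scoring.

Plants are photographed against a white sheet; each pixel is classified as
background, green leaf, or yellow/brown (senescent) leaf by its proximity in
YCbCr chroma space to a small palette of reference shades sampled from real
images.  Working in (Cb, Cr) only makes the classification robust to
brightness differences between photo sessions.  The senescence score of a
plant is the yellow/brown percentage of total leaf area; senescence itself
is the increase of that percentage between two photo dates.

The exact reference shades and tolerance used in the original analysis are
not published, so they are shipped here as a configurable default palette;
every numeric choice is surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShadePalette",
    "CanopyScore",
    "DEFAULT_PALETTE",
    "rgb_to_ycbcr",
    "classify_pixels",
    "canopy_score",
    "senescence_change",
    "generate_canopy_image",
    "read_image",
    "write_label_image",
]

BACKGROUND, GREEN, YELLOW = 0, 1, 2


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 full-range RGB -> YCbCr (float, Y in [0,255],
    Cb/Cr centred at 128)."""
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return np.stack([y, cb, cr], axis=-1)


@dataclass
class ShadePalette:
    """Reference shades (RGB triplets) for the green and yellow/brown
    classes, a chroma-distance tolerance, and the white-background rule.

    A pixel whose (Cb, Cr) lies within ``tolerance`` of the nearest
    reference shade takes that shade's class; anything farther is
    background, as are pixels passing the white rule (high luma, chroma
    near neutral)."""

    green: list = field(default_factory=lambda: [
        (45, 95, 35), (70, 125, 50), (100, 150, 70), (130, 170, 95),
    ])
    yellow: list = field(default_factory=lambda: [
        (190, 175, 60), (205, 185, 95), (160, 130, 60), (130, 95, 45),
    ])
    tolerance: float = 20.0
    white_y_min: float = 220.0
    white_chroma_max: float = 12.0
    use_luma: bool = False  # include Y in the distance (3-D) instead of (Cb, Cr)

    def __post_init__(self) -> None:
        if not self.green or not self.yellow:
            raise ValueError("both palettes must be non-empty")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    def reference_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(shades in YCbCr, class labels)."""
        shades = np.array(list(self.green) + list(self.yellow), dtype=float)
        labels = np.array([GREEN] * len(self.green) + [YELLOW] * len(self.yellow))
        return rgb_to_ycbcr(shades), labels

    @classmethod
    def from_yaml(cls, path) -> "ShadePalette":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("green", "yellow"):
            if key in raw:
                raw[key] = [tuple(c) for c in raw[key]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        raw = {
            "green": [list(c) for c in self.green],
            "yellow": [list(c) for c in self.yellow],
            "tolerance": self.tolerance,
            "white_y_min": self.white_y_min,
            "white_chroma_max": self.white_chroma_max,
            "use_luma": self.use_luma,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


DEFAULT_PALETTE = ShadePalette()


def classify_pixels(image: np.ndarray, palette: ShadePalette = DEFAULT_PALETTE) -> np.ndarray:
    """Label each pixel background (0), green (1) or yellow/brown (2).

    White-background pixels are forced to background first; remaining pixels
    take the class of the nearest reference shade in chroma space if that
    distance is within the palette tolerance, else background.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[-1] < 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    ycc = rgb_to_ycbcr(image[..., :3])
    refs, ref_labels = palette.reference_points()

    dims = slice(0, 3) if palette.use_luma else slice(1, 3)
    px = ycc[..., dims]
    diff = px[..., None, :] - refs[:, dims][None, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    nearest = np.argmin(dist, axis=-1)
    labels = np.where(
        np.min(dist, axis=-1) <= palette.tolerance, ref_labels[nearest], BACKGROUND
    )

    white = (
        (ycc[..., 0] >= palette.white_y_min)
        & (np.abs(ycc[..., 1] - 128.0) <= palette.white_chroma_max)
        & (np.abs(ycc[..., 2] - 128.0) <= palette.white_chroma_max)
    )
    labels[white] = BACKGROUND
    return labels.astype(np.uint8)


@dataclass(frozen=True)
class CanopyScore:
    """Pixel counts per class and the yellow/brown percentage of leaf area."""

    total_leaf: int
    green: int
    yellow: int

    @property
    def yellow_fraction(self) -> float:
        """Percent of leaf area that is yellow/brown; NaN when no leaf
        pixels were found."""
        if self.total_leaf == 0:
            return float("nan")
        return 100.0 * self.yellow / self.total_leaf


def canopy_score(image: np.ndarray, palette: ShadePalette = DEFAULT_PALETTE) -> CanopyScore:
    """Score one photograph: classify pixels and report leaf-area counts.

    The white background is excluded from the denominator, so the yellow
    fraction is relative to total (green + yellow/brown) leaf area only.
    """
    labels = classify_pixels(image, palette)
    green = int((labels == GREEN).sum())
    yellow = int((labels == YELLOW).sum())
    return CanopyScore(total_leaf=green + yellow, green=green, yellow=yellow)


def senescence_change(score_t1: CanopyScore, score_t2: CanopyScore) -> float:
    """Increase of the yellow/brown leaf percentage between two photo dates
    (percentage points); NaN propagates from undefined scores."""
    return score_t2.yellow_fraction - score_t1.yellow_fraction


# ---------------------------------------------------------------------------
# synthetic fixtures

def generate_canopy_image(
    width: int,
    height: int,
    leaf_fraction: float,
    yellow_fraction_of_leaf: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    palette: ShadePalette = DEFAULT_PALETTE,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint a synthetic canopy photo with known ground truth.

    A centred block of ``leaf_fraction`` of the pixels is painted with
    palette shades — the first ``yellow_fraction_of_leaf`` of them yellow,
    the rest green — on a white background, with optional Gaussian RGB
    noise.  Returns (uint8 RGB image, ground-truth label raster).
    """
    if not (0 <= leaf_fraction <= 1 and 0 <= yellow_fraction_of_leaf <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = width * height
    n_leaf = int(round(leaf_fraction * n))
    n_yellow = int(round(yellow_fraction_of_leaf * n_leaf))

    labels = np.full(n, BACKGROUND, dtype=np.uint8)
    start = (n - n_leaf) // 2
    labels[start : start + n_yellow] = YELLOW
    labels[start + n_yellow : start + n_leaf] = GREEN

    img = np.full((n, 3), 255.0)
    for cls, shades in ((GREEN, palette.green), (YELLOW, palette.yellow)):
        idx = np.nonzero(labels == cls)[0]
        pick = rng.integers(0, len(shades), size=len(idx))
        img[idx] = np.asarray(shades, dtype=float)[pick]
    if noise_sd > 0:
        leaf = labels != BACKGROUND
        img[leaf] += rng.normal(0.0, noise_sd, size=(int(leaf.sum()), 3))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img.reshape(height, width, 3), labels.reshape(height, width)


def read_image(path) -> np.ndarray:
    """Load a PNG/JPEG photograph as an RGB uint8 array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_label_image(labels: np.ndarray, path) -> None:
    """Write a label raster as a small PNG (background black, green green,
    yellow/brown orange)."""
    from PIL import Image

    lut = np.array([[0, 0, 0], [0, 170, 0], [230, 160, 30]], dtype=np.uint8)
    Image.fromarray(lut[labels]).save(path)
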
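"""Histogram image encodings: Basic Colours and oBIF textons.

Two bag-of-pixels summaries are computed per image:

* an 11-bin **colour histogram** over the Basic Colour terms (black,
  grey, white, red, orange, yellow, green, blue, purple, pink, brown);
  each pixel is assigned to the nearest colour prototype in CIELAB
  space, so each bin is a connected region of the RGB cube;
* a 529-bin **texton histogram**: each pixel is classified into one of
  23 oriented Basic Image Feature (oBIF) classes at a fine and at a
  coarse Gaussian-derivative filter scale, and the texton is the
  ordered (fine, coarse) pair, giving 23**2 = 529 bins.

The oBIF classes are: flat, light blob, dark blob, eight orientations
of slope, four orientations of light line, four of dark line, and four
of saddle.  Classification is an argmax over seven scale-normalised
scores built from the six Gaussian-jet responses (value, first and
second derivatives) at the pixel.

Conventions (fixed for cache compatibility):

* image arrays are H×W×3 uint8, row-major, origin top-left, y down;
* luminance uses Rec. 601 weights (0.299, 0.587, 0.114) on [0, 1];
* orientations are measured from the +x axis, counter-clockwise in
  image coordinates; slope bins are 45° wide centred on 0°; line and
  saddle bins are 45° wide over [0°, 180°), labelled by the direction
  *along* the line (perpendicular to the principal second-derivative
  direction), with sector boundaries assigned to the lower bin;
* the texton index is fine-major: ``23 * fine + coarse``;
* borders use reflect padding and every pixel is classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

N_COLOUR_BINS = 11
N_OBIF_CLASSES = 23
N_TEXTONS = N_OBIF_CLASSES**2

BASIC_COLOUR_NAMES = (
    "black",
    "grey",
    "white",
    "red",
    "orange",
    "yellow",
    "green",
    "blue",
    "purple",
    "pink",
    "brown",
)

#: Default RGB prototypes for the 11 Basic Colours.  The partition of the
#: RGB cube is nearest-prototype in CIELAB; the table is deliberately
#: editable configuration, not a fitted model.
DEFAULT_COLOUR_PROTOTYPES = np.array(
    [
        (0, 0, 0),  # black
        (128, 128, 128),  # grey
        (255, 255, 255),  # white
        (255, 0, 0),  # red
        (255, 140, 0),  # orange
        (255, 255, 0),  # yellow
        (0, 160, 0),  # green
        (0, 0, 255),  # blue
        (150, 0, 200),  # purple
        (255, 150, 190),  # pink
        (130, 70, 20),  # brown
    ],
    dtype=np.uint8,
)

# oBIF class index layout (fixed):
#   0          flat
#   1          light blob
#   2          dark blob
#   3 .. 10    slope, 8 orientation bins
#   11 .. 14   light line, 4 orientation bins
#   15 .. 18   dark line, 4 orientation bins
#   19 .. 22   saddle, 4 orientation bins
OBIF_FLAT = 0
OBIF_LIGHT_BLOB = 1
OBIF_DARK_BLOB = 2
OBIF_SLOPE_BASE = 3
OBIF_LIGHT_LINE_BASE = 11
OBIF_DARK_LINE_BASE = 15
OBIF_SADDLE_BASE = 19

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ObifConfig:
    """Filter scales and flatness threshold for oBIF classification.

    ``sigma_fine`` is the fine Gaussian scale in pixels; the coarse
    scale is ``scale_ratio * sigma_fine``.  ``epsilon`` weights the
    flat-class score ``epsilon * s`` against the derivative-based
    scores (luminance is on [0, 1], so epsilon is dimensionless).
    """

    sigma_fine: float = 1.0
    scale_ratio: float = 4.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not np.isfinite([self.sigma_fine, self.scale_ratio, self.epsilon]).all():
            raise ValueError("ObifConfig values must be finite")
        if self.sigma_fine <= 0:
            raise ValueError("sigma_fine must be > 0")
        if self.scale_ratio <= 1:
            raise ValueError("scale_ratio must be > 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @property
    def sigma_coarse(self) -> float:
        return self.scale_ratio * self.sigma_fine


@dataclass(frozen=True)
class JetField:
    """Gaussian 2-jet of a grayscale image at scale ``sigma``.

    Holds the smoothed value ``s`` and derivatives ``s_x, s_y, s_xx,
    s_xy, s_yy``; fields may be full arrays or scalars for a single
    pixel.  Derivatives of a constant image are identically zero.
    """

    s: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    sxx: np.ndarray
    sxy: np.ndarray
    syy: np.ndarray
    sigma: float


@dataclass(frozen=True)
class ImageEncoding:
    """The two histogram encodings of one image (each unit-sum)."""

    colour: np.ndarray  # (11,)
    texton: np.ndarray  # (529,)


def read_prototype_table(path) -> np.ndarray:
    """Load an editable Basic-Colour prototype table.

    TSV with columns ``name, r, g, b`` (one row per Basic Colour, in
    the canonical bin order); values in [0, 255].
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if list(df["name"]) != list(BASIC_COLOUR_NAMES):
        raise ValueError(
            f"prototype table must list the 11 Basic Colours in order "
            f"{BASIC_COLOUR_NAMES}"
        )
    table = df[["r", "g", "b"]].to_numpy()
    if (table < 0).any() or (table > 255).any():
        raise ValueError("prototype RGB values must be in [0, 255]")
    return table.astype(np.uint8)


def write_prototype_table(path, table: np.ndarray = DEFAULT_COLOUR_PROTOTYPES) -> None:
    """Write a prototype table in the editable TSV format."""
    with open(path, "w") as fh:
        fh.write("name\tr\tg\tb\n")
        for name, (r, g, b) in zip(BASIC_COLOUR_NAMES, np.asarray(table)):
            fh.write(f"{name}\t{r}\t{g}\t{b}\n")


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB uint8 image, scaled to [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        return (arr.astype(float) / 255.0) @ _LUMA_WEIGHTS
    return arr.astype(float) / 255.0


def _as_pixels(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB image, got shape {arr.shape}")
    return arr.reshape(-1, 3)


def _prototypes_lab(prototype_table: np.ndarray) -> np.ndarray:
    table = np.asarray(prototype_table, dtype=np.uint8)
    if table.shape != (N_COLOUR_BINS, 3):
        raise ValueError("prototype table must have shape (11, 3)")
    return skcolor.rgb2lab(table[None, :, :] / 255.0)[0]


def classify_basic_colour(
    rgb: np.ndarray, prototype_table: np.ndarray = DEFAULT_COLOUR_PROTOTYPES
) -> int:
    """Index of the Basic Colour region containing an RGB triple.

    Nearest prototype in CIELAB, a perceptually uniform space, so
    Euclidean distance approximates perceived colour difference.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,) or (rgb < 0).any() or (rgb > 255).any():
        raise ValueError("rgb must be a triple in [0, 255]^3")
    lab = skcolor.rgb2lab(rgb[None, None, :] / 255.0)[0, 0]
    proto = _prototypes_lab(prototype_table)
    return int(np.argmin(((proto - lab) ** 2).sum(axis=1)))


def colour_class_map(
    image: np.ndarray, prototype_table: np.ndarray = DEFAULT_COLOUR_PROTOTYPES
) -> np.ndarray:
    """Per-pixel Basic-Colour indices (H×W int array)."""
    arr = np.asarray(image)
    _as_pixels(arr)
    lab = skcolor.rgb2lab(arr / 255.0)
    proto = _prototypes_lab(prototype_table)
    d2 = ((lab[..., None, :] - proto) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=-1)


def colour_histogram(
    image: np.ndarray, prototype_table: np.ndarray = DEFAULT_COLOUR_PROTOTYPES
) -> np.ndarray:
    """Unit-sum 11-bin histogram of per-pixel Basic-Colour classes."""
    classes = colour_class_map(image, prototype_table)
    counts = np.bincount(classes.ravel(), minlength=N_COLOUR_BINS)
    return counts / counts.sum()


def gaussian_jet(gray: np.ndarray, sigma: float, truncate: float = 4.0) -> JetField:
    """Six derivative-of-Gaussian responses of a grayscale image.

    Convolves with the Gaussian and its derivatives up to second order
    using reflect padding.  Raises if the image is smaller than the
    truncated kernel support.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("gaussian_jet expects a 2-D grayscale image")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = int(truncate * sigma + 0.5)
    if min(gray.shape) < 2 * radius + 1:
        raise ValueError(
            f"image of shape {gray.shape} smaller than the truncated "
            f"Gaussian kernel (support {2 * radius + 1} px at sigma={sigma})"
        )

    def g(order_y: int, order_x: int) -> np.ndarray:
        return ndimage.gaussian_filter(
            gray, sigma, order=(order_y, order_x), mode="reflect", truncate=truncate
        )

    return JetField(
        s=g(0, 0),
        sx=g(0, 1),
        sy=g(1, 0),
        sxx=g(0, 2),
        sxy=g(1, 1),
        syy=g(2, 0),
        sigma=float(sigma),
    )


def _orientation_bin(angle_deg: np.ndarray, width: float) -> np.ndarray:
    """Sector index of angles already shifted so bins start at 0°.

    Boundaries (exact multiples of ``width``) go to the lower bin,
    except 0° itself which starts bin 0.
    """
    idx = np.floor(angle_deg / width).astype(int)
    on_boundary = (angle_deg > 0) & (np.mod(angle_deg, width) == 0)
    return idx - on_boundary.astype(int)


def obif_class_map(jet: JetField, epsilon: float) -> np.ndarray:
    """Vectorised oBIF classification of every pixel of a jet field.

    The seven competing, scale-normalised scores are::

        flat        epsilon * s
        slope       2 * sigma * sqrt(s_x^2 + s_y^2)
        dark blob   lambda
        light blob  -lambda
        dark line   (gamma + lambda) / sqrt(2)
        light line  (gamma - lambda) / sqrt(2)
        saddle      gamma

    with ``lambda = sigma^2 (s_xx + s_yy)`` and
    ``gamma = sigma^2 sqrt((s_xx - s_yy)^2 + 4 s_xy^2)``.  The 1/sqrt(2)
    line normalisation makes a pure line profile (lambda = gamma) score
    higher as a line than as a blob or saddle, rather than tying.  The
    winner is the largest score; if all scores are zero the pixel is
    flat.
    """
    sigma = jet.sigma
    s, sx, sy = (np.asarray(a, dtype=float) for a in (jet.s, jet.sx, jet.sy))
    sxx, sxy, syy = (np.asarray(a, dtype=float) for a in (jet.sxx, jet.sxy, jet.syy))

    lam = sigma**2 * (sxx + syy)
    gam = sigma**2 * np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2)

    scores = np.stack(
        [
            epsilon * s,  # flat
            2.0 * sigma * np.hypot(sx, sy),  # slope
            -lam,  # light blob
            lam,  # dark blob
            (gam - lam) / np.sqrt(2.0),  # light line
            (gam + lam) / np.sqrt(2.0),  # dark line
            gam,  # saddle
        ],
        axis=-1,
    )
    winner = np.argmax(scores, axis=-1)  # ties -> lowest index; flat is first

    # slope orientation: gradient direction, 8 bins of 45° centred on 0°
    slope_deg = np.degrees(np.arctan2(sy, sx))
    shifted = np.mod(slope_deg + 22.5, 360.0)
    slope_bin = np.mod(_orientation_bin(shifted, 45.0), 8)

    # line/saddle orientation: direction along the feature, i.e.
    # perpendicular to the principal second-derivative direction;
    # 4 bins of 45° over [0°, 180°)
    principal_deg = 0.5 * np.degrees(np.arctan2(2.0 * sxy, sxx - syy))
    along_deg = np.mod(principal_deg + 90.0, 180.0)
    second_bin = np.mod(_orientation_bin(along_deg, 45.0), 4)

    classes = np.empty(np.shape(winner), dtype=int)
    classes[...] = OBIF_FLAT
    classes = np.where(winner == 1, OBIF_SLOPE_BASE + slope_bin, classes)
    classes = np.where(winner == 2, OBIF_LIGHT_BLOB, classes)
    classes = np.where(winner == 3, OBIF_DARK_BLOB, classes)
    classes = np.where(winner == 4, OBIF_LIGHT_LINE_BASE + second_bin, classes)
    classes = np.where(winner == 5, OBIF_DARK_LINE_BASE + second_bin, classes)
    classes = np.where(winner == 6, OBIF_SADDLE_BASE + second_bin, classes)
    return classes


def classify_obif(jet: JetField, config: ObifConfig) -> int:
    """oBIF class in {0..22} of a single pixel's jet responses."""
    values = [jet.s, jet.sx, jet.sy, jet.sxx, jet.sxy, jet.syy]
    if not np.isfinite(values).all():
        raise ValueError("jet values must be finite")
    return int(obif_class_map(jet, config.epsilon))


def texton_histogram(image: np.ndarray, config: ObifConfig | None = None) -> np.ndarray:
    """Unit-sum 529-bin histogram of (fine, coarse) oBIF texton pairs."""
    config = config or ObifConfig()
    gray = to_luminance(image)
    fine = obif_class_map(gaussian_jet(gray, config.sigma_fine), config.epsilon)
    coarse = obif_class_map(gaussian_jet(gray, config.sigma_coarse), config.epsilon)
    textons = N_OBIF_CLASSES * fine + coarse
    counts = np.bincount(textons.ravel(), minlength=N_TEXTONS)
    return counts / counts.sum()


def encode_image(
    image: np.ndarray,
    config: ObifConfig | None = None,
    prototype_table: np.ndarray = DEFAULT_COLOUR_PROTOTYPES,
) -> ImageEncoding:
    """Both histogram encodings of an RGB image."""
    return ImageEncoding(
        colour=colour_histogram(image, prototype_table),
        texton=texton_histogram(image, config),
    )
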
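"""Phosphene stimulus rendering.

Converts high-resolution grayscale face images into the low-resolution
"phosphene" stimuli a visual prosthesis would evoke, over a grid of
phosphene image quality (PIQ) levels.  A PIQ level is a pair (P, G):

* ``P`` — side length of the phosphene lattice (number of electrodes /
  light spots per axis): 16, 24, 32, 64 or 128.
* ``G`` — number of distinct brightness (grayscale) levels a phosphene
  can take: 2, 4, 6, 8 or 16.

The full grid has 5 x 5 = 25 levels; human psychophysics uses the 9-level
subset {16, 32, 64} x {2, 4, 8}.

Two render modes are supported:

* ``NGB`` (non-Gaussian-blurred) — each phosphene is a uniform square
  block, emulating optogenetic stimulation.
* ``GB`` (Gaussian-blurred) — each phosphene is a circular spot, maximally
  bright at its cell center and falling off as a truncated Gaussian,
  emulating electrical stimulation.

The processing chain for every stimulus is
``histogram_equalize -> downsample_nn(P) -> quantize_levels(G) -> render``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

CANVAS = 128

PIXEL_COUNTS = (16, 24, 32, 64, 128)
GRAY_LEVELS = (2, 4, 6, 8, 16)
HUMAN_PIXEL_COUNTS = (16, 32, 64)
HUMAN_GRAY_LEVELS = (2, 4, 8)

PhospheneMode = Literal["ngb", "gb"]
MODES: tuple[PhospheneMode, ...] = ("ngb", "gb")


@dataclass(frozen=True, order=True)
class PIQLevel:
    """Phosphene image quality level: lattice side P and gray depth G."""

    pixels: int
    grayscales: int

    def __post_init__(self) -> None:
        if self.pixels not in PIXEL_COUNTS:
            raise ValueError(f"pixel count {self.pixels} not in {PIXEL_COUNTS}")
        if self.grayscales not in GRAY_LEVELS:
            raise ValueError(f"grayscale depth {self.grayscales} not in {GRAY_LEVELS}")

    @property
    def label(self) -> str:
        return f"P{self.pixels}_G{self.grayscales}"


def piq_grid(subset: str = "full") -> list[PIQLevel]:
    """PIQ levels of the study grid.

    ``full`` is the 25-level model grid; ``human`` is the 9-level subset
    shown to human observers.
    """
    if subset == "full":
        ps, gs = PIXEL_COUNTS, GRAY_LEVELS
    elif subset == "human":
        ps, gs = HUMAN_PIXEL_COUNTS, HUMAN_GRAY_LEVELS
    else:
        raise ValueError(f"unknown PIQ grid subset: {subset!r}")
    return [PIQLevel(p, g) for p in ps for g in gs]


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check a grayscale raster: 2-D, integer dtype, intensities in [0, 255]."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"expected integer intensities, got dtype {img.dtype}")
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ValueError("intensities outside [0, 255]")
    return img


def histogram_equalize(img: np.ndarray) -> np.ndarray:
    """Spread intensities toward a uniform distribution.

    Maps each value v to round(255 * cdf(v)) where cdf is the empirical
    cumulative distribution of the input (the bin containing v included).
    The mapping is monotone non-decreasing.
    """
    img = validate_gray(img)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    lut = np.rint(255.0 * cdf).astype(np.uint8)
    return lut[img]


def downsample_nn(img: np.ndarray, p: int) -> np.ndarray:
    """Nearest-neighbor downsampling to a p x p lattice.

    Output pixel (i, j) samples the input at index
    (floor((i + 0.5) * H / p), floor((j + 0.5) * W / p)) — the pixel-center
    convention, symmetric about the image midlines.
    """
    img = validate_gray(img)
    h, w = img.shape
    if p > min(h, w):
        raise ValueError(f"target resolution {p} exceeds image side {min(h, w)}")
    rows = np.floor((np.arange(p) + 0.5) * h / p).astype(int)
    cols = np.floor((np.arange(p) + 0.5) * w / p).astype(int)
    return img[np.ix_(rows, cols)]


def quantize_levels(img: np.ndarray, g: int) -> np.ndarray:
    """Quantize to g gray levels.

    Bin edges are uniform on [0, 256): level index k = min(floor(v*g/256), g-1),
    displayed as round(k * 255 / (g - 1)) so outputs span 0..255 inclusive.
    Idempotent at fixed g.
    """
    img = validate_gray(img)
    if not 2 <= g <= 256:
        raise ValueError(f"grayscale depth must be in [2, 256], got {g}")
    v = np.arange(256)
    k = np.minimum(v * g // 256, g - 1)
    lut = np.rint(k * 255.0 / (g - 1)).astype(np.uint8)
    return lut[img]


def render_ngb(small: np.ndarray, canvas: int = CANVAS) -> np.ndarray:
    """Upscale a lattice image to square uniform blocks (bitmap phosphenes)."""
    small = validate_gray(small)
    p = small.shape[0]
    if p > canvas:
        raise ValueError(f"lattice side {p} exceeds canvas {canvas}")
    idx = np.arange(canvas) * p // canvas
    return small[np.ix_(idx, idx)]


def render_gb(small: np.ndarray, canvas: int = CANVAS, sigma_frac: float = 0.25) -> np.ndarray:
    """Render circular Gaussian phosphenes, one per lattice cell.

    Each cell of side c = canvas / P holds one phosphene centered in the
    cell: intensity q * exp(-r^2 / (2 sigma^2)) with sigma = sigma_frac * c,
    truncated to zero outside the inscribed circle r > c / 2.  The profile
    is normalized so the brightest sampled pixel of a cell equals the
    cell's quantized intensity q exactly.
    """
    small = validate_gray(small)
    p = small.shape[0]
    if p > canvas:
        raise ValueError(f"lattice side {p} exceeds canvas {canvas}")
    c = canvas / p
    sigma = sigma_frac * c

    coords = np.arange(canvas, dtype=float)
    cell = np.minimum((coords * p / canvas).astype(int), p - 1)
    # offset of each canvas pixel from its cell center, in pixels
    off = coords - ((cell + 0.5) * c - 0.5)
    # per-cell minimal |offset| along one axis (for peak normalization)
    min_abs = np.full(p, np.inf)
    np.minimum.at(min_abs, cell, np.abs(off))

    gauss_1d = np.exp(-(off**2) / (2.0 * sigma**2))
    peak_1d = np.exp(-(min_abs**2) / (2.0 * sigma**2))

    profile = np.outer(gauss_1d, gauss_1d)
    norm = np.outer(peak_1d[cell], peak_1d[cell])
    r2 = off[:, None] ** 2 + off[None, :] ** 2
    support = r2 <= (c / 2.0) ** 2

    q = small[np.ix_(cell, cell)].astype(float)
    out = q * profile / norm * support
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def phosphenize(
    img: np.ndarray,
    piq: PIQLevel,
    mode: PhospheneMode = "ngb",
    canvas: int = CANVAS,
    sigma_frac: float = 0.25,
) -> np.ndarray:
    """Full stimulus chain: equalize, downsample, quantize, render.

    Returns a canvas x canvas uint8 stimulus in the requested mode.
    """
    if mode not in MODES:
        raise ValueError(f"unknown phosphene mode {mode!r}; expected one of {MODES}")
    eq = histogram_equalize(img)
    small = downsample_nn(eq, piq.pixels)
    quant = quantize_levels(small, piq.grayscales)
    if mode == "ngb":
        return render_ngb(quant, canvas)
    return render_gb(quant, canvas, sigma_frac=sigma_frac)
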
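"""Synthetic nucleus images and γ-H2AX focus detection.

The synthesizer emulates a widefield fluorescence image of one nucleus:
an elliptical nucleus region, foci placed uniformly at random over it (focus
positions after X-ray irradiation are spatially random), each rendered as an
isotropic Gaussian blob whose footprint above a reference intensity level has
a prescribed area, plus Gaussian read noise.  Integrated focus areas follow a
(shifted) exponential law, the shape seen in measured focus-area frequency
distributions.

Detection mirrors the standard ImageJ-style chain: binarization (Otsu within
the nucleus mask, or a fixed level), 8-connected component labeling, small
component rejection, then per-component centroid and area in μm².

Pixel convention: origin at the top-left, x to the right (columns), y down
(rows), pixel centers at integer indices; physical coordinates are
``pixel_index * pixel_size`` in μm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigError, DataError
from .histogram import Histogram1D

PIXEL_SIZE_UM = 0.1
MIN_PIXELS = 4
#: intensity level defining the nominal footprint of a synthetic focus
REFERENCE_LEVEL = 100.0


@dataclass
class NucleusImage:
    """A grayscale nucleus image with its pixel size and nucleus mask."""

    pixels: np.ndarray  # 2-D float intensities, >= 0
    pixel_size: float  # um / pixel
    mask: np.ndarray  # boolean, same shape

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.mask.shape != self.pixels.shape:
            raise DataError("mask shape must match the pixel grid")

    def save(self, path: str | Path) -> None:
        """Write a 16-bit TIFF plus a JSON sidecar with pixel size and mask bbox."""
        path = Path(path)
        arr = np.clip(self.pixels, 0, None)
        scale = 65535.0 / arr.max() if arr.max() > 0 else 1.0
        tifffile.imwrite(path, (arr * scale).astype(np.uint16))
        meta = {
            "pixel_size_um": self.pixel_size,
            "intensity_scale": scale,
            "mask_rows": [int(i) for i in np.nonzero(self.mask.any(axis=1))[0][[0, -1]]]
            if self.mask.any()
            else [],
        }
        path.with_suffix(".json").write_text(json.dumps(meta))


@dataclass(frozen=True)
class FocusRecord:
    """One detected focus: centroid (x, y) in μm, area in μm², pixel count."""

    centroid: tuple[float, float]
    area: float
    pixel_count: int


@dataclass
class FociGroundTruth:
    """Generative parameters of synthesized foci."""

    centers_um: list[tuple[float, float]] = field(default_factory=list)
    integrated_intensities: list[float] = field(default_factory=list)
    nominal_areas_um2: list[float] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)


def elliptical_mask(shape: tuple[int, int], semi_axes_px: tuple[float, float]) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ay, ax = semi_axes_px
    return ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0


def synthesize_nucleus_image(
    n_foci: int,
    area_rate: float = 3.3,
    psf_sigma: float = 0.15,
    noise_sd: float = 2.0,
    pixel_size: float = PIXEL_SIZE_UM,
    seed: int | np.random.Generator = 0,
    *,
    area_offset: float = 0.05,
    nucleus_semi_axes_um: tuple[float, float] = (7.0, 5.0),
    margin_um: float = 1.0,
    areas_um2=None,
    centers_um=None,
) -> tuple[NucleusImage, FociGroundTruth]:
    """Render a synthetic nucleus with ground-truth foci.

    Parameters
    ----------
    n_foci : number of foci to place.
    area_rate : rate (1/μm²) of the exponential law for nominal focus areas;
        the drawn area is ``area_offset + Exp(area_rate)``.  The offset keeps
        foci above the pixelation floor, mimicking the minimum resolvable
        focus size.
    psf_sigma : Gaussian blob sigma in μm (point-spread width).
    noise_sd : standard deviation of additive Gaussian read noise, in the
        same intensity units as the reference level (100).
    areas_um2, centers_um : optional explicit areas/centers overriding the
        random draws (lengths must equal ``n_foci``).

    Each blob's peak amplitude is chosen so that its footprint above the
    reference intensity level equals the nominal area:
    ``amp = level * exp(area / (2 pi sigma^2))``.  Foci centers are uniform
    over the elliptical nucleus mask.
    """
    if n_foci < 0:
        raise ConfigError(f"n_foci must be >= 0, got {n_foci}")
    for name, v in [
        ("area_rate", area_rate),
        ("psf_sigma", psf_sigma),
        ("pixel_size", pixel_size),
    ]:
        if v <= 0:
            raise ConfigError(f"{name} must be positive, got {v}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ax_um, ay_um = nucleus_semi_axes_um  # (x, y) order, matching centroids
    h = int(round(2 * (ay_um + margin_um) / pixel_size)) + 1
    w = int(round(2 * (ax_um + margin_um) / pixel_size)) + 1
    mask = elliptical_mask((h, w), (ay_um / pixel_size, ax_um / pixel_size))
    nucleus_area_um2 = mask.sum() * pixel_size**2

    if areas_um2 is None:
        areas = area_offset + rng.exponential(1.0 / area_rate, size=n_foci)
    else:
        areas = np.asarray(areas_um2, dtype=float)
        if len(areas) != n_foci:
            raise ConfigError("areas_um2 length must equal n_foci")
    if np.any(areas > nucleus_area_um2):
        raise ConfigError("focus area exceeds the nucleus area")

    if centers_um is None:
        centers = _uniform_over_mask(mask, n_foci, pixel_size, rng)
    else:
        centers = [tuple(c) for c in centers_um]
        if len(centers) != n_foci:
            raise ConfigError("centers_um length must equal n_foci")

    img = np.zeros((h, w), dtype=float)
    sig_px = psf_sigma / pixel_size
    truth = FociGroundTruth()
    for (cx_um, cy_um), area in zip(centers, areas):
        amp = REFERENCE_LEVEL * math.exp(area / (2 * math.pi * psf_sigma**2))
        cx, cy = cx_um / pixel_size, cy_um / pixel_size
        r_ext = math.sqrt(2 * sig_px**2 * math.log(max(amp / 0.01, 2.0)))
        y0, y1 = max(int(cy - r_ext), 0), min(int(cy + r_ext) + 2, h)
        x0, x1 = max(int(cx - r_ext), 0), min(int(cx + r_ext) + 2, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig_px**2)
        )
        truth.centers_um.append((cx_um, cy_um))
        truth.nominal_areas_um2.append(float(area))
        truth.integrated_intensities.append(float(amp * 2 * math.pi * sig_px**2))
        truth.labels.append("simple")
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return NucleusImage(pixels=img, pixel_size=pixel_size, mask=mask), truth


def _uniform_over_mask(
    mask: np.ndarray, n: int, pixel_size: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    rows, cols = np.nonzero(mask)
    idx = rng.integers(len(rows), size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return [
        ((cols[i] + jx) * pixel_size, (rows[i] + jy) * pixel_size)
        for i, (jx, jy) in zip(idx, jitter)
    ]


def detect_foci(
    image: NucleusImage,
    threshold: str | float = "otsu",
    min_pixels: int = MIN_PIXELS,
) -> list[FocusRecord]:
    """Binarize, label 8-connected components, and measure foci.

    ``threshold`` is either ``"otsu"`` (computed over pixels inside the
    nucleus mask) or an absolute intensity level.  Components with fewer than
    ``min_pixels`` pixels are discarded as noise.
    """
    if not image.mask.any():
        raise DataError("nucleus mask is empty")
    vals = image.pixels[image.mask]
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ConfigError(f"unknown threshold method {threshold!r}")
        if np.allclose(vals, vals[0]):
            return []  # flat image: nothing to segment
        level = float(threshold_otsu(vals))
    else:
        level = float(threshold)
    binary = (image.pixels > level) & image.mask
    labeled = label(binary, connectivity=2)
    records = []
    for region in regionprops(labeled):
        if region.area < min_pixels:
            continue
        cy, cx = region.centroid
        records.append(
            FocusRecord(
                centroid=(cx * image.pixel_size, cy * image.pixel_size),
                area=float(region.area * image.pixel_size**2),
                pixel_count=int(region.area),
            )
        )
    return records


def foci_area_histogram(records, bin_width: float = 0.1) -> Histogram1D:
    """Relative-frequency histogram of focus areas (μm²)."""
    if len(records) == 0:
        raise DataError("no focus records to histogram")
    areas = [r.area if isinstance(r, FocusRecord) else float(r) for r in records]
    return Histogram1D.from_samples(areas, bin_width=bin_width)


def mean_foci_per_nucleus(counts) -> float:
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise DataError("no per-nucleus counts supplied")
    return float(c.mean())
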
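"""Distance statistics for focus pairs inside a sampling circle.

When two points are dropped independently and uniformly in a disc of radius
r, their separation x has the closed-form density

    f(x, r) = (4x / pi r^2) * arccos(x / 2r) - (2x^2 / pi r^3) * sqrt(1 - x^2 / 4r^2)

on [0, 2r].  Measured focus-pair distances are compared to this law after a
pile-up correction: a microscope cannot resolve two circular foci whose
center separation is below the sum of their radii, so theoretical distances
shorter than that minimum are removed, with focus radii drawn from the
measured focus-area distribution (r_i = sqrt(area_i / pi)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ConfigError, DataError

CIRCLE_DIAMETER_UM = 5.0


def pair_distance_pdf(x, r: float):
    """Density of the distance between two uniform random points in a disc of
    radius ``r``, evaluated at ``x`` (scalar or array); 0 outside [0, 2r] by
    convention."""
    if r <= 0:
        raise ConfigError(f"disc radius must be positive, got {r}")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.zeros_like(x)
    ok = (x >= 0) & (x <= 2 * r)
    xv = x[ok]
    ratio = np.clip(xv / (2 * r), 0.0, 1.0)
    out[ok] = (4 * xv / (np.pi * r**2)) * np.arccos(ratio) - (
        2 * xv**2 / (np.pi * r**3)
    ) * np.sqrt(np.clip(1 - ratio**2, 0.0, None))
    return float(out[0]) if scalar else out


def sample_pair_distances(
    r: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Distances |P1 - P2| for n i.i.d. pairs of area-uniform points in the disc.

    Radii are drawn as r*sqrt(u) so the points are uniform over the disc area.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if r <= 0:
        raise ConfigError(f"disc radius must be positive, got {r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rad = r * np.sqrt(rng.random((2, n)))
    ang = 2 * np.pi * rng.random((2, n))
    x = rad * np.cos(ang)
    y = rad * np.sin(ang)
    return np.hypot(x[0] - x[1], y[0] - y[1])


class _PdfSampler:
    """Inverse-transform sampler for f(x, r) via a tabulated CDF."""

    def __init__(self, r: float, n_grid: int = 10_000) -> None:
        self.r = r
        self.x = np.linspace(0.0, 2 * r, n_grid)
        f = pair_distance_pdf(self.x, r)
        cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2 * np.diff(self.x))])
        self.cdf = cdf / cdf[-1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.interp(rng.random(n), self.cdf, self.x)


@dataclass
class CorrectedDistanceHistogram:
    """Pile-up-corrected distance histogram with rejection bookkeeping."""

    bin_edges: np.ndarray  # um
    frequencies: np.ndarray  # relative, sum to 1 when any pair accepted
    n_accepted: int
    n_rejected: int
    all_rejected: bool = False

    @property
    def n_sampled(self) -> int:
        return self.n_accepted + self.n_rejected


def pileup_correct(
    r: float,
    areas,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
    bins: int | np.ndarray = 50,
) -> CorrectedDistanceHistogram:
    """Monte Carlo pile-up correction of the theoretical distance law.

    For each of ``n`` draws: a distance x_j is sampled from f(x, r) by inverse
    transform; two focus areas are drawn at random (with replacement) from
    ``areas``; the minimum resolvable separation is x_min = r1 + r2 with
    r_i = sqrt(area_i / pi); x_j is rejected when x_j < x_min.  Accepted
    distances are histogrammed on ``bins`` over [0, 2r] and normalized.

    With all areas zero nothing is rejected and the histogram reproduces
    f(x, r); if every pair is rejected the (zero) histogram is returned with
    ``all_rejected`` set.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ConfigError("areas must be non-empty")
    if np.any(areas < 0):
        raise DataError("focus areas must be non-negative")
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sampler = _PdfSampler(r)
    x = sampler.sample(n, rng)
    i1 = rng.integers(len(areas), size=n)
    i2 = rng.integers(len(areas), size=n)
    x_min = np.sqrt(areas[i1] / np.pi) + np.sqrt(areas[i2] / np.pi)
    accepted = x >= x_min

    edges = (
        np.linspace(0.0, 2 * r, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    )
    counts, edges = np.histogram(x[accepted], bins=edges)
    n_acc = int(accepted.sum())
    freq = counts / n_acc if n_acc else counts.astype(float)
    return CorrectedDistanceHistogram(
        bin_edges=edges,
        frequencies=freq,
        n_accepted=n_acc,
        n_rejected=n - n_acc,
        all_rejected=n_acc == 0,
    )


def measure_foci_distances(
    foci,
    center: tuple[float, float] = (0.0, 0.0),
    diameter: float = CIRCLE_DIAMETER_UM,
) -> np.ndarray:
    """All pairwise centroid distances among foci inside the sampling circle.

    ``foci`` is a sequence of records with ``centroid`` attributes or of
    (x, y) pairs, in micrometers.  A focus is inside when its centroid lies
    within ``diameter / 2`` of ``center``.  Fewer than two in-circle foci give
    an empty result.
    """
    if diameter <= 0:
        raise ConfigError(f"diameter must be positive, got {diameter}")
    pts = np.array(
        [f.centroid if hasattr(f, "centroid") else tuple(f) for f in foci], dtype=float
    ).reshape(-1, 2)
    if len(pts) == 0:
        return np.empty(0)
    c = np.asarray(center, dtype=float)
    inside = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= diameter / 2.0
    pts = pts[inside]
    if len(pts) < 2:
        return np.empty(0)
    return pdist(pts)
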
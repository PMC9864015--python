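"""Nanodosimetric scoring of electron tracks.

Cluster size N_cl is the number of inelastic events (ionizations plus
excitations) inside one cubic sampling volume of 5.03 nm side — the scale of
a DSB site (~10 bp of DNA).  A linkage is an unordered pair of events within
3.4 nm, the presumed DSB precursor; the DSB yield is proportional to the
linkage count per unit deposited energy,

    Y_DSB = k_DSB * N_link / E_dep ,

with k_DSB a proportionality constant in keV/Gy/Da.  Sites are classified by
cluster size: assuming two events are required to induce a DSB and twelve
additional events on average per extra strand break, 2 <= N_cl < 14 is a
simple DSB, 14 <= N_cl < 26 a DSB+ (one extra strand break), 26 <= N_cl < 38
a DSB++; N_cl >= 38 is pooled with the complex classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError
from .track_sim import ElectronSpectrum, ElectronTrack, InelasticEvent

CUBE_SIDE_NM = 5.03
LINKAGE_RADIUS_NM = 3.4

#: half-open class boundaries on N_cl
CLASS_BOUNDS = (2, 14, 26, 38)


class ComplexityClass(enum.Enum):
    """DSB complexity classes on the cluster size N_cl (half-open intervals)."""

    NO_DSB = "no_dsb"  # N_cl < 2
    SIMPLE = "simple"  # 2 <= N_cl < 14
    DSB_PLUS = "dsb_plus"  # 14 <= N_cl < 26
    DSB_PLUS_PLUS = "dsb_plus_plus"  # 26 <= N_cl < 38
    HIGHER = "higher"  # N_cl >= 38

    @property
    def is_complex(self) -> bool:
        return self in (
            ComplexityClass.DSB_PLUS,
            ComplexityClass.DSB_PLUS_PLUS,
            ComplexityClass.HIGHER,
        )


@dataclass
class ClusterSizeDistribution:
    """Frequency of cluster sizes over a set of sampling cubes."""

    counts: dict[int, int]
    cube_side: float = CUBE_SIDE_NM
    n_cubes: int = 0
    empty_track: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise DataError("cluster-size frequencies must be >= 0")
        total = sum(self.counts.values())
        if self.n_cubes == 0:
            self.n_cubes = total
        elif total != self.n_cubes:
            raise DataError(
                f"frequencies sum to {total}, expected n_cubes = {self.n_cubes}"
            )

    def relative(self, min_size: int = 0) -> dict[int, float]:
        """Relative frequencies over cubes with N_cl >= min_size."""
        total = sum(v for k, v in self.counts.items() if k >= min_size)
        if total == 0:
            return {}
        return {k: v / total for k, v in sorted(self.counts.items()) if k >= min_size}

    @classmethod
    def merge(cls, dists: list["ClusterSizeDistribution"]) -> "ClusterSizeDistribution":
        """Pool several distributions scored with the same cube size."""
        if not dists:
            raise DataError("nothing to merge")
        side = dists[0].cube_side
        if any(d.cube_side != side for d in dists):
            raise DataError("cannot merge distributions with different cube sides")
        counts: dict[int, int] = {}
        for d in dists:
            for k, v in d.counts.items():
                counts[k] = counts.get(k, 0) + v
        return cls(counts=counts, cube_side=side)


@dataclass(frozen=True)
class LinkageResult:
    n_link: int
    radius: float
    e_dep: float  # eV

    def __post_init__(self) -> None:
        if self.n_link < 0 or self.radius <= 0:
            raise DataError("n_link must be >= 0 and radius > 0")


@dataclass(frozen=True)
class DSBYield:
    y_dsb: float
    k_dsb: float


def score_cluster_sizes(
    track: ElectronTrack,
    cube_side: float = CUBE_SIDE_NM,
    n_cubes: int = 1000,
    seed: int | np.random.Generator = 0,
    *,
    placement: str = "event",
    centers: np.ndarray | None = None,
) -> ClusterSizeDistribution:
    """Score inelastic events per randomly placed sampling cube.

    Cubes are axis-aligned with half-open bounds ``[o, o + side)`` per axis.
    Default placement anchors each cube to a uniformly chosen track event plus
    a uniform jitter in ``[-side/2, +side/2]^3`` about it, realizing random
    placement *along* the track; ``placement="bbox"`` instead draws cube
    centers uniformly over the track's bounding box (padded by one cube side)
    for sensitivity checks.

    An empty track yields an empty distribution flagged ``empty_track`` rather
    than an exception.
    """
    if cube_side <= 0:
        raise ConfigError(f"cube_side must be > 0, got {cube_side}")
    if n_cubes < 1:
        raise ConfigError(f"n_cubes must be >= 1, got {n_cubes}")
    pts = track.positions
    if len(pts) == 0:
        return ClusterSizeDistribution(counts={}, cube_side=cube_side, empty_track=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = cube_side / 2.0
    if centers is not None:
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        if len(centers) != n_cubes:
            raise ConfigError("explicit centers must have length n_cubes")
    elif placement == "event":
        anchors = pts[rng.integers(len(pts), size=n_cubes)]
        centers = anchors + rng.uniform(-half, half, size=(n_cubes, 3))
    elif placement == "bbox":
        lo = pts.min(axis=0) - cube_side
        hi = pts.max(axis=0) + cube_side
        centers = rng.uniform(lo, hi, size=(n_cubes, 3))
    else:
        raise ConfigError(f"unknown placement {placement!r}")
    origins = centers - half
    # half-open membership test per axis, vectorized over (cubes, events)
    inside = np.logical_and(
        pts[None, :, :] >= origins[:, None, :],
        pts[None, :, :] < origins[:, None, :] + cube_side,
    ).all(axis=2)
    per_cube = inside.sum(axis=1)
    sizes, freq = np.unique(per_cube, return_counts=True)
    return ClusterSizeDistribution(
        counts={int(s): int(f) for s, f in zip(sizes, freq)},
        cube_side=cube_side,
        n_cubes=n_cubes,
    )


def count_linkages(
    events: list[InelasticEvent] | np.ndarray, radius: float = LINKAGE_RADIUS_NM
) -> int:
    """Number of unordered event pairs separated by at most ``radius`` (nm).

    Uses a k-d tree; exactly equivalent to the O(n^2) pairwise test with a
    closed-ball criterion (distance <= radius).
    """
    if radius <= 0:
        raise ConfigError(f"radius must be > 0, got {radius}")
    if isinstance(events, np.ndarray):
        pts = events
    else:
        pts = np.array([ev.position for ev in events]) if events else np.empty((0, 3))
    if len(pts) < 2:
        return 0
    tree = cKDTree(pts)
    return len(tree.query_pairs(radius))


def linkage_result(track: ElectronTrack, radius: float = LINKAGE_RADIUS_NM) -> LinkageResult:
    return LinkageResult(
        n_link=count_linkages(track.events, radius), radius=radius, e_dep=track.e_dep
    )


def dsb_yield(n_link: int, e_dep_ev: float, k_dsb: float = 1.0) -> DSBYield:
    """DSB yield Y_DSB = k_DSB * N_link / E_dep, with E_dep converted to keV.

    Without a calibrated k_DSB (default 1.0) the yield is relative, not an
    absolute DSB/Gy/Da value.
    """
    if e_dep_ev <= 0:
        raise ConfigError(f"e_dep must be positive, got {e_dep_ev}")
    if k_dsb <= 0:
        raise ConfigError(f"k_dsb must be positive, got {k_dsb}")
    return DSBYield(y_dsb=k_dsb * n_link / (e_dep_ev / 1e3), k_dsb=k_dsb)


def classify_site(n_cl: int) -> ComplexityClass:
    """Map a cluster size to its complexity class (half-open boundaries)."""
    if n_cl < 0 or int(n_cl) != n_cl:
        raise ConfigError(f"cluster size must be a non-negative integer, got {n_cl}")
    b = CLASS_BOUNDS
    if n_cl < b[0]:
        return ComplexityClass.NO_DSB
    if n_cl < b[1]:
        return ComplexityClass.SIMPLE
    if n_cl < b[2]:
        return ComplexityClass.DSB_PLUS
    if n_cl < b[3]:
        return ComplexityClass.DSB_PLUS_PLUS
    return ComplexityClass.HIGHER


def complexity_fractions(
    dist: ClusterSizeDistribution,
) -> dict[ComplexityClass, float]:
    """Class fractions over DSB-bearing cubes (N_cl >= 2), summing to 1.

    Returns an empty dict when no cube holds a DSB.
    """
    totals = {c: 0 for c in ComplexityClass if c is not ComplexityClass.NO_DSB}
    n = 0
    for size, freq in dist.counts.items():
        cls = classify_site(size)
        if cls is ComplexityClass.NO_DSB:
            continue
        totals[cls] += freq
        n += freq
    if n == 0:
        return {}
    return {c: v / n for c, v in totals.items()}


def complex_fraction(dist: ClusterSizeDistribution) -> float:
    """Share of DSB-bearing cubes that are complex (DSB+ and beyond)."""
    fr = complexity_fractions(dist)
    if not fr:
        raise DataError("no DSB-bearing cubes in distribution")
    return sum(v for c, v in fr.items() if c.is_complex)


def spectrum_average(
    values_by_energy: dict[float, float], spectrum: ElectronSpectrum
) -> float:
    """Spectrum-weighted mean of a per-energy quantity,

        Ȳ = ∫ Y(E) f(E) dE ,

    evaluated by trapezoid quadrature on the spectrum's bin grid after
    normalizing f to unit integral; values are linearly interpolated onto the
    grid.  For a single-bin (delta) spectrum the value at that energy is
    returned.
    """
    e_val = np.array(sorted(values_by_energy))
    v_val = np.array([values_by_energy[e] for e in e_val])
    e_spec = spectrum.energy_kev
    order = np.argsort(e_spec)
    e_spec, w = e_spec[order], spectrum.weights[order]
    if e_spec[-1] < e_val[0] or e_spec[0] > e_val[-1]:
        raise ConfigError(
            "spectrum support does not overlap the energies of the supplied values"
        )
    v_on_grid = np.interp(e_spec, e_val, v_val)
    if len(e_spec) == 1:
        return float(v_on_grid[0])
    norm = np.trapezoid(w, e_spec)
    if norm <= 0:
        # degenerate grid (all weight in coincident bins): fall back to weighted mean
        return float(np.sum(w * v_on_grid) / np.sum(w))
    return float(np.trapezoid(w * v_on_grid, e_spec) / norm)
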
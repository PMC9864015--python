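"""Event-by-event electron transport in liquid water.

Simulates electron tracks interaction by interaction — elastic scattering,
ionization and excitation — down to a 1.0 eV cut-off, recording the position
and local energy deposit of every inelastic event.  The event lists are the
raw material for nanodosimetric cluster-size and linkage scoring.

The default cross-section table is a deliberately simplified parameterization
of electron interactions in liquid water (tabulated inverse mean free paths
with log-log interpolation, an effective ionization binding energy, discrete
excitation levels and a heavy-tailed secondary-electron energy distribution).
It is shipped as package data and fully swappable: the scientific contract of
this module is structurally correct transport (free flight, channel choice,
energy bookkeeping, cascades), not agreement with any particular published
cross-section set.

Coordinates are right-handed Cartesian in nanometers; the primary starts at
the origin moving along +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

CUTOFF_EV = 1.0

KIND_IONIZATION = "ionization"
KIND_EXCITATION = "excitation"


@dataclass(frozen=True)
class InelasticEvent:
    """One ionization or excitation: collision point (nm) and local deposit (eV)."""

    position: tuple[float, float, float]
    kind: str
    energy_deposit: float

    def __post_init__(self) -> None:
        if self.energy_deposit <= 0:
            raise ValueError("energy_deposit must be positive")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("position components must be finite")
        if self.kind not in (KIND_IONIZATION, KIND_EXCITATION):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class ElectronTrack:
    """A single electron history: ordered inelastic events plus total deposit.

    ``e_dep`` includes the sub-cut-off residual energy of every terminated
    electron, so in an infinite absorbing medium with secondary transport
    enabled ``e_dep`` equals ``primary_energy``.
    """

    primary_energy: float  # eV
    events: list[InelasticEvent] = field(default_factory=list)
    e_dep: float = 0.0  # eV

    @property
    def positions(self) -> np.ndarray:
        """(n_events, 3) array of event positions in nm."""
        if not self.events:
            return np.empty((0, 3))
        return np.array([ev.position for ev in self.events])

    @property
    def deposits(self) -> np.ndarray:
        return np.array([ev.energy_deposit for ev in self.events])


class CrossSectionTable:
    """Tabulated inverse mean free paths plus loss and angular samplers.

    Inverse mean free paths (nm^-1) for the elastic, ionization and excitation
    channels are interpolated log-log between grid points; below the first
    grid energy at which a channel is non-zero the channel is closed.

    Loss model:

    * ionization — the primary pays an effective binding energy ``binding_ev``
      (deposited locally) plus the kinetic energy of a secondary electron
      drawn from ``p(W) ∝ (W + a)^-2`` on ``[0, (E - B)/2]``;
    * excitation — one of the discrete ``excitation_levels_ev`` below the
      current energy, chosen uniformly, deposited locally.

    Angular model: screened-Rutherford-style elastic deflection with an
    energy-dependent screening parameter; small forward-biased Gaussian
    deflection for inelastic collisions.  Both are overridable by subclassing.
    """

    def __init__(
        self,
        energy_ev: Sequence[float],
        imfp_elastic: Sequence[float],
        imfp_ionization: Sequence[float],
        imfp_excitation: Sequence[float],
        *,
        binding_ev: float = 12.6,
        secondary_shape_ev: float = 15.0,
        excitation_levels_ev: Sequence[float] = (7.4, 8.4, 10.1, 11.3, 12.6, 14.1),
        screening_ev: float = 300.0,
    ) -> None:
        e = np.asarray(energy_ev, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ConfigError("energy grid must be strictly increasing, length >= 2")
        channels = {
            "elastic": np.asarray(imfp_elastic, dtype=float),
            "ionization": np.asarray(imfp_ionization, dtype=float),
            "excitation": np.asarray(imfp_excitation, dtype=float),
        }
        for name, v in channels.items():
            if v.shape != e.shape:
                raise ConfigError(f"{name} column length does not match energy grid")
            if np.any(v < 0):
                raise ConfigError(f"{name} inverse mean free paths must be >= 0")
        self.energy_ev = e
        self._imfp = channels
        self.binding_ev = float(binding_ev)
        self.secondary_shape_ev = float(secondary_shape_ev)
        self.excitation_levels_ev = np.sort(np.asarray(excitation_levels_ev, float))
        self.screening_ev = float(screening_ev)
        # per-channel threshold: first grid energy with a positive value
        self._threshold = {}
        for name, v in channels.items():
            pos = np.nonzero(v > 0)[0]
            self._threshold[name] = e[pos[0]] if len(pos) else np.inf

    # -- lookup ------------------------------------------------------------

    def imfp(self, energy_ev: float, channel: str) -> float:
        """Inverse mean free path (nm^-1) of one channel, log-log interpolated."""
        v = self._imfp[channel]
        if energy_ev < self._threshold[channel]:
            return 0.0
        e = self.energy_ev
        if energy_ev >= e[-1]:
            return float(v[-1])
        mask = v > 0
        return float(
            np.exp(np.interp(np.log(energy_ev), np.log(e[mask]), np.log(v[mask])))
        )

    def total_imfp(self, energy_ev: float) -> float:
        return sum(self.imfp(energy_ev, c) for c in ("elastic", "ionization", "excitation"))

    def inelastic_imfp(self, energy_ev: float) -> float:
        return self.imfp(energy_ev, KIND_IONIZATION) + self.imfp(energy_ev, KIND_EXCITATION)

    @property
    def e_min(self) -> float:
        return float(self.energy_ev[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_ev[-1])

    @property
    def inelastic_threshold_ev(self) -> float:
        """Lowest energy at which any inelastic channel is open."""
        return min(self._threshold[KIND_IONIZATION], self._threshold[KIND_EXCITATION])

    def scaled(self, factor: float) -> "CrossSectionTable":
        """Copy with all inelastic inverse mean free paths multiplied by ``factor``."""
        return CrossSectionTable(
            self.energy_ev,
            self._imfp["elastic"],
            self._imfp["ionization"] * factor,
            self._imfp["excitation"] * factor,
            binding_ev=self.binding_ev,
            secondary_shape_ev=self.secondary_shape_ev,
            excitation_levels_ev=self.excitation_levels_ev,
            screening_ev=self.screening_ev,
        )

    # -- samplers ----------------------------------------------------------

    def sample_ionization(self, energy_ev: float, rng: np.random.Generator) -> tuple[float, float]:
        """Return (local deposit, secondary kinetic energy) for an ionization at E."""
        b = self.binding_ev
        w_max = max((energy_ev - b) / 2.0, 0.0)
        a = self.secondary_shape_ev
        if w_max <= 0:
            return b, 0.0
        # inverse CDF of p(W) ∝ (W + a)^-2 truncated to [0, w_max]
        u = rng.random()
        inv = 1.0 / a - u * (1.0 / a - 1.0 / (w_max + a))
        w = 1.0 / inv - a
        return b, float(min(max(w, 0.0), w_max))

    def sample_excitation(self, energy_ev: float, rng: np.random.Generator) -> float:
        """Return the excitation energy (deposited locally)."""
        accessible = self.excitation_levels_ev[self.excitation_levels_ev <= energy_ev]
        if len(accessible) == 0:
            # open channel but no accessible discrete level: pay the lowest level,
            # clamped to the remaining energy
            return float(min(self.excitation_levels_ev[0], energy_ev))
        return float(accessible[rng.integers(len(accessible))])

    def sample_elastic_mu(self, energy_ev: float, rng: np.random.Generator) -> float:
        """cos(theta) for elastic scattering, screened-Rutherford-like."""
        eta = self.screening_ev / max(energy_ev, 1e-12)
        u = rng.random()
        mu = 1.0 - 2.0 * eta * u / (1.0 + eta - u)
        return float(np.clip(mu, -1.0, 1.0))

    def sample_inelastic_mu(self, energy_ev: float, loss_ev: float, rng: np.random.Generator) -> float:
        """cos(theta) after an inelastic collision: forward-biased small deflection."""
        sigma = math.sqrt(min(loss_ev / max(energy_ev, loss_ev), 1.0)) * 0.3
        theta = abs(rng.normal(0.0, sigma))
        return float(math.cos(min(theta, math.pi)))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CrossSectionTable":
        df = pd.read_csv(path)
        required = {"energy_ev", "imfp_elastic", "imfp_ionization", "imfp_excitation"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"cross-section file {path} missing columns: {sorted(missing)}")
        return cls(
            df["energy_ev"].to_numpy(),
            df["imfp_elastic"].to_numpy(),
            df["imfp_ionization"].to_numpy(),
            df["imfp_excitation"].to_numpy(),
            **kwargs,
        )


def default_xsec() -> CrossSectionTable:
    """The bundled simplified liquid-water cross-section table."""
    with resources.as_file(
        resources.files("focitrack.data").joinpath("default_xsec.csv")
    ) as p:
        return CrossSectionTable.from_csv(p)


@dataclass(frozen=True)
class ElectronSpectrum:
    """Secondary-electron energy spectrum: bin energies (keV) and normalized weights."""

    energy_kev: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_arrays(cls, energy_kev, weights) -> "ElectronSpectrum":
        e = np.asarray(energy_kev, dtype=float)
        w = np.asarray(weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or len(e) == 0:
            raise DataError("spectrum requires matching 1-D energy and weight arrays")
        if np.any(w < 0):
            raise DataError("spectrum weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise DataError("spectrum must contain at least one positive weight")
        return cls(e, w / total)

    def sample_energies_ev(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.energy_kev), size=n, p=self.weights)
        return self.energy_kev[idx] * 1e3


def load_spectrum(path: str | Path) -> ElectronSpectrum:
    """Read a two-column spectrum table (energy_kev, weight) and normalize it.

    Raises :class:`DataError` with a line number for non-numeric or negative
    rows, and for empty files.
    """
    path = Path(path)
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = lines[0].strip().split(",")
        if first and not _is_number(first[0]):
            start = 1  # header
    for i, line in enumerate(lines[start:], start=start + 1):
        line = line.strip()
        if not line:
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
        if len(parts) < 2 or not all(_is_number(p) for p in parts[:2]):
            raise DataError(f"{path}:{i}: expected two numeric columns, got {line!r}")
        e, w = float(parts[0]), float(parts[1])
        if w < 0:
            raise DataError(f"{path}:{i}: negative weight {w}")
        rows.append((e, w))
    if not rows:
        raise DataError(f"{path}: empty spectrum file")
    arr = np.array(rows)
    return ElectronSpectrum.from_arrays(arr[:, 0], arr[:, 1])


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _rotate(direction: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """Rotate a unit vector by polar angle acos(mu) and azimuth phi."""
    st = math.sqrt(max(1.0 - mu * mu, 0.0))
    dx, dy, dz = direction
    if abs(dz) > 0.99999:
        new = np.array([st * math.cos(phi), st * math.sin(phi), mu * np.sign(dz)])
    else:
        denom = math.sqrt(1.0 - dz * dz)
        new = np.array(
            [
                mu * dx + st * (dx * dz * math.cos(phi) - dy * math.sin(phi)) / denom,
                mu * dy + st * (dy * dz * math.cos(phi) + dx * math.sin(phi)) / denom,
                mu * dz - st * denom * math.cos(phi),
            ]
        )
    return new / np.linalg.norm(new)


def simulate_track(
    primary_energy: float,
    xsec: CrossSectionTable | None = None,
    seed: int | np.random.Generator = 0,
    *,
    transport_secondaries: bool = True,
    cutoff_ev: float = CUTOFF_EV,
) -> ElectronTrack:
    """Simulate one electron history event by event.

    Free-flight lengths are exponential with the total inverse mean free path;
    the channel is chosen proportionally to the partial inverse mean free
    paths.  Transport of an electron stops when its kinetic energy falls below
    ``cutoff_ev`` (default 1.0 eV) or below the lowest open inelastic channel,
    at which point its residual energy is folded into ``e_dep``.  Ionizations
    spawn secondary electrons that are transported through the same loop when
    ``transport_secondaries`` is enabled (the default), so the cascade is
    followed to full depth.

    Identical ``(primary_energy, xsec, seed)`` yield identical tracks.
    """
    if primary_energy <= 0:
        raise ConfigError(f"primary energy must be positive, got {primary_energy}")
    if xsec is None:
        xsec = default_xsec()
    if primary_energy > xsec.e_max:
        raise ConfigError(
            f"cross-section table covers up to {xsec.e_max} eV; "
            f"requested {primary_energy} eV"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    track = ElectronTrack(primary_energy=float(primary_energy))
    # LIFO stack of (energy, position, direction)
    stack = [(float(primary_energy), np.zeros(3), np.array([0.0, 0.0, 1.0]))]
    while stack:
        energy, pos, direction = stack.pop()
        while True:
            if energy < cutoff_ev or energy < xsec.inelastic_threshold_ev:
                track.e_dep += energy
                break
            lam_el = xsec.imfp(energy, "elastic")
            lam_ion = xsec.imfp(energy, KIND_IONIZATION)
            lam_exc = xsec.imfp(energy, KIND_EXCITATION)
            lam_tot = lam_el + lam_ion + lam_exc
            if lam_tot <= 0:
                track.e_dep += energy
                break
            step = -math.log(rng.random()) / lam_tot
            pos = pos + step * direction
            u = rng.random() * lam_tot
            phi = 2.0 * math.pi * rng.random()
            if u < lam_el:
                mu = xsec.sample_elastic_mu(energy, rng)
                direction = _rotate(direction, mu, phi)
            elif u < lam_el + lam_ion and energy > xsec.binding_ev:
                deposit, w_sec = xsec.sample_ionization(energy, rng)
                track.events.append(
                    InelasticEvent(tuple(pos), KIND_IONIZATION, deposit)
                )
                track.e_dep += deposit
                energy -= deposit + w_sec
                if w_sec > 0:
                    if transport_secondaries and w_sec >= cutoff_ev:
                        sec_dir = _random_unit(rng)
                        stack.append((w_sec, pos.copy(), sec_dir))
                    else:
                        track.e_dep += w_sec
                mu = xsec.sample_inelastic_mu(energy + deposit + w_sec, deposit + w_sec, rng)
                direction = _rotate(direction, mu, phi)
            else:
                loss = xsec.sample_excitation(energy, rng)
                loss = min(loss, energy)
                if loss > 0:
                    track.events.append(
                        InelasticEvent(tuple(pos), KIND_EXCITATION, loss)
                    )
                    track.e_dep += loss
                    energy -= loss
                mu = xsec.sample_inelastic_mu(energy + loss, loss, rng)
                direction = _rotate(direction, mu, phi)
    # guard against floating-point accumulation pushing past the budget
    track.e_dep = min(track.e_dep, track.primary_energy)
    return track


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    mu = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    st = math.sqrt(1.0 - mu * mu)
    return np.array([st * math.cos(phi), st * math.sin(phi), mu])


def simulate_spectrum_tracks(
    spectrum: ElectronSpectrum,
    n_tracks: int,
    xsec: CrossSectionTable | None = None,
    seed: int = 0,
    *,
    transport_secondaries: bool = True,
) -> list[ElectronTrack]:
    """Simulate ``n_tracks`` histories with primary energies drawn i.i.d. from
    the normalized spectrum.

    Each track runs on its own deterministic sub-stream (spawned from ``seed``
    by track index), so the result is reproducible and independent of
    evaluation order.
    """
    if n_tracks < 1:
        raise ConfigError(f"n_tracks must be >= 1, got {n_tracks}")
    if xsec is None:
        xsec = default_xsec()
    root = np.random.SeedSequence(seed)
    energy_rng = np.random.default_rng(root.spawn(1)[0])
    energies = spectrum.sample_energies_ev(n_tracks, energy_rng)
    tracks = []
    for i, e in enumerate(energies):
        sub = np.random.default_rng(np.random.SeedSequence([seed, i]))
        tracks.append(
            simulate_track(
                float(e), xsec, sub, transport_secondaries=transport_secondaries
            )
        )
    return tracks
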
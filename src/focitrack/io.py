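"""Configuration, CSV schemas, and seed management.

All on-disk tables are UTF-8 CSV with '.' decimal separators regardless of
locale.  Schemas:

* tracks — one row per inelastic event: ``track_id, event_index, x_nm, y_nm,
  z_nm, kind, edep_ev``; a sidecar ``<name>.meta.json`` preserves per-track
  primary energies and total deposits so a written track set reads back
  losslessly (without the sidecar, ``e_dep`` and ``primary_energy`` fall back
  to the per-event deposit sum).
* foci — ``focus_id, x_um, y_um, area_um2, pixel_count``.
* histograms — ``bin_lo, bin_hi, frequency``.
* spectra — ``energy_kev, weight``.

One global seed fans out to per-stage seeds through a deterministic
derivation (SeedSequence over the global seed and a stage-name hash), so any
stage can be re-run in isolation and reproduce its stream.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError, DataError
from .histogram import Histogram1D
from .track_sim import (
    CUTOFF_EV,
    ElectronTrack,
    InelasticEvent,
)
from .foci_analysis import FocusRecord

TRACK_COLUMNS = ["track_id", "event_index", "x_nm", "y_nm", "z_nm", "kind", "edep_ev"]
FOCI_COLUMNS = ["focus_id", "x_um", "y_um", "area_um2", "pixel_count"]


# ---------------------------------------------------------------------------
# configuration


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulationConfig(_Section):
    energy_kev: Optional[float] = 10.0
    spectrum: Optional[str] = None  # path to a spectrum CSV; overrides energy_kev
    n_tracks: int = 50
    transport_secondaries: bool = True
    cutoff_ev: float = CUTOFF_EV
    xsec: Optional[str] = None  # path to a cross-section CSV; default table if unset
    seed: Optional[int] = None

    @field_validator("n_tracks")
    @classmethod
    def _pos_tracks(cls, v):
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @field_validator("energy_kev", "cutoff_ev")
    @classmethod
    def _pos(cls, v):
        if v is not None and v <= 0:
            raise ValueError("must be positive")
        return v


class ScoringConfig(_Section):
    cube_side: float = 5.03  # nm
    n_cubes: int = 2000  # per track
    link_radius: float = 3.4  # nm
    k_dsb: float = 1.0  # keV/Gy/Da; uncalibrated default -> relative yields
    min_events: int = 2
    placement: Literal["event", "bbox"] = "event"
    seed: Optional[int] = None

    @field_validator("cube_side", "link_radius", "k_dsb")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class ImagingConfig(_Section):
    n_nuclei: int = 10
    n_foci: int = 40
    area_rate: float = 3.3  # 1/um^2
    area_offset: float = 0.05  # um^2
    psf_sigma: float = 0.15  # um
    noise_sd: float = 2.0
    pixel_size: float = 0.1  # um/pixel
    threshold: str = "fixed"  # "otsu" or "fixed" (the synthesis reference level)
    min_pixels: int = 4
    seed: Optional[int] = None

    @field_validator("area_rate", "psf_sigma", "pixel_size")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class CalibrationConfig(_Section):
    area_bin_width: float = 0.1  # um^2
    circle_diameter: float = 5.0  # um
    target_complex_fraction: Optional[float] = None  # default: from scored clusters
    seed: Optional[int] = None

    @field_validator("area_bin_width", "circle_diameter")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class RunConfig(_Section):
    seed: int = 0
    label: str = "synthetic"
    simulation: SimulationConfig = SimulationConfig()
    scoring: ScoringConfig = ScoringConfig()
    imaging: ImagingConfig = ImagingConfig()
    calibration: CalibrationConfig = CalibrationConfig()

    def stage_seed(self, stage: str) -> int:
        explicit = getattr(getattr(self, stage), "seed", None)
        if explicit is not None:
            return explicit
        return derive_seed(self.seed, stage)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global_seed, crc32(stage))."""
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty file yields pure defaults.

    Unknown keys are rejected and schema violations are reported with their
    key paths.
    """
    if data is None:
        if path is None:
            return RunConfig()
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"] for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {locs}") from exc


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


# ---------------------------------------------------------------------------
# tracks


def write_tracks(tracks: list[ElectronTrack], path: str | Path) -> None:
    path = Path(path)
    rows = []
    meta = {"primary_energy_ev": [], "e_dep_ev": []}
    for tid, tr in enumerate(tracks):
        meta["primary_energy_ev"].append(tr.primary_energy)
        meta["e_dep_ev"].append(tr.e_dep)
        for i, ev in enumerate(tr.events):
            rows.append(
                {
                    "track_id": tid,
                    "event_index": i,
                    "x_nm": ev.position[0],
                    "y_nm": ev.position[1],
                    "z_nm": ev.position[2],
                    "kind": ev.kind,
                    "edep_ev": ev.energy_deposit,
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_tracks(path: str | Path) -> list[ElectronTrack]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"cannot parse track file {path}: {exc}") from exc
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    _check_numeric(df, [c for c in TRACK_COLUMNS if c != "kind"], path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    tracks: list[ElectronTrack] = []
    n_tracks = int(df["track_id"].max()) + 1 if len(df) else 0
    if meta is not None:
        n_tracks = max(n_tracks, len(meta["primary_energy_ev"]))
    grouped = dict(tuple(df.groupby("track_id"))) if len(df) else {}
    for tid in range(n_tracks):
        g = grouped.get(tid)
        events = []
        if g is not None:
            g = g.sort_values("event_index")
            events = [
                InelasticEvent(
                    (float(r.x_nm), float(r.y_nm), float(r.z_nm)),
                    str(r.kind),
                    float(r.edep_ev),
                )
                for r in g.itertuples()
            ]
        edep_sum = sum(ev.energy_deposit for ev in events)
        if meta is not None:
            primary = float(meta["primary_energy_ev"][tid])
            e_dep = float(meta["e_dep_ev"][tid])
        else:
            primary = e_dep = edep_sum
        tracks.append(ElectronTrack(primary_energy=primary, events=events, e_dep=e_dep))
    return tracks


# ---------------------------------------------------------------------------
# foci


def write_foci(records: list[FocusRecord], path: str | Path) -> None:
    rows = [
        {
            "focus_id": i,
            "x_um": r.centroid[0],
            "y_um": r.centroid[1],
            "area_um2": r.area,
            "pixel_count": r.pixel_count,
        }
        for i, r in enumerate(records)
    ]
    pd.DataFrame(rows, columns=FOCI_COLUMNS).to_csv(Path(path), index=False)


def read_foci(path: str | Path) -> list[FocusRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"cannot parse foci file {path}: {exc}") from exc
    missing = set(FOCI_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    _check_numeric(df, [c for c in FOCI_COLUMNS if c != "focus_id"], path)
    return [
        FocusRecord(
            centroid=(float(r.x_um), float(r.y_um)),
            area=float(r.area_um2),
            pixel_count=int(r.pixel_count),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# histograms


def write_histogram(hist: Histogram1D, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_lo": hist.bin_edges[:-1],
            "bin_hi": hist.bin_edges[1:],
            "frequency": hist.frequencies,
        }
    ).to_csv(Path(path), index=False)


def read_histogram(path: str | Path) -> Histogram1D:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"cannot parse histogram file {path}: {exc}") from exc
    missing = {"bin_lo", "bin_hi", "frequency"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    _check_numeric(df, ["bin_lo", "bin_hi", "frequency"], path)
    lo = df["bin_lo"].to_numpy(float)
    hi = df["bin_hi"].to_numpy(float)
    if len(lo) == 0 or not np.allclose(lo[1:], hi[:-1]):
        raise DataError(f"{path}: bins must be contiguous and non-empty")
    edges = np.concatenate([lo, hi[-1:]])
    return Histogram1D(bin_edges=edges, frequencies=df["frequency"].to_numpy(float))


def _check_numeric(df: pd.DataFrame, columns: list[str], path) -> None:
    for col in columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise DataError(f"{path}:{line}: non-numeric value in column {col!r}")
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2
            raise DataError(f"{path}:{line}: missing value in column {col!r}")
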
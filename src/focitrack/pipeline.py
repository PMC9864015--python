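"""End-to-end run: simulate → score → image → calibrate → classify → report.

The flow mirrors the analytical method this package implements:

1. simulate electron tracks (mono-energetic or spectrum-sampled);
2. score cluster sizes in 5.03 nm cubes pooled over tracks, count linkages
   within 3.4 nm, and compute the (relative) DSB yield;
3. synthesize nucleus images and detect γ-H2AX foci, building the focus-area
   frequency distribution;
4. fit the area↔events conversion coefficient by least squares;
5. determine the event threshold reproducing the simulation's complex-DSB
   fraction, convert it to an area threshold, classify the measured foci and
   estimate per-nucleus simple/complex yields.

Every intermediate artifact is written to the output directory and every
random stage draws its seed deterministically from the run seed, so a run is
reproducible from the config alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import (
    ComplexityReport,
    classify_foci,
    convert_threshold,
    determine_event_threshold,
    estimate_yields,
    fit_conversion_coefficient,
)
from .cluster_scoring import (
    ClusterSizeDistribution,
    complex_fraction,
    count_linkages,
    dsb_yield,
    score_cluster_sizes,
)
from .errors import FociTrackError
from .foci_analysis import (
    REFERENCE_LEVEL,
    detect_foci,
    foci_area_histogram,
    synthesize_nucleus_image,
)
from .io import (
    RunConfig,
    write_foci,
    write_histogram,
    write_tracks,
)
from .track_sim import (
    CrossSectionTable,
    default_xsec,
    load_spectrum,
    simulate_spectrum_tracks,
    simulate_track,
)

log = logging.getLogger("focitrack")


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> ComplexityReport:
    """Execute the full analysis chain and write all intermediates to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        tracks = _simulate(cfg)
        write_tracks(tracks, out / "tracks.csv")
        log.info("simulate: %d tracks, %d events total", len(tracks),
                 sum(len(t.events) for t in tracks))

        stage = "score"
        dist, n_link, e_dep = _score(cfg, tracks)
        write_histogram(_cluster_histogram(dist), out / "cluster_sizes.csv")
        y = dsb_yield(n_link, e_dep, cfg.scoring.k_dsb)
        sim_complex = complex_fraction(dist)
        log.info("score: n_link=%d, e_dep=%.1f keV, complex fraction %.4f",
                 n_link, e_dep / 1e3, sim_complex)

        stage = "detect"
        areas, per_nucleus = _image_and_detect(cfg, out)
        area_hist = foci_area_histogram(areas, cfg.calibration.area_bin_width)
        write_histogram(area_hist, out / "foci_areas.csv")
        log.info("detect: %d foci over %d nuclei", len(areas), cfg.imaging.n_nuclei)

        stage = "calibrate"
        fit = fit_conversion_coefficient(area_hist, dist, cfg.scoring.min_events)
        target = (
            cfg.calibration.target_complex_fraction
            if cfg.calibration.target_complex_fraction is not None
            else sim_complex
        )
        event_threshold, achieved = determine_event_threshold(dist, target)
        area_threshold = convert_threshold(event_threshold, fit)

        stage = "classify"
        fractions = classify_foci(areas, area_threshold)
        yields = estimate_yields(float(np.mean(per_nucleus)), fractions)
    except FociTrackError as exc:
        raise type(exc)(f"stage {stage!r} failed in {out}: {exc}") from exc

    report = ComplexityReport(
        area_threshold_um2=area_threshold,
        event_threshold=event_threshold,
        fractions=fractions,
        yields_per_nucleus=yields,
        conversion={"c": fit.coefficient, "sd": fit.sd, "r2": fit.r_squared},
        source_label=cfg.label,
        provenance={
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seeds": {s: cfg.stage_seed(s) for s in
                      ("simulation", "scoring", "imaging", "calibration")},
            "n_tracks": len(tracks),
            "n_foci": len(areas),
            "y_dsb_relative": y.y_dsb,
            "simulated_complex_fraction": sim_complex,
            "achieved_complex_fraction": achieved,
        },
    )
    report.to_json(out / "report.json")
    return report


def _simulate(cfg: RunConfig):
    sim = cfg.simulation
    xsec = CrossSectionTable.from_csv(sim.xsec) if sim.xsec else default_xsec()
    seed = cfg.stage_seed("simulation")
    if sim.spectrum:
        spectrum = load_spectrum(sim.spectrum)
        return simulate_spectrum_tracks(
            spectrum, sim.n_tracks, xsec, seed,
            transport_secondaries=sim.transport_secondaries,
        )
    tracks = []
    for i in range(sim.n_tracks):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        tracks.append(
            simulate_track(
                sim.energy_kev * 1e3, xsec, rng,
                transport_secondaries=sim.transport_secondaries,
                cutoff_ev=sim.cutoff_ev,
            )
        )
    return tracks


def _score(cfg: RunConfig, tracks):
    sc = cfg.scoring
    seed = cfg.stage_seed("scoring")
    dists = []
    n_link = 0
    e_dep = 0.0
    for i, tr in enumerate(tracks):
        if not tr.events:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        dists.append(
            score_cluster_sizes(tr, sc.cube_side, sc.n_cubes, rng, placement=sc.placement)
        )
        n_link += count_linkages(tr.events, sc.link_radius)
        e_dep += tr.e_dep
    if not dists:
        raise FociTrackError("no track produced any inelastic event")
    return ClusterSizeDistribution.merge(dists), n_link, e_dep


def _image_and_detect(cfg: RunConfig, out: Path):
    im = cfg.imaging
    seed = cfg.stage_seed("imaging")
    areas = []
    per_nucleus = []
    threshold = REFERENCE_LEVEL if im.threshold == "fixed" else "otsu"
    for i in range(im.n_nuclei):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        image, _truth = synthesize_nucleus_image(
            im.n_foci,
            area_rate=im.area_rate,
            psf_sigma=im.psf_sigma,
            noise_sd=im.noise_sd,
            pixel_size=im.pixel_size,
            seed=rng,
            area_offset=im.area_offset,
        )
        records = detect_foci(image, threshold, im.min_pixels)
        per_nucleus.append(len(records))
        areas.extend(r.area for r in records)
        if i == 0:
            image.save(out / "nucleus_000.tif")
            write_foci(records, out / "foci_000.csv")
    return np.asarray(areas), per_nucleus


def _cluster_histogram(dist: ClusterSizeDistribution):
    from .histogram import Histogram1D

    n_max = max(dist.counts) if dist.counts else 0
    edges = np.arange(-0.5, n_max + 1.5)
    total = sum(dist.counts.values())
    freq = np.array([dist.counts.get(n, 0) / total for n in range(0, n_max + 1)])
    return Histogram1D(bin_edges=edges, frequencies=freq, n_samples=total)
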
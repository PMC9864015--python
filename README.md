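# focitrack

Quantifying DNA double-strand-break (DSB) complexity from γ-H2AX focus
images, by bridging nanometer-scale track-structure simulation and
micrometer-scale fluorescence microscopy.

## The problem

When cells are irradiated with photons, secondary electrons deposit energy in
clustered ionizations and excitations. A DSB arises where at least two such
events fall within ~10 bp (3.4 nm) of DNA; DSBs coupled with additional
strand breaks in the same stretch (*complex* DSBs: DSB+, DSB++) are the most
cytotoxic lesions. Microscopy sees none of this directly — it sees γ-H2AX
foci, μm-scale spots marking DSB sites. The question this package addresses:
**how can the complexity of the underlying nm-scale damage be read from the
μm-scale focus area?**

The method rests on one calibrated proportionality. Both the focus-area
frequency distribution and the simulated distribution of inelastic-event
counts per nanometric cube (*cluster size* N_cl, scored in
5.03 × 5.03 × 5.03 nm³ volumes along electron tracks) are close to
exponential, so a single conversion coefficient *c* (events per μm²)
superimposes them; *c* is determined by least squares on the binned relative
frequencies. In the reference calibration this coefficient is
13.2 ± 0.268 μm⁻². The cluster-size threshold separating simple from complex
DSBs — 2 ≤ N_cl < 14 simple, 14 ≤ N_cl < 26 DSB+, 26 ≤ N_cl < 38 DSB++ —
then converts into an area threshold T/c, and the complex fraction of any
focus sample is the share of foci at or above that area.

Supporting machinery, all implemented here:

- **track_sim** — event-by-event electron transport in liquid water down to
  a 1.0 eV cut-off, with a simplified, swappable cross-section table;
- **cluster_scoring** — cluster sizes in randomly placed cubes, linkages
  (event pairs within 3.4 nm), the DSB yield
  Y_DSB = k_DSB · N_link / E_dep, and spectrum averaging
  Ȳ = ∫ Y(E) f(E) dE;
- **geometry_stats** — the closed-form density of the distance between two
  uniform random points in a disc of radius r,
  f(x,r) = (4x/πr²)·arccos(x/2r) − (2x²/πr³)·√(1 − x²/4r²),
  and the pile-up correction that removes focus-pair distances a microscope
  cannot resolve;
- **foci_analysis** — synthetic nucleus images with ground-truth foci, and
  ImageJ-style detection (binarization → 8-connected labeling → area in μm²);
- **calibration / pipeline** — exponential fits, the conversion coefficient,
  threshold conversion, simple/complex fractions and per-nucleus yields.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 42
simulation:
  energy_kev: 2.0
  n_tracks: 20
scoring:
  n_cubes: 1000
imaging:
  n_nuclei: 5
  n_foci: 40
YAML
focitrack run --config demo.yaml --out demo_run
focitrack report demo_run/report.json
```

prints

```
source: synthetic
conversion c = 13.289 ± 0.222 /um^2 (r2=0.915)
event threshold = 14 -> area threshold = 1.0535 um^2
fractions: simple 0.885, complex 0.115
yields/nucleus: {'complex': 3.4000000000000004, 'simple': 26.2}
```

Reading this: 20 simulated 2 keV electron tracks were scored with 1000 cubes
each; 5 synthetic nuclei with ~40 foci each were rendered and detected. The
least-squares superposition of the focus-area and cluster-size distributions
gives c ≈ 13.3 events/μm², so the 14-event complexity threshold corresponds
to foci of ≈ 1.05 μm². About 11% of detected foci exceed it, and with ~29.6
foci per nucleus that splits into ≈ 26.2 simple and ≈ 3.4 complex DSBs per
nucleus. All intermediates (tracks, histograms, images, report) are written
to `demo_run/` and the run is byte-reproducible from the config and seed.

The same stages are available individually (`focitrack simulate`, `score`,
`synth-image`, `detect`, `distances`, `theory-distances`, `calibrate`,
`classify`) and as library functions (`import focitrack`).

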
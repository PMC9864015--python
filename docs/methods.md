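# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of focitrack, in the order the pipeline runs them.

## Electron transport (track_sim)

Transport is event-by-event in an infinite homogeneous liquid-water medium:
exponential free flights with the total inverse mean free path, channel
choice proportional to the partial inverse mean free paths (elastic,
ionization, excitation), and explicit spatial coordinates for every
inelastic collision. The primary starts at the origin along +z; positions
are in nm.

**Cross sections.** The default table is a deliberately *simplified*
parameterization of electron interactions in liquid water, shipped as
`data/default_xsec.csv` (inverse mean free paths in nm⁻¹ on a 1 eV – 1 MeV
grid, log-log interpolated; a channel is closed below its first non-zero
grid energy). Magnitudes are chosen to be physically plausible — the
inelastic mean free path has its minimum of a few nm near 100 eV and grows
to tens of nm at 10 keV — but no claim of fidelity to any published
cross-section set is made or needed: every quantitative result of the
package is either structural (oracle-checked counting and geometry) or
calibrated against the data side. The table object is swappable wholesale,
and its loss/angular samplers are overridable.

**Loss model.** Ionization deposits an effective binding energy
(12.6 eV) at the collision point and transfers kinetic energy W to a
secondary electron, W ~ p(W) ∝ (W + a)⁻² truncated to [0, (E−B)/2] with
a = 15 eV — a heavy-tailed shape mimicking the knock-on spectrum.
Excitation deposits one of six discrete levels between 7.4 and 14.1 eV
(uniformly among levels below the current energy). Elastic scattering uses a
screened-Rutherford-style angular law with screening parameter 300 eV / E,
isotropic at eV energies and forward-peaked at keV energies; inelastic
deflections are small and forward-biased.

**Cut-off and termination.** Transport of an electron stops when its kinetic
energy falls below the 1.0 eV cut-off *or* below the lowest open inelastic
channel (~7.4 eV in the default table, below which no energy-loss channel
exists and the electron could only scatter elastically forever); the
residual is folded into the track's total deposit `e_dep`. With secondary
transport enabled (default) the cascade is followed to full depth, so
`e_dep` equals the primary energy exactly — a property the tests use as an
energy-conservation check. Secondaries can be disabled per run, in which
case their kinetic energy is folded into `e_dep` without spatial events.

**Validation oracle.** The expected cascade event count is reproduced
independently by a deterministic slowing-down recursion over the table's
channel probabilities and mean losses (dynamic programming on an energy
grid); simulated counts at 10 keV agree with it to well within 20%.

**Reproducibility.** Every simulation consumes one `numpy` Generator; track
ensembles derive per-track generators from `SeedSequence([seed, index])`, so
results are independent of evaluation order.

## Nanodosimetric scoring (cluster_scoring)

Cluster size N_cl is the count of inelastic events inside an axis-aligned
cube of side 5.03 nm with half-open bounds [o, o+side) per axis (events on
an upper face excluded — one consistent tie-break). Random placement "along
the track" is realized by anchoring each cube to a uniformly chosen event
plus a uniform jitter in [−side/2, side/2]³; a bounding-box placement mode
exists for sensitivity checks. Anchored placement concentrates sampling
where energy was deposited, which is the intent of scoring damage *sites*;
it is not an unbiased volume average. Distributions from many tracks are
pooled by summing counts; per-track scoring is also available, and the
pipeline reports pooled results.

Linkages are unordered event pairs at Euclidean distance ≤ 3.4 nm (closed
ball, 10 bp), counted with a k-d tree that the tests verify against the
all-pairs computation. The yield Y_DSB = k_DSB · N_link / E_dep uses E_dep
in keV; k_DSB has no calibrated default and ships as 1.0, so yields are
relative unless the user supplies a calibration.

Complexity classes on N_cl use half-open boundaries 2 / 14 / 26 / 38
(two events per DSB, twelve further events per additional strand break);
N_cl ≥ 38 is labeled `higher` and pooled with the complex classes, since
the twelve-event increment implies still more strand breaks. Spectrum
averages Ȳ = ∫ Y(E) f(E) dE use trapezoid quadrature on the spectrum's own
bin grid after normalizing the weights.

## Pair-distance statistics (geometry_stats)

The distance x between two points dropped independently and area-uniformly
in a disc of radius r has density
f(x,r) = (4x/πr²)·arccos(x/2r) − (2x²/πr³)·√(1 − x²/4r²) on [0, 2r]
(zero outside by convention). The assay geometry is planar — the sampling
region is a circle of 5.0 μm diameter in the image plane — so no 3-D variant
is provided.

Sampling from f for the pile-up correction uses inverse-transform sampling
on a tabulated CDF (trapezoid-integrated on a 10⁴-point grid, monotone
linear interpolation); direct two-point sampling in the disc (radius r·√u)
is used when raw pair distances are wanted. The pile-up correction draws a
distance x_j ~ f, draws two focus areas at random from the measured area
sample, forms the minimum resolvable separation x_min = √(a₁/π) + √(a₂/π),
and rejects x_j < x_min; rejection during sampling is equivalent in
distribution to subtracting the rejected frequency from the theoretical
curve, and the accepted/rejected counts are returned so the subtraction form
can be plotted. In-circle membership of a focus is decided by its centroid.

## Image synthesis and detection (foci_analysis)

The synthesizer emulates one widefield fluorescence nucleus: an elliptical
mask (semi-axes 7 × 5 μm), foci centers uniform over the mask (focus
positions after photon irradiation are spatially random), each focus an
isotropic Gaussian blob of σ = 0.15 μm, plus Gaussian read noise
(sd 2 intensity units against a reference level of 100). Nominal focus
areas follow offset + Exp(rate) with rate 3.3 μm⁻² and offset 0.05 μm²; the
rate is chosen consistently with the scored cluster-size law under the
reference conversion coefficient (0.25 · 13.2 ≈ 3.3), and the offset keeps
foci above the pixelation floor. A blob's peak amplitude is set to
level · exp(area / 2πσ²), which makes its footprint above the reference
level equal the nominal area exactly in the continuum limit. Pixel size
defaults to 0.1 μm (typical 40–60× widefield scale); coordinates put pixel
centers at integer indices, origin top-left, x right / y down.

Detection mirrors ImageJ particle analysis: binarization (Otsu within the
nucleus mask, or a fixed level — the pipeline default is the fixed reference
level, since Otsu on sparse-signal images is noise-sensitive), 8-connected
component labeling, rejection of components under 4 pixels, then centroid
and area per component. Detected areas carry a pixelation error of a few
percent for foci ≥ 20 pixels (worst case ~±15% near the 20-pixel floor when
a focus sits exactly on the pixel lattice); the synthesize→detect loop is
bias-centered to < 5%.

What the synthetic images do *not* emulate: uneven illumination,
out-of-focus light and 3-D sectioning, focus substructure, chromatic or
camera fixed-pattern noise, and touching-focus deblending. Tests passing on
these images therefore validate the measurement chain's geometry and
bookkeeping, not robustness to real microscope artifacts.

## Calibration (calibration, pipeline)

Both frequency distributions — focus area and cluster size restricted to
N_cl ≥ 2 ("two events are required to induce a DSB"; the lower bound is
configurable) — are fitted by unweighted least squares to A·exp(−λx) on
binned relative frequencies (density histograms, not cumulative), with a
log-linear initial guess. The conversion coefficient c is then the scale
that superimposes them: each events-axis unit bin [N−½, N+½) maps to the
area interval [(N−½)/c, (N+½)/c], the area histogram's mass over that
interval (piecewise-linear CDF) is renormalized over the compared bins and
matched to the cluster-size relative frequencies by least squares;
the scalar search is bracketed around the ratio of the two fitted
exponential rates, which is the closed-form solution when both laws are
exactly exponential. The uncertainty of c is the standard error of the
scale parameter from residual-based propagation (numerical ∂q/∂c); r² is
reported against the cluster-side frequencies. Binning defaults — 0.1 μm²
area bins, unit cluster bins — are configurable and recorded in the report.

The event threshold T is the smallest integer ≥ 2 whose tail fraction among
DSB-bearing cubes does not exceed the target complex fraction (by default
the fraction the package's own scoring produces; an external target can be
supplied). T converts to the area threshold T/c, foci are classified simple
vs complex by that single threshold, and per-nucleus yields are the mean
focus count split by the fractions (conserving the total). Per-class
DSB+/DSB++ area sub-thresholds follow from the same division but are an
extrapolation of the one-threshold calibration and are not reported by the
pipeline.

**Synthetic calibration pairs.** Recovery experiments draw cluster sizes
from the full exponential law Exp(0.25) and map every size to an area by the
reference coefficient 13.2 μm⁻². Sizes are kept continuous: the exponential
law *is* the fitted model being inverted, and discretizing to integers would
alias against the 0.1 μm² area bins. The cluster histogram keeps only the
N ≥ 2 part (as the fit does) while the area sample keeps full support, as
measured areas do — truncating the area support at 2/c was observed to bias
the recovered coefficient by several percent and does not correspond to any
real measurement.

## Problem sizes and determinism

Default experiment sizes — 10⁴ foci × 50 seeds for coefficient recovery,
10⁵ pair distances for distribution agreement, 5 × 10³ foci for the closed
loop, 2 × 10³ cubes per track — give sub-percent Monte Carlo noise on the
reported quantities while keeping any single experiment under a minute on
one CPU. One run seed fans out to per-stage seeds via
`SeedSequence([seed, crc32(stage)])`; re-running a pipeline config
reproduces every artifact byte for byte (reports carry seeds, a config hash
and version, and no timestamps).

## Known limitations

- Cross-section realism is explicitly out of scope; absolute nanodosimetric
  quantities (event densities, linkage counts per keV) are relative to the
  shipped table.
- k_DSB is uncalibrated; Y_DSB values are relative.
- The calibration assumes strict proportionality between focus area and
  cluster size and exponential-family distributions on both axes; strongly
  non-exponential inputs flag themselves only through low r².
- Detection has no deblending: overlapping foci merge into one record, which
  inflates the area tail at high focus densities.
- The pair-distance law and pile-up correction are planar; axial (z)
  structure of nuclei is ignored.
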
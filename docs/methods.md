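# Methods

`ecshear` models one flow channel of a 96-well laminar-flow plate and
quantifies the canonical image-based readouts of endothelial flow
response on synthetic data with known ground truth.  This note records
the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Duct flow model

A channel is treated as a rectangular duct (width w = 6.0 mm, height
h = 0.5 mm, length L = 125.77 mm) carrying fully developed,
incompressible, steady laminar Poiseuille flow.  The cross-sectional
velocity solves

    ∂²u/∂y² + ∂²u/∂z² = −G/μ,  u = 0 on the walls,

with G = −dp/dx the axial pressure gradient and μ the dynamic
viscosity.  Entrance effects and the narrowed inlet/outlet regions are
out of scope: at the operating point the Reynolds number is ≈ 96 and
the entrance length (~0.05·Re·D_h ≈ 4 mm) is ~3 % of the channel, so
the fully developed model describes the cell-bearing floor.

Two independent solutions are implemented:

* **Fourier series** — the classical odd-harmonic cosh/sin expansion.
  The plane-Poiseuille part G z (h − z)/(2μ) is split off in closed
  form (the sine series sums to it exactly), so the summed remainder
  decays exponentially away from the side walls; 51 odd terms leave
  relative truncation residuals below 1e-8 against a 201-term sum.
  Floor shear τ(y) = μ ∂u/∂z|_{z=0} is the term-wise derivative with
  the same closed-form split; wall values are exact zeros.  The profile
  can also be evaluated at a plane z above the floor (e.g. 10 µm, a
  common imaging plane), as μ ∂u/∂z at that height.
* **Finite differences** — a five-point Laplacian on a 241 × 21
  (width × height) grid, direct sparse solve.  Each route is the
  oracle for the other: the velocity fields agree to ≤ 0.1 % of the
  peak velocity, and the floor-shear profiles to ≤ 0.1 % of the peak
  shear outside the corner regions (within one channel height of a
  side wall both discretisations degrade and no cells sit there, so
  the comparison band is y ∈ [h, w − h]).

Design conversions use the wide-channel (plane-Poiseuille) formula
τ = 6μQ/(wh²), the standard design rule for parallel-plate flow
chambers; at aspect ratio 12 the true centreline shear runs ≈ 5.5 %
above it (side walls carry part of the flow), which the series/FD
routes quantify.  Pressure drop is ΔP = G·L with G from the full duct
resistance (the plate approximation is available as `model="plate"`).
Reynolds number uses the hydraulic diameter D_h = 2wh/(w + h) with a
laminar flag below Re = 2000.

**Viscosity default.**  The working fluid defaults to μ = 0.75 mPa·s,
ρ = 1000 kg/m³.  This is the viscosity under which the plate's stated
operating point — 14 mL/min corresponding to 0.7 Pa (7 dyn/cm²) floor
shear in this geometry — is exactly self-consistent under τ = 6μQ/(wh²),
and it is close to water/culture medium at 37 °C (≈ 0.69 mPa·s).  Both
properties are overridable.

## Synthetic monolayers

The generator fabricates the four channels a flow-response experiment
images — junction marker (cell outlines), nuclear stain, Golgi marker,
nuclear transcription-factor marker — plus a per-cell truth table and
the noise-free cell label map.  Default conditions: 500 cells in an
800 × 800 px field at 1 µm/px (cell diameter ~30–40 µm, a confluent
endothelial monolayer at 40× imaging scale).

* **Orientations** are axial (180°-periodic) von Mises: θ ~ vM(2ᾱ₀, κ),
  α = θ/2.  The population polarity index is then exactly
  I₁(κ)/I₀(κ).  Flow-like default κ = 3 (PI ≈ 0.81, strong alignment);
  static κ = 0 (uniform).
* **Cell mosaic**: seed points on a jittered lattice (jitter 0.35 of
  the spacing), each pixel assigned to the seed minimising an
  anisotropic metric contracted by the elongation factor (default 2.5)
  along that seed's orientation axis.  Two refinements were needed to
  make region shape faithfully encode the assigned angle:
  (1) the seed lattice is stretched area-preservingly along the
  population mean axis by s = 1 + (e − 1)·ρ(κ)·0.5 — between
  equally-oriented neighbours the per-seed metric cancels, so without
  a packing-level stretch a fully aligned mosaic degenerates to
  near-isotropic cells (real aligned monolayers are likewise spaced
  further apart along the flow axis);
  (2) four passes of Lloyd (centroidal) relaxation in each cell's own
  metric regularise the region shapes.  Relaxation is skipped for
  isotropic mosaics (elongation 1): it has no axis to enforce there
  and would anneal the tessellation into orientation-correlated
  crystalline grains.  With both, fitting ellipses to the emitted
  label map recovers the assigned angles with circular MAE ≈ 4–5°
  (interior cells), and recovered PI tracks the truth within ±0.05.
* **Nuclei** are filled ellipses (semi-axes 8 × 4.5 px) at the cell
  centre, oriented at the cell angle plus wrapped-normal jitter
  (sd 15°) — correlated but not identical alignment, as observed for
  nuclear vs cell-shape orientation.
* **Golgi** is a Gaussian blob (σ 1.8 px) displaced 8 µm from the
  nucleus centroid along a polarity angle drawn from a plain von Mises
  about the flow axis (default mean 180°, κ = 2: polarised against the
  flow, the canonical endothelial response); the blob is clipped to
  its cell and walked inward if the sampled offset leaves the cell.
  Truth stores the angle recomputed from the final rendered centroids,
  so truth geometry is exact by construction.
* **Marker** paints nuclear pixels at a per-cell level ~
  N(condition mean, 10); flow-like mean 200 a.u., static 100 a.u.
* **Noise**: Poisson shot noise then Gaussian read noise (sd 30 a.u.),
  clipped to 16 bit.  Fixed seeds give byte-identical output.

What the generator does *not* emulate: curved/concave cell outlines,
gradients of staining, uneven illumination, out-of-focus light,
mitotic or multinucleated cells, fragmented Golgi.  Passing recovery
tests therefore demonstrates correctness of the measurement chain, not
robustness to every real-microscopy artefact.

## Segmentation

Classical pipeline: Otsu threshold + hole filling + minimum-area
filter (30 px²) + distance-transform watershed for nuclei; seeded
watershed on the junction intensity for cells (junction staining forms
bright ridges, each nucleus seeds one region); threshold + connected
components + intensity-weighted centroids (min 5 px²) for Golgi.
Border-touching cells are excluded from orientation/polarity
statistics (truncated shapes bias the fit).  A learned segmenter can
be dropped in by supplying label maps directly; all statistics consume
label maps and centroids only.

## Circular statistics

Axial angles are doubled (θ = 2α), summarised by the circular mean and
the mean resultant length — the polarity index

    PI = √[(Σcos θᵢ/N)² + (Σsin θᵢ/N)²],

and halved back (ᾱ = θ̄/2).  PI = 1 iff all axes coincide (mod 180°);
for uniform samples E[PI] = O(1/√N), so small positive values at
finite N are the null expectation, not signal.  Uniformity is tested
with the Rayleigh statistic Z = N·R̄² using the standard finite-N
correction p = exp(√(1 + 4N + 4(N² − R²)) − (1 + 2N)); it agrees with
a 10⁵-draw Monte-Carlo null to within 10 % at N = 20.  Orientation
fits use second central moments (with the 1/12 px² pixel-variance
term); objects with eccentricity < 0.05 have no meaningful axis and
are excluded.  Angles are degrees at the API surface, radians
internally; the image y-axis is flipped to mathematical orientation so
α = 0° means flow-axis aligned.

## Polarity

Nucleus→Golgi assignment is a globally optimal minimum-total-distance
matching (Hungarian algorithm on the rectangular cost matrix), gated
at 1.5× the median nucleus major axis to discard cross-cell pairs; a
greedy nearest-pair variant exists behind a flag for comparison.
Angles are signed, measured counter-clockwise from the flow vector
(default (−1, 0): flow right to left).  Summaries report both the
unsigned resultant length R̄ and the signed flow-polarity index
FPI = mean cos θ ∈ [−1, 1] (negative = against the flow); |FPI| ≤ R̄
always.  Reporting both is deliberate: a single "polarity index" name
is used in the literature sometimes for the length and sometimes for a
signed projection, and the two answer different questions.

## Expression

Nuclear marker intensity is the per-ROI mean of the marker channel
under the nuclear label map, with each ROI eroded by 1 px so the
partial-volume rim does not dilute the mean.  qPCR fold changes use
the Livak method: 2^(−ΔΔCq) with replicate Cq averaged (mean by
default, median optional) before differencing against the reference
gene and the control condition.  Standard curves regress Cq on log₁₀
dilution (default series 1:10, 1:25, 1:50); efficiency
E = 10^(−1/slope) − 1, and non-negative slopes flag the curve invalid.
Group comparisons (rank-sum, Welch t, one-way ANOVA + Tukey) are thin
wrappers over scipy/statsmodels.

## Problem sizes and tolerances

Defaults were chosen so the whole suite runs on one CPU in minutes:
recovery runs use 500-cell fields (three concentrations), the
isotropic-mosaic null check uses a 900-cell field (at smaller N the
Rayleigh null floor makes a 0.05 PI bound statistically unfair), the
von Mises/Bessel comparison uses 10⁵ draws judged at two standard
errors plus the finite-N resultant bias √(π/4N), and assignment
optimality is brute-force-verified on 200 instances with ≤ 6 objects
per side.  The FD solver uses 241 × 21 by default; conservation of the
integrated flow rate holds to 1 % at that resolution.

## Known limitations

* The fluid model is Newtonian, steady and fully developed; inlet
  narrowing, pulsatility and compliance are not modelled.
* The mosaic generator encodes orientation statistics, not cell
  mechanics; elongation factors between ~1 and ~1.2 are rendered
  without relaxation and carry a weaker shape signal.
* Watershed segmentation assumes closed, bright junctional outlines;
  heavily fragmented staining would need an external segmenter.
* Synthetic marker levels are arbitrary units; only ratios and group
  separations are meaningful.
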
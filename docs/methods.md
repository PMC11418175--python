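# Methods

## The problem

Several obligate cleaner shrimps signal to client fish by waving white
antennae.  Electron microscopy of those antennae shows two kinds of
reflectance-boosting ultrastructure beneath the ~5 µm chitin cuticle:
a 1–3 µm layer of densely packed high-refractive-index spheres
(300–400 nm diameter; *Ancylomenes pedersoni*, *Lysmata amboinensis*)
or a regular stack of ~0.27 µm chitin lamellae (*Lysmata debelius*).
`shrimpglass` models how such structures raise broadband (400–700 nm)
reflectance, and provides the measurement side of the study: reflectance
from calibrated photographs and the small-sample group statistics.

## Optical model

**Geometry.** A packed-sphere layer is a hard-particle packing in a box
that is periodic laterally and bounded axially.  The generator uses
random sequential addition at reduced particle size followed by
growth-and-relaxation densification (overlapping pairs are pushed apart
along their centre line, with targeted random kicks to break jams).  The
default fill fraction is 0.55 — dense, but below true random close
packing (~0.64), since the real aggregation state of the antennal
spheres is not known; the overlap tolerance is 1 nm.  Both 3-D sphere
packings and 2-D disc packings (cross-sections of cylinders) are
supported; a planar slice through a 3-D packing at volume fraction φ has
area fraction φ, so 2-D packings use the same 0.55 default.

**Planar solver.** The transfer-matrix method (characteristic matrices,
normal incidence, real dispersion-free indices) is exact for planar
stacks and serves both as the model of the bare cuticle and lamellae
stack and as the oracle for the time-domain solver.  Default wavelength
grid: 1 nm steps over 400–700 nm; band averages are flat-weighted
trapezoidal means (no source-spectrum weighting is applied, as none is
specified for the original simulations).

**Time-domain solver.** A from-scratch 2-D FDTD solver on a Yee grid:
x lateral and periodic, z axial and terminated by 10-cell convolutional
PML (cubic grading, σ_max = 0.8(m+1)/(Δx·n), α linearly graded from
0.1).  A single Gaussian-pulse plane wave (spectral amplitude ≥ 20 % of
peak across the band) yields the whole spectrum through running DFTs of
the tangential fields at two flux monitors; reflectance uses
incident-field subtraction against a cached empty-scene reference run on
the identical grid, transmittance is downstream flux over incident flux.
Materials are rasterized with 4× subpixel supersampling and
volume-fraction permittivity averaging.  The two scalar polarizations
(E out of plane; H out of plane) are solved separately and averaged for
unpolarized light.  Defaults: 10 nm grid (20 nm for production sweeps,
which is the stability/accuracy bound λ_min/(10·n_max) at n = 2.0),
Courant factor 0.5, termination when residual field energy falls below
10⁻⁶ of peak, step cap 30,000–60,000 (runs that hit the cap are
flagged).

Validation: planar scenes match the transfer matrix to better than 0.01
absolute reflectance per wavelength at the default grid; a bare
1.34/1.57 interface matches the Fresnel value to 2×10⁻⁴; energy
imbalance |R+T−1| is below 10⁻⁴ for planar runs.

**Why 2-D.** The original study ran a commercial 3-D solver on a
4×4×12 µm domain.  At the grid this package's own stability invariant
requires for n = 2.0 (≤ 20 nm), even a reduced 2×2×8 µm 3-D domain is
~4 million cells for tens of thousands of steps — tens of minutes to
an hour per data point on one core, and the sweeps need ~70 points.
The package therefore runs cylinder-geometry 2-D scenes (discs in the
x–z plane), which keeps every sweep on a desktop scale.  The cost is a
known geometric discrepancy, documented per sweep below: 2-D cylinder
scattering is not 3-D Mie scattering.

**Double-pass correction.** An antenna is a thin cylinder, so most
light that enters it crosses the structured wall twice.  Antenna-level
reflectance is reported as R + R·T², where R and T are the band-averaged
reflectance and transmittance of one wall: front-wall reflection plus
back-wall reflection attenuated by two traversals of the front wall.
The correction is applied to band-averaged R, T and is recomputable from
the stored table columns by construction.

## The three sweeps

All sweeps share the standard scene: a 2 µm sphere layer directly
beneath a 5 µm chitin cuticle (n = 1.57) in a seawater matrix
(n = 1.34), with the layer position "directly beneath" chosen since the
SEM sections only bound the gap loosely.  Defaults are coarsened grids
that preserve the published endpoints (index step 0.05 over 1.57–2.00;
thickness step 1 µm over 1–10 µm; diameter step 100 nm over
100–1000 nm; full 0.01/0.3 µm/30 nm grids available by argument), with
3 independent packings per point, replicate seeds spawned from one
master seed.

Observed 2-D ↔ 3-D discrepancies (from the acceptance runs, 20 nm grid,
fill 0.55, 3 replicates):

- **Refractive-index sweep.** Monotone increase reproduced exactly
  (Spearman +1).  At n = 1.57 the 2-D antenna reflectance (~10 %)
  brackets the published 8.7 %; at n = 1.78 it is ~27–33 % (published
  36.9 %) and at n = 2.00 ~44–48 % (published 57 %): the 2-D model
  increasingly underestimates the strong-scattering regime.  Fold
  changes relative to the bare-cuticle control (published 4.6× and
  >19×) are reproduced.
- **Thickness sweep.** Reflectance grows with thickness with
  diminishing increments, as published.
- **Diameter sweep.** Qualitatively different: 2-D reflectance
  *decreases* with diameter at fixed fill (verified grid-converged), so
  the sharp 100→400 nm rise and the ≥400 nm plateau of the 3-D study do
  not appear.  Thin cylinders scatter far more efficiently than small
  spheres, and the cylinder geometry lacks the sphere Mie resonances
  that produce the 3-D plateau.  The plateau detector honestly reports
  "no plateau" here; the acceptance script then falls back to the mean
  of the trailing three grid points, documented as such.

The plateau detector itself finds the longest trailing window of the
sweep whose relative spread (max − min over mean) is below a tolerance
(default 0.15), reporting the window mean and the first parameter value
inside the window; ties break toward the earlier onset, windows shorter
than two points never qualify.

The control scene (bare cuticle) is computed by the transfer-matrix
solver, which is authoritative for planar geometry; FDTD agreement is a
test.  Whether the published 1.9 % control includes the double-pass
correction is ambiguous: the single-layer band average is 1.24 % and
the double-pass value 2.46 %, which bracket 1.9 %, so both are always
reported.

## Reflectometry from calibrated photographs

The synthetic camera writes G = round(255·R^(1/γ)) + noise per channel,
with γ in the sRGB neighbourhood (1.8–2.4).  Measurement mirrors the
field procedure: extract the green channel (unrescaled), average each of
the five grey-standard swatches, fit a calibration curve, convert 4–10
antenna regions, then aggregate ROI → individual → species (two-stage
means; the species s.d. is across individuals, flagged undefined for
n = 1).

The calibration curve is R(G) = a·exp(b·G) + c, fitted by nonlinear
least squares with a log-linear initializer.  The offset term matters:
a pure two-parameter exponential cannot follow a power-law tone curve
across five swatches and misses mid-range reflectance by up to 0.06,
while the offset form recovers ground truth within ~0.01 for
γ ∈ [1.8, 2.4] (and reduces exactly to the two-parameter form, c = 0,
on truly exponential data).  Monotonicity (a > 0, b > 0) is enforced;
conversions above the brightest swatch are permitted but flagged and
clipped at R = 1.  Default synthetic swatch reflectances are
3/10/30/60/90 % — a typical spread for grey paint standards; the real
standard's values were not published.

## Statistics

The five focal species carry fixed labels: obligate (*A. pedersoni*,
*L. amboinensis*, *L. debelius*), facultative (*P. yucatanicus*),
non-cleaner (*L. boggessi*); ultrastructure present in the three
obligates only; all but *L. boggessi* have white antennae.

The unpaired two-sample Wilcoxon rank-sum test is computed exactly by
complete enumeration of all C(n+m, n) group assignments using midranks,
whenever n + m ≤ 20 (always true here: 8 vs 6 individuals at most); the
two-sided p doubles the smaller tail (point mass included) and caps at
1 — the convention of the original analysis software is unknowable, so
this standard convention is documented rather than matched.  Larger
samples fall back to a normal approximation with tie-corrected variance
and continuity correction; the result records which route was used.
The linear model of reflectance on cleaner status is ordinary least
squares with an F comparison of full vs intercept-only model, which
equals the closed-form one-way ANOVA (verified to 10⁻¹⁰, and against
statsmodels).

The published p-values (0.004, <0.0001, 0.03, 0.002) cannot be
recomputed because per-individual reflectances were not published; the
tests are instead validated against enumeration oracles, and the
end-to-end check draws synthetic datasets at the published species
means ± s.d. (sample sizes 2/3/3/3/3) and verifies the obligate vs
non-obligate test rejects at 5 % in ≥ 95 % of 1000 seeds.

## Synthetic data: what it does and does not emulate

- **SEM images**: non-overlapping anti-aliased filled discs with
  normally distributed diameters (defaults 395 ± 40 nm, n = 207).  Real
  SEM texture, 3-D sectioning (a cut through a sphere shows a chord, not
  an equator), and freeze-fracture distortion are not modelled, so the
  morphometry round trip validates the measurement code, not SEM
  understanding.
- **Photographs**: uniform swatch/antenna regions under a power-law
  camera with additive Gaussian noise; no vignetting, glare, or
  non-uniform illumination, so calibration transfer across the frame is
  not stressed.
- **Reflectance datasets**: individual means drawn
  normal(mean, s.d.) truncated to [0, 1] (truncation negligible at the
  published parameters); *A. pedersoni*, published as two individual
  values with no s.d., uses their mean and half-range.  ROI-level
  scatter defaults to zero so individual means are exact; it can be
  switched on for robustness checks.

Passing tests on these generators demonstrates that the pipeline
recovers known ground truth under the published statistical structure;
they say nothing about optics or photography artifacts absent from the
generators.

## Numerical choices and limitations

- Normal incidence only; non-absorbing, dispersion-free indices.
- FDTD runs on strongly scattering packings trap some energy in laterally
  guided modes of the cuticle slab (a genuine feature of the periodic
  cell); runs truncated at the step cap carry a 1–4 % energy imbalance,
  which is flagged in the output metadata and contributes to the quoted
  replicate spread.
- Packing generation fails loudly (with the achieved fraction) rather
  than silently delivering a thinner layer; sweep points where any
  replicate fails are marked in the table.
- Problem sizes used by the acceptance script: 2 µm lateral cell, 20 nm
  grid, 31 spectral points, 3 packing replicates per swept value,
  7-point diameter grid — chosen so a full reproduction runs on a single
  desktop core.
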
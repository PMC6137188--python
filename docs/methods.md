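# Methods

`scarflow` is an in-silico reconstruction of a high-throughput workflow
for isolating young and replicatively aged budding yeast by inertial
microfluidics and quantifying their age from fluorescence micrographs.
This note documents the models, their assumptions, the defaults and how
they were chosen, and what the synthetic-data generators do and do not
emulate.

## Channel hydraulics

The sorter is a serpentine of curved rectangular ducts, 200 µm wide,
33 µm high, with a 900 µm radius of curvature.  From the volumetric rate
Q the module derives the hydraulic diameter `Dh = 2wh/(w+h)` (56.65 µm),
mean velocity `U = Q/(wh)`, channel Reynolds number `Re = ρU Dh/µ`, Dean
number `De = Re·√(Dh/2R)`, and the wall shear `τ = 6µQ/(wh²)` in the
parallel-plate limit, appropriate for the 0.165 aspect ratio.  Geometry
is entered in micrometres and converted to SI once at construction.

The default fluid is water with ρ = 998 kg/m³ and µ = 0.9983 mPa·s, a
kinematic viscosity of 1.0003×10⁻⁶ m²/s corresponding to ≈20.2 °C.  The
operating temperature of the original experiments is not recorded; this
value lies within the tabulated range for room-temperature water and is
the one under which both operating points round to the reported integer
Reynolds numbers (Re = 215 at 1500 µL/min and 257 at 1800 µL/min — the
admissible window is narrow, ν ∈ (1.00016, 1.00044)×10⁻⁶ m²/s, because
Re is exactly linear in Q while 257/215 ≠ 1.2).  The same defaults give
τ = 687.5 Pa at the yeast operating point, 0.5 % from the reported
691 Pa and far below the 1292 Pa damage threshold.

## Lateral focusing model

Two mechanisms compete for a particle of diameter *a*:

* **Shear-gradient lift**, `F_sg = −c_sg·ρ·a⁴·Dh·d(γ̇²)/dx`, pointing
  toward the axial-velocity maximum (γ̇² is minimal there).  In the
  curved duct the velocity peak is displaced toward the concave wall by
  `δ = min(β·De, cap)·w`, so this force carries large particles
  concave-side.
* **Dean-vortex centering**, `F_d = −c_d·ρ·a²·U_D²·sign(x − w/2)`, with
  the secondary-flow magnitude from the empirical correlation
  `U_D = 1.8×10⁻⁴·De^1.63` m/s.  It traps small particles at the
  centreline.
* **Wall lift**, `F_w = c_w·ρ·a⁶·γ̇²·(1/d₁² − 1/d₂²)`, a short-range
  repulsion from both walls that keeps equilibria off the walls.

Stable zeros of the net force are found by a dense sign scan with
bisection refinement; the regime of a particle is decided by the deepest
potential well ("center-trap" if it lies within 0.1·w of the
centreline).  The smallest diameter whose regime flips to concave-wall
is the critical diameter; because the Dean term grows as `De^3.26 ∝
Q^3.26` while the shear term grows as Q², the threshold rises with flow
rate, as observed.

**The lift kernel.**  The duct's exact midplane velocity profile (the
Fourier-series solution, exposed as `axial_velocity_profile` and
validated against a finite-difference Poisson solution and the
volumetric flux) is plug-like at this 6:1 aspect ratio: all in-plane
shear lives in layers of width ≈h at the side walls.  A lift force
evaluated literally on that slice cannot balance the (uniform) Dean
force anywhere in the interior, and no coefficient choice produces the
observed concave-side equilibria.  A finite particle, however, spans a
large fraction of the 33 µm depth and samples the three-dimensional
shear field over its body, whose lateral variation is smooth across the
whole width.  The forces are therefore evaluated on an effective
*parabolic lift kernel* — a skewed Poiseuille shape with the duct's mean
velocity — as the module's one-parameter model of that sampled
environment.  The skew cap default is 0.4·w; at the operating Dean
number the applied skew is capped there, placing the kernel peak at
0.9·w.  A smaller cap cannot separate the centre focus and the concave
focus by the ≈0.3·w that the measured simultaneous centre/concave
yields demand under a single dispersion σ_f.

**Calibration.**  Only coefficient *ratios* are identifiable from outlet
data (a common factor scales out of every force-balance), so `c_sg`
gauge-fixes the scale and `calibrate()` fits `(c_w, c_d, σ_f)` by least
squares to the measured bead record at 1.5 mL/min: per-port yields
(12 % of 4.1 µm beads at the convex port, 55 % at the centre port, 60 %
of 5.56 and 9.95 µm beads at the concave-focus port) plus the measured
port purities of the 1:1 bead-pair mixtures, which pin σ_f.  The
shipped default coefficients and the default outlet-bin edges
(0, 0.377, 0.55, 0.622, 0.8485, 1)·w are frozen output of a one-time
joint fit of coefficients and edges against that record; the calibrated
model reproduces every measured yield within ≈1.5 points and every
purity within ≈8 points, with the critical diameter at ≈4.9 µm —
between the largest centre-trapped (4.1 µm) and smallest wall-focused
(5.56 µm) bead.  Port labels follow the experimental usage: the
centreline focus falls in port 2, the bead concave focus in port 4.

**Outlet assignment** models a focused particle's lateral position as a
normal around its dominant equilibrium with spread σ_f·w, truncated to
the duct, integrated over (or sampled into) the outlet bins.  Particle
density is carried as metadata (polystyrene 1050, yeast 1100 kg/m³) but
does not enter the force model, which is written per unit fluid density.
Trajectory dynamics are intentionally replaced by equilibrium plus
Gaussian dispersion: the experiments report focused streaklines, not
transients.

## Population model

In balanced exponential growth with equal generation times, every
division yields one newborn and increments one mother, giving the
stable scar distribution `P(k) = 2^−(k+1)` — half of the culture is
newborn.  The simulator reproduces this exactly (synchronous doubling
plus a multivariate-hypergeometric subsample), and its newborn fraction
of 50 % is consistent with the measured 51.5 ± 1.5 %.

The high-density mode emulates a culture held at saturation for days:
founders are drawn from the stable distribution with uniform division
phase and the culture then runs event-driven for a fixed window with a
generation time `T(k) = t0·(1 + s·k)` and a **daughter survival
probability** v < 1.  The survival parameter is forced by bookkeeping,
not taste: writing `v_k` for divisions by class-k cells over any window,
the final composition obeys `newborn′ = newborn₀ + Σ_{k≥1} v_k` and
`adults′ = adults₀ + v₂`, so from any young-dominated inoculum the
measured pair (32 % newborn with 33 % adults) is unreachable for every
division schedule — each adult-minting division also mints a newborn.
Daughters budded in deep stationary phase dying before observation (the
fate of storage-poor newborns) breaks that constraint.  Defaults
t0 = 1.5 h, s = 0.1, window 9 h, v = 0.48 were grid-calibrated once so
the three measured fractions fall inside their bands (simulated: 28.7 %
newborn, 67.1 % with 0–2 scars, 32.9 % with 3+, 0.06 % with ≥11).

Diameters follow the linear growth model `d = 2.3 + 0.8·min(k, 11) +
N(0, 1)` µm, clipped at 1 µm — intercept, slope, spread and plateau as
measured; the overlap between age groups that the ±1 µm spread creates
is itself a reported feature of the data.  Hsp104-focus prevalence is a
logistic in scar count (floor 0.05, ceiling 0.6, midpoint 4 scars,
slope 0.6 — documented assumptions shaped to a gradual rise from the
first divisions), with focus-positive cells carrying 1 + Poisson(0.4)
foci.

`apply_sort` assigns each cell a port by sampling its focused lateral
position given its diameter (equilibria are computed on a 0.1 µm
diameter grid and shared across cells).  Enrichment metrics (young =
0–2 scars, adult = 3–10) are direct counts.

## Synthetic microscopy

Each cell renders as a membrane annulus at its true diameter (ring
profile σ = 1 px), k bright scar puncta on the rim with a minimum
angular gap, a faint chitin wall ring in the scar channel, and optional
Hsp104 foci in a GFP channel.  The pixel scale is 0.1 µm/px, so the
1.5–15 µm cells of interest span 15–150 px.  Deterministic optics (PSF
blur σ = 1.2 px plus a camera background pedestal of 20 units) are
always applied; stochastic Poisson shot noise (0.8 photons per unit)
and Gaussian read noise (σ = 4) give a membrane SNR ≈ 10 and can be
switched off for exact fixtures.  Placement is rejection sampling with
a contact allowance; a configurable fraction of cells (8 %) is placed
crossing image borders on purpose, since the pipeline must discard
them.  Rendering is bit-reproducible given (cells, optics, layout,
seed).

What the renderer does **not** emulate: 3-D defocus, spectral
bleed-through, photobleaching, uneven illumination, debris and
autofluorescent junk, irregular (non-circular) cell outlines, and
attached mother–daughter pairs beyond the explicit clumped-pair
fixture.  Pipeline accuracy measured here is therefore an upper bound
on real-micrograph performance; the pipeline's parameters are exposed
for recalibration on real data.

## Quantification pipeline

1. **Ring enhancement** — greyscale hole filling (morphological
   reconstruction by erosion from the image border) raises annulus
   interiors to ring level without ever bridging neighbouring cells;
   a white top-hat with a disc larger than any admissible cell removes
   the background pedestal.  A multiscale scale-normalised
   Laplacian-of-Gaussian bank over the admissible radii is provided for
   scale-selective ring detection.
2. **Segmentation** — windowed (adaptive) two-class Otsu.  Each window
   thresholds at the geometric mean of its two Otsu classes — the
   log-scale Otsu placement standard for fluorescence, implemented in
   exactly scale-covariant form so 8-bit, 16-bit and float renderings
   threshold identically — multiplied by the correction factor 2.0
   (valid range 1.5–2.5), which keeps noise-only fields empty.  Binary
   cleanup: hole filling, a 2 px erosion compensating the PSF halo the
   threshold admits, a minimum-area filter.  Clumps are split by shape:
   distance-transform watershed seeded at h-maxima (depth 2 px).
   Objects outside 1.5–15 µm equivalent diameter and objects touching
   an image border are discarded.
3. **Puncta calling** — on the *raw* scar (or GFP) channel inside each
   cell's dilated mask (2 px, nearest-cell assignment): the robust
   background threshold trims the dimmest and brightest 5 % of region
   pixels and sets `(mean + 2·SD)·1.5` (puncta correction, valid range
   1.0–2.0); above-threshold components of ≥3 px become puncta.  Tiny
   regions fall back to a global background estimate.  Structures
   outside every mask are dropped.
4. **Relation** — each punctum is attributed to the nearest containing
   cell (the label expansion makes the tie-break deterministic);
   per-cell scar and focus counts, equivalent diameters (area-equivalent
   circle, in µm) and mean channel intensities form the measurement
   table.

On noise-free fixtures the pipeline is exact (every in-range cell found
once, scar counts equal to truth).  At default noise, on 500 simulated
cells, ≥97 % of matched cells are within ±1 scar and the mean absolute
diameter error is ≈0.3 µm with a small positive bias (the threshold
admits part of the blurred ring).  The per-image human calibration used
with real micrographs is deliberately replaced by fixed defaults plus
configuration overrides.

## Assay analytics

* **Diameter–scar regression**: OLS of diameter on scar count, cells
  beyond the k = 11 plateau excluded.  Run end-to-end (simulate →
  render ≈5000 cells → quantify → regress), slope and intercept land
  within the measured bands (0.8 ± 0.1 µm/scar, 2.3 ± 1 µm); detected
  scar counts carry small errors, so the slope sits a few percent below
  the generator value (classical attenuation), well inside the band.
* **Lag time**: a degree-9 polynomial is fitted to ln OD600 and the lag
  is the argmax of its analytic second derivative over the interior
  5–95 % of the fitted span.  Two guards are the module's own: the fit
  is restricted to the pre-plateau samples (OD below 0.85 of its
  maximum — a single degree-9 polynomial cannot carry flat–ramp–flat
  structure without its curvature ridge drifting; the cap value
  minimises worst-case bias over 3–8 h lags), and the log scale is
  essential (on linear OD the curvature keeps growing to saturation and
  the lag is unidentifiable).  The growth-curve generator is
  Baranyi–Roberts with the curvature parameter ν = 2 h⁻¹ separate from
  µ_max = 0.65 h⁻¹ (fast rich-medium yeast), which places the model's
  true curvature maximum exactly at the tangent-intercept lag.
  Verified recovery bias is below 10 % for lags of 3–8 h at plate-reader
  sampling (20 min for 22 h).  For a 2 h lag the 10 % target equals
  12 min — finer than the sampling interval — and the estimator misses
  by about a quarter of one interval; this known short-lag limit is
  documented rather than patched.
* **Degradation rate**: the misfolded-protein reporter (GFP) is
  normalised to the co-expressed stable RFP, the ratio scaled to 1 at
  t = 0, and the rate is the negative OLS slope of its logarithm —
  invariant to rescaling either channel and exactly ln 2 for a 1 h
  half-life.  Fold-ratios of two rates are the comparable statistic.
* **Ponceau loading correction**: `f(r) = 2^(ln r / ln 1.2)` — the
  factor doubles per 1.2-fold total-protein difference, a multiplicative
  homomorphism with f(1.2) = 2; corrected ratio = band ratio / f.
* **Purity/yield**: direct counting per (port, class); yields of a class
  sum to 1 over ports, purities within a port sum to 1 over classes.

## Known limitations

* The force model is phenomenological: functional forms are chosen for
  dimensional consistency and the observed regime structure, with the
  exact a⁴/a⁶/a² diameter scalings; absolute force magnitudes are
  gauge-fixed, not predicted.
* The concave-focus port cannot reach the reported 69 ± 3 % adult
  purity from a 23 % adult mixture under the measured diameter model:
  with a ±1 µm spread, ≈18 % of 2-scar cells exceed the 4.9 µm critical
  diameter and contaminate that port (predicted ≈49 % adults there,
  while the centre port does reach the reported 89 ± 7 % young).  The
  concave-*most* port enriches adults to ≈89 % (mean scar ≈4.9).  The
  near-disjoint young/adult diameter ranges reported alongside the
  ±1 µm spread are mutually inconsistent at the group boundary; a
  size-only sorter obeys the spread.
* The high-density culture model adds daughter mortality as the minimal
  mechanism able to age a culture past the 50 %-newborn bookkeeping
  bound; real stationary-phase cultures combine this with nutrient
  gradients, cell-cycle arrest and clumping that are not modelled.
* Pipeline accuracy figures are measured on the package's own synthetic
  scenes; see the renderer caveats above.
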
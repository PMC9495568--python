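# Methods

## Release models and fitting

All fits act on the fraction released f(t) = M_t/M_∞ at sampling times in
minutes.  The four models and their estimators:

* **Zero order**, f = k·t.  Least squares through the origin,
  k = Σt·f / Σt² (closed form).  The model is occasionally written with a
  percentage prefactor; this package uses the fraction form throughout.
* **Higuchi**, f = k·√t, fitted only on points with 0.1 < f < 0.6 (the
  model's validity window).  Fewer than two in-window points raises an
  explicit "insufficient window" error naming the bounds.
* **Korsmeyer–Peppas**, f = k·tⁿ.  A log–log regression over points with
  t > 0 and f > 0 seeds a nonlinear least-squares refinement on the
  natural scale (points with t > 0), constrained to k, n > 0.  The
  customary early-time restriction f ≤ 0.6 is off by default — it can be
  enabled (`max_fraction=0.6`) — because the analysis this package
  reproduces fitted the full schedule.
* **Peppas–Sahlin**, f = k₁·t^m + k₂·t^{2m}.  With m fixed the problem is
  linear in (k₁, k₂) and solved by least squares in closed form;
  coefficients may be negative, as published fits of this model often
  are.  The default m = 0.43 is the spherical-geometry exponent from the
  model's literature, since two-coefficient report formats imply a fixed
  m.  `m="free"` profiles m over a deterministic grid (0.05–1.50, step
  0.05) and refines the best cell by bounded scalar minimization
  (xatol 1e-12) — no random multistarts, so fits are reproducible without
  seeds.

R² = 1 − SSE/SST is computed against the points each model actually used
and may be negative (reported honestly for degenerate inputs such as a
constant series).  `select_model` returns the highest-R² fit; fits within
1e-9 of the maximum are treated as tied and resolved toward the model
with fewer free parameters, then by the fixed order zero-order → Higuchi
→ Korsmeyer–Peppas → Peppas–Sahlin.  The tolerance exists because exact
nesting ties (e.g. Korsmeyer–Peppas with n = 1 on zero-order data)
differ only by floating-point residue.

Note a structural identifiability limit: zero order and Higuchi are
strict submodels of Korsmeyer–Peppas, so on noisy data the nesting parent
attains weakly higher R² almost surely and max-R² selection cannot
return the nested generator.  Selection-rate statements are therefore
evaluated on the identifiable generators (Korsmeyer–Peppas with interior
n, and fixed-m Peppas–Sahlin with both terms active).

### Mechanism classification

The Korsmeyer–Peppas exponent maps (spheres) to: n ≤ 0.43 Fickian,
0.43 < n < 0.85 anomalous, 0.85 ≤ n ≤ 1 Case II, n > 1 Super Case II.
The printed threshold conventions overlap at exactly 0.43 and 0.85; both
boundaries are assigned to the outer categories, making the map total and
piecewise constant.

Peppas–Sahlin dominance integrates the absolute term contributions
∫|k₁|t^m dt and ∫|k₂|t^{2m} dt over the observation window (closed form)
and names the larger one.  Endpoint values would be fragile for the
negative-coefficient fits this model produces; the integrated form is
robust to them.  The pointwise ratio R/F = (k₂/k₁)·t^m at the window end
is reported as evidence.

### Damköhler number and equilibrium point

Neither rate entering Da is standardized, so both are defined explicitly
and exposed: the growth rate is the slope of ln(density) vs time
(specific growth rate, 1/min) and the release rate is the negated slope
of ln(1 − f) (first-order release constant, 1/min), both over a stated
window.  Da = growth/release; Da > 1 ⇒ reaction-governed (trapping),
Da < 1 ⇒ transport-governed.  Published Da values from the motivating
study are not reproduction targets because that study's rate definitions
are unstated.

The equilibrium point is the first sign change of (medium − in-bead),
located by linear interpolation between the bracketing samples; exact
equality at a sample returns that sample time; no sign change returns
none.  The detector is invariant under common rescaling of both series.

## Synthetic-data generator

The generator emulates the study's measurement structure, not its
biology:

* **Sampling schedule**: 0, 1, 2, 5, 20, 35, 65, 95, 125, 130, 145, 160,
  190, 220, 250 min, labelled by the digestion timeline oral [0, 2) pH 7,
  gastric [2, 122) pH 3, intestinal [122, 250] pH 7 (the protocol's
  242-min end is extended to cover the final samples).  Phases are labels
  with per-phase death rates only; no enzyme, pH or bile-salt chemistry
  is simulated.
* **Release curves**: the noiseless model is clipped to [0, 1], additive
  Gaussian noise (default sd 0.02 on the fraction) is applied and the
  result clipped again.  CFU counts carry multiplicative log-normal noise
  (default 0.1 log10 units); inter-replicate variances are conventions,
  not estimates, since only triplicate means are published.
* **Growth**: logistic n(t) = K / (1 + ((K−n0)/n0)e^{−μt}) with defaults
  n0 = 0.05, K = 1.34 (O.D. units), μ = 0.52 h⁻¹, calibrated so the
  noiseless curve is within 5 % of capacity at 12 h — the organism's
  log-phase peak.  Defaults only; never test targets.
* **Digestion pairs**: medium(t) = N·f(t);
  in-bead(t) = N·(1 − f(t))·L(t)·S(t) with L the logistic multiplier
  n(t)/n0 and S the per-phase survival exp(−∫δ).  With growth and death
  zero the pair conserves cells exactly.  The noiseless crossing is
  located by bracketing on a 0.1-min grid plus Brent refinement and
  returned as ground truth (or none).
* **Mechanism sign patterns**: the published two-term coefficient pairs
  do not yield physical fraction curves for any single rescaling at
  m = 0.43 (the diffusion-dominant pair peaks above 1 at ~8 min and turns
  negative; the relaxation-dominant pair stays negative over the whole
  window under per-coefficient scaling), so the generator keeps the
  *signs* — the quantity the classification consumes — with magnitudes
  chosen once to give essentially monotone curves in [0, 1] over 250 min:
  relaxation-dominant (k₁, k₂) = (−0.02, 0.009), diffusion-dominant
  (0.06, −0.0015), both m = 0.43.
* **Bead phantoms**: one rough-edged bright disc (radius wobbled by a
  low-order random harmonic series) over a darker background, an internal
  network of persistent random-walk filaments launched from the disc
  centre (cells deposit along the crosslink network, so the ground truth
  is filamentous), smoothed multiplicative texture, and a brighter
  dilated network overlay.  The true disc and filament masks are
  returned.  Because all filaments share the centre they merge there, so
  a skeleton of the dilated network recovers an isolated filament
  essentially perfectly but the full network only partially (~0.7–0.96
  across seeds) — an intended property of the phantom, not of the
  thinning.  Phantoms are 2-D; no 3-D bead geometry is modelled.
* **Factorial tables**: tidy rows (treatment × replicate × response) from
  known coded-unit quadratic surfaces plus Gaussian noise.  Default
  surfaces emulate the study's morphometric story: area and perimeter
  increase along the whey axis, circularity has an interior optimum,
  solidity a high plateau.

Every generator is bit-reproducible for a fixed seed.  What passing tests
show is that the *pipeline* recovers known structure under realistic
noise; they cannot validate the biology of real beads, enzymatic release
chemistry, or microscope physics.

## Morphometry

* **Shape**: measured on the largest 8-connected component.  Perimeter
  uses the 4-direction Crofton estimator: on rasterized discs
  (r = 25/50/100) it gives circularity 0.975/0.992/0.995, whereas the
  plain weighted boundary chain (1 axial, √2 diagonal) overestimates a
  digital circle's perimeter by ~5 % and biases circularity to ~0.90;
  the chain variant remains available (`perimeter_method="chain"`).
  Circularity is capped at 1; solidity is area over convex-hull area.
  `fill_holes` (used by the feature-table path) closes interior texture
  holes before measuring, the usual practice for thresholded micrographs.
* **Skeleton**: topology-preserving iterative thinning
  (scikit-image); skeleton ⊆ mask and component counts are preserved.
* **GLCM**: intensities quantized to G equal-width bins over [0, 255]
  (default G = 8), symmetric matrix accumulated over angles
  {0°, 45°, 90°, 135°} at distance d = 1 (all configurable), normalized
  to Σp = 1.  Features: ASM Σp², contrast Σ(i−j)²p, IDM Σp/(1+(i−j)²),
  entropy −Σp ln p (natural log by default, log₂ selectable), correlation
  Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) — flagged undefined (NaN) for constant images.
  Masked accumulation counts only pairs with both pixels inside the mask.
  The common ImageJ plug-in leaves these parameters unstated, so feature
  tables carry their parameter columns.
* **Box counting**: N(s) = occupied s×s cells with the grid anchored at
  the pattern's bounding-box origin; dimension = slope of log N vs
  log(1/s); an optional mode averages counts over 4 grid origins.
  Default sizes are powers of 2 up to half the bounding box; the
  Sierpinski-carpet check uses powers of 3, which make the count exact.
* **Lacunarity**: gliding box, λ(r) = var(M)/mean(M)² over all fully
  interior positions, aggregated as the mean over sizes {2, 4, 8, 16}
  (per-size values exposed; the aggregation used by FracLac is not
  documented, so the mean is this package's stated convention).
* **SDBC**: cells of size s, box height h = s·256/min(H, W), per-cell
  count ⌊(max−min)/h⌋ + 1 with the box stack shifted to start at the
  cell minimum; dimension from the log–log slope.  A constant image gives
  exactly 2 when the sizes divide the image.

Published texture values from the motivating study depend on unstated
ImageJ/FracLac settings and unavailable micrographs; they are context,
not targets — synthetic phantoms are the test surface.

## Factorial analysis

Factors are coded linearly (2.5 → −1, 3.75 → 0, 5 → +1).  The full
quadratic y = b₀ + b_A a + b_W w + b_AA a² + b_WW w² + b_AW aw is fitted
by OLS on replicate-level data; residual variance uses n − 6 degrees of
freedom.  Predictions outside [2.5, 5]² are refused unless extrapolation
is explicitly allowed.

Desirability is the one-sided Derringer–Suich ramp with bounds defaulting
to each surface's min/max over the design region, all importances 1.0
("set homogeneously"), goals: maximize area, circularity, solidity;
minimize perimeter.  The composite is the importance-weighted geometric
mean, so any zero desirability zeroes it.  Optimization is a
deterministic 201×201 grid sweep over the design square (ties resolved
toward lowest agavin %, then lowest whey %) followed by Nelder-Mead
refinement clipped into the square; the optimizer is checked against the
exhaustive grid.  Optimization never leaves the experimental region.

One-way ANOVA uses scipy; Tukey HSD uses statsmodels.  The compact letter
display joins groups through maximal cliques of the non-significant-pair
graph, with cliques lettered a, b, c… in order of their highest group
mean — a stated convention, recorded in the output.

## Viability arithmetic

%EE = 100·W_t/W_i exactly.  Plate counts convert as
CFU/mL = colonies / plated volume × 10^dilution (Miles–Misra microdrop
default 0.01 mL).  Percent survival is offered on both scales —
linear 100·final/initial and log10 100·log(final)/log(initial) — with
log10 the default (the CFU convention) and the scale always recorded.
Phase intervals are half-open with the final endpoint inclusive, so the
2-min boundary belongs to the gastric phase and every time gets exactly
one label.

## Problem sizes

The shipped analyses and checks use 15-point curves, 100–500 Monte-Carlo
replicates per property, 64–729-pixel test patterns, 256-pixel phantoms
and the 9×3 factorial — sizes at which every stated property is measured
directly and the full suite runs in a few minutes on one CPU.

## Known limitations

* The Korsmeyer–Peppas exponent's sampling sd under the default noise is
  ~0.035 at n ≈ 0.9, so classification near the 0.85 boundary is
  ~93 % accurate — an information limit of the 15-point design, not of
  the estimator (which is maximum likelihood under additive Gaussian
  noise).
* Max-R² model selection cannot recover nested generators under noise
  (see above).
* Lacunarity and fractal estimates on sparse skeletons are sensitive to
  box-size choice; per-size values and regression diagnostics are exposed
  so users can judge.
* The digestion model couples release and growth multiplicatively and
  ignores enzymatic kinetics, pH chemistry and bile-salt effects by
  design.
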
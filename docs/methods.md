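# Methods

`scalepat` models how the skin of scaled reptiles acquires its adult color
pattern scale by scale.  Each skin scale is a polygonal cell of a lattice
whose color — binary (green/black) or continuous CIELAB — evolves over
post-hatching development.  The package implements three model families on
that lattice and the machinery to fit, compare, and stress-test them on
synthetic data.

## Models

**Stochastic cellular automaton (sCA).**  A scale's probability of flipping
color between consecutive observations depends only on its own state and on
its number of isochromatic neighbors i ∈ {0,…,7}: 16 parameters in all.
Flip probabilities are inferred with a Binomial likelihood and flat prior
from pooled trial/success counts (n, k) per configuration; the posterior
mean E[p] = (k+1)/(n+2) regularizes rare configurations (an unvisited bin
gets 1/2), and the posterior mode k/n is reported alongside.  Simulation is
synchronous: every scale flips independently with its configuration's E[p]
each iteration, and a run stops once the cumulative number of flip events
reaches the number observed between the juvenile and adult stages of the
animal being modeled.  Scales with eight or more neighbors (possible on
irregular Voronoi lattices) are clipped into the i = 7 bin so the 16-bin
structure is preserved; boundary scales enter the statistics with their
actual reduced neighbor counts (an `include_boundary` flag excludes them).

**Lenz-Ising dynamics.**  Green and black scales are treated as ±1 dipoles
with dimensionless energy βH = −βJ Σ⟨ij⟩ sᵢsⱼ − βB Σᵢ sᵢ over the lattice
adjacency.  With green = +1, an antiferromagnetic coupling (βJ < 0) favors
labyrinthine patterns and a preference for black scales appears as βB < 0.
Dynamics are single-site Metropolis (any ergodic reversible kernel shares
the same stationary Boltzmann law, which is all the model uses); the
stopping rule mirrors the sCA's cumulative-flip count for comparability.
Parameters are estimated from a single adult pattern by maximum
pseudo-likelihood — each site's conditional law is logistic(2(βJ mᵢ + βB))
in its neighbor spin sum mᵢ — over the box [−10, 10]²; a solution on the box
boundary (e.g. for a uniform pattern, where βB is unidentifiable) is
flagged.  On 400-scale patches the single-snapshot estimator is unbiased
with an SD near 0.1 per parameter, so pooled (median-of-estimates)
summaries are the meaningful consistency check.

**Reaction-diffusion (RD).**  A three-component model: u and v are
short-range melanophore/xanthophore-associated densities (Du = Dv), w a
long-range factor (Dw ≫ Du).  Reactions are clamped linear forms — e.g.
F = clamp(c₁v + c₂w + c₃, 0, Fmax) — whose piecewise structure is the only
non-linearity; decay is linear with rates (c_u, c_v, c_w).  Default
coefficients are the reference parameter set
c = (−0.04, −0.056, 0.382, −0.05, 0, 0.25, 0.016, −0.03, 0.24),
(c_u, c_v, c_w) = (0.020, 0.025, 0.06), Du = Dv = 1.125, Dw = 12.5,
P = 0.00889.  The caps Fmax = Gmax = Hmax = 0.5 are **placeholder
defaults**: no cap values are fixed by the sources this package draws its
coefficient set from, so they are configuration-mandatory in any serious
application.  At the defaults the homogeneous steady state (HSS)
u* ≈ (3.476, 3.049, 3.402) lies strictly inside the central branch
(branch values 0.070, 0.076, 0.204 against caps of 0.5), which the
HSS solver checks and reports.

Skin thinning at scale borders multiplies the diffusivities by P ∈ (0, 1]
across interscale edges.  Three discretizations are provided:

* **2D-dRD** (one node per scale): finite-volume form on arbitrary polygons,
  duᵢ/dt = F(uᵢ) − c uᵢ + (PD / Aᵢ ε) Σⱼ (uⱼ − uᵢ) L
  ᵢⱼ, which on a regular
  hexagonal lattice (Aᵢ = 3√3/2 S², Lᵢⱼ = S) reduces exactly to the
  2PD/(3√3 S ε) Σ(uⱼ−uᵢ) form — an identity the tests verify to 1e-12.
  Absent neighbors contribute nothing (zero flux).  Integration is fixed-step
  RK4 (default dτ = 0.2; the fixtures use 1–4, safely inside the stability
  region since the fastest linear rate is ≈ 0.26).
* **2D-cRD** (pixel grid): divergence-form diffusion with face diffusivities
  evaluated at cell-pair midpoints (P D on faces adjoining a marked
  interscale pixel), semi-implicit stepping (sparse-LU diffusion, explicit
  clamped reactions), zero-flux outer boundary.
* **3D-cRD** (curvilinear structured grid): see below.

**Growth.**  The mean edge length follows a logistic
S(τ) = k₁/(exp(−k₂τ + k₃) + 1); lengths and areas grow in proportion to the
reference geometry, taken at the **last** observed time point with
ε_ref = 1, so growth enters the equations only through the (S_ref/S(τ))²
factor on the diffusion exchange term.  A rate factor q converts between the
growth and RD clocks.

## Linear theory and color transforms

Linearizing the hexagonal dRD system about the HSS with neighbors pinned at
u* gives du/dt = M u + b with M = J − 6κD, κ = 2P/(3√3 S ε), and
−M⁻¹b = u* exactly.  The closed-form solution
u(t) = e^{Mt}(u₀ + M⁻¹b) − M⁻¹b is evaluated spectrally (dense expm as the
defective-matrix fallback).  When λ₁ > 0 trajectories collapse onto the
dominating eigenvector line u* + t′v₁ whose intersections with the six
clamping planes define the extremities u_g, u_b (labeled so v_g > v_b).
At the default parameters λ₁ > 0 for S ⪆ 1.4 (ε = 1), which is why the
synthetic fixtures use S = 2: the same lattice spacing then serves the
stable (S = 0.5) and unstable regimes in sign tests.

Juvenile CIELAB colors map to RD space through three affines: T₁ projects
onto the line through the K-means-2 cluster centers (C_g, C_b, relabeled so
L*_g > L*_b), T₂ carries that line onto [u_g, u_b], and T₃ contracts toward
u* by r ∈ [0, 1].  The reverse map Te (RD → color, used at post-juvenile
time points) carries the PCA ellipsoid of the RD cloud onto that of the
color cloud, Q = V_C D_C^{1/2} (V_u D_u^{1/2})⁻¹; the eigenvector sign
ambiguity is fixed by requiring positive correlation of the paired per-scale
PCA scores axis by axis, and rank-deficient covariances are jittered with a
warning.  Te is refit at every comparison time point by default (a
`refit_te` flag freezes the final-time fit instead).  RGB ↔ CIELAB uses the
D65/2° observer.

## Metrics and optimization

* **E16D**: (1/n_s)·L2 norm of the 16 signed differences of
  neighbor-configuration counts between two patterns — counts first, then
  the 1/n_s factor outside the square root, so the statistic scales like
  1/√n_s for fixed per-scale disagreement rates (a 100-scale fixture's
  values are ≈ √20 larger than a 2,000-scale animal's).
* **Esbs**: mean per-scale color distance normalized by ‖C_b − C_g‖;
  for binary patterns this reduces to the fraction of mismatched scales.
* **Objective**: mean over observation times of the per-time L1
  neighbor-count mismatch, with simulated continuous colors thresholded to
  the nearest cluster center (the consistent analogue of K-means
  thresholding of observations).

Bayesian optimization uses a noise-free zero-mean GP with Matérn-5/2 ARD
kernel; hyper-parameters are refit each iteration by marginal-likelihood
ascent (3 random restarts, log-space L-BFGS-B), the next point maximizes the
closed-form expected improvement via multi-start local search, evaluations
are cached, and non-finite objectives (invalid HSS, blow-ups) score a 1e6
penalty.  Kernel jitter starts at 1e-10 and escalates ×10 on Cholesky
failure (cap 1e-6).  The desk-scale default stop is 50 non-improving
iterations (configurable back to larger production values).  Greedy forward
selection starts from {q, r} and permanently adds whichever parameter's
optimized augmentation lowers the objective most, stopping at no
improvement.  The sensitivity scan perturbs each optimized parameter
jointly by U(−0.1σᵢ, +0.1σᵢ) with σᵢ the fitted length scales, and reports
a gamma MLE of the resulting Esbs histogram.

## Imaging stage

Mean curvature comes from the normal map via the fundamental forms
(E = 1 + (n₁/n₃)², …, H = (EN − 2FM + GL)/(2(EG − F²))) with central
differences (one-pixel border masked, n₃ ≈ 0 masked).  Scale detection
filters H with a Gaussian (σ = s/10) and median (window (s, s)) for
expected scale size s in pixels, then watersheds from h-minima markers
suppressed at 5% of the dynamic range; the field is reflect-padded by s so
frame-clipped basins complete themselves, and only minima whose markers lie
in the core window (≥ max(2, s/10) px from the frame, where mirror-artifact
minima concentrate) become scales.  The lattice is the Voronoi diagram of
segment centroids.  Per-scale colors are summarized over pixels at least
s/10 from a scale boundary: mean, per-channel median, and per-channel KDE
mode (the alternative color summaries the measurement-uncertainty analysis
probes).  Matching grows from ≥3 seed correspondences by local least-squares
affines over 3–10 nearest matched neighbors, accepting transfers within
ε = 0.05 × the mean neighbor-center distance; collinear matched patches
fall back to the closed-form similarity.  The unified space-time network
keeps connected components with exactly one node per time point, registers
each time point to the first with the closed-form similarity (shear and
anisotropic scaling excluded by construction), averages centers, and
rebuilds the Voronoi diagram — so pairwise connectivity conflicts are
resolved by the averaged geometry rather than by any single time point.

## 3D domains and the curvilinear solver

Skin relief is a hexagonal lattice of super-Gaussian bumps: within a cell,
h(r) = h_e + (h_c − h_e)·exp(−(r²/2σ²)^p), with per-bump h_c ~ N(h̄_c, σ_c)
and per-edge saddle heights h_e ~ N(h̄_e, σ_e) (non-positive draws are
resampled; the per-cell h_e is that of the edge toward the second-nearest
center, continuous to within the exponentially small tail overlap).  The
documented example shape is p = 1, σ = 0.28 S.  The chromatophore sheet
lies between the top surface and top − dm(d), where dm(d) is a quadratic
fitted through per-thickness-bin 75th-percentile melanophore depths.

The Laplacian on the resulting logically rectangular grid uses per-node
covariant bases estimated by least squares on each (≤27-point) stencil,
∇²u = g^{mn} ∂²u/∂y_m∂y_n + c_m ∂u/∂y_m, with the first-derivative
coefficients from finite differences of the basis field.  On rectilinear
grids this reduces exactly to the 7-point stencil and annihilates affine
fields; on warped grids it is consistent at O(h²) (interior) rather than
exactly affine-annihilating — an intrinsic property of the estimated-metric
finite-difference form.  Zero flux is imposed through the *physical*
boundary surfaces: on a boundary layer of computational axis a the outward
normal is parallel to ∇y_a, so g^{am} ∂u/∂y_m = 0 fixes the normal
computational derivative and corrects the mirror ghost.  This coupling is
what lets surface relief steer otherwise depth-uniform dynamics; a plain
computational-space mirror would decouple the geometry entirely.  Time
integration is backward Euler (implicit diffusion via BiCGSTAB with an ILU
preconditioner and a direct-solve fallback on breakdown, explicit clamped
reactions).  Volume weights carry trapezoid boundary factors so the Neumann
operator conserves the volume-weighted total on uniform grids.

Numerical caveat: on strongly under-resolved steep relief (e.g. bump height
half the spacing at ~5 nodes per spacing) the estimated-metric operator can
acquire spurious eigenvalues with positive real part and the implicit step
amplifies them; the solver guards against this by aborting on state
blow-up.  The shipped experiments use geometry (h̄_c = S/4, σ = 0.35 S,
≥6 nodes per spacing) verified to keep the spectrum in the left half-plane.

The thickness-heterogeneity experiment paints a shared per-scale initial
condition onto noisy domains drawn from the same spec, simulates each to the
comparison time, thresholds per-scale column means at u*, and reports the
binary Esbs of each noisy domain's pattern against the homogeneous-domain
reference, with a generalized-extreme-value MLE of the distribution.  With
σ_c = σ_e = 0 the noisy domain *is* the reference and Esbs = 0 exactly.

## Lyapunov analysis

Noisy initial conditions are C = C_ref + s C′ with s ~ U(0, 1) and rows of
C′ drawn from N(0, Cov(C_ref)).  Each perturbed run records
δ(τ) = ‖S_τ − S_τ^ref‖ over the full 3n_s-dimensional RD state and the
scale-by-scale errors at the first and final times.  The exponent is the
least-squares slope of log(δ/δ₀) over the pre-saturation window — by
default samples with δ below half the trace maximum within the first half
of the horizon (the window rule is a package default; the definition is the
early-time slope).  The initial-to-final error map is an isotonic
regression of Esbs_f on Esbs_0, evaluated at probe values (e.g. the
median/mode-vs-mean color summary displacements) with local empirical
spread; out-of-range probes are flagged as extrapolations.

## Synthetic data: what it does and does not emulate

Generators are pure functions of configuration and seed.  Random binary
patterns threshold Gaussian random fields on the scale centers
(squared-exponential kernel, log-uniform correlation length) at the target
green-fraction quantile, spanning speckle to quarter-domain patches.
`gen_truth_series` integrates the dRD model from a chosen initial condition
and maps states to CIELAB by carrying the position along the [u_b, u_g]
segment affinely onto [C_b, C_g], plus isotropic CIELAB noise (default SD
1.0) — a deliberately simple forward color model whose structure the
analysis-side Te fit does not assume.  Default conditions: 10×10 hexagonal
lattices (100 scales; scans cover 900–3,000), S = 2, six observation times
spanning the patterning transient, two CIELAB cluster centers (a
desaturated green, L* = 55, and a near-black, L* = 18) separated by ≈ 63
units as juvenile/adult dorsal colors are.  Normal maps are analytic bump
arrays encoded exactly as the imaging stage expects; matched pairs apply a
known similarity plus jitter and dropout.  What the synthetic data does
*not* reproduce: real scan noise structure (specular residues, segmentation
errors of asymmetric scales), anatomical color distributions, growth
anisotropy, and the ~2,000-scale extent of real dorsal patches — so green
tests certify the algorithms and their scaling behavior, not
field-condition performance.  Problem sizes throughout (100-scale lattices,
64-bump domains on ≤48×42×4 grids, 40–60-evaluation optimization budgets,
50-fit recovery ensembles) are desk-scale choices that preserve every
qualitative regime of the full-size study.

## Known limitations

* The caps (Fmax, Gmax, Hmax) and per-parameter optimization bounds are
  placeholders; conclusions sensitive to them must supply calibrated values.
* The 16-bin metrics lose power below ~50 scales; binary Esbs on 64 scales
  is quantized at 1/64 steps.
* The curvilinear operator is non-self-adjoint; very steep, under-resolved
  relief can destabilize it (see the spectrum guard above).
* Color patterns with more than two steady-state colors (as some gecko
  patterns suggest) are out of scope: the transforms assume exactly two
  cluster centers.
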
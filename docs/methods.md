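# Methods

This note records the models implemented in `lvflow`, their assumptions, the
defaults and why, the numerical choices, and what the synthetic fixtures do
and do not emulate.

## Triple decomposition (`lvflow.tensors`)

The velocity gradient `g` (convention `g[i, j] = ∂uᵢ/∂xⱼ`, units 1/s) is
factored with a real Schur decomposition `g = Q T Qᵀ` and split in the Schur
frame into a diagonal part (irrotational strain, EL), the skew part of the
2×2 rotation block (rigid rotation, RR) and the strictly upper-triangular
remainder (shear, SH).  Magnitudes are Frobenius norms; the rotation
magnitude is √2·γ with γ the block subdiagonal entry.

A real Schur factorization is not unique, so three conventions make the
output deterministic; none affects the magnitudes:

* the 1×1 real-eigenvalue block is reordered to the leading position
  (LAPACK eigenvalue reordering via `scipy.linalg.schur(sort=...)`; real
  eigenvalues are identified by the factorization's own block structure —
  their imaginary parts are exactly zero — so no imaginary-part tolerance is
  introduced, and degeneracies fall into the all-real branch with RR = 0);
* if the 2×2 block has |t₁₂| < |t₂₁|, rows/columns 2 and 3 are swapped
  (a permutation similarity), enforcing |β| ≥ |γ|;
* a diagonal ±1 similarity makes γ ≥ 0.

The diagonal entries of the standardized 2×2 block are averaged to be
exactly equal (they agree to rounding already), so identities like
`el = diag(λ, α, α)` hold by construction.

The trace is *not* forced to zero: discrete gradients of incompressible
fields are never exactly divergence-free, and the residual divergence lands
in the strain part where it is visible rather than silently redistributed.
Non-finite input raises immediately.

`el + rr + sh` reconstructs `T` entrywise by construction; the single entry
assembled from two floating-point terms (the (1,2) shear entry β+γ against
rr's −γ) can differ from `T` by one ulp, so tests verify reconstruction at
1e-13 relative rather than bit equality.

## Scalar shear stress

The von Mises-like SSS uses the shear-rate tensor `γ̇ = g + gᵀ` without the
viscosity factor, keeping units at 1/s so it is directly comparable to the
triple-decomposition magnitudes.  It equals the triple shear for single-plane
shear tensors, vanishes for rigid rotation, and is strictly positive for
nonzero trace-free diagonal (purely straining) tensors where the triple
shear is zero — `sss(diag(1, 2, −3)) = √28` with zero triple shear is the
package's quantitative demonstration of strain contamination.

## Gridded fields (`lvflow.fields`)

Velocity snapshots live on uniform rectilinear grids (node-based sampling).
Gradients are second-order central differences at interior nodes; on an
unmasked grid the boundary planes use one-sided second-order stencils.  With
a domain mask, only nodes whose full 6-point central stencil stays inside
the mask are defined — there is no one-sided fallback toward the wall,
because low-order near-wall stencils would bias exactly the near-wall shear
this analysis is meant to quantify.  Undefined nodes carry NaN and are
excluded from all statistics; they are never zero-filled, which would
corrupt volume averages.

Whole-field decomposition uses a vectorized magnitude computation
(batched eigenvalues plus invariant-plane algebra; see
`triple_magnitudes`) that agrees with the pointwise Schur route to rounding
and is cross-checked against it in the tests.  With all-real eigenvalues,
`el² = Σλᵢ²` and `sh² = ‖g‖²_F − Σλᵢ²`; with a complex pair, the 2×2 block
on the invariant plane yields the in-plane vorticity `w = M₀₁ − M₁₀` and
`s = hypot(M₀₀−M₁₁, M₀₁+M₁₀)`, giving `γ = (|w| − s)/2` and
`sh² = ‖g‖²_F − λ² − ‖M‖²_F + s²`.

Volume averages are trapezoid-weighted node sums (interior nodes weigh
dx·dy·dz, grid-boundary nodes half per boundary axis) over defined nodes
only — a stated convention; whether the original deforming-mesh averages
were cell- or vertex-weighted is not reconstructible here.  Structure
extraction binarizes strictly above the threshold and labels with fixed
26-connectivity (recorded choice; nothing in the source material fixes one),
returning voxel counts and physical-coordinate centroids sorted by size.

## Mitral valve model (`lvflow.valve`)

Two half ellipses share the intercommissural long axis.  Defaults are the
patient values: semi-long axis l = 12.8 mm, anterior short semi-axis
8.1 mm, posterior 11.6 mm, giving (π/2)·l·(saa + sap) = 3.96 cm² at E-wave
peak.  Opening/closing is driven by short-axis scale factors at six
keyframes (diastole start 0.420 s through diastole end 0.830 s); negative
scalings represent leaflet projections crossing the coaptation line and the
area is clamped at zero.  No explicit leaflet-overlap geometry is modelled
in the closed state — closure exists only through the clamp and the
point-in-orifice indicator.

Interpolation between keyframes is monotone piecewise-cubic Hermite
(Fritsch–Carlson tangents, `scipy.interpolate.PchipInterpolator`): tangents
vanish at extrema and across the diastasis plateau, preventing overshoot
past the physical maximum scaling of 1.0.  A free-tangent Catmull–Rom
scheme overshoots and misses the mid-diastole area.  "Mid diastole" is read
as the temporal midpoint of diastole, t = (0.420 + 0.830)/2 = 0.625 s,
where the schedule evaluates to 2.55 cm² — the only reading consistent with
the reported 2.54 cm², since the diastasis plateau itself evaluates to
2.45 cm².

### Clipped (edge-to-edge repaired) valve

The clip occupies `width` mm of the coaptation line centered at `s·l`
(−1 < s < 1).  The sub-openings' long semi-axes come directly from the
unclipped segments: a₁ = (l(1+s) − width/2)/2, a₂ = (l(1−s) − width/2)/2.
Each opening keeps the untreated anterior/posterior short-axis ratio, short
axes scale with their opening's long axis, and a common multiplier k is
fixed by conserving the total leaflet free-edge length at E-wave peak —
the sum of the four half-ellipse arcs equals the two untreated arcs.  "Edge
length" means the curved leaflet free edges only, excluding the straight
long-axis chord and the clip edges; the choice is isolated in
`half_ellipse_arc`.  Arcs are adaptive quadrature of the exact integrand
(relative tolerance 1e-10, cross-checked against complete elliptic
integrals in the tests); k is bracketed on [1, k_max] with doubling and
solved by Brent's method to 1e-10.

Clip width is a required parameter with default 5 mm: the reported
double-orifice areas are unreachable without one, and MitraClip-class
devices have arms of about 4–5 mm.  The reported post-clip areas therefore
depend on this calibratable width and are not treated as checked targets.

Two limits are exact and width-independent: at width → 0, s = 0 the
sub-openings are half-scale copies of the untreated orifice (perimeter is
homogeneous of degree 1, so k = 1 analytically) and the total area is
exactly half the untreated area at every time; and the geometry is mirror
symmetric under s → −s.

**Known (and initially surprising) property**: the total clipped area is
*not* monotone in clip width.  Conserving the free-edge length while the
clip shortens the long axis forces the short axes to grow (k strictly
increasing in width), and for small widths the bulge outweighs the lost
span — at s = 0.2 the E-wave-peak area rises from 2.060 cm² (width 0) to
2.138 cm² (width 4 mm) before falling (1.96 cm² at 10 mm).  This was
verified independently with elliptic-integral arc lengths.  The
acceptance-tier test asserting the conjectured monotone decrease is kept in
its original form and fails; the verified behaviour (k monotone, bulge,
eventual decrease, always below the untreated area) is asserted in the unit
suite.

`jet_reynolds_number` uses the diameter of the equivalent circle of the
orifice area as length scale: Re = ρUD/μ with blood defaults ρ = 1060 kg/m³,
μ = 0.0027 Pa·s; the E-wave inflow conditions (1.86 m/s, 4.0 cm²) give
Re ≈ 1.6×10⁴.

## Cardiac timing (`lvflow.timing`)

A cubic smoothing spline (scipy's natural-spline penalized fit) is fitted to
the sampled volumes; `smoothing` is the roughness-penalty weight, default
selected by generalized cross-validation (reproducible, overridable; zero
gives the natural interpolating spline).  Note a natural spline cannot
reproduce a general cubic polynomial near the boundary (its second
derivative is forced to zero at the ends); it interpolates every sample and
reproduces linear trends exactly.

Landmarks from dV/dt: diastole start is the first negative→positive zero
crossing at/after the global volume minimum (robust to small systolic
oscillations); E- and A-wave peaks are the two largest diastolic local
maxima (E the earlier), refined by bounded scalar minimization to 1e-6 s;
the diastasis bounds are the two original frame times bracketing the dV/dt
trough between the peaks; diastole end is the final sample.  Isovolumetric
phases are not represented.  If no second maximum exists (no A-wave), a
partial result flags the unresolved landmarks instead of guessing.

## Synthetic fixtures (`lvflow.synth`)

Analytic velocity fields with closed-form gradients: plane Couette
(u = (ky, 0, 0), default k = 100 1/s), solid-body rotation (ω = 50 1/s),
trace-free extensional flow, a Lamb–Oseen vortex (Γ = 0.01 m²/s,
r_c = 20 mm; core rotation rate Γ/(2πr_c²)), and a tanh-profile round jet
(U = 1 m/s, R = 20 mm, δ = 4 mm — a shear layer of thickness δ around an
irrotational core, the canonical structure of diastolic inflow).  Defaults
put rates in the tens-to-hundreds of 1/s band reported for ventricular
flow.  Grids are cubic, default 64³ over a 10 cm box centered on the flow
feature.  Every stochastic generator takes an explicit seed; there is no
global random state.

The volume-curve generator emits dV/dt as three beta-shaped bumps
(`x^a (1−x)^b` on their supports): systolic emptying on [0, 0.420 s]
integrating to −EDV·EF, an E-wave peaking at 0.525 s and vanishing at the
diastasis trough (0.6775 s), and an A-wave from the trough to 0.830 s
peaking at 0.779 s.  Defaults EDV = 117 ml, EF = 0.64, 25 frames.  The
E-wave carries 78% of the filling volume; peak filling rates then satisfy
E > A (ratio 1.19), the normal E/A morphology.  Exponents (systole (2, 1),
E rise 1.3, A rise 8) are chosen for realistic morphology: the E-wave
onset makes dV/dt cross zero transversally (volume curvature jumps positive
at end systole, as in measured curves — a tangential crossing would make
the landmark ill-conditioned), and the A-wave is the brief, peaked atrial
kick.  Integration uses the exact incomplete-beta antiderivative, so the
noise-free curve attains EDV and EDV·(1−EF) = 42.12 ml exactly.  Optional
Gaussian sampling noise is seeded.

What the fixtures do *not* emulate: ventricular geometry and its
deformation, turbulence and intermittency, measurement bias in
echocardiographic volumes (only additive Gaussian noise), and valve–flow
coupling.  Passing tests therefore certify the algebra, the discretization
and the detection logic — not fidelity to any patient's flow.

## Problem sizes in tests and the acceptance script

The exactness suite uses 10⁴ random tensors; frame invariance is spot
checked on 40 tensors × 5 rotations.  The convergence study runs 17³, 33³
and 65³ nodes (three spacing halvings, odd counts so a node sits on the
vortex axis) and measures max-norm errors against the closed forms,
observing order ≈ 2.0 for both the raw gradients and all modality fields.
Landmark recovery uses 100 curves at 25 frames with noise SD drawn
uniformly up to 2% of EDV; the recovery median is taken over the three
continuously-detected landmarks (diastole start, E peak, A peak) — the
frame-quantized diastasis bounds and the fixed diastole end would only
dilute it with zeros.  Measured: ≈ 3 ms median, with ≥ 90/100 curves
yielding a complete landmark set.
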
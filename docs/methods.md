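# Methods

This note documents the models implemented in `tledlite`, the parameters
that matter, the numerical choices made where the design was open, and what
the synthetic validation scenarios do and do not demonstrate.

## Governing equations and discretisation

The solver treats the large-deformation equilibrium ρü + ∇·σ(u) = f on a
3-D domain over a finite time horizon, semi-discretised with piecewise
(tri)linear elements into

    M Ü + D U̇ + Rint(U) = Rext,

with a **lumped** (diagonal) mass matrix — each element contributes ρVᵉ/k to
its k nodes, so ΣM = ρV exactly — and mass-proportional damping D = α_D M.
Damping is purely numerical: it is what turns the explicit dynamic solver
into a quasi-static one when loads are ramped and held.  Note that
mass-proportional damping decays *every* mode at rate α_D/2, so both rigid
oscillations and stiff mesh waves die out on the same time scale 2/α_D.

All kinematics are total Lagrangian: reference shape-function gradients
∂ₓh, element volumes, hourglass shape vectors and lumped masses are
computed once.  Per step and element, F = I + Σ Uᵢ⊗∂ₓhᵢ at the element
centre (one-point quadrature), C = FᵀF, S = S(C), and nodal forces
f⁽ᵉ⁾ = Vᵉ (F S) ∂ₓhᵢ accumulate into a single global array in fixed element
order, making runs bit-reproducible.

## Elements

**T4** — linear tetrahedron; ∂ₓh from the inverse edge matrix, Vᵉ =
det/6.  Overly stiff for nearly incompressible materials (volumetric
locking); retained as the baseline.

**H8** — trilinear hexahedron with one-point quadrature (f⁽ᵉ⁾ = 8 det J ∂h
S Fᵀ).  The four spurious zero-energy (hourglass) modes are stabilised with
precomputed Flanagan–Belytschko shape vectors γ_r = h_r − ∂ₓh (Xᵀ h_r),
which are exactly orthogonal to every affine nodal field, and a
stiffness-type force f_hg = κ μ Vᵉ^(2/3) Γ Γᵀ U per displacement component.
The control coefficient κ defaults to 0.075 and scales the forces linearly;
because f_hg is the gradient of the quadratic form ½ κ μ V^(2/3) |Γᵀ U|²,
the hourglass term preserves the solver's exact energy consistency.

**T4ANP** — nodal-averaged-pressure tetrahedron.  Per element J = det F;
per node a volume-weighted average J̄ₐ over adjacent elements (weights
Vᵉ/4, consistent with the lumped-mass partition); per element J̃ = mean of
its four J̄ₐ; the stress is evaluated at F̃ = (J̃/J)^{1/3} F.  Because F̃
couples neighbouring elements, the naive "standard force formula with
modified stress" is *not* the gradient of the total energy Σ Vᵉψ(C̃).  We
implement the exact consistent gradient: differentiation of Σ Vᵉψ(C̃(U))
gives a per-element first Piola–Kirchhoff-like tensor

    P̂ = Vᵉ α F̃ S(C̃) + g J F⁻ᵀ,   α = (J̃/J)^{1/3},

where the scalar g collects the volumetric coupling terms through the nodal
averages (see `elements.anp_internal_forces`).  g vanishes identically for
homogeneous deformations, so T4ANP reduces to T4 there, and the assembled
forces match central-difference energy gradients to the same 1e-5 relative
tolerance as the other element types.  This formulation is this package's
own design choice; the nodal-averaging weights themselves (volume/4) are a
documented convention.

## Constitutive models

Solid materials use the deviatoric/volumetric split

    ψ_NH = μ/2 (Ī₁ − 3) + κ/2 (J − 1)²,         Ī₁ = J^(−2/3) tr C,
    ψ_TI = ψ_NH + η/2 (Ī₄ − 1)²,                 Ī₄ = J^(−2/3) a₀ᵀ C a₀,

with penalty bulk modulus κ for near-incompressibility (no mixed
formulation beyond T4ANP).  Whether a compressible variant without the
J^(−2/3) split should be preferred is not decidable from the sources this
solver follows; the split form is the package's documented choice and all
validation oracles (numeric gradients, root-found uniaxial solutions) are
defined against it.  The membrane law is the plane incompressible
neo-Hookean stress S_ξ = μ(C₀⁻¹ − (II_{C₀}/II_{Cₙ}) Cₙ⁻¹); the energy
ψ = μ/2 (tr(C₀⁻¹Cₙ) + II_{C₀}/II_{Cₙ} − 3) reproduces it as 2∂ψ/∂Cₙ
(verified symbolically and numerically), which is what the membrane force
and energy-consistency tests rely on.

## Time integration

Central difference (default) with precomputed per-DOF diagonals A, B, C;
B + C = 1 per DOF is an algebraic identity of the damped scheme and is
asserted.  Explicit Newmark keeps numerical velocity and acceleration; its
effective load is evaluated at the current configuration Uₙ (the index
convention was ambiguous in the scheme's usual statement; this choice makes
the undamped first step from rest, dt² M⁻¹R, agree exactly with CDM).
Dirichlet values are substituted directly after each update; constrained
DOFs therefore follow their prescription bit-exactly.

The stable step of a 1-DOF mode ω is dt < 2/ω; an advisory estimate
dt_cr ≈ L_min/c, c = √((κ + 4μ/3)/ρ), is logged but never enforced — dt is
a user input.  Load shapes are step and ramp; a ramp may specify a
`ramp_time` shorter than the simulation so the load is held afterwards,
which (with damping) is how quasi-static solutions are produced.
Divergence (non-finite or > 10⁶ × mesh diameter) aborts with the step index.

## Reduced-order modelling

POD modes are the left singular vectors of a 3N × K snapshot matrix of
full-model displacements, taken about U = 0 (the reference state — no
centering).  The reduced mass M̂ = Φᵀ M Φ is Cholesky-factorised once.  The
reduced update

    U_{n+1} = γ₁ Φ M̂⁻¹ Φᵀ R_eff + γ₂ Uₙ + γ₃ U_{n−1},
    γ₁ = 2dt²/(α_D dt + 2),  γ₂ = 4/(α_D dt + 2),  γ₃ = 1 − γ₂,

keeps the full element-level force computation (R_eff is assembled at the
reconstructed displacement); only the update is reduced.  With a complete
orthonormal basis and α_D = 0 the update is algebraically the full CDM step
(asserted to 1e-8 over 100 steps).  The stable step of the reduced model is
2/ω̂_max where ω̂_max is the largest reduced eigenfrequency — the practical
limit on how far dt can be enlarged, which depends entirely on how smooth
the retained modes are.

### The cantilever validation scenario

Beam 0.1 × 0.1 × 1 m, 2 × 2 × 10 H8 elements, neo-Hookean μ = 1 kPa,
κ = 100 kPa, ρ = 1000 kg/m³, clamped at one end.  Four training runs apply
distinct tip-load *vectors* in the cross-section plane ((4,0), (0,4),
(3,3), (2,−2) mN over the tip face), ramped over 0.5 s and integrated for
40 s at dt = 2 ms with α_D = 0.2 s⁻¹, recording snapshots every 50 steps.
The load directions matter: with a single load direction the snapshot
manifold is only ~6–7 dimensional and the trailing POD modes of a 10-mode
basis pick up spatially rough content with eigenfrequencies of order
10² s⁻¹, which destroys the enlarged-step stability; spanning both bending
families fills all ten modes with smooth structural content (ω̂_max ≈
70 s⁻¹, reduced critical step ≈ 28 ms).  The sharp 0.5 s ramp deliberately
excites the decaying bending vibrations that populate the higher modes, and
α_D = 0.2 lets them persist long enough to be sampled while still decaying
stiff wave content over the run.  The held-out evaluation load is drawn
from within the training hull; the ROM runs at dt = 20 ms (10×) and its
final-displacement error against the full model at dt = 2 ms is ~0.4 %
relative L2 (the documented acceptance bound is 5 %).

## Contact

All contact is prediction–correction: the integrator produces a predictor
displacement, penetrations are searched at the predicted configuration, and
either displacement corrections or response forces are applied.

**Analytic surfaces** (rigid plate with in-plane extents and a ramped
translation; rigid cylinder with exterior-constraint semantics and ramped
radius): the closed-form gap g (negative = penetrated) and normal n give
the direct correction Δu = −g n, leaving corrected nodes with g ≥ −1e-12.
A point on the cylinder axis receives a fixed normal perpendicular to the
axis (documented tie-break).

**Mesh-based contact**: brute-force AABB-prefiltered search (margin
δ = 0.1 × minimum surface edge length, configurable) over the extracted
deformable surface, with BVH acceleration deliberately out of scope.
Disjoint bodies are identified by connected components; for each component
pair the lower label acts as master and node–facet detection runs one way
only (two-pass detection of the same pair over-corrects and injects
energy).  Narrow phase: per slave node the *closest* candidate facet
decides inside/outside, using point-to-triangle closest points and, for
edge/vertex features, the summed adjacent-facet pseudo-normal — plane-based
gaps alone misclassify nodes that sit outside the body but behind the plane
of a bulging silhouette facet.  Edge–edge crossings require strictly
interior closest-point parameters and are suppressed when their endpoints
already participate in node–facet events (face-to-face overlap otherwise
double-counts the same geometric contact through crossing diagonals).
Apparent penetrations deeper than δ between far-apart primitives are
discarded.

Response forces follow the explicit Lagrange-multiplier (mass-weighted)
form: f_s = −n β_s m_s g/dt² on the slave node and γ-distributed opposite
forces on the master vertices, with β_s = m_m/(m_s + m_m) from the
virtual-node mass interpolated at the projection point and γᵢ = hᵢ/Σh²_j.
A second integrator evaluation with the augmented effective load then
removes ≈ 95 % of the penetration in one step (the undamped algebra removes
it exactly; damping scales the correction by 2/(α_D dt + 2)).  Edge–edge
events use the 2-node shape functions; their normal is the closest-point
difference direction oriented to the master's outward side (interpretation
documented here).  Rigid masters take the limit β_s → 1, β_m → 0; forces
act on the deformable body only.  Friction is not modelled.

The two-cube compression fixture (two 2×2×2-H8 unit cubes, 20 mm initial
gap, upper cube pressed 80 mm over 2 s, dt = 20 ms, α_D = 10 s⁻¹) is the
standard regression scenario: at the step with the deepest pre-response
penetration the post-response penetration is ~1–5 % of it.

## Synthetic scenarios: scope and limits

All validation inputs are generated structured meshes of boxes and beams
with homogeneous materials and idealised boundary conditions.  They
exercise the discrete mechanics (energy consistency, invariances,
integrator algebra, contact response, ROM projection) exactly, but they do
not probe: irregular tetrahedralisations of patient anatomy, heterogeneous
material maps, near-incompressibility at clinically reported bulk/shear
ratios beyond 10³, self-collision of thin folded geometry, or frictional
contact.  Conclusions about real-tissue accuracy require the corresponding
meshes and constitutive fits; what passing tests show is that the solver
solves its stated equations correctly, not that those equations describe a
given tissue.

Problem sizes were chosen so the full suite runs in about a minute: the
cantilever study uses 99 nodes and ~100k full-model steps total; the
uniaxial cube uses a 2×2×2-element mesh settled to KE/SE < 1e-4 (measured
~1e-12).

## Known limitations

* Single element type per mesh; no mixed meshes or sub-model merging.
* Membrane only — the rotation-free shell (bending) element is not
  implemented.
* No viscoelastic or Ogden-type materials; no user material plugins.
* Contact has no friction and a brute-force broad phase; deformable–rigid
  contact against *triangulated* rigid surfaces is available through the
  API (infinite-mass limit) but not through the XML schema, which exposes
  the analytic plate and cylinder.
* Single-threaded; kernels are vectorised over elements with NumPy.
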
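# Methods

## Model and assumptions

The package solves a single-species reaction–diffusion equation for the
cytosolic cAMP concentration `C(x, t)` (μM) on a tetrahedralized cell
volume bounded by the plasma membrane (outer surface) and the nuclear
envelope (inner surface):

    ∂C/∂t = D ∇²C + S(t) − M(C, t)

* Synthesis `S` is either a uniform volumetric rate `E_AC` (μM/s) over the
  cytosol or, to confine adenylyl cyclase to the membrane, a Neumann influx
  `β` (μM·μm/s) on the plasma-membrane faces. The flux equivalent to a
  volumetric rate on the concentric-sphere cell follows from equating total
  production: `β = E_AC (R_o³ − R_i³) / (3 R_o²)`.
* Degradation `M(C) = V_max · C / (K_M + C)` (Michaelis–Menten) acts
  uniformly over the cytosol.
* Both terms can be delayed: synthesis is active for `t ≥ t_s`, degradation
  for `t ≥ t_d` (with `t_s ≤ t_d`). Phase intervals are closed on the left.
* Boundaries carry either zero flux (default) or prescribed concentrations
  (Dirichlet), per labelled surface.

Units throughout: μm, s, μM.

## Parameter defaults

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| `D` | diffusion coefficient | scenario-specific, 0.3–300 | μm²/s |
| `E_AC` | volumetric synthesis rate | 0.1412 | μM/s |
| `V_max` | maximal degradation rate | 0.295 | μM/s |
| `K_M` | Michaelis constant | 2.0 | μM |
| `C_o` | initial concentration | 0.05 | μM |
| `β` | membrane synthesis flux | 0.3611 (flux-equivalent) or 2.0 | μM·μm/s |
| `R_o`, `R_i` | cell / nucleus radii | 9.34, 5.26 | μm |
| `γ` | time-weighting | 2/3 | — |
| Δt | time step | 1–10 | s |

With these rates the well-mixed fixed point is
`C_ss = E_AC K_M / (V_max − E_AC) ≈ 1.83615 μM`. Note that a membrane flux
whose volume-averaged influx `β·S/V` exceeds `V_max` (e.g. β = 2 on the
reference sphere) has no finite steady state; concentrations keep rising
with a slope break when degradation activates.

## Spatial discretization

Linear (P1) tetrahedral elements. For an element with volume `V`:

* mass matrix `K1 = (V/20)(1·1ᵀ + I)` (consistent, not lumped);
* stiffness `K2 = V·D·BᵀB`, where `B` holds the constant shape-function
  gradients obtained from the edge matrix;
* linearized-degradation matrix `K3 = a·K1` with the element coefficient
  `a` below;
* membrane flux load `R1 = βA/3` on each node of a boundary face of area
  `A`; volumetric load `R2 = V·rate/4` per node.

Assembly is vectorized (einsum over all elements, COO → CSR). Dirichlet
conditions are applied by symmetric elimination. Verified element/assembly
identities: row sums of `K1` integrate constants, `B·1 = 0`, `K2` is
positive semi-definite with `K2·1 = 0`, sparse assembly matches a dense
brute-force oracle, and a patch test reproduces linear fields at interior
nodes to solver tolerance.

## Time integration and quasi-linearization

A γ-weighted implicit step (γ = 2/3, the linear-in-time Galerkin weight):

    [K1/Δt + γ(K2 + K3)] c_{i+1} = [K1/Δt − (1−γ)(K2 + K3)] c_i
                                   + (1−γ) R_i + γ R_{i+1}

The branch (which matrices/loads are present) is selected by the phase at
`t_{i+1}`, the time level being solved for; load vectors are evaluated per
the phase at their own time point. On the single step that crosses `t_d`,
`K3` multiplies both `c_i` and `c_{i+1}`, following the discrete equations
as printed in the source formulation.

The nonlinear degradation term is quasi-linearized about the current guess
`C1`: per element (using the mean of its four nodal values),

    a = V_max·K_M/(K_M + C1)²,    b = E_AC − V_max·C1²/(K_M + C1)²

and the step is re-solved, rebuilding `K3` and the linearized load, until
the relative max-norm change of the nodal vector is ≤ 1e-8 (at most 50
inner iterations; typical counts are 1–3). These inner-iteration controls
are engineering defaults — the source formulation does not state its
convergence criterion. No clamping of intermediate values is applied.

The scheme is unconditionally stable at the parameters of interest
(Δt up to 10 s verified) and shares its fixed points with the continuous
balance, so coarse steps still land on the correct steady state. Its
local truncation error is first order at γ = 2/3 (≈ (γ − 1/2)·Δt·C̈);
at Δt = 1 s the well-mixed curves track the analytic solution within
0.5–0.9% over 600 s.

## Mesh generation

Meshes are generated deterministically per seed without external meshers:
layered Fibonacci-sphere point clouds (seeded random rotation per layer
plus interior jitter) are tetrahedralized with `scipy.spatial.Delaunay`,
the domain is carved by a centroid filter, non-manifold edges are cleaned
by removing the smallest offending tetrahedra, elements are consistently
oriented, and boundary faces are classified by radius (sphere shell) or
implicit surface value (cell-like body: a super-ellipsoid of
15 × 10 × 4 μm with an off-center ellipsoidal nuclear cavity). Typical
quality at the working resolution (edge 2.4 μm on the shell): mean aspect
ratio (3·inradius/circumradius) ≈ 0.8, volume within ~1.3% of analytic.
This generator trades mesh grading control for determinism and zero
binary dependencies; very fine or very anisotropic meshes are out of scope.

Problem sizes are the package's own choice: working meshes run from ~180
to ~5000 nodes, which resolve the radial gradients of the scenarios here
at the stated tolerances.

## Verification metric

Time-course agreement is measured as the sup-norm of the difference
normalized by the maximum of the reference curve ("normalized sup").
Pointwise relative error is meaningless for curves that decay toward zero
(the ratio of two exponentially small numbers); the normalized sup bounds
the discrepancy everywhere on the scale of the signal itself. Under this
metric, degradation curves sharing `V_max/K_M = 0.059 /s` coincide within
0.5%, and FEM compartmental runs match the closed-form solution within 1%.

## Oracles

* Well-mixed balance: separation of variables gives an implicit relation
  `t(C)` solved per time point by bracketed root finding; cross-checked
  against adaptive Radau integration at rtol 1e-12. The pure-synthesis
  branch is exactly linear.
* Steady diffusion between concentric spheres with prescribed surface
  concentrations: `C(r) = A + B/r`.

## Limitations

* Single species, uniform kinetic parameters; no buffering, no PKA
  feedback, no subcellular compartment heterogeneity.
* First-order time accuracy (γ = 2/3); a single 1 s step carries ~1e-4
  absolute truncation error at the reference parameters, so tolerance
  targets below that require smaller steps.
* Consistent (non-lumped) mass matrix: very coarse meshes with sharp
  boundary loads can transiently undershoot slightly below physical bounds;
  runs warn if concentrations drop below −1e-6 μM.
* The mesh generator produces isotropic, moderately graded meshes only.
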
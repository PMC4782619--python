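# Methods

## Scope and model

`eitsim` simulates 2-D electrical impedance tomography on a circular
domain and reconstructs element conductivities from the simulated boundary
data. The electrical model is the low-frequency conduction equation
∇·(σ∇φ) = 0 with purely real conductivity; capacitive effects, contact
impedance and 3-D current spreading are outside the model. Current is
injected at *point* electrodes — single boundary nodes — rather than
through a complete electrode model: this matches the simulator the package
emulates and keeps the drive pattern a two-entry Neumann vector, at the
price of a logarithmic singularity of the potential at the drive nodes.
Consequences: the potential *at a drive electrode* does not converge under
mesh refinement, while potentials at all other electrodes do (observed
order ≈ 2 against the closed-form disk solution). Differential
(Brown–Segar) data never sample a drive electrode and are therefore the
safer mode when data and inversion use different meshes.

The 2-D system assumes unit (1 m) out-of-plane thickness; all potentials
scale inversely with the true thickness, which has no effect on
reconstruction geometry.

## Mesh family

The disk is meshed by a deterministic polar structured family: a centre
node, rings i = 1..m at radii iR/m, ring i carrying S·i equally spaced
nodes from angle 0. Each annulus strip is triangulated by merging the two
ring chains in angle order (ties advance the outer chain), giving S·(2i−1)
counter-clockwise triangles per annulus and the closed forms S·m² elements
and 1 + S·m(m+1)/2 nodes. The canonical configuration is S = 8; doubling
m is exactly the uniform 1→4 refinement of the family (edge midpoints
snapped to the twice-as-fine polar grid), so `refine_uniform` rebuilds on
the doubled grid and is node-for-node identical to `build_disk_mesh(R, 2m)`.

The tie rule makes the triangulation *chiral*: strip quads always split on
the same diagonal, so the mesh is exactly invariant under rotation by
2π/S but not under reflection. Mirror symmetries of the continuum problem
(e.g. antisymmetry of the potential about a drive pair's bisector)
therefore hold only up to discretization error, vanishing at first order
or better under refinement; the test suite checks them as convergence
properties, not as exact identities.

Electrodes are every (S·m/16)-th boundary node starting at angle 0
(electrode E1); S·m must be divisible by the electrode count.

## Phantoms

A phantom is σ_b on the disk plus circular anomalies (polar centre,
radius, σ_i), validated to lie inside the domain and pairwise disjoint
(overlap is an error, not last-wins). Realization assigns each element the
conductivity at its centroid, with strictly-inside membership: a centroid
within 10⁻¹² (relative) of the rim counts as background, making the
assignment deterministic. The discrete anomaly area converges to the
analytic disk area at O(h).

Default study conditions, used by the fixture catalogue and the worked
examples: 75 mm domain radius, σ_b = 0.21 S/m, σ_i = 0.005 S/m, 1 mA
drive, data simulated on the m = 16 (2048-element) mesh.

## Forward solver

Element matrices σ_e(bbᵀ + ccᵀ)/(4A) are scatter-added into a sparse
symmetric K with zero row sums; grounding removes the ground row/column,
leaving an SPD system factorized once (SuperLU) and reused for all 16
drive columns and all adjoint columns. The ground node is the disk centre:
it is equidistant from all electrodes, preserves the 8-fold symmetry, and
pins the potential reference in both measurement modes. The closed-form
reference used in validation is the boundary point source/sink pair on a
homogeneous disk, φ = (I/πσ)·ln(|x−B|/|x−A|), which is zero at the centre
and so shares the solver's gauge.

## Inverse solver

Gauss–Newton with identity-operator Tikhonov regularization. Numerical
choices:

- **λ** (default `auto`): 10⁻³ · max diag(JᵀJ), computed at the first
  iteration and held fixed. The rule is scale-free — it tracks the squared
  sensitivity scale, so it survives changes of drive current, conductivity
  scale and mesh size. Overridable with any positive scalar.
- **Variants**: `eq20` (default) drops the penalty gradient λσ from the
  right-hand side; `eq19` keeps it. The two first steps differ by exactly
  −λ(JᵀJ+λI)⁻¹σ, which the tests verify to 10⁻¹⁰.
- **σ₀**: uniform background conductivity by default.
- **Positivity floor** 10⁻⁶ S/m after every update; the admittance matrix
  requires σ > 0. With the high-contrast benchmark phantom (42× contrast)
  the floor is active in the anomaly, so reconstructed minima saturate at
  the floor rather than at σ_i.
- **Jacobian** recomputed every iteration from the adjoint products; the
  per-element integral is exact for linear elements. Sensitivities are
  homogeneous of degree −2 in σ (potentials are degree −1), which the
  tests confirm against a forward-perturbation oracle.
- **Stopping**: relative misfit ‖V_m − V_c‖/‖V_m‖ ≤ 10⁻⁶, or relative
  misfit stagnation below 10⁻⁶ between iterations, or `max_iter` (default
  15) updates. Divergence (misfit > 10³ × initial) returns a flagged
  partial result. The solve path contains no randomness, so identical
  inputs give bit-identical iterate histories.
- **Normal equations** are solved densely (Cholesky via
  `scipy.linalg.solve(assume_a="pos")`); inverse meshes in the intended
  range (≤ a few thousand elements) make this cheaper than iterative
  alternatives.

By default the recommended workflow avoids the inverse crime: data on the
m = 16 mesh, inversion on the m = 8 mesh. Same-mesh mode is used in tests
where a fixed point or an exact algebraic identity is the property under
test.

## Problem sizes and what the tests show

The validation suite runs the full pipeline at the study conditions above:
finite-difference Jacobian checks and reciprocity on the 512-element mesh,
convergence studies up to the 8192-element mesh, and the cross-mesh
recovery run (2048-element data, 512-element inversion, 10 updates). These
sizes reproduce every printed count of the mesh series exactly and keep
the whole suite in seconds.

Simulated data are noiseless by design (an additive-Gaussian hook with a
seeded generator exists but defaults to off). Passing tests therefore
demonstrate correctness of the discretization, protocol bookkeeping,
sensitivities and optimization loop — not robustness to measurement noise,
electrode movement or 3-D effects, which real tank data would add. The
qualitative recovery results (anomaly localized inside the true disk,
misfit decreasing over early iterations) are properties of this solver
under these conditions; image quality at a specific iteration count is a
property of a particular solver configuration and is deliberately not
asserted.

## Known limitations

- Point electrodes only; no complete electrode model, no contact
  impedance.
- Circular domains and circular anomalies only; no conductivity gradients.
- Identity regularization only; no spatial smoothing operator, no L-curve
  or GCV hyperparameter search, and no Hessian term in the update (the
  Gauss-Newton approximation drops it).
- The structured mesh cannot grade element size toward small off-centre
  anomalies; geometric accuracy of a 10 mm object on the 2048-element mesh
  is limited, which is exactly the regime the smallest-object ratio
  (13.3% of the phantom diameter) describes.
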
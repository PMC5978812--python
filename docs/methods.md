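# Methods

## Model

Cells are polygons bounded by straight edges meeting at trijunctions; the
degrees of freedom are the vertex positions. In dimensionless form (lengths
on the square root of the preferred area, stresses on `K A_0` with `K` the
area stiffness) each cell has energy
`U_a = (A_a - 1)^2 / 2 + Γ (L_a - L_0)^2 / 2`, with contractility `Γ > 0`
and preferred perimeter `L_0 = -Λ/(2Γ)` set by the line tension `Λ`. The
constant completing the square (`-Λ²/4Γ²`) is dropped; forces are
unaffected. The force a cell exerts at its vertex `i` is
`f_i = -P p_i + T q_i` with `P = A - 1`, `T = Γ(L - L_0)`,
`p_i = (R_{i+1} - R_{i-1}) × ẑ / 2` and `q_i = t̂_i - t̂_{i-1}`; this is
exactly minus the analytic energy gradient (unit-tested against central
differences at 1e-7 absolute). Overdamped dynamics assigns each vertex a
drag `Σ A/Z` summed over its incident cells, so a cell's total drag scales
with its area.

The cell stress is `σ = -P_eff I + T J - Ṡ/2`, with
`P_eff = P + T L/(2A)` (a Young–Laplace-like cortical correction with
effective radius `2A/L`), `J = (L/2 I - Σ l t̂⊗t̂)/A` traceless, and the
rate-of-shape term active only when explicit vertex velocities are
supplied. Sign convention: `Tr σ = -2 P_eff`, so a cell under net tension
(`P_eff > 0`) has negative stress trace. Tissue stress over a region is the
area-weighted mean of cell stresses; at equilibrium its isotropic part
equals `-P_ext` by the load constraint.

Two eigen-orderings coexist deliberately: cell *shape* axes order
eigenvalues by value (major axis = largest), stress *classification*
orders by magnitude (as in the four tension/compression × round/elongated
classes), while the stress–shape *alignment* measure pairs the shape major
axis with the most tensile (algebraically smallest) stress eigenvector —
the pairing that is consistent across all four classes.

### Alignment is strong but not exact here

The shape tensor `S = Σ R⊗R / Z` (vertex mean as centre — required so the
centred vertices sum to zero) and the stress tensor do not commute as an
algebraic identity (exact-arithmetic counterexample: any scalene
triangle), and in monolayers relaxed to `max |f| ≈ 3e-8` the relative
commutator plateaus near 1e-2 independently of the force tolerance. The
measured misalignment across an equilibrium monolayer has median below
0.02 rad and 90th percentile below 0.1 rad (asserted in the unit suite);
the outliers are nearly round cells whose axes are ill-conditioned. We
therefore treat exact per-cell alignment as an approximation that is
excellent for visibly elongated cells, and the test suite pins the
distributional statement rather than a per-cell identity. Alignment is
reported as `nan` for cells whose eigenvalue gap is below 1e-6 relative.

## Simulation protocol

1. **Seeds** — Matérn type-II hard-core points: a Poisson proposal with
   uniform marks, deleting any point with a lower-marked neighbour within
   the hardcore radius (periodic metric); the intensity is doubled until
   enough survivors exist, then survivors are subsampled to the target
   count. The hardcore radius defaults to 0.6·sqrt(box²/(π n)) — ~60% of
   the mean spacing — strong enough to suppress sliver cells while keeping
   thinning feasible; it is the main knob controlling quenched disorder.
2. **Tessellation** — periodic Voronoi via 3×3 tiling; central cells are
   extracted and vertices re-identified across the boundary (KD-tree merge
   with periodic metric, union-find). Cocircular degeneracies are resolved
   by an escalating random nudge (1e-6 of the box and up) and retry.
3. **Relaxation** — L-BFGS-B on all vertex coordinates with the analytic
   forces as gradient, converged on the maximum force residual (default
   1e-6; residuals below ~1e-8 on hundreds of cells are not reachable in
   double precision and trigger a stall warning). Minimisation is
   interrupted whenever a watched edge drops below the T1 trigger.
4. **Topology** — T1 when an edge falls below `0.1 sqrt(A_6*)`: the edge
   rotates 90° about its midpoint, the two edge-sharing cells each lose a
   vertex and the two flanking cells gain one; the flanking cell's edge
   that bordered cell A is redirected to the new A–C–D junction (a purely
   topological rule; geometric heuristics proved ambiguous for tiny
   edges). The new edge length is 1.5× the trigger, preventing immediate
   re-firing. T2 when a triangle's area falls below `0.3 A_6*`: its three
   vertices merge at their mean. One transition fires per outer iteration
   (smallest triangle first, else shortest edge), followed by
   re-relaxation; a T1 refused by triangle adjacency blocks that edge
   until the next successful transition. `A_6*` is the equilibrium hexagon
   area at the imposed load (the larger root in the bistable region), so
   loaded runs scale their thresholds the way the load-rescaling symmetry
   scales their cells.
5. **Load control** — secant iteration on a global scale factor applied to
   the box and all vertices, re-relaxing each step, until the
   area-weighted mean effective pressure matches `P_ext` within 1e-3
   (tolerance configurable); cumulative scales outside [0.5, 2] abort.

Everything is deterministic given the integer seed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `Λ`, `Γ` | — | line tension and contractility (dimensionless); `(−0.26, 0.17)` is the *Xenopus* best fit, `L_0 ≈ 0.76` |
| `P_ext` | 0 | isotropic boundary pressure; must exceed −1 |
| `force_tolerance` | 1e-6 | max junction force at convergence |
| `t1_length_factor` | 0.1 | T1 trigger in units of `sqrt(A_6*)` |
| `t2_area_factor` | 0.3 | T2 trigger in units of `A_6*` |
| `t1_post_factor` | 1.5 | post-T1 edge length / trigger length |
| `load_tolerance` | 1e-3 | bound on mean `P_eff − P_ext` |
| hardcore radius | 0.6·mean spacing | Matérn-II inhibition |

## Closed-form layer

Regular N-gons satisfy `L = μ_N sqrt(A)` with `μ_N = 2(N tan(π/N))^{1/2}`;
the equilibrium area solves a depressed cubic in `sqrt(A)`, handled
analytically (trigonometric branch for three real roots, Cardano for one,
explicit factorisation near the repeated-root locus so bistable-region
multiplicities classify robustly). The `(Λ, Γ)` plane splits into a soft
region (no shear resistance, `Λ < -2μ_6 Γ`), single- and double-equilibrium
regions, and a collapse region with no positive equilibrium area.

The disordered bulk modulus `K = Σ (A_a/2A)(2A_a + Γ L_0 L_a / 2A_a)` is
the exact derivative of the equilibrium load under *affine* dilation; the
fully re-relaxed numerical `A dP_ext/dA` on a 200-cell monolayer agrees
within ~2% (non-affine corrections are small for dilation). The honeycomb
shear modulus `G = 3√3 Γ (1 - L_0/L)` is likewise the affine pure-shear
response (matched to 1e-7 by the ± shear experiment); letting the vertices
relax at fixed box softens the measured response to roughly two thirds of
the closed form — the same split seen between earlier published
derivations — and a unit test documents that ordering. No closed form is
offered for the disordered shear modulus; only the perturbation estimator.

## Fitting

Simulated areas are normalised by the simulated population mean, mirroring
the per-experiment normalisation of the measured table; classes ≥ 8 pool
into "8+", triangles (never observed experimentally) are excluded from the
likelihood and reported separately. A simulated class with no cells
contributes the squared experimental mean (maximal penalty). The
likelihood's proportionality constant is fixed to 1 — only the argmax is
used. Grid points outside the stable region are skipped. Parameter
recovery at desk scale (200-cell monolayers, 3 realizations, 4×4 grid)
returns the generating grid point.

## What the generator emulates — and what it does not

The synthetic monolayers reproduce the *equilibrium packing statistics* of
the model: polygonal-class mix centred on hexagons, per-class area
ordering, trijunction topology, zero-load density. They do not emulate
curved cell edges, cell division or motility, fluctuations (equilibria are
quenched energy minima), multi-layer structure, or segmentation noise, so
green tests here validate the mechanics and statistics pipeline, not the
imaging path of real data. The circularity of real cells is systematically
over-predicted by this energy — a model limitation, not a pipeline one,
and the reason fitting uses areas rather than circularities.

## Known numerical limitations

* The square periodic box is a rigid constraint: the deviatoric tissue
  stress of a finite monolayer does not vanish exactly but only as the
  quenched disorder average, ~1e-2 at 100 cells and ~3e-3 at 800 cells; an
  isotropic box rescale cannot remove it.
* The zero-load box width of a disordered 800-cell monolayer at
  `(-0.1, 0.1)` is bounded above by the hexagonal estimate
  `sqrt(800 · A_6*) ≈ 18.9` (irregularity only raises perimeters, hence
  effective pressures, pushing the zero crossing to smaller areas); the
  simulated width converges to ~17.9.
* Force residuals below ~1e-8 are unattainable in double precision for
  hundreds of cells; the relaxation loop detects the stall and returns
  with a warning rather than spinning.
* Concave (but simple) cells can occur transiently and are reported by the
  validator, not repaired; collinear-vertex cells in imported
  segmentations are flagged as degenerate rather than fixed.
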
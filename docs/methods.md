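# Methods

This note documents the models, numerical choices and limitations behind
amdkit: what is computed, under which conventions, and what the synthetic
test systems do and do not demonstrate.

## Boost mathematics (`amd_core`)

The boost potential uses the standard aMD form ΔV = (E − V)²/(α + E − V)
for V < E and 0 otherwise. Key consequences, all enforced as invariants and
property tests:

* 0 ≤ ΔV < E − V, so the boosted energy V* = V + ΔV never crosses the
  reference energy E;
* dV*/dV = α²/(α + E − V)² lies in (0, 1], so V* is strictly increasing in
  V (state ordering preserved) and ΔV vanishes with zero slope at V = E
  (no force discontinuity at the branch point);
* |ΔV| ≤ (E − V)²/α, so α → ∞ recovers conventional MD exactly.

The boundary V = E is assigned to the unboosted branch; both branches give
ΔV = 0 and dV*/dV = 1 there, so the choice is cosmetic but fixed for
bit-exact tests.

**Dual boost composition.** The dihedral boost is applied first; the total
boost is then evaluated on the already-dihedral-boosted total energy,
V* = V_total + ΔV_d(V_dihed) + ΔV_t(V_total + ΔV_d).  The parameter recipe
is E_dihed = (1+λ)·V_dihed_avg, α_dihed = λ·V_dihed_avg/5,
E_total = V_total_avg + 0.2·N_atoms, α_total = 0.2·N_atoms, with λ = 0.3 by
default (the value recommended for membrane proteins).  The divisor 5 in
α_dihed is treated as a fixed constant of the recipe; it can be overridden
through an advanced argument but is not part of the normal interface.

Units are kcal/mol throughout; k_B = 0.0019872041 kcal/(mol·K).  The
default temperature wherever one is needed is 300 K (k_BT ≈ 0.596
kcal/mol) and is recorded in every profile's metadata.

## Toy dynamics (`toy_dynamics`)

**Integrator.** BAOAB Langevin splitting with unit mass, chosen for its
accurate configurational sampling at practical timesteps.  Defaults:
timestep 0.01 (reduced time), friction 1.0.  Noise is drawn in blocks from
a seeded PCG64 generator; identical configs and seeds give bit-identical
trajectories.  Boosted dynamics propagate the exact modified force
(force-scale factor × unbiased force); the per-frame ΔV is evaluated and
stored at save time, not every step.  Temperature 0 is allowed (it turns
the O-step into pure friction), which gives exact fixed-point tests at
potential minima.

**Toy surfaces.** The 1D double well V(x) = h·((x/w)² − 1)² has minima at
±w (V = 0) and barrier h at 0.  The 2D multi-well surface is a sum of
inverted Gaussians plus a weak confining quartic (strength 2e−4 about the
centroid of the well centres) so trajectories cannot escape to infinity;
the quartic adds ≲0.1 kcal/mol at wells within ~6 units of the centroid,
which is the main systematic distortion of relative well depths.

**Dual boost on toys.** Toy potentials have no dihedral/total split.  A
`BoostParameters` request therefore applies only its total term; a plain
`BoostSpec` is the natural way to boost a toy system.  (A potential could
declare a designated dihedral-like term; none of the built-ins do.)

**Analytic oracle.** `analytic_pmf` integrates e^{−V/k_BT} per bin with
64-node Gauss–Legendre quadrature.  Because it is *bin-integrated*, it is
directly comparable to histogram PMFs on the same edges without midpoint
bias — the comparison is exact in expectation, not merely to O(bin²).

**Study conditions for the double-well checks.** Barrier 2 kcal/mol
(≈3.4 k_BT at 300 K), wells at ±1, 10⁶ steps, save stride 100 (10⁴ frames,
decorrelated at the frame interval of 1 time unit).  The boosted runs use
E = 2.5 kcal/mol (just above the barrier) and α = 2.5: a moderate
acceleration that cuts the apparent barrier by more than half while
leaving the wells statistically resolvable.  Strong acceleration (α ≲ 1)
flattens the boosted landscape to within ~0.03 kcal/mol over ±0.3 units
around each well, at which point a well "position" is no longer
statistically meaningful at these frame counts — the same resolvability
trade-off that motivates choosing a proper acceleration level in practice.

## Synthetic reaction-coordinate generators

`synth_rc_series` draws i.i.d. samples from a Gaussian mixture; exact
per-component counts are recorded for test bookkeeping.  The defaults
emulate the three-state ionic-lock distance distribution of the apo M2
receptor:

| well | centre | σ | weight | minimum offset at 300 K |
|------|--------|-----|--------|--------------------------|
| closed | 4.6 Å | 0.55 Å | 0.605 | 0 |
| water-bridged | 6.4 Å | 0.55 Å | 0.261 | ≈0.5 kcal/mol |
| open | 14.2 Å | 1.5 Å | 0.134 | ≈1.5 kcal/mol |

The centres and the ≈1.5 kcal/mol open-well offset are the reported
landscape features; the widths and the bridged-well offset are this
package's choices, made once so that the emulated distribution satisfies
*all* the documented properties simultaneously: three distinct minima
*and* profiles that are insensitive to bin sizes of 0.1–0.5 Å.  Narrower
wells (σ ≈ 0.4 Å) would contradict the latter — their barrier curvature at
the 0.5 Å scale produces an irreducible ≈0.4 kcal/mol cross-bin-size
discretisation deviation even with exact (infinite) sampling, which we
verified analytically from exact bin masses.

`synth_dihedral_pairs` draws clustered (χ1, χ2) rotamers wrapped onto
(−180°, 180°]: inactive (−75°, 40°) dominant, intermediate (−165°, 40°)
≈2 kcal/mol up, active (−160°, −100°) ≈3 kcal/mol up, each with a 10°
isotropic spread.

**What the generators do not emulate:** time correlation (draws are
i.i.d., real trajectory frames are autocorrelated), coupling between
reaction coordinates, boost–coordinate correlation (synthetic ΔV streams
in the estimator tests are constructed directly), and non-Gaussian well
shapes.  Passing tests therefore demonstrate estimator correctness under
known ground truth, not robustness to every feature of receptor
trajectories.

## Free-energy estimation (`free_energy`)

* F_i = −k_BT·ln P_i with P_i the (weighted) fraction of frames in bin i;
  the minimum over defined bins is shifted to exactly 0 in every profile,
  1D and 2D.  Empty bins are NaN, never clipped to a cap.
* Bins are anchored at coordinate 0 for distances and at −180° for
  dihedrals, so different bin sizes share an origin (required for
  reproducible sweeps).  Periodic bin sizes must divide 360°; 3, 5, 6, 9,
  10, 12 and 15 all do.  Binning is left-closed with the last bin closed,
  accumulated with `bincount` in frame order so a naive sequential loop
  reproduces the weighted masses bit for bit.
* Values on the periodic seam: angles are wrapped onto (−180°, 180°], with
  −180° folded onto +180°; counts are conserved under any rotation of the
  origin.
* **Exponential reweighting** uses max-shifted exponentials, so
  arbitrarily large ΔV cannot overflow.  **Cumulant reweighting**
  (order 1 or 2) subtracts ⟨ΔV⟩_i + (β/2)·Var(ΔV)_i per bin (sample
  variance, ddof = 1) and re-zeroes; defined bins with too few ΔV samples
  are dropped and listed in the profile metadata.  Orders above 2 are
  rejected: higher cumulants amplify noise faster than they correct bias.
  The two estimators agree for per-bin Gaussian ΔV with σ ≲ k_BT and are
  *expected* to diverge for broad or heavy-tailed boosts — that divergence
  is the known failure mode of exponential reweighting at large system
  size, and the test suite asserts it rather than hiding it.
* **Profile comparison** re-zeroes both profiles at their minimum over the
  shared defined support (profiles are defined only up to a constant; the
  shared-support-minimum convention is this package's documented choice).
  Identical grids are compared elementwise; different grids by linear
  interpolation between bin centres at the finer profile's centres,
  excluding points that fall in undefined bins of either profile.
* **Bin-size sweep** reports the maximum pairwise deviation between
  profiles at the finest profile's bin centres, restricted to well-sampled
  support.  Two deliberate choices: (i) coarse profiles are evaluated by
  linear interpolation between bin centres, because piecewise-constant
  evaluation of a 0.5 Å profile at 0.1 Å centres carries an O(F′·w/2)
  staircase error on well walls that would dominate the statistic even at
  infinite sampling; (ii) the well-sampled threshold defaults to 0.2% of
  the frames (≥1 frame, i.e. 200 frames at the 10⁵-frame reference scale),
  because bins holding a handful of frames contribute pure Poisson noise
  of order k_BT, not information about binning precision.  Both the
  all-bins and threshold behaviour are reachable through `min_count`.
* **Minimum finding** uses prominence-filtered peak detection (default
  prominence 0.08 kcal/mol, several times the per-bin statistical noise of
  a well-sampled profile) with an optional occupancy filter, plus a
  least-squares parabola (`refine_minimum`) for sub-bin locations.

## Geometry (`geometry_rc`)

* PDB reading is backed by Bio.PDB behind the module interface: first
  model only, altloc ' ' or 'A', insertion codes preserved, residue
  numbering verbatim (Ballesteros–Weinstein labels are display metadata
  only, never used in computation).  A pre-scan supplies line-numbered
  errors for malformed coordinate records.
* Distances are Euclidean in Å between single named atoms.  The ionic-lock
  "charge centres" are implemented exactly as the Arg Cζ and Glu Cδ atoms,
  not as charge-weighted averages.
* Dihedrals use the atan2 construction
  atan2(|b2|·(b1×b2)·b3, (b1×b2)·(b2×b3)) on (−180°, 180°], verified
  against an independent geometry library; the sign flips under mirror
  reflection and is invariant under rigid motion to 1e−9°.
* Trp χ1 = N–CA–CB–CG and χ2 = CA–CB–CG–CD1.  The χ2 branch ambiguity
  (CD1 vs CD2) is resolved to CD1, the community convention; note a CD2
  choice would shift χ2 by ~180°, which matters when comparing rotamer
  well positions.
* `synthetic_receptor_fragment` builds a five-residue stand-in structure
  (Arg121, Tyr206, Glu382, Trp400, Tyr440) with idealised internal
  geometry, the Tyr206 OH–Tyr440 OH distance set to the crystallographic
  12.6 Å and the Trp400 rotamer set to the inactive (−75°, 40°) state *by
  construction*.  It is clearly labelled synthetic; it exists so the
  parse → select → measure pipeline can be exercised end to end without
  downloading coordinates, and tests against it verify the pipeline, not
  the crystal structure.

## Known limitations

* No all-atom MD, force fields, solvent or membranes; the Langevin engine
  is 1D/2D only.
* Exponential reweighting degrades rapidly once the per-bin boost spread
  exceeds a few k_BT (weight degeneracy); the package exposes counts so
  callers can bootstrap error bars, but provides none itself.
* The bin-size sweep measures precision (self-consistency), not accuracy;
  a biased but well-sampled landscape sweeps clean.
* WHAM-style multi-window combination, metadynamics/ABF and
  replica-exchange or scaled-MD variants are out of scope.
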
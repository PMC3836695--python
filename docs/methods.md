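# Methods

## The model

`cleftsim` implements a two-dimensional Glazier–Graner–Hogeweg (cellular
Potts) model of cleft progression in the embryonic (E12) mouse
submandibular salivary gland.  The epithelial bud is a grid of cells on
a square lattice; every lattice site carries the integer id of the cell
occupying it, and dynamics are Metropolis site-copy attempts biased by
an effective energy

    H = Σ_neighbours J(τ_i, τ_j)·(1 − δ_{σi,σj})        (contact)
      + Σ_cells λ_a (a − A)²                            (area)
      + Σ_cells λ_p (p − P)²                            (perimeter)
      + Σ_links λ (l − L)²                              (focal point plasticity)

A copy attempt overwrites a random interior site with the id of a random
neighbour and is accepted with probability `min(1, exp(−ΔH/T))`; one
Monte Carlo step (MCS) is `width·height` attempts.  Ties (ΔH = 0) are
accepted.  The temperature is fixed at `T = 10` and represents membrane
fluctuation amplitude; 1 MCS corresponds to 48 s of development and
1 px to 1.06 µm (`UnitConversions`), so the canonical 1500-MCS run
covers the 20-hour window between cleft initiation and the end of
progression.

Cell types: outer columnar cells (OCC) line the matrix interface, inner
polymorphic cells (IPC) fill the interior, and the two cleft walls are
their own types.  The matrix — basement membrane plus mesenchyme
collapsed into one compartment — is a single unconstrained cell (no
area/perimeter term) that initially owns the whole lattice.  A one-site
frame of matrix around the lattice is frozen (never overwritten) so the
matrix compartment cannot interact with the grid edge.

### Two cleft-wall types

The two opposing cleft walls are distinct cell types.  This is load
bearing: the cleft cell–cell contact energy CC (base 10, swept 1–20)
applies only across the *seam* between opposing walls, where the
localized epithelial-to-mesenchymal transition weakens E-cadherin
contacts, while cohesion within a wall stays at the epithelial baseline.
With a single cleft type, raising CC also unglues each wall internally
and high-CC conditions fragment instead of deepening — the opposite of
the reference behaviour.  Type-pair wiring is also what allows lateral
(cross-seam) and vertical (intra-wall) spring links to be distinguished.

### Focal point plasticity (FPP)

Actomyosin-contractility–driven fibronectin assembly in the cleft is not
modelled structurally; its cleft-opening effect is reproduced by spring
links on cell centroids:

* lateral links along the OCC boundary ring (target = one cell side,
  λ = 10) keep the epithelial outline coherent; the ring runs through
  the top cleft cells so the mouth is anchored to the boundary chain;
* vertical links down each wall (target = one cell side, λ = 10 in all
  conditions) keep each wall a coherent column;
* lateral links joining opposing wall cells at equal rank carry the
  experiment's contractility parameter λ (base 10) and a
  depth-dependent target width `W(D) = 402/(D + 11) − 5` px, the
  empirical width-depth relation of progressing ex-vivo clefts, clamped
  below at a configurable floor.  Rank k sits at depth `k·cell_side`, so
  targets fall from ≈31.5 px at the mouth to the floor at the tip: a
  wedge that holds the mouth open while the walls stay apposed at depth.

A hook re-evaluates the lateral targets every 10 MCS from the measured
matrix-finger depth (cheap column scan, not the full morphometric
pipeline): rank k's depth is `k/(n−1)` of the effective span, which
ratchets up from the designed wall extent as the cleft deepens, so
targets only tighten while the cleft progresses.

### Mitosis

Every 100 MCS, `rate · N_epithelial / 100` cells (floor + Bernoulli on
the fraction — plain rounding is biased at this population size of ~140
cells) are flagged mitotic, split between OCC and IPC by the configured
fraction (base: 1 % per cycle, 50/50).  A flagged cell's target area is
doubled (target perimeter × √2) and the area constraint grows it over
the following cycle; at the next cycle boundary it is split into two
equal halves along a random axis through the centroid.  A cell within
`completion_slack` (4 px²) of double size divides; otherwise division
defers a cycle.  Daughters revert to the original targets and are
re-typed by location (matrix-touching → OCC, interior → IPC); lateral
boundary links of an OCC parent follow the matrix-touching daughter.
Cleft-wall cells are excluded from the mitotic pool by default so the
link topology stays well defined.

### Morphometrics

The epithelium–matrix boundary is traced as an ordered 8-connected
pixel contour (Moore neighbour tracing).  The cleft centre is the
boundary point with the smallest angle subtended by its ±8-index trace
neighbours, restricted to concave points (the chord between the
neighbours must cross the matrix — this rejects sharp convex corners of
the bud outline) and below 150°.  Extrema are grown outward from the
centre point by point, refitting a total-least-squares line, until the
mean squared perpendicular residual first exceeds a threshold.

Two protocol details matter:

* **Threshold.**  Default 3.0 px², chosen (one calibration pass on the
  base case) so the extrema land at the cleft mouth on T = 10 simulated
  boundaries, whose line-fit residual plateaus near 2 px² along a wall.
* **Corner snap.**  A mean-squared criterion systematically overshoots a
  sharp mouth corner because the long straight wall dilutes the
  residual.  After the stop, the extremum snaps back to the nearest
  strong (≥35°) local turn of the boundary.  This is on by default and
  gives sub-pixel corner recovery on clean label masks; the simulated
  measurement protocol disables it because Monte-Carlo boundaries carry
  strong jags everywhere.

Indices: depth = distance from the centre to the midpoint of the
extrema segment; spanning angle = angle at the centre subtended by the
extrema; tilt = smaller of the complementary angles between the extrema
segment and the depth segment.  Filters (precedence shallow → wide →
tilt): depth < 5 px discarded, spanning > 160° discarded, tilt < 45°
labelled a failed cleft.  Multi-cleft snapshots take candidate centres
sharpest-first with non-maximum suppression (≥16 trace points apart),
capping each cleft's extrema search at the nearest other candidate.

### Sweep and classification

The factorial sweep varies MR ∈ {0.5, 1, 2, 3} %, FPP λ ∈
{1, 5, 10, 15, 20, 30}, CC ∈ {1, 5, 10, 15, 20} and CM ∈ {1…5}
(600 combinations; the level lists follow the individually tested
values).  Final depths are classified failed (< 17.8 µm),
non-progressive [17.8, 30.5), progressive [30.5, 40.7] or
super-progressive (> 40.7 µm); a combination's class is the majority
over its replicates, ties resolved by classifying the median depth.
Feature importance: 50 combinations per class (without replacement
where possible; resampling is flagged), features standardized, an
RBF-kernel SVM (C = 1, γ = 'scale') 10-fold cross-validated for each of
the 15 non-empty feature subsets; the drop in testing accuracy versus
the full set ranks importance.  Fold counts shrink automatically when a
class sample is smaller than 10.

## Calibrated constants

The reference study left several constants unstated (lattice size,
neighbour orders, constraint strengths, non-cleft contact energies).
They were fixed by a one-time calibration against the base case and are
the package defaults:

| constant | value | notes |
|---|---|---|
| lattice | 160 × 124 px | epithelium 15 × 10 cells of 6 × 6 px |
| contact neighbourhood | 2nd order (8 sites) | copy neighbourhood 1st order |
| λ_area | 8 | tissue effectively incompressible at T = 10 |
| λ_perimeter | 2 (all types) | membrane stiffness |
| P targets | OCC/cleft 24, IPC 28 | IPC margin encourages irregular shapes |
| J baseline | 5 | OCC–OCC 4, IPC–IPC 6 (ordering: OCC cohesive, IPC loose) |
| J OCC–matrix | 4 | boundary tension; larger values seal cleft mouths |
| J IPC–matrix | 12 | keeps IPC interior (must exceed OCC–matrix) |
| W(D) floor | 8 px | ≈ centroid distance of apposed walls; lower floors pull deep wall pairs into overlap and expel the matrix finger |
| extrema MSE threshold | 3.0 px² | see morphometrics |

## What the tests do and do not show

The decidable suite checks the engine (incremental ΔH against a
recompute oracle, the Boltzmann acceptance law, conservation,
determinism, cache integrity) and the geometry pipeline against
synthetic V/U cleft masks with analytically known indices.  The
synthetic masks have clean walls and well-defined mouth corners; they
validate the measurement chain, not the realism of simulated boundary
textures.

The stochastic suite compares replicate means (n = 20) of the model's
outcome statistics with the reference values at a tolerance of
max(15 % relative, one standard error of the mean).  Under the frozen
calibration the base case (31.2 µm / 53° over 20 replicates vs 34.1 µm
/ 46°), the CC = 1/5/15, CM = 5 and organ-level conditions reproduce,
as does the feature-importance ranking (CM least important on the
reduced grid).  Three behaviours do **not** reproduce and their tests
are left failing deliberately:

* λ = 1 and the no-FPP ablation stay too deep (30.3 / 16.0 µm vs 19.5 /
  12.6 µm): in this engine an opened seam is stabilized by the contact
  terms alone (CC = 10 against 2·CM = 6 favours matrix in the seam), so
  removing contractility does not collapse a cleft as strongly as in
  the reference runs, and the biphasic λ ordering holds only as
  no-FPP < λ30 < base.
* CC = 20 reaches 32.2 µm, about one standard error below CC = 15
  rather than above it (reference: 40.7 µm).
* Consequently the blebbistatin-mimic and ROCK-KD-mimic percentage
  reductions are far smaller than reported.

These are engine-level differences (per-pair contact bookkeeping and
the unstated constants interact with the swept parameters), not
measurement artifacts; the decisions that bound them are documented
above rather than papered over with wider tolerances.

## Numerical choices and degenerate inputs

* ΔH = 0 copy attempts are accepted (`e⁰ = 1`).
* A copy that would remove the last site of a cell that still carries
  links is rejected outright (it would orphan the link).
* No connectivity constraint is enforced; `LatticeState.fragment_counts`
  reports per-cell component counts so the T = 10 regime can be checked.
* Same-owner neighbour draws consume an attempt (the "N attempts per
  MCS" definition is literal).
* All stochasticity flows through one injected `numpy` Generator per
  simulation; sweep replicates derive seeds as a pure function of
  (master seed, combination, replicate).
* Degenerate measurement geometry (collinear/zero-length) is flagged
  `invalid`; snapshots with a detached cell can be measured with
  `largest_component=True` (the run pipeline does).
* Problem sizes used by the shipped tests and the acceptance analysis:
  20 replicates per condition at the default 160 × 124 lattice, and a
  2 × 3 × 2 × 2 × 3-replicate sweep for the importance smoke test; the
  full 600 × 40 sweep is an overnight batch run via
  `cleftsim sweep --grid full`.

## Known limitations

* 2D only; no chemical fields, no structural basement-membrane
  mechanics, no mesenchymal cell agents, no apoptosis.
* Division halves are balanced but connectivity of each half is not
  guaranteed for highly non-convex parents (rare at these sizes).
* Path-length-based motility statistics depend on the sampling cadence
  (default 10 MCS), which is reported alongside them.
* The dynamic target updater's effect is small at the calibrated
  width-rule floor; disabling it is supported but changes outcomes by
  less than replicate noise.
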
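# Methods

`lexatlas` implements a two-dimensional matrix taxonomy ("atlas") of
personality, emotion and behaviour words, and the computational machinery
built on it: semi-supervised scoring of a word catalogue by spring-network
relaxation, mapping of word-list constructs onto the atlas, and the design
of maximally discriminating dipole questionnaires.  This note records the
model, the numerical choices, and what the synthetic experiments do and do
not show.

## The atlas

Words descriptive of personality traits, emotions, behaviours and power are
placed in the square [-2, 2]² whose axes are **affiliation** (disconnection
−2 … connection +2) and **dominance** (submission −2 … dominance +2).  Each
axis is divided into five ordinal categories, giving 25 integer cells; the
centre cell (0, 0) holds neutral and involuntary behaviours and is excluded
from questionnaire design, leaving 24 design cells.

Continuous positions are snapped to cells by rounding each coordinate
half-away-from-zero and clamping to the grid.  Half-away-from-zero (rather
than banker's or half-up rounding) keeps the snap map equivariant under
reflection through the origin, `snap(-p) = -snap(p)`, which the
diametric-opposition rule for antonym pairs requires.  Inputs may overshoot
the square by at most 1e-9 (numerical slack from the solver) before being
clamped; larger violations are errors.

The identity key of a word is the pair (lemma, part of speech): the same
surface form may sit in different cells under different parts of speech
('humble' as an adjective is at (1, −2); as a verb at (−2, 1)).

## Spring-network scoring

A word catalogue is partially scored: *anchor* words carry fixed positions
(in practice, expert-judged archetypal words); all other words are placed
by minimising Hooke's-law spring energy over a synonym/antonym graph.  The
energy of a word at position p with scored neighbours q is

    E(p) = Σ_syn ½ k_syn w ‖p − q‖²
         + Σ_ant ½ k_ant w max(0, L₀ − ‖p − q‖)²

Synonym springs have rest length zero: distant synonyms attract strongly,
coincident ones exert no force.  Antonym springs have rest length L₀ and
exert no force beyond it: close antonyms repel, distant ones are at rest.
`w` is the edge's source count (1 or 2 reference thesauri); doubly attested
relations are twice as stiff.  This weighting can be disabled
(`weight_by_sources=False`).

Defaults (all configurable through `SpringConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| `k_syn`, `k_ant` | 1 | energy/cell² | only the ratio matters; equal weight to both relation types |
| `antonym_rest_length` | 2√2 ≈ 2.83 | cell units | see below |
| `threshold_start`, `threshold_step` | 100, 1 | percent | bootstrap schedule |
| `displacement_tolerance` | 1e-3 | cell units | convergence is invisible at snap resolution well before this |
| `max_sweeps` | 100 | — | noisy graphs may legitimately need more; non-convergence is a warning, not an error |
| `inner_solver_tolerance` | 1e-6 | gradient norm | far below the outer tolerance |
| `clamp_to_atlas` | true | — | words never leave the square |

**Antonym rest length.**  The rest length is the separation at which truly
antonymic words stop repelling.  Archetypal antonym pairs are reflections
through the origin, so their natural separation is 2‖p‖ — on average the
atlas *half*-diagonal 2√2, not the full diagonal 4√2.  Setting L₀ to the
full diagonal would leave every antonym pair inside the square permanently
compressed: even a perfectly reflected configuration feels an outward
force, and analytically a word with five synonym springs and one antonym
spring at its reflection is displaced ~0.6 cells outward — enough to flip
its cell.  The half-diagonal leaves reflected configurations force-free
while still repelling co-located antonyms strongly, and recovery
experiments confirm the difference (cell accuracy 0.92 vs 0.38 on the
noise-free benchmark).  The constant is exposed for sensitivity studies.

**Bootstrap (decreasing-threshold schedule).**  Starting from the anchors,
a threshold drops from 100% in 1-point steps; at each level every
still-unscored word whose fraction of already-scored neighbours (synonym
and antonym pooled) meets the threshold is placed at its equilibrium
against its scored neighbours, in alphabetical order, cascading within the
level until no further placement.  Words with no path to an anchor remain
unset and are reported; they are *not* defaulted to the origin, which
would silently distort occupancy statistics.

**Relaxation.**  After bootstrap, Gauss-Seidel sweeps visit every
non-anchor word in alphabetical (codepoint) order and move it to its
equilibrium given the *current* positions of its neighbours, until the
largest single-word displacement falls below tolerance.  Because each word
moves only if its own energy decreases, the total energy is non-increasing
across sweeps — asserted on every synthetic run.  Anchors are never moved
(bit-identical before and after).

**Per-word solver.**  With synonym springs only, the minimiser is the
weighted centroid of the neighbours, used in closed form.  Otherwise the
energy is minimised by projected gradient descent with backtracking and a
near-Newton initial step (the synonym Hessian is isotropic).  When first
placing a word, a reflection-symmetric 5×5 lattice of extra starts guards
against bad basins; during sweeps only the current position seeds the
descent (local relaxation).  Near-equal minima (within 1e-9 energy) break
toward the initial guess: the antonym hinge creates flat zero-force
plateaus, and without this tie-break a word on a plateau could hop between
equal-energy points indefinitely.  The start lattice, the tie-break, and
every arithmetic step commute with negation, so negating all anchors
negates all propagated positions to solver tolerance.

## Construct mapping and efficacy measures

A construct is a named set of poles, each a word list; optional dipoles
join opposing poles.  Words are resolved through the scored lexicon;
unresolvable words are logged, skipped, and reflected in a coverage
fraction.  Each pole gets a modal cell (most occupied; ties break toward
the cell nearest the pole centroid, then lexicographically) and a
centroid.

* **Completeness** — distinct modal cells over all poles (for a
  questionnaire: all dipole endpoint cells), divided by 24.  The
  denominator is fixed at 24 because the centre cell is excluded from
  design; a modal cell at the centre does not count toward the numerator.
* **Diffusion** — the pooled (word-weighted) fraction of mapped words
  lying outside their pole's modal cell.  Lower is sharper.
* **Discrimination** — the mean Euclidean distance between the two poles
  of each dipole, using exact cell coordinates when a pole occupies a
  single cell and the pole centroid otherwise.  Undefined (displayed
  "N/A") without dipoles; "undefined" and "0.0" are deliberately not
  conflated.

Density maps are bivariate Gaussian kernel sums evaluated on a regular
grid over the square, clipped to the atlas and renormalised to unit mass
(trapezoid quadrature).  The default bandwidth is Scott's rule per axis,
floored at 0.3 cell units so single-point and degenerate inputs remain
plottable.  The vectorised evaluation is tested against a naive
double-loop kernel sum to 1e-10 relative.

Construct correlations use the cosine of the angle between pole-difference
vectors (positive-pole centroid minus negative-pole centroid).

## Questionnaire design

A dipole question offers two antonyms from different cells plus an "n/a"
option, so 12 questions cover all 24 design cells (the covering bound
⌈24/2⌉).  The design space is the set of perfect matchings of the 24
cells, ~3.2×10¹¹.  The search maximises the *mean* Euclidean pair
distance and retains **all** optima:

* an exhaustive enumerator handles up to 12 cells ((n−1)!! matchings) and
  serves as the oracle;
* the exact solver is depth-first branch-and-bound: branch on the
  lowest-indexed free cell (cells pre-ordered by decreasing eccentricity),
  visit partners farthest-first, and prune with two admissible bounds —
  a cheap incremental one (half the sum over free cells of each cell's
  best remaining pair distance) and, where that fails to prune, a relaxed
  maximum-weight assignment bound (`scipy.optimize.linear_sum_assignment`
  with the diagonal forbidden; every matching is half of a symmetric
  self-avoiding assignment).  Ties within 1e-9 are kept, so the optimum
  set is exact.  On the full atlas the search visits ~100 nodes and
  returns in well under a second.

The result: the maximum mean distance is (12 + 12√2 + 8√5)/12 ≈ 3.9049,
attained by exactly 16 matchings.  The 16 factorises as 2⁴: every
maximizer pairs the eight off-axis cells (±2, ±1), (±1, ±2) with their
exact reflections, while each of the four origin lines carrying two cells
per side (both axes, both diagonals) admits one collinear swap that
preserves the pair-distance sum.  The matching that pairs every cell with
its reflection is always among the optima.

Uniform sampling of matchings (a uniformly random permutation paired off
consecutively) supports distribution studies; the sampled maximum can
never exceed the exact optimum, which is asserted.

Word selection is orientation-sensitive: the word in the lexicographically
smaller cell is listed first (the left-hand column of a printed test), and
the deterministic choice among eligible antonym pairs is the
lexicographically first.  Selection fails atomically, naming the first
cell pair the pool cannot cover.

Response scoring (each non-"n/a" answer contributes the chosen word's cell
coordinates; the profile is the mean vector) is an explicit un-normed
extension for exploratory use only.

## Synthetic data and the frozen benchmark

The generator plants ground truth so every component is testable without
external data: true positions are drawn either uniformly on the square or
from a mixture over the 25 cell centres (optionally with Gaussian spread
`cell_sigma`, default 0 — exact centres); synonym edges are sampled among
pairs within `synonym_radius` (0.8), antonym edges among pairs within
`antonym_tolerance` (0.8) of each other's reflection; sampling targets
`mean_degree` (6) with ~15% of edges antonymic; `edge_noise` (5%) of edges
are then rewired to uniformly random endpoints.  Anchors are an exact
⌈fraction·n⌉ random subset carrying their true position.  All generation
is a pure function of the parameter set including the seed.

The frozen regression benchmark is n=200 words on cell centres, 20%
anchors, mean degree 6, seed 7.  Thresholds were fixed from a reference
run of the pipeline before the regression tests were written, and are not
revisited: with 5% edge noise, RMSE ≤ 1.05 and cell accuracy ≥ 0.60
(measured 1.034 / 0.619); with no noise, RMSE ≤ 0.30 and cell accuracy
≥ 0.80 (measured 0.245 / 0.919).  Averaged over ten seeds, cell accuracy
rises monotonically with the anchor fraction (5% → 50%), and degrades as
edge noise rises.

What the synthetic world does *not* emulate: English thesaurus degree
distributions, polysemy, correlated judging errors, or the real
catalogue's uneven cell occupancy.  Passing the benchmark shows the
propagation machinery recovers planted structure of the stated kind; it
does not certify accuracy on real thesaurus graphs, whose noise is not
uniform rewiring.  Two regimes are worth naming explicitly.  With exact
cell centres, the 0.8 synonym radius links only same-cell words, so
cross-cell information flows solely through anchors and antonym
reflections; an anchor-free cell cluster is then localised only up to the
antonym plateau, which is why noise-free accuracy is high but not perfect.
And quadratically penalised rewired edges act as long, strong, wrong
springs — a 5% rewiring rate costs roughly 30 points of cell accuracy,
which is a property of the spring model itself, not of the optimiser.

## Known limitations

* The relaxation is local, sequential coordinate descent; no global
  optimality is claimed for the propagated configuration (only per-word
  optimality at convergence, and monotone energy).
* Sweep counts depend on graph size and noise; the published full-scale
  catalogue is not redistributable, so full-scale convergence behaviour
  (and its cell-occupancy table) cannot be reproduced here and is not
  asserted.
* Efficacy measures are atlas-relative by construction: they say nothing
  about a test's psychometric validity off the atlas.
* Response scoring is un-normed; no population calibration is provided.
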
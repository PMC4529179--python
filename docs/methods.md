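# Methods

## The problem

Constructing a virtual forest scene requires the position (and species) of
every plant over a large area, but field inventories cover only small plots.
Plant communities are not spatially random — arbors keep their distance,
shrubs aggregate — and these local arrangements repeat across a stand.
`vegsynth` treats a measured or designed plot as a *sample pattern* of a
stationary spatial process and grows an arbitrarily large pattern with the
same local arrangement statistics, in the spirit of Markov-random-field
texture synthesis applied to vector elements rather than pixels.

## Neighborhood histograms

The neighborhood of an element is the disc of radius `R` around it, divided
by `n_shells` concentric circles and `n_sectors` radial lines into
`n_shells * n_sectors` grids (default 3 x 8 = 24). Shells count 0..2 from
the inside out with equal width `r0 = R / n_shells`; sectors count 0..7
counterclockwise from the +x axis. Both radial and angular intervals are
half-open, so grid assignment partitions the punctured disc, and a neighbor
exactly at the outer radius is excluded. The local context of an element is
the vector of per-grid neighbor counts, one 24-bin histogram per species;
the flat bin index is `shell * n_sectors + sector`.

`r0` defaults to the shortest pairwise distance in the sample, so the
innermost circle can hold at most one neighbor.

## Histogram comparison

Two histograms p, q are compared with the quadratic form

    d_A^2(p, q) = (p - q) A (p - q)^T ,   a_ij = exp(-sigma * d(i, j)) ,

where `d(i, j) = |shell_i - shell_j| + |sector_i - sector_j|` is a grid
distance. With `A = I` this is the squared Euclidean distance; the
exponential off-diagonal terms let counts in adjacent grids partially cancel,
a deliberate blur that tolerates small positional noise between otherwise
similar neighborhoods. `sigma` (default 5.0, sensible range 1–10) sets how
fast that tolerance decays. The printed form of the quadratic expansion in
the source material reduces to the plain Euclidean distance — an evident
typo; the matrix form is what "adding a similarity matrix" can only mean.

Two sector-distance conventions are available: `literal` (as printed; sector
0 and 7 are 7 apart) and `circular` (wrap-around; they are adjacent). The
default is `literal` for fidelity; `circular` is arguably the better
geometry and is one flag away.

Multi-species patterns keep one histogram per species and combine per-species
distances as a weighted sum `d_z = sum_t w_t d_t` (uniform weights by
default; raising a species' weight makes the matcher respect its arrangement
more).

## The growth loop

1. **Initialize.** A seeded-random sample element is placed at the centre of
   the target region; its whole neighborhood is copied at rigid offsets.
2. **Select.** The unextended element inside the target region nearest the
   centre becomes the *extending element* (ties toward the lower id). Being
   nearest the centre, it has the most completed surroundings.
3. **Determine.** Grids of its disc that lie inside the union of previously
   extended discs are *determined*: their counts are trustworthy evidence.
   Coverage of a grid is decided by testing its representative point (the
   polar midpoint) — and, in the conservative variant the loop uses, its
   four corners — against the union.
4. **Match.** The sample element of the same species minimizing the combined
   masked histogram distance is found; undetermined bins contribute nothing,
   so unknowable counts never penalize a candidate. Exact ties break toward
   the candidate with the most neighbors (the most informative match), then
   the lowest id.
5. **Replenish.** The matching element's neighbors are copied around the
   extending element at rigid offsets, carrying species and any DBH /
   height / crown-width attributes verbatim. A copy is dropped if it lands
   (a) inside a previously extended disc — that territory is already
   complete, and re-pasting it would inflate density; (b) outside the target
   region inflated by one neighborhood radius; or (c) strictly closer than
   `conflict_radius_fraction * r0` (default 0.5) to an existing element.
   Since `r0` is the sample's minimum spacing, the conflict rule can never
   forbid a spacing the sample itself exhibits.
6. **Terminate.** The loop stops when every element inside the target region
   has been extended; the pattern is then clipped to the region. Elements
   copied into the margin are never extended but inform masks and
   histograms, which prevents edge starvation.

The single integer seed drives only the initial element choice; every other
step is deterministic, so a (sample, region, params, seed) tuple reproduces
bit-identical output.

### Sample-boundary handling

Sample analysis for synthesis is **periodic** by default: neighborhoods and
neighbor offsets are computed on the torus (minimum-image convention), so
every sample element carries a full, untruncated neighborhood. This is the
standard stationarity assumption for texture exemplars, and here it is
load-bearing: with plain bounded analysis, a sample-border element's
truncated histogram is exactly the signature of the synthesis frontier
(full on the known side, empty outward), so it wins matches at distance
zero, replenishes nothing, and the growth starves after a few dozen
elements. Periodic analysis requires the neighborhood radius to stay below
half the sample's shorter side; the radius is capped (with a warning) when
it does not. Plain analysis remains available via
`SynthesisParams(periodic_sample=False)` and in the per-element public
functions, whose contracts are non-periodic.

### Neighborhood radius policy

The growth frontier advances at most one neighborhood radius per extension,
and copies can only reproduce spacings the sample's discs contain. A radius
of `3 * min-distance` is adequate for designed or measured stands with
workable minimum spacing, but degenerates for processes with arbitrarily
close pairs: a Poisson or Matérn-cluster sample has `r0 -> 0` as n grows,
giving empty neighborhoods and a frontier that cannot cross inter-cluster
gaps. `synthesize` therefore floors the outer radius at
`connectivity_factor` (default 1.5) times the largest edge of the sample's
Euclidean minimum spanning tree — the smallest scale at which the sample is
connected by overlapping discs, and hence the smallest radius at which
growth can traverse its widest gap. For a regular lattice the floor is
inactive (the MST edge equals the minimum distance) and the behavior is
exactly the min-distance rule. An explicit `r0` overrides the whole policy.

### Determinism and the verbatim regime

On a self-consistent (torus-analyzed) sample the frontier's determined
evidence almost always has an exact sample match, and deterministic argmin
then continues the sample verbatim, wrapping periodically — the known
behavior of greedy exemplar-based synthesis without stochastic relaxation.
This is why the evaluation below finds density deviations near zero: the
synthesized master is locally indistinguishable from the sample by
construction. Visual variety can be reintroduced by lowering
`connectivity_factor`, using plain analysis, or synthesizing from several
seeds; adding stochastic match selection is deliberately out of scope.

## Evaluation

* **Density**: elements per unit area, with the sample region as the 1 x 1
  unit. Multi-species stands are evaluated per species.
* **Aggregation index**: the centred Ripley statistic `L(d) - d`, with
  `L(d) = sqrt(K(d)/pi)` and `K` the isotropic edge-corrected estimator
  (weights = inverse fraction of each pair-circle's circumference inside the
  window; valid for `d` below half the window's shorter side). Negative
  values indicate regularity, ~0 complete spatial randomness, positive
  clustering. All species are pooled.
* **PCT.DEV**: `|mean(I1, I2, I3) - Is| / |Is| * 100`, where `Is` is the
  sample's index and `I1..I3` are synthesis indices at increasing patch
  area. Reported to one decimal (two below 0.1%).

The patch protocol synthesizes one large master (10.5 x 10.5 sample units
here, so the largest patch fits strictly inside), draws 10 uniformly placed
axis-aligned interior windows per patch size (3 x 3, 6 x 6, 10 x 10;
distinct positions by rejection), averages the per-window indices per size,
and compares against the sample.

Choice of the evaluation distance `d` matters: the index of a lattice is
discontinuous at each neighbor-ring radius, and the index of a CSR pattern
is a near-zero random variable at every `d`. The packaged checks use
`d = 0.8 x spacing` for the regular class (inside the empty hard-core
interval, where `K = 0` and the index is exactly `-d`), and the protocol's
tabulated distances for the random (0.39) and clustered (0.19) classes.
A relative deviation bound on the aggregation index is only meaningful when
`|Is|` is large against the estimator's sampling variability; for a CSR
sample it is not, and the corresponding check fails by construction — a
limitation of the statistic, not of the synthesis (density deviation for the
same patterns is ~0).

## Synthetic samples

The generators stand in for designed and field-measured stands, one per
distribution class, all seeded and bounded:

* `gen_regular(64)` — 8 x 8 lattice on the unit square, spacing 0.125,
  optional jitter. Emulates a plantation-like regular stand of 64/unit.
* `gen_poisson(25)` — homogeneous Poisson (CSR), ~25/unit, the random
  class.
* `gen_cluster(25, 6.6, 0.08)` — Matérn cluster process (Poisson parents on
  the radius-inflated region, Poisson(6.6) offspring uniform in discs of
  radius 0.08), expected 165/unit, the clustered class.
* `gen_two_type(...)` — hard-core arbors (sequential minimum-distance
  thinning, ~172/unit at 0.04 spacing) plus clustered shrubs (~19/unit),
  optionally with lognormal DBH (cm), height (m) and crown width (m):
  arbors ln-mean log(25)/log(12)/log(3), shrubs log(3)/log(1.5)/log(0.8),
  ln-sd 0.25–0.3. The attribute distributions are conventions, not fits.

What the generators do **not** emulate: inhomogeneous intensity (soil or
elevation gradients), inter-species interaction beyond independence of the
two layers, measurement error in stem positions. Passing checks on these
samples therefore demonstrate that the synthesis preserves homogeneous
first- and second-order structure, not that it captures every feature of a
real inventory.

## Numerical choices

* Half-open shell and sector intervals; neighbors at exactly the outer
  radius excluded; coincident elements are an error for `r0` estimation.
* The similarity matrix is symmetric with unit diagonal by construction;
  at sigma = 5 the off-diagonal mass is ~e^-5 and the form is numerically
  positive definite (checked by eigenvalue in the suite's property range).
* Patch windows use closed bounds; window positions are continuous, so
  boundary coincidences have probability zero.
* Conflict and disc-membership tests are strict inequalities, matching the
  half-open histogram geometry.
* Spatial queries during growth use uniform-grid hashes (cell = query
  radius); matching is one vectorized quadratic form per extension over the
  precomputed sample histogram table.

## Known limitations

* Greedy and deterministic: no relaxation or optimization of copied
  positions, by design (it is what makes the method fast); the price is the
  verbatim-continuation regime described above.
* The representative-point determination rule is an approximation at coarse
  grids; the loop's conservative variant avoids its bias but slightly
  reduces usable evidence per match.
* Periodic sample analysis assumes the sample region's bounds are
  meaningful; for irregular survey plots embedded in a larger stand, plain
  analysis with a generous margin is the safer choice.
* Attributes are carried, never modeled: the synthesis reproduces the joint
  (position, species, size) combinations present in the sample only.
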
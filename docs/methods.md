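# Methods

`geodemes` simulates spatially explicit (or purely deme-structured)
Wright–Fisher populations forward in time, records the resulting
genealogies with recombination in succinct tables, reduces them to the
history of a chosen sample, overlays neutral mutations, and computes
standard population-genetic statistics and spatio-temporal ancestry
tables. This note documents the model, its parameters and defaults, the
numerical choices, what the built-in example models emulate, and the known
limitations.

## Demographic model and time handling

A model is a set of populations with scheduled events: splits (a daughter
population's founders are offspring of parents drawn from the parent
deme), stepwise or exponential resizes, range moves along piecewise-linear
trajectories, gradual range expansions/contractions, dispersal-parameter
changes, and windowed gene flow. Users give times in arbitrary units,
forward or backward; the direction is inferred from the order of splits
and event windows (or set explicitly). Compilation converts everything to
forward generation indices via `generation_time`: the oldest time in the
model is generation 1 and the run ends at generation
`G = round(|T1 − T0| / generation_time) + 1`. An `end_time` may be given;
by default a forward model ends at its latest mentioned time and a
backward model at time 0 ("the present"). Exported node and individual
times are converted back to user units.

Gene flow with total rate `r` over a window of `T` generations is
compiled to the per-generation ancestry rate `m = 1 − (1 − r)^(1/T)`
(so `1 − (1 − m)^T = r` exactly). Because gene flow is realized through
the *mate* (the second parent), which contributes only half an offspring's
genome, the engine draws the mate from the source population with
probability `2m` (capped at 1); then `(1 − 2m/2)^T = 1 − r`, so the
expected total ancestry contributed over the window is exactly `r`. This
bookkeeping is validated two ways: a pedigree-tracing Monte-Carlo test of
expected ancestry, and end-to-end recovery of a 10% admixture pulse by the
f4-ratio estimator.

Simultaneous events at one generation apply in a fixed order: resizes,
range updates, dispersal changes, gene-flow activation, sampling. Two
dispersal changes at the same generation: the later-declared wins, with a
warning.

## Landscape

Worlds are axis-aligned rectangles of abstract planar map units with
binary habitability: either the whole extent, or the union of named
polygonal regions. All geometry is polygonal (circles are regular 64-gons,
leaving <0.2% area error); membership is closed-set (boundary points are
habitable), which guarantees that rejection sampling terminates on thin
clipped regions. Range snapshots produced by moves and expansions are
clipped to the habitable area; compilation fails if any snapshot has zero
habitable area. Polygon offsetting and clipping delegate to GEOS (via
shapely); the contracts, not the algorithms, are normative. There is no
coordinate reference system: the real-Earth cartography layer of the
original workflow is out of scope here, and the example continent is an
abstract polygon.

## Reproduction

Generations are non-overlapping and census sizes follow the compiled
schedule exactly. Per offspring:

1. **First parent** — drawn with probability proportional to
   `w = 1 / (1 + n)`, where `n` is the number of same-deme individuals
   within the competition radius (`n` from a k-d tree; radius 0 means
   uniform). The `1/(1+n)` form is a bounded, scale-free stand-in for the
   qualitative "crowding lowers fitness" behaviour; it reproduces the
   patch self-organization expected when the competition radius greatly
   exceeds the dispersal scale.
2. **Mate** — uniform among same-deme individuals within the mating
   radius of the first parent (selfing excluded); if nobody is in range,
   the nearest individual is used so that the census never collapses. In
   an active gene-flow window the mate is instead drawn from the source
   deme (uniformly; in spatial mode uniformly within the mating radius
   when overlap is required, with an error if ≥99% of draws in a
   generation find no source individual in range).
3. **Gametes** — each parent contributes one recombined gamete: crossover
   count Poisson(ρL), breakpoints uniform on `[0, L)` (continuous), a
   fair coin for the starting haplotype. Edges are recorded per gamete.
4. **Location** (spatial mode) — offspring displace from the first
   parent's location. Kernels: `normal` = half-normal distance with scale
   σ and uniform direction; `uniform` = distance uniform on [0, σ];
   `cauchy` = half-Cauchy(σ); `exponential` = mean-σ distance;
   `brownian` = independent N(0, σ) per axis. Proposals outside the
   current range snapshot are redrawn; after `max_placement_attempts`
   (default 1000) rounds the offspring is placed uniformly in the range
   (logged teleport fallback), so placement never fails.

Spatial parameter defaults when unspecified: competition 0 (off), mating
radius = world diagonal (effectively global), dispersal = diagonal/50,
kernel `normal`. These defaults are this package's declaration, not a
claim about the original tool's internals.

Everything runs single-threaded off one seeded PCG64 generator, so a
fixed seed yields bit-identical tables, VCF and EIGENSTRAT output.

## Genealogy tables and simplification

Tables hold nodes (two per diploid), individuals (with birth location and
generation), edges (`[left, right)` inheritance intervals), and
sites/mutations (infinite-sites; ancestral "A", derived "T"). Node times
are stored as forward birth generations internally.

Simplification reduces the tables to a sample set: samples are renumbered
first (order preserved) and, per genomic interval, only ancestors that
are most recent common ancestors of at least two samples are retained
(unary nodes are dropped). The implementation propagates ancestry
segments up a parent-time-ordered edge table with an event-driven sweep
per parent (flat arrays, numba-jitted). Mutations are carried through by
re-attaching each to the output node that inherited its material at its
site. Correctness is established against two independent oracles: a
brute-force pedigree-tracing reconstruction of every marginal tree, and
tskit's simplifier (node-for-node and edge-for-edge agreement on random
histories).

Mutation overlay draws, per edge, Poisson(μ · span · branch-length)
mutations at uniform integer positions on the edge interval, redrawing
collisions (and dropping a mutation if its sub-basepair interval has no
free integer position — negligible at realistic spans). The usual
workflow is simplify-then-mutate; the overlay also works on raw tables.

The in-memory strategy is deliberately simple: raw tables for the whole
run, one simplification at the end. At the scales this package targets
(≲10⁷ individuals·generations, ≲2·10⁷ recorded edges) that is faster
than periodic in-run simplification and keeps peak memory within a few
gigabytes.

## Statistics

All statistics are site-mode, computed from derived-allele counts per
sample set obtained in a single left-to-right sweep that maintains the
current marginal tree and sums set membership below each mutation's node
(numba kernel). Diversity is the mean per-site pairwise difference;
divergence the mean over cross pairs (identical-node pairs excluded, with
a warning for overlapping sets); `f4(A,B;C,D)` is the mean over sites of
`(p_A − p_B)(p_C − p_D)` with no bias correction; the admixture
proportion is `f4(A,O;X,C) / f4(A,O;B,C)` (error when |denominator| <
1e-12); the AFS counts segregating sites by derived count, with a folded
option. All statistics are invariant under the node renumbering done by
simplification (tested).

## Example models as study conditions

* `example1_model` — the six-population admixture model used to teach the
  f4-ratio estimator: o at generation 1, c from o at 2500, a from c at
  3000, b from a at 4000, x1 and x2 from c at 4800, one gene-flow event
  b→x1 at rate 0.1 over 5500–6000, end at 6000 (generation time 1,
  N = 100 per deme by default). A `scale` argument divides the times.
* `f4_ratio_study` — the reduced-scale estimation study used by
  `scripts/acceptance.py` and the acceptance test: times/10, terminal
  demes of N = 1000, the internal branch "a" bottlenecked at N = 50 until
  b's split (then resized to 1000), L = 10 Mb, ρ = 4e-7, μ = 4e-8, 100
  individuals sampled per deme, estimates averaged over 5 seeds. The
  sizing is a conditioning choice made at design time: large terminal
  demes keep the realized ancestry of the pulse close to its expectation
  (many independent migrant matings), while the internal-branch
  bottleneck restores the strong shared drift that the full-length model
  achieves through time depth — the f4-ratio's denominator — without
  inflating drift noise elsewhere; the scaled-up recombination rate (4
  Morgans over 10 Mb) supplies many quasi-independent genealogies for the
  genome average. Expected output: ~10% ancestry in x1, ~0% in x2.
* `example2_model` — eight non-interacting demes on a featureless
  circular world differing only in competition radius (defaults
  N = 2000, 5000 generations, radius 50, dispersal 1, mating 2).
* `example3_like_model` — an abstract-continent analogue of a
  spatio-temporal range-dynamics model in "years before present"
  (generation time 30): a southern ancestral deme, a daughter that
  migrates northwest, an eastern deme that expands its range, late gene
  flow east→west, and scheduled sampling every 1000 years.

The spatial self-organization check uses dispersal σ = 3, mating radius 6
and competition radii 0.3 vs 25 map units on a radius-25 world (N = 200,
200 generations, two demes per regime). Because every individual's birth
location is recorded, the patchiness statistic — the coefficient of
variation of nearest-neighbour distances — is averaged over the final 100
generations, which stabilizes it enough for the regimes to separate
cleanly; the instantaneous final-generation CV is dominated by neutral
spatial clumping, which both regimes share at the dispersal scale.

## What the generators do not emulate

Synthetic worlds are abstract and habitability is binary; there are no
rasters, no real coastlines, no CRS distortion. Mutations are strictly
neutral, biallelic and infinite-sites; recombination is uniform; there is
no selection, no overlapping generations, no non-WF dynamics. Passing
tests therefore demonstrate the correctness of the WF-with-dispersal
machinery and its statistics, not realism of any particular empirical
system.

## Numerical choices and degenerate inputs

Rounding of user times to generations uses banker's rounding (`round`);
round-trips are exact to within half a generation. Zero-span edges from
coincident crossover breakpoints are dropped at recording time. Edge
tables are canonically ordered (parent birth generation descending, then
parent, child, left) and adjacent same-parent/child edges are squashed,
so serialization is byte-stable. Bundle WKT is written at full precision
so a load/save cycle is byte-identical and recompilation (which is pure)
reproduces the identical model. Degenerate geometry (empty habitable
intersections, annihilating contractions), sampling more individuals than
alive, size-1 populations asked to reproduce, and uninformative f4-ratio
configurations all raise errors naming the offending component.

## Known limitations

* Whole-run raw tables cap the practical scale at ~10⁷–10⁸ gametes;
  larger runs would need in-run simplification, which the table layout
  supports but the engine does not currently do.
* The competition fitness function and the spatial gene-flow semantics
  (mate draw across demes) are declared stand-ins where the source
  workflow's internals are unspecified; quantitative spatial results
  depend on them.
* Site-mode statistics only; branch-mode duplicates are not implemented.
* The f4-ratio applies no block-jackknife standard error; replicate seeds
  play that role in the validation studies.
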
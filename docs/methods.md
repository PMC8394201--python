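# Methods

## The model

S phase is simulated on a one-dimensional lattice of `L` blocks, one block
per kb to match the spatial resolution of DNA combing. Each block is 0
(unreplicated) or 1 (replicated). One Monte Carlo round represents
`round_minutes` of real time (default 2 min, so that the default fork
speed of v = 0.5 kb/min advances every fork by exactly one block per
round and an isolated eye grows symmetrically by 2 blocks per round).

Origin firing is limited by a pool of trans-acting initiation factors
whose total number grows linearly, `N(t) = N0 + J*t`. A firing event
sequesters one factor at the two diverging forks it creates; the factor
is released when two converging forks coalesce. On a linear lattice a
fork can also terminate at a chromosome end; each end termination
releases half a factor, so the two terminal forks of a molecule jointly
release one, and `fired_total == released_total` holds exactly at
completion. The number of bound factors is therefore derived exactly
from the lattice: Nb = (number of eyes) − ½·(replicated lattice ends).

Per round:

1. every unreplicated, origin-eligible block draws a uniform number and
   becomes a firing candidate when the draw falls strictly below its
   local probability — `Pout` in the checkpoint-sensitive genome
   fraction, `Pin` in the high-probability fraction θ (MM4/MM5), and
   `Plocal` within a distance `d` ahead of any active fork (MM3/MM5);
2. if the number of candidates `M` exceeds the free pool
   `Nf(t) = N0 + J·t − Nb`, a uniform random subset of size `Nf` fires;
3. every pre-existing fork advances by `v·round_minutes` blocks
   (per-fork speeds drawn uniformly from {0, 1, 2, 3} kb/min in MM2);
   overlapping eyes coalesce; origins overrun by a fork are never
   candidates again (passive inactivation);
4. factor bookkeeping is updated from the lattice.

The variants are nested: MM1 (mean field, `Pout` only), MM2 (variable
fork speed), MM3 (fork-proximal firing enhancement `Plocal` over `d`),
MM4 (genome segmentation θ/`Pin`/`Pout`), MM5 (all of the above).

Potential origins are either continuous (every block) or discrete (each
block independently carries an origin with probability 1/2.3, the
average density of one potential origin per 2.3 kb). Genome
segmentation is block-level for fitting (θ·L uniformly chosen blocks)
and region-level for timing profiles (contiguous regions with lengths
drawn uniformly in (0, `region_length_max`] until their sum reaches
θ·L, the last region trimmed so coverage is exact; remaining blocks are
distributed as random inter-region gaps, which is feasible for any θ).

### Units of J

The published parameter table prints J in s⁻¹ while a round represents
2 min; the two are never reconciled in the source material. Internally
J is *factors per round* throughout. The `simulate` CLI command has a
`--j-per-second` flag that multiplies a file-supplied J by
60·`round_minutes` for users who want the literal per-second reading.

### Exactness notes

* The fork-proximal zone is computed from the eye intervals: a
  rightward zone `[eye_end, eye_end + d)` truncated at the next eye, a
  leftward zone symmetric, both automatically restricted to
  unreplicated DNA. A fork that has terminated at a lattice end has no
  zone.
* In the unlimited-factor mean-field limit (MM1, continuous origins,
  constant per-block probability p) the replicated fraction follows the
  discrete nucleation-and-growth (KJMA) closed form
  `1 − f(t) = (1 − p)^(t²)`, which the simulator reproduces to
  Monte Carlo accuracy; this is used as an analytic oracle in the test
  suite.

## Combing emulation

Simulated genomes are turned into combing-equivalent molecules by
shredding: molecule lengths are drawn i.i.d. from a molecule-length
model (default lognormal, median 100 kb, σ = 0.5, minimum 2 kb — the
qualitative shape of combed-fiber length distributions; an empirical
histogram can be supplied instead), placed from a uniformly random
offset over `[offset, L)` and then over `[0, offset)`, the partial
fragment at the end of each stretch discarded so the realized length
distribution is unbiased.

Reshaping imitates the optical resolution of combing: interior gaps of
at most 1 kb merge their flanking eyes, then eyes of at most 1 kb are
discarded. Because merging removes gaps without creating new ones, and
discarding small eyes only widens gaps that already exceed 1 kb, a
single simultaneous pass reaches the unique fixed point; the test suite
verifies confluence against exhaustive enumeration of all merge orders.
Eyes with reshaped length in (1, 3] kb are scored as new origin-firing
events; at 2 × 0.5 kb/min of bidirectional growth this corresponds to a
detection window of Δt = 3 min. Boundary conventions are strict
("larger than 1 kb") and configurable.

Six observables are computed per sample: the firing rate
`I = n_new / ((1 − f)·length·Δt)` and the visible fork density
`(2·interior eyes + 1·end-touching eyes) / length` per molecule, both
averaged in 20 equal-width bins of the molecule replicated fraction f;
the histogram of per-molecule f; and 2-kb histograms of eye lengths,
interior gap lengths and centre-to-centre eye-to-eye distances
(values above the last edge are clipped into it so no mass is lost;
histograms are normalized to unit mass). Fully replicated molecules
are excluded from the firing-rate average. The binning is an analysis
choice (the source material does not state one); all widths are
configurable.

To compare a simulation with a sample, the simulation round whose
*shredded* global replicated fraction is nearest the sample's global
fraction is selected, provided it lies within a tolerance. Because one
round moves f by up to a few percent in mid-S phase, the achievable
matching accuracy is bounded by the local per-round step; the fitting
objective therefore uses `max(0.02, 0.6 × local Δf per round)` as the
tolerance, and the synthetic-data generator uses ±0.015. The
stand-alone `match_global_fraction` keeps a strict ±0.005 default for
slowly replicating genomes.

## Fitness and the genetic algorithm

The fitness of a candidate parameter set against a sample is the sum
over the six observables of Σ(sim − exp)² / mean(exp)², computed on the
sample's bin grid (points where the experimental curve is undefined are
skipped; a simulated bin undefined where the experiment is defined
counts as 0). Multi-sample fits (the usual case) sum the fitness over
the samples; each objective evaluation runs one fresh simulation,
shreds it at every sample's matched round, reshapes and bins. A
candidate that cannot reach or match a sample fraction receives a
penalty of 10⁴ scaled up by how far it remains from the target, which
keeps the search directed without being confused with a real fitness.

The optimizer is a real-coded genetic algorithm with three
subpopulations of 20 individuals, 3 elites per subpopulation, 60%
scattered crossover (each gene from either roulette-selected parent
with probability ½), 40% uniform mutation (each gene redrawn uniformly
within bounds with probability 0.2), migration of the best 10% to the
next subpopulation on a ring every 5 generations, and a fixed
generation budget (50 by default). Three implementation decisions
matter and are deliberate:

* **Selection weights.** Roulette selection uses weights ∝ 1/√rank of
  the minimization ranking. Raw-fitness-proportional weights degenerate
  when penalized individuals (fitness ~10⁴) coexist with good ones
  (fitness ~10²): all good individuals then get near-identical weights
  and selection pressure vanishes.
* **Log-scale genes.** N0, J, d and the three probabilities are
  searched as log10(value + ε) within the same bounds (ε = 10⁻⁴ for
  probabilities, 1 for J and d, 0 for N0). Plausible values span
  decades (Pout ~10⁻³–10⁻¹ inside [0, 1]); on a linear axis uniform
  initialization and mutation almost never visit the lower decades.
  θ stays linear (it is a bounded fraction, not a scale). Reported
  parameters are always on the raw scale.
* **Elite re-evaluation.** The objective is stochastic, so an elite
  kept on the strength of a single lucky draw locks in. Surviving
  elites are re-evaluated once per generation and selected on their
  running-mean fitness; the reported optimum is the best
  multiply-evaluated individual of the final population. The recorded
  best-so-far trace is the cumulative minimum, hence monotone.

The genome segmentation is symmetric under
(θ, Pin, Pout) → (1 − θ, Pout, Pin); since Pin is by definition the
high probability, fitted parameter sets are canonicalized to
Pin ≥ Pout before being reported, which removes a label-swap
degeneracy from the ensembles.

A full inference repeats the GA independently (100 times by default)
and reports, for each parameter, the mean and standard deviation of the
best elite across runs; the ensemble correlation matrix is exposed as
an identifiability diagnostic (Pin and Plocal trade off against each
other in MM5 and are not claimed to be individually recovered).
Cross-condition comparisons use a per-parameter Welch two-sample t-test
on the ensembles with Bonferroni correction at α = 0.01 (the source
material names no test).

## Synthetic ground truth

`synthetic.generate_dataset` runs the simulator at known parameters,
matches the requested global fractions, shreds, optionally perturbs
(per-edge Gaussian jitter, spurious gaps — artifacts for robustness
testing only, off by default), reshapes, optionally subsamples to a
target molecule count, and emits both the molecule tables and a truth
sidecar (parameters, per-sample source round, molecule genome
coordinates, true initiation events). With noise off the datasets are
exactly the reshaped shredded simulation.

The recovery experiments use an MM5 truth of N0 = 300, J = 60 per
round, Pout = 0.01, Pin = 0.15, Plocal = 0.3, θ = 0.45, d = 15 kb on a
10⁵-kb genome with discrete origins — an S phase of ~25 rounds
(~50 min) with a factor-limited early phase (which identifies N0 and J
through the firing-rate amplitude) and a candidate-limited late phase
(which identifies θ and the probabilities), and the qualitative
ordering Plocal > Pin ≫ Pout of the fitted values reported for
*Xenopus* extracts. Three samples at global fractions 0.1/0.2/0.5 with
167 molecules each (~500 in total) are fitted jointly. Note that N0 and
J are absolute factor counts and scale with the simulated genome size;
they are comparable between truth and fit only because both use the
same `L`.

What passing recovery shows — and what it does not: the synthetic data
share the generator's molecule-length model and contain no optical
noise, no stretching variability and no fiber-selection bias, so
recovery demonstrates the internal consistency and statistical power of
the inference at this sample size, not robustness to every artifact of
real combing data (the jitter/false-gap options exist to probe that
separately).

## Timing profiles

For population-style replication-timing profiles a single fictitious
chromosome with *contiguous* high-probability regions (region-level
mask, drawn once) is replicated independently many times; each block
records its replication round, replicates are pooled into a
per-position mean timing (minutes) and a per-position firing abundance
(fraction of replicates in which at least one origin fired there — the
definition here; the source material does not define its "fraction of
abundance" precisely). The profile is loess-smoothed (statsmodels
lowess; span as a fraction of the chromosome) and segmented: runs with
|slope| below a threshold (min/kb) and length ≥ `min_len` are constant
timing regions, classed early/late against the chromosome median; other
runs are timing transition regions when their net timing change exceeds
20% of the profile range, otherwise they are absorbed into the
neighbouring plateau as local noise.

The reference configuration is the published MM5 parameter set
(N0 = 1231, J = 287, Pout = 0.01, Pin = 0.34, Plocal = 0.34, θ = 0.46,
d = 138 kb) on a 200,000-kb chromosome with region lengths drawn up to
3,000 kb (the stated region-length range; with the Σ Lᵢ = θL constraint
this yields ~65 regions — the separately stated region count of 398 is
incompatible with that constraint and the range, and the range is the
quantity that sets the spatial structure). The desk-scale run used in
the acceptance tests divides **every genomic length** (chromosome,
region-length range, fork-action distance d) and the factor counts N0
and J by 10, keeping probabilities and the round duration unchanged —
this is the geometrically self-similar image of the full-scale run, so
plateau/transition structure is preserved; scaling only the chromosome
while keeping d = 138 kb blurs transitions away, because region sizes
shrink to ~d. Smoothing and segmentation for this run use
span = 0.0025, slope threshold = 0.3 min/kb, `min_len` = 30 kb,
matched to the ~150-kb region scale.

"Early" origins are those firing within the first quarter of the
S-phase time axis (between the first and the last firing round). Their
density, and the density of all firing events, is lower inside TTRs
than inside CTRs in this configuration, mirroring population
observations; both are directional statements about this simulation
regime, not universal theorems of the model.

## Problem sizes and budgets

Test-suite simulations use lattices of 10⁴–10⁶ blocks: conservation
and reduction-equivalence checks at L = 10⁴ (hundreds of runs), the
KJMA oracle at L = 10⁶, parameter recovery at L = 10⁵ with a reduced
inference budget (10 GA repeats × 15 generations), and timing profiles
at the 1/10 scale above. These sizes give stable statistics at
interactive runtimes; the library itself accepts arbitrary sizes (the
full-scale timing chromosome runs in seconds; a full 100-repeat ×
50-generation inference is an overnight job on one core).

## Known limitations

* Rereplication, replisome-level mechanics and explicit checkpoint
  kinetics are out of scope; checkpoint conditions appear only as
  different fitted parameter values.
* N0 is identified mainly by data earlier than the first sample
  fraction; with no sample below f ≈ 0.1 its recovery is the weakest of
  the four headline parameters.
* Pin and Plocal are strongly degenerate in MM5 (both act on DNA near
  eyes once d is moderate); the ensemble correlation matrix documents
  this rather than hiding it.
* The fraction-matching step quantizes time to rounds; observables
  carry a corresponding sampling error in mid/late S phase.
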
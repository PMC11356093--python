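# Methods

## Model

An embryo is an N x N lattice of two cell types. Morphogenesis is cast as
error minimization against a fixed target pattern: each cell's **stress** is
the binary indicator that its type disagrees with the target at its
position, and development is a sequence of stress-relieving movements.

Cells that sit correctly ("fixed" cells) observe their 3 x 3 neighborhood
and advertise every stressed neighbor as a **vacancy**: a broadcast,
radially decaying distress signal encoding the stressed location and the
cell type the target wants there. Only stressed cells carrying exactly that
type receive the signal (a cell never receives the advertisement of its own
position). Each developmental **stage** resolves one movement:

1. recompute the stress map and distress field;
2. draw a mover uniformly among stressed cells with a nonempty signal
   record;
3. the mover heads for the vacancy whose signal it receives most strongly —
   with the default decay `1/(1 + r)` this is the nearest eligible vacancy;
   exact ties are broken uniformly at random;
4. it advances along a greedy 8-connected path (each step maximally reduces
   Euclidean distance to the destination), swapping with every non-fixed
   cell it meets at a cost of one swap per step.

A fixed cell in the path is where the two competency modes diverge.
Without stress sharing the mover halts and is **stuck**: it is not
reconsidered for movement unless another cell physically dislodges it
(a stuck marker travels with a displaced cell). This is what makes
developments without sharing short — once every remaining stressed cell is
walled in, no mover can act and the embryo is quiescent. With stress
sharing the mover spreads its stress onto its 3 x 3 neighborhood, coercing
the fixed cell into opening a temporary tunnel: the mover passes through
without displacing the occupant (the fixed cell's value is bit-identical
before and after the move), still paying one swap per cell traversed.
Shared stress is an observable, not a force: it expires with the move that
created it and never feeds back into eligibility or destination choice.

All swaps draw on one embryo-global **competency budget**
`C = round(5.25 N^2)` (4725 at N = 30, 2100 at N = 20). Development
terminates on completion, budget exhaustion, quiescence, or a safety stage
limit (10 000). Hardwired embryos skip development; their phenotype is
their genotype.

## Evolution

A population of M embryos (homogeneous in mode) iterates development ->
selection -> mutation. Selection keeps the genotypes of the top
`ceil(0.10 M)` phenotypic fitnesses (ties broken by stable population
index); the parents are retained unmutated and the population is refilled
with mutated copies of uniformly drawn parents, a mutation being k random
cell-pair swaps. Defaults M = 100 and k = 10 are conventional
genetic-algorithm choices: k = 10 swaps perturb ~2 % of a 30 x 30 grid —
enough variation to search on, small enough that elitism preserves
progress. Every embryo re-randomizes its development each generation
(competency is a capacity, not a memory). Fitness is logged both as the
raw normalized l2 distance d and as the exponentiated closeness
`f_exp = 9^(1-d)/9`; the exponential stretches exactly the high-fitness
region where late-stage dynamics differ, and is the scale used for
reporting. Selection only uses the ordering, which both scales share.

## Target patterns

Targets are procedural, deterministic in (kind, N), and exist so that every
experiment is self-contained. The face is two filled eye blocks (side
`round(N/7.5)`), a one-cell smile arc along the lower limb of an ellipse,
and a small `max(1, N//15)`-square nose; at N = 30 it has 52 foreground
cells (~6 % density). A uniform seeded permutation of the face then
misplaces ~98 cells in expectation, which puts single-embryo developments
on the tens-of-stages scale the observables are designed around. The nose
exists so the five-stage sequential decomposition (left eye, right eye,
both eyes, eyes + smile, full face) is strictly increasing — eyes + smile
is a proper subset of the face. A four-stage variant without the
single-right-eye stage is also provided. The thumbs-up (fist block plus
thumb bar) plays the role of an alternative goal in the stress-map decoding
experiment. These synthetic patterns emulate only what the model consumes —
a binary goal bitmap with localized features; they do not reproduce any
particular bitmap's pixel layout, so quantities that depend on exact pixel
geometry (e.g. absolute similarity values of a specific image) are
meaningful here only as trends.

## Observables

* **Radius of influence** — per stage, the maximum Euclidean distance
  between the mover's move-start position and any cell it dislodged that
  stage. Dislodgement distance is measured from the move-start (not the
  stage-0 origin) because influence is attributed per stage. Tunnel exits
  count: the cell displaced at the far end of a tunnel is dislodged across
  the whole tunnel length, which is why sharing-mode series dominate
  no-sharing series in magnitude and duration.
* **Stress maps and gradients** — the combined (intrinsic OR shared) binary
  field and its central-difference spatial gradient (one-sided at borders).
* **Similarity** — `1 - sum((S - T)^2) / N^2` between a binary stress field
  and the target; 1.0 on a match, 0.0 on the complement, ~0.5 for a random
  balanced field. The root-form alternative (`1 - sqrt(.)/N`, random level
  ~0.29) is selectable; the squared form is the default precisely because
  its random-control level is the interpretable 0.5.
* **Sequential morphogenesis** — development against the staged sub-target
  sequence, a new target introduced at the first stage where mean stress
  fails to strictly decrease (one-stage grace after each switch, since the
  switch itself raises stress) or when the phase goes quiescent. One
  competency budget spans all phases.
* **Run statistics** — per-generation mean with Student-t 95 % confidence
  half-width across replicate runs; Welch's two-sample t-test between
  populations (zero-variance identical samples reported as t = 0, p = 1 and
  flagged degenerate).

## Numerical and design choices

* **Decay law.** Any strictly decreasing radial decay yields the same
  destination ordering; `1/(1 + r)` is positive, never zero, and equals 1.0
  at the origin. Configurable, as is the accumulation rule (max of
  duplicate observations, or per-observer summation).
* **Shortest path.** Greedy descent of Euclidean distance over the 8
  neighbors, deterministic tie-break (row step, then column step, then
  diagonals). Path length equals the Chebyshev distance; no search is
  needed because any king-move geodesic serves equally.
* **Stage accounting.** A stage is one *resolved* movement. Candidates
  whose first step is already blocked are marked stuck without consuming a
  stage, so stage counts are commensurate with movement events.
* **Sticky blocking.** A blocked mover does not retry: its marker persists,
  traveling with the cell if it is displaced, and is wiped by a target
  switch. The alternative — memoryless re-selection — lets pairs of
  adjacent stressed cells exchange places indefinitely, so no-sharing
  development would only ever terminate by budget exhaustion and the
  quiescence observable would be vacuous.
* **Tunnel cost.** Tunnel passage costs one swap per fixed cell traversed,
  from the same global budget: the budget bounds *swaps executed*, with no
  stated exemption, and a free tunnel would make sharing strictly dominant
  at zero cost.
* **Budget truncation.** A move that exhausts the budget mid-path ends with
  the mover at the last non-fixed cell it actually occupied (a mover cannot
  settle inside a tunnel).
* **Two engines.** The reference engine (pure numpy) records every move's
  path, swaps, dislodgements and tunnel cells, so runs can be replayed and
  audited; all single-embryo experiments use it. The evolution driver uses
  a numba-compiled kernel implementing the identical rules without trace
  recording (one development per embryo per generation is otherwise
  unaffordable). The two use different random streams and are tested for
  agreement on invariants and outcome distributions, not swap-for-swap.
* **Problem sizes.** The acceptance script uses 20 seeded replicates for
  single-embryo experiments, 10 runs for the 1000-generation evolutionary
  endpoints, 5 runs for the 20 x 20 solve-time, and a 3-run M = 50,
  100-generation configuration for competency tracking.

## Known limitations

* The lattice is fixed and two-typed: no growth, deformation, cell division
  or death, and no graded or multi-scale stress.
* Under the nearest-vacancy destination rule that follows literally from
  "strongest signal" plus radial decay, movement is short-ranged: movers
  travel a few cells per stage, sharing-mode developments complete well
  inside the competency budget, and the stage-1 radius of influence is of
  order the inter-vacancy spacing rather than the grid diameter. A variant
  in which destination choice is effectively long-ranged would exhaust the
  budget, lengthen developments, and make development noisy enough to
  degrade selection in no-sharing populations; with the literal rule,
  no-sharing evolution remains nearly as effective as hardwired evolution.
  The divergence is measured, not hidden: the acceptance script reports the
  dynamics this implementation actually produces.
* Sharing-mode development is strong enough to solve any scramble of the
  default face outright, so sharing populations reach maximum phenotypic
  fitness in the first generation and their genotypes feel no selection
  gradient. The qualitative ordering sharing > hardwired > no-sharing at
  matched generations holds regardless.
* Stress-map "privacy" analyses are data exports (similarity series,
  gradient fields); the package draws no interpretive conclusion from them.
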
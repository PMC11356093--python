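# morphoglue

An agent-based model of **stress-driven morphogenesis**: misplaced cells on a
binary lattice relieve positional stress by migrating toward advertised
vacancies, optionally *sharing* their stress to tunnel through correctly
placed neighbors — all wrapped in a genetic algorithm so the developmental
layer's effect on evolution can be measured. The package is aimed at
computational developmental biologists and artificial-life researchers who
want a reproducible, fully instrumented reference implementation of this
class of model: every run is seeded, every movement is traced, and every
observable (radius of influence, stress maps and gradients, stress/target
similarity, sequential morphogenesis) is exported as plain CSV/JSON.

## The model

An embryo is an N x N grid E of cell types {0, 1}; a target morphology T
(by default a procedurally drawn smiling face) defines where each type
belongs. A cell at (i, j) is **stressed** iff E\_ij != T\_ij, otherwise it is
**fixed**. Fixed cells watch their 3 x 3 neighborhood and broadcast a
radially decaying distress signal (strength 1/(1 + r), 1.0 at the origin)
advertising each stressed neighbor's location and the cell type needed
there. One stressed cell per developmental stage — chosen uniformly among
those receiving signals of their own type — moves toward the strongest
signal it receives, swapping along a greedy 8-connected shortest path. A
fixed cell in the way either blocks the mover permanently (*no-sharing*
mode) or, if the mover can share stress onto its 3 x 3 neighborhood, opens a
temporary tunnel that reverts after passage (*sharing* mode). Development
ends when the target is formed, when the embryo-global competency budget
C = round(5.25 N^2) swaps (4725 at N = 30) is spent, or when no mover can
act. *Hardwired* embryos skip development entirely.

Fitness against the target is the normalized l2 distance

```
d = (1/N^2) * sqrt( sum_ij (E_ij - T_ij)^2 )  =  sqrt(m) / N^2
```

for m mismatched cells, reported as the exponentiated closeness
`f_exp = 9^(1-d) / 9` (1.0 exactly at a perfect match, 1/9 at d = 1). The
genetic algorithm iterates development -> selection (top 10 % by phenotypic
fitness, elitist) -> mutation (10 random cell-pair swaps per offspring) over
homogeneous populations of each mode.

## Worked example

```python
from morphoglue import DevelopmentParams, develop, fitness, make_pattern, scramble

face = make_pattern("face", 30)          # 52 foreground cells on a 30x30 grid
genome = scramble(face, 7)               # seeded uniform permutation of the face
print(fitness(genome, face).f_exp)       # genotype fitness of the scramble
for mode in ("sharing", "no_sharing", "hardwired"):
    res = develop(genome, face, DevelopmentParams(mode=mode, seed=7))
    print(mode, res.status, res.stages, res.swaps_total,
          round(fitness(res.phenotype, face).f_exp, 4))
```

prints

```
0.9754
sharing     completed  52  300  1.0
no_sharing  quiescent  24   27  0.9776
hardwired   hardwired   0    0  0.9754
```

The scramble misplaces 104 cells (genotype fitness 0.9754 on the
exponentiated scale). With stress sharing the embryo reorganizes completely
— 52 movement stages, 300 swaps of its 4725-swap budget, fitness 1.0.
Without sharing, movers jam against fixed cells and development goes
quiescent after 24 stages and only 27 swaps, barely improving the pattern;
a hardwired embryo does not move at all.

The same experiments are available from the shell:

```bash
morphoglue make-pattern --kind face --n 30 --out face.pbm
morphoglue develop --target face.pbm --mode sharing --seed 7 \
    --trace trace.csv --out phenotype.pbm
morphoglue evolve --target face.pbm --mode hardwired --pop 100 \
    --gens 1000 --runs 10 --seed 1 --out evo/
morphoglue run --config experiment.json --out results/   # named templates
```

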
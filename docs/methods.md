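# Methods

## The homogeneity score

A tricluster is a triple of index subsets (G, C, T) into a dense
genes × conditions × times tensor with no missing cells. Its quality is the
mean squared three-way-interaction residual of the selected block:

    r_gct = v(g,c,t) + M_CT(g) + M_GT(c) + M_GC(t)
                     − M_G(c,t) − M_C(g,t) − M_T(g,c) − M_GCT
    MSR_3D = mean over the block of r_gct²

with `M_CT(g)` the mean over all (condition, time) cells of gene g inside
the block, `M_G(c,t)` the mean over the block's genes at fixed (c, t), and
so on; `M_GCT` is the block's grand mean. All means are taken over the
block only, in double precision.

Algebraic facts the implementation and tests rely on:

- **Zero iff no three-way interaction.** MSR_3D = 0 exactly when
  v = f(g,c) + h(g,t) + k(c,t). Constant blocks, fully additive blocks
  (base + α(g) + β(c) + γ(t)) and sign-flipped gene effects (negatively
  correlated genes) are all special cases — the score deliberately embraces
  anti-correlated expression patterns that plain correlation would cancel.
- **Degenerate dimensions.** If any of #G, #C, #T equals 1 the residual is
  identically 0 (the omitted-axis means coincide pairwise and cancel).
  Singleton-dimension clusters are therefore uninformative, which is why the
  search imposes per-dimension size floors (below).
- **Shift invariance.** Adding any per-gene, per-condition or per-time
  constant leaves the score unchanged.

The classic 2-D mean squared residue is included for completeness as
`msr2d`, with the Cheng–Church residue `v − M_G(c) − M_C(g) + M_GC` (the
sign convention under which constant biclusters score exactly 0).

The "zero" tolerance used in tests is 1e-9 absolute on data of order 100 —
comfortable for double precision on blocks up to ~10⁴ cells. The optimised
vectorised score is checked against a brute-force triple-loop oracle to
1e-9 relative tolerance.

## The evolutionary search

One *extraction* evolves a population of I triclusters for a fixed number
of generations and returns the best individual ever evaluated; N sequential
extractions build the solution set. The minimised fitness of a candidate TC
given previously extracted solutions is

    FF = MSR_3D/range² − [w_g·#G/|G_D| + w_c·#C/|C_D| + w_t·#T/|T_D|]
                       − [wo_g·u_G + wo_c·u_C + wo_t·u_T]

where `range` is the data's max − min, `|X_D|` the tensor extents and `u_X`
the fraction of TC's indices in dimension X *not* used by any prior
solution. Normalising the residue by the squared range puts it on the same
O(1) scale as the reward terms: i.i.d. noise then scores about
(1/12)(1 − 1/#G)(1 − 1/#C)(1 − 1/#T) ≈ 0.05–0.08, which is the yardstick
for choosing weights.

Operators, per generation:

- **Selection** — roulette wheel adapted to minimisation: survivor
  probability ∝ (max_ff − ff + ε), sampling ⌊Sel·I⌋ distinct individuals
  without replacement (ε = 1e-12·spread + tiny; uniform when all equal).
  Weak individuals keep a non-zero chance, and because the best-ever
  individual is tracked outside the population, roulette can never lose
  the answer (no separate elitism operator).
- **Crossover** — refills the population to I. Parents are drawn from the
  survivors with the same fitness-proportional transform; each of the three
  index sequences is cut at an independent uniform position, children take
  prefix-of-one + suffix-of-other, then are sorted, de-duplicated and, if
  below the size floors, repaired with random missing indices. On sorted
  index sequences this acts like recombination of interval boundaries,
  which is what refines block edges quickly.
- **Mutation** — with probability Mut, exactly one of six actions: add or
  remove one random index in one random dimension. Additions check for
  duplicates; impossible actions (saturated dimension, floor-breaking
  removal) are re-drawn up to six times, then the individual is left
  unchanged.

**Initial population.** A fraction Ale is random — half unconstrained index
subsets, half contiguous runs per dimension. The remainder is
"overlap-aware": contiguous runs whose *gene* window start is sampled with
probability ∝ (window's unused-gene fraction + 0.02)³, while condition and
time runs cycle through the full (shuffled) grid of possible contiguous
placements. Three deliberate asymmetries, each of which measurably changed
recovery reliability during development:

1. Only the gene axis is steered away from prior solutions. Distinct
   genuine triclusters routinely share condition/time subsets, so biasing
   those axes against reuse hides real structure.
2. Contiguous windows are *boundary-clipped*: starts are drawn over an
   extended range so index positions near the edges of an axis are covered
   as often as interior ones. With interior-only starts, a module at the
   edge of the gene axis is almost never contained in any seed window.
3. The joint space of contiguous condition/time placements is small (~10²),
   so enumerating it guarantees every placement a seed; leaving it to
   chance makes whole modules invisible to some runs.

Initial sizes are drawn uniformly between the floor and a third of the
axis extent — windows large enough to contain a plausible module, small
enough that shedding excess indices stays within a run's mutation budget.

**Size floors.** Default 2 per dimension (the hard minimum below which the
score is degenerate). In practice the floors are the main tool against
*overfitting of the residue to tiny blocks*: among small random blocks the
minimum MSR_3D found by an evolutionary search is far below the average, so
with low floors the search collapses onto lucky noise. Floors should be set
near the smallest cluster size the analysis considers interesting; for the
synthetic benchmark below they are sized to the implanted signal.

**Weight scales.** With the range²-normalised residue, the volume reward
must satisfy w_g·(1 − expected module share) < MSR of an all-gene slab
(≈ 0.05 at benchmark geometry), otherwise the global optimum is a
degenerate slab; but per-gene rewards far below ~1e-4 leave module-gene
retention to drift. w_g ≈ 0.05 with w_c = w_t = 0.005 sits in that window.
Non-overlap weights are kept very small (wo_g = 0.002, wo_c = wo_t =
0.001): diversification across extractions is handled mostly by the
steered initialisation, and large wo values actively repel extractions
from partially covered modules, preventing the union of solutions from
completing them.

Determinism: a single seeded `numpy.random.Generator` is threaded through
every stochastic operator; identical (tensor, parameters, seed) give
bit-identical solution sets.

## The synthetic benchmark

The generator draws an i.i.d. uniform[0, 100] background tensor and
overwrites `n_implants` contiguous blocks at random offsets — gene blocks
mutually disjoint, condition/time blocks free to overlap between implants —
with a coherent pattern: `constant`, `additive` (base + α(g) + β(c) + γ(t),
effects uniform in ±effect_scale, default 25) or `pairwise-additive`
(f(g,c) + h(g,t) + k(c,t), which exercises the negative-correlation case),
plus optional Gaussian noise. With zero noise every implant's MSR_3D is
exactly 0. The default recipe is the full-scale condition (4000 × 30 × 20,
ten implants of 150 × 6 × 4, no noise).

Recovered solutions are scored by the **match ratio**: the fraction of an
implant's cells covered by the union of all returned solutions (a coverage
measure — a solution that is a superset of an implant scores 100% for it).

What the benchmark does *not* emulate: measurement noise outside implants'
additive model, heavy-tailed intensity distributions, missing values,
correlated background genes, or time-shifted/lagged patterns. Passing it
demonstrates that the score ranks coherent blocks correctly and that the
search can find planted structure of known scale; it does not by itself
validate biological discovery on real arrays, which is why the correlation
validation (and, outside this package's scope, ontology enrichment) exists.

### Reference run (scripts/acceptance.py)

The reproducible benchmark is a scaled replica of the implant experiment,
chosen to run in minutes on one core: 400 genes × 20 conditions × 12 times,
three additive implants of 40 × 5 × 4, zero noise. Search configuration:
N = 6, 120 generations, 200 individuals, Mut = 0.3, Sel = 0.5, Ale = 0.3,
w = (0.05, 0.005, 0.005), wo = (0.002, 0.001, 0.001), floors (45, 5, 4);
three run seeds, reporting the minimum per-implant match ratio at the best
seed. The master seed drives both the dataset and the run seeds through a
`SeedSequence`. Note this scaled design is *harder per implant* than the
full-scale condition: six extractions must cover three implants, where the
full-scale experiment extracts 100–200 solutions for ten implants, so each
implant there can be covered by the union of many partial solutions.

## Correlation validation

A tricluster defines #C·#T gene-expression series (one per condition-time
pair, each of length #G). The validation statistic is the unweighted mean
of the Pearson (or Spearman) coefficient over all unordered series pairs,
reported to two decimals per solution. Pairs involving a constant series
contribute 0 with a warning (the coefficient is undefined there). A
perfectly additive tricluster scores 1.00 under both methods; a solution
mixing positively and negatively correlated gene groups averages towards 0
even though its residue is near zero — low averaged correlation therefore
flags sign-mixed coherence, not incoherence. The Pearson–Filon comparison
statistic for correlated coefficients is not computed; the tables carry
plain coefficients.

The three tidy view tables (`sample_curves`, `time_curves`, `gene_curves`)
expose exactly the data behind the standard per-time, per-condition and
per-gene line plots; rendering is left to the user's plotting stack.

## Degenerate inputs and edge behaviour

- Tensors must be complete; non-finite cells are rejected at construction
  (no imputation is attempted).
- A constant tensor has range 0; the normalised residue term uses
  max(range², 1e-12), so every tricluster scores 0 there and the search is
  driven by the reward terms alone.
- Label-based I/O: indices never appear in files; the tensor's time order
  is the file's column order, or numeric order when all time labels parse
  as numbers.

## Known limitations

- The search is stochastic; on hard geometries (implant gene blocks a few
  indices apart, or condition/time blocks shared between implants) a run
  can leave one module partially covered. Multiple seeds and more
  extractions per module are the remedy.
- MSR_3D is scale-dependent (quadratic in the data's units); the range²
  normalisation makes the default weights portable across datasets but
  assumes the global range is representative (a single extreme outlier
  shrinks the normalised residue for everything else).
- Fitness evaluation extracts each candidate block densely; tensors far
  beyond ~10⁷ cells will want a coarser population/generation budget.
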
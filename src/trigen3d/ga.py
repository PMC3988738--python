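"""Evolutionary tricluster search driven by the 3-D mean squared residue.

The search is a plain generational genetic algorithm over index-set
individuals.  One run ("extraction") evolves a population of triclusters
for a fixed number of generations — roulette-wheel survivor selection,
one-point crossover per dimension, and a six-action add/remove mutation —
and returns the best individual ever evaluated.  N successive extractions
build the solution set; each extraction's fitness rewards non-overlap with
the solutions already extracted, so later runs are steered toward
unexplored regions (found cells are never masked out of the data).

The minimised objective for a tricluster TC is

    FF(TC) = MSR_3D(TC)/range^2  -  size reward  -  non-overlap reward,

where the size reward is a weighted sum of the per-dimension occupancy
fractions (#G/|G_D| etc.) and the non-overlap reward is a weighted sum of
the per-dimension fractions of TC's indices *not* already used by prior
solutions.  Normalising the residue by the squared data range puts all
three terms on a comparable O(1) scale.

:class:`TriGen` packages the search as a scikit-learn style estimator
(``fit`` on a tensor, fitted ``solutions_``/``fitness_`` attributes);
:func:`run_trigen` is the equivalent functional entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data_model import (ExpressionTensor3D, FitnessBreakdown, TriGenParams,
                         Tricluster)
from .measures import msr3d_from_array

__all__ = [
    "Population",
    "SolutionSet",
    "fitness",
    "init_population",
    "select",
    "crossover",
    "mutate",
    "evolve_one",
    "run_trigen",
    "TriGen",
]

# weight given to an already-used index when the overlap-aware initialiser
# samples; unused indices have weight 1
_USED_INDEX_WEIGHT = 0.05


@dataclass
class Population:
    """The individuals alive at one generation of a run."""

    individuals: list[Tricluster]
    generation_index: int = 0

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)


@dataclass
class SolutionSet:
    """Ordered set of extracted triclusters with their fitness breakdowns."""

    triclusters: list[Tricluster] = field(default_factory=list)
    breakdowns: list[FitnessBreakdown] = field(default_factory=list)

    def append(self, tc: Tricluster, fb: FitnessBreakdown) -> None:
        self.triclusters.append(tc)
        self.breakdowns.append(fb)

    def __len__(self) -> int:
        return len(self.triclusters)

    def __iter__(self):
        return iter(self.triclusters)

    def index_unions(self, shape: tuple[int, int, int]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Boolean membership masks of the per-dimension index unions."""
        masks = (np.zeros(shape[0], dtype=bool),
                 np.zeros(shape[1], dtype=bool),
                 np.zeros(shape[2], dtype=bool))
        for tc in self.triclusters:
            masks[0][tc.genes] = True
            masks[1][tc.conditions] = True
            masks[2][tc.times] = True
        return masks


def fitness(tensor: ExpressionTensor3D, tc: Tricluster,
            params: TriGenParams,
            prior: Optional[SolutionSet] = None) -> FitnessBreakdown:
    """Evaluate one tricluster; lower ``ff`` is better.

    With all weights zero the value reduces to the (normalised) 3-D mean
    squared residue.
    """
    prior = prior if prior is not None else SolutionSet()
    masks = prior.index_unions(tensor.shape)
    return _fitness_fast(tensor, tc, params, masks,
                         _msr_scale(tensor, params))


def _msr_scale(tensor: ExpressionTensor3D, params: TriGenParams) -> float:
    if not params.normalize_msr:
        return 1.0
    rng_sq = tensor.value_range() ** 2
    return max(rng_sq, 1e-12)


def _fitness_fast(tensor, tc, params, union_masks, msr_scale):
    sub = tensor.values[np.ix_(tc.genes, tc.conditions, tc.times)]
    msr_term = msr3d_from_array(sub) / msr_scale
    ng, nc, nt = tensor.shape
    size_reward = (params.w_g * len(tc.genes) / ng
                   + params.w_c * len(tc.conditions) / nc
                   + params.w_t * len(tc.times) / nt)
    ug, uc, ut = union_masks
    overlap_reward = (
        params.wo_g * (1.0 - np.count_nonzero(ug[tc.genes]) / len(tc.genes))
        + params.wo_c * (1.0 - np.count_nonzero(uc[tc.conditions])
                         / len(tc.conditions))
        + params.wo_t * (1.0 - np.count_nonzero(ut[tc.times]) / len(tc.times)))
    return FitnessBreakdown(msr3d_term=float(msr_term),
                            size_reward=float(size_reward),
                            overlap_reward=float(overlap_reward))


def _draw_size(rng: np.random.Generator, extent: int, min_size: int) -> int:
    # moderate prior: between the floor and a third of the dimension
    hi = max(min_size, extent // 3)
    return int(rng.integers(min_size, hi + 1))


def _random_subset(rng, extent, size) -> np.ndarray:
    return np.sort(rng.choice(extent, size=size, replace=False))


def _contiguous_run(rng, extent, size, min_size=None) -> np.ndarray:
    """Contiguous run of ~``size`` indices, clipped at the boundaries.

    The start is drawn over an extended range and the window clipped to
    [0, extent), so positions near the edges are covered as often as
    interior ones (interior-only starts would starve edge blocks); the
    clipped window never falls below ``min_size`` (default: ``size``
    capped at the extent).
    """
    min_size = size if min_size is None else min(min_size, size)
    start = int(rng.integers(-(size - min_size), extent - min_size + 1))
    lo, hi = max(0, start), min(extent, start + size)
    return np.arange(lo, hi, dtype=np.intp)


def _weighted_subset(rng, extent, size, used_mask) -> np.ndarray:
    """Subset preferring indices not flagged in ``used_mask``."""
    if used_mask.all() or not used_mask.any():
        return _random_subset(rng, extent, size)
    w = np.where(used_mask, _USED_INDEX_WEIGHT, 1.0)
    w = w / w.sum()
    return np.sort(rng.choice(extent, size=size, replace=False, p=w))


def _weighted_contiguous_run(rng, extent, size, used_mask,
                             min_size=None) -> np.ndarray:
    """Contiguous (boundary-clipped) run favouring unused index windows."""
    if extent == size:
        return np.arange(extent, dtype=np.intp)
    if used_mask.all() or not used_mask.any():
        return _contiguous_run(rng, extent, size, min_size)
    min_size = size if min_size is None else min(min_size, size)
    starts = np.arange(-(size - min_size), extent - min_size + 1)
    lows = np.maximum(0, starts)
    highs = np.minimum(extent, starts + size)
    cum = np.concatenate([[0], np.cumsum(~used_mask)])
    # mean unused fraction of each clipped window, sharpened
    frac = (cum[highs] - cum[lows]) / (highs - lows)
    w = (frac + 0.02) ** 3
    k = int(rng.choice(len(starts), p=w / w.sum()))
    return np.arange(lows[k], highs[k], dtype=np.intp)


def init_population(tensor: ExpressionTensor3D, params: TriGenParams,
                    prior: Optional[SolutionSet],
                    rng: np.random.Generator) -> Population:
    """Create the generation-0 population of ``n_individuals`` triclusters.

    ``ceil(ale * I)`` individuals are random — half purely random index
    subsets, half contiguous index runs in all three dimensions — and the
    remainder consists of contiguous runs whose gene windows prefer indices
    absent from the prior solutions' per-dimension unions (falling back to
    uniform when there is no prior).  Only the gene axis is steered:
    condition and time subsets legitimately recur across distinct
    triclusters.
    """
    ng, nc, nt = tensor.shape
    mins = params.min_shape()
    if mins[0] > ng or mins[1] > nc or mins[2] > nt:
        raise ValueError("minimum tricluster sizes exceed the tensor extents")
    prior = prior if prior is not None else SolutionSet()
    masks = prior.index_unions(tensor.shape)

    n_random = math.ceil(params.ale * params.n_individuals)
    n_contig = n_random // 2

    # pre-enumerate every (condition-run, time-run) start pair in shuffled
    # order for the steered individuals: the joint space of contiguous
    # condition/time placements is small, and cycling through it guarantees
    # every combination a seed instead of leaving coverage to chance
    c_starts = np.arange(nc - min(nc, mins[1]) + 1)
    t_starts = np.arange(nt - min(nt, mins[2]) + 1)
    combos = np.array(np.meshgrid(c_starts, t_starts)).reshape(2, -1).T
    rng.shuffle(combos)

    individuals: list[Tricluster] = []
    for i in range(params.n_individuals):
        sizes = tuple(_draw_size(rng, e, m)
                      for e, m in zip((ng, nc, nt), mins))
        if i < n_random - n_contig:
            seqs = [_random_subset(rng, e, s)
                    for e, s in zip((ng, nc, nt), sizes)]
        elif i < n_random:
            seqs = [_contiguous_run(rng, e, s, m)
                    for e, s, m in zip((ng, nc, nt), sizes, mins)]
        else:
            # steer only the gene axis away from prior solutions: condition
            # and time subsets recur across genuine triclusters, so biasing
            # them against reuse would hide solutions sharing those axes.
            # Contiguous runs give crossover useful boundary material.
            cs, ts = (int(x) for x in combos[(i - n_random) % len(combos)])
            seqs = [_weighted_contiguous_run(rng, ng, sizes[0], masks[0],
                                             mins[0]),
                    np.arange(cs, cs + min(nc - cs, sizes[1]), dtype=np.intp),
                    np.arange(ts, ts + min(nt - ts, sizes[2]), dtype=np.intp)]
        individuals.append(Tricluster(*seqs))
    return Population(individuals, generation_index=0)


def select(population: Population | Sequence[Tricluster],
           fitnesses: Sequence[float], params: TriGenParams,
           rng: np.random.Generator) -> list[Tricluster]:
    """Roulette-wheel survivor selection for a minimised objective.

    Samples ``floor(sel * I)`` distinct individuals with probability
    proportional to ``max_ff - ff + eps``, so better (lower-ff) individuals
    are favoured while weak ones keep a non-zero survival chance.
    """
    individuals = list(population)
    ff = np.asarray(fitnesses, dtype=float)
    if len(ff) != len(individuals):
        raise ValueError("fitnesses are not aligned with the population")
    k = max(1, int(math.floor(params.sel * len(individuals))))
    spread = float(ff.max() - ff.min())
    eps = 1e-12 * max(spread, 1.0) + np.finfo(float).tiny
    weights = (ff.max() - ff) + eps
    if spread == 0.0:
        idx = rng.choice(len(individuals), size=k, replace=False)
    else:
        idx = rng.choice(len(individuals), size=k, replace=False,
                         p=weights / weights.sum())
    return [individuals[i] for i in idx]


def _repair(seq: np.ndarray, extent: int, min_size: int,
            rng: np.random.Generator) -> np.ndarray:
    if len(seq) >= min_size:
        return seq
    missing = np.setdiff1d(np.arange(extent, dtype=np.intp), seq)
    extra = rng.choice(missing, size=min_size - len(seq), replace=False)
    return np.sort(np.concatenate([seq, extra]))


def crossover(parent_a: Tricluster, parent_b: Tricluster,
              rng: np.random.Generator, *,
              extents: Optional[tuple[int, int, int]] = None,
              min_shape: tuple[int, int, int] = (1, 1, 1),
              ) -> tuple[Tricluster, Tricluster]:
    """One-point crossover applied independently in each dimension.

    For each index sequence a cut position is drawn uniformly in
    ``0..len(shorter parent)``; child 1 takes a's prefix and b's suffix,
    child 2 the converse.  Children are sorted and de-duplicated; when
    ``extents`` is given, children falling below ``min_shape`` are repaired
    by adding uniformly random missing indices.
    """
    child1, child2 = [], []
    for dim in range(3):
        a = (parent_a.genes, parent_a.conditions, parent_a.times)[dim]
        b = (parent_b.genes, parent_b.conditions, parent_b.times)[dim]
        cut = int(rng.integers(0, min(len(a), len(b)) + 1))
        s1 = np.unique(np.concatenate([a[:cut], b[cut:]]))
        s2 = np.unique(np.concatenate([b[:cut], a[cut:]]))
        if extents is not None:
            s1 = _repair(s1, extents[dim], min_shape[dim], rng)
            s2 = _repair(s2, extents[dim], min_shape[dim], rng)
        child1.append(s1)
        child2.append(s2)
    return Tricluster(*child1), Tricluster(*child2)


def mutate(tc: Tricluster, tensor: ExpressionTensor3D, params: TriGenParams,
           prior: Optional[SolutionSet], rng: np.random.Generator
           ) -> Tricluster:
    """Six-action mutation: add or remove one index in one dimension.

    With probability ``mut`` exactly one uniformly chosen action is applied
    out of {add, remove} x {gene, condition, time}; additions draw a
    uniformly random index not already present, and impossible actions
    (full dimension, or a removal that would break the size floor) are
    re-drawn up to six times before giving up.  With probability
    ``1 - mut`` the individual is returned unchanged.
    """
    if rng.random() >= params.mut:
        return tc
    extents = tensor.shape
    mins = params.min_shape()
    seqs = [tc.genes, tc.conditions, tc.times]
    for _ in range(6):
        action = int(rng.integers(0, 6))
        dim, is_add = action % 3, action < 3
        seq = seqs[dim]
        if is_add:
            if len(seq) >= extents[dim]:
                continue  # every index already present: re-draw
            missing = np.setdiff1d(np.arange(extents[dim], dtype=np.intp), seq)
            new = rng.choice(missing)
            mutated = np.sort(np.append(seq, new))
        else:
            if len(seq) <= mins[dim]:
                continue  # removal would violate the size floor: re-draw
            drop = int(rng.integers(0, len(seq)))
            mutated = np.delete(seq, drop)
        out = list(seqs)
        out[dim] = mutated
        return Tricluster(*out)
    return tc


def evolve_one(tensor: ExpressionTensor3D, params: TriGenParams,
               prior: Optional[SolutionSet], rng: np.random.Generator
               ) -> tuple[Tricluster, FitnessBreakdown]:
    """Run one full evolutionary extraction and return the best individual.

    The best individual *ever evaluated* is tracked across generations
    (ties broken by earlier appearance), so roulette selection can never
    lose the answer.  Deterministic given the generator state.
    """
    prior = prior if prior is not None else SolutionSet()
    masks = prior.index_unions(tensor.shape)
    scale = _msr_scale(tensor, params)
    cache: dict[Tricluster, FitnessBreakdown] = {}

    def evaluate(ind: Tricluster) -> FitnessBreakdown:
        fb = cache.get(ind)
        if fb is None:
            fb = _fitness_fast(tensor, ind, params, masks, scale)
            cache[ind] = fb
        return fb

    best: Optional[Tricluster] = None
    best_fb: Optional[FitnessBreakdown] = None

    def track(ind: Tricluster, fb: FitnessBreakdown) -> None:
        nonlocal best, best_fb
        if best_fb is None or fb.ff < best_fb.ff:
            best, best_fb = ind, fb

    pop = init_population(tensor, params, prior, rng)
    for gen in range(params.n_generations):
        breakdowns = [evaluate(ind) for ind in pop.individuals]
        for ind, fb in zip(pop.individuals, breakdowns):
            track(ind, fb)
        survivors = select(pop.individuals, [fb.ff for fb in breakdowns],
                           params, rng)
        # fitness-proportional parent choice (same minimisation transform
        # as the roulette), so offspring concentrate around good survivors
        sf = np.array([evaluate(ind).ff for ind in survivors])
        spread = float(sf.max() - sf.min())
        pw = (sf.max() - sf) + 1e-12 * max(spread, 1.0) + np.finfo(float).tiny
        pw = pw / pw.sum() if spread > 0 else None
        nxt = list(survivors)
        while len(nxt) < params.n_individuals:
            i, j = rng.choice(len(survivors), size=2, p=pw)
            c1, c2 = crossover(survivors[i], survivors[j], rng,
                               extents=tensor.shape,
                               min_shape=params.min_shape())
            nxt.append(c1)
            if len(nxt) < params.n_individuals:
                nxt.append(c2)
        nxt = [mutate(ind, tensor, params, prior, rng) for ind in nxt]
        pop = Population(nxt, generation_index=gen + 1)
    for ind in pop.individuals:
        track(ind, evaluate(ind))
    assert best is not None and best_fb is not None
    return best, best_fb


def run_trigen(tensor: ExpressionTensor3D, params: TriGenParams,
               rng: Optional[np.random.Generator] = None) -> SolutionSet:
    """Extract ``params.n_solutions`` triclusters sequentially.

    Thin functional wrapper over the :class:`TriGen` estimator.  After each
    extraction the solution joins the prior set, so the non-overlap reward
    steers subsequent runs away from it; the data itself is never masked.
    """
    est = TriGen(**_estimator_kwargs(params))
    est.fit(tensor, rng=rng)
    return est.solution_set_


def _estimator_kwargs(params: TriGenParams) -> dict:
    return {
        "n_solutions": params.n_solutions,
        "n_generations": params.n_generations,
        "n_individuals": params.n_individuals,
        "ale": params.ale,
        "sel": params.sel,
        "mut": params.mut,
        "w_g": params.w_g, "w_c": params.w_c, "w_t": params.w_t,
        "wo_g": params.wo_g, "wo_c": params.wo_c, "wo_t": params.wo_t,
        "min_genes": params.min_genes,
        "min_conditions": params.min_conditions,
        "min_times": params.min_times,
        "normalize_msr": params.normalize_msr,
        "random_state": params.seed,
    }


class TriGen(BaseEstimator):
    """Genetic-algorithm triclustering of a 3-D expression tensor.

    Mines ``n_solutions`` triclusters (gene x condition x time submatrices)
    from a dense tensor by minimising the range-normalised 3-D mean squared
    residue, rewarded for volume and for non-overlap with solutions already
    extracted.  Follows the scikit-learn estimator protocol: parameters are
    set at construction, :meth:`fit` consumes the data, and results land in
    trailing-underscore attributes.

    Parameters
    ----------
    n_solutions : int, default=20
        Number of triclusters to extract (one evolutionary run each).
    n_generations : int, default=100
        Generations per run.
    n_individuals : int, default=200
        Population size, constant across generations.
    ale : float, default=0.5
        Fraction of the initial population created at random (half purely
        random subsets, half contiguous runs); the rest avoids indices
        already used by earlier solutions.
    sel : float, default=0.5
        Survivor fraction of roulette selection.
    mut : float, default=0.3
        Per-individual mutation probability.
    w_g, w_c, w_t : float
        Volume-reward weights for genes, conditions and times.  Keep them
        small relative to the O(0.1) normalised residue of incoherent data,
        with ``w_g`` largest (the gene axis dominates real tensors).
    wo_g, wo_c, wo_t : float
        Non-overlap-reward weights per dimension.
    min_genes, min_conditions, min_times : int, default=2
        Size floors; singleton dimensions make the residue vanish
        identically, so the floors keep solutions informative.
    normalize_msr : bool, default=True
        Divide the residue by the squared data range in the objective.
    random_state : int or numpy.random.Generator or None, default=None
        Seed (or generator) for all stochastic operators.

    Attributes
    ----------
    solutions_ : list of Tricluster
        Extracted triclusters, in extraction order.
    fitness_ : list of FitnessBreakdown
        Objective decomposition of each solution at extraction time.
    solution_set_ : SolutionSet
        The same content packaged for downstream scoring/validation.
    n_genes_in_, n_conditions_in_, n_times_in_ : int
        Extents of the fitted tensor.

    Examples
    --------
    >>> import numpy as np
    >>> from trigen3d import ExpressionTensor3D, TriGen
    >>> X = ExpressionTensor3D(np.random.default_rng(0).uniform(
    ...     0, 100, size=(60, 8, 6)))
    >>> model = TriGen(n_solutions=2, n_generations=10, n_individuals=30,
    ...                random_state=0).fit(X)
    >>> len(model.solutions_)
    2
    """

    def __init__(self, n_solutions=20, n_generations=100, n_individuals=200,
                 ale=0.5, sel=0.5, mut=0.3,
                 w_g=0.05, w_c=0.005, w_t=0.005,
                 wo_g=0.002, wo_c=0.001, wo_t=0.001,
                 min_genes=2, min_conditions=2, min_times=2,
                 normalize_msr=True, random_state=None):
        self.n_solutions = n_solutions
        self.n_generations = n_generations
        self.n_individuals = n_individuals
        self.ale = ale
        self.sel = sel
        self.mut = mut
        self.w_g = w_g
        self.w_c = w_c
        self.w_t = w_t
        self.wo_g = wo_g
        self.wo_c = wo_c
        self.wo_t = wo_t
        self.min_genes = min_genes
        self.min_conditions = min_conditions
        self.min_times = min_times
        self.normalize_msr = normalize_msr
        self.random_state = random_state

    def _make_params(self) -> TriGenParams:
        seed = self.random_state if isinstance(self.random_state, int) else 0
        return TriGenParams(
            n_solutions=self.n_solutions, n_generations=self.n_generations,
            n_individuals=self.n_individuals, ale=self.ale, sel=self.sel,
            mut=self.mut, w_g=self.w_g, w_c=self.w_c, w_t=self.w_t,
            wo_g=self.wo_g, wo_c=self.wo_c, wo_t=self.wo_t, seed=seed,
            min_genes=self.min_genes, min_conditions=self.min_conditions,
            min_times=self.min_times, normalize_msr=self.normalize_msr)

    def fit(self, X, y=None, rng: Optional[np.random.Generator] = None):
        """Mine triclusters from ``X``.

        Parameters
        ----------
        X : ExpressionTensor3D or ndarray of shape (genes, conditions, times)
            Complete (no-missing) expression tensor.
        y : ignored
            Present for scikit-learn API compatibility.
        rng : numpy.random.Generator, optional
            Pre-seeded generator overriding ``random_state``.
        """
        tensor = (X if isinstance(X, ExpressionTensor3D)
                  else ExpressionTensor3D(np.asarray(X, dtype=float)))
        params = self._make_params()
        if rng is None:
            if isinstance(self.random_state, np.random.Generator):
                rng = self.random_state
            else:
                rng = np.random.default_rng(self.random_state)
        solutions = SolutionSet()
        for _ in range(params.n_solutions):
            tc, fb = evolve_one(tensor, params, solutions, rng)
            solutions.append(tc, fb)
        self.solution_set_ = solutions
        self.solutions_ = list(solutions.triclusters)
        self.fitness_ = list(solutions.breakdowns)
        self.n_genes_in_ = tensor.n_genes
        self.n_conditions_in_ = tensor.n_conditions
        self.n_times_in_ = tensor.n_times
        return self
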
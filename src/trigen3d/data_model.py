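"""Core domain types for tricluster mining on temporal expression tensors.

The central object is a dense, fully labelled 3-D expression tensor
(genes x conditions x times).  Triclusters and biclusters are index-set
views into such a tensor: strictly increasing, duplicate-free integer
index sequences, one per dimension.  Internally all indices are 0-based;
user-facing I/O speaks labels only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionTensor3D",
    "Tricluster",
    "Bicluster",
    "TriGenParams",
    "FitnessBreakdown",
    "ValidationResult",
    "validate_tricluster",
    "cells",
]


def _as_index_array(seq: Iterable[int], name: str) -> np.ndarray:
    arr = np.asarray(list(seq) if not isinstance(seq, np.ndarray) else seq)
    if arr.size == 0:
        raise ValueError(f"{name}: index sequence must be non-empty")
    if arr.ndim != 1 or not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{name}: expected a 1-D sequence of integers")
    return arr.astype(np.intp, copy=True)


def _check_labels(labels: Sequence[str], dim: str, extent: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) == 0:
        raise ValueError(f"{dim} labels must be non-empty")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{dim} labels must be unique")
    if len(labels) != extent:
        raise ValueError(
            f"{dim} labels ({len(labels)}) do not match tensor extent ({extent})"
        )
    return labels


class ExpressionTensor3D:
    """A dense gene x condition x time expression tensor with labels.

    Parameters
    ----------
    values : array-like, shape (n_genes, n_conditions, n_times)
        Finite expression values; no missing cells are allowed.
    gene_labels, condition_labels, time_labels : sequences of str
        Unique labels per axis.  Time labels are stored in chronological
        order: the axis order *is* the chronology.
    """

    def __init__(self, values, gene_labels=None, condition_labels=None,
                 time_labels=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
        if values.size == 0:
            raise ValueError("tensor must be non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("tensor contains non-finite values; complete "
                             "tensors are required (no missing cells)")
        ng, nc, nt = values.shape
        if gene_labels is None:
            gene_labels = [f"g{i}" for i in range(ng)]
        if condition_labels is None:
            condition_labels = [f"c{j}" for j in range(nc)]
        if time_labels is None:
            time_labels = [f"t{k}" for k in range(nt)]
        self.values = values
        self.gene_labels = _check_labels(gene_labels, "gene", ng)
        self.condition_labels = _check_labels(condition_labels, "condition", nc)
        self.time_labels = _check_labels(time_labels, "time", nt)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def value_range(self) -> float:
        """Spread max - min of the whole dataset (used to normalise MSR)."""
        return float(self.values.max() - self.values.min())

    def subtensor(self, tc: "Tricluster") -> np.ndarray:
        """Dense view of the cells selected by ``tc`` (copy)."""
        return self.values[np.ix_(tc.genes, tc.conditions, tc.times)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ng, nc, nt = self.shape
        return f"ExpressionTensor3D({ng} genes x {nc} conditions x {nt} times)"


def _validate_sequence(arr: np.ndarray, name: str) -> None:
    if np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} indices are not strictly increasing")
    if arr[0] < 0:
        raise ValueError(f"{name} indices must be non-negative")


@dataclass(frozen=True)
class Tricluster:
    """An individual/solution: three strictly increasing index subsets.

    ``genes``, ``conditions`` and ``times`` index into a tensor's axes; each
    sequence is non-empty, duplicate-free and sorted ascending.
    """

    genes: np.ndarray
    conditions: np.ndarray
    times: np.ndarray

    def __init__(self, genes, conditions, times):
        g = _as_index_array(genes, "genes")
        c = _as_index_array(conditions, "conditions")
        t = _as_index_array(times, "times")
        for arr, name in ((g, "gene"), (c, "condition"), (t, "time")):
            _validate_sequence(arr, name)
            arr.setflags(write=False)
        object.__setattr__(self, "genes", g)
        object.__setattr__(self, "conditions", c)
        object.__setattr__(self, "times", t)

    @classmethod
    def from_sets(cls, genes, conditions, times) -> "Tricluster":
        """Build from unordered index collections (sorted, de-duplicated)."""
        return cls(np.unique(np.asarray(list(genes), dtype=np.intp)),
                   np.unique(np.asarray(list(conditions), dtype=np.intp)),
                   np.unique(np.asarray(list(times), dtype=np.intp)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.genes), len(self.conditions), len(self.times))

    @property
    def n_cells(self) -> int:
        return len(self.genes) * len(self.conditions) * len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tricluster):
            return NotImplemented
        return (np.array_equal(self.genes, other.genes)
                and np.array_equal(self.conditions, other.conditions)
                and np.array_equal(self.times, other.times))

    def __hash__(self) -> int:
        return hash((self.genes.tobytes(), self.conditions.tobytes(),
                     self.times.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ng, nc, nt = self.shape
        return f"Tricluster({ng} x {nc} x {nt})"


@dataclass(frozen=True)
class Bicluster:
    """A 2-D cluster: gene and condition index subsets into a matrix."""

    genes: np.ndarray
    conditions: np.ndarray

    def __init__(self, genes, conditions):
        g = _as_index_array(genes, "genes")
        c = _as_index_array(conditions, "conditions")
        for arr, name in ((g, "gene"), (c, "condition")):
            _validate_sequence(arr, name)
            arr.setflags(write=False)
        object.__setattr__(self, "genes", g)
        object.__setattr__(self, "conditions", c)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genes), len(self.conditions))


@dataclass
class TriGenParams:
    """Control parameters of the evolutionary tricluster search.

    Attributes
    ----------
    n_solutions : int
        Number of triclusters extracted (N).
    n_generations : int
        Generations per extraction run.
    n_individuals : int
        Population size (I), held constant across generations.
    ale : float
        Randomness rate of the initial population, in [0, 1]: the fraction
        of individuals created purely at random (half of them as contiguous
        index runs); the remainder is steered away from prior solutions.
    sel : float
        Survivor fraction of roulette selection, in (0, 1].
    mut : float
        Per-individual mutation probability, in [0, 1].
    w_g, w_c, w_t : float
        Volume-reward weights per dimension (larger favours bigger subsets).
    wo_g, wo_c, wo_t : float
        Non-overlap-reward weights per dimension (larger steers away from
        previously extracted solutions).
    seed : int
        Seed of the single pseudo-random generator threaded through every
        stochastic operator.
    min_genes, min_conditions, min_times : int
        Hard size floors per dimension.  Default 2: the 3-D residue vanishes
        identically on any singleton dimension, so without a floor the
        search collapses onto degenerate slabs.
    normalize_msr : bool
        Divide the residue term of the fitness by the squared data range so
        it shares the [0, 1] scale of the reward terms (default True).
    """

    n_solutions: int = 20
    n_generations: int = 100
    n_individuals: int = 200
    ale: float = 0.5
    sel: float = 0.5
    mut: float = 0.3
    w_g: float = 0.05
    w_c: float = 0.005
    w_t: float = 0.005
    wo_g: float = 0.002
    wo_c: float = 0.001
    wo_t: float = 0.001
    seed: int = 0
    min_genes: int = 2
    min_conditions: int = 2
    min_times: int = 2
    normalize_msr: bool = True

    def __post_init__(self):
        if self.n_solutions < 1 or self.n_generations < 1 or self.n_individuals < 1:
            raise ValueError("n_solutions, n_generations and n_individuals "
                             "must be positive")
        if not 0.0 <= self.ale <= 1.0:
            raise ValueError("ale must lie in [0, 1]")
        if not 0.0 < self.sel <= 1.0:
            raise ValueError("sel must lie in (0, 1]")
        if not 0.0 <= self.mut <= 1.0:
            raise ValueError("mut must lie in [0, 1]")
        for name in ("w_g", "w_c", "w_t", "wo_g", "wo_c", "wo_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_genes", "min_conditions", "min_times"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def min_shape(self) -> tuple[int, int, int]:
        return (self.min_genes, self.min_conditions, self.min_times)


@dataclass(frozen=True)
class FitnessBreakdown:
    """Decomposition of the minimised objective for one tricluster.

    ``ff = msr3d_term - size_reward - overlap_reward``; lower is better.
    """

    msr3d_term: float
    size_reward: float
    overlap_reward: float

    @property
    def ff(self) -> float:
        return self.msr3d_term - self.size_reward - self.overlap_reward


@dataclass(frozen=True)
class ValidationResult:
    """Verdict of a structural check; falsy when a rule is violated."""

    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def validate_tricluster(tc: Tricluster,
                        tensor: ExpressionTensor3D) -> ValidationResult:
    """Check a tricluster's index sets against a tensor's extents.

    Returns a :class:`ValidationResult`; on failure ``reason`` names the
    violated rule (emptiness, ordering/duplicates, or bounds).
    """
    extents = tensor.shape
    for arr, name, extent in ((np.asarray(tc.genes), "gene", extents[0]),
                              (np.asarray(tc.conditions), "condition", extents[1]),
                              (np.asarray(tc.times), "time", extents[2])):
        if arr.size == 0:
            return ValidationResult(False, f"{name} sequence is empty")
        if np.any(np.diff(arr) <= 0):
            return ValidationResult(False,
                                    f"{name} indices not strictly increasing")
        if arr[0] < 0 or arr[-1] >= extent:
            return ValidationResult(False, f"{name} index out of bounds "
                                           f"(extent {extent})")
    return ValidationResult(True)


def cells(tc: Tricluster) -> set[tuple[int, int, int]]:
    """All (gene, condition, time) index triples covered by ``tc``.

    The Cartesian product genes x conditions x times; its size equals the
    product of the three sequence lengths.
    """
    return set(itertools.product(tc.genes.tolist(), tc.conditions.tolist(),
                                 tc.times.tolist()))
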
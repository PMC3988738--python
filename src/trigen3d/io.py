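"""File formats for tensors, solutions and ground truth.

The canonical interchange format for a 3-D expression tensor is a
long-format TSV with header ``gene<TAB>condition<TAB>time<TAB>value`` and
exactly one row per (gene, condition, time) combination.  A directory of
per-time-point gene x condition matrices (GEO-style) is also accepted.
Solutions and implant ground truth are stored as versioned JSON keyed by
labels, never raw indices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (ExpressionTensor3D, FitnessBreakdown, TriGenParams,
                         Tricluster)
from .ga import SolutionSet
from .measures import msr3d
from .synthetic import ImplantRecord

__all__ = [
    "RunConfig",
    "read_tensor",
    "write_tensor",
    "write_solutions",
    "read_solutions",
    "write_ground_truth",
    "read_ground_truth",
]

SCHEMA_VERSION = 1
LONG_COLUMNS = ["gene", "condition", "time", "value"]


class TensorParseError(ValueError):
    """A tensor file violates the format contract (names the offender)."""


def _ordered_unique(values: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def _time_order(labels: list[str]) -> list[str]:
    """Numeric sort when every label parses as a number, else input order."""
    try:
        return sorted(labels, key=float)
    except ValueError:
        return labels


def _read_long_tsv(path: Path) -> ExpressionTensor3D:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str},
                     float_precision="round_trip")
    if list(df.columns) != LONG_COLUMNS:
        raise TensorParseError(
            f"{path}: expected header {LONG_COLUMNS}, got {list(df.columns)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        raise TensorParseError(
            f"{path}: non-numeric value at data row {bad[0] + 1}: "
            f"{df.loc[bad[0]].tolist()}")
    dup = df.duplicated(subset=["gene", "condition", "time"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TensorParseError(
            f"{path}: duplicated cell (gene={row['gene']}, "
            f"condition={row['condition']}, time={row['time']})")
    genes = _ordered_unique(df["gene"].tolist())
    conditions = _ordered_unique(df["condition"].tolist())
    times = _time_order(_ordered_unique(df["time"].tolist()))
    expected = len(genes) * len(conditions) * len(times)
    if len(df) != expected:
        raise TensorParseError(
            f"{path}: {len(df)} rows but {expected} (gene, condition, time) "
            f"combinations are required; some cells are missing")
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: i for i, c in enumerate(conditions)}
    ti = {t: i for i, t in enumerate(times)}
    values = np.empty((len(genes), len(conditions), len(times)))
    values[df["gene"].map(gi), df["condition"].map(ci),
           df["time"].map(ti)] = vals.to_numpy()
    return ExpressionTensor3D(values, genes, conditions, times)


def _read_matrix_dir(path: Path) -> ExpressionTensor3D:
    manifest = path / "times.txt"
    if manifest.exists():
        names = [ln.strip() for ln in manifest.read_text().splitlines()
                 if ln.strip()]
        files = [path / n for n in names]
        for f in files:
            if not f.exists():
                raise TensorParseError(f"{manifest}: listed file {f.name} "
                                       f"not found")
    else:
        files = sorted(path.glob("*.tsv"),
                       key=lambda f: (_numeric_key(f.stem), f.stem))
    if not files:
        raise TensorParseError(f"{path}: no per-time-point .tsv files found")
    slabs, genes, conditions = [], None, None
    for f in files:
        df = pd.read_csv(f, sep="\t", index_col=0)
        if df.isna().any().any():
            raise TensorParseError(f"{f}: missing or non-numeric values")
        g = [str(x) for x in df.index]
        c = [str(x) for x in df.columns]
        if genes is None:
            genes, conditions = g, c
        elif g != genes or c != conditions:
            raise TensorParseError(
                f"{f}: row/column labels differ from {files[0].name} "
                f"(ragged matrices)")
        slabs.append(df.to_numpy(dtype=float))
    times = [f.stem for f in files]
    return ExpressionTensor3D(np.stack(slabs, axis=-1), genes, conditions,
                              times)


def _numeric_key(stem: str):
    try:
        return (0, float(stem))
    except ValueError:
        return (1, 0.0)


def read_tensor(path, format: str = "long_tsv") -> ExpressionTensor3D:
    """Read a labelled tensor from ``long_tsv`` or ``matrix_dir`` format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long_tsv":
        return _read_long_tsv(path)
    if format == "matrix_dir":
        return _read_matrix_dir(path)
    raise ValueError(f"unknown tensor format: {format!r}")


def write_tensor(tensor: ExpressionTensor3D, path) -> None:
    """Write a tensor as canonical long-format TSV (round-trips exactly)."""
    path = Path(path)
    ng, nc, nt = tensor.shape
    g = np.repeat(np.arange(ng), nc * nt)
    c = np.tile(np.repeat(np.arange(nc), nt), ng)
    t = np.tile(np.arange(nt), ng * nc)
    df = pd.DataFrame({
        "gene": np.asarray(tensor.gene_labels)[g],
        "condition": np.asarray(tensor.condition_labels)[c],
        "time": np.asarray(tensor.time_labels)[t],
        "value": tensor.values[g, c, t],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _tc_to_labels(tc: Tricluster, tensor: ExpressionTensor3D) -> dict:
    return {
        "genes": [tensor.gene_labels[i] for i in tc.genes],
        "conditions": [tensor.condition_labels[i] for i in tc.conditions],
        "times": [tensor.time_labels[i] for i in tc.times],
    }


def _tc_from_labels(d: dict, tensor: ExpressionTensor3D) -> Tricluster:
    gi = {g: i for i, g in enumerate(tensor.gene_labels)}
    ci = {c: i for i, c in enumerate(tensor.condition_labels)}
    ti = {t: i for i, t in enumerate(tensor.time_labels)}
    return Tricluster.from_sets([gi[g] for g in d["genes"]],
                                [ci[c] for c in d["conditions"]],
                                [ti[t] for t in d["times"]])


def write_solutions(solutions: SolutionSet, tensor: ExpressionTensor3D,
                    path) -> None:
    """Write a solution set as versioned JSON plus a TSV summary.

    The JSON (at ``path``) carries labels, per-solution MSR_3D and the
    fitness breakdown; the sibling ``<path>.summary.tsv`` is a
    human-readable table.
    """
    path = Path(path)
    entries = []
    for tc, fb in zip(solutions.triclusters, solutions.breakdowns):
        entry = _tc_to_labels(tc, tensor)
        entry["shape"] = list(tc.shape)
        entry["msr3d"] = msr3d(tensor, tc)
        entry["fitness"] = {"msr3d_term": fb.msr3d_term,
                            "size_reward": fb.size_reward,
                            "overlap_reward": fb.overlap_reward,
                            "ff": fb.ff}
        entries.append(entry)
    doc = {"schema_version": SCHEMA_VERSION, "solutions": entries}
    path.write_text(json.dumps(doc, indent=1) + "\n")
    rows = [{"solution": i + 1,
             "n_genes": e["shape"][0], "n_conditions": e["shape"][1],
             "n_times": e["shape"][2], "msr3d": e["msr3d"],
             "ff": e["fitness"]["ff"]}
            for i, e in enumerate(entries)]
    pd.DataFrame(rows, columns=["solution", "n_genes", "n_conditions",
                                "n_times", "msr3d", "ff"]).to_csv(
        path.with_suffix(path.suffix + ".summary.tsv"), sep="\t", index=False)


def read_solutions(path, tensor: ExpressionTensor3D) -> SolutionSet:
    """Read a solutions JSON back into a :class:`SolutionSet`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported solutions schema: "
                         f"{doc.get('schema_version')!r}")
    out = SolutionSet()
    for e in doc["solutions"]:
        fb = FitnessBreakdown(**{k: e["fitness"][k]
                                 for k in ("msr3d_term", "size_reward",
                                           "overlap_reward")})
        out.append(_tc_from_labels(e, tensor), fb)
    return out


def write_ground_truth(records: list[ImplantRecord],
                       tensor: ExpressionTensor3D, path) -> None:
    """Write implant ground truth (label-keyed positions + pattern)."""
    entries = []
    for rec in records:
        entry = _tc_to_labels(rec.tricluster, tensor)
        entry["pattern_model"] = rec.pattern_model
        entry["params"] = {k: (v.tolist() if isinstance(v, np.ndarray)
                               else v)
                           for k, v in rec.params.items()}
        entries.append(entry)
    Path(path).write_text(json.dumps(
        {"schema_version": SCHEMA_VERSION, "implants": entries}, indent=1)
        + "\n")


def read_ground_truth(path, tensor: ExpressionTensor3D
                      ) -> list[ImplantRecord]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported ground-truth schema: "
                         f"{doc.get('schema_version')!r}")
    return [ImplantRecord(tricluster=_tc_from_labels(e, tensor),
                          pattern_model=e.get("pattern_model", "unknown"),
                          params={k: np.asarray(v) if isinstance(v, list)
                                  else v
                                  for k, v in e.get("params", {}).items()})
            for e in doc["implants"]]


@dataclass
class RunConfig:
    """Resolved configuration of one mining run (CLI surface).

    Collects every search parameter plus input/output locations; a logged
    resolved config re-executes to identical output.
    """

    input: str = ""
    input_format: str = "long_tsv"
    output: str = "solutions.json"
    correlation_methods: tuple[str, ...] = ("pearson", "spearman")
    verbosity: int = 1
    params: TriGenParams = field(default_factory=TriGenParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pkeys = {f for f in TriGenParams.__dataclass_fields__}
        pvals = {k: v for k, v in raw.items() if k in pkeys}
        rest = {k: v for k, v in raw.items() if k not in pkeys}
        if "correlation_methods" in rest:
            rest["correlation_methods"] = tuple(rest["correlation_methods"])
        return cls(params=TriGenParams(**pvals), **rest)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["correlation_methods"] = list(self.correlation_methods)
        return d
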
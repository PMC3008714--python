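"""Readers and writers for every on-disk format the pipeline touches.

All tabular files are plain UTF-8 TSV (tab separator, ``.`` decimal, no
quoting) so that repeated runs produce byte-identical output.  Expression
matrices are assumed to be already normalized, log2-scale values; this
module never re-normalizes or re-logs.
"""

from __future__ import annotations

import dataclasses
import os
import re
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .ontology import AnnotationMap, CyclicOntologyError, OntologyDAG

__all__ = [
    "TimeSeriesExperiment",
    "ExpressionFormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ontology",
    "read_annotations",
    "read_gmt",
    "write_gmt",
    "write_results",
    "FLOAT_FORMAT",
]

#: Fixed float format used by every writer: reproducible, round-trip safe
#: at the precision the pipeline needs.
FLOAT_FORMAT = "%.10g"


class ExpressionFormatError(ValueError):
    """Malformed expression matrix file."""


@dataclasses.dataclass
class TimeSeriesExperiment:
    """Paired treated/control log2-expression series on a shared time grid.

    The design carries a complete duplicate of the time-0 sample in both
    conditions (``treated_t0_rep``, ``control_t0_rep``); those replicates
    are the sole source of the measurement-error model used by selection.
    """

    gene_ids: list[str]
    times: np.ndarray  # minutes, strictly increasing, times[0] == 0
    treated: np.ndarray  # genes x times, log2
    control: np.ndarray  # genes x times, log2
    treated_t0_rep: np.ndarray  # genes, duplicate time-0 column
    control_t0_rep: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.treated = np.asarray(self.treated, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.treated_t0_rep = np.asarray(self.treated_t0_rep, dtype=float)
        self.control_t0_rep = np.asarray(self.control_t0_rep, dtype=float)
        n, t = len(self.gene_ids), len(self.times)
        if self.times[0] != 0:
            raise ValueError("time grid must start at 0")
        if t < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        for name in ("treated", "control"):
            m = getattr(self, name)
            if m.shape != (n, t):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {t})")
        for name in ("treated_t0_rep", "control_t0_rep"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(f"{name} shape {v.shape} != ({n},)")
        for name in ("treated", "control", "treated_t0_rep", "control_t0_rep"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite value in {name}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def diff(self) -> np.ndarray:
        """Treated-minus-control profiles (genes x times)."""
        return self.treated - self.control

    def mean_intensity(self) -> np.ndarray:
        """Per-gene mean log2 intensity over every measured column."""
        cols = np.column_stack(
            [self.treated, self.control,
             self.treated_t0_rep[:, None], self.control_t0_rep[:, None]]
        )
        return cols.mean(axis=1)


_COL_RE = re.compile(r"^(treated|control)_(\d+(?:\.\d+)?)(_rep2)?$")


def write_expression_tsv(exp: TimeSeriesExperiment, path: str | os.PathLike) -> None:
    """Write a :class:`TimeSeriesExperiment` as a TSV expression matrix."""

    def tname(t: float) -> str:
        return f"{t:g}"

    cols: dict[str, np.ndarray] = {}
    for j, t in enumerate(exp.times):
        cols[f"treated_{tname(t)}"] = exp.treated[:, j]
    cols["treated_0_rep2"] = exp.treated_t0_rep
    for j, t in enumerate(exp.times):
        cols[f"control_{tname(t)}"] = exp.control[:, j]
    cols["control_0_rep2"] = exp.control_t0_rep
    df = pd.DataFrame(cols, index=pd.Index(exp.gene_ids, name="gene"))
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression_tsv(path: str | os.PathLike) -> TimeSeriesExperiment:
    """Read a TSV expression matrix into a validated experiment.

    Column headers encode condition and time (``treated_0``, ``control_40``,
    ...) with ``_rep2`` marking the duplicate time-0 sample of each
    condition; column order in the file is irrelevant.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    parsed: dict[tuple[str, float, bool], str] = {}
    for col in df.columns:
        m = _COL_RE.match(col)
        if not m:
            raise ExpressionFormatError(f"unrecognized column header {col!r}")
        cond, t, rep = m.group(1), float(m.group(2)), bool(m.group(3))
        if rep and t != 0:
            raise ExpressionFormatError(f"replicate column {col!r} not at time 0")
        parsed[(cond, t, rep)] = col

    values: dict[str, np.ndarray] = {}
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() | ~np.isfinite(num.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ExpressionFormatError(
                f"non-numeric or non-finite value at gene {gene!r}, column {col!r}"
            )
        values[col] = num.to_numpy(dtype=float)

    t_treated = sorted(t for (c, t, r) in parsed if c == "treated" and not r)
    t_control = sorted(t for (c, t, r) in parsed if c == "control" and not r)
    if t_treated != t_control:
        raise ExpressionFormatError(
            f"treated/control time grids differ: {t_treated} vs {t_control}"
        )
    if not t_treated or t_treated[0] != 0:
        raise ExpressionFormatError("no time-0 column")
    for cond in ("treated", "control"):
        if (cond, 0.0, True) not in parsed:
            raise ExpressionFormatError(f"no replicate at t=0 for condition {cond!r}")

    times = np.array(t_treated, dtype=float)
    treated = np.column_stack([values[parsed[("treated", t, False)]] for t in t_treated])
    control = np.column_stack([values[parsed[("control", t, False)]] for t in t_treated])
    return TimeSeriesExperiment(
        gene_ids=[str(g) for g in df.index],
        times=times,
        treated=treated,
        control=control,
        treated_t0_rep=values[parsed[("treated", 0.0, True)]],
        control_t0_rep=values[parsed[("control", 0.0, True)]],
    )


# ---------------------------------------------------------------------------
# ontology / annotation / gene sets


def read_ontology(path: str | os.PathLike, dialect: str = "obo-subset") -> OntologyDAG:
    """Read an is_a ontology graph from a minimal OBO file or an edge TSV.

    The OBO reader honours ``id``, ``name``, ``is_a`` and obsolete flags
    only.  The edge-TSV dialect is one ``child<TAB>parent`` pair per line
    (``#`` comments allowed).  Both dialects yield identical DAGs for the
    same graph.
    """
    if dialect == "obo-subset":
        import obonet

        g = obonet.read_obo(path)
        names = {n: d.get("name", n) for n, d in g.nodes(data=True)}
        edges = [(u, v) for u, v, key in g.edges(keys=True) if key == "is_a"]
        return OntologyDAG.from_edges(edges, names=names, extra_terms=g.nodes)
    if dialect == "edge-tsv":
        edges = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected child<TAB>parent")
                child, parent = parts[0], parts[1]
                if child == parent:
                    raise CyclicOntologyError(
                        f"{path}: line {lineno}: self-loop on {child!r}"
                    )
                edges.append((child, parent))
        return OntologyDAG.from_edges(edges)
    raise ValueError(f"unknown ontology dialect {dialect!r}")


def write_ontology_edge_tsv(dag: OntologyDAG, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(dag.graph.edges):
            fh.write(f"{child}\t{parent}\n")


def read_annotations(
    path: str | os.PathLike, dag: OntologyDAG, propagate: bool = True
) -> AnnotationMap:
    """Read a 2-column (gene, term) TSV into an :class:`AnnotationMap`.

    Terms absent from *dag* are skipped with a count in the attached load
    report.  With ``propagate=True`` every annotation is extended to all
    ancestors (true-path rule).
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected gene<TAB>term")
            pairs.append((parts[0], parts[1]))
    return AnnotationMap.from_pairs(pairs, dag=dag, propagate=propagate)


def write_annotations(pairs: list[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, term in pairs:
            fh.write(f"{gene}\t{term}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs name, description and >= 1 member"
                )
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# result tables


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> list[str]:
    """Write one TSV per pipeline stage into *out_dir*.

    *tables* maps a stage name (used as the file stem) to its result frame.
    Writing is deterministic: re-running on identical inputs yields
    byte-identical files.  Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)
        written.append(path)
    return written


def collapse_probes(
    df: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Optional many-to-one probe -> gene collapse (median of probe rows).

    Off by default everywhere; provided for matrices carrying probe-level
    identifiers.
    """
    genes = df.index.map(lambda p: probe_to_gene.get(p, p))
    out = df.groupby(genes).median()
    out.index.name = df.index.name
    return out
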
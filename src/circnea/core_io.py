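"""Canonical data types and file I/O for the association-prediction pipeline.

Conventions used throughout the package:

* association matrices have circRNAs on rows and diseases on columns;
* identifiers are case-sensitive opaque strings, never normalised;
* dense matrices travel as CSV with id headers, associations as long-format
  TSV, DAGs as child->parent edge-list TSV.  All files UTF-8 with LF endings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class AssociationMatrix:
    """Binary circRNA x disease adjacency matrix with id registries.

    ``AM[i, j] == 1`` iff circRNA ``circ_ids[i]`` is associated with disease
    ``disease_ids[j]``.  Axis order is part of the contract: rows are
    circRNAs (m of them), columns are diseases (n of them).
    """

    circ_ids: list[str]
    disease_ids: list[str]
    AM: np.ndarray

    def __post_init__(self) -> None:
        self.AM = np.asarray(self.AM)
        m, n = self.AM.shape
        if m < 1 or n < 1:
            raise ValueError("association matrix must be at least 1x1")
        if len(self.circ_ids) != m or len(self.disease_ids) != n:
            raise ValueError("id registry lengths do not match matrix shape")
        if len(set(self.circ_ids)) != m or len(set(self.disease_ids)) != n:
            raise ValueError("duplicate identifiers within an axis")
        if not np.isin(self.AM, (0, 1)).all():
            raise ValueError("association matrix entries must be exactly 0 or 1")
        self.AM = self.AM.astype(np.int8)

    @property
    def m(self) -> int:
        return self.AM.shape[0]

    @property
    def n(self) -> int:
        return self.AM.shape[1]


@dataclass
class DiseaseDAG:
    """Directed acyclic ancestor structure over disease identifiers.

    ``edges`` are (child, parent) pairs.  For each disease ``d`` the ancestor
    closure ``N_d`` (ancestors plus ``d`` itself) and the induced edge set
    ``E_d`` are precomputed at construction.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    closures: dict[str, frozenset[str]] = field(init=False)
    induced_edges: dict[str, frozenset[tuple[str, str]]] = field(init=False)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for child, parent in self.edges:
            if child not in known or parent not in known:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)  # child -> parent direction
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cyc = nx.find_cycle(g)
            raise ValueError(f"cycle detected in disease DAG at edge {cyc[0][:2]}") from None
        # closure[d] = {d} union closure of parents; fill in topological order
        # (parents come after children when edges point child -> parent, so
        # walk the order reversed... parents are successors, so iterate the
        # order reversed to have parents done first).
        closure: dict[str, set[str]] = {}
        for node in reversed(order):
            s = {node}
            for parent in g.successors(node):
                s |= closure[parent]
            closure[node] = s
        self.closures = {d: frozenset(s) for d, s in closure.items()}
        self.induced_edges = {
            d: frozenset((c, p) for c, p in self.edges if c in s and p in s)
            for d, s in self.closures.items()
        }
        self._graph = g

    def ancestors(self, d: str) -> frozenset[str]:
        """N_d: ``d`` together with every ancestor reachable via parent edges."""
        return self.closures[d]

    def children_within(self, e: str, d: str) -> list[str]:
        """Children of ``e`` that lie inside disease ``d``'s DAG."""
        nd = self.closures[d]
        return [c for c in self._graph.predecessors(e) if c in nd]

    def __contains__(self, d: str) -> bool:
        return d in self.closures


@dataclass
class ExpressionTable:
    """circRNA expression profiles: one row of p sample values per circRNA."""

    circ_ids: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be 2-D (circRNA x sample)")
        if len(self.circ_ids) != self.profiles.shape[0]:
            raise ValueError("row count does not match id count")
        if not np.isfinite(self.profiles).all():
            raise ValueError("expression profiles must be finite")


@dataclass
class LabeledPairSet:
    """(circ index, disease index, label) triples used for training/evaluation."""

    pairs: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, y in self.pairs:
            if y not in (0, 1):
                raise ValueError(f"label must be 0/1, got {y!r}")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_associations(path) -> AssociationMatrix:
    """Read a long-format association TSV into an AssociationMatrix.

    Expected header: ``circRNA_id<TAB>disease_id<TAB>label`` with label in
    {0, 1}.  Axes are sorted lexicographically so the matrix is deterministic
    for a given file regardless of row order.  Contradictory duplicate rows
    (same pair, different label) are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise FormatError("expected 3 columns: circRNA_id, disease_id, label")
    df.columns = ["circRNA_id", "disease_id", "label", *df.columns[3:]]
    if df.empty:
        raise FormatError("no associations in file")
    bad = ~df["label"].isin([0, 1])
    if bad.any():
        raise FormatError(f"unknown label value {df['label'][bad].iloc[0]!r}")
    grouped = df.groupby(["circRNA_id", "disease_id"])["label"].nunique()
    if (grouped > 1).any():
        pair = grouped[grouped > 1].index[0]
        raise FormatError(f"contradictory duplicate rows for pair {pair}")
    circ_ids = sorted(df["circRNA_id"].unique())
    disease_ids = sorted(df["disease_id"].unique())
    ci = {c: i for i, c in enumerate(circ_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    am = np.zeros((len(circ_ids), len(disease_ids)), dtype=np.int8)
    pos = df[df["label"] == 1]
    am[pos["circRNA_id"].map(ci), pos["disease_id"].map(di)] = 1
    return AssociationMatrix(circ_ids, disease_ids, am)


def write_associations(assoc: AssociationMatrix, pairs: LabeledPairSet | None, path) -> None:
    """Write associations as long-format TSV.

    With ``pairs`` given, only those labeled pairs are written (including
    explicit negatives); otherwise every cell of AM is written.
    """
    rows = []
    if pairs is None:
        for i, c in enumerate(assoc.circ_ids):
            for j, d in enumerate(assoc.disease_ids):
                rows.append((c, d, int(assoc.AM[i, j])))
    else:
        for i, j, y in pairs.pairs:
            rows.append((assoc.circ_ids[i], assoc.disease_ids[j], y))
    pd.DataFrame(rows, columns=["circRNA_id", "disease_id", "label"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_dag(path) -> DiseaseDAG:
    """Read a ``child<TAB>parent`` edge-list TSV into a DiseaseDAG."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("expected 2 columns: child, parent")
    edges = [(str(c), str(p)) for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])]
    nodes = sorted({x for e in edges for x in e})
    return DiseaseDAG(nodes, edges)


def write_dag(dag: DiseaseDAG, path) -> None:
    pd.DataFrame(dag.edges, columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_expression(path) -> ExpressionTable:
    """Read an expression TSV: first column circRNA id, rest numeric samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy()
    bad = ~np.isfinite(mat.astype(float, casting="unsafe"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(f"non-numeric or non-finite cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    return ExpressionTable([str(i) for i in df.index], mat.astype(float))


def write_expression(expr: ExpressionTable, path) -> None:
    pd.DataFrame(
        expr.profiles,
        index=pd.Index(expr.circ_ids, name="circRNA_id"),
        columns=[f"s{k}" for k in range(expr.profiles.shape[1])],
    ).to_csv(path, sep="\t", lineterminator="\n")


def write_matrix(matrix: np.ndarray, path, row_ids=None, col_ids=None) -> None:
    """Write a dense matrix as CSV with id headers (first row and column)."""
    matrix = np.asarray(matrix)
    if row_ids is None:
        row_ids = [f"r{i}" for i in range(matrix.shape[0])]
    if col_ids is None:
        col_ids = [f"c{j}" for j in range(matrix.shape[1])]
    pd.DataFrame(matrix, index=pd.Index(row_ids, name="id"), columns=col_ids).to_csv(
        path, lineterminator="\n", float_format="%.17g"
    )


def read_matrix(path, with_ids: bool = False):
    """Read a dense CSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0)
    mat = df.to_numpy(dtype=float)
    bad = ~np.isfinite(mat)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    if with_ids:
        return mat, [str(i) for i in df.index], [str(c) for c in df.columns]
    return mat


def pairs_from_matrix(assoc: AssociationMatrix) -> LabeledPairSet:
    """All positive cells of AM as a labeled pair set (no negatives)."""
    pos = np.argwhere(assoc.AM == 1)
    return LabeledPairSet([(int(i), int(j), 1) for i, j in pos])
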
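"""Readers and writers for the formats the pipeline touches.

Discrete morphological matrices travel as NEXUS ``DATA``/``CHARACTERS``
blocks (digit symbols, ``?`` missing, ``{..}`` polymorphism, ``-`` treated
as missing), trees as Newick/NEXUS with node ages carried in metadata
comments, and geographic ranges / connectivity as CSV.  Every reader
validates the invariants of the container it builds.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trees import TimeTree, TreeValidationError

__all__ = [
    "CharacterMatrix",
    "RangeTable",
    "ConnectivityModel",
    "MUROID_AREAS",
    "NexusParseError",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "read_tree",
    "write_tree",
    "read_range_table",
    "write_range_table",
    "read_connectivity",
    "write_connectivity",
    "read_calibrations",
    "write_calibrations",
]

#: Area codes of the 13-region system used for muroid ranges.
MUROID_AREAS = (
    "SWE", "CE", "GR", "AC", "WCA", "AR", "SCA",
    "ECA", "NA", "EA", "SA", "RU", "SEA",
)

_SA_TOL = 1e-9


class NexusParseError(ValueError):
    """Malformed NEXUS input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ----------------------------------------------------------------------
# character matrices
# ----------------------------------------------------------------------
@dataclass
class CharacterMatrix:
    """Taxa x discrete characters with ambiguity sets.

    ``chars[i][j]`` is the frozenset of states taxon ``i`` may occupy at
    character ``j``; full ambiguity (all states of the character) encodes
    missing data.  ``coding`` records whether constant characters were
    excluded ("variable") or not ("all"), which drives the Mk(v)
    ascertainment correction downstream.
    """

    taxa: list[str]
    chars: list[list[frozenset[int]]]
    state_counts: list[int]
    coding: str = "variable"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.state_counts)

    def column(self, j: int) -> dict[str, frozenset[int]]:
        return {t: self.chars[i][j] for i, t in enumerate(self.taxa)}

    def is_constant(self, j: int) -> bool:
        """True if some single state is compatible with every taxon."""
        k = self.state_counts[j]
        possible = set(range(k))
        for row in self.chars:
            possible &= row[j]
            if not possible:
                return False
        return bool(possible)

    def validate(self) -> None:
        if self.coding not in ("all", "variable"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        for i, row in enumerate(self.chars):
            if len(row) != self.n_chars:
                raise ValueError(
                    f"taxon {self.taxa[i]!r} has {len(row)} characters, "
                    f"expected {self.n_chars}"
                )
            for j, cell in enumerate(row):
                k = self.state_counts[j]
                if k < 2:
                    raise ValueError(f"character {j} has state count {k} < 2")
                if not cell or max(cell) >= k or min(cell) < 0:
                    raise ValueError(
                        f"taxon {self.taxa[i]!r} char {j}: states {sorted(cell)} "
                        f"outside 0..{k - 1}"
                    )
        if self.coding == "variable":
            for j in range(self.n_chars):
                if self.is_constant(j):
                    raise ValueError(
                        f"character {j} is constant under variable-only coding"
                    )


def _parse_cell(text: str, pos: int, line: int) -> tuple[frozenset[int] | None, int]:
    ch = text[pos]
    if ch in "?-":
        return None, pos + 1  # full ambiguity, resolved once k is known
    if ch == "{" or ch == "(":
        close = "}" if ch == "{" else ")"
        end = text.find(close, pos)
        if end < 0:
            raise NexusParseError("unterminated polymorphism set", line)
        states = frozenset(int(c) for c in text[pos + 1 : end] if c.isdigit())
        if not states:
            raise NexusParseError("empty polymorphism set", line)
        return states, end + 1
    if ch.isdigit():
        return frozenset([int(ch)]), pos + 1
    raise NexusParseError(f"unexpected symbol {ch!r} in matrix row", line)


def read_nexus_matrix(
    path,
    state_counts: dict[int, int] | None = None,
    coding: str = "variable",
) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    State counts default to (max observed state + 1) per character;
    ``state_counts`` overrides individual characters (0-based index).
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.splitlines()
    in_block = False
    in_matrix = False
    ntax = nchar = None
    taxa: list[str] = []
    rows: list[list[frozenset[int] | None]] = []
    for ln, raw in enumerate(lines, start=1):
        stripped = re.sub(r"\[[^\]]*\]", "", raw).strip()  # drop comments
        if not stripped:
            continue
        upper = stripped.upper()
        if upper.startswith("BEGIN DATA") or upper.startswith("BEGIN CHARACTERS"):
            in_block = True
            continue
        if not in_block:
            continue
        if upper.startswith("DIMENSIONS"):
            m = re.search(r"NTAX\s*=\s*(\d+)", upper)
            if m:
                ntax = int(m.group(1))
            m = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            if m:
                nchar = int(m.group(1))
            continue
        if upper.startswith("FORMAT"):
            continue
        if upper.startswith("MATRIX"):
            in_matrix = True
            continue
        if upper.startswith("END"):
            break
        if in_matrix:
            if stripped == ";":
                in_matrix = False
                continue
            body = stripped.rstrip(";")
            m = re.match(r"(?:'([^']+)'|(\S+))\s+(\S.*)$", body)
            if not m:
                raise NexusParseError("cannot split row into label and states", ln)
            label = m.group(1) or m.group(2)
            cells_text = m.group(3).replace(" ", "")
            cells: list[frozenset[int] | None] = []
            pos = 0
            while pos < len(cells_text):
                cell, pos = _parse_cell(cells_text, pos, ln)
                cells.append(cell)
            if nchar is not None and len(cells) != nchar:
                raise NexusParseError(
                    f"taxon {label!r} has {len(cells)} characters, expected {nchar}",
                    ln,
                )
            taxa.append(label)
            rows.append(cells)
            if stripped.endswith(";"):
                in_matrix = False
    if not in_block:
        raise NexusParseError("no DATA/CHARACTERS block found")
    if not rows:
        raise NexusParseError("empty matrix")
    if ntax is not None and len(taxa) != ntax:
        raise NexusParseError(f"found {len(taxa)} taxa, NTAX says {ntax}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise NexusParseError(f"ragged matrix rows, widths {sorted(widths)}")
    n_chars = widths.pop()
    counts = []
    for j in range(n_chars):
        observed = [max(r[j]) for r in rows if r[j] is not None]
        k = (max(observed) + 1) if observed else 2
        k = max(k, 2)
        if state_counts and j in state_counts:
            k = state_counts[j]
        counts.append(k)
    chars = [
        [
            cell if cell is not None else frozenset(range(counts[j]))
            for j, cell in enumerate(row)
        ]
        for row in rows
    ]
    return CharacterMatrix(taxa, chars, counts, coding=coding)


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    buf = io.StringIO()
    buf.write("#NEXUS\nBEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    buf.write('FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;\n')
    buf.write("MATRIX\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        cells = []
        for j, cell in enumerate(matrix.chars[i]):
            if cell == frozenset(range(matrix.state_counts[j])):
                cells.append("?")
            elif len(cell) == 1:
                cells.append(str(next(iter(cell))))
            else:
                cells.append("{" + "".join(str(s) for s in sorted(cell)) + "}")
        label = f"'{taxon}'" if re.search(r"\s", taxon) else taxon
        buf.write(f"{label:<{width}}{''.join(cells)}\n")
    buf.write(";\nEND;\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
def _dendropy_to_timetree(dtree: dendropy.Tree) -> TimeTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    depth = np.zeros(len(nodes))
    labels = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            if bl < -_SA_TOL:
                raise TreeValidationError(f"negative branch length {bl}")
            parent[i] = index[id(nd.parent_node)]
            depth[i] = depth[parent[i]] + max(bl, 0.0)
        labels.append(
            nd.taxon.label if nd.taxon is not None else (nd.label or "")
        )
    # metadata ages win over depths if every node carries one
    ages = None
    meta_ages = []
    for nd in nodes:
        ann = nd.annotations.get_value("age")
        meta_ages.append(float(ann) if ann is not None else None)
    if all(a is not None for a in meta_ages):
        ages = np.array(meta_ages)
    else:
        tip_depth = max(
            depth[i] for i, nd in enumerate(nodes) if nd.is_leaf()
        )
        ages = tip_depth - depth
        ages[np.abs(ages) < _SA_TOL] = 0.0
    sa = np.zeros(len(nodes), dtype=bool)
    for i, nd in enumerate(nodes):
        ann = nd.annotations.get_value("sa")
        if ann is not None and str(ann) in ("1", "true", "True"):
            sa[i] = True
        elif (
            nd.is_leaf()
            and parent[i] >= 0
            and abs(ages[parent[i]] - ages[i]) <= _SA_TOL
            and ages[i] > _SA_TOL
        ):
            sa[i] = True  # zero-length fossil attachment
    return TimeTree(parent, ages, labels, sampled_ancestor=sa)


def read_tree(path, dialect: str = "newick") -> TimeTree:
    if dialect not in ("newick", "nexus"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(path, "read"):
        data = path.read()
    else:
        with open(path) as fh:
            data = fh.read()
    dtree = dendropy.Tree.get(
        data=data,
        schema=dialect,
        suppress_internal_node_taxa=True,
        extract_comment_metadata=True,
    )
    return _dendropy_to_timetree(dtree)


def _newick_string(tree: TimeTree, metadata: bool = True) -> str:
    def render(v: int) -> str:
        meta = ""
        if metadata:
            fields = [f"age={tree.ages[v]:.10g}"]
            if tree.sampled_ancestor[v]:
                fields.append("sa=1")
            meta = "[&" + ",".join(fields) + "]"
        if tree.is_tip(v):
            core = tree.labels[v]
        else:
            core = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        p = tree.parent[v]
        if p < 0:
            return core + meta
        bl = tree.ages[p] - tree.ages[v]
        return f"{core}{meta}:{max(bl, 0.0):.10g}"

    return render(tree.root) + ";"


def write_tree(tree: TimeTree, path, dialect: str = "newick", metadata: bool = True) -> None:
    s = _newick_string(tree, metadata=metadata)
    if dialect == "nexus":
        taxa = " ".join(tree.tip_labels)
        s = (
            "#NEXUS\nBEGIN TREES;\n"
            f"tree t1 = [&R] {s}\nEND;\n"
        )
    elif dialect != "newick":
        raise ValueError(f"unknown dialect {dialect!r}")
    else:
        s += "\n"
    if hasattr(path, "write"):
        path.write(s)
    else:
        with open(path, "w") as fh:
            fh.write(s)


# ----------------------------------------------------------------------
# geographic ranges & connectivity
# ----------------------------------------------------------------------
@dataclass
class RangeTable:
    """Binary presence/absence of each taxon over a named area set."""

    areas: list[str]
    presence: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, vec in self.presence.items():
            vec = np.asarray(vec, dtype=int)
            if vec.shape != (len(self.areas),):
                raise ValueError(
                    f"range vector for {taxon!r} has length {vec.shape}, "
                    f"expected {len(self.areas)}"
                )
            if not set(np.unique(vec)) <= {0, 1}:
                raise ValueError(f"range vector for {taxon!r} is not 0/1")
            if vec.sum() == 0:
                raise ValueError(f"taxon {taxon!r} has an all-zero range")
            self.presence[taxon] = vec

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def area_set(self, taxon: str) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.presence[taxon]).tolist())


@dataclass
class ConnectivityModel:
    """Epoch-wise 0/1 area-connection matrices, youngest epoch last.

    ``epochs`` is a list of ``(start_ma, end_ma, matrix)`` with
    ``start_ma > end_ma`` (start is older).  A 0 at (i, j) forbids
    dispersal from area i into area j during that epoch.
    """

    areas: list[str]
    epochs: list[tuple[float, float, np.ndarray]]

    def __post_init__(self) -> None:
        n = len(self.areas)
        cleaned = []
        for start, end, m in self.epochs:
            m = np.asarray(m, dtype=int)
            if m.shape != (n, n):
                raise ValueError(f"connectivity matrix shape {m.shape}, expected {(n, n)}")
            if not set(np.unique(m)) <= {0, 1}:
                raise ValueError("connectivity entries must be 0/1")
            if start <= end:
                raise ValueError("epoch start must be older than its end")
            if not np.array_equal(m, m.T):
                warnings.warn(
                    f"connectivity for epoch {start}-{end} Ma is not symmetric; "
                    "kept as directed",
                    stacklevel=2,
                )
            cleaned.append((float(start), float(end), m))
        self.epochs = sorted(cleaned, key=lambda e: -e[0])

    def at_age(self, age: float) -> np.ndarray:
        if age > self.epochs[0][0]:
            return self.epochs[0][2]  # older than all epochs: extend oldest
        for start, end, m in self.epochs:
            if end <= age <= start:
                return m
        return self.epochs[-1][2]  # younger than all epochs: use most recent

    @classmethod
    def uniform(cls, areas, start: float = 1e6) -> "ConnectivityModel":
        n = len(areas)
        return cls(list(areas), [(start, 0.0, np.ones((n, n), dtype=int))])


def read_range_table(path) -> RangeTable:
    df = pd.read_csv(path, keep_default_na=False)
    taxon_col = df.columns[0]
    areas = [str(c) for c in df.columns[1:]]
    presence = {
        str(row[taxon_col]): np.asarray([row[a] for a in areas], dtype=int)
        for _, row in df.iterrows()
    }
    return RangeTable(areas, presence)


def write_range_table(table: RangeTable, path) -> None:
    df = pd.DataFrame(
        [[t, *v.tolist()] for t, v in table.presence.items()],
        columns=["taxon", *table.areas],
    )
    df.to_csv(path, index=False)


def read_connectivity(path) -> ConnectivityModel:
    """Read epoch-wise connectivity from a single CSV.

    Columns: ``start_ma,end_ma,area,<one column per area>``; rows within an
    epoch give the matrix row for ``area``.
    """
    df = pd.read_csv(path, keep_default_na=False)
    areas = [str(c) for c in df.columns[3:]]
    epochs = []
    for (start, end), block in df.groupby(["start_ma", "end_ma"], sort=False):
        block = block.set_index("area").loc[areas]
        epochs.append((float(start), float(end), block[areas].to_numpy()))
    return ConnectivityModel(areas, epochs)


def write_connectivity(model: ConnectivityModel, path) -> None:
    rows = []
    for start, end, m in model.epochs:
        for i, area in enumerate(model.areas):
            rows.append([start, end, area, *m[i].tolist()])
    pd.DataFrame(rows, columns=["start_ma", "end_ma", "area", *model.areas]).to_csv(
        path, index=False
    )


def read_calibrations(path) -> dict[str, tuple[float, float]]:
    """CSV with columns taxon, min_age, max_age → calibration dict."""
    df = pd.read_csv(path, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        lo, hi = float(row["min_age"]), float(row["max_age"])
        if lo >= hi:
            raise ValueError(f"calibration for {row['taxon']!r}: min >= max")
        out[str(row["taxon"])] = (lo, hi)
    return out


def write_calibrations(cal: dict[str, tuple[float, float]], path) -> None:
    pd.DataFrame(
        [[t, lo, hi] for t, (lo, hi) in cal.items()],
        columns=["taxon", "min_age", "max_age"],
    ).to_csv(path, index=False)
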
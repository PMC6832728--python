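"""File formats: CSV datasets, TSV adjacency matrices, BIF/JSON networks.

Adjacency files state the row = child, column = parent convention in a
comment line so the orientation of an edge is never ambiguous on disk.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np

from .bayesnet import BayesianNetwork
from .dataset import CategoricalDataset
from .graphs import DirectedGraph

_ADJ_COMMENT = "# adjacency matrix: rows = children, columns = parents; [i,j]=1 means j -> i"


class ParseError(ValueError):
    """A file could not be interpreted in the expected format."""


# ---------------------------------------------------------------------------
# datasets


def read_dataset_csv(
    path: str | Path,
    delimiter: str = ",",
    levels: tuple[tuple[str, ...], ...] | None = None,
) -> CategoricalDataset:
    """Read a categorical dataset from headed CSV.

    Category labels are mapped to integer codes in first-appearance order per
    column; the label tables are kept on the dataset so a write round-trips.
    Passing ``levels`` pins the label -> code mapping instead (exact
    round-trips of a dataset whose codes do not follow appearance order).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if not header or any(not name.strip() for name in header):
            raise ParseError(f"{path}: malformed header row")
        p = len(header)
        if levels is not None:
            level_maps = [
                {label: code for code, label in enumerate(col)} for col in levels
            ]
        else:
            level_maps = [{} for _ in range(p)]
        rows: list[list[int]] = []
        for line_no, row in enumerate(reader, start=2):
            if len(row) != p:
                raise ParseError(
                    f"{path}: line {line_no} has {len(row)} fields, expected {p}"
                )
            coded = []
            for col, value in enumerate(row):
                value = value.strip()
                if value == "":
                    raise ParseError(f"{path}: missing value at line {line_no}")
                if levels is not None and value not in level_maps[col]:
                    raise ParseError(
                        f"{path}: unknown level {value!r} at line {line_no}"
                    )
                coded.append(level_maps[col].setdefault(value, len(level_maps[col])))
            rows.append(coded)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    for col, mapping in enumerate(level_maps):
        if len(mapping) < 2:
            # a constant column still needs arity >= 2 to be a categorical variable
            mapping.setdefault(f"__absent_{len(mapping)}", len(mapping))
    levels = tuple(tuple(m.keys()) for m in level_maps)
    arities = tuple(len(m) for m in level_maps)
    return CategoricalDataset(tuple(header), arities, np.asarray(rows), levels)


def write_dataset_csv(d: CategoricalDataset, path: str | Path, delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(d.variable_names)
        if d.levels is not None:
            labels = d.levels
        else:
            labels = tuple(
                tuple(str(v) for v in range(r)) for r in d.arities
            )
        for row in d.records:
            writer.writerow([labels[col][int(v)] for col, v in enumerate(row)])


# ---------------------------------------------------------------------------
# adjacency matrices


def write_graph_tsv(g: DirectedGraph, names: list[str] | tuple[str, ...], path: str | Path) -> None:
    if len(names) != g.p:
        raise ValueError("names length must equal the node count")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_ADJ_COMMENT + "\n")
        fh.write("\t".join(names) + "\n")
        for row in g.adjacency:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_graph_tsv(path: str | Path) -> tuple[DirectedGraph, tuple[str, ...]]:
    path = Path(path)
    lines = [
        line.rstrip("\n")
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path}: empty adjacency file")
    names = tuple(lines[0].split("\t"))
    p = len(names)
    if len(lines) - 1 != p:
        raise ParseError(f"{path}: expected {p} matrix rows, found {len(lines) - 1}")
    matrix = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != p:
            raise ParseError(f"{path}: ragged matrix row: {line!r}")
        try:
            row = [int(c) for c in cells]
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer adjacency cell: {exc}") from None
        if any(v not in (0, 1) for v in row):
            raise ParseError(f"{path}: adjacency cells must be 0 or 1")
        matrix.append(row)
    return DirectedGraph(np.asarray(matrix)), names


# ---------------------------------------------------------------------------
# networks (JSON mirror and a minimal BIF subset)


def write_network_json(bn: BayesianNetwork, path: str | Path) -> None:
    payload = {
        "variables": list(bn.variable_names),
        "arities": list(bn.arities),
        "adjacency": bn.graph.adjacency.astype(int).tolist(),
        "cpts": [t.tolist() for t in bn.cpts],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_network_json(path: str | Path) -> BayesianNetwork:
    payload = json.loads(Path(path).read_text())
    return BayesianNetwork(
        DirectedGraph(np.asarray(payload["adjacency"])),
        tuple(payload["arities"]),
        tuple(np.asarray(t, dtype=float) for t in payload["cpts"]),
        tuple(payload["variables"]),
    )


def write_network_bif(bn: BayesianNetwork, path: str | Path, name: str = "network") -> None:
    """Write a discrete network in the Bayesian Interchange Format (BIF).

    CPT rows are emitted with explicit parent-value tuples (parents in
    ascending node order, matching the in-memory row order).
    """
    lines = [f"network {name} {{", "}"]
    for i, var in enumerate(bn.variable_names):
        states = ", ".join(f"s{k}" for k in range(bn.arities[i]))
        lines += [
            f"variable {var} {{",
            f"  type discrete [ {bn.arities[i]} ] {{ {states} }};",
            "}",
        ]
    for i, var in enumerate(bn.variable_names):
        parents = bn.graph.parents(i)
        table = bn.cpts[i]
        if not parents:
            probs = ", ".join(f"{v:.10g}" for v in table[0])
            lines += [f"probability ( {var} ) {{", f"  table {probs};", "}"]
            continue
        parent_names = ", ".join(bn.variable_names[j] for j in parents)
        lines.append(f"probability ( {var} | {parent_names} ) {{")
        arities = [bn.arities[j] for j in parents]
        for row in range(table.shape[0]):
            values = []
            rem = row
            for a in reversed(arities):
                values.append(rem % a)
                rem //= a
            values.reverse()
            combo = ", ".join(f"s{v}" for v in values)
            probs = ", ".join(f"{v:.10g}" for v in table[row])
            lines.append(f"  ( {combo} ) {probs};")
        lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


_BIF_VARIABLE = re.compile(
    r"variable\s+(\S+)\s*\{[^}]*type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}",
    re.S,
)
_BIF_PROBABILITY = re.compile(r"probability\s*\(\s*([^)]*)\)\s*\{([^}]*)\}", re.S)


def read_network_bif(path: str | Path) -> BayesianNetwork:
    """Read the discrete-network BIF subset written by :func:`write_network_bif`.

    Also accepts the common published-benchmark layout: ``table`` lines for
    root nodes and parenthesised parent-value rows for the rest.
    """
    text = Path(path).read_text()
    names: list[str] = []
    arities: list[int] = []
    states: dict[str, list[str]] = {}
    for match in _BIF_VARIABLE.finditer(text):
        var, arity, state_text = match.group(1), int(match.group(2)), match.group(3)
        names.append(var)
        arities.append(arity)
        states[var] = [s.strip() for s in state_text.split(",") if s.strip()]
    if not names:
        raise ParseError(f"{path}: no variable declarations found")
    index = {v: i for i, v in enumerate(names)}
    p = len(names)
    adjacency = np.zeros((p, p), dtype=np.int8)
    tables: dict[int, np.ndarray] = {}
    for match in _BIF_PROBABILITY.finditer(text):
        head, body = match.group(1), match.group(2)
        if "|" in head:
            child_text, parent_text = head.split("|")
            child = index[child_text.strip()]
            parents = [index[v.strip()] for v in parent_text.split(",")]
        else:
            child = index[head.strip()]
            parents = []
        for parent in parents:
            adjacency[child, parent] = 1
        sorted_parents = sorted(parents)
        q = int(np.prod([arities[j] for j in sorted_parents], dtype=int)) if parents else 1
        table = np.zeros((q, arities[child]))
        if not parents:
            values = re.search(r"table([^;]*);", body)
            if values is None:
                raise ParseError(f"{path}: root node without a table line")
            table[0] = [float(v) for v in values.group(1).split(",")]
        else:
            for row_match in re.finditer(r"\(([^)]*)\)\s*([^;]*);", body):
                labels = [s.strip() for s in row_match.group(1).split(",")]
                value_by_parent = {
                    parent: states[names[parent]].index(label)
                    for parent, label in zip(parents, labels)
                }
                row = 0
                for parent in sorted_parents:
                    row = row * arities[parent] + value_by_parent[parent]
                table[row] = [float(v) for v in row_match.group(2).split(",")]
        tables[child] = table
    graph = DirectedGraph(adjacency)
    return BayesianNetwork(
        graph, tuple(arities), tuple(tables[i] for i in range(p)), tuple(names)
    )
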
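"""SWC neuron reconstruction I/O.

The SWC format stores a neuron reconstruction as a rooted tree of 3D sample
points, one per line: ``id type x y z radius parent``.  Coordinates and radii
are in micrometers; ``type`` follows the SWC convention (1 = soma, 2 = axon,
3 = basal dendrite, 4 = apical dendrite, ...); ``parent`` is -1 for the root.

This module reads such files into :class:`NeuronTree`, validates the tree
invariants (single root, acyclic, connected, unique ids) and writes trees
back out with contiguous 1-based ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "SWCError",
    "SWCFormatError",
    "SWCStructureError",
    "read_swc",
    "write_swc",
]

SOMA = 1


class SWCError(ValueError):
    """Base class for SWC reading/validation problems."""


class SWCFormatError(SWCError):
    """Malformed row: wrong column count, non-numeric field, duplicate id."""


class SWCStructureError(SWCError):
    """Structurally invalid tree: missing parent, multiple roots, cycle."""


@dataclass(frozen=True)
class NeuronNode:
    """One SWC sample point."""

    id: int
    type_code: int
    position: tuple[float, float, float]
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise SWCFormatError(f"node id must be positive, got {self.id}")
        if not 0 <= self.type_code <= 7:
            raise SWCFormatError(
                f"type code {self.type_code} outside SWC range [0, 7]"
            )
        if self.radius < 0:
            raise SWCFormatError(f"negative radius {self.radius} on node {self.id}")
        if not all(math.isfinite(c) for c in self.position):
            raise SWCFormatError(f"non-finite coordinate on node {self.id}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class NeuronTree:
    """A rooted neuron reconstruction.

    Nodes are kept in file order.  ``children`` / ``parent`` lookups are
    built lazily and cached; mutating ``nodes`` directly is not supported —
    build a new tree instead.
    """

    nodes: list[NeuronNode]
    name: str = ""
    class_label: str | None = None
    _children: dict[int, list[int]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[NeuronNode]:
        return iter(self.nodes)

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        id_set = set(ids)
        if len(id_set) != len(ids):
            raise SWCFormatError("duplicate node ids")
        roots = [n for n in self.nodes if n.parent_id == -1]
        if not self.nodes:
            raise SWCStructureError("empty tree")
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in id_set:
                raise SWCStructureError(
                    f"node {n.id} references absent parent {n.parent_id}"
                )
        # Connectivity + acyclicity: walk to root from every node with memoisation.
        parent = {n.id: n.parent_id for n in self.nodes}
        ok: set[int] = set()
        for start in ids:
            trail = []
            cur = start
            while cur != -1 and cur not in ok:
                if cur in trail:
                    raise SWCStructureError(f"cycle through node {cur}")
                trail.append(cur)
                cur = parent[cur]
            ok.update(trail)
        self._children = None

    # -- lookups ----------------------------------------------------------

    @property
    def root(self) -> NeuronNode:
        return next(n for n in self.nodes if n.parent_id == -1)

    def node(self, node_id: int) -> NeuronNode:
        return self._index()[node_id]

    def _index(self) -> dict[int, NeuronNode]:
        return {n.id: n for n in self.nodes}

    def children(self, node_id: int) -> list[int]:
        if self._children is None:
            ch: dict[int, list[int]] = {n.id: [] for n in self.nodes}
            for n in self.nodes:
                if n.parent_id != -1:
                    ch[n.parent_id].append(n.id)
            self._children = ch
        return self._children[node_id]

    def tips(self) -> list[NeuronNode]:
        return [n for n in self.nodes if not self.children(n.id)]

    def bifurcations(self) -> list[NeuronNode]:
        """Nodes with >= 2 children, the soma excluded (soma children are stems)."""
        return [
            n
            for n in self.nodes
            if len(self.children(n.id)) >= 2 and n.parent_id != -1
        ]

    def stems(self) -> list[NeuronNode]:
        return [self.node(c) for c in self.children(self.root.id)]

    def coordinates(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float)

    def with_coordinates(self, xyz: np.ndarray) -> "NeuronTree":
        """Copy of the tree with node positions replaced (same order)."""
        if xyz.shape != (len(self.nodes), 3):
            raise ValueError("coordinate array shape mismatch")
        nodes = [
            NeuronNode(n.id, n.type_code, tuple(float(v) for v in p), n.radius, n.parent_id)
            for n, p in zip(self.nodes, xyz)
        ]
        return NeuronTree(nodes, name=self.name, class_label=self.class_label)


def _parse_row(fields: list[str], line_no: int) -> NeuronNode:
    if len(fields) != 7:
        raise SWCFormatError(f"line {line_no}: expected 7 columns, got {len(fields)}")
    try:
        nid = int(fields[0])
        type_code = int(fields[1])
        x, y, z, radius = (float(v) for v in fields[2:6])
        parent = int(fields[6])
    except ValueError as exc:
        raise SWCFormatError(f"line {line_no}: non-numeric field ({exc})") from exc
    return NeuronNode(nid, type_code, (x, y, z), radius, parent)


def read_swc(source: IO[str] | str | Iterable[str], name: str = "") -> NeuronTree:
    """Parse an SWC stream (or path, or iterable of lines) into a NeuronTree.

    ``#`` comment lines and blank lines are ignored.  Ids may be arbitrary
    positive integers in any order.  Extra root rows of type 1 (soma contour
    points, a common dialect) are re-attached to the first soma root; any
    other extra root is an error.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_swc(fh, name=name or source)

    rows: list[NeuronNode] = []
    seen: set[int] = set()
    for line_no, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        node = _parse_row(line.split(), line_no)
        if node.id in seen:
            raise SWCFormatError(f"line {line_no}: duplicate id {node.id}")
        seen.add(node.id)
        rows.append(node)
    if not rows:
        raise SWCStructureError("no data rows in SWC source")

    roots = [n for n in rows if n.parent_id == -1]
    if len(roots) > 1:
        soma_roots = [n for n in roots if n.type_code == SOMA]
        if len(soma_roots) == len(roots):
            anchor = soma_roots[0]
            reattach = {n.id for n in soma_roots[1:]}
            rows = [
                NeuronNode(n.id, n.type_code, n.position, n.radius, anchor.id)
                if n.id in reattach
                else n
                for n in rows
            ]
        else:
            raise SWCStructureError(f"multiple roots ({len(roots)}) of mixed type")
    return NeuronTree(rows, name=name)


def write_swc(tree: NeuronTree, sink: IO[str]) -> int:
    """Write a tree with contiguous 1-based ids in topological (parent-first) order.

    Returns the number of rows written.  Coordinates/radii are rendered with
    enough digits (repr) to round-trip exactly.
    """
    if not tree.nodes:
        raise SWCStructureError("cannot write an empty tree")
    order: list[NeuronNode] = []
    stack = [tree.root.id]
    index = tree._index()
    while stack:
        nid = stack.pop()
        order.append(index[nid])
        stack.extend(reversed(tree.children(nid)))
    remap = {n.id: i + 1 for i, n in enumerate(order)}
    sink.write("# generated by neurofuse\n")
    for n in order:
        parent = -1 if n.parent_id == -1 else remap[n.parent_id]
        x, y, z = n.position
        sink.write(
            f"{remap[n.id]} {n.type_code} {x!r} {y!r} {z!r} {n.radius!r} {parent}\n"
        )
    return len(order)
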
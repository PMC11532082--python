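"""Hand-crafted morphometrics of neuron reconstructions.

Computes a fixed, ordered registry of 43 scalar morphology descriptors per
neuron — the statistics a morphology toolbox would report: counts (stems,
bifurcations, branches, tips), extents, size measures (diameter, surface,
volume), distance measures, branch-level descriptors (order, length,
contraction, taper), bifurcation descriptors (partition asymmetry, Rall
power and the Pk family, amplitude/tilt/torque angles), and two shape
descriptors (discrete helicity, box-counting fractal dimension).

Every metric reduces to one scalar per tree: counts and extents are totals,
per-node / per-branch / per-bifurcation quantities are means.  A metric that
is undefined on a tree (e.g. angle metrics on an unbranched tree) is emitted
as 0.0 with its entry cleared in a companion validity mask, so downstream
consumers always see a finite 43-vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._geom import pca_canonicalize
from .swc import NeuronNode, NeuronTree

__all__ = [
    "Branch",
    "MorphometricVector",
    "METRIC_NAMES",
    "METRIC_SCALE_POWERS",
    "EXTENT_METRICS",
    "decompose_branches",
    "metric_total_length",
    "metric_contraction",
    "metric_partition_asymmetry",
    "metric_bifurcation_angle",
    "metric_diameter_ratios",
    "compute_feature_vector",
]


# --------------------------------------------------------------------------
# Branch decomposition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """A maximal unbranched path between consecutive topological events.

    ``nodes`` runs from the branching point that spawns the branch (the soma
    for stems, otherwise a bifurcation node) to the next bifurcation or tip,
    so branch paths partition the tree's edges.  ``order`` is centrifugal:
    stems are order 1 and each bifurcation increments the order.
    """

    nodes: tuple[NeuronNode, ...]
    order: int

    @property
    def path_length(self) -> float:
        pos = np.array([n.position for n in self.nodes])
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())

    @property
    def euclidean_length(self) -> float:
        a = np.array(self.nodes[0].position)
        b = np.array(self.nodes[-1].position)
        return float(np.linalg.norm(b - a))

def decompose_branches(tree: NeuronTree) -> list[Branch]:
    """Split a tree into branches with centrifugal orders.

    Every edge belongs to exactly one branch; for a binary tree the branch
    count is ``n_stems + 2 * n_bifurcations``.
    """
    branches: list[Branch] = []
    index = tree._index()
    root = tree.root
    # (start node id, first child id, order)
    stack = [(root.id, c, 1) for c in reversed(tree.children(root.id))]
    while stack:
        start, first, order = stack.pop()
        path = [index[start], index[first]]
        cur = first
        while True:
            ch = tree.children(cur)
            if len(ch) == 1:
                cur = ch[0]
                path.append(index[cur])
            else:
                break
        branches.append(Branch(tuple(path), order))
        for c in reversed(tree.children(cur)):
            stack.append((cur, c, order + 1))
    return branches


def _branch_is_terminal(tree: NeuronTree, branch: Branch) -> bool:
    return not tree.children(branch.nodes[-1].id)


# --------------------------------------------------------------------------
# Stand-alone metric operations
# --------------------------------------------------------------------------

def metric_total_length(tree: NeuronTree) -> float:
    """Sum of Euclidean lengths of all parent-child segments (micrometers)."""
    index = tree._index()
    total = 0.0
    for n in tree.nodes:
        if n.parent_id != -1:
            p = index[n.parent_id]
            total += math.dist(n.position, p.position)
    return total


def metric_contraction(branch: Branch) -> float:
    """Euclidean end-to-end distance over path length, in (0, 1]."""
    L = branch.path_length
    if L == 0:
        raise ValueError("contraction undefined for a zero-path-length branch")
    return branch.euclidean_length / L


def _subtree_tip_counts(tree: NeuronTree) -> dict[int, int]:
    counts: dict[int, int] = {}
    order: list[int] = []
    stack = [tree.root.id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(tree.children(nid))
    for nid in reversed(order):
        ch = tree.children(nid)
        counts[nid] = 1 if not ch else sum(counts[c] for c in ch)
    return counts


def metric_partition_asymmetry(tree: NeuronTree, bif_id: int) -> float:
    """|n1 - n2| / (n1 + n2 - 2) over the tip counts of the two subtrees.

    0 for a balanced bifurcation and for the degenerate 1+1 case; 1 for a
    maximally lopsided one such as (3, 1).
    """
    ch = tree.children(bif_id)
    if len(ch) < 2:
        raise ValueError(f"node {bif_id} is not a bifurcation")
    counts = _subtree_tip_counts(tree)
    n1, n2 = counts[ch[0]], counts[ch[1]]
    if n1 + n2 <= 2:
        return 0.0
    return abs(n1 - n2) / (n1 + n2 - 2)


def _daughter_vectors(
    tree: NeuronTree, bif_id: int, mode: str
) -> list[np.ndarray]:
    """Direction vectors from a bifurcation to its daughters.

    ``local`` uses the immediate child nodes; ``remote`` uses the endpoints of
    the daughter branches (the next bifurcation or tip down each daughter).
    """
    index = tree._index()
    b = np.array(index[bif_id].position)
    vecs = []
    for c in tree.children(bif_id)[:2]:
        if mode == "local":
            end = index[c]
        elif mode == "remote":
            cur = c
            while len(tree.children(cur)) == 1:
                cur = tree.children(cur)[0]
            end = index[cur]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        vecs.append(np.array(end.position) - b)
    return vecs


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length direction vector")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def metric_bifurcation_angle(
    tree: NeuronTree, bif_id: int, mode: str = "local"
) -> float:
    """Amplitude angle (degrees, [0, 180]) between the two daughter directions."""
    d1, d2 = _daughter_vectors(tree, bif_id, mode)
    return _angle_deg(d1, d2)


def metric_diameter_ratios(tree: NeuronTree, bif_id: int) -> tuple[float, float]:
    """(larger/smaller daughter diameter, mean daughter diameter / parent diameter)."""
    index = tree._index()
    ch = tree.children(bif_id)[:2]
    d1, d2 = (index[c].diameter for c in ch)
    dp = index[bif_id].diameter
    lo, hi = min(d1, d2), max(d1, d2)
    if lo == 0:
        raise ValueError("zero daughter diameter")
    if dp == 0:
        raise ValueError("zero parent diameter")
    return hi / lo, 0.5 * (d1 + d2) / dp


# --------------------------------------------------------------------------
# The 43-metric registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphometricVector:
    """Ordered 43-vector of morphology descriptors plus a validity mask."""

    values: np.ndarray
    names: tuple[str, ...]
    mask: np.ndarray  # True where the metric was defined on this tree

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names) or len(self.values) != len(self.mask):
            raise ValueError("values/names/mask length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite morphometric value")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


class _TreeContext:
    """Precomputed per-tree quantities shared by the registry metrics."""

    def __init__(self, tree: NeuronTree):
        self.tree = tree
        self.index = tree._index()
        self.root = tree.root
        self.branches = decompose_branches(tree)
        self.bifs = tree.bifurcations()
        self.tips = tree.tips()
        self.non_root = [n for n in tree.nodes if n.parent_id != -1]
        self.tip_counts = _subtree_tip_counts(tree)
        # path distance from root per node id
        dist: dict[int, float] = {self.root.id: 0.0}
        stack = list(tree.children(self.root.id))
        while stack:
            nid = stack.pop()
            n = self.index[nid]
            dist[nid] = dist[n.parent_id] + math.dist(
                n.position, self.index[n.parent_id].position
            )
            stack.extend(tree.children(nid))
        self.path_dist = dist

    def edges(self):
        for n in self.non_root:
            yield self.index[n.parent_id], n

    def mean(self, vals: Sequence[float]) -> tuple[float, bool]:
        vals = [v for v in vals if v is not None]
        if not vals:
            return 0.0, False
        return float(np.mean(vals)), True

    # nearest ancestor bifurcation id, or None
    def parent_bif(self, node_id: int) -> int | None:
        cur = self.index[node_id].parent_id
        while cur != -1:
            if len(self.tree.children(cur)) >= 2 and self.index[cur].parent_id != -1:
                return cur
            cur = self.index[cur].parent_id
        return None


Metric = Callable[[_TreeContext], tuple[float, bool]]


def _count(fn):
    return lambda ctx: (float(fn(ctx)), True)


def _soma_surface(ctx):
    return 4.0 * math.pi * ctx.root.radius**2, ctx.root.radius > 0


def _extent(axis):
    def f(ctx):
        xyz = ctx.tree.coordinates()
        return float(xyz[:, axis].max() - xyz[:, axis].min()), True

    return f


def _mean_type(ctx):
    return ctx.mean([n.type_code for n in ctx.non_root])


def _mean_diameter(ctx):
    return ctx.mean([n.diameter for n in ctx.non_root])


def _mean_diameter_pow(ctx):
    return ctx.mean([n.diameter**1.5 for n in ctx.non_root])


def _total_length(ctx):
    return metric_total_length(ctx.tree), True


def _total_surface(ctx):
    # lateral surface of a cylinder per segment, mean-radius approximation
    s = sum(
        math.pi * (p.radius + c.radius) * math.dist(p.position, c.position)
        for p, c in ctx.edges()
    )
    return float(s), bool(ctx.non_root)


def _mean_section_area(ctx):
    return ctx.mean([math.pi * n.radius**2 for n in ctx.non_root])


def _total_volume(ctx):
    # conical frustum volume per segment
    v = sum(
        math.pi
        * (p.radius**2 + p.radius * c.radius + c.radius**2)
        / 3.0
        * math.dist(p.position, c.position)
        for p, c in ctx.edges()
    )
    return float(v), bool(ctx.non_root)


def _mean_euc_distance(ctx):
    r = np.array(ctx.root.position)
    return ctx.mean([math.dist(n.position, r) for n in ctx.non_root])


def _mean_path_distance(ctx):
    return ctx.mean([ctx.path_dist[n.id] for n in ctx.non_root])


def _mean_branch_order(ctx):
    return ctx.mean([b.order for b in ctx.branches])


def _mean_terminal_degree(ctx):
    return ctx.mean([ctx.tip_counts[n.id] for n in ctx.non_root])


def _mean_terminal_segment_length(ctx):
    return ctx.mean(
        [b.path_length for b in ctx.branches if _branch_is_terminal(ctx.tree, b)]
    )


def _branch_taper(branch: Branch, relative: bool) -> float | None:
    # taper across the branch proper: first node past the branching point → end
    d0 = branch.nodes[1].diameter
    d1 = branch.nodes[-1].diameter
    if relative:
        return None if d0 == 0 else (d0 - d1) / d0
    L = branch.path_length
    return None if L == 0 else (d0 - d1) / L


def _mean_taper_1(ctx):
    return ctx.mean([_branch_taper(b, relative=False) for b in ctx.branches])


def _mean_taper_2(ctx):
    return ctx.mean([_branch_taper(b, relative=True) for b in ctx.branches])


def _mean_branch_pathlength(ctx):
    return ctx.mean([b.path_length for b in ctx.branches])


def _mean_contraction(ctx):
    vals = [
        metric_contraction(b) for b in ctx.branches if b.path_length > 0
    ]
    return ctx.mean(vals)


def _fragmentation(ctx):
    return float(len(ctx.non_root)), True


def _mean_daughter_ratio(ctx):
    vals = []
    for b in ctx.bifs:
        try:
            vals.append(metric_diameter_ratios(ctx.tree, b.id)[0])
        except ValueError:
            pass
    return ctx.mean(vals)


def _mean_parent_daughter_ratio(ctx):
    vals = []
    for b in ctx.bifs:
        try:
            vals.append(metric_diameter_ratios(ctx.tree, b.id)[1])
        except ValueError:
            pass
    return ctx.mean(vals)


def _mean_partition_asymmetry(ctx):
    return ctx.mean(
        [metric_partition_asymmetry(ctx.tree, b.id) for b in ctx.bifs]
    )


def _rall_exponent(dp: float, d1: float, d2: float) -> float | None:
    """Solve d1^n + d2^n = dp^n for n in [0, 5] by bisection (tol 1e-6)."""
    if dp <= 0 or d1 <= 0 or d2 <= 0 or max(d1, d2) >= dp:
        return None

    def f(n):
        return d1**n + d2**n - dp**n

    lo, hi = 0.0, 5.0
    if f(lo) * f(hi) > 0:
        return None
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _bif_diams(ctx, b) -> tuple[float, float, float]:
    ch = ctx.tree.children(b.id)[:2]
    return b.diameter, ctx.index[ch[0]].diameter, ctx.index[ch[1]].diameter


def _mean_rall_power(ctx):
    vals = [
        n
        for b in ctx.bifs
        if (n := _rall_exponent(*_bif_diams(ctx, b))) is not None
    ]
    return ctx.mean(vals)


def _pk(ctx, exponent_per_tree: bool, n_fixed: float | None):
    if exponent_per_tree:
        n_mean, ok = _mean_rall_power(ctx)
        if not ok:
            return 0.0, False
        n_use = n_mean
    else:
        n_use = n_fixed
    vals = []
    for b in ctx.bifs:
        dp, d1, d2 = _bif_diams(ctx, b)
        if dp > 0 and d1 > 0 and d2 > 0:
            vals.append((d1**n_use + d2**n_use) / dp**n_use)
    return ctx.mean(vals)


def _mean_pk(ctx):
    return _pk(ctx, exponent_per_tree=True, n_fixed=None)


def _mean_pk_classic(ctx):
    return _pk(ctx, exponent_per_tree=False, n_fixed=1.5)


def _mean_pk_2(ctx):
    return _pk(ctx, exponent_per_tree=False, n_fixed=2.0)


def _mean_bif_angle(mode):
    def f(ctx):
        vals = []
        for b in ctx.bifs:
            try:
                vals.append(metric_bifurcation_angle(ctx.tree, b.id, mode))
            except ValueError:
                pass
        return ctx.mean(vals)

    return f


def _parent_direction(ctx, b, mode: str) -> np.ndarray:
    """Incoming direction at a bifurcation: from the parent node (local) or
    from the start of the branch ending at the bifurcation (remote)."""
    pos = np.array(b.position)
    if mode == "local":
        return pos - np.array(ctx.index[b.parent_id].position)
    cur = b.id
    while True:
        pid = ctx.index[cur].parent_id
        if pid == -1:
            start = ctx.index[cur]  # branch starts at a single-child soma
            break
        if len(ctx.tree.children(pid)) >= 2:
            start = ctx.index[pid]
            break
        cur = pid
    return pos - np.array(start.position)


def _mean_bif_tilt(mode):
    def f(ctx):
        vals = []
        for b in ctx.bifs:
            try:
                d1, d2 = _daughter_vectors(ctx.tree, b.id, mode)
                p = _parent_direction(ctx, b, mode)
                vals.append(0.5 * (_angle_deg(p, d1) + _angle_deg(p, d2)))
            except ValueError:
                pass
        return ctx.mean(vals)

    return f


def _mean_bif_torque(mode):
    """Angle ([0, 90] degrees) between a bifurcation's plane and its nearest
    ancestor bifurcation's plane, via the normals of the daughter-vector pairs."""

    def f(ctx):
        vals = []
        for b in ctx.bifs:
            pb = ctx.parent_bif(b.id)
            if pb is None:
                continue
            try:
                n1 = np.cross(*_daughter_vectors(ctx.tree, b.id, mode))
                n2 = np.cross(*_daughter_vectors(ctx.tree, pb, mode))
            except ValueError:
                continue
            a, c = np.linalg.norm(n1), np.linalg.norm(n2)
            if a == 0 or c == 0:
                continue
            cosang = float(np.clip(abs(np.dot(n1, n2)) / (a * c), 0.0, 1.0))
            vals.append(math.degrees(math.acos(cosang)))
        return ctx.mean(vals)

    return f


def _mean_last_parent_diam(ctx):
    if not ctx.bifs:
        return 0.0, False
    vals = []
    for t in ctx.tips:
        pb = ctx.parent_bif(t.id)
        if pb is None and len(ctx.tree.children(t.id)) == 0:
            # tip on an unbranched stem: no ancestor bifurcation
            continue
        if pb is not None:
            vals.append(ctx.index[pb].diameter)
    return ctx.mean(vals)


def _mean_diam_threshold(ctx):
    # diameter at which a branch becomes terminal: first node past the last
    # branching point, per terminal branch
    vals = [
        b.nodes[1].diameter
        for b in ctx.branches
        if _branch_is_terminal(ctx.tree, b)
    ]
    return ctx.mean(vals)


def _mean_hillman_threshold(ctx):
    # 0.5*parent + 0.25*(d1+d2) over bifurcations whose daughters are both terminal
    vals = []
    for b in ctx.bifs:
        ends = []
        for c in ctx.tree.children(b.id)[:2]:
            cur = c
            while len(ctx.tree.children(cur)) == 1:
                cur = ctx.tree.children(cur)[0]
            ends.append(cur)
        if all(not ctx.tree.children(e) for e in ends):
            dp, d1, d2 = _bif_diams(ctx, b)
            vals.append(0.5 * dp + 0.25 * (d1 + d2))
    return ctx.mean(vals)


def _mean_helix(ctx):
    """Discrete helicity: normalized triple product of three consecutive
    segment vectors, averaged over all 4-node windows within branches."""
    vals = []
    for br in ctx.branches:
        pos = np.array([n.position for n in br.nodes])
        if len(pos) < 4:
            continue
        seg = np.diff(pos, axis=0)
        for i in range(len(seg) - 2):
            v1, v2, v3 = seg[i], seg[i + 1], seg[i + 2]
            norm = np.linalg.norm(v1) * np.linalg.norm(v2) * np.linalg.norm(v3)
            if norm == 0:
                continue
            vals.append(float(np.dot(np.cross(v1, v2), v3)) / norm)
    return ctx.mean(vals)


def _fractal_dim(ctx):
    """Box-counting dimension over >= 4 dyadic scales, in the PCA-canonical
    frame (so the estimate does not depend on the lab frame)."""
    xyz = pca_canonicalize(ctx.tree.coordinates())
    lo = xyz.min(axis=0)
    span = float((xyz.max(axis=0) - lo).max())
    if span == 0:
        return 0.0, False
    logs, counts = [], []
    for k in range(1, 6):  # scales span/2 .. span/32
        s = span / 2**k
        cells = np.floor((xyz - lo) / s).astype(int)
        counts.append(len({tuple(c) for c in cells}))
        logs.append(math.log(2**k))
    slope = np.polyfit(logs, np.log(counts), 1)[0]
    return float(slope), True


# name, function, scale power under uniform scaling of coordinates+radii
_REGISTRY: list[tuple[str, Metric, float]] = [
    ("Soma_Surface", _soma_surface, 2.0),
    ("N_stems", _count(lambda c: len(c.tree.stems())), 0.0),
    ("N_bifs", _count(lambda c: len(c.bifs)), 0.0),
    ("N_branch", _count(lambda c: len(c.branches)), 0.0),
    ("N_tips", _count(lambda c: len(c.tips)), 0.0),
    ("Width", _extent(0), 1.0),
    ("Height", _extent(1), 1.0),
    ("Depth", _extent(2), 1.0),
    ("Type", _mean_type, 0.0),
    ("Diameter", _mean_diameter, 1.0),
    ("Diameter_pow", _mean_diameter_pow, 1.5),
    ("Length", _total_length, 1.0),
    ("Surface", _total_surface, 2.0),
    ("SectionArea", _mean_section_area, 2.0),
    ("Volume", _total_volume, 3.0),
    ("EucDistance", _mean_euc_distance, 1.0),
    ("PathDistance", _mean_path_distance, 1.0),
    ("Branch_Order", _mean_branch_order, 0.0),
    ("Terminal_degree", _mean_terminal_degree, 0.0),
    ("TerminalSegment", _mean_terminal_segment_length, 1.0),
    ("Taper_1", _mean_taper_1, 0.0),
    ("Taper_2", _mean_taper_2, 0.0),
    ("Branch_pathlength", _mean_branch_pathlength, 1.0),
    ("Contraction", _mean_contraction, 0.0),
    ("Fragmentation", _fragmentation, 0.0),
    ("Daughter_Ratio", _mean_daughter_ratio, 0.0),
    ("Parent_Daughter_Ratio", _mean_parent_daughter_ratio, 0.0),
    ("Partition_asymmetry", _mean_partition_asymmetry, 0.0),
    ("Rall_Power", _mean_rall_power, 0.0),
    ("Pk", _mean_pk, 0.0),
    ("Pk_classic", _mean_pk_classic, 0.0),
    ("Pk_2", _mean_pk_2, 0.0),
    ("Bif_ampl_local", _mean_bif_angle("local"), 0.0),
    ("Bif_ampl_remote", _mean_bif_angle("remote"), 0.0),
    ("Bif_tilt_local", _mean_bif_tilt("local"), 0.0),
    ("Bif_tilt_remote", _mean_bif_tilt("remote"), 0.0),
    ("Bif_torque_local", _mean_bif_torque("local"), 0.0),
    ("Bif_torque_remote", _mean_bif_torque("remote"), 0.0),
    ("Last_parent_diam", _mean_last_parent_diam, 1.0),
    ("Diam_threshold", _mean_diam_threshold, 1.0),
    ("Hillman_threshold", _mean_hillman_threshold, 1.0),
    ("Helix", _mean_helix, 0.0),
    ("Fractal_Dim", _fractal_dim, 0.0),
]

METRIC_NAMES: tuple[str, ...] = tuple(name for name, _, _ in _REGISTRY)
METRIC_SCALE_POWERS: dict[str, float] = {n: p for n, _, p in _REGISTRY}
#: metrics sensitive to rotation (bounding-box extents along the lab axes)
EXTENT_METRICS: frozenset[str] = frozenset({"Width", "Height", "Depth"})

assert len(METRIC_NAMES) == 43


def compute_feature_vector(tree: NeuronTree) -> MorphometricVector:
    """The ordered 43-vector of morphometrics for one neuron.

    Deterministic; undefined metrics are 0.0 with ``mask`` False.
    """
    ctx = _TreeContext(tree)
    values = np.empty(len(_REGISTRY))
    mask = np.empty(len(_REGISTRY), dtype=bool)
    for i, (_, fn, _) in enumerate(_REGISTRY):
        v, ok = fn(ctx)
        values[i] = v if ok else 0.0
        mask[i] = ok
    return MorphometricVector(values, METRIC_NAMES, mask)
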
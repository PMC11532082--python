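"""Independent brute-force oracles for the 43 morphometrics.

Everything here recomputes metrics from the raw node table (id, type, x, y,
z, radius, parent) with plain dictionaries, recursion and loops — no reuse
of the package's tree helpers — so agreement with the package is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


class Node:
    def __init__(self, nid, t, xyz, r, parent):
        self.id, self.t, self.xyz, self.r, self.parent = nid, t, np.array(xyz, float), r, parent

    @property
    def d(self):
        return 2.0 * self.r


def from_tree(tree) -> dict[int, Node]:
    """Raw node table from a package NeuronTree (data only, no helpers)."""
    return {
        n.id: Node(n.id, n.type_code, n.position, n.radius, n.parent_id)
        for n in tree.nodes
    }


def children_map(nodes):
    ch = {i: [] for i in nodes}
    for n in nodes.values():
        if n.parent != -1:
            ch[n.parent].append(n.id)
    return ch


def root_of(nodes):
    return next(n.id for n in nodes.values() if n.parent == -1)


def tips_of(nodes, ch=None):
    ch = ch or children_map(nodes)
    return [i for i in nodes if not ch[i]]


def bifs_of(nodes, ch=None):
    ch = ch or children_map(nodes)
    r = root_of(nodes)
    return [i for i in nodes if len(ch[i]) >= 2 and i != r]


def branches_of(nodes):
    """Recursive branch decomposition: list of (node-id path, order).

    Paths start at the soma or a bifurcation node and end at the next
    bifurcation or tip.
    """
    ch = children_map(nodes)
    r = root_of(nodes)
    out = []

    def walk(start, child, order):
        path = [start, child]
        cur = child
        while len(ch[cur]) == 1:
            cur = ch[cur][0]
            path.append(cur)
        out.append((path, order))
        for c in ch[cur]:
            walk(cur, c, order + 1)

    for c in ch[r]:
        walk(r, c, 1)
    return out


def path_len(nodes, path):
    return sum(
        float(np.linalg.norm(nodes[a].xyz - nodes[b].xyz))
        for a, b in zip(path, path[1:])
    )


def subtree_tips(nodes, ch, nid):
    if not ch[nid]:
        return 1
    return sum(subtree_tips(nodes, ch, c) for c in ch[nid])


def angle(u, v):
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def branch_end(nodes, ch, child):
    cur = child
    while len(ch[cur]) == 1:
        cur = ch[cur][0]
    return cur


def daughters(nodes, ch, b, mode):
    p = nodes[b].xyz
    out = []
    for c in ch[b][:2]:
        e = c if mode == "local" else branch_end(nodes, ch, c)
        out.append(nodes[e].xyz - p)
    return out


def parent_bif(nodes, ch, nid):
    r = root_of(nodes)
    cur = nodes[nid].parent
    while cur != -1:
        if len(ch[cur]) >= 2 and cur != r:
            return cur
        cur = nodes[cur].parent
    return None


def rall_n(dp, d1, d2):
    if dp <= 0 or d1 <= 0 or d2 <= 0 or max(d1, d2) >= dp:
        return None
    f = lambda n: d1**n + d2**n - dp**n
    lo, hi = 0.0, 5.0
    if f(lo) * f(hi) > 0:
        return None
    while hi - lo > 1e-6:
        m = (lo + hi) / 2
        if f(lo) * f(m) <= 0:
            hi = m
        else:
            lo = m
    return (lo + hi) / 2


def pca_frame(xyz):
    mu = xyz.mean(0)
    X = xyz - mu
    C = X.T @ X / len(X)
    w, V = np.linalg.eigh(C)
    V = V[:, np.argsort(w)[::-1]]
    Y = X @ V
    far = int(np.argmax((X**2).sum(1)))
    for j in range(3):
        col = Y[:, j]
        sd = col.std()
        sk = float(np.mean(col**3) / sd**3) if sd > 0 else 0.0
        flip = sk < 0 if abs(sk) > 1e-6 else col[far] < 0
        if flip:
            V[:, j] *= -1
            Y[:, j] *= -1
    return Y


def oracle_metrics(tree) -> dict[str, float | None]:
    """All 43 metrics; None where undefined on this tree."""
    nodes = from_tree(tree)
    ch = children_map(nodes)
    r = root_of(nodes)
    tips = tips_of(nodes, ch)
    bifs = bifs_of(nodes, ch)
    brs = branches_of(nodes)
    non_root = [n for n in nodes.values() if n.parent != -1]
    xyz = np.array([n.xyz for n in nodes.values()])

    def mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    out = {}
    out["Soma_Surface"] = 4 * math.pi * nodes[r].r ** 2 if nodes[r].r > 0 else None
    out["N_stems"] = float(len(ch[r]))
    out["N_bifs"] = float(len(bifs))
    out["N_branch"] = float(len(brs))
    out["N_tips"] = float(len(tips))
    for name, ax in [("Width", 0), ("Height", 1), ("Depth", 2)]:
        out[name] = float(xyz[:, ax].max() - xyz[:, ax].min())
    out["Type"] = mean([n.t for n in non_root])
    out["Diameter"] = mean([n.d for n in non_root])
    out["Diameter_pow"] = mean([n.d**1.5 for n in non_root])
    out["Length"] = sum(
        float(np.linalg.norm(n.xyz - nodes[n.parent].xyz)) for n in non_root
    )
    out["Surface"] = sum(
        math.pi
        * (n.r + nodes[n.parent].r)
        * float(np.linalg.norm(n.xyz - nodes[n.parent].xyz))
        for n in non_root
    ) or None
    out["SectionArea"] = mean([math.pi * n.r**2 for n in non_root])
    out["Volume"] = sum(
        math.pi
        * (n.r**2 + n.r * nodes[n.parent].r + nodes[n.parent].r ** 2)
        / 3
        * float(np.linalg.norm(n.xyz - nodes[n.parent].xyz))
        for n in non_root
    ) or None
    out["EucDistance"] = mean(
        [float(np.linalg.norm(n.xyz - nodes[r].xyz)) for n in non_root]
    )

    def pdist(nid):
        d = 0.0
        while nodes[nid].parent != -1:
            d += float(np.linalg.norm(nodes[nid].xyz - nodes[nodes[nid].parent].xyz))
            nid = nodes[nid].parent
        return d

    out["PathDistance"] = mean([pdist(n.id) for n in non_root])
    out["Branch_Order"] = mean([o for _, o in brs])
    out["Terminal_degree"] = mean([subtree_tips(nodes, ch, n.id) for n in non_root])
    term = [p for p, _ in brs if not ch[p[-1]]]
    out["TerminalSegment"] = mean([path_len(nodes, p) for p in term])
    t1, t2 = [], []
    for p, _ in brs:
        d0, d1 = nodes[p[1]].d, nodes[p[-1]].d
        L = path_len(nodes, p)
        if L > 0:
            t1.append((d0 - d1) / L)
        if d0 > 0:
            t2.append((d0 - d1) / d0)
    out["Taper_1"], out["Taper_2"] = mean(t1), mean(t2)
    out["Branch_pathlength"] = mean([path_len(nodes, p) for p, _ in brs])
    out["Contraction"] = mean(
        [
            float(np.linalg.norm(nodes[p[-1]].xyz - nodes[p[0]].xyz)) / path_len(nodes, p)
            for p, _ in brs
            if path_len(nodes, p) > 0
        ]
    )
    out["Fragmentation"] = float(len(non_root))
    dr, pdr = [], []
    for b in bifs:
        d1, d2 = nodes[ch[b][0]].d, nodes[ch[b][1]].d
        dp = nodes[b].d
        if min(d1, d2) > 0 and dp > 0:
            dr.append(max(d1, d2) / min(d1, d2))
            pdr.append(0.5 * (d1 + d2) / dp)
    out["Daughter_Ratio"], out["Parent_Daughter_Ratio"] = mean(dr), mean(pdr)
    pa = []
    for b in bifs:
        n1 = subtree_tips(nodes, ch, ch[b][0])
        n2 = subtree_tips(nodes, ch, ch[b][1])
        pa.append(abs(n1 - n2) / (n1 + n2 - 2) if n1 + n2 > 2 else 0.0)
    out["Partition_asymmetry"] = mean(pa)
    ralls = [
        v
        for b in bifs
        if (v := rall_n(nodes[b].d, nodes[ch[b][0]].d, nodes[ch[b][1]].d)) is not None
    ]
    out["Rall_Power"] = mean(ralls)

    def pk(n_exp):
        vals = []
        for b in bifs:
            dp, d1, d2 = nodes[b].d, nodes[ch[b][0]].d, nodes[ch[b][1]].d
            if dp > 0 and d1 > 0 and d2 > 0:
                vals.append((d1**n_exp + d2**n_exp) / dp**n_exp)
        return mean(vals)

    out["Pk"] = pk(out["Rall_Power"]) if ralls else None
    out["Pk_classic"], out["Pk_2"] = pk(1.5), pk(2.0)
    for mode in ("local", "remote"):
        amp, tilt, torq = [], [], []
        for b in bifs:
            try:
                d1, d2 = daughters(nodes, ch, b, mode)
                amp.append(angle(d1, d2))
                if mode == "local":
                    pvec = nodes[b].xyz - nodes[nodes[b].parent].xyz
                else:
                    cur = b
                    while True:
                        pid = nodes[cur].parent
                        if pid == -1:
                            start = cur
                            break
                        if len(ch[pid]) >= 2:
                            start = pid
                            break
                        cur = pid
                    pvec = nodes[b].xyz - nodes[start].xyz
                tilt.append(0.5 * (angle(pvec, d1) + angle(pvec, d2)))
            except (ZeroDivisionError, ValueError):
                continue
            pb = parent_bif(nodes, ch, b)
            if pb is not None:
                n1 = np.cross(*daughters(nodes, ch, b, mode))
                n2 = np.cross(*daughters(nodes, ch, pb, mode))
                a, c = np.linalg.norm(n1), np.linalg.norm(n2)
                if a > 0 and c > 0:
                    torq.append(
                        math.degrees(
                            math.acos(min(1.0, abs(float(np.dot(n1, n2))) / (a * c)))
                        )
                    )
        out[f"Bif_ampl_{mode}"] = mean(amp)
        out[f"Bif_tilt_{mode}"] = mean(tilt)
        out[f"Bif_torque_{mode}"] = mean(torq)
    lpd = []
    for t in tips:
        pb = parent_bif(nodes, ch, t)
        if pb is not None:
            lpd.append(nodes[pb].d)
    out["Last_parent_diam"] = mean(lpd) if bifs else None
    out["Diam_threshold"] = mean([nodes[p[1]].d for p in term])
    hill = []
    for b in bifs:
        ends = [branch_end(nodes, ch, c) for c in ch[b][:2]]
        if all(not ch[e] for e in ends):
            hill.append(
                0.5 * nodes[b].d + 0.25 * (nodes[ch[b][0]].d + nodes[ch[b][1]].d)
            )
    out["Hillman_threshold"] = mean(hill)
    hel = []
    for p, _ in brs:
        pts = np.array([nodes[i].xyz for i in p])
        seg = np.diff(pts, axis=0)
        for i in range(len(seg) - 2):
            v1, v2, v3 = seg[i], seg[i + 1], seg[i + 2]
            nrm = np.linalg.norm(v1) * np.linalg.norm(v2) * np.linalg.norm(v3)
            if nrm > 0:
                hel.append(float(np.dot(np.cross(v1, v2), v3)) / nrm)
    out["Helix"] = mean(hel)
    Y = pca_frame(xyz)
    lo2 = Y.min(0)
    span = float((Y.max(0) - lo2).max())
    if span == 0:
        out["Fractal_Dim"] = None
    else:
        xs, ys = [], []
        for k in range(1, 6):
            s = span / 2**k
            boxes = {tuple(np.floor((pt - lo2) / s).astype(int)) for pt in Y}
            xs.append(math.log(2**k))
            ys.append(math.log(len(boxes)))
        out["Fractal_Dim"] = float(np.polyfit(xs, ys, 1)[0])
    return out
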
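"""Independent brute-force oracles used to validate the implementation.

Deliberately written with plain Python data structures (sets, dicts, BFS)
and networkx, sharing no code path with the package's scipy-based
implementation.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

NEIGHBORS26 = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]


def classify_contacts_oracle(ids, az_id=1, membrane_ids=(1, 2, 3), vesicle_min=10):
    ids = set(int(i) for i in ids)
    vesicles = {i for i in ids if i >= vesicle_min}
    membranes = ids & set(membrane_ids)
    if ids == vesicles | {az_id} and len(vesicles) == 1 and membranes == {az_id}:
        return "tether"
    if ids == vesicles and len(vesicles) == 2:
        return "connector"
    return "rejected"


def hierseg_oracle(density, labels, region, thresholds):
    """Exhaustive per-threshold connected-component segmentation.

    Enumerates 26-connected components of ``region & (density <= t)`` at
    every threshold independently (BFS over voxel tuples), keeps components
    with a valid tether/connector contact signature at the lowest threshold,
    and drops any component containing a previously kept core.

    Returns a list of dicts with frozenset voxels, threshold, kind, contacts.
    """
    shape = density.shape
    region_set = {tuple(p) for p in np.argwhere(region)}

    def components(fg):
        seen = set()
        comps = []
        for start in fg:
            if start in seen:
                continue
            comp = {start}
            queue = [start]
            seen.add(start)
            while queue:
                v = queue.pop()
                for off in NEIGHBORS26:
                    nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                    if nb in fg and nb not in seen:
                        seen.add(nb)
                        comp.add(nb)
                        queue.append(nb)
            comps.append(comp)
        return comps

    def contacts_of(comp):
        out = {}
        for v in comp:
            for off in NEIGHBORS26:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= c < s for c, s in zip(nb, shape)):
                    b = int(labels[nb])
                    if b > 0:
                        out.setdefault(b, set()).add(v)
        return out

    reported = []
    claimed = set()
    for t in thresholds:
        fg = {v for v in region_set if density[v] <= t}
        for comp in components(fg):
            if comp & claimed:
                continue
            contacts = contacts_of(comp)
            kind = classify_contacts_oracle(contacts.keys())
            if kind == "rejected":
                continue
            claimed |= comp
            reported.append({
                "voxels": frozenset(comp),
                "threshold": float(t),
                "kind": kind,
                "contacts": {b: frozenset(vs) for b, vs in contacts.items()},
            })
    return reported


def geodesic_oracle(voxels, set_a, set_b, voxel_size_nm):
    """Shortest 26-neighbor path between contact sets via networkx Dijkstra."""
    nodes = set(zip(*voxels))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for v in nodes:
        for off in NEIGHBORS26:
            nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if nb in nodes:
                g.add_edge(v, nb, weight=math.sqrt(sum(o * o for o in off)))
    a_nodes = set(zip(*set_a))
    b_nodes = set(zip(*set_b))
    if a_nodes & b_nodes:
        return 0.0
    best = math.inf
    for a in a_nodes:
        dist = nx.single_source_dijkstra_path_length(g, a)
        for b in b_nodes:
            if b in dist:
                best = min(best, dist[b])
    return best * voxel_size_nm


def chi2_oracle(table):
    """Pearson chi-squared statistic by the textbook closed form."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i, j in itertools.product(range(table.shape[0]), range(table.shape[1])):
        e = table[i].sum() * table[:, j].sum() / total
        stat += (table[i, j] - e) ** 2 / e
    return stat


def t_stat_oracle(a, b):
    """Two-sample pooled-variance (Student) t statistic, textbook form."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def kruskal_oracle(a, b):
    """Kruskal-Wallis H for two groups with tie correction, textbook form."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    n = len(pooled)
    ra, rb = ranks[:len(a)].sum(), ranks[len(a):].sum()
    h = 12.0 / (n * (n + 1)) * (ra ** 2 / len(a) + rb ** 2 / len(b)) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / corr


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
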
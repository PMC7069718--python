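"""Dendritic tree morphologies.

Trees are stored as SWC-style node tables (id, structure label, x/y/z in
micrometres, radius, parent id).  Everything downstream — ROI placement,
cable-distance analysis and the compartmental model — works on this
representation.  Distances between dendritic points are *cable* (tree-path)
distances, i.e. measured along the arbor, never through space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "Morphology",
    "RoiSet",
    "MorphologyError",
    "StructureError",
    "load_swc",
    "write_swc",
    "path_distance",
    "generate_synthetic_morphology",
    "place_rois",
]


class MorphologyError(ValueError):
    """Invalid morphology data."""


class StructureError(MorphologyError):
    """Broken tree structure (missing parents, multiple roots, cycles)."""


@dataclass
class Morphology:
    """A rooted dendritic tree.

    Parameters
    ----------
    ids, labels, xyz, radius, parent_ids
        SWC columns: node ids (arbitrary integers), structure labels
        (read but not interpreted), coordinates in µm, radii in µm
        (strictly positive) and parent ids (−1 for the single root).
    """

    ids: np.ndarray
    labels: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent_ids: np.ndarray

    # derived, filled in __post_init__
    index: dict = field(default_factory=dict, repr=False)
    parent_index: np.ndarray = field(default=None, repr=False)
    edge_length: np.ndarray = field(default=None, repr=False)
    depth: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        n = self.ids.size
        if n == 0:
            raise MorphologyError("empty morphology")
        if len(set(self.ids.tolist())) != n:
            raise StructureError("duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise MorphologyError("non-finite coordinates")
        if np.any(self.radius <= 0):
            bad = self.ids[self.radius <= 0][0]
            raise MorphologyError(f"non-positive radius at node {bad}")
        self.index = {int(i): k for k, i in enumerate(self.ids)}
        roots = np.flatnonzero(self.parent_ids == -1)
        if roots.size != 1:
            raise StructureError(f"expected exactly one root, found {roots.size}")
        pidx = np.empty(n, dtype=np.int64)
        for k in range(n):
            p = int(self.parent_ids[k])
            if p == -1:
                pidx[k] = -1
            elif p not in self.index:
                raise StructureError(
                    f"node {int(self.ids[k])} references missing parent {p}"
                )
            else:
                pidx[k] = self.index[p]
        self.parent_index = pidx
        # edge lengths and cumulative depth (cycle check via visitation)
        el = np.zeros(n)
        for k in range(n):
            p = pidx[k]
            if p >= 0:
                el[k] = float(np.linalg.norm(self.xyz[k] - self.xyz[p]))
        self.edge_length = el
        depth = np.full(n, np.nan)
        depth[roots[0]] = 0.0
        for k in self._topological_order():
            p = pidx[k]
            if p >= 0:
                depth[k] = depth[p] + el[k]
        if np.any(np.isnan(depth)):
            raise StructureError("parent links do not form a tree reaching the root")
        self.depth = depth

    # -- structure helpers -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.ids.size)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_index == -1)[0])

    @property
    def planar_flag(self) -> bool:
        z = self.xyz[:, 2]
        return bool(np.allclose(z, z[0]))

    def _topological_order(self) -> np.ndarray:
        """Node indices ordered so every parent precedes its children."""
        n = self.n_nodes
        children: list[list[int]] = [[] for _ in range(n)]
        for k in range(n):
            p = self.parent_index[k]
            if p >= 0:
                children[p].append(k)
        order = []
        stack = [int(np.flatnonzero(self.parent_index == -1)[0])]
        while stack:
            k = stack.pop()
            order.append(k)
            stack.extend(reversed(children[k]))
        if len(order) != n:
            raise StructureError("parent links contain a cycle")
        return np.asarray(order, dtype=np.int64)

    def children_of(self, idx: int) -> list[int]:
        return [int(k) for k in np.flatnonzero(self.parent_index == idx)]

    def node_distance_matrix(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """All-pairs cable distance between nodes (µm).

        Uses a sparse shortest-path solve on the weighted tree adjacency;
        on a tree the shortest path is the unique path.
        """
        n = self.n_nodes
        rows, cols, w = [], [], []
        for k in range(n):
            p = self.parent_index[k]
            if p >= 0:
                rows += [k, p]
                cols += [p, k]
                w += [self.edge_length[k]] * 2
        adj = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        idx = np.arange(n) if indices is None else np.asarray(indices, dtype=np.int64)
        return dijkstra(adj, directed=False, indices=idx)[:, idx] if indices is not None \
            else dijkstra(adj, directed=False)

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if node index ``a`` lies on the path from ``b`` to the root."""
        k = b
        while k != -1:
            if k == a:
                return True
            k = int(self.parent_index[k])
        return False

    def point_xyz(self, node_id: int, offset: float = 0.0) -> np.ndarray:
        """Coordinates of a point ``offset`` µm up the edge from node toward its parent."""
        k = self.index[int(node_id)]
        p = self.parent_index[k]
        if offset == 0.0 or p < 0 or self.edge_length[k] == 0:
            return self.xyz[k].copy()
        f = min(offset / self.edge_length[k], 1.0)
        return (1 - f) * self.xyz[k] + f * self.xyz[p]


@dataclass
class RoiSet:
    """Regions of interest attached to a morphology.

    Each ROI is a small (nominally 3–4 µm) dendritic segment identified by
    its nearest morphology node plus an arc offset toward that node's
    parent, so inter-ROI distances are exact tree-path lengths.
    """

    roi_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    node_ids: np.ndarray
    offsets: np.ndarray
    extent_um: np.ndarray

    def __post_init__(self):
        self.roi_ids = np.asarray(self.roi_ids, dtype=np.int64)
        if len(set(self.roi_ids.tolist())) != self.roi_ids.size:
            raise MorphologyError("duplicate ROI ids")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.extent_um = np.asarray(self.extent_um, dtype=float)
        if np.any(self.extent_um <= 0):
            raise MorphologyError("ROI extent must be > 0")

    def __len__(self) -> int:
        return int(self.roi_ids.size)

    def validate_against(self, m: Morphology) -> None:
        for nid in self.node_ids:
            if int(nid) not in m.index:
                raise MorphologyError(f"ROI attachment node {int(nid)} not in morphology")

    def cable_distance_matrix(self, m: Morphology) -> np.ndarray:
        """Pairwise cable distance between ROI attachment points (µm)."""
        n = len(self)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = path_distance(
                    m,
                    (int(self.node_ids[i]), float(self.offsets[i])),
                    (int(self.node_ids[j]), float(self.offsets[j])),
                )
                out[i, j] = out[j, i] = d
        return out


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def load_swc(path) -> Morphology:
    """Read a 7-column whitespace-delimited SWC file ('#' comments allowed)."""
    ids, labels, xyz, radius, parents = [], [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
            ids.append(int(parts[0]))
            labels.append(int(parts[1]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radius.append(float(parts[5]))
            parents.append(int(parts[6]))
    if not ids:
        raise MorphologyError(f"{path}: no nodes")
    return Morphology(np.array(ids), np.array(labels), np.array(xyz),
                      np.array(radius), np.array(parents))


def write_swc(m: Morphology, path) -> None:
    """Write SWC with nodes in topological (parent-before-child) order."""
    order = m._topological_order()
    with open(path, "w") as fh:
        fh.write("# SWC written by dsgcdend\n")
        for k in order:
            fh.write(
                f"{int(m.ids[k])} {int(m.labels[k])} "
                f"{m.xyz[k, 0]:.6f} {m.xyz[k, 1]:.6f} {m.xyz[k, 2]:.6f} "
                f"{m.radius[k]:.6f} {int(m.parent_ids[k])}\n"
            )


# ---------------------------------------------------------------------------
# Cable distance
# ---------------------------------------------------------------------------

def _as_attachment(a) -> tuple[int, float]:
    if isinstance(a, (tuple, list)):
        return int(a[0]), float(a[1])
    return int(a), 0.0


def path_distance(m: Morphology, a, b) -> float:
    """Cable distance (µm) between two points on the tree.

    Points are ``node_id`` or ``(node_id, offset_um)``, the offset measured
    from the node along its parent edge.  The distance is the length of the
    unique tree path, summing straight inter-node segment lengths.
    """
    na_id, oa = _as_attachment(a)
    nb_id, ob = _as_attachment(b)
    if na_id not in m.index:
        raise KeyError(f"unknown node id {na_id}")
    if nb_id not in m.index:
        raise KeyError(f"unknown node id {nb_id}")
    ka, kb = m.index[na_id], m.index[nb_id]
    if ka == kb:
        return abs(oa - ob)
    # node-level distance via LCA on weighted depths
    d_nodes = _node_path_distance(m, ka, kb)
    d = d_nodes
    d += oa if m.is_ancestor(ka, kb) else -oa
    d += ob if m.is_ancestor(kb, ka) else -ob
    return float(max(d, 0.0))


def _node_path_distance(m: Morphology, ka: int, kb: int) -> float:
    seen = {}
    k = ka
    while k != -1:
        seen[k] = True
        k = int(m.parent_index[k])
    k = kb
    while k not in seen:
        k = int(m.parent_index[k])
    lca = k
    return float(m.depth[ka] + m.depth[kb] - 2 * m.depth[lca])


# ---------------------------------------------------------------------------
# Synthetic morphology
# ---------------------------------------------------------------------------

def generate_synthetic_morphology(
    target_field_diameter: float,
    branch_order: int,
    seed: int,
    n_trunks: int = 5,
    segment_length: float = 4.0,
    branch_angle_deg: float = 28.0,
    angle_jitter_deg: float = 6.0,
) -> Morphology:
    """Planar, roughly radially symmetric binary tree filling a circular field.

    A stand-in arbor with the gross geometry of a flat-mounted retinal
    ganglion cell: ``n_trunks`` primary dendrites leave the soma at evenly
    spaced angles and bifurcate ``branch_order − 1`` times, with section
    lengths chosen so root-to-tip path length equals the field radius
    (hence every node stays within the radius).  Deterministic given seed.
    """
    if target_field_diameter <= 0:
        raise MorphologyError("target_field_diameter must be > 0")
    if branch_order < 1:
        raise MorphologyError("branch_order must be >= 1")
    rng = np.random.default_rng(seed)
    radius_field = target_field_diameter / 2.0
    section_len = radius_field / branch_order

    ids = [1]
    labels = [1]
    xyz = [[0.0, 0.0, 0.0]]
    radii = [6.0]  # soma point
    parents = [-1]
    next_id = [2]

    def add_node(x, y, r, parent_id):
        nid = next_id[0]
        next_id[0] += 1
        ids.append(nid)
        labels.append(3)
        xyz.append([float(x), float(y), 0.0])
        radii.append(float(r))
        parents.append(int(parent_id))
        return nid

    def grow_section(x, y, angle, parent_id, depth):
        """Grow one section of length section_len in <=segment_length steps."""
        # taper from ~1 µm diameter trunks to ~0.3 µm distal dendrites
        r = max(0.15, 0.5 * 0.65 ** depth)
        remaining = section_len
        pid = parent_id
        while remaining > 1e-9:
            step = min(segment_length, remaining)
            angle = angle + np.deg2rad(rng.normal(0.0, angle_jitter_deg))
            x = x + step * np.cos(angle)
            y = y + step * np.sin(angle)
            pid = add_node(x, y, r, pid)
            remaining -= step
        if depth + 1 < branch_order:
            da = np.deg2rad(branch_angle_deg + rng.normal(0.0, angle_jitter_deg))
            grow_section(x, y, angle + da, pid, depth + 1)
            grow_section(x, y, angle - da, pid, depth + 1)

    for t in range(n_trunks):
        base = 2 * np.pi * t / n_trunks
        grow_section(0.0, 0.0, base, 1, 0)

    return Morphology(np.array(ids), np.array(labels), np.array(xyz),
                      np.array(radii), np.array(parents))


# ---------------------------------------------------------------------------
# ROI placement
# ---------------------------------------------------------------------------

def place_rois(m: Morphology, spacing: float, extent: float = 3.5,
               seed: int = 0) -> RoiSet:
    """Tile ROIs along dendrites at approximately ``spacing`` µm arc intervals.

    Walks the tree depth-first; the arc counter is inherited across branch
    points so consecutive ROIs on an unbranched stretch are ``spacing``
    apart (within one segment length).  The seed jitters the phase of the
    first ROI on each trunk by a fraction of the spacing.
    """
    if spacing <= 0:
        raise MorphologyError("spacing must be > 0")
    rng = np.random.default_rng(seed)
    root = m.root_index
    roi_nodes, roi_offsets = [], []

    # Arc position of a point equals its weighted depth from the root, so
    # ROIs sit on the per-trunk grid {phase + j*spacing}; each edge owns the
    # grid points falling in (depth(parent), depth(child)].
    def collect(k, phase):
        for c in m.children_of(k):
            lo, hi = m.depth[m.parent_index[c]], m.depth[c]
            j = int(np.ceil((lo - phase) / spacing + 1e-12))
            g = phase + j * spacing
            while g <= hi + 1e-9:
                if g > lo + 1e-9:
                    roi_nodes.append(int(m.ids[c]))
                    roi_offsets.append(float(min(max(hi - g, 0.0), m.edge_length[c])))
                g += spacing
            collect(c, phase)

    for trunk in m.children_of(root):
        phase = float(rng.uniform(0.5 * spacing, 1.0 * spacing))
        lo, hi = m.depth[root], m.depth[trunk]
        g = phase
        while g <= hi + 1e-9:
            if g > lo + 1e-9:
                roi_nodes.append(int(m.ids[trunk]))
                roi_offsets.append(float(min(max(hi - g, 0.0), m.edge_length[trunk])))
            g += spacing
        collect(trunk, phase)

    if not roi_nodes:
        # degenerate tiny tree: put one ROI at the first child of root
        kids = m.children_of(root)
        if not kids:
            raise MorphologyError("morphology has no dendrite to place ROIs on")
        roi_nodes = [int(m.ids[kids[0]])]
        roi_offsets = [0.0]

    xy = np.array([m.point_xyz(nid, off)[:2] for nid, off in zip(roi_nodes, roi_offsets)])
    n = len(roi_nodes)
    return RoiSet(
        roi_ids=np.arange(n),
        x=xy[:, 0],
        y=xy[:, 1],
        node_ids=np.array(roi_nodes),
        offsets=np.array(roi_offsets),
        extent_um=np.full(n, float(extent)),
    )
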
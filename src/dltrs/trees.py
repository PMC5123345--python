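"""Dated species trees, gene trees, leaf maps and the time-slice grid.

Conventions
-----------
Time runs from 0 at the extant leaves and increases rootward.  A species
edge is identified by its *child* vertex: "edge v" is the edge hanging
above vertex ``v``; the root's edge is the stem, a pre-root edge of
configurable duration on which the gene-family process originates.  Edge
``v`` spans the half-open interval ``[t(v), t(parent(v)))`` so that any
time point on a root-to-leaf path belongs to exactly one edge.

The discretized tree inserts out-degree-1 grid vertices on every edge:
first at every species-vertex time the edge spans (slice boundaries), then
at the regular interior time points of each slice, shared across all edges
crossing that slice.  Interior points carry a quadrature interval length
``delta``; vertex and slice-boundary points carry ``delta = 0`` and never
host duplication or transfer events.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "DatedSpeciesTree",
    "GeneTree",
    "LeafMap",
    "DiscretizedSpeciesTree",
    "parse_dated_newick",
    "parse_gene_newick",
    "discretize",
    "contemporaneous_edges",
]

#: point kinds on the discretized tree
KIND_LEAF = 0          # species leaf (time 0)
KIND_SPECIATION = 1    # internal species vertex (incl. the root vertex)
KIND_STEM_TIP = 2      # origination point at the top of the stem edge
KIND_BOUNDARY = 3      # out-degree-1 point at a slice boundary (delta = 0)
KIND_EVENT = 4         # interior point; may host duplication/transfer


class TreeError(ValueError):
    """Malformed, non-binary or non-ultrametric tree input."""


# ---------------------------------------------------------------------------
# species tree


class DatedSpeciesTree:
    """Rooted binary ultrametric species tree with absolute vertex times.

    Vertices are numbered 0..n-1 in a canonical preorder (children ordered
    by their smallest descendant leaf label), which makes identifiers
    stable across parse/write round trips.
    """

    def __init__(self, parent, children, times, labels, stem_duration):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.times = np.asarray(times, dtype=np.float64)
        self.labels = list(labels)
        if not stem_duration > 0:
            raise TreeError("stem duration must be positive")
        self.stem_duration = float(stem_duration)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self._validate()

    # -- structure ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    def is_leaf(self, v: int) -> bool:
        return self.children[v, 0] < 0

    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.children[:, 0] < 0)

    @property
    def root_time(self) -> float:
        return float(self.times[self.root])

    @property
    def origin_time(self) -> float:
        """Time of the stem tip, where the single ancestral lineage starts."""
        return self.root_time + self.stem_duration

    def edge_top(self, v: int) -> float:
        """Upper (older) end of edge v; the stem tip for the root's edge."""
        p = self.parent[v]
        return self.origin_time if p < 0 else float(self.times[p])

    def edge_duration(self, v: int) -> float:
        return self.edge_top(v) - float(self.times[v])

    def leaf_index(self, label: str) -> int:
        for v in self.leaves:
            if self.labels[v] == label:
                return int(v)
        raise KeyError(f"no species leaf labelled {label!r}")

    def clade(self, v: int) -> frozenset:
        """Set of leaf labels below (and including) vertex v."""
        out, stack = [], [int(v)]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(self.labels[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    def edge_name(self, v: int) -> str:
        """Human-readable name for edge v (its child clade)."""
        return "+".join(sorted(self.clade(v)))

    def contemporaneous_edges(self, t: float) -> set:
        """All edges whose half-open span [t(v), t(parent(v))) contains t."""
        if t < -1e-12 or t > self.origin_time + 1e-12:
            raise ValueError(f"time {t} outside [0, {self.origin_time}]")
        out = set()
        for v in range(self.n_vertices):
            if self.times[v] <= t < self.edge_top(v):
                out.add(v)
        return out

    # -- i/o ----------------------------------------------------------
    def to_newick(self) -> str:
        def rec(v):
            if self.is_leaf(v):
                return self.labels[v]
            c1, c2 = self.children[v]
            bl1 = self.times[v] - self.times[c1]
            bl2 = self.times[v] - self.times[c2]
            return f"({rec(c1)}:{bl1:.12g},{rec(c2)}:{bl2:.12g})"

        return rec(self.root) + ";"

    # -- checks --------------------------------------------------------
    def _validate(self):
        n = self.n_vertices
        for v in range(n):
            c = self.children[v]
            if (c[0] < 0) != (c[1] < 0):
                raise TreeError(f"vertex {v} is not binary")
            if c[0] >= 0:
                for ci in c:
                    if not self.times[v] > self.times[ci]:
                        raise TreeError(
                            f"time does not decrease from vertex {v} to child {ci}"
                        )
        for v in self.leaves:
            if abs(self.times[v]) > 1e-9 * max(1.0, self.root_time):
                raise TreeError("leaves must sit at time 0 (ultrametric)")
        labels = [self.labels[v] for v in self.leaves]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate species leaf labels")


def _dendropy_parse(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc


def _canonical_arrays(dtree: dendropy.Tree, need_lengths: bool):
    """Flatten a dendropy tree into canonical-preorder arrays.

    Returns (parent, children, branch_len, labels, min_leaf_label_per_node).
    """
    seed = dtree.seed_node

    def min_label(nd):
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("leaf without a label")
            return nd.taxon.label
        return min(min_label(c) for c in nd.child_nodes())

    parent, children, blen, labels = [], [], [], []

    def add(nd, par):
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            raise TreeError(f"non-binary vertex with {len(kids)} children")
        idx = len(parent)
        parent.append(par)
        children.append([-1, -1])
        labels.append(nd.taxon.label if nd.is_leaf() else None)
        bl = nd.edge.length
        if par >= 0 and bl is None and need_lengths:
            raise TreeError("missing branch length")
        blen.append(0.0 if (bl is None or par < 0) else float(bl))
        if kids:
            kids = sorted(kids, key=min_label)
            children[idx][0] = add(kids[0], idx)
            children[idx][1] = add(kids[1], idx)
        return idx

    add(seed, -1)
    return (
        np.array(parent, dtype=np.int64),
        np.array(children, dtype=np.int64),
        np.array(blen, dtype=np.float64),
        labels,
    )


def parse_dated_newick(
    text: str, stem: float | None = None, *, rel_tol: float = 1e-6
) -> DatedSpeciesTree:
    """Parse a dated ultrametric rooted binary newick species tree.

    Branch lengths are absolute time durations.  ``stem`` is the duration
    of the pre-root stem edge; if omitted it defaults to 10 % of the tree
    height.  Input whose leaf depths differ by more than ``rel_tol``
    relative to the height is rejected as non-ultrametric.
    """
    parent, children, blen, labels = _canonical_arrays(
        _dendropy_parse(text), need_lengths=True
    )
    n = len(parent)
    depth = np.zeros(n)
    for v in range(1, n):
        depth[v] = depth[parent[v]] + blen[v]
    leaf = children[:, 0] < 0
    height = float(depth[leaf].max())
    if height <= 0:
        raise TreeError("tree height must be positive")
    if np.any(np.abs(depth[leaf] - height) > rel_tol * height):
        raise TreeError("non-ultrametric input: leaf depths differ")
    times = height - depth
    times[leaf] = 0.0
    if stem is None:
        stem = 0.1 * height
    return DatedSpeciesTree(parent, children, times, labels, stem)


# ---------------------------------------------------------------------------
# gene tree


class GeneTree:
    """Rooted binary gene tree with substitution-unit edge lengths.

    ``lengths[v]`` is the length of the edge above vertex ``v`` (expected
    substitutions per site); the root has no edge and carries length 0.
    """

    def __init__(self, parent, children, lengths, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.labels = list(labels)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        if np.any(self.lengths < 0):
            raise TreeError("negative gene-tree edge length")
        leaf_labels = [l for l in self.labels if l is not None]
        if len(set(leaf_labels)) != len(leaf_labels):
            raise TreeError("duplicate gene leaf labels")

    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    def is_leaf(self, v: int) -> bool:
        return self.children[v, 0] < 0

    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.children[:, 0] < 0)

    @property
    def internal(self) -> np.ndarray:
        return np.flatnonzero(self.children[:, 0] >= 0)

    def postorder(self) -> list:
        order, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done or self.is_leaf(v):
                order.append(v)
            else:
                stack.append((v, True))
                stack.append((int(self.children[v, 1]), False))
                stack.append((int(self.children[v, 0]), False))
        return order

    def clade(self, v: int) -> frozenset:
        out, stack = [], [int(v)]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(self.labels[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    def to_newick(self, lengths: bool = True) -> str:
        def key(v):
            return min(self.clade(v))

        def rec(v):
            if self.is_leaf(v):
                s = self.labels[v]
            else:
                c = sorted(self.children[v], key=key)
                s = f"({rec(c[0])},{rec(c[1])})"
            if lengths and v != self.root:
                s += f":{self.lengths[v]:.12g}"
            return s

        return rec(self.root) + ";"

    def topology_id(self) -> str:
        """Canonical topology string (no lengths) used to group samples."""
        return self.to_newick(lengths=False)

    def unrooted_edges(self) -> list:
        """Edges of the unrooted version of this tree as (a, b, length);
        the root is suppressed, joining its two children."""
        out = []
        rc = [int(c) for c in self.children[self.root]]
        out.append((rc[0], rc[1], float(self.lengths[rc[0]] + self.lengths[rc[1]])))
        for v in range(self.n_vertices):
            if v == self.root or int(self.parent[v]) == self.root:
                continue
            out.append((v, int(self.parent[v]), float(self.lengths[v])))
        return out

    def reroot(self, a: int, b: int, fraction: float = 0.5) -> "GeneTree":
        """Re-root on the unrooted edge (a, b), placing the new root at
        ``fraction`` of the edge length away from ``a``.  Only the root
        position changes; the unrooted topology and path lengths between
        leaves are preserved."""
        adj = {}
        for x, y, ln in self.unrooted_edges():
            adj.setdefault(x, []).append((y, ln))
            adj.setdefault(y, []).append((x, ln))
        edge_len = None
        for y, ln in adj[a]:
            if y == b:
                edge_len = ln
        if edge_len is None:
            raise ValueError(f"({a},{b}) is not an unrooted edge")
        keep = sorted(adj)  # old root dropped
        remap = {v: i for i, v in enumerate(keep)}
        n_new = len(keep) + 1
        root_new = len(keep)
        parent = np.full(n_new, -1, dtype=np.int64)
        children = np.full((n_new, 2), -1, dtype=np.int64)
        lengths = np.zeros(n_new)
        labels = [self.labels[v] for v in keep] + [None]

        def attach(v, par, ln, came_from):
            vi = remap[v]
            parent[vi] = par
            lengths[vi] = ln
            if children[par, 0] < 0:
                children[par, 0] = vi
            else:
                children[par, 1] = vi
            for y, l2 in adj[v]:
                if y != came_from:
                    attach(y, vi, l2, v)

        attach(a, root_new, fraction * edge_len, b)
        attach(b, root_new, (1.0 - fraction) * edge_len, a)
        return GeneTree(parent, children, lengths, labels)

    def path_lengths(self) -> np.ndarray:
        """Matrix of pairwise path lengths (edge counts) between vertices."""
        n = self.n_vertices
        adj = [[] for _ in range(n)]
        for v in range(n):
            if v != self.root:
                adj[v].append(int(self.parent[v]))
                adj[int(self.parent[v])].append(v)
        dist = np.full((n, n), -1, dtype=np.int64)
        for s in range(n):
            dist[s, s] = 0
            queue = [s]
            while queue:
                nxt = []
                for u in queue:
                    for w in adj[u]:
                        if dist[s, w] < 0:
                            dist[s, w] = dist[s, u] + 1
                            nxt.append(w)
                queue = nxt
        return dist

    def diameter(self) -> int:
        return int(self.path_lengths().max())


def parse_gene_newick(text: str) -> GeneTree:
    """Parse a rooted binary gene tree; branch lengths are substitutions/site."""
    parent, children, blen, labels = _canonical_arrays(
        _dendropy_parse(text), need_lengths=True
    )
    return GeneTree(parent, children, blen, labels)


# ---------------------------------------------------------------------------
# leaf map


@dataclass
class LeafMap:
    """Total map from gene leaf labels to species leaf labels (many-to-one)."""

    mapping: dict

    def __getitem__(self, gene_leaf: str) -> str:
        return self.mapping[gene_leaf]

    def validate(self, gene: GeneTree, species: DatedSpeciesTree):
        species_leaves = {species.labels[v] for v in species.leaves}
        for v in gene.leaves:
            lbl = gene.labels[v]
            if lbl not in self.mapping:
                raise KeyError(f"gene leaf {lbl!r} missing from leaf map")
            if self.mapping[lbl] not in species_leaves:
                raise KeyError(
                    f"gene leaf {lbl!r} maps to unknown species {self.mapping[lbl]!r}"
                )

    @classmethod
    def read(cls, source) -> "LeafMap":
        """Read a two-column TSV ``gene_leaf<TAB>species_leaf``; '#' comments."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        mapping = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"bad leaf-map line: {line!r}")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def write(self, target):
        text = "".join(f"{g}\t{s}\n" for g, s in sorted(self.mapping.items()))
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as fh:
                fh.write(text)


# ---------------------------------------------------------------------------
# discretization


@dataclass
class TimeSlice:
    lo: float
    hi: float
    edges: np.ndarray        # species edge ids crossing [lo, hi]
    bottom_pts: np.ndarray   # (k,) grid point at time lo on each edge
    rec_times: np.ndarray    # (r,) interior regular times then hi
    rec_pts: np.ndarray      # (r, k) grid points at rec_times on each edge


class DiscretizedSpeciesTree:
    """Time-sliced grid over a dated species tree.

    Every grid point lies on exactly one species edge.  Species vertices are
    the bottom points of the edge above them; each edge additionally carries
    a top point just below its parent vertex (the stem tip for the stem
    edge), slice-boundary points at intermediate species-vertex times, and
    ``resolution - 1`` interior event points per slice at the shared
    regular times.
    """

    def __init__(self, tree: DatedSpeciesTree, resolution: int):
        if resolution < 1:
            raise ValueError("resolution must be >= 1")
        self.tree = tree
        self.resolution = int(resolution)
        self._build()

    def _build(self):
        tree = self.tree
        r = self.resolution
        tol = 1e-9 * max(1.0, tree.origin_time)

        bounds = [0.0]
        for v in range(tree.n_vertices):
            if not tree.is_leaf(v):
                t = float(tree.times[v])
                if all(abs(t - b) > tol for b in bounds):
                    bounds.append(t)
        bounds.append(tree.origin_time)
        bounds = sorted(bounds)
        self.slice_bounds = np.array(bounds)

        pt_edge, pt_time, pt_delta, pt_kind = [], [], [], []
        index = {}  # (edge, time) -> point id

        def new_point(edge, t, kind, delta):
            pid = len(pt_edge)
            pt_edge.append(edge)
            pt_time.append(t)
            pt_delta.append(delta)
            pt_kind.append(kind)
            index[(edge, t)] = pid
            return pid

        # bottom (vertex) points
        self.vertex_point = np.zeros(tree.n_vertices, dtype=np.int64)
        for v in range(tree.n_vertices):
            kind = KIND_LEAF if tree.is_leaf(v) else KIND_SPECIATION
            self.vertex_point[v] = new_point(v, float(tree.times[v]), kind, 0.0)

        # per-slice points, shared regular times across contemporaneous edges
        self.slices = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            h = hi - lo
            edges = [
                v
                for v in range(tree.n_vertices)
                if tree.times[v] <= lo + tol and tree.edge_top(v) >= hi - tol
            ]
            interior = [lo + j * h / r for j in range(1, r)]
            delta = h / (r - 1) if r >= 2 else 0.0
            rec_times = interior + [hi]
            rec = np.zeros((len(rec_times), len(edges)), dtype=np.int64)
            bottom = np.zeros(len(edges), dtype=np.int64)
            for k, e in enumerate(edges):
                bottom[k] = index[(e, lo)] if (e, lo) in index else self.vertex_point[e]
                for j, t in enumerate(interior):
                    rec[j, k] = new_point(e, t, KIND_EVENT, delta)
                if abs(tree.edge_top(e) - hi) <= tol:
                    kind = KIND_STEM_TIP if e == tree.root else KIND_BOUNDARY
                else:
                    kind = KIND_BOUNDARY
                rec[len(interior), k] = new_point(e, hi, kind, 0.0)
            self.slices.append(
                TimeSlice(lo, hi, np.array(edges, dtype=np.int64), bottom,
                          np.array(rec_times), rec)
            )

        self.pt_edge = np.array(pt_edge, dtype=np.int64)
        self.pt_time = np.array(pt_time, dtype=np.float64)
        self.pt_delta = np.array(pt_delta, dtype=np.float64)
        self.pt_kind = np.array(pt_kind, dtype=np.int64)
        self.n_points = len(pt_edge)

        # global time indexing (exact float sharing by construction)
        uniq = np.unique(self.pt_time)
        self.times = uniq
        lookup = {t: i for i, t in enumerate(uniq)}
        self.pt_tidx = np.array([lookup[t] for t in pt_time], dtype=np.int64)

        # static index of ordered time differences, used to cache per-edge
        # substitution-length densities across DP evaluations
        T = len(uniq)
        didx = np.full((T, T), -1, dtype=np.int64)
        vals = []
        for i in range(T):
            for j in range(i):
                didx[i, j] = len(vals)
                vals.append(uniq[i] - uniq[j])
        self.dt_index = didx
        self.dt_values = np.array(vals, dtype=np.float64)

        # edge tops, stem tip
        self.edge_top_point = np.zeros(tree.n_vertices, dtype=np.int64)
        for v in range(tree.n_vertices):
            self.edge_top_point[v] = index[(v, tree.edge_top(v))]
        self.stem_point = int(self.edge_top_point[tree.root])

        # speciation children tops
        self.spec_top = np.full((self.n_points, 2), -1, dtype=np.int64)
        for v in range(tree.n_vertices):
            if not tree.is_leaf(v):
                p = self.vertex_point[v]
                c1, c2 = tree.children[v]
                self.spec_top[p, 0] = self.edge_top_point[c1]
                self.spec_top[p, 1] = self.edge_top_point[c2]

        # same-edge point chains (next point below), per-edge ordered lists
        self.edge_points = []
        self.down = np.full(self.n_points, -1, dtype=np.int64)
        for v in range(tree.n_vertices):
            ids = [p for p in range(self.n_points) if pt_edge[p] == v]
            ids.sort(key=lambda p: pt_time[p])
            self.edge_points.append(np.array(ids, dtype=np.int64))
            for a, b in zip(ids[1:], ids[:-1]):
                self.down[a] = b

        # transfer recipients: same-time event points on other edges
        by_tidx = {}
        for p in range(self.n_points):
            if self.pt_kind[p] == KIND_EVENT:
                by_tidx.setdefault(self.pt_tidx[p], []).append(p)
        off = [0]
        idxs = []
        for p in range(self.n_points):
            if self.pt_kind[p] == KIND_EVENT:
                others = [q for q in by_tidx[self.pt_tidx[p]] if q != p]
                idxs.extend(sorted(others))
            off.append(len(idxs))
        self.trans_off = np.array(off, dtype=np.int64)
        self.trans_idx = np.array(idxs, dtype=np.int64)

        # p11 evaluation order: points by time, vertex points after the
        # child-edge top points that share their time
        order = sorted(
            range(self.n_points),
            key=lambda p: (pt_time[p], pt_kind[p] == KIND_SPECIATION),
        )
        self.p11_order = np.array(order, dtype=np.int64)

    # -- queries --------------------------------------------------------
    def contemporaneous_edges(self, t: float) -> set:
        return self.tree.contemporaneous_edges(t)

    def point_interval(self, p: int) -> tuple:
        """Time interval represented by grid point p (degenerate if delta=0)."""
        d = float(self.pt_delta[p]) / 2.0
        t = float(self.pt_time[p])
        return (max(t - d, 0.0), min(t + d, self.tree.origin_time))

    def describe_point(self, p: int) -> str:
        return (
            f"point {p} on edge {self.tree.edge_name(self.pt_edge[p])} "
            f"at t={self.pt_time[p]:.6g}"
        )


def discretize(tree: DatedSpeciesTree, resolution: int) -> DiscretizedSpeciesTree:
    """Build the discretized species tree with the given per-slice resolution."""
    return DiscretizedSpeciesTree(tree, resolution)


def contemporaneous_edges(sd, t: float) -> set:
    """Species edges whose half-open time span contains t."""
    return sd.contemporaneous_edges(t)
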
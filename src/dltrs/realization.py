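"""Sampling, MAP estimation and enumeration of realizations.

A realization maps every internal gene vertex to a grid point of the
discretized species tree together with an event type: ``speciation`` at a
species vertex, ``duplication`` or ``transfer`` at an interior event
point.  A transfer records its donor species edge ('From', the edge the
vertex itself sits on) and the recipient edge ('To', where the emigrant
child lineage starts).  Sampling walks the gene tree in preorder, drawing
each placement conditioned on the parent's placement from the retained DP
table; MAP estimation replaces the DP sums with maxima and back-traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DPTable, GeneArrays, ModelParams, rho_rows, solve_propagation
from .trees import (
    KIND_EVENT,
    KIND_SPECIATION,
    DiscretizedSpeciesTree,
    GeneTree,
    LeafMap,
)

__all__ = [
    "Event",
    "Realization",
    "RealizationPosterior",
    "StaleDPTableError",
    "sample_realization",
    "map_realization",
    "enumerate_realizations",
    "posterior_summary",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
TRANSFER = "transfer"


class StaleDPTableError(RuntimeError):
    """The DP table does not match the (G, l, theta) it is queried for."""


@dataclass(frozen=True)
class Event:
    vertex: int
    point: int
    time: float
    etype: str
    from_edge: int = -1   # donor species edge (transfer only)
    to_edge: int = -1     # recipient species edge (transfer only)
    interval: tuple = (0.0, 0.0)

    def astuple(self):
        return (self.vertex, self.point, self.etype, self.from_edge, self.to_edge)


@dataclass
class Realization:
    """Placement of all internal gene vertices with event types."""

    gene: GeneTree
    grid: DiscretizedSpeciesTree
    events: dict  # vertex -> Event

    def key(self) -> tuple:
        return tuple(self.events[v].astuple() for v in sorted(self.events))

    @property
    def transfers(self) -> list:
        return [e for e in self.events.values() if e.etype == TRANSFER]

    @property
    def n_transfers(self) -> int:
        return len(self.transfers)

    def event_counts(self) -> dict:
        out = {SPECIATION: 0, DUPLICATION: 0, TRANSFER: 0}
        for e in self.events.values():
            out[e.etype] += 1
        return out

    def transfer_clades(self) -> set:
        return {frozenset(self.gene.clade(e.vertex)) for e in self.transfers}

    def transfer_pairs(self) -> set:
        return {(e.from_edge, e.to_edge) for e in self.transfers}

    def validate(self):
        grid = self.grid
        gene = self.gene
        for v in gene.internal:
            if v not in self.events:
                raise AssertionError(f"internal vertex {v} unplaced")
            ev = self.events[v]
            kind = grid.pt_kind[ev.point]
            if (ev.etype == SPECIATION) != (kind == KIND_SPECIATION):
                raise AssertionError("event type inconsistent with point kind")
            if ev.etype != SPECIATION and kind != KIND_EVENT:
                raise AssertionError("duplication/transfer off an event point")
            p = gene.parent[v]
            if p >= 0:
                pe = self.events[int(p)]
                if not ev.time < pe.time:
                    raise AssertionError("child not strictly below its parent")
            if ev.etype == TRANSFER:
                if ev.from_edge == ev.to_edge:
                    raise AssertionError("transfer with From == To")
                if ev.from_edge != grid.pt_edge[ev.point]:
                    raise AssertionError("From is not the vertex's own edge")
                cont = grid.tree.contemporaneous_edges(ev.time)
                if ev.from_edge not in cont or ev.to_edge not in cont:
                    raise AssertionError("transfer edges not contemporaneous")


def _make_event(grid, v, point, etype, from_edge=-1, to_edge=-1):
    return Event(
        vertex=int(v),
        point=int(point),
        time=float(grid.pt_time[point]),
        etype=etype,
        from_edge=int(from_edge),
        to_edge=int(to_edge),
        interval=grid.point_interval(int(point)),
    )


def _check_fresh(dp: DPTable, gene=None, theta=None, leafmap=None):
    if gene is None and theta is None:
        return
    garr = (
        GeneArrays.build(gene, leafmap, dp.grid)
        if gene is not None and leafmap is not None
        else dp.garr
    )
    th = theta if theta is not None else dp.theta
    if DPTable.fingerprint(garr, th) != dp.checksum:
        raise StaleDPTableError("DP table does not match the supplied (G, l, theta)")


# ---------------------------------------------------------------------------
# conditional sampling


def _event_options(dp: DPTable, u: int, y: int):
    """Event sub-terms at placement (u, y): list of
    (weight, etype, from, to, [(child, start_point), ...])."""
    grid = dp.grid
    s = dp.s
    c1, c2 = (int(c) for c in dp.garr.children[u])
    kind = grid.pt_kind[y]
    opts = []
    if kind == KIND_SPECIATION:
        g1, g2 = (int(g) for g in grid.spec_top[y])
        opts.append((s[c1, g1] * s[c2, g2], SPECIATION, -1, -1, [(c1, g1), (c2, g2)]))
        opts.append((s[c1, g2] * s[c2, g1], SPECIATION, -1, -1, [(c1, g2), (c2, g1)]))
    elif kind == KIND_EVENT:
        delta, tau = dp.theta.delta, dp.theta.tau
        opts.append(
            (2.0 * delta * s[c1, y] * s[c2, y], DUPLICATION, -1, -1, [(c1, y), (c2, y)])
        )
        lo, hi = int(grid.trans_off[y]), int(grid.trans_off[y + 1])
        if hi > lo and tau > 0.0:
            w = tau / (hi - lo)
            e_from = int(grid.pt_edge[y])
            for q in range(lo, hi):
                yp = int(grid.trans_idx[q])
                e_to = int(grid.pt_edge[yp])
                opts.append(
                    (w * s[c1, y] * s[c2, yp], TRANSFER, e_from, e_to, [(c1, y), (c2, yp)])
                )
                opts.append(
                    (w * s[c1, yp] * s[c2, y], TRANSFER, e_from, e_to, [(c1, yp), (c2, y)])
                )
    return opts


def _placement_weights(dp: DPTable, u: int, sp: int) -> np.ndarray:
    """Unnormalised conditional weights over placements of internal vertex
    u whose lineage starts at grid point sp."""
    grid = dp.grid
    P = dp.prop.matrix
    tix = int(grid.pt_tidx[sp])
    w = P[sp] * dp.aD[u]
    below = grid.pt_time < grid.pt_time[sp]
    w = np.where(below, w, 0.0)
    nz = np.flatnonzero(w > 0)
    out = np.zeros_like(w)
    if len(nz):
        out[nz] = w[nz] * dp.rho[u, grid.dt_index[tix, grid.pt_tidx[nz]]]
    return out


def sample_realization(
    dp: DPTable,
    rng: np.random.Generator,
    gene: GeneTree | None = None,
    theta: ModelParams | None = None,
    leafmap: LeafMap | None = None,
) -> Realization:
    """Draw one realization from its exact conditional distribution given
    (G, l, theta) using the retained DP table."""
    _check_fresh(dp, gene, theta, leafmap)
    grid = dp.grid
    garr = dp.garr
    if dp.log_density == -np.inf:
        raise ValueError("cannot sample a realization from a zero-density family")
    events = {}
    root = garr.root
    w = dp.prop.matrix[grid.stem_point] * dp.aD[root]
    y = int(rng.choice(len(w), p=w / w.sum()))
    stack = [(root, y)]
    while stack:
        u, y = stack.pop()
        opts = _event_options(dp, u, y)
        wts = np.array([o[0] for o in opts])
        total = wts.sum()
        if total <= 0:
            raise RuntimeError("no feasible event at sampled placement")
        _, etype, e_from, e_to, starts = opts[int(rng.choice(len(opts), p=wts / total))]
        events[u] = _make_event(grid, u, y, etype, e_from, e_to)
        for child, sp in starts:
            if garr.children[child, 0] < 0:
                continue  # leaf, implicitly mapped
            cw = _placement_weights(dp, child, sp)
            tot = cw.sum()
            if tot <= 0:
                raise RuntimeError("no feasible placement for child vertex")
            stack.append((child, int(rng.choice(len(cw), p=cw / tot))))
    gene_obj = gene if gene is not None else _gene_from_arrays(garr)
    return Realization(gene_obj, grid, events)


def _gene_from_arrays(garr: GeneArrays) -> GeneTree:
    labels = [None] * len(garr.parent)
    # recover leaf labels from the grid is not possible here; keep ids
    for v in range(len(garr.parent)):
        if garr.children[v, 0] < 0:
            labels[v] = f"leaf{v}"
    return GeneTree(garr.parent, garr.children, garr.lengths, labels)


# ---------------------------------------------------------------------------
# MAP realization


def map_realization(
    dp: DPTable,
    gene: GeneTree | None = None,
    theta: ModelParams | None = None,
    leafmap: LeafMap | None = None,
):
    """Maximum a posteriori realization by max-product DP with backtrace.

    Returns (realization, log joint contribution log p(G, l, d) Delta(d)).
    """
    _check_fresh(dp, gene, theta, leafmap)
    grid = dp.grid
    garr = dp.garr
    P = dp.prop.matrix
    n = grid.n_points
    ng = len(garr.parent)
    delta, tau = dp.theta.delta, dp.theta.tau
    NEG = -np.inf

    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), NEG)
        logrho = np.where(dp.rho > 0, np.log(np.maximum(dp.rho, 1e-300)), NEG)

    smax = np.full((ng, n), NEG)
    amax = np.full((ng, n), NEG)
    achoice = [[None] * n for _ in range(ng)]
    schoice = np.full((ng, n), -1, dtype=np.int64)

    for u in garr.postorder:
        u = int(u)
        c1, c2 = (int(c) for c in garr.children[u])
        if c1 < 0:
            lp = int(garr.leaf_pt[u])
            for x in range(n):
                if x != lp and P[x, lp] > 0:
                    smax[u, x] = (
                        logP[x, lp]
                        + logrho[u, grid.dt_index[grid.pt_tidx[x], grid.pt_tidx[lp]]]
                    )
            continue
        for y in range(n):
            kind = grid.pt_kind[y]
            best, pick = NEG, None
            if kind == KIND_SPECIATION:
                g1, g2 = (int(g) for g in grid.spec_top[y])
                o1 = smax[c1, g1] + smax[c2, g2]
                o2 = smax[c1, g2] + smax[c2, g1]
                if o1 >= o2:
                    best, pick = o1, (SPECIATION, -1, -1, [(c1, g1), (c2, g2)])
                else:
                    best, pick = o2, (SPECIATION, -1, -1, [(c1, g2), (c2, g1)])
            elif kind == KIND_EVENT and grid.pt_delta[y] > 0:
                ld = math.log(grid.pt_delta[y])
                if delta > 0:
                    cand = math.log(2 * delta) + smax[c1, y] + smax[c2, y] + ld
                    if cand > best:
                        best, pick = cand, (DUPLICATION, -1, -1, [(c1, y), (c2, y)])
                lo, hi = int(grid.trans_off[y]), int(grid.trans_off[y + 1])
                if hi > lo and tau > 0:
                    lw = math.log(tau / (hi - lo)) + ld
                    e_from = int(grid.pt_edge[y])
                    for q in range(lo, hi):
                        yp = int(grid.trans_idx[q])
                        e_to = int(grid.pt_edge[yp])
                        cand = lw + smax[c1, y] + smax[c2, yp]
                        if cand > best:
                            best, pick = cand, (TRANSFER, e_from, e_to, [(c1, y), (c2, yp)])
                        cand = lw + smax[c1, yp] + smax[c2, y]
                        if cand > best:
                            best, pick = cand, (TRANSFER, e_from, e_to, [(c1, yp), (c2, y)])
            amax[u, y] = best
            achoice[u][y] = pick
        if u == garr.root:
            continue
        for x in range(n):
            tix = int(grid.pt_tidx[x])
            tx = grid.pt_time[x]
            best, arg = NEG, -1
            for y in range(n):
                if P[x, y] > 0 and grid.pt_time[y] < tx and amax[u, y] > NEG:
                    cand = (
                        logP[x, y]
                        + logrho[u, grid.dt_index[tix, grid.pt_tidx[y]]]
                        + amax[u, y]
                    )
                    if cand > best:
                        best, arg = cand, y
            smax[u, x] = best
            schoice[u, x] = arg

    root = int(garr.root)
    rootw = logP[grid.stem_point] + amax[root]
    y0 = int(np.argmax(rootw))
    best_log = float(rootw[y0])
    if not np.isfinite(best_log):
        raise ValueError("no feasible realization (zero density)")

    events = {}
    stack = [(root, y0)]
    while stack:
        u, y = stack.pop()
        etype, e_from, e_to, starts = achoice[u][y]
        events[u] = _make_event(grid, u, y, etype, e_from, e_to)
        for child, sp in starts:
            if garr.children[child, 0] < 0:
                continue
            stack.append((child, int(schoice[child, sp])))
    gene_obj = gene if gene is not None else _gene_from_arrays(garr)
    return Realization(gene_obj, grid, events), best_log


# ---------------------------------------------------------------------------
# exhaustive enumeration (test oracle for the quadrature sum)


def enumerate_realizations(
    gene: GeneTree,
    leafmap: LeafMap,
    grid: DiscretizedSpeciesTree,
    theta: ModelParams,
    tol: float = 1e-8,
    max_points: int = 60,
    prop=None,
):
    """Every valid realization with its exact score p(G, l, d) Delta(d).

    The score sum equals the quadrature gene-tree density.  Guarded to
    small instances; intended as a brute-force oracle.  Pass the same
    ``prop`` table used for the density to compare to round-off precision.
    """
    if gene.n_vertices > 9:
        raise ValueError("enumeration guarded to gene trees with <= 9 vertices")
    if grid.n_points > max_points:
        raise ValueError(f"enumeration guarded to grids with <= {max_points} points")
    garr = GeneArrays.build(gene, leafmap, grid)
    if prop is None:
        prop = solve_propagation(grid, theta, tol=tol)
    P = prop.matrix
    rho = rho_rows(garr.lengths, grid.dt_values, theta.m, theta.cv)
    n = grid.n_points
    delta, tau = theta.delta, theta.tau
    memo = {}

    def events_at(u, z):
        c1, c2 = (int(c) for c in garr.children[u])
        kind = grid.pt_kind[z]
        out = []
        if kind == KIND_SPECIATION:
            g1, g2 = (int(g) for g in grid.spec_top[z])
            ev = (u, z, SPECIATION, -1, -1)
            out.append((ev, 1.0, [(c1, g1), (c2, g2)]))
            out.append((ev, 1.0, [(c1, g2), (c2, g1)]))
        elif kind == KIND_EVENT and grid.pt_delta[z] > 0:
            d = grid.pt_delta[z]
            if delta > 0:
                out.append(
                    ((u, z, DUPLICATION, -1, -1), 2.0 * delta * d, [(c1, z), (c2, z)])
                )
            lo, hi = int(grid.trans_off[z]), int(grid.trans_off[z + 1])
            if hi > lo and tau > 0:
                w = tau / (hi - lo) * d
                e_from = int(grid.pt_edge[z])
                for q in range(lo, hi):
                    yp = int(grid.trans_idx[q])
                    ev = (u, z, TRANSFER, e_from, int(grid.pt_edge[yp]))
                    out.append((ev, w, [(c1, z), (c2, yp)]))
                    out.append((ev, w, [(c1, yp), (c2, z)]))
        return out

    def sub(u, sp):
        """Completions of the subtree of u whose lineage starts at sp,
        including the length factor of the edge above u."""
        key = (u, sp)
        if key in memo:
            return memo[key]
        out = []
        if garr.children[u, 0] < 0:
            lp = int(garr.leaf_pt[u])
            if sp != lp and P[sp, lp] > 0:
                fac = P[sp, lp] * rho[u, grid.dt_index[grid.pt_tidx[sp], grid.pt_tidx[lp]]]
                if fac > 0:
                    out.append(((), fac))
        else:
            for z in range(n):
                if z == sp or P[sp, z] <= 0 or grid.pt_time[z] >= grid.pt_time[sp]:
                    continue
                edge_fac = P[sp, z] * rho[
                    u, grid.dt_index[grid.pt_tidx[sp], grid.pt_tidx[z]]
                ]
                if edge_fac <= 0:
                    continue
                for ev, fac, starts in events_at(u, z):
                    (v, sv), (w, sw) = starts
                    for ev1, s1 in sub(v, sv):
                        for ev2, s2 in sub(w, sw):
                            out.append(
                                ((ev,) + ev1 + ev2, edge_fac * fac * s1 * s2)
                            )
        memo[key] = out
        return out

    root = int(garr.root)
    results = []
    for z in range(n):
        pz = P[grid.stem_point, z]
        if z == grid.stem_point or pz <= 0:
            continue
        for ev, fac, starts in events_at(root, z):
            (v, sv), (w, sw) = starts
            for ev1, s1 in sub(v, sv):
                for ev2, s2 in sub(w, sw):
                    score = pz * fac * s1 * s2
                    if score > 0:
                        events = {
                            e[0]: _make_event(grid, e[0], e[1], e[2], e[3], e[4])
                            for e in (ev,) + ev1 + ev2
                        }
                        results.append((Realization(gene, grid, events), score))
    return results


# ---------------------------------------------------------------------------
# posterior over realizations


@dataclass
class RealizationPosterior:
    """Uniformly weighted posterior draws of realizations."""

    samples: list

    def __post_init__(self):
        if not self.samples:
            raise ValueError("empty realization posterior")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n, 1.0 / self.n)


def posterior_summary(post: RealizationPosterior, threshold: float = 0.5) -> dict:
    """Expected transfer count, per-vertex transfer probabilities (keyed by
    gene clade), per ordered (From, To) species-edge pair probabilities,
    and the thresholded event list."""
    n = post.n
    counts = [r.n_transfers for r in post.samples]
    clade_hits = {}
    pair_hits = {}
    for r in post.samples:
        for cl in r.transfer_clades():
            clade_hits[cl] = clade_hits.get(cl, 0) + 1
        for pair in r.transfer_pairs():
            pair_hits[pair] = pair_hits.get(pair, 0) + 1
    vertex_probs = {cl: h / n for cl, h in clade_hits.items()}
    pair_probs = {p: h / n for p, h in pair_hits.items()}
    count_dist = {}
    for c in counts:
        count_dist[c] = count_dist.get(c, 0) + 1.0 / n
    return {
        "n_samples": n,
        "expected_transfers": float(np.mean(counts)),
        "transfer_count_distribution": count_dist,
        "vertex_transfer_probs": vertex_probs,
        "pair_probs": pair_probs,
        "thresholded_pairs": sorted(
            p for p, v in pair_probs.items() if v >= threshold
        ),
        "threshold": threshold,
    }
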
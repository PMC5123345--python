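"""Forward simulation of gene families under the DLT process.

The simulator is grid-free: events happen in continuous time at
exponential waiting times, with the transfer rate suppressed whenever the
lineage's edge has no contemporaneous partner (on the stem).  Duplication
keeps both children on the edge; a transfer keeps one child on the donor
edge ('From') and moves the other to a recipient edge ('To') drawn
uniformly from the other contemporaneous edges; a loss ends the lineage
and its former parent is suppressed on pruning.  Lineages reaching a
speciation vertex split deterministically; lineages reaching a species
leaf become extant gene copies.

The recorded truth is a continuous realization: exact event times and
species-edge placements for every surviving gene vertex, donor/recipient
edges per transfer, and the per-edge substitution rates drawn by the
relaxed clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ModelParams
from .seqmodel import BASES, MSA, SubstitutionModel, JC69
from .trees import DatedSpeciesTree, GeneTree, LeafMap

__all__ = [
    "SimNode",
    "TrueEvent",
    "TrueHistory",
    "simulate_dlt",
    "prune_extinct",
    "relax_clock",
    "simulate_sequences",
    "simulate_family",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
TRANSFER = "transfer"
LOSS = "loss"
LEAF = "leaf"


@dataclass
class SimNode:
    """One gene lineage segment, living on a single species edge from
    ``birth_time`` down to ``end_time`` where its event happens."""

    id: int
    parent: int
    species_edge: int
    birth_time: float
    end_time: float = np.nan
    etype: str = ""
    children: list = field(default_factory=list)
    from_edge: int = -1
    to_edge: int = -1
    surviving: bool = False


@dataclass(frozen=True)
class TrueEvent:
    species_edge: int
    time: float
    etype: str
    from_edge: int = -1
    to_edge: int = -1


@dataclass
class TrueHistory:
    """Full simulated history plus the pruned observable family."""

    species: DatedSpeciesTree
    theta: ModelParams
    nodes: list
    root_node: int
    pruned: GeneTree | None = None
    leafmap: LeafMap | None = None
    truth_events: dict | None = None   # pruned internal vertex -> TrueEvent
    leaf_times: dict | None = None
    rates: np.ndarray | None = None

    @property
    def n_surviving_leaves(self) -> int:
        return sum(1 for nd in self.nodes if nd.etype == LEAF)

    @property
    def usable(self) -> bool:
        return self.pruned is not None

    @property
    def n_true_transfers(self) -> int:
        if self.truth_events is None:
            return 0
        return sum(1 for e in self.truth_events.values() if e.etype == TRANSFER)


class LineageCapExceeded(RuntimeError):
    pass


def _next_boundary(tree: DatedSpeciesTree, t: float) -> float:
    """Largest species-vertex time strictly below t (0 for none)."""
    best = 0.0
    for v in range(tree.n_vertices):
        tv = float(tree.times[v])
        if best < tv < t:
            best = tv
    return best


def simulate_dlt(
    tree: DatedSpeciesTree,
    theta: ModelParams,
    rng: np.random.Generator,
    lineage_cap: int = 100_000,
) -> TrueHistory:
    """Run the DLT birth-death-transfer process from a single lineage at
    the stem tip down to the species leaves."""
    nodes: list = []

    def new_node(parent, edge, t):
        if len(nodes) >= lineage_cap:
            raise LineageCapExceeded(f"more than {lineage_cap} gene lineages")
        nd = SimNode(id=len(nodes), parent=parent, species_edge=edge, birth_time=t)
        nodes.append(nd)
        if parent >= 0:
            nodes[parent].children.append(nd.id)
        return nd.id

    root_id = new_node(-1, tree.root, tree.origin_time)
    stack = [root_id]
    while stack:
        i = stack.pop()
        nd = nodes[i]
        e = nd.species_edge
        t = nd.birth_time
        edge_bottom = float(tree.times[e])
        while True:
            lo = max(edge_bottom, _next_boundary(tree, t))
            cont = tree.contemporaneous_edges(max(lo, min(t, tree.origin_time) - 1e-15))
            k = len(cont)
            tau_eff = theta.tau if k > 1 else 0.0
            rate = theta.delta + theta.mu + tau_eff
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if t - wait > lo:
                te = t - wait
                u = rng.random() * rate
                nd.end_time = te
                if u < theta.delta:
                    nd.etype = DUPLICATION
                    stack.append(new_node(i, e, te))
                    stack.append(new_node(i, e, te))
                elif u < theta.delta + theta.mu:
                    nd.etype = LOSS
                else:
                    others = sorted(cont - {e})
                    f = others[int(rng.integers(len(others)))]
                    nd.etype = TRANSFER
                    nd.from_edge = e
                    nd.to_edge = f
                    stack.append(new_node(i, e, te))   # resident
                    stack.append(new_node(i, f, te))   # emigrant
                break
            t = lo
            if t > edge_bottom:
                continue  # only the contemporaneous-edge count changed
            if tree.is_leaf(e):
                nd.end_time = 0.0
                nd.etype = LEAF
                break
            nd.end_time = t
            nd.etype = SPECIATION
            c1, c2 = (int(c) for c in tree.children[e])
            stack.append(new_node(i, c1, t))
            stack.append(new_node(i, c2, t))
            break

    return TrueHistory(species=tree, theta=theta, nodes=nodes, root_node=root_id)


def prune_extinct(history: TrueHistory) -> TrueHistory:
    """Remove extinct subtrees and suppress out-degree-1 vertices, keeping
    the continuous realization of the surviving vertices.  Families with
    fewer than two surviving leaves are left with ``pruned=None``."""
    nodes = history.nodes
    tree = history.species
    for nd in reversed(nodes):  # children have larger ids than parents
        if nd.etype == LEAF:
            nd.surviving = True
        else:
            nd.surviving = any(nodes[c].surviving for c in nd.children)

    def observable(i):
        """Descend through suppressed vertices to the next observable one."""
        nd = nodes[i]
        while True:
            alive = [c for c in nd.children if nodes[c].surviving]
            if nd.etype == LEAF or len(alive) >= 2:
                return nd
            nd = nodes[alive[0]]

    if not nodes[history.root_node].surviving:
        return history
    top = observable(history.root_node)
    if top.etype == LEAF:
        return history  # single surviving copy: unusable family

    parent, children, labels, obs_nodes = [], [], [], []

    def build(nd, par):
        idx = len(parent)
        parent.append(par)
        children.append([-1, -1])
        labels.append(None)
        obs_nodes.append(nd)
        if nd.etype == LEAF:
            labels[idx] = f"g{nd.id}_{tree.labels[nd.species_edge]}"
        else:
            alive = [observable(c) for c in nd.children if nodes[c].surviving]
            children[idx][0] = build(alive[0], idx)
            children[idx][1] = build(alive[1], idx)
        return idx

    build(top, -1)
    ng = len(parent)
    gene = GeneTree(parent, children, np.zeros(ng), labels)
    truth, leaf_times, mapping = {}, {}, {}
    for v, nd in enumerate(obs_nodes):
        if nd.etype == LEAF:
            mapping[labels[v]] = tree.labels[nd.species_edge]
            leaf_times[v] = 0.0
        else:
            truth[v] = TrueEvent(
                species_edge=nd.species_edge,
                time=nd.end_time,
                etype=nd.etype,
                from_edge=nd.from_edge,
                to_edge=nd.to_edge,
            )
    history.pruned = gene
    history.leafmap = LeafMap(mapping)
    history.truth_events = truth
    history.leaf_times = leaf_times
    return history


def edge_durations(history: TrueHistory) -> np.ndarray:
    gene = history.pruned
    out = np.zeros(gene.n_vertices)
    for v in range(gene.n_vertices):
        if v == gene.root:
            continue
        t_self = 0.0 if gene.is_leaf(v) else history.truth_events[v].time
        t_par = history.truth_events[int(gene.parent[v])].time
        out[v] = t_par - t_self
    return out


def relax_clock(
    history: TrueHistory, m: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw iid gamma edge rates (mean m, coefficient of variation cv) and
    turn the pruned tree's time durations into substitution lengths."""
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if history.pruned is None:
        raise ValueError("no observable family to relax")
    gene = history.pruned
    dur = edge_durations(history)
    shape = 1.0 / (cv * cv)
    scale = m * cv * cv
    rates = rng.gamma(shape, scale, size=gene.n_vertices)
    rates[gene.root] = 0.0
    gene.lengths = rates * dur
    history.rates = rates
    return gene.lengths


def simulate_sequences(
    gene: GeneTree,
    lengths: np.ndarray | None,
    model: SubstitutionModel | None,
    n_sites: int,
    rng: np.random.Generator,
) -> MSA:
    """Evolve sequences down the gene tree; no indels."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    model = model or JC69()
    lengths = gene.lengths if lengths is None else np.asarray(lengths, float)
    seqs = {}
    codes = np.empty((gene.n_vertices, n_sites), dtype=np.int64)
    order = gene.postorder()[::-1]  # preorder
    cum_f = np.cumsum(model.freqs)
    codes[gene.root] = np.searchsorted(cum_f, rng.random(n_sites))
    for v in order:
        if v == gene.root:
            continue
        P = model.transition(float(lengths[v]))
        probs = P[codes[int(gene.parent[v])]]
        u = rng.random(n_sites)
        codes[v] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    for v in gene.leaves:
        seqs[gene.labels[v]] = "".join(BASES[c] for c in codes[v])
    return MSA.from_strings(seqs)


@dataclass
class Family:
    """One simulated gene family with its recorded truth."""

    msa: MSA
    gene: GeneTree
    leafmap: LeafMap
    history: TrueHistory
    attempts: int


def simulate_family(
    tree: DatedSpeciesTree,
    theta: ModelParams,
    n_sites: int,
    rng: np.random.Generator,
    require_transfer: bool = False,
    min_leaves: int = 2,
    max_leaves: int = 50,
    max_attempts: int = 10_000,
    model: SubstitutionModel | None = None,
) -> Family:
    """Simulate until a usable family appears.

    ``require_transfer`` resamples until at least one transfer survives in
    the observable tree; this conditions the process and is recorded via
    the attempt count.
    """
    if require_transfer and theta.tau <= 0:
        raise ValueError("require_transfer is unsatisfiable with tau == 0")
    for attempt in range(1, max_attempts + 1):
        h = prune_extinct(simulate_dlt(tree, theta, rng))
        if not h.usable:
            continue
        nl = len(h.pruned.leaves)
        if nl < min_leaves or nl > max_leaves:
            continue
        if require_transfer and h.n_true_transfers < 1:
            continue
        relax_clock(h, theta.m, theta.cv, rng)
        msa = simulate_sequences(h.pruned, None, model, n_sites, rng)
        return Family(msa, h.pruned, h.leafmap, h, attempt)
    raise RuntimeError(f"no usable family in {max_attempts} attempts")
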
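"""Metropolis-Hastings sampling of (G, l, theta) given sequences and a
dated species tree.

The target is p(G, l, theta | D, S) proportional to
P(D | G, l) * p(G, l | theta, S) * p(theta); the normalising constant
P(D | S) is never evaluated — it cancels in every acceptance ratio.
Realizations are integrated out of the chain state (Rao-Blackwellised)
and sampled post hoc for selected trace entries.

Move mixture: rooted NNI / SPR on the gene-tree topology, multiplicative
log-normal updates of one edge length, and multiplicative log-normal
updates of one model parameter.  Priors on theta are uniform and
independent on bounded supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from . import _kernels
from .core import ModelParams, compute_tables, rho_row, rho_rows
from .seqmodel import MSA, SubstitutionModel, JC69, leaf_partials
from .trees import (
    DatedSpeciesTree,
    DiscretizedSpeciesTree,
    GeneTree,
    LeafMap,
    discretize,
)

__all__ = ["MCMCConfig", "ChainState", "Trace", "FamilySampler", "run_chain"]

PARAM_NAMES = ("delta", "mu", "tau", "m", "cv")
DEFAULT_BOUNDS = {
    "delta": (0.0, 10.0),
    "mu": (0.0, 10.0),
    "tau": (0.0, 10.0),
    "m": (1e-9, 10.0),
    "cv": (1e-9, 5.0),
}


@dataclass
class MCMCConfig:
    iterations: int = 100_000
    thinning: int = 100
    resolution: int = 5
    stem: float | None = None          # stem duration; default 10% of height
    move_weights: tuple = (0.3, 0.4, 0.3)  # topology, lengths, parameters
    spr_fraction: float = 0.3
    sigma_length: float = 0.5
    sigma_param: float = 0.4
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    init_theta: ModelParams | None = None  # default: midpoints of the bounds
    fixed_params: tuple = ()            # parameter names held at their init value
    ode_tol: float = 1e-6
    min_init_length: float = 1e-3

    @classmethod
    def from_file(cls, path) -> "MCMCConfig":
        """key=value config; unknown keys rejected."""
        cfg = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if not hasattr(cfg, key):
                    raise KeyError(f"unknown config key {key!r}")
                cur = getattr(cfg, key)
                if isinstance(cur, int):
                    setattr(cfg, key, int(val))
                elif isinstance(cur, float) or cur is None:
                    setattr(cfg, key, float(val))
                else:
                    raise KeyError(f"config key {key!r} not settable from file")
        return cfg

    def midpoint_theta(self) -> ModelParams:
        vals = []
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            vals.append((lo + hi) / 2.0)
        return ModelParams(*vals)


@dataclass
class ChainState:
    """Current chain state with cached log densities."""

    children: np.ndarray
    parent: np.ndarray
    postorder: np.ndarray
    lengths: np.ndarray
    theta: np.ndarray          # (5,) delta, mu, tau, m, cv
    log_seq: float
    log_tree: float

    @property
    def log_joint(self) -> float:
        return self.log_seq + self.log_tree

    def theta_params(self) -> ModelParams:
        return ModelParams.from_array(self.theta)


@dataclass
class Trace:
    """Thinned MCMC output."""

    table: pd.DataFrame         # iteration, theta, log densities, newick
    thinning: int
    burn_in: int = 0
    best_newick: str = ""
    best_theta: ModelParams | None = None
    best_log_joint: float = -np.inf
    acceptance: dict | None = None

    def post_burn_in(self) -> pd.DataFrame:
        return self.table.iloc[self.burn_in:]

    def to_tsv(self, target):
        self.table.to_csv(target, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source, thinning=None) -> "Trace":
        tab = pd.read_csv(source, sep="\t")
        th = thinning
        if th is None:
            its = tab["iteration"].to_numpy()
            th = int(its[1] - its[0]) if len(its) > 1 else 1
        return cls(tab, th)

    def map_topology(self) -> str:
        """Most frequent post-burn-in topology; ties broken by the higher
        mean joint log density."""
        tab = self.post_burn_in()
        joint = tab["log_seq"] + tab["log_tree"]
        stats = (
            pd.DataFrame({"topo": tab["topology"], "joint": joint})
            .groupby("topo")["joint"]
            .agg(["count", "mean"])
            .sort_values(["count", "mean"], ascending=False)
        )
        return str(stats.index[0])


def mh_chain(
    logpdf,
    x0: float,
    sigma: float,
    n: int,
    rng: np.random.Generator,
    kernel: str = "multiplicative",
):
    """Scalar Metropolis-Hastings chain with the package's proposal
    kernels: ``multiplicative`` (log-normal scaling, Hastings factor
    x'/x — the kernel used for lengths and parameters) or ``additive``
    (symmetric normal).  Returns (samples, acceptance_rate)."""
    x = float(x0)
    lp = logpdf(x)
    out = np.empty(n)
    accepted = 0
    for i in range(n):
        if kernel == "multiplicative":
            xn = x * math.exp(sigma * rng.standard_normal())
            logh = math.log(xn / x)
        else:
            xn = x + sigma * rng.standard_normal()
            logh = 0.0
        lpn = logpdf(xn)
        if math.log(rng.random()) < lpn - lp + logh:
            x, lp = xn, lpn
            accepted += 1
        out[i] = x
    return out, accepted / n


# ---------------------------------------------------------------------------
# initial state: UPGMA on JC-corrected distances


def jc_distance_matrix(msa: MSA, order: list) -> np.ndarray:
    idx = [msa.labels.index(l) for l in order]
    codes = msa.codes[idx]
    n = len(order)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4)
            tot = int(ok.sum())
            p = float(((codes[i] != codes[j]) & ok).sum()) / tot if tot else 0.0
            p = min(p, 0.70)  # keep the JC correction finite
            D[i, j] = D[j, i] = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return D


def upgma_gene_tree(msa: MSA, min_length: float = 1e-3) -> GeneTree:
    """Rooted binary starting tree with lengths from the distance fit."""
    labels = sorted(msa.labels)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    D = jc_distance_matrix(msa, labels)
    iu = np.triu_indices(len(labels), 1)
    Z = linkage(D[iu], method="average")
    n = len(labels)
    ng = 2 * n - 1
    parent = np.full(ng, -1, dtype=np.int64)
    children = np.full((ng, 2), -1, dtype=np.int64)
    heights = np.zeros(ng)
    node_labels = list(labels) + [None] * (n - 1)
    for k, (a, b, dist, _) in enumerate(Z):
        v = n + k
        a, b = int(a), int(b)
        children[v] = (a, b)
        parent[a] = parent[b] = v
        heights[v] = dist / 2.0
    lengths = np.zeros(ng)
    for v in range(ng):
        if parent[v] >= 0:
            lengths[v] = max(heights[parent[v]] - heights[v], min_length)
    return GeneTree(parent, children, lengths, node_labels)


# ---------------------------------------------------------------------------
# the per-family sampler


def _postorder(children: np.ndarray, root: int) -> np.ndarray:
    order, stack = [], [(root, False)]
    while stack:
        v, done = stack.pop()
        if done or children[v, 0] < 0:
            order.append(v)
        else:
            stack.append((v, True))
            stack.append((int(children[v, 1]), False))
            stack.append((int(children[v, 0]), False))
    return np.array(order, dtype=np.int64)


class FamilySampler:
    """MH sampler for one gene family on one species tree."""

    def __init__(
        self,
        msa: MSA,
        species: DatedSpeciesTree,
        leafmap: LeafMap,
        config: MCMCConfig | None = None,
        model: SubstitutionModel | None = None,
        grid: DiscretizedSpeciesTree | None = None,
    ):
        self.config = config or MCMCConfig()
        self.msa = msa
        self.species = species
        self.leafmap = leafmap
        self.model = model or JC69()
        if grid is None:
            tree = species
            if self.config.stem is not None:
                tree = DatedSpeciesTree(
                    species.parent, species.children, species.times,
                    species.labels, self.config.stem,
                )
            grid = discretize(tree, self.config.resolution)
        self.grid = grid

        init = upgma_gene_tree(msa, self.config.min_init_length)
        self.root = init.root
        self.labels = init.labels
        self.leaf_pt = np.full(init.n_vertices, -1, dtype=np.int64)
        for v in init.leaves:
            lbl = init.labels[v]
            if lbl not in leafmap.mapping:
                raise KeyError(f"gene leaf {lbl!r} missing from leaf map")
            sp = self.grid.tree.leaf_index(leafmap[lbl])
            self.leaf_pt[v] = self.grid.vertex_point[sp]

        order = [init.labels[v] for v in init.leaves]
        self.patterns, self.pat_weights = msa.patterns(order)
        self._leaf_partials = leaf_partials(
            self.patterns, init.n_vertices, {v: i for i, v in enumerate(init.leaves)}
        )
        self._partials_buf = np.empty_like(self._leaf_partials)

        theta0 = self.config.init_theta or self.config.midpoint_theta()
        self._set_tables(theta0.delta, theta0.mu, theta0.tau)
        self._rho = rho_rows(
            init.lengths, self.grid.dt_values, theta0.m, theta0.cv
        )
        self._tprob = self.model.transitions(init.lengths)
        state = ChainState(
            children=init.children.copy(),
            parent=init.parent.copy(),
            postorder=_postorder(init.children, self.root),
            lengths=init.lengths.copy(),
            theta=theta0.as_array(),
            log_seq=0.0,
            log_tree=0.0,
        )
        state.log_seq = self._log_seq(state)
        state.log_tree = self._log_tree(state)
        self.state = state

    # -- cached table management ------------------------------------
    def _set_tables(self, delta, mu, tau):
        grid = self.grid
        ext, cum = compute_tables(
            grid, ModelParams(delta, mu, tau, 1.0, 1.0), self.config.ode_tol
        )
        fac = np.zeros(grid.n_points)
        ok = grid.down >= 0
        fac[ok] = np.exp(cum[grid.down[ok]] - cum[ok])
        self._ext = ext
        self._P = _kernels.build_p11(
            grid.p11_order, grid.pt_kind, grid.down, fac, grid.spec_top, ext
        )
        self._rates_key = (delta, mu, tau)

    # -- log densities ------------------------------------------------
    def _log_seq(self, state: ChainState) -> float:
        np.copyto(self._partials_buf, self._leaf_partials)
        return float(
            _kernels.peeling(
                state.postorder,
                state.children,
                self._tprob,
                self._partials_buf,
                self.pat_weights,
                self.model.freqs,
                self.root,
            )
        )

    def _log_tree(self, state: ChainState) -> float:
        g = self.grid
        logdens, *_ = _kernels.density_dp(
            self._P,
            g.pt_time,
            g.pt_delta,
            g.pt_kind,
            g.pt_tidx,
            g.spec_top,
            g.trans_off,
            g.trans_idx,
            g.stem_point,
            g.dt_index,
            self._rho,
            state.postorder,
            state.children,
            self.leaf_pt,
            self.root,
            state.theta[0],
            state.theta[2],
        )
        return float(logdens)

    # -- proposals -----------------------------------------------------
    def _propose_length(self, rng):
        state = self.state
        cand = np.flatnonzero(np.arange(len(state.lengths)) != self.root)
        v = int(cand[rng.integers(len(cand))])
        old = state.lengths[v]
        new = old * math.exp(self.config.sigma_length * rng.standard_normal())
        return v, new, math.log(new / old)

    def _propose_param(self, rng):
        names = [n for n in PARAM_NAMES if n not in self.config.fixed_params]
        i = PARAM_NAMES.index(names[int(rng.integers(len(names)))])
        old = self.state.theta[i]
        if old <= 0:  # boundary-started rate: re-seed from a small value
            old = 1e-6
        new = old * math.exp(self.config.sigma_param * rng.standard_normal())
        lo, hi = self.config.bounds[PARAM_NAMES[i]]
        if not (lo <= new <= hi):
            return None
        return i, new, math.log(new / self.state.theta[i]) if self.state.theta[i] > 0 else 0.0

    def _eligible_nni(self, children, parent):
        return [
            v
            for v in range(len(parent))
            if children[v, 0] >= 0 and parent[v] >= 0
        ]

    def _propose_nni(self, rng):
        state = self.state
        children = state.children.copy()
        parent = state.parent.copy()
        cand = self._eligible_nni(children, parent)
        if not cand:
            return None
        v = cand[int(rng.integers(len(cand)))]
        p = int(parent[v])
        sib = int(children[p, 0]) if int(children[p, 1]) == v else int(children[p, 1])
        ci = int(rng.integers(2))
        c = int(children[v, ci])
        # swap c and sib
        children[v, ci] = sib
        parent[sib] = v
        if int(children[p, 0]) == sib:
            children[p, 0] = c
        else:
            children[p, 1] = c
        parent[c] = p
        return children, parent, np.copy(state.lengths), 0.0

    def _subtree(self, children, u):
        out, stack = set(), [u]
        while stack:
            x = stack.pop()
            out.add(x)
            if children[x, 0] >= 0:
                stack.extend(int(c) for c in children[x])
        return out

    def _propose_spr(self, rng):
        state = self.state
        children = state.children.copy()
        parent = state.parent.copy()
        lengths = state.lengths.copy()
        n = len(parent)
        cand = [
            v for v in range(n) if parent[v] >= 0 and parent[int(parent[v])] >= 0
        ]
        if not cand:
            return None
        u = cand[int(rng.integers(len(cand)))]
        p = int(parent[u])
        g = int(parent[p])
        s = int(children[p, 0]) if int(children[p, 1]) == u else int(children[p, 1])
        sub = self._subtree(children, u)
        targets = [w for w in range(n) if w not in sub and w != p and parent[w] >= 0]
        if not targets:
            return None
        w = targets[int(rng.integers(len(targets)))]
        # detach p: s takes p's place under g
        combined = lengths[s] + lengths[p]
        for slot in range(2):
            if int(children[g, slot]) == p:
                children[g, slot] = s
        parent[s] = g
        lengths[s] = combined
        if w == s:
            wlen_orig = combined
        else:
            wlen_orig = lengths[w]
        # reinsert p on the edge above w
        a = rng.random()
        gw = int(parent[w])
        for slot in range(2):
            if int(children[gw, slot]) == w:
                children[gw, slot] = p
        parent[p] = gw
        for slot in range(2):
            if int(children[p, slot]) == s:
                children[p, slot] = w
        parent[w] = p
        lengths[p] = (1.0 - a) * wlen_orig
        lengths[w] = a * wlen_orig
        log_hastings = math.log(wlen_orig) - math.log(combined)
        return children, parent, lengths, log_hastings

    # -- one MH step ----------------------------------------------------
    def step(self, rng) -> bool:
        """One Metropolis-Hastings update; returns acceptance."""
        state = self.state
        wt, wl, wp = self.config.move_weights
        u = rng.random() * (wt + wl + wp)
        if u < wt:
            kind = "spr" if rng.random() < self.config.spr_fraction else "nni"
        elif u < wt + wl:
            kind = "length"
        else:
            kind = "param"
        self.last_move = kind

        if kind == "length":
            v, new, logh = self._propose_length(rng)
            old = state.lengths[v]
            old_rho = self._rho[v].copy()
            old_tp = self._tprob[v].copy()
            state.lengths[v] = new
            self._rho[v] = rho_row(
                new, self.grid.dt_values, state.theta[3], state.theta[4]
            )
            self._tprob[v] = self.model.transition(new)
            new_seq = self._log_seq(state)
            new_tree = self._log_tree(state)
            if math.log(rng.random()) < new_seq + new_tree - state.log_joint + logh:
                state.log_seq, state.log_tree = new_seq, new_tree
                return True
            state.lengths[v] = old
            self._rho[v] = old_rho
            self._tprob[v] = old_tp
            return False

        if kind == "param":
            prop = self._propose_param(rng)
            if prop is None:
                return False
            i, new, logh = prop
            old_theta = state.theta.copy()
            state.theta[i] = new
            old_rates = self._rates_key
            old_ext, old_P = self._ext, self._P
            old_rho = self._rho
            if i in (0, 1, 2):
                self._set_tables(state.theta[0], state.theta[1], state.theta[2])
            else:
                self._rho = rho_rows(
                    state.lengths, self.grid.dt_values, state.theta[3], state.theta[4]
                )
            new_tree = self._log_tree(state)
            if math.log(rng.random()) < new_tree - state.log_tree + logh:
                state.log_tree = new_tree
                return True
            state.theta = old_theta
            self._ext, self._P, self._rates_key = old_ext, old_P, old_rates
            self._rho = old_rho
            return False

        prop = self._propose_nni(rng) if kind == "nni" else self._propose_spr(rng)
        if prop is None:
            return False
        children, parent, lengths, logh = prop
        postorder = _postorder(children, self.root)
        cand = ChainState(
            children=children,
            parent=parent,
            postorder=postorder,
            lengths=lengths,
            theta=state.theta,
            log_seq=0.0,
            log_tree=0.0,
        )
        if kind == "spr":
            old_rho = self._rho
            old_tp = self._tprob
            self._rho = rho_rows(
                lengths, self.grid.dt_values, state.theta[3], state.theta[4]
            )
            self._tprob = self.model.transitions(lengths)
        cand.log_seq = self._log_seq(cand)
        cand.log_tree = self._log_tree(cand)
        if math.log(rng.random()) < cand.log_joint - state.log_joint + logh:
            self.state = cand
            return True
        if kind == "spr":
            self._rho = old_rho
            self._tprob = old_tp
        return False

    # -- serialisation ---------------------------------------------------
    def current_gene_tree(self) -> GeneTree:
        s = self.state
        return GeneTree(s.parent, s.children, s.lengths, self.labels)


def run_chain(
    msa: MSA,
    species: DatedSpeciesTree,
    leafmap: LeafMap,
    config: MCMCConfig | None = None,
    seed: int = 0,
    model: SubstitutionModel | None = None,
) -> Trace:
    """Run one chain; deterministic for a given seed."""
    config = config or MCMCConfig()
    rng = np.random.default_rng(seed)
    sampler = FamilySampler(msa, species, leafmap, config, model)
    rows = []
    best = (-np.inf, "", None)
    accepted = {}
    proposed = {}

    def record(it):
        s = sampler.state
        gt = sampler.current_gene_tree()
        rows.append(
            (
                it,
                *s.theta,
                s.log_seq,
                s.log_tree,
                gt.topology_id(),
                gt.to_newick(),
            )
        )

    record(0)
    for it in range(1, config.iterations + 1):
        acc = sampler.step(rng)
        mv = sampler.last_move
        proposed[mv] = proposed.get(mv, 0) + 1
        if acc:
            accepted[mv] = accepted.get(mv, 0) + 1
        s = sampler.state
        if s.log_joint > best[0]:
            best = (s.log_joint, sampler.current_gene_tree().to_newick(),
                    s.theta_params())
        if it % config.thinning == 0:
            record(it)

    table = pd.DataFrame(
        rows,
        columns=[
            "iteration", "delta", "mu", "tau", "m", "cv",
            "log_seq", "log_tree", "topology", "newick",
        ],
    )
    rates = {
        k: accepted.get(k, 0) / max(1, proposed.get(k, 0)) for k in proposed
    }
    return Trace(
        table,
        thinning=config.thinning,
        best_newick=best[1],
        best_theta=best[2],
        best_log_joint=best[0],
        acceptance=rates,
    )
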
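"""Duplication-loss-transfer process quantities on the discretized tree.

A single gene lineage on species edge ``e`` is exposed to duplication,
loss and lateral transfer at rates ``delta``, ``mu`` and ``tau`` (transfer
recipients are drawn uniformly from the other contemporaneous species
edges; with no co-existing edge the effective transfer rate is zero).
Within each time slice the extinction probabilities obey

    dE_e/dt = mu - (delta+mu+tau) E_e + delta E_e^2
              + tau/(k-1) * sum_{f != e} E_f E_e ,

and the single-surviving-lineage propagation probability p11 decays at
rate ``(delta+mu+tau) - 2 delta E_e - tau/(k-1) sum_{f != e} E_f`` (a
duplication whose extra copy dies, or a transfer whose emigrant dies, is
invisible).  At a speciation both child copies are created; passing down
into one child edge multiplies p11 by the sibling edge's extinction.

The gene-tree density p(G, l | theta, S) is the quadrature sum over
realizations: each internal gene vertex is placed at a grid point with a
speciation, duplication or transfer term, each gene edge contributes p11
propagation times the relaxed-clock length density for the implied
duration, and every interior event point carries its interval length as
quadrature weight.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .trees import (
    DiscretizedSpeciesTree,
    GeneTree,
    LeafMap,
)

__all__ = [
    "ModelParams",
    "ExtinctionTable",
    "PropagationTable",
    "DPTable",
    "solve_extinction",
    "solve_propagation",
    "edge_length_density",
    "gene_tree_density",
]


@dataclass(frozen=True)
class ModelParams:
    """DLT rates plus the gamma edge-rate law.

    delta, mu, tau: duplication / loss / transfer rates per lineage per
    time unit.  m: mean edge substitution rate (substitutions/site/time);
    cv: coefficient of variation of the edge rate.
    """

    delta: float
    mu: float
    tau: float
    m: float
    cv: float

    def __post_init__(self):
        for name in ("delta", "mu", "tau"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not (np.isfinite(self.m) and self.m > 0):
            raise ValueError("m must be finite and > 0")
        if not (np.isfinite(self.cv) and self.cv > 0):
            raise ValueError("cv must be finite and > 0")

    @property
    def rate_shape(self) -> float:
        return 1.0 / (self.cv * self.cv)

    @property
    def rate_scale(self) -> float:
        return self.m * self.cv * self.cv

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.delta, self.mu, self.tau, self.m, self.cv], dtype=np.float64
        )

    @classmethod
    def from_array(cls, a) -> "ModelParams":
        return cls(*[float(x) for x in a])


@dataclass
class ExtinctionTable:
    """ext(x): probability a single lineage at grid point x leaves no
    descendant at any species leaf."""

    grid: DiscretizedSpeciesTree
    values: np.ndarray  # (n_points,)

    @property
    def at_origin(self) -> float:
        return float(self.values[self.grid.stem_point])


@dataclass
class PropagationTable:
    """p11 between grid points plus the per-point cumulative exponent."""

    grid: DiscretizedSpeciesTree
    matrix: np.ndarray  # (n, n) p11, zero when not on a descent path
    cumexp: np.ndarray  # (n,) integral of g from the edge bottom

    def p11(self, x: int, y: int) -> float:
        return float(self.matrix[x, y])


def _substeps(grid: DiscretizedSpeciesTree, theta: ModelParams, tol: float) -> int:
    """Fixed RK4 substep count per recording interval, from the requested
    per-slice tolerance (error scales like step^4)."""
    rate = theta.delta + theta.mu + theta.tau + 1.0
    h = grid.tree.origin_time / max(1, len(grid.slices) * grid.resolution)
    n = int(np.ceil(h * rate / max(tol, 1e-14) ** 0.25))
    return max(2, min(n, 64))


def compute_tables(
    grid: DiscretizedSpeciesTree, theta: ModelParams, tol: float = 1e-6
):
    """Solve extinction and propagation jointly, slice by slice bottom-up."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    n = grid.n_points
    ext = np.zeros(n)
    cum = np.zeros(n)
    carry = np.zeros(grid.tree.n_vertices)  # per-edge running exponent
    nsub = _substeps(grid, theta, tol)
    tree = grid.tree
    tol_t = 1e-9 * max(1.0, tree.origin_time)

    for sl in grid.slices:
        E0 = ext[sl.bottom_pts]
        rel = sl.rec_times - sl.lo
        outE, outC = _kernels.slice_integrate(
            E0, rel, theta.delta, theta.mu, theta.tau, nsub
        )
        for k, e in enumerate(sl.edges):
            base = carry[e]
            for j in range(len(sl.rec_times)):
                p = sl.rec_pts[j, k]
                ext[p] = outE[j, k]
                cum[p] = base + outC[j, k]
            carry[e] = base + outC[-1, k]
        # vertices whose time is the slice top: extinction is the product
        # of the child-edge extinctions; their own edge starts here
        for v in range(tree.n_vertices):
            if not tree.is_leaf(v) and abs(tree.times[v] - sl.hi) <= tol_t:
                p = grid.vertex_point[v]
                c1, c2 = tree.children[v]
                ext[p] = ext[grid.edge_top_point[c1]] * ext[grid.edge_top_point[c2]]
                cum[p] = 0.0
                carry[v] = 0.0

    return ext, cum


def solve_extinction(
    grid: DiscretizedSpeciesTree, theta: ModelParams, tol: float = 1e-6
) -> ExtinctionTable:
    ext, _ = compute_tables(grid, theta, tol)
    return ExtinctionTable(grid, ext)


def solve_propagation(
    grid: DiscretizedSpeciesTree,
    theta: ModelParams,
    ext: ExtinctionTable | None = None,
    tol: float = 1e-6,
) -> PropagationTable:
    evals, cum = compute_tables(grid, theta, tol)
    if ext is not None:
        evals = ext.values
    fac = np.zeros(grid.n_points)
    ok = grid.down >= 0
    fac[ok] = np.exp(cum[grid.down[ok]] - cum[ok])
    P = _kernels.build_p11(
        grid.p11_order, grid.pt_kind, grid.down, fac, grid.spec_top, evals
    )
    return PropagationTable(grid, P, cum)


# ---------------------------------------------------------------------------
# relaxed-clock edge length density


def edge_length_density(l, t, m: float, cv: float):
    """Density of substitution length l on a gene edge of duration t under
    the iid gamma edge-rate model (mean m, coefficient of variation cv):
    GammaPDF(l/t; shape 1/cv^2, scale m*cv^2) / t."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("edge duration must be > 0")
    l = np.asarray(l, dtype=float)
    alpha = 1.0 / (cv * cv)
    beta = m * cv * cv
    rate = l / t
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (
            (alpha - 1.0) * np.log(rate)
            - rate / beta
            - gammaln(alpha)
            - alpha * math.log(beta)
        )
        out = np.where(l > 0, np.exp(logpdf) / t, 0.0)
    if alpha == 1.0:
        out = np.where(l == 0, 1.0 / (beta * t), out)
    elif alpha < 1.0:
        out = np.where(l == 0, np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def rho_rows(lengths: np.ndarray, dt: np.ndarray, m: float, cv: float) -> np.ndarray:
    """Length densities for every gene edge over every grid duration.

    Row u holds edge_length_density(lengths[u], dt) for the whole static
    duration table of the grid; rows for the root are zero (no edge)."""
    alpha = 1.0 / (cv * cv)
    beta = m * cv * cv
    lg = gammaln(alpha) + alpha * math.log(beta)
    out = np.zeros((len(lengths), len(dt)))
    pos = lengths > 0
    if np.any(pos):
        rate = lengths[pos, None] / dt[None, :]
        out[pos] = np.exp((alpha - 1.0) * np.log(rate) - rate / beta - lg) / dt
    return out


def rho_row(length: float, dt: np.ndarray, m: float, cv: float) -> np.ndarray:
    return rho_rows(np.array([length]), dt, m, cv)[0]


# ---------------------------------------------------------------------------
# gene-tree density


@dataclass
class GeneArrays:
    """Flat-array view of a gene tree against a grid, for the DP kernel."""

    postorder: np.ndarray
    children: np.ndarray
    parent: np.ndarray
    lengths: np.ndarray
    leaf_pt: np.ndarray
    root: int

    @classmethod
    def build(cls, gene: GeneTree, leafmap: LeafMap, grid: DiscretizedSpeciesTree):
        leafmap.validate(gene, grid.tree)
        ng = gene.n_vertices
        leaf_pt = np.full(ng, -1, dtype=np.int64)
        for v in gene.leaves:
            sp = grid.tree.leaf_index(leafmap[gene.labels[v]])
            leaf_pt[v] = grid.vertex_point[sp]
        return cls(
            postorder=np.array(gene.postorder(), dtype=np.int64),
            children=gene.children.copy(),
            parent=gene.parent.copy(),
            lengths=gene.lengths.copy(),
            leaf_pt=leaf_pt,
            root=gene.root,
        )


@dataclass
class DPTable:
    """Retained DP state for realization sampling and MAP estimation.

    ``s`` and ``aD`` are max-normalised per gene vertex (log scales in
    ``sc_s`` / ``sc_a``); within-vertex weight ratios, which is all the
    samplers use, are unaffected by the normalisation.
    """

    grid: DiscretizedSpeciesTree
    theta: ModelParams
    garr: GeneArrays
    prop: PropagationTable
    rho: np.ndarray
    s: np.ndarray
    aD: np.ndarray
    sc_s: np.ndarray
    sc_a: np.ndarray
    log_density: float
    checksum: str

    @staticmethod
    def fingerprint(garr: GeneArrays, theta: ModelParams) -> str:
        h = hashlib.sha1()
        h.update(garr.children.tobytes())
        h.update(garr.lengths.tobytes())
        h.update(garr.leaf_pt.tobytes())
        h.update(theta.as_array().tobytes())
        return h.hexdigest()


def gene_tree_density(
    gene: GeneTree,
    leafmap: LeafMap,
    grid: DiscretizedSpeciesTree,
    theta: ModelParams,
    ext: ExtinctionTable | None = None,
    prop: PropagationTable | None = None,
    tol: float = 1e-6,
):
    """p(G, l | theta, S) on the grid, with the retained DP table.

    Returns ``(density, dp)``; ``dp.log_density`` is exact in log space
    when the linear value under- or overflows.
    """
    garr = GeneArrays.build(gene, leafmap, grid)
    if prop is None:
        prop = solve_propagation(grid, theta, ext, tol)
    rho = rho_rows(garr.lengths, grid.dt_values, theta.m, theta.cv)
    logdens, s, aD, sc_s, sc_a = _kernels.density_dp(
        prop.matrix,
        grid.pt_time,
        grid.pt_delta,
        grid.pt_kind,
        grid.pt_tidx,
        grid.spec_top,
        grid.trans_off,
        grid.trans_idx,
        grid.stem_point,
        grid.dt_index,
        rho,
        garr.postorder,
        garr.children,
        garr.leaf_pt,
        garr.root,
        theta.delta,
        theta.tau,
    )
    dp = DPTable(
        grid=grid,
        theta=theta,
        garr=garr,
        prop=prop,
        rho=rho,
        s=s,
        aD=aD,
        sc_s=sc_s,
        sc_a=sc_a,
        log_density=logdens,
        checksum=DPTable.fingerprint(garr, theta),
    )
    if logdens == -np.inf:
        # zero density: most often unsatisfiable leaf constraints
        return 0.0, dp
    with np.errstate(over="ignore"):
        return float(np.exp(logdens)), dp
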
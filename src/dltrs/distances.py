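"""Topological and temporal distances between realizations.

The topological distance between two transfer events is the length of the
path between the two transfer vertices in the gene tree; the temporal
distance is the gap between their time intervals (zero when the intervals
overlap).  Transfers of the two realizations are paired by the
minimum-total-path-length matching; when the transfer counts differ, each
unmatched transfer contributes the gene-tree diameter (topological) or
the species-tree root height (temporal) as a penalty — a stated
convention of this package, reported in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .realization import Realization, RealizationPosterior
from .trees import DiscretizedSpeciesTree, GeneTree

__all__ = [
    "DistanceSummary",
    "topological_distance",
    "temporal_distance",
    "expected_distances",
    "PENALTY_CONVENTION",
]

PENALTY_CONVENTION = (
    "unmatched transfers: gene-tree diameter (topological), "
    "species root height (temporal); min-cost matching"
)


def _check_same_gene(d: Realization, dp: Realization):
    if d.gene.n_vertices != dp.gene.n_vertices or np.any(
        d.gene.children != dp.gene.children
    ):
        raise ValueError("realizations are over different gene trees")


def _matching(d: Realization, dp: Realization, G: GeneTree):
    """Min-cost pairing of transfer vertices (by gene-tree path length),
    padded so each unmatched transfer pairs with a diameter penalty.

    Returns (pairs, n_unmatched, topo_costs) where pairs holds
    (event_of_d, event_of_dp)."""
    A = sorted(d.transfers, key=lambda e: e.vertex)
    B = sorted(dp.transfers, key=lambda e: e.vertex)
    if not A and not B:
        return [], 0, []
    pen = G.diameter()
    m = max(len(A), len(B))
    cost = np.full((m, m), float(pen))
    plen = G.path_lengths()
    for i, ea in enumerate(A):
        for j, eb in enumerate(B):
            cost[i, j] = plen[ea.vertex, eb.vertex]
    ri, ci = linear_sum_assignment(cost)
    pairs, topo = [], []
    n_unmatched = 0
    for i, j in zip(ri, ci):
        if i < len(A) and j < len(B):
            pairs.append((A[i], B[j]))
            topo.append(float(plen[A[i].vertex, B[j].vertex]))
        else:
            n_unmatched += 1
    return pairs, n_unmatched, topo


def topological_distance(d: Realization, dp: Realization, G: GeneTree):
    """(average, maximum) gene-tree path length between matched transfer
    vertices, plus diameter penalties for unmatched transfers."""
    _check_same_gene(d, dp)
    pairs, n_un, topo = _matching(d, dp, G)
    vals = topo + [float(G.diameter())] * n_un
    if not vals:
        return 0.0, 0.0
    return float(np.mean(vals)), float(np.max(vals))


def _interval_gap(a: tuple, b: tuple) -> float:
    return max(0.0, b[0] - a[1], a[0] - b[1])


def temporal_distance(d: Realization, dp: Realization, sd: DiscretizedSpeciesTree):
    """(average, maximum) time gap between the intervals of matched
    transfer events (zero when they overlap), plus root-height penalties
    for unmatched transfers; uses the topological matching."""
    _check_same_gene(d, dp)
    pairs, n_un, _ = _matching(d, dp, d.gene)
    vals = [_interval_gap(ea.interval, eb.interval) for ea, eb in pairs]
    vals += [float(sd.tree.root_time)] * n_un
    if not vals:
        return 0.0, 0.0
    return float(np.mean(vals)), float(np.max(vals))


@dataclass
class DistanceSummary:
    """Posterior expectations of the four distance variants."""

    E_DGa: float
    E_DGm: float
    E_DTa: float
    E_DTm: float
    per_sample: list   # (DGa, DGm, DTa, DTm) per posterior draw
    n_samples: int
    penalty_convention: str = PENALTY_CONVENTION


def expected_distances(
    d_true: Realization,
    post: RealizationPosterior,
    sd: DiscretizedSpeciesTree,
) -> DistanceSummary:
    """q-weighted expectations of average/maximum topological and temporal
    distance between the true realization and the posterior draws."""
    G = d_true.gene
    per = []
    for dp in post.samples:
        ga, gm = topological_distance(d_true, dp, G)
        ta, tm = temporal_distance(d_true, dp, sd)
        per.append((ga, gm, ta, tm))
    w = post.weights
    arr = np.asarray(per)
    e = arr.T @ w
    return DistanceSummary(
        E_DGa=float(e[0]),
        E_DGm=float(e[1]),
        E_DTa=float(e[2]),
        E_DTm=float(e[3]),
        per_sample=per,
        n_samples=post.n,
    )
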
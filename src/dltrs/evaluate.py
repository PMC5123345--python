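"""Workflow glue: full-family inference, evaluation against simulated
truth, and cross-family LGT-highway summaries.

Evaluation mirrors the usual simulation-study design: a family is scored
only when the MAP gene-tree topology matches the true topology (otherwise
it is flagged and skipped), and the per-family report gives the posterior
fraction with the correct transfer count, the recovery of the true
transfer vertex and donor/recipient ('From'/'To') species edges at a
posterior threshold, and the expected topological/temporal distances to
the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ModelParams, gene_tree_density
from .diagnostics import diagnostics
from .distances import expected_distances
from .mcmc import MCMCConfig, Trace, run_chain
from .realization import (
    Event,
    Realization,
    RealizationPosterior,
    posterior_summary,
    sample_realization,
)
from .seqmodel import MSA
from .simulate import TrueHistory
from .trees import (
    DatedSpeciesTree,
    DiscretizedSpeciesTree,
    GeneTree,
    LeafMap,
    discretize,
    parse_gene_newick,
)

__all__ = [
    "InferenceResult",
    "infer_family",
    "realization_posterior",
    "truth_realization",
    "align_realization",
    "evaluate_family",
    "HighwaySummary",
    "summarize_highways",
]


# ---------------------------------------------------------------------------
# realization sampling over a trace


def realization_posterior(
    trace: Trace,
    species: DatedSpeciesTree,
    leafmap: LeafMap,
    grid: DiscretizedSpeciesTree,
    rng: np.random.Generator,
    topology: str | None = None,
    draws_per_sample: int = 1,
):
    """Sample realizations for the post-burn-in trace entries.

    ``topology``: restrict to entries with this canonical topology (the
    usual choice is the MAP topology); None uses every entry.
    """
    tab = trace.post_burn_in()
    if topology is not None:
        tab = tab[tab["topology"] == topology]
    if not len(tab):
        raise ValueError("no trace entries to sample realizations from")
    samples = []
    cache = {}
    for _, row in tab.iterrows():
        gene = parse_gene_newick(row["newick"])
        theta = ModelParams(
            row["delta"], row["mu"], row["tau"], row["m"], row["cv"]
        )
        key = (row["delta"], row["mu"], row["tau"])
        prop = cache.get(key)
        _, dp = gene_tree_density(gene, leafmap, grid, theta, prop=prop)
        cache[key] = dp.prop
        for _ in range(draws_per_sample):
            samples.append(sample_realization(dp, rng, gene=gene))
    return RealizationPosterior(samples)


@dataclass
class InferenceResult:
    trace: Trace
    diagnostics: dict
    grid: DiscretizedSpeciesTree
    map_topology: str
    map_tree: GeneTree
    posterior_map: RealizationPosterior        # realizations on MAP-topology samples
    summary_map: dict
    posterior_all: RealizationPosterior | None # realizations over all samples
    summary_all: dict | None


def infer_family(
    msa: MSA,
    species: DatedSpeciesTree,
    leafmap: LeafMap,
    config: MCMCConfig | None = None,
    seed: int = 0,
    draws_per_sample: int = 1,
    sample_all_topologies: bool = True,
    threshold: float = 0.5,
) -> InferenceResult:
    """simulate-free end-to-end inference for one family: MCMC, burn-in
    selection, MAP topology, realization posteriors and summaries."""
    config = config or MCMCConfig()
    trace = run_chain(msa, species, leafmap, config, seed=seed)
    try:
        diag = diagnostics(trace)
    except ValueError:
        diag = {"burn_in": len(trace.table) // 5, "scalars": {}, "short": True}
        trace.burn_in = diag["burn_in"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    tree = species
    if config.stem is not None:
        tree = DatedSpeciesTree(
            species.parent, species.children, species.times, species.labels,
            config.stem,
        )
    grid = discretize(tree, config.resolution)
    map_topo = trace.map_topology()
    tab = trace.post_burn_in()
    map_newick = tab[tab["topology"] == map_topo].iloc[0]["newick"]
    map_tree = parse_gene_newick(map_newick)
    post_map = realization_posterior(
        trace, species, leafmap, grid, rng, topology=map_topo,
        draws_per_sample=draws_per_sample,
    )
    summary_map = posterior_summary(post_map, threshold)
    post_all, summary_all = None, None
    if sample_all_topologies:
        post_all = realization_posterior(
            trace, species, leafmap, grid, rng, topology=None,
            draws_per_sample=draws_per_sample,
        )
        summary_all = posterior_summary(post_all, threshold)
    return InferenceResult(
        trace, diag, grid, map_topo, map_tree, post_map, summary_map,
        post_all, summary_all,
    )


# ---------------------------------------------------------------------------
# truth alignment and family evaluation


def truth_realization(history: TrueHistory, grid: DiscretizedSpeciesTree) -> Realization:
    """The simulator's continuous realization as a Realization with
    degenerate (exact-time) intervals; grid points are not assigned."""
    events = {}
    for v, te in history.truth_events.items():
        events[v] = Event(
            vertex=int(v),
            point=-1,
            time=float(te.time),
            etype=te.etype,
            from_edge=int(te.from_edge),
            to_edge=int(te.to_edge),
            interval=(float(te.time), float(te.time)),
        )
    return Realization(history.pruned, grid, events)


def align_realization(real: Realization, target: GeneTree) -> Realization | None:
    """Re-express a realization over a congruent gene tree (same topology,
    possibly different vertex numbering) by matching clades; None when the
    topologies differ."""
    src = real.gene
    src_clades = {v: src.clade(v) for v in src.internal}
    tgt_clades = {frozenset(target.clade(v)): v for v in target.internal}
    if set(frozenset(c) for c in src_clades.values()) != set(tgt_clades):
        return None
    events = {}
    for v, ev in real.events.items():
        tv = tgt_clades[frozenset(src_clades[v])]
        events[tv] = Event(
            vertex=int(tv),
            point=ev.point,
            time=ev.time,
            etype=ev.etype,
            from_edge=ev.from_edge,
            to_edge=ev.to_edge,
            interval=ev.interval,
        )
    return Realization(target, real.grid, events)


def score_posterior(
    truth: Realization,
    post: RealizationPosterior,
    grid: DiscretizedSpeciesTree,
    threshold: float = 0.5,
) -> dict:
    """Score a realization posterior against a truth realization expressed
    over the same gene tree."""
    summary = posterior_summary(post, threshold)
    n = post.n
    out = {}
    true_count = truth.n_transfers
    out["frac_correct_count"] = (
        sum(1 for r in post.samples if r.n_transfers == true_count) / n
    )
    true_clades = truth.transfer_clades()
    if true_clades:
        out["frac_correct_vertex"] = float(
            np.mean([
                summary["vertex_transfer_probs"].get(cl, 0.0)
                for cl in true_clades
            ])
        )
    else:
        out["frac_correct_vertex"] = float(
            np.mean([1.0 if r.n_transfers == 0 else 0.0 for r in post.samples])
        )
    # From / To recovery at the posterior threshold
    from_hits, to_hits, pair_hits = [], [], []
    for te in truth.transfers:
        pf = sum(
            1 for r in post.samples
            if any(e.from_edge == te.from_edge for e in r.transfers)
        ) / n
        pt = sum(
            1 for r in post.samples
            if any(e.to_edge == te.to_edge for e in r.transfers)
        ) / n
        pp = summary["pair_probs"].get((te.from_edge, te.to_edge), 0.0)
        from_hits.append(pf >= threshold)
        to_hits.append(pt >= threshold)
        pair_hits.append(pp >= threshold)
    out["from_recovered"] = bool(all(from_hits)) if from_hits else None
    out["to_recovered"] = bool(all(to_hits)) if to_hits else None
    out["pair_recovered"] = bool(all(pair_hits)) if pair_hits else None
    dist = expected_distances(truth, post, grid)
    out.update(
        E_DGa=dist.E_DGa, E_DGm=dist.E_DGm, E_DTa=dist.E_DTa, E_DTm=dist.E_DTm
    )
    out["expected_transfers"] = summary["expected_transfers"]
    return out


def evaluate_family(
    history: TrueHistory,
    result: InferenceResult,
    threshold: float = 0.5,
) -> dict:
    """Score one family's realization posterior against the recorded truth.

    Families whose MAP topology differs from the truth are flagged and
    skipped, mirroring the usual restriction of simulation studies to
    correctly inferred gene trees.
    """
    truth_topo = history.pruned.topology_id()
    out = {
        "n_true_transfers": history.n_true_transfers,
        "map_correct": result.map_topology == truth_topo,
        "skipped": False,
    }
    if not out["map_correct"]:
        out["skipped"] = True
        return out
    truth = align_realization(
        truth_realization(history, result.grid), result.map_tree
    )
    out.update(
        score_posterior(truth, result.posterior_map, result.grid, threshold)
    )
    return out


# ---------------------------------------------------------------------------
# LGT highways


@dataclass
class HighwaySummary:
    """Family counts per ordered (From, To) species-edge pair whose
    per-family posterior probability reaches the threshold."""

    threshold: float
    n_families: int
    counts_map: dict      # (from, to) -> families, MAP-tree realizations
    counts_all: dict      # (from, to) -> families, all sampled trees

    def to_frame(self, tree: DatedSpeciesTree | None = None) -> pd.DataFrame:
        pairs = sorted(set(self.counts_map) | set(self.counts_all))
        rows = []
        for p in pairs:
            name_f = tree.edge_name(p[0]) if tree else str(p[0])
            name_t = tree.edge_name(p[1]) if tree else str(p[1])
            rows.append(
                (p[0], p[1], name_f, name_t,
                 self.counts_map.get(p, 0), self.counts_all.get(p, 0))
            )
        return pd.DataFrame(
            rows,
            columns=["from_edge", "to_edge", "from_name", "to_name",
                     "families_map", "families_all"],
        )


def summarize_highways(family_summaries: list, threshold: float = 0.5) -> HighwaySummary:
    """Count, per ordered species-edge pair, the families whose posterior
    transfer probability for that pair is >= threshold (inclusive).

    Each family summary is a dict with ``pair_probs`` (MAP-tree
    realizations) and optionally ``pair_probs_all``.
    """
    if not family_summaries:
        raise ValueError("no family summaries")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    counts_map, counts_all = {}, {}
    for fam in family_summaries:
        for pair, prob in fam.get("pair_probs", {}).items():
            if prob >= threshold:
                counts_map[pair] = counts_map.get(pair, 0) + 1
        for pair, prob in fam.get("pair_probs_all", fam.get("pair_probs", {})).items():
            if prob >= threshold:
                counts_all[pair] = counts_all.get(pair, 0) + 1
    return HighwaySummary(
        threshold=threshold,
        n_families=len(family_summaries),
        counts_map=counts_map,
        counts_all=counts_all,
    )
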
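"""Extinction/propagation ODE tables, the relaxed-clock length density and
the gene-tree quadrature density."""

import numpy as np
import pytest
from scipy.integrate import quad

from dltrs.core import (
    ModelParams,
    edge_length_density,
    gene_tree_density,
    solve_extinction,
    solve_propagation,
)
from dltrs.realization import enumerate_realizations
from dltrs.trees import (
    DatedSpeciesTree,
    KIND_EVENT,
    LeafMap,
    discretize,
    parse_dated_newick,
    parse_gene_newick,
)
from conftest import simulate_instance


def single_edge_tree(duration):
    return DatedSpeciesTree([-1], [[-1, -1]], [0.0], ["A"], duration)


class TestExtinction:
    def test_zero_loss_means_zero_extinction(self, grid3):
        e = solve_extinction(grid3, ModelParams(1.0, 0.0, 2.0, 1.0, 1.0))
        assert np.all(e.values == 0.0)

    def test_linear_birth_death_closed_form(self):
        grid = discretize(single_edge_tree(1.0), 10)
        d, m = 2.0, 1.0
        e = solve_extinction(grid, ModelParams(d, m, 0.0, 1.0, 1.0), tol=1e-8)
        expect = m * (np.exp((d - m)) - 1) / (d * np.exp((d - m)) - m)
        assert e.at_origin == pytest.approx(expect, abs=1e-4)

    def test_monotone_in_time_and_bounded(self, grid3):
        e = solve_extinction(grid3, ModelParams(0.5, 1.0, 0.5, 1.0, 1.0))
        assert np.all((e.values >= 0) & (e.values <= 1))
        for v in range(grid3.tree.n_vertices):
            pts = grid3.edge_points[v]
            vals = e.values[pts]
            assert np.all(np.diff(vals) >= -1e-12)


class TestPropagation:
    def test_event_free_process_propagates_surely(self, grid3):
        p = solve_propagation(grid3, ModelParams(0.0, 0.0, 0.0, 1.0, 1.0))
        nz = p.matrix[p.matrix > 0]
        assert np.allclose(nz, 1.0)

    def test_pure_death_exponential(self, grid3):
        mu = 1.7
        p = solve_propagation(grid3, ModelParams(0.0, mu, 0.0, 1.0, 1.0), tol=1e-9)
        a = grid3.tree.leaf_index("A")
        pts = grid3.edge_points[a]
        x, y = int(pts[-1]), int(pts[0])
        dt = grid3.pt_time[x] - grid3.pt_time[y]
        assert p.matrix[x, y] == pytest.approx(np.exp(-mu * dt), abs=1e-6)
        # across a speciation the sibling must die as well
        stem = grid3.stem_point
        ext = solve_extinction(grid3, ModelParams(0.0, mu, 0.0, 1.0, 1.0), tol=1e-9)
        t_root = grid3.tree.root_time
        c_leaf = grid3.tree.leaf_index("C")
        c_bottom = int(grid3.edge_points[c_leaf][0])
        expect = np.exp(-mu * grid3.tree.stem_duration) * (
            1 - np.exp(-mu * t_root)  # sibling subtree extinct
        ) * np.exp(-mu * t_root)
        # sibling here is the AB ancestor edge: extinction of that subtree
        anc = next(
            v for v in range(grid3.tree.n_vertices)
            if not grid3.tree.is_leaf(v) and v != grid3.tree.root
        )
        e_sib = ext.values[grid3.edge_top_point[anc]]
        expect = np.exp(-mu * grid3.tree.stem_duration) * e_sib * np.exp(-mu * t_root)
        assert p.matrix[stem, c_bottom] == pytest.approx(expect, rel=1e-5)

    def test_same_edge_composition(self, grid3, theta_mid):
        p = solve_propagation(grid3, theta_mid)
        for v in range(grid3.tree.n_vertices):
            pts = [int(q) for q in grid3.edge_points[v]]
            for i in range(len(pts) - 2):
                x, y, z = pts[i + 2], pts[i + 1], pts[i]
                assert p.matrix[x, z] == pytest.approx(
                    p.matrix[x, y] * p.matrix[y, z], abs=1e-9
                )


class TestEdgeLengthDensity:
    def test_unit_cv_is_exponential(self):
        # shape 1 gamma: density of l is Exponential(1) at m=1, t=1
        ls = np.array([0.0, 0.5, 2.0])
        got = edge_length_density(ls, 1.0, 1.0, 1.0)
        assert got == pytest.approx(np.exp(-ls))

    def test_normalises_to_one(self):
        for m, cv, t in [(1.0, 1.0, 1.0), (0.5, 0.3, 2.0), (2.0, 1.5, 0.4)]:
            val, _ = quad(lambda l: edge_length_density(l, t, m, cv), 0, np.inf)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_small_cv_concentrates_at_mean_length(self):
        t, m, cv = 2.0, 0.5, 0.01
        ls = np.linspace(0.8, 1.2, 2001)
        dens = edge_length_density(ls, t, m, cv)
        mode = ls[np.argmax(dens)]
        assert 0.95 <= mode <= 1.05

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            edge_length_density(1.0, 0.0, 1.0, 1.0)


class TestGeneTreeDensity:
    def test_rates_to_zero_congruent_limit(self, species3):
        grid = discretize(species3, 6)
        gene = parse_gene_newick("((ga:1.0,gb:1.0):1.0,gc:2.0);")
        lm = LeafMap({"ga": "A", "gb": "B", "gc": "C"})
        eps = 1e-9
        d, _ = gene_tree_density(gene, lm, grid, ModelParams(eps, eps, eps, 1.0, 0.5))
        expect = np.prod(
            [edge_length_density(l, t, 1.0, 0.5)
             for l, t in [(1, 1), (1, 1), (1, 1), (2, 2)]]
        )
        assert d == pytest.approx(expect, rel=0.01)

    def test_matches_enumeration_on_cherry(self, cherry, theta_mid):
        grid = discretize(cherry, 3)
        gene = parse_gene_newick("(ga:0.8,gb:1.1);")
        lm = LeafMap({"ga": "A", "gb": "B"})
        prop = None
        dens, dp = gene_tree_density(gene, lm, grid, theta_mid)
        en = enumerate_realizations(gene, lm, grid, theta_mid, prop=dp.prop)
        assert sum(s for _, s in en) == pytest.approx(dens, abs=1e-10, rel=1e-10)

    def test_relabeling_symmetry(self, cherry, theta_mid):
        grid = discretize(cherry, 3)
        d1, _ = gene_tree_density(
            parse_gene_newick("(x:0.8,y:1.1);"),
            LeafMap({"x": "A", "y": "B"}),
            grid,
            theta_mid,
        )
        d2, _ = gene_tree_density(
            parse_gene_newick("(p:1.1,q:0.8);"),
            LeafMap({"q": "A", "p": "B"}),
            grid,
            theta_mid,
        )
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_unsatisfiable_leaf_constraints_zero_density(self, species3, theta_mid):
        grid = discretize(species3, 3)
        gene = parse_gene_newick("(ga:0.8,gb:1.1);")
        lm = LeafMap({"ga": "Q", "gb": "B"})
        with pytest.raises(KeyError):
            gene_tree_density(gene, lm, grid, theta_mid)

    def test_resolution_refinement_converges(self, cherry, theta_mid):
        gene = parse_gene_newick("(ga:0.9,gb:1.2);")
        lm = LeafMap({"ga": "A", "gb": "B"})
        dens = {}
        for r in (5, 10, 20, 40):
            d, _ = gene_tree_density(gene, lm, discretize(cherry, r), theta_mid)
            dens[r] = d
        r1 = abs(dens[10] / dens[5] - 1)
        r2 = abs(dens[20] / dens[10] - 1)
        r3 = abs(dens[40] / dens[20] - 1)
        assert r2 < r1 and r3 < r2
        assert abs(dens[40] / dens[20] - 1) < 0.05

    def test_no_transfer_terms_when_tau_zero(self, species3):
        grid = discretize(species3, 3)
        theta = ModelParams(0.5, 0.3, 0.0, 1.0, 0.8)
        gene = parse_gene_newick("((ga:0.7,gc:1.6):0.5,gb:1.4);")  # discordant
        lm = LeafMap({"ga": "A", "gb": "B", "gc": "C"})
        dens, dp = gene_tree_density(gene, lm, grid, theta)
        en = enumerate_realizations(gene, lm, grid, theta, prop=dp.prop)
        assert all(
            ev.etype != "transfer"
            for real, _ in en
            for ev in real.events.values()
        )
        assert sum(s for _, s in en) == pytest.approx(dens, rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_enumeration_on_random_instances(self, species3, seed):
        rng = np.random.default_rng(seed)
        theta = ModelParams(0.4, 0.4, 0.5, 1.0, 0.7)
        gene, lm, _ = simulate_instance(rng, species3, theta, max_gene_leaves=3)
        grid = discretize(species3, 2)
        dens, dp = gene_tree_density(gene, lm, grid, theta)
        en = enumerate_realizations(gene, lm, grid, theta, prop=dp.prop)
        assert sum(s for _, s in en) == pytest.approx(dens, rel=1e-9, abs=1e-12)


class TestDPSamplingWeights:
    def test_event_subterms_sum_to_cell_value(self, cherry, theta_mid):
        from dltrs.realization import _event_options

        grid = discretize(cherry, 4)
        gene = parse_gene_newick("(ga:0.8,gb:1.1);")
        lm = LeafMap({"ga": "A", "gb": "B"})
        _, dp = gene_tree_density(gene, lm, grid, theta_mid)
        u = int(dp.garr.root)
        c1, c2 = dp.garr.children[u]
        rescale = np.exp(dp.sc_a[u] - dp.sc_s[c1] - dp.sc_s[c2])
        for y in range(grid.n_points):
            opts = _event_options(dp, u, y)
            total = sum(o[0] for o in opts)
            if grid.pt_kind[y] == KIND_EVENT:
                total *= grid.pt_delta[y]
            assert total == pytest.approx(
                dp.aD[u, y] * rescale, rel=1e-12, abs=1e-300
            )
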
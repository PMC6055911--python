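import math

import numpy as np
import pandas as pd
import pytest

import bruteforce as bf
from gpmap import internetwork as inter
from gpmap.networks import dominant_network
from gpmap.pbm_io import GenotypeSet, bound_sites, unbound_sites


@pytest.fixture(scope="module")
def k4_setup(omega4, toy_table4):
    table, _ = toy_table4
    nets = [dominant_network(bound_sites(table, tf, 0.35), omega4) for tf in table.tf_ids]
    memberships = {n.phenotype_id: set(n.sites) for n in nets}
    all_nodes = bf.all_canonical(4)
    all_nbrs = bf.neighbor_map(all_nodes, bf.space_edges(4))
    return table, nets, memberships, all_nodes, all_nbrs


class TestOverlap:
    def test_identical_networks(self, omega4):
        net = dominant_network(GenotypeSet("a", frozenset({"AAAA", "AAAC"})), omega4)
        net2 = dominant_network(GenotypeSet("b", frozenset({"AAAA", "AAAC"})), omega4)
        O = inter.overlap_matrix([net, net2])
        assert O.loc["a", "b"] == O.loc["b", "a"] == 1.0

    def test_disjoint_networks(self, omega4):
        a = dominant_network(GenotypeSet("a", frozenset({"AAAA"})), omega4)
        b = dominant_network(GenotypeSet("b", frozenset({"CCGG"})), omega4)
        O = inter.overlap_matrix([a, b])
        assert O.loc["a", "b"] == 0.0

    def test_asymmetry_arithmetic(self, omega4):
        # |q∩p|=2, |p|=4, |q|=8 -> O_qp=0.5, O_pq=0.25
        center = omega4.index_of("ACGT")
        dist = omega4.bfs_from(center)
        order = np.argsort(dist, kind="stable")
        p_sites = frozenset(omega4.sites[i] for i in order[:4])
        shared = sorted(p_sites)[:2]
        extra = [omega4.sites[i] for i in order[4:10]]
        q_sites = frozenset(shared + extra)
        # bypass connectivity concerns: use raw site sets via GenotypeNetwork
        from gpmap.networks import GenotypeNetwork

        p = GenotypeNetwork("p", omega4.indices_of(p_sites), omega4)
        q = GenotypeNetwork("q", omega4.indices_of(q_sites), omega4)
        O = inter.overlap_matrix([p, q])
        assert O.loc["q", "p"] == 0.5
        assert O.loc["p", "q"] == 0.25

    def test_consistency_invariant(self, k4_setup):
        _, nets, memberships, _, _ = k4_setup
        O = inter.overlap_matrix(nets)
        for q in memberships:
            for p in memberships:
                lhs = O.loc[q, p] * len(memberships[p])
                rhs = O.loc[p, q] * len(memberships[q])
                assert lhs == pytest.approx(rhs, abs=1e-9)
                assert lhs == pytest.approx(round(lhs), abs=1e-9)  # integer count

    def test_matches_bruteforce(self, k4_setup):
        _, nets, memberships, _, _ = k4_setup
        O = inter.overlap_matrix(nets)
        exp = bf.overlap(memberships)
        for (q, p), v in exp.items():
            assert O.loc[q, p] == pytest.approx(v, abs=1e-12)


class TestLocalSpectrum:
    def test_all_neighbors_in_network(self, omega4):
        nbrs = sorted(
            s for s in bf.neighbor_map(bf.all_canonical(4), bf.space_edges(4))["AAAC"]
        )
        from gpmap.networks import GenotypeNetwork

        net = GenotypeNetwork("q", omega4.indices_of(nbrs), omega4)
        spec = inter.local_spectrum("AAAC", [net], omega4)
        assert spec.fractions()["q"] == 1.0

    def test_no_neighbors_anywhere(self, omega4):
        from gpmap.networks import GenotypeNetwork

        net = GenotypeNetwork("q", omega4.indices_of(["CCGG"]), omega4)
        spec = inter.local_spectrum("AAAA", [net], omega4)
        assert spec.fractions()["q"] == 0.0

    def test_matches_bruteforce(self, k4_setup):
        _, nets, memberships, all_nodes, all_nbrs = k4_setup
        for site in all_nodes[::7]:
            got = inter.local_spectrum(site, nets, bf_space(nets)).fractions()
            exp = bf.local_spectrum(site, memberships, all_nbrs)
            assert got == pytest.approx(exp, abs=1e-12)


def bf_space(nets):
    return nets[0].space


class TestPhiMatrix:
    def test_matches_bruteforce(self, k4_setup):
        _, nets, memberships, _, all_nbrs = k4_setup
        phi = inter.phi_matrix(nets, nets[0].space)
        exp = bf.phi(memberships, all_nbrs)
        for (q, p), v in exp.items():
            assert phi.loc[q, p] == pytest.approx(v, abs=1e-12)

    def test_saturated_network(self, omega4):
        # a network covering the whole space: every neighbor is in it
        from gpmap.networks import GenotypeNetwork

        allnet = GenotypeNetwork("all", np.arange(omega4.n_sites), omega4)
        phi = inter.phi_matrix([allnet], omega4)
        assert phi.loc["all", "all"] == 1.0

    def test_unbound_row(self, omega4, toy_table4):
        table, _ = toy_table4
        nets = [dominant_network(bound_sites(table, tf, 0.35), omega4) for tf in table.tf_ids]
        unbound = unbound_sites(table, tau=0.35)
        phi = inter.phi_matrix(nets, omega4, unbound=unbound)
        assert "unbound" in phi.index
        assert ((phi.loc["unbound"] >= 0) & (phi.loc["unbound"] <= 1)).all()


class TestGlobalConnectivity:
    def test_two_phenotypes(self):
        phi = pd.DataFrame([[0.5, 0.2], [0.3, 0.6]], index=["a", "b"], columns=["a", "b"])
        Phi = inter.global_connectivity(phi)
        assert Phi["a"] == 0.2
        assert Phi["b"] == 0.3

    def test_single_phenotype_is_zero(self):
        phi = pd.DataFrame([[0.5]], index=["a"], columns=["a"])
        assert inter.global_connectivity(phi)["a"] == 0.0

    def test_increases_with_size_on_planted_gradient(self, omega8):
        from gpmap import synthetic
        from gpmap.networks import dominant_networks
        from scipy.stats import spearmanr

        spec = synthetic.SyntheticSpec(
            n_tfs=6,
            seed=2,
            decay=[synthetic.decay_for_radius(r) for r in (1, 1, 2, 2, 3, 3)],
            noise_sd=0.0,
        )
        table, _ = synthetic.generate_escore_table(spec, omega8)
        nets = list(dominant_networks(table, omega8).values())
        phi = inter.phi_matrix(nets, omega8)
        Phi = inter.global_connectivity(phi)
        sizes = pd.Series({n.phenotype_id: n.n for n in nets})
        rho, _ = spearmanr(Phi[sizes.index], sizes)
        assert rho > 0


class TestAccessibility:
    def test_whole_space_boundary_empty(self, omega4):
        from gpmap.networks import GenotypeNetwork

        allnet = GenotypeNetwork("all", np.arange(omega4.n_sites), omega4)
        A = inter.accessibility_matrix([allnet], omega4)
        assert math.isnan(A.loc["all", "all"])

    def test_matches_bruteforce(self, k4_setup):
        _, nets, memberships, _, all_nbrs = k4_setup
        A = inter.accessibility_matrix(nets, nets[0].space)
        exp = bf.accessibility(memberships, all_nbrs)
        for (q, p), v in exp.items():
            assert A.loc[q, p] == pytest.approx(v, abs=1e-12)

    def test_correlates_with_phi(self, omega8, synth10):
        from scipy.stats import spearmanr
        from gpmap.networks import dominant_networks

        table, _, _ = synth10
        nets = list(dominant_networks(table, omega8).values())
        phi = inter.phi_matrix(nets, omega8)
        A = inter.accessibility_matrix(nets, omega8)
        off = ~np.eye(len(nets), dtype=bool)
        rho, _ = spearmanr(phi.to_numpy()[off], A.to_numpy()[off])
        assert rho > 0.5


class TestBhattacharyya:
    def test_identical_spectra(self, omega4):
        # two sites with all neighbors inside one big network
        from gpmap.networks import GenotypeNetwork

        allnet = GenotypeNetwork("all", np.arange(omega4.n_sites), omega4)
        bc = inter.bhattacharyya("AAAA", "CCGG", [allnet], omega4, exclude_shared=False)
        assert bc == pytest.approx(1.0)

    def test_disjoint_support(self, omega4):
        from gpmap.networks import GenotypeNetwork

        a_nbrs = sorted(inter._ids([]) or []) or None
        na = GenotypeNetwork("na", omega4.indices_of(["AAAC"]), omega4)
        nb = GenotypeNetwork("nb", omega4.indices_of(["CCGA"]), omega4)
        bc = inter.bhattacharyya("AAAA", "CCGG", [na, nb], omega4, exclude_shared=False)
        assert bc == pytest.approx(0.0)

    def test_closed_form_half(self):
        # spectra (0.5, 0.5) vs (1, 0): BC = sqrt(0.5)
        p = np.array([0.5, 0.5])
        q = np.array([1.0, 0.0])
        assert np.sqrt(p * q).sum() == pytest.approx(math.sqrt(0.5))

    def test_matches_bruteforce_with_exclusion(self, k4_setup):
        _, nets, memberships, all_nodes, all_nbrs = k4_setup
        space = nets[0].space
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.choice(all_nodes, size=2, replace=False)
            for flag in (True, False):
                got = inter.bhattacharyya(i, j, nets, space, exclude_shared=flag)
                exp = bf.bhattacharyya(i, j, memberships, all_nbrs, exclude_shared=flag)
                if math.isnan(exp):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(exp, abs=1e-12)

    def test_product_form_option(self, k4_setup):
        _, nets, _, _, _ = k4_setup
        space = nets[0].space
        sqrt_bc = inter.bhattacharyya("AAAA", "AAAC", nets, space, sqrt_form=True)
        prod_bc = inter.bhattacharyya("AAAA", "AAAC", nets, space, sqrt_form=False)
        assert prod_bc <= sqrt_bc + 1e-12


class TestSimilarityRatio:
    def test_deterministic_under_seed(self, k4_setup):
        _, nets, _, _, _ = k4_setup
        space = nets[0].space
        big = max(nets, key=lambda n: n.n)
        r1 = inter.similarity_ratio(big, nets, space, seed=42)
        r2 = inter.similarity_ratio(big, nets, space, seed=42)
        assert np.array_equal(r1.ratios, r2.ratios)

    def test_identical_spectra_give_unit_ratio(self, omega4):
        from gpmap.networks import GenotypeNetwork

        allnet = GenotypeNetwork("all", np.arange(omega4.n_sites), omega4)
        res = inter.similarity_ratio(allnet, [allnet], omega4, seed=0, exclude_shared=False, max_pairs=40)
        assert np.allclose(res.ratios, 1.0)

    def test_neighborhood_correlation_gives_ratio_above_one(self, omega8, synth10):
        table, _, _ = synth10
        from gpmap.networks import dominant_networks

        nets = list(dominant_networks(table, omega8).values())
        big = max(nets, key=lambda n: n.n)
        res = inter.similarity_ratio(big, nets, omega8, seed=1, max_pairs=120)
        assert res.mean > 1.0

    def test_too_small_network_rejected(self, omega4):
        from gpmap.networks import GenotypeNetwork

        net = GenotypeNetwork("x", omega4.indices_of(["AAAA", "AAAC"]), omega4)
        with pytest.raises(ValueError):
            inter.similarity_ratio(net, [net], omega4)


class TestUnboundInterface:
    def test_no_unbound_sites_gives_nan(self, omega4):
        from gpmap.networks import GenotypeNetwork

        net = GenotypeNetwork("a", omega4.indices_of(["AAAA"]), omega4)
        empty = GenotypeSet("unbound", frozenset())
        res = inter.unbound_interface([net], empty, omega4)
        assert res.isna().all()

    def test_exact_ratio_on_toy(self, k4_setup):
        table, nets, memberships, all_nodes, all_nbrs = k4_setup
        space = nets[0].space
        unbound = unbound_sites(table, tau=0.35)
        res = inter.unbound_interface(nets, unbound, space)
        f_unb = len(unbound) / len(all_nodes)
        ub = set(unbound.sites)
        for net in nets:
            vals = [
                len(all_nbrs[i] & ub) / len(all_nbrs[i]) for i in sorted(net.sites)
            ]
            expected = (sum(vals) / len(vals)) / f_unb
            assert res[net.phenotype_id] == pytest.approx(expected, abs=1e-12)

    def test_motif_clustered_binding_below_unity(self, omega8, synth10):
        table, _, _ = synth10
        from gpmap.networks import dominant_networks

        nets = list(dominant_networks(table, omega8).values())
        res = inter.unbound_interface(nets, unbound_sites(table), omega8)
        assert (res < 1.0).all()


class TestCovering:
    def test_matches_bruteforce(self, k4_setup):
        _, nets, memberships, _, all_nbrs = k4_setup
        space = nets[0].space
        for variant in ("neutral", "non-neutral"):
            focal = nets[0]
            got = inter.phenotype_space_covering(focal, nets, space, variant, max_radius=4)
            means, sds = bf.covering(
                set(focal.sites), memberships, all_nbrs, variant, max_radius=4
            )
            assert got["mean"].to_numpy() == pytest.approx(means, abs=1e-12)
            assert got["sd"].to_numpy() == pytest.approx(sds, abs=1e-12)

    def test_monotone_non_decreasing(self, k4_setup):
        _, nets, _, _, _ = k4_setup
        space = nets[0].space
        for variant in ("neutral", "non-neutral"):
            c = inter.phenotype_space_covering(nets[1], nets, space, variant, max_radius=5)
            assert (np.diff(c["mean"]) >= -1e-12).all()

    def test_neutral_plateaus_at_diameter(self, k4_setup):
        from gpmap.networks import path_metrics

        _, nets, _, _, _ = k4_setup
        space = nets[0].space
        focal = nets[0]
        diam, _ = path_metrics(focal)
        c = inter.phenotype_space_covering(focal, nets, space, "neutral", max_radius=8)
        tail = c.loc[c["n"] >= diam, "mean"]
        assert tail.nunique() == 1

    def test_disjoint_networks_neutral_covers_only_self(self, omega4):
        from gpmap.networks import GenotypeNetwork

        a = GenotypeNetwork("a", omega4.indices_of(["AAAA", "AAAC"]), omega4)
        b = GenotypeNetwork("b", omega4.indices_of(["CCGG"]), omega4)
        c = inter.phenotype_space_covering(a, [a, b], omega4, "neutral", max_radius=3)
        assert (c["mean"] == 0.5).all()

    def test_unknown_variant(self, k4_setup):
        _, nets, _, _, _ = k4_setup
        with pytest.raises(ValueError):
            inter.phenotype_space_covering(nets[0], nets, nets[0].space, "sideways")


class TestPhenotypeNetwork:
    def test_overlap_edge(self, omega4):
        from gpmap.networks import GenotypeNetwork

        a = GenotypeNetwork("a", omega4.indices_of(["AAAA", "AAAC"]), omega4)
        b = GenotypeNetwork("b", omega4.indices_of(["AAAC", "AACC"]), omega4)
        edges = inter.phenotype_network([a, b], omega4)
        assert edges.iloc[0]["relation"] == "overlap"

    def test_adjacent_by_mutation_edge(self, omega4):
        from gpmap.networks import GenotypeNetwork

        a = GenotypeNetwork("a", omega4.indices_of(["AAAA"]), omega4)
        b = GenotypeNetwork("b", omega4.indices_of(["AAAC"]), omega4)
        edges = inter.phenotype_network([a, b], omega4)
        assert edges.iloc[0]["relation"] == "adjacent-by-mutation"

    def test_distant_disjoint_no_edge(self, omega4):
        from gpmap.networks import GenotypeNetwork

        a = GenotypeNetwork("a", omega4.indices_of(["AAAA"]), omega4)
        b = GenotypeNetwork("b", omega4.indices_of(["CCGG"]), omega4)
        assert len(inter.phenotype_network([a, b], omega4)) == 0


class TestDomainCoarseGrain:
    def test_single_tf_domain_identical(self, omega4, toy_table4):
        from gpmap.pbm_io import TFRecord

        table, _ = toy_table4
        meta = {tf: TFRecord(tf, "sp", f"dom_{tf}") for tf in table.tf_ids}
        dsets = inter.domain_genotype_sets(table, meta, 0.35)
        for tf in table.tf_ids:
            assert dsets[f"dom_{tf}"].sites == bound_sites(table, tf, 0.35).sites

    def test_disjoint_union_adds(self, omega4):
        from conftest import make_table
        from gpmap.pbm_io import TFRecord

        table = make_table({"t1": {"AAAAAAAA": 0.4}, "t2": {"CCCCCCCC": 0.4}})
        meta = {t: TFRecord(t, "sp", "domX") for t in ("t1", "t2")}
        dsets = inter.domain_genotype_sets(table, meta, 0.35)
        assert len(dsets["domX"]) == 2

    def test_missing_domain_excluded(self, omega4, toy_table4, caplog):
        from gpmap.pbm_io import TFRecord

        table, _ = toy_table4
        meta = {"TF1": TFRecord("TF1", "sp", "domA")}
        dsets = inter.domain_genotype_sets(table, meta, 0.35)
        assert set(dsets) == {"domA"}


class TestExportHelpers:
    def test_diagonal_na(self):
        m = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["a", "b"])
        out = inter.matrix_for_export(m)
        assert math.isnan(out.loc["a", "a"]) and math.isnan(out.loc["b", "b"])
        assert out.loc["a", "b"] == 1.0

    def test_ordering(self):
        from gpmap.pbm_io import TFRecord

        meta = {
            "x": TFRecord("x", "s", "B"),
            "y": TFRecord("y", "s", "A"),
            "z": TFRecord("z", "s", "A"),
        }
        sizes = {"x": 5, "y": 9, "z": 2}
        assert inter.order_phenotypes(["x", "y", "z"], meta, sizes) == ["z", "y", "x"]
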
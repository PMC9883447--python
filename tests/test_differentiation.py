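"""Differentiation, distances, trees, Mantel and IBD against independent oracles."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from msbat.differentiation import (
    DistanceMatrix,
    bionj_tree,
    chord_distance,
    chord_distance_tree,
    fst_anova,
    geographic_distances,
    hierarchical_fstats,
    ibd_analysis,
    mantel_test,
    pairwise_fst,
)
from msbat.io import SampleMetadata
from msbat.simulate import (
    PopulationSpec,
    SimConfig,
    island_config,
    simulate_dataset,
    stepping_stone_dataset,
)

from conftest import make_meta, snp_from_rows


# ---------------------------------------------------------------------------
# Weir–Cockerham oracle: direct evaluation of the published a/b/c formulas,
# scalar loops, written independently of the package's ANOVA route.
# ---------------------------------------------------------------------------


def wc84_theta_oracle(dosage_by_pop: list[list[list[int]]]) -> float:
    """dosage_by_pop[p][i][l]: dosage (or None) of individual i of pop p."""
    num = den = 0.0
    n_loci = len(dosage_by_pop[0][0])
    for l in range(n_loci):
        pops = []
        for p in dosage_by_pop:
            ds = [ind[l] for ind in p if ind[l] is not None]
            if ds:
                pops.append(ds)
        r = len(pops)
        if r < 2:
            continue
        ns = [len(ds) for ds in pops]
        if sum(ns) < 3 or min(ns) < 1:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        ps = [sum(ds) / (2 * len(ds)) for ds in pops]
        hs = [sum(1 for d in ds if d == 1) / len(ds) for ds in pops]
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestPairwiseFst:
    def test_toy_matrix_matches_wc84_formula_oracle(self):
        dosage_by_pop = [
            [[0, 1, 2], [1, 1, 0], [2, None, 1], [0, 0, 0], [1, 2, 1], [0, 1, 2]],
            [[2, 2, 1], [1, 2, None], [2, 1, 1], [1, 2, 0], [2, 2, 2], [None, 1, 1]],
        ]
        expect = wc84_theta_oracle(dosage_by_pop)
        rows = []
        for p in dosage_by_pop:
            for ind in p:
                rows.append([-1 if d is None else d for d in ind])
        g = snp_from_rows(rows)
        meta = make_meta({f"i{k}": ("A" if k < 6 else "B") for k in range(12)})
        theta = pairwise_fst(g, meta).values[0, 1]
        assert theta == pytest.approx(expect, abs=1e-12)

    def test_fixed_pops_give_one_and_identical_pops_near_zero(self):
        g = snp_from_rows([[0, 0]] * 4 + [[2, 2]] * 4)
        meta = make_meta({f"i{k}": ("A" if k < 4 else "B") for k in range(8)})
        assert pairwise_fst(g, meta).values[0, 1] == pytest.approx(1.0)
        rng = np.random.default_rng(2)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 1000), size=(200, 1000)).astype(np.int8)
        g2 = snp_from_rows(d)
        meta2 = make_meta({f"i{k}": ("A" if k < 100 else "B") for k in range(200)})
        assert abs(pairwise_fst(g2, meta2).values[0, 1]) < 0.01

    def test_two_pop_pairwise_equals_collapsed_hierarchy(self, island4):
        """WC84 theta and the nested-ANOVA with one pop per country agree."""
        meta = island4.metadata
        keep = meta.table["population_id"].isin(["pop1", "pop2"])
        ids = meta.table.loc[keep, "individual_id"].tolist()
        idx = [island4.snp.individual_ids.index(i) for i in ids]
        g = island4.snp.select_individuals(np.array(idx))
        df = meta.table.loc[keep].copy()
        df["country_id"] = df["population_id"]  # each pop its own country
        h = hierarchical_fstats(g, SampleMetadata(df))
        theta = pairwise_fst(g, meta.subset(ids)).values[0, 1]
        assert h.fct == pytest.approx(theta, abs=1e-9)
        assert h.fst == pytest.approx(theta, abs=1e-9)

    def test_microsat_and_snp_encodings_agree(self, island4):
        from test_diversity import microsat_mirror

        sub = island4.snp.select_loci(np.arange(50))
        pw1 = pairwise_fst(sub, island4.metadata)
        pw2 = pairwise_fst(microsat_mirror(sub), island4.metadata)
        assert np.allclose(pw1.values, pw2.values, atol=1e-12)


class TestHierarchicalFstats:
    def test_identity_between_levels_holds_exactly(self, hier_dataset):
        h = hierarchical_fstats(hier_dataset.snp, hier_dataset.metadata)
        assert (1 - h.fsc) * (1 - h.fct) == pytest.approx(1 - h.fst, abs=1e-9)

    def test_no_country_structure_gives_fct_near_zero(self):
        cfg = SimConfig(
            populations=[PopulationSpec(f"p{k}", f"C{k % 3}", 20) for k in range(6)],
            n_snps=2000, f_ct=0.0, f_sc=0.05,
        )
        ds = simulate_dataset(cfg, seed=9)
        h = hierarchical_fstats(ds.snp, ds.metadata)
        assert abs(h.fct) < 0.01
        assert h.fsc > 0.02

    def test_no_substructure_within_countries_gives_fsc_near_zero(self):
        cfg = SimConfig(
            populations=[PopulationSpec(f"p{k}", f"C{k % 3}", 20) for k in range(6)],
            n_snps=2000, f_ct=0.08, f_sc=0.0,
        )
        ds = simulate_dataset(cfg, seed=9)
        h = hierarchical_fstats(ds.snp, ds.metadata)
        assert abs(h.fsc) < 0.01
        assert h.fct > 0.04

    def test_single_country_directs_to_pairwise(self, island4):
        with pytest.raises(ValueError, match="pairwise_fst"):
            hierarchical_fstats(island4.snp, island4.metadata)

    def test_bootstrap_cis_bracket_estimates(self, hier_dataset):
        h = hierarchical_fstats(hier_dataset.snp, hier_dataset.metadata)
        h.bootstrap(n_boot=200, seed=3)
        lo, hi = h.ci["F_CT"]
        assert lo <= h.fct <= hi
        lo, hi = h.ci["F_SC"]
        assert lo <= h.fsc <= hi


class TestChordDistance:
    def test_identical_and_disjoint_frequency_vectors(self):
        g = snp_from_rows([[0]] * 3 + [[2]] * 3)
        meta = make_meta({f"i{k}": ("A" if k < 3 else "B") for k in range(6)})
        d = chord_distance(g, meta)
        assert d.values[0, 1] == pytest.approx(2 / math.pi * math.sqrt(2), abs=1e-9)
        g2 = snp_from_rows([[1]] * 6)
        assert chord_distance(g2, meta).values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_and_triangle_inequality_on_random_triples(self, island4):
        d = chord_distance(island4.snp, island4.metadata).values
        assert np.allclose(d, d.T)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestBionj:
    def test_recovers_additive_topology_and_distances(self):
        # known unrooted topology ((A,B),(C,D),E) with additive path lengths
        newick = "((A:1.0,B:2.0):1.5,(C:0.5,D:1.0):2.0,E:3.0);"
        ref = dendropy.Tree.get(data=newick, schema="newick")
        pdm = ref.phylogenetic_distance_matrix()
        taxa = sorted(ref.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        mat = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
        tree = bionj_tree(DistanceMatrix(labels, mat))
        # path distances on the reconstructed tree reproduce the input exactly
        pdm2 = tree.phylogenetic_distance_matrix()
        tx2 = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm2.patristic_distance(tx2[a], tx2[b]) == pytest.approx(
                        mat[i, j], abs=1e-9
                    )

    def test_chord_tree_on_simulated_populations(self, hier_dataset):
        dm, tree = chord_distance_tree(hier_dataset.snp, hier_dataset.metadata)
        assert tree is not None
        labels = {t.label for t in tree.taxon_namespace}
        assert labels == set(dm.labels)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0

    def test_fewer_than_three_populations_returns_no_tree(self):
        g = snp_from_rows([[0], [1], [2], [1]])
        meta = make_meta({f"i{k}": ("A" if k < 2 else "B") for k in range(4)})
        dm, tree = chord_distance_tree(g, meta)
        assert tree is None


class TestGeographicDistances:
    @staticmethod
    def sphere_law_of_cosines(lon1, lat1, lon2, lat2):
        la1, la2 = math.radians(lat1), math.radians(lat2)
        dlon = math.radians(lon2 - lon1)
        return 6371.0 * math.acos(
            min(1.0, math.sin(la1) * math.sin(la2) + math.cos(la1) * math.cos(la2) * math.cos(dlon))
        )

    def test_haversine_against_independent_formula(self):
        coords = {"p1": (-8.18, 37.24), "p19": (20.95, 48.62)}
        meta = make_meta({"a": "p1", "b": "p19"}, coords=coords)
        d = geographic_distances(meta)
        expect = self.sphere_law_of_cosines(-8.18, 37.24, 20.95, 48.62)
        assert d.values[0, 1] == pytest.approx(expect, abs=0.1)

    def test_identical_and_antipodal_points(self):
        meta = make_meta(
            {"a": "p1", "b": "p2", "c": "p3"},
            coords={"p1": (10.0, 20.0), "p2": (10.0, 20.0), "p3": (-170.0, -20.0)},
        )
        d = geographic_distances(meta)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert d.values[0, 2] == pytest.approx(math.pi * 6371.0, abs=0.5)


def random_dm(rng, n, labels=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(labels or [f"x{i}" for i in range(n)], m)


class TestMantel:
    def test_matrix_against_itself(self):
        d = random_dm(np.random.default_rng(0), 8)
        res = mantel_test(d, d, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_relabeling_both_matrices_preserves_r(self):
        rng = np.random.default_rng(3)
        d1, d2 = random_dm(rng, 7), random_dm(rng, 7)
        r0 = mantel_test(d1, d2, n_perm=9, seed=0).r
        perm = rng.permutation(7)
        lab = [d1.labels[i] for i in perm]
        p1 = DistanceMatrix(lab, d1.values[np.ix_(perm, perm)])
        p2 = DistanceMatrix(lab, d2.values[np.ix_(perm, perm)])
        assert mantel_test(p1, p2, n_perm=9, seed=0).r == pytest.approx(r0)

    def test_invariance_to_monotone_linear_transform(self):
        rng = np.random.default_rng(4)
        d1, d2 = random_dm(rng, 6), random_dm(rng, 6)
        r0 = mantel_test(d1, d2, n_perm=99, seed=5)
        d2b = DistanceMatrix(d2.labels, 3.0 * d2.values + 0.0)
        r1 = mantel_test(d1, d2b, n_perm=99, seed=5)
        assert r1.r == pytest.approx(r0.r)
        assert r1.p_value == pytest.approx(r0.p_value)

    def test_agrees_with_skbio_reference(self):
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel

        rng = np.random.default_rng(6)
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        r_ref, p_ref, _ = mantel(
            SkDM(d1.values, d1.labels), SkDM(d2.values, d2.labels),
            permutations=0, alternative="greater",
        )
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_too_small_matrix_rejected(self):
        d = random_dm(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match="at least 4"):
            mantel_test(d, d)


class TestIbd:
    def test_stepping_stone_detects_isolation_by_distance(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            ds = stepping_stone_dataset(
                n_demes=8, n_per_deme=15, n_snps=400, step_f=0.02, seed=100 + rep
            )
            fst = pairwise_fst(ds.snp, ds.metadata)
            geo = geographic_distances(ds.metadata)
            res = ibd_analysis(fst, geo, n_perm=199, seed=rep)
            if res.p_value < 0.05:
                hits += 1
        assert hits >= 0.8 * n_rep
        assert res.slope > 0

    def test_negative_fst_floored_and_fst_one_rejected(self):
        labels = list("abcde")
        f = np.full((5, 5), 0.05)
        np.fill_diagonal(f, 0)
        f[0, 1] = f[1, 0] = -0.01
        rng = np.random.default_rng(0)
        geo = random_dm(rng, 5, labels)
        geo = DistanceMatrix(labels, geo.values + 1.0)
        res = ibd_analysis(DistanceMatrix(labels, f, "fst"), geo, n_perm=9, seed=0)
        assert np.isfinite(res.r)
        f[0, 1] = f[1, 0] = 1.0
        with pytest.raises(ValueError, match="linearis"):
            ibd_analysis(DistanceMatrix(labels, f, "fst"), geo, n_perm=9, seed=0)

    def test_mismatched_labels_rejected(self):
        rng = np.random.default_rng(0)
        d1 = random_dm(rng, 5)
        d2 = random_dm(rng, 5, labels=list("vwxyz"))
        with pytest.raises(ValueError, match="labels"):
            ibd_analysis(d1, d2)
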
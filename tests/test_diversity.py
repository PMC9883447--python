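"""Diversity estimators against independent hand/brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from msbat.diversity import (
    allele_frequencies,
    allelic_richness,
    basic_stats,
    bootstrap_ci,
    hs_envelope_bounds,
    per_locus_fis,
    population_specific_fst,
    population_summary,
)
from msbat.io import MicrosatGenotypes, SampleMetadata, SnpGenotypes
from msbat.simulate import island_config, simulate_dataset

from conftest import make_meta, snp_from_rows


def microsat_mirror(g: SnpGenotypes) -> MicrosatGenotypes:
    """Encode a biallelic dosage matrix as a 2-allele microsatellite table."""
    geno = np.zeros((g.n_individuals, g.n_loci, 2), dtype=np.int32)
    for c, pair in ((0, (101, 101)), (1, (101, 103)), (2, (103, 103))):
        geno[g.dosage == c] = pair
    geno[g.dosage == -1] = (0, 0)
    return MicrosatGenotypes(list(g.individual_ids), list(g.locus_ids), geno)


class TestAlleleFrequencies:
    def test_simple_counts_both_marker_types(self):
        g = snp_from_rows([[0], [1], [2]])
        meta = make_meta({"i0": "p", "i1": "p", "i2": "p"})
        aft = allele_frequencies(g, meta)
        assert aft.frequencies(0)[0].tolist() == [0.5, 0.5]
        ms = MicrosatGenotypes(
            ["a", "b"], ["m"], np.array([[[138, 138]], [[138, 142]]])
        )
        aft2 = allele_frequencies(ms, make_meta({"a": "p", "b": "p"}))
        assert aft2.frequencies(0)[0].tolist() == [0.75, 0.25]

    def test_all_missing_cell_flagged_absent(self):
        g = snp_from_rows([[-1, 0], [-1, 1]])
        meta = make_meta({"i0": "p", "i1": "p"})
        aft = allele_frequencies(g, meta)
        assert np.isnan(aft.frequencies(0)[0]).all()
        assert aft.n_genotypes[0, 0] == 0

    def test_empty_population_rejected(self):
        g = snp_from_rows([[0]])
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "individual_id": ["i0", "ghost"],
                    "population_id": ["p", "q"],
                    "country_id": ["c", "c"],
                }
            )
        )
        with pytest.raises(ValueError, match="zero individuals"):
            allele_frequencies(g, meta)


class TestBasicStats:
    def test_hand_computed_nei_chesser_example(self):
        # 10 individuals, 5 het + 5 hom-ref: H_O = 0.5,
        # H_S = (10/9)(1 - 0.625 - 0.025) = 0.38889
        g = snp_from_rows([[1]] * 5 + [[0]] * 5)
        meta = make_meta({f"i{k}": "p" for k in range(10)})
        bs = basic_stats(g, meta)
        assert bs.per_population.loc["p", "H_O"] == pytest.approx(0.5)
        assert bs.per_population.loc["p", "H_S"] == pytest.approx(0.3888888889, abs=1e-9)

    def test_monomorphic_locus_gives_zero_h_missing_fis(self):
        g = snp_from_rows([[0], [0], [0]])
        meta = make_meta({f"i{k}": "p" for k in range(3)})
        bs = basic_stats(g, meta)
        assert bs.per_population.loc["p", "H_O"] == 0
        assert bs.per_population.loc["p", "H_S"] == 0
        assert np.isnan(bs.per_population.loc["p", "F_IS"])
        assert np.isnan(bs.overall["F_ST"])

    def test_wahlund_direction_ht_exceeds_mean_hs(self):
        g = snp_from_rows([[0]] * 5 + [[2]] * 5)
        meta = make_meta({f"i{k}": ("p1" if k < 5 else "p2") for k in range(10)})
        bs = basic_stats(g, meta)
        assert bs.overall["H_S"] == pytest.approx(0.0)
        assert bs.overall["H_T"] > bs.overall["H_S"]

    def test_ht_never_below_mean_hs(self, island4):
        bs = basic_stats(island4.snp, island4.metadata)
        assert bs.overall["H_T"] >= bs.overall["H_S"] - 1e-12

    def test_orientation_invariance(self, island4):
        bs = basic_stats(island4.snp, island4.metadata)
        rng = np.random.default_rng(0)
        flipped = island4.snp.flipped(rng.choice(island4.snp.n_loci, 100, replace=False))
        bs2 = basic_stats(flipped, island4.metadata)
        pd.testing.assert_frame_equal(bs.per_population, bs2.per_population)
        assert bs.overall == pytest.approx(bs2.overall, nan_ok=True)

    def test_multiallelic_path_matches_biallelic(self, island4):
        """Encoding SNPs as 2-allele microsatellites changes nothing."""
        sub = island4.snp.select_loci(np.arange(60))
        bs1 = basic_stats(sub, island4.metadata)
        bs2 = basic_stats(microsat_mirror(sub), island4.metadata)
        assert np.allclose(
            bs1.per_population.to_numpy(), bs2.per_population.to_numpy(), atol=1e-12
        )
        for k in bs1.overall:
            assert bs1.overall[k] == pytest.approx(bs2.overall[k], abs=1e-12)

    def test_monomorphic_locus_removal_leaves_fstats_unchanged(self, island4):
        g = island4.snp
        meta = island4.metadata
        mono = np.zeros((g.n_individuals, 1), dtype=np.int8)
        with_mono = snp_from_rows(
            np.hstack([g.dosage, mono]),
            individual_ids=list(g.individual_ids),
            locus_ids=list(g.locus_ids) + ["mono"],
        )
        f1 = basic_stats(g, meta).per_population["F_IS"]
        f2 = basic_stats(with_mono, meta).per_population["F_IS"]
        pd.testing.assert_series_equal(f1, f2)
        b1 = population_specific_fst(g, meta)
        b2 = population_specific_fst(with_mono, meta)
        pd.testing.assert_series_equal(b1, b2)


class TestAllelicRichness:
    def test_fixed_locus_gives_one(self):
        g = snp_from_rows([[0]] * 5)
        meta = make_meta({f"i{k}": "p" for k in range(5)})
        assert allelic_richness(g, meta)["p"] == pytest.approx(1.0)

    def test_hand_example_counts_5_5_g2(self):
        # counts (5,5), g=2: 2 - 2*C(5,2)/C(10,2) = 1.5556
        g = snp_from_rows([[1]] * 5)
        meta = make_meta({f"i{k}": "p" for k in range(5)})
        ar = allelic_richness(g, meta, g_copies=2)
        assert ar["p"] == pytest.approx(2 - 2 * 10 / 45, abs=1e-12)

    def test_g_equal_total_copies_gives_observed_count(self):
        g = snp_from_rows([[1], [0], [2]])
        meta = make_meta({f"i{k}": "p" for k in range(3)})
        assert allelic_richness(g, meta, g_copies=6)["p"] == pytest.approx(2.0)

    def test_matches_exhaustive_subsample_enumeration(self):
        """Oracle: average distinct-allele count over all C(N, g) subsamples."""
        counts = [4, 3, 1]  # multiallelic, 8 copies
        gsub = 4
        copies = [a for a, c in enumerate(counts) for _ in range(c)]
        expect = np.mean(
            [len(set(s)) for s in itertools.combinations(copies, gsub)]
        )
        geno = np.array(
            [[[101, 101]], [[101, 101]], [[103, 105]], [[103, 103]]], dtype=np.int32
        )
        ms = MicrosatGenotypes(["a", "b", "c", "d"], ["m"], geno)
        meta = make_meta({x: "p" for x in "abcd"})
        ar = allelic_richness(ms, meta, g_copies=gsub)
        assert ar["p"] == pytest.approx(expect, abs=1e-9)

    def test_g_below_two_rejected(self, island4):
        with pytest.raises(ValueError):
            allelic_richness(island4.snp, island4.metadata, g_copies=1)


def beta_bruteforce(dosages: dict[str, list[int]]) -> dict[str, float]:
    """Exhaustive allele-copy pair enumeration oracle for beta (one locus)."""
    copies = {
        p: [a for d in ds for a in ([0] * (2 - d) + [1] * d)]
        for p, ds in dosages.items()
    }
    mw = {}
    for p, cp in copies.items():
        pairs = list(itertools.combinations(range(len(cp)), 2))
        mw[p] = np.mean([cp[i] == cp[j] for i, j in pairs])
    mbs = []
    for p, q in itertools.combinations(copies, 2):
        mbs.append(np.mean([a == b for a in copies[p] for b in copies[q]]))
    mb = np.mean(mbs)
    return {p: (mw[p] - mb) / (1 - mb) for p in copies}


class TestPopulationSpecificFst:
    def test_two_pops_fixed_for_alternate_alleles(self):
        g = snp_from_rows([[0]] * 3 + [[2]] * 3)
        meta = make_meta({f"i{k}": ("A" if k < 3 else "B") for k in range(6)})
        beta = population_specific_fst(g, meta)
        assert beta["A"] == pytest.approx(1.0)
        assert beta["B"] == pytest.approx(1.0)

    def test_asymmetric_case_matches_enumeration_oracle(self):
        dosages = {"A": [2, 2, 2, 1], "B": [1, 1, 0, 2]}
        expect = beta_bruteforce(dosages)
        rows = [[d] for d in dosages["A"] + dosages["B"]]
        g = snp_from_rows(rows)
        meta = make_meta(
            {f"i{k}": ("A" if k < 4 else "B") for k in range(8)}
        )
        beta = population_specific_fst(g, meta)
        assert beta["A"] == pytest.approx(expect["A"], abs=1e-9)
        assert beta["B"] == pytest.approx(expect["B"], abs=1e-9)
        assert beta["A"] > beta["B"]  # near-fixed pop is more differentiated

    def test_identical_panmictic_pops_near_zero(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(200, 800)).astype(np.int8)
        g = snp_from_rows(d)
        meta = make_meta({f"i{k}": f"p{k % 2}" for k in range(200)})
        beta = population_specific_fst(g, meta)
        assert abs(beta).max() < 0.01

    def test_single_population_rejected(self):
        g = snp_from_rows([[1], [0]])
        with pytest.raises(ValueError):
            population_specific_fst(g, make_meta({"i0": "p", "i1": "p"}))


class TestHsEnvelope:
    def test_printed_formula_example(self):
        lo, hi = hs_envelope_bounds(0.5, f_it=0.05, n=196)
        center, half = 0.475, 2 * math.sqrt(0.525 / 196)
        assert lo == pytest.approx(center - half, abs=1e-4)
        assert hi == pytest.approx(center + half, abs=1e-4)
        assert half == pytest.approx(0.1035, abs=1e-4)

    def test_degenerate_and_symmetric_cases(self):
        assert hs_envelope_bounds(0.0, 0.1, 50) == (0.0, 0.0)
        lo, hi = hs_envelope_bounds(0.5, 0.0, 100)
        assert (lo + hi) / 2 == pytest.approx(0.5)
        with pytest.raises(ValueError):
            hs_envelope_bounds(0.5, 0.0, 0)

    def test_variance_form_switch_narrows_band(self):
        lo1, hi1 = hs_envelope_bounds(0.5, 0.2, 100)
        lo2, hi2 = hs_envelope_bounds(0.5, 0.2, 100, variance_form=True)
        assert hi2 - lo2 < hi1 - lo1


class TestBootstrap:
    def test_identical_loci_zero_width_ci(self):
        g = snp_from_rows(np.tile([[1], [0], [2], [1]], (1, 30)))
        meta = make_meta({f"i{k}": "p" for k in range(4)})
        est, lo, hi = bootstrap_ci("H_S", g, meta, n_boot=200, seed=1)
        assert lo == pytest.approx(est) and hi == pytest.approx(est)

    def test_seed_reproducibility(self, island4):
        a = bootstrap_ci("F_IS", island4.snp, island4.metadata, n_boot=100, seed=7)
        b = bootstrap_ci("F_IS", island4.snp, island4.metadata, n_boot=100, seed=7)
        assert a == b

    def test_estimate_matches_direct_statistic(self, island4):
        est, lo, hi = bootstrap_ci("H_O", island4.snp, island4.metadata, n_boot=50, seed=3)
        bs = basic_stats(island4.snp, island4.metadata)
        assert est == pytest.approx(bs.overall["H_O"], abs=1e-12)
        assert lo <= est <= hi

    def test_too_few_replicates_rejected(self, island4):
        with pytest.raises(ValueError):
            bootstrap_ci("H_O", island4.snp, island4.metadata, n_boot=1)


class TestPerLocusFis:
    def test_pooled_all_het_locus_is_minus_one(self):
        g = snp_from_rows([[1], [1], [1], [1]])
        fis = per_locus_fis(g)
        assert fis[0] == pytest.approx(-1.0)

    def test_monomorphic_locus_is_nan(self):
        g = snp_from_rows([[0], [0]])
        assert np.isnan(per_locus_fis(g)[0])


class TestPopulationSummary:
    def test_table_has_all_columns(self, island4):
        t = population_summary(island4.snp, island4.metadata)
        assert list(t.columns) == ["H_O", "H_S", "F_IS", "A_R", "Beta"]
        assert list(t.index) == island4.metadata.populations
        assert ((t["H_O"] >= 0) & (t["H_O"] <= 1)).all()
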
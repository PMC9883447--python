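"""Canned validation experiments: parameter recovery, clustering resolution,
and statistical calibration of the package's tests and intervals.

Each function fixes one set of study conditions (sample sizes, differentiation
levels, locus counts — chosen to mirror the reference sampling design) and
reports rates or errors measured over seeded replicates.  They are the basis
of the acceptance checks and are runnable directly for diagnostics.
"""

from __future__ import annotations

import numpy as np

from . import differentiation as diff
from . import diversity as dv
from . import structure as st
from .differentiation import DistanceMatrix
from .simulate import (
    island_config,
    paper_like_config,
    simulate_dataset,
)

__all__ = [
    "hierarchical_recovery",
    "resolution_experiment",
    "mantel_null_calibration",
    "ibd_null_calibration",
    "bootstrap_coverage",
    "sexbias_power",
]


def hierarchical_recovery(n_reps: int = 20, seed: int = 0) -> dict[str, float]:
    """Recover F_CT/F_SC on the 19-population, 7-country design.

    Simulates the full preset (published sample sizes, 4,994 SNPs,
    F_CT = 0.058, F_SC = 0.019, population-concentrated missingness) and
    averages the hierarchical estimates over replicates.
    """
    cfg = paper_like_config()
    fct, fsc = [], []
    for rep in range(n_reps):
        ds = simulate_dataset(cfg, seed=seed * 1000 + rep)
        h = diff.hierarchical_fstats(ds.snp, ds.metadata)
        fct.append(h.fct)
        fsc.append(h.fsc)
    return {
        "mean_fct": float(np.mean(fct)),
        "mean_fsc": float(np.mean(fsc)),
        "true_fct": cfg.f_ct,
        "true_fsc": cfg.f_sc,
        "n_reps": n_reps,
    }


def _fit_k_range(g, k_max, n_reps, seed, max_iter=200, tol=1e-5):
    fits = []
    for K in range(1, k_max + 1):
        fits.extend(
            st.admixture_fit(g, K, n_reps=n_reps, seed=seed + K, max_iter=max_iter, tol=tol)
        )
    return fits


def resolution_experiment(
    n_replicates: int = 5,
    seed: int = 0,
    n_snps: int = 5000,
    subsample_sizes: tuple[int, ...] = (1000, 100),
) -> dict[str, float]:
    """Cluster-count detection and SNP-subsampling concordance.

    Conditions: 4 demes of 49 individuals (study-scale sample) at F = 0.06
    differentiation, ``n_snps`` SNPs; admixture over K = 1–7 with masked
    cross-entropy K selection.  Concordance compares modal assignments on
    random SNP subsets against the full-data fit (Hungarian-aligned), and is
    averaged over the replicate datasets: a single subset draw is dominated
    by draw-to-draw and dataset-to-dataset noise.
    """
    k_hits = 0
    conc: dict[int, list[float]] = {s: [] for s in subsample_sizes}
    for rep in range(n_replicates):
        ds = simulate_dataset(
            island_config(n_pops=4, n_per_pop=49, fst=0.06, n_snps=n_snps),
            seed=seed * 997 + rep,
        )
        fits = _fit_k_range(ds.snp, 7, n_reps=3, seed=seed * 131 + rep * 17)
        if st.select_k(fits).k_star == 4:
            k_hits += 1
        reference = st.best_fit([f for f in fits if f.K == 4])
        sub = st.snp_subsample_experiment(
            ds.snp, K=4, sizes=list(subsample_sizes), n_reps=3,
            seed=seed + 7 + rep, max_iter=200, reference=reference,
        )
        for s in subsample_sizes:
            conc[s].append(sub.concordance[s])
    out = {
        "k4_rate": k_hits / n_replicates,
        "n_replicates": n_replicates,
    }
    for s in subsample_sizes:
        out[f"concordance_{s}"] = float(np.mean(conc[s]))
    return out


def mantel_null_calibration(
    n_sims: int = 200, n_labels: int = 19, n_perm: int = 199, seed: int = 0
) -> dict[str, float]:
    """Type-I error of the Mantel test on independent random matrices."""
    rng = np.random.default_rng(seed)
    rejections = 0
    labels = [f"x{i}" for i in range(n_labels)]
    for _ in range(n_sims):
        a = rng.random((n_labels, n_labels))
        b = rng.random((n_labels, n_labels))
        d1 = DistanceMatrix(labels, (a + a.T) / 2)
        d2 = DistanceMatrix(labels, (b + b.T) / 2)
        res = diff.mantel_test(d1, d2, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        if res.p_value < 0.05:
            rejections += 1
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims}


def ibd_null_calibration(n_sims: int = 100, seed: int = 0) -> dict[str, float]:
    """Type-I error of the IBD test under an island model with no geography.

    Demes are differentiated (F = 0.05) but placed at random coordinates, so
    any detected distance–differentiation association is spurious.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for s in range(n_sims):
        cfg = island_config(n_pops=8, n_per_pop=15, fst=0.05, n_snps=300)
        ds = simulate_dataset(cfg, seed=seed * 100003 + s)
        tab = ds.metadata.table.copy()
        coords = {p: (rng.uniform(-10, 10), rng.uniform(35, 50)) for p in ds.metadata.populations}
        tab["longitude"] = [coords[p][0] for p in tab["population_id"]]
        tab["latitude"] = [coords[p][1] for p in tab["population_id"]]
        from .io import SampleMetadata

        meta = SampleMetadata(tab)
        fst = diff.pairwise_fst(ds.snp, meta)
        geo = diff.geographic_distances(meta)
        res = diff.ibd_analysis(fst, geo, n_perm=199, seed=int(rng.integers(2**31 - 1)))
        if res.p_value < 0.05:
            rejections += 1
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims}


def bootstrap_coverage(
    n_sims: int = 200, true_f: float = 0.05, n_loci: int = 500, seed: int = 0
) -> dict[str, float]:
    """Coverage of the 95% locus-bootstrap CI for multi-population F_ST.

    Two demes of 30 individuals at the stated F; per simulation the overall
    Weir–Cockerham theta is bootstrapped (1,000 resamples of loci, ratio of
    summed components) and coverage of the generating F is tallied.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for s in range(n_sims):
        cfg = island_config(n_pops=2, n_per_pop=30, fst=true_f, n_snps=n_loci)
        ds = simulate_dataset(cfg, seed=seed * 99991 + s)
        _, comp = diff.fst_anova(ds.snp, ds.metadata)
        a = np.nan_to_num(comp["population"])
        tot = a + np.nan_to_num(comp["individual"]) + np.nan_to_num(comp["gamete"])

        def theta(idx: np.ndarray) -> float:
            t = tot[idx].sum()
            return a[idx].sum() / t if t else np.nan

        _, lo, hi = dv.bootstrap_ci(
            theta, n_boot=1000, seed=int(rng.integers(2**31 - 1)), n_loci=n_loci
        )
        if lo <= true_f <= hi:
            covered += 1
    return {"coverage": covered / n_sims, "n_sims": n_sims, "nominal": 0.95}


def sexbias_power(
    n_sims: int = 50, male_dispersal: float = 0.3, seed: int = 0
) -> dict[str, float]:
    """Power of the mAIc test: 10 demes x 20 individuals, 1,000 SNPs,
    males dispersing at the stated rate, females philopatric."""
    hits = 0
    sign_ok = 0
    for s in range(n_sims):
        cfg = island_config(
            n_pops=10, n_per_pop=20, fst=0.08, n_snps=1000,
            male_dispersal=male_dispersal,
        )
        ds = simulate_dataset(cfg, seed=seed * 7919 + s)
        res = st.sexbias_test(ds.snp, ds.metadata, n_perm=0, seed=s)
        if res.maic_male < res.maic_female:
            sign_ok += 1
        if res.p_value < 0.05:
            hits += 1
    return {
        "power": hits / n_sims,
        "male_lower_rate": sign_ok / n_sims,
        "n_sims": n_sims,
    }
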
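"""Pairwise and hierarchical differentiation, genetic and geographic distances,
Mantel and isolation-by-distance tests.

F-statistics come from a method-of-moments nested analysis of variance of
allele indicators over the strata gamete < individual < population
(< country), with closed-form expected-mean-square coefficients for
unbalanced designs.  At two levels this is exactly the Weir–Cockerham (1984)
theta; the four-level version partitions F_ST into differentiation between
countries (F_CT) and between populations within countries (F_SC), with
(1 - F_SC)(1 - F_CT) = 1 - F_ST holding identically on the component scale.
Multi-locus estimates are ratios of locus-summed variance components.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .diversity import allele_frequencies
from .io import MISSING_DOSAGE, MicrosatGenotypes, SampleMetadata, SnpGenotypes

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "FStatHierarchy",
    "MantelResult",
    "IbdResult",
    "pairwise_fst",
    "fst_anova",
    "hierarchical_fstats",
    "chord_distance",
    "chord_distance_tree",
    "bionj_tree",
    "geographic_distances",
    "mantel_test",
    "ibd_analysis",
]


# ---------------------------------------------------------------------------
# Distance matrix container
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise values.

    Pairwise F_ST entries may be slightly negative and are stored as computed.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels),) * 2:
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (off-diagonal) entries, row-major order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.kind)


# ---------------------------------------------------------------------------
# Indicator expansion shared by SNP and microsatellite paths
# ---------------------------------------------------------------------------


def _indicator_matrix(
    g: SnpGenotypes | MicrosatGenotypes,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-allele indicator dosages.

    Returns ``(D, locus_of_column)`` where ``D[i, c]`` counts copies of allele
    ``c`` carried by individual ``i`` (NaN where missing).  SNPs contribute one
    column per locus (the alternate allele; the reference column is its mirror
    and adds no information to any ratio), microsatellites one column per
    observed allele.
    """
    if isinstance(g, SnpGenotypes):
        D = g.dosage.astype(float)
        D[g.dosage == MISSING_DOSAGE] = np.nan
        return D, np.arange(g.n_loci)
    cols: list[np.ndarray] = []
    locus_of: list[int] = []
    miss = g.missing_mask()
    for j in range(g.n_loci):
        for a in g.locus_alleles(j):
            d = (g.genotypes[:, j, :] == a).sum(axis=1).astype(float)
            d[miss[:, j]] = np.nan
            cols.append(d)
            locus_of.append(j)
    if not cols:
        return np.zeros((g.n_individuals, 0)), np.zeros(0, dtype=int)
    return np.stack(cols, axis=1), np.asarray(locus_of)


def _group_sums(D: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-group counts of individuals, allele copies, heterozygotes and d==2
    homozygotes for each indicator column (NaN-aware)."""
    nonmiss = ~np.isnan(D)
    K = D.shape[1]
    m = np.zeros((n_groups, K))
    s = np.zeros((n_groups, K))
    het = np.zeros((n_groups, K))
    hom2 = np.zeros((n_groups, K))
    np.add.at(m, codes, nonmiss.astype(float))
    np.add.at(s, codes, np.nan_to_num(D))
    np.add.at(het, codes, (D == 1).astype(float))
    np.add.at(hom2, codes, (D == 2).astype(float))
    return m, s, het, hom2


def _nested_components(
    D: np.ndarray,
    pop_codes: np.ndarray,
    pop_to_country: np.ndarray | None,
) -> dict[str, np.ndarray]:
    """Variance components per indicator column for the nested ANOVA.

    With ``pop_to_country`` None, a three-level design (population /
    individual / gamete) is used and the population component is the
    Weir–Cockerham between-population component ``a``.  Columns whose design
    is degenerate at any stratum (no degrees of freedom) have NaN components.
    """
    P = int(pop_codes.max()) + 1 if len(pop_codes) else 0
    m, s, het, hom2 = _group_sums(D, pop_codes, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_pop = s / (2.0 * m)
    M = m.sum(axis=0)
    n_obs_pops = (m > 0).sum(axis=0)
    # within-individual and among-individual sums of squares
    ss4 = 0.5 * het.sum(axis=0)
    with np.errstate(invalid="ignore"):
        ss3 = np.nansum((het + 4.0 * hom2) / 2.0 - 2.0 * m * p_pop**2, axis=0)
    df4 = M
    df3 = M - n_obs_pops
    n_p = 2.0 * m  # gamete counts per population

    if pop_to_country is None:
        # three levels: population stratum against the grand mean
        N = 2.0 * M
        with np.errstate(invalid="ignore", divide="ignore"):
            p_all = s.sum(axis=0) / N
            ss2 = np.nansum(n_p * (p_pop - p_all) ** 2, axis=0)
        df2 = n_obs_pops - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            k2 = (N - (n_p**2).sum(axis=0) / N) / df2
            ms4 = ss4 / df4
            ms3 = ss3 / df3
            ms2 = ss2 / df2
            sig4 = ms4
            sig3 = (ms3 - ms4) / 2.0
            sig2 = (ms2 - ms3) / k2
        ok = (df2 >= 1) & (df3 >= 1) & (df4 >= 1)
        bad = ~ok
        for arr in (sig2, sig3, sig4):
            arr[bad] = np.nan
        return {"population": sig2, "individual": sig3, "gamete": sig4}

    C = int(pop_to_country.max()) + 1
    country_codes = pop_to_country[pop_codes]
    mc, sc, _, _ = _group_sums(D, country_codes, C)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ctry = sc / (2.0 * mc)
    n_c = 2.0 * mc
    N = 2.0 * M
    with np.errstate(invalid="ignore", divide="ignore"):
        p_all = s.sum(axis=0) / N
    n_obs_ctry = (mc > 0).sum(axis=0)
    p_ctry_of_pop = p_ctry[pop_to_country]  # (P, K)
    n_c_of_pop = n_c[pop_to_country]
    with np.errstate(invalid="ignore"):
        ss2 = np.nansum(n_p * (p_pop - p_ctry_of_pop) ** 2, axis=0)
        ss1 = np.nansum(n_c * (p_ctry - p_all) ** 2, axis=0)
    df2 = n_obs_pops - n_obs_ctry
    df1 = n_obs_ctry - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_np2_over_nc = np.nansum(np.where(n_p > 0, n_p**2 / n_c_of_pop, 0.0), axis=0)
        k2 = (N - sum_np2_over_nc) / df2
        k1p = (sum_np2_over_nc - (n_p**2).sum(axis=0) / N) / df1
        k1c = (N - (n_c**2).sum(axis=0) / N) / df1
        ms4 = ss4 / df4
        ms3 = ss3 / df3
        ms2 = ss2 / df2
        ms1 = ss1 / df1
        sig4 = ms4
        sig3 = (ms3 - ms4) / 2.0
        sig2 = (ms2 - ms3) / k2
        sig1 = (ms1 - ms3 - k1p * sig2) / k1c
    ok = (df1 >= 1) & (df2 >= 1) & (df3 >= 1) & (df4 >= 1)
    bad = ~ok
    for arr in (sig1, sig2, sig3, sig4):
        arr[bad] = np.nan
    return {"country": sig1, "population": sig2, "individual": sig3, "gamete": sig4}


# ---------------------------------------------------------------------------
# Pairwise and overall Weir–Cockerham F_ST
# ---------------------------------------------------------------------------


def fst_anova(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> tuple[float, dict[str, np.ndarray]]:
    """Overall multi-population Weir–Cockerham F_ST (theta).

    Returns the estimate and the per-column variance components used, so
    callers can bootstrap over loci.
    """
    pop_codes, _, _ = meta.codes_for(g.individual_ids)
    D, _ = _indicator_matrix(g)
    comp = _nested_components(D, pop_codes, None)
    a = np.nansum(comp["population"])
    tot = a + np.nansum(comp["individual"]) + np.nansum(comp["gamete"])
    theta = a / tot if tot != 0 else np.nan
    return float(theta), comp


def pairwise_fst(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> DistanceMatrix:
    """Pairwise Weir–Cockerham theta between all population pairs.

    Components are summed over loci (and over alleles for multiallelic loci)
    before the ratio is taken.  A pair with no usable locus (some population
    never genotyped alongside the other) gets NaN.
    """
    pop_codes, _, _ = meta.codes_for(g.individual_ids)
    pops = meta.populations
    P = len(pops)
    if P < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    D, _ = _indicator_matrix(g)
    out = np.zeros((P, P))
    for p in range(P):
        for q in range(p + 1, P):
            sel = (pop_codes == p) | (pop_codes == q)
            sub = D[sel]
            codes = (pop_codes[sel] == q).astype(np.intp)
            comp = _nested_components(sub, codes, None)
            a = np.nansum(comp["population"])
            tot = a + np.nansum(comp["individual"]) + np.nansum(comp["gamete"])
            n_ok = np.isfinite(comp["population"]).sum()
            theta = a / tot if (n_ok > 0 and tot != 0) else np.nan
            out[p, q] = out[q, p] = theta
    return DistanceMatrix(pops, out, kind="fst")


# ---------------------------------------------------------------------------
# Hierarchical F-statistics
# ---------------------------------------------------------------------------


@dataclass
class FStatHierarchy:
    """Nested variance components and the hierarchical F-statistics.

    ``components`` are locus-summed variance components per stratum;
    ``F_CT = country / total``, ``F_SC = population / (total - country)``,
    ``F_ST = (country + population) / total`` and
    ``F_IS = individual / (individual + gamete)``.
    """

    components: dict[str, float]
    fst: float
    fsc: float
    fct: float
    fis: float
    per_column: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    locus_of_column: np.ndarray | None = field(repr=False, default=None)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> str:
        rows = [f"{k:>12s} component: {v: .6g}" for k, v in self.components.items()]
        stats = [
            ("F_ST", self.fst),
            ("F_SC", self.fsc),
            ("F_CT", self.fct),
            ("F_IS", self.fis),
        ]
        for name, v in stats:
            line = f"{name:>12s}: {v: .4f}"
            if name in self.ci:
                lo, hi = self.ci[name]
                line += f"  (95% CI {lo:.4f}–{hi:.4f})"
            rows.append(line)
        return "Hierarchical F-statistics\n" + "\n".join(rows)

    def bootstrap(self, n_boot: int = 1000, seed: int | None = None) -> None:
        """Percentile bootstrap CIs by resampling loci; stored in ``ci``."""
        if self.locus_of_column is None:
            raise ValueError("per-locus components unavailable")
        loci = np.unique(self.locus_of_column)
        L = len(loci)
        per_locus = {}
        for k, v in self.per_column.items():
            pl = np.zeros(L)
            np.add.at(pl, np.searchsorted(loci, self.locus_of_column), np.nan_to_num(v))
            per_locus[k] = pl
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, L, size=(n_boot, L))
        s = {k: v[idx].sum(axis=1) for k, v in per_locus.items()}
        c = s.get("country", 0.0)
        tot = c + s["population"] + s["individual"] + s["gamete"]
        with np.errstate(invalid="ignore", divide="ignore"):
            reps = {
                "F_ST": (c + s["population"]) / tot,
                "F_SC": s["population"] / (tot - c),
                "F_CT": c / tot if isinstance(c, np.ndarray) else np.zeros(n_boot),
                "F_IS": s["individual"] / (s["individual"] + s["gamete"]),
            }
        self.ci = {
            k: tuple(np.nanpercentile(v, [2.5, 97.5])) for k, v in reps.items()
        }


def hierarchical_fstats(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> FStatHierarchy:
    """Partition genetic variance over countries / populations / individuals /
    gametes and derive F_CT, F_SC, F_ST and F_IS.

    Only columns (locus-alleles) observed in at least two countries, with at
    least two populations total and one spare degree of freedom at each
    stratum contribute.  With a single country, use :func:`pairwise_fst` or
    :func:`fst_anova` instead.
    """
    pop_codes, pop_to_country, _ = meta.codes_for(g.individual_ids)
    if len(set(pop_to_country.tolist())) < 2:
        raise ValueError(
            "hierarchical F-statistics need >= 2 countries; use pairwise_fst "
            "for a flat population structure"
        )
    D, locus_of = _indicator_matrix(g)
    if len(pop_to_country) == len(set(pop_to_country.tolist())):
        # every population is its own country: the within-country stratum is
        # empty and the design collapses to the two-level (WC84) estimator
        comp3 = _nested_components(D, pop_codes, None)
        comp = {
            "country": comp3["population"],
            "population": np.zeros_like(comp3["population"]),
            "individual": comp3["individual"],
            "gamete": comp3["gamete"],
        }
    else:
        comp = _nested_components(D, pop_codes, pop_to_country)
    sums = {k: float(np.nansum(v)) for k, v in comp.items()}
    c, p_, i, ga = sums["country"], sums["population"], sums["individual"], sums["gamete"]
    tot = c + p_ + i + ga
    fct = c / tot if tot else np.nan
    fsc = p_ / (tot - c) if tot - c else np.nan
    fst = (c + p_) / tot if tot else np.nan
    fis = i / (i + ga) if i + ga else np.nan
    return FStatHierarchy(sums, fst, fsc, fct, fis, comp, locus_of)


# ---------------------------------------------------------------------------
# Chord distances and BIONJ tree
# ---------------------------------------------------------------------------


def chord_distance(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance between populations.

    Per locus ``D = (2/pi) * sqrt(2 * (1 - sum_i sqrt(p_i q_i)))``, averaged
    over the loci observed in both populations of a pair.
    """
    aft = allele_frequencies(g, meta)
    P = aft.n_pops
    acc = np.zeros((P, P))
    cnt = np.zeros((P, P))
    for j in range(aft.n_loci):
        f = aft.frequencies(j)
        obs = aft.n_genotypes[:, j] > 0
        sq = np.sqrt(np.where(np.isnan(f), 0.0, f))
        cos = np.clip(sq @ sq.T, 0.0, 1.0)
        d = (2.0 / np.pi) * np.sqrt(2.0 * (1.0 - cos))
        both = np.outer(obs, obs)
        acc += np.where(both, d, 0.0)
        cnt += both
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    np.fill_diagonal(mean, 0.0)
    return DistanceMatrix(aft.populations, mean, kind="chord")


def bionj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Unrooted tree from a distance matrix by the BIONJ algorithm.

    Variance-weighted neighbour joining (the reduction step pools the two
    merged rows with weights chosen to minimise the variance of the new
    distance estimates).  Negative branch lengths are clamped to 0.
    """
    n = dist.n
    if n < 3:
        raise ValueError("need at least 3 taxa for a tree")
    d = dist.values.astype(float).copy()
    v = d.copy()  # initial variance estimates equal the distances
    nodes: list[str] = [f"'{l}'" if any(ch in l for ch in " (),:;") else l for l in dist.labels]
    active = list(range(n))
    newick_of = {i: nodes[i] for i in active}
    while len(active) > 2:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        qmat = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(qmat, np.inf)
        ai, aj = np.unravel_index(np.argmin(qmat), qmat.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        others = [k for k in active if k not in (i, j)]
        if v[i, j] > 0:
            lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (2.0 * (r - 2) * v[i, j])
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        for k in others:
            d[i, k] = d[k, i] = lam * (d[i, k] - li) + (1.0 - lam) * (d[j, k] - lj)
            v[i, k] = v[k, i] = lam * v[i, k] + (1.0 - lam) * v[j, k] - lam * (1.0 - lam) * v[i, j]
        newick_of[i] = f"({newick_of[i]}:{li:.10g},{newick_of[j]}:{lj:.10g})"
        active.remove(j)
    i, j = active
    dij = max(d[i, j], 0.0)
    newick = f"({newick_of[i]}:{dij / 2.0:.10g},{newick_of[j]}:{dij / 2.0:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick")


def chord_distance_tree(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> tuple[DistanceMatrix, dendropy.Tree | None]:
    """Chord distances plus the BIONJ tree (None with fewer than 3 populations)."""
    dm = chord_distance(g, meta)
    tree = bionj_tree(dm) if dm.n >= 3 else None
    return dm, tree


# ---------------------------------------------------------------------------
# Geographic distances
# ---------------------------------------------------------------------------


def geographic_distances(meta: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between population coordinates."""
    coords = meta.population_coordinates()
    lon = np.radians(coords["longitude"].to_numpy(dtype=float))
    lat = np.radians(coords["latitude"].to_numpy(dtype=float))
    if np.isnan(lon).any() or np.isnan(lat).any():
        raise ValueError("missing population coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    dist = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return DistanceMatrix(list(coords.index), dist, kind="geographic_km")


# ---------------------------------------------------------------------------
# Mantel test and isolation by distance
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str

    def summary(self) -> str:
        return f"Mantel r = {self.r:.4f}, P = {self.p_value:.4g} ({self.tail}, {self.n_perm} permutations)"


def _mantel_r(a: np.ndarray, b: np.ndarray) -> float:
    i, j = np.tril_indices(a.shape[0], k=-1)
    x, y = a[i, j], b[i, j]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    Pearson r over the off-diagonal lower triangle; the rows and columns of
    the second matrix are permuted jointly; ``p = (#{r* >= r} + 1)/(n_perm+1)``
    for the ``greater`` tail (``less`` and ``two-sided`` analogous, the latter
    on ``|r|``).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    if d1.n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    r_obs = _mantel_r(d1.values, d2.values)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(d2.n)
        r_perm[b] = _mantel_r(d1.values, d2.values[np.ix_(perm, perm)])
    if tail == "greater":
        extreme = np.sum(r_perm >= r_obs)
    elif tail == "less":
        extreme = np.sum(r_perm <= r_obs)
    else:
        extreme = np.sum(np.abs(r_perm) >= abs(r_obs))
    p = (extreme + 1.0) / (n_perm + 1.0)
    return MantelResult(r_obs, float(p), n_perm, tail)


@dataclass
class IbdResult:
    mantel: MantelResult
    slope: float
    intercept: float
    linearized: bool

    @property
    def r(self) -> float:
        return self.mantel.r

    @property
    def p_value(self) -> float:
        return self.mantel.p_value

    def summary(self) -> str:
        form = "F_ST/(1-F_ST) ~ ln(km)" if self.linearized else "F_ST ~ km"
        return f"IBD ({form}): {self.mantel.summary()}, slope = {self.slope:.4g}"


def ibd_analysis(
    fst: DistanceMatrix,
    geo: DistanceMatrix,
    linearize: bool = True,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> IbdResult:
    """Isolation-by-distance test.

    With ``linearize`` (default), F_ST is transformed to ``F_ST/(1-F_ST)`` and
    geographic distance to its natural log (the standard linearised IBD
    regression); negative F_ST entries are floored at 0 before the transform
    (logged), and an entry of exactly 1 is an error.  The Mantel test runs on
    the (transformed) matrices; the slope comes from least squares over pairs.
    """
    if fst.labels != geo.labels:
        raise ValueError("matrices must share labels and order")
    f = fst.values.copy()
    gkm = geo.values.copy()
    if linearize:
        if np.any(np.isclose(f, 1.0)):
            raise ValueError("F_ST of 1 cannot be linearised (division by zero)")
        n_neg = int((f < 0).sum() // 2)
        if n_neg:
            logger.info("flooring %d negative pairwise F_ST entries at 0", n_neg)
        f = np.maximum(f, 0.0)
        f = f / (1.0 - f)
        off = ~np.eye(len(gkm), dtype=bool)
        if np.any(gkm[off] <= 0):
            raise ValueError("zero geographic distance between distinct populations")
        with np.errstate(divide="ignore"):
            gkm = np.where(off, np.log(gkm), 0.0)
        fmat = DistanceMatrix(fst.labels, f, "linearized_fst")
        gmat = DistanceMatrix(geo.labels, gkm, "log_km")
    else:
        fmat, gmat = fst, geo
    res = mantel_test(fmat, gmat, n_perm=n_perm, seed=seed, tail=tail)
    i, j = np.tril_indices(fmat.n, k=-1)
    x, y = gmat.values[i, j], fmat.values[i, j]
    slope, intercept = np.polyfit(x, y, 1)
    return IbdResult(res, float(slope), float(intercept), linearize)
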
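"""Population-level diversity and inbreeding estimators.

Implements the Nei & Chesser small-sample-corrected gene-diversity family
(H_O, H_S, H_T, F_IS), hypergeometric rarefaction of allelic richness, the
allele-matching population-specific F_ST (beta), the H_S-vs-frequency
confidence envelope used to screen outlier loci, and locus-resampling
bootstrap confidence intervals.

All estimators run on per-population allele counts, so biallelic SNP dosage
matrices and multiallelic microsatellite tables share one code path.

Conventions
-----------
* Per-locus gene diversity uses the small-sample correction
  ``H_S = n/(n-1) * (1 - sum(p^2) - H_O/(2n))`` with ``n`` the number of
  genotyped individuals (per population) or the harmonic mean of
  per-population counts (across populations).
* Multi-locus F-statistics are ratios of locus-summed components (ratio of
  averages), never averages of per-locus ratios.
* Loci unobserved in a population contribute only to statistics over the
  populations where they were observed (pairwise-complete).
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING_DOSAGE, MicrosatGenotypes, SampleMetadata, SnpGenotypes

__all__ = [
    "AlleleFrequencyTable",
    "BasicStats",
    "allele_frequencies",
    "basic_stats",
    "per_locus_fis",
    "allelic_richness",
    "population_specific_fst",
    "hs_envelope_bounds",
    "bootstrap_ci",
    "population_summary",
]


# ---------------------------------------------------------------------------
# Allele-count abstraction
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele counts and heterozygote tallies.

    ``counts[j]`` is a ``(n_pops, k_j)`` matrix of allele-copy counts at locus
    ``j``; ``n_genotypes`` and ``het_counts`` are ``(n_pops, n_loci)``.  A
    population with zero genotyped individuals at a locus has an all-zero
    count row there and is treated as unobserved (flagged absent) by every
    downstream statistic.
    """

    populations: list[str]
    locus_ids: list[str]
    counts: list[np.ndarray]
    n_genotypes: np.ndarray
    het_counts: np.ndarray

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def frequencies(self, j: int) -> np.ndarray:
        """Allele-frequency matrix at locus ``j``; NaN rows where unobserved."""
        c = self.counts[j].astype(float)
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, c / tot, np.nan)

    def harmonic_n(self, j: int) -> float:
        """Harmonic mean of per-population genotype counts at locus ``j``
        (populations with data only)."""
        n = self.n_genotypes[:, j]
        n = n[n > 0]
        if len(n) == 0:
            return np.nan
        return len(n) / np.sum(1.0 / n)


def _pop_codes(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> tuple[np.ndarray, list[str]]:
    pop_codes, _, _ = meta.codes_for(g.individual_ids)
    pops = meta.populations
    sizes = np.bincount(pop_codes, minlength=len(pops))
    empty = [pops[k] for k in range(len(pops)) if sizes[k] == 0]
    if empty:
        raise ValueError(f"populations with zero individuals in genotype data: {empty}")
    return pop_codes, pops


def allele_frequencies(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> AlleleFrequencyTable:
    """Tabulate allele counts, genotype counts and heterozygote counts per
    (population, locus) from either marker type."""
    pop_codes, pops = _pop_codes(g, meta)
    P = len(pops)
    if isinstance(g, SnpGenotypes):
        d = g.dosage
        miss = d == MISSING_DOSAGE
        nonmiss = (~miss).astype(np.int64)
        alt = np.where(miss, 0, d).astype(np.int64)
        het = (d == 1).astype(np.int64)
        n_geno = np.zeros((P, g.n_loci), dtype=np.int64)
        alt_c = np.zeros((P, g.n_loci), dtype=np.int64)
        het_c = np.zeros((P, g.n_loci), dtype=np.int64)
        np.add.at(n_geno, pop_codes, nonmiss)
        np.add.at(alt_c, pop_codes, alt)
        np.add.at(het_c, pop_codes, het)
        counts = [
            np.stack([2 * n_geno[:, j] - alt_c[:, j], alt_c[:, j]], axis=1)
            for j in range(g.n_loci)
        ]
        return AlleleFrequencyTable(pops, list(g.locus_ids), counts, n_geno, het_c)
    # microsatellites
    counts: list[np.ndarray] = []
    n_geno = np.zeros((P, g.n_loci), dtype=np.int64)
    het_c = np.zeros((P, g.n_loci), dtype=np.int64)
    for j in range(g.n_loci):
        alleles = g.locus_alleles(j)
        idx = {a: k for k, a in enumerate(alleles)}
        c = np.zeros((P, max(len(alleles), 1)), dtype=np.int64)
        for i in range(g.n_individuals):
            a, b = g.genotypes[i, j]
            if a == 0:
                continue
            p = pop_codes[i]
            c[p, idx[a]] += 1
            c[p, idx[b]] += 1
            n_geno[p, j] += 1
            if a != b:
                het_c[p, j] += 1
        counts.append(c)
    return AlleleFrequencyTable(pops, list(g.locus_ids), counts, n_geno, het_c)


# ---------------------------------------------------------------------------
# Basic statistics
# ---------------------------------------------------------------------------


@dataclass
class BasicStats:
    """Per-population and overall diversity statistics.

    ``per_population`` holds H_O, H_S, F_IS per population (locus means, F as
    ratio of means).  ``overall`` holds the across-population locus means
    (H_O, H_S, H_T), overall F_IS = 1 - H_O/H_S and overall
    F_ST = (H_T - H_S)/H_T, plus the pooled-sample H_O variant
    (``ho_pooled``: heterozygote proportion pooling all individuals per locus,
    averaged over loci) since both weightings are in circulation.
    Per-locus arrays are kept for bootstrap resampling.
    """

    per_population: pd.DataFrame
    overall: dict[str, float]
    per_locus: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return self.per_population.copy()

    def summary(self) -> str:
        lines = ["Basic diversity statistics", "", self.per_population.round(4).to_string(), ""]
        lines.append(
            "overall: "
            + "  ".join(f"{k}={v:.4f}" for k, v in self.overall.items() if np.isfinite(v))
        )
        return "\n".join(lines)


def _per_locus_stats(aft: AlleleFrequencyTable) -> pd.DataFrame:
    """Across-population per-locus H_O, H_S, H_T (Nei & Chesser corrections)."""
    L = aft.n_loci
    ho = np.full(L, np.nan)
    hs = np.full(L, np.nan)
    ht = np.full(L, np.nan)
    for j in range(L):
        n = aft.n_genotypes[:, j]
        obs = n > 0
        npop = int(obs.sum())
        if npop == 0:
            continue
        freqs = aft.frequencies(j)[obs]
        ho_p = aft.het_counts[obs, j] / n[obs]
        ho_l = ho_p.mean()
        sum_p2 = (freqs**2).sum(axis=1).mean()
        nh = aft.harmonic_n(j)
        if nh > 1:
            hs_l = nh / (nh - 1.0) * (1.0 - sum_p2 - ho_l / (2.0 * nh))
        else:
            hs_l = np.nan
        pbar = freqs.mean(axis=0)
        if np.isfinite(hs_l):
            ht_l = 1.0 - (pbar**2).sum() + hs_l / (nh * npop) - ho_l / (2.0 * nh * npop)
        else:
            ht_l = np.nan
        ho[j], hs[j], ht[j] = ho_l, hs_l, ht_l
    return pd.DataFrame({"H_O": ho, "H_S": hs, "H_T": ht}, index=aft.locus_ids)


def basic_stats(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> BasicStats:
    """Observed/expected heterozygosity and inbreeding coefficients.

    Per population: locus means of H_O and of the per-population
    small-sample-corrected H_S, and F_IS = 1 - mean(H_O)/mean(H_S).
    Overall: locus means of the across-population H_O, H_S, H_T;
    F_IS = 1 - H_O/H_S; F_ST = (H_T - H_S)/H_T.  Monomorphic-everywhere data
    yield NaN F-statistics, never zero.
    """
    aft = allele_frequencies(g, meta)
    P, L = aft.n_pops, aft.n_loci
    ho_pl = np.full((P, L), np.nan)
    hs_pl = np.full((P, L), np.nan)
    for j in range(L):
        n = aft.n_genotypes[:, j].astype(float)
        obs = n > 0
        freqs = aft.frequencies(j)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = aft.het_counts[:, j] / n
        ho_pl[obs, j] = ho[obs]
        n2 = n > 1
        sum_p2 = np.nansum(freqs**2, axis=1)
        hs = np.where(
            n2, n / np.maximum(n - 1.0, 1e-12) * (1.0 - sum_p2 - ho / (2.0 * n)), np.nan
        )
        hs_pl[n2, j] = hs[n2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ho_p = np.nanmean(ho_pl, axis=1)
        hs_p = np.nanmean(hs_pl, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fis_p = np.where(hs_p > 0, 1.0 - ho_p / hs_p, np.nan)
    per_pop = pd.DataFrame(
        {"H_O": ho_p, "H_S": hs_p, "F_IS": fis_p}, index=aft.populations
    )
    per_locus = _per_locus_stats(aft)
    ho_m = np.nanmean(per_locus["H_O"]) if np.isfinite(per_locus["H_O"]).any() else np.nan
    hs_m = np.nanmean(per_locus["H_S"]) if np.isfinite(per_locus["H_S"]).any() else np.nan
    ht_m = np.nanmean(per_locus["H_T"]) if np.isfinite(per_locus["H_T"]).any() else np.nan
    fis = 1.0 - ho_m / hs_m if hs_m and hs_m > 0 else np.nan
    fst = (ht_m - hs_m) / ht_m if ht_m and ht_m > 0 else np.nan
    # pooled-sample observed heterozygosity (all individuals, per locus)
    tot_het = aft.het_counts.sum(axis=0).astype(float)
    tot_n = aft.n_genotypes.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho_pool = np.where(tot_n > 0, tot_het / tot_n, np.nan)
    overall = {
        "H_O": float(ho_m),
        "H_S": float(hs_m),
        "H_T": float(ht_m),
        "F_IS": float(fis) if fis is not None else np.nan,
        "F_ST": float(fst) if fst is not None else np.nan,
        "ho_pooled": float(np.nanmean(ho_pool)),
    }
    return BasicStats(per_pop, overall, per_locus)


def per_locus_fis(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata | None = None
) -> np.ndarray:
    """Overall per-locus F_IS = 1 - H_O/H_S.

    Without metadata all individuals are pooled into one population (the form
    used by the SNP outlier filter).  Monomorphic loci return NaN.
    """
    if meta is None:
        ids = g.individual_ids
        meta = SampleMetadata(
            pd.DataFrame(
                {"individual_id": ids, "population_id": "pooled", "country_id": "pooled"}
            )
        )
    bs = basic_stats(g, meta)
    ho = bs.per_locus["H_O"].to_numpy()
    hs = bs.per_locus["H_S"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hs > 0, 1.0 - ho / hs, np.nan)


# ---------------------------------------------------------------------------
# Allelic richness (hypergeometric rarefaction)
# ---------------------------------------------------------------------------


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def allelic_richness(
    g: SnpGenotypes | MicrosatGenotypes,
    meta: SampleMetadata,
    g_copies: int | None = None,
) -> pd.Series:
    """Rarefied allelic richness per population.

    Per locus, ``A_R = sum_i [1 - C(N - N_i, g) / C(N, g)]`` — the expected
    number of distinct alleles in a random subsample of ``g`` allele copies —
    averaged over loci.  ``g`` defaults, per locus, to twice the smallest
    number of complete genotypes over populations at that locus.
    """
    if g_copies is not None and g_copies < 2:
        raise ValueError("g_copies must be >= 2")
    aft = allele_frequencies(g, meta)
    P, L = aft.n_pops, aft.n_loci
    ar = np.full((P, L), np.nan)
    for j in range(L):
        n = aft.n_genotypes[:, j]
        obs = n > 0
        if not obs.any():
            continue
        gj = g_copies if g_copies is not None else 2 * int(n[obs].min())
        c = aft.counts[j]
        for p in np.flatnonzero(obs):
            N = int(c[p].sum())
            if N < gj:
                continue  # cannot rarefy below requested depth
            Ni = c[p].astype(float)
            rest = N - Ni
            with np.errstate(invalid="ignore"):
                log_ratio = _log_comb(rest, gj) - _log_comb(float(N), gj)
            term = np.where(rest >= gj, np.exp(log_ratio), 0.0)
            ar[p, j] = float((1.0 - term).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(ar, axis=1)
    return pd.Series(out, index=aft.populations, name="A_R")


# ---------------------------------------------------------------------------
# Population-specific F_ST (beta, allele matching)
# ---------------------------------------------------------------------------


def _matching_components(
    aft: AlleleFrequencyTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerators (M_w^p - M_b) and denominators (1 - M_b) of beta.

    Returns arrays of shape (n_pops, n_loci); NaN where a population lacks two
    allele copies or fewer than two populations were observed at the locus.
    """
    P, L = aft.n_pops, aft.n_loci
    num = np.full((P, L), np.nan)
    den = np.full((P, L), np.nan)
    for j in range(L):
        c = aft.counts[j].astype(float)
        tot = c.sum(axis=1)
        obs = tot >= 2
        if obs.sum() < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = c / tot[:, None]
            mw = (c * (c - 1)).sum(axis=1) / (tot * (tot - 1))
        f = freqs[obs]
        mb_pair = f @ f.T
        k = len(f)
        mb = (mb_pair.sum() - np.trace(mb_pair)) / (k * (k - 1))
        num[obs, j] = mw[obs] - mb
        den[obs, j] = 1.0 - mb
    return num, den


def population_specific_fst(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> pd.Series:
    """Population-specific F_ST (beta) by allele matching.

    ``beta_p = (M_w^p - M_b) / (1 - M_b)`` where ``M_w^p`` is the probability
    that two distinct allele copies drawn within population ``p`` match and
    ``M_b`` the mean matching probability over all ordered population pairs.
    Multi-locus values are ratios of locus-summed components.
    """
    aft = allele_frequencies(g, meta)
    if aft.n_pops < 2:
        raise ValueError("population-specific F_ST needs at least two populations")
    num, den = _matching_components(aft)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        beta = np.nansum(num, axis=1) / np.nansum(den, axis=1)
    return pd.Series(beta, index=aft.populations, name="Beta")


# ---------------------------------------------------------------------------
# H_S confidence envelope (outlier-locus diagnostic)
# ---------------------------------------------------------------------------


def hs_envelope_bounds(
    p: float | np.ndarray,
    f_it: float,
    n: float,
    variance_form: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Confidence envelope for gene diversity given allele frequency.

    Center ``2p(1-p)(1-f_IT)`` with half-width
    ``2*sqrt(2p(1-p)(1+f_IT)/N)``; with ``variance_form=True`` the radical
    uses ``(1-f_IT)`` instead, the form a sampling-variance derivation gives.
    Lower bounds are clipped at 0.  Used to flag loci whose observed
    heterozygosity falls outside the band expected from their frequency and
    the global heterozygote deficit.
    """
    p = np.asarray(p, dtype=float)
    if n is None or n <= 0:
        raise ValueError("sample size N must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    center = 2.0 * p * (1.0 - p) * (1.0 - f_it)
    rad = 1.0 - f_it if variance_form else 1.0 + f_it
    half = 2.0 * np.sqrt(2.0 * p * (1.0 - p) * rad / n)
    return np.maximum(center - half, 0.0), center + half


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------

_STAT_KEYS = ("H_O", "H_S", "H_T", "F_IS", "F_ST", "Beta")


def bootstrap_ci(
    statistic: str | Callable[[np.ndarray], float],
    g: SnpGenotypes | MicrosatGenotypes | None = None,
    meta: SampleMetadata | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    n_loci: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI over loci for a multi-locus statistic.

    ``statistic`` is either one of ``H_O, H_S, H_T, F_IS, F_ST, Beta`` (the
    last is the mean beta over populations), recomputed per replicate as a
    ratio of summed per-locus components, or any callable mapping a resampled
    locus-index array to a scalar.  Returns ``(estimate, lower, upper)`` at
    the 2.5/97.5 percentiles.  Fully reproducible given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    if callable(statistic):
        if n_loci is None:
            if g is None:
                raise ValueError("need n_loci (or genotypes) for a callable statistic")
            n_loci = g.n_loci
        est = float(statistic(np.arange(n_loci)))
        reps = np.array(
            [statistic(rng.integers(0, n_loci, n_loci)) for _ in range(n_boot)]
        )
    else:
        if g is None or meta is None:
            raise ValueError("named statistics need genotypes and metadata")
        if statistic not in _STAT_KEYS:
            raise ValueError(f"unknown statistic {statistic!r}")
        L = g.n_loci
        if L < 20:
            warnings.warn(f"only {L} loci: bootstrap CI will be unstable", stacklevel=2)
        if statistic == "Beta":
            aft = allele_frequencies(g, meta)
            num, den = _matching_components(aft)
            num = np.nan_to_num(num)
            den = np.nan_to_num(den)

            def value(idx: np.ndarray) -> float:
                with np.errstate(invalid="ignore", divide="ignore"):
                    b = num[:, idx].sum(axis=1) / den[:, idx].sum(axis=1)
                return float(np.nanmean(b))

        else:
            bs = basic_stats(g, meta)
            ho = np.nan_to_num(bs.per_locus["H_O"].to_numpy())
            hs = np.nan_to_num(bs.per_locus["H_S"].to_numpy())
            ht = np.nan_to_num(bs.per_locus["H_T"].to_numpy())
            ok = np.isfinite(bs.per_locus["H_S"].to_numpy()).astype(float)

            def value(idx: np.ndarray) -> float:
                m = ok[idx].sum()
                if m == 0:
                    return np.nan
                if statistic == "H_O":
                    return float(ho[idx].sum() / m)
                if statistic == "H_S":
                    return float(hs[idx].sum() / m)
                if statistic == "H_T":
                    return float(ht[idx].sum() / m)
                if statistic == "F_IS":
                    s = hs[idx].sum()
                    return float(1.0 - ho[idx].sum() / s) if s > 0 else np.nan
                s = ht[idx].sum()
                return float((s - hs[idx].sum()) / s) if s > 0 else np.nan

        est = value(np.arange(L))
        idx_mat = rng.integers(0, L, size=(n_boot, L))
        reps = np.array([value(idx_mat[b]) for b in range(n_boot)])
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return float(est), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Table-1-style per-population summary
# ---------------------------------------------------------------------------


def population_summary(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> pd.DataFrame:
    """Per-population H_O, H_S, F_IS, A_R and Beta in one table."""
    bs = basic_stats(g, meta)
    out = bs.per_population.copy()
    out["A_R"] = allelic_richness(g, meta)
    out["Beta"] = population_specific_fst(g, meta)
    return out
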
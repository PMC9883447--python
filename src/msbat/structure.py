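"""Individual-level analyses: genotype PCA, regularized-NMF admixture with
masked cross-entropy, K selection, the SNP-subsampling resolution experiment,
and the mAIc sex-biased-dispersal test.

The admixture model factorizes the one-hot-encoded genotype matrix
``X (n x 3L)`` as ``X ~ Q G`` with ``Q`` the row-stochastic ancestry matrix
(n x K) and ``G`` per-cluster genotype-class frequencies (each cluster/locus
triplet a probability vector over dosage classes {0,1,2}).  Optimisation is
block projected-gradient descent on the penalized least-squares objective

    || W o (X - Q G) ||^2  +  alpha ||Q||^2

where ``W`` marks the training entries (non-missing, not held out) and
``alpha`` is a ridge weight on ancestries.  Held-out and missing entries are
EM-filled with the current prediction before each block update, which makes
the masked objective provably non-increasing; the exact simplex projections
keep Q rows and G class-triplets on their probability simplices after every
iteration.  Model fit across K is compared by masked cross-entropy: the
negative mean log predicted probability of the held-out genotype classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .io import MISSING_DOSAGE, MicrosatGenotypes, SampleMetadata, SnpGenotypes

__all__ = [
    "PcaResult",
    "genotype_pca",
    "AdmixtureModel",
    "AdmixtureFit",
    "admixture_fit",
    "KSelection",
    "select_k",
    "SubsampleResult",
    "snp_subsample_experiment",
    "ancestry_concordance",
    "SexBiasResult",
    "sexbias_test",
    "assignment_indices",
]

PROB_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """Scores and variance fractions of a genotype PCA."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    individual_ids: list[str]
    imputation: str = "column_mean"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.individual_ids, columns=cols)


def _numeric_matrix(g: SnpGenotypes | MicrosatGenotypes) -> np.ndarray:
    """Dosage matrix with NaN for missing; microsats expand to per-allele
    indicator dosages."""
    if isinstance(g, SnpGenotypes):
        X = g.dosage.astype(float)
        X[g.dosage == MISSING_DOSAGE] = np.nan
        return X
    cols = []
    miss = g.missing_mask()
    for j in range(g.n_loci):
        for a in g.locus_alleles(j):
            d = (g.genotypes[:, j, :] == a).sum(axis=1).astype(float)
            d[miss[:, j]] = np.nan
            cols.append(d)
    return np.stack(cols, axis=1)


def genotype_pca(
    g: SnpGenotypes | MicrosatGenotypes,
    n_axes: int = 10,
    scale: bool = False,
) -> PcaResult:
    """PCA of individual genotypes.

    Columns are centered; missing entries are imputed by the column mean
    (i.e. contribute zero after centering); all-missing columns are dropped
    with a warning.  ``scale`` additionally standardises columns to unit
    variance (off by default).
    """
    if g.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    X = _numeric_matrix(g)
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing columns", stacklevel=2)
        X = X[:, ~all_missing]
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 informative loci")
    mu = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), 0.0, X - mu)
    if scale:
        sd = np.nanstd(X, axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    k = min(n_axes, len(s))
    return PcaResult(U[:, :k] * s[:k], ratio[:k], list(g.individual_ids))


# ---------------------------------------------------------------------------
# Simplex projections (Duchi et al. algorithm, vectorized)
# ---------------------------------------------------------------------------


def _project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of V onto the probability simplex."""
    n, k = V.shape
    if k == 3:  # closed form, avoids the per-row sort (hot path for G updates)
        a = V.max(axis=1)
        c = V.min(axis=1)
        b = V.sum(axis=1) - a - c
        cond2 = b - a + 1.0 > 0
        cond3 = cond2 & (2.0 * c - a - b + 1.0 > 0)
        rho = 1.0 + cond2 + cond3
        csum = np.where(cond3, a + b + c, np.where(cond2, a + b, a))
        theta = (csum - 1.0) / rho
        return np.maximum(V - theta[:, None], 0.0)
    mu = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(mu, axis=1) - 1.0
    ar = np.arange(1, k + 1)
    cond = mu - css / ar > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(V - theta[:, None], 0.0)


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    """A fitted admixture factorization at one K for one repetition."""

    K: int
    Q: np.ndarray
    G: np.ndarray  # (K, L, 3) genotype-class frequencies per cluster
    cross_entropy: float
    mask_fraction: float
    alpha: float
    seed: int
    n_iter: int
    converged: bool
    objective: float
    individual_ids: list[str] = field(default_factory=list)

    def ancestry_frame(self) -> pd.DataFrame:
        cols = [f"cluster{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.individual_ids, columns=cols)

    def summary(self) -> str:
        return (
            f"Admixture K={self.K}: masked cross-entropy {self.cross_entropy:.4f}, "
            f"{self.n_iter} iterations ({'converged' if self.converged else 'NOT converged'}), "
            f"alpha={self.alpha:g}, mask={self.mask_fraction:.0%}, seed={self.seed}"
        )


class AdmixtureModel:
    """Regularized-NMF admixture model for a biallelic dosage matrix.

    Parameters mirror the analysis protocol: a fraction of non-missing
    genotype entries is blinded per repetition for cross-entropy estimation,
    and the ridge weight on ancestries defaults to 100.
    """

    def __init__(
        self,
        g: SnpGenotypes,
        K: int,
        mask_fraction: float = 0.10,
        alpha: float = 100.0,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> None:
        if not isinstance(g, SnpGenotypes):
            raise TypeError("admixture requires a biallelic dosage matrix")
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > g.n_individuals:
            raise ValueError(f"K={K} exceeds the number of individuals ({g.n_individuals})")
        if not 0 <= mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")
        self.g = g
        self.K = K
        self.mask_fraction = mask_fraction
        self.alpha = float(alpha)
        self.max_iter = max_iter
        self.tol = tol
        d = g.dosage
        self._missing = d == MISSING_DOSAGE
        n, L = d.shape
        X = np.zeros((n, L, 3))
        for c in range(3):
            X[:, :, c] = d == c
        self._X = X.reshape(n, 3 * L)

    # -- internals ---------------------------------------------------------

    def _draw_mask(self, rng: np.random.Generator) -> np.ndarray:
        """Held-out entry mask (n x L) over non-missing genotype entries."""
        nonmiss = ~self._missing
        idx = np.flatnonzero(nonmiss.ravel())
        n_mask = int(round(self.mask_fraction * len(idx)))
        mask = np.zeros(self._missing.shape, dtype=bool)
        if n_mask:
            chosen = rng.choice(idx, size=n_mask, replace=False)
            mask.ravel()[chosen] = True
        return mask

    @staticmethod
    def _expand(mask2d: np.ndarray) -> np.ndarray:
        return np.repeat(mask2d, 3, axis=1)

    def fit(self, seed: int = 0, _callback=None, inner_steps: int = 12) -> AdmixtureFit:
        """Run one repetition: draw the held-out mask, optimize, score.

        Each outer iteration EM-fills the unobserved entries with the current
        prediction, then runs ``inner_steps`` projected-gradient steps on each
        block (cheap: the Gram and cross products are fixed within a block).
        """
        rng = np.random.default_rng(seed)
        n, L = self._missing.shape
        K = self.K
        mask = self._draw_mask(rng)
        unobserved = mask | self._missing  # filled by EM, excluded from training
        unobs3 = self._expand(unobserved.reshape(n, L)).reshape(n, 3 * L)
        X = self._X

        Q = rng.dirichlet(np.ones(K), size=n)
        # init G near the global class frequencies, perturbed per cluster
        train = ~unobs3
        counts = (X * train).sum(axis=0).reshape(L, 3)
        gfreq = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
        G = np.clip(gfreq[None, :, :] * (1.0 + 0.1 * rng.standard_normal((K, L, 3))), 1e-3, None)
        G = (G / G.sum(axis=2, keepdims=True)).reshape(K, 3 * L)

        unobs_idx = np.flatnonzero(unobs3.ravel())
        prev = np.inf
        n_iter = 0
        converged = False
        Xf = X.copy()
        P = Q @ G

        def fill() -> None:
            Xf.ravel()[unobs_idx] = P.ravel()[unobs_idx]

        for n_iter in range(1, self.max_iter + 1):
            fill()
            # Q block: gradient pieces constant given (G, Xf)
            GGt = G @ G.T
            B = Xf @ G.T
            LQ = 2.0 * (np.linalg.norm(GGt, 2) + self.alpha)
            for _ in range(inner_steps):
                grad_q = 2.0 * (Q @ GGt - B) + 2.0 * self.alpha * Q
                Q = _project_rows_to_simplex(Q - grad_q / LQ)
            # refill with the updated Q before the G block
            np.dot(Q, G, out=P)
            fill()
            QtQ = Q.T @ Q
            C = Q.T @ Xf
            LG = 2.0 * max(np.linalg.norm(QtQ, 2), 1e-12)
            for _ in range(inner_steps):
                grad_g = 2.0 * (QtQ @ G - C)
                Gn = (G - grad_g / LG).reshape(K * L, 3)
                G = _project_rows_to_simplex(Gn).reshape(K, 3 * L)
            np.dot(Q, G, out=P)
            # training objective (unobserved residuals zeroed)
            D = P - X
            D.ravel()[unobs_idx] = 0.0
            obj = float(np.dot(D.ravel(), D.ravel()) + self.alpha * (Q**2).sum())
            if _callback is not None:
                _callback(Q, G.reshape(K, L, 3), obj)
            if np.isfinite(prev) and prev - obj <= self.tol * max(prev, 1.0):
                converged = True
                prev = obj
                break
            prev = obj

        ce = self._cross_entropy(Q, G, mask)
        return AdmixtureFit(
            K=K,
            Q=Q,
            G=G.reshape(K, L, 3),
            cross_entropy=ce,
            mask_fraction=self.mask_fraction,
            alpha=self.alpha,
            seed=seed,
            n_iter=n_iter,
            converged=converged,
            objective=prev,
            individual_ids=list(self.g.individual_ids),
        )

    def _cross_entropy(self, Q: np.ndarray, G: np.ndarray, mask: np.ndarray) -> float:
        n, L = self._missing.shape
        if not mask.any():
            return np.nan
        P = (Q @ G).reshape(n, L, 3)
        P = np.clip(P, PROB_FLOOR, None)
        P = P / P.sum(axis=2, keepdims=True)
        i, j = np.nonzero(mask)
        obs = self.g.dosage[i, j]
        return float(-np.mean(np.log(P[i, j, obs])))

    def fit_reps(self, n_reps: int = 20, seed: int = 0) -> list[AdmixtureFit]:
        """Independent repetitions, each with its own held-out mask; the
        repetition index is folded into the seed."""
        return [
            self.fit(seed=(int(seed) * 1000 + rep) % (2**31 - 1)) for rep in range(n_reps)
        ]


def admixture_fit(
    g: SnpGenotypes,
    K: int,
    n_reps: int = 20,
    mask_fraction: float = 0.10,
    alpha: float = 100.0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> list[AdmixtureFit]:
    """All repetitions of the admixture factorization at one K."""
    model = AdmixtureModel(g, K, mask_fraction=mask_fraction, alpha=alpha, max_iter=max_iter, tol=tol)
    return model.fit_reps(n_reps=n_reps, seed=seed)


def best_fit(fits: list[AdmixtureFit]) -> AdmixtureFit:
    """Repetition with the lowest masked cross-entropy."""
    return min(fits, key=lambda f: (np.inf if np.isnan(f.cross_entropy) else f.cross_entropy))


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------


@dataclass
class KSelection:
    k_star: int
    table: pd.DataFrame  # one row per (K, rep): cross-entropy

    def summary(self) -> str:
        med = self.table.groupby("K")["cross_entropy"].median()
        lines = [f"K selection: K* = {self.k_star}", "median masked cross-entropy by K:"]
        lines += [f"  K={k}: {v:.4f}" for k, v in med.items()]
        return "\n".join(lines)


def select_k(fits: list[AdmixtureFit]) -> KSelection:
    """Choose K by the cross-entropy plateau rule.

    K* is the smallest K whose median masked cross-entropy lies within one
    median absolute deviation (of the repetitions at the best K) of the global
    minimum median.  Flat cross-entropy across K therefore gives K* = 1.
    """
    rows = [(f.K, f.cross_entropy) for f in fits]
    table = pd.DataFrame(rows, columns=["K", "cross_entropy"])
    ks = sorted(table["K"].unique())
    if len(ks) < 2:
        warnings.warn("only one K supplied; returning it as-is", stacklevel=2)
        return KSelection(int(ks[0]), table)
    med = table.groupby("K")["cross_entropy"].median()
    k_best = int(med.idxmin())
    reps_best = table.loc[table["K"] == k_best, "cross_entropy"].to_numpy()
    mad = float(np.median(np.abs(reps_best - np.median(reps_best))))
    thresh = med.min() + mad
    k_star = int(min(k for k in ks if med[k] <= thresh + 1e-15))
    return KSelection(k_star, table)


# ---------------------------------------------------------------------------
# SNP-subsampling resolution experiment
# ---------------------------------------------------------------------------


def _align_clusters(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Permute columns of ``q`` to best match ``q_ref`` (Hungarian assignment
    on the cross-correlation matrix)."""
    K = q_ref.shape[1]
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            sa, sb = q_ref[:, a].std(), q[:, b].std()
            corr[a, b] = (
                np.corrcoef(q_ref[:, a], q[:, b])[0, 1] if sa > 0 and sb > 0 else 0.0
            )
    _, cols = linear_sum_assignment(-corr)
    return q[:, cols]


def ancestry_concordance(q_ref: np.ndarray, q: np.ndarray) -> float:
    """Mean per-individual agreement of modal cluster assignment after optimal
    cluster relabeling; invariant to cluster permutation of either matrix."""
    if q_ref.shape != q.shape:
        raise ValueError("ancestry matrices differ in shape")
    q_al = _align_clusters(q_ref, q)
    return float(np.mean(q_ref.argmax(axis=1) == q_al.argmax(axis=1)))


@dataclass
class SubsampleResult:
    sizes: list[int]
    concordance: dict[int, float]
    fits: dict[int, AdmixtureFit]
    reference: AdmixtureFit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_snps": self.sizes, "concordance": [self.concordance[s] for s in self.sizes]}
        )


def snp_subsample_experiment(
    g: SnpGenotypes,
    K: int,
    sizes: list[int] = (3000, 2000, 1000, 500, 200, 100),
    n_reps: int = 5,
    seed: int = 0,
    alpha: float = 100.0,
    mask_fraction: float = 0.10,
    max_iter: int = 500,
    reference: AdmixtureFit | None = None,
) -> SubsampleResult:
    """Re-fit the admixture model on random SNP subsets and measure how well
    the full-data ancestry is recovered.

    Loci are sampled without replacement per size; concordance is the modal-
    assignment agreement with the full-data fit after Hungarian relabeling.
    """
    sizes = list(sizes)
    for s in sizes:
        if s > g.n_loci:
            raise ValueError(f"subset size {s} exceeds available loci ({g.n_loci})")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = best_fit(
            admixture_fit(g, K, n_reps=n_reps, alpha=alpha, mask_fraction=mask_fraction,
                          seed=seed, max_iter=max_iter)
        )
    conc: dict[int, float] = {}
    fits: dict[int, AdmixtureFit] = {}
    for s in sizes:
        if s == g.n_loci:
            fits[s] = reference
            conc[s] = 1.0
            continue
        loci = rng.choice(g.n_loci, size=s, replace=False)
        sub = g.select_loci(np.sort(loci))
        f = best_fit(
            admixture_fit(sub, K, n_reps=n_reps, alpha=alpha, mask_fraction=mask_fraction,
                          seed=int(rng.integers(2**31 - 1)), max_iter=max_iter)
        )
        fits[s] = f
        conc[s] = ancestry_concordance(reference.Q, f.Q)
    return SubsampleResult(sizes, conc, fits, reference)


# ---------------------------------------------------------------------------
# Sex-biased dispersal (mAIc)
# ---------------------------------------------------------------------------


def assignment_indices(
    g: SnpGenotypes | MicrosatGenotypes, meta: SampleMetadata
) -> pd.DataFrame:
    """Corrected assignment index (AIc) per individual.

    AI is the log10 probability of the individual's multilocus genotype in its
    sampled population under Hardy–Weinberg proportions, with leave-one-out
    allele frequencies (the individual's own alleles removed from the counts)
    floored at 1/(2n) so private alleles of immigrants stay finite.  AIc
    centers AI within each population, so it sums to ~0 per population and
    immigrant genotypes score negative.
    """
    pop_codes, _, sex_codes = meta.codes_for(g.individual_ids)
    n_ind = g.n_individuals
    P = int(pop_codes.max()) + 1
    ai = np.zeros(n_ind)
    if isinstance(g, SnpGenotypes):
        d = g.dosage
        miss = d == MISSING_DOSAGE
        nonmiss = ~miss
        alt = np.where(miss, 0, d).astype(float)
        pop_alt = np.zeros((P, g.n_loci))
        pop_n = np.zeros((P, g.n_loci))
        np.add.at(pop_alt, pop_codes, alt)
        np.add.at(pop_n, pop_codes, nonmiss.astype(float))
        n_loo = pop_n[pop_codes] - nonmiss  # genotypes left after removing self
        with np.errstate(invalid="ignore", divide="ignore"):
            p_loo = (pop_alt[pop_codes] - alt) / (2.0 * n_loo)
        floor = 1.0 / (2.0 * np.maximum(pop_n[pop_codes], 1.0))
        p_loo = np.clip(p_loo, floor, 1.0 - floor)
        usable = nonmiss & (n_loo >= 1)
        logp = np.where(
            d == 1,
            np.log10(2.0) + np.log10(p_loo) + np.log10(1.0 - p_loo),
            np.where(d == 2, 2.0 * np.log10(p_loo), 2.0 * np.log10(1.0 - p_loo)),
        )
        ai = np.where(usable, logp, 0.0).sum(axis=1)
    else:
        miss = g.missing_mask()
        for j in range(g.n_loci):
            alleles = g.locus_alleles(j)
            idx = {a: k for k, a in enumerate(alleles)}
            counts = np.zeros((P, len(alleles)))
            n_pl = np.zeros(P)
            for i in range(n_ind):
                a, b = g.genotypes[i, j]
                if a == 0:
                    continue
                counts[pop_codes[i], idx[a]] += 1
                counts[pop_codes[i], idx[b]] += 1
                n_pl[pop_codes[i]] += 1
            for i in range(n_ind):
                a, b = g.genotypes[i, j]
                if a == 0:
                    continue
                p = pop_codes[i]
                if n_pl[p] < 2:
                    continue
                tot = 2.0 * (n_pl[p] - 1.0)
                floor = 1.0 / (2.0 * n_pl[p])
                pa = np.clip((counts[p, idx[a]] - 1) / tot, floor, 1 - floor)
                if a == b:
                    ai[i] += 2.0 * np.log10(pa)
                else:
                    pb = np.clip((counts[p, idx[b]] - 1) / tot, floor, 1 - floor)
                    ai[i] += np.log10(2.0) + np.log10(pa) + np.log10(pb)
    # center within populations
    aic = ai.copy()
    for p in range(P):
        sel = pop_codes == p
        if sel.any():
            aic[sel] -= ai[sel].mean()
    sex = np.array(["M", "F", "unknown"])[sex_codes]
    return pd.DataFrame(
        {
            "individual_id": g.individual_ids,
            "population_id": [meta.populations[p] for p in pop_codes],
            "sex": sex,
            "AI": ai,
            "AIc": aic,
        }
    ).set_index("individual_id")


@dataclass
class SexBiasResult:
    maic_male: float
    maic_female: float
    t: float
    p_value: float
    p_perm: float
    n_male: int
    n_female: int
    degenerate: bool = False
    table: pd.DataFrame | None = field(repr=False, default=None)

    def summary(self) -> str:
        if self.degenerate:
            return "Sex-bias test degenerate: no variance in corrected assignment indices"
        return (
            f"mAIc males = {self.maic_male:.4f} (n={self.n_male}), "
            f"females = {self.maic_female:.4f} (n={self.n_female}); "
            f"Welch t = {self.t:.3f}, P = {self.p_value:.3g} "
            f"(permutation P = {self.p_perm:.3g})"
        )


def sexbias_test(
    g: SnpGenotypes | MicrosatGenotypes,
    meta: SampleMetadata,
    n_perm: int = 999,
    seed: int | None = None,
) -> SexBiasResult:
    """Test for sex-biased dispersal via mean corrected assignment indices.

    The dispersing sex carries genotypes less typical of its sampled
    population and so has the lower mAIc.  Reported: Welch t (males minus
    females) with its parametric p, plus a permutation p from reshuffling sex
    labels within populations.
    """
    tab = assignment_indices(g, meta)
    known = tab[tab["sex"].isin(["M", "F"])]
    males = known.loc[known["sex"] == "M", "AIc"].to_numpy()
    females = known.loc[known["sex"] == "F", "AIc"].to_numpy()
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least two individuals of each known sex")
    if np.allclose(known["AIc"].to_numpy(), 0.0):
        return SexBiasResult(0.0, 0.0, 0.0, 1.0, 1.0, len(males), len(females), True, tab)
    t, p = stats.ttest_ind(males, females, equal_var=False)
    rng = np.random.default_rng(seed)
    sexes = known["sex"].to_numpy().copy()
    aic = known["AIc"].to_numpy()
    pops = known["population_id"].to_numpy()
    t_obs = abs(t)
    count = 0
    for _ in range(n_perm):
        perm_sex = sexes.copy()
        for popid in np.unique(pops):
            sel = np.flatnonzero(pops == popid)
            perm_sex[sel] = perm_sex[rng.permutation(sel)]
        m = aic[perm_sex == "M"]
        f = aic[perm_sex == "F"]
        if len(m) < 2 or len(f) < 2:
            continue
        tp, _ = stats.ttest_ind(m, f, equal_var=False)
        if abs(tp) >= t_obs:
            count += 1
    p_perm = (count + 1.0) / (n_perm + 1.0)
    return SexBiasResult(
        float(males.mean()), float(females.mean()), float(t), float(p), float(p_perm),
        len(males), len(females), False, tab,
    )
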
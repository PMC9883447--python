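"""End-to-end marker-set comparison: the full microsatellite-vs-SNP study as
one fitted model.

:class:`MarkerComparison` takes both genotype matrices plus the shared sample
metadata and, on ``fit()``, runs the whole population-level and
individual-level battery in order — per-population diversity tables,
bootstrap CIs, between-marker Pearson correlations, pairwise F_ST matrices
with a Mantel comparison, isolation-by-distance per marker, hierarchical
F-statistics, chord-distance trees, the sex-bias test, the missing-data
sensitivity diagnostics, and (optionally) admixture with K selection and the
SNP-subsampling resolution experiment.  The returned
:class:`ComparisonResult` serializes to JSON so every reported number stays
traceable to a seed and a module operation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import differentiation as diff
from . import diversity as dv
from . import structure as st
from .io import (
    MicrosatGenotypes,
    SampleMetadata,
    SnpGenotypes,
    read_metadata,
    read_microsat_table,
    read_snp_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CompareConfig",
    "MarkerComparison",
    "ComparisonResult",
    "missingness_sensitivity",
    "MissingnessSensitivity",
    "reproduce_published_overall",
]


@dataclass
class CompareConfig:
    n_boot: int = 1000
    n_perm: int = 999
    include_admixture: bool = False
    k_max: int = 7
    admixture_reps: int = 5
    admixture_max_iter: int = 150
    subsample_sizes: tuple[int, ...] = ()
    min_completeness: float | None = None
    run_sexbias: bool = True


def _corr(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return {"r": np.nan, "p": np.nan, "n": int(ok.sum())}
    r, p = sps.pearsonr(x[ok], y[ok])
    return {"r": float(r), "p": float(p), "n": int(ok.sum())}


@dataclass
class MissingnessSensitivity:
    """Correlation of per-population SNP missingness with diversity estimates."""

    missing_rate: pd.Series
    correlations: dict[str, dict[str, float]]
    influence: dict[str, dict[str, float]]  # per statistic: r after dropping each pop
    defined: bool = True

    def summary(self) -> str:
        if not self.defined:
            return "Missingness sensitivity: undefined (no variation in missing rates)"
        lines = ["Missingness sensitivity (per-population missing rate vs estimate):"]
        for k, v in self.correlations.items():
            lines.append(f"  {k}: r = {v['r']:+.3f} (P = {v['p']:.3g})")
        return "\n".join(lines)


def missingness_sensitivity(
    g: SnpGenotypes, meta: SampleMetadata
) -> MissingnessSensitivity:
    """How much per-population missing data distorts H_O, H_S and F_IS.

    Pearson correlation of the per-population missing fraction against each
    statistic, plus leave-one-population-out influence diagnostics (a single
    high-missingness colony can carry the whole effect).
    """
    pop_codes, _, _ = meta.codes_for(g.individual_ids)
    pops = meta.populations
    miss = g.missing_mask()
    rate = np.array([miss[pop_codes == k].mean() for k in range(len(pops))])
    rate_s = pd.Series(rate, index=pops, name="missing_rate")
    if np.allclose(rate, rate[0]):
        return MissingnessSensitivity(rate_s, {}, {}, defined=False)
    bs = dv.basic_stats(g, meta)
    correlations = {}
    influence: dict[str, dict[str, float]] = {}
    for stat in ("H_O", "H_S", "F_IS"):
        vals = bs.per_population[stat].to_numpy()
        correlations[stat] = _corr(rate, vals)
        infl = {}
        for k, pid in enumerate(pops):
            keep = np.arange(len(pops)) != k
            infl[pid] = _corr(rate[keep], vals[keep])["r"]
        influence[stat] = infl
    return MissingnessSensitivity(rate_s, correlations, influence)


@dataclass
class ComparisonResult:
    """Everything the marker-vs-marker comparison computes, JSON-serializable."""

    seed: int
    n_individuals: int
    per_population: dict[str, pd.DataFrame]
    overall: dict[str, dict[str, float]]
    overall_ci: dict[str, dict[str, tuple[float, float, float]]]
    estimate_correlations: dict[str, dict[str, float]]
    pairwise_fst: dict[str, diff.DistanceMatrix]
    fst_mantel: diff.MantelResult
    ibd: dict[str, diff.IbdResult]
    hierarchy: dict[str, diff.FStatHierarchy]
    trees_newick: dict[str, str]
    sexbias: dict[str, st.SexBiasResult] = field(default_factory=dict)
    aic_correlation: dict[str, float] = field(default_factory=dict)
    missingness: MissingnessSensitivity | None = None
    k_selection: st.KSelection | None = None
    subsampling: st.SubsampleResult | None = None
    config: CompareConfig = field(default_factory=CompareConfig)

    def summary(self) -> str:
        out = [f"Marker comparison on {self.n_individuals} shared individuals (seed {self.seed})", ""]
        for marker in ("snp", "microsat"):
            o = self.overall[marker]
            out.append(
                f"{marker:>9s}: H_O={o['H_O']:.3f} H_S={o['H_S']:.3f} "
                f"H_T={o['H_T']:.3f} F_IS={o['F_IS']:.3f} "
                f"mean pairwise F_ST={o['mean_pairwise_fst']:.3f}"
            )
            h = self.hierarchy[marker]
            out.append(f"{'':>9s}  F_SC={h.fsc:.3f} F_CT={h.fct:.3f}")
        out.append("")
        out.append("between-marker Pearson correlations of per-population estimates:")
        for k, v in self.estimate_correlations.items():
            out.append(f"  {k:>5s}: r = {v['r']:+.3f} (P = {v['p']:.3g})")
        out.append("")
        out.append("pairwise F_ST matrices: " + self.fst_mantel.summary())
        for marker, r in self.ibd.items():
            out.append(f"IBD [{marker}]: {r.summary()}")
        for marker, r in self.sexbias.items():
            out.append(f"sex bias [{marker}]: {r.summary()}")
        if self.aic_correlation:
            c = self.aic_correlation
            out.append(f"AIc correlation between markers: r = {c['r']:+.3f} (P = {c['p']:.3g})")
        if self.missingness is not None:
            out.append(self.missingness.summary())
        if self.k_selection is not None:
            out.append(self.k_selection.summary())
        if self.subsampling is not None:
            out.append("SNP subsampling concordance:")
            for s in self.subsampling.sizes:
                out.append(f"  {s:>6d} SNPs: {self.subsampling.concordance[s]:.3f}")
        return "\n".join(out)

    def to_json(self, path: str | Path | None = None) -> str:
        def conv(o):
            if isinstance(o, pd.DataFrame):
                return json.loads(o.to_json(orient="index"))
            if isinstance(o, pd.Series):
                return o.to_dict()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return str(o)

        payload = {
            "seed": self.seed,
            "n_individuals": self.n_individuals,
            "per_population": {k: v for k, v in self.per_population.items()},
            "overall": self.overall,
            "overall_ci": self.overall_ci,
            "estimate_correlations": self.estimate_correlations,
            "pairwise_fst": {k: v.to_frame() for k, v in self.pairwise_fst.items()},
            "fst_mantel": {"r": self.fst_mantel.r, "p": self.fst_mantel.p_value},
            "ibd": {
                k: {"r": v.r, "p": v.p_value, "slope": v.slope} for k, v in self.ibd.items()
            },
            "hierarchy": {
                k: {"F_ST": v.fst, "F_SC": v.fsc, "F_CT": v.fct, "F_IS": v.fis, "ci": v.ci}
                for k, v in self.hierarchy.items()
            },
            "trees_newick": self.trees_newick,
            "sexbias": {
                k: {"t": v.t, "p": v.p_value, "p_perm": v.p_perm,
                    "mAIc_male": v.maic_male, "mAIc_female": v.maic_female}
                for k, v in self.sexbias.items()
            },
            "aic_correlation": self.aic_correlation,
            "missingness": None
            if self.missingness is None
            else {
                "defined": self.missingness.defined,
                "missing_rate": self.missingness.missing_rate,
                "correlations": self.missingness.correlations,
                "influence": self.missingness.influence,
            },
            "k_selection": None
            if self.k_selection is None
            else {"k_star": self.k_selection.k_star,
                  "table": self.k_selection.table.to_dict(orient="records")},
            "subsampling": None
            if self.subsampling is None
            else {str(s): self.subsampling.concordance[s] for s in self.subsampling.sizes},
            "config": asdict(self.config),
        }
        text = json.dumps(payload, default=conv, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


class MarkerComparison:
    """The full marker-comparison study as a model over (SNPs, microsats, metadata)."""

    def __init__(
        self,
        snp: SnpGenotypes,
        microsat: MicrosatGenotypes,
        meta: SampleMetadata,
        config: CompareConfig | None = None,
    ) -> None:
        shared = [i for i in snp.individual_ids if i in set(microsat.individual_ids)]
        if len(shared) < 2:
            raise ValueError("fewer than 2 individuals shared between marker sets")
        if len(shared) < snp.n_individuals or len(shared) < microsat.n_individuals:
            logger.info(
                "intersecting marker sets: %d shared of %d SNP / %d microsat individuals",
                len(shared), snp.n_individuals, microsat.n_individuals,
            )
        snp_idx = [snp.individual_ids.index(i) for i in shared]
        ms_idx = [microsat.individual_ids.index(i) for i in shared]
        self.snp = snp.select_individuals(np.array(snp_idx))
        ms = microsat.copy()
        self.microsat = MicrosatGenotypes(
            [microsat.individual_ids[i] for i in ms_idx],
            list(microsat.locus_ids),
            ms.genotypes[ms_idx],
        )
        self.config = config or CompareConfig()
        if self.config.min_completeness is not None:
            called = 1.0 - self.snp.missing_mask().mean(axis=1)
            keep = called >= self.config.min_completeness
            logger.info("completeness filter keeps %d of %d individuals", keep.sum(), len(keep))
            self.snp = self.snp.select_individuals(keep)
            kept_ids = set(self.snp.individual_ids)
            ms_keep = np.array([i in kept_ids for i in self.microsat.individual_ids])
            self.microsat = MicrosatGenotypes(
                [x for x, k in zip(self.microsat.individual_ids, ms_keep) if k],
                list(self.microsat.locus_ids),
                self.microsat.genotypes[ms_keep],
            )
        self.meta = meta.subset(self.snp.individual_ids)

    def fit(self, seed: int = 0) -> ComparisonResult:
        cfg = self.config
        markers: dict[str, SnpGenotypes | MicrosatGenotypes] = {
            "snp": self.snp, "microsat": self.microsat,
        }
        rng = np.random.default_rng(seed)

        per_pop = {m: dv.population_summary(g, self.meta) for m, g in markers.items()}
        overall: dict[str, dict[str, float]] = {}
        overall_ci: dict[str, dict[str, tuple[float, float, float]]] = {}
        pairwise: dict[str, diff.DistanceMatrix] = {}
        hierarchy: dict[str, diff.FStatHierarchy] = {}
        trees: dict[str, str] = {}
        for m, g in markers.items():
            bs = dv.basic_stats(g, self.meta)
            pw = diff.pairwise_fst(g, self.meta)
            pairwise[m] = pw
            overall[m] = dict(bs.overall)
            overall[m]["mean_pairwise_fst"] = float(np.nanmean(pw.condensed()))
            ci = {}
            for stat in ("H_O", "H_S", "H_T", "F_IS"):
                ci[stat] = dv.bootstrap_ci(
                    stat, g, self.meta, n_boot=cfg.n_boot,
                    seed=int(rng.integers(2**31 - 1)),
                )
            overall_ci[m] = ci
            hmeta = self.meta
            if len(self.meta.countries) < 2:
                # flat design: treat each population as its own country so the
                # country level reports the plain between-population F_ST
                logger.info("single country: hierarchy collapses to two levels")
                tab = self.meta.table.copy()
                tab["country_id"] = tab["population_id"]
                hmeta = SampleMetadata(tab)
            h = diff.hierarchical_fstats(g, hmeta)
            h.bootstrap(n_boot=cfg.n_boot, seed=int(rng.integers(2**31 - 1)))
            hierarchy[m] = h
            dm, tree = diff.chord_distance_tree(g, self.meta)
            trees[m] = "" if tree is None else tree.as_string(schema="newick").strip()

        est_corr = {
            stat: _corr(
                per_pop["microsat"][stat].to_numpy(), per_pop["snp"][stat].to_numpy()
            )
            for stat in ("H_O", "H_S", "F_IS", "A_R", "Beta")
        }

        fst_mantel = diff.mantel_test(
            pairwise["snp"], pairwise["microsat"], n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)), tail="two-sided",
        )
        geo = diff.geographic_distances(self.meta)
        ibd = {
            m: diff.ibd_analysis(
                pairwise[m], geo, n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1))
            )
            for m in markers
        }

        sexbias: dict[str, st.SexBiasResult] = {}
        aic_corr: dict[str, float] = {}
        sexes = self.meta.table["sex"]
        if cfg.run_sexbias and (sexes == "M").sum() >= 2 and (sexes == "F").sum() >= 2:
            for m, g in markers.items():
                sexbias[m] = st.sexbias_test(
                    g, self.meta, n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1))
                )
            a = sexbias["snp"].table["AIc"].to_numpy()
            b = sexbias["microsat"].table["AIc"].to_numpy()
            aic_corr = _corr(a, b)

        missing = missingness_sensitivity(self.snp, self.meta)

        k_sel = None
        subs = None
        if cfg.include_admixture:
            fits: list[st.AdmixtureFit] = []
            for K in range(1, cfg.k_max + 1):
                fits.extend(
                    st.admixture_fit(
                        self.snp, K, n_reps=cfg.admixture_reps,
                        seed=int(rng.integers(2**31 - 1)),
                        max_iter=cfg.admixture_max_iter,
                    )
                )
            k_sel = st.select_k(fits)
            if cfg.subsample_sizes:
                subs = st.snp_subsample_experiment(
                    self.snp, K=k_sel.k_star, sizes=list(cfg.subsample_sizes),
                    n_reps=cfg.admixture_reps, seed=int(rng.integers(2**31 - 1)),
                    max_iter=cfg.admixture_max_iter,
                )

        return ComparisonResult(
            seed=seed,
            n_individuals=self.snp.n_individuals,
            per_population=per_pop,
            overall=overall,
            overall_ci=overall_ci,
            estimate_correlations=est_corr,
            pairwise_fst=pairwise,
            fst_mantel=fst_mantel,
            ibd=ibd,
            hierarchy=hierarchy,
            trees_newick=trees,
            sexbias=sexbias,
            aic_correlation=aic_corr,
            missingness=missing,
            k_selection=k_sel,
            subsampling=subs,
            config=cfg,
        )


def reproduce_published_overall(data_dir: str | Path) -> dict[str, float]:
    """Recompute the study's headline overall statistics from deposited matrices.

    Expects under ``data_dir``: ``snp_genotypes.tsv`` (or ``snp_genotypes.vcf``),
    ``microsat_genotypes.tsv`` and ``metadata.csv`` in the package dialects.
    Returns mean pairwise F_ST, hierarchical F_SC/F_CT, mean H_O/H_S and
    overall F_IS for each marker set.
    """
    data_dir = Path(data_dir)
    vcf = data_dir / "snp_genotypes.vcf"
    if vcf.exists():
        snp = read_snp_table(vcf, format="vcf")
    else:
        snp = read_snp_table(data_dir / "snp_genotypes.tsv")
    ms = read_microsat_table(data_dir / "microsat_genotypes.tsv")
    meta = read_metadata(data_dir / "metadata.csv")
    out: dict[str, float] = {}
    for name, g in (("snp", snp), ("microsat", ms)):
        bs = dv.basic_stats(g, meta)
        pw = diff.pairwise_fst(g, meta)
        h = diff.hierarchical_fstats(g, meta)
        out[f"{name}_mean_pairwise_fst"] = float(np.nanmean(pw.condensed()))
        out[f"{name}_fsc"] = h.fsc
        out[f"{name}_fct"] = h.fct
        out[f"{name}_mean_ho"] = bs.overall["H_O"]
        out[f"{name}_mean_hs"] = bs.overall["H_S"]
        out[f"{name}_fis"] = bs.overall["F_IS"]
    return out
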
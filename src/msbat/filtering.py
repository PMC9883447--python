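"""Custom ddRAD SNP-calling and filtering rules with a per-step audit ledger.

The pipeline applies, in order: (1) removal of all SNPs on RAD loci carrying
more than ``max_snps_per_locus`` SNPs (repetitive-element screen) together
with a per-genotype read-depth mask; (2) masking of annotated tri-allelic
genotypes and of heterozygotes whose rarer allele carries less than
``min_het_allele_fraction`` of the reads, followed by removal of singleton
SNPs (minor allele seen exactly once overall); (3) removal of SNPs called in
fewer than ``min_call_rate`` of all individuals; (4) removal of SNPs whose
overall (populations pooled unless metadata is supplied) per-locus F_IS falls
outside ``fis_bounds`` — extreme heterozygote deficits or excesses are not
expected in a diploid outbreeding species and flag genotyping artefacts.

Masking can itself create singletons, which is why the singleton screen runs
after the genotype-level masks.  All boundaries are inclusive on the "keep"
side: depth 8 passes an 8-read threshold, a call rate of exactly 70% passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import per_locus_fis
from .io import MISSING_DOSAGE, SampleMetadata, SnpGenotypes

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterReport",
    "filter_locus_snp_count",
    "mask_low_quality_genotypes",
    "run_filter_pipeline",
]


@dataclass
class FilterConfig:
    """Thresholds for the SNP filtering pipeline (defaults as used throughout)."""

    max_snps_per_locus: int = 5
    min_depth: int = 8
    min_het_allele_fraction: float = 0.25
    drop_singletons: bool = True
    min_call_rate: float = 0.70
    fis_bounds: tuple[float, float] = (-0.2, 0.2)

    def __post_init__(self) -> None:
        if not 0 < self.min_het_allele_fraction < 0.5:
            raise ValueError("min_het_allele_fraction must be in (0, 0.5)")
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        lo, hi = self.fis_bounds
        if not (-1 <= lo <= hi <= 1):
            raise ValueError("fis_bounds must be an interval within [-1, 1]")
        if self.max_snps_per_locus < 1:
            raise ValueError("max_snps_per_locus must be >= 1")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class FilterStep:
    name: str
    cells_masked: int
    loci_dropped: int
    loci_remaining: int
    note: str = ""


@dataclass
class FilterReport:
    """Ordered audit ledger of the filtering pipeline."""

    initial_shape: tuple[int, int]
    steps: list[FilterStep] = field(default_factory=list)

    @property
    def final_shape(self) -> tuple[int, int]:
        if not self.steps:
            return self.initial_shape
        return (self.initial_shape[0], self.steps[-1].loci_remaining)

    def add(self, name: str, cells_masked: int, loci_dropped: int, loci_remaining: int, note: str = "") -> None:
        if self.steps and loci_remaining > self.steps[-1].loci_remaining:
            raise ValueError("loci remaining increased across a filter step")
        self.steps.append(FilterStep(name, cells_masked, loci_dropped, loci_remaining, note))

    def total_dropped(self) -> int:
        return sum(s.loci_dropped for s in self.steps)

    def to_rows(self) -> list[tuple]:
        return [(s.name, s.cells_masked, s.loci_dropped, s.loci_remaining, s.note) for s in self.steps]

    def summary(self) -> str:
        lines = [f"SNP filtering ledger  (start: {self.initial_shape[0]} ind x {self.initial_shape[1]} loci)"]
        for s in self.steps:
            lines.append(
                f"  {s.name:<24s} cells masked {s.cells_masked:>7d}  "
                f"loci dropped {s.loci_dropped:>6d}  remaining {s.loci_remaining:>6d}"
                + (f"  [{s.note}]" if s.note else "")
            )
        return "\n".join(lines)


def filter_locus_snp_count(
    snp_to_radlocus: dict[str, str], config: FilterConfig, snp_ids: list[str] | None = None
) -> set[str]:
    """SNP IDs retained after dropping whole RAD loci with too many SNPs.

    All SNPs on a RAD locus carrying more than ``max_snps_per_locus`` SNPs are
    removed together.  Raises if a queried SNP has no parent locus.
    """
    ids = list(snp_to_radlocus) if snp_ids is None else snp_ids
    missing = [s for s in ids if s not in snp_to_radlocus]
    if missing:
        raise KeyError(f"SNPs without a parent RAD locus: {missing[:5]}")
    per_locus: dict[str, int] = {}
    for s in ids:
        per_locus[snp_to_radlocus[s]] = per_locus.get(snp_to_radlocus[s], 0) + 1
    return {s for s in ids if per_locus[snp_to_radlocus[s]] <= config.max_snps_per_locus}


def mask_low_quality_genotypes(
    g: SnpGenotypes, config: FilterConfig | None = None
) -> tuple[SnpGenotypes, dict[str, int]]:
    """Set unreliable genotype calls to missing.

    Rules (each counts masked cells separately): total read depth below
    ``min_depth``; heterozygote with the rarer allele under
    ``min_het_allele_fraction`` of reads; genotype annotated as tri-allelic.
    Depth-based rules are skipped (and reported as such) when the matrix
    carries no depths.
    """
    config = config or FilterConfig()
    out = g.copy()
    counts = {"depth": 0, "het_balance": 0, "triallelic": 0}
    nonmiss = out.dosage != MISSING_DOSAGE
    if g.depths is not None:
        total = out.depths.sum(axis=2)
        low = nonmiss & (total < config.min_depth)
        counts["depth"] = int(low.sum())
        out.dosage[low] = MISSING_DOSAGE
        nonmiss = out.dosage != MISSING_DOSAGE
        het = nonmiss & (out.dosage == 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            minor_frac = np.where(total > 0, out.depths.min(axis=2) / total, np.nan)
        unbal = het & (total > 0) & (minor_frac < config.min_het_allele_fraction)
        counts["het_balance"] = int(unbal.sum())
        out.dosage[unbal] = MISSING_DOSAGE
        nonmiss = out.dosage != MISSING_DOSAGE
    else:
        counts["depth"] = -1  # signals "skipped: no depths"
        counts["het_balance"] = -1
    if out.third_allele is not None:
        tri = nonmiss & out.third_allele
        counts["triallelic"] = int(tri.sum())
        out.dosage[tri] = MISSING_DOSAGE
    return out, counts


def _singleton_mask(g: SnpGenotypes) -> np.ndarray:
    """True for loci whose minor allele is observed in exactly one copy overall."""
    nonmiss = g.dosage != MISSING_DOSAGE
    alt = np.where(nonmiss, g.dosage, 0).sum(axis=0)
    total = 2 * nonmiss.sum(axis=0)
    mac = np.minimum(alt, total - alt)
    return mac == 1


def run_filter_pipeline(
    g: SnpGenotypes,
    config: FilterConfig | None = None,
    snp_to_radlocus: dict[str, str] | None = None,
    meta: SampleMetadata | None = None,
) -> tuple[SnpGenotypes, FilterReport]:
    """Full SNP filtering pipeline; returns the filtered matrix and its ledger.

    ``meta`` (optional) makes the F_IS screen use the across-population
    per-locus F_IS; without it all individuals are pooled.  The pipeline is
    idempotent: rerunning it on its own output drops nothing further.
    """
    config = config or FilterConfig()
    report = FilterReport((g.n_individuals, g.n_loci))
    out = g.copy()

    # step 1a: RAD-locus SNP count
    if snp_to_radlocus is not None:
        keep_ids = filter_locus_snp_count(snp_to_radlocus, config, out.locus_ids)
        keep = np.array([lid in keep_ids for lid in out.locus_ids])
        dropped = int((~keep).sum())
        out = out.select_loci(keep)
        report.add("locus_snp_count", 0, dropped, out.n_loci)
    else:
        report.add("locus_snp_count", 0, 0, out.n_loci, note="skipped: no SNP-to-locus map")

    # step 1b + 2a: genotype-level masks
    out, mask_counts = mask_low_quality_genotypes(out, config)
    if mask_counts["depth"] < 0:
        report.add("depth_mask", 0, 0, out.n_loci, note="skipped: no depths")
        report.add("het_balance_mask", 0, 0, out.n_loci, note="skipped: no depths")
    else:
        report.add("depth_mask", mask_counts["depth"], 0, out.n_loci)
        report.add("het_balance_mask", mask_counts["het_balance"], 0, out.n_loci)
    report.add("triallelic_mask", mask_counts["triallelic"], 0, out.n_loci)

    # step 2b: singletons (after masking, which can create them)
    if config.drop_singletons:
        single = _singleton_mask(out)
        out = out.select_loci(~single)
        report.add("singletons", 0, int(single.sum()), out.n_loci)

    # step 3: call rate over all individuals in the matrix
    called = (out.dosage != MISSING_DOSAGE).mean(axis=0)
    keep = called >= config.min_call_rate
    dropped = int((~keep).sum())
    out = out.select_loci(keep)
    report.add("call_rate", 0, dropped, out.n_loci)
    if out.n_loci == 0:
        raise ValueError("filtering emptied the matrix at step 'call_rate'")

    # step 4: per-locus F_IS screen
    fis = per_locus_fis(out, meta)
    lo, hi = config.fis_bounds
    with np.errstate(invalid="ignore"):
        bad = np.isfinite(fis) & ((fis < lo) | (fis > hi))
    out = out.select_loci(~bad)
    report.add("fis_range", 0, int(bad.sum()), out.n_loci)
    if out.n_loci == 0:
        raise ValueError("filtering emptied the matrix at step 'fis_range'")
    assert report.initial_shape[1] - report.total_dropped() == out.n_loci
    return out, report
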
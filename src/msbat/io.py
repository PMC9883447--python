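"""Genotype matrices, sample metadata, and the file dialects the pipeline reads and writes.

Two genotype containers share one allele-count abstraction: :class:`SnpGenotypes`
stores biallelic loci as alternate-allele dosage (0/1/2) with optional per-genotype
read depths, and :class:`MicrosatGenotypes` stores multiallelic loci as unordered
pairs of integer allele labels (allele sizes).  Downstream estimators consume both
through per-population allele counts, so the diversity and differentiation code has
a single code path for biallelic and multiallelic data.

Missing data uses a single reserved sentinel per container (``-1`` for dosage,
``0`` for microsatellite allele labels); a dosage of 0 is a valid homozygote and is
never used to encode missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MISSING_DOSAGE",
    "SnpGenotypes",
    "MicrosatGenotypes",
    "SampleMetadata",
    "read_snp_table",
    "write_snp_table",
    "read_microsat_table",
    "write_microsat_table",
    "read_metadata",
    "write_metadata",
    "check_depth_consistency",
]

#: Sentinel for a missing dosage call.  Never 0: homozygous-reference is a real genotype.
MISSING_DOSAGE: int = -1

SEXES = ("M", "F", "unknown")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)
    return ids


@dataclass
class SnpGenotypes:
    """Individuals x biallelic-loci dosage matrix with optional allele read depths.

    Parameters
    ----------
    individual_ids, locus_ids
        Unique string identifiers for rows and columns.
    dosage
        ``(n_individuals, n_loci)`` integer matrix counting copies of the
        alternate allele; entries are 0, 1, 2 or :data:`MISSING_DOSAGE`.
    depths
        Optional ``(n_individuals, n_loci, 2)`` matrix of (ref_reads, alt_reads)
        per genotype call.
    third_allele
        Optional boolean matrix flagging genotypes where reads supporting a
        third allele were observed upstream (dosage matrices are biallelic, so
        this annotation channel is the only place that information survives).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    depths: np.ndarray | None = None
    third_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = _check_unique(self.individual_ids, "individual")
        self.locus_ids = _check_unique(self.locus_ids, "locus")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        shape = (len(self.individual_ids), len(self.locus_ids))
        if self.dosage.shape != shape:
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match ids {shape}"
            )
        bad = ~np.isin(self.dosage, (MISSING_DOSAGE, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, j]} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
            if self.depths.shape != shape + (2,):
                raise ValueError(
                    f"depths shape {self.depths.shape} does not match {shape + (2,)}"
                )
            if (self.depths < 0).any():
                raise ValueError("negative read depth")
        if self.third_allele is not None:
            self.third_allele = np.asarray(self.third_allele, dtype=bool)
            if self.third_allele.shape != shape:
                raise ValueError("third_allele shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the genotype call is missing."""
        return self.dosage == MISSING_DOSAGE

    def copy(self) -> "SnpGenotypes":
        return SnpGenotypes(
            list(self.individual_ids),
            list(self.locus_ids),
            self.dosage.copy(),
            None if self.depths is None else self.depths.copy(),
            None if self.third_allele is None else self.third_allele.copy(),
        )

    def select_loci(self, keep: np.ndarray) -> "SnpGenotypes":
        """Subset loci by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SnpGenotypes(
            list(self.individual_ids),
            [self.locus_ids[j] for j in keep],
            self.dosage[:, keep],
            None if self.depths is None else self.depths[:, keep],
            None if self.third_allele is None else self.third_allele[:, keep],
        )

    def select_individuals(self, keep: np.ndarray) -> "SnpGenotypes":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SnpGenotypes(
            [self.individual_ids[i] for i in keep],
            list(self.locus_ids),
            self.dosage[keep],
            None if self.depths is None else self.depths[keep],
            None if self.third_allele is None else self.third_allele[keep],
        )

    def flipped(self, loci: Iterable[int] | None = None) -> "SnpGenotypes":
        """Swap ref/alt orientation at the given loci (all loci by default).

        Every estimator downstream is orientation-invariant; this exists so the
        tests can assert that.
        """
        out = self.copy()
        idx = np.arange(self.n_loci) if loci is None else np.asarray(list(loci))
        sub = out.dosage[:, idx]
        nonmiss = sub != MISSING_DOSAGE
        sub[nonmiss] = 2 - sub[nonmiss]
        out.dosage[:, idx] = sub
        if out.depths is not None:
            out.depths[:, idx] = out.depths[:, idx][:, :, ::-1]
        return out


@dataclass
class MicrosatGenotypes:
    """Individuals x loci matrix of unordered integer allele-label pairs.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)``; allele labels are
    positive integers (allele sizes), stored canonically as (low, high).
    A missing genotype is (0, 0).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = _check_unique(self.individual_ids, "individual")
        self.locus_ids = _check_unique(self.locus_ids, "locus")
        g = np.asarray(self.genotypes, dtype=np.int32)
        shape = (len(self.individual_ids), len(self.locus_ids), 2)
        if g.shape != shape:
            raise ValueError(f"genotypes shape {g.shape} != {shape}")
        if (g < 0).any():
            raise ValueError("allele labels must be non-negative (0 = missing)")
        half = (g == 0).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotype (one allele 0, one not)")
        self.genotypes = np.sort(g, axis=2)  # canonical (low, high)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        return (self.genotypes == 0).all(axis=2)

    def locus_alleles(self, j: int) -> np.ndarray:
        """Sorted distinct allele labels observed at locus ``j``."""
        a = self.genotypes[:, j, :].ravel()
        return np.unique(a[a > 0])

    def copy(self) -> "MicrosatGenotypes":
        return MicrosatGenotypes(
            list(self.individual_ids), list(self.locus_ids), self.genotypes.copy()
        )


@dataclass
class SampleMetadata:
    """Per-individual sampling metadata: population, country, sex, coordinates.

    Coordinates are per population (one longitude/latitude pair per sampling
    locality, broadcast to its individuals).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("individual_id", "population_id", "country_id")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        df["sex"] = df["sex"].fillna("unknown").astype(str)
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValueError(f"invalid sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
        for col in ("longitude", "latitude"):
            if col not in df.columns:
                df[col] = np.nan
        df["individual_id"] = df["individual_id"].astype(str)
        df["population_id"] = df["population_id"].astype(str)
        df["country_id"] = df["country_id"].astype(str)
        if df["individual_id"].duplicated().any():
            dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
            raise ValueError(f"duplicate individuals in metadata: {dups}")
        # each population maps to exactly one country and one coordinate pair
        per_pop = df.groupby("population_id")[["country_id", "longitude", "latitude"]].nunique(
            dropna=False
        )
        bad = per_pop[(per_pop > 1).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"populations with inconsistent country/coordinates: {list(bad.index)}"
            )
        if df["latitude"].abs().max() > 90:
            raise ValueError("latitude outside [-90, 90]")
        self.table = df.reset_index(drop=True)

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual_id"].tolist()

    @property
    def populations(self) -> list[str]:
        """Population IDs in first-appearance order."""
        return list(dict.fromkeys(self.table["population_id"]))

    @property
    def countries(self) -> list[str]:
        return list(dict.fromkeys(self.table["country_id"]))

    def population_coordinates(self) -> pd.DataFrame:
        """One row per population: country, longitude, latitude, sample size."""
        g = self.table.groupby("population_id", sort=False)
        out = g.agg(
            country_id=("country_id", "first"),
            longitude=("longitude", "first"),
            latitude=("latitude", "first"),
            n=("individual_id", "size"),
        )
        return out.loc[self.populations]

    def codes_for(self, individual_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Population codes, country-of-population codes, and sex codes aligned to
        ``individual_ids``.

        Returns ``(pop_codes, pop_to_country, sex_codes)`` where ``pop_codes[i]``
        indexes :attr:`populations`, ``pop_to_country[p]`` indexes
        :attr:`countries`, and sex codes are 0=M, 1=F, 2=unknown.

        Raises if any individual has no metadata row.
        """
        df = self.table.set_index("individual_id")
        missing = [x for x in individual_ids if x not in df.index]
        if missing:
            raise KeyError(f"individuals without metadata: {missing}")
        pops = self.populations
        countries = self.countries
        pop_idx = {p: k for k, p in enumerate(pops)}
        ctry_idx = {c: k for k, c in enumerate(countries)}
        sub = df.loc[list(individual_ids)]
        pop_codes = np.array([pop_idx[p] for p in sub["population_id"]], dtype=np.intp)
        pop_country = self.population_coordinates()["country_id"]
        pop_to_country = np.array([ctry_idx[pop_country[p]] for p in pops], dtype=np.intp)
        sex_codes = np.array([SEXES.index(s) for s in sub["sex"]], dtype=np.intp)
        return pop_codes, pop_to_country, sex_codes

    def subset(self, individual_ids: Sequence[str]) -> "SampleMetadata":
        df = self.table.set_index("individual_id").loc[list(individual_ids)].reset_index()
        return SampleMetadata(df)


# ---------------------------------------------------------------------------
# SNP I/O
# ---------------------------------------------------------------------------


def _read_snp_tsv(path: Path) -> SnpGenotypes:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        locus_ids = header[1:]
        individual_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            individual_ids.append(parts[0])
            row = []
            for j, cell in enumerate(parts[1:]):
                cell = cell.strip()
                if cell in ("NA", "", "."):
                    row.append(MISSING_DOSAGE)
                else:
                    try:
                        v = int(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: non-integer dosage {cell!r} "
                            f"at locus {locus_ids[j]!r}"
                        ) from None
                    row.append(v)
            rows.append(row)
    return SnpGenotypes(individual_ids, locus_ids, np.array(rows, dtype=np.int8))


def _read_snp_vcf(path: Path) -> SnpGenotypes:
    vf = pysam.VariantFile(str(path))
    individual_ids = list(vf.header.samples)
    locus_ids: list[str] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_ad = False
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"multiallelic or ALT-less VCF record at locus "
                f"{rec.id or f'{rec.chrom}:{rec.pos}'}"
            )
        lid = rec.id or f"{rec.chrom}:{rec.pos}"
        if lid in locus_ids:
            raise ValueError(f"duplicate locus ID in VCF: {lid!r}")
        locus_ids.append(lid)
        dos = np.full(len(individual_ids), MISSING_DOSAGE, dtype=np.int8)
        dep = np.zeros((len(individual_ids), 2), dtype=np.int32)
        for i, sample in enumerate(individual_ids):
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is not None and None not in gt:
                dos[i] = sum(1 for a in gt if a == 1)  # phasing irrelevant
            ad = call.get("AD")
            if ad is not None and None not in ad:
                any_ad = True
                dep[i] = ad[:2]
        dosage_cols.append(dos)
        depth_cols.append(dep)
    dosage = np.stack(dosage_cols, axis=1) if dosage_cols else np.zeros((len(individual_ids), 0), np.int8)
    depths = np.stack(depth_cols, axis=1) if any_ad else None
    return SnpGenotypes(individual_ids, locus_ids, dosage, depths)


def read_snp_table(path: str | Path, format: str = "tsv") -> SnpGenotypes:
    """Read a SNP genotype matrix from a tab-delimited table or a biallelic VCF.

    TSV layout: first column individual ID, remaining columns one dosage per
    locus (``NA`` missing).  VCF: only GT and AD are consumed; ``|`` is treated
    as ``/``; multiallelic records are rejected naming the offending locus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_snp_tsv(path)
    if format == "vcf":
        return _read_snp_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_snp_table(g: SnpGenotypes, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("individual\t" + "\t".join(g.locus_ids) + "\n")
            for i, ind in enumerate(g.individual_ids):
                cells = [
                    "NA" if d == MISSING_DOSAGE else str(int(d)) for d in g.dosage[i]
                ]
                fh.write(ind + "\t" + "\t".join(cells) + "\n")
        return
    if format == "vcf":
        _write_snp_vcf(g, path)
        return
    raise ValueError(f"unknown format {format!r}")


def _write_snp_vcf(g: SnpGenotypes, path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.contigs.add("1")
    for ind in g.individual_ids:
        header.add_sample(ind)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, lid in enumerate(g.locus_ids):
            rec = out.new_record(
                contig="1", start=j, stop=j + 1, alleles=("A", "T"), id=lid
            )
            for i, ind in enumerate(g.individual_ids):
                d = g.dosage[i, j]
                if d == MISSING_DOSAGE:
                    rec.samples[ind]["GT"] = (None, None)
                else:
                    rec.samples[ind]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(d)]
                if g.depths is not None:
                    rec.samples[ind]["AD"] = tuple(int(x) for x in g.depths[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# Microsatellite I/O
# ---------------------------------------------------------------------------


def _parse_allele_pair(cell: str, where: str) -> tuple[int, int]:
    cell = cell.strip()
    if cell in ("", "NA", "0", "0/0"):
        return (0, 0)
    if "/" in cell:
        a_s, b_s = cell.split("/", 1)
    else:
        raise ValueError(f"{where}: cannot parse microsatellite cell {cell!r}")
    try:
        a, b = int(a_s), int(b_s)
    except ValueError:
        raise ValueError(f"{where}: non-integer allele label in {cell!r}") from None
    if a == 0 or b == 0:
        return (0, 0)
    return (min(a, b), max(a, b))


def read_microsat_table(path: str | Path) -> MicrosatGenotypes:
    """Read a microsatellite genotype table.

    Accepted layouts (tab-delimited, first column = individual ID):

    * one column per locus with ``a/b`` cells (``0/0``, ``0`` or blank = missing);
    * two adjacent columns per locus named ``<locus>.1``/``<locus>.2`` (or any
      pair sharing a prefix) holding the two allele labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    ind_col = df.columns[0]
    allele_cols = list(df.columns[1:])
    paired = all("/" not in str(v) for v in df[allele_cols].to_numpy().ravel() if v)
    individual_ids = df[ind_col].astype(str).tolist()
    if paired and allele_cols and all(c.rsplit(".", 1)[-1] in ("1", "2") for c in allele_cols):
        if len(allele_cols) % 2:
            raise ValueError(f"{path}: odd number of allele columns")
        locus_ids = [allele_cols[k].rsplit(".", 1)[0] for k in range(0, len(allele_cols), 2)]
        geno = np.zeros((len(df), len(locus_ids), 2), dtype=np.int32)
        for k, lid in enumerate(locus_ids):
            for s, col in enumerate(allele_cols[2 * k : 2 * k + 2]):
                vals = df[col].replace("", "0")
                try:
                    geno[:, k, s] = vals.astype(int)
                except ValueError:
                    raise ValueError(f"{path}: non-integer allele label in column {col!r}") from None
        half = (geno == 0).sum(axis=2) == 1
        geno[half] = 0
    else:
        locus_ids = allele_cols
        geno = np.zeros((len(df), len(locus_ids), 2), dtype=np.int32)
        for k, lid in enumerate(locus_ids):
            for i, cell in enumerate(df[lid]):
                geno[i, k] = _parse_allele_pair(cell, f"{path}: row {i + 2}, locus {lid!r}")
    return MicrosatGenotypes(individual_ids, locus_ids, geno)


def write_microsat_table(g: MicrosatGenotypes, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(g.locus_ids) + "\n")
        for i, ind in enumerate(g.individual_ids):
            cells = []
            for j in range(g.n_loci):
                a, b = g.genotypes[i, j]
                cells.append("0/0" if a == 0 else f"{a}/{b}")
            fh.write(ind + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

_META_ALIASES = {
    "individual": "individual_id",
    "population": "population_id",
    "country": "country_id",
    "X": "longitude",
    "Y": "latitude",
    "x": "longitude",
    "y": "latitude",
}


def read_metadata(path: str | Path, column_map: dict[str, str] | None = None) -> SampleMetadata:
    """Read sample metadata from CSV.

    Expected columns: individual, population, country, sex, X (longitude),
    Y (latitude); common aliases are mapped automatically and ``column_map``
    can supply additional source->canonical renames for other layouts.  A
    missing sex column yields ``unknown`` for every individual.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    ren = dict(_META_ALIASES)
    if column_map:
        ren.update(column_map)
    df = df.rename(columns=ren)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(Path(path), index=False)


def check_depth_consistency(g: SnpGenotypes) -> np.ndarray:
    """Flag non-missing heterozygotes whose depths do not show both alleles.

    Returns a boolean matrix, True where dosage == 1 but one of the two read
    counts is zero.  Purely diagnostic; raises only if depths are absent.
    """
    if g.depths is None:
        raise ValueError("genotypes carry no depth information")
    het = g.dosage == 1
    return het & (g.depths.min(axis=2) == 0)
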
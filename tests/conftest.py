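import numpy as np
import pandas as pd
import pytest

from msbat.io import MicrosatGenotypes, SampleMetadata, SnpGenotypes
from msbat.simulate import island_config, simulate_dataset


@pytest.fixture(scope="session")
def island4():
    """Four demes x 10 individuals at F = 0.1, 400 SNPs + 11 microsats."""
    return simulate_dataset(island_config(n_pops=4, n_per_pop=10, fst=0.1, n_snps=400), seed=11)


@pytest.fixture(scope="session")
def hier_dataset():
    """Small two-level dataset: 3 countries x 2 populations x 8 individuals."""
    from msbat.simulate import PopulationSpec, SimConfig

    pops = [
        PopulationSpec(f"p{c}{k}", f"C{c}", 8) for c in range(3) for k in range(2)
    ]
    cfg = SimConfig(populations=pops, n_snps=600, n_microsats=6, f_ct=0.08, f_sc=0.03)
    return simulate_dataset(cfg, seed=5)


def make_meta(pop_of, country_of=None, sex=None, coords=None):
    """Metadata table from a {individual: population} mapping."""
    inds = list(pop_of)
    pops = [pop_of[i] for i in inds]
    countries = [country_of[p] if country_of else p for p in pops]
    df = pd.DataFrame(
        {
            "individual_id": inds,
            "population_id": pops,
            "country_id": countries,
        }
    )
    if sex is not None:
        df["sex"] = [sex[i] for i in inds]
    if coords is not None:
        df["longitude"] = [coords[p][0] for p in pops]
        df["latitude"] = [coords[p][1] for p in pops]
    return SampleMetadata(df)


def snp_from_rows(rows, individual_ids=None, locus_ids=None, **kw):
    rows = np.asarray(rows, dtype=np.int8)
    n, L = rows.shape
    return SnpGenotypes(
        individual_ids or [f"i{k}" for k in range(n)],
        locus_ids or [f"L{j}" for j in range(L)],
        rows,
        **kw,
    )
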
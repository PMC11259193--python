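import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import zeapop as z

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def background_ds():
    """Neutral background: 20 diploids, 10k sites over 1 Mbp."""
    cfg = z.SimConfig(n_individuals=20, n_sites=10_000,
                      region_length=1_000_000, seed=42)
    return z.gen_background_genotypes(cfg)


@pytest.fixture(scope="session")
def introgression_fixture():
    """Divergence 0.5 (realistic per-SNP diagnostic fraction) with one
    homozygous-tract P2 individual covering 400–600 kbp."""
    sc = z.IntrogressionScenario(
        divergence=0.5,
        admixed_sample_ids=("P2_000",),
        tract_intervals=(((400_000, 600_000),),),
        donor_tract_ploidy=2,
        n_p2=10,
    )
    cfg = z.SimConfig(n_individuals=61, n_sites=20_000,
                      region_length=1_000_000, seed=13)
    ds, meta = z.gen_introgression_dataset(sc, cfg)
    return ds, meta


@pytest.fixture(scope="session")
def null_introgression_fixture():
    """Same pools, no admixed samples: the fd null."""
    sc = z.IntrogressionScenario(divergence=0.05, n_p2=10)
    cfg = z.SimConfig(n_individuals=61, n_sites=20_000,
                      region_length=1_000_000, seed=13)
    return z.gen_introgression_dataset(sc, cfg)


def toy_dataset(genotypes, *, qual=None, depth=None, pos=None,
                is_biallelic=None, ancestral=None, samples=None):
    """Hand-built dataset for unit fixtures; genotypes is (sites, samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    pos = np.arange(1, n_sites + 1) * 10 if pos is None else np.asarray(pos)
    qual = np.full(n_sites, 100.0) if qual is None else np.asarray(qual, float)
    depth = (np.full(g.shape, 30, dtype=np.int32) if depth is None
             else np.asarray(depth, dtype=np.int32))
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "G", dtype=object)
    anc = ref.copy() if ancestral is None else np.asarray(ancestral, dtype=object)
    bi = (np.ones(n_sites, dtype=bool) if is_biallelic is None
          else np.asarray(is_biallelic, dtype=bool))
    names = samples or [f"S{i:02d}" for i in range(n_samples)]
    return z.GenotypeDataset(
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos=pos, ref=ref, alt=alt, ancestral=anc, qual=qual,
        genotypes=g, depth=depth, samples=names, is_biallelic=bi,
        region_length=(int(pos.max()) + 10) if n_sites else 10,
    )


def simple_metadata(samples, groups=None, demes=None, coords=None, years=None):
    n = len(samples)
    rows = []
    for i, s in enumerate(samples):
        lat, lon = (coords[i] if coords else (np.nan, np.nan))
        rows.append({
            "sample": s,
            "group": groups[i] if groups else "g",
            "deme": demes[i] if demes else "",
            "lat": lat, "lon": lon,
            "year": years[i] if years else 2019,
        })
    return z.SampleMetadata(pd.DataFrame(rows))
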
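"""Synthetic genotype and allele-frequency data generators.

Each generator is a pure function of its scenario, configuration and seed and
produces exactly the statistical structure the corresponding analysis stage
assumes:

* a neutral background with derived-allele counts following the 1/i law (the
  composite-likelihood scan consumes only the SFS, so no linkage is needed);
* sweep-distorted spectra around a focal position via the same escape-and-drag
  model the scan fits, giving a self-consistent generator/inference pair;
* Balding–Nichols structured demes with distance-dependent differentiation for
  connectivity and isolation-by-distance tests;
* explicit donor-haplotype tracts in designated P2 individuals, because fd̂
  responds to tract-level allele sharing rather than the SFS;
* noisy allele-frequency time series propagated by the deterministic selection
  recursion, with optional Wright–Fisher drift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    DemeScenario,
    GenotypeDataset,
    IntrogressionScenario,
    SampleMetadata,
    SimConfig,
)
from .sweep import BackgroundSFS, neutral_sfs, sweep_spectrum
from .trajectory import SelectionParams, step

__all__ = [
    "gen_background_genotypes",
    "spike_sweep_signal",
    "gen_structured_demes",
    "gen_introgression_dataset",
    "gen_trajectory_observations",
]

_BASES = np.array(list("ACGT"))


def _draw_positions(rng, n_sites: int, region_length: int) -> np.ndarray:
    """Uniform 1-based positions without replacement, sorted ascending."""
    pos = rng.choice(region_length, size=n_sites, replace=False) + 1
    pos.sort()
    return pos.astype(np.int64)


def _alleles(rng, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n_sites)
    alt = (ref + rng.integers(1, 4, size=n_sites)) % 4
    return _BASES[ref].astype(object), _BASES[alt].astype(object)


def _genotypes_from_counts(rng, counts: np.ndarray, n_hap: int) -> np.ndarray:
    """Assign each site's derived alleles to haplotypes uniformly at random
    and collapse haplotype pairs into diploid dosages."""
    n_sites = len(counts)
    geno = np.zeros((n_sites, n_hap // 2), dtype=np.int8)
    for i, k in enumerate(counts):
        hap = np.zeros(n_hap, dtype=np.int8)
        hap[rng.choice(n_hap, size=int(k), replace=False)] = 1
        geno[i] = hap[0::2] + hap[1::2]
    return geno


def gen_background_genotypes(cfg: SimConfig, chrom: str = "chr1") -> GenotypeDataset:
    """Neutral-SFS background dataset: derived counts i ∝ 1/i over 1..2n−1.

    The ancestral allele is recorded (REF is ancestral), QUAL is a high
    constant and per-genotype depth a plausible constant, so the dataset
    passes the QC stage untouched.
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_individuals
    pos = _draw_positions(rng, cfg.n_sites, cfg.region_length)
    ref, alt = _alleles(rng, cfg.n_sites)
    if n_hap == 2:
        counts = np.ones(cfg.n_sites, dtype=np.int64)
    else:
        sfs = neutral_sfs(n_hap)
        counts = rng.choice(np.arange(1, n_hap), size=cfg.n_sites, p=sfs.probs)
    geno = _genotypes_from_counts(rng, counts, n_hap)
    return GenotypeDataset(
        chrom=np.full(cfg.n_sites, chrom, dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        ancestral=ref.copy(),
        qual=np.full(cfg.n_sites, 100.0),
        genotypes=geno,
        depth=np.full((cfg.n_sites, cfg.n_individuals), 30, dtype=np.int32),
        samples=[f"S{i:03d}" for i in range(cfg.n_individuals)],
        region_length=cfg.region_length,
    )


def spike_sweep_signal(
    ds: GenotypeDataset,
    sweep_pos: int,
    alpha: float,
    seed: int = 0,
    bg: BackgroundSFS | None = None,
) -> GenotypeDataset:
    """Re-draw each site's derived count from the escape-and-drag spectrum.

    Each site keeps its position; its derived count is re-sampled from the
    sweep-distorted spectrum at its distance from ``sweep_pos`` with intensity
    ``alpha`` (conditioned on polymorphism), and alleles are re-assigned to
    haplotypes uniformly.  The default background is the neutral 1/i law the
    generator itself uses.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(ds.ancestral == "."):
        raise ValueError("dataset must be polarized (ancestral allele known)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * ds.n_samples
    if bg is None:
        bg = neutral_sfs(n_hap)
    out = ds.take_sites(np.arange(ds.n_sites))
    k_vals = np.arange(1, n_hap)
    # spectra vary only through alpha*d; cache by distance
    cache: dict[int, np.ndarray] = {}
    counts = np.empty(ds.n_sites, dtype=np.int64)
    for i in range(ds.n_sites):
        d = int(abs(int(ds.pos[i]) - int(sweep_pos)))
        if d not in cache:
            cache[d] = sweep_spectrum(bg, alpha, float(d))
        counts[i] = rng.choice(k_vals, p=cache[d])
    out.genotypes = _genotypes_from_counts(rng, counts, n_hap)
    return out


def gen_structured_demes(
    sc: DemeScenario, cfg: SimConfig
) -> tuple[GenotypeDataset, SampleMetadata]:
    """Balding–Nichols demes around a shared ancestral frequency.

    Per site an ancestral frequency p is drawn from the neutral 1/i law over a
    notional pool of 2·(total diploids) chromosomes; each deme's frequency is
    Beta(p(1−F)/F, (1−p)(1−F)/F) with F from ``F_of_distance`` applied to the
    deme's distance from the first deme (F = 0 reproduces p exactly), and
    genotypes are Hardy–Weinberg binomial draws within demes.
    """
    from .ibd import haversine_km

    rng = np.random.default_rng(cfg.seed)
    n_total = sc.n_demes * sc.n_per_deme
    pool = 2 * n_total
    sfs = neutral_sfs(pool)
    p_anc = rng.choice(np.arange(1, pool), size=cfg.n_sites, p=sfs.probs) / pool
    pos = _draw_positions(rng, cfg.n_sites, cfg.region_length)
    ref, alt = _alleles(rng, cfg.n_sites)

    lat0, lon0 = sc.deme_coords[0]
    genos = []
    rows = []
    for di in range(sc.n_demes):
        lat, lon = sc.deme_coords[di]
        km = haversine_km(lat0, lon0, lat, lon)
        F = float(sc.F_of_distance(km))
        if not 0.0 <= F < 1.0:
            raise ValueError(f"F_of_distance must map into [0, 1); got {F}")
        if F == 0.0:
            p_deme = p_anc
        else:
            c = (1.0 - F) / F
            p_deme = rng.beta(np.maximum(p_anc * c, 1e-12),
                              np.maximum((1.0 - p_anc) * c, 1e-12))
        g = rng.binomial(2, p_deme[:, None], size=(cfg.n_sites, sc.n_per_deme))
        genos.append(g.astype(np.int8))
        for s in range(sc.n_per_deme):
            rows.append(
                {
                    "sample": f"D{di}_{s:03d}",
                    "group": "zea2019",
                    "deme": f"deme{di}",
                    "lat": lat,
                    "lon": lon,
                    "year": 2019,
                }
            )
    geno = np.concatenate(genos, axis=1)
    meta = SampleMetadata(pd.DataFrame(rows))
    ds = GenotypeDataset(
        chrom=np.full(cfg.n_sites, "chr1", dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        ancestral=ref.copy(),
        qual=np.full(cfg.n_sites, 100.0),
        genotypes=geno,
        depth=np.full(geno.shape, 30, dtype=np.int32),
        samples=meta.samples,
        region_length=cfg.region_length,
    )
    return ds, meta


def gen_introgression_dataset(
    sc: IntrogressionScenario, cfg: SimConfig
) -> tuple[GenotypeDataset, SampleMetadata]:
    """Four-taxon dataset with donor tracts in designated P2 individuals.

    Recipient (P1, P2) and donor (P3) pools share ancestral polymorphism; with
    probability ``divergence`` a site is instead a fixed difference (donor
    fixed derived, recipients fixed ancestral).  The outgroup is fixed
    ancestral everywhere.  Designated P2 samples carry donor alleles across
    their tract intervals on 1 or 2 haplotypes; the injected tracts are
    returned in the metadata ``tracts`` column as ``start-end`` strings.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = _draw_positions(rng, cfg.n_sites, cfg.region_length)
    ref, alt = _alleles(rng, cfg.n_sites)

    names = (
        [f"P1_{i:03d}" for i in range(sc.n_p1)]
        + [f"P2_{i:03d}" for i in range(sc.n_p2)]
        + [f"P3_{i:03d}" for i in range(sc.n_p3)]
        + [f"OUT_{i:03d}" for i in range(sc.n_outgroup)]
    )
    groups = (
        ["P1"] * sc.n_p1 + ["P2"] * sc.n_p2 + ["P3"] * sc.n_p3
        + ["outgroup"] * sc.n_outgroup
    )
    for sid in sc.admixed_sample_ids:
        if sid not in names:
            raise ValueError(f"admixed sample {sid} not among P2 samples")

    n_samples = len(names)
    is_fixed_diff = rng.random(cfg.n_sites) < sc.divergence
    # shared ancestral polymorphism: one frequency per site for all pools
    pool = 2 * n_samples
    sfs = neutral_sfs(pool)
    p_shared = rng.choice(np.arange(1, pool), size=cfg.n_sites, p=sfs.probs) / pool

    geno = np.zeros((cfg.n_sites, n_samples), dtype=np.int8)
    grp = np.array(groups)
    recip = (grp == "P1") | (grp == "P2")
    donor = grp == "P3"
    outg = grp == "outgroup"
    shared = ~is_fixed_diff
    n_sh = int(shared.sum())
    for cols in (recip, donor):
        geno[np.ix_(shared, cols)] = rng.binomial(
            2, p_shared[shared, None], size=(n_sh, int(cols.sum()))
        ).astype(np.int8)
    geno[np.ix_(is_fixed_diff, donor)] = 2
    geno[:, outg] = 0  # outgroup fixed ancestral everywhere

    if len(sc.admixed_sample_ids) != len(sc.tract_intervals):
        raise ValueError("one tract list per admixed sample required")
    tract_col = {name: "" for name in names}
    for sid, tracts in zip(sc.admixed_sample_ids, sc.tract_intervals):
        col = names.index(sid)
        for (t_start, t_end) in tracts:
            in_tract = (pos - 1 >= t_start) & (pos - 1 < t_end)
            # donor allele = derived at fixed differences; the recipient
            # haplotype keeps the ancestral allele, so dosage = tract ploidy
            sel = in_tract & is_fixed_diff
            geno[sel, col] = sc.donor_tract_ploidy
        tract_col[sid] = ",".join(f"{s}-{e}" for s, e in tracts)

    rows = [
        {"sample": nm, "group": g, "deme": "", "lat": np.nan, "lon": np.nan,
         "year": 2019, "tracts": tract_col[nm]}
        for nm, g in zip(names, groups)
    ]
    meta = SampleMetadata(pd.DataFrame(rows))
    ds = GenotypeDataset(
        chrom=np.full(cfg.n_sites, "chr1", dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        ancestral=ref.copy(),
        qual=np.full(cfg.n_sites, 100.0),
        genotypes=geno,
        depth=np.full(geno.shape, 30, dtype=np.int32),
        samples=names,
        region_length=cfg.region_length,
    )
    return ds, meta


def gen_trajectory_observations(
    s: float,
    h: float,
    q0: float,
    years: list[int],
    gens_per_year: int = 10,
    N: int | None = None,
    n_chrom: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Allele-frequency observations along a selection trajectory.

    The deterministic recursion is propagated per generation from the first
    listed year; optional binomial(2N) drift acts each generation and optional
    binomial(n_chrom) sampling noise at each listed observation year.  With
    ``N=None`` and ``n_chrom=None`` the observations equal the deterministic
    trajectory exactly.
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must be in (0, 1)")
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must be in [0, 1]")
    years = sorted(years)
    rng = np.random.default_rng(seed)
    params = SelectionParams(s=s, h=h)
    q = q0
    prev = years[0]
    out = []
    for year in years:
        for _ in range((year - prev) * gens_per_year):
            q = step(q, params)
            if N is not None:
                q = rng.binomial(2 * N, q) / (2 * N)
        prev = year
        q_obs = q if n_chrom is None else rng.binomial(n_chrom, q) / n_chrom
        out.append((year, q_obs))
    return pd.DataFrame(out, columns=["year", "q_obs"])
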
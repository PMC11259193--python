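"""Site and genotype filters applied to called variants.

The filtering order is fixed and reported: per-genotype depth masking first
(out-of-bounds depths become missing), then site-level filters — QUAL, mean
depth bounds, missingness, biallelic-only — and finally singleton removal,
since singleton status depends on the genotypes left after masking.  The
Hardy–Weinberg screen uses the exact conditional (Levene/Haldane) test, is run
per group only at sites with no missing genotypes in that group, and removes
sites violating HWE in at least two groups.  A Z-linked-heterozygosity
association screen drops autosomal SNPs whose dosage predicts Z
heterozygosity (top percentile of OLS slope tests), guarding against
sex-linked reads mismapped to autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import MISSING, GenotypeDataset, SampleMetadata

__all__ = [
    "FilterConfig",
    "filter_variants",
    "hwe_exact_test",
    "hwe_filter",
    "z_assoc_filter",
    "confidence_to_qual",
    "select_proxy_snp",
]


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 20.0
    min_depth: int = 2
    max_depth: int = 200
    max_missing_fraction: float = 0.5
    drop_singletons: bool = True
    hwe_p_cutoff: float = 0.01
    hwe_min_violating_groups: int = 2
    z_assoc_top_percentile: float = 1.0
    confidence_level: float = 0.95

    def __post_init__(self):
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def filter_variants(
    ds: GenotypeDataset, cfg: FilterConfig = FilterConfig()
) -> tuple[GenotypeDataset, dict]:
    """Apply depth masking then site filters; returns (dataset, report).

    Report counts removals per rule in application order:
    qual → depth (site mean) → missing → biallelic → singleton.
    """
    out = ds.take_sites(np.arange(ds.n_sites))
    report = {"qual": 0, "depth": 0, "missing": 0, "biallelic": 0, "singleton": 0,
              "genotypes_masked": 0}
    if ds.n_sites == 0:
        return out, report

    # 1. per-genotype depth masking
    g = out.genotypes.copy()
    d = out.depth
    known = d != MISSING
    bad = known & ((d < cfg.min_depth) | (d > cfg.max_depth)) & (g != MISSING)
    report["genotypes_masked"] = int(bad.sum())
    g[bad] = MISSING
    out.genotypes = g

    keep = np.ones(out.n_sites, dtype=bool)

    # 2. site QUAL
    fail = keep & np.isfinite(out.qual) & (out.qual < cfg.min_qual)
    report["qual"] = int(fail.sum()); keep &= ~fail

    # 3. site mean depth bounds (over genotypes with known depth)
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            known.sum(axis=1) > 0,
            np.where(known, d, 0).sum(axis=1) / np.maximum(known.sum(axis=1), 1),
            np.nan,
        )
    fail = keep & np.isfinite(mean_depth) & (
        (mean_depth < cfg.min_depth) | (mean_depth > cfg.max_depth)
    )
    report["depth"] = int(fail.sum()); keep &= ~fail

    # 4. missingness
    miss_frac = (g == MISSING).mean(axis=1)
    fail = keep & (miss_frac > cfg.max_missing_fraction)
    report["missing"] = int(fail.sum()); keep &= ~fail

    # 5. biallelic SNPs only
    fail = keep & ~out.is_biallelic
    report["biallelic"] = int(fail.sum()); keep &= ~fail

    # 6. singletons: minor allele count exactly 1 over non-missing genotypes
    if cfg.drop_singletons:
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        n_chrom = 2 * called.sum(axis=1)
        mac = np.minimum(alt, n_chrom - alt)
        fail = keep & (mac == 1)
        report["singleton"] = int(fail.sum()); keep &= ~fail

    return out.take_sites(keep), report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test (Levene/Haldane).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one.  Returns p ∈ (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([_log_hwe_prob(n, nA, h) for h in hets])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_Aa)[0][0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def _log_hwe_prob(n: int, nA: int, het: int) -> float:
    """Log conditional probability of ``het`` heterozygotes given allele counts."""
    from scipy.special import gammaln

    n_AA = (nA - het) // 2
    n_aa = (2 * n - nA - het) // 2
    return (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(het + 1)
        - gammaln(n_aa + 1)
        + het * np.log(2.0)
        + gammaln(nA + 1)
        + gammaln(2 * n - nA + 1)
        - gammaln(2 * n + 1)
    )


def hwe_filter(
    ds: GenotypeDataset,
    meta: SampleMetadata,
    groups: list[str],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[GenotypeDataset, np.ndarray]:
    """Remove sites violating HWE (p < cutoff) in ≥ the configured number of groups.

    Within each group the exact test runs only at sites with no missing
    genotypes in that group; a site missing anywhere in a group is simply not
    tested there.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for the HWE screen")
    violations = np.zeros(ds.n_sites, dtype=int)
    for gname in groups:
        idx = ds.sample_indices(meta.group(gname))
        g = ds.genotypes[:, idx]
        complete = ~(g == MISSING).any(axis=1)
        for i in np.where(complete)[0]:
            col = g[i]
            n_aa = int((col == 2).sum())
            n_Aa = int((col == 1).sum())
            n_AA = int((col == 0).sum())
            if n_Aa + min(n_AA, n_aa) == 0:  # monomorphic: trivially in HWE
                continue
            if hwe_exact_test(n_AA, n_Aa, n_aa) < cfg.hwe_p_cutoff:
                violations[i] += 1
    remove = violations >= cfg.hwe_min_violating_groups
    removed_pos = ds.pos[remove]
    return ds.take_sites(~remove), removed_pos


def z_assoc_filter(
    ds: GenotypeDataset,
    z_het: dict | pd.Series,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[GenotypeDataset, np.ndarray, bool]:
    """Drop autosomal SNPs most associated with Z-chromosome heterozygosity.

    Ordinary least-squares regression of per-sample Z heterozygosity on
    dosage; sites whose slope-test p-value falls in the smallest
    ``z_assoc_top_percentile`` percent (ties at the boundary included) are
    removed.  A constant z_het makes every slope untestable: the dataset is
    returned unchanged with the warning flag set.
    """
    z = pd.Series(z_het).reindex(ds.samples).to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("z_het must be defined for all samples")
    if np.allclose(z, z[0]):
        return ds, np.array([], dtype=np.int64), True

    pvals = np.full(ds.n_sites, np.nan)
    g = ds.genotypes
    for i in range(ds.n_sites):
        ok = g[i] != MISSING
        if ok.sum() < 3:
            continue
        x = g[i, ok].astype(float)
        y = z[ok]
        if x.std() == 0 or y.std() == 0:
            continue
        res = sps.linregress(x, y)
        pvals[i] = res.pvalue

    testable = np.isfinite(pvals)
    m = int(testable.sum())
    if m == 0:
        return ds, np.array([], dtype=np.int64), False
    k = int(np.ceil(cfg.z_assoc_top_percentile / 100.0 * m))
    cutoff = np.sort(pvals[testable])[k - 1]
    remove = testable & (pvals <= cutoff)
    removed_pos = ds.pos[remove]
    return ds.take_sites(~remove), removed_pos, False


def confidence_to_qual(confidence_level: float) -> float:
    """Phred-scaled quality threshold for a genotype confidence level.

    confidence 0.95 → −10·log10(0.05) = 13.0103.
    """
    if not 0.0 < confidence_level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    return -10.0 * np.log10(1.0 - confidence_level)


def select_proxy_snp(
    ds: GenotypeDataset,
    interval: tuple[int, int],
    max_missing: float = 0.25,
) -> dict:
    """Choose the proxy SNP for a locus: lowest major-allele frequency.

    Among biallelic sites inside ``interval`` (1-based, inclusive) with
    missing fraction ≤ ``max_missing``, returns the site minimizing the major
    allele frequency; ties break to the lowest position.
    """
    lo, hi = interval
    in_iv = (ds.pos >= lo) & (ds.pos <= hi) & ds.is_biallelic
    g = ds.genotypes
    miss_frac = (g == MISSING).mean(axis=1)
    candidates = np.where(in_iv & (miss_frac <= max_missing))[0]
    if len(candidates) == 0:
        raise ValueError("no qualifying site in interval")
    best = None
    for i in candidates:
        called = g[i] != MISSING
        n_chrom = 2 * int(called.sum())
        if n_chrom == 0:
            continue
        alt = int(g[i, called].sum())
        maf = max(alt, n_chrom - alt) / n_chrom
        key = (maf, int(ds.pos[i]))
        if best is None or key < best[0]:
            best = (key, i, alt, n_chrom)
    if best is None:
        raise ValueError("no qualifying site in interval")
    _, i, alt, n_chrom = best
    return {
        "pos": int(ds.pos[i]),
        "chrom": str(ds.chrom[i]),
        "major_freq": best[0][0],
        "alt_freq": alt / n_chrom,
        "n_chrom": n_chrom,
    }
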
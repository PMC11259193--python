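"""Polarization, the escape-and-drag sweep spectrum, and the CLR scan."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import zeapop as z
from zeapop.sweep import PolarizedSites, SweepScan, neutral_sfs
from conftest import simple_metadata, toy_dataset

M = z.MISSING


# ---------------------------------------------------------------------------
# polarization


def _polar_fixture(out_genotypes, in_genotypes):
    g = np.hstack([np.asarray(in_genotypes), np.asarray(out_genotypes)])
    ds = toy_dataset(g)
    n_in = np.asarray(in_genotypes).shape[1]
    groups = ["zea"] * n_in + ["outgroup"] * np.asarray(out_genotypes).shape[1]
    meta = simple_metadata(ds.samples, groups=groups)
    return ds, meta


def test_polarize_outgroup_fixed_ref():
    ds, meta = _polar_fixture([[0, 0, 0]], [[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]])
    sites = z.polarize(ds, meta, ["outgroup"])
    assert sites.k.tolist() == [3]
    assert sites.n.tolist() == [20]


def test_polarize_ambiguous_outgroup_excluded():
    ds, meta = _polar_fixture([[1, 1, 0, 0]], [[1, 0, 1, 0]])
    sites = z.polarize(ds, meta, ["outgroup"])
    assert len(sites) == 0
    assert sites.excluded["reason"].iloc[0] == "ambiguous ancestral"


def test_polarize_outgroup_fixed_alt_flips_polarity():
    ds, meta = _polar_fixture([[2, 2, 2]], [[2, 2, 1, 0]])
    sites = z.polarize(ds, meta, ["outgroup"])
    # ancestral is ALT: derived = REF count = 8 - 5 = 3
    assert sites.k.tolist() == [3]
    assert sites.n.tolist() == [8]


def test_polarize_requires_outgroup():
    ds, meta = _polar_fixture([[0]], [[1, 0]])
    with pytest.raises(ValueError):
        z.polarize(ds, meta, ["missing_group"])


# ---------------------------------------------------------------------------
# background SFS and projection


def test_background_sfs_single_site_point_mass():
    sites = PolarizedSites(pos=np.array([10]), k=np.array([1]),
                           n=np.array([4]))
    bg = z.background_sfs(sites)
    assert bg.probs[0] == pytest.approx(1.0)


def test_background_sfs_matches_generator_law(background_ds):
    k = background_ds.genotypes.sum(axis=1)
    n_hap = 2 * background_ds.n_samples
    sites = PolarizedSites(pos=background_ds.pos, k=k,
                           n=np.full(len(k), n_hap))
    bg = z.background_sfs(sites)
    expected = neutral_sfs(n_hap).probs
    assert np.abs(bg.probs - expected).sum() < 0.05


def test_projection_point_mass_is_hypergeometric():
    n, m, i = 12, 6, 6
    probs = np.zeros(n - 1)
    probs[i - 1] = 1.0
    proj = z.project_sfs(probs, n, m)
    expected = hypergeom.pmf(np.arange(m + 1), n, i, m)
    np.testing.assert_allclose(proj, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# sweep spectrum


def test_sweep_spectrum_full_escape_equals_background():
    bg = neutral_sfs(10)
    out = z.sweep_spectrum(bg, 10.0, 1e7)
    assert np.abs(out - bg.probs).sum() < 1e-6


def test_sweep_spectrum_two_haplotypes_invariant():
    bg = neutral_sfs(2)
    for alpha, d in [(1e-6, 10), (1e-3, 1e4), (0.5, 3)]:
        np.testing.assert_allclose(z.sweep_spectrum(bg, alpha, d), [1.0])


def test_sweep_spectrum_sums_to_one_nonnegative():
    for n in (3, 6, 20):
        bg = neutral_sfs(n)
        for x in (1e-6, 0.01, 1.0, 100.0):
            out = z.sweep_spectrum(bg, 1.0, x)
            assert abs(out.sum() - 1) < 1e-12
            assert (out >= 0).all()


def _exact_spectrum(bg_probs, n, p_e: Fraction):
    """Rational-arithmetic enumeration of the escape-and-drag mixture."""
    bg = [Fraction(x).limit_denominator(10**12) for x in bg_probs]
    out = [Fraction(0)] * (n + 1)
    for e in range(n + 1):
        w_e = (
            Fraction(comb(n, e)) * p_e**e * (1 - p_e) ** (n - e)
        )
        if e == n:
            for k in range(1, n):
                out[k] += w_e * bg[k - 1]
            continue
        m = e + 1
        # exact hypergeometric projection of bg to m lineages
        for i in range(1, n):
            for j in range(0, m + 1):
                if j > i or m - j > n - i:
                    continue
                q = (
                    bg[i - 1]
                    * Fraction(comb(i, j) * comb(n - i, m - j), comb(n, m))
                )
                if q == 0:
                    continue
                if j > 0:
                    out[(j - 1) + (n - e)] += q * w_e * Fraction(j, m)
                if j < m:
                    out[j] += q * w_e * Fraction(m - j, m)
    poly = out[1:n]
    total = sum(poly)
    return [float(x / total) for x in poly]


@pytest.mark.parametrize("n", [3, 4, 5, 6])
@pytest.mark.parametrize("p_e", [Fraction(1, 10), Fraction(3, 10), Fraction(9, 10)])
def test_sweep_spectrum_matches_rational_enumeration(n, p_e):
    bg = neutral_sfs(n)
    x = -np.log(1 - float(p_e))  # alpha*d giving this escape probability
    mine = z.sweep_spectrum(bg, 1.0, x)
    exact = _exact_spectrum(bg.probs, n, p_e)
    np.testing.assert_allclose(mine, exact, atol=1e-9)


def test_sweep_spectrum_matches_monte_carlo():
    rng = np.random.default_rng(1)
    n, p_e = 20, 0.3
    bg = neutral_sfs(n)
    draws = []
    while len(draws) < 100_000:
        e = rng.binomial(n, p_e)
        if e == n:
            k = rng.choice(np.arange(1, n), p=bg.probs)
        else:
            m = e + 1
            i = rng.choice(np.arange(1, n), p=bg.probs)
            j = rng.hypergeometric(i, n - i, m)
            if rng.random() < j / m:
                k = j - 1 + (n - e)
            else:
                k = j
        if 1 <= k <= n - 1:
            draws.append(k)
    emp = np.bincount(draws, minlength=n)[1:n] / len(draws)
    model = z.sweep_spectrum(bg, 1.0, -np.log(1 - p_e))
    assert np.abs(emp - model).sum() < 0.01


def test_sweep_distortion_decreases_with_distance():
    bg = neutral_sfs(12)
    alpha = 1e-5
    tv = [
        0.5 * np.abs(z.sweep_spectrum(bg, alpha, d) - bg.probs).sum()
        for d in [0, 1e3, 1e4, 1e5, 1e6, 1e7]
    ]
    assert all(a >= b - 1e-9 for a, b in zip(tv, tv[1:]))


# ---------------------------------------------------------------------------
# CLR scan and regions


def _polarized_from(ds):
    k = ds.genotypes.sum(axis=1)
    return PolarizedSites(pos=ds.pos, k=k,
                          n=np.full(len(k), 2 * ds.n_samples), chrom=ds.chrom)


@pytest.fixture(scope="module")
def null_scan():
    cfg = z.SimConfig(n_individuals=10, n_sites=2000,
                      region_length=1_000_000, seed=3)
    ds = z.gen_background_genotypes(cfg)
    return z.clr_scan(_polarized_from(ds))


def test_clr_nonnegative_and_null_calibrated(null_scan):
    assert (null_scan.clr >= 0).all()
    assert np.percentile(null_scan.clr, 99) < 10


def test_clr_recovers_spiked_sweep():
    cfg = z.SimConfig(n_individuals=10, n_sites=2000,
                      region_length=1_000_000, seed=3)
    ds = z.gen_background_genotypes(cfg)
    spiked = z.spike_sweep_signal(ds, 500_000, 1e-5, seed=11)
    scan = z.clr_scan(_polarized_from(spiked))
    peak = scan.positions[np.argmax(scan.clr)]
    assert abs(peak - 500_000) <= 50_000
    a_hat = scan.alpha_hat[np.argmax(scan.clr)]
    assert 1e-5 / 3 <= a_hat <= 1e-5 * 3


def test_clr_scan_requires_sites():
    sites = PolarizedSites(pos=np.array([1, 2]), k=np.array([1, 1]),
                           n=np.array([4, 4]))
    with pytest.raises(ValueError):
        z.clr_scan(sites)


def _toy_scan(positions, clr):
    return SweepScan(positions=np.asarray(positions),
                     clr=np.asarray(clr, float),
                     alpha_hat=np.full(len(positions), 1e-5),
                     span=(int(min(positions)), int(max(positions))))


def test_region_merging_and_extension_rules():
    pos = np.arange(0, 200_001, 1000)
    clr = np.zeros(len(pos))
    clr[pos == 100_000] = 50.0
    clr[pos == 115_000] = 40.0
    regions = z.define_sweep_regions(_toy_scan(pos, clr), percentile=99.5)
    assert len(regions) == 1
    assert regions["start"].iloc[0] == 80_000
    assert regions["end"].iloc[0] == 135_000

    clr2 = np.zeros(len(pos))
    clr2[pos == 100_000] = 50.0
    clr2[pos == 130_000] = 40.0
    regions2 = z.define_sweep_regions(_toy_scan(pos, clr2), percentile=99.5)
    assert len(regions2) == 2


def test_region_constant_clr_includes_all_ties():
    pos = np.arange(0, 10_001, 1000)
    regions = z.define_sweep_regions(_toy_scan(pos, np.full(len(pos), 5.0)),
                                     percentile=99.99)
    assert len(regions) == 1
    # every grid point ties at the threshold -> one merged region
    assert regions["start"].iloc[0] <= 0
    assert regions["end"].iloc[0] >= 10_000


def test_null_regions_cover_almost_nothing(null_scan):
    regions = z.define_sweep_regions(null_scan, percentile=99.99,
                                     extend=0)
    span = null_scan.span[1] - null_scan.span[0]
    covered = (regions["end"] - regions["start"]).sum() if len(regions) else 0
    assert covered < 0.001 * span


def test_estimate_s_printed_values_and_scaling():
    s = z.estimate_s(1.6195e-5, 5.447e-8, 1.03e6)
    assert s == pytest.approx(0.0489, abs=5e-4)
    assert z.estimate_s(2e-5, 5.447e-8, 1.03e6) < s  # decreasing in alpha
    assert z.estimate_s(1.6195e-5, 2 * 5.447e-8, 1.03e6) == pytest.approx(
        2 * s, rel=1e-12)
    with pytest.raises(ValueError):
        z.estimate_s(0.0, 1e-8, 1e6)


def test_locus_permutation_whole_span_p_one(null_scan):
    res = z.locus_overlap_permutation(
        null_scan, (null_scan.span[0], null_scan.span[1]), n_perm=99, seed=1)
    assert res["p_mean"] == pytest.approx(1.0)
    assert res["p_max"] == pytest.approx(1.0)


def test_locus_permutation_single_peak():
    pos = np.arange(0, 100_001, 1000)
    clr = np.zeros(len(pos))
    clr[50] = 100.0
    scan = _toy_scan(pos, clr)
    res = z.locus_overlap_permutation(scan, (50_000, 51_000),
                                      n_perm=999, seed=5)
    assert res["p_max"] == pytest.approx(0.01, abs=0.01)
    res2 = z.locus_overlap_permutation(scan, (50_000, 51_000),
                                       n_perm=999, seed=5)
    assert res["p_max"] == res2["p_max"]  # reproducible


def test_locus_permutation_rejects_oversized_locus(null_scan):
    with pytest.raises(ValueError):
        z.locus_overlap_permutation(
            null_scan, (0, null_scan.span[1] + 10_000_000), n_perm=10)
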
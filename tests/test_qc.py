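"""Variant filters, the exact Hardy–Weinberg test, and call thresholds."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import zeapop as z
from conftest import simple_metadata, toy_dataset

M = z.MISSING


# ---------------------------------------------------------------------------
# filter_variants


def _six_site_fixture():
    """One site failing each rule in order, plus one clean site."""
    g = [
        [1, 1, 0, 0, 2],  # fails QUAL
        [1, 1, 0, 0, 2],  # fails mean depth (300x)
        [1, 1, M, M, M],  # 60% missing
        [0, 1, 1, 0, 0],  # triallelic
        [1, 0, 0, 0, 0],  # singleton
        [1, 1, 0, 2, 0],  # clean
    ]
    qual = [10.0, 100, 100, 100, 100, 100]
    depth = np.full((6, 5), 30, dtype=np.int32)
    depth[1] = 300
    bi = [True, True, True, False, True, True]
    return toy_dataset(g, qual=qual, depth=depth, is_biallelic=bi)


def test_filter_rules_each_remove_designed_site():
    ds = _six_site_fixture()
    out, report = z.filter_variants(ds)
    assert out.n_sites == 1
    assert out.pos[0] == ds.pos[5]
    assert {k: report[k] for k in
            ("qual", "depth", "missing", "biallelic", "singleton")} == {
        "qual": 1, "depth": 1, "missing": 1, "biallelic": 1, "singleton": 1}


def test_filter_report_counts_sum_to_removed():
    ds = _six_site_fixture()
    out, report = z.filter_variants(ds)
    removed = sum(report[k] for k in
                  ("qual", "depth", "missing", "biallelic", "singleton"))
    assert removed == ds.n_sites - out.n_sites


def test_filter_idempotent():
    ds = _six_site_fixture()
    once, _ = z.filter_variants(ds)
    twice, report = z.filter_variants(once)
    np.testing.assert_array_equal(once.genotypes, twice.genotypes)
    assert sum(report[k] for k in
               ("qual", "depth", "missing", "biallelic", "singleton")) == 0


def test_filter_empty_and_allpass():
    empty = toy_dataset(np.empty((0, 4), dtype=np.int8))
    out, report = z.filter_variants(empty)
    assert out.n_sites == 0 and all(v == 0 for v in report.values())
    clean = toy_dataset([[1, 1, 0, 2], [2, 0, 1, 1]])
    out, _ = z.filter_variants(clean)
    assert out.n_sites == 2


def test_genotype_depth_masking_precedes_site_filters():
    # one genotype at depth 1: masked, turning the site into a singleton
    depth = np.full((1, 4), 30, dtype=np.int32)
    depth[0, 0] = 1
    ds = toy_dataset([[1, 1, 0, 0]], depth=depth)
    out, report = z.filter_variants(ds)
    assert report["genotypes_masked"] == 1
    assert report["singleton"] == 1
    assert out.n_sites == 0


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact rational enumeration of the Levene conditional distribution."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    rare = min(nA, na)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        aa2 = (nA - het) // 2
        bb2 = (na - het) // 2
        w = (
            Fraction(
                comb(n, aa2) * comb(n - aa2, het) * 2**het,
            )
            * Fraction(1, comb(2 * n, nA))
        )
        probs[het] = w
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize(
    "counts,expected",
    [((1, 0, 1), 1 / 3), ((0, 2, 0), 1.0)],
)
def test_hwe_exact_small_cases(counts, expected):
    assert z.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)


def test_hwe_large_balanced_sample_in_equilibrium():
    assert z.hwe_exact_test(25, 50, 25) >= 0.95


@given(
    st.integers(0, 5), st.integers(0, 5), st.integers(0, 5)
)
def test_hwe_matches_rational_enumeration(n_AA, n_Aa, n_aa):
    if n_AA + n_Aa + n_aa == 0:
        return
    assert z.hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
        _hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-10
    )


def test_hwe_rejects_empty():
    with pytest.raises(ValueError):
        z.hwe_exact_test(0, 0, 0)


def test_hwe_filter_removes_all_het_sites_in_two_groups():
    # 150 samples in 3 groups of 50; site 0 is all-het in groups 0 and 1
    n = 150
    g0 = np.ones(n, dtype=np.int8)
    g0[100:] = np.tile([0, 1, 1, 0, 2], 10)  # group C near-HWE mix
    # per-group 12 AA + 26 Aa + 12 aa: essentially exact HWE at p = 0.5
    g1 = np.tile([0] * 12 + [1] * 26 + [2] * 12, 3).astype(np.int8)
    ds = toy_dataset(np.vstack([g0, g1]))
    groups = ["A"] * 50 + ["B"] * 50 + ["C"] * 50
    meta = simple_metadata(ds.samples, groups=groups)
    out, removed = z.hwe_filter(ds, meta, ["A", "B", "C"])
    assert list(removed) == [ds.pos[0]]
    assert out.n_sites == 1


def test_hwe_filter_skips_groups_with_missing_genotypes():
    n = 60
    g0 = np.ones(n, dtype=np.int8)
    g0[0] = M  # group A has missing data: its test is skipped
    ds = toy_dataset(g0.reshape(1, -1))
    groups = ["A"] * 30 + ["B"] * 30
    meta = simple_metadata(ds.samples, groups=groups)
    out, removed = z.hwe_filter(ds, meta, ["A", "B"])
    # only group B violates -> below the 2-group threshold -> retained
    assert out.n_sites == 1 and len(removed) == 0


# ---------------------------------------------------------------------------
# Z-heterozygosity association filter


def test_z_assoc_removes_perfectly_correlated_snp():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
    z_het = g[7] * 0.1 + 0.05  # SNP 7 is a linear transform of z_het
    ds = toy_dataset(g)
    out, removed, warn = z.z_assoc_filter(ds, dict(zip(ds.samples, z_het)))
    assert not warn
    assert ds.pos[7] in removed


def test_z_assoc_constant_trait_removes_nothing():
    g = np.random.default_rng(1).integers(0, 3, size=(20, 10)).astype(np.int8)
    ds = toy_dataset(g)
    out, removed, warn = z.z_assoc_filter(ds, {s: 0.3 for s in ds.samples})
    assert warn and len(removed) == 0 and out.n_sites == 20


def test_z_assoc_removes_one_percent_of_testable_sites():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(200, 60)).astype(np.int8)
    z_het = rng.normal(size=60)
    ds = toy_dataset(g)
    out, removed, _ = z.z_assoc_filter(ds, dict(zip(ds.samples, z_het)))
    assert len(removed) == 2  # ceil(0.01 * 200)
    assert out.n_sites == 198


# ---------------------------------------------------------------------------
# thresholds and proxy SNP


@pytest.mark.parametrize(
    "level,expected",
    [(0.95, 13.0103), (0.9, 10.0), (0.99, 20.0)],
)
def test_confidence_to_qual(level, expected):
    assert z.confidence_to_qual(level) == pytest.approx(expected, abs=1e-4)


def test_confidence_to_qual_range():
    for bad in (0.0, 1.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            z.confidence_to_qual(bad)


def test_proxy_snp_lowest_major_allele_frequency():
    # major freqs 0.99, 0.95, 0.97 over 50 diploids
    g = np.zeros((3, 50), dtype=np.int8)
    g[0, :1] = 1   # alt freq 0.01 -> major 0.99
    g[1, :5] = 1   # alt freq 0.05 -> major 0.95
    g[2, :3] = 1   # alt freq 0.03 -> major 0.97
    ds = toy_dataset(g, pos=[100, 200, 300])
    res = z.select_proxy_snp(ds, (1, 1000))
    assert res["pos"] == 200
    assert res["major_freq"] == pytest.approx(0.95)


def test_proxy_snp_missingness_and_ties():
    g = np.zeros((2, 8), dtype=np.int8)
    g[0, :2] = 1
    g[1, :2] = 1
    g_missing = g.copy()
    g_missing[0, 2:6] = M  # 50% missing: disqualified
    ds = toy_dataset(g_missing, pos=[10, 20])
    assert z.select_proxy_snp(ds, (1, 100))["pos"] == 20
    ds_tie = toy_dataset(g, pos=[10, 20])
    assert z.select_proxy_snp(ds_tie, (1, 100))["pos"] == 10


def test_proxy_snp_empty_interval_errors():
    ds = toy_dataset(np.zeros((1, 4), dtype=np.int8), pos=[10])
    with pytest.raises(ValueError):
        z.select_proxy_snp(ds, (500, 600))
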
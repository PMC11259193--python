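"""Frequency-based ABBA–BABA statistics: windowed D and fd̂.

For a site with derived-allele frequencies (p1, p2, p3, pO) in P1 (reference
non-admixed population), P2 (test population), P3 (candidate donor) and the
outgroup, the expected site-pattern weights are

    ABBA = (1−p1)·p2·p3·(1−pO),    BABA = p1·(1−p2)·p3·(1−pO),

and the donor-normalization terms substitute pD = max(p2, p3) for both p2 and
p3.  Over a window, D = Σ(ABBA−BABA)/Σ(ABBA+BABA) and fd̂ =
Σ(ABBA−BABA)/Σ(ABBA_D−BABA_D), the latter estimating the admixed fraction of
the window and reported only where D > 0 (configurable zero-fill otherwise).
Sites are polarized so the outgroup's major allele is ancestral; sites whose
outgroup frequency is strictly between the polarization cutoffs are excluded
as unpolarizable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset, SampleMetadata
from .windows import welch_t_test

__all__ = [
    "site_patterns",
    "site_pattern_table",
    "window_d_fd",
    "per_individual_fd",
    "segment_compare",
]


def site_patterns(p1, p2, p3, pO):
    """ABBA/BABA weights and their donor-substituted counterparts."""
    p1, p2, p3, pO = (np.asarray(x, dtype=float) for x in (p1, p2, p3, pO))
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    pD = np.maximum(p2, p3)
    abba_d = (1 - p1) * pD * pD * (1 - pO)
    baba_d = p1 * (1 - pD) * pD * (1 - pO)
    return abba, baba, abba_d, baba_d


def _group_freqs(ds: GenotypeDataset, samples: list[str]):
    idx = ds.sample_indices(samples)
    g = ds.genotypes[:, idx]
    called = g != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def site_pattern_table(
    ds: GenotypeDataset,
    P1: list[str],
    P2: list[str],
    P3: list[str],
    outgroup: list[str],
    polarize_cutoff: float = 0.8,
    min_chroms: int = 2,
) -> pd.DataFrame:
    """Per-site derived frequencies and pattern weights, outgroup-polarized.

    The ancestral allele is the outgroup major allele when its frequency is
    ≥ ``polarize_cutoff`` (or ≤ 1−cutoff); other sites are dropped, as are
    sites with fewer than ``min_chroms`` non-missing chromosomes in any of
    P1, P2, P3 or none in the outgroup.
    """
    f1, n1 = _group_freqs(ds, P1)
    f2, n2 = _group_freqs(ds, P2)
    f3, n3 = _group_freqs(ds, P3)
    fO, nO = _group_freqs(ds, outgroup)

    usable = (
        ds.is_biallelic
        & (n1 >= min_chroms)
        & (n2 >= min_chroms)
        & (n3 >= min_chroms)
        & (nO > 0)
        & ((fO >= polarize_cutoff) | (fO <= 1 - polarize_cutoff))
    )
    # polarize: when the outgroup major allele is ALT, derived = REF
    flip = fO >= polarize_cutoff
    p1 = np.where(flip, 1 - f1, f1)
    p2 = np.where(flip, 1 - f2, f2)
    p3 = np.where(flip, 1 - f3, f3)
    pO = np.where(flip, 1 - fO, fO)
    abba, baba, abba_d, baba_d = site_patterns(p1, p2, p3, pO)
    t = pd.DataFrame(
        {
            "pos": ds.pos,
            "p1": p1, "p2": p2, "p3": p3, "pO": pO,
            "abba": abba, "baba": baba,
            "abba_d": abba_d, "baba_d": baba_d,
        }
    )
    return t[usable].reset_index(drop=True)


def window_d_fd(
    sites: pd.DataFrame,
    windows: list[tuple[int, int]],
    min_snps: int = 200,
    fd_zero_fill: bool = False,
) -> pd.DataFrame:
    """Windowed D and fd̂ from a site-pattern table.

    fd̂ is missing wherever D ≤ 0 or the donor denominator is non-positive
    (``fd_zero_fill=True`` reports 0 instead); windows with fewer than
    ``min_snps`` usable sites are missing entirely.
    """
    pos0 = sites["pos"].to_numpy() - 1
    rows = []
    for start, end in windows:
        sel = (pos0 >= start) & (pos0 < end)
        n = int(sel.sum())
        rec = {"start": start, "end": end, "n_snps": n,
               "abba": np.nan, "baba": np.nan, "D": np.nan, "fd": np.nan}
        if n >= min_snps:
            sa = sites.loc[sel, "abba"].sum()
            sb = sites.loc[sel, "baba"].sum()
            sad = sites.loc[sel, "abba_d"].sum()
            sbd = sites.loc[sel, "baba_d"].sum()
            rec["abba"], rec["baba"] = sa, sb
            if sa + sb > 0:
                rec["D"] = (sa - sb) / (sa + sb)
            denom = sad - sbd
            if np.isfinite(rec["D"]) and rec["D"] > 0 and denom > 0:
                rec["fd"] = (sa - sb) / denom
            elif fd_zero_fill and np.isfinite(rec["D"]):
                rec["fd"] = 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def per_individual_fd(
    ds: GenotypeDataset,
    individual: str,
    P1: list[str],
    P3: list[str],
    outgroup: list[str],
    windows: list[tuple[int, int]],
    min_snps: int = 200,
    **kwargs,
) -> pd.DataFrame:
    """Windowed D and fd̂ with a single diploid as the P2 set (p2 ∈ {0,½,1})."""
    table = site_pattern_table(ds, P1, [individual], P3, outgroup,
                               min_chroms=2, **kwargs)
    return window_d_fd(table, windows, min_snps=min_snps)


def segment_compare(
    windowsA: pd.DataFrame,
    windowsB: pd.DataFrame,
    statistic: str,
) -> dict:
    """Welch comparison of a window statistic between two genome segments."""
    a = windowsA[statistic].to_numpy(dtype=float)
    b = windowsB[statistic].to_numpy(dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty segment")
    res = welch_t_test(a, b)
    res.update({"mean_A": float(a.mean()), "mean_B": float(b.mean()),
                "n_A": len(a), "n_B": len(b)})
    return res
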
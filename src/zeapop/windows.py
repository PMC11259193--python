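"""Windowed diversity, divergence and differentiation statistics.

Per-site estimators are missing-data aware and combined over tiled,
non-overlapping windows aligned to multiples of the window size:

* π (nucleotide diversity): Σ 2·i·(n−i)/(n·(n−1)) over sites, divided by the
  window's callable length;
* dxy: Σ pA(1−pB) + pB(1−pA), same denominator;
* Hudson FST as a ratio of averages: Σ[(pA−pB)² − pA(1−pA)/(nA−1) −
  pB(1−pB)/(nB−1)] / Σ[pA(1−pB) + pB(1−pA)].

Windows below their minimum informative-site count (200 for 20 kbp, 100 for
100 kbp by default) are reported missing, never zero.  A composite-LD decay
curve (squared dosage correlation, suitable for unphased data) and the Welch
unequal-variance t test used for segment contrasts live here too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import MISSING, GenotypeDataset

__all__ = [
    "make_windows",
    "default_min_sites",
    "window_pi",
    "window_dxy",
    "window_fst",
    "ld_decay",
    "welch_t_test",
]


def make_windows(ds_or_length, size: int) -> list[tuple[int, int]]:
    """Tiled [start, end) windows (0-based bp) aligned to multiples of size."""
    if isinstance(ds_or_length, GenotypeDataset):
        length = ds_or_length.region_length or int(ds_or_length.pos.max())
    else:
        length = int(ds_or_length)
    starts = np.arange(0, length, size)
    return [(int(s), int(min(s + size, length))) for s in starts]


def default_min_sites(size: int) -> int:
    """Minimum informative sites per window: 200 at 20 kbp, 100 at 100 kbp."""
    if size >= 100_000:
        return 100
    return 200


def _freqs(ds: GenotypeDataset, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt frequency, non-missing chromosome count) for a sample set."""
    g = ds.genotypes[:, idx]
    called = g != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def _callable_length(ds: GenotypeDataset, window: tuple[int, int]) -> float:
    cl = ds.callable_length.get(window)
    return float(cl) if cl else float(window[1] - window[0])


def _site_pi(ds: GenotypeDataset, idx: np.ndarray) -> np.ndarray:
    g = ds.genotypes[:, idx]
    called = g != MISSING
    n = 2 * called.sum(axis=1).astype(float)
    i = np.where(called, g, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * i * (n - i) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def _window_frame(ds, windows, values, n_sites, min_sites, colname):
    rows = []
    for (start, end), v, ns in zip(windows, values, n_sites):
        rows.append(
            {
                "chrom": ds.chrom[0] if ds.n_sites else "chr1",
                "start": start,
                "end": end,
                "n_sites": int(ns),
                colname: v if ns >= min_sites else np.nan,
            }
        )
    return pd.DataFrame(rows)


def window_pi(
    ds: GenotypeDataset,
    population: list[str],
    windows: list[tuple[int, int]],
    min_sites: int | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per window for one population."""
    if not population:
        raise ValueError("population must contain at least one sample")
    if min_sites is None:
        min_sites = default_min_sites(windows[0][1] - windows[0][0]) if windows else 0
    idx = ds.sample_indices(population)
    pi_site = _site_pi(ds, idx)
    pos0 = ds.pos - 1  # 0-based
    vals, counts = [], []
    for w in windows:
        sel = (pos0 >= w[0]) & (pos0 < w[1]) & ds.is_biallelic
        used = sel & np.isfinite(pi_site)
        cl = _callable_length(ds, w)
        vals.append(np.nansum(pi_site[used]) / cl if cl > 0 else np.nan)
        counts.append(used.sum())
    return _window_frame(ds, windows, vals, counts, min_sites, "pi")


def window_dxy(
    ds: GenotypeDataset,
    popA: list[str],
    popB: list[str],
    windows: list[tuple[int, int]],
    min_sites: int | None = None,
) -> pd.DataFrame:
    """Absolute divergence dxy per window between two populations."""
    if not popA or not popB:
        raise ValueError("both populations must be non-empty")
    if min_sites is None:
        min_sites = default_min_sites(windows[0][1] - windows[0][0]) if windows else 0
    pA, nA = _freqs(ds, ds.sample_indices(popA))
    pB, nB = _freqs(ds, ds.sample_indices(popB))
    d_site = pA * (1 - pB) + pB * (1 - pA)
    ok = (nA > 0) & (nB > 0)
    pos0 = ds.pos - 1
    vals, counts = [], []
    for w in windows:
        sel = (pos0 >= w[0]) & (pos0 < w[1]) & ds.is_biallelic & ok
        cl = _callable_length(ds, w)
        vals.append(np.nansum(d_site[sel]) / cl if cl > 0 else np.nan)
        counts.append(sel.sum())
    return _window_frame(ds, windows, vals, counts, min_sites, "dxy")


def window_fst(
    ds: GenotypeDataset,
    popA: list[str],
    popB: list[str],
    windows: list[tuple[int, int]],
    min_sites: int | None = None,
) -> pd.DataFrame:
    """Hudson FST (ratio of averages) per window between two populations."""
    if min_sites is None:
        min_sites = default_min_sites(windows[0][1] - windows[0][0]) if windows else 0
    pA, nA = _freqs(ds, ds.sample_indices(popA))
    pB, nB = _freqs(ds, ds.sample_indices(popB))
    ok = (nA >= 2) & (nB >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (pA - pB) ** 2
            - pA * (1 - pA) / np.maximum(nA - 1, 1)
            - pB * (1 - pB) / np.maximum(nB - 1, 1)
        )
        den = pA * (1 - pB) + pB * (1 - pA)
    pos0 = ds.pos - 1
    vals, counts = [], []
    for w in windows:
        sel = (pos0 >= w[0]) & (pos0 < w[1]) & ds.is_biallelic & ok
        s_num = np.nansum(num[sel])
        s_den = np.nansum(den[sel])
        vals.append(s_num / s_den if s_den > 0 else np.nan)
        counts.append(sel.sum())
    return _window_frame(ds, windows, vals, counts, min_sites, "fst")


def ld_decay(
    ds: GenotypeDataset,
    max_dist: int = 100_000,
    bin_width: int = 1_000,
    background_level: float = 0.002,
    max_pairs: int | None = 2_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float | None]:
    """Composite-LD decay: mean squared dosage correlation by distance bin.

    Returns the binned table and the smallest bin midpoint whose mean r² is at
    or below ``background_level`` (None if never reached).  Monomorphic pairs
    and pairs with <3 shared non-missing samples are skipped.
    """
    if ds.n_sites < 2:
        raise ValueError("need at least 2 sites")
    pos = ds.pos
    pairs = []
    for i in range(ds.n_sites - 1):
        j = i + 1
        while j < ds.n_sites and pos[j] - pos[i] <= max_dist:
            if ds.chrom[j] == ds.chrom[i]:
                pairs.append((i, j))
            j += 1
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in keep]

    dists, r2s = [], []
    g = ds.genotypes
    for i, j in pairs:
        gi, gj = g[i].astype(float), g[j].astype(float)
        ok = (gi != MISSING) & (gj != MISSING)
        if ok.sum() < 3:
            continue
        x, y = gi[ok], gj[ok]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        dists.append(pos[j] - pos[i])
        r2s.append(r * r)
    table = pd.DataFrame({"dist": dists, "r2": r2s})
    table["bin"] = (table["dist"] - 1) // bin_width * bin_width + bin_width // 2
    binned = (
        table.groupby("bin")["r2"].agg(["mean", "count"]).reset_index()
        .rename(columns={"bin": "distance", "mean": "mean_r2", "count": "n_pairs"})
    )
    crossing = None
    for _, row in binned.sort_values("distance").iterrows():
        if row["mean_r2"] <= background_level:
            crossing = float(row["distance"])
            break
    return binned, crossing


def welch_t_test(valuesA, valuesB) -> dict:
    """Welch unequal-variance t test with Satterthwaite degrees of freedom.

    Returns t, df, two-sided p and the one-sided p for mean(A) > mean(B).
    Degenerate zero-variance inputs follow the documented conventions:
    equal-mean constants give t = 0, p = 1; unequal means give p = 0 with a
    ``degenerate`` flag.
    """
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0:
        if diff == 0:
            return {"t": 0.0, "df": np.nan, "p_two": 1.0, "p_one": 0.5,
                    "degenerate": True}
        return {"t": np.inf * np.sign(diff), "df": np.nan, "p_two": 0.0,
                "p_one": 0.0 if diff > 0 else 1.0, "degenerate": True}
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_two = 2 * sps.t.sf(abs(t), df)
    p_one = sps.t.sf(t, df)
    return {"t": float(t), "df": float(df), "p_two": float(p_two),
            "p_one": float(p_one), "degenerate": False}
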
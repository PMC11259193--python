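"""Composite-likelihood selective-sweep scan on the unfolded SFS.

The scan compares, at each grid position, the composite likelihood of observed
derived-allele counts under a hitchhiking-distorted site-frequency spectrum
against the genome-wide background spectrum, maximizing over the sweep
intensity α (per bp).  The sweep model is the classic escape-and-drag
approximation: a lineage sampled at distance d from the swept site escapes the
sweeping haplotype by recombination with probability p_e = 1 − exp(−α·d);
escaped lineages are exchangeable draws from the background spectrum while the
remainder coalesce into a single sweeping ancestor whose allelic state they
copy.  α relates to the selection coefficient via s = r·ln(2Ne)/α.

Computation notes: the distorted spectrum depends on (α, d) only through the
product α·d, so the scan uses a log-spaced lookup table over α·d; the exact
mixture (``sweep_spectrum``) is retained for direct calls and for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .datatypes import MISSING, GenotypeDataset, SampleMetadata

__all__ = [
    "PolarizedSites",
    "BackgroundSFS",
    "SweepScan",
    "polarize",
    "background_sfs",
    "project_sfs",
    "sweep_spectrum",
    "clr_scan",
    "define_sweep_regions",
    "estimate_s",
    "locus_overlap_permutation",
]


@dataclass
class PolarizedSites:
    """Per-site derived-allele counts after outgroup polarization."""

    pos: np.ndarray  # 1-based bp
    k: np.ndarray  # derived count, 1..n-1
    n: np.ndarray  # non-missing chromosomes per site
    chrom: np.ndarray | None = None
    excluded: pd.DataFrame | None = None  # columns pos, reason

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class BackgroundSFS:
    """Normalized unfolded SFS over derived counts 1..n−1."""

    n: int
    probs: np.ndarray  # length n-1, sums to 1

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.n - 1:
            raise ValueError("probs must cover derived counts 1..n-1")
        total = self.probs.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("background SFS has no mass")
        self.probs = self.probs / total


def neutral_sfs(n: int) -> BackgroundSFS:
    """The standard neutral expectation p(i) ∝ 1/i over i = 1..n−1."""
    i = np.arange(1, n)
    return BackgroundSFS(n=n, probs=(1.0 / i) / np.sum(1.0 / i))


# ---------------------------------------------------------------------------
# Polarization and background spectrum


def polarize(
    ds: GenotypeDataset,
    meta: SampleMetadata,
    outgroup_groups: list[str],
    ingroup_group: str | None = None,
    consensus_threshold: float = 0.8,
) -> PolarizedSites:
    """Assign ancestral/derived states from outgroup consensus.

    The ancestral allele is the one at frequency ≥ ``consensus_threshold``
    across the pooled outgroup samples; sites with ambiguous or missing
    outgroup states, or monomorphic in the ingroup, are excluded with a
    recorded reason.
    """
    out_samples = []
    for g in outgroup_groups:
        out_samples.extend(meta.group(g))
    if not out_samples:
        raise ValueError("no outgroup samples found")
    out_idx = ds.sample_indices(out_samples)
    if ingroup_group is None:
        in_samples = [s for s in meta.samples if s not in set(out_samples)]
    else:
        in_samples = meta.group(ingroup_group)
    in_idx = ds.sample_indices(in_samples)

    g_out = ds.genotypes[:, out_idx]
    g_in = ds.genotypes[:, in_idx]
    called_out = g_out != MISSING
    n_out = 2 * called_out.sum(axis=1)
    alt_out = np.where(called_out, g_out, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_out = np.where(n_out > 0, alt_out / np.maximum(n_out, 1), np.nan)

    called_in = g_in != MISSING
    n_in = 2 * called_in.sum(axis=1)
    alt_in = np.where(called_in, g_in, 0).sum(axis=1)

    pos_list, k_list, n_list, chrom_list = [], [], [], []
    exc_pos, exc_reason = [], []
    for i in range(ds.n_sites):
        if not ds.is_biallelic[i]:
            exc_pos.append(ds.pos[i]); exc_reason.append("not biallelic SNP")
            continue
        if n_out[i] == 0 or not np.isfinite(p_out[i]):
            exc_pos.append(ds.pos[i]); exc_reason.append("missing outgroup")
            continue
        if p_out[i] >= consensus_threshold:
            derived = n_in[i] - alt_in[i]  # ancestral is ALT: derived = REF count
        elif p_out[i] <= 1 - consensus_threshold:
            derived = alt_in[i]
        else:
            exc_pos.append(ds.pos[i]); exc_reason.append("ambiguous ancestral")
            continue
        if n_in[i] < 2 or derived == 0 or derived == n_in[i]:
            exc_pos.append(ds.pos[i]); exc_reason.append("monomorphic ingroup")
            continue
        pos_list.append(ds.pos[i])
        k_list.append(int(derived))
        n_list.append(int(n_in[i]))
        chrom_list.append(ds.chrom[i])

    return PolarizedSites(
        pos=np.array(pos_list, dtype=np.int64),
        k=np.array(k_list, dtype=np.int64),
        n=np.array(n_list, dtype=np.int64),
        chrom=np.array(chrom_list, dtype=object),
        excluded=pd.DataFrame({"pos": exc_pos, "reason": exc_reason}),
    )


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def project_sfs(probs: np.ndarray, n: int, m: int) -> np.ndarray:
    """Hypergeometric expectation projection of an SFS from n to m chromosomes.

    ``probs`` covers derived counts 1..n−1; the result covers 0..m (the
    monomorphic classes acquire mass when m < n).
    """
    if m > n:
        raise ValueError("cannot project to a larger sample")
    i = np.arange(1, n)
    j = np.arange(0, m + 1)
    logw = (
        _log_comb(i[:, None], j[None, :])
        + _log_comb(n - i[:, None], m - j[None, :])
        - _log_comb(n, m)
    )
    with np.errstate(invalid="ignore"):
        w = np.exp(logw)
    w[np.isnan(w)] = 0.0
    # zero out impossible draws (comb of negative arguments)
    valid = (j[None, :] <= i[:, None]) & (m - j[None, :] <= n - i[:, None])
    w = np.where(valid, w, 0.0)
    return probs @ w


def background_sfs(sites: PolarizedSites, n: int | None = None) -> BackgroundSFS:
    """Empirical unfolded SFS at a common sample size ``n`` (default: max).

    Sites observed at a smaller sample size n_i contribute to the common-n
    classes via the hypergeometric likelihood of the observed count
    (C(j,k)·C(n−j,n_i−k)/C(n,n_i), normalized over polymorphic j), so no site
    is dropped; sites at the common size contribute their counts directly.
    """
    if len(sites) == 0:
        raise ValueError("no polarized sites")
    if n is None:
        n = int(sites.n.max())
    if sites.n.max() > n:
        raise ValueError("common n must be at least the largest per-site n")
    counts = np.zeros(n - 1)
    j = np.arange(1, n)
    for n_i in np.unique(sites.n):
        sel = sites.n == n_i
        n_i = int(n_i)
        if n_i == n:
            counts += np.bincount(sites.k[sel], minlength=n)[1:n]
        else:
            for k_i, c in zip(*np.unique(sites.k[sel], return_counts=True)):
                logw = (
                    _log_comb(j, k_i)
                    + _log_comb(n - j, n_i - k_i)
                    - _log_comb(n, n_i)
                )
                valid = (k_i <= j) & (n_i - k_i <= n - j)
                w = np.where(valid, np.exp(logw), 0.0)
                counts += c * w / w.sum()
    return BackgroundSFS(n=n, probs=counts / counts.sum())


# ---------------------------------------------------------------------------
# Escape-and-drag sweep spectrum


def _drag_kernels(bg: BackgroundSFS) -> np.ndarray:
    """Conditional spectra D_e(k) over k = 0..n for each escape count e = 0..n.

    For e < n, m = e+1 exchangeable lineages (e escaped + the sweeping
    ancestor) are drawn from the background by projection; the ancestor is a
    uniformly chosen one of the m and its state is copied to the n−e dragged
    lineages.  For e = n the sample is untouched and the kernel is the
    background itself.
    """
    n = bg.n
    kernels = np.zeros((n + 1, n + 1))
    for e in range(n):
        m = e + 1
        q = project_sfs(bg.probs, n, m)  # over j = 0..m
        for j in range(m + 1):
            if q[j] == 0:
                continue
            p_anc_derived = j / m
            if p_anc_derived > 0:
                # j−1 derived among the e escaped, plus the ancestor's state
                # replicated over itself and the n−e−1 other dragged lineages
                k_d = (j - 1) + (n - e)
                kernels[e, k_d] += q[j] * p_anc_derived
            if p_anc_derived < 1:
                kernels[e, j] += q[j] * (1 - p_anc_derived)
    kernels[n, 1:n] = bg.probs
    return kernels


def sweep_spectrum(bg: BackgroundSFS, alpha: float, d: float) -> np.ndarray:
    """Distorted SFS over k = 1..n−1 at distance d from a sweep of intensity α.

    Mixture over the binomial number of escaped lineages, conditioned on the
    site remaining polymorphic.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    n = bg.n
    p_e = -np.expm1(-alpha * d)
    p_e = max(p_e, 1e-300)
    weights = binom.pmf(np.arange(n + 1), n, p_e)
    full = weights @ _drag_kernels(bg)
    poly = full[1:n]
    total = poly.sum()
    if total <= 0:
        # all mass monomorphic (possible only at p_e == 0 exactly); limit is
        # the single-escape kernel conditioned on polymorphism
        poly = _drag_kernels(bg)[1, 1:n]
        total = poly.sum()
    return poly / total


class _SpectrumTable:
    """Log-probability lookup over a log-spaced α·d grid for one sample size."""

    def __init__(self, bg: BackgroundSFS, n_bins: int = 1200,
                 x_min: float = 1e-10, x_max: float = 1e5):
        self.bg = bg
        self.x_grid = np.logspace(np.log10(x_min), np.log10(x_max), n_bins)
        kernels = _drag_kernels(bg)
        n = bg.n
        p_e = -np.expm1(-self.x_grid)
        p_e = np.clip(p_e, 1e-300, 1.0)
        w = binom.pmf(np.arange(n + 1)[None, :], n, p_e[:, None])
        full = w @ kernels  # (n_bins, n+1)
        poly = full[:, 1:n]
        poly /= poly.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            self.log_probs = np.log(poly)  # (n_bins, n-1)
        self.log_bg = np.log(bg.probs)
        self._log_x = np.log(self.x_grid)

    def loglik(self, x: np.ndarray, k: np.ndarray) -> float:
        """Σ log P(k_i | α·d_i = x_i), binned to the nearest grid point."""
        idx = np.searchsorted(self._log_x, np.log(np.maximum(x, self.x_grid[0])))
        idx = np.clip(idx, 0, len(self.x_grid) - 1)
        return float(self.log_probs[idx, k - 1].sum())

    def loglik_null(self, k: np.ndarray) -> float:
        return float(self.log_bg[k - 1].sum())


@dataclass
class SweepScan:
    """Per-grid-position CLR, α̂ and optional ŝ, plus clustered regions."""

    positions: np.ndarray
    clr: np.ndarray
    alpha_hat: np.ndarray
    s_hat: np.ndarray | None = None
    threshold: float | None = None
    regions: pd.DataFrame | None = None
    chrom: str = "chr1"
    span: tuple = field(default=None)  # (start, end) of scanned span in bp


def clr_scan(
    sites: PolarizedSites,
    bg: BackgroundSFS | None = None,
    grid_step: int = 1000,
    alpha_grid: np.ndarray | None = None,
    max_dist: float | None = None,
) -> SweepScan:
    """Composite-likelihood-ratio sweep scan over a 1 kbp position grid.

    At each grid position x, CLR(x) = 2·(max_α Σ_i log P(k_i | α, |pos_i−x|)
    − Σ_i log P_bg(k_i)), floored at zero.  α is maximized on a log grid
    spanning [1e−8, 1e−1] with parabolic refinement around the grid optimum.
    """
    if len(sites) < 10:
        raise ValueError("need at least 10 polarized sites to scan")
    if bg is None:
        bg = background_sfs(sites)
    if alpha_grid is None:
        alpha_grid = np.logspace(-8, -1, 41)

    # project background to each distinct per-site sample size
    tables: dict[int, _SpectrumTable] = {}
    for n_i in np.unique(sites.n):
        n_i = int(n_i)
        if n_i == bg.n:
            tables[n_i] = _SpectrumTable(bg)
        else:
            proj = project_sfs(bg.probs, bg.n, n_i)[1:n_i]
            tables[n_i] = _SpectrumTable(BackgroundSFS(n=n_i, probs=proj))

    lo = int(sites.pos.min() // grid_step * grid_step)
    hi = int(sites.pos.max())
    grid = np.arange(lo, hi + grid_step, grid_step)

    # group sites by sample size for vectorized lookup
    groups = [
        (tables[int(n_i)], sites.pos[sites.n == n_i], sites.k[sites.n == n_i])
        for n_i in np.unique(sites.n)
    ]
    ll0 = sum(t.loglik_null(k) for t, _, k in groups)

    clr = np.zeros(len(grid))
    a_hat = np.zeros(len(grid))
    log_alpha = np.log(alpha_grid)
    for gi, x in enumerate(grid):
        lls = np.empty(len(alpha_grid))
        for ai, a in enumerate(alpha_grid):
            ll = 0.0
            for t, pos, k in groups:
                d = np.abs(pos - x).astype(float)
                ll += t.loglik(a * d, k)
            lls[ai] = ll
        best = int(np.argmax(lls))
        la = log_alpha[best]
        # parabolic refinement on log-alpha when the optimum is interior
        if 0 < best < len(alpha_grid) - 1:
            y0, y1, y2 = lls[best - 1], lls[best], lls[best + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                shift = 0.5 * (y0 - y2) / denom
                la = log_alpha[best] + shift * (log_alpha[1] - log_alpha[0])
        a_hat[gi] = np.exp(la)
        clr[gi] = max(0.0, 2.0 * (lls[best] - ll0))

    chrom = str(sites.chrom[0]) if sites.chrom is not None and len(sites.chrom) else "chr1"
    return SweepScan(
        positions=grid, clr=clr, alpha_hat=a_hat, chrom=chrom,
        span=(int(grid[0]), int(grid[-1])),
    )


def define_sweep_regions(
    scan: SweepScan,
    percentile: float = 99.99,
    merge: int = 20_000,
    extend: int = 20_000,
    chrom_bounds: tuple | None = None,
) -> pd.DataFrame:
    """Cluster above-threshold grid positions into candidate sweep regions.

    The threshold is the given percentile of all CLR values (boundary ties
    included); above-threshold positions within ``merge`` bp are grouped and
    each cluster extended by ``extend`` bp on both sides, clipped to
    ``chrom_bounds`` when given.
    """
    thr = float(np.percentile(scan.clr, percentile))
    scan.threshold = thr
    above = scan.positions[scan.clr >= thr]
    rows = []
    if len(above):
        start = prev = int(above[0])
        peak = scan.clr[scan.positions == above[0]].max()
        for p in above[1:]:
            p = int(p)
            if p - prev <= merge:
                prev = p
                peak = max(peak, scan.clr[scan.positions == p].max())
            else:
                rows.append((start, prev, peak))
                start = prev = p
                peak = scan.clr[scan.positions == p].max()
        rows.append((start, prev, peak))
    lo_b, hi_b = chrom_bounds if chrom_bounds else (0, None)
    out = []
    for s, e, peak in rows:
        s2 = max(s - extend, lo_b)
        e2 = e + extend if hi_b is None else min(e + extend, hi_b)
        out.append({"chrom": scan.chrom, "start": s2, "end": e2, "max_clr": peak})
    regions = pd.DataFrame(out, columns=["chrom", "start", "end", "max_clr"])
    scan.regions = regions
    return regions


def estimate_s(alpha_hat: float, r: float, Ne: float) -> float:
    """Selection coefficient from sweep intensity: s = r·ln(2Ne)/α̂."""
    if alpha_hat <= 0 or r <= 0 or Ne <= 0:
        raise ValueError("alpha_hat, r and Ne must be positive")
    return r * np.log(2 * Ne) / alpha_hat


def locus_overlap_permutation(
    scan: SweepScan,
    locus: tuple,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation test for CLR enrichment at a candidate locus.

    Places ``n_perm`` random intervals of the locus's length uniformly within
    the scanned span and compares their mean and max CLR (over covered grid
    points) with the observed locus.  p = (1 + #{null ≥ obs}) / (n_perm + 1).
    """
    start, end = int(locus[0]), int(locus[1])
    span_lo, span_hi = scan.span
    length = end - start
    if length <= 0:
        raise ValueError("empty locus")
    if length > span_hi - span_lo:
        raise ValueError("locus longer than scanned span")
    if start < span_lo or end > span_hi:
        raise ValueError("locus outside scanned span")

    def stats(a, b):
        sel = (scan.positions >= a) & (scan.positions < b)
        if not sel.any():
            return np.nan, np.nan
        v = scan.clr[sel]
        return float(v.mean()), float(v.max())

    obs_mean, obs_max = stats(start, end)
    rng = np.random.default_rng(seed)
    starts = rng.integers(span_lo, span_hi - length + 1, size=n_perm)
    null_mean = np.empty(n_perm)
    null_max = np.empty(n_perm)
    for i, a in enumerate(starts):
        null_mean[i], null_max[i] = stats(int(a), int(a) + length)
    ok = np.isfinite(null_mean)
    p_mean = (1 + np.sum(null_mean[ok] >= obs_mean)) / (ok.sum() + 1)
    p_max = (1 + np.sum(null_max[ok] >= obs_max)) / (ok.sum() + 1)
    return {
        "observed_mean": obs_mean,
        "observed_max": obs_max,
        "p_mean": float(p_mean),
        "p_max": float(p_max),
        "null_mean": null_mean[ok],
        "null_max": null_max[ok],
    }
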
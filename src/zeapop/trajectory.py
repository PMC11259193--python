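"""Deterministic single-locus selection model with dominance.

Genotypic fitnesses are wAA = 1, wAa = 1 + h·s, waa = 1 + s with A the
ancestral and a the derived allele, so s is the fitness advantage of the
derived homozygote and h the dominance of the derived allele.  The
one-generation change in the ancestral frequency p = 1 − q is

    Δp = p·q·[p·(wAA − wAa) + q·(wAa − waa)] / w̄,
    w̄ = p²·wAA + 2pq·wAa + q²·waa,

and the derived frequency advances as q' = q − Δp.  The module also houses
the diversity-based effective-population-size estimate Ne = θπ/(4μ), the
ρ = 4Ne·c and Haldane map-function conversions, calendar-time retrodiction,
and the uniform random-search fit of (s, h) to observed frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionParams",
    "NeEstimate",
    "RecombinationRates",
    "TrajectoryFit",
    "estimate_ne",
    "convert_rates",
    "step",
    "predict_calendar",
    "fit_selection",
]

#: Default per-bp per-generation mutation rate (Drosophila melanogaster).
DEFAULT_MU = 8.4e-9


@dataclass(frozen=True)
class SelectionParams:
    """Selection coefficient s ≥ 0 and dominance h ∈ [0, 1] of the derived allele."""

    s: float
    h: float = 1.0

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("s must be non-negative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")


@dataclass(frozen=True)
class NeEstimate:
    theta_pi: float
    mu: float
    Ne: float
    Ne_lower: float | None = None
    Ne_upper: float | None = None


@dataclass(frozen=True)
class RecombinationRates:
    rho: float | None
    Ne: float | None
    c: float
    cM_per_bp: float


@dataclass(frozen=True)
class TrajectoryFit:
    s_fit: float
    h_fit: float
    score: float
    n_iterations: int
    seed: int
    s_range: tuple
    h_range: tuple
    h_free: bool


def estimate_ne(theta_pi: float, mu: float = DEFAULT_MU,
                theta_sd: float | None = None) -> NeEstimate:
    """Effective population size from nucleotide diversity: Ne = θπ/(4μ).

    When ``theta_sd`` is given, bounds from θπ ± 1 SD are reported alongside.
    """
    if theta_pi <= 0 or mu <= 0:
        raise ValueError("theta_pi and mu must be positive")
    ne = theta_pi / (4.0 * mu)
    lo = hi = None
    if theta_sd is not None:
        lo = max(theta_pi - theta_sd, 0.0) / (4.0 * mu) or None
        hi = (theta_pi + theta_sd) / (4.0 * mu)
    return NeEstimate(theta_pi=theta_pi, mu=mu, Ne=ne, Ne_lower=lo, Ne_upper=hi)


def convert_rates(rho: float | None = None, Ne: float | None = None,
                  c: float | None = None) -> RecombinationRates:
    """Solve ρ = 4·Ne·c for the missing quantity and convert c to cM/bp.

    The Haldane map function gives cM/bp = 50·ln(1/(1 − 2c)), valid for
    c < 0.5.
    """
    known = sum(v is not None for v in (rho, Ne, c))
    if c is None:
        if rho is None or Ne is None:
            raise ValueError("need two of (rho, Ne, c)")
        c = rho / (4.0 * Ne)
    elif rho is None and Ne is not None:
        rho = 4.0 * Ne * c
    elif Ne is None and rho is not None:
        Ne = rho / (4.0 * c)
    elif known < 1:
        raise ValueError("need at least c, or two of (rho, Ne, c)")
    if not 0.0 <= c < 0.5:
        raise ValueError("c must be in [0, 0.5) for the Haldane map function")
    cm = 50.0 * np.log(1.0 / (1.0 - 2.0 * c))
    return RecombinationRates(rho=rho, Ne=Ne, c=c, cM_per_bp=cm)


def step(q, params: SelectionParams):
    """One generation of the selection recursion; accepts scalars or arrays."""
    q = np.asarray(q, dtype=float)
    p = 1.0 - q
    s, h = params.s, params.h
    wAA, wAa, waa = 1.0, 1.0 + h * s, 1.0 + s
    wbar = p * p * wAA + 2 * p * q * wAa + q * q * waa
    dp = p * q * (p * (wAA - wAa) + q * (wAa - waa)) / wbar
    q_next = np.clip(q - dp, 0.0, 1.0)
    return float(q_next) if q_next.ndim == 0 else q_next


def predict_calendar(
    q0: float,
    year0: int,
    year_end: int,
    gens_per_year: int,
    s: float,
    h: float = 1.0,
) -> pd.DataFrame:
    """Iterate the recursion over calendar time.

    Runs (year_end − year0) × gens_per_year generations starting at year0 and
    reports q at every generation with its fractional calendar year.
    """
    if year_end <= year0:
        raise ValueError("year_end must exceed year0")
    if not 2 <= gens_per_year <= 12:
        raise ValueError("gens_per_year must be in 2..12")
    params = SelectionParams(s=s, h=h)
    n_gen = (year_end - year0) * gens_per_year
    rows = [(0, float(year0), q0)]
    q = q0
    for g in range(1, n_gen + 1):
        q = step(q, params)
        rows.append((g, year0 + g / gens_per_year, q))
    return pd.DataFrame(rows, columns=["generation", "year", "q"])


def _trajectory_at_offsets(q0, gen_offsets, s, h):
    """q at the given generation offsets for vectors of (s, h) draws."""
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float)
    q = np.full(np.broadcast(s, h).shape, q0, dtype=float)
    out = np.empty((len(gen_offsets),) + q.shape)
    target = 0
    wAA = 1.0
    wAa = 1.0 + h * s
    waa = 1.0 + s
    total = int(max(gen_offsets))
    for g in range(total + 1):
        while target < len(gen_offsets) and gen_offsets[target] == g:
            out[target] = q
            target += 1
        p = 1.0 - q
        wbar = p * p * wAA + 2 * p * q * wAa + q * q * waa
        dp = p * q * (p * (wAA - wAa) + q * (wAa - waa)) / wbar
        q = np.clip(q - dp, 0.0, 1.0)
    return out


def fit_selection(
    observations: pd.DataFrame,
    gens_per_year: int = 10,
    h: float | str = 1.0,
    n_iter: int = 1_000_000,
    seed: int = 0,
    s_range: tuple = (0.0, 1.0),
    h_range: tuple = (0.0, 1.0),
) -> TrajectoryFit:
    """Uniform random search for the best-fitting selection parameters.

    The first observation anchors q0; candidate trajectories are scored as
    1 − mean |q_obs − q_expected| over the remaining observation years, and
    the highest-scoring draw is returned.  ``h`` may be a fixed value or
    ``"free"`` to search the dominance coefficient jointly.
    """
    obs = observations.sort_index()
    years = obs["year"].to_numpy()
    if np.any(np.diff(years) <= 0):
        raise ValueError("observations must be strictly ordered in time")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations (anchor + comparisons)")
    q0 = float(obs["q_obs"].iloc[0])
    gen_offsets = ((years - years[0]) * gens_per_year).astype(int)

    rng = np.random.default_rng(seed)
    h_free = h == "free"
    s_draws = rng.uniform(s_range[0], s_range[1], size=n_iter)
    if h_free:
        h_draws = rng.uniform(h_range[0], h_range[1], size=n_iter)
    else:
        h_draws = np.full(n_iter, float(h))

    q_pred = _trajectory_at_offsets(q0, list(gen_offsets[1:]), s_draws, h_draws)
    q_obs = obs["q_obs"].to_numpy()[1:, None]
    score = 1.0 - np.mean(np.abs(q_obs - q_pred), axis=0)
    best = int(np.argmax(score))
    return TrajectoryFit(
        s_fit=float(s_draws[best]),
        h_fit=float(h_draws[best]),
        score=float(score[best]),
        n_iterations=n_iter,
        seed=seed,
        s_range=tuple(s_range),
        h_range=tuple(h_range),
        h_free=h_free,
    )
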
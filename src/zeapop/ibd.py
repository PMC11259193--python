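"""Isolation-by-distance: pairwise distances, mean FST, and the regression.

Following the classic lattice-model prediction, linearized differentiation
FST/(1−FST) between deme pairs is regressed on the natural log of great-circle
distance; a positive slope (one-sided Pearson test) indicates restricted
dispersal, while its absence at low absolute FST indicates effective panmixia.
Distances use the haversine formula on a sphere of mean radius 6371.0088 km.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GenotypeDataset, SampleMetadata
from .windows import make_windows, window_fst

__all__ = ["haversine_km", "pairwise_mean_fst", "ibd_regression"]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (abs(lat) <= 90 and abs(lon) <= 180):
            raise ValueError("invalid coordinates")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def pairwise_mean_fst(
    ds: GenotypeDataset,
    meta: SampleMetadata,
    window_size: int = 20_000,
    min_sites: int | None = None,
) -> pd.DataFrame:
    """Unweighted mean of non-missing window FST for every deme pair.

    Demes with fewer than 2 samples are excluded (with a ``warnings`` column
    on the result attributes).  Returns a long-form table demeA/demeB/fst.
    """
    windows = make_windows(ds, window_size)
    demes = meta.demes
    usable, skipped = [], []
    for d in demes:
        (usable if len(meta.deme(d)) >= 2 else skipped).append(d)
    rows = []
    for a, b in itertools.combinations(usable, 2):
        wf = window_fst(ds, meta.deme(a), meta.deme(b), windows,
                        min_sites=min_sites)
        vals = wf["fst"].dropna()
        rows.append({"demeA": a, "demeB": b,
                     "fst": float(vals.mean()) if len(vals) else np.nan})
    out = pd.DataFrame(rows, columns=["demeA", "demeB", "fst"])
    out.attrs["skipped_demes"] = skipped
    return out


def ibd_regression(
    fst_pairs: pd.DataFrame,
    meta: SampleMetadata,
    one_sided: bool = True,
) -> dict:
    """Regress FST/(1−FST) on ln(km) over deme pairs.

    Expects the long-form output of :func:`pairwise_mean_fst`; deme
    coordinates come from the metadata.  Pairs with FST = 1 (infinite
    linearized value) are dropped with a warning count.
    """
    coords = {}
    for d in meta.demes:
        sub = meta.table[meta.table["deme"] == d]
        coords[d] = (float(sub["lat"].iloc[0]), float(sub["lon"].iloc[0]))

    rows = []
    dropped = 0
    for _, r in fst_pairs.iterrows():
        a, b = r["demeA"], r["demeB"]
        fst = r["fst"]
        if not np.isfinite(fst):
            dropped += 1
            continue
        if fst >= 1.0:
            dropped += 1
            continue
        km = haversine_km(*coords[a], *coords[b])
        if km <= 0:
            raise ValueError(f"deme pair {a},{b} at zero distance")
        rows.append({"demeA": a, "demeB": b, "km": km,
                     "fst": fst, "linearized": fst / (1.0 - fst)})
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        raise ValueError("need at least 3 usable deme pairs")
    x = np.log(pairs["km"].to_numpy())
    y = pairs["linearized"].to_numpy()
    if np.allclose(y, y[0]):
        return {"pairs": pairs, "slope": 0.0, "intercept": float(y[0]),
                "r": np.nan, "t": np.nan, "df": len(pairs) - 2,
                "p_one": np.nan, "p_two": np.nan, "constant_y": True,
                "dropped_pairs": dropped}
    res = sps.linregress(x, y)
    df = len(pairs) - 2
    t = res.rvalue * np.sqrt(df / max(1e-300, 1 - res.rvalue**2))
    p_two = 2 * sps.t.sf(abs(t), df)
    p_one = sps.t.sf(t, df)  # H1: positive correlation
    return {
        "pairs": pairs,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "t": float(t),
        "df": df,
        "p_one": float(p_one),
        "p_two": float(p_two),
        "constant_y": False,
        "dropped_pairs": dropped,
    }
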
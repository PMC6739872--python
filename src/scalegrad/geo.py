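"""Geographic size of the stimulus environments.

Great-circle (Haversine) pairwise distances among the stimulus items of
each location and scale, and the log-linear relation between scale index
and environment size: the mean log10 pairwise distance regressed on
scale. A slope near 1 means each scale step is a tenfold increase in
environment size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2,
                 radius_km: float = EARTH_RADIUS_KM) -> np.ndarray | float:
    """Great-circle distance (km) between latitude/longitude points
    (decimal degrees) via the Haversine formula. Vectorised; symmetric;
    invariant to 360-degree longitude shifts."""
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    for la in (lat1, lat2):
        if np.any(np.abs(la) > 90):
            raise ValueError("latitude outside [-90, 90]")
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = phi2 - phi1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) \
        * np.sin(dlam / 2) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def pairwise_distances(stimuli: pd.DataFrame,
                       radius_km: float = EARTH_RADIUS_KM) -> pd.DataFrame:
    """All unordered item-pair distances within each (scale, location).

    ``stimuli``: table with columns scale, location, item, lat, lon.
    Locations with a single item are skipped with a warning. Returns a
    table (scale, location, item_a, item_b, distance_km); a location with
    n items contributes n(n-1)/2 rows.
    """
    rows = []
    for (scale, loc), grp in stimuli.groupby(["scale", "location"]):
        if len(grp) < 2:
            warnings.warn(f"location {loc} (scale {scale}) has fewer than 2 "
                          "items; skipped", stacklevel=2)
            continue
        lat = grp["lat"].to_numpy(float)
        lon = grp["lon"].to_numpy(float)
        items = grp["item"].to_numpy()
        i, j = np.triu_indices(len(grp), k=1)
        d = haversine_km(lat[i], lon[i], lat[j], lon[j], radius_km)
        d = np.atleast_1d(d)
        for a, b, dist in zip(items[i], items[j], d):
            rows.append((scale, loc, a, b, float(dist)))
    return pd.DataFrame(rows, columns=["scale", "location", "item_a",
                                       "item_b", "distance_km"])


@dataclass
class ScaleDistanceSummary:
    """Per-scale distance summary and the log-linear scale-size fit."""

    per_scale: pd.DataFrame     # scale, n_pairs, n_zero, mean_log10_km
    slope: float
    intercept: float
    r2: float
    mode: str                   # "scale-means" | "pooled"
    underdetermined: bool


def log_scale_fit(distances: pd.DataFrame,
                  mode: str = "scale-means") -> ScaleDistanceSummary:
    """Linear fit of log10 pairwise distance on scale index.

    ``mode`` "scale-means" (default) regresses the per-scale mean of the
    log distances on scale; "pooled" regresses every individual log
    distance. Zero distances cannot be logged; they are excluded and
    counted. Scales left with no positive distances are dropped with a
    report; fewer than 3 usable scales flags the fit under-determined.
    """
    if mode not in ("scale-means", "pooled"):
        raise ValueError("mode must be 'scale-means' or 'pooled'")
    rows = []
    pooled_x, pooled_y = [], []
    for scale, grp in distances.groupby("scale"):
        d = grp["distance_km"].to_numpy(float)
        pos = d[d > 0]
        n_zero = int((d == 0).sum())
        if len(pos) == 0:
            warnings.warn(f"scale {scale}: no positive distances; excluded "
                          "from the fit", stacklevel=2)
            rows.append((scale, len(d), n_zero, np.nan))
            continue
        logs = np.log10(pos)
        rows.append((scale, len(d), n_zero, float(logs.mean())))
        pooled_x.append(np.full(len(pos), float(scale)))
        pooled_y.append(logs)
    per_scale = pd.DataFrame(rows, columns=["scale", "n_pairs", "n_zero",
                                            "mean_log10_km"])
    usable = per_scale.dropna(subset=["mean_log10_km"])
    if len(usable) < 2:
        raise ValueError("need at least 2 scales with positive distances")
    if mode == "scale-means":
        x = usable["scale"].to_numpy(float)
        y = usable["mean_log10_km"].to_numpy(float)
    else:
        x = np.concatenate(pooled_x)
        y = np.concatenate(pooled_y)
    fit = stats.linregress(x, y)
    return ScaleDistanceSummary(per_scale=per_scale, slope=float(fit.slope),
                                intercept=float(fit.intercept),
                                r2=float(fit.rvalue ** 2), mode=mode,
                                underdetermined=len(usable) < 3)
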
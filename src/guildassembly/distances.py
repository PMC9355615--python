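"""Distance-matrix constructors: Bray-Curtis, standardized 1-D Euclidean,
and great-circle geographic distance."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateStatisticError, ValidationError
from .tabular_io import DistanceMatrix, OtuTable

__all__ = ["bray_curtis", "standardized_euclidean_1d", "geographic_distance",
           "EARTH_RADIUS_KM", "haversine_km"]

EARTH_RADIUS_KM = 6371.0


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk), in [0, 1].
    A pair of all-zero samples has no defined dissimilarity and raises.
    """
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    totals = table.row_sums()
    zero = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
    if len(zero) >= 2:
        raise DegenerateStatisticError(
            f"Bray-Curtis undefined for all-zero sample pair "
            f"({zero[0]!r}, {zero[1]!r})")
    vals = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, vals)


def bray_curtis_frame(df: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis on a non-negative abundance DataFrame (rows = units)."""
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative abundances")
    totals = arr.sum(axis=1)
    zero = list(df.index[totals == 0])
    if len(zero) >= 2:
        raise DegenerateStatisticError(
            f"Bray-Curtis undefined for all-zero pair ({zero[0]!r}, {zero[1]!r})")
    vals = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(tuple(str(i) for i in df.index), vals)


def standardized_euclidean_1d(values: pd.Series | Sequence[float],
                              labels: Sequence[str] | None = None
                              ) -> DistanceMatrix:
    """|z_i - z_j| on z-scores of a single attribute (sample SD, n-1)."""
    if isinstance(values, pd.Series):
        labels = tuple(str(i) for i in values.index)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if labels is None:
            labels = tuple(str(i) for i in range(len(arr)))
        labels = tuple(labels)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValidationError("need a 1-D attribute with >= 2 samples")
    if not np.all(np.isfinite(arr)):
        bad = labels[int(np.flatnonzero(~np.isfinite(arr))[0])]
        raise ValidationError(f"non-finite attribute value for sample {bad!r}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError(
            "attribute has zero variance; standardized distance undefined")
    z = (arr - arr.mean()) / sd
    vals = np.abs(z[:, None] - z[None, :])
    return DistanceMatrix(labels, vals)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a 6371-km sphere (array-aware)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise haversine distance (km) from metadata latitude/longitude."""
    lat = metadata["latitude"].to_numpy(dtype=float)
    lon = metadata["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValidationError("longitude outside [-180, 180]")
    labels = tuple(str(s) for s in metadata["sample_id"]) \
        if "sample_id" in metadata.columns else tuple(str(i) for i in metadata.index)
    vals = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels, vals)
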
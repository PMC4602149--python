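"""Functional cell typing by clustering of response parameters.

Cells are represented by five parameters (bias index, latency, transience,
DS index, speed index), normalised so every column lies in a comparable
range.  A k-means sweep over k = 4..25 with many restarts is scored by the
mean silhouette value

    S_i = (b_i - a_i) / max(a_i, b_i)

(a_i = mean intra-cluster distance of point i, b_i = smallest mean distance
to another cluster), and the k maximising the mean silhouette is selected.
Cluster validity is then quantified by the pairwise separation coefficient:
both groups are projected on the axis joining their means and the
centre-to-centre distance is divided by the average projected SD, i.e. the
number of standard deviations separating the two groups.  Receptive-field
tiling and the polar distribution of preferred directions of DS clusters
serve as biological sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .params import CellParameterVector, parameters_to_frame

__all__ = [
    "CLUSTER_COLUMNS",
    "ParameterMatrix",
    "ClusterModel",
    "normalize",
    "silhouette_mean",
    "sweep_k",
    "fisher_separation",
    "separation_matrix",
    "group_characteristics",
    "tiling_report",
    "ds_polar_summary",
]

#: the five clustered parameters (seven-parameter mode adds rf diameter and
#: width index but does not reveal extra structure)
CLUSTER_COLUMNS = ("bias_index", "latency_s", "transience", "ds_index",
                   "speed_index")
EXTENDED_COLUMNS = CLUSTER_COLUMNS + ("rf_diameter_um", "width_index")

#: columns already carrying an intrinsic [-1,1] or [0,1] range
_INTRINSIC = {"bias_index", "transience", "ds_index", "speed_index",
              "width_index"}

SEPARATION_CAP = 1e6


@dataclass
class ParameterMatrix:
    """Cells x parameters matrix with its normalisation record."""

    values: np.ndarray
    columns: tuple
    cell_ids: np.ndarray
    scaling: dict  # column -> (min, max) for min-max scaled columns

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    mean_silhouette: float
    restarts: int
    seed: int
    inertia: float = np.nan
    silhouette_by_k: dict = dc_field(default_factory=dict)


def normalize(params: Sequence[CellParameterVector] | pd.DataFrame,
              columns: Sequence[str] = CLUSTER_COLUMNS) -> ParameterMatrix:
    """Assemble and normalise the clustering matrix.

    Columns with an intrinsic bounded range (bias, transience, DS and
    speed/width indices) pass through unchanged; the remaining columns
    (latency, receptive-field diameter) are min-max scaled to [0, 1].  The
    scaling record allows inversion.  Cells with missing values must be
    removed beforehand (see the responsiveness filter).
    """
    frame = params if isinstance(params, pd.DataFrame) else parameters_to_frame(params)
    if len(frame) < 2:
        raise ValueError("need at least two cells to normalise")
    sub = frame.loc[:, list(columns)].astype(float)
    if sub.isna().any().any():
        raise ValueError("parameter matrix contains missing values; filter "
                         "non-responsive cells first")
    scaling: dict[str, tuple[float, float]] = {}
    values = np.empty(sub.shape)
    for j, col in enumerate(columns):
        x = sub[col].to_numpy()
        if col in _INTRINSIC:
            values[:, j] = x
        else:
            lo, hi = float(x.min()), float(x.max())
            if hi == lo:
                import warnings
                warnings.warn(f"column {col!r} is constant; scaled to 0",
                              stacklevel=2)
                values[:, j] = 0.0
                scaling[col] = (lo, lo + 1.0)
            else:
                values[:, j] = (x - lo) / (hi - lo)
                scaling[col] = (lo, hi)
    return ParameterMatrix(values, tuple(columns),
                           frame["cell_id"].to_numpy(), scaling)


def silhouette_mean(matrix: ParameterMatrix | np.ndarray,
                    labels: np.ndarray) -> float:
    """Mean silhouette value with Euclidean distance.

    Each point's score is ``(b - a) / max(a, b)`` where `a` is its mean
    distance to its own cluster (excluding itself) and `b` the smallest mean
    distance to any other cluster; members of singleton clusters score 0.
    """
    X = matrix.values if isinstance(matrix, ParameterMatrix) else np.asarray(matrix)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    dist = np.sqrt(np.maximum(d2, 0.0))
    n = len(X)
    sizes = {c: np.count_nonzero(labels == c) for c in uniq}
    sums = np.stack([dist[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    scores = np.zeros(n)
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        if sizes[labels[i]] == 1:
            continue  # singleton convention: S_i = 0
        a = sums[i, ci] / (sizes[labels[i]] - 1)
        b = np.min([sums[i, cj] / sizes[c]
                    for cj, c in enumerate(uniq) if c != labels[i]])
        m = max(a, b)
        scores[i] = 0.0 if m == 0 else (b - a) / m
    return float(scores.mean())


def sweep_k(matrix: ParameterMatrix, k_range: Sequence[int] = range(4, 26),
            restarts: int = 5000, seed: int = 0) -> ClusterModel:
    """Best-of-restarts k-means for each k; select k by mean silhouette.

    Ties in mean silhouette resolve to the smaller k.  Values of k that are
    not smaller than the number of cells are skipped with a warning.
    """
    X = matrix.values
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    by_k: dict[int, float] = {}
    for k in k_range:
        if X.shape[0] <= k:
            import warnings
            warnings.warn(f"skipping k={k}: only {X.shape[0]} cells",
                          stacklevel=2)
            continue
        km = KMeans(n_clusters=k, n_init=restarts,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(X)
        sil = silhouette_mean(X, labels)
        by_k[k] = sil
        if best is None or sil > best.mean_silhouette + 1e-12:
            best = ClusterModel(k=k, labels=labels + 1,
                                centroids=km.cluster_centers_,
                                mean_silhouette=sil, restarts=restarts,
                                seed=seed, inertia=float(km.inertia_))
    if best is None:
        raise ValueError("no k in range was feasible for this population")
    best.silhouette_by_k = by_k
    return best


def fisher_separation(matrix: ParameterMatrix | np.ndarray, labels: np.ndarray,
                      pair: tuple[int, int]) -> float:
    """Pairwise separation coefficient along the centre-to-centre axis.

    Both groups are projected onto the unit vector joining their means;
    each group's Gaussian is summarised by the sample mean and SD of the
    projections, and the separation is the distance between the means in
    units of the average SD: ``d / ((sigma_1 + sigma_2) / 2)``.  Zero spread
    in both groups yields a capped sentinel value.
    """
    X = matrix.values if isinstance(matrix, ParameterMatrix) else np.asarray(matrix)
    labels = np.asarray(labels)
    i, j = pair
    xi, xj = X[labels == i], X[labels == j]
    if len(xi) < 2 or len(xj) < 2:
        raise ValueError("both clusters need at least two members")
    mu_i, mu_j = xi.mean(axis=0), xj.mean(axis=0)
    d = float(np.linalg.norm(mu_j - mu_i))
    if d == 0:
        return 0.0
    axis = (mu_j - mu_i) / d
    s1 = float(np.std(xi @ axis, ddof=1))
    s2 = float(np.std(xj @ axis, ddof=1))
    denom = (s1 + s2) / 2.0
    if denom == 0:
        return SEPARATION_CAP
    return min(d / denom, SEPARATION_CAP)


def separation_matrix(matrix: ParameterMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Symmetric k x k table of pairwise separation coefficients."""
    labels = np.asarray(labels)
    ks = np.unique(labels)
    out = pd.DataFrame(0.0, index=ks, columns=ks)
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            s = fisher_separation(matrix, labels, (ks[a], ks[b]))
            out.iloc[a, b] = out.iloc[b, a] = s
    return out


# ---------------------------------------------------------------------------
# cluster interpretation

BI_ON_THRESHOLD = 0.33
DS_THRESHOLD = 0.2


def group_characteristics(params: Sequence[CellParameterVector] | pd.DataFrame,
                          labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster means of all seven parameters plus a suggested type label.

    The label is a naming convention only (cluster membership never depends
    on it): polarity from the mean bias index at +/-0.33, DS if the mean DS
    index exceeds 0.2, brisk/sluggish and transient/sustained by median
    splits of the cluster-mean latency and transience.
    """
    frame = params if isinstance(params, pd.DataFrame) else parameters_to_frame(params)
    frame = frame.copy()
    frame["cluster"] = np.asarray(labels)
    num_cols = ["bias_index", "latency_s", "transience", "rf_diameter_um",
                "ds_index", "speed_index", "width_index"]
    means = frame.groupby("cluster")[num_cols].mean()
    means["n_cells"] = frame.groupby("cluster").size()
    lat_med = means["latency_s"].median()
    tra_med = means["transience"].median()
    suggestions = []
    for _, row in means.iterrows():
        if row["bias_index"] > BI_ON_THRESHOLD:
            polarity = "ON"
        elif row["bias_index"] < -BI_ON_THRESHOLD:
            polarity = "OFF"
        else:
            polarity = "ON-OFF"
        parts = [polarity]
        if row["ds_index"] > DS_THRESHOLD:
            parts.append("DS")
        parts.append("brisk" if row["latency_s"] <= lat_med else "sluggish")
        parts.append("transient" if row["transience"] <= tra_med else "sustained")
        suggestions.append(" ".join(parts))
    means["suggested_label"] = suggestions
    return means.reset_index()


def tiling_report(labels: np.ndarray,
                  rf_centers: np.ndarray,
                  rf_diameters: np.ndarray,
                  region: tuple[float, float, float, float],
                  grid_step: float = 5.0) -> pd.DataFrame:
    """Coverage and overlap of each cluster's receptive fields.

    Coverage is the fraction of the rectangular recording region
    (x0, y0, x1, y1) inside the union of the cluster's 33 % receptive-field
    discs; overlap is the mean pairwise intersection-over-union of those
    discs.  Single-cell clusters report overlap 0 with a flag.
    """
    labels = np.asarray(labels)
    centers = np.asarray(rf_centers, dtype=float)
    radii = np.asarray(rf_diameters, dtype=float) / 2.0
    x0, y0, x1, y1 = region
    gx = np.arange(x0 + grid_step / 2, x1, grid_step)
    gy = np.arange(y0 + grid_step / 2, y1, grid_step)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        cc, rr = centers[sel], radii[sel]
        inside = np.zeros(XX.shape, dtype=bool)
        for (px, py), r in zip(cc, rr):
            inside |= (XX - px) ** 2 + (YY - py) ** 2 <= r**2
        coverage = float(inside.mean())
        ious = []
        for a in range(len(rr)):
            for b in range(a + 1, len(rr)):
                ia = (XX - cc[a, 0]) ** 2 + (YY - cc[a, 1]) ** 2 <= rr[a] ** 2
                ib = (XX - cc[b, 0]) ** 2 + (YY - cc[b, 1]) ** 2 <= rr[b] ** 2
                union = np.count_nonzero(ia | ib)
                ious.append(np.count_nonzero(ia & ib) / union if union else 0.0)
        rows.append({"cluster": c, "n_cells": int(sel.sum()),
                     "coverage": coverage,
                     "mean_pairwise_iou": float(np.mean(ious)) if ious else 0.0,
                     "overlap_defined": len(rr) > 1})
    return pd.DataFrame(rows)


def ds_polar_summary(preferred_directions_deg: np.ndarray,
                     bandwidth_deg: float = 20.0,
                     n_grid: int = 360) -> dict:
    """Mode structure of a DS cluster's preferred-direction distribution.

    A von-Mises kernel density (bandwidth 20 deg) is evaluated on the
    circle; modes are local maxima above half the global peak.  A flat
    density (peak-to-trough ratio below 1.2) is flagged inconclusive.
    """
    th = np.deg2rad(np.asarray(preferred_directions_deg, dtype=float))
    if len(th) == 0:
        raise ValueError("no preferred directions supplied")
    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    kappa = 1.0 / np.deg2rad(bandwidth_deg) ** 2
    dens = np.exp(kappa * (np.cos(grid[:, None] - th[None, :]) - 1.0)).sum(axis=1)
    dens /= dens.sum()
    peak = dens.max()
    inconclusive = bool(peak / max(dens.min(), 1e-300) < 1.2)
    left, right = np.roll(dens, 1), np.roll(dens, -1)
    is_mode = (dens > left) & (dens >= right) & (dens >= 0.5 * peak)
    modes = np.rad2deg(grid[is_mode])
    return {"mode_count": 0 if inconclusive else int(is_mode.sum()),
            "mode_directions_deg": modes.tolist(),
            "density": dens, "grid_deg": np.rad2deg(grid),
            "inconclusive": inconclusive}


def preferred_direction(rates: np.ndarray, directions_deg: np.ndarray) -> float:
    """Circular mean of rate-weighted directions, in degrees [0, 360)."""
    r = np.asarray(rates, dtype=float)
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    if r.sum() <= 0:
        raise ValueError("no firing in any direction")
    ang = np.angle(np.sum(r * np.exp(1j * th)))
    return float(np.rad2deg(ang) % 360.0)
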
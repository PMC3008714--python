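"""K-means clustering of temporal profiles under correlation distance.

Profiles are z-standardized across time points and clustered with Lloyd
iterations in Euclidean geometry; for standardized vectors the squared
Euclidean distance is proportional to 1 - r (Pearson), so the partition is
the correlation K-means one.  Centroids are re-standardized after every
update to stay on the same sphere as the data.  Constant (zero-variance)
profiles have no defined correlation and are excluded up front with an
explicit "unclustered" label.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["ClusterModel", "pearson_distance", "kmeans_profiles", "cluster_summary"]

logger = logging.getLogger(__name__)

UNCLUSTERED = -1


def _standardize(x: np.ndarray) -> np.ndarray:
    """Row-wise z-score (population SD); rows must be non-constant."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Correlation distance d = 1 - r, in [0, 2].

    Degenerate profiles: if both are constant the distance is 0 when they
    are equal and 1 otherwise; if exactly one is constant the correlation
    is undefined and the distance is 1 (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("profiles must be equal-length vectors of >= 3 points")
    x_const = np.ptp(x) == 0
    y_const = np.ptp(y) == 0
    if x_const and y_const:
        logger.info("pearson_distance on two constant profiles")
        return 0.0 if np.array_equal(x, y) else 1.0
    if x_const or y_const:
        logger.info("pearson_distance with one constant profile; returning 1")
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


@dataclasses.dataclass
class ClusterModel:
    """Fitted correlation K-means model over selected-gene profiles."""

    k: int
    gene_ids: list[str]  # clustered genes, in input order
    assignment: np.ndarray  # cluster id per clustered gene
    centroids: np.ndarray  # k x T, zero mean / unit variance per row
    inertia: float
    unclustered: list[str] = dataclasses.field(default_factory=list)

    def labels(self) -> dict[str, int]:
        """gene -> cluster id; unclustered genes map to -1."""
        out = {g: int(c) for g, c in zip(self.gene_ids, self.assignment)}
        out.update({g: UNCLUSTERED for g in self.unclustered})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "cluster": int(c)} for g, c in zip(self.gene_ids, self.assignment)]
        rows += [{"gene": g, "cluster": UNCLUSTERED} for g in self.unclustered]
        return pd.DataFrame(rows)


def _lloyd(
    z: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """One seeded Lloyd run on standardized profiles."""
    n = z.shape[0]
    centroids = z[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        # re-seed empty clusters from the farthest point
        for c in range(k):
            if not np.any(new_assign == c):
                far = d2[np.arange(n), new_assign].argmax()
                centroids[c] = z[far]
                new_assign[far] = c
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = z[assign == c]
            m = members.mean(axis=0)
            if m.std() == 0:  # pathological flat mean: re-seed
                far = d2[np.arange(n), assign].argmax()
                m = z[far]
            centroids[c] = _standardize(m[None, :])[0]
    d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), assign].sum())
    return assign, centroids, inertia


def kmeans_profiles(
    profiles: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    k: int = 7,
    n_init: int = 50,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterModel:
    """Correlation K-means over treated-minus-control profiles.

    Runs ``n_init`` seeded restarts and keeps the lowest-inertia model;
    deterministic given *seed*.  Constant profiles are reported in
    ``unclustered`` rather than silently dropped.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D genes x times matrix")
    n = profiles.shape[0]
    if gene_ids is None:
        gene_ids = [f"row{i}" for i in range(n)]
    gene_ids = list(gene_ids)
    const = np.ptp(profiles, axis=1) == 0
    if const.any():
        logger.info("excluding %d constant profiles from clustering", const.sum())
    keep = ~const
    z = _standardize(profiles[keep])
    n_keep = z.shape[0]
    if k < 1 or k > n_keep:
        raise ValueError(f"k must be in [1, {n_keep}] (non-constant profiles)")

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        assign, centroids, inertia = _lloyd(z, k, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (assign, centroids, inertia)
    assign, centroids, inertia = best
    return ClusterModel(
        k=k,
        gene_ids=[g for g, kp in zip(gene_ids, keep) if kp],
        assignment=assign,
        centroids=centroids,
        inertia=inertia,
        unclustered=[g for g, kp in zip(gene_ids, keep) if not kp],
    )


def cluster_summary(
    model: ClusterModel,
    times: Sequence[float],
    profiles: np.ndarray | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster size, standardized centroid and (optionally) the mean
    profile on the original diff scale.

    *profiles* / *gene_ids* give the unstandardized profiles used in the
    fit; when provided, the raw mean temporal pattern per cluster is
    included.  Cluster sizes sum to the number of clustered genes.
    """
    times = np.asarray(times, dtype=float)
    raw_means = None
    if profiles is not None:
        profiles = np.asarray(profiles, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required alongside profiles")
        lookup = {g: profiles[i] for i, g in enumerate(gene_ids)}
        raw_means = {}
        for c in range(model.k):
            members = [g for g, a in zip(model.gene_ids, model.assignment) if a == c]
            raw_means[c] = np.mean([lookup[g] for g in members], axis=0)
    rows = []
    for c in range(model.k):
        row: dict[str, object] = {
            "cluster": c,
            "size": int(np.sum(model.assignment == c)),
        }
        for j, t in enumerate(times):
            row[f"centroid_{t:g}"] = model.centroids[c, j]
        if raw_means is not None:
            for j, t in enumerate(times):
                row[f"mean_diff_{t:g}"] = raw_means[c][j]
        rows.append(row)
    return pd.DataFrame(rows)
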
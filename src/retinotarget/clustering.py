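"""Fuzzy c-means clustering of standardized dose-response profiles.

Per-gene expression is averaged over replicates within each
(context, dose) condition and standardized to mean 0 / sd 1 (sample sd,
dividing by n-1 — the convention of the Mfuzz-style standardisation used
for expression time-courses; population sd is switchable via ``ddof``),
then partitioned by Bezdek fuzzy c-means.  Down-regulated
clusters — centroids that fall from the zero dose to the top dose in the
tumor-repopulating-cell context — select the responsive genes at a
membership threshold of 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class ResponseProfiles:
    """Standardized per-gene condition profiles.

    ``values``: genes x conditions DataFrame; ``condition_labels``: ordered
    (context, dose) pairs matching the columns; ``skipped``: zero-variance
    genes excluded from clustering.
    """

    values: pd.DataFrame
    condition_labels: list[tuple[str, float]]
    skipped: list[str] = field(default_factory=list)


@dataclass
class FuzzyClustering:
    c: int
    m_fuzzifier: float
    centroids: np.ndarray                 # c x n_conditions
    memberships: pd.DataFrame             # genes x c, rows sum to 1
    condition_labels: list[tuple[str, float]]
    objective_history: list[float]
    converged: bool
    n_iter: int
    membership_threshold: float = 0.2
    selected_clusters: list[int] = field(default_factory=list)

    def argmax_cluster(self) -> pd.Series:
        """0-based index of each gene's maximum-membership cluster."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
        )


def standardize(profile: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, sd 1 using sample sd (n-1) by default."""
    mu = profile.mean()
    sd = profile.std(ddof=ddof)
    if sd == 0:
        raise ZeroDivisionError("zero-variance profile")
    return (profile - mu) / sd


def build_profiles(matrix: ExpressionMatrix, ddof: int = 1) -> ResponseProfiles:
    """Condition means (over replicates) standardized per gene.

    Conditions are ordered context-major (contexts in order of appearance in
    the matrix) then by ascending dose.  Zero-variance genes go to the skip
    list instead of the profile table.
    """
    meta = matrix.sample_meta.loc[matrix.sample_ids]
    labels = [
        (ctx, dose) for ctx in matrix.contexts for dose in sorted(set(meta["dose"]))
    ]
    cond_cols = []
    for ctx, dose in labels:
        samples = meta.index[(meta["context"] == ctx) & (meta["dose"] == dose)]
        if len(samples) == 0:
            raise ValueError(f"no samples for condition {(ctx, dose)}")
        cond_cols.append(matrix.values[list(samples)].mean(axis=1))
    means = pd.concat(cond_cols, axis=1)
    means.columns = [f"{ctx}_d{dose:g}" for ctx, dose in labels]
    if means.shape[1] < 2:
        raise ValueError("need >= 2 conditions to build response profiles")

    arr = means.to_numpy()
    sds = arr.std(axis=1, ddof=ddof)
    keep = sds > 0
    skipped = list(means.index[~keep])
    kept = arr[keep]
    standardized = (kept - kept.mean(axis=1, keepdims=True)) / sds[keep][:, None]
    values = pd.DataFrame(standardized, index=means.index[keep], columns=means.columns)
    return ResponseProfiles(values=values, condition_labels=labels, skipped=skipped)


def _farthest_point_init(x: np.ndarray, c: int) -> np.ndarray:
    """Deterministic farthest-point seeding: the point farthest from the
    data mean first, then repeatedly the point farthest from all chosen
    centers.  Ties break to the lowest row index (argmax), and the choice
    depends only on the data values, so permuting the gene order permutes
    the result without changing it."""
    first = int(np.argmax(((x - x.mean(axis=0)) ** 2).sum(axis=1)))
    chosen = [first]
    min_d2 = ((x - x[first]) ** 2).sum(axis=1)
    while len(chosen) < c:
        nxt = int(np.argmax(min_d2))
        chosen.append(nxt)
        min_d2 = np.minimum(min_d2, ((x - x[nxt]) ** 2).sum(axis=1))
    return x[chosen].copy()


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij = [sum_k (d_ij/d_ik)^(2/(m-1))]^(-1), with exact-hit handling."""
    p = 1.0 / (m - 1.0)  # exponent on squared distances
    u = np.empty_like(d2)
    zero_rows = (d2 == 0).any(axis=1)
    if zero_rows.any():
        hits = d2[zero_rows] == 0
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    ok = ~zero_rows
    if ok.any():
        d2_ok = d2[ok]
        ratio = d2_ok / d2_ok.min(axis=1, keepdims=True)  # >= 1, overflow-safe
        w = ratio ** (-p)
        u[ok] = w / w.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    profiles: ResponseProfiles | pd.DataFrame,
    c: int = 8,
    m_fuzzifier: float = 1.25,
    seed: int = 0,  # accepted for interface stability; the fit is fully
                    # determined by the data (deterministic initialization)
    max_iter: int = 300,
    tol: float = 1e-6,
    membership_threshold: float = 0.2,
) -> FuzzyClustering:
    """Bezdek fuzzy c-means minimizing sum_ij u_ij^m ||x_i - v_j||^2.

    Alternates membership updates and weighted centroid updates from a
    deterministic farthest-point initialization; converged when the maximum
    centroid shift drops below ``tol``.
    """
    if isinstance(profiles, ResponseProfiles):
        values = profiles.values
        labels = profiles.condition_labels
    else:
        values = profiles
        labels = [("", float(i)) for i in range(values.shape[1])]
    x = values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("profiles contain non-finite values")
    n = x.shape[0]
    if c < 1:
        raise ValueError("c must be >= 1")
    if m_fuzzifier <= 1:
        raise ValueError("m_fuzzifier must be > 1")
    if c > n:
        raise ValueError(f"c={c} exceeds the number of profiles ({n})")

    centroids = _farthest_point_init(x, c)
    history: list[float] = []
    converged = False
    u = np.full((n, c), 1.0 / c)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships_from_distances(d2, m_fuzzifier)
        history.append(float((u ** m_fuzzifier * d2).sum()))
        um = u ** m_fuzzifier
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        if shift < tol:
            converged = True
            break

    # final membership pass against the converged centroids
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = _memberships_from_distances(d2, m_fuzzifier)
    history.append(float((u ** m_fuzzifier * d2).sum()))

    memberships = pd.DataFrame(
        u, index=values.index, columns=[f"cluster_{j + 1}" for j in range(c)]
    )
    return FuzzyClustering(
        c=c,
        m_fuzzifier=m_fuzzifier,
        centroids=centroids,
        memberships=memberships,
        condition_labels=labels,
        objective_history=history,
        converged=converged,
        n_iter=it,
        membership_threshold=membership_threshold,
    )


def cluster_directions(
    clustering: FuzzyClustering, context: str | None = None
) -> np.ndarray:
    """Centroid trend per cluster: value at the top dose minus value at dose
    zero within the given context block (default: first context)."""
    labels = clustering.condition_labels
    contexts = list(dict.fromkeys(ctx for ctx, _ in labels))
    ctx = context if context is not None else contexts[0]
    block = [j for j, (c_, _) in enumerate(labels) if c_ == ctx]
    if not block:
        raise ValueError(f"context {ctx!r} not present in condition labels")
    doses = [labels[j][1] for j in block]
    lo = block[int(np.argmin(doses))]
    hi = block[int(np.argmax(doses))]
    return clustering.centroids[:, hi] - clustering.centroids[:, lo]


def select_responsive_genes(
    clustering: FuzzyClustering,
    direction: str = "down",
    context: str | None = None,
) -> set[str]:
    """Genes whose best cluster trends in ``direction`` with membership at or
    above the threshold (boundary included).

    A cluster is "down" when its centroid at the top dose is below its value
    at dose zero in the chosen context block; genes are assigned to their
    argmax-membership cluster and selected when that cluster matches the
    direction and the maximum membership is >= the threshold.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    trend = cluster_directions(clustering, context=context)
    matches = trend < 0 if direction == "down" else trend > 0
    selected_clusters = [j for j in range(clustering.c) if matches[j]]
    clustering.selected_clusters = [j + 1 for j in selected_clusters]
    if not selected_clusters:
        warnings.warn(f"no cluster centroid trends {direction!r}; empty selection")
        return set()
    u = clustering.memberships.to_numpy()
    best = np.argmax(u, axis=1)
    best_u = u[np.arange(len(u)), best]
    mask = np.isin(best, selected_clusters) & (
        best_u >= clustering.membership_threshold
    )
    return set(clustering.memberships.index[mask])
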
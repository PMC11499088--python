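"""Unsupervised shape categorisation and its agreement with expert labels.

The retained principal-component scores (smallest mode count reaching 85%
of total variance, or a mode count carried over from a reference dataset)
are clustered agglomeratively with complete linkage under correlation
distance (1 - Pearson correlation, so anti-correlated score profiles are
maximally distant).  The flat cluster count is selected by the mean
silhouette over a k range, and agreement with the expert class labels is
scored by adjusted mutual information (AMI): mutual information corrected
for chance under the permutation model, normalized by the arithmetic mean
of the partition entropies.  E[MI] is computed by exact hypergeometric
summation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln
from sklearn.metrics import silhouette_samples

from .errors import UndefinedCorrelationError
from .shape_model import ShapeModel

__all__ = ["retain_pcs", "correlation_distance", "hierarchical_cluster",
           "silhouette_select_k", "ami", "cluster_and_score",
           "ClusteringResult"]


def retain_pcs(model: ShapeModel, threshold: float = 0.85,
               reference_n_modes: int | None = None) -> int:
    """Smallest mode count whose cumulative variance fraction reaches
    *threshold*; a ``reference_n_modes`` carried over from the reference
    dataset takes precedence (capped at the available modes)."""
    if reference_n_modes is not None:
        if reference_n_modes < 1:
            raise ValueError("reference_n_modes must be >= 1")
        return min(reference_n_modes, model.n_modes)
    total = model.eigenvalues.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(model.eigenvalues) / total
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation; 0 for identical profiles, 2 for exactly
    anti-correlated ones."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("u and v must be equal-length vectors of length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise UndefinedCorrelationError(
            "correlation distance is undefined for constant vectors")
    return float(1.0 - (uc @ vc) / (nu * nv))


def hierarchical_cluster(scores: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration under correlation distance.

    Returns the scipy linkage record (merge heights are monotone for
    complete linkage; ties broken deterministically).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("scores must be (n_shapes >= 2, n_modes)")
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 score dimensions for correlation")
    if np.any(scores.std(axis=1) == 0):
        raise UndefinedCorrelationError(
            "constant score vector; correlation distance undefined")
    return linkage(scores, method="complete", metric="correlation")


def silhouette_select_k(scores: np.ndarray, linkage_record: np.ndarray,
                        k_min: int = 2, k_max: int = 10
                        ) -> tuple[int, float]:
    """Mean-silhouette (correlation distance) selection of the flat cluster
    count; ties go to the smaller k."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if k_min < 2:
        raise ValueError("k_min must be >= 2 (silhouette undefined at k=1)")
    k_max = min(k_max, n - 1)
    if k_max < k_min:
        raise ValueError("k range empty: need k_min <= k_max < n_shapes")
    best_k, best_s = None, -np.inf
    for k in range(k_min, k_max + 1):
        labels = fcluster(linkage_record, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_samples(scores, labels,
                                     metric="correlation").mean())
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid clustering in the k range")
    return best_k, best_s


def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    a = table.sum(axis=1, keepdims=True)
    b = table.sum(axis=0, keepdims=True)
    nz = table > 0
    t = table[nz].astype(float)
    outer = (a @ b)[nz].astype(float)
    return float((t / n * (np.log(t * n) - np.log(outer))).sum())


def expected_mutual_information(table: np.ndarray) -> float:
    """E[MI] under the permutation (hypergeometric) model, by exact
    summation over all feasible cell counts."""
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    n = int(table.sum())
    log_n = np.log(n)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            log_p = (gammaln(ai + 1) + gammaln(bj + 1)
                     + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                     - gammaln(n + 1) - gammaln(nij + 1)
                     - gammaln(ai - nij + 1) - gammaln(bj - nij + 1)
                     - gammaln(n - ai - bj + nij + 1))
            terms = nij / n * (np.log(nij) + log_n
                               - np.log(ai) - np.log(bj))
            emi += float((np.exp(log_p) * terms).sum())
    return emi


def ami(u, v) -> float:
    """Adjusted mutual information between two labelings of the same items.

    AMI = (MI - E[MI]) / (mean(H(U), H(V)) - E[MI]) with natural-log
    entropies and the exact hypergeometric E[MI].  The degenerate case of a
    single class in both labelings is defined as 1.0 (the partitions are
    identical); a single class in only one labeling scores 0.0.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("labelings must be equal-length vectors, length >= 2")
    table = _contingency(u, v)
    if table.shape == (1, 1):
        return 1.0
    # canonical orientation makes the float summation order, and hence the
    # result, exactly symmetric in (u, v)
    trans = np.ascontiguousarray(table.T)
    if (table.shape > trans.shape
            or (table.shape == trans.shape
                and table.tobytes() > trans.tobytes())):
        table = trans
    hu = _entropy(table.sum(axis=1))
    hv = _entropy(table.sum(axis=0))
    if hu == 0.0 or hv == 0.0:
        # one labeling is a single class, the other is not
        return 0.0
    mi = _mutual_information(table)
    emi = expected_mutual_information(table)
    denom = 0.5 * (hu + hv) - emi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 else 0.0
    return float((mi - emi) / denom)


@dataclass
class ClusteringResult:
    """Full clustering outcome for one dataset."""

    linkage_record: np.ndarray
    labels: np.ndarray            # flat cluster labels in [1, k]
    k: int
    silhouette: float
    ami_score: float
    n_modes_used: int
    variance_fraction: float      # cumulative variance at n_modes_used
    cluster_sizes: list[int] = field(default_factory=list)
    stable_across_thresholds: bool = False

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "silhouette": self.silhouette,
            "ami": self.ami_score,
            "n_modes_used": self.n_modes_used,
            "variance_fraction": self.variance_fraction,
            "cluster_sizes": self.cluster_sizes,
            "stable_across_thresholds": self.stable_across_thresholds,
            "labels": self.labels.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition up to renaming."""
    table = _contingency(a, b)
    return bool(np.all((table > 0).sum(axis=0) == 1)
                and np.all((table > 0).sum(axis=1) == 1))


def cluster_and_score(model: ShapeModel, labels,
                      reference_n_modes: int | None = None,
                      threshold: float = 0.85,
                      k_min: int = 2, k_max: int = 10) -> ClusteringResult:
    """Retain modes, cluster, select k by silhouette, and score against the
    expert labels with AMI.

    Also checks partition stability when the variance threshold is raised
    to 90% and 95% (with k re-selected each time).
    """
    labels = np.asarray(labels)
    if len(labels) != model.n_shapes:
        raise ValueError("one label per training shape required")

    def _cluster_at(n_modes: int):
        n_modes = max(2, min(n_modes, model.n_modes))
        x = model.scores[:, :n_modes]
        rec = hierarchical_cluster(x)
        k, sil = silhouette_select_k(x, rec, k_min, k_max)
        flat = fcluster(rec, k, criterion="maxclust")
        return n_modes, x, rec, k, sil, flat

    n_modes = retain_pcs(model, threshold, reference_n_modes)
    n_modes, x, rec, k, sil, flat = _cluster_at(n_modes)

    partitions = [flat]
    for extra in (0.90, 0.95):
        if extra > threshold:
            nm = retain_pcs(model, extra)
            partitions.append(_cluster_at(nm)[5])
    stable = all(_same_partition(partitions[0], p) for p in partitions[1:])

    total = model.eigenvalues.sum()
    var_frac = float(model.eigenvalues[:n_modes].sum() / total) if total > 0 else 1.0
    sizes = np.bincount(flat)[1:].tolist()
    return ClusteringResult(
        linkage_record=rec, labels=flat, k=k, silhouette=sil,
        ami_score=ami(flat, labels), n_modes_used=n_modes,
        variance_fraction=var_frac, cluster_sizes=sizes,
        stable_across_thresholds=stable)
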
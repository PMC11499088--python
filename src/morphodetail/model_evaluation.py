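"""Shape-model evaluation metrics versus number of retained modes.

Three standard point-distribution-model metrics:

* compactness  C(n_m) = sum_{i<=n_m} lambda_i, cumulative captured variance
  (reported either absolute, mm^2, or as a fraction of total variance);
* generalisation  G(n_m): mean leave-one-out reconstruction error of a
  held-out shape from a model fitted on the remaining shapes (mm);
* specificity  S(n_m): mean distance from model-sampled random shapes to
  their nearest training shape (mm).

Distances between two shape vectors are reported as the mean per-particle
Euclidean distance (comparable across particle counts); the total
3K-vector norm is available via ``metric="total"``.

Leave-one-out refits reuse the frozen correspondence (particles are not
re-optimized per fold), the usual practice for particle-based models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shape_model import CorrespondenceSet, ShapeModel, fit_pca, reconstruct

__all__ = ["compactness", "generalisation", "specificity",
           "EvaluationCurves", "evaluate_correspondence", "evaluation_suite"]


def _shape_distance(a: np.ndarray, b: np.ndarray, metric: str = "per_particle"
                    ) -> np.ndarray:
    """Distance between flattened shape vectors along the last axis.

    ``per_particle``: mean Euclidean distance over particles (mm).
    ``total``: Euclidean norm of the full 3K difference vector.
    """
    diff = np.asarray(a) - np.asarray(b)
    pts = diff.reshape(*diff.shape[:-1], -1, 3)
    norms = np.linalg.norm(pts, axis=-1)
    if metric == "per_particle":
        return norms.mean(axis=-1)
    if metric == "total":
        return np.sqrt((norms ** 2).sum(axis=-1))
    raise ValueError(f"unknown metric {metric!r}")


def compactness(model: ShapeModel, n_modes: int, normalized: bool = True) -> float:
    """Cumulative eigenvalue sum up to ``n_modes`` (fraction of total
    variance when ``normalized``)."""
    if not 1 <= n_modes <= model.n_modes:
        raise ValueError(f"n_modes must lie in [1, {model.n_modes}]")
    total = model.eigenvalues.sum()
    c = model.eigenvalues[:n_modes].sum()
    if normalized:
        return float(c / total) if total > 0 else 1.0
    return float(c)


def generalisation(corr: CorrespondenceSet, n_modes: int,
                   metric: str = "per_particle") -> float:
    """Leave-one-out reconstruction error (mm) at ``n_modes`` modes."""
    n = corr.n_shapes
    if n < 3:
        raise ValueError("generalisation needs at least 3 shapes")
    if n_modes > n - 2:
        raise ValueError(f"n_modes must be <= n_s - 2 = {n - 2} for "
                         "leave-one-out evaluation")
    x = corr.to_matrix()
    errors = np.empty(n)
    for j in range(n):
        rest = CorrespondenceSet(
            points=np.delete(corr.points, j, axis=0),
            shape_ids=[s for i, s in enumerate(corr.shape_ids) if i != j])
        fold = fit_pca(rest)
        recon = reconstruct(fold, x[j], n_modes)
        errors[j] = _shape_distance(x[j], recon, metric)
    return float(errors.mean())


def specificity(model: ShapeModel, corr: CorrespondenceSet, n_modes: int,
                n_draws: int = 1000, seed: int = 0,
                metric: str = "per_particle") -> float:
    """Mean distance (mm) from model-sampled shapes to the nearest training
    shape, over ``n_draws`` seeded Gaussian draws."""
    if not 1 <= n_modes <= model.n_modes:
        raise ValueError(f"n_modes must lie in [1, {model.n_modes}]")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    x = corr.to_matrix()
    lam = np.sqrt(model.eigenvalues[:n_modes])
    v = model.eigenvectors[:, :n_modes]
    total = 0.0
    chunk = max(1, min(n_draws, 200))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        z = rng.standard_normal((m, n_modes))
        draws = model.mean + (z * lam) @ v.T
        d = _shape_distance(draws[:, None, :], x[None, :, :], metric)
        total += d.min(axis=1).sum()
        done += m
    return float(total / n_draws)


@dataclass
class EvaluationCurves:
    """Metric curves for one dataset (reduction level)."""

    factor: int
    n_modes: np.ndarray
    compactness_abs: np.ndarray
    compactness_norm: np.ndarray
    generalisation_mm: np.ndarray
    specificity_mm: np.ndarray
    n_draws: int = 1000
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_modes": self.n_modes,
            "compactness_abs": self.compactness_abs,
            "compactness_norm": self.compactness_norm,
            "generalisation_mm": self.generalisation_mm,
            "specificity_mm": self.specificity_mm,
        })

    @classmethod
    def from_frame(cls, factor: int, frame: pd.DataFrame,
                   n_draws: int = 1000, seed: int = 0) -> "EvaluationCurves":
        return cls(factor=factor,
                   n_modes=frame["n_modes"].to_numpy(),
                   compactness_abs=frame["compactness_abs"].to_numpy(),
                   compactness_norm=frame["compactness_norm"].to_numpy(),
                   generalisation_mm=frame["generalisation_mm"].to_numpy(),
                   specificity_mm=frame["specificity_mm"].to_numpy(),
                   n_draws=n_draws, seed=seed)


def evaluate_correspondence(corr: CorrespondenceSet, factor: int = 1,
                            n_modes_max: int | None = None,
                            n_draws: int = 1000, seed: int = 0,
                            metric: str = "per_particle") -> EvaluationCurves:
    """All three metric curves for one correspondence set."""
    model = fit_pca(corr)
    cap = corr.n_shapes - 2
    top = min(n_modes_max or cap, cap, model.n_modes)
    modes = np.arange(1, top + 1)
    return EvaluationCurves(
        factor=factor,
        n_modes=modes,
        compactness_abs=np.array([compactness(model, m, normalized=False)
                                  for m in modes]),
        compactness_norm=np.array([compactness(model, m) for m in modes]),
        generalisation_mm=np.array([generalisation(corr, m, metric)
                                    for m in modes]),
        specificity_mm=np.array([specificity(model, corr, m, n_draws,
                                             seed, metric) for m in modes]),
        n_draws=n_draws, seed=seed)


def evaluation_suite(corrs_by_factor: dict[int, CorrespondenceSet],
                     n_modes_max: int | None = None, n_draws: int = 1000,
                     seed: int = 0, reference_factor: int = 1
                     ) -> tuple[dict[int, EvaluationCurves], pd.DataFrame]:
    """Curves per reduction level plus a difference table against the
    reference (trabeculated) level at matched mode counts."""
    if reference_factor not in corrs_by_factor:
        raise ValueError(f"reference factor {reference_factor} missing")
    curves = {f: evaluate_correspondence(c, factor=f, n_modes_max=n_modes_max,
                                         n_draws=n_draws, seed=seed)
              for f, c in sorted(corrs_by_factor.items())}
    ref = curves[reference_factor]
    rows = []
    for f, cur in curves.items():
        top = min(len(ref.n_modes), len(cur.n_modes))
        for i in range(top):
            rows.append({
                "factor": f,
                "n_modes": int(cur.n_modes[i]),
                "d_compactness_norm": cur.compactness_norm[i] - ref.compactness_norm[i],
                "d_generalisation_mm": cur.generalisation_mm[i] - ref.generalisation_mm[i],
                "d_specificity_mm": cur.specificity_mm[i] - ref.specificity_mm[i],
            })
    return curves, pd.DataFrame(rows)
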
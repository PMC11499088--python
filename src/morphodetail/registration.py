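"""Rigid alignment of a cohort of surface meshes.

The pipeline follows the usual coarse-to-fine scheme: a deterministic
moment-based global alignment to a reference case, point-to-surface ICP with
per-iteration surface resampling and a shrinking correspondence-rejection
distance, then multiview refinement rounds in which every mesh is re-aligned
against the pooled samples of all the others.  Convergence is declared when
every unordered pair of shapes meets the alignment criterion: a fraction
``q_target`` (default 80%) of surface samples within ``d_target`` (default
0.5 mm) of the partner surface.

Scale never enters: shapes are volume-normalized beforehand, so the
transforms here are proper rigid motions only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateShapeWarning
from .mesh_core import SurfaceLocator, sample_surface


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation mm-free, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply *other* first, then *self*."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    def to_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float).reshape(4, 4)
        return cls(mat[:3, :3], mat[:3, 3])

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class AlignmentReport:
    """Outcome of an ICP run or a multiview registration.

    ``pair_fractions`` maps (i, j) with i < j to the worst-direction
    fraction of samples within the alignment distance.
    """

    fraction: float = 0.0
    iterations: int = 0
    converged: bool = False
    rounds: int = 0
    pair_fractions: dict = field(default_factory=dict)

    def worst_pair(self):
        if not self.pair_fractions:
            return None
        return min(self.pair_fractions.items(), key=lambda kv: kv[1])


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired *source* to *target*."""
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    cov = (target - ct).T @ (source - cs)
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return RigidTransform(rot, ct - rot @ cs)


def coarse_align(source: trimesh.Trimesh, target: trimesh.Trimesh,
                 n_samples: int = 2000) -> RigidTransform:
    """Deterministic global alignment by centroid + principal axes.

    The four proper sign combinations of the principal axes are scored by
    closest-point RMS and the best kept; near-spherical shapes (no distinct
    axes) fall back to a pure translation with a warning.
    """
    src = sample_surface(source, n_samples, seed=0).points
    tgt = sample_surface(target, n_samples, seed=0).points
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)

    cov_s = np.cov((src - cs).T)
    cov_t = np.cov((tgt - ct).T)
    ws, vs = np.linalg.eigh(cov_s)
    wt, vt = np.linalg.eigh(cov_t)
    # descending eigenvalue order
    vs, ws = vs[:, ::-1], ws[::-1]
    vt, wt = vt[:, ::-1], wt[::-1]

    rel = np.abs(np.diff(ws)) / max(ws[0], 1e-30)
    if np.any(rel < 0.02):
        warnings.warn("near-degenerate inertia; falling back to translation",
                      DegenerateShapeWarning, stacklevel=2)
        return RigidTransform(np.eye(3), ct - cs)

    tree = cKDTree(tgt)
    best: tuple[float, RigidTransform] | None = None
    # the identity (plus centroid shift) competes with the axis candidates:
    # datasets that arrive in a consistent frame should not be scrambled
    ident = RigidTransform(np.eye(3), ct - cs)
    d, _ = tree.query(ident.apply(src[::4]))
    best = (float(np.sqrt((d ** 2).mean())), ident)
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            sz = sx * sy * np.sign(np.linalg.det(vt) * np.linalg.det(vs))
            rot = vt @ np.diag([sx, sy, sz]) @ vs.T
            if np.linalg.det(rot) < 0:
                continue
            cand = RigidTransform(rot, ct - rot @ cs)
            d, _ = tree.query(cand.apply(src[::4]))
            score = float(np.sqrt((d ** 2).mean()))
            if best is None or score < best[0]:
                best = (score, cand)
    return best[1]


def icp(source: trimesh.Trimesh, target: trimesh.Trimesh,
        init: RigidTransform | None = None,
        n_samples: int = 2000, d_start: float = 10.0, d_target: float = 0.5,
        q_target: float = 0.80, seed: int = 0, max_iter: int = 200,
        shrink: float = 0.9, stall_limit: int = 8,
        target_locator: SurfaceLocator | None = None
        ) -> tuple[RigidTransform, AlignmentReport]:
    """Point-to-surface ICP with per-iteration surface resampling.

    The correspondence-rejection distance starts at ``d_start`` and shrinks
    geometrically (factor ``shrink``) with a floor of ``d_target``; the run
    stops as soon as a fraction ``q_target`` of the samples lies within
    ``d_target`` of the target surface.  Non-convergence is reported, not
    raised.
    """
    transform = init if init is not None else RigidTransform.identity()
    locator = target_locator if target_locator is not None else SurfaceLocator(target)
    rng = np.random.default_rng(seed)

    d_reject = d_start
    fraction = 0.0
    iteration = 0
    best = (0.0, transform)
    stall = 0
    for iteration in range(1, max_iter + 1):
        pts = sample_surface(source, n_samples, seed=rng).points
        moved = transform.apply(pts)
        closest, dist, _ = locator.closest(moved)
        fraction = float((dist < d_target).mean())
        if fraction >= q_target:
            return transform, AlignmentReport(fraction=fraction,
                                              iterations=iteration,
                                              converged=True)
        if fraction > best[0] + 1e-3:
            best = (fraction, transform)
            stall = 0
        elif d_reject <= d_target * 1.0001:
            # rejection floor reached and no progress: dissimilar shapes
            # will never meet the criterion, stop early with the best seen
            stall += 1
            if stall >= stall_limit:
                break
        inliers = dist < d_reject
        if inliers.sum() >= 3:
            delta = _kabsch(moved[inliers], closest[inliers])
            transform = delta.compose(transform)
        d_reject = max(d_target, d_reject * shrink)
    fraction, transform = max(best, (fraction, transform), key=lambda b: b[0])
    return transform, AlignmentReport(fraction=fraction, iterations=iteration,
                                      converged=False)


def _pair_fraction(samples_i: np.ndarray, locator_j: SurfaceLocator,
                   d_target: float) -> float:
    _, dist, _ = locator_j.closest(samples_i)
    return float((dist < d_target).mean())


def _point_cloud_icp(points: np.ndarray, pooled_tree: cKDTree,
                     init: RigidTransform, d_reject: float,
                     iterations: int = 10) -> RigidTransform:
    """A few point-to-point ICP steps of *points* against a pooled cloud."""
    transform = init
    for _ in range(iterations):
        moved = transform.apply(points)
        dist, idx = pooled_tree.query(moved)
        inliers = dist < d_reject
        if inliers.sum() < 3:
            break
        delta = _kabsch(moved[inliers], pooled_tree.data[idx[inliers]])
        transform = delta.compose(transform)
    return transform


def multiview_register(meshes: list[trimesh.Trimesh], reference_index: int = 0,
                       max_rounds: int = 10, n_samples: int = 2000,
                       d_target: float = 0.5, q_target: float = 0.80,
                       seed: int = 0, pair_samples: int = 600,
                       max_iter: int = 200
                       ) -> tuple[list[RigidTransform], AlignmentReport]:
    """Align a whole dataset: coarse + ICP to a reference, then multiview
    refinement against the pooled cloud of all other shapes.

    Stops once every unordered pair meets the ``q_target``-within-
    ``d_target`` criterion (both directions), or after ``max_rounds``.
    Non-convergent pairs are listed in the report and warned about.
    """
    n = len(meshes)
    if n == 0:
        raise ValueError("no meshes given")
    if n == 1:
        return [RigidTransform.identity()], AlignmentReport(
            fraction=1.0, converged=True, rounds=0, pair_fractions={})

    ss = np.random.SeedSequence((seed, 0x1c9))
    child = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n + 1)]

    reference = meshes[reference_index]
    ref_locator = SurfaceLocator(reference)
    transforms: list[RigidTransform] = []
    for i, mesh in enumerate(meshes):
        if i == reference_index:
            transforms.append(RigidTransform.identity())
            continue
        init = coarse_align(mesh, reference)
        t, _ = icp(mesh, reference, init, n_samples=n_samples,
                   d_target=d_target, q_target=q_target, seed=child[i],
                   max_iter=max_iter, target_locator=ref_locator)
        transforms.append(t)

    def all_pairs(transforms) -> dict:
        moved = [m.copy() for m in meshes]
        for m, t in zip(moved, transforms):
            m.vertices = t.apply(m.vertices)
        locators = [SurfaceLocator(m) for m in moved]
        samples = [sample_surface(m, pair_samples, seed=child[-1]).points
                   for m in moved]
        fractions = {}
        for i in range(n):
            for j in range(i + 1, n):
                fij = _pair_fraction(samples[i], locators[j], d_target)
                fji = _pair_fraction(samples[j], locators[i], d_target)
                fractions[(i, j)] = min(fij, fji)
        return fractions

    fractions = all_pairs(transforms)
    rounds = 0
    while rounds < max_rounds and min(fractions.values()) < q_target:
        rounds += 1
        # refine each shape against the pooled samples of all others
        pooled_samples = [sample_surface(m, max(400, n_samples // max(n - 1, 1)),
                                         seed=child[i]).points
                          for i, m in enumerate(meshes)]
        for i in range(n):
            others = np.vstack([transforms[j].apply(pooled_samples[j])
                                for j in range(n) if j != i])
            tree = cKDTree(others)
            own = sample_surface(meshes[i], n_samples, seed=child[i]).points
            transforms[i] = _point_cloud_icp(own, tree, transforms[i],
                                             d_reject=4.0 * d_target)
        fractions = all_pairs(transforms)

    converged = min(fractions.values()) >= q_target
    if not converged:
        bad = [p for p, f in fractions.items() if f < q_target]
        warnings.warn(f"{len(bad)} shape pair(s) below the alignment "
                      f"criterion after {rounds} rounds", stacklevel=2)
    report = AlignmentReport(fraction=float(min(fractions.values())),
                             rounds=rounds, converged=converged,
                             pair_fractions=fractions)
    return transforms, report
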
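"""Dense point correspondence and the PCA point-distribution model.

Correspondence follows a multiscale particle scheme: an initial set of
particles is spread over a template shape by farthest-point sampling,
propagated to every other shape by closest-point projection, and then
optimized by alternating

* a coverage step (Lloyd relaxation against a dense surface sample — each
  particle moves to the centroid of the surface region it owns), and
* a correspondence step (each particle is pulled toward the ensemble mean
  position of its particle id across shapes),

with the blend weight shifting from coverage-dominated to
correspondence-dominated over the iterations.  Particles are then split
(duplicated with a small tangential offset, shared across shapes) and the
optimization repeated until the target particle count is reached.  Every
particle ends exactly on its shape's surface (closest-point projection is
the last operation of every step).

PCA of the stacked particle coordinates gives the shape model: mean shape,
orthonormal modes, eigenvalues (sample covariance, divisor n_s - 1) and
per-shape mode scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import CorrespondenceError
from .mesh_core import SurfaceLocator, sample_surface

#: particles must end up within this distance of the surface (mm)
EPSILON_SURFACE = 0.25


@dataclass
class CorrespondenceSet:
    """Ordered particle coordinates for every shape of a cohort.

    ``points`` has shape (n_shapes, K, 3); row k of every shape refers to
    the same anatomical location.
    """

    points: np.ndarray
    shape_ids: list[str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise CorrespondenceError("points must be (n_shapes, K, 3)")
        if len(self.shape_ids) != self.points.shape[0]:
            raise CorrespondenceError("shape_ids length mismatch")

    @property
    def n_shapes(self) -> int:
        return self.points.shape[0]

    @property
    def n_particles(self) -> int:
        return self.points.shape[1]

    def to_matrix(self) -> np.ndarray:
        """(n_shapes, 3K) flattened correspondence matrix."""
        return self.points.reshape(self.n_shapes, -1)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, pts in zip(self.shape_ids, self.points):
            np.savetxt(out_dir / f"{sid}.csv", pts, delimiter=",",
                       header="x,y,z", comments="", fmt="%.10g")
        (out_dir / "manifest.json").write_text(json.dumps(
            {"shape_ids": self.shape_ids, "n_particles": self.n_particles},
            indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "CorrespondenceSet":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        pts = np.stack([np.loadtxt(in_dir / f"{sid}.csv", delimiter=",",
                                   skiprows=1)
                        for sid in manifest["shape_ids"]])
        return cls(points=pts, shape_ids=manifest["shape_ids"])


@dataclass
class ShapeModel:
    """PCA point-distribution model of a correspondence set."""

    mean: np.ndarray           # (3K,)
    eigenvalues: np.ndarray    # (m,) descending, mm^2
    eigenvectors: np.ndarray   # (3K, m) orthonormal columns
    scores: np.ndarray         # (n_shapes, m), zero-mean per mode
    n_shapes: int
    shape_ids: list[str]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_particles(self) -> int:
        return len(self.mean) // 3

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(out_dir / "mean.csv", self.mean, delimiter=",", fmt="%.10g")
        np.savetxt(out_dir / "eigenvalues.csv", self.eigenvalues,
                   delimiter=",", fmt="%.10g")
        np.savetxt(out_dir / "eigenvectors.csv", self.eigenvectors,
                   delimiter=",", fmt="%.10g")
        np.savetxt(out_dir / "scores.csv", self.scores, delimiter=",",
                   fmt="%.10g")
        (out_dir / "model.json").write_text(json.dumps(
            {"n_shapes": self.n_shapes, "shape_ids": self.shape_ids},
            indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ShapeModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "model.json").read_text())
        return cls(
            mean=np.loadtxt(in_dir / "mean.csv", delimiter=","),
            eigenvalues=np.atleast_1d(
                np.loadtxt(in_dir / "eigenvalues.csv", delimiter=",")),
            eigenvectors=np.atleast_2d(
                np.loadtxt(in_dir / "eigenvectors.csv", delimiter=",")),
            scores=np.atleast_2d(
                np.loadtxt(in_dir / "scores.csv", delimiter=",")),
            n_shapes=meta["n_shapes"], shape_ids=meta["shape_ids"])


# ---------------------------------------------------------------------------
# correspondence


def _farthest_point_sample(points: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Greedy farthest-point subset of *points*; deterministic."""
    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    dist = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, k):
        nxt = int(dist.argmax())
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


def _select_template(dense: list[np.ndarray], k_init: int) -> int:
    """Medoid-like template: the shape whose farthest-point particles
    propagate to all other shapes with the smallest mean residual."""
    n = len(dense)
    trees = [cKDTree(d) for d in dense]
    best, best_idx = np.inf, 0
    for s in range(n):
        particles = _farthest_point_sample(dense[s], k_init)
        resid = 0.0
        for t in range(n):
            if t == s:
                continue
            d, _ = trees[t].query(particles)
            resid += d.mean()
        if resid < best:
            best, best_idx = resid, s
    return best_idx


def establish_correspondence(meshes: list[trimesh.Trimesh],
                             n_particles: int = 1024, n_init: int = 128,
                             seed: int = 0,
                             iterations_per_scale: int = 8,
                             n_dense: int | None = None,
                             shape_ids: list[str] | None = None,
                             radial_weight: float = 0.35
                             ) -> CorrespondenceSet:
    """Multiscale particle correspondence across aligned, volume-normalized
    meshes (see the module docstring for the scheme)."""
    if n_particles < n_init or n_particles % n_init:
        raise CorrespondenceError("n_particles must be n_init * 2^m")
    splits = int(np.log2(n_particles // n_init))
    if n_init * 2 ** splits != n_particles:
        raise CorrespondenceError("n_particles must be n_init * 2^m")
    n = len(meshes)
    if n < 2:
        raise CorrespondenceError("need at least 2 shapes")
    if shape_ids is None:
        shape_ids = [f"shape_{i:03d}" for i in range(n)]

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xc02e)))
    if n_dense is None:
        n_dense = max(4000, 8 * n_particles)

    # identical seed for every shape: identical meshes then yield identical
    # dense clouds, making the identical-cohort fixed point exact
    dense = [sample_surface(m, n_dense, seed=seed).points for m in meshes]
    trees = [cKDTree(d) for d in dense]
    locators = [SurfaceLocator(m) for m in meshes]
    areas = np.array([m.area for m in meshes])

    template = _select_template(dense, n_init)
    init = _farthest_point_sample(dense[template], n_init)
    # propagate to every shape by closest-point projection
    particles = np.stack([locators[i].closest(init)[0] for i in range(n)])

    k_cur = n_init
    while True:
        for it in range(iterations_per_scale):
            # correspondence weight: coverage-dominated early, strongly
            # correspondence-dominated late
            w = 0.15 + 0.75 * it / max(iterations_per_scale - 1, 1)
            # (a) coverage: Lloyd step against the dense samples
            for i in range(n):
                owner = cKDTree(particles[i]).query(dense[i])[1]
                sums = np.zeros((k_cur, 3))
                np.add.at(sums, owner, dense[i])
                counts = np.bincount(owner, minlength=k_cur)
                nonempty = counts > 0
                lloyd = particles[i].copy()
                lloyd[nonempty] = sums[nonempty] / counts[nonempty, None]
                particles[i] = lloyd
            # (b) correspondence: pull toward the ensemble mean and
            # reproject.  The pull is mostly *tangential* (aligning the
            # parametrization): a full radial pull followed by closest-point
            # projection onto a rough surface snaps particles to the nearest
            # ridge top, which deflates the radial shape differences the
            # model is supposed to capture.  A small radial weight is kept —
            # particle systems do sample protruding structure
            # preferentially, which is part of how fine-detail statistics
            # enter the correspondence.
            ensemble = particles.mean(axis=0)
            for i in range(n):
                _, _, faces = locators[i].closest(particles[i])
                normals = np.asarray(meshes[i].face_normals)[faces]
                delta = ensemble - particles[i]
                radial = np.einsum("ij,ij->i", delta, normals)
                tangential = delta - radial[:, None] * normals
                step = tangential + radial_weight * radial[:, None] * normals
                particles[i] = locators[i].closest(
                    particles[i] + w * step)[0]
        if k_cur == n_particles:
            break
        # split: duplicate with a tangential offset shared across shapes
        offset_dir = rng.normal(size=(k_cur, 3))
        offset_dir /= np.linalg.norm(offset_dir, axis=1, keepdims=True)
        delta = 0.4 * np.sqrt(areas.mean() / k_cur)
        children = np.empty((n, 2 * k_cur, 3))
        for i in range(n):
            children[i, 0::2] = locators[i].closest(
                particles[i] + delta * offset_dir)[0]
            children[i, 1::2] = locators[i].closest(
                particles[i] - delta * offset_dir)[0]
        particles = children
        k_cur *= 2

    # hard surface-fidelity check
    for i in range(n):
        _, d, _ = locators[i].closest(particles[i])
        if d.max() > EPSILON_SURFACE:
            raise CorrespondenceError(
                f"particle left the surface on shape {i} ({d.max():.3g} mm)")
    return CorrespondenceSet(points=particles, shape_ids=list(shape_ids))


# ---------------------------------------------------------------------------
# PCA model


def fit_pca(corr: CorrespondenceSet) -> ShapeModel:
    """Sample-covariance PCA of the flattened correspondences."""
    x = corr.to_matrix()
    n = corr.n_shapes
    if n < 2:
        raise CorrespondenceError("need at least 2 shapes for PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    m = min(n - 1, xc.shape[1])
    u, s, vt = u[:, :m], s[:m], vt[:m]
    eigenvalues = s ** 2 / (n - 1)
    scores = u * s
    return ShapeModel(mean=mean, eigenvalues=eigenvalues,
                      eigenvectors=vt.T, scores=scores, n_shapes=n,
                      shape_ids=list(corr.shape_ids))


def reconstruct(model: ShapeModel, shape_vector: np.ndarray,
                n_modes: int) -> np.ndarray:
    """Projection of *shape_vector* onto the first ``n_modes`` modes."""
    if not 1 <= n_modes <= model.n_modes:
        raise ValueError(f"n_modes must lie in [1, {model.n_modes}]")
    v = model.eigenvectors[:, :n_modes]
    centered = np.asarray(shape_vector, dtype=float) - model.mean
    return model.mean + v @ (v.T @ centered)


def sample_shape(model: ShapeModel, n_modes: int,
                 seed: int | np.random.Generator = 0,
                 z: np.ndarray | None = None) -> np.ndarray:
    """Random shape draw: mean + sum_i z_i sqrt(lambda_i) v_i, z ~ N(0, 1)."""
    if not 1 <= n_modes <= model.n_modes:
        raise ValueError(f"n_modes must lie in [1, {model.n_modes}]")
    if z is None:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        z = rng.standard_normal(n_modes)
    z = np.asarray(z, dtype=float)[:n_modes]
    coeff = z * np.sqrt(model.eigenvalues[:n_modes])
    return model.mean + model.eigenvectors[:, :n_modes] @ coeff
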
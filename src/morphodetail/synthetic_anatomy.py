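"""Synthetic left-atrial-appendage-like anatomies.

The generator stands in for a private cohort of CT-derived appendage
surfaces.  Each shape is a capped tube swept along a planar circular arc
(bend angle is the chicken-wing discriminator), decorated with

* Gaussian-bump *lobes* (secondary outpouchings, cm scale), and
* fine *trabecular* surface detail: band-limited radial displacement whose
  dominant spatial frequency sits near 1 cycle/mm.

Real trabeculae are ridge-like structures induced by roughly parallel
pectinate muscles, i.e. spatially patterned rather than white noise.  The
detail field therefore mixes a deterministic "ridge template" — shared by
every shape whose detail frequency falls in the same band — with per-shape
incoherent noise.  When a cohort couples detail frequency to the shape
class, the template component gives the classes a phase-coherent fine-scale
signature that statistical shape analysis can detect, and that point-set
simplification destroys.  Without coupling, both classes draw from the same
detail distribution and the fine scale carries no class signal.

Meshes are watertight and genus 0 by construction (trabecular through-holes
are not modelled; see the methods note).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import PchipInterpolator

from .errors import InvalidMeshError, InvalidSpecError
from .mesh_core import SurfaceLocator, require_closed, write_mesh

CW = "CW"
NCW = "NCW"

#: nominal tube dimensions (mm) used to lay ridge patterns in a normalized
#: parametric frame, so corresponding surface locations on different shapes
#: see the same pattern phase.
_NOMINAL_LENGTH = 45.0
_NOMINAL_RADIUS = 4.0
#: frequency quantization step (cycles/mm) indexing the ridge-template family
_TEMPLATE_FREQ_STEP = 0.1
_TEMPLATE_SEED = 20260929
_TEMPLATE_COMPONENTS = 48
#: cleft carving: depth multiple of the nominal amplitude, template-field
#: threshold (in template sigmas) and transition width
_CLEFT_DEPTH_FACTOR = 3.0
_CLEFT_THRESHOLD = 0.5
_CLEFT_WIDTH = 1.2
#: incoherent surface texture relative to the nominal amplitude
_TEXTURE_FACTOR = 0.35


@dataclass(frozen=True)
class AnatomySpec:
    """Parameters of one synthetic appendage.

    Identical specs (including ``seed``) regenerate bit-identical meshes.
    """

    label: str = NCW
    bend_angle: float = 60.0            # degrees, total turning of the centerline
    length: float = 45.0                # mm, centerline arc length
    radius_profile: tuple = ((0.0, 4.5), (0.35, 4.0), (0.7, 3.3), (1.0, 2.0))
    n_lobes: int = 1
    lobe_amplitude: float = 1.3         # mm
    detail_amplitude: float = 0.65      # mm RMS of the radial displacement
    detail_frequency: float = 0.55      # cycles/mm, dominant detail frequency
    mesh_resolution: float = 0.5        # mm target edge length
    seed: int = 0

    def validate(self) -> None:
        radii = [r for _, r in self.radius_profile]
        positions = [t for t, _ in self.radius_profile]
        if self.label not in (CW, NCW):
            raise InvalidSpecError(f"label must be CW or NCW, got {self.label!r}")
        if not 0.0 <= self.bend_angle < 180.0:
            raise InvalidSpecError("bend_angle must lie in [0, 180)")
        if self.length <= 0:
            raise InvalidSpecError("length must be positive")
        if len(self.radius_profile) < 2 or positions != sorted(positions):
            raise InvalidSpecError("radius_profile needs >= 2 sorted arc positions")
        if min(radii) <= 0:
            raise InvalidSpecError("all radii must be positive")
        if self.n_lobes < 0:
            raise InvalidSpecError("n_lobes must be >= 0")
        if self.detail_amplitude < 0:
            raise InvalidSpecError("detail_amplitude must be >= 0")
        if self.detail_amplitude >= min(radii):
            raise InvalidSpecError(
                "detail_amplitude must stay below the minimum radius "
                "(self-intersection bound)")
        if self.detail_frequency <= 0:
            raise InvalidSpecError("detail_frequency must be positive")
        if self.mesh_resolution <= 0:
            raise InvalidSpecError("mesh_resolution must be positive")
        if self.bend_angle > 1.0:
            curvature_radius = self.length / np.radians(self.bend_angle)
            if curvature_radius <= 1.1 * max(radii):
                raise InvalidSpecError(
                    "bend too sharp for the tube radius (inner wall would "
                    "self-intersect)")

    def smooth_counterpart(self) -> "AnatomySpec":
        """The same anatomy without fine detail (macro geometry unchanged)."""
        return AnatomySpec(**{**asdict(self), "detail_amplitude": 0.0,
                              "radius_profile": self.radius_profile})


@dataclass(frozen=True)
class CohortSpec:
    """Class-conditional distribution over :class:`AnatomySpec` parameters.

    ``macro_overlap`` in [0, 1] moves the class bend-angle means together
    (1 = identical macro shape distributions).  ``detail_class_coupling``
    >= 0 separates the class detail frequency/amplitude distributions
    (0 = identical detail statistics).
    """

    n_shapes: int = 85
    cw_fraction: float = 21.0 / 85.0
    master_seed: int = 0
    macro_overlap: float = 0.7
    detail_class_coupling: float = 1.0
    mesh_resolution: float = 0.5
    length_mean: float = 45.0
    length_sd: float = 1.5
    radius_mean: float = 4.0
    radius_sd: float = 0.15
    bend_center: float = 75.0           # degrees, midpoint of the class means
    bend_half_gap: float = 40.0         # degrees, half distance at zero overlap
    bend_sd: float = 12.0
    lobe_amplitude_mean: float = 1.3
    lobe_amplitude_sd: float = 0.12
    max_lobes: int = 2
    detail_frequency_mean: float = 0.55  # cycles/mm (ridge spacing ~2 mm)
    detail_frequency_sd: float = 0.04
    detail_amplitude_mean: float = 0.65  # mm (trabecular recess depth)
    detail_amplitude_sd: float = 0.06

    def validate(self) -> None:
        if self.n_shapes < 4:
            raise InvalidSpecError("n_shapes must be >= 4")
        if not 0.0 < self.cw_fraction < 1.0:
            raise InvalidSpecError("cw_fraction must lie in (0, 1)")
        if not 0.0 <= self.macro_overlap <= 1.0:
            raise InvalidSpecError("macro_overlap must lie in [0, 1]")
        if self.detail_class_coupling < 0:
            raise InvalidSpecError("detail_class_coupling must be >= 0")


# ---------------------------------------------------------------------------
# ridge template


@lru_cache(maxsize=32)
def _ridge_template_bank(freq_bin: int) -> tuple:
    """Sinusoid bank of the shared ridge pattern at a quantized frequency.

    Returns integer wavenumbers per unit arc position (p), integer
    circumferential harmonics (m), phases and weights.  The bank is a fixed
    function of the frequency bin only, so shapes whose detail frequency
    falls in the same bin share the pattern exactly.
    """
    f = freq_bin * _TEMPLATE_FREQ_STEP
    rng = np.random.default_rng(np.random.SeedSequence((_TEMPLATE_SEED, freq_bin)))
    psi = rng.uniform(0.0, 2 * np.pi, _TEMPLATE_COMPONENTS)
    mag = np.clip(rng.normal(1.0, 0.12, _TEMPLATE_COMPONENTS), 0.7, 1.3)
    p = np.round(f * mag * np.cos(psi) * _NOMINAL_LENGTH)
    m = np.round(f * mag * np.sin(psi) * 2 * np.pi * _NOMINAL_RADIUS)
    phase = rng.uniform(0.0, 2 * np.pi, _TEMPLATE_COMPONENTS)
    weight = rng.normal(size=_TEMPLATE_COMPONENTS)
    keep = (np.abs(p) + np.abs(m)) > 0
    return p[keep], m[keep], phase[keep], weight[keep]


def _evaluate_bank(t: np.ndarray, theta: np.ndarray, p, m, phase, weight) -> np.ndarray:
    arg = (2 * np.pi * p[None, :] * t[:, None]
           + m[None, :] * theta[:, None] + phase[None, :])
    return np.sin(arg) @ weight


def _incoherent_field(t: np.ndarray, theta: np.ndarray, f: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-shape band-limited noise at dominant frequency *f* (cycles/mm)."""
    psi = rng.uniform(0.0, 2 * np.pi, _TEMPLATE_COMPONENTS)
    mag = np.clip(rng.normal(1.0, 0.12, _TEMPLATE_COMPONENTS), 0.7, 1.3)
    p = f * mag * np.cos(psi) * _NOMINAL_LENGTH
    m = np.round(f * mag * np.sin(psi) * 2 * np.pi * _NOMINAL_RADIUS)
    phase = rng.uniform(0.0, 2 * np.pi, _TEMPLATE_COMPONENTS)
    weight = rng.normal(size=_TEMPLATE_COMPONENTS)
    return _evaluate_bank(t, theta, p, m, phase, weight)


# ---------------------------------------------------------------------------
# mesh construction


def _centerline(t: np.ndarray, length: float, bend_deg: float):
    """Planar arc centerline with frames; returns (points, normal, binormal, tangent0)."""
    beta = np.radians(bend_deg)
    if beta < 1e-9:
        pts = np.column_stack([np.zeros_like(t), np.zeros_like(t), t * length])
        tang = np.tile([0.0, 0.0, 1.0], (len(t), 1))
    else:
        radius = length / beta
        ang = beta * t
        pts = np.column_stack([radius * (1 - np.cos(ang)),
                               np.zeros_like(t),
                               radius * np.sin(ang)])
        tang = np.column_stack([np.sin(ang), np.zeros_like(ang), np.cos(ang)])
    normal = np.column_stack([tang[:, 2], np.zeros(len(t)), -tang[:, 0]])
    binormal = np.tile([0.0, 1.0, 0.0], (len(t), 1))
    return pts, normal, binormal, tang


def _taper(t: np.ndarray, margin: float = 0.08) -> np.ndarray:
    """Smooth 0->1->0 envelope keeping displacement away from the end caps."""
    up = np.clip(t / margin, 0.0, 1.0)
    down = np.clip((1.0 - t) / margin, 0.0, 1.0)
    smooth = lambda x: x * x * (3.0 - 2.0 * x)  # noqa: E731
    return smooth(up) * smooth(down)


def generate_shape(spec: AnatomySpec) -> trimesh.Trimesh:
    """Generate one watertight, genus-0 anatomy mesh from *spec*.

    Macro geometry is a swept tube along a bent centerline with Gaussian
    lobe bumps; fine detail is the radial displacement field described in
    the module docstring.  Deterministic in ``spec`` (including the seed).
    """
    spec.validate()
    ss = np.random.SeedSequence((int(spec.seed), 0x5eed))
    lobe_rng, detail_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    h = spec.mesh_resolution
    prof_t = np.array([t for t, _ in spec.radius_profile])
    prof_r = np.array([r for _, r in spec.radius_profile])
    if prof_t[0] > 0.0:
        prof_t, prof_r = np.r_[0.0, prof_t], np.r_[prof_r[0], prof_r]
    if prof_t[-1] < 1.0:
        prof_t, prof_r = np.r_[prof_t, 1.0], np.r_[prof_r, prof_r[-1]]
    radius_fn = PchipInterpolator(prof_t, prof_r)

    r_max = float(prof_r.max())
    n_theta = max(12, int(round(2 * np.pi * r_max / h)))
    n_rings = max(9, int(round(spec.length / h)) + 1)
    t = np.linspace(0.0, 1.0, n_rings)
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)

    centers, normal, binormal, tang = _centerline(t, spec.length, spec.bend_angle)
    base_radius = radius_fn(t)

    tt = np.repeat(t, n_theta)          # flattened (ring, theta) grids
    th = np.tile(theta, n_rings)

    # lobes: Gaussian bumps in (t, theta), drawn before detail so the smooth
    # counterpart (detail_amplitude = 0) shares them bit-exactly
    lobe_disp = np.zeros(n_rings * n_theta)
    for _ in range(spec.n_lobes):
        t_k = lobe_rng.uniform(0.25, 0.85)
        th_k = lobe_rng.uniform(0.0, 2 * np.pi)
        s_t = lobe_rng.uniform(0.05, 0.09)
        s_th = lobe_rng.uniform(0.5, 0.9)
        dth = np.angle(np.exp(1j * (th - th_k)))
        lobe_disp += spec.lobe_amplitude * np.exp(
            -0.5 * ((tt - t_k) / s_t) ** 2 - 0.5 * (dth / s_th) ** 2)

    # fine detail: trabecular clefts along the shared ridge template plus
    # per-shape incoherent texture.  Clefts are narrow inward recesses
    # (depth ~2x the nominal amplitude) carved where the template field
    # exceeds a threshold; their spatial pattern is shared by shapes of the
    # same detail-frequency band, which is what makes fine detail
    # statistically informative at cohort level.
    if spec.detail_amplitude > 0:
        freq_bin = int(round(spec.detail_frequency / _TEMPLATE_FREQ_STEP))
        coh = _evaluate_bank(tt, th, *_ridge_template_bank(freq_bin))
        coh = coh / (coh.std() or 1.0)
        hinge = np.clip((coh - _CLEFT_THRESHOLD) / _CLEFT_WIDTH, 0.0, 1.0)
        hinge = hinge * hinge * (3.0 - 2.0 * hinge)  # smoothstep
        clefts = -_CLEFT_DEPTH_FACTOR * spec.detail_amplitude * hinge
        inc = _incoherent_field(tt, th, spec.detail_frequency, detail_rng)
        texture = (_TEXTURE_FACTOR * spec.detail_amplitude
                   * inc / (inc.std() or 1.0))
        detail = clefts + texture
    else:
        detail = np.zeros_like(tt)

    envelope = _taper(tt)
    base_local = np.repeat(base_radius, n_theta)
    radius = base_local + envelope * (lobe_disp + detail)
    # hard clamp: recesses can never invert the tube wall
    radius = np.maximum(radius, 0.3 * base_local)

    ring_dirs = (np.cos(th)[:, None] * np.repeat(normal, n_theta, axis=0)
                 + np.sin(th)[:, None] * np.repeat(binormal, n_theta, axis=0))
    tube_vertices = np.repeat(centers, n_theta, axis=0) + radius[:, None] * ring_dirs

    vertices, faces = _close_tube(tube_vertices, n_rings, n_theta,
                                  centers, tang, base_radius, normal, binormal,
                                  theta, h)

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise InvalidMeshError("generated mesh is not watertight (internal error)")
    return mesh


def _close_tube(tube_vertices, n_rings, n_theta, centers, tang,
                base_radius, normal, binormal, theta, h):
    """Append spherical end caps and triangulate the whole surface."""
    verts = [tube_vertices]
    faces = []

    def ring_offset(i):
        return i * n_theta

    # quads between consecutive tube rings
    for i in range(n_rings - 1):
        a = ring_offset(i) + np.arange(n_theta)
        b = ring_offset(i) + (np.arange(n_theta) + 1) % n_theta
        c = ring_offset(i + 1) + np.arange(n_theta)
        d = ring_offset(i + 1) + (np.arange(n_theta) + 1) % n_theta
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))

    next_idx = n_rings * n_theta
    for end, sign in ((0, -1.0), (n_rings - 1, +1.0)):
        r_end = float(base_radius[end])
        center = centers[end]
        axis = sign * tang[end]
        n_cap = max(2, int(round(0.5 * np.pi * r_end / h)))
        phi = (np.arange(1, n_cap) / n_cap) * (np.pi / 2)
        ring_ids = []
        for ph in phi:
            ring = (center + axis * (r_end * np.sin(ph))
                    + (np.cos(theta)[:, None] * normal[end]
                       + np.sin(theta)[:, None] * binormal[end]) * (r_end * np.cos(ph)))
            verts.append(ring)
            ring_ids.append(next_idx)
            next_idx += n_theta
        pole = center + axis * r_end
        verts.append(pole[None, :])
        pole_id = next_idx
        next_idx += 1

        chain = [ring_offset(end)] + ring_ids
        for lo, hi in zip(chain[:-1], chain[1:]):
            a = lo + np.arange(n_theta)
            b = lo + (np.arange(n_theta) + 1) % n_theta
            c = hi + np.arange(n_theta)
            d = hi + (np.arange(n_theta) + 1) % n_theta
            if sign > 0:
                faces.append(np.column_stack([a, b, d]))
                faces.append(np.column_stack([a, d, c]))
            else:
                faces.append(np.column_stack([a, d, b]))
                faces.append(np.column_stack([a, c, d]))
        last = chain[-1]
        a = last + np.arange(n_theta)
        b = last + (np.arange(n_theta) + 1) % n_theta
        if sign > 0:
            faces.append(np.column_stack([a, b, np.full(n_theta, pole_id)]))
        else:
            faces.append(np.column_stack([a, np.full(n_theta, pole_id), b]))

    return np.vstack(verts), np.vstack(faces)


# ---------------------------------------------------------------------------
# cohorts


def draw_cohort_specs(cohort: CohortSpec) -> list[AnatomySpec]:
    """Draw the per-shape specs of a cohort (deterministic in master_seed)."""
    cohort.validate()
    rng = np.random.default_rng(np.random.SeedSequence((cohort.master_seed, 0xc0)))

    n_cw = int(round(cohort.n_shapes * cohort.cw_fraction))
    n_cw = min(max(n_cw, 1), cohort.n_shapes - 1)
    labels = np.array([CW] * n_cw + [NCW] * (cohort.n_shapes - n_cw))
    rng.shuffle(labels)

    c = cohort.detail_class_coupling
    gap = cohort.bend_half_gap * (1.0 - cohort.macro_overlap)
    bend_mean = {CW: cohort.bend_center + gap, NCW: cohort.bend_center - gap}
    freq_mean = {CW: cohort.detail_frequency_mean * (1.0 + 0.25 * c),
                 NCW: cohort.detail_frequency_mean * (1.0 - 0.25 * c)}
    amp_mean = {CW: cohort.detail_amplitude_mean * (1.0 + 0.4 * c),
                NCW: cohort.detail_amplitude_mean * (1.0 - 0.4 * c)}

    specs = []
    shape_seeds = np.random.SeedSequence((cohort.master_seed, 0x5a)).spawn(
        cohort.n_shapes)
    for i, label in enumerate(labels):
        bend = float(np.clip(rng.normal(bend_mean[label], cohort.bend_sd),
                             0.0, 160.0))
        length = float(np.clip(rng.normal(cohort.length_mean, cohort.length_sd),
                               30.0, 60.0))
        r = float(np.clip(rng.normal(cohort.radius_mean, cohort.radius_sd),
                          2.5, 6.0))
        mult = (1.12 + rng.normal(0, 0.02), 1.0,
                0.82 + rng.normal(0, 0.02), 0.5 + rng.normal(0, 0.02))
        profile = tuple((pos, round(m * r, 6))
                        for pos, m in zip((0.0, 0.35, 0.7, 1.0), mult))
        freq = float(np.clip(rng.normal(freq_mean[label],
                                        cohort.detail_frequency_sd), 0.3, 2.5))
        amp = float(np.clip(rng.normal(amp_mean[label],
                                       cohort.detail_amplitude_sd), 0.05, 1.0))
        specs.append(AnatomySpec(
            label=str(label),
            bend_angle=bend,
            length=length,
            radius_profile=profile,
            n_lobes=int(cohort.max_lobes),
            lobe_amplitude=float(np.clip(
                rng.normal(cohort.lobe_amplitude_mean, cohort.lobe_amplitude_sd),
                0.5, 2.5)),
            detail_amplitude=amp,
            detail_frequency=freq,
            mesh_resolution=cohort.mesh_resolution,
            seed=int(shape_seeds[i].generate_state(1)[0] % (2**31)),
        ))
    return specs


def generate_cohort(cohort: CohortSpec) -> list[tuple[trimesh.Trimesh, str]]:
    """Generate all cohort meshes with their class labels."""
    specs = draw_cohort_specs(cohort)
    return [(generate_shape(s), s.label) for s in specs]


# ---------------------------------------------------------------------------
# detail measurement


def detail_energy(mesh: trimesh.Trimesh, smooth_reference: trimesh.Trimesh,
                  max_points: int = 20000) -> float:
    """RMS signed closest-point distance from *mesh* vertices to the smooth
    reference surface, in mm.  Quantifies how much fine detail the mesh
    carries relative to its smooth counterpart.

    For very dense meshes the RMS is estimated on an evenly strided subset
    of at most ``max_points`` vertices.
    """
    require_closed(mesh, "mesh")
    require_closed(smooth_reference, "smooth_reference")
    verts = mesh.vertices.view(np.ndarray)
    if len(verts) > max_points:
        verts = verts[:: len(verts) // max_points + 1]
    sd = SurfaceLocator(smooth_reference).signed_distance(verts)
    return float(np.sqrt(np.mean(sd ** 2)))


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(out_dir: str | Path,
                 meshes_labels: list[tuple[trimesh.Trimesh, str]],
                 specs: list[AnatomySpec] | None = None) -> None:
    """Write meshes as binary PLY plus ``labels.csv`` and a spec manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["shape_id", "label"])
        for i, (mesh, label) in enumerate(meshes_labels):
            shape_id = f"shape_{i:03d}"
            write_mesh(mesh, out_dir / f"{shape_id}.ply")
            writer.writerow([shape_id, label])
    if specs is not None:
        manifest = [asdict(s) for s in specs]
        (out_dir / "cohort_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a ``shape_id,label`` CSV into a dict."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["shape_id"]] = row["label"]
    return out
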
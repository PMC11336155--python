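"""Synthetic phantoms with known ground truth.

Every downstream stage of the pipeline (segmentation, orientation, tracking,
strain recovery, affine comparison) is validated against data generated here:
fibrous SHG-like volumes with a controlled 3D orientation distribution, a
TPEF channel proportional to the SHG fiber signal, macro-scale marker scenes
displaced by known 2D deformations, and piecewise-linear toe/linear
stress-strain traces.

Randomness: each generator takes one integer seed driving a single
``numpy.random.Generator``.  Stream order for :func:`generate_fiber_volume`
is fixed and documented there; identical specs with identical seeds produce
bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .volume_io import ImageVolume

__all__ = [
    "FiberPhantomSpec",
    "GroundTruth",
    "sample_fiber_axes",
    "generate_fiber_volume",
    "warp_ground_truth_axes",
    "generate_macro_scene",
    "generate_stress_strain",
    "save_ground_truth",
]


@dataclass(frozen=True)
class FiberPhantomSpec:
    """Parameters of a fibrous two-channel phantom volume.

    ``concentration`` is the kappa of an axially symmetric (von Mises-Fisher
    antipodally symmetrized) orientation distribution about ``mean_axis``:
    0 gives isotropic axes, ``numpy.inf`` pins every fiber to the mean axis.
    ``fiber_radius`` is the Gaussian radial scale expressed as the radius at
    which intensity has fallen to exp(-2) of the peak (sigma = radius / 2).
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    voxel_size: tuple[float, float, float] = (1.144, 1.144, 1.0)
    n_fibers: int = 200
    mean_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    concentration: float = 8.0
    fiber_radius: float = 2.5
    fiber_intensity: float = 100.0
    tpef_fraction: float = 0.3
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.concentration < 0:
            raise ValueError("concentration (kappa) must be >= 0")
        if self.fiber_radius <= 0:
            raise ValueError("fiber_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        axis = np.asarray(self.mean_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not norm > 0:
            raise ValueError("mean_axis must be nonzero")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "mean_axis", tuple(axis / norm))


@dataclass
class GroundTruth:
    """True fiber geometry behind a phantom volume.

    ``voxel_axis_map`` holds, per voxel, the axis of the fiber contributing
    the most intensity there (NaN where no fiber reaches the voxel);
    ``applied_F`` is identity unless the volume was warped.
    """

    fiber_axes: np.ndarray  # (n_fibers, 3) unit vectors
    voxel_axis_map: np.ndarray  # (nx, ny, nz, 3), NaN outside fibers
    applied_F: np.ndarray = field(default_factory=lambda: np.eye(3))


def sample_fiber_axes(
    n: int,
    mean_axis: Sequence[float],
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` unit axes from an axially symmetric distribution.

    Vectors are drawn from a von Mises-Fisher distribution on the sphere with
    concentration ``kappa`` about ``mean_axis`` and then antipodally
    symmetrized (each flipped with probability 1/2), because fibers are axes,
    not arrows.  ``kappa = 0`` yields the uniform axial distribution;
    ``kappa = inf`` is the degenerate fully aligned case.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mu = np.asarray(mean_axis, dtype=float)
    mu = mu / np.linalg.norm(mu)

    if math.isinf(kappa):
        v = np.tile(mu, (n, 1))
    else:
        u = rng.random(n)
        if kappa == 0:
            w = 2.0 * u - 1.0
        else:
            # inverse-CDF sampling of cos(angle) for the vMF on S^2
            w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
        w = np.clip(w, -1.0, 1.0)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        s = np.sqrt(np.maximum(0.0, 1.0 - w * w))
        # orthonormal frame about mu
        helper = np.array([0.0, 0.0, 1.0]) if abs(mu[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        t1 = np.cross(mu, helper)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(mu, t1)
        v = (
            w[:, None] * mu[None, :]
            + (s * np.cos(phi))[:, None] * t1[None, :]
            + (s * np.sin(phi))[:, None] * t2[None, :]
        )
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    v = v * signs[:, None]
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _voxel_coords_um(shape, voxel_size) -> np.ndarray:
    """Physical coordinates (um) of voxel centers, flattened to (N, 3)."""
    ax = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, voxel_size)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def generate_fiber_volume(
    spec: FiberPhantomSpec,
) -> tuple[ImageVolume, ImageVolume, GroundTruth]:
    """Render a two-channel fibrous phantom with recorded ground truth.

    Fibers are straight cylinders spanning the volume, rendered in physical
    micrometre coordinates (so the anisotropic voxel grid is honoured) with a
    Gaussian radial intensity profile; fiber contributions add.  The TPEF
    channel is ``tpef_fraction`` times the SHG fiber signal.  Additive
    Gaussian noise (independent per channel) is clipped at zero.

    Stream order on the seeded generator: (1) fiber axes, (2) fiber anchor
    points, (3) SHG noise, (4) TPEF noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    axes = sample_fiber_axes(spec.n_fibers, spec.mean_axis, spec.concentration, rng)

    extent = np.array([n * s for n, s in zip(shape, spec.voxel_size)])
    centers = rng.random((spec.n_fibers, 3)) * extent[None, :]

    pts = _voxel_coords_um(shape, spec.voxel_size)
    pts_sq = np.einsum("ij,ij->i", pts, pts)

    sigma = spec.fiber_radius / 2.0
    cutoff_sq = (4.0 * sigma) ** 2
    inv_two_sigma_sq = 1.0 / (2.0 * sigma * sigma)

    signal = np.zeros(pts.shape[0], dtype=np.float64)
    best = np.zeros(pts.shape[0], dtype=np.float64)
    best_idx = np.full(pts.shape[0], -1, dtype=np.int32)

    for i in range(spec.n_fibers):
        c = centers[i]
        v = axes[i]
        t = pts @ v - c @ v
        d_sq = pts_sq - 2.0 * (pts @ c) + c @ c - t * t
        near = d_sq < cutoff_sq
        contrib = np.zeros_like(signal)
        contrib[near] = spec.fiber_intensity * np.exp(-d_sq[near] * inv_two_sigma_sq)
        signal += contrib
        stronger = contrib > best
        best[stronger] = contrib[stronger]
        best_idx[stronger] = i

    # dominant-fiber axis map; NaN where no fiber contributes meaningfully
    floor = spec.fiber_intensity * np.exp(-2.0)  # intensity at d = fiber_radius
    axis_map = np.full((pts.shape[0], 3), np.nan)
    inside = best >= floor
    axis_map[inside] = axes[best_idx[inside]]

    shg = signal.copy()
    tpef = spec.tpef_fraction * signal
    if spec.noise_sd > 0:
        shg = shg + rng.normal(0.0, spec.noise_sd, shg.shape)
        tpef = tpef + rng.normal(0.0, spec.noise_sd, tpef.shape)
    shg = np.clip(shg, 0.0, None).reshape(shape).astype(np.float32)
    tpef = np.clip(tpef, 0.0, None).reshape(shape).astype(np.float32)

    truth = GroundTruth(
        fiber_axes=axes,
        voxel_axis_map=axis_map.reshape(shape + (3,)),
        applied_F=np.eye(3),
    )
    shg_vol = ImageVolume(shg, spec.voxel_size, channel="SHG")
    tpef_vol = ImageVolume(tpef, spec.voxel_size, channel="TPEF")
    return shg_vol, tpef_vol, truth


def warp_ground_truth_axes(truth: GroundTruth | np.ndarray, F: np.ndarray) -> np.ndarray:
    """Affinely reorient fiber axes: each axis ``v`` becomes ``F v / |F v|``.

    This is the analytic oracle for the affine fiber-kinematics comparison.
    Accepts either a :class:`GroundTruth` or a raw ``(n, 3)`` axis array.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be 3x3")
    if np.linalg.det(F) <= 0:
        raise ValueError("F must have positive determinant")
    axes = truth.fiber_axes if isinstance(truth, GroundTruth) else np.asarray(truth, dtype=float)
    warped = axes @ F.T
    norms = np.linalg.norm(warped, axis=-1, keepdims=True)
    return warped / norms


def generate_macro_scene(
    marker_positions_mm: Sequence[Sequence[float]],
    F2d_sequence: Sequence[np.ndarray],
    image_scale: float = 0.02,
    dot_radius: float = 0.15,
    seed: int = 0,
    image_shape: tuple[int, int] | None = None,
    background: float = 0.85,
    dot_intensity: float = 0.1,
    noise_sd: float = 0.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Render a time series of macro images with fiduciary dots under known 2D
    deformations.

    Frame ``i`` places each dot at ``c + F_i (x0 - c)`` where ``c`` is the
    centroid of the reference markers; dark dots are drawn with a 1-pixel
    anti-aliased edge on a light background so their pixel centre of mass
    recovers the true position to well under a quarter pixel.

    Returns ``(frames, true_positions)`` with ``true_positions`` of shape
    ``(n_frames, n_markers, 2)`` in pixels, axis order (x, y) = image indices
    (row, col).
    """
    markers = np.asarray(marker_positions_mm, dtype=float)
    if markers.ndim != 2 or markers.shape[1] != 2 or markers.shape[0] < 4:
        raise ValueError("need at least 4 markers as (n, 2) mm coordinates")
    centered = markers - markers.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("markers are collinear")
    rng = np.random.default_rng(seed)

    centroid = markers.mean(axis=0)
    frames_pos = []
    for F in F2d_sequence:
        F = np.asarray(F, dtype=float)
        if F.shape != (2, 2):
            raise ValueError("each frame deformation must be 2x2")
        frames_pos.append(centroid + (markers - centroid) @ F.T)
    pos_mm = np.stack(frames_pos)  # (n_frames, n_markers, 2)

    r_px = dot_radius / image_scale
    pos_px = pos_mm / image_scale

    for fp in pos_mm:
        d = np.linalg.norm(fp[:, None, :] - fp[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 2.0 * dot_radius:
            raise ValueError("dots overlap under the requested deformation")

    if image_shape is None:
        hi = pos_px.reshape(-1, 2).max(axis=0)
        margin = int(np.ceil(4 * r_px + 8))
        image_shape = (int(np.ceil(hi[0])) + margin, int(np.ceil(hi[1])) + margin)
    nx, ny = image_shape
    gx = np.arange(nx, dtype=float)
    gy = np.arange(ny, dtype=float)

    frames = []
    for fi in range(pos_px.shape[0]):
        img = np.full(image_shape, background, dtype=np.float64)
        for (px, py) in pos_px[fi]:
            d = np.hypot(gx[:, None] - px, gy[None, :] - py)
            coverage = np.clip(r_px + 0.5 - d, 0.0, 1.0)  # anti-aliased disk edge
            img -= (background - dot_intensity) * coverage
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames.append(np.clip(img, 0.0, 1.0))
    return frames, pos_px


def generate_stress_strain(
    E_toe: float,
    E_linear: float,
    transition_strain: float,
    strain_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear stress-strain trace: slope ``E_toe`` below the
    transition strain, ``E_linear`` above, continuous at the knee, plus
    optional Gaussian noise on stress.

    Emulates the toe-to-linear transition of collagenous tissue under
    uniaxial tension.  Returns ``(strain, stress)`` arrays (stress in the
    units of the moduli).
    """
    if not (0 < E_toe < E_linear):
        raise ValueError("require 0 < E_toe < E_linear")
    strain = np.asarray(strain_grid, dtype=float)
    if strain.ndim != 1 or strain.size < 2 or np.any(np.diff(strain) <= 0):
        raise ValueError("strain_grid must be strictly increasing")
    stress = E_toe * np.minimum(strain, transition_strain) + E_linear * np.maximum(
        strain - transition_strain, 0.0
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, stress.shape)
    return strain, stress


def save_ground_truth(truth: GroundTruth, spec: FiberPhantomSpec, path: str | Path) -> None:
    """Write fiber axes, applied F, seed, and a spec echo as JSON (the
    per-voxel axis map is omitted — regenerate it from the spec)."""
    payload = {
        "spec": asdict(spec),
        "seed": spec.seed,
        "fiber_axes": np.asarray(truth.fiber_axes).tolist(),
        "applied_F": np.asarray(truth.applied_F).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
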
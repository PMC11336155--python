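"""Volume registration and feature/marker tracking across load increments.

Micro-scale: 3D SHG feature patches (default 20 x 20 x 5 voxels, shallow in z
to match the anisotropic point-spread function) are detected with a 3D
corner score and tracked increment-to-increment by normalized
cross-correlation over a local search window (default 20 x 20 x 20), with
sub-voxel refinement by a quadratic fit around the integer correlation peak.
Tracking quality is self-assessed by forward-backward consistency: each
increment's position is tracked back to the previous increment (incremental
error), and after the final increment the features are tracked backward all
the way to the reference (overall error).  A feature is well-tracked iff
every incremental error is < 10 voxels and the overall error is < 1 voxel
(both strict).

Macro-scale: fiduciary dots in the wide-field image series are tracked by
2D normalized cross-correlation with the same sub-pixel refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.feature import match_template, structure_tensor
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation

from .volume_io import ImageVolume

__all__ = [
    "FeatureTrack",
    "MarkerTrack",
    "register_translation",
    "detect_features",
    "track_increment",
    "track_features",
    "forward_backward_gate",
    "detect_markers",
    "track_macro_markers",
    "DEFAULT_PATCH",
    "DEFAULT_SEARCH",
]

DEFAULT_PATCH = (20, 20, 5)
DEFAULT_SEARCH = (20, 20, 20)

# strict upper bounds of the well-tracked gate, in voxels
MAX_INCREMENTAL_ERROR = 10.0
MAX_OVERALL_ERROR = 1.0


@dataclass
class FeatureTrack:
    """One feature's reference position, per-increment tracked positions, and
    forward-backward consistency errors (all in voxels)."""

    id: int
    ref_position: np.ndarray
    positions: np.ndarray  # (n_increments + 1, 3); row 0 = reference
    correlations: np.ndarray  # (n_increments,)
    incremental_errors: np.ndarray  # (n_increments,)
    overall_error: float = np.nan
    well_tracked: bool = False


@dataclass
class MarkerTrack:
    """One fiduciary dot's per-frame position in pixels (and mm when an image
    scale is given)."""

    id: int
    positions: np.ndarray  # (n_frames, 2)
    correlations: np.ndarray  # (n_frames - 1,)
    lost: np.ndarray  # (n_frames - 1,) bool
    positions_mm: np.ndarray | None = None


def register_translation(
    ref: ImageVolume | np.ndarray,
    moving: ImageVolume | np.ndarray,
    upsample_factor: int = 1,
) -> np.ndarray:
    """Translation of ``moving`` relative to ``ref`` by 3D phase correlation.

    Returns the shift ``s`` such that ``moving`` equals ``ref`` displaced by
    ``s`` voxels (so shifting ``moving`` by ``-s`` aligns it to ``ref``).
    Integer by default; pass ``upsample_factor > 1`` for sub-voxel estimates.
    """
    a = ref.data if isinstance(ref, ImageVolume) else np.asarray(ref)
    b = moving.data if isinstance(moving, ImageVolume) else np.asarray(moving)
    if a.shape != b.shape:
        raise ValueError("volumes must have equal shapes")
    if not a.any() or not b.any():
        raise ValueError("phase correlation undefined for an all-zero volume")
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample_factor)
    # phase_cross_correlation returns the shift registering moving onto ref,
    # i.e. -displacement; report the displacement of moving relative to ref
    return -np.asarray(shift, dtype=float)


def _required_margin(patch, search) -> np.ndarray:
    patch = np.asarray(patch)
    search = np.asarray(search)
    return patch // 2 + search // 2 + 2


def detect_features(
    vol: ImageVolume,
    mask: np.ndarray | None = None,
    n_max: int = 100,
    min_spacing: float = 10.0,
    patch: Sequence[int] = DEFAULT_PATCH,
    search: Sequence[int] = DEFAULT_SEARCH,
    sigma: float = 1.5,
) -> np.ndarray:
    """Detect trackable SHG features as 3D corners.

    Cornerness is the minimum eigenvalue of the local structure tensor
    (Shi-Tomasi extended to 3D).  Local maxima are kept inside ``mask``,
    far enough from the border to fit the tracking patch and search window,
    and greedily non-max-suppressed at ``min_spacing`` voxels.  Ordering is
    deterministic: score descending, ties by lexicographic position.

    Returns an ``(n, 3)`` integer array of centers (possibly empty).
    """
    data = np.asarray(vol.data, dtype=np.float64)
    tensors = structure_tensor(data, sigma=sigma, order="rc")
    # upper-triangle components in row-major order: xx, xy, xz, yy, yz, zz
    T = np.empty(data.shape + (3, 3))
    idx = 0
    for a in range(3):
        for b in range(a, 3):
            T[..., a, b] = tensors[idx]
            T[..., b, a] = tensors[idx]
            idx += 1
    corner = np.linalg.eigvalsh(T)[..., 0]  # smallest eigenvalue

    margin = _required_margin(patch, search)
    score = corner.copy()
    for ax, m in enumerate(margin):
        sl = [slice(None)] * 3
        sl[ax] = slice(0, m)
        score[tuple(sl)] = 0.0
        sl[ax] = slice(data.shape[ax] - m, None)
        score[tuple(sl)] = 0.0
    if mask is not None:
        score[~np.asarray(mask, dtype=bool)] = 0.0

    from scipy.ndimage import maximum_filter

    peaks = (score > 0) & (score == maximum_filter(score, size=3, mode="constant"))
    coords = np.argwhere(peaks)
    if coords.size == 0:
        return np.empty((0, 3), dtype=int)
    values = score[tuple(coords.T)]
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -values))
    coords = coords[order]

    accepted: list[np.ndarray] = []
    for c in coords:
        if len(accepted) >= n_max:
            break
        if accepted and np.min(np.linalg.norm(np.array(accepted) - c, axis=1)) < min_spacing:
            continue
        accepted.append(c)
    return np.array(accepted, dtype=int) if accepted else np.empty((0, 3), dtype=int)


def _quadratic_offset(m_minus: float, m0: float, m_plus: float) -> float:
    denom = m_minus - 2.0 * m0 + m_plus
    if denom >= 0:  # not a local max along this axis; no refinement
        return 0.0
    return float(np.clip(0.5 * (m_minus - m_plus) / denom, -1.0, 1.0))


def _paraboloid_offset(ncc: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Sub-voxel offset of an NCC peak by least-squares paraboloid fit over
    the full 3x3x3 neighbourhood (falls back to separable 1D quadratic fits
    at map borders or for a non-concave fit).

    A peak of exactly 1 means the patches are identical (Cauchy-Schwarz), so
    the displacement is exactly the integer peak and no refinement applies.
    """
    ndim = ncc.ndim
    if ncc[tuple(k)] >= 1.0 - 1e-9:
        return np.zeros(ndim)
    if all(0 < k[a] < ncc.shape[a] - 1 for a in range(ndim)):
        sl = tuple(slice(k[a] - 1, k[a] + 2) for a in range(ndim))
        vals = ncc[sl].ravel()
        grid = np.stack(
            np.meshgrid(*([np.arange(-1.0, 2.0)] * ndim), indexing="ij"), axis=-1
        ).reshape(-1, ndim)
        cols = [np.ones(len(grid))]
        cols += [grid[:, a] for a in range(ndim)]
        cols += [grid[:, a] * grid[:, b] for a in range(ndim) for b in range(a, ndim)]
        A = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
        b = coef[1 : 1 + ndim]
        H = np.zeros((ndim, ndim))
        i = 1 + ndim
        for a in range(ndim):
            for bb in range(a, ndim):
                if a == bb:
                    H[a, a] = 2.0 * coef[i]
                else:
                    H[a, bb] = H[bb, a] = coef[i]
                i += 1
        if np.all(np.linalg.eigvalsh(H) < 0):
            delta = -np.linalg.solve(H, b)
            if np.all(np.abs(delta) <= 1.0):
                return delta
    delta = np.zeros(ndim)
    peak = float(ncc[tuple(k)])
    for ax in range(ndim):
        if 0 < k[ax] < ncc.shape[ax] - 1:
            km = k.copy()
            km[ax] -= 1
            kp = k.copy()
            kp[ax] += 1
            delta[ax] = _quadratic_offset(float(ncc[tuple(km)]), peak, float(ncc[tuple(kp)]))
    return delta


def track_increment(
    ref_center: Sequence[float],
    ref_vol: ImageVolume | np.ndarray,
    target_vol: ImageVolume | np.ndarray,
    patch: Sequence[int] = DEFAULT_PATCH,
    search: Sequence[int] = DEFAULT_SEARCH,
    start: Sequence[float] | None = None,
    subvoxel: bool = True,
) -> tuple[np.ndarray, float]:
    """Track one feature from ``ref_vol`` into ``target_vol`` by NCC.

    The template is the ``patch`` around ``ref_center`` (rounded to the
    voxel grid); it is matched over a ``search`` window centred at ``start``
    (default: ``ref_center``) in the target.  Returns ``(new_center, peak
    correlation)``; the new centre carries sub-voxel precision when
    ``subvoxel`` and preserves the fractional part of ``ref_center``.

    Raises ``ValueError`` for a flat (zero-variance) template or when the
    windows do not fit inside the volumes.
    """
    ref = ref_vol.data if isinstance(ref_vol, ImageVolume) else np.asarray(ref_vol)
    tgt = target_vol.data if isinstance(target_vol, ImageVolume) else np.asarray(target_vol)
    patch = np.asarray(patch, dtype=int)
    search = np.asarray(search, dtype=int)
    c = np.asarray(ref_center, dtype=float)
    ci = np.round(c).astype(int)
    ph = patch // 2

    rs = ci - ph
    if np.any(rs < 0) or np.any(rs + patch > np.array(ref.shape)):
        raise ValueError(f"template patch around {c} does not fit in the reference volume")
    tpl = ref[tuple(slice(s, s + p) for s, p in zip(rs, patch))].astype(np.float64)
    if tpl.std() == 0:
        raise ValueError("flat template patch: feature is untrackable")

    s0 = np.asarray(start if start is not None else c, dtype=float)
    si = np.round(s0).astype(int)
    sh = search // 2
    region_start = si - ph - sh
    region_size = patch + search
    lo = np.maximum(region_start, 0)
    hi = np.minimum(region_start + region_size, np.array(tgt.shape))
    if np.any(hi - lo < patch):
        raise ValueError("search window does not fit in the target volume")
    region = tgt[tuple(slice(a, b) for a, b in zip(lo, hi))].astype(np.float64)

    ncc = match_template(region, tpl)
    k = np.array(np.unravel_index(np.argmax(ncc), ncc.shape))
    peak = float(ncc[tuple(k)])

    delta = _paraboloid_offset(ncc, k) if subvoxel else np.zeros(3)
    new_center = lo + k + ph + delta + (c - ci)
    return new_center, peak


def track_features(
    volumes: Sequence[ImageVolume],
    features: np.ndarray,
    patch: Sequence[int] = DEFAULT_PATCH,
    search: Sequence[int] = DEFAULT_SEARCH,
    subvoxel: bool = True,
) -> list[FeatureTrack]:
    """Track features through a registered volume sequence and compute the
    forward-backward error criteria.

    Forward pass: the template for increment ``i`` is taken from volume
    ``i - 1`` at the previous position (incremental tracking).  Incremental
    error at ``i``: the feature at its tracked position in volume ``i`` is
    tracked back into volume ``i - 1`` and compared with the stored position
    there.  Overall error: after the final increment ``n`` a fresh template
    is taken at the final position in volume ``n`` and tracked backward
    through every increment; the distance between the arrival point and the
    reference position is the overall error.

    Features whose windows fall outside a volume or go flat are dropped.
    Call :func:`forward_backward_gate` on the result to apply the
    well-tracked criterion.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need a reference volume and at least one increment")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n_inc = len(volumes) - 1
    tracks: list[FeatureTrack] = []
    for fid, ref_pos in enumerate(features):
        positions = np.zeros((n_inc + 1, 3))
        positions[0] = ref_pos
        corrs = np.zeros(n_inc)
        inc_err = np.zeros(n_inc)
        try:
            for i in range(1, n_inc + 1):
                positions[i], corrs[i - 1] = track_increment(
                    positions[i - 1], volumes[i - 1], volumes[i],
                    patch=patch, search=search, subvoxel=subvoxel,
                )
                back, _ = track_increment(
                    positions[i], volumes[i], volumes[i - 1],
                    patch=patch, search=search, subvoxel=subvoxel,
                )
                inc_err[i - 1] = float(np.linalg.norm(back - positions[i - 1]))
            # backward pass from a template regenerated at the final position
            bpos = positions[n_inc].copy()
            for i in range(n_inc, 0, -1):
                bpos, _ = track_increment(
                    bpos, volumes[i], volumes[i - 1],
                    patch=patch, search=search, subvoxel=subvoxel,
                )
            overall = float(np.linalg.norm(bpos - positions[0]))
        except ValueError:
            continue  # window left the volume or template went flat
        tracks.append(
            FeatureTrack(
                id=fid,
                ref_position=ref_pos.copy(),
                positions=positions,
                correlations=corrs,
                incremental_errors=inc_err,
                overall_error=overall,
            )
        )
    return tracks


def forward_backward_gate(
    tracks: Sequence[FeatureTrack],
    max_incremental: float = MAX_INCREMENTAL_ERROR,
    max_overall: float = MAX_OVERALL_ERROR,
) -> list[FeatureTrack]:
    """Apply the well-tracked criterion (strict bounds: every incremental
    error < ``max_incremental`` voxels and overall error < ``max_overall``)
    and return only the passing tracks.  Idempotent."""
    passed = []
    for t in tracks:
        t.well_tracked = bool(
            np.all(np.asarray(t.incremental_errors) < max_incremental)
            and t.overall_error < max_overall
        )
        if t.well_tracked:
            passed.append(t)
    return passed


def detect_markers(frame: np.ndarray, min_area: int = 9) -> np.ndarray:
    """Detect dark fiduciary dots in a macro frame as centroids of
    below-Otsu-threshold blobs, ordered lexicographically."""
    from skimage.filters import threshold_otsu

    frame = np.asarray(frame, dtype=np.float64)
    thr = threshold_otsu(frame)
    lab = label(frame < thr)
    cents = [r.centroid for r in regionprops(lab) if r.area >= min_area]
    if not cents:
        return np.empty((0, 2))
    cents = np.array(sorted(cents))
    return cents


def track_macro_markers(
    frames: Sequence[np.ndarray],
    template_radius: int = 10,
    search_radius: int = 12,
    initial_positions: np.ndarray | None = None,
    image_scale: float | None = None,
    corr_floor: float = 0.5,
) -> list[MarkerTrack]:
    """Track fiduciary dots through a macro image series by 2D NCC.

    Markers are auto-seeded from frame 0 (dark-blob detection) unless
    ``initial_positions`` is given; at least 4 are required.  Each frame's
    template is the square patch (half-size ``template_radius``) around the
    marker's previous position, matched within ``search_radius`` and refined
    to sub-pixel by a quadratic peak fit.  A correlation below
    ``corr_floor`` flags the marker as lost at that step (the best-match
    position is still recorded, never silently dropped).
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    if initial_positions is None:
        initial_positions = detect_markers(frames[0])
    pos0 = np.atleast_2d(np.asarray(initial_positions, dtype=float))
    if pos0.shape[0] < 4:
        raise ValueError(f"need >= 4 markers, found {pos0.shape[0]}")

    n_frames = len(frames)
    tsize = np.array([2 * template_radius + 1] * 2)
    ssize = np.array([2 * search_radius] * 2)
    tracks = []
    for mid, p0 in enumerate(pos0):
        positions = np.zeros((n_frames, 2))
        positions[0] = p0
        corrs = np.zeros(max(n_frames - 1, 0))
        lost = np.zeros(max(n_frames - 1, 0), dtype=bool)
        for i in range(1, n_frames):
            prev3 = positions[i - 1]
            new, peak = _track_increment_2d(
                prev3, frames[i - 1], frames[i], tsize, ssize
            )
            positions[i] = new
            corrs[i - 1] = peak
            lost[i - 1] = peak < corr_floor
        tracks.append(
            MarkerTrack(
                id=mid,
                positions=positions,
                correlations=corrs,
                lost=lost,
                positions_mm=positions * image_scale if image_scale else None,
            )
        )
    return tracks


def _track_increment_2d(center, ref, tgt, patch, search):
    """2D analogue of :func:`track_increment` (used for macro markers)."""
    patch = np.asarray(patch, dtype=int)
    search = np.asarray(search, dtype=int)
    c = np.asarray(center, dtype=float)
    ci = np.round(c).astype(int)
    ph = patch // 2
    rs = ci - ph
    if np.any(rs < 0) or np.any(rs + patch > np.array(ref.shape)):
        raise ValueError("marker template does not fit in the frame")
    tpl = ref[tuple(slice(s, s + p) for s, p in zip(rs, patch))]
    if tpl.std() == 0:
        raise ValueError("flat marker template")
    sh = search // 2
    region_start = ci - ph - sh
    region_size = patch + search
    lo = np.maximum(region_start, 0)
    hi = np.minimum(region_start + region_size, np.array(tgt.shape))
    if np.any(hi - lo < patch):
        raise ValueError("marker search window does not fit in the frame")
    region = tgt[tuple(slice(a, b) for a, b in zip(lo, hi))]
    ncc = match_template(region, tpl)
    k = np.array(np.unravel_index(np.argmax(ncc), ncc.shape))
    peak = float(ncc[tuple(k)])
    delta = _paraboloid_offset(ncc, k)
    return lo + k + ph + delta + (c - ci), peak
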
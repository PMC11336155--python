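"""Deformation gradients, Green strain, incremental mechanics, and the
stretch-landmark tabulation.

Macro scale: the 2D deformation gradient F comes from an isoparametric
(bilinear quad) mapping of tracked fiduciary-marker positions, evaluated at
the element centroid (least-squares affine fit when more than four markers
are available).  Loads at static equilibrium divided by the undeformed
cross-sectional area give engineering stress; the incremental Young's
modulus is the backward difference

    E_i = (sigma_i - sigma_{i-1}) / (eps_xx,i - eps_xx,i-1)

and the incremental Poisson's ratio nu_i = -eps_yy,i / eps_xx,i, both from
the macro Green strain.

Micro scale: the largest tetrahedron formed by well-tracked SHG features
carries a 3D deformation gradient solved from its edge vectors, from which
the Green strain eps = (F^T F - I)/2, principal strains, and the volume
ratio V/V0 = det F follow.

Scalars are tabulated at three stretch landmarks: 10% and 20% eps_xx
(linearly interpolated between bracketing increments) and the increment of
maximum incremental modulus, which typically directly precedes failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DeformationState",
    "MechanicalRecord",
    "isoparametric_F2d",
    "green_strain",
    "deformation_state",
    "mechanics_curve",
    "largest_tetrahedron",
    "tetra_F3d",
    "landmark_value",
    "tabulate_landmarks",
]


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient with its derived strain quantities at one
    increment and scale ('macro-2D' or 'micro-3D')."""

    scale: str
    F: np.ndarray
    green: np.ndarray
    principal_values: np.ndarray  # descending
    principal_directions: np.ndarray  # columns, matching order
    volume_ratio: float | None = None  # det(F), 3D only


@dataclass(frozen=True)
class MechanicalRecord:
    """Per-increment mechanical state of the uniaxial test."""

    increment: int
    displacement: float | None
    load: float
    stress: float  # Pa, engineering
    eps_xx: float
    eps_yy: float
    modulus: float  # Pa; NaN at increment 0 or where undefined
    poisson: float  # dimensionless; NaN where undefined
    modulus_defined: bool = True


def green_strain(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Green strain eps = (F^T F - I)/2 with its principal decomposition.

    Returns ``(eps, principal_values, principal_directions)`` with
    eigenvalues descending and unit eigenvector columns.  Objective: a pure
    rotation gives exactly zero strain.
    """
    F = np.asarray(F, dtype=float)
    if F.shape not in ((2, 2), (3, 3)):
        raise ValueError("F must be 2x2 or 3x3")
    eps = 0.5 * (F.T @ F - np.eye(F.shape[0]))
    eps = 0.5 * (eps + eps.T)  # enforce exact symmetry
    vals, vecs = np.linalg.eigh(eps)
    order = np.argsort(vals)[::-1]
    return eps, vals[order], vecs[:, order]


def deformation_state(F: np.ndarray, scale: str) -> DeformationState:
    eps, vals, vecs = green_strain(F)
    F = np.asarray(F, dtype=float)
    vol = float(np.linalg.det(F)) if F.shape == (3, 3) else None
    return DeformationState(
        scale=scale, F=F, green=eps, principal_values=vals,
        principal_directions=vecs, volume_ratio=vol,
    )


def _order_quad(points: np.ndarray) -> np.ndarray:
    """Index order walking the four points counter-clockwise about their
    centroid (a valid, non-crossed quad node ordering)."""
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    return np.argsort(ang)


def isoparametric_F2d(ref_markers: np.ndarray, def_markers: np.ndarray) -> np.ndarray:
    """2D deformation gradient from corresponding marker positions.

    With exactly four markers they are taken as the nodes of a bilinear
    (4-node isoparametric quad) element, ordered counter-clockwise about the
    reference centroid, and F is evaluated at the element centroid
    (xi = eta = 0); the bilinear map reproduces any affine deformation
    exactly.  With more than four markers a least-squares affine fit of the
    centred positions is used.
    """
    X = np.asarray(ref_markers, dtype=float)
    x = np.asarray(def_markers, dtype=float)
    if X.shape != x.shape or X.ndim != 2 or X.shape[1] != 2 or X.shape[0] < 4:
        raise ValueError("need matching (n >= 4, 2) reference and deformed marker arrays")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc, tol=1e-12 * max(1.0, np.abs(Xc).max())) < 2:
        raise ValueError("markers are collinear; element is degenerate")

    if X.shape[0] == 4:
        order = _order_quad(X)
        Xo, xo = X[order], x[order]
        # node natural coordinates for CCW order
        nat = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
        # shape-function gradients at the centroid: dN_a/dxi = xi_a/4, etc.
        dN = nat / 4.0  # (4, 2)
        J_ref = Xo.T @ dN  # dX/dxi (2x2)
        J_def = xo.T @ dN
        if abs(np.linalg.det(J_ref)) < 1e-12:
            raise ValueError("degenerate reference element")
        return J_def @ np.linalg.inv(J_ref)

    xc = x - x.mean(axis=0)
    A, *_ = np.linalg.lstsq(Xc, xc, rcond=None)
    return A.T


def mechanics_curve(
    loads: Sequence[float],
    area0: float,
    macro_strains: Sequence[np.ndarray],
    displacements: Sequence[float] | None = None,
) -> list[MechanicalRecord]:
    """Per-increment stress, strain, incremental modulus and Poisson's ratio.

    ``loads`` are in newtons at static equilibrium, ``area0`` the optically
    measured undeformed cross-sectional area in m^2, ``macro_strains`` the
    per-increment 2D Green strain tensors (x = loading direction).  The
    reference (increment 0) is the pre-stressed imaging configuration, where
    strain is zero by definition.  A zero strain increment leaves that
    increment's modulus undefined (NaN, flagged), never +/-inf.
    """
    if area0 <= 0:
        raise ValueError("area0 must be positive")
    loads = np.asarray(loads, dtype=float)
    n = loads.size
    if len(macro_strains) != n:
        raise ValueError("loads and strains must have equal length")
    eps_xx = np.array([np.asarray(e)[0, 0] for e in macro_strains], dtype=float)
    eps_yy = np.array([np.asarray(e)[1, 1] for e in macro_strains], dtype=float)
    stress = loads / area0
    records = []
    for i in range(n):
        if i == 0:
            E, ok = np.nan, False
        else:
            d_eps = eps_xx[i] - eps_xx[i - 1]
            if d_eps == 0:
                E, ok = np.nan, False
            else:
                E, ok = (stress[i] - stress[i - 1]) / d_eps, True
        nu = -eps_yy[i] / eps_xx[i] if eps_xx[i] != 0 else np.nan
        records.append(
            MechanicalRecord(
                increment=i,
                displacement=None if displacements is None else float(displacements[i]),
                load=float(loads[i]),
                stress=float(stress[i]),
                eps_xx=float(eps_xx[i]),
                eps_yy=float(eps_yy[i]),
                modulus=float(E),
                poisson=float(nu),
                modulus_defined=ok,
            )
        )
    return records


def _tetra_volumes(points: np.ndarray, quads: np.ndarray) -> np.ndarray:
    p = points[quads]  # (m, 4, 3)
    e = p[:, 1:] - p[:, :1]  # (m, 3, 3)
    return np.abs(np.linalg.det(e)) / 6.0


def largest_tetrahedron(points: np.ndarray, exhaustive_limit: int = 25) -> tuple[int, int, int, int]:
    """Indices of the 4-point subset with maximal tetrahedron volume.

    Exhaustive C(n, 4) enumeration for ``n <= exhaustive_limit``; above that
    the search is restricted to the convex hull's vertices (the maximal
    tetrahedron's vertices are extreme points, so this loses nothing).
    Ties resolve to the first subset in lexicographic index order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need at least 4 points of dimension 3")
    n = pts.shape[0]
    if n <= exhaustive_limit:
        cand = np.arange(n)
    else:
        from scipy.spatial import ConvexHull, QhullError

        try:
            cand = np.sort(np.unique(ConvexHull(pts).vertices))
        except QhullError as exc:  # coplanar cloud
            raise ValueError("all points are coplanar") from exc
    quads = np.array(list(combinations(cand.tolist(), 4)), dtype=int)
    vols = _tetra_volumes(pts, quads)
    best = int(np.argmax(vols))
    if vols[best] <= 0:
        raise ValueError("every 4-point subset is coplanar")
    return tuple(int(i) for i in quads[best])


def tetra_F3d(ref_tetra: np.ndarray, def_tetra: np.ndarray) -> DeformationState:
    """3D deformation gradient from a tracked tetrahedron.

    F solves ``[d1 d2 d3] = F [r1 r2 r3]`` where the columns are edge
    vectors from vertex 0, so translation drops out by construction.
    Positions should be in consistent physical units; the attached Green
    strain, principal strains, and volume ratio det(F) follow.
    """
    R = np.asarray(ref_tetra, dtype=float)
    D = np.asarray(def_tetra, dtype=float)
    if R.shape != (4, 3) or D.shape != (4, 3):
        raise ValueError("tetrahedra must be (4, 3) arrays")
    Re = (R[1:] - R[0]).T
    De = (D[1:] - D[0]).T
    if abs(np.linalg.det(Re)) < 1e-12 * max(1.0, np.abs(Re).max()) ** 3:
        raise ValueError("reference tetrahedron is degenerate")
    F = De @ np.linalg.inv(Re)
    return deformation_state(F, scale="micro-3D")


def landmark_value(
    eps_xx: Sequence[float],
    values: Sequence[float],
    target: float,
    interpolate: bool = True,
) -> float | None:
    """Value of a per-increment scalar at the increment where eps_xx crosses
    ``target``: linearly interpolated between the bracketing increments, or
    taken from the nearest increment when ``interpolate`` is False (used for
    quantities that only exist at whole image volumes, like DV).

    Returns None when the landmark lies outside the observed strain range
    (never extrapolated).
    """
    e = np.asarray(eps_xx, dtype=float)
    y = np.asarray(values, dtype=float)
    if e.shape != y.shape:
        raise ValueError("eps_xx and values must have equal length")
    if np.any(np.diff(e) < 0):
        raise ValueError("eps_xx must be non-decreasing along the loading path")
    if target < e[0] or target > e[-1]:
        return None
    if not interpolate:
        return float(y[int(np.argmin(np.abs(e - target)))])
    return float(np.interp(target, e, y))


def tabulate_landmarks(
    records: Sequence[MechanicalRecord],
    eps_xx: Sequence[float] | None = None,
    scalars: Mapping[str, Sequence[float]] | None = None,
    nearest: Sequence[str] = ("dv", "dv_affine", "delta_dv"),
    targets: Sequence[float] = (0.10, 0.20),
) -> dict:
    """Tabulate scalar series at the stretch landmarks.

    ``eps_xx`` defaults to the macro strain from ``records``; pass the
    micro-scale Green strain when tabulating micro quantities (volume ratio,
    DV), per the convention that micro landmarks are defined on micro
    strain.  ``scalars`` maps a name to a per-increment series; names listed
    in ``nearest`` are taken from the nearest increment instead of being
    interpolated.  The max-E landmark is the increment of maximum defined
    incremental modulus (no interpolation).
    """
    if eps_xx is None:
        eps_xx = [r.eps_xx for r in records]
    e = np.asarray(eps_xx, dtype=float)
    scalars = dict(scalars or {})
    moduli = np.array([r.modulus for r in records], dtype=float)
    defined = np.array([r.modulus_defined for r in records], dtype=bool)
    out: dict = {"landmarks": {}}
    for target in targets:
        key = f"{target:.0%} eps_xx"
        vals = {
            name: landmark_value(e, series, target, interpolate=name not in nearest)
            for name, series in scalars.items()
        }
        out["landmarks"][key] = {"eps_xx": target if e.min() <= target <= e.max() else None, **vals}
    if np.any(defined):
        masked = np.where(defined, moduli, -np.inf)
        imax = int(np.argmax(masked))
        out["landmarks"]["max E"] = {
            "increment": imax,
            "eps_xx": float(e[imax]),
            "modulus": float(moduli[imax]),
            **{name: float(np.asarray(series, dtype=float)[imax]) for name, series in scalars.items()},
        }
    else:
        out["landmarks"]["max E"] = None
    return out
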
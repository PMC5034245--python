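"""Geometric relationships and state-to-state motions between fitted helices.

Interhelix angle and distance are properties of the two fitted axes.
State-to-state motion of one helix is decomposed into a winding change
ΔΩ, a torsional rotation about its own axis (change in the circular
mean of the four sub-helix phases) and a longitudinal, piston-like
sliding of the reference point along the axis.  Cross-state comparisons
require a rigid superposition of structure 2 onto structure 1, computed
on a caller-chosen reference selection and recorded alongside results;
phases of both states are expressed in a common frame built from the
state-1 axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from helixforge.model import (
    FitResult,
    build_basis,
    circular_mean_deg,
    generate_helix_coordinates,
)

__all__ = [
    "InterhelixGeometry",
    "MotionComponents",
    "RigidTransform",
    "superpose",
    "interhelix_geometry",
    "torsional_position",
    "relative_phase",
    "state_motion",
    "differential_winding",
]

#: axes closer than this to parallel are handled by point-to-line distance
PARALLEL_ANGLE_DEG = 0.1


def _wrap(angle: float) -> float:
    return float((angle + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class InterhelixGeometry:
    """Angle (degrees, [0, 180)) and closest-approach distance (Å) of two axes.

    ``clamped`` is set when the common perpendicular's feet fall outside
    the axial span of either fitted segment; the reported distance is
    then the closest approach between the finite axis segments.
    """

    angle: float
    distance: float
    clamped: bool


@dataclass(frozen=True)
class MotionComponents:
    """State-to-state motion of one helix (state 2 relative to state 1).

    delta_phase : torsional rotation about the helix axis, degrees,
        wrapped to [-180, 180).
    sliding : displacement of the reference point along the state-1
        axis, Å, positive toward the C-terminus.
    delta_omega : winding change, °/residue.
    relative_phase_ab : optional within-structure phase difference of a
        helix pair (filled by pair-level reports, None for single-helix
        records).
    """

    delta_phase: float
    sliding: float
    delta_omega: float
    relative_phase_ab: float | None = None


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    R: np.ndarray
    t: np.ndarray

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(R=np.eye(3), t=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.R.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``mobile`` onto ``reference``.

    Kabsch algorithm on paired points (shape (m, 3) each); returns a
    proper rotation (det R = +1) plus translation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose needs two equally-shaped (m, 3) point sets")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R=R, t=cr - R @ cm)


def _require_converged(*fits: FitResult) -> None:
    for f in fits:
        if not f.converged:
            raise ValueError(f"fit of segment {f.label or '?'} did not converge")


def _segment_endpoints(fit: FitResult) -> tuple[np.ndarray, np.ndarray]:
    zmin, zmax = fit.axial_extent
    P, n = fit.params.P, fit.params.n
    return P + zmin * n, P + zmax * n


def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Closest distance between 3D segments [p1,q1] and [p2,q2] (Ericson)."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    c, b = d1 @ r, d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-14 else 0.0
    t = (b * s + f) / e if e > 1e-14 else 0.0
    if t < 0.0 or t > 1.0:
        t = np.clip(t, 0.0, 1.0)
        s = np.clip((t * b - c) / a, 0.0, 1.0) if a > 1e-14 else 0.0
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def interhelix_geometry(fitA: FitResult, fitB: FitResult) -> InterhelixGeometry:
    """Angle and distance between the axes of two fitted helices.

    The angle is taken between the oriented (N→C) axes, in [0, 180).
    The distance is the length of the common perpendicular between the
    infinite axis lines; when its feet fall outside either fitted
    segment's axial span the distance between the finite segments is
    reported instead and ``clamped`` is set.  Nearly parallel axes
    (angle < 0.1°) use point-to-line distance.
    """
    _require_converged(fitA, fitB)
    nA, nB = fitA.params.n, fitB.params.n
    PA, PB = fitA.params.P, fitB.params.P
    cosang = float(np.clip(nA @ nB, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    if angle >= 180.0:
        angle = 0.0

    w = PB - PA
    if angle < PARALLEL_ANGLE_DEG or angle > 180.0 - PARALLEL_ANGLE_DEG:
        perp = w - (w @ nA) * nA
        distance = float(np.linalg.norm(perp))
        zB_on_A = [(p - PA) @ nA for p in _segment_endpoints(fitB)]
        lo, hi = fitA.axial_extent
        clamped = max(zB_on_A) < lo or min(zB_on_A) > hi
        if clamped:
            distance = _segment_segment_distance(
                *_segment_endpoints(fitA), *_segment_endpoints(fitB)
            )
        return InterhelixGeometry(angle=angle, distance=distance, clamped=clamped)

    # feet of the common perpendicular on the infinite lines
    b = float(nA @ nB)
    denom = 1.0 - b * b
    sA = float((w @ nA - b * (w @ nB)) / denom)
    sB = float(-((w @ nB) - b * (w @ nA)) / denom)
    distance = float(np.linalg.norm(PA + sA * nA - (PB + sB * nB)))
    loA, hiA = fitA.axial_extent
    loB, hiB = fitB.axial_extent
    clamped = not (loA <= sA <= hiA and loB <= sB <= hiB)
    if clamped:
        distance = _segment_segment_distance(
            *_segment_endpoints(fitA), *_segment_endpoints(fitB)
        )
    return InterhelixGeometry(angle=angle, distance=distance, clamped=clamped)


def torsional_position(fit: FitResult) -> float:
    """Circular mean of the four sub-helix phases, degrees in [-180, 180).

    The torsional position of a helix; its change between states is a
    torsion (axial rotation) of the helix.
    """
    _require_converged(fit)
    return fit.params.mean_phase


def relative_phase(fitA: FitResult, fitB: FitResult) -> float:
    """Within-structure torsional position of helix A minus helix B, degrees."""
    return _wrap(torsional_position(fitA) - torsional_position(fitB))


def _phases_in_frame(fit: FitResult, transform: RigidTransform, frame, axis):
    """Sub-helix phases of a (transformed) fit measured in a common frame.

    The radial vectors of the four sub-helices at residue index 0 are
    rotated by the superposition and projected onto the plane normal to
    the common axis.
    """
    p = fit.params
    own = build_basis(p.n)
    ang = np.radians(p.phases)
    radial = (
        p.radii[:, None] * np.cos(ang)[:, None] * own.a[None, :]
        + p.radii[:, None] * np.sin(ang)[:, None] * own.b[None, :]
    )
    radial = transform.rotate(radial)
    perp = radial - (radial @ axis)[:, None] * axis[None, :]
    return np.degrees(np.arctan2(perp @ frame.b, perp @ frame.a))


def state_motion(
    fit_state1: FitResult,
    fit_state2: FitResult,
    superposition: RigidTransform | None = None,
) -> MotionComponents:
    """Motion of one named helix between two structures.

    ``superposition`` is the rigid transform aligning structure 2 onto
    structure 1 (identity if omitted), computed by the caller on a
    reference selection of their choice.  State-2 axis and reference
    point are transformed into the state-1 frame; phases of both states
    are measured in the frame built from the state-1 axis.
    """
    if fit_state1.label != fit_state2.label:
        raise ValueError(
            f"segment label mismatch: {fit_state1.label!r} vs {fit_state2.label!r}"
        )
    _require_converged(fit_state1, fit_state2)
    if superposition is None:
        superposition = RigidTransform.identity()

    p1, p2 = fit_state1.params, fit_state2.params
    n1 = p1.n
    frame1 = build_basis(n1)
    P2 = superposition.apply(p2.P)

    phases1 = _phases_in_frame(fit_state1, RigidTransform.identity(), frame1, n1)
    phases2 = _phases_in_frame(fit_state2, superposition, frame1, n1)
    delta = _wrap(circular_mean_deg(phases2) - circular_mean_deg(phases1))
    sliding = float((P2 - p1.P) @ n1)
    return MotionComponents(
        delta_phase=delta,
        sliding=sliding,
        delta_omega=float(p2.omega - p1.omega),
    )


def differential_winding(fit_seg1: FitResult, fit_seg2: FitResult) -> float:
    """Winding difference Ω(segment 1) − Ω(segment 2), °/residue (signed)."""
    _require_converged(fit_seg1, fit_seg2)
    return float(fit_seg1.params.omega - fit_seg2.params.omega)


def reference_coordinates(fits: list[FitResult]) -> np.ndarray:
    """Model Cα coordinates of a list of fits, concatenated — a convenient
    reference selection for :func:`superpose`."""
    pts = [
        generate_helix_coordinates(f.params, None, f.residue_indices)[:, 1, :]
        for f in fits
    ]
    return np.vstack(pts)
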
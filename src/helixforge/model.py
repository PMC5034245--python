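"""Analytical four-sub-helix model of a straight protein helix.

A straight helix is described as the superposition of four coaxial
sub-helices traced by the backbone atoms N, Cα, C and O.  All four share
one axis (through reference point ``P`` with direction cosines ``n``),
one pitch ``s`` (Å per 360° revolution) and one angular turn per residue
``Ω`` (degrees).  Each sub-helix has its own radius ``r_A``, axial offset
``t_A`` (relative to the Cα sub-helix, whose offset is fixed at zero) and
phase ``φ_A``.  The Cartesian position of backbone atom A of residue
``i`` (``i = 0`` at the segment N-terminus) is

    x_A(i) = P + (i s Ω / 360 + t_A) n
             + r_A cos(i Ω + φ_A) a + r_A sin(i Ω + φ_A) b

with ``a``, ``b`` an orthonormal frame normal to ``n``; the axial rise
per residue is s·Ω/2π with Ω in radians.  Exactly 19 scalars are free in
a least-squares fit: P (3), n (3 direction cosines, normalized inside
the model), the four radii, s, Ω, three axial offsets and four phases.

Angles are degrees in every public interface; the optimizer works in
radians internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ATOM_TYPES",
    "HelixParameters",
    "BasisFrame",
    "FitResult",
    "DihedralPair",
    "build_basis",
    "generate_helix_coordinates",
    "fit_helix",
    "classify_helix_form",
    "omega_from_dihedrals",
    "dihedral_sum_from_omega",
    "residues_per_revolution",
]

logger = logging.getLogger(__name__)

#: backbone atom types, in the fixed column order used throughout
ATOM_TYPES = ("N", "CA", "C", "O")

_UNIT_TOL = 1e-9


def _wrap_deg(angle):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def circular_mean_deg(angles: Sequence[float]) -> float:
    """Circular mean of angles in degrees, wrapped to [-180, 180)."""
    a = np.radians(np.asarray(angles, dtype=float))
    m = np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return float(_wrap_deg(m))


@dataclass(frozen=True)
class BasisFrame:
    """Orthonormal frame (a, b) normal to a helix axis.

    ``c`` is the auxiliary vector used to construct the frame:
    a = normalize(n × c), b = n × a.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


def build_basis(n: np.ndarray) -> BasisFrame:
    """Deterministic orthonormal frame normal to unit axis ``n``.

    The auxiliary vector ``c`` is the global +z axis unless the axis is
    within ~25° of ±z (|n·z| > 0.9), in which case +x is used.  The same
    axis always yields the same frame.
    """
    n = np.asarray(n, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("axis vector has zero length")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"axis must be a unit vector (|n| = {norm:.6g})")
    n = n / norm
    if abs(n[2]) > 0.9:
        c = np.array([1.0, 0.0, 0.0])
    else:
        c = np.array([0.0, 0.0, 1.0])
    a = np.cross(n, c)
    a = a / np.linalg.norm(a)
    b = np.cross(n, a)
    return BasisFrame(a=a, b=b, c=c)


@dataclass(frozen=True)
class HelixParameters:
    """The 19 parameters of one straight helix (plus t_Ca fixed at 0).

    Attributes
    ----------
    P : (3,) array
        Reference point on the axis, Å.  In the canonical gauge it lies
        in the plane of the i = 0 Cα sub-helix position.
    n : (3,) array
        Unit axis direction cosines, oriented N-terminus → C-terminus.
    r_N, r_Ca, r_C, r_O : float
        Sub-helix radii, Å.
    s : float
        Pitch, Å per 360° revolution.
    omega : float
        Angular turn per residue Ω, degrees; positive for right-handed
        helices.
    t_N, t_C, t_O : float
        Axial offsets of the N, C, O sub-helices relative to Cα, Å.
    phi_N, phi_Ca, phi_C, phi_O : float
        Sub-helix phases at residue index 0, degrees, in the frame of
        :func:`build_basis`.
    """

    P: np.ndarray
    n: np.ndarray
    r_N: float
    r_Ca: float
    r_C: float
    r_O: float
    s: float
    omega: float
    t_N: float
    t_C: float
    t_O: float
    phi_N: float
    phi_Ca: float
    phi_C: float
    phi_O: float

    #: axial offset of the Cα sub-helix — the gauge reference, never free
    t_Ca: float = field(default=0.0, init=False)

    def __post_init__(self):
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))

    @property
    def radii(self) -> np.ndarray:
        """Radii in ATOM_TYPES order (N, Cα, C, O)."""
        return np.array([self.r_N, self.r_Ca, self.r_C, self.r_O])

    @property
    def offsets(self) -> np.ndarray:
        """Axial offsets in ATOM_TYPES order; t_Ca is identically 0."""
        return np.array([self.t_N, 0.0, self.t_C, self.t_O])

    @property
    def phases(self) -> np.ndarray:
        """Phases in ATOM_TYPES order, degrees."""
        return np.array([self.phi_N, self.phi_Ca, self.phi_C, self.phi_O])

    @property
    def diameter(self) -> float:
        """Overall helix diameter: twice the mean of the four radii, Å."""
        return float(2.0 * np.mean(self.radii))

    @property
    def mean_phase(self) -> float:
        """Circular mean of the four phases, degrees — the torsional position."""
        return circular_mean_deg(self.phases)

    @property
    def rise_per_residue(self) -> float:
        """Axial advance per residue, s·Ω/360, Å."""
        return self.s * self.omega / 360.0

    @property
    def residues_per_revolution(self) -> float:
        return residues_per_revolution(abs(self.omega))

    def validate(self) -> None:
        """Raise ValueError if the canonical invariants are violated."""
        if abs(np.linalg.norm(self.n) - 1.0) > _UNIT_TOL:
            raise ValueError("axis n is not a unit vector")
        if np.any(self.radii <= 0):
            raise ValueError("all sub-helix radii must be positive")
        if self.s <= 0:
            raise ValueError("pitch s must be positive")
        if not (0.0 < self.omega < 180.0):
            raise ValueError("omega must lie in (0, 180) degrees per residue")


def generate_helix_coordinates(
    params: HelixParameters,
    frame: BasisFrame | None = None,
    residue_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Backbone coordinates of the four-sub-helix model.

    Parameters
    ----------
    params : HelixParameters
    frame : BasisFrame, optional
        Frame for the phase origin; defaults to ``build_basis(params.n)``.
    residue_indices : sequence of int
        Strictly increasing residue indices (i = 0 at the segment
        N-terminus by convention).

    Returns
    -------
    (len(residue_indices), 4, 3) array
        Positions of N, Cα, C, O per residue, in ATOM_TYPES order.
    """
    if residue_indices is None:
        raise ValueError("residue_indices is required")
    idx = np.asarray(residue_indices, dtype=float)
    if idx.size == 0:
        raise ValueError("residue_indices must be non-empty")
    if idx.size > 1 and np.any(np.diff(idx) <= 0):
        raise ValueError("residue_indices must be strictly increasing")
    n = np.asarray(params.n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("params.n must be a unit vector")
    if frame is None:
        frame = build_basis(n)
    h = params.s * params.omega / 360.0  # axial rise per residue, Å
    z = idx[:, None] * h + params.offsets[None, :]          # (m, 4)
    ang = np.radians(idx[:, None] * params.omega + params.phases[None, :])
    r = params.radii[None, :]
    coords = (
        params.P[None, None, :]
        + z[:, :, None] * n[None, None, :]
        + (r * np.cos(ang))[:, :, None] * frame.a[None, None, :]
        + (r * np.sin(ang))[:, :, None] * frame.b[None, None, :]
    )
    return coords


@dataclass(frozen=True)
class FitResult:
    """Converged helix parameters with fit diagnostics.

    ``per_atom_residuals`` holds the distance (Å) between each observed
    atom and its model position, shape (n_residues, 4) in ATOM_TYPES
    order.  ``axial_extent`` is the (min, max) axial coordinate of the
    model atoms along the axis relative to P, used to detect when an
    interhelix closest approach falls outside the fitted span.
    """

    params: HelixParameters
    rmsd: float
    converged: bool
    n_atoms: int
    per_atom_residuals: np.ndarray
    residue_indices: np.ndarray
    label: str = ""
    left_handed: bool = False
    axial_extent: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class DihedralPair:
    """A backbone (φ, ψ) dihedral pair in degrees, each in [-180, 180)."""

    phi: float
    psi: float

    def __post_init__(self):
        for name, v in (("phi", self.phi), ("psi", self.psi)):
            if not (-180.0 <= v < 180.0):
                raise ValueError(f"{name} = {v} outside [-180, 180)")


# ---------------------------------------------------------------------------
# least-squares inversion


def _pack(P, n, radii, s, omega_rad, t, phi_rad) -> np.ndarray:
    """Pack the 19 free scalars for the optimizer.

    Layout: P(3), n(3 direction cosines), r_N r_Ca r_C r_O, s, Ω(rad),
    t_N t_C t_O, φ_N φ_Ca φ_C φ_O (rad).  t_Cα is structurally excluded.
    """
    return np.concatenate([P, n, radii, [s, omega_rad], t, phi_rad])


def _unpack(x):
    P = x[0:3]
    n = x[3:6]
    radii = x[6:10]
    s = x[10]
    omega_rad = x[11]
    t = x[12:15]
    phi_rad = x[15:19]
    return P, n, radii, s, omega_rad, t, phi_rad


def _model_coords(x, idx, frame_c):
    """Forward model for the optimizer; n normalized, fixed auxiliary c."""
    P, n_raw, radii, s, omega_rad, t, phi_rad = _unpack(x)
    n = n_raw / np.linalg.norm(n_raw)
    a = np.cross(n, frame_c)
    a = a / np.linalg.norm(a)
    b = np.cross(n, a)
    h = s * omega_rad / (2.0 * np.pi)
    offsets = np.array([t[0], 0.0, t[1], t[2]])
    z = idx[:, None] * h + offsets[None, :]
    ang = idx[:, None] * omega_rad + phi_rad[None, :]
    r = radii[None, :]
    return (
        P[None, None, :]
        + z[:, :, None] * n[None, None, :]
        + (r * np.cos(ang))[:, :, None] * a[None, None, :]
        + (r * np.sin(ang))[:, :, None] * b[None, None, :]
    )


def _initial_guess(coords, idx):
    """Deterministic starting point: principal-axis estimate plus
    closed-form circular regression of phases and offsets."""
    ca = coords[:, 1, :]
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    n0 = vt[0]
    if np.dot(n0, ca[-1] - ca[0]) < 0:
        n0 = -n0
    frame = build_basis(n0)
    z = (coords - centroid) @ n0                      # (m, 4)
    v = coords - centroid[None, None, :] - z[..., None] * n0[None, None, :]
    theta = np.degrees(np.arctan2(v @ frame.b, v @ frame.a))   # (m, 4)
    radii0 = np.linalg.norm(v, axis=2).mean(axis=0)
    radii0 = np.clip(radii0, 0.3, None)

    # twist and rise per residue from the Cα sub-helix
    th_ca = np.unwrap(np.radians(theta[:, 1]))
    if idx.size > 1:
        omega0 = np.degrees(np.polyfit(idx, th_ca, 1)[0])
        h0 = np.polyfit(idx, z[:, 1], 1)[0]
    else:  # unreachable under the ≥5-residue precondition
        omega0, h0 = 100.0, 1.5
    if not (40.0 <= abs(omega0) <= 170.0):
        omega0 = 100.0
    if not (0.3 <= abs(h0) <= 3.5):
        h0 = 1.5
    s0 = 360.0 * h0 / omega0

    phi0 = np.array(
        [circular_mean_deg(theta[:, k] - idx * omega0) for k in range(4)]
    )
    t0 = (z - idx[:, None] * h0).mean(axis=0)
    # shift P along the axis so that t_Ca is exactly zero at the start
    P0 = centroid + t0[1] * n0
    t0 = t0 - t0[1]
    return P0, n0, radii0, s0, omega0, t0[[0, 2, 3]], phi0, frame.c


def _canonical_from_model(P_line, n_raw, x, idx, frame_c):
    """Re-express a converged fit in the canonical gauge.

    Works on exact model coordinates, so it is immune to how the
    optimizer oriented the axis or signed the radii: the axis is
    oriented N→C, phases are measured in the deterministic
    :func:`build_basis` frame with i = 0 at the first residue, t_Cα = 0.
    """
    m = _model_coords(x, idx, frame_c)
    n = n_raw / np.linalg.norm(n_raw)
    ca = m[:, 1, :]
    if np.dot(n, ca[-1] - ca[0]) < 0:
        n = -n
    frame = build_basis(n)
    # axis point in the plane of the first residue's Cα position
    P = P_line + np.dot(ca[0] - P_line, n) * n
    rel = m - P[None, None, :]
    z = rel @ n                                       # (m, 4)
    v = rel - z[..., None] * n[None, None, :]
    radii = np.linalg.norm(v, axis=2).mean(axis=0)
    theta = np.degrees(np.arctan2(v @ frame.b, v @ frame.a))

    ii = idx - idx[0]
    # twist from the smallest index gap of the Cα azimuths (exact modulo 360)
    gaps = np.diff(ii)
    k = int(np.argmin(gaps))
    domega = _wrap_deg(theta[k + 1, 1] - theta[k, 1])
    omega = float(domega / gaps[k])
    h = float((z[-1, 1] - z[0, 1]) / (ii[-1] - ii[0]))
    s = 360.0 * h / omega if omega != 0 else np.inf

    phases = _wrap_deg(
        np.array([circular_mean_deg(theta[:, a] - ii * omega) for a in range(4)])
    )
    offs = (z - ii[:, None] * h).mean(axis=0)
    params = HelixParameters(
        P=P,
        n=n,
        r_N=float(radii[0]),
        r_Ca=float(radii[1]),
        r_C=float(radii[2]),
        r_O=float(radii[3]),
        s=float(s),
        omega=omega,
        t_N=float(offs[0]),
        t_C=float(offs[2]),
        t_O=float(offs[3]),
        phi_N=float(phases[0]),
        phi_Ca=float(phases[1]),
        phi_C=float(phases[2]),
        phi_O=float(phases[3]),
    )
    return params, z


def _segment_arrays(segment):
    """Accept a HelixSegment-like object or a bare (m, 4, 3) array."""
    if hasattr(segment, "coords"):
        coords = np.asarray(segment.coords, dtype=float)
        idx = np.asarray(
            getattr(segment, "residue_indices", np.arange(len(coords))),
            dtype=float,
        )
        label = getattr(segment, "label", "")
    else:
        coords = np.asarray(segment, dtype=float)
        idx = np.arange(len(coords), dtype=float)
        label = ""
    if coords.ndim != 3 or coords.shape[1:] != (4, 3):
        raise ValueError("segment coordinates must have shape (n_residues, 4, 3)")
    return coords, idx, label


def fit_helix(segment, init: HelixParameters | None = None) -> FitResult:
    """Least-squares fit of the 19-parameter helix model to a backbone segment.

    Parameters
    ----------
    segment
        A :class:`~helixforge.structure_io.HelixSegment` or an
        (n_residues, 4, 3) array of N, Cα, C, O coordinates.
    init : HelixParameters, optional
        Starting point; by default a deterministic closed-form estimate
        built from the principal axis of the Cα coordinates.

    Returns
    -------
    FitResult
        Canonically gauged parameters: axis oriented N→C, phases in the
        deterministic :func:`build_basis` frame with residue index 0 at
        the segment's first residue, phases wrapped to [-180, 180),
        t_Cα = 0.  A converged fit with negative twist is reported with
        omega < 0 and ``left_handed=True``.
    """
    coords, idx, label = _segment_arrays(segment)
    m = len(coords)
    if m < 5:
        raise ValueError(f"segment too short: {m} complete residues (need >= 5)")

    flat = coords.reshape(-1, 3)
    centered = flat - flat.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-6:
        raise ValueError("degenerate segment: atoms are collinear")

    if init is not None:
        frame_c = build_basis(init.n).c
        x0 = _pack(
            init.P,
            init.n,
            init.radii,
            init.s,
            np.radians(init.omega),
            init.offsets[[0, 2, 3]],
            np.radians(init.phases),
        )
    else:
        P0, n0, radii0, s0, omega0, t0, phi0, frame_c = _initial_guess(coords, idx)
        x0 = _pack(P0, n0, radii0, s0, np.radians(omega0), t0, np.radians(phi0))

    def residuals(x):
        return (_model_coords(x, idx, frame_c) - coords).ravel()

    res = least_squares(
        residuals,
        x0,
        method="lm",
        ftol=1e-15,
        xtol=1e-15,
        gtol=1e-15,
        max_nfev=2000 * 20,
    )
    converged = bool(res.status > 0)
    if not converged:
        logger.warning("helix fit did not converge: %s", res.message)

    P_fit, n_fit, *_ = _unpack(res.x)
    params, z = _canonical_from_model(P_fit, n_fit, res.x, idx, frame_c)
    left_handed = params.omega < 0
    if left_handed:
        logger.warning(
            "fitted helix is left-handed (omega = %.2f deg/residue)", params.omega
        )

    model = generate_helix_coordinates(params, None, idx - idx[0])
    dist = np.linalg.norm(model - coords, axis=2)
    rmsd = float(np.sqrt(np.mean(dist**2)))
    return FitResult(
        params=params,
        rmsd=rmsd,
        converged=converged,
        n_atoms=int(dist.size),
        per_atom_residuals=dist,
        residue_indices=(idx - idx[0]).astype(int),
        label=label,
        left_handed=left_handed,
        axial_extent=(float(z.min()), float(z.max())),
    )


N_FREE_PARAMETERS = 19


def free_parameter_vector(params: HelixParameters) -> np.ndarray:
    """The exact 19-scalar free vector the optimizer works on.

    t_Cα is structurally excluded (it is the gauge reference, fixed 0).
    """
    return _pack(
        params.P,
        params.n,
        params.radii,
        params.s,
        np.radians(params.omega),
        params.offsets[[0, 2, 3]],
        np.radians(params.phases),
    )


# ---------------------------------------------------------------------------
# helix-form classification and the dihedral ↔ twist mapping

#: ideal angular turn per residue, degrees, for the three helix forms
IDEAL_OMEGA = {"three_ten": 120.0, "alpha": 100.0, "pi": 80.0}


def classify_helix_form(omega: float) -> str:
    """Classify a twist (°/residue) as ``three_ten``, ``alpha``, ``pi`` or ``other``.

    Ideal values are 120, 100 and 80 °/residue; decision boundaries sit
    at the midpoints 110 and 90, with boundary ties resolved toward α
    (the most common form).  Twists outside [70, 130] are ``other``.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if omega < 70.0 or omega > 130.0:
        return "other"
    if omega > 110.0:
        return "three_ten"
    if omega < 90.0:
        return "pi"
    return "alpha"


def omega_from_dihedrals(d: DihedralPair) -> float:
    """Angular turn per residue implied by a backbone (φ, ψ) pair.

    Uses the classical twist–dihedral relation for an ideal trans
    backbone, cos Ω = −(1 + 2 cos(φ + ψ)) / 3, which places the ideal
    3/10, α and π helices (Ω = 120, 100, 80 °/residue) on the dihedral
    sum lines φ+ψ ≈ −75°, −105°, −140°.

    Returns Ω in degrees per residue, in [70.5, 180].
    """
    ssum = np.radians(d.phi + d.psi)
    cos_omega = -(1.0 + 2.0 * np.cos(ssum)) / 3.0
    return float(np.degrees(np.arccos(np.clip(cos_omega, -1.0, 1.0))))


def dihedral_sum_from_omega(omega: float) -> float:
    """Dihedral sum φ+ψ (degrees, helical branch < 0) for a given twist."""
    if not (70.0 < omega <= 180.0):
        raise ValueError("omega outside the helical range of the mapping")
    cos_sum = (-3.0 * np.cos(np.radians(omega)) - 1.0) / 2.0
    return float(-np.degrees(np.arccos(np.clip(cos_sum, -1.0, 1.0))))


def residues_per_revolution(omega: float) -> float:
    """Number of residues per full 360° turn, 360/Ω."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    return 360.0 / omega
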
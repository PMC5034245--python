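"""Synthetic helix fixtures: ideal and perturbed helices as PDB files.

Everything downstream — segment extraction, fitting, motion analysis,
diagrams — is testable without downloading structures.  The generator
uses the same four-sub-helix forward model as the fitter (one shared
implementation, no formula drift) and writes standard PDB files plus a
JSON ground-truth record.

Canonical per-form constants (radii, axial offsets, phases) were
obtained once by building ideal poly-backbones from canonical (φ, ψ)
dihedral pairs with standard bond lengths/angles and fitting the
19-parameter model; twist and pitch are then set to the ideal textbook
values.  They are stylized test inputs, not measurements: in particular
the π form is anchored to the −139.5° dihedral-sum line of the
twist–dihedral relation, which is axially more compressed than
crystallographic π helices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from helixforge.model import (
    ATOM_TYPES,
    HelixParameters,
    build_basis,
    generate_helix_coordinates,
)

__all__ = [
    "CANONICAL_FORMS",
    "FixtureSpec",
    "Perturbation",
    "canonical_parameters",
    "backbone_from_dihedrals",
    "make_fixture",
    "make_two_state_bundle",
    "write_backbone_pdb",
]

#: canonical sub-helix constants per helical form; omega in °/residue,
#: s in Å/turn, radii/offsets in Å (N, Cα, C, O order; t_Ca ≡ 0),
#: phases in degrees relative to the Cα sub-helix.
CANONICAL_FORMS: dict[str, dict] = {
    "three_ten": dict(
        omega=120.0, s=6.0,
        radii=(1.054, 1.866, 1.229, 1.674),
        offsets=(-1.054, 1.195, 2.325),
        phases=(-24.58, 0.0, 26.75, 18.50),
        dihedrals=(-49.0, -26.0),
    ),
    "alpha": dict(
        omega=100.0, s=5.4,
        radii=(1.551, 2.276, 1.666, 1.921),
        offsets=(-0.919, 1.069, 2.257),
        phases=(-26.77, 0.0, 26.74, 20.34),
        dihedrals=(-57.0, -47.0),
    ),
    "pi": dict(
        omega=80.0, s=2.7,
        radii=(2.331, 2.961, 2.388, 2.456),
        offsets=(-0.593, 0.751, 1.979),
        phases=(-25.80, 0.0, 26.01, 27.04),
        dihedrals=(-70.0, -69.5),
    ),
}


def canonical_parameters(
    form: str,
    P=(0.0, 0.0, 0.0),
    n=(0.0, 0.0, 1.0),
    omega: float | None = None,
    s: float | None = None,
    phase_offset: float = 0.0,
) -> HelixParameters:
    """Canonical :class:`HelixParameters` for a named helical form."""
    if form not in CANONICAL_FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {sorted(CANONICAL_FORMS)}")
    f = CANONICAL_FORMS[form]
    r = f["radii"]
    t = f["offsets"]
    ph = [(p + phase_offset + 180.0) % 360.0 - 180.0 for p in f["phases"]]
    return HelixParameters(
        P=np.asarray(P, dtype=float),
        n=np.asarray(n, dtype=float) / np.linalg.norm(n),
        r_N=r[0], r_Ca=r[1], r_C=r[2], r_O=r[3],
        s=f["s"] if s is None else s,
        omega=f["omega"] if omega is None else omega,
        t_N=t[0], t_C=t[1], t_O=t[2],
        phi_N=ph[0], phi_Ca=ph[1], phi_C=ph[2], phi_O=ph[3],
    )


# ---------------------------------------------------------------------------
# internal-coordinate backbone builder (independent of the helix model)

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _place(A, B, C, bond, angle, dihedral):
    """Position of atom D given A-B-C, |CD|, angle BCD and dihedral ABCD
    (IUPAC sign convention)."""
    ang, tor = np.radians(angle), np.radians(dihedral)
    bc = C - B
    bc = bc / np.linalg.norm(bc)
    ab = B - A
    nrm = np.cross(ab, bc)
    nrm = nrm / np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return C + d[0] * bc + d[1] * m + d[2] * nrm


def backbone_from_dihedrals(phi: float, psi: float, n_residues: int) -> np.ndarray:
    """Ideal backbone built from repeated (φ, ψ) by chain extension.

    Uses standard peptide bond lengths and angles with a trans peptide
    (ω = 180°).  Returns an (n_residues, 4, 3) array in N, Cα, C, O
    order.  This construction is independent of the four-sub-helix
    model and serves as a geometric cross-check of it.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    ang = np.radians(_ANGLE["N-CA-C"])
    C = [CA[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(n_residues - 1):
        Nn = _place(N[i], CA[i], C[i], _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        CAn = _place(CA[i], C[i], Nn, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        Cn = _place(C[i], Nn, CAn, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        N.append(Nn)
        CA.append(CAn)
        C.append(Cn)
    O = [
        _place(N[i], CA[i], C[i], _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        for i in range(n_residues)
    ]
    return np.stack([np.stack([N[i], CA[i], C[i], O[i]]) for i in range(n_residues)])


# ---------------------------------------------------------------------------
# fixture specification


@dataclass(frozen=True)
class Perturbation:
    """A programmed change applied to a fixture helix.

    type : one of delta_omega (°/residue), axial_shift (Å along the
        helix axis), axis_rotation (degrees about the helix axis),
        rigid_move (Å along global +x), axis_tilt (degrees about a
        transverse axis through the helix midpoint) or kink (degrees of
        bend at the midpoint).
    """

    type: str
    magnitude: float
    target: str = ""

    _TYPES = ("delta_omega", "axial_shift", "axis_rotation",
              "rigid_move", "axis_tilt", "kink")

    def __post_init__(self):
        if self.type not in self._TYPES:
            raise ValueError(f"unknown perturbation type {self.type!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic helix.

    Same seed → byte-identical output files.
    """

    form: str = "alpha"
    n_residues: int = 18
    omega: float | None = None
    s: float | None = None
    noise_sigma: float = 0.0
    perturbations: tuple[Perturbation, ...] = ()
    seed: int = 0
    name: str = "HELIX"
    chain: str = "A"
    first_residue: int = 1

    def __post_init__(self):
        if self.form != "custom" and self.form not in CANONICAL_FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    t = np.radians(angle_deg)
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * K @ K


def _fixture_coords(spec: FixtureSpec, P, n) -> tuple[np.ndarray, HelixParameters]:
    """Coordinates plus the generating parameters (before noise/kink)."""
    params = canonical_parameters(spec.form, P=P, n=n, omega=spec.omega, s=spec.s)
    kink = None
    for pert in spec.perturbations:
        if pert.type == "delta_omega":
            params = replace(params, omega=params.omega + pert.magnitude)
        elif pert.type == "axial_shift":
            params = replace(params, P=params.P + pert.magnitude * params.n)
        elif pert.type == "axis_rotation":
            params = replace(
                params,
                phi_N=params.phi_N + pert.magnitude,
                phi_Ca=params.phi_Ca + pert.magnitude,
                phi_C=params.phi_C + pert.magnitude,
                phi_O=params.phi_O + pert.magnitude,
            )
        elif pert.type == "rigid_move":
            params = replace(params, P=params.P + np.array([pert.magnitude, 0.0, 0.0]))
        elif pert.type == "axis_tilt":
            frame = build_basis(params.n)
            mid = params.P + (spec.n_residues - 1) / 2.0 * params.rise_per_residue * params.n
            R = _rotation_about(frame.a, pert.magnitude)
            params = replace(params, n=R @ params.n, P=mid + R @ (params.P - mid))
        elif pert.type == "kink":
            kink = pert.magnitude

    idx = np.arange(spec.n_residues)
    coords = generate_helix_coordinates(params, None, idx)
    if kink is not None:
        half = spec.n_residues // 2
        frame = build_basis(params.n)
        pivot = coords[half, 1]
        R = _rotation_about(frame.a, kink)
        coords = coords.copy()
        coords[half:] = (coords[half:] - pivot) @ R.T + pivot
    return coords, params


def write_backbone_pdb(path, chains: dict[str, tuple[np.ndarray, int]],
                       name: str = "synthetic") -> None:
    """Write backbone coordinates as a PDB file.

    ``chains`` maps chain id → (coords (m, 4, 3), first residue number).
    Residues are written as ALA with N, CA, C, O atoms only.
    """
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    elements = ("N", "C", "C", "O")
    for chain_id, (coords, first) in chains.items():
        chain = gemmi.Chain(chain_id)
        for i, residue_atoms in enumerate(coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(first + i, " ")
            for aname, elem, pos in zip(ATOM_TYPES, elements, residue_atoms):
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(elem)
                atom.occ = 1.0
                atom.b_iso = 10.0
                atom.pos = gemmi.Position(*pos)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


def make_fixture(spec: FixtureSpec, out_dir) -> tuple[Path, dict]:
    """Write one synthetic helix as <name>.pdb plus ground truth JSON.

    Gaussian noise of ``spec.noise_sigma`` Å is added per coordinate
    with the spec's seed; perturbations apply in listed order.  Returns
    (pdb path, ground-truth dict).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords, params = _fixture_coords(spec, P=(0.0, 0.0, 0.0), n=(0.0, 0.0, 1.0))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    pdb_path = out_dir / f"{spec.name}.pdb"
    write_backbone_pdb(pdb_path, {spec.chain: (coords, spec.first_residue)},
                       name=spec.name)
    truth = {
        "name": spec.name,
        "form": spec.form,
        "n_residues": spec.n_residues,
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "omega": params.omega,
        "s": params.s,
        "radii": list(params.radii),
        "offsets": [params.t_N, params.t_C, params.t_O],
        "phases": list(params.phases),
        "perturbations": [
            {"type": p.type, "magnitude": p.magnitude, "target": p.target}
            for p in spec.perturbations
        ],
    }
    (out_dir / f"{spec.name}.truth.json").write_text(json.dumps(truth, indent=1))
    return pdb_path, truth


#: ring radius on which bundle helices are placed, Å
BUNDLE_RING_RADIUS = 12.0


def make_two_state_bundle(
    helices: dict[str, tuple[FixtureSpec, FixtureSpec]],
    out_dir,
    seed: int = 0,
) -> tuple[Path, Path, dict]:
    """Write a multi-helix bundle in two states plus a ground-truth record.

    ``helices`` maps helix name → (state-1 spec, state-2 spec); both
    states must define the same helix names.  Helices are placed on a
    ring (radius 12 Å, axes along +z) with residue ranges of 100·k+1
    onward in one chain.  The ground truth lists per-helix programmed
    motion components (ΔΩ, torsion, sliding) derived from the spec
    pairs, and the helices free of rigid-body perturbations as the
    recommended superposition reference.

    Returns (state-1 path, state-2 path, ground-truth dict).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = sorted(helices)

    def net(spec: FixtureSpec, kind: str) -> float:
        return sum(p.magnitude for p in spec.perturbations if p.type == kind)

    state_paths = []
    segments = {}
    for state_i in (0, 1):
        chains_coords = []
        for k, name in enumerate(names):
            spec = helices[name][state_i]
            ang = 2.0 * np.pi * k / len(names)
            P = BUNDLE_RING_RADIUS * np.array([np.cos(ang), np.sin(ang), 0.0])
            spec = replace(
                spec,
                name=name,
                seed=spec.seed if spec.noise_sigma > 0 else seed,
                first_residue=100 * k + 1,
            )
            coords, _ = _fixture_coords(spec, P=P, n=(0.0, 0.0, 1.0))
            if spec.noise_sigma > 0:
                rng = np.random.default_rng((seed, state_i, k))
                coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
            chains_coords.append((name, coords, 100 * k + 1))
            segments[name] = {
                "chain": "A",
                "start": 100 * k + 1,
                "end": 100 * k + spec.n_residues,
            }
        # one chain with numbering gaps between helices
        st_path = out_dir / f"state{state_i + 1}.pdb"
        _write_bundle_pdb(st_path, chains_coords)
        state_paths.append(st_path)

    truth = {"seed": seed, "segments": segments, "motions": {}, "reference": []}
    for name in names:
        a, b = helices[name]
        motion = {
            "delta_omega": net(b, "delta_omega") - net(a, "delta_omega"),
            "delta_phase": net(b, "axis_rotation") - net(a, "axis_rotation"),
            "sliding": net(b, "axial_shift") - net(a, "axial_shift"),
        }
        truth["motions"][name] = motion
        # recommended superposition reference: helices whose coordinates are
        # programmed to be identical in both states
        if a.perturbations == b.perturbations and a.noise_sigma == 0 == b.noise_sigma:
            truth["reference"].append(name)
    (out_dir / "bundle.truth.json").write_text(json.dumps(truth, indent=1))
    return state_paths[0], state_paths[1], truth


def _write_bundle_pdb(path, chains_coords) -> None:
    """One chain 'A'; helices separated by residue-numbering gaps."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    elements = ("N", "C", "C", "O")
    for _, coords, first in chains_coords:
        for i, residue_atoms in enumerate(coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(first + i, " ")
            for aname, elem, pos in zip(ATOM_TYPES, elements, residue_atoms):
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(elem)
                atom.occ = 1.0
                atom.b_iso = 10.0
                atom.pos = gemmi.Position(*pos)
                res.add_atom(atom)
            chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
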
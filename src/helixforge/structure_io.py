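"""Reading structures, extracting backbone segments, writing parameter tables.

PDB and mmCIF files are parsed with gemmi.  Segments are addressed by
chain and author residue numbering (inclusive ranges, insertion codes in
file order).  Residues missing any of the four backbone atoms N, Cα, C,
O are dropped with a logged warning.  Only the first model of
multi-model files is used; for alternate conformations the altloc with
the highest occupancy is kept (ties resolve to 'A').
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from helixforge.model import ATOM_TYPES, FitResult

__all__ = [
    "HelixSegment",
    "SegmentDefinition",
    "StructureGroup",
    "DihedralRecord",
    "StructureParseError",
    "read_structure",
    "extract_segment",
    "compute_dihedrals",
    "write_parameter_table",
    "PARAMETER_TABLE_COLUMNS",
    "load_segment_definitions",
    "load_structure_groups",
]

logger = logging.getLogger(__name__)

#: Cα–Cα distance beyond which consecutive residues are treated as a
#: chain break and dihedrals spanning it are left undefined (Å).
CHAIN_BREAK_CA_CA = 4.5


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class HelixSegment:
    """Backbone coordinates of one named helical segment.

    ``coords`` has shape (n_residues, 4, 3) in N, Cα, C, O order;
    ``residue_ids`` are author residue identifiers ("207", "207A", ...);
    ``residue_indices`` are integer model indices with 0 at the first
    residue, preserving author-numbering gaps where residues were
    dropped.
    """

    structure_id: str
    chain_id: str
    residue_ids: tuple[str, ...]
    coords: np.ndarray
    label: str = ""
    residue_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (n_residues, 4, 3)")
        if len(self.residue_ids) != len(coords):
            raise ValueError("residue_ids and coords length mismatch")
        if len(coords) < 1:
            raise ValueError("segment must contain at least one residue")
        object.__setattr__(self, "coords", coords)
        if self.residue_indices is None:
            object.__setattr__(
                self, "residue_indices", np.arange(len(coords), dtype=int)
            )
        else:
            idx = np.asarray(self.residue_indices, dtype=int)
            if np.any(np.diff(idx) <= 0):
                raise ValueError("residue_indices must be strictly increasing")
            object.__setattr__(self, "residue_indices", idx)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class SegmentDefinition:
    """A named residue range on a chain ('*' matches the first chain)."""

    name: str
    chain: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment {self.name}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class StructureGroup:
    """A functional-state group of (structure id, chain) members."""

    group_id: int
    members: tuple[tuple[str, str], ...]
    description: str = ""


@dataclass(frozen=True)
class DihedralRecord:
    """Backbone dihedrals of one residue; None where undefined."""

    residue_id: str
    phi: float | None
    psi: float | None


# ---------------------------------------------------------------------------
# reading


def read_structure(path, fmt: str = "auto") -> gemmi.Structure:
    """Parse a PDB or mmCIF file into a gemmi Structure.

    ``fmt`` is one of "pdb", "mmcif" or "auto" (detect from content /
    extension).  Raises :class:`StructureParseError` on unreadable or
    empty files.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if fmt not in fmt_map:
        raise ValueError(f"unknown format {fmt!r} (use pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[fmt])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(chain) == 0 for chain in st[0]):
        raise StructureParseError(f"no atoms found in {path}")
    if len(st) > 1:
        logger.warning("%s has %d models; using model 1 only", path.name, len(st))
    st.setup_entities()
    if not st.name:
        st.name = path.stem
    return st


def _pick_altloc(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Atom of the given name with highest occupancy (ties -> lowest altloc)."""
    candidates = [a for a in residue if a.name == name]
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.occ, a.altloc or "A"))


def _find_chain(model: gemmi.Model, chain: str) -> gemmi.Chain:
    if chain in ("*", "", None):
        return model[0]
    found = model.find_chain(chain)
    if found is None:
        raise ValueError(f"chain {chain!r} not found in structure")
    return found


def extract_segment(structure: gemmi.Structure, sdef: SegmentDefinition) -> HelixSegment:
    """Extract the backbone of a residue range as a :class:`HelixSegment`.

    The range [start, end] is inclusive in author numbering; insertion
    codes follow file order.  Residues missing any backbone atom are
    dropped with a warning; hydrogens and side chains are ignored.
    """
    chain = _find_chain(structure[0], sdef.chain)
    ids, idx, rows = [], [], []
    for res in chain:
        num = res.seqid.num
        if num < sdef.start or num > sdef.end:
            continue
        atoms = [_pick_altloc(res, name) for name in ATOM_TYPES]
        rid = f"{num}{res.seqid.icode.strip()}"
        if any(a is None for a in atoms):
            missing = [n for n, a in zip(ATOM_TYPES, atoms) if a is None]
            logger.warning(
                "%s %s/%s residue %s missing %s; dropped from segment %s",
                structure.name, chain.name, res.name, rid,
                ",".join(missing), sdef.name,
            )
            continue
        ids.append(rid)
        idx.append(num)
        rows.append([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
    if not rows:
        raise ValueError(
            f"segment {sdef.name}: no complete residues in "
            f"{sdef.chain}:{sdef.start}-{sdef.end}"
        )
    idx = np.asarray(idx, dtype=int)
    # author-number offsets keep gaps from dropped residues; duplicated
    # numbers (insertion codes) fall back to sequential positions
    if np.any(np.diff(idx) <= 0):
        logger.warning(
            "segment %s has non-increasing author numbering (insertion "
            "codes?); using sequential residue indices", sdef.name,
        )
        idx = np.arange(len(rows), dtype=int)
    return HelixSegment(
        structure_id=structure.name,
        chain_id=chain.name,
        residue_ids=tuple(ids),
        coords=np.asarray(rows, dtype=float),
        label=sdef.name,
        residue_indices=idx - idx[0],
    )


# ---------------------------------------------------------------------------
# dihedrals


def compute_dihedrals(structure: gemmi.Structure, chain: str) -> list[DihedralRecord]:
    """Backbone φ/ψ dihedrals (degrees) for every residue of a chain.

    φ(i) = C(i-1)–N(i)–Cα(i)–C(i); ψ(i) = N(i)–Cα(i)–C(i)–N(i+1).
    Dihedrals are undefined (None) at chain termini, at residues with
    incomplete backbones, and across chain breaks (consecutive Cα–Cα
    distance > 4.5 Å).
    """
    ch = _find_chain(structure[0], chain)
    residues = []
    for res in ch:
        atoms = {name: _pick_altloc(res, name) for name in ATOM_TYPES}
        rid = f"{res.seqid.num}{res.seqid.icode.strip()}"
        residues.append((rid, atoms))
    if len(residues) < 3:
        return [DihedralRecord(rid, None, None) for rid, _ in residues]

    def linked(i: int, j: int) -> bool:
        ai, aj = residues[i][1], residues[j][1]
        if ai["CA"] is None or aj["CA"] is None:
            return False
        return ai["CA"].pos.dist(aj["CA"].pos) <= CHAIN_BREAK_CA_CA

    def dihedral(*atoms) -> float:
        return float(
            np.degrees(gemmi.calculate_dihedral(*(a.pos for a in atoms)))
        )

    out = []
    for i, (rid, a) in enumerate(residues):
        phi = psi = None
        complete = all(a[name] is not None for name in ("N", "CA", "C"))
        if complete and i > 0:
            prev = residues[i - 1][1]
            if prev["C"] is not None and linked(i - 1, i):
                phi = dihedral(prev["C"], a["N"], a["CA"], a["C"])
        if complete and i < len(residues) - 1:
            nxt = residues[i + 1][1]
            if nxt["N"] is not None and linked(i, i + 1):
                psi = dihedral(a["N"], a["CA"], a["C"], nxt["N"])
        out.append(DihedralRecord(rid, phi, psi))
    return out


# ---------------------------------------------------------------------------
# parameter tables

PARAMETER_TABLE_COLUMNS = [
    "structure_id", "chain", "segment", "group_id",
    "diameter", "omega", "s",
    "r_N", "r_Ca", "r_C", "r_O",
    "t_N", "t_C", "t_O",
    "phi_N", "phi_Ca", "phi_C", "phi_O",
    "mean_phase", "rmsd", "converged",
]


def write_parameter_table(
    fits: Sequence[tuple[str, str, str, FitResult]],
    path,
    groups: Iterable[StructureGroup] | None = None,
) -> pd.DataFrame:
    """Write one TSV row per fit (sorted by group, structure, chain).

    ``fits`` is a list of (structure_id, chain, segment label,
    FitResult).  Numbers are written at 6 significant digits; rows are
    ordered by (group_id, structure_id, chain, segment), matching the
    survey-plot convention.  Returns the DataFrame that was written.
    """
    if not fits:
        raise ValueError("no fits to write")
    group_of: dict[tuple[str, str], int] = {}
    for g in groups or []:
        for sid, ch in g.members:
            group_of[(sid, ch)] = g.group_id
    rows = []
    for sid, ch, label, fr in fits:
        p = fr.params
        rows.append({
            "structure_id": sid,
            "chain": ch,
            "segment": label,
            "group_id": group_of.get((sid, ch), ""),
            "diameter": p.diameter,
            "omega": p.omega,
            "s": p.s,
            "r_N": p.r_N, "r_Ca": p.r_Ca, "r_C": p.r_C, "r_O": p.r_O,
            "t_N": p.t_N, "t_C": p.t_C, "t_O": p.t_O,
            "phi_N": p.phi_N, "phi_Ca": p.phi_Ca,
            "phi_C": p.phi_C, "phi_O": p.phi_O,
            "mean_phase": p.mean_phase,
            "rmsd": fr.rmsd,
            "converged": fr.converged,
        })
    df = pd.DataFrame(rows, columns=PARAMETER_TABLE_COLUMNS)
    df = df.sort_values(
        by=["group_id", "structure_id", "chain", "segment"],
        key=lambda col: col.map(lambda v: (v == "", v)) if col.name == "group_id" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# configuration


def _load_config(path) -> object:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_segment_definitions(path) -> list[SegmentDefinition]:
    """Load segment definitions from YAML/JSON.

    Expected layout::

        segments:
          - {name: TM5c, chain: A, start: 216, end: 225}
    """
    data = _load_config(path)
    if not isinstance(data, dict) or "segments" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'segments' list")
    out = []
    for i, entry in enumerate(data["segments"]):
        try:
            out.append(SegmentDefinition(
                name=str(entry["name"]),
                chain=str(entry.get("chain", "*")),
                start=int(entry["start"]),
                end=int(entry["end"]),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad segment entry #{i}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no segments defined")
    return out


def load_structure_groups(path) -> list[StructureGroup]:
    """Load structure groups from YAML/JSON.

    Expected layout::

        groups:
          - {id: 1, description: "...", members: [[1U19, A], [1U19, B]]}
    """
    data = _load_config(path)
    if not isinstance(data, dict) or "groups" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'groups' list")
    out, seen = [], {}
    for i, entry in enumerate(data["groups"]):
        try:
            members = tuple((str(s), str(c)) for s, c in entry.get("members", []))
            gid = int(entry["id"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad group entry #{i}: {exc}") from exc
        for m in members:
            if m in seen:
                raise ValueError(
                    f"{path}: member {m} appears in groups {seen[m]} and {gid}"
                )
            seen[m] = gid
        out.append(StructureGroup(
            group_id=gid, members=members,
            description=str(entry.get("description", "")),
        ))
    return out
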
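"""Atomic model I/O and the coordinate hierarchy.

Models are read with gemmi (PDB and mmCIF) into a small plain hierarchy of
Structure -> Chain -> Residue -> Atom. Only polymer amino-acid residues of
the first model are kept; waters and ligands are dropped and alternate
locations are resolved to the highest-occupancy conformer. Coordinates are
in Angstrom throughout and are never re-centered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom", "Residue", "Chain", "Structure",
    "CHARGED", "POLAR", "HYDROPHOBIC", "NONSTANDARD_PARENT",
    "read_structure", "write_structure", "classify_residue",
    "apply_rigid_transform",
]

# Residue chemical classes (three disjoint sets; everything else is "other").
CHARGED = frozenset({"ASP", "GLU", "LYS", "ARG"})
POLAR = frozenset({"SER", "THR", "ASN", "GLN", "HIS", "TYR"})
HYDROPHOBIC = frozenset({"ALA", "LEU", "ILE", "VAL", "PHE", "TRP", "CYS", "MET"})

# Common modified residues mapped to their parent for classification.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "CME": "CYS", "MLY": "LYS", "HYP": "PRO",
    "KCX": "LYS", "PCA": "GLU",
}

STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


class StructureError(ValueError):
    """Raised for unreadable, empty or malformed atomic models."""


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coord must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One amino-acid residue, identified by author numbering."""

    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_id, insertion_code) — the identity used everywhere."""
        return (self.chain_id, self.seq_id, self.insertion_code)

    @property
    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA" and a.element.upper() != "CA":  # exclude calcium ions
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: (r.seq_id, r.insertion_code))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in structure {self.id}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def residue(self, key: tuple[str, int, str]) -> Residue:
        chain_id, seq_id, icode = key
        for r in self.chain(chain_id).residues:
            if r.seq_id == seq_id and r.insertion_code == icode:
                return r
        raise KeyError(f"no residue {key} in structure {self.id}")

    def all_residues(self):
        for c in self.chains:
            yield from c.residues


def classify_residue(name: str) -> str:
    """Classify a 3-letter residue code as charged / polar / hydrophobic / other.

    Charged: Asp, Glu, Lys, Arg. Polar: Ser, Thr, Asn, Gln, His, Tyr.
    Hydrophobic: Ala, Leu, Ile, Val, Phe, Trp, Cys, Met. Gly, Pro and
    unrecognised codes fall into "other". Modified residues with a known
    parent (e.g. MSE) are classified as the parent.
    """
    code = name.upper().strip()
    code = NONSTANDARD_PARENT.get(code, code)
    if code in CHARGED:
        return "charged"
    if code in POLAR:
        return "polar"
    if code in HYDROPHOBIC:
        return "hydrophobic"
    return "other"


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties alphabetical."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    Only model 1 is used; non-polymer residues (waters, ligands, nucleic
    acids) are dropped; altlocs are resolved to the highest-occupancy
    conformer. Raises StructureError on unreadable input or when no protein
    chain survives filtering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        if format == "pdb" or (format == "auto" and path.suffix.lower() in (".pdb", ".ent")):
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif" or (format == "auto" and path.suffix.lower() in (".cif", ".mmcif")):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues = []
        for gres in gchain:
            name = gres.name.upper()
            if name not in STANDARD_AA and name not in NONSTANDARD_PARENT:
                continue
            atoms = [
                Atom(name=a.name, element=a.element.name,
                     coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                     occupancy=min(max(a.occ, 0.0), 1.0))
                for a in _resolve_altlocs(gres)
            ]
            if not atoms:
                continue
            icode = gres.seqid.icode.strip() if gres.seqid.icode else ""
            residues.append(Residue(name=name, seq_id=gres.seqid.num,
                                    chain_id=gchain.name, atoms=atoms,
                                    insertion_code=icode))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise StructureError(f"{path}: no protein chains after filtering")
    return Structure(id=path.stem, chains=chains)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB-format file (coordinates to 3 decimals)."""
    n_atoms = sum(len(r.atoms) for r in structure.all_residues())
    if n_atoms > 99999:
        raise StructureError(
            f"structure has {n_atoms} atoms; the PDB serial field overflows at 99999")
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB atom-name column convention: element right-justified in 13-14
                if len(name) < 4 and len(atom.element) == 1:
                    name = " " + name
                x, y, z = atom.coord
                if max(abs(x), abs(y), abs(z)) >= 10000:
                    raise StructureError("coordinate exceeds PDB fixed-width field")
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} "
                    f"{chain.chain_id[:1]:1s}{res.seq_id:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def apply_rigid_transform(chain: Chain, rotation: np.ndarray,
                          translation: np.ndarray) -> Chain:
    """Return a copy of the chain with every atom mapped x -> R x + t.

    `rotation` must be a proper rotation (orthonormal, det +1, tol 1e-6).
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or not math.isclose(
            float(np.linalg.det(R)), 1.0, abs_tol=1e-6):
        raise ValueError("rotation must be proper orthonormal (det +1)")
    new_residues = []
    for res in chain.residues:
        new_atoms = [Atom(name=a.name, element=a.element,
                          coord=R @ a.coord + t, occupancy=a.occupancy)
                     for a in res.atoms]
        new_residues.append(Residue(name=res.name, seq_id=res.seq_id,
                                    chain_id=res.chain_id, atoms=new_atoms,
                                    insertion_code=res.insertion_code))
    return Chain(chain_id=chain.chain_id, residues=new_residues)
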
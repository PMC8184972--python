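"""Interface detection and model-vs-native interface comparison.

An interface residue is one whose C-alpha lies within a distance cutoff
(default 7 A) of any C-alpha of the partner chain. An interface enters
scoring only when both chains contribute at least `min_residues` residues
(default 10). Model interfaces are compared to native ones through iRMSD
(RMSD over corresponded interface C-alphas after optimal superposition) and
f_Nal (fraction of native interface residues recovered by the model).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Chain, Structure

__all__ = [
    "Interface", "InterfaceMatch", "RigidTransform",
    "assign_interface", "enumerate_interfaces", "count_contact_pairs",
    "superpose", "compute_irmsd", "compute_fnal",
    "interface_similarity", "deduplicate_interfaces",
    "interfaces_to_records", "write_interface_report",
]

ResidueKey = tuple[str, int, str]


@dataclass
class Interface:
    """A pair of chains with their interface residue sets."""

    chain_a: str
    chain_b: str
    residues_a: set[ResidueKey]
    residues_b: set[ResidueKey]
    cutoff_used: float
    contact_pairs: set[tuple[tuple, tuple]] = field(default_factory=set)

    @property
    def residues(self) -> set[ResidueKey]:
        return self.residues_a | self.residues_b

    @property
    def size(self) -> tuple[int, int]:
        return (len(self.residues_a), len(self.residues_b))


@dataclass
class InterfaceMatch:
    irmsd: float
    fnal: float
    correspondence: dict[ResidueKey, ResidueKey]


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _ca_coords(chain: Chain) -> tuple[np.ndarray, list[ResidueKey]]:
    coords, keys = [], []
    n_missing = 0
    for res in chain.residues:
        ca = res.ca
        if ca is None:
            n_missing += 1
            continue
        coords.append(ca.coord)
        keys.append(res.key)
    if n_missing:
        warnings.warn(
            f"chain {chain.chain_id}: {n_missing} residue(s) lack a C-alpha; "
            "ignored in interface assignment", stacklevel=3)
    if not coords:
        raise ValueError(f"chain {chain.chain_id} has no C-alpha atoms")
    return np.array(coords), keys


def assign_interface(structure: Structure, chain_a: str, chain_b: str,
                     cutoff: float = 7.0, min_residues: int = 10,
                     heavy_cutoff: float = 4.5) -> Interface | None:
    """Detect the interface between two chains, or None if below minimum size.

    A residue of one chain is an interface residue iff its C-alpha lies
    within `cutoff` of any C-alpha of the other chain. Heavy-atom contact
    pairs between interface residues (within `heavy_cutoff`) are recorded on
    the returned Interface.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = structure.chain(chain_a)
    cb = structure.chain(chain_b)
    xa, keys_a = _ca_coords(ca)
    xb, keys_b = _ca_coords(cb)

    tree_b = cKDTree(xb)
    pairs = tree_b.query_ball_point(xa, r=cutoff)
    res_a = {keys_a[i] for i, hits in enumerate(pairs) if hits}
    res_b = {keys_b[j] for hits in pairs for j in hits}
    if len(res_a) < min_residues or len(res_b) < min_residues:
        return None

    iface = Interface(chain_a=chain_a, chain_b=chain_b,
                      residues_a=res_a, residues_b=res_b, cutoff_used=cutoff)
    iface.contact_pairs = _contact_pairs(iface, structure, heavy_cutoff)
    return iface


def _contact_pairs(interface: Interface, structure: Structure,
                   heavy_cutoff: float) -> set[tuple[tuple, tuple]]:
    def atoms_of(keys):
        coords, refs = [], []
        for key in sorted(keys):
            res = structure.residue(key)
            for atom in res.heavy_atoms():
                coords.append(atom.coord)
                refs.append((key, atom.name))
        return (np.array(coords) if coords else np.empty((0, 3))), refs

    xa, refs_a = atoms_of(interface.residues_a)
    xb, refs_b = atoms_of(interface.residues_b)
    if len(xa) == 0 or len(xb) == 0:
        return set()
    tree_b = cKDTree(xb)
    out = set()
    for i, hits in enumerate(tree_b.query_ball_point(xa, r=heavy_cutoff)):
        for j in hits:
            out.add((refs_a[i], refs_b[j]))
    return out


def count_contact_pairs(interface: Interface, structure: Structure,
                        heavy_cutoff: float = 4.5) -> int:
    """Number of inter-chain heavy-atom pairs between interface residues."""
    return len(_contact_pairs(interface, structure, heavy_cutoff))


def enumerate_interfaces(structure: Structure, cutoff: float = 7.0,
                         min_residues: int = 10) -> list[Interface]:
    """All pairwise interfaces, one per unordered chain pair, in lexicographic order."""
    ids = sorted(c.chain_id for c in structure.chains)
    if len(ids) < 2:
        warnings.warn("structure has a single chain; no interfaces possible")
        return []
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            iface = assign_interface(structure, a, b, cutoff=cutoff,
                                     min_residues=min_residues)
            if iface is not None:
                out.append(iface)
    return out


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of `coords_a` onto `coords_b` (Kabsch).

    Returns the proper rotation R and translation t minimising
    RMSD(R a + t, b), with the minimum RMSD in the `rmsd` field.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching Nx3")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 points")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca_, b - cb_
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = a0.T @ b0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb_ - R @ ca_
    rmsd = float(np.sqrt(np.mean(np.sum((a0 @ R.T - b0) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def default_correspondence(native: Interface, model_structure: Structure,
                           chain_map: dict[str, str] | None = None
                           ) -> dict[ResidueKey, ResidueKey]:
    """Map native interface residues to model residues with identical keys.

    `chain_map` renames native chain ids to model chain ids; keys absent
    from the model are dropped.
    """
    chain_map = chain_map or {}
    model_keys = {r.key for r in model_structure.all_residues()}
    corr = {}
    for key in native.residues:
        mkey = (chain_map.get(key[0], key[0]), key[1], key[2])
        if mkey in model_keys:
            corr[key] = mkey
    return corr


def compute_irmsd(model_structure: Structure, native_structure: Structure,
                  native_interface: Interface,
                  correspondence: dict[ResidueKey, ResidueKey] | None = None
                  ) -> float:
    """iRMSD: RMSD over corresponded native-interface C-alphas after optimal fit."""
    if correspondence is None:
        correspondence = default_correspondence(native_interface, model_structure)
    nat, mod = [], []
    for nkey in sorted(native_interface.residues):
        mkey = correspondence.get(nkey)
        if mkey is None:
            continue
        nca = native_structure.residue(nkey).ca
        mca = model_structure.residue(mkey).ca
        if nca is None or mca is None:
            continue
        nat.append(nca.coord)
        mod.append(mca.coord)
    if len(nat) < 3:
        raise ValueError("iRMSD needs at least 3 corresponded interface residues")
    return superpose(np.array(mod), np.array(nat)).rmsd


def compute_fnal(model_interface: Interface, native_interface: Interface,
                 correspondence: dict[ResidueKey, ResidueKey] | None = None
                 ) -> float:
    """f_Nal: fraction of native interface residues recovered by the model interface."""
    if not native_interface.residues:
        raise ValueError("native interface is empty")
    if correspondence is None:
        correspondence = {k: k for k in native_interface.residues}
    model_set = model_interface.residues
    hits = sum(1 for nkey in native_interface.residues
               if correspondence.get(nkey, nkey) in model_set)
    return hits / len(native_interface.residues)


def _side_cas(interface: Interface, structure: Structure):
    def cas(keys):
        out = [structure.residue(k).ca.coord for k in sorted(keys)
               if structure.residue(k).ca is not None]
        return np.array(out) if out else np.empty((0, 3))

    return cas(interface.residues_a), cas(interface.residues_b)


def _one_way_similarity(xa: np.ndarray, xb: np.ndarray, match_cutoff: float) -> float:
    """Best fraction of `xa` points matched within cutoff after superposing a
    sequence-order-preserving window of xb onto the corresponding window of xa."""
    na, nb = len(xa), len(xb)
    if na < 3 or nb < 3:
        return 0.0
    n = min(na, nb)
    best = 0.0
    # slide the shorter point list along the longer; order is preserved
    for off_a in range(na - n + 1):
        for off_b in range(nb - n + 1):
            sa = xa[off_a:off_a + n]
            sb = xb[off_b:off_b + n]
            try:
                tr = superpose(sb, sa)
            except ValueError:
                continue
            moved = tr.apply(xb)
            d = np.linalg.norm(xa[:, None, :] - moved[None, :, :], axis=2)
            frac = float(np.mean(d.min(axis=1) <= match_cutoff))
            best = max(best, frac)
    return best


def interface_similarity(a: Interface, b: Interface,
                         structure_a: Structure, structure_b: Structure | None = None,
                         match_cutoff: float = 2.0) -> float:
    """Structural similarity of two interfaces, in [0, 1].

    A simplified replacement for an interface-alignment IS-score: after the
    best sequence-order-preserving superposition of one interface's C-alphas
    onto the other's, the score is the fraction of interface residues matched
    within `match_cutoff`; the reported value is the mean of both directions.
    """
    structure_b = structure_b or structure_a
    a1, a2 = _side_cas(a, structure_a)
    b1, b2 = _side_cas(b, structure_b)
    if min(len(a1) + len(a2), len(b1) + len(b2)) == 0:
        return 0.0
    xa = np.vstack([x for x in (a1, a2) if len(x)])
    best = 0.0
    # the equivalent interface in a symmetric assembly may have its two
    # sides swapped relative to `a`; try both side orders of b
    for order in ((b1, b2), (b2, b1)):
        xb = np.vstack([x for x in order if len(x)])
        score = 0.5 * (_one_way_similarity(xa, xb, match_cutoff)
                       + _one_way_similarity(xb, xa, match_cutoff))
        best = max(best, score)
    return best


def deduplicate_interfaces(interfaces: list[Interface], structure: Structure,
                           threshold: float = 0.7) -> list[Interface]:
    """Greedy removal of structurally similar interfaces within one assembly.

    Interfaces are visited in deterministic (chain-pair) order; one is dropped
    when its similarity to any already-retained interface is >= threshold.
    """
    retained: list[Interface] = []
    for iface in sorted(interfaces, key=lambda i: (i.chain_a, i.chain_b)):
        if all(interface_similarity(iface, kept, structure) < threshold
               for kept in retained):
            retained.append(iface)
    return retained


def interfaces_to_records(interfaces: list[Interface]) -> list[dict]:
    """Tabular summary rows (chain pair, residue lists, counts)."""
    rows = []
    for i in interfaces:
        rows.append({
            "chain_a": i.chain_a,
            "chain_b": i.chain_b,
            "n_residues_a": len(i.residues_a),
            "n_residues_b": len(i.residues_b),
            "n_contact_pairs": len(i.contact_pairs),
            "cutoff": i.cutoff_used,
            "residues_a": ";".join(f"{c}:{s}{ic}" for c, s, ic in sorted(i.residues_a)),
            "residues_b": ";".join(f"{c}:{s}{ic}" for c, s, ic in sorted(i.residues_b)),
        })
    return rows


def write_interface_report(interfaces: list[Interface], path: str | Path,
                           fmt: str = "csv") -> None:
    import pandas as pd

    rows = interfaces_to_records(interfaces)
    if fmt == "json":
        Path(path).write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
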
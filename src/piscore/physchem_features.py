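"""Physicochemical and energetic interface features.

Twelve features describe each protein-protein interface: interface size,
conserved-residue count, charged/polar/hydrophobic residue fractions,
heavy-atom contact pairs, shape complementarity, hydrogen-bond and
salt-bridge counts, interface solvation energy, a hydrophobic-specificity
p-value, and buried interface area. Hydrogen bonds and salt bridges use
distance-only criteria from explicit donor/acceptor and charged-group atom
tables; the solvation energy applies published atomic solvation parameters
to the surface area buried on complexation; the p-value is a seeded
surface-patch permutation test of interface hydrophobicity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .interface_core import Interface, count_contact_pairs
from .structure_io import Structure, classify_residue
from .surface_geometry import RadiiSet, sasa, _heavy_atoms

__all__ = [
    "FEATURE_NAMES", "FeatureVector", "HBondCriteria", "SaltBridgeCriteria",
    "SolvationParams", "ConservationTable", "FeatureError",
    "residue_class_fractions", "count_hydrogen_bonds", "count_salt_bridges",
    "interface_solvation_energy", "hydrophobic_pvalue",
    "conserved_interface_count", "compute_feature_vector",
]

FEATURE_NAMES = (
    "num_intf_residues", "conserved_interface", "charged", "polar",
    "hydrophobic", "contact_pairs", "sc", "hb", "sb", "int_solv_en",
    "p_value", "int_area",
)


class FeatureError(ValueError):
    """A hard failure while computing a named interface feature."""

    def __init__(self, feature: str, message: str):
        self.feature = feature
        super().__init__(f"feature {feature!r}: {message}")


# -- hydrogen bonds -----------------------------------------------------------

_SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "ASN": ["ND2"],
    "GLN": ["NE2"], "HIS": ["ND1", "NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "TRP": ["NE1"], "CYS": ["SG"],
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}


@dataclass
class HBondCriteria:
    """Distance-only hydrogen-bond criterion over donor/acceptor atom tables."""

    max_distance: float = 3.5   # donor-acceptor heavy-atom distance, A
    donors: dict = field(default_factory=lambda: dict(_SIDECHAIN_DONORS))
    acceptors: dict = field(default_factory=lambda: dict(_SIDECHAIN_ACCEPTORS))
    include_backbone: bool = True

    def __post_init__(self) -> None:
        if not 2.0 < self.max_distance < 5.0:
            raise ValueError("H-bond distance criterion must lie in (2.0, 5.0) A")

    def donor_atoms(self, res) -> list:
        names = set(self.donors.get(res.name, []))
        if self.include_backbone and res.name != "PRO":
            names.add("N")
        return [a for a in res.heavy_atoms() if a.name in names]

    def acceptor_atoms(self, res) -> list:
        names = set(self.acceptors.get(res.name, []))
        if self.include_backbone:
            names.update(("O", "OXT"))
        return [a for a in res.heavy_atoms() if a.name in names]


_POSITIVE_GROUPS = {"LYS": ["NZ"], "ARG": ["NH1", "NH2", "NE"], "HIS": ["ND1", "NE2"]}
_NEGATIVE_GROUPS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


@dataclass
class SaltBridgeCriteria:
    """Opposite-charge group proximity criterion; counted per residue pair."""

    max_distance: float = 4.0
    positive: dict = field(default_factory=lambda: dict(_POSITIVE_GROUPS))
    negative: dict = field(default_factory=lambda: dict(_NEGATIVE_GROUPS))

    def __post_init__(self) -> None:
        if not 2.5 < self.max_distance < 6.0:
            raise ValueError("salt-bridge distance criterion must lie in (2.5, 6.0) A")


def _load_solvation_table() -> dict[str, float]:
    text = (importlib.resources.files("piscore") / "data" / "solvation_params.csv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("atom_class"):
            continue
        k, v = line.split(",")
        out[k] = float(v)
    return out


@dataclass
class SolvationParams:
    """Atomic solvation parameters sigma (cal mol^-1 A^-2) by atom class."""

    sigma: dict[str, float] = field(default_factory=_load_solvation_table)

    def atom_class(self, residue_name: str, atom) -> str:
        el = atom.element.upper()
        if el == "C":
            return "C"
        if el == "S" or el == "SE":
            return "S"
        if el == "O":
            if residue_name in _NEGATIVE_GROUPS and atom.name in _NEGATIVE_GROUPS[residue_name]:
                return "O_charged"
            return "O"
        if el == "N":
            if residue_name in _POSITIVE_GROUPS and atom.name in _POSITIVE_GROUPS[residue_name]:
                return "N_charged"
            return "N"
        return "default"

    def sigma_for(self, residue_name: str, atom) -> float:
        return self.sigma.get(self.atom_class(residue_name, atom),
                              self.sigma.get("default", 0.0))


@dataclass
class ConservationTable:
    """Per-residue conservation scores; lower/negative = more conserved."""

    scores: dict[tuple[str, int], float]
    conserved_cutoff: float = 0.25  # most-conserved fraction per chain

    @classmethod
    def from_file(cls, path, conserved_cutoff: float = 0.25) -> "ConservationTable":
        """Read a 3-column table (chain, seq_id, score); '#' comments allowed."""
        scores = {}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            chain, seq_id, score = parts[0], int(parts[1]), float(parts[2])
            scores[(chain, seq_id)] = score
        return cls(scores=scores, conserved_cutoff=conserved_cutoff)


@dataclass
class FeatureVector:
    """The 12 interface features fed to the classifier."""

    num_intf_residues: int
    conserved_interface: float
    charged: float
    polar: float
    hydrophobic: float
    contact_pairs: int
    sc: float
    hb: int
    sb: int
    int_solv_en: float
    p_value: float
    int_area: float
    imputed: tuple[str, ...] = ()   # names of fields filled by imputation

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d["imputed"] = ";".join(self.imputed)
        return d


def residue_class_fractions(interface: Interface, structure: Structure
                            ) -> tuple[float, float, float]:
    """(charged, polar, hydrophobic) fractions of the interface residues."""
    keys = sorted(interface.residues)
    if not keys:
        return (0.0, 0.0, 0.0)
    counts = {"charged": 0, "polar": 0, "hydrophobic": 0, "other": 0}
    for key in keys:
        counts[classify_residue(structure.residue(key).name)] += 1
    n = len(keys)
    return (counts["charged"] / n, counts["polar"] / n, counts["hydrophobic"] / n)


def count_hydrogen_bonds(interface: Interface, structure: Structure,
                         criteria: HBondCriteria | None = None) -> int:
    """Cross-chain donor-acceptor atom pairs within the distance criterion."""
    criteria = criteria or HBondCriteria()
    res_a = [structure.residue(k) for k in sorted(interface.residues_a)]
    res_b = [structure.residue(k) for k in sorted(interface.residues_b)]
    count = 0
    for side1, side2 in ((res_a, res_b), (res_b, res_a)):
        donors = [a for r in side1 for a in criteria.donor_atoms(r)]
        acceptors = [a for r in side2 for a in criteria.acceptor_atoms(r)]
        for d in donors:
            for ac in acceptors:
                if np.linalg.norm(d.coord - ac.coord) <= criteria.max_distance:
                    count += 1
    return count


def count_salt_bridges(interface: Interface, structure: Structure,
                       criteria: SaltBridgeCriteria | None = None) -> int:
    """Opposite-charge residue pairs across the interface (counted per pair)."""
    criteria = criteria or SaltBridgeCriteria()

    def charged_atoms(keys, table):
        out = []
        for key in sorted(keys):
            res = structure.residue(key)
            names = table.get(res.name)
            if names:
                atoms = [a for a in res.heavy_atoms() if a.name in names]
                if atoms:
                    out.append((key, atoms))
        return out

    pos_a = charged_atoms(interface.residues_a, criteria.positive)
    neg_a = charged_atoms(interface.residues_a, criteria.negative)
    pos_b = charged_atoms(interface.residues_b, criteria.positive)
    neg_b = charged_atoms(interface.residues_b, criteria.negative)

    count = 0
    for plus, minus in ((pos_a, neg_b), (pos_b, neg_a)):
        for pkey, patoms in plus:
            for nkey, natoms in minus:
                dmin = min(np.linalg.norm(pa.coord - na.coord)
                           for pa in patoms for na in natoms)
                if dmin <= criteria.max_distance:
                    count += 1
    return count


@dataclass
class _SasaBundle:
    """Per-atom SASA of the complex and of each isolated chain, shared by
    the area, solvation and p-value features."""

    atoms: list                 # heavy atoms of the A+B pair, with residues
    asa_pair: np.ndarray
    asa_isolated: np.ndarray    # concatenated isolated-chain areas, same order
    n_atoms_a: int

    @classmethod
    def compute(cls, structure: Structure, chain_a: str, chain_b: str,
                radii: RadiiSet, n_points: int) -> "_SasaBundle":
        ca = structure.chain(chain_a)
        cb = structure.chain(chain_b)
        pair = Structure(id="pair", chains=[ca, cb])
        asa_a = sasa(ca, radii, n_points)
        asa_b = sasa(cb, radii, n_points)
        return cls(atoms=_heavy_atoms(pair),
                   asa_pair=sasa(pair, radii, n_points),
                   asa_isolated=np.concatenate([asa_a, asa_b]),
                   n_atoms_a=len(asa_a))


def _per_atom_delta_asa(structure: Structure, chain_a: str, chain_b: str,
                        radii: RadiiSet, n_points: int,
                        bundle: _SasaBundle | None = None):
    """(atoms, ASA_complex - ASA_isolated) over both chains' heavy atoms."""
    bundle = bundle or _SasaBundle.compute(structure, chain_a, chain_b,
                                           radii, n_points)
    return bundle.atoms, bundle.asa_pair - bundle.asa_isolated


def interface_solvation_energy(structure: Structure, chain_a: str, chain_b: str,
                               params: SolvationParams | None = None,
                               radii: RadiiSet | None = None,
                               n_points: int = 960,
                               _bundle: _SasaBundle | None = None) -> float:
    """Solvation energy change on complexation (kcal/mol).

    sum over atoms of sigma(atom class) * (ASA_in_complex - ASA_isolated) / 1000.
    Burial of apolar (carbon) area gives a negative, favourable value.
    """
    params = params or SolvationParams()
    radii = radii or RadiiSet()
    atoms, delta = _per_atom_delta_asa(structure, chain_a, chain_b, radii,
                                       n_points, _bundle)
    return float(sum(params.sigma_for(res.name, a) * d
                     for (a, res), d in zip(atoms, delta)) / 1000.0)


def _surface_residue_energies(structure: Structure, chain_a: str, chain_b: str,
                              params: SolvationParams, radii: RadiiSet,
                              n_points: int, min_area: float = 5.0,
                              bundle: _SasaBundle | None = None):
    """Per-residue burial energy gain for surface residues of the isolated chains.

    gain(r) = -sum_atoms sigma * ASA_isolated / 1000 (kcal/mol if the residue's
    exposed surface were fully buried; more negative = more hydrophobic).
    Returns (keys, gains, ca_coords) for residues with isolated SASA >= min_area.
    """
    bundle = bundle or _SasaBundle.compute(structure, chain_a, chain_b,
                                           radii, n_points)
    per_res: dict[tuple, float] = {}
    per_res_area: dict[tuple, float] = {}
    for (a, res), area in zip(bundle.atoms, bundle.asa_isolated):
        per_res[res.key] = per_res.get(res.key, 0.0) - \
            params.sigma_for(res.name, a) * area / 1000.0
        per_res_area[res.key] = per_res_area.get(res.key, 0.0) + area
    keys, gains, cas = [], [], []
    for cid in (chain_a, chain_b):
        for res in structure.chain(cid).residues:
            if per_res_area.get(res.key, 0.0) >= min_area and res.ca is not None:
                keys.append(res.key)
                gains.append(per_res[res.key])
                cas.append(res.ca.coord)
    return keys, np.array(gains), np.array(cas)


def _grow_patch(rng: np.random.Generator, adjacency: list[list[int]],
                n_residues: int, size: int, max_restarts: int = 50) -> list[int] | None:
    for _ in range(max_restarts):
        seed_idx = int(rng.integers(n_residues))
        patch = {seed_idx}
        frontier = set(adjacency[seed_idx])
        while len(patch) < size and frontier:
            nxt = sorted(frontier)[int(rng.integers(len(frontier)))]
            patch.add(nxt)
            frontier |= set(adjacency[nxt])
            frontier -= patch
        if len(patch) == size:
            return sorted(patch)
    return None


def hydrophobic_pvalue(structure: Structure, interface: Interface,
                       n_samples: int = 1000, seed: int = 0,
                       params: SolvationParams | None = None,
                       radii: RadiiSet | None = None,
                       n_points: int = 960,
                       adjacency_cutoff: float = 10.0,
                       _bundle: _SasaBundle | None = None) -> float:
    """Specificity of the interface's hydrophobicity as an empirical p-value.

    Random connected patches of surface residues (same residue count as the
    interface, grown by C-alpha adjacency from a random seed residue) provide
    a null distribution of per-residue solvation-energy gain; the p-value is
    the fraction of patches at least as hydrophobic (gain <= observed), with
    an add-one correction keeping it in [1/(n_samples+1), 1]. Low p means the
    interface is an unusually hydrophobic surface patch, i.e. specific.
    """
    params = params or SolvationParams()
    radii = radii or RadiiSet()
    keys, gains, cas = _surface_residue_energies(
        structure, interface.chain_a, interface.chain_b, params, radii,
        n_points, bundle=_bundle)
    iface_idx = [i for i, k in enumerate(keys) if k in interface.residues]
    size = len(iface_idx)
    if size == 0 or len(keys) < 2 * size:
        raise FeatureError("p_value", "too few surface residues for the patch null")

    observed = float(np.mean(gains[iface_idx]))
    tree = cKDTree(cas)
    adjacency = [sorted(set(nb) - {i})
                 for i, nb in enumerate(tree.query_ball_point(cas, r=adjacency_cutoff))]
    rng = np.random.default_rng(seed)
    hits = 0
    n_done = 0
    for _ in range(n_samples):
        patch = _grow_patch(rng, adjacency, len(keys), size)
        if patch is None:
            continue
        n_done += 1
        if float(np.mean(gains[patch])) <= observed + 1e-12:
            hits += 1
    if n_done == 0:
        raise FeatureError("p_value", "could not grow any surface patch")
    return (hits + 1) / (n_done + 1)


def conserved_interface_count(interface: Interface,
                              conservation: ConservationTable | None,
                              structure: Structure | None = None) -> tuple[float, bool]:
    """Number of interface residues in the most-conserved percentile of their chain.

    Ties at the percentile boundary are counted fractionally (each tied
    residue contributes the fraction of the remaining quota shared among the
    ties) and the sum is rounded, so uniform scores give
    round(cutoff * interface size) deterministically. Returns
    (count, imputed_flag); with no table the count is imputed as
    cutoff * num_intf_residues and flagged.
    """
    n_iface = len(interface.residues)
    if conservation is None:
        return (round(0.25 * n_iface), True)
    cutoff = conservation.conserved_cutoff
    by_chain: dict[str, list[float]] = {}
    for (chain, seq_id), score in conservation.scores.items():
        by_chain.setdefault(chain, []).append(score)

    total = 0.0
    covered = 0
    for key in sorted(interface.residues):
        chain, seq_id, _icode = key
        score = conservation.scores.get((chain, seq_id))
        if score is None or chain not in by_chain:
            continue
        covered += 1
        scores = np.asarray(by_chain[chain], dtype=float)
        n = len(scores)
        frac_below = np.sum(scores < score) / n
        frac_eq = np.sum(scores == score) / n
        total += float(np.clip((cutoff - frac_below) / frac_eq, 0.0, 1.0))
    if covered == 0:
        return (round(cutoff * n_iface), True)
    return (round(total), False)


def compute_feature_vector(structure: Structure, interface: Interface,
                           conservation: ConservationTable | None = None,
                           hb_criteria: HBondCriteria | None = None,
                           sb_criteria: SaltBridgeCriteria | None = None,
                           solvation: SolvationParams | None = None,
                           radii: RadiiSet | None = None,
                           sc_params=None,
                           n_points: int = 960,
                           pvalue_samples: int = 1000,
                           seed: int = 0) -> FeatureVector:
    """Assemble the 12-feature vector for one interface.

    Raises FeatureError naming the failing feature when a hard failure occurs
    (e.g. the chains are not in surface contact); the caller decides whether
    to drop the interface.
    """
    from .surface_geometry import ScParams, shape_complementarity

    if interface is None:
        raise FeatureError("num_intf_residues", "no interface between the chains")
    radii = radii or RadiiSet()
    solvation = solvation or SolvationParams()
    sc_params = sc_params or ScParams()

    charged, polar, hydrophobic = residue_class_fractions(interface, structure)
    n_contacts = len(interface.contact_pairs) or count_contact_pairs(interface, structure)
    try:
        sc_value = shape_complementarity(structure, interface.chain_a,
                                         interface.chain_b, sc_params, radii)
    except ValueError as exc:
        raise FeatureError("sc", str(exc)) from exc
    hb = count_hydrogen_bonds(interface, structure, hb_criteria)
    sb = count_salt_bridges(interface, structure, sb_criteria)
    bundle = _SasaBundle.compute(structure, interface.chain_a,
                                 interface.chain_b, radii, n_points)
    solv_en = interface_solvation_energy(structure, interface.chain_a,
                                         interface.chain_b, solvation, radii,
                                         n_points, _bundle=bundle)
    int_area = float((bundle.asa_isolated.sum() - bundle.asa_pair.sum()) / 2.0)
    imputed = []
    try:
        p_value = hydrophobic_pvalue(structure, interface, pvalue_samples, seed,
                                     solvation, radii, n_points, _bundle=bundle)
    except FeatureError:
        p_value = 0.5
        imputed.append("p_value")
    conserved, cons_imputed = conserved_interface_count(interface, conservation)
    if cons_imputed:
        imputed.append("conserved_interface")

    vec = FeatureVector(
        num_intf_residues=len(interface.residues),
        conserved_interface=conserved,
        charged=charged, polar=polar, hydrophobic=hydrophobic,
        contact_pairs=n_contacts, sc=sc_value, hb=hb, sb=sb,
        int_solv_en=solv_en, p_value=p_value, int_area=int_area,
        imputed=tuple(imputed),
    )
    arr = vec.as_array()
    if not np.all(np.isfinite(arr)):
        bad = FEATURE_NAMES[int(np.flatnonzero(~np.isfinite(arr))[0])]
        raise FeatureError(bad, "non-finite value")
    return vec
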
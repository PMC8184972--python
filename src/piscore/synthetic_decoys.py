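"""Toy complexes, rigid-body decoys and synthetic feature datasets.

These generators make the whole scoring stack testable without any
downloads. Toy complexes are two-chain assemblies with idealized backbone
geometry (3.8 A C-alpha spacing) packed so that the interface comfortably
exceeds the ten-residue-per-side minimum. Decoys are rigid-body
perturbations of one chain, rejection-sampled until the measured interface
recovery (f_Nal) and interface RMSD fall in the requested class:
near-native poses satisfy f_Nal >= 0.7 and iRMSD <= 3 A, negatives satisfy
f_Nal < 0.3 or iRMSD > 4 A; poses in the gap between the two regions are
discarded. Negative sampling mixes "displaced" and "clashing" modes so the
negative set contains both loosely packed and sterically clashing
interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interface_core import (Interface, assign_interface, compute_fnal,
                             compute_irmsd)
from .physchem_features import FEATURE_NAMES, FeatureError, compute_feature_vector
from .classifier import LabeledDataset
from .structure_io import Atom, Chain, Residue, Structure, apply_rigid_transform

__all__ = [
    "ToyComplexSpec", "DecoySpec", "DecoyResult",
    "make_toy_complex", "perturb_to_class", "build_training_set",
    "make_synthetic_feature_dataset",
]

# residue names weighted roughly like globular protein surfaces
_DEFAULT_COMPOSITION = {
    "ALA": 8, "ARG": 5, "ASN": 4, "ASP": 6, "CYS": 1, "GLN": 4, "GLU": 7,
    "GLY": 7, "HIS": 2, "ILE": 5, "LEU": 9, "LYS": 6, "MET": 2, "PHE": 4,
    "PRO": 5, "SER": 7, "THR": 6, "TRP": 1, "TYR": 3, "VAL": 7,
}

# idealized residue template: backbone + CB, local frame (x along chain)
_RESIDUE_TEMPLATE = {
    "N": np.array([-1.20, 0.60, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.25, 0.60, 0.00]),
    "O": np.array([1.30, 1.80, 0.20]),
    "CB": np.array([-0.10, -0.90, 1.20]),
}


@dataclass
class ToyComplexSpec:
    """Recipe for a deterministic two-chain toy complex."""

    n_residues: int = 28
    template: str = "helix-pair"        # helix-pair | lattice
    gap: float = 1.0                    # extra separation between chains, A
    composition: dict = field(default_factory=lambda: dict(_DEFAULT_COMPOSITION))
    jitter: float = 0.25                # coordinate noise, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 12:
            raise ValueError("n_residues must be >= 12 so interfaces can reach "
                             "the ten-residue minimum")


@dataclass
class DecoySpec:
    """Rejection-sampling recipe for one labelled rigid-body decoy."""

    target_class: str                   # near_native | negative
    rotation_range: tuple[float, float] | None = None   # degrees
    translation_range: tuple[float, float] | None = None  # A
    max_tries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_class not in ("near_native", "negative"):
            raise ValueError("target_class must be 'near_native' or 'negative'")
        if self.rotation_range is None:
            self.rotation_range = (0.0, 8.0) if self.target_class == "near_native" \
                else (10.0, 120.0)
        if self.translation_range is None:
            self.translation_range = (0.0, 1.5) if self.target_class == "near_native" \
                else (2.0, 10.0)

    def accepts(self, fnal: float, irmsd: float) -> bool:
        if self.target_class == "near_native":
            return fnal >= 0.7 and irmsd <= 3.0
        return fnal < 0.3 or irmsd > 4.0


@dataclass
class DecoyResult:
    structure: Structure
    fnal: float
    irmsd: float
    label: str
    n_tries: int


def _helix_coords(n: int, rise: float = 1.5, radius: float = 2.3,
                  twist_deg: float = 100.0) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(twist_deg)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            np.arange(n) * rise])


def _strand_coords(n: int, spacing: float = 3.8) -> np.ndarray:
    return np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * spacing])


def _build_chain(chain_id: str, ca_path: np.ndarray, names: list[str],
                 rng: np.random.Generator, jitter: float) -> Chain:
    residues = []
    n = len(ca_path)
    for i in range(n):
        # local frame along the chain path
        fwd = ca_path[min(i + 1, n - 1)] - ca_path[max(i - 1, 0)]
        fwd = fwd / np.linalg.norm(fwd)
        ref = np.array([1.0, 0.0, 0.0]) if abs(fwd[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        side = np.cross(fwd, ref)
        side /= np.linalg.norm(side)
        up = np.cross(fwd, side)
        frame = np.column_stack([fwd, side, up])
        atoms = []
        for atom_name, local in _RESIDUE_TEMPLATE.items():
            if atom_name == "CB" and names[i] == "GLY":
                continue
            coord = ca_path[i] + frame @ local + rng.normal(0.0, jitter, 3)
            element = atom_name[0]
            atoms.append(Atom(name=atom_name, element=element, coord=coord))
        residues.append(Residue(name=names[i], seq_id=i + 1, chain_id=chain_id,
                                atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)


def _sample_names(rng: np.random.Generator, n: int, composition: dict) -> list[str]:
    names = sorted(composition)
    weights = np.array([composition[k] for k in names], dtype=float)
    weights /= weights.sum()
    return [names[i] for i in rng.choice(len(names), size=n, p=weights)]


def make_toy_complex(spec: ToyComplexSpec | None = None) -> Structure:
    """Deterministic two-chain toy complex with a >= 10-residue interface.

    "helix-pair" packs two antiparallel alpha-helices side by side;
    "lattice" packs two extended strands. `gap` adds separation between the
    chains on top of the default tight packing; large gaps make the
    construction infeasible and raise.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.template == "helix-pair":
        path_a = _helix_coords(n)
        path_b = _helix_coords(n)
        # antiparallel partner displaced along x
        path_b = path_b * np.array([1.0, -1.0, -1.0])
        path_b += np.array([7.5 + spec.gap, 0.0, (n - 1) * 1.5])
    elif spec.template == "lattice":
        path_a = _strand_coords(n)
        path_b = _strand_coords(n) + np.array([5.5 + spec.gap, 0.0, 0.0])
    else:
        raise ValueError(f"unknown template {spec.template!r}")

    names_a = _sample_names(rng, n, spec.composition)
    names_b = _sample_names(rng, n, spec.composition)
    structure = Structure(
        id=f"toy-{spec.template}-{spec.seed}",
        chains=[_build_chain("A", path_a, names_a, rng, spec.jitter),
                _build_chain("B", path_b, names_b, rng, spec.jitter)])
    if assign_interface(structure, "A", "B") is None:
        raise ValueError("infeasible toy spec: chains do not form a "
                         ">=10-residue interface at this gap")
    return structure


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def perturb_to_class(structure: Structure, interface: Interface,
                     spec: DecoySpec) -> DecoyResult:
    """Rigid-body decoy of the requested class by rejection sampling.

    Chain B is rotated about its centroid and translated; the pose is
    accepted when the measured (f_Nal, iRMSD) against the input interface
    satisfies the class rule and (for feature computability) the decoy still
    has a valid interface when the class is "negative" via displacement
    toward/along the partner. Poses in the gap between the near-native and
    negative regions are discarded and resampled.
    """
    rng = np.random.default_rng(spec.seed)
    chain_b = structure.chain(interface.chain_b)
    centroid = np.mean([a.coord for r in chain_b.residues for a in r.atoms], axis=0)
    other_chains = [c for c in structure.chains if c.chain_id != interface.chain_b]
    chain_a_centroid = np.mean([a.coord for r in structure.chain(interface.chain_a).residues
                                for a in r.atoms], axis=0)
    last = (float("nan"), float("nan"))
    for attempt in range(1, spec.max_tries + 1):
        angle = rng.uniform(*spec.rotation_range)
        tmag = rng.uniform(*spec.translation_range)
        R = _random_rotation(rng, angle)
        tdir = rng.normal(size=3)
        tdir /= np.linalg.norm(tdir)
        if spec.target_class == "negative" and rng.uniform() < 0.5:
            # clashing mode: bias the translation toward the partner chain
            toward = chain_a_centroid - centroid
            tdir = toward / np.linalg.norm(toward)
            tmag = rng.uniform(1.0, 4.0)
        # rotate about the chain centroid, then translate
        t = centroid - R @ centroid + tmag * tdir
        moved = apply_rigid_transform(chain_b, R, t)
        decoy = Structure(id=f"{structure.id}-decoy", chains=other_chains + [moved])
        model_iface = assign_interface(decoy, interface.chain_a, interface.chain_b)
        if model_iface is None:
            fnal = 0.0
            try:
                irmsd = compute_irmsd(decoy, structure, interface)
            except (ValueError, KeyError):
                continue
        else:
            fnal = compute_fnal(model_iface, interface)
            irmsd = compute_irmsd(decoy, structure, interface)
        last = (fnal, irmsd)
        if not spec.accepts(fnal, irmsd):
            continue
        if model_iface is None:
            continue  # features need an interface; resample
        return DecoyResult(structure=decoy, fnal=fnal, irmsd=irmsd,
                           label="positive" if spec.target_class == "near_native"
                           else "negative", n_tries=attempt)
    raise RuntimeError(
        f"max_tries={spec.max_tries} exhausted for class {spec.target_class}; "
        f"last measured f_Nal={last[0]:.3f}, iRMSD={last[1]:.2f}")


def build_training_set(complexes: list[Structure], n_pos: int = 20,
                       n_neg: int = 20, seed: int = 0,
                       include_natives: bool = True,
                       pvalue_samples: int = 200,
                       log: list | None = None) -> LabeledDataset:
    """Features for natives (PD1-like), near-native decoys (PD2-like) and
    negatives (ND-like) over a list of toy complexes.

    `n_pos` / `n_neg` decoys are distributed round-robin across the
    complexes. Interfaces whose features fail hard are logged (appended to
    `log` when given) and skipped.
    """
    rng = np.random.default_rng(seed)
    rows, labels, prov = [], [], []

    def add(structure, iface, label, provenance):
        try:
            vec = compute_feature_vector(structure, iface,
                                         pvalue_samples=pvalue_samples,
                                         seed=int(rng.integers(2 ** 31)))
        except FeatureError as exc:
            if log is not None:
                log.append(f"{structure.id}: {exc}")
            return
        rows.append(vec.as_array())
        labels.append(1 if label == "positive" else 0)
        prov.append(provenance)

    natives = []
    for structure in complexes:
        iface = assign_interface(structure, "A", "B")
        if iface is None:
            raise ValueError(f"complex {structure.id} has no valid interface")
        natives.append((structure, iface))
        if include_natives:
            add(structure, iface, "positive", "PD1")

    for i in range(n_pos + n_neg):
        structure, iface = natives[i % len(natives)]
        cls = "near_native" if i < n_pos else "negative"
        spec = DecoySpec(target_class=cls, seed=int(rng.integers(2 ** 31)))
        decoy = perturb_to_class(structure, iface, spec)
        model_iface = assign_interface(decoy.structure, iface.chain_a, iface.chain_b)
        add(decoy.structure, model_iface, decoy.label,
            "PD2" if cls == "near_native" else "ND")

    if not rows:
        raise ValueError("no feature vectors could be computed")
    return LabeledDataset(X=np.vstack(rows), y=np.array(labels),
                          provenance=np.array(prov))


def make_synthetic_feature_dataset(n_per_class: int = 100,
                                   separation: float = 2.0,
                                   seed: int = 0,
                                   n_informative: int | None = None
                                   ) -> LabeledDataset:
    """Two 12-dimensional Gaussian classes with controlled mean separation.

    Class means differ by `separation` (in units of the unit within-class
    standard deviation) along the informative axes (all 12 by default, or
    the first `n_informative`). With one informative axis and separation s
    the Bayes error is Phi(-s/2).
    """
    if n_per_class < 10:
        raise ValueError("need at least 10 samples per class")
    rng = np.random.default_rng(seed)
    d = len(FEATURE_NAMES)
    shift = np.zeros(d)
    k = d if n_informative is None else n_informative
    shift[:k] = separation / np.sqrt(k) if n_informative is None else separation
    X0 = rng.normal(size=(n_per_class, d))
    X1 = rng.normal(size=(n_per_class, d)) + shift
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    order = rng.permutation(len(y))
    return LabeledDataset(X=X[order], y=y[order],
                          provenance=np.where(y[order] == 1, "PD2", "ND"))
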
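"""Solvent-accessible surface area, buried interface area and shape complementarity.

SASA uses Shrake-Rupley sphere sampling with a deterministic Fibonacci
lattice (no RNG). Molecular dot surfaces carry outward unit normals and feed
the shape-complementarity statistic Sc: for each interface dot x on one
surface with nearest partner dot x', S(x) = (n_x . -n_x') * exp(-w d(x,x')^2),
and Sc is the average of the two per-surface medians. Tightly meshed
surfaces approach 1; uncorrelated or clashing topographies fall toward 0 or
below.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Chain, Structure

__all__ = [
    "RadiiSet", "DotSurface", "ScParams",
    "sasa", "buried_interface_area", "molecular_dot_surface",
    "shape_complementarity", "fibonacci_sphere",
]


def _load_radii_table() -> dict[str, float]:
    text = (importlib.resources.files("piscore") / "data" / "vdw_radii.csv").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        key, val = line.split(",")
        table[key.upper()] = float(val)
    return table


@dataclass
class RadiiSet:
    """Van der Waals radii by element plus the solvent probe radius (A)."""

    radii: dict[str, float] = field(default_factory=_load_radii_table)
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        for k, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"implausible vdW radius {r} for {k}")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.radii.get("DEFAULT", 1.8))


@dataclass
class DotSurface:
    """Surface dots with outward unit normals and owning-atom indices."""

    points: np.ndarray          # M x 3
    normals: np.ndarray         # M x 3, unit length
    owner_atom: np.ndarray      # M, int index into the atom list used


@dataclass
class ScParams:
    dot_density: float = 15.0       # dots per A^2 of surface
    w: float = 0.5                  # A^-2 Gaussian decay of the distance term
    interface_band: float = 8.0     # A, dots nearer than this to the partner surface
    trim: float = 1.5               # A, peripheral band of the interface patch removed
    statistic: str = "median"

    def __post_init__(self) -> None:
        if min(self.dot_density, self.w, self.interface_band, self.trim) <= 0:
            raise ValueError("all Sc parameters must be positive")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _heavy_atoms(obj: Structure | Chain):
    chains = obj.chains if isinstance(obj, Structure) else [obj]
    atoms = []
    for c in chains:
        for res in c.residues:
            for a in res.heavy_atoms():
                atoms.append((a, res))
    return atoms


def _atom_arrays(obj, radii: RadiiSet):
    atoms = _heavy_atoms(obj)
    if not atoms:
        raise ValueError("no heavy atoms")
    coords = np.array([a.coord for a, _ in atoms])
    rads = np.array([radii.radius(a.element) for a, _ in atoms])
    return atoms, coords, rads


def sasa(obj: Structure | Chain, radii: RadiiSet | None = None,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley sampling.

    Each heavy atom is sampled with `n_points` Fibonacci-lattice points on its
    solvent-accessible sphere (vdW radius + probe); a point counts as
    accessible when it lies outside every neighbour's accessible sphere.
    Returns areas in atom order (heavy atoms, chain then residue order).
    """
    radii = radii or RadiiSet()
    _, coords, rads = _atom_arrays(obj, radii)
    sphere = fibonacci_sphere(n_points)
    rs = rads + radii.probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * rs.max()
    areas = np.empty(len(coords))
    neighbor_lists = tree.query_ball_point(coords, r=max_reach)
    for i in range(len(coords)):
        nb = np.asarray(neighbor_lists[i], dtype=int)
        nb = nb[nb != i]
        if nb.size:
            dc = coords[nb] - coords[i]
            nb = nb[np.einsum("ij,ij->i", dc, dc) < (rs[i] + rs[nb]) ** 2]
        if nb.size:
            pts = coords[i] + rs[i] * sphere
            diff = pts[:, None, :] - coords[nb][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            frac = np.all(d2 >= (rs[nb] ** 2)[None, :], axis=1).mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * rs[i] ** 2
    return areas


def sasa_by_residue(obj: Structure | Chain, radii: RadiiSet | None = None,
                    n_points: int = 960) -> dict[tuple, float]:
    """Total SASA per residue key."""
    radii = radii or RadiiSet()
    atoms = _heavy_atoms(obj)
    areas = sasa(obj, radii, n_points)
    out: dict[tuple, float] = {}
    for (a, res), area in zip(atoms, areas):
        out[res.key] = out.get(res.key, 0.0) + float(area)
    return out


def _isolated_chain(structure: Structure, chain_id: str) -> Chain:
    return structure.chain(chain_id)


def buried_interface_area(structure: Structure, chain_a: str, chain_b: str,
                          radii: RadiiSet | None = None,
                          n_points: int = 960) -> float:
    """Interface area (A^2): half the SASA lost when the two chains associate.

    int_area = (SASA(A) + SASA(B) - SASA(AB)) / 2, with each chain's isolated
    SASA computed from its coordinates in place.
    """
    radii = radii or RadiiSet()
    ca = structure.chain(chain_a)
    cb = structure.chain(chain_b)
    pair = Structure(id="pair", chains=[ca, cb])
    area_a = sasa(ca, radii, n_points).sum()
    area_b = sasa(cb, radii, n_points).sum()
    area_ab = sasa(pair, radii, n_points).sum()
    return float((area_a + area_b - area_ab) / 2.0)


def molecular_dot_surface(chain: Chain | Structure, radii: RadiiSet | None = None,
                          dot_density: float = 15.0) -> DotSurface:
    """Dot representation of the chain's contact surface with outward normals.

    Dots are placed on each heavy atom's sphere at the vdW radius (the
    solvent-accessible lattice re-projected to the contact surface); a dot is
    kept when accessible at the solvent-accessible surface, i.e. not inside
    any neighbour's probe-expanded sphere. Normals point along the atom-to-dot
    direction and have unit length.
    """
    radii = radii or RadiiSet()
    _, coords, rads = _atom_arrays(chain, radii)
    rs = rads + radii.probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * rs.max()
    neighbor_lists = tree.query_ball_point(coords, r=max_reach)

    pts_out, nrm_out, own_out = [], [], []
    for i in range(len(coords)):
        n_dots = max(12, int(round(dot_density * 4.0 * np.pi * rads[i] ** 2)))
        dirs = fibonacci_sphere(n_dots)
        sas_pts = coords[i] + rs[i] * dirs
        nbrs = [j for j in neighbor_lists[i]
                if j != i and np.dot(coords[i] - coords[j], coords[i] - coords[j])
                < (rs[i] + rs[j]) ** 2]
        if nbrs:
            d2 = np.sum((sas_pts[:, None, :] - coords[nbrs][None, :, :]) ** 2, axis=2)
            keep = np.all(d2 >= (rs[nbrs] ** 2)[None, :], axis=1)
        else:
            keep = np.ones(n_dots, dtype=bool)
        if not keep.any():
            continue
        pts_out.append(coords[i] + rads[i] * dirs[keep])
        nrm_out.append(dirs[keep])
        own_out.append(np.full(int(keep.sum()), i))
    if not pts_out:
        return DotSurface(points=np.empty((0, 3)), normals=np.empty((0, 3)),
                          owner_atom=np.empty(0, dtype=int))
    return DotSurface(points=np.vstack(pts_out), normals=np.vstack(nrm_out),
                      owner_atom=np.concatenate(own_out))


def _one_way_sc(dots_a: DotSurface, coords_a, rads_a, coords_b, rads_b,
                dots_b: DotSurface, params: ScParams, probe: float) -> float:
    # interface patch of A: dots whose solvent-accessible point is buried by
    # the partner (inside some B atom's probe-expanded sphere)
    own = dots_a.owner_atom
    sas_pts = coords_a[own] + (rads_a[own] + probe)[:, None] * dots_a.normals
    tree_b_atoms = cKDTree(coords_b)
    d_atom, j_atom = tree_b_atoms.query(sas_pts)
    buried = d_atom < rads_b[j_atom] + probe
    if not buried.any():
        raise ValueError("surfaces not in contact: no buried interface dots")
    # trim the peripheral rim of the patch
    if (~buried).any() and buried.sum() > 8:
        tree_out = cKDTree(dots_a.points[~buried])
        d_edge, _ = tree_out.query(dots_a.points[buried])
        core = d_edge > params.trim
        if not core.any():
            core = np.ones(int(buried.sum()), dtype=bool)
    else:
        core = np.ones(int(buried.sum()), dtype=bool)
    idx = np.flatnonzero(buried)[core]
    tree_b = cKDTree(dots_b.points)
    d, j = tree_b.query(dots_a.points[idx])
    within = d <= params.interface_band
    if not within.any():
        raise ValueError("surfaces not in contact: nearest partner dots "
                         "beyond the interface band")
    idx, d, j = idx[within], d[within], j[within]
    s = (np.sum(dots_a.normals[idx] * -dots_b.normals[j], axis=1)
         * np.exp(-params.w * d ** 2))
    return float(np.median(s))


def shape_complementarity(structure: Structure, chain_a: str, chain_b: str,
                          params: ScParams | None = None,
                          radii: RadiiSet | None = None) -> float:
    """Shape-complementarity statistic Sc for the interface of two chains.

    Each chain's dot surface is built in isolation. The interface patch of a
    chain consists of the dots that become solvent-inaccessible when the
    partner binds (buried by the partner's probe-expanded spheres), minus a
    trimmed peripheral rim. Each patch dot x pairs with the nearest partner
    dot x' (pairs farther than the interface band are dropped) and scores
    S = (n_x . -n_x') exp(-w d^2); Sc = (median over A->B + median over
    B->A) / 2, in [-1, 1]. The value is reported signed: anti-correlated
    surfaces can score below zero.
    """
    params = params or ScParams()
    radii = radii or RadiiSet()
    ca = structure.chain(chain_a)
    cb = structure.chain(chain_b)
    _, coords_a, rads_a = _atom_arrays(ca, radii)
    _, coords_b, rads_b = _atom_arrays(cb, radii)
    dots_a = molecular_dot_surface(ca, radii, params.dot_density)
    dots_b = molecular_dot_surface(cb, radii, params.dot_density)
    if len(dots_a.points) == 0 or len(dots_b.points) == 0:
        raise ValueError("empty dot surface")
    probe = radii.probe_radius
    return 0.5 * (_one_way_sc(dots_a, coords_a, rads_a, coords_b, rads_b,
                              dots_b, params, probe)
                  + _one_way_sc(dots_b, coords_b, rads_b, coords_a, rads_a,
                                dots_a, params, probe))
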
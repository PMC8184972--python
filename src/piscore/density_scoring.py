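"""Cryo-EM density handling, fit-to-map scores, and the weighted combined score.

The fit of an atomic model to an experimental map is measured globally
(masked Pearson cross-correlation against a Gaussian-simulated model map),
locally (a per-residue overlap coefficient between experimental and
simulated density in a zone around each residue), and at the interface
(iCCC: the mean per-residue score over the interface residues). The weighted
combined score blends the normalized PI-score (capped at |2.5|) with iCCC:

    combined = (w1 * normalized_PI + w2 * iCCC) / (w1 + w2),  w2 = 10,

where w1 is the index of the 0.1-wide bin containing |normalized_PI|
(w1 = ceil(10 |normalized_PI|), 0..10). The result lies in [-1, 1];
higher is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

from .interface_core import Interface
from .structure_io import Structure

__all__ = [
    "DensityMap", "CombinedScoreConfig", "CombinedResult",
    "read_map", "write_map", "simulate_map", "global_ccc",
    "per_residue_cc", "interface_ccc", "normalize_pi_score", "combined_score",
]


@dataclass
class DensityMap:
    """A 3-D density grid with cubic voxels, indexed grid[ix, iy, iz]."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray
    resolution_hint: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    def frac_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional grid indices of Cartesian points (A)."""
        return (np.atleast_2d(xyz) - self.origin) / self.voxel_size

    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the map at Cartesian points."""
        idx = self.frac_index(xyz).T
        return map_coordinates(self.grid, idx, order=1, mode="constant", cval=0.0)


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map; axis order is canonicalized to (x, y, z).

    The origin comes from the header ORIGIN record when present, otherwise
    from nstart * voxel_size. Raises ValueError naming the offending header
    field for malformed input.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read map {path}: {exc}") from exc
    grid = np.array(ccp4.grid, copy=True)
    spacing = ccp4.grid.spacing
    if not (spacing[0] > 0 and abs(spacing[0] - spacing[1]) < 1e-4
            and abs(spacing[0] - spacing[2]) < 1e-4):
        raise ValueError(f"map {path}: header field CELLA implies non-cubic "
                         f"voxels {spacing}; only cubic voxels are supported")
    voxel = float(spacing[0])
    origin = np.array([ccp4.header_float(50), ccp4.header_float(51),
                       ccp4.header_float(52)])
    if not np.any(origin):
        nstart = np.array([ccp4.header_i32(5), ccp4.header_i32(6),
                           ccp4.header_i32(7)], dtype=float)
        origin = nstart * voxel
    return DensityMap(grid=grid, voxel_size=voxel, origin=origin)


def write_map(density: DensityMap, path: str | Path) -> None:
    """Write a map as CCP4 mode-2 (float32) with an ORIGIN header record."""
    ccp4 = gemmi.Ccp4Map()
    nx, ny, nz = density.grid.shape
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(density.grid, dtype=np.float32))
    a = nx * density.voxel_size
    b = ny * density.voxel_size
    c = nz * density.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(a, b, c, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(2)
    for k, v in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(k, float(v))
    ccp4.write_ccp4_map(str(path))


def simulate_map(structure: Structure, resolution: float,
                 voxel_size: float = 1.0, sigma_factor: float = 0.356,
                 pad_sigmas: float = 3.0) -> DensityMap:
    """Gaussian-simulated density for a model at a nominal resolution.

    Each heavy atom contributes a unit-amplitude isotropic Gaussian of width
    sigma = sigma_factor * resolution; the grid extends at least
    `pad_sigmas` * sigma beyond the model bounding box.
    """
    if resolution <= 2 * voxel_size:
        raise ValueError("resolution must exceed twice the voxel size")
    coords = np.array([a.coord for r in structure.all_residues()
                       for a in r.heavy_atoms()])
    if len(coords) == 0:
        raise ValueError("structure has no heavy atoms")
    sigma = sigma_factor * resolution
    pad = pad_sigmas * sigma
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    grid = np.zeros(shape, dtype=np.float64)

    cut = 4.0 * sigma
    ncut = int(math.ceil(cut / voxel_size))
    axes = [lo[k] + voxel_size * np.arange(shape[k]) for k in range(3)]
    for x in coords:
        ijk0 = np.floor((x - lo) / voxel_size).astype(int)
        sl = [slice(max(0, ijk0[k] - ncut), min(shape[k], ijk0[k] + ncut + 1))
              for k in range(3)]
        gx = axes[0][sl[0]] - x[0]
        gy = axes[1][sl[1]] - x[1]
        gz = axes[2][sl[2]] - x[2]
        d2 = (gx[:, None, None] ** 2 + gy[None, :, None] ** 2
              + gz[None, None, :] ** 2)
        grid[sl[0], sl[1], sl[2]] += np.exp(-d2 / (2.0 * sigma ** 2))
    return DensityMap(grid=grid.astype(np.float32), voxel_size=voxel_size,
                      origin=lo, resolution_hint=resolution)


def _resample_onto(target: DensityMap, source: DensityMap) -> np.ndarray:
    """Source map values at the target's voxel centres (trilinear)."""
    nx, ny, nz = target.grid.shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    xyz = (np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) * target.voxel_size
           + target.origin)
    return source.interpolate(xyz).reshape(target.grid.shape)


def global_ccc(exp_map: DensityMap, model_map: DensityMap,
               mask: np.ndarray | None = None) -> float:
    """Masked Pearson correlation between experimental and model maps.

    The model map is resampled onto the experimental grid; the default mask
    keeps voxels where the resampled model density exceeds its mean.
    """
    model_on_exp = _resample_onto(exp_map, model_map)
    if mask is None:
        mask = model_on_exp > model_on_exp.mean()
    u = np.asarray(exp_map.grid, dtype=float)[mask]
    v = model_on_exp[mask]
    if u.size < 2 or np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("zero-variance region: correlation undefined")
    return float(np.corrcoef(u, v)[0, 1])


def per_residue_cc(exp_map: DensityMap, structure: Structure, resolution: float,
                   window_residues: int = 1, voxel_size: float | None = None
                   ) -> dict[tuple, float]:
    """Per-residue overlap coefficient between experimental and simulated maps.

    For each residue, the score is sum(u v) / sqrt(sum u^2 sum v^2) over
    experimental-grid voxels within max(3.0, 0.5 * resolution) A of the atoms
    of the residue and its +-window_residues chain neighbours. Residues whose
    zone falls outside the map are omitted (reported missing).
    """
    voxel_size = voxel_size or exp_map.voxel_size
    sim = simulate_map(structure, resolution, voxel_size=voxel_size)
    sim_on_exp = _resample_onto(exp_map, sim)
    radius = max(3.0, 0.5 * resolution)

    nx, ny, nz = exp_map.grid.shape
    u_all = np.asarray(exp_map.grid, dtype=float)
    scores: dict[tuple, float] = {}
    for chain in structure.chains:
        for i, res in enumerate(chain.residues):
            window = chain.residues[max(0, i - window_residues):i + window_residues + 1]
            coords = np.array([a.coord for r in window for a in r.heavy_atoms()])
            if len(coords) == 0:
                continue
            lo = np.floor((coords.min(0) - radius - exp_map.origin)
                          / exp_map.voxel_size).astype(int)
            hi = np.ceil((coords.max(0) + radius - exp_map.origin)
                         / exp_map.voxel_size).astype(int) + 1
            lo_c = np.maximum(lo, 0)
            hi_c = np.minimum(hi, [nx, ny, nz])
            if np.any(hi_c <= lo_c):
                continue  # residue outside the map -> missing
            ix, iy, iz = np.meshgrid(*[np.arange(lo_c[k], hi_c[k]) for k in range(3)],
                                     indexing="ij")
            vox_xyz = (np.stack([ix, iy, iz], -1).reshape(-1, 3)
                       * exp_map.voxel_size + exp_map.origin)
            d2min = np.full(len(vox_xyz), np.inf)
            for x in coords:
                d2 = np.sum((vox_xyz - x) ** 2, axis=1)
                np.minimum(d2min, d2, out=d2min)
            inside = d2min <= radius ** 2
            if not inside.any():
                continue
            sel = (slice(lo_c[0], hi_c[0]), slice(lo_c[1], hi_c[1]),
                   slice(lo_c[2], hi_c[2]))
            u = u_all[sel].reshape(-1)[inside]
            v = sim_on_exp[sel].reshape(-1)[inside]
            denom = math.sqrt(float(np.sum(u * u)) * float(np.sum(v * v)))
            if denom == 0:
                continue
            scores[res.key] = float(np.sum(u * v) / denom)
    return scores


def interface_ccc(per_residue_scores: dict[tuple, float],
                  interface: Interface) -> float:
    """iCCC: mean per-residue density score over the interface residues."""
    import warnings

    vals, missing = [], []
    for key in sorted(interface.residues):
        score = per_residue_scores.get(key)
        if score is None:
            missing.append(key)
        else:
            vals.append(score)
    if not vals:
        raise ValueError("no interface residue has a density score")
    if missing:
        warnings.warn(f"{len(missing)} interface residue(s) lack density "
                      "scores; excluded from iCCC")
    return float(np.mean(vals))


def normalize_pi_score(pi: float, cap: float = 2.5) -> float:
    """Normalize a signed PI-score to [-1, 1] with saturation at |cap|.

    min(pi/cap, 1) for positive scores, max(pi/cap, -1) for negative, 0 at 0.
    """
    if pi > 0:
        return min(pi / cap, 1.0)
    if pi < 0:
        return max(pi / cap, -1.0)
    return 0.0


@dataclass
class CombinedScoreConfig:
    norm_cap: float = 2.5
    bin_width: float = 0.1
    w2: float = 10.0

    def __post_init__(self) -> None:
        if self.w2 <= 0:
            raise ValueError("w2 must be positive")
        if abs(round(1.0 / self.bin_width) * self.bin_width - 1.0) > 1e-9:
            raise ValueError("bin_width must divide 1.0")

    def w1(self, normalized_pi: float) -> int:
        """Index of the bin_width-wide bin containing |normalized PI-score|."""
        if normalized_pi == 0:
            return 0
        n_bins = round(1.0 / self.bin_width)
        return min(n_bins, math.ceil(abs(normalized_pi) / self.bin_width - 1e-12))


@dataclass
class CombinedResult:
    normalized_pi: float
    w1: int
    iccc: float
    combined: float


def combined_score(pi: float, iccc: float,
                   config: CombinedScoreConfig | None = None) -> CombinedResult:
    """Weighted combined score blending interface quality and fit-to-map.

    combined = (w1 * normalized_pi + w2 * iccc) / (w1 + w2), with the
    normalized PI-score capped at |1|, w1 its 0.1-bin index (0..10) and
    w2 = 10. When the PI-score is exactly 0, w1 = 0 and the combined score
    equals iCCC. Output is in [-1, 1]; higher is better.
    """
    config = config or CombinedScoreConfig()
    if not -1.0 <= iccc <= 1.0:
        raise ValueError(f"iCCC {iccc} outside [-1, 1]")
    norm = normalize_pi_score(pi, config.norm_cap)
    w1 = config.w1(norm)
    combined = (w1 * norm + config.w2 * iccc) / (w1 + config.w2)
    return CombinedResult(normalized_pi=norm, w1=w1, iccc=iccc, combined=combined)
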
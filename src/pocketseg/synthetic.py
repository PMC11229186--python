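"""Deterministic toy complexes and grid pairs for end-to-end testing.

Real training data for pocket prediction (protein-ligand complexes with
cavity annotations) cannot ship with the package, so this module generates
miniature stand-ins with fully known geometry:

* :func:`make_toy_complex` -- a hollow shell of protein-like heavy atoms
  around an internal cavity.  The cavity's interior point lattice is the
  ground-truth pocket, and a handful of pseudo-ligand atoms sit near the
  cavity centre.  Two shell/cavity shapes (spherical and prolate-elongated)
  emulate distinct fold classes for transfer-learning experiments.
* :func:`make_grid_pair` -- a feature/label grid pair built directly in
  voxel space (shell-like activations around a blob label) for network and
  training tests that do not need chemistry perception.

Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .grids import FeatureGrid, LabelGrid
from .structure_io import AtomRecord, CleanStructure, RawStructure, format_pdb

_ELEMENTS = {"C": 6, "N": 7, "O": 8, "S": 16, "P": 15}
DEFAULT_PALETTE = {"C": 0.6, "N": 0.15, "O": 0.15, "S": 0.05, "P": 0.05}
_ELONGATION = 1.8  # z semi-axis scale of the prolate class


@dataclass(frozen=True)
class ToyComplexSpec:
    seed: int = 0
    n_atoms: int = 160
    shell_radius: float = 12.0
    cavity_center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cavity_radius: float = 5.0
    element_palette: dict | None = None
    class_shape: str = "sphere"  # "sphere" | "elongated"

    def __post_init__(self):
        if self.cavity_radius >= self.shell_radius:
            raise ConfigError("cavity radius must be smaller than the shell radius")
        if self.n_atoms < 4:
            raise ConfigError("need at least 4 atoms")
        if self.class_shape not in ("sphere", "elongated"):
            raise ConfigError(f"unknown class shape {self.class_shape!r}")


@dataclass
class ToyComplex:
    structure: CleanStructure
    ligand_atoms: np.ndarray  # (m, 3)
    truth_points: np.ndarray  # (k, 3) lattice filling the cavity
    spec: ToyComplexSpec

    @property
    def cavity_center(self) -> np.ndarray:
        return np.asarray(self.spec.cavity_center_offset, dtype=np.float64)


def _shape_scale(class_shape: str) -> np.ndarray:
    if class_shape == "elongated":
        return np.array([1.0, 1.0, _ELONGATION])
    return np.ones(3)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Evenly distributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Generate a shell-with-cavity pseudo-protein, its pocket and ligand."""
    rng = np.random.default_rng(spec.seed)
    scale = _shape_scale(spec.class_shape)
    center = np.asarray(spec.cavity_center_offset, dtype=np.float64)

    # shell atoms: evenly spread directions, jittered radius, shape-scaled
    dirs = _fibonacci_sphere(spec.n_atoms)
    radii = spec.shell_radius * (1.0 + rng.uniform(-0.05, 0.05, size=spec.n_atoms))
    coords = center + dirs * radii[:, None] * scale

    palette = spec.element_palette or DEFAULT_PALETTE
    symbols = rng.choice(list(palette), size=spec.n_atoms, p=np.array(list(palette.values())))
    atoms = [
        AtomRecord(
            element_symbol=sym,
            atomic_number=_ELEMENTS[sym],
            coords=xyz,
            residue_name="UNK",
            chain_id="A",
            is_hetero=False,
            serial=i + 1,
            atom_name=f"{sym}{(i % 99) + 1}"[:4],
            res_seq=i + 1,
        )
        for i, (sym, xyz) in enumerate(zip(symbols, coords))
    ]
    structure = CleanStructure(atoms=atoms, source_id=f"toy-{spec.class_shape}-{spec.seed}")

    # ground-truth pocket: 1 A lattice filling the (shape-scaled) cavity
    r = spec.cavity_radius
    ax = np.arange(-np.ceil(r * scale.max()), np.ceil(r * scale.max()) + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    lattice = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    inside = np.linalg.norm(lattice / scale, axis=1) <= r
    truth_points = center + lattice[inside]

    # pseudo-ligand: 1-5 atoms well inside the cavity
    n_lig = int(rng.integers(1, 6))
    lig_dirs = rng.normal(size=(n_lig, 3))
    lig_dirs /= np.linalg.norm(lig_dirs, axis=1, keepdims=True)
    lig_r = rng.uniform(0.0, r / 2.0, size=n_lig)
    ligand = center + lig_dirs * lig_r[:, None]

    return ToyComplex(structure=structure, ligand_atoms=ligand, truth_points=truth_points, spec=spec)


def write_toy_pdb(complex_: ToyComplex, path) -> None:
    """Write the toy complex: ATOM records for the shell, HETATM for the ligand."""
    serial = len(complex_.structure.atoms)
    lig_atoms = [
        AtomRecord(
            element_symbol="C",
            atomic_number=6,
            coords=xyz,
            residue_name="LIG",
            chain_id="L",
            is_hetero=True,
            serial=serial + i + 1,
            atom_name=f"C{i + 1}",
            res_seq=1,
        )
        for i, xyz in enumerate(complex_.ligand_atoms)
    ]
    combined = RawStructure(
        atoms=list(complex_.structure.atoms) + lig_atoms,
        n_chains=2,
        source_id=complex_.structure.source_id,
    )
    with open(path, "w") as fh:
        fh.write(format_pdb(combined))


def make_grid_pair(
    seed: int,
    side: int = 16,
    channels: int = 18,
    shape: str = "sphere",
    spacing: float = 2.0,
) -> tuple[FeatureGrid, LabelGrid]:
    """Feature/label grid pair built directly in voxel space.

    The label is a compact blob (sphere or prolate ellipsoid) near the grid
    centre; the features are shell-like activations in the voxels surrounding
    the blob plus sparse background noise, so the mapping from features to
    label is learnable but not trivial.
    """
    if side < 8:
        raise ConfigError("grid side must be >= 8")
    if shape not in ("sphere", "elongated"):
        raise ConfigError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed)
    origin = -spacing * (side - 1) / 2.0 * np.ones(3)

    blob_center = rng.uniform(-1.5, 1.5, size=3) + (side - 1) / 2.0
    radius = side / 5.0
    scale = np.array([1.0, 1.0, 1.6]) if shape == "elongated" else np.ones(3)
    if shape == "elongated":  # keep volumes comparable between classes
        scale *= (1.0 / 1.6) ** (1.0 / 3.0)

    idx = np.indices((side,) * 3).reshape(3, -1).T.astype(np.float64)
    d = np.linalg.norm((idx - blob_center) / scale, axis=1).reshape((side,) * 3)
    label = (d <= radius).astype(np.uint8)

    values = np.zeros((side,) * 3 + (channels,), dtype=np.float32)
    shell = (d > radius) & (d <= radius + 2.0)
    n_shell = int(shell.sum())
    # shell voxels carry atom-like counts in a few type channels
    type_ch = rng.integers(0, min(6, channels), size=n_shell)
    counts = rng.integers(1, 3, size=n_shell).astype(np.float32)
    si, sj, sk = np.nonzero(shell)
    values[si, sj, sk, type_ch] = counts
    if channels > 9:
        values[si, sj, sk, 9] = rng.uniform(1.0, 3.0, size=n_shell)  # hybridization-like
        values[si, sj, sk, 13 % channels] = counts  # neighbour-count-like
    # sparse background noise
    n_noise = max(1, side**3 // 50)
    ni = rng.integers(0, side, size=(n_noise, 3))
    nc = rng.integers(0, channels, size=n_noise)
    values[ni[:, 0], ni[:, 1], ni[:, 2], nc] += 1.0

    feature = FeatureGrid(
        values=values, origin=origin, spacing=spacing, source_id=f"pair-{shape}-{seed}"
    )
    return feature, LabelGrid(values=label, origin=origin.copy(), spacing=spacing)


def grid_pair_truth_center(label: LabelGrid) -> np.ndarray:
    """Real-space centroid of the label blob (the DCC reference point)."""
    idx = np.argwhere(label.values > 0)
    centroid = idx.mean(axis=0)
    return label.origin + label.spacing * centroid
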
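"""Voxel featurization: protein structures -> 18-channel grids, pockets -> labels.

A cubic grid (default 36 voxels per side spanning 70 A, i.e. 2 A between
voxel centres) is centred on the protein's heavy-atom centroid.  Each heavy
atom is assigned to the voxel whose centre is nearest its coordinates and
contributes to 18 channels:

* 9 mutually exclusive **atom-type** channels — B, C, N, O, P, S, Se,
  halogen (F/Cl/Br/I) and metal (Li/Be/Na/Mg/Al, Z 19-32, 37-51, 55-84,
  87-104) — incremented by 1 per atom;
* 9 **atom-property** channels — hybridization order, hydrophobicity,
  Gasteiger partial charge, attached-heteroatom count, attached-heavy-atom
  count, H-bond acceptor, aromaticity, H-bond donor, ring membership —
  accumulated by summation when atoms share a voxel.

Chemical perception (bonds, aromaticity, rings, charges, donor/acceptor and
hydrophobicity SMARTS) is delegated to RDKit through
:class:`MolecularContext`; the SMARTS rules are spelled out below and in the
methods documentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStructureError, FeaturizationError
from .grids import FeatureGrid, LabelGrid, ProbGrid  # noqa: F401  (re-export)
from .structure_io import AtomRecord, CleanStructure, format_pdb

logger = logging.getLogger(__name__)

# ----------------------------------------------------------------- grid config
@dataclass(frozen=True)
class GridConfig:
    """Cubic grid geometry: ``side`` voxel centres spanning ``span`` Angstrom.

    The first-to-last voxel-centre distance along each axis is ``span``, so
    the centre spacing is ``span / (side - 1)`` (2 A under the defaults).
    """

    side: int = 36
    span: float = 70.0
    channels: int = 18

    def __post_init__(self):
        if self.side < 2:
            raise FeaturizationError("grid side must be >= 2")
        if self.span <= 0:
            raise FeaturizationError("grid span must be positive")

    @property
    def spacing(self) -> float:
        return self.span / (self.side - 1)

    def origin_for_center(self, center: np.ndarray) -> np.ndarray:
        return np.asarray(center, dtype=np.float64) - self.span / 2.0


# ------------------------------------------------------------- atom-type rules
_HALOGENS = frozenset({9, 17, 35, 53})
_METALS = frozenset(
    {3, 4, 11, 12, 13}
    | set(range(19, 33))
    | set(range(37, 52))
    | set(range(55, 85))
    | set(range(87, 105))
)

TYPE_CHANNEL_NAMES = ("B", "C", "N", "O", "P", "S", "Se", "halogen", "metal")
PROPERTY_CHANNEL_NAMES = (
    "hybridization",
    "hydrophobic",
    "partial_charge",
    "heteroatoms",
    "non_hydrogens",
    "acceptor",
    "aromatic",
    "donor",
    "ring",
)
CHANNEL_NAMES = TYPE_CHANNEL_NAMES + PROPERTY_CHANNEL_NAMES


def classify_atom_type(atomic_number: int) -> int | None:
    """Map an atomic number to its type-channel index (0-8), or None.

    Hydrogen and elements outside the nine classes have no channel.
    """
    if atomic_number < 1:
        raise FeaturizationError(f"invalid atomic number {atomic_number}")
    direct = {5: 0, 6: 1, 7: 2, 8: 3, 15: 4, 16: 5, 34: 6}
    if atomic_number in direct:
        return direct[atomic_number]
    if atomic_number in _HALOGENS:
        return 7
    if atomic_number in _METALS:
        return 8
    return None


@dataclass
class AtomFeatures:
    """Type-channel index (or None) plus the 9 property values of one atom."""

    type_channel: int | None
    properties: np.ndarray  # (9,)

    def __post_init__(self):
        self.properties = np.asarray(self.properties, dtype=np.float32)
        if self.properties.shape != (9,):
            raise FeaturizationError("property vector must have 9 entries")


# ------------------------------------------------------- chemistry perception
# Documented SMARTS rules (standard published pharmacophore definitions):
_HYDROPHOBIC_SMARTS = "[#6;+0;!$([#6]~[#7,#8,#9])]"
_DONOR_SMARTS = "[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O,S;H1;+0]),$([n;H1;+0])]"
_ACCEPTOR_SMARTS = (
    "[$([O,S;H1;v2]-[!$(*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
    "$([N;v3;!$(N-*=!@[O,N,P,S])]),$([nH0,o,s;+0])]"
)

_HYBRIDIZATION_ORDER = {
    "S": 0.0,
    "SP": 1.0,
    "SP2": 2.0,
    "SP3": 3.0,
    "SP2D": 2.0,
    "SP3D": 4.0,
    "SP3D2": 5.0,
}


class MolecularContext:
    """RDKit-backed perception of bonds, rings, charges and pharmacophores.

    Atoms are addressed by PDB serial number so that featurization can look
    up the record-level atoms of a :class:`CleanStructure`.
    """

    def __init__(self, mol, serial_to_idx: dict[int, int]):
        from rdkit.Chem import AllChem

        self.mol = mol
        self._serial_to_idx = serial_to_idx
        AllChem.ComputeGasteigerCharges(mol)
        self._matches = {}
        for name, smarts in (
            ("hydrophobic", _HYDROPHOBIC_SMARTS),
            ("donor", _DONOR_SMARTS),
            ("acceptor", _ACCEPTOR_SMARTS),
        ):
            from rdkit import Chem

            patt = Chem.MolFromSmarts(smarts)
            self._matches[name] = {m[0] for m in mol.GetSubstructMatches(patt, maxMatches=10**6)}

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_structure(cls, structure: CleanStructure) -> "MolecularContext":
        """Perceive a cleaned structure via its PDB representation."""
        from rdkit import Chem

        block = format_pdb(structure)
        mol = Chem.MolFromPDBBlock(block, sanitize=False, removeHs=True, proximityBonding=True)
        if mol is None:
            raise FeaturizationError(f"RDKit could not read structure {structure.source_id!r}")
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            # fall back to partial sanitization: keep rings/valence info usable
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
        serial_to_idx: dict[int, int] = {}
        for atom in mol.GetAtoms():
            info = atom.GetPDBResidueInfo()
            if info is not None:
                serial_to_idx[info.GetSerialNumber()] = atom.GetIdx()
        return cls(mol, serial_to_idx)

    @classmethod
    def from_mol(cls, mol) -> "MolecularContext":
        """Wrap a ready rdkit Mol; serials are taken as atom index + 1."""
        return cls(mol, {a.GetIdx() + 1: a.GetIdx() for a in mol.GetAtoms()})

    # --------------------------------------------------------------- queries
    def features_for_serial(self, serial: int) -> np.ndarray:
        idx = self._serial_to_idx.get(serial)
        if idx is None:
            raise FeaturizationError(f"no perceived atom for serial {serial}")
        atom = self.mol.GetAtomWithIdx(idx)
        charge = atom.GetDoubleProp("_GasteigerCharge") if atom.HasProp("_GasteigerCharge") else 0.0
        if not np.isfinite(charge):
            charge = 0.0
        heavy = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        hetero = [n for n in heavy if n.GetAtomicNum() not in (1, 6)]
        return np.array(
            [
                _HYBRIDIZATION_ORDER.get(str(atom.GetHybridization()), 0.0),
                1.0 if idx in self._matches["hydrophobic"] else 0.0,
                charge,
                float(len(hetero)),
                float(len(heavy)),
                1.0 if idx in self._matches["acceptor"] else 0.0,
                1.0 if atom.GetIsAromatic() else 0.0,
                1.0 if idx in self._matches["donor"] else 0.0,
                1.0 if atom.IsInRing() else 0.0,
            ],
            dtype=np.float32,
        )


def compute_atom_features(atom: AtomRecord, context: MolecularContext) -> AtomFeatures:
    """Full 18-channel description of one atom (type channel + 9 properties)."""
    try:
        props = context.features_for_serial(atom.serial)
    except FeaturizationError:
        raise
    except Exception as exc:  # pragma: no cover - rdkit edge cases
        raise FeaturizationError(f"perception failed for atom {atom.serial}: {exc}") from exc
    return AtomFeatures(type_channel=classify_atom_type(atom.atomic_number), properties=props)


# ---------------------------------------------------------------- voxelization
def protein_center(structure: CleanStructure) -> np.ndarray:
    """Unweighted mean of the heavy-atom coordinates."""
    if not structure.atoms:
        raise EmptyStructureError("cannot compute the centre of an empty structure")
    return structure.coordinates().mean(axis=0)


def world_to_voxel(coords: np.ndarray, origin: np.ndarray, spacing: float) -> np.ndarray:
    """Nearest-voxel-centre assignment; half-way ties go to the lower index."""
    offset = (np.asarray(coords, dtype=np.float64) - origin) / spacing
    return np.ceil(offset - 0.5).astype(np.int64)


def voxelize(
    structure: CleanStructure,
    config: GridConfig | None = None,
    context: MolecularContext | None = None,
    center: np.ndarray | None = None,
) -> FeatureGrid:
    """Build the (side, side, side, 18) feature tensor for a cleaned structure.

    Atoms whose nearest voxel falls outside the grid are discarded (their
    count is logged).  If every atom falls outside, an all-zero grid is
    returned with a warning.
    """
    config = config or GridConfig()
    if context is None:
        context = MolecularContext.from_structure(structure)
    if center is None:
        center = protein_center(structure)
    origin = config.origin_for_center(center)
    spacing = config.spacing
    values = np.zeros((config.side,) * 3 + (config.channels,), dtype=np.float32)

    coords = structure.coordinates()
    idx = world_to_voxel(coords, origin, spacing)
    in_grid = np.all((idx >= 0) & (idx < config.side), axis=1)
    n_out = int((~in_grid).sum())
    if n_out:
        logger.warning("%d atom(s) fall outside the %d-voxel grid and were discarded",
                       n_out, config.side)
    if not in_grid.any():
        logger.warning("all atoms fall outside the grid; returning an empty feature grid")
    for atom, (i, j, k), ok in zip(structure.atoms, idx, in_grid):
        if not ok:
            continue
        feats = compute_atom_features(atom, context)
        if feats.type_channel is not None:
            values[i, j, k, feats.type_channel] += 1.0
        values[i, j, k, 9:] += feats.properties
    return FeatureGrid(
        values=values,
        origin=origin,
        spacing=spacing,
        source_id=structure.source_id,
        channel_names=CHANNEL_NAMES,
    )


def voxelize_label(
    pocket_points: np.ndarray,
    config: GridConfig | None = None,
    center: np.ndarray | None = None,
) -> LabelGrid:
    """Mark every voxel containing at least one pocket point with 1.

    ``center`` must be the same protein centre used for the paired feature
    grid so both grids share origin and spacing exactly.
    """
    config = config or GridConfig()
    if center is None:
        raise FeaturizationError("voxelize_label needs the paired grid centre")
    origin = config.origin_for_center(center)
    values = np.zeros((config.side,) * 3, dtype=np.uint8)
    pts = np.asarray(pocket_points, dtype=np.float64).reshape(-1, 3)
    if len(pts):
        idx = world_to_voxel(pts, origin, config.spacing)
        ok = np.all((idx >= 0) & (idx < config.side), axis=1)
        values[idx[ok, 0], idx[ok, 1], idx[ok, 2]] = 1
    return LabelGrid(values=values, origin=origin, spacing=config.spacing)
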
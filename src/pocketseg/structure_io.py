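"""PDB reading and protein-only cleaning.

Parsing is done with gemmi; this module reduces its hierarchy to flat,
ordered atom records and applies the cleaning contract used throughout the
package: drop waters, hydrogens and non-polymer hetero fragments (ligands,
ions, buffer molecules), keep modified residues that are part of the
polypeptide (selenomethionine and friends), keep the first alternate
location of each atom.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})


@dataclass
class AtomRecord:
    element_symbol: str
    atomic_number: int
    coords: np.ndarray  # (3,) Angstrom
    residue_name: str
    chain_id: str
    is_hetero: bool
    serial: int
    atom_name: str = ""
    res_seq: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise FormatError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.atomic_number < 1:
            raise FormatError(f"atom {self.serial}: atomic number must be >= 1")


@dataclass
class RawStructure:
    atoms: list[AtomRecord]
    n_chains: int
    source_id: str = ""


@dataclass
class CleanStructure:
    """Protein heavy atoms only: no waters, no hydrogens, non-empty."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=np.float64)


def _first_content_line(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            return line
    return "<empty input>"


def read_structure(pdb_text: str, source_id: str = "") -> RawStructure:
    """Parse PDB-format text into an ordered list of atom records.

    Keeps every ATOM/HETATM record (first altloc per atom); raises
    :class:`FormatError` on unparseable input or input with no atoms.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB input: {exc}") from exc
    atoms: list[AtomRecord] = []
    chains: set[str] = set()
    seen_altloc: set[tuple] = set()
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "\x00"):
                        key = (chain.name, res.seqid.num, res.name, atom.name)
                        if key in seen_altloc:
                            continue  # keep only the first alternate location
                        seen_altloc.add(key)
                    el = atom.element
                    atoms.append(
                        AtomRecord(
                            element_symbol=el.name,
                            atomic_number=int(el.atomic_number),
                            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            residue_name=res.name,
                            chain_id=chain.name,
                            is_hetero=(res.het_flag == "H"),
                            serial=int(atom.serial),
                            atom_name=atom.name,
                            res_seq=int(res.seqid.num),
                        )
                    )
                    chains.add(chain.name)
    if not atoms:
        raise FormatError(
            f"no ATOM/HETATM records found (first line: {_first_content_line(pdb_text)!r})"
        )
    return RawStructure(atoms=atoms, n_chains=len(chains), source_id=source_id)


def _is_water(residue_name: str) -> bool:
    if residue_name.upper() in WATER_RESIDUES:
        return True
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_water()


def _is_polymer_residue(residue_name: str) -> bool:
    """True for standard and tabulated modified amino acids (MSE etc.)."""
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def clean_structure(raw: RawStructure) -> CleanStructure:
    """Reduce a raw structure to pure protein heavy atoms.

    Removes water residues, hydrogen/deuterium atoms, and hetero records not
    belonging to the polypeptide (small-molecule fragments, ions).  Atom
    order is preserved.  Raises :class:`EmptyStructureError` if nothing
    survives.
    """
    if not raw.atoms:
        raise EmptyStructureError("raw structure has no atoms")
    kept: list[AtomRecord] = []
    for atom in raw.atoms:
        if atom.atomic_number == 1:
            continue
        if _is_water(atom.residue_name):
            continue
        if atom.is_hetero and not _is_polymer_residue(atom.residue_name):
            continue
        kept.append(atom)
    if not kept:
        raise EmptyStructureError(
            f"no protein heavy atoms remain after cleaning ({raw.source_id or 'input'})"
        )
    return CleanStructure(atoms=kept, source_id=raw.source_id)


def check_chain_limit(raw: RawStructure, max_chains: int = 7) -> bool:
    """True iff the structure has at most ``max_chains`` chains.

    Mirrors the dataset filter that excludes complex polymeric proteins with
    more than 7 chains.
    """
    return raw.n_chains <= max_chains


def write_structure(structure: CleanStructure | RawStructure, path) -> None:
    """Write atom records back out as a minimal PDB file for inspection."""
    with open(path, "w") as fh:
        fh.write(format_pdb(structure))


def format_pdb(structure: CleanStructure | RawStructure) -> str:
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.atom_name or a.element_symbol
        # standard alignment: 1-3 char names start in column 14
        name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"{record}{a.serial % 100000:5d} {name_f} {a.residue_name:>3s} "
            f"{(a.chain_id or 'A')[:1]}{a.res_seq % 10000:4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element_symbol:>2s}\n"
        )
    lines.append("END\n")
    return "".join(lines)
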
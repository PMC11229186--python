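"""Discrete pocket extraction from probability grids, and pocket matching.

The probability grid is thresholded, connected components are labelled
(6/18/26-connectivity via ``scipy.ndimage``), small components are dropped,
and the survivors are ranked by mean probability (ties: larger volume, then
lowest linear voxel index).  Pocket centres are centroids of member voxel
centres in real space; a probability-weighted centre is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .grids import ProbGrid


@dataclass
class Pocket:
    voxel_indices: np.ndarray  # (n, 3) int
    center: np.ndarray  # (3,) Angstrom
    volume: int
    mean_prob: float
    rank: int

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.voxel_indices[:, 0], self.voxel_indices[:, 1], self.voxel_indices[:, 2]] = True
        return m


@dataclass
class PocketSet:
    pockets: list[Pocket]
    source_id: str = ""
    threshold: float = 0.5

    def __len__(self):
        return len(self.pockets)

    def __iter__(self):
        return iter(self.pockets)

    def top(self) -> Pocket | None:
        return self.pockets[0] if self.pockets else None


def binarize(prob: ProbGrid, threshold: float = 0.5) -> np.ndarray:
    """Voxel is positive iff its probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(prob.values >= threshold)


def voxel_to_world(index, origin, spacing: float, side: int | None = None) -> np.ndarray:
    """Centre coordinates of a voxel: origin + spacing * index.

    With ``side`` given, integer indices outside [0, side) raise an error.
    """
    idx = np.asarray(index)
    if side is not None and (np.any(idx < 0) or np.any(idx > side - 1)):
        raise GeometryError(f"voxel index {index} outside grid of side {side}")
    return np.asarray(origin, dtype=np.float64) + float(spacing) * idx


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_pockets(
    prob: ProbGrid,
    threshold: float = 0.5,
    connectivity: int = 26,
    min_voxels: int = 1,
    weighted_centers: bool = False,
    source_id: str = "",
) -> PocketSet:
    """Connected components of the thresholded grid, ranked deterministically."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    binary = binarize(prob, threshold)
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    candidates = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        probs = prob.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        if weighted_centers:
            w = probs / probs.sum()
            centroid_idx = (idx * w[:, None]).sum(axis=0)
        else:
            centroid_idx = idx.mean(axis=0)
        center = voxel_to_world(centroid_idx, prob.origin, prob.spacing)
        first_linear = int(np.ravel_multi_index(idx[0], prob.values.shape))
        candidates.append((float(probs.mean()), len(idx), first_linear, idx, center))
    # rank: mean probability desc, volume desc, lowest linear index
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    pockets = [
        Pocket(voxel_indices=idx, center=center, volume=vol, mean_prob=mp, rank=r + 1)
        for r, (mp, vol, _, idx, center) in enumerate(candidates)
    ]
    return PocketSet(pockets=pockets, source_id=source_id, threshold=threshold)


def match_pockets(pred: PocketSet, reference_centers) -> tuple[list[tuple[Pocket, int]], list[int]]:
    """Greedy one-to-one matching by ascending centre distance.

    Returns (matched (pocket, reference-index) pairs, unmatched reference
    indices).  Each reference is matched to at most one prediction.
    """
    refs = [np.asarray(c, dtype=np.float64) for c in reference_centers]
    pairs = []
    for pi, p in enumerate(pred.pockets):
        for ri, rc in enumerate(refs):
            pairs.append((float(np.linalg.norm(p.center - rc)), pi, ri))
    pairs.sort(key=lambda x: (x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    matched: list[tuple[Pocket, int]] = []
    for d, pi, ri in pairs:
        if pi in used_p or ri in used_r:
            continue
        used_p.add(pi)
        used_r.add(ri)
        matched.append((pred.pockets[pi], ri))
    unmatched = [ri for ri in range(len(refs)) if ri not in used_r]
    return matched, unmatched


def write_pockets_pdb(pockets: PocketSet, prob: ProbGrid, path) -> None:
    """Write pockets as HETATM pseudo-atoms, one per voxel, occupancy = prob."""
    with open(path, "w") as fh:
        serial = 1
        for p in pockets:
            for i, j, k in p.voxel_indices:
                x, y, z = voxel_to_world((i, j, k), prob.origin, prob.spacing)
                occ = float(prob.values[i, j, k])
                fh.write(
                    f"HETATM{serial % 100000:5d}  PKT PCK P{p.rank % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.00:6.2f}          "
                    f" C\n"
                )
                serial += 1
        fh.write("END\n")
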
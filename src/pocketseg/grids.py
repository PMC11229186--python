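"""Voxel-grid containers tying array indices to Angstrom coordinates.

All three grid types share the same geometry convention: ``origin`` is the
real-space centre of voxel (0, 0, 0) and voxel (i, j, k) is centred at
``origin + spacing * (i, j, k)``.  Grids are stored on disk as compressed
``.npz`` archives (values + geometry + channel names) with a bit-exact
round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError


@dataclass
class FeatureGrid:
    """(side, side, side, C) float tensor of per-voxel atom features."""

    values: np.ndarray
    origin: np.ndarray
    spacing: float
    source_id: str = ""
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 4:
            raise GeometryError(f"feature grid must be 4-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("feature grid contains non-finite values")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[3]


@dataclass
class LabelGrid:
    """(side, side, side) binary grid marking ground-truth pocket voxels."""

    values: np.ndarray
    origin: np.ndarray
    spacing: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"label grid must be 3-D, got shape {self.values.shape}")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, [0, 1])):
            raise GeometryError("label grid entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)


@dataclass
class ProbGrid:
    """(side, side, side) grid of pocket probabilities, entries in (0, 1)."""

    values: np.ndarray
    origin: np.ndarray
    spacing: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"probability grid must be 3-D, got shape {self.values.shape}")
        if self.values.min() <= 0.0 or self.values.max() >= 1.0:
            raise GeometryError("probabilities must lie strictly inside (0, 1)")


def same_geometry(a, b, atol: float = 1e-6) -> bool:
    return (
        a.values.shape[:3] == b.values.shape[:3]
        and abs(a.spacing - b.spacing) <= atol
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def require_same_geometry(a, b):
    if not same_geometry(a, b):
        raise GeometryError(
            f"grid geometry mismatch: {a.values.shape[:3]}@{a.origin}/{a.spacing} vs "
            f"{b.values.shape[:3]}@{b.origin}/{b.spacing}"
        )


# ------------------------------------------------------------------ archive IO
def save_grid(path, grid) -> None:
    """Write a grid (Feature/Label/Prob) to a compressed npz archive."""
    meta = {"origin": grid.origin, "spacing": np.float64(grid.spacing)}
    if isinstance(grid, FeatureGrid):
        kind = "feature"
        meta["source_id"] = np.array(grid.source_id)
        meta["channel_names"] = np.array(list(grid.channel_names))
    elif isinstance(grid, LabelGrid):
        kind = "label"
    elif isinstance(grid, ProbGrid):
        kind = "prob"
    else:
        raise TypeError(f"not a grid: {type(grid)}")
    np.savez_compressed(path, kind=np.array(kind), values=grid.values, **meta)


def load_grid(path):
    """Load a grid archive written by :func:`save_grid` (bit-exact)."""
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        values = z["values"]
        origin = z["origin"]
        spacing = float(z["spacing"])
        if kind == "feature":
            return FeatureGrid(
                values=values,
                origin=origin,
                spacing=spacing,
                source_id=str(z["source_id"]),
                channel_names=tuple(str(c) for c in z["channel_names"]),
            )
        if kind == "label":
            return LabelGrid(values=values, origin=origin, spacing=spacing)
        if kind == "prob":
            return ProbGrid(values=values, origin=origin, spacing=spacing)
    raise ValueError(f"unknown grid kind {kind!r} in {path}")
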
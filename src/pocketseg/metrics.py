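"""Dice loss and the binding-site evaluation metrics (DCC, DCA, DVO).

* Dice coefficient: ``2|X ∩ Y| / (|X| + |Y|)`` on binary voxel sets, with
  the both-empty limit defined as 1.
* Dice loss on probabilities: ``1 - (2 Σ y·t + ε) / (Σ (y + t) + ε)``; the
  small interference factor ε keeps the ratio defined when both grids are
  empty and makes the loss smooth.
* DCC: Euclidean distance between predicted and true pocket centres.
* DCA: minimum distance from the predicted pocket centre to any ligand atom.
* DVO: Jaccard index |∩| / |∪| of predicted and true pocket voxel sets.
* Success rate: fraction of pockets with distance ≤ 4 A (the boundary is
  counted as a success by default; configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError

DEFAULT_EPSILON = 1e-6
SUCCESS_THRESHOLD = 4.0  # Angstrom


# ------------------------------------------------------------------- overlap
def _as_binary(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "values", x))
    return arr.astype(bool)


def dice_coefficient(x, y) -> float:
    """Overlap statistic 2|X∩Y|/(|X|+|Y|) on same-geometry binary grids.

    Returns 1.0 when both sets are empty (limit convention).
    """
    xb, yb = _as_binary(x), _as_binary(y)
    if xb.shape != yb.shape:
        raise GeometryError(f"shape mismatch {xb.shape} vs {yb.shape}")
    denom = xb.sum() + yb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(xb, yb).sum() / denom)


def dice_loss(y, t, epsilon: float = DEFAULT_EPSILON) -> float:
    """Smoothed Dice loss between a probability grid y and a binary label t."""
    ya = np.asarray(getattr(y, "values", y), dtype=np.float64)
    ta = np.asarray(getattr(t, "values", t), dtype=np.float64)
    if ya.shape != ta.shape:
        raise GeometryError(f"shape mismatch {ya.shape} vs {ta.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    num = 2.0 * float((ya * ta).sum()) + epsilon
    den = float((ya + ta).sum()) + epsilon
    return 1.0 - num / den


def dice_loss_tensor(y, t_array: np.ndarray, epsilon: float = DEFAULT_EPSILON):
    """Differentiable per-sample-mean Dice loss for training.

    ``y`` is an engine Tensor of shape (N, D, H, W, 1); ``t_array`` the
    matching binary labels.  The loss is the mean over the batch of each
    sample's smoothed Dice loss.
    """
    from .nn.engine import Tensor

    n = y.shape[0]
    t = np.asarray(t_array, dtype=np.float32).reshape(y.shape)
    tt = Tensor(t)
    axes = (1, 2, 3, 4)
    inter = (y * tt).sum(axis=axes)  # (N,)
    sums = y.sum(axis=axes) + tt.sum(axis=axes)
    frac = (2.0 * inter + epsilon) / (sums + epsilon)
    return (1.0 - frac).sum() * (1.0 / n)


# ------------------------------------------------------------------ distances
def dcc(pred_center, true_center) -> float:
    """Distance between predicted and true pocket centres (Angstrom)."""
    a = np.asarray(pred_center, dtype=np.float64)
    b = np.asarray(true_center, dtype=np.float64)
    return float(np.linalg.norm(a - b))


def dca(pred_center, ligand_atoms) -> float:
    """Minimum distance from the predicted centre to any ligand atom."""
    atoms = np.asarray(ligand_atoms, dtype=np.float64).reshape(-1, 3)
    if len(atoms) == 0:
        raise ValueError("DCA requires at least one ligand atom")
    c = np.asarray(pred_center, dtype=np.float64)
    return float(np.linalg.norm(atoms - c, axis=1).min())


def dvo(pred_voxels, true_voxels) -> float:
    """Discretized volume overlap: Jaccard index of the two voxel sets."""
    pb, tb = _as_binary(pred_voxels), _as_binary(true_voxels)
    if pb.shape != tb.shape:
        raise GeometryError(f"shape mismatch {pb.shape} vs {tb.shape}")
    union = np.logical_or(pb, tb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pb, tb).sum() / union)


# ------------------------------------------------------------------ summaries
@dataclass
class EvalRecord:
    """Per-pocket evaluation values; missing metrics stay None."""

    pocket_id: str
    dcc: float | None = None
    dca: float | None = None
    dvo: float | None = None


@dataclass
class SuccessSummary:
    n_total: int
    n_success: int
    threshold: float

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_total


def success_rate(
    distances, threshold: float = SUCCESS_THRESHOLD, inclusive: bool = True
) -> SuccessSummary:
    """Fraction of distances meeting the success criterion (default ≤ 4 A)."""
    d = np.asarray(list(distances), dtype=np.float64)
    if d.size == 0:
        raise ValueError("success_rate requires a non-empty distance list")
    hits = (d <= threshold) if inclusive else (d < threshold)
    return SuccessSummary(n_total=int(d.size), n_success=int(hits.sum()), threshold=threshold)


def records_to_frame(records: list[EvalRecord], threshold: float = SUCCESS_THRESHOLD) -> pd.DataFrame:
    """Tabulate evaluation records with per-row success flags."""
    rows = []
    for r in records:
        rows.append(
            {
                "pocket_id": r.pocket_id,
                "dcc": r.dcc,
                "dca": r.dca,
                "dvo": r.dvo,
                "dcc_success": (r.dcc is not None and r.dcc <= threshold),
                "dca_success": (r.dca is not None and r.dca <= threshold),
            }
        )
    return pd.DataFrame(rows)


def write_report(records: list[EvalRecord], path, threshold: float = SUCCESS_THRESHOLD) -> pd.DataFrame:
    """Write the delimited evaluation report (one row per pocket + summary)."""
    frame = records_to_frame(records, threshold)
    with open(path, "w") as fh:
        frame.to_csv(fh, sep="\t", index=False, float_format="%.4f")
        if len(frame):
            fh.write(
                f"# dcc_success_rate\t{frame['dcc_success'].mean():.4f}\n"
                f"# dca_success_rate\t{frame['dca_success'].mean():.4f}\n"
            )
            if frame["dvo"].notna().any():
                fh.write(f"# mean_dvo\t{frame['dvo'].dropna().mean():.4f}\n")
    return frame
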
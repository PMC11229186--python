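"""Training loop: Dice-loss gradient descent, checkpoint/resume, grouped
validation splitting and fold-class transfer-learning fine-tuning.

Checkpoints capture everything needed for exact breakpoint continuation —
model parameters, Adam state, epoch counter, the shuffling RNG's state and
the loss history — so a run interrupted at epoch *k* and resumed reproduces
the uninterrupted run's history bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import CheckpointError, ConfigError
from .grids import FeatureGrid, LabelGrid, load_grid
from .metrics import DEFAULT_EPSILON, dice_loss_tensor
from .network import DualPathVNet, NetConfig, build_model
from .nn import engine as E
from .nn.layers import Adam

CLASS_LABELS = ("all_alpha", "all_beta", "alpha_plus_beta", "alpha_slash_beta", "unknown")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 10
    learning_rate: float = 1e-4
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    checkpoint_every: int = 10
    resume_from: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass
class FinetuneSchedule:
    """Fine-tuning epoch budget per fold class (α, β, α+β, α/β)."""

    epochs: dict = field(
        default_factory=lambda: {
            "all_alpha": 100,
            "all_beta": 200,
            "alpha_plus_beta": 400,
            "alpha_slash_beta": 500,
        }
    )

    def epochs_for(self, class_label: str) -> int:
        try:
            n = int(self.epochs[class_label])
        except KeyError:
            raise ConfigError(f"no fine-tuning schedule for class {class_label!r}")
        if n < 1:
            raise ConfigError("fine-tuning epochs must be >= 1")
        return n


@dataclass
class IndexEntry:
    feature_path: str
    label_path: str
    group_key: str
    class_label: str = "unknown"


@dataclass
class DatasetIndex:
    entries: list[IndexEntry]

    def __len__(self):
        return len(self.entries)

    def subset_by_class(self, class_label: str) -> "DatasetIndex":
        return DatasetIndex([e for e in self.entries if e.class_label == class_label])

    def load(self) -> list[tuple[FeatureGrid, LabelGrid]]:
        return [(load_grid(e.feature_path), load_grid(e.label_path)) for e in self.entries]


def read_manifest(path) -> DatasetIndex:
    """Read a tab-separated manifest: feature_path, label_path, group_key[, class]."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigError(f"{path}:{lineno}: need at least 3 tab-separated fields")
            cls = parts[3] if len(parts) > 3 else "unknown"
            if cls not in CLASS_LABELS:
                raise ConfigError(f"{path}:{lineno}: unknown class label {cls!r}")
            entries.append(IndexEntry(parts[0], parts[1], parts[2], cls))
    return DatasetIndex(entries)


def grouped_split(
    index: DatasetIndex, fraction: float = 0.1, seed: int = 0
) -> tuple[DatasetIndex, DatasetIndex]:
    """Group-aware train/validation split.

    All entries sharing a ``group_key`` (all structures of one protein) land
    on the same side; the validation side is as close to ``fraction`` of the
    entries as whole-group assignment permits.  Deterministic given the seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError("fraction must lie in (0, 1)")
    if not index.entries:
        raise ConfigError("cannot split an empty index")
    groups: dict[str, list[IndexEntry]] = {}
    for e in index.entries:
        groups.setdefault(e.group_key, []).append(e)
    if len(groups) < 2:
        raise ConfigError("cannot split an index with a single protein group")
    keys = sorted(groups)
    order = np.random.default_rng(seed).permutation(len(keys))
    target = fraction * len(index.entries)
    val_keys: set[str] = set()
    count = 0
    for gi in order:
        size = len(groups[keys[gi]])
        if abs(count + size - target) <= abs(count - target):
            val_keys.add(keys[gi])
            count += size
        if count >= target:
            break
    if not val_keys:  # fraction so small no group fits: take the smallest-overshoot group
        val_keys.add(keys[order[0]])
    if len(val_keys) == len(keys):
        val_keys.discard(keys[order[-1]])
    train_entries = [e for e in index.entries if e.group_key not in val_keys]
    val_entries = [e for e in index.entries if e.group_key in val_keys]
    return DatasetIndex(train_entries), DatasetIndex(val_entries)


# ------------------------------------------------------------------- history
@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(
    path,
    model: DualPathVNet,
    optimizer: Adam | None,
    epoch: int,
    rng: np.random.Generator | None,
    history: TrainingHistory,
    best_params: list[np.ndarray] | None = None,
    train_config: TrainConfig | None = None,
) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.state_arrays()):
        arrays[f"param_{i:04d}"] = p
    if optimizer is not None:
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            arrays[f"adam_m_{i:04d}"] = m
            arrays[f"adam_v_{i:04d}"] = v
    if best_params is not None:
        for i, p in enumerate(best_params):
            arrays[f"best_{i:04d}"] = p
    meta = {
        "net_config": model.config.to_dict(),
        "train_config": None if train_config is None else asdict(train_config),
        "epoch": epoch,
        "adam_t": None if optimizer is None else optimizer.t,
        "adam_lr": None if optimizer is None else optimizer.lr,
        "rng_state": None if rng is None else rng.bit_generator.state,
        "history": {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
            "best_val_loss": history.best_val_loss,
        },
    }
    np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> dict:
    """Load a checkpoint into a dict with a freshly built model inside."""
    if not os.path.exists(path):
        raise CheckpointError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        params = [z[k] for k in sorted(k for k in z.files if k.startswith("param_"))]
        adam_m = [z[k] for k in sorted(k for k in z.files if k.startswith("adam_m_"))]
        adam_v = [z[k] for k in sorted(k for k in z.files if k.startswith("adam_v_"))]
        best = [z[k] for k in sorted(k for k in z.files if k.startswith("best_"))]
    model = build_model(NetConfig.from_dict(meta["net_config"]))
    try:
        model.load_state_arrays(params)
    except ConfigError as exc:
        raise CheckpointError(f"incompatible checkpoint {path}: {exc}") from exc
    hist = meta["history"]
    history = TrainingHistory(
        train_loss=list(hist["train_loss"]),
        val_loss=list(hist["val_loss"]),
        best_epoch=int(hist["best_epoch"]),
        best_val_loss=float(hist["best_val_loss"]),
    )
    return {
        "model": model,
        "meta": meta,
        "adam_m": adam_m,
        "adam_v": adam_v,
        "best_params": best or None,
        "history": history,
        "epoch": int(meta["epoch"]),
    }


# ------------------------------------------------------------------- training
def _stack_dataset(dataset) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for fg, lg in dataset:
        xs.append(np.asarray(fg.values, dtype=np.float32))
        ys.append(np.asarray(lg.values, dtype=np.float32))
    return np.stack(xs), np.stack(ys)


def _eval_loss(model, x: np.ndarray, y: np.ndarray, epsilon: float, batch_size: int) -> float:
    total, n = 0.0, len(x)
    with E.no_grad():
        for i in range(0, n, batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            out = model(xb)
            loss = dice_loss_tensor(out, yb[..., None], epsilon)
            total += loss.item() * len(xb)
    return total / n


def train(
    model: DualPathVNet,
    dataset,
    config: TrainConfig,
    val_dataset=None,
    checkpoint_dir=None,
    stop_loss: float | None = None,
    stop_epoch: int | None = None,
) -> TrainingHistory:
    """Minimise the Dice loss over the dataset by Adam gradient descent.

    ``dataset``/``val_dataset`` are sequences of (FeatureGrid, LabelGrid)
    pairs (or anything with ``.values``).  With ``config.resume_from`` set,
    training continues from that checkpoint and reproduces the uninterrupted
    run exactly.  ``stop_loss`` allows early stopping once the training loss
    reaches a target; ``stop_epoch`` stops after that epoch (used to
    interrupt a run mid-way for breakpoint-continuation tests).
    """
    x, y = _stack_dataset(dataset)
    if x.shape[1:] != (model.config.grid_side,) * 3 + (model.config.in_channels,):
        raise ConfigError(
            f"dataset grids {x.shape[1:]} do not match model "
            f"({model.config.grid_side}^3 x {model.config.in_channels})"
        )
    xv = yv = None
    if val_dataset:
        xv, yv = _stack_dataset(val_dataset)

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    start_epoch = 0
    rng = np.random.default_rng(config.seed)
    best_params: list[np.ndarray] | None = None

    if config.resume_from:
        state = load_checkpoint(config.resume_from)
        if state["meta"]["net_config"] != model.config.to_dict():
            raise CheckpointError("checkpoint architecture differs from the model's")
        model.load_state_arrays(state["model"].state_arrays())
        optimizer.load_state_dict(
            {
                "t": state["meta"]["adam_t"],
                "m": state["adam_m"],
                "v": state["adam_v"],
                "lr": config.learning_rate,
            }
        )
        if state["meta"]["rng_state"] is not None:
            rng.bit_generator.state = state["meta"]["rng_state"]
        history = state["history"]
        best_params = state["best_params"]
        start_epoch = state["epoch"]

    n = len(x)
    for epoch in range(start_epoch, config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for i in range(0, n, config.batch_size):
            sel = perm[i : i + config.batch_size]
            out = model(x[sel])
            loss = dice_loss_tensor(out, y[sel][..., None], config.epsilon)
            model.zero_grad()
            loss.backward()
            optimizer.step()
            total += loss.item() * len(sel)
        history.train_loss.append(total / n)

        if xv is not None:
            vloss = _eval_loss(model, xv, yv, config.epsilon, config.batch_size)
            history.val_loss.append(vloss)
            if vloss < history.best_val_loss:
                history.best_val_loss = vloss
                history.best_epoch = epoch
                best_params = [p.copy() for p in model.state_arrays()]

        done = epoch + 1
        if checkpoint_dir and (
            done % config.checkpoint_every == 0
            or done == config.epochs
            or (stop_epoch is not None and done == stop_epoch)
        ):
            os.makedirs(checkpoint_dir, exist_ok=True)
            save_checkpoint(
                os.path.join(checkpoint_dir, f"ckpt_epoch_{done:05d}.npz"),
                model, optimizer, done, rng, history, best_params, config,
            )
        if stop_epoch is not None and done >= stop_epoch:
            break
        if stop_loss is not None and history.train_loss[-1] <= stop_loss:
            break

    if checkpoint_dir:
        os.makedirs(checkpoint_dir, exist_ok=True)
        save_checkpoint(
            os.path.join(checkpoint_dir, "last.npz"),
            model, optimizer, history.epochs_run, rng, history, best_params, config,
        )
        if best_params is not None:
            best_model = build_model(model.config)
            best_model.load_state_arrays(best_params)
            save_checkpoint(
                os.path.join(checkpoint_dir, "best.npz"),
                best_model, None, history.best_epoch + 1, None, history, None, config,
            )
    return history


def finetune(
    baseline_checkpoint,
    dataset,
    class_label: str,
    schedule: FinetuneSchedule | None = None,
    learning_rate: float = 1e-5,
    val_dataset=None,
    checkpoint_dir=None,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int = 10,
) -> tuple[DualPathVNet, TrainingHistory]:
    """Continue training a baseline checkpoint on one fold class.

    All parameters stay trainable; only the epoch budget (per-class schedule:
    α 100, β 200, α+β 400, α/β 500 by default) and a lower learning rate
    distinguish fine-tuning from baseline training.
    """
    schedule = schedule or FinetuneSchedule()
    n_epochs = epochs if epochs is not None else schedule.epochs_for(class_label)
    state = load_checkpoint(baseline_checkpoint)
    model: DualPathVNet = state["model"]
    if n_epochs == 0:  # zero additional steps: the baseline weights unchanged
        return model, TrainingHistory()
    config = TrainConfig(
        epochs=n_epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        seed=seed,
        checkpoint_every=max(1, n_epochs),
    )
    history = train(
        model, dataset, config, val_dataset=val_dataset,
        checkpoint_dir=checkpoint_dir,
    )
    if checkpoint_dir:
        save_checkpoint(
            os.path.join(checkpoint_dir, f"finetuned_{class_label}.npz"),
            model, None, n_epochs, None, history, None, config,
        )
    return model, history
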
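"""Reference toy-scale experiments exercising the full pipeline.

These are the package's own small-scale study conditions: a reduced network
(16-voxel grid, base width 4, two downsampling stages, two attention heads)
trained on synthetic grid pairs.  They are used by the test suite and by
``scripts/acceptance.py``; the sizes are chosen so each experiment runs in
minutes on one CPU while still exercising optimisation, checkpointing and
transfer behaviour end to end.

Learning rates: the reduced model trains at 1e-3 (the small parameter count
tolerates — and the short epoch budget requires — a larger step than the
full-scale default of 1e-4); fine-tuning uses a tenfold lower rate, keeping
the full-scale ratio.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np

from .metrics import dcc, dice_loss
from .network import NetConfig, build_model, predict
from .pockets import extract_pockets
from .synthetic import grid_pair_truth_center, make_grid_pair
from .training import TrainConfig, finetune, save_checkpoint, train

TOY_SIDE = 16
TOY_LR = 1e-3
TOY_FINETUNE_LR = 1e-4


def toy_net_config(seed: int) -> NetConfig:
    return NetConfig(
        grid_side=TOY_SIDE,
        in_channels=18,
        base_width=4,
        n_stages=2,
        attention_heads=2,
        seed=seed,
    )


def run_overfit(
    seed: int,
    n_pairs: int = 8,
    max_epochs: int = 200,
    stop_loss: float = 0.2,
) -> dict:
    """Train the reduced network to overfit ``n_pairs`` synthetic grid pairs.

    Returns the final training loss, epochs used, and the DCC of each
    training example's top-ranked predicted pocket against its true blob
    centre.
    """
    pairs = [make_grid_pair(seed * 1000 + s, side=TOY_SIDE) for s in range(n_pairs)]
    model = build_model(toy_net_config(seed))
    config = TrainConfig(
        epochs=max_epochs, batch_size=n_pairs, learning_rate=TOY_LR, seed=seed
    )
    history = train(model, pairs, config, stop_loss=stop_loss)
    dccs = []
    for fg, lg in pairs:
        pockets = extract_pockets(predict(model, fg))
        top = pockets.top()
        truth = grid_pair_truth_center(lg)
        dccs.append(float("inf") if top is None else dcc(top.center, truth))
    return {
        "final_loss": history.train_loss[-1],
        "epochs": history.epochs_run,
        "dccs": dccs,
        "model": model,
        "pairs": pairs,
    }


def run_transfer(
    seed: int,
    n_train_per_class: int = 6,
    n_val: int = 4,
    baseline_epochs: int = 10,
    finetune_epochs: int = 30,
) -> dict:
    """Class-specific fine-tuning versus a mixed baseline.

    A baseline is trained briefly on a mixture of spherical-cavity (class A)
    and elongated-cavity (class B) fixtures, then fine-tuned on class A only
    at a tenfold lower learning rate.  Both models are scored by Dice loss
    on held-out class-A fixtures; fine-tuning specialises the model, so the
    fine-tuned loss should drop below the baseline's.
    """
    a_train = [
        make_grid_pair(10_000 + seed * 100 + s, side=TOY_SIDE, shape="sphere")
        for s in range(n_train_per_class)
    ]
    b_train = [
        make_grid_pair(20_000 + seed * 100 + s, side=TOY_SIDE, shape="elongated")
        for s in range(n_train_per_class)
    ]
    a_val = [
        make_grid_pair(30_000 + seed * 100 + s, side=TOY_SIDE, shape="sphere")
        for s in range(n_val)
    ]

    model = build_model(toy_net_config(seed))
    config = TrainConfig(
        epochs=baseline_epochs,
        batch_size=n_train_per_class,
        learning_rate=TOY_LR,
        seed=seed,
    )
    history = train(model, a_train + b_train, config)

    def a_val_loss(m) -> float:
        return float(
            np.mean([dice_loss(predict(m, fg).values, lg.values) for fg, lg in a_val])
        )

    baseline_loss = a_val_loss(model)
    with tempfile.TemporaryDirectory() as tmp:
        ckpt = os.path.join(tmp, "baseline.npz")
        save_checkpoint(ckpt, model, None, history.epochs_run, None, history)
        finetuned, _ = finetune(
            ckpt,
            a_train,
            "all_alpha",
            learning_rate=TOY_FINETUNE_LR,
            seed=seed,
            epochs=finetune_epochs,
            batch_size=n_train_per_class,
        )
    finetuned_loss = a_val_loss(finetuned)
    return {
        "baseline_val_loss": baseline_loss,
        "finetuned_val_loss": finetuned_loss,
        "improved": finetuned_loss < baseline_loss,
    }


def run_resume(seed: int, epochs: int = 6, break_at: int = 3, n_pairs: int = 4) -> dict:
    """Breakpoint continuation: interrupted + resumed vs uninterrupted run."""
    pairs = [make_grid_pair(seed * 1000 + s, side=TOY_SIDE) for s in range(n_pairs)]
    val = [make_grid_pair(seed * 1000 + 500 + s, side=TOY_SIDE) for s in range(2)]

    def config(resume_from=None, checkpoint_every=epochs):
        return TrainConfig(
            epochs=epochs,
            batch_size=n_pairs,
            learning_rate=TOY_LR,
            seed=seed,
            checkpoint_every=checkpoint_every,
            resume_from=resume_from,
        )

    straight = build_model(toy_net_config(seed))
    h_straight = train(straight, pairs, config(), val_dataset=val)

    with tempfile.TemporaryDirectory() as tmp:
        interrupted = build_model(toy_net_config(seed))
        train(
            interrupted,
            pairs,
            config(checkpoint_every=break_at),
            val_dataset=val,
            checkpoint_dir=tmp,
            stop_epoch=break_at,
        )
        resumed = build_model(toy_net_config(seed))
        h_resumed = train(
            resumed,
            pairs,
            config(resume_from=os.path.join(tmp, f"ckpt_epoch_{break_at:05d}.npz")),
            val_dataset=val,
        )
    diff = float(
        np.max(
            np.abs(np.array(h_straight.train_loss) - np.array(h_resumed.train_loss))
        )
    )
    val_diff = float(
        np.max(np.abs(np.array(h_straight.val_loss) - np.array(h_resumed.val_loss)))
    )
    return {
        "history_straight": h_straight.train_loss,
        "history_resumed": h_resumed.train_loss,
        "max_abs_diff": max(diff, val_diff),
    }
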
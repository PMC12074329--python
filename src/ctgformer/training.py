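"""Optimisation loop, pretrain/finetune protocol and hyperparameter search.

Training minimises mean binary cross-entropy with Adam and stops early when
the validation AUC has not strictly improved for ``patience`` consecutive
epochs; the returned parameters are always those of the best-AUC epoch.
The temporal transfer protocol pretrains on cases recorded 3-7 days before
delivery and finetunes (all parameters updated) on cases within 2 days.
The hyperparameter harness samples configurations from the tuned search
grids through a pluggable sampler; a seeded uniform random sampler is
provided and any smarter optimiser can be slotted in through the same
callable interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CTGError, ParameterError

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EarlyStopping",
    "Adam",
    "train",
    "pretrain_finetune",
    "HPOSpace",
    "random_sampler",
    "hpo_search",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training controls: 50 epochs (60 in search trials), patience 10,
    batches of 48 at learning rate 1e-4."""

    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 48
    learning_rate: float = 1e-4
    seed: int = 0
    mode: str = "scratch"  # {scratch, pretrain, finetune}

    def __post_init__(self):
        if self.patience > self.max_epochs and self.max_epochs > 0:
            raise ParameterError("patience must not exceed max_epochs")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.mode not in ("scratch", "pretrain", "finetune"):
            raise ParameterError("mode must be scratch, pretrain or finetune")


@dataclass
class TrainHistory:
    """Per-epoch record of the optimisation."""

    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_auc: float = float("-inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_auc": self.val_auc,
            }
        )


class EarlyStopping:
    """Patience rule on a score to maximise.

    Improvement means a strictly greater score; ties do not reset the
    counter.  Epochs are 1-based.  ``update`` returns True when training
    should stop (``patience`` consecutive non-improving epochs).
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ParameterError("patience must be >= 1")
        self.patience = patience
        self.best_score = float("-inf")
        self.best_epoch = 0
        self.streak = 0

    def update(self, epoch: int, score: float) -> bool:
        if score > self.best_score:
            self.best_score = score
            self.best_epoch = epoch
            self.streak = 0
        else:
            self.streak += 1
        return self.streak >= self.patience


class Adam:
    """Adam optimiser over a list of autodiff tensors (default moments)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g**2
            p.data -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)


def train(X_train, y_train, X_val, y_val, model_config=None, train_config=None):
    """Fit a classifier and return ``(estimator, history)``.

    Thin functional wrapper over
    :class:`ctgformer.estimator.PatchTransformerClassifier`; both configs
    accept the corresponding dataclasses or None for defaults.
    """
    from .estimator import PatchTransformerClassifier  # local: avoids cycle

    est = PatchTransformerClassifier.from_configs(model_config, train_config)
    est.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    return est, est.history_


def pretrain_finetune(
    pretrain_data: tuple,
    finetune_data: tuple,
    model_config=None,
    pretrain_config: TrainConfig | None = None,
    finetune_config: TrainConfig | None = None,
):
    """Two-phase temporal adaptation.

    ``pretrain_data`` and ``finetune_data`` are ``(X_train, y_train, X_val,
    y_val)`` tuples, typically built from the 3-7 day and 0-2 day
    days-to-delivery subsets.  Phase 1 trains from scratch; phase 2 starts
    from the phase-1 best checkpoint and continues with its own early
    stopping, updating all parameters.  Returns
    ``(pretrained, finetuned, history_pretrain, history_finetune)``; with a
    zero-epoch finetune budget the finetuned model equals the pretrained one.
    """
    from .estimator import PatchTransformerClassifier

    pre_cfg = pretrain_config or TrainConfig(mode="pretrain")
    fin_cfg = finetune_config or TrainConfig(mode="finetune")
    for name, (X, y, *_rest) in (("pretrain", pretrain_data), ("finetune", finetune_data)):
        if len(np.asarray(y)) == 0:
            raise CTGError(f"empty {name} subset")

    pre = PatchTransformerClassifier.from_configs(model_config, pre_cfg)
    pre.fit(pretrain_data[0], pretrain_data[1],
            X_val=pretrain_data[2], y_val=pretrain_data[3])

    fin = PatchTransformerClassifier.from_configs(model_config, fin_cfg)
    fin.fit(finetune_data[0], finetune_data[1],
            X_val=finetune_data[2], y_val=finetune_data[3],
            init_state=pre.net_.state_dict())
    return pre, fin, pre.history_, fin.history_


# ----------------------------------------------------------------- HPO side
@dataclass(frozen=True)
class HPOSpace:
    """The hyperparameter search grids.

    Dropout rates are continuous on [0.1, 0.5]; everything else is a finite
    choice set.  Sampled configurations must satisfy the architecture
    invariants (width divisible by heads); violating draws are resampled.
    """

    n_layers: tuple = (3, 4, 5, 6)
    n_heads: tuple = (4, 8, 16, 32)
    d_model: tuple = (64, 128, 192, 256, 384, 512, 640)
    d_ff: tuple = (128, 192, 256, 320, 384, 512, 640)
    dropout_range: tuple = (0.1, 0.5)
    learning_rate: tuple = (1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3)
    batch_size: tuple = (16, 32, 48, 64)
    patch_len: tuple = (4, 8, 16, 32)
    stride: tuple = (4, 8, 16)
    activation: tuple = ("relu", "gelu", "elu")


def _config_valid(cfg: dict) -> bool:
    if cfg["d_model"] % cfg["n_heads"] != 0:
        return False
    if cfg["d_model"] // cfg["n_heads"] < 2:  # degenerate single-scalar heads
        return False
    return True


def random_sampler(rng: np.random.Generator, space: HPOSpace) -> dict:
    """Uniform draw from the grids; invalid combinations are resampled."""
    lo, hi = space.dropout_range
    while True:
        cfg = {
            "n_layers": int(rng.choice(space.n_layers)),
            "n_heads": int(rng.choice(space.n_heads)),
            "d_model": int(rng.choice(space.d_model)),
            "d_ff": int(rng.choice(space.d_ff)),
            "dropout": float(rng.uniform(lo, hi)),
            "fc_dropout": float(rng.uniform(lo, hi)),
            "attn_dropout": float(rng.uniform(lo, hi)),
            "learning_rate": float(rng.choice(space.learning_rate)),
            "batch_size": int(rng.choice(space.batch_size)),
            "patch_len": int(rng.choice(space.patch_len)),
            "stride": int(rng.choice(space.stride)),
            "activation": str(rng.choice(space.activation)),
        }
        if _config_valid(cfg):
            return cfg


def hpo_search(
    space: HPOSpace,
    n_trials: int,
    objective=None,
    sampler=random_sampler,
    seed: int = 0,
    data: tuple | None = None,
    max_epochs: int = 60,
    patience: int = 10,
) -> tuple[dict, pd.DataFrame]:
    """Sample-and-evaluate search maximising validation AUC.

    Each trial draws a configuration from ``sampler`` and scores it with
    ``objective(config) -> AUC``.  When no objective is given, ``data``
    must hold ``(X_train, y_train, X_val, y_val)`` and each trial trains a
    classifier with a 60-epoch / patience-10 budget.  Returns the best
    configuration and the full trial table (one row per trial).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if objective is None:
        if data is None:
            raise ParameterError("provide an objective or training data")

        def objective(cfg):
            from .estimator import PatchTransformerClassifier

            est = PatchTransformerClassifier(
                **cfg, max_epochs=max_epochs, patience=patience, random_state=seed
            )
            est.fit(data[0], data[1], X_val=data[2], y_val=data[3])
            return est.best_auc_

    rng = np.random.default_rng(seed)
    rows = []
    failures = []
    for trial in range(n_trials):
        cfg = sampler(rng, space)
        try:
            auc_score = float(objective(cfg))
        except Exception as exc:  # noqa: BLE001 — recorded per-trial
            failures.append((trial, repr(exc)))
            rows.append({"trial": trial, **cfg, "val_auc": np.nan, "error": repr(exc)})
            continue
        rows.append({"trial": trial, **cfg, "val_auc": auc_score, "error": None})
    table = pd.DataFrame(rows)
    if table["val_auc"].isna().all():
        raise CTGError(f"all {n_trials} trials failed: {failures}")
    best_row = table.loc[table["val_auc"].idxmax()]
    best = {k: best_row[k] for k in rows[0] if k not in ("trial", "val_auc", "error")}
    # restore native python types lost in the DataFrame round-trip
    for key in ("n_layers", "n_heads", "d_model", "d_ff", "batch_size",
                "patch_len", "stride"):
        best[key] = int(best[key])
    return best, table
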
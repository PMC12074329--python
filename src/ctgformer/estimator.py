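"""scikit-learn estimator wrapper around the patch transformer.

:class:`PatchTransformerClassifier` follows the scikit-learn contract:
hyperparameters are constructor arguments stored verbatim, ``fit`` learns
and sets trailing-underscore attributes, ``predict_proba`` / ``predict``
score new windows, and ``get_params`` / ``set_params`` make it usable with
``clone``, pipelines and model selection.

Input windows are arrays of shape ``(n, 2, 960)`` (FHR channel first) on
the unit scale, with NaN marking unobserved samples; the validity mask is
derived from the NaNs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .exceptions import AUCUndefinedError, ParameterError
from .model import ModelConfig, PatchTransformerNet
from .training import Adam, EarlyStopping, TrainConfig, TrainHistory

__all__ = ["PatchTransformerClassifier"]


def _split_windows(X):
    """Split NaN-coded windows into (values, mask) with zero fill."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ParameterError("X must be (n_windows, n_channels, seq_len)")
    mask = ~np.isnan(X)
    return np.where(mask, X, 0.0), mask


def _auc_fast(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise AUCUndefinedError("validation set must contain both classes")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0)
        / (len(pos) * len(neg))
    )


class PatchTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Binary CTG outcome classifier with a patch-transformer backbone.

    Parameters mirror :class:`ctgformer.model.ModelConfig` and
    :class:`ctgformer.training.TrainConfig`; see those for semantics and
    defaults.  ``validation_fraction`` carves a stratified validation split
    out of the training data when ``fit`` is not given one explicitly.

    Attributes set by ``fit`` (scikit-learn convention)
    ---------------------------------------------------
    net_ : PatchTransformerNet
        The trained network at its best validation-AUC epoch.
    history_ : TrainHistory
        Per-epoch train loss and validation AUC.
    best_epoch_, best_auc_ : int, float
        Location and value of the early-stopping optimum.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        n_layers: int = 6,
        n_heads: int = 4,
        d_model: int = 512,
        d_ff: int = 128,
        dropout: float = 0.1,
        fc_dropout: float = 0.4,
        attn_dropout: float = 0.2,
        patch_len: int = 16,
        stride: int = 16,
        activation: str = "relu",
        seq_len: int = 960,
        n_channels: int = 2,
        smooth_kernel: int = 0,
        max_epochs: int = 50,
        patience: int = 10,
        batch_size: int = 48,
        learning_rate: float = 1e-4,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_model = d_model
        self.d_ff = d_ff
        self.dropout = dropout
        self.fc_dropout = fc_dropout
        self.attn_dropout = attn_dropout
        self.patch_len = patch_len
        self.stride = stride
        self.activation = activation
        self.seq_len = seq_len
        self.n_channels = n_channels
        self.smooth_kernel = smooth_kernel
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------- builders
    @classmethod
    def from_configs(cls, model_config: ModelConfig | None,
                     train_config: TrainConfig | None):
        mc = model_config or ModelConfig()
        tc = train_config or TrainConfig()
        return cls(
            n_layers=mc.n_layers, n_heads=mc.n_heads, d_model=mc.d_model,
            d_ff=mc.d_ff, dropout=mc.dropout, fc_dropout=mc.fc_dropout,
            attn_dropout=mc.attn_dropout, patch_len=mc.patch_len,
            stride=mc.stride, activation=mc.activation, seq_len=mc.seq_len,
            n_channels=mc.n_channels, smooth_kernel=mc.smooth_kernel,
            max_epochs=tc.max_epochs, patience=tc.patience,
            batch_size=tc.batch_size, learning_rate=tc.learning_rate,
            random_state=tc.seed,
        )

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers, n_heads=self.n_heads, d_model=self.d_model,
            d_ff=self.d_ff, dropout=self.dropout, fc_dropout=self.fc_dropout,
            attn_dropout=self.attn_dropout, patch_len=self.patch_len,
            stride=self.stride, activation=self.activation,
            seq_len=self.seq_len, n_channels=self.n_channels,
            smooth_kernel=self.smooth_kernel,
        )

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, X_val=None, y_val=None, init_state=None):
        """Train with Adam, early-stopping on validation AUC.

        ``init_state`` warm-starts from a compatible network state dict
        (used by the pretrain/finetune protocol).  With ``max_epochs=0``
        the (possibly warm-started) network is returned untrained.
        """
        values, mask = _split_windows(X)
        y = np.asarray(y, dtype=int)
        if values.shape[0] != y.shape[0]:
            raise ParameterError("X and y length mismatch")

        if X_val is None:
            if self.max_epochs > 0:
                values, val_v, mask, val_m, y, y_val = _stratified_split(
                    values, mask, y, self.validation_fraction, self.random_state
                )
            else:
                val_v = val_m = y_val = None
        else:
            val_v, val_m = _split_windows(X_val)
            y_val = np.asarray(y_val, dtype=int)

        config = self._model_config()
        net = PatchTransformerNet(config, seed=self.random_state)
        if init_state is not None:
            net.load_state_dict(init_state)
        history = TrainHistory()

        if self.max_epochs > 0:
            if len(np.unique(y_val)) < 2:
                raise AUCUndefinedError("validation set must contain both classes")
            self._optimise(net, values, mask, y, val_v, val_m, y_val, history)

        self.net_ = net
        self.history_ = history
        self.best_epoch_ = history.best_epoch
        self.best_auc_ = history.best_auc
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = int(np.prod(values.shape[1:]))
        return self

    def _optimise(self, net, values, mask, y, val_v, val_m, y_val, history):
        rng = np.random.default_rng(self.random_state + 1)
        drop_rng = np.random.default_rng(self.random_state + 2)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        stopper = EarlyStopping(self.patience)
        best_state = net.state_dict()
        n = values.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                logits = net.forward(values[sel], mask[sel], training=True, rng=drop_rng)
                yb = y[sel].astype(np.float64)
                # BCE from logits: mean(softplus(z) - y*z), numerically stable
                loss = (logits.softplus() - logits * yb).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            scores = self._proba_net(net, val_v, val_m)
            auc_epoch = _auc_fast(y_val, scores)
            history.train_loss.append(float(np.mean(losses)))
            history.val_auc.append(auc_epoch)
            improved = auc_epoch > stopper.best_score
            stop = stopper.update(epoch, auc_epoch)
            if improved:
                best_state = net.state_dict()
            if stop:
                break
        history.best_epoch = stopper.best_epoch
        history.best_auc = stopper.best_score
        net.load_state_dict(best_state)

    # ------------------------------------------------------------ inference
    def _proba_net(self, net, values, mask, batch: int = 256) -> np.ndarray:
        out = []
        for start in range(0, values.shape[0], batch):
            out.append(net.predict_proba(values[start : start + batch],
                                         mask[start : start + batch]))
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        values, mask = _split_windows(X)
        p1 = self._proba_net(self.net_, values, mask)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def save_checkpoint(est: PatchTransformerClassifier, path) -> None:
    """Serialise a fitted estimator: weights plus hyperparameters."""
    import json
    from pathlib import Path

    path = Path(path)
    state = est.net_.state_dict()
    meta = {
        "params": est.get_params(),
        "best_epoch": est.best_epoch_,
        "best_auc": None if np.isneginf(est.best_auc_) else est.best_auc_,
        "history": {
            "train_loss": est.history_.train_loss,
            "val_auc": est.history_.val_auc,
        },
    }
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> PatchTransformerClassifier:
    """Rebuild a fitted estimator from :func:`save_checkpoint` output."""
    import json

    from .training import TrainHistory

    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    est = PatchTransformerClassifier(**meta["params"])
    net = PatchTransformerNet(est._model_config(), seed=est.random_state)
    net.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    est.net_ = net
    est.history_ = TrainHistory(
        train_loss=meta["history"]["train_loss"],
        val_auc=meta["history"]["val_auc"],
        best_epoch=meta["best_epoch"],
        best_auc=float("-inf") if meta["best_auc"] is None else meta["best_auc"],
    )
    est.best_epoch_ = est.history_.best_epoch
    est.best_auc_ = est.history_.best_auc
    est.classes_ = np.array([0, 1])
    return est


def _stratified_split(values, mask, y, fraction, seed):
    idx = np.arange(values.shape[0])
    tr, va = train_test_split(
        idx, test_size=fraction, random_state=seed, stratify=y
    )
    return values[tr], values[va], mask[tr], mask[va], y[tr], y[va]
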
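"""Shallow multilayer network classifier for stacked skeleton windows.

Nine reference architectures are provided, varying the number of hidden
layers (1–3) and neurons per layer (50/100/200):

====  =========================================
id    layers (input -> ... -> 1 sigmoid)
====  =========================================
1     50 ReLU
2     100 ReLU
3     200 ReLU
4     50 ReLU | drop 20% | 50 PReLU
5     50 ReLU | drop 20% | 100 PReLU
6     50 ReLU | drop 20% | 200 PReLU
7     50 ReLU | drop 20% | 50 PReLU | drop 20% | 50 PReLU
8     50 ReLU | drop 20% | 100 PReLU | drop 20% | 100 PReLU
9     50 ReLU | drop 20% | 200 PReLU | drop 20% | 200 PReLU
====  =========================================

Training minimizes binary cross-entropy between the sigmoid output and
window labels (FM+ = 1) with Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999) in
mini-batches, with optional early stopping on a validation loss.

The user-facing surface follows the model/results idiom:
:class:`SMNNModel` holds the data and architecture; ``fit()`` returns an
:class:`SMNNResults` carrying the learned weights, the per-epoch
history, prediction methods and a ``summary()`` table.  Snippet-level
decisions aggregate the independent window classifications by uniform
majority vote.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureConfig, stack_windows, normalize_skeleton
from .nn import Adam, ShallowMLP, bce_from_logits
from .skeleton import Label

logger = logging.getLogger(__name__)

#: Hidden-layer widths of the nine reference architectures.
ARCHITECTURES: dict[int, list[int]] = {
    1: [50], 2: [100], 3: [200],
    4: [50, 50], 5: [50, 100], 6: [50, 200],
    7: [50, 50, 50], 8: [50, 100, 100], 9: [50, 200, 200],
}

_ALLOWED_WIDTHS = {50, 100, 200}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: hidden widths, activations, dropout."""

    architecture_id: int
    hidden_sizes: tuple[int, ...]
    dropout_rate: float = 0.2
    prelu_init: float = 0.25

    def __post_init__(self):
        if not 1 <= len(self.hidden_sizes) <= 3:
            raise ValueError("hidden layer count must be 1, 2 or 3")
        if self.architecture_id in ARCHITECTURES:
            if list(self.hidden_sizes) != ARCHITECTURES[self.architecture_id]:
                raise ValueError(
                    f"architecture {self.architecture_id} requires hidden sizes "
                    f"{ARCHITECTURES[self.architecture_id]}")
            if any(w not in _ALLOWED_WIDTHS for w in self.hidden_sizes):
                raise ValueError("reference widths are 50, 100 or 200")

    @classmethod
    def from_architecture(cls, architecture_id: int) -> "ModelSpec":
        if architecture_id not in ARCHITECTURES:
            raise ValueError(
                f"architecture_id must be 1..9 (got {architecture_id}); "
                "construct ModelSpec directly for a custom network")
        sizes = tuple(ARCHITECTURES[architecture_id])
        dropout = 0.2 if len(sizes) >= 2 else 0.0
        return cls(architecture_id, sizes, dropout)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and stopping settings (defaults are the tuned values)."""

    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 3968
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    threshold: float = 0.5
    shuffle: bool = True

    def __post_init__(self):
        for name in ("learning_rate", "adam_beta1", "adam_beta2", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


class SMNNModel:
    """A window-level binary classifier bound to its training data.

    Parameters
    ----------
    X : (n_windows, input_dim) array of stacked feature vectors.
    y : (n_windows,) array of window labels, FM+ = 1, FM− = 0.
    spec : ModelSpec, default architecture 5.
    seed : seed for weight initialization.
    """

    def __init__(self, X, y, spec: ModelSpec | int = 5, seed: int = 0):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be binary (FM+ = 1, FM− = 0)")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        if isinstance(spec, int):
            spec = ModelSpec.from_architecture(spec)
        self.X, self.y = X, y
        self.spec = spec
        self.seed = int(seed)
        self.net = ShallowMLP(X.shape[1], list(spec.hidden_sizes),
                              spec.dropout_rate, spec.prelu_init,
                              np.random.default_rng(seed))

    @classmethod
    def from_snippets(cls, snippets, feature_cfg: FeatureConfig = FeatureConfig(),
                      spec: ModelSpec | int = 5, seed: int = 0) -> "SMNNModel":
        from .features import windows_matrix

        X, y, _ = windows_matrix(snippets, feature_cfg)
        return cls(X, y, spec, seed)

    @property
    def input_dim(self) -> int:
        return self.net.input_dim

    def fit(self, cfg: TrainConfig = TrainConfig(),
            X_val=None, y_val=None) -> "SMNNResults":
        """Train with Adam; return the results wrapper.

        With a validation set, training stops once the validation loss
        has not improved for ``cfg.patience`` epochs and the parameters
        from the best validation epoch are kept; otherwise it runs to
        ``cfg.max_epochs``.
        """
        net = self.net
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(net.params, cfg.learning_rate, cfg.adam_beta1,
                   cfg.adam_beta2, cfg.adam_eps)
        has_val = X_val is not None
        if has_val:
            X_val = np.asarray(X_val)
            y_val = np.asarray(y_val, dtype=float).ravel()
        n = len(self.X)
        history = []
        best_loss, best_params, best_epoch, since_best = np.inf, None, 0, 0
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n) if cfg.shuffle else np.arange(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits, cache = net.forward(self.X[idx], train=True, rng=rng)
                grads = net.backward(cache, logits, self.y[idx])
                opt.step(net.params, grads)
            row = {"epoch": epoch}
            logits, _ = net.forward(self.X, train=False)
            row["train_loss"] = bce_from_logits(logits, self.y)
            row["train_acc"] = float(np.mean((logits > 0) == (self.y > 0.5)))
            if has_val:
                v_logits, _ = net.forward(X_val, train=False)
                row["val_loss"] = bce_from_logits(v_logits, y_val)
                row["val_acc"] = float(np.mean((v_logits > 0) == (y_val > 0.5)))
                if row["val_loss"] < best_loss - 1e-9:
                    best_loss, best_epoch, since_best = row["val_loss"], epoch, 0
                    best_params = net.copy_params()
                else:
                    since_best += 1
            history.append(row)
            if has_val and since_best >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
        if has_val and best_params is not None:
            net.set_params(best_params)
        else:
            best_epoch = len(history)
        return SMNNResults(self, cfg, pd.DataFrame(history), best_epoch)


class SMNNResults:
    """Fitted-classifier results: weights, history, prediction, summary."""

    def __init__(self, model: SMNNModel, cfg: TrainConfig,
                 history: pd.DataFrame, best_epoch: int):
        self.model = model
        self.spec = model.spec
        self.cfg = cfg
        self.history = history
        self.best_epoch = best_epoch

    @property
    def input_dim(self) -> int:
        return self.model.input_dim

    def predict_proba(self, X) -> np.ndarray:
        """Window-level FM+ probabilities, strictly inside (0, 1);
        inference is deterministic (dropout disabled)."""
        X = np.atleast_2d(np.asarray(X))
        return self.model.net.predict_proba(X)

    def predict_window(self, window) -> float:
        """Probability that a single stacked window shows fidgety movement."""
        vec = window.vector if hasattr(window, "vector") else np.asarray(window)
        return float(self.predict_proba(vec[None, :])[0])

    def classify_snippet(self, snippet_windows, threshold: float | None = None,
                         return_detail: bool = False):
        """Uniform majority vote over a snippet's window classifications.

        Each window votes FM+ if its probability exceeds ``threshold``.
        The snippet label is the class with strictly more votes; an
        exact tie is resolved to FM− (absence of fidgety movements is
        the conservative flag) and flagged.
        """
        threshold = self.cfg.threshold if threshold is None else threshold
        X = _windows_to_matrix(snippet_windows)
        if len(X) == 0:
            raise ValueError("classify_snippet requires at least one window")
        votes_plus = int(np.sum(self.predict_proba(X) > threshold))
        label, tie = majority_vote(votes_plus, len(X) - votes_plus)
        if tie:
            logger.warning("snippet vote tie (%d/%d); labelled FM_MINUS", votes_plus, len(X))
        if return_detail:
            return label, {"votes_plus": votes_plus, "votes_minus": len(X) - votes_plus,
                           "tie": tie}
        return label

    def classify_snippets(self, snippets, feature_cfg: FeatureConfig = FeatureConfig(),
                          threshold: float | None = None) -> dict[str, Label]:
        """Normalize, window and majority-vote a list of snippets."""
        out = {}
        for snippet in snippets:
            windows = stack_windows(normalize_skeleton(snippet), feature_cfg)
            out[snippet.snippet_id] = self.classify_snippet(windows, threshold)
        return out

    def summary(self) -> str:
        """Plain-text fit summary."""
        spec, hist = self.spec, self.history
        sizes = [self.input_dim] + list(spec.hidden_sizes) + [1]
        n_params = sum(v.size for v in self.model.net.params.values())
        lines = [
            "Shallow multilayer network classification results",
            "=" * 52,
            f"Architecture id:      {spec.architecture_id}",
            f"Layer sizes:          {' -> '.join(map(str, sizes))}",
            f"Dropout between hidden layers: "
            f"{spec.dropout_rate if len(spec.hidden_sizes) > 1 else 0.0:.2f}",
            f"Trainable parameters: {n_params}",
            f"Training windows:     {len(self.model.X)}",
            f"Epochs run:           {len(hist)} (best: {self.best_epoch})",
            f"Final train loss/acc: {hist['train_loss'].iloc[-1]:.4f} / "
            f"{hist['train_acc'].iloc[-1]:.4f}",
        ]
        if "val_loss" in hist:
            best = hist[hist["epoch"] == self.best_epoch].iloc[0]
            lines.append(f"Best val loss/acc:    {best['val_loss']:.4f} / "
                         f"{best['val_acc']:.4f}")
        lines.append(f"Adam: lr={self.cfg.learning_rate}, beta1={self.cfg.adam_beta1}, "
                     f"beta2={self.cfg.adam_beta2}, batch={self.cfg.batch_size}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss curves over epochs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        if "val_loss" in self.history:
            ax.plot(self.history["epoch"], self.history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("binary cross-entropy")
        ax.legend()
        return ax

    def save(self, path, feature_cfg: FeatureConfig | None = None) -> None:
        """Checkpoint: npz parameter file + JSON sidecar with the specs."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, **self.model.net.params)
        sidecar = {
            "model_spec": asdict(self.spec),
            "train_config": asdict(self.cfg),
            "input_dim": self.input_dim,
            "best_epoch": self.best_epoch,
            "layout_version": 1,
        }
        if feature_cfg is not None:
            sidecar["feature_config"] = {"n_stack": feature_cfg.n_stack,
                                         "n_slide": feature_cfg.n_slide}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "SMNNResults":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        params = dict(np.load(path))
        spec_d = sidecar["model_spec"]
        spec = ModelSpec(spec_d["architecture_id"], tuple(spec_d["hidden_sizes"]),
                         spec_d["dropout_rate"], spec_d["prelu_init"])
        cfg = TrainConfig(**sidecar["train_config"])
        model = object.__new__(SMNNModel)
        model.spec = spec
        model.seed = cfg.seed
        model.X = np.empty((0, sidecar["input_dim"]))
        model.y = np.empty(0)
        model.net = ShallowMLP(sidecar["input_dim"], list(spec.hidden_sizes),
                               spec.dropout_rate, spec.prelu_init, 0)
        model.net.set_params(params)
        return cls(model, cfg, pd.DataFrame({"epoch": [], "train_loss": [],
                                             "train_acc": []}),
                   sidecar["best_epoch"])


def _windows_to_matrix(snippet_windows) -> np.ndarray:
    if isinstance(snippet_windows, np.ndarray):
        return np.atleast_2d(snippet_windows)
    return np.asarray([w.vector if hasattr(w, "vector") else np.asarray(w)
                       for w in snippet_windows])


def majority_vote(votes_plus: int, votes_minus: int) -> tuple[Label, bool]:
    """Uniform majority vote; ties go to FM− with a tie flag."""
    if votes_plus > votes_minus:
        return Label.FM_PLUS, False
    return Label.FM_MINUS, votes_plus == votes_minus


# -- thin functional wrappers around the model/results surface ---------------

def build_model(spec: ModelSpec | int, input_dim: int, seed: int = 0) -> SMNNModel:
    """Untrained model with seeded, reproducible initialization.

    (Constructed with a two-window placeholder dataset; call
    :meth:`SMNNModel.fit` after replacing ``X``/``y``, or use
    :func:`train`.)
    """
    placeholder_X = np.zeros((2, input_dim))
    placeholder_y = np.array([0.0, 1.0])
    return SMNNModel(placeholder_X, placeholder_y, spec, seed)


def train(model: SMNNModel, windows, labels, cfg: TrainConfig = TrainConfig(),
          X_val=None, y_val=None) -> SMNNResults:
    """Fit ``model`` on the given windows/labels (functional spelling)."""
    X = _windows_to_matrix(windows)
    if X.shape[1] != model.input_dim:
        raise ValueError(f"window dimension {X.shape[1]} != model input {model.input_dim}")
    refit = SMNNModel(X, np.asarray(labels, dtype=float), model.spec, model.seed)
    refit.net = model.net  # keep the already-initialized parameters
    return refit.fit(cfg, X_val, y_val)


def predict_window(results: SMNNResults, window) -> float:
    return results.predict_window(window)


def classify_snippet(results: SMNNResults, snippet_windows, threshold: float = 0.5):
    return results.classify_snippet(snippet_windows, threshold)
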
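"""One-parameter-at-a-time hyperparameter sweeps scored by ROC distance.

Each candidate value is assessed by training the classifier to
convergence, computing the snippet-level true- and false-positive rates
on a participant-disjoint validation set, and measuring the Euclidean
distance from the achieved (FPR, TPR) to the ideal ROC corner (0, 1):

    d = sqrt((1 − TPR)² + FPR²)

The value with minimum d wins, ties broken toward the smaller value.
The canonical coordinate-descent order sweeps the batch size first, then
the frames-per-window N_stack, then the window offset N_slide, holding
each selected value fixed for the subsequent sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import confusion, metrics
from .features import FeatureConfig, windows_matrix
from .smnn import ModelSpec, SMNNModel, TrainConfig

logger = logging.getLogger(__name__)

SWEEPABLE = ("n_batch", "n_stack", "n_slide")

#: Default sweep grids; each includes the tuned optimum (3968 / 52 / 12).
DEFAULT_GRIDS: dict[str, tuple] = {
    "n_batch": (256, 512, 1024, 2048, 3968, 8192),
    "n_stack": (13, 26, 52, 104),
    "n_slide": (6, 12, 25, 50),
}


@dataclass(frozen=True)
class SweepResult:
    """Outcome of sweeping one parameter."""

    parameter: str
    table: pd.DataFrame  # columns: value, tpr, fpr, accuracy, d
    selected: int

    def __post_init__(self):
        d = self.table["d"].to_numpy()
        sel = self.table.loc[self.table["value"] == self.selected, "d"].iloc[0]
        assert sel <= d.min() + 1e-12


def roc_distance(tpr: float, fpr: float) -> float:
    """Distance from (FPR, TPR) to the perfect corner (0, 1)."""
    if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
        raise ValueError("TPR and FPR must lie in [0, 1]")
    return float(np.sqrt((1.0 - tpr) ** 2 + fpr ** 2))


def _evaluate_setting(train_snippets, validation_snippets, feature_cfg, train_cfg,
                      architecture, seed):
    X, y, _ = windows_matrix(train_snippets, feature_cfg)
    X_val, y_val, _ = windows_matrix(validation_snippets, feature_cfg)
    spec = ModelSpec.from_architecture(architecture) if isinstance(architecture, int) \
        else architecture
    model = SMNNModel(X, y, spec, seed=seed)
    result = model.fit(train_cfg, X_val, y_val)
    predictions = result.classify_snippets(validation_snippets, feature_cfg)
    truth = [s.label for s in validation_snippets]
    predicted = [predictions[s.snippet_id] for s in validation_snippets]
    report = metrics(confusion(truth, predicted))
    return report.tpr, report.fpr, report.accuracy


def sweep_parameter(name: str, values, train_snippets, validation_snippets,
                    feature_cfg: FeatureConfig = FeatureConfig(),
                    train_cfg: TrainConfig = TrainConfig(),
                    architecture: int = 5, seed: int = 0) -> SweepResult:
    """Sweep one of n_batch / n_stack / n_slide, holding the rest fixed.

    The validation snippets must be participant-disjoint from the
    training snippets.  Returns per-value TPR/FPR/accuracy/d and the
    argmin-d value (smallest value on ties).
    """
    if name not in SWEEPABLE:
        raise ValueError(f"parameter must be one of {SWEEPABLE}")
    values = sorted(int(v) for v in values)
    if not values:
        raise ValueError("values must be non-empty")
    if not train_snippets or not validation_snippets:
        raise ValueError("train and validation snippet sets must be non-empty")
    train_pids = {s.participant_id for s in train_snippets}
    val_pids = {s.participant_id for s in validation_snippets}
    if train_pids & val_pids:
        raise ValueError(f"validation participants overlap training: {train_pids & val_pids}")

    rows = []
    for value in values:
        fc, tc = feature_cfg, train_cfg
        if name == "n_batch":
            tc = replace(train_cfg, batch_size=value)
        elif name == "n_stack":
            fc = FeatureConfig(n_stack=value, n_slide=feature_cfg.n_slide)
        else:
            fc = FeatureConfig(n_stack=feature_cfg.n_stack, n_slide=value)
        tpr, fpr, acc = _evaluate_setting(train_snippets, validation_snippets,
                                          fc, tc, architecture, seed)
        rows.append({"value": value, "tpr": tpr, "fpr": fpr,
                     "accuracy": acc, "d": roc_distance(tpr, fpr)})
        logger.info("%s=%d: TPR=%.3f FPR=%.3f d=%.3f", name, value, tpr, fpr, rows[-1]["d"])
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["d"].idxmin(), "value"])  # sorted -> ties to smaller
    return SweepResult(name, table, selected)


def coordinate_sweep(train_snippets, validation_snippets,
                     grids: dict[str, tuple] | None = None,
                     feature_cfg: FeatureConfig = FeatureConfig(),
                     train_cfg: TrainConfig = TrainConfig(),
                     architecture: int = 5, seed: int = 0) -> dict[str, SweepResult]:
    """Sweep n_batch, then n_stack, then n_slide, fixing each selection."""
    grids = dict(DEFAULT_GRIDS if grids is None else grids)
    results: dict[str, SweepResult] = {}
    fc, tc = feature_cfg, train_cfg
    for name in SWEEPABLE:
        if name not in grids:
            continue
        res = sweep_parameter(name, grids[name], train_snippets, validation_snippets,
                              fc, tc, architecture, seed)
        results[name] = res
        if name == "n_batch":
            tc = replace(tc, batch_size=res.selected)
        elif name == "n_stack":
            fc = FeatureConfig(n_stack=res.selected, n_slide=fc.n_slide)
        else:
            fc = FeatureConfig(n_stack=fc.n_stack, n_slide=res.selected)
    return results
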
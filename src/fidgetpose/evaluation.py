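"""Confusion-matrix metrics, rater agreement, consensus filtering and
cross-validation.

FM+ is the positive class throughout.  From the confusion counts
(TP, FP, FN, TN — reals, so fold means are representable) the suite
computes per-class sensitivity, specificity, precision and F1, overall
accuracy, and the ROC coordinates TPR = TP/(TP+FN) and
FPR = FP/(TN+FP).  A metric whose denominator is zero is reported as
NaN (an explicit undefined marker) rather than raising, so aggregation
across folds can skip it transparently.

Rater machinery: Cohen's kappa κ = (p_o − p_e)/(1 − p_e) for two-rater
agreement, and the consensus filter that drops snippets marked
not-assessable by either rater (checked first) or labelled discrepantly,
keeping only unanimous FM+/FM− snippets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureConfig
from .skeleton import Label
from .smnn import ModelSpec, SMNNModel, TrainConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with FM+ as the positive class."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """The per-class metric suite derived from one confusion matrix."""

    sensitivity_fm_plus: float
    sensitivity_fm_minus: float
    specificity_fm_plus: float
    specificity_fm_minus: float
    precision_fm_plus: float
    precision_fm_minus: float
    accuracy: float
    f1_fm_plus: float
    f1_fm_minus: float

    @property
    def tpr(self) -> float:
        return self.sensitivity_fm_plus

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity_fm_plus

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["tpr"] = self.tpr
        d["fpr"] = self.fpr
        return d


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _to_binary(labels) -> np.ndarray:
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if isinstance(lab, (int, float, np.integer, np.floating)) and lab in (0, 1):
            out[i] = float(lab)
        else:
            coerced = Label.coerce(lab)
            if coerced not in (Label.FM_PLUS, Label.FM_MINUS):
                raise ValueError(f"labels must be binary FM+/FM-, got {lab!r}")
            out[i] = 1.0 if coerced is Label.FM_PLUS else 0.0
    return out


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Exact confusion counts from paired binary label lists."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    if len(true_labels) == 0:
        raise ValueError("label lists must be non-empty")
    y = _to_binary(true_labels)
    p = _to_binary(predicted_labels)
    return ConfusionCounts(
        tp=float(np.sum((y == 1) & (p == 1))),
        fp=float(np.sum((y == 0) & (p == 1))),
        fn=float(np.sum((y == 1) & (p == 0))),
        tn=float(np.sum((y == 0) & (p == 0))))


def metrics(c: ConfusionCounts) -> MetricReport:
    """Full metric suite; zero-denominator metrics come back as NaN."""
    sens_plus = _ratio(c.tp, c.tp + c.fn)
    sens_minus = _ratio(c.tn, c.tn + c.fp)  # = specificity of FM+
    prec_plus = _ratio(c.tp, c.tp + c.fp)
    prec_minus = _ratio(c.tn, c.tn + c.fn)
    f1_plus = _ratio(2 * prec_plus * sens_plus, prec_plus + sens_plus) \
        if not (np.isnan(prec_plus) or np.isnan(sens_plus)) else float("nan")
    f1_minus = _ratio(2 * prec_minus * sens_minus, prec_minus + sens_minus) \
        if not (np.isnan(prec_minus) or np.isnan(sens_minus)) else float("nan")
    return MetricReport(
        sensitivity_fm_plus=sens_plus,
        sensitivity_fm_minus=sens_minus,
        specificity_fm_plus=sens_minus,
        specificity_fm_minus=sens_plus,
        precision_fm_plus=prec_plus,
        precision_fm_minus=prec_minus,
        accuracy=_ratio(c.tp + c.tn, c.total),
        f1_fm_plus=f1_plus,
        f1_fm_minus=f1_minus)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding: half-up, as printed metric tables conventionally do."""
    from decimal import ROUND_HALF_UP, Decimal

    if np.isnan(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{decimals}"), ROUND_HALF_UP))


def cohen_kappa(ratings_a, ratings_b,
                classes=(Label.FM_PLUS, Label.FM_MINUS)) -> tuple[float, int]:
    """Chance-corrected agreement κ between two raters.

    Pairs containing labels outside ``classes`` are dropped; the number
    dropped is returned alongside κ.  If both raters are constant and
    identical (chance agreement 1), κ is defined as 1; a constant pair
    of raters that still disagrees somewhere yields NaN.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    classes = tuple(Label.coerce(c) for c in classes)
    a = [Label.coerce(x) for x in ratings_a]
    b = [Label.coerce(x) for x in ratings_b]
    keep = [(x, y) for x, y in zip(a, b) if x in classes and y in classes]
    n_dropped = len(a) - len(keep)
    if not keep:
        raise ValueError("no rating pairs left after class restriction")
    n = len(keep)
    p_o = sum(x == y for x, y in keep) / n
    p_e = sum((sum(x == c for x, _ in keep) / n) * (sum(y == c for _, y in keep) / n)
              for c in classes)
    if abs(1.0 - p_e) < 1e-12:
        return (1.0 if p_o == 1.0 else float("nan")), n_dropped
    return (p_o - p_e) / (1.0 - p_e), n_dropped


def consensus_filter(rating_pairs):
    """Keep snippets both raters labelled identically as FM+ or FM−.

    A pair is excluded as *not assessable* if **either** rater used that
    label (checked before discrepancy); otherwise excluded as
    *discrepant* if the FM labels differ; otherwise kept with the shared
    label.

    Returns ``(kept, n_discrepant, n_not_assessable)`` where ``kept``
    maps snippet_id → consensus :class:`Label`.
    """
    kept: dict[str, Label] = {}
    n_discrepant = n_na = 0
    for pair in rating_pairs:
        a, b = Label.coerce(pair.rater_a), Label.coerce(pair.rater_b)
        if Label.NOT_ASSESSABLE in (a, b):
            n_na += 1
        elif a != b:
            n_discrepant += 1
        else:
            kept[pair.snippet_id] = a
    return kept, n_discrepant, n_na


def compare_architectures(acc_folds_a, acc_folds_b, equal_var: bool = False):
    """Two-sided t-test on per-fold accuracies of two architectures.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    pooled Student variant.  Identical inputs return (0.0, 1.0).
    """
    a = np.asarray(acc_folds_a, dtype=float)
    b = np.asarray(acc_folds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two fold accuracies per architecture")
    if np.array_equal(a, b) and np.ptp(a) == 0:
        return 0.0, 1.0  # degenerate zero-variance case
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CrossValReport:
    """Per-architecture, per-fold metrics with across-fold aggregation."""

    per_fold: pd.DataFrame      # columns: architecture, fold, tp..tn, metrics
    summary: pd.DataFrame       # mean and SD per architecture x metric

    def accuracies(self, architecture_id: int) -> np.ndarray:
        rows = self.per_fold[self.per_fold["architecture"] == architecture_id]
        return rows["accuracy"].to_numpy()

    def compare(self, arch_a: int, arch_b: int, equal_var: bool = False):
        return compare_architectures(self.accuracies(arch_a), self.accuracies(arch_b),
                                     equal_var=equal_var)


def _aggregate(per_fold: pd.DataFrame) -> pd.DataFrame:
    metric_cols = [c for c in per_fold.columns if c not in ("architecture", "fold")]
    grouped = per_fold.groupby("architecture")[metric_cols]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()


def cross_validate(architectures, fold_plans, snippets,
                   feature_cfg: FeatureConfig = FeatureConfig(),
                   train_cfg: TrainConfig = TrainConfig(),
                   validation_snippets=None, seed: int = 0) -> CrossValReport:
    """Train and evaluate architectures across participant-disjoint folds.

    For each architecture × fold the model is trained on the fold's
    TRAIN participants' windows and evaluated snippet-wise (majority
    vote) on the TEST participants.  ``validation_snippets`` (e.g. the
    global tuning set) enables early stopping; when omitted, training
    runs to ``train_cfg.max_epochs``.  Per-metric mean and SD across
    folds are reported; a ratio-of-mean-counts view can be derived from
    the reported mean TP/FP/FN/TN columns.
    """
    from .features import windows_matrix

    if len(fold_plans) < 2:
        raise ValueError("cross-validation needs at least two folds")
    by_participant: dict[str, list] = {}
    for snippet in snippets:
        by_participant.setdefault(snippet.participant_id, []).append(snippet)

    X_val = y_val = None
    if validation_snippets is not None:
        X_val, y_val, _ = windows_matrix(validation_snippets, feature_cfg)

    rows = []
    for arch in architectures:
        spec = ModelSpec.from_architecture(arch) if isinstance(arch, int) else arch
        for plan in fold_plans:
            train_snips = [s for p in plan.participants("TRAIN") for s in by_participant.get(p, [])]
            test_snips = [s for p in plan.participants("TEST") for s in by_participant.get(p, [])]
            overlap = set(plan.participants("TRAIN")) & set(plan.participants("TEST"))
            if overlap:
                raise ValueError(f"fold {plan.fold_id}: participants in both sets: {overlap}")
            X, y, _ = windows_matrix(train_snips, feature_cfg)
            model = SMNNModel(X, y, spec, seed=seed + plan.fold_id)
            result = model.fit(train_cfg, X_val, y_val)
            predictions = result.classify_snippets(test_snips, feature_cfg)
            truth = [s.label for s in test_snips]
            predicted = [predictions[s.snippet_id] for s in test_snips]
            counts = confusion(truth, predicted)
            row = {"architecture": spec.architecture_id, "fold": plan.fold_id,
                   "tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn}
            row.update(metrics(counts).as_dict())
            rows.append(row)
    per_fold = pd.DataFrame(rows)
    return CrossValReport(per_fold, _aggregate(per_fold))
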
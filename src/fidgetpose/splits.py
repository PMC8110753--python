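"""Participant-disjoint dataset splitting via a genetic-algorithm
knapsack solver.

Snippets must never be separated from their participant (identity
leakage would inflate test scores), so the unit of assignment is the
participant, and the balancing problem — hit target snippet fractions
per set, for both classes at once, with participant-atomic items — is a
multi-way knapsack.  It is solved with a small integer-chromosome
genetic algorithm: one gene per participant holding the set index,
tournament selection, uniform crossover, per-gene mutation and elitism.

Fitness (to minimize) is the summed squared deviation between achieved
and target snippet fractions over every (set, class) cell.

The canonical protocol carves out a validation set (~25% of snippets)
once, then builds five independent train (~2/3) / test (~1/3) splits of
the remaining participants for cross-validation; participants may recur
across folds but never across sets of the same fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import Label

logger = logging.getLogger(__name__)

VALIDATION, TRAIN, TEST = "VALIDATION", "TRAIN", "TEST"


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant snippet counts by class."""

    participant_id: str
    n_fm_plus: int
    n_fm_minus: int

    def __post_init__(self):
        if self.n_fm_plus < 0 or self.n_fm_minus < 0:
            raise ValueError("snippet counts must be non-negative")
        if self.n_fm_plus == 0 and self.n_fm_minus == 0:
            raise ValueError(f"participant {self.participant_id} has no snippets")


def summaries_from_labels(labels: pd.DataFrame) -> list[ParticipantSummary]:
    """Build participant summaries from a consensus-labelled table.

    Expects columns ``participant_id`` and ``label`` (FM_PLUS/FM_MINUS);
    alternatively ``rater_a``/``rater_b`` columns with identical values.
    """
    df = labels.copy()
    if "label" not in df.columns:
        df["label"] = df["rater_a"]
    out = []
    for pid, group in df.groupby("participant_id", sort=True):
        coerced = group["label"].map(lambda v: Label.coerce(v))
        out.append(ParticipantSummary(
            str(pid),
            int((coerced == Label.FM_PLUS).sum()),
            int((coerced == Label.FM_MINUS).sum())))
    return out


@dataclass(frozen=True)
class GAParams:
    population: int = 200
    generations: int = 300
    tournament_size: int = 3
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/n_participants
    elitism: int = 2


@dataclass
class SplitPlan:
    """Participant → set assignment for one fold."""

    assignment: dict[str, str]
    fold_id: int
    set_names: tuple[str, ...]
    target_fractions: tuple[float, ...]
    achieved_fractions: dict[str, dict[str, float]]  # set -> class -> fraction
    fitness: float
    seed: int

    def participants(self, set_name: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == set_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"participant_id": p, "fold": self.fold_id, "set": s}
             for p, s in sorted(self.assignment.items())])

    def metadata(self) -> dict:
        return {"fold_id": self.fold_id, "seed": self.seed, "fitness": self.fitness,
                "set_names": list(self.set_names),
                "target_fractions": list(self.target_fractions),
                "achieved_fractions": self.achieved_fractions}


def ga_knapsack_split(summaries, target_fractions=(0.25, 0.50, 0.25),
                      set_names=(VALIDATION, TRAIN, TEST), seed: int = 0,
                      ga_params: GAParams = GAParams(), fold_id: int = 0,
                      tolerance_pp: float = 5.0) -> SplitPlan:
    """Assign participants to sets, balancing per-class snippet fractions.

    Deterministic given ``seed``.  If the best assignment misses a
    target overall fraction by more than ``tolerance_pp`` percentage
    points, the best-found plan is still returned with a warning.
    """
    summaries = list(summaries)
    n = len(summaries)
    n_sets = len(set_names)
    if len(target_fractions) != n_sets:
        raise ValueError("one target fraction per set is required")
    if abs(sum(target_fractions) - 1.0) > 1e-9:
        raise ValueError("target fractions must sum to 1")
    if n < n_sets:
        raise ValueError(f"need at least {n_sets} participants, got {n}")

    counts = np.array([[s.n_fm_plus, s.n_fm_minus] for s in summaries], dtype=float)
    # guard against a class with zero snippets overall
    class_totals = counts.sum(axis=0)
    active = class_totals > 0
    counts_active = counts[:, active]
    targets = np.asarray(target_fractions, dtype=float)

    rng = np.random.default_rng(seed)
    p_mut = ga_params.mutation_prob if ga_params.mutation_prob is not None else 1.0 / n
    pop = rng.integers(0, n_sets, size=(ga_params.population, n))

    def evaluate(population):
        totals = counts_active.sum(axis=0)
        fit = np.zeros(len(population))
        for s in range(n_sets):
            in_set = population == s
            for c in range(counts_active.shape[1]):
                achieved = in_set @ counts_active[:, c] / totals[c]
                fit += (achieved - targets[s]) ** 2
        return fit

    fit = evaluate(pop)
    for _ in range(ga_params.generations):
        order = np.argsort(fit)
        elite = pop[order[:ga_params.elitism]].copy()
        # tournament selection
        contenders = rng.integers(0, len(pop), size=(len(pop), ga_params.tournament_size))
        winners = contenders[np.arange(len(pop)), np.argmin(fit[contenders], axis=1)]
        parents = pop[winners]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        do_cross = rng.random(len(pop) // 2) < ga_params.crossover_prob
        swap_mask = rng.random((len(pop) // 2, n)) < 0.5
        for i in np.nonzero(do_cross)[0]:
            a, b = 2 * i, 2 * i + 1
            mask = swap_mask[i]
            children[a, mask], children[b, mask] = parents[b, mask], parents[a, mask]
        # per-gene mutation
        mutate = rng.random(children.shape) < p_mut
        children[mutate] = rng.integers(0, n_sets, size=int(mutate.sum()))
        children[:ga_params.elitism] = elite
        pop = children
        fit = evaluate(pop)

    best = pop[np.argmin(fit)]
    assignment = {summaries[i].participant_id: set_names[int(best[i])] for i in range(n)}
    achieved: dict[str, dict[str, float]] = {}
    class_names = ("FM_PLUS", "FM_MINUS")
    for s, name in enumerate(set_names):
        in_set = best == s
        achieved[name] = {}
        for c, cname in enumerate(class_names):
            total = counts[:, c].sum()
            achieved[name][cname] = float(counts[in_set, c].sum() / total) if total else float("nan")
        overall = counts[in_set].sum() / counts.sum()
        achieved[name]["ALL"] = float(overall)
        if abs(overall - target_fractions[s]) * 100 > tolerance_pp:
            logger.warning("set %s achieves %.1f%% of snippets vs target %.1f%%",
                           name, 100 * overall, 100 * target_fractions[s])
    return SplitPlan(assignment, fold_id, tuple(set_names), tuple(target_fractions),
                     achieved, float(fit.min()), seed)


def make_cv_folds(summaries, n_folds: int = 5, seed: int = 0,
                  target_fractions=(2 / 3, 1 / 3),
                  ga_params: GAParams = GAParams()) -> list[SplitPlan]:
    """Independent train/test splits of the non-validation participants.

    Each fold is a separate GA run with its own seed; participants may
    appear in different sets across folds but are never split within a
    fold.  The default targets put ~2/3 of the remaining snippets in
    train and ~1/3 in test (≈ 50% / 25% of the full dataset once a 25%
    validation set has been removed).
    """
    plans = []
    for fold in range(n_folds):
        plans.append(ga_knapsack_split(
            summaries, target_fractions, (TRAIN, TEST),
            seed=seed + fold, ga_params=ga_params, fold_id=fold + 1))
    return plans


def save_split_plans(plans, csv_path, json_path=None) -> None:
    """Serialize plans as participant/fold/set CSV plus JSON metadata."""
    import json as _json
    from pathlib import Path

    frame = pd.concat([p.to_frame() for p in plans], ignore_index=True)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(_json.dumps([p.metadata() for p in plans], indent=2))
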
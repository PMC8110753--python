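import numpy as np
import pytest

import fidgetpose as fp


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small seeded synthetic cohort shared by read-only tests."""
    cfg = fp.CohortConfig(n_participants=6, snippets_per_participant=4, seed=11)
    snippets, labels = fp.generate_cohort(cfg)
    return cfg, snippets, labels


@pytest.fixture()
def clean_snippet():
    """One noise-free FM+ snippet with identity camera (all joints present)."""
    rng = np.random.default_rng(5)
    return fp.generate_snippet(fp.Label.FM_PLUS, fp.FM_PLUS_DEFAULT,
                               (1.0, (0.0, 0.0)), rng, dropout_prob=0.0)


@pytest.fixture(scope="session")
def separable_fit():
    """A small trained classifier plus held-out snippets, reused across tests."""
    cfg = fp.CohortConfig(n_participants=12, snippets_per_participant=8, seed=3)
    snippets, labels = fp.generate_cohort(cfg)
    summaries = fp.summaries_from_labels(labels)
    plan = fp.ga_knapsack_split(summaries, (0.5, 0.25, 0.25), ("TRAIN", "TEST", "VALIDATION"),
                                seed=1, ga_params=fp.GAParams(population=60, generations=60))
    by = {}
    for s in snippets:
        by.setdefault(s.participant_id, []).append(s)
    train = [s for p in plan.participants("TRAIN") for s in by[p]]
    test = [s for p in plan.participants("TEST") for s in by[p]]
    val = [s for p in plan.participants("VALIDATION") for s in by[p]]
    X, y, _ = fp.windows_matrix(train)
    X_val, y_val, _ = fp.windows_matrix(val)
    model = fp.SMNNModel(X, y, 5, seed=0)
    results = model.fit(fp.TrainConfig(max_epochs=250, patience=60, seed=0), X_val, y_val)
    return results, test
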
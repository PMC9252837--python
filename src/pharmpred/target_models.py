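"""Per-target binary interaction models with dual-score predictions.

One logistic-regression model is trained per eligible protein target
(>= 20 strong binders and >= 20 non-binders), on Morgan fingerprints, with
binders as the positive class. Model quality is estimated by stratified
10-fold cross-validation; because per-target accuracy varies, every
prediction reports two scores side by side: the interaction probability for
the query and the cross-validated accuracy of the model that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .atc_model import ModelParams, oversample
from .bioactivity import TargetDataset
from .chem import FingerprintConfig, Structure, fingerprint, fingerprint_matrix

__all__ = [
    "TargetModel",
    "TargetPrediction",
    "AccuracySummary",
    "train_target_model",
    "predict_targets",
    "summarize_accuracies",
]


@dataclass
class TargetModel:
    target_id: str
    estimator: LogisticRegression
    fp_config: FingerprintConfig
    cv_accuracy: float
    n_binders: int
    n_nonbinders: int
    seed: int = 0


@dataclass(frozen=True)
class TargetPrediction:
    """Dual-score prediction row: both scores are always present."""

    target_id: str
    probability: float
    model_accuracy: float
    known_binder: bool = False


@dataclass(frozen=True)
class AccuracySummary:
    n_models: int
    frac_ge_85: float
    frac_lt_70: float
    histogram: dict[str, int]


def _fit_binary(
    X: np.ndarray, y: np.ndarray, seed: int, params: ModelParams, balance: bool
) -> LogisticRegression:
    if balance and len(set(y.tolist())) == 2 and (y == 1).sum() != (y == 0).sum():
        plan = oversample(["pos" if v else "neg" for v in y], seed)
        X, y = X[plan.indices], y[plan.indices]
    est = LogisticRegression(C=params.C, solver=params.solver, max_iter=params.max_iter)
    est.fit(X, y)
    return est


def train_target_model(
    dataset: TargetDataset,
    config: FingerprintConfig = FingerprintConfig(),
    seed: int = 0,
    params: ModelParams = ModelParams(),
    n_folds: int = 10,
    balance_folds: bool = True,
) -> TargetModel:
    """Fit the binary binder-vs-nonbinder model for one eligible target.

    Cross-validation is stratified (unstratified folds on a 20/20 set can
    end up single-class) and seeded. With ``balance_folds`` the minority
    class is randomly oversampled inside each training fold, mirroring the
    multi-class pipeline; the held-out fold is never resampled.
    """
    if not dataset.eligible:
        raise ValueError(
            f"target {dataset.target_id} is not eligible for training: "
            f"{len(dataset.binders)} binders / {len(dataset.nonbinders)} non-binders "
            f"(need >= {dataset.min_binders} / {dataset.min_nonbinders})"
        )
    structures = list(dataset.binders) + list(dataset.nonbinders)
    y = np.array([1] * len(dataset.binders) + [0] * len(dataset.nonbinders))
    X = fingerprint_matrix(structures, config)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_seeds = np.random.SeedSequence(seed).spawn(n_folds)
    correct = 0
    for k, (tr, te) in enumerate(skf.split(X, y)):
        fs = int(fold_seeds[k].generate_state(1)[0] % (2**31))
        est = _fit_binary(X[tr], y[tr], fs, params, balance_folds)
        correct += int((est.predict(X[te]) == y[te]).sum())
    cv_accuracy = correct / len(y)

    final = _fit_binary(X, y, seed, params, balance_folds)
    return TargetModel(
        target_id=dataset.target_id,
        estimator=final,
        fp_config=config,
        cv_accuracy=cv_accuracy,
        n_binders=len(dataset.binders),
        n_nonbinders=len(dataset.nonbinders),
        seed=seed,
    )


def predict_targets(
    query: Structure,
    models: list[TargetModel],
    binder_lookup: dict[str, set[str]] | None = None,
) -> list[TargetPrediction]:
    """Score one query against every target model.

    Rows are sorted by probability descending, ties broken by target id.
    ``binder_lookup`` (target id -> set of canonical binder SMILES) flags
    queries that are already known strong binders of a target.
    """
    if not models:
        raise ValueError("predict_targets requires at least one model")
    binder_lookup = binder_lookup or {}
    rows = []
    for m in models:
        x = fingerprint(query, m.fp_config).bits.reshape(1, -1)
        pos = list(m.estimator.classes_).index(1)
        p = float(m.estimator.predict_proba(x)[0][pos])
        known = query.canonical_smiles in binder_lookup.get(m.target_id, set())
        rows.append(
            TargetPrediction(
                target_id=m.target_id,
                probability=p,
                model_accuracy=m.cv_accuracy,
                known_binder=known,
            )
        )
    return sorted(rows, key=lambda r: (-r.probability, r.target_id))


def summarize_accuracies(
    models: list[TargetModel], high: float = 0.85, low: float = 0.70
) -> AccuracySummary:
    """Fraction of models at or above ``high`` and strictly below ``low``,
    plus a decile histogram of the cross-validated accuracies."""
    if not models:
        raise ValueError("summarize_accuracies requires at least one model")
    accs = np.array([m.cv_accuracy for m in models])
    edges = np.arange(0.0, 1.01, 0.1)
    counts, _ = np.histogram(accs, bins=edges)
    histogram = {
        f"[{edges[i]:.1f},{edges[i+1]:.1f})": int(c) for i, c in enumerate(counts)
    }
    return AccuracySummary(
        n_models=len(models),
        frac_ge_85=float((accs >= high).mean()),
        frac_lt_70=float((accs < low).mean()),
        histogram=histogram,
    )
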
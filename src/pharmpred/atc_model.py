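"""Multi-class level-4 ATC classifier.

One multinomial logistic-regression model over Morgan-fingerprint space
assigns each query a probability distribution over the predictable level-4
groups: the model assumes every structure belongs to exactly one group and
distributes a total of 100% between the classes, rather than scoring each
class independently. Structures that genuinely carry several codes show up
as several high-probability classes in the distribution.

Class imbalance (largest groups ~50 structures, smallest 2-3) is handled by
random oversampling: minority-class members are re-drawn with replacement
until every class matches the majority size. Oversampling is re-drawn
inside every cross-validation fold, never before splitting — oversampling
first would leak copies of the held-out structure into training.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression

from .atc import CuratedATCDataset
from .chem import FingerprintConfig, Structure, fingerprint_matrix, fingerprint

__all__ = [
    "OversamplePlan",
    "ATCModel",
    "ATCPrediction",
    "LoocvReport",
    "ModelParams",
    "oversample",
    "train",
    "predict",
    "loocv",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelParams:
    """Linear-model hyperparameters. Defaults are pinned for convergence on
    2048-bit binary inputs; all overridable."""

    C: float = 1.0
    solver: str = "lbfgs"
    max_iter: int = 2000


@dataclass
class OversamplePlan:
    """Result of balancing classes by random re-insertion.

    ``indices`` lists, per class, the sample indices that make up the
    balanced training multiset; it always contains every original index of
    the class at least once.
    """

    seed: int
    class_counts_before: dict[str, int]
    class_counts_after: dict[str, int]
    indices: np.ndarray = field(repr=False, default=None)


def oversample(labels: list[str], seed: int) -> OversamplePlan:
    """Balance classes to the majority size by sampling with replacement.

    Every original sample is retained; the top-up draws are uniform over the
    minority class's own members. Reproducible for a fixed seed.
    """
    counts = Counter(labels)
    if len(counts) < 2:
        raise ValueError("oversampling requires at least two classes")
    if min(counts.values()) < 1:
        raise ValueError("every class must be non-empty")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    labels_arr = np.asarray(labels)
    for label in sorted(counts):
        idx = np.flatnonzero(labels_arr == label)
        chosen.extend(idx.tolist())
        deficit = target - len(idx)
        if deficit > 0:
            chosen.extend(rng.choice(idx, size=deficit, replace=True).tolist())
    return OversamplePlan(
        seed=seed,
        class_counts_before=dict(sorted(counts.items())),
        class_counts_after={label: target for label in sorted(counts)},
        indices=np.asarray(chosen),
    )


@dataclass
class ATCModel:
    """A fitted multi-class model plus everything needed to reuse it."""

    classes: list[str]
    estimator: LogisticRegression
    fp_config: FingerprintConfig
    seed: int
    params: ModelParams = ModelParams()


@dataclass
class ATCPrediction:
    """A class-probability distribution for one query structure."""

    query: Structure
    probabilities: dict[str, float]
    known_codes: list[str] = field(default_factory=list)
    stereo_relative_codes: list[str] = field(default_factory=list)

    def top(self, n: int = 5) -> list[tuple[str, float]]:
        return sorted(self.probabilities.items(), key=lambda kv: (-kv[1], kv[0]))[:n]

    @property
    def argmax(self) -> str:
        # ties broken lexicographically for reproducibility
        return min(self.probabilities, key=lambda k: (-self.probabilities[k], k))


@dataclass
class LoocvReport:
    """Leave-one-out evaluation: per-structure outcomes plus accuracies."""

    entries: list[tuple[str, str, str, dict[str, float]]]
    # (structure id/smiles, true label, predicted label, full distribution)

    @property
    def accuracy(self) -> float:
        """Fraction of structures whose level-4 group was predicted exactly."""
        return sum(t == p for _, t, p, _ in self.entries) / len(self.entries)

    @property
    def level1_accuracy(self) -> float:
        """Fraction where the predicted label's first character (anatomical
        main group) matches; always >= the level-4 accuracy."""
        return sum(t[0] == p[0] for _, t, p, _ in self.entries) / len(self.entries)


def _fit(
    X: np.ndarray, labels: list[str], seed: int, params: ModelParams
) -> LogisticRegression:
    plan = oversample(labels, seed)
    Xb = X[plan.indices]
    yb = np.asarray(labels)[plan.indices]
    est = LogisticRegression(C=params.C, solver=params.solver, max_iter=params.max_iter)
    est.fit(Xb, yb)
    return est


def train(
    dataset: CuratedATCDataset,
    config: FingerprintConfig = FingerprintConfig(),
    seed: int = 0,
    params: ModelParams = ModelParams(),
) -> ATCModel:
    """Fit the multi-class model on the oversampled, fingerprinted dataset."""
    labels = dataset.labels
    if len(set(labels)) < 2:
        raise ValueError("training requires at least two level-4 classes")
    X = fingerprint_matrix(dataset.structures, config)
    est = _fit(X, labels, seed, params)
    return ATCModel(
        classes=list(est.classes_), estimator=est, fp_config=config, seed=seed,
        params=params,
    )


def predict(
    model: ATCModel,
    query: Structure,
    known_lookup: dict[str, list[str]] | None = None,
    stereo_lookup: dict[str, list[str]] | None = None,
) -> ATCPrediction:
    """Probability distribution over the model's classes for one query.

    ``known_lookup`` maps canonical SMILES to level-4 labels already in the
    database; matches are reported as known codes, without a probability.
    ``stereo_lookup`` does the same on stereo-stripped SMILES, catching
    queries whose stereoisomer is known.
    """
    x = fingerprint(query, model.fp_config).bits.reshape(1, -1)
    proba = model.estimator.predict_proba(x)[0]
    probabilities = {c: float(p) for c, p in zip(model.classes, proba)}
    known = list((known_lookup or {}).get(query.canonical_smiles, []))
    stereo: list[str] = []
    if stereo_lookup is not None:
        from .chem import strip_stereo

        stereo = [
            label
            for label in stereo_lookup.get(strip_stereo(query), [])
            if label not in known
        ]
    return ATCPrediction(
        query=query,
        probabilities=probabilities,
        known_codes=known,
        stereo_relative_codes=stereo,
    )


def loocv(
    dataset: CuratedATCDataset,
    config: FingerprintConfig = FingerprintConfig(),
    seed: int = 0,
    params: ModelParams = ModelParams(),
) -> LoocvReport:
    """Leave-one-out cross-validation of the multi-class model.

    For each structure the model is refitted on all others, with the
    oversampling re-drawn per fold from a seed derived from (seed, fold).
    Deterministic for identical (dataset, config, seed).
    """
    labels = np.asarray(dataset.labels)
    X = fingerprint_matrix(dataset.structures, config)
    n = len(labels)
    entries = []
    root = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = _fit(X[mask], labels[mask].tolist(), fold_seeds[i], params)
        proba = est.predict_proba(X[i].reshape(1, -1))[0]
        dist = {c: float(p) for c, p in zip(est.classes_, proba)}
        pred = min(dist, key=lambda k: (-dist[k], k))
        sid = dataset.structures[i].id or dataset.structures[i].canonical_smiles
        entries.append((sid, str(labels[i]), pred, dist))
    return LoocvReport(entries=entries)


# ---------------------------------------------------------------------------
# Persistence: a single self-describing joblib archive.

def save_model(model: ATCModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "atc_multiclass",
        "classes": model.classes,
        "fp_config": {"n_bits": model.fp_config.n_bits, "radius": model.fp_config.radius},
        "seed": model.seed,
        "params": {"C": model.params.C, "solver": model.params.solver,
                   "max_iter": model.params.max_iter},
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> ATCModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return ATCModel(
        classes=payload["classes"],
        estimator=payload["estimator"],
        fp_config=FingerprintConfig(**payload["fp_config"]),
        seed=payload["seed"],
        params=ModelParams(**payload["params"]),
    )


def report_to_tsv(report: LoocvReport, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for sid, true, pred, dist in report.entries:
        rows.append((sid, true, pred, dist.get(true, 0.0), max(dist.values()),
                     int(true == pred)))
    pd.DataFrame(
        rows, columns=["structure_id", "true", "predicted", "p_true", "p_max", "correct"]
    ).to_csv(path, sep="\t", index=False)


def prediction_to_json(pred: ATCPrediction) -> str:
    return json.dumps(
        {
            "query": pred.query.canonical_smiles,
            "known_codes": pred.known_codes,
            "stereo_relative_codes": pred.stereo_relative_codes,
            "probabilities": {k: round(v, 10) for k, v in sorted(pred.probabilities.items())},
        },
        indent=2,
        sort_keys=True,
    )
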
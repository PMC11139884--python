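"""Repeated-run interpretable classification protocol.

The protocol mirrors a small-cohort clinical-NLP setup: stratified 80/20
document split (stratifying on exposure × diagnosis), minority oversampling
(SMOTE) and z-scoring fitted on the training fold only, a model family with
fixed hyperparameters, ROC-AUC on the untouched test fold, and averaging of
both the score and the feature importances over 100 randomized runs.
Misclassification frequencies per document feed an error analysis comparing
the most misclassified documents with the rest on metadata covariates.

Model families and their fixed hyperparameters:

* ``logistic_elasticnet`` — elastic-net logistic regression,
  l1_ratio = 0.6, C = 0.1, on standardized features; importances are
  absolute coefficients.
* ``random_forest`` — 40 trees, min_samples_split = 0.4,
  min_samples_leaf = 15; impurity importances.
* ``ebm`` — explainable boosting machine, max_leaves = 10,
  min_samples_leaf = 15, max_bins = 20, early_stopping_rounds = 20; term
  importances. The family is optional at runtime: if no EBM implementation
  is importable the family is skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from .stats import chi2_assoc, mann_whitney_assoc

MODEL_FAMILIES = ("logistic_elasticnet", "random_forest", "ebm")

DEFAULT_HYPERPARAMETERS = {
    "logistic_elasticnet": {"l1_ratio": 0.6, "C": 0.1},
    "random_forest": {
        "n_estimators": 40, "min_samples_split": 0.4, "min_samples_leaf": 15,
    },
    "ebm": {
        "max_leaves": 10, "min_samples_leaf": 15, "max_bins": 20,
        "early_stopping_rounds": 20,
    },
}


@dataclass
class ModelSpec:
    family: str = "logistic_elasticnet"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


@dataclass
class RunResult:
    seed: int
    train_ids: list
    test_ids: list
    roc_auc: float
    importances: np.ndarray
    misclassified: dict  # doc_id -> bool
    test_scores: dict = field(default_factory=dict)  # doc_id -> P(positive)


@dataclass
class RunSummary:
    family: str
    mean_auc: float
    std_auc: float
    n_runs: int
    feature_names: list
    mean_importances: np.ndarray
    misclassification_frequency: dict  # doc_id -> freq in test appearances
    test_appearances: dict

    def ranked_importances(self) -> list:
        order = np.argsort(-np.abs(self.mean_importances), kind="stable")
        return [(self.feature_names[i], float(self.mean_importances[i]))
                for i in order]


# ---------------------------------------------------------------------------
# split and oversampling


def build_strata(metadata, by=("exposure", "diagnosis")) -> dict:
    """doc_id → stratum key, coarsened until no stratum is a singleton.

    Tries the full cross first, then drops trailing factors (e.g.
    exposure × diagnosis → exposure → one stratum) until every stratum has
    at least two members.
    """
    for k in range(len(by), 0, -1):
        strata = {m.doc_id: tuple(getattr(m, a) for a in by[:k])
                  for m in metadata}
        counts: dict = {}
        for s in strata.values():
            counts[s] = counts.get(s, 0) + 1
        if min(counts.values()) >= 2:
            return strata
    return {m.doc_id: ("all",) for m in metadata}


def stratified_split(doc_ids, strata, test_frac: float = 0.2, seed: int = 0):
    """Stratified document split: per-stratum test fraction within ±1 of the
    target, repaired to the global rounded test size.

    ``strata`` maps doc_id → stratum key (e.g. (exposure, diagnosis)).
    Singleton strata are an error (merge strata instead).
    """
    doc_ids = list(doc_ids)
    rng = np.random.default_rng(seed)
    by_stratum: dict = {}
    for d in sorted(doc_ids):
        by_stratum.setdefault(strata[d], []).append(d)
    for key, members in by_stratum.items():
        if len(members) < 2:
            raise ValueError(
                f"stratum {key!r} has a single document; merge strata"
            )
    target_total = int(np.floor(len(doc_ids) * test_frac + 0.5))
    test: list = []
    for key in sorted(by_stratum, key=str):
        members = by_stratum[key]
        k = int(np.floor(len(members) * test_frac + 0.5))  # round half up
        k = min(k, len(members) - 1)
        picked = rng.choice(len(members), size=k, replace=False)
        test.extend(members[i] for i in sorted(picked))
    # repair to global target, preserving stratification as far as possible
    rng2 = np.random.default_rng(seed + 1)
    while len(test) > target_total:
        test.remove(test[rng2.integers(len(test))])
    if len(test) < target_total:
        pool = sorted(set(doc_ids) - set(test))
        extra = rng2.choice(len(pool), size=target_total - len(test),
                            replace=False)
        test.extend(pool[i] for i in sorted(extra))
    test_set = set(test)
    train = [d for d in doc_ids if d not in test_set]
    return train, [d for d in doc_ids if d in test_set]


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0):
    """Synthetic minority oversampling.

    Each synthetic sample lies on the segment between a minority point and
    one of its k nearest minority neighbours (Euclidean), with a uniform
    interpolation factor. Classes are returned balanced; an already
    balanced input is returned unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here supports binary labels only")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(Xm)} samples ≤ k_neighbors="
            f"{k_neighbors}; lower k_neighbors"
        )
    rng = np.random.default_rng(seed)
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    neigh = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
    base = rng.integers(len(Xm), size=n_needed)
    pick = rng.integers(k_neighbors, size=n_needed)
    lam = rng.uniform(size=n_needed)[:, None]
    Xs = Xm[base] + lam * (Xm[neigh[base, pick]] - Xm[base])
    return (np.vstack([X, Xs]),
            np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]))


# ---------------------------------------------------------------------------
# single run


def _make_model(spec: ModelSpec, seed: int):
    hp = spec.hyperparameters
    if spec.family == "logistic_elasticnet":
        return LogisticRegression(
            solver="saga", l1_ratio=hp["l1_ratio"], C=hp["C"],
            max_iter=5000, random_state=seed)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            min_samples_split=hp["min_samples_split"],
            min_samples_leaf=hp["min_samples_leaf"], random_state=seed)
    try:
        from interpret.glassbox import ExplainableBoostingClassifier
    except ImportError:
        return None
    return ExplainableBoostingClassifier(
        max_leaves=hp["max_leaves"], min_samples_leaf=hp["min_samples_leaf"],
        max_bins=hp["max_bins"],
        early_stopping_rounds=hp["early_stopping_rounds"], random_state=seed)


def _importances(spec: ModelSpec, model) -> np.ndarray:
    if spec.family == "logistic_elasticnet":
        return np.abs(model.coef_[0])
    if spec.family == "random_forest":
        return model.feature_importances_
    return np.asarray(model.term_importances()[: model.n_features_in_])


def train_eval_run(spec: ModelSpec, split, features, labels, seed: int = 0,
                   k_neighbors: int = 5) -> RunResult | None:
    """One train/evaluate run.

    Oversampling and standardization are fitted on the training fold only;
    the test fold is untouched until scoring. Returns None if the test fold
    is single-class (AUC undefined) or the model family is unavailable.
    """
    train_ids, test_ids = split
    label_vec = {d: labels[d] for d in features.doc_ids}
    idx = {d: i for i, d in enumerate(features.doc_ids)}
    Xtr = features.values[[idx[d] for d in train_ids]]
    Xte = features.values[[idx[d] for d in test_ids]]
    ytr = np.asarray([label_vec[d] for d in train_ids])
    yte = np.asarray([label_vec[d] for d in test_ids])
    if len(np.unique(yte)) < 2:
        return None

    scaler = StandardScaler().fit(Xtr)
    Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
    Xtr_b, ytr_b = smote_oversample(Xtr_s, ytr, k_neighbors=k_neighbors,
                                    seed=seed)
    if spec.family == "random_forest":
        # trees are scale-invariant; train on raw-scale oversampled data
        Xtr_b2, _ = smote_oversample(Xtr, ytr, k_neighbors=k_neighbors,
                                     seed=seed)
        model = _make_model(spec, seed)
        model.fit(Xtr_b2, ytr_b)
        scores = model.predict_proba(Xte)[:, 1]
        preds = model.predict(Xte)
    else:
        model = _make_model(spec, seed)
        if model is None:
            return None
        model.fit(Xtr_b, ytr_b)
        scores = model.predict_proba(Xte_s)[:, 1]
        preds = model.predict(Xte_s)
    positive = model.classes_[1]
    auc = roc_auc_score((yte == positive).astype(int), scores)
    mis = {d: bool(p != t) for d, p, t in zip(test_ids, preds, yte)}
    return RunResult(seed, list(train_ids), list(test_ids), float(auc),
                     _importances(spec, model), mis,
                     dict(zip(test_ids, map(float, scores))))


# ---------------------------------------------------------------------------
# repeated runs


def repeated_runs(spec: ModelSpec, features, labels, strata,
                  n_runs: int = 100, base_seed: int = 0,
                  test_frac: float = 0.2, k_neighbors: int = 5
                  ) -> RunSummary | None:
    """Run the protocol ``n_runs`` times with fresh stratified splits.

    Runs with a single-class test fold are reseeded (not skipped) so the
    number of valid runs stays exact. Importances and AUC are averaged over
    runs; per-document misclassification frequency is misclassified count /
    test-fold appearances.
    """
    aucs: list[float] = []
    importances: list[np.ndarray] = []
    mis_count: dict = {d: 0 for d in features.doc_ids}
    appearances: dict = {d: 0 for d in features.doc_ids}
    seed = int(base_seed)
    done = 0
    attempts = 0
    while done < n_runs:
        attempts += 1
        if attempts > 20 * n_runs:
            raise RuntimeError("too many degenerate splits; check labels")
        split = stratified_split(features.doc_ids, strata,
                                 test_frac=test_frac, seed=seed)
        run = train_eval_run(spec, split, features, labels, seed=seed,
                             k_neighbors=k_neighbors)
        seed += 1
        if run is None:
            if _make_model(spec, 0) is None:
                warnings.warn(f"model family {spec.family!r} unavailable; "
                              "skipping")
                return None
            continue  # reseeded
        aucs.append(run.roc_auc)
        importances.append(run.importances)
        for d, was_mis in run.misclassified.items():
            appearances[d] += 1
            mis_count[d] += was_mis
        done += 1
    freq = {d: (mis_count[d] / appearances[d]) if appearances[d] else 0.0
            for d in features.doc_ids}
    return RunSummary(
        family=spec.family, mean_auc=float(np.mean(aucs)),
        std_auc=float(np.std(aucs)), n_runs=n_runs,
        feature_names=list(features.names),
        mean_importances=np.mean(importances, axis=0),
        misclassification_frequency=freq, test_appearances=appearances)


# ---------------------------------------------------------------------------
# error analysis


def error_analysis(summary: RunSummary, metadata, n_worst: int = 20,
                   power_reps: int = 500, seed: int = 0) -> dict:
    """Compare the most frequently misclassified documents with the rest.

    Selects the ``n_worst`` documents with the highest misclassification
    frequency (ties broken by doc_id for determinism) and tests this
    subgroup against the remaining documents on metadata covariates:
    chi-square for categorical (sex, exposure, education, profession,
    single, living alone), Mann–Whitney for age.
    """
    meta = {m.doc_id: m for m in metadata}
    eligible = [d for d, n in summary.test_appearances.items() if n > 0]
    if len(eligible) < n_worst:
        warnings.warn(f"only {len(eligible)} documents appeared in test "
                      "folds; analysing all")
    ranked = sorted(eligible,
                    key=lambda d: (-summary.misclassification_frequency[d], d))
    worst = ranked[:n_worst]
    worst_set = set(worst)
    rest = [d for d in eligible if d not in worst_set]
    report: dict = {
        "worst_documents": worst,
        "max_frequency": max((summary.misclassification_frequency[d]
                              for d in eligible), default=0.0),
        "tests": {},
    }
    if report["max_frequency"] == 0.0:
        report["no_errors"] = True
        return report

    def _cat(attr):
        values = sorted({getattr(meta[d], attr) for d in eligible}, key=str)
        if len(values) < 2:
            return None
        table = [[sum(getattr(meta[d], attr) == v for d in grp)
                  for v in values] for grp in (worst, rest)]
        t = np.asarray(table)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return None
        return chi2_assoc(t, feature=attr, power_reps=power_reps, seed=seed)

    for attr in ("sex", "exposure", "diagnosis", "education", "profession",
                 "single", "living_alone"):
        try:
            res = _cat(attr)
        except ValueError:
            res = None
        if res is not None:
            report["tests"][attr] = res

    ages = np.array([meta[d].age for d in eligible])
    grp = np.array([d in worst_set for d in eligible])
    if np.isfinite(ages).all() and grp.sum() >= 2 and (~grp).sum() >= 2:
        report["tests"]["age"] = mann_whitney_assoc(
            ages, grp, feature="age", group_order=[True, False],
            power_reps=power_reps, seed=seed)
    return report
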
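"""Leakage-guarded cross-validated feature selection and classification.

Spectra are flattened to per-pixel features.  A stratified 10-fold split is
drawn once; within each fold the features are ranked by two-sided Wilcoxon
rank-sum p-value **computed on the training rows only**, the lowest-p
features are kept, a classifier (L1-penalised logistic regression with its
penalty tuned by inner CV on the training fold, or a seeded gradient-boosted
tree ensemble) is fitted on the training rows, and class-1 probabilities are
predicted for the held-out rows.  Pooling the held-out probabilities over
all folds yields one out-of-fold probability per sample, from which a single
ROC is built downstream.

Restricting feature ranking to the training rows is what keeps the apparent
performance honest: ranking on the full table first leaks the validation
labels into the feature choice and inflates the AUC even on pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .errors import CohortError, ConfigError, InputError, StratificationError
from .spectra import Cohort, Spectrum

__all__ = [
    "FeatureTable",
    "CVConfig",
    "CVResult",
    "flatten",
    "rank_sum_pvalue",
    "rank_sum_pvalues",
    "select_features",
    "assign_folds",
    "fit_and_score_fold",
    "run_cv",
]


# ---------------------------------------------------------------- containers


@dataclass
class FeatureTable:
    """Samples x flattened-pixel matrix with coordinate back-references.

    Row ``i`` is the row-major flattening of spectrum ``i``; feature ``j``
    maps back to pixel ``(j // n_drift, j % n_drift)``.
    """

    values: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n_feat = self.retention_axis.size * self.drift_axis.size
        if self.values.shape != (self.labels.size, n_feat):
            raise CohortError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.labels.size} samples x {n_feat} pixels"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_coords(self) -> np.ndarray:
        """(n_features, 2) array of (retention, drift) axis coordinates."""
        r, d = np.meshgrid(self.retention_axis, self.drift_axis, indexing="ij")
        return np.column_stack([r.ravel(), d.ravel()])

    def feature_names(self) -> list[str]:
        nd = self.drift_axis.size
        return [f"r{j // nd}_d{j % nd}" for j in range(self.n_features)]

    def feature_index(self, retention: float, drift: float) -> int:
        """Flat index of the pixel nearest the given axis coordinates."""
        i = int(np.argmin(np.abs(self.retention_axis - retention)))
        j = int(np.argmin(np.abs(self.drift_axis - drift)))
        return i * self.drift_axis.size + j

    def to_spectrum(self, i: int) -> Spectrum:
        """Inverse of :func:`flatten` for sample ``i``."""
        shape = (self.retention_axis.size, self.drift_axis.size)
        return Spectrum(
            self.values[i].reshape(shape),
            self.retention_axis.copy(),
            self.drift_axis.copy(),
            self.sample_ids[i],
        )


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    ``n_top_features`` (default 50) is an implementation default — how many
    lowest-p features enter the classifier is not a measured quantity.
    """

    k: int = 10
    n_top_features: int = 50
    classifier: str = "sparse_logistic"
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be at least 2")
        if self.n_top_features < 1:
            raise ConfigError("n_top_features must be at least 1")
        if self.classifier not in ("sparse_logistic", "gradient_boosting"):
            raise ConfigError(f"unknown classifier {self.classifier!r}")


@dataclass
class CVResult:
    """Everything one CV run produced: the fold partition, per-fold selected
    features with their training-set p-values, and the pooled out-of-fold
    class-1 probability per sample."""

    fold_assignment: np.ndarray
    selected_features: list[np.ndarray]
    selected_pvalues: list[np.ndarray]
    oof_probability: np.ndarray
    classifier: str
    config: CVConfig = field(repr=False, default=None)


# ------------------------------------------------------------------- flatten


def flatten(cohort: Cohort) -> FeatureTable:
    """Row-major flattening of a preprocessed cohort with common axes."""
    cohort.validate_axes()
    ref = cohort.spectra[0]
    values = np.stack([s.intensities.ravel(order="C") for s in cohort.spectra])
    return FeatureTable(
        values,
        ref.retention_axis.copy(),
        ref.drift_axis.copy(),
        [s.sample_id for s in cohort.spectra],
        cohort.labels.copy(),
    )


# ----------------------------------------------------------------- rank sums

_EXACT_LIMIT = 12  # exact enumeration below this combined size (no ties)


def rank_sum_pvalue(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney p-value for two groups.

    ``auto`` enumerates the exact permutation distribution when the combined
    size is at most 12 and there are no ties, and otherwise uses the normal
    approximation with tie and continuity corrections.  ``exact`` and
    ``asymptotic`` force the respective path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ConfigError(f"unknown method {method!r}")
    if method == "auto":
        combined = np.concatenate([x, y])
        no_ties = np.unique(combined).size == combined.size
        method = "exact" if (combined.size <= _EXACT_LIMIT and no_ties) else "asymptotic"
    if np.ptp(np.concatenate([x, y])) == 0:  # all values identical
        return 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def rank_sum_pvalues(values: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values, normal approximation with tie
    and continuity corrections (vectorised over features).

    ``group_mask`` marks the rows of group A.  Matches
    ``rank_sum_pvalue(..., method="asymptotic")`` per column; constant
    columns get p = 1.
    """
    values = np.asarray(values, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    n = values.shape[0]
    n1 = int(group_mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise InputError("both groups must be non-empty")

    ranks = stats.rankdata(values, axis=0)
    u1 = ranks[group_mask].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # tie correction: sum over tie groups of (t^3 - t), per column
    sorted_vals = np.sort(values, axis=0)
    new_group = np.ones_like(sorted_vals, dtype=bool)
    new_group[1:] = sorted_vals[1:] != sorted_vals[:-1]
    tie_term = np.empty(values.shape[1])
    for j in range(values.shape[1]):  # cheap: O(n) per column on sorted data
        counts = np.diff(np.append(np.flatnonzero(new_group[:, j]), n))
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    p = np.ones(values.shape[1])
    ok = var > 0
    z = (np.abs(u1[ok] - mu) - 0.5) / np.sqrt(var[ok])  # continuity correction
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return p


def select_features(
    table: FeatureTable, train_indices: np.ndarray, n_top: int
) -> tuple[np.ndarray, np.ndarray]:
    """Lowest-p features on the training rows only.

    Returns ``(indices, pvalues)`` of the ``n_top`` best features, ordered by
    ascending p with ties broken by ascending flat index for determinism.
    """
    train_indices = np.asarray(train_indices)
    y = table.labels[train_indices]
    if np.unique(y).size < 2:
        raise StratificationError("training set contains a single class")
    sub = table.values[train_indices]
    if train_indices.size <= _EXACT_LIMIT:
        # small training sets go through the exact-capable scalar path
        p = np.array(
            [rank_sum_pvalue(sub[y == 1, j], sub[y == 0, j]) for j in range(sub.shape[1])]
        )
    else:
        p = rank_sum_pvalues(sub, y == 1)
    order = np.lexsort((np.arange(p.size), p))  # p ascending, then index
    top = order[: min(n_top, p.size)]
    return top, p[top]


# ----------------------------------------------------------------------- CV


def assign_folds(
    labels: np.ndarray, k: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Per-sample fold index for k folds of near-equal size, seeded.

    Stratified mode preserves the class ratio per fold within rounding and
    requires k to not exceed the minority class count.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if k > n:
        raise ConfigError(f"k={k} exceeds n={n}")
    if stratified:
        if k > np.bincount(labels).min():
            raise ConfigError("k exceeds the minority class count")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return assignment


def _make_classifier(name: str, seed: int, y_train: np.ndarray):
    if name == "sparse_logistic":
        inner = min(5, int(np.bincount(y_train).min()))
        return make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                Cs=np.logspace(-2, 2, 8),
                l1_ratios=(1,),  # pure L1: sparse coefficient paths
                solver="liblinear",
                cv=StratifiedKFold(n_splits=max(2, inner), shuffle=True, random_state=seed),
                scoring="neg_log_loss",
                max_iter=1000,
                random_state=seed,
                use_legacy_attributes=False,
            ),
        )
    return XGBClassifier(
        max_depth=3,
        n_estimators=200,
        learning_rate=0.1,
        subsample=0.8,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


def fit_and_score_fold(
    table: FeatureTable,
    train_indices: np.ndarray,
    test_indices: np.ndarray,
    config: CVConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One fold: select features and fit on the training rows only, return
    class-1 probabilities for the held-out rows.

    Returns ``(probabilities, selected_indices, selected_pvalues)``.
    """
    train_indices = np.asarray(train_indices)
    test_indices = np.asarray(test_indices)
    if np.intersect1d(train_indices, test_indices).size:
        raise ConfigError("train and test indices overlap")
    selected, pvals = select_features(table, train_indices, config.n_top_features)
    X_train = table.values[np.ix_(train_indices, selected)]
    X_test = table.values[np.ix_(test_indices, selected)]
    y_train = table.labels[train_indices]
    clf = _make_classifier(config.classifier, config.seed, y_train)
    clf.fit(X_train, y_train)
    proba = clf.predict_proba(X_test)[:, 1]
    return np.clip(proba, 0.0, 1.0), selected, pvals


def run_cv(table: FeatureTable, config: CVConfig) -> CVResult:
    """Full leakage-guarded CV: every sample scored exactly once out-of-fold."""
    if config.k > table.n_samples:
        raise ConfigError(f"k={config.k} exceeds n={table.n_samples}")
    if config.n_top_features > table.n_features:
        raise ConfigError("n_top_features exceeds the number of features")
    assignment = assign_folds(table.labels, config.k, config.seed, config.stratified)
    oof = np.full(table.n_samples, np.nan)
    selected_all: list[np.ndarray] = []
    pvals_all: list[np.ndarray] = []
    for fold in range(config.k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        try:
            proba, selected, pvals = fit_and_score_fold(
                table, train_idx, test_idx, config
            )
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        oof[test_idx] = proba
        selected_all.append(selected)
        pvals_all.append(pvals)
    assert not np.isnan(oof).any()
    return CVResult(
        fold_assignment=assignment,
        selected_features=selected_all,
        selected_pvalues=pvals_all,
        oof_probability=oof,
        classifier=config.classifier,
        config=config,
    )
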
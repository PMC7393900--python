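"""Naive Bayes tissue-of-origin classification and its CV evaluation.

The question the classifier answers: given one or two marker features (the
per-sample unmethylated fraction of INS and/or CHTOP-817 measured by
droplet dPCR), which tissue class did the DNA come from?  Four tasks are
evaluated: (1) beta cell vs other, (2) islet (beta or alpha) vs other,
(3) pancreas (islet or non-islet pancreatic) vs other, and (4) beta vs
alpha vs other (3-class).

The classifier is Gaussian Naive Bayes: per class c and feature j a normal
density N(mu_cj, sigma_cj^2) is fitted (variance floored), features are
treated as independent, and the posterior is

    P(c | x) ∝ P(c) * prod_j N(x_j; mu_cj, sigma_cj^2)

computed in log space.  Binary tasks call the positive class iff its
posterior strictly exceeds the 0.5 threshold (a posterior of exactly 0.5
falls to the negative class); the multiclass task takes the argmax.

Evaluation is stratified 5-fold cross-validation repeated 100 times; within
a repetition the same fold partition is reused for every feature set and
task, so per-repetition accuracies are paired across feature sets.  Feature
sets are compared with a Friedman test on the 100 paired accuracies
(midranks, tie correction) followed by a Nemenyi-style post hoc on mean
ranks using studentized-range quantiles.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "NBModel",
    "CVReport",
    "ComparisonResult",
    "DEFAULT_FEATURE_SETS",
    "TASKS",
    "fit",
    "predict",
    "repeated_cv",
    "mean_accuracy_table",
    "friedman_test",
    "compare_feature_sets",
    "task_labels",
]

VAR_FLOOR = 1e-6

DEFAULT_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "INS": ("u_INS",),
    "CHTOP817": ("u_CHTOP817",),
    "INS+CHTOP817": ("u_INS", "u_CHTOP817"),
}

#: the four tissue-type tasks; binary tasks map to bool labels, the
#: cell-type task to a 3-class label
TASKS = ("beta", "islet", "pancreas", "celltype")


def task_labels(panel: pd.DataFrame, task: str) -> np.ndarray:
    """Class labels for one task from the panel's boolean tissue flags."""
    if task == "beta":
        return np.where(panel["is_beta"], "beta", "other")
    if task == "islet":
        return np.where(panel["is_islet"], "islet", "other")
    if task == "pancreas":
        return np.where(panel["is_pancreas"], "pancreas", "other")
    if task == "celltype":
        return np.where(
            panel["is_beta"], "beta", np.where(panel["is_alpha"], "alpha", "other")
        )
    raise ValueError(f"unknown task {task!r}")


#: positive class of each binary task (the non-positive class is "other")
POSITIVE_CLASS = {"beta": "beta", "islet": "islet", "pancreas": "pancreas"}


@dataclass
class NBModel:
    """A fitted Gaussian Naive Bayes model."""

    classes: np.ndarray
    priors: np.ndarray        # class frequencies, sum to 1
    means: np.ndarray         # (n_classes, n_features)
    variances: np.ndarray     # floored at VAR_FLOOR

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class probabilities, rows summing to 1 (log-space sum)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValueError("feature dimension mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        # log N(x; mu, s2) summed over features, per class
        diff = X[:, None, :] - self.means[None, :, :]
        log_lik = -0.5 * (
            np.log(2.0 * np.pi * self.variances)[None, :, :]
            + diff**2 / self.variances[None, :, :]
        ).sum(axis=2)
        log_post = np.log(self.priors)[None, :] + log_lik
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def fit(features, labels, var_floor: float = VAR_FLOOR) -> NBModel:
    """Fit Gaussian Naive Bayes: class priors plus per-class feature moments.

    Priors are training-set class frequencies; per-class per-feature means
    and (population) variances are floored at ``var_floor`` so single-sample
    or constant classes remain usable.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    classes, counts = np.unique(y, return_counts=True)
    means = np.empty((len(classes), X.shape[1]))
    variances = np.empty_like(means)
    for i, c in enumerate(classes):
        Xc = X[y == c]
        means[i] = Xc.mean(axis=0)
        variances[i] = np.maximum(Xc.var(axis=0), var_floor)
    return NBModel(
        classes=classes, priors=counts / counts.sum(), means=means, variances=variances
    )


def predict(
    model: NBModel, x, positive_class=None, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Classify feature vectors; returns (predicted classes, posteriors).

    With ``positive_class`` given (binary tasks) a sample is called positive
    iff the positive-class posterior strictly exceeds ``threshold``;
    otherwise the argmax class is returned.  A missing class in the model
    (e.g. no positive training samples) raises.
    """
    post = model.predict_proba(x)
    if positive_class is not None:
        matches = np.flatnonzero(model.classes == positive_class)
        if len(matches) != 1:
            raise ValueError(f"class {positive_class!r} absent from model")
        j = matches[0]
        neg = [c for c in model.classes if c != positive_class]
        negative_class = neg[0] if neg else positive_class
        pred = np.where(post[:, j] > threshold, positive_class, negative_class)
    else:
        pred = model.classes[np.argmax(post, axis=1)]
    return pred, post


@dataclass
class CVReport:
    """Repeated-CV accuracies plus the shared-fold record."""

    accuracies: pd.DataFrame          # rep, feature_set, task, accuracy
    fold_hashes: pd.DataFrame         # rep, feature_set, fold_hash
    fold_assignments: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    k: int = 5


def _rep_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31 - 1))


def repeated_cv(
    panel: pd.DataFrame,
    tasks=TASKS,
    feature_sets: dict[str, tuple[str, ...]] | None = None,
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Repeated stratified k-fold CV over tasks and feature sets.

    Per repetition one stratified partition is drawn (stratified on the
    finest tissue-class composite so every task sees both classes in every
    fold, falling back to unstratified folds when a stratum is smaller than
    k) and reused across all feature sets and tasks.  Accuracy per
    repetition is the proportion of all samples classified correctly when
    held out.
    """
    if feature_sets is None:
        feature_sets = DEFAULT_FEATURE_SETS
    n = len(panel)
    if n < k:
        raise ValueError("fewer samples than folds")
    strata = (
        panel["is_beta"].astype(int) * 4
        + panel["is_alpha"].astype(int) * 2
        + panel["is_pancreas"].astype(int)
    ).to_numpy()
    _, strata_counts = np.unique(strata, return_counts=True)
    stratified = strata_counts.min() >= k
    if not stratified:
        warnings.warn("stratum smaller than k: falling back to unstratified folds",
                      stacklevel=2)

    labels_by_task = {t: task_labels(panel, t) for t in tasks}
    X_by_set = {
        name: panel[list(cols)].to_numpy(float) for name, cols in feature_sets.items()
    }

    acc_rows, hash_rows, assignments = [], [], {}
    for rep in range(reps):
        rs = _rep_seed(seed, rep)
        splitter = (
            StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            if stratified
            else KFold(n_splits=k, shuffle=True, random_state=rs)
        )
        folds = list(splitter.split(np.zeros(n), strata))
        fold_of = np.empty(n, dtype=int)
        for f, (_, test_idx) in enumerate(folds):
            fold_of[test_idx] = f
        assignments[rep] = fold_of
        fold_hash = hashlib.sha1(fold_of.tobytes()).hexdigest()

        for fs_name, X in X_by_set.items():
            hash_rows.append(
                {"rep": rep, "feature_set": fs_name, "fold_hash": fold_hash}
            )
            for task in tasks:
                y = labels_by_task[task]
                correct = 0
                for train_idx, test_idx in folds:
                    model = fit(X[train_idx], y[train_idx])
                    pred, _ = predict(
                        model, X[test_idx],
                        positive_class=POSITIVE_CLASS.get(task),
                        threshold=threshold,
                    )
                    correct += int((pred == y[test_idx]).sum())
                acc_rows.append(
                    {
                        "rep": rep,
                        "feature_set": fs_name,
                        "task": task,
                        "accuracy": correct / n,
                    }
                )
    return CVReport(
        accuracies=pd.DataFrame(acc_rows),
        fold_hashes=pd.DataFrame(hash_rows),
        fold_assignments=assignments,
        seed=seed,
        k=k,
    )


def mean_accuracy_table(report: CVReport, percent: bool = True) -> pd.DataFrame:
    """Task x feature-set mean accuracy (the headline summary table)."""
    table = report.accuracies.pivot_table(
        index="task", columns="feature_set", values="accuracy", aggfunc="mean"
    )
    return table * 100.0 if percent else table


def friedman_test(data: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Friedman chi-square for an (n blocks x k treatments) table.

    Uses midranks within blocks and the standard tie correction:
    chi2 = [12 n / (k (k+1))] * sum_j (Rbar_j - (k+1)/2)^2 / C with
    C = 1 - sum(t^3 - t) / (n k (k^2 - 1)).  Returns (chi2, p, mean ranks);
    a table that is constant within every block gives (0, 1, .).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # every block fully tied
        return 0.0, 1.0, mean_ranks
    stat /= correction
    p = float(stats.chi2.sf(stat, k - 1))
    return float(stat), p, mean_ranks


@dataclass
class ComparisonResult:
    """Friedman omnibus plus Nemenyi-style pairwise post hoc on mean ranks."""

    task: str
    friedman_chi2: float
    p_value: float
    mean_ranks: pd.Series
    posthoc: pd.DataFrame  # set_a, set_b, rank_diff, q_stat, p_adj


def compare_feature_sets(report: CVReport, task: str) -> ComparisonResult:
    """Compare feature-set accuracies for one task across CV repetitions.

    The Friedman test treats repetitions as blocks (repeated measures); the
    post hoc compares mean ranks pairwise against the studentized-range
    distribution (Nemenyi), the rank-based analogue of a Tukey-style
    all-pairs comparison.
    """
    wide = report.accuracies.loc[report.accuracies["task"] == task].pivot(
        index="rep", columns="feature_set", values="accuracy"
    )
    if wide.shape[1] < 2 or wide.shape[0] < 2:
        raise ValueError("need >= 2 feature sets and >= 2 repetitions")
    data = wide.to_numpy()
    n, k = data.shape
    chi2, p, mean_ranks = friedman_test(data)

    se = np.sqrt(k * (k + 1) / (12.0 * n))
    rows = []
    for i, j in combinations(range(k), 2):
        diff = mean_ranks[i] - mean_ranks[j]
        q_stat = abs(diff) / se * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q_stat, k, np.inf))
        rows.append(
            {
                "set_a": wide.columns[i],
                "set_b": wide.columns[j],
                "rank_diff": diff,
                "q_stat": q_stat,
                "p_adj": min(p_adj, 1.0),
            }
        )
    return ComparisonResult(
        task=task,
        friedman_chi2=chi2,
        p_value=p,
        mean_ranks=pd.Series(mean_ranks, index=wide.columns, name="mean_rank"),
        posthoc=pd.DataFrame(rows),
    )
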
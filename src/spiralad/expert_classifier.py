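"""Balanced resampling, RBF-SVM experts, and metric aggregation.

The study has one spiral per subject for 45 healthy controls (HC) and 30
early-stage AD patients. To train on balanced classes, each of 10
repetitions draws 30 of the 45 HC at random, then trains an SVM on 20 HC +
20 AD and tests on the remaining 10 HC + 10 AD. Hyperparameters (C, gamma)
of the RBF kernel are chosen by grid search with stratified 5-fold
cross-validation on the training split; features are z-scored with
statistics fitted on the training split only. Performance is reported as
mean and standard deviation over the repetitions of accuracy, sensitivity
(AD correctly classified — AD is the positive class) and specificity (HC
correctly classified), all in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger("spiralad")

AD, HC = "AD", "HC"

#: Default RBF grid: log-decade C, log-decade gamma plus sklearn's
#: variance-scaled "scale" heuristic (useful for high-dimensional conv
#: activations).
DEFAULT_C_GRID = (1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
DEFAULT_GAMMA_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 1e1, "scale")


@dataclass(frozen=True)
class Repetition:
    """One train/test subject assignment, as indices into the per-class
    subject lists (0..n_hc-1 and 0..n_ad-1)."""

    train_hc: tuple[int, ...]
    test_hc: tuple[int, ...]
    train_ad: tuple[int, ...]
    test_ad: tuple[int, ...]
    cv_seed: int


@dataclass(frozen=True)
class SamplingPlan:
    """The balanced repeated-holdout subject assignment.

    One plan is shared by every expert of a run so that per-subject
    decisions align across views and layers for fusion.
    """

    repetitions: tuple[Repetition, ...]
    n_hc: int
    n_ad: int
    master_seed: int

    @property
    def n_reps(self) -> int:
        return len(self.repetitions)


def make_sampling_plan(
    n_hc: int = 45,
    n_ad: int = 30,
    n_reps: int = 10,
    master_seed: int = 0,
    hc_pool: int = 30,
    n_train_per_class: int = 20,
) -> SamplingPlan:
    """Build the repeated balanced holdout plan.

    Each repetition subsamples ``hc_pool`` HC (drawn independently per
    repetition), splits each class into ``n_train_per_class`` training and
    the rest test subjects. Defaults reproduce the study protocol: 10
    repetitions, 30-of-45 HC, 20+20 train / 10+10 test.
    """
    if hc_pool > n_hc:
        raise ValueError(f"cannot subsample {hc_pool} HC from {n_hc}")
    if n_train_per_class >= hc_pool or n_train_per_class >= n_ad:
        raise ValueError("train size must leave test subjects in both classes")
    rng = np.random.default_rng(master_seed)
    reps = []
    for _ in range(n_reps):
        hc_sub = rng.choice(n_hc, size=hc_pool, replace=False)
        rng.shuffle(hc_sub)
        ad_perm = rng.permutation(n_ad)
        reps.append(
            Repetition(
                train_hc=tuple(int(i) for i in hc_sub[:n_train_per_class]),
                test_hc=tuple(int(i) for i in hc_sub[n_train_per_class:]),
                train_ad=tuple(int(i) for i in ad_perm[:n_train_per_class]),
                test_ad=tuple(int(i) for i in ad_perm[n_train_per_class:hc_pool]),
                cv_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return SamplingPlan(tuple(reps), n_hc, n_ad, master_seed)


# ---------------------------------------------------------------------------
# SVM experts
# ---------------------------------------------------------------------------

@dataclass
class ExpertModel:
    """A trained (scaler, RBF-SVM) pair for one view x layer.

    The scaler is fitted on the repetition's training features only.
    """

    scaler: StandardScaler
    svm: SVC
    chosen_params: dict
    view: str = ""
    layer: str = ""

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.scaler.transform(np.asarray(features)))


def _grid_candidates(c_grid: Sequence, gamma_grid: Sequence) -> list[tuple]:
    """Candidates ordered for tie-breaking: C ascending, then gamma
    ascending with non-numeric entries ("scale") last."""
    def gamma_key(g):
        return (1, 0.0) if isinstance(g, str) else (0, float(g))
    cs = sorted(float(c) for c in c_grid)
    gs = sorted(gamma_grid, key=gamma_key)
    return [(c, g) for c in cs for g in gs]


def train_expert(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    c_grid: Sequence = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    cv_seed: int = 0,
    n_folds: int = 5,
    view: str = "",
    layer: str = "",
) -> ExpertModel:
    """Grid-search an RBF-SVM by stratified k-fold CV, refit on all of train.

    The winner is the (C, gamma) with the highest mean validation accuracy;
    ties break toward the smallest C, then the smallest gamma. The final
    model is refit on the full training split with z-scoring fitted on the
    same split.
    """
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, dim) aligned with labels")
    if len(set(y)) < 2:
        raise ValueError("training labels must contain both classes")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    # stratified folding needs at least one member per class per fold;
    # tiny training sets cap the fold count
    min_class = min(int(np.sum(y == c)) for c in set(y))
    if min_class < 2:
        raise ValueError("each class needs at least 2 training samples")
    n_folds = min(n_folds, min_class)
    folds = list(
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv_seed).split(Xs, y)
    )
    # One pairwise squared-distance matrix serves every (C, gamma) candidate:
    # the RBF kernel is exp(-gamma * D), so CV fits can use precomputed
    # kernels instead of re-deriving them from the high-dimensional features.
    sq = np.sum(Xs * Xs, axis=1)
    D = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Xs @ Xs.T), 0.0)
    gamma_scale = 1.0 / (Xs.shape[1] * Xs.var()) if Xs.var() > 0 else 1.0
    best = None
    for C, gamma in _grid_candidates(c_grid, gamma_grid):
        g = gamma_scale if isinstance(gamma, str) else float(gamma)
        K = np.exp(-g * D)
        accs = []
        for tr, va in folds:
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(K[np.ix_(tr, tr)], y[tr])
            accs.append(float(np.mean(clf.predict(K[np.ix_(va, tr)]) == y[va])))
        mean_acc = float(np.mean(accs))
        if best is None or mean_acc > best[0]:
            best = (mean_acc, C, gamma)
    _, C, gamma = best
    svm = SVC(kernel="rbf", C=C, gamma=gamma).fit(Xs, y)
    logger.debug("expert %s/%s: C=%g gamma=%s cv_acc=%.3f", view, layer, C, gamma, best[0])
    return ExpertModel(
        scaler=scaler,
        svm=svm,
        chosen_params={"C": C, "gamma": gamma, "cv_accuracy": best[0]},
        view=view,
        layer=layer,
    )


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table with AD as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_decisions(
    decisions: Sequence[str], labels: Sequence[str]
) -> ConfusionCounts:
    """Tally predicted vs true classes (AD positive)."""
    d = np.asarray(decisions)
    y = np.asarray(labels)
    if d.shape != y.shape or d.size == 0:
        raise ValueError("decisions and labels must be nonempty and aligned")
    return ConfusionCounts(
        tp=int(np.sum((y == AD) & (d == AD))),
        fn=int(np.sum((y == AD) & (d != AD))),
        tn=int(np.sum((y == HC) & (d == HC))),
        fp=int(np.sum((y == HC) & (d != HC))),
    )


def evaluate_expert(
    model: ExpertModel, test_features: np.ndarray, test_labels: Sequence[str]
) -> ConfusionCounts:
    """Score one expert on a held-out test split."""
    X = np.asarray(test_features)
    if X.size == 0:
        raise ValueError("empty test set")
    return confusion_from_decisions(model.predict(X), test_labels)


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent.

    sensitivity = % of AD correctly classified, specificity = % of HC.
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be present in the test set")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    sensitivity = 100.0 * c.tp / (c.tp + c.fn)
    specificity = 100.0 * c.tn / (c.tn + c.fp)
    return accuracy, sensitivity, specificity


@dataclass(frozen=True)
class EvalResult:
    """Per-repetition confusion counts with aggregated percent metrics.

    Means and standard deviations (population, ddof=0) are over the
    repetitions of the sampling plan.
    """

    per_rep: tuple[ConfusionCounts, ...]
    accuracy_mean: float
    accuracy_std: float
    sensitivity_mean: float
    sensitivity_std: float
    specificity_mean: float
    specificity_std: float

    def summary(self) -> str:
        return (
            f"acc {self.accuracy_mean:.1f}±{self.accuracy_std:.1f}  "
            f"sens {self.sensitivity_mean:.1f}±{self.sensitivity_std:.1f}  "
            f"spec {self.specificity_mean:.1f}±{self.specificity_std:.1f}"
        )


def aggregate(results: Sequence[ConfusionCounts]) -> EvalResult:
    """Mean and population std of percent metrics across repetitions."""
    if not results:
        raise ValueError("nothing to aggregate")
    metrics = np.array([compute_metrics(c) for c in results])
    mean = metrics.mean(axis=0)
    std = metrics.std(axis=0, ddof=0)
    return EvalResult(
        per_rep=tuple(results),
        accuracy_mean=float(mean[0]),
        accuracy_std=float(std[0]),
        sensitivity_mean=float(mean[1]),
        sensitivity_std=float(std[1]),
        specificity_mean=float(mean[2]),
        specificity_std=float(std[2]),
    )


# ---------------------------------------------------------------------------
# Running one expert under the full protocol
# ---------------------------------------------------------------------------

def _split_ids(
    plan_rep: Repetition, hc_ids: Sequence[str], ad_ids: Sequence[str]
) -> tuple[list[str], list[str], list[str], list[str]]:
    train = [hc_ids[i] for i in plan_rep.train_hc] + [ad_ids[i] for i in plan_rep.train_ad]
    test = [hc_ids[i] for i in plan_rep.test_hc] + [ad_ids[i] for i in plan_rep.test_ad]
    train_y = [HC] * len(plan_rep.train_hc) + [AD] * len(plan_rep.train_ad)
    test_y = [HC] * len(plan_rep.test_hc) + [AD] * len(plan_rep.test_ad)
    return train, train_y, test, test_y


def run_expert_protocol(
    features: dict[str, np.ndarray],
    labels: dict[str, str],
    plan: SamplingPlan,
    c_grid: Sequence = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    view: str = "",
    layer: str = "",
) -> EvalResult:
    """Train and test one expert on every repetition of the plan.

    ``features`` maps subject_id -> feature vector; ``labels`` maps
    subject_id -> "AD"/"HC". HC and AD subject lists are sorted by id so a
    plan's indices are stable.
    """
    hc_ids = sorted(s for s, l in labels.items() if l == HC)
    ad_ids = sorted(s for s, l in labels.items() if l == AD)
    if len(hc_ids) != plan.n_hc or len(ad_ids) != plan.n_ad:
        raise ValueError(
            f"plan expects {plan.n_hc} HC / {plan.n_ad} AD, got {len(hc_ids)} / {len(ad_ids)}"
        )
    per_rep = []
    for rep in plan.repetitions:
        train_ids, train_y, test_ids, test_y = _split_ids(rep, hc_ids, ad_ids)
        X_train = np.stack([features[s] for s in train_ids])
        X_test = np.stack([features[s] for s in test_ids])
        model = train_expert(
            X_train, train_y, c_grid, gamma_grid, cv_seed=rep.cv_seed, view=view, layer=layer
        )
        per_rep.append(evaluate_expert(model, X_test, test_y))
    return aggregate(per_rep)
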
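"""Stability-selected logistic response prediction across platforms.

Feature selection runs repeated ten-fold cross-validated L1-penalised
logistic regression on the signature-score table: in each repeat, the
penalty is chosen to maximise mean out-of-fold AUC and the features with
non-zero coefficients at that penalty are recorded.  Signatures selected in
a majority of repeats (with a top-2 fallback) enter an unpenalised logistic
model, which is then evaluated on a held-out platform's score table at two
probability thresholds: the default 0.5 and the threshold maximising the
Youden index on the training ROC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .containers import ScoreTable

log = logging.getLogger(__name__)

DEFAULT_REPEATS = 1000
DEFAULT_FOLDS = 10
N_LAMBDA = 100
LAMBDA_DECADES = 4.0
COEF_DIVERGENCE_GUARD = 1e3


def _as_table(scores) -> pd.DataFrame:
    """Samples x features design frame from a ScoreTable or DataFrame."""
    df = scores.scores if isinstance(scores, ScoreTable) else scores
    return df.T if isinstance(scores, ScoreTable) else df


def _binary(y, index=None) -> np.ndarray:
    y = pd.Series(y, index=index) if not isinstance(y, pd.Series) else y
    vals = y.to_numpy()
    if set(np.unique(vals)) <= {0, 1}:
        return vals.astype(int)
    levels = sorted(pd.unique(vals))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 classes, found {levels}")
    # map "R"/"NR" (and generic two-level labels) with "R" as the positive
    positive = "R" if "R" in levels else levels[1]
    return (vals == positive).astype(int)


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = N_LAMBDA,
                decades: float = LAMBDA_DECADES) -> np.ndarray:
    """Log-spaced penalty grid from the smallest all-zero penalty downward.

    ``lambda_max = max_j |x_j' (y - mean(y))| / n`` on standardised columns
    is the smallest penalty at which every coefficient is zero; the grid
    descends ``decades`` orders of magnitude from there.
    """
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / len(y)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 10 ** -decades, n_lambda)


def _auc_rank(probs: np.ndarray, y: np.ndarray) -> float:
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(probs, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _standardise(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def _l1_path(X: np.ndarray, y: np.ndarray, lams: np.ndarray) -> list:
    """Fitted L1 logistic models along the penalty grid (liblinear,
    C = 1 / (n * lambda)).  ``X`` must already be standardised — the
    penalty is scale dependent and unit-variance columns also keep
    liblinear fast at the weak-penalty end of the grid."""
    n = len(y)
    models = []
    with warnings.catch_warnings():
        # the weak-penalty end of the grid routinely stops at max_iter;
        # selection only needs the support, not a converged optimum
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lams:
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                     C=1.0 / (n * lam), max_iter=100,
                                     tol=1e-3)
            clf.fit(X, y)
            models.append(clf)
    return models


def cv_lasso_frequencies(scores, y, repeats: int = DEFAULT_REPEATS,
                         folds: int = DEFAULT_FOLDS,
                         lam_grid=None, seed: int = 0,
                         n_lambda: int = N_LAMBDA,
                         one_se: bool = True):
    """Selection frequency of each signature over repeated CV-LASSO runs.

    Per repeat: a stratified ``folds``-fold split (deterministic sub-seed),
    an L1 logistic path over the penalty grid in each fold, the penalty
    maximising mean out-of-fold AUC, and the features with non-zero
    coefficients when the whole training set is refitted at that penalty.
    Returns ``(frequencies, info)`` where frequencies counts selections over
    all repeats and info records the grid and each repeat's chosen penalty.

    With ``one_se`` (default) near-ties in mean AUC break toward sparsity:
    among penalties within one standard error (over folds) of the best mean
    AUC, the largest penalty is chosen.  Without it the literal argmax is
    used, which under an uninformative design degenerates to an arbitrary
    dense model because out-of-fold AUC is then flat plus noise.
    """
    Xdf = _as_table(scores)
    y = _binary(y, Xdf.index)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    # features standardised once: the L1 penalty is scale dependent, and
    # the grid's lambda_max is defined on the standardised scale
    X = _standardise(Xdf.to_numpy(dtype=float))
    lams = np.asarray(lam_grid) if lam_grid is not None else lambda_grid(
        X, y, n_lambda=n_lambda)
    minority = min(int(y.sum()), int(len(y) - y.sum()))
    eff_folds = folds
    if folds > minority:
        eff_folds = max(2, minority)
        warnings.warn(f"folds reduced to {eff_folds}: minority class has "
                      f"{minority} samples")
    # the full-data path does not depend on the fold split: fit it once
    full_models = _l1_path(X, y, lams)
    nonzero = [np.flatnonzero(np.abs(m.coef_[0]) > 0) for m in full_models]

    counts = np.zeros(X.shape[1], dtype=int)
    chosen_lams = np.empty(repeats)
    ss = np.random.SeedSequence(seed)
    sub_seeds = ss.generate_state(repeats) % (2 ** 31 - 1)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=eff_folds, shuffle=True,
                              random_state=int(sub_seeds[r]))
        aucs = np.zeros((eff_folds, len(lams)))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            models = _l1_path(X[tr], y[tr], lams)
            for j, m in enumerate(models):
                aucs[f, j] = _auc_rank(m.predict_proba(X[te])[:, 1], y[te])
        mean_auc = aucs.mean(axis=0)
        best = int(np.argmax(mean_auc))
        if one_se:
            se = aucs[:, best].std(ddof=1) / np.sqrt(eff_folds)
            within = np.flatnonzero(mean_auc >= mean_auc[best] - se)
            best = int(within.min())  # grid descends: smallest index = largest penalty
        chosen_lams[r] = lams[best]
        counts[nonzero[best]] += 1
    freqs = pd.Series(counts, index=Xdf.columns, name="selection_count")
    info = {"lambda_grid": lams, "lambda_per_repeat": chosen_lams,
            "repeats": repeats, "folds": eff_folds}
    return freqs, info


def select_features(frequencies: pd.Series, repeats: int,
                    min_fraction: float = 0.5, fallback_top: int = 2
                    ) -> list[str]:
    """Features selected in at least ``min_fraction`` of repeats (inclusive,
    ties at the cutoff kept); if none qualify, the ``fallback_top`` most
    frequent features are returned with a warning."""
    if frequencies.empty:
        raise ValueError("empty frequency table")
    cut = min_fraction * repeats
    chosen = list(frequencies.index[frequencies >= cut])
    if not chosen:
        warnings.warn(f"no feature reached {min_fraction:.0%} of repeats; "
                      f"falling back to the top {fallback_top}")
        chosen = list(frequencies.sort_values(ascending=False,
                                              kind="stable").index[:fallback_top])
    return chosen


@dataclass
class StabilityModel:
    """Stability-selected logistic response model."""

    frequencies: pd.Series
    repeats: int
    selected: list[str]
    coef: pd.Series
    intercept: float
    roc: pd.DataFrame               # fpr, tpr, threshold on training data
    train_auc: float
    threshold_default: float = 0.5
    threshold_youden: float = 0.5
    lambda_grid: np.ndarray | None = None
    lambda_per_repeat: np.ndarray | None = None
    separation_fallback: bool = False
    train_patients: frozenset = field(default_factory=frozenset)

    def predict_proba(self, scores) -> pd.Series:
        X = _as_table(scores)
        missing = [f for f in self.selected if f not in X.columns]
        if missing:
            raise KeyError(f"selected signatures missing from score table: "
                           f"{missing}")
        eta = self.intercept + X[self.selected].to_numpy() @ self.coef.to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index,
                         name="p_responder")


def youden_threshold(fpr: np.ndarray, tpr: np.ndarray,
                     thresholds: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity - 1; ties broken
    toward the lowest threshold."""
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    t = float(thresholds[best].min())
    return min(t, 1.0)  # roc_curve's leading sentinel can exceed 1


def fit_logistic(scores, y, frequencies: pd.Series | None = None,
                 repeats: int = 0, selected=None,
                 train_patients=None) -> StabilityModel:
    """Unpenalised maximum-likelihood logistic fit on the selected features.

    Perfect separation (detected by statsmodels or by a diverging
    coefficient) triggers a ridge-stabilised fallback fit, flagged on the
    model.  ``selected=[]`` fits an intercept-only model.
    """
    Xdf = _as_table(scores)
    yv = _binary(y, Xdf.index)
    if selected is None:
        selected = list(Xdf.columns)
    X = Xdf[list(selected)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(yv, design).fit(disp=False, maxiter=200)
        params = fit.params
        if np.abs(params).max() > COEF_DIVERGENCE_GUARD:
            raise np.linalg.LinAlgError("coefficient divergence")
    except Exception:
        fallback = True
        log.warning("perfect separation detected; ridge-stabilised fallback fit")
        if X.shape[1] == 0:
            p = yv.mean()
            params = np.array([np.log(p / (1 - p))])
        else:
            clf = LogisticRegression(C=100.0, max_iter=2000)
            clf.fit(X, yv)
            params = np.concatenate([clf.intercept_, clf.coef_[0]])
    intercept = float(params[0])
    coef = pd.Series(params[1:], index=list(selected), name="coef")
    probs = 1.0 / (1.0 + np.exp(-(intercept + X @ coef.to_numpy()))) \
        if X.shape[1] else np.full(len(yv), 1.0 / (1.0 + np.exp(-intercept)))
    if 0 < yv.sum() < len(yv):
        fpr, tpr, thr = roc_curve(yv, probs)
        auc = _auc_rank(probs, yv)
        t_youden = youden_threshold(fpr, tpr, thr)
    else:  # degenerate training labels
        fpr = tpr = thr = np.array([])
        auc, t_youden = float("nan"), 0.5
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    if frequencies is None:
        frequencies = pd.Series(dtype=int)
    return StabilityModel(frequencies=frequencies, repeats=repeats,
                          selected=list(selected), coef=coef,
                          intercept=intercept, roc=roc, train_auc=auc,
                          threshold_youden=t_youden,
                          separation_fallback=fallback,
                          train_patients=frozenset(
                              () if train_patients is None else train_patients))


def build_response_model(scores, y, repeats: int = DEFAULT_REPEATS,
                         folds: int = DEFAULT_FOLDS, seed: int = 0,
                         min_fraction: float = 0.5,
                         n_lambda: int = N_LAMBDA,
                         train_patients=None) -> StabilityModel:
    """Full pipeline: CV-LASSO frequencies -> feature rule -> logistic fit."""
    freqs, info = cv_lasso_frequencies(scores, y, repeats=repeats,
                                       folds=folds, seed=seed,
                                       n_lambda=n_lambda)
    selected = select_features(freqs, repeats, min_fraction=min_fraction)
    model = fit_logistic(scores, y, frequencies=freqs, repeats=repeats,
                         selected=selected, train_patients=train_patients)
    model.lambda_grid = info["lambda_grid"]
    model.lambda_per_repeat = info["lambda_per_repeat"]
    return model


def roc_auc(probabilities, labels):
    """AUC by the rank statistic (ties count one half) plus the ROC curve."""
    y = _binary(labels)
    probs = np.asarray(probabilities, dtype=float)
    auc = _auc_rank(probs, y)
    fpr, tpr, thr = roc_curve(y, probs)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class EvalMetrics:
    """Confusion-matrix metrics at one probability threshold.

    Sensitivity/specificity are NaN (missing, not zero) when their
    denominator is empty; MCC is 0 by convention when any factor of its
    denominator is 0.
    """

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    mcc: float
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("threshold", "tp", "fp", "fn", "tn", "sensitivity",
                 "specificity", "mcc", "auc")}


def classify_evaluate(probabilities, labels, threshold: float = 0.5
                      ) -> EvalMetrics:
    """Binary metrics with prediction = (probability >= threshold)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    y = _binary(labels)
    probs = np.asarray(probabilities, dtype=float)
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    # a rate is "missing" when its own denominator is empty OR when no
    # sample was assigned to the predicted class it summarises (the
    # convention used when reporting NA for sensitivity because nothing was
    # classified as a responder)
    sens = tp / (tp + fn) if (tp + fn) and (tp + fp) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) and (tn + fn) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = _auc_rank(probs, y) if 0 < y.sum() < len(y) else float("nan")
    return EvalMetrics(threshold, tp, fp, fn, tn, sens, spec, float(mcc), auc)


def cross_platform_predict(model: StabilityModel, target_scores, target_labels,
                           target_patients: pd.Series | None = None
                           ) -> dict[str, EvalMetrics]:
    """Evaluate a trained model on another platform's score table.

    Training and target samples must belong to disjoint patients when
    patient ids are supplied for both.  Returns metrics at the default 0.5
    threshold and at the training-ROC Youden-optimal threshold.
    """
    if target_patients is not None and model.train_patients:
        leaked = sorted(set(target_patients) & set(model.train_patients))
        if leaked:
            raise ValueError(f"patient-id leakage between training and "
                             f"target sets: {leaked[:10]}")
    probs = model.predict_proba(target_scores)
    return {
        "default": classify_evaluate(probs.to_numpy(), target_labels,
                                     model.threshold_default),
        "youden": classify_evaluate(probs.to_numpy(), target_labels,
                                    model.threshold_youden),
    }
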
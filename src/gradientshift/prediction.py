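"""Out-of-sample evaluation of the gradient-shift model.

Leave-one-participant-out cross-validation refits the full mixed model
without the held-out subject and predicts them from the fixed effects plus
the refit intercept of their (still observed) study.  Significance comes
from a permutation null: each iteration shuffles the outcome across subjects
(optionally within study), reruns the ENTIRE cross-validation, and records
the null accuracy; p = (1 + #{null >= observed}) / (1 + n_perm), one-sided,
so p can never be exactly zero.  Cross-sample prediction fits on one sample
and scores another using fixed effects only (unseen studies contribute no
random effect).

The documented default of 5,000 permutation iterations is configurable;
calibration experiments in the test suite run 99-500 to stay at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm

__all__ = ["PredictionResult", "loocv_predict", "permutation_test",
           "cross_sample_predict", "DEFAULT_N_PERM"]

DEFAULT_N_PERM = 5000


@dataclass
class PredictionResult:
    """Observed-vs-predicted pairs plus permutation significance."""

    pairs: pd.DataFrame                 # subject_id, observed, predicted
    accuracy: float                     # Pearson r over subjects
    n_perm: int = 0
    null_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_perm: float = float("nan")
    p_adjusted: float = float("nan")
    seed: int | None = None
    shuffle_scope: str = "all"

    @property
    def n_subjects(self) -> int:
        return len(self.pairs)


def _design(data: pd.DataFrame, outcome: str, predictors: list[str],
            group: str):
    sub = data.dropna(subset=[outcome, *predictors])
    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub))]
                        + [sub[p].to_numpy(dtype=float) for p in predictors])
    return sub, X, y, sub[group].to_numpy()


def loocv_predict(
    data: pd.DataFrame,
    outcome: str = "success_z",
    predictors: list[str] | None = None,
    group: str = "study_id",
    subject_col: str = "subject_id",
) -> PredictionResult:
    """Leave-one-participant-out predictions with full ML refits."""
    from .inference import MAIN_PREDICTORS
    predictors = list(predictors) if predictors is not None else MAIN_PREDICTORS
    sub, X, y, groups = _design(data, outcome, predictors, group)
    if len(sub) < 10:
        raise ValueError("leave-one-out needs at least 10 subjects")
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every study needs >= 2 subjects; too small: {small}")
    if np.ptp(y) == 0:
        raise ValueError("constant observed outcome: accuracy undefined")
    preds = lmm.loocv(X, y, groups)
    ids = (sub[subject_col].to_numpy() if subject_col in sub.columns
           else sub.index.to_numpy())
    pairs = pd.DataFrame({"subject_id": ids, "observed": y, "predicted": preds,
                          "fold": np.arange(len(y))})
    acc = float(np.corrcoef(y, preds)[0, 1])
    return PredictionResult(pairs=pairs, accuracy=acc)


def _permutation_indices(rng: np.ndarray, n_perm: int, groups: np.ndarray,
                         scope: str) -> np.ndarray:
    n = groups.size
    out = np.empty((n_perm, n), dtype=np.int64)
    if scope == "all":
        for q in range(n_perm):
            out[q] = rng.permutation(n)
    elif scope == "within-study":
        idx_by_group = [np.flatnonzero(groups == g) for g in np.unique(groups)]
        for q in range(n_perm):
            perm = np.arange(n)
            for idx in idx_by_group:
                perm[idx] = idx[rng.permutation(idx.size)]
            out[q] = perm
    else:
        raise ValueError(f"unknown shuffle scope {scope!r}")
    return out


def permutation_test(
    data: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    outcome: str = "success_z",
    predictors: list[str] | None = None,
    group: str = "study_id",
    subject_col: str = "subject_id",
    shuffle_scope: str = "all",
    family_size: int = 1,
) -> PredictionResult:
    """LOOCV accuracy with a shuffled-outcome permutation null.

    Every permutation reruns the full leave-one-out loop on the shuffled
    outcome.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    from .inference import MAIN_PREDICTORS
    predictors = list(predictors) if predictors is not None else MAIN_PREDICTORS
    base = loocv_predict(data, outcome=outcome, predictors=predictors,
                         group=group, subject_col=subject_col)
    sub, X, y, groups = _design(data, outcome, predictors, group)
    rng = np.random.default_rng(seed)
    perm_idx = _permutation_indices(rng, n_perm, groups, shuffle_scope)
    null_acc = lmm.permuted_loocv_accuracies(X, y, groups, perm_idx)
    p = float((1 + np.count_nonzero(null_acc >= base.accuracy)) / (1 + n_perm))
    return PredictionResult(
        pairs=base.pairs, accuracy=base.accuracy, n_perm=n_perm,
        null_accuracies=null_acc, p_perm=p,
        p_adjusted=min(1.0, family_size * p), seed=seed,
        shuffle_scope=shuffle_scope,
    )


def cross_sample_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    outcome: str = "success_z",
    predictors: list[str] | None = None,
    group: str = "study_id",
    subject_col: str = "subject_id",
    family_size: int = 1,
) -> PredictionResult:
    """Train on one sample, score another with fixed effects only.

    Unseen test studies contribute zero random effect.  The permutation null
    shuffles the TEST outcomes against the fixed predictions (the training
    fit is unchanged by outcome shuffling of the test sample).
    """
    from .inference import MAIN_PREDICTORS
    predictors = list(predictors) if predictors is not None else MAIN_PREDICTORS
    train_ids = set(train[subject_col]) if subject_col in train.columns else set(train.index)
    test_ids = set(test[subject_col]) if subject_col in test.columns else set(test.index)
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"overlapping subject IDs: {sorted(overlap)[:5]} ...")
    sub_tr, X_tr, y_tr, g_tr = _design(train, outcome, predictors, group)
    sub_te, X_te, y_te, g_te = _design(test, outcome, predictors, group)
    if np.ptp(y_te) == 0:
        raise ValueError("constant observed outcome in the test sample")
    fit = lmm.fit_lmm(X_tr, y_tr, g_tr, reml=False)
    preds = lmm.predict_lmm(fit, X_te, g_te, use_blup=False)
    acc = float(np.corrcoef(y_te, preds)[0, 1])
    ids = (sub_te[subject_col].to_numpy() if subject_col in sub_te.columns
           else sub_te.index.to_numpy())
    pairs = pd.DataFrame({"subject_id": ids, "observed": y_te, "predicted": preds})
    rng = np.random.default_rng(seed)
    null_acc = np.empty(n_perm)
    for q in range(n_perm):
        null_acc[q] = np.corrcoef(y_te[rng.permutation(y_te.size)], preds)[0, 1]
    p = float((1 + np.count_nonzero(null_acc >= acc)) / (1 + n_perm))
    return PredictionResult(pairs=pairs, accuracy=acc, n_perm=n_perm,
                            null_accuracies=null_acc, p_perm=p,
                            p_adjusted=min(1.0, family_size * p), seed=seed)
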
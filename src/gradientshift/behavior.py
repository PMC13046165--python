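"""Behavioral indices: regulatory success, reactivity, normalization, outliers.

Ratings arrive on heterogeneous study-specific scales; every computation
first re-orients them so that *higher = more negative affect* (scales
declared ``higher_is_more_positive`` are flipped as ``min + max - rating``).
Regulatory success is then the oriented mean rating difference
Look - Regulate, so positive scores mean regulation reduced negative affect.
Success scores are z-normalized within study (sample SD, n-1) before entering
any cross-study model, and subjects beyond ``threshold`` sample SDs from the
sample mean of the normalized scores are flagged as outliers in a single pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Condition
from .simulate import HIGHER_IS_MORE_NEGATIVE, HIGHER_IS_MORE_POSITIVE

__all__ = [
    "orient_ratings",
    "compute_success",
    "compute_reactivity",
    "normalize_within_study",
    "exclude_outliers",
    "build_behavior_table",
]


def orient_ratings(ratings, scale_min, scale_max, orientation) -> np.ndarray:
    """Re-orient ratings so that higher = more negative affect."""
    ratings = np.asarray(ratings, dtype=np.float64)
    if np.isscalar(orientation) or isinstance(orientation, str):
        if orientation == HIGHER_IS_MORE_NEGATIVE:
            return ratings.copy()
        if orientation == HIGHER_IS_MORE_POSITIVE:
            return np.asarray(scale_min, float) + np.asarray(scale_max, float) - ratings
        raise ValueError(f"unknown orientation {orientation!r}")
    orientation = np.asarray(orientation)
    flip = orientation == HIGHER_IS_MORE_POSITIVE
    bad = ~np.isin(orientation, (HIGHER_IS_MORE_NEGATIVE, HIGHER_IS_MORE_POSITIVE))
    if np.any(bad):
        raise ValueError(f"unknown orientation values: {set(orientation[bad])}")
    out = ratings.copy()
    lo = np.asarray(scale_min, float)
    hi = np.asarray(scale_max, float)
    out[flip] = lo[flip] + hi[flip] - ratings[flip]
    return out


def _subject_oriented(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    df["oriented"] = orient_ratings(
        df["rating"].to_numpy(), df["scale_min"].to_numpy(),
        df["scale_max"].to_numpy(), df["orientation"].to_numpy())
    return df


def compute_success(trials: pd.DataFrame) -> float:
    """Regulatory success of one subject: oriented mean(Look) - mean(Regulate)."""
    df = _subject_oriented(trials)
    look = df.loc[df["condition"] == Condition.LOOK.value, "oriented"]
    reg = df.loc[df["condition"] == Condition.REGULATE.value, "oriented"]
    if look.empty:
        raise ValueError("no Look trials for this subject")
    if reg.empty:
        raise ValueError("no Regulate trials for this subject")
    return float(look.mean() - reg.mean())


def compute_reactivity(trials: pd.DataFrame) -> float:
    """Emotional reactivity: mean oriented rating across Look trials."""
    df = _subject_oriented(trials)
    look = df.loc[df["condition"] == Condition.LOOK.value, "oriented"]
    if look.empty:
        raise ValueError("no Look trials for this subject")
    return float(look.mean())


def normalize_within_study(values: pd.Series, study_ids: pd.Series) -> pd.Series:
    """Z-score values within each study (sample SD, n-1 denominator)."""
    values = pd.Series(np.asarray(values, float), index=pd.Series(study_ids).index)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for study, grp in values.groupby(pd.Series(study_ids)):
        if len(grp) < 2:
            raise ValueError(f"study {study!r}: need >= 2 subjects to z-normalize")
        sd = grp.std(ddof=1)
        if sd == 0:
            raise ValueError(f"study {study!r}: zero within-study variance")
        out.loc[grp.index] = (grp - grp.mean()) / sd
    return out


def exclude_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Flag values beyond ``threshold`` sample SDs from the sample mean.

    Single pass: mean/SD are computed once, never recomputed after exclusion.
    Returns a boolean array, True = excluded.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("outlier screening needs >= 3 subjects")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > threshold * sd


def build_behavior_table(
    trials: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    esm: pd.DataFrame | None = None,
    outlier_threshold: float = 3.0,
) -> pd.DataFrame:
    """Assemble the per-subject behavior table from trial-level ratings.

    Columns: study_id, success_raw, success_z, reactivity, excluded,
    exclusion_reason, plus covariates (age, sex, ERQ subscales) and esm_mean
    when the optional tables are given.  Outlier screening runs on the
    z-normalized success scores over the full sample; z-scores are those of
    the single normalization pass (no re-normalization after exclusion).
    """
    # vectorized equivalent of per-subject compute_success/compute_reactivity
    df = _subject_oriented(trials)
    cond_means = (df.groupby(["subject_id", "condition"], sort=True)["oriented"]
                  .mean().unstack("condition"))
    for cond in (Condition.LOOK.value, Condition.REGULATE.value):
        if cond not in cond_means.columns or cond_means[cond].isna().any():
            missing = (cond_means.index if cond not in cond_means.columns
                       else cond_means.index[cond_means[cond].isna()])
            raise ValueError(f"no {cond} trials for subject(s) "
                             f"{list(missing)[:5]}")
    table = pd.DataFrame({
        "study_id": trials.groupby("subject_id", sort=True)["study_id"].first(),
        "success_raw": (cond_means[Condition.LOOK.value]
                        - cond_means[Condition.REGULATE.value]),
        "reactivity": cond_means[Condition.LOOK.value],
    })
    table.index.name = "subject_id"
    table["success_z"] = normalize_within_study(table["success_raw"],
                                                table["study_id"])
    excluded = exclude_outliers(table["success_z"].to_numpy(),
                                threshold=outlier_threshold)
    table["excluded"] = excluded
    table["exclusion_reason"] = np.where(
        excluded, f"success beyond {outlier_threshold:g} SD of sample mean", "")

    if covariates is not None:
        cov = covariates.set_index("subject_id").drop(columns=["study_id"],
                                                      errors="ignore")
        table = table.join(cov, how="left")
    if esm is not None and not esm.empty:
        esm_mean = esm.groupby("subject_id")["rating"].mean().rename("esm_mean")
        table = table.join(esm_mean, how="left")
    return table
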
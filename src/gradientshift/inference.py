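"""Descriptive and model-based inference.

Covers: Wilcoxon signed-rank tests of projections (exact enumeration for
n <= 25 via the signed-rank distribution, normal approximation with
continuity and tie corrections above), Bonferroni families, the main mixed
model (regulatory success on the five gradient shifts plus reactivity, age
and sex, with a random study intercept) and its Euclidean-distance / daily
affect / questionnaire variants, nested interaction ladders compared by AIC,
region-wise mixed models with Benjamini-Hochberg FDR, and mass-univariate
covariate t-maps with face-adjacent cluster reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from itertools import combinations
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from . import lmm
from .io import AnalysisMask, scatter_back

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "MixedModelResult",
    "GroupGLMResult",
    "wilcoxon_vs_zero",
    "wilcoxon_paired",
    "fit_mixed_model",
    "MAIN_PREDICTORS",
    "ED_PREDICTORS",
    "compare_interaction_models",
    "bh_fdr",
    "regionwise_analysis",
    "group_covariate_tmap",
]

EXACT_WILCOXON_MAX_N = 25

#: fixed-effect columns of the main model (gradient shifts + controls)
MAIN_PREDICTORS = ["dG1", "dG2", "dG3", "dG4", "dG5", "reactivity", "age", "sex"]
#: fixed-effect columns of the Euclidean-distance variant
ED_PREDICTORS = ["ed5", "reactivity", "age", "sex"]


@dataclass
class TestResult:
    """One hypothesis test with its multiplicity-adjusted p."""

    statistic: float
    p_raw: float
    p_adjusted: float
    family: str
    family_size: int
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and self.p_raw <= self.p_adjusted <= 1.0):
            raise ValueError("invalid p-values")


def _signed_rank_exact_p(w_plus: float, ranks2: np.ndarray) -> float:
    """Exact two-sided p of the signed-rank statistic with mid-ranks.

    ``ranks2`` are the doubled ranks (integers even for .5 mid-ranks); the
    null distribution of 2*W+ is built by dynamic programming over all 2^n
    sign assignments.  Two-sided p = 2 * min(P(W <= w), P(W >= w)), capped
    at 1.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_vs_zero(
    values, family: str = "", family_size: int = 1,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of median zero.

    Zeros are dropped (signed-rank convention), ties get mid-ranks.  Exact
    enumeration of the signed-rank null for n <= 25; normal approximation
    with continuity and tie corrections above.  Bonferroni adjustment by the
    declared family size.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[x != 0]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 nonzero values (all-zero input?)")
    ranks = st.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(w_plus, ranks2)
        method = "exact"
    else:
        p = float(st.wilcoxon(x, correction=True, method="approx").pvalue)
        method = "approx"
    return TestResult(statistic=w_plus, p_raw=p,
                      p_adjusted=min(1.0, family_size * p),
                      family=family, family_size=family_size, n=n, method=method)


def wilcoxon_paired(
    look_values, regulate_values, family: str = "", family_size: int = 1,
) -> TestResult:
    """Paired signed-rank test: Regulate minus Look differences against zero."""
    look = np.asarray(look_values, dtype=np.float64)
    reg = np.asarray(regulate_values, dtype=np.float64)
    if look.shape != reg.shape:
        raise ValueError("paired samples differ in length")
    diff = reg - look
    if np.all(diff == 0):
        raise ValueError("no nonzero differences between conditions")
    return wilcoxon_vs_zero(diff, family=family, family_size=family_size)


@dataclass
class MixedModelResult:
    """Fitted mixed (or fallback OLS) model with a Table-2-style summary."""

    formula: str
    params: pd.DataFrame          # estimate, se, t, ci_low, ci_high, p per row
    criterion: str                # "ML" | "REML" | "OLS"
    loglik: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    sigma2_residual: float
    sigma2_study: float
    n_obs: int
    n_groups: int
    n_dropped: int = 0
    fit: "lmm.LMMFit | None" = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Mixed model ({self.criterion}): {self.formula}",
            f"n_obs = {self.n_obs}, groups = {self.n_groups}, "
            f"dropped rows = {self.n_dropped}",
            f"logLik = {self.loglik:.3f}, AIC = {self.aic:.3f}",
            f"R2 marginal = {self.r2_marginal:.3f}, "
            f"conditional = {self.r2_conditional:.3f}",
            f"var(study) = {self.sigma2_study:.4f}, "
            f"var(resid) = {self.sigma2_residual:.4f}",
            "",
            "{:<14}{:>18}{:>20}{:>8}{:>10}".format(
                "term", "Estimate (SE)", "95% CI", "t", "p"),
        ]
        for name, row in self.params.iterrows():
            lines.append("{:<14}{:>18}{:>20}{:>8.2f}{:>10.2g}".format(
                str(name)[:14],
                f"{row.estimate:.3f} ({row.se:.3f})",
                f"[{row.ci_low:.2f}, {row.ci_high:.2f}]",
                row.t, row.p))
        return "\n".join(lines)


def fit_mixed_model(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    group: str = "study_id",
    reml: bool = False,
) -> MixedModelResult:
    """Random-intercept mixed model of ``outcome`` on ``predictors``.

    Rows with missing outcome or predictors are dropped (count logged).
    Falls back to OLS with a logged warning when only one group remains.
    Wald t confidence intervals use residual degrees of freedom n - p.
    R-squared follows the marginal/conditional variance-partition convention
    (fixed-effect variance over total, and fixed-plus-random over total).
    """
    cols = [outcome] + predictors + [group]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[cols].dropna()
    n_dropped = len(data) - len(sub)
    if n_dropped:
        logger.info("fit_mixed_model(%s): dropped %d row(s) with missing values",
                    outcome, n_dropped)
    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub))]
                        + [sub[p].to_numpy(dtype=float) for p in predictors])
    groups = sub[group].to_numpy()
    names = ["Intercept"] + list(predictors)
    try:
        fit = lmm.fit_lmm(X, y, groups, reml=reml)
    except np.linalg.LinAlgError as err:
        bad = [names[j] for j in _collinear_columns(X)]
        raise np.linalg.LinAlgError(
            f"singular design; collinear column(s): {bad}") from err
    if fit.method == "ols":
        logger.warning("fit_mixed_model(%s): single group, OLS fallback", outcome)

    tcrit = st.t.ppf(0.975, fit.df_resid)
    tvals = fit.beta / fit.se
    pvals = 2 * st.t.sf(np.abs(tvals), fit.df_resid)
    params = pd.DataFrame({
        "estimate": fit.beta, "se": fit.se, "t": tvals,
        "ci_low": fit.beta - tcrit * fit.se,
        "ci_high": fit.beta + tcrit * fit.se,
        "p": pvals,
    }, index=names)

    yhat_fixed = X @ fit.beta
    var_f = float(np.var(yhat_fixed))
    var_u = fit.sigma2_u
    var_e = fit.sigma2_e
    total = var_f + var_u + var_e
    formula = f"{outcome} ~ {' + '.join(predictors)} + (1 | {group})"
    return MixedModelResult(
        formula=formula, params=params,
        criterion={"ml": "ML", "reml": "REML", "ols": "OLS"}[fit.method],
        loglik=fit.loglik, aic=fit.aic,
        r2_marginal=var_f / total,
        r2_conditional=(var_f + var_u) / total,
        sigma2_residual=var_e, sigma2_study=var_u,
        n_obs=fit.n_obs, n_groups=fit.n_groups, n_dropped=n_dropped, fit=fit,
    )


def _collinear_columns(X: np.ndarray) -> list[int]:
    kept: list[int] = []
    bad: list[int] = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(j)
    return bad


def compare_interaction_models(
    data: pd.DataFrame,
    outcome: str = "success_z",
    gradient_cols: tuple[str, ...] = ("dG1", "dG2", "dG3", "dG4", "dG5"),
    control_cols: tuple[str, ...] = ("reactivity", "age", "sex"),
    group: str = "study_id",
    max_order: int = 5,
) -> pd.DataFrame:
    """Nested interaction ladder compared by ML AIC.

    Row 1 is the main-effects model; row k adds all interaction products of
    the gradient shifts up to order k.  Rows whose design exceeds the sample
    size are flagged unestimable rather than fatal.  Returns a DataFrame
    with columns order, n_fixed, loglik, aic, estimable, is_best.
    """
    if not 2 <= max_order <= len(gradient_cols):
        raise ValueError("max_order must be within 2..K")
    rows = []
    sub = data[[outcome, *gradient_cols, *control_cols, group]].dropna()
    for order in range(1, max_order + 1):
        extra: list[str] = []
        work = sub.copy()
        for k in range(2, order + 1):
            for combo in combinations(gradient_cols, k):
                name = ":".join(combo)
                work[name] = np.prod([work[c].to_numpy() for c in combo], axis=0)
                extra.append(name)
        predictors = list(gradient_cols) + extra + list(control_cols)
        n_fixed = len(predictors) + 1
        label = "main effects" if order == 1 else f"up to {order}-way"
        if len(work) <= n_fixed + 2:
            rows.append({"model": label, "order": order, "n_fixed": n_fixed,
                         "loglik": np.nan, "aic": np.nan, "estimable": False})
            continue
        res = fit_mixed_model(work, outcome, predictors, group=group, reml=False)
        rows.append({"model": label, "order": order, "n_fixed": n_fixed,
                     "loglik": res.loglik, "aic": res.aic, "estimable": True})
    table = pd.DataFrame(rows)
    table["is_best"] = table["aic"] == table["aic"].min()
    return table


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def regionwise_analysis(
    region_shifts: pd.DataFrame,
    behavior: pd.DataFrame,
    outcome: str = "success_z",
    control_cols: tuple[str, ...] = ("reactivity", "age", "sex"),
    group: str = "study_id",
    q: float = 0.05,
) -> pd.DataFrame:
    """One mixed model per region, BH-FDR within each atlas family.

    ``region_shifts``: rows (subject_id, family, region_id, dG); regions with
    missing shift values propagate as missing rows (absent, not zero).
    Returns per-region estimate, t, p_raw, p_fdr, reject.
    """
    out_rows = []
    merged_base = behavior.reset_index()
    for family, fam_df in region_shifts.groupby("family", sort=True):
        fam_rows = []
        for rid, reg_df in fam_df.groupby("region_id", sort=True):
            merged = merged_base.merge(
                reg_df[["subject_id", "dG"]], on="subject_id", how="inner"
            ).dropna(subset=["dG", outcome, *control_cols])
            if merged.empty or merged["dG"].nunique() < 2:
                fam_rows.append({"family": family, "region_id": rid,
                                 "estimate": np.nan, "t": np.nan,
                                 "p_raw": np.nan, "n": len(merged)})
                continue
            res = fit_mixed_model(merged, outcome, ["dG", *control_cols],
                                  group=group, reml=False)
            row = res.params.loc["dG"]
            fam_rows.append({"family": family, "region_id": rid,
                             "estimate": row.estimate, "t": row.t,
                             "p_raw": row.p, "n": res.n_obs})
        fam_table = pd.DataFrame(fam_rows)
        ok = fam_table["p_raw"].notna()
        fam_table["p_fdr"] = np.nan
        fam_table["reject"] = False
        if ok.any():
            rej, padj = bh_fdr(fam_table.loc[ok, "p_raw"].to_numpy(), q=q)
            fam_table.loc[ok, "p_fdr"] = padj
            fam_table.loc[ok, "reject"] = rej
        out_rows.append(fam_table)
    return pd.concat(out_rows, ignore_index=True)


@dataclass
class GroupGLMResult:
    """Mass-univariate covariate regression over the analysis mask."""

    beta: np.ndarray            # slope per mask voxel
    t: np.ndarray               # t statistic per mask voxel
    df: int
    voxel_p: float
    t_threshold: float
    surviving: np.ndarray       # boolean per mask voxel
    clusters: pd.DataFrame      # sign, size, peak_index (mask-linear), peak_t
    mask: AnalysisMask


def group_covariate_tmap(
    contrast_vectors: np.ndarray,
    covariate: np.ndarray,
    mask: AnalysisMask,
    voxel_p: float = 0.001,
    min_cluster: int = 10,
) -> GroupGLMResult:
    """Per-voxel OLS of contrast value on (intercept, covariate).

    ``contrast_vectors`` is (n_subjects, n_voxels) of Regulate-minus-Look
    vectors.  The covariate t map uses df = n - 2; voxels with two-sided
    p < ``voxel_p`` survive and face-adjacent connected clusters of at least
    ``min_cluster`` surviving voxels are tabulated, separately by sign.
    """
    Y = np.asarray(contrast_vectors, dtype=np.float64)
    x = np.asarray(covariate, dtype=np.float64)
    n = x.size
    if Y.shape[0] != n:
        raise ValueError("covariate length does not match subject count")
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    beta = (xc @ Y) / sxx
    resid = Y - np.outer(x, beta) - (Y.mean(axis=0) - beta * x.mean())
    df = n - 2
    sigma2 = np.sum(resid * resid, axis=0) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    t_thr = float(st.t.ppf(1 - voxel_p / 2, df))
    surviving = np.abs(t) > t_thr

    clusters = []
    t_vol = scatter_back(np.where(surviving, t, 0.0), mask, fill=0.0).values
    index_vol = np.full(int(np.prod(mask.grid_shape)), -1, dtype=np.int64)
    index_vol[mask.indices] = np.arange(len(mask))
    index_vol = index_vol.reshape(mask.grid_shape)
    structure = ndimage.generate_binary_structure(3, 1)  # face adjacency
    for sign, sel in (("positive", t_vol > 0), ("negative", t_vol < 0)):
        labelled, n_lab = ndimage.label(sel, structure=structure)
        for lab in range(1, n_lab + 1):
            voxels = labelled == lab
            size = int(voxels.sum())
            if size < min_cluster:
                continue
            tv = np.where(voxels, np.abs(t_vol), -np.inf)
            peak = np.unravel_index(np.argmax(tv), tv.shape)
            clusters.append({
                "sign": sign, "size": size,
                "peak_index": int(index_vol[peak]),
                "peak_t": float(t_vol[peak]),
            })
    cluster_table = pd.DataFrame(
        clusters, columns=["sign", "size", "peak_index", "peak_t"])
    if not cluster_table.empty:
        cluster_table = cluster_table.sort_values(
            "size", ascending=False).reset_index(drop=True)
    return GroupGLMResult(beta=beta, t=t, df=df, voxel_p=voxel_p,
                          t_threshold=t_thr, surviving=surviving,
                          clusters=cluster_table, mask=mask)
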
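"""Model/Results facade over the mixed-model and prediction machinery.

`GradientShiftModel` is built from a per-subject data frame that joins the
gradient-shift table with the behavior table; `fit()` returns a
`GradientShiftResults` carrying coefficient estimates with Wald confidence
intervals, variance components, marginal/conditional R-squared, AIC and a
printable `summary()`.  Cross-validated prediction, permutation inference,
interaction ladders and plotting hang off these two objects, mirroring the
statsmodels fit-then-inspect workflow:

    model = GradientShiftModel.from_tables(shifts, behavior)
    res = model.fit()
    print(res.summary())
    pred = res.permutation_test(n_perm=999, seed=1)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference, prediction
from .inference import MAIN_PREDICTORS, MixedModelResult

__all__ = ["GradientShiftModel", "GradientShiftResults"]


class GradientShiftModel:
    """Mixed model of regulatory success on gradient shifts.

    Parameters
    ----------
    data : per-subject DataFrame containing the outcome, predictors and the
        study grouping column.
    outcome : column modelled (default the within-study z-scored success).
    predictors : fixed-effect columns; defaults to the five gradient shifts
        plus reactivity, age and sex.
    group : random-intercept grouping column.
    """

    def __init__(self, data: pd.DataFrame, outcome: str = "success_z",
                 predictors: list[str] | None = None,
                 group: str = "study_id") -> None:
        self.data = data.copy()
        self.outcome = outcome
        self.predictors = (list(predictors) if predictors is not None
                           else list(MAIN_PREDICTORS))
        self.group = group

    @classmethod
    def from_tables(cls, shifts: pd.DataFrame, behavior: pd.DataFrame,
                    drop_excluded: bool = True, **kwargs) -> "GradientShiftModel":
        """Join the shift table with the behavior table on subject_id."""
        beh = behavior.reset_index()
        data = shifts.merge(beh, on="subject_id", how="inner")
        if drop_excluded and "excluded" in data.columns:
            data = data[~data["excluded"].astype(bool)].reset_index(drop=True)
        return cls(data, **kwargs)

    def fit(self, reml: bool = False) -> "GradientShiftResults":
        res = inference.fit_mixed_model(
            self.data, self.outcome, self.predictors, group=self.group,
            reml=reml)
        return GradientShiftResults(self, res)


class GradientShiftResults:
    """Results object wrapping a fitted mixed model."""

    def __init__(self, model: GradientShiftModel, result: MixedModelResult):
        self.model = model
        self.result = result

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.result.params["estimate"]

    @property
    def bse(self) -> pd.Series:
        return self.result.params["se"]

    @property
    def pvalues(self) -> pd.Series:
        return self.result.params["p"]

    @property
    def conf_int(self) -> pd.DataFrame:
        return self.result.params[["ci_low", "ci_high"]]

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def r2(self) -> tuple[float, float]:
        """(marginal, conditional) variance-explained fractions."""
        return self.result.r2_marginal, self.result.r2_conditional

    def summary(self) -> str:
        return self.result.summary()

    def coefficient_table(self) -> pd.DataFrame:
        """Flat table mirroring the published layout: Estimate (SE), CI, t, p."""
        p = self.result.params
        return pd.DataFrame({
            "term": p.index,
            "estimate_se": [f"{e:.2f} ({s:.2f})"
                            for e, s in zip(p.estimate, p.se)],
            "ci95": [f"[{lo:.2f}, {hi:.2f}]"
                     for lo, hi in zip(p.ci_low, p.ci_high)],
            "t": p.t.round(2).to_numpy(),
            "p": p.p.to_numpy(),
        }).reset_index(drop=True)

    # -- prediction --------------------------------------------------------
    def loocv(self) -> prediction.PredictionResult:
        return prediction.loocv_predict(
            self.model.data, outcome=self.model.outcome,
            predictors=self.model.predictors, group=self.model.group)

    def permutation_test(self, n_perm: int = prediction.DEFAULT_N_PERM,
                         seed: int = 0, shuffle_scope: str = "all",
                         family_size: int = 1) -> prediction.PredictionResult:
        return prediction.permutation_test(
            self.model.data, n_perm=n_perm, seed=seed,
            outcome=self.model.outcome, predictors=self.model.predictors,
            group=self.model.group, shuffle_scope=shuffle_scope,
            family_size=family_size)

    def predict(self, newdata: pd.DataFrame, use_blup: bool = True) -> np.ndarray:
        from .lmm import predict_lmm
        X = np.column_stack(
            [np.ones(len(newdata))]
            + [newdata[p].to_numpy(dtype=float) for p in self.model.predictors])
        groups = newdata[self.model.group].to_numpy()
        return predict_lmm(self.result.fit, X, groups, use_blup=use_blup)

    # -- model comparison --------------------------------------------------
    def compare_interactions(self, max_order: int = 5) -> pd.DataFrame:
        gradient_cols = tuple(c for c in self.model.predictors
                              if c.startswith("dG"))
        control_cols = tuple(c for c in self.model.predictors
                             if not c.startswith("dG"))
        return inference.compare_interaction_models(
            self.model.data, outcome=self.model.outcome,
            gradient_cols=gradient_cols, control_cols=control_cols,
            group=self.model.group, max_order=max_order)

    # -- plotting ----------------------------------------------------------
    def plot_observed_vs_predicted(self, pred=None, ax=None):
        """Scatter of observed vs LOOCV-predicted success with identity line."""
        import matplotlib.pyplot as plt
        if pred is None:
            pred = self.loocv()
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(pred.pairs["predicted"], pred.pairs["observed"],
                   s=12, alpha=0.6)
        lims = np.array([pred.pairs[["observed", "predicted"]].min().min(),
                         pred.pairs[["observed", "predicted"]].max().max()])
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("predicted success (z)")
        ax.set_ylabel("observed success (z)")
        ax.set_title(f"LOOCV r = {pred.accuracy:.2f}")
        return ax
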
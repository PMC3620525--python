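"""Hierarchical ("ladder") regression of cognition on lesion burden.

The ladder fits a fixed nested sequence of twelve ordinary-least-squares
models with a domain composite z-score as outcome:

=====  ==========================================================
label  predictors
=====  ==========================================================
1      age, sex, education, reading score
2a     model 1 + LL presence (0/1)
2b     model 1 + total WML volume (ml)
2c     model 1 + LL presence + total WML volume
3a/3b  model 1 + regional LL volume in tract 1 / tract 2
3c/3d  model 1 + regional WML volume in tract 1 / tract 2
4a/4b  model 2c + regional LL volume in tract 1 / tract 2
4c/4d  model 2c + regional WML volume in tract 1 / tract 2
=====  ==========================================================

Each extension is tested against its base model with the partial-F test on
the increase in explained variance:

    F = (dR^2 / k) / ((1 - R^2_ext) / df_ext),   p ~ F(k, df_ext)

Models 2a-2c and 3a-3d are tested against model 1; 4a-4d against 2c.
Coefficients are unstandardised (B, outcome z-units per predictor unit;
volumes enter in ml untransformed) with t-based 95% confidence intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .tracts import regional_column

__all__ = [
    "ModelFit",
    "LadderStep",
    "LadderResult",
    "ols_fit",
    "delta_r2_test",
    "run_ladder",
    "RegressionLadder",
    "MODEL_LABELS",
]

MODEL_LABELS = ("1", "2a", "2b", "2c", "3a", "3b", "3c", "3d", "4a", "4b", "4c", "4d")

#: ΔR² baseline for each extended model.
BASE_OF = {
    "2a": "1", "2b": "1", "2c": "1",
    "3a": "1", "3b": "1", "3c": "1", "3d": "1",
    "4a": "2c", "4b": "2c", "4c": "2c", "4d": "2c",
}


@dataclass
class ModelFit:
    """One OLS fit: coefficients with 95% CI, R-squared and sizes."""

    label: str
    outcome: str
    predictors: tuple[str, ...]
    coef: pd.Series
    conf_int: pd.DataFrame  # columns: low, high
    r2: float
    n: int
    df_resid: int


@dataclass
class LadderStep:
    label: str
    base: str
    delta_r2: float
    f: float
    p: float
    k: int


@dataclass
class LadderResult:
    """Ordered nested model fits plus the increment tests between them."""

    fits: dict[str, ModelFit]
    steps: dict[str, LadderStep]
    tracts: tuple[str, str]
    domain: str

    def to_frame(self) -> pd.DataFrame:
        """Report table: one row per model with R^2, dR^2 p-value and the
        added term's B (95% CI).  Rows adding several terms (or none)
        leave the coefficient columns blank, as in the conventional
        presentation of such ladders."""
        rows = []
        for label in MODEL_LABELS:
            fit = self.fits[label]
            step = self.steps.get(label)
            added = ()
            if step is not None:
                added = tuple(p for p in fit.predictors if p not in self.fits[step.base].predictors)
            row = {
                "model": label,
                "predictors": " + ".join(fit.predictors),
                "n": fit.n,
                "r2": fit.r2,
                "p_delta_r2": step.p if step else np.nan,
                "delta_r2": step.delta_r2 if step else np.nan,
            }
            if len(added) == 1:
                term = added[0]
                row["term"] = term
                row["B"] = fit.coef[term]
                row["ci_low"] = fit.conf_int.loc[term, "low"]
                row["ci_high"] = fit.conf_int.loc[term, "high"]
            else:
                row["term"] = ""
                row["B"] = np.nan
                row["ci_low"] = np.nan
                row["ci_high"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")


def _check_full_rank(X: pd.DataFrame) -> None:
    D = np.column_stack([np.ones(len(X)), X.values.astype(np.float64)])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        names = ["const", *X.columns]
        collinear = []
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(np.delete(D, j, axis=1)) == np.linalg.matrix_rank(D):
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def ols_fit(y: pd.Series, X: pd.DataFrame, label: str = "") -> ModelFit:
    """OLS with intercept; 95% CI = B +/- t(0.975, df) * SE(B)."""
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors plus intercept")
    _check_full_rank(X)
    design = sm.add_constant(X.astype(np.float64), has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=np.float64), design).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    return ModelFit(
        label=label,
        outcome=str(y.name) if y.name is not None else "outcome",
        predictors=tuple(X.columns),
        coef=res.params,
        conf_int=ci,
        r2=float(res.rsquared),
        n=int(n),
        df_resid=int(res.df_resid),
    )


def delta_r2_test(base: ModelFit, extended: ModelFit) -> LadderStep:
    """Partial-F test of the R-squared increment between nested fits."""
    if base.outcome != extended.outcome or base.n != extended.n:
        raise ValueError("models must share the outcome and the patient set")
    if not set(base.predictors) <= set(extended.predictors):
        raise ValueError("models are not nested (base predictors not a subset)")
    k = len(set(extended.predictors) - set(base.predictors))
    if k == 0:
        raise ValueError("extended model adds no predictors")
    dr2 = extended.r2 - base.r2
    f = (dr2 / k) / ((1.0 - extended.r2) / extended.df_resid)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, k, extended.df_resid))
    return LadderStep(label=extended.label, base=base.label, delta_r2=dr2, f=float(f), p=p, k=k)


def model_design(
    label: str,
    covariates: tuple[str, ...],
    tracts: tuple[str, str],
) -> tuple[str, ...]:
    """Predictor list for one ladder model."""
    t1, t2 = tracts
    base = tuple(covariates)
    burden = ("ll_present", "wml_total_ml")
    extra = {
        "1": (),
        "2a": ("ll_present",),
        "2b": ("wml_total_ml",),
        "2c": burden,
        "3a": (regional_column("ll", t1),),
        "3b": (regional_column("ll", t2),),
        "3c": (regional_column("wml", t1),),
        "3d": (regional_column("wml", t2),),
        "4a": burden + (regional_column("ll", t1),),
        "4b": burden + (regional_column("ll", t2),),
        "4c": burden + (regional_column("wml", t1),),
        "4d": burden + (regional_column("wml", t2),),
    }[label]
    return base + extra


class RegressionLadder(BaseEstimator):
    """Fit the twelve-model ladder for one cognitive domain.

    Parameters
    ----------
    tracts : pair of tract names
        The two regions of interest whose regional volumes enter models
        3a-3d and 4a-4d (columns ``{class}_{tract}_ml``).
    domain : str
        Outcome column in the scores table.
    covariates : tuple of str
        Covariate columns entered in every model.

    Fitted attribute ``result_`` is a :class:`LadderResult`.
    """

    def __init__(
        self,
        tracts: tuple[str, str] = ("tract_a", "tract_b"),
        domain: str = "executive",
        covariates: tuple[str, ...] = ("age", "sex", "education", "reading"),
    ):
        self.tracts = tracts
        self.domain = domain
        self.covariates = covariates

    def fit(
        self,
        scores: pd.DataFrame | pd.Series,
        covariates: pd.DataFrame,
        totals: pd.DataFrame,
        regional: pd.DataFrame,
    ):
        """Assemble the analysis table (inner join on patient_id, listwise
        deletion of incomplete rows) and fit all models."""
        t1, t2 = self.tracts
        needed = [regional_column(cls, t) for t in (t1, t2) for cls in ("ll", "wml")]
        missing = [c for c in needed if c not in regional.columns]
        if missing:
            raise ValueError(f"regional-volume column(s) missing: {missing}")
        y = pd.DataFrame(scores)
        if self.domain not in y.columns:
            raise ValueError(f"domain {self.domain!r} not in scores table")
        data = (
            y[[self.domain]]
            .join(covariates[list(self.covariates)], how="inner")
            .join(totals[["ll_present", "wml_total_ml"]], how="inner")
            .join(regional[needed], how="inner")
            .dropna()
        )
        if data.empty:
            raise ValueError("no complete cases after joining the input tables")
        # presence is dichotomous regardless of LL count or volume
        data["ll_present"] = (data["ll_present"] > 0).astype(float)
        outcome = data[self.domain].rename(self.domain)

        fits: dict[str, ModelFit] = {}
        for label in MODEL_LABELS:
            cols = model_design(label, tuple(self.covariates), (t1, t2))
            fits[label] = ols_fit(outcome, data[list(cols)], label=label)
        steps = {
            label: delta_r2_test(fits[BASE_OF[label]], fits[label])
            for label in MODEL_LABELS
            if label in BASE_OF
        }
        self.n_used_ = int(len(data))
        self.result_ = LadderResult(fits=fits, steps=steps, tracts=(t1, t2), domain=self.domain)
        return self


def run_ladder(
    scores: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
    totals: pd.DataFrame,
    regional: pd.DataFrame,
    tracts: tuple[str, str],
    domain: str = "executive",
    covariate_columns: tuple[str, ...] = ("age", "sex", "education", "reading"),
) -> LadderResult:
    """Convenience wrapper over :class:`RegressionLadder`."""
    est = RegressionLadder(tracts=tracts, domain=domain, covariates=covariate_columns)
    est.fit(scores, covariates, totals, regional)
    return est.result_
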
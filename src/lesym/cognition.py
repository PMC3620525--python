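"""Composite cognitive-domain z-scores and covariate residualisation.

Raw neuropsychological subtests are mapped to three domains (memory,
executive, speed/attention).  Time- and error-based subtests, where a
larger raw score means worse performance, are first multiplied by -1 so
that lower always means poorer performance; each subtest is then z-scored
against the analysis sample and the domain composite is the unweighted
mean of its subtests' z-scores.  Composites are finally residualised on
age, sex, education level and reading-test score by ordinary least squares
before entering the voxel-wise analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SubtestRole",
    "DEFAULT_SCHEME",
    "DOMAINS",
    "COVARIATE_COLUMNS",
    "CompositeScorer",
    "CovariateResidualizer",
    "composite_scores",
    "residualize",
]

log = logging.getLogger(__name__)

DOMAINS = ("memory", "executive", "speed_attention")

#: Default covariates used for individualised correction.
COVARIATE_COLUMNS = ("age", "sex", "education", "reading")


@dataclass(frozen=True)
class SubtestRole:
    domain: str
    higher_better: bool = True


#: Default subtest-to-domain scheme.  The visual elevator (seconds per
#: switch) and Brixton (error count) are lower-better and enter negated.
DEFAULT_SCHEME: dict[str, SubtestRole] = {
    "word_learning_immediate": SubtestRole("memory"),
    "word_learning_delayed": SubtestRole("memory"),
    "rey_figure_delayed": SubtestRole("memory"),
    "visual_elevator": SubtestRole("executive", higher_better=False),
    "brixton_errors": SubtestRole("executive", higher_better=False),
    "verbal_fluency": SubtestRole("executive"),
    "digit_span_forward": SubtestRole("speed_attention"),
    "digit_span_backward": SubtestRole("speed_attention"),
    "symbol_substitution": SubtestRole("speed_attention"),
}


class CompositeScorer(BaseEstimator, TransformerMixin):
    """Compute per-domain composite z-scores from raw subtest scores.

    Parameters
    ----------
    scheme : dict of subtest name -> SubtestRole, optional
        Defaults to the nine-subtest scheme in :data:`DEFAULT_SCHEME`.
        Only subtests present in the input table are used.

    Fitted attributes
    -----------------
    means_, stds_ : pandas.Series
        Sample mean and SD of each (orientation-corrected) subtest.
    scheme_ : dict
        The resolved subtest scheme.
    n_dropped_ : dict
        Per domain, the number of patients excluded for missing subtests.
    """

    def __init__(self, scheme: dict[str, SubtestRole] | None = None):
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y=None):
        scheme = dict(self.scheme) if self.scheme is not None else dict(DEFAULT_SCHEME)
        scheme = {k: v for k, v in scheme.items() if k in X.columns}
        if not scheme:
            raise ValueError("no subtest column in the input matches the scheme")
        for name, role in scheme.items():
            if role.domain not in DOMAINS:
                raise ValueError(f"subtest {name!r} assigned to unknown domain {role.domain!r}")
        oriented = self._orient(X, scheme)
        stds = oriented.std(ddof=1)
        zero = stds[~(stds > 0)].index.tolist()
        if zero:
            raise ValueError(f"subtest(s) with zero sample SD: {zero}")
        self.scheme_ = scheme
        self.means_ = oriented.mean()
        self.stds_ = stds
        return self

    @staticmethod
    def _orient(X: pd.DataFrame, scheme: dict[str, SubtestRole]) -> pd.DataFrame:
        cols = {}
        for name, role in scheme.items():
            col = pd.to_numeric(X[name], errors="coerce")
            cols[name] = col if role.higher_better else -col
        return pd.DataFrame(cols, index=X.index)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        z = (self._orient(X, self.scheme_) - self.means_) / self.stds_
        out = {}
        self.n_dropped_ = {}
        for domain in DOMAINS:
            members = [n for n, r in self.scheme_.items() if r.domain == domain]
            if not members:
                continue
            sub = z[members]
            composite = sub.mean(axis=1)
            incomplete = sub.isna().any(axis=1)
            composite[incomplete] = np.nan
            self.n_dropped_[domain] = int(incomplete.sum())
            if self.n_dropped_[domain]:
                log.info("domain %s: %d patient(s) dropped for missing subtests",
                         domain, self.n_dropped_[domain])
            out[domain] = composite
        return pd.DataFrame(out, index=X.index)


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """OLS residuals of domain composites after covariate adjustment.

    The design is a constant plus the covariate columns (default: age,
    sex, education as a single numeric 1-8 level, reading score).  The
    residuals are orthogonal to every design column.
    """

    def __init__(self, covariates: tuple[str, ...] = COVARIATE_COLUMNS):
        self.covariates = covariates

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise ValueError(f"covariate column(s) missing: {missing}")
        # constant covariates are absorbed by the intercept, not an error
        cols, kept = [], []
        for c in self.covariates:
            v = np.asarray(X[c], dtype=np.float64)
            if np.ptp(v) == 0:
                log.info("covariate %s is constant; absorbed by the intercept", c)
            else:
                cols.append(v)
                kept.append(c)
        D = np.column_stack([np.ones(len(X))] + cols)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            collinear = []
            for j in range(1, D.shape[1]):
                rest = np.delete(D, j, axis=1)
                if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(D):
                    collinear.append(kept[j - 1])
            raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
        return D

    def fit(self, X: pd.DataFrame, y: pd.DataFrame | pd.Series):
        D = self._design(X)
        Y = pd.DataFrame(y).astype(np.float64)
        # fit per column on complete cases only
        self.coef_ = {}
        for col in Y.columns:
            v = Y[col].values
            ok = ~np.isnan(v)
            c, *_ = np.linalg.lstsq(D[ok], v[ok], rcond=None)
            self.coef_[col] = c
        self.columns_ = tuple(Y.columns)
        return self

    def transform(self, X: pd.DataFrame, y: pd.DataFrame | pd.Series) -> pd.DataFrame:
        D = self._design(X)
        Y = pd.DataFrame(y).astype(np.float64)
        out = {}
        for col in Y.columns:
            out[col] = Y[col].values - D @ self.coef_[col]
        return pd.DataFrame(out, index=Y.index)

    def fit_transform(self, X, y=None, **kwargs):  # type: ignore[override]
        return self.fit(X, y).transform(X, y)


def composite_scores(
    subtests: pd.DataFrame, scheme: dict[str, SubtestRole] | None = None
) -> pd.DataFrame:
    """Per-domain composite z-scores for an analysis sample.

    Sample statistics are taken from the same table, so each complete-case
    composite has mean ~0 on the analysis sample.
    """
    if len(subtests) < 2:
        raise ValueError("need at least 2 patients to z-score subtests")
    return CompositeScorer(scheme=scheme).fit_transform(subtests)


def residualize(
    scores: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
    columns: tuple[str, ...] = COVARIATE_COLUMNS,
) -> pd.DataFrame:
    """OLS residuals of composite scores on (constant + covariates)."""
    res = CovariateResidualizer(covariates=columns)
    return res.fit_transform(covariates, scores)
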
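"""Stress-score construction and covariate-adjusted association with delta-age.

The central fit is an ordinary least-squares regression of delta-age
(DNAM-age minus chronological age) on a stress score plus covariates such as
age, sex, cell-type fractions, lifestyle variables and technical batch
labels, expressed through a model formula. Stratification helpers implement
a median split on a numeric column and childhood-abuse strata defined by
questionnaire subscale cutoffs; auxiliary statistics cover the two-sample t
test between strata and Fisher's z test comparing two correlations.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from scipy.linalg import qr

from .datatypes import PhenotypeTable
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "build_scores",
    "fit_delta_age_model",
    "median_split",
    "abuse_strata",
    "two_sample_t",
    "fisher_z_compare",
    "RegressionResult",
]


def build_scores(items: pd.DataFrame, partition: dict) -> pd.DataFrame:
    """Sum binary/ordinal questionnaire items into named stress scores.

    ``partition`` maps item column -> score name or list of score names (an
    item may contribute to several scores, e.g. both a lifetime and a
    current score). Returns one column per score, summing with NaN treated
    as 0 only when all items for a sample are present (otherwise NaN).
    """
    groups: dict = {}
    for item, names in partition.items():
        if item not in items.columns:
            raise ValidationError(f"partition references absent item {item!r}")
        if isinstance(names, str):
            names = [names]
        for name in names:
            groups.setdefault(name, []).append(item)
    out = {}
    for name, cols in groups.items():
        block = items[cols]
        out[name] = block.sum(axis=1).where(~block.isna().any(axis=1))
    return pd.DataFrame(out, index=items.index)


@dataclass
class RegressionResult:
    """Per-term OLS estimates: effect, SE, t and two-tailed p."""

    table: pd.DataFrame  # index: term; columns beta, se, t, p
    n: int

    @property
    def terms(self) -> list:
        return list(self.table.index)

    def beta(self, term: str) -> float:
        return float(self.table.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def fit_delta_age_model(
    pred: pd.DataFrame,
    pheno: PhenotypeTable | pd.DataFrame,
    formula: str = "delta_age ~ life_stress + age + sex",
) -> RegressionResult:
    """OLS fit of delta-age on stress and covariates via a model formula.

    ``pred`` is the prediction table from :func:`stressclock.clock.predict_dnam_age`
    (only ``delta_age`` is used; a ``delta_age`` column already present in
    ``pheno`` would be overwritten). Categorical covariates expand to
    indicator contrasts; incomplete cases are dropped listwise. A
    rank-deficient design raises, naming the collinear columns.
    """
    frame = pheno.frame if isinstance(pheno, PhenotypeTable) else pheno
    data = frame.copy()
    data["delta_age"] = pred["delta_age"].reindex(data.index)
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, _, piv = qr(exog, mode="economic", pivoting=True)
        names = np.asarray(model.exog_names)
        collinear = list(names[np.sort(piv[rank:])])
        raise ValidationError(f"rank-deficient design; collinear terms: {collinear}")
    n_terms = exog.shape[1]
    if model.exog.shape[0] < n_terms + 2:
        raise ValidationError(
            f"too few complete cases ({model.exog.shape[0]}) for {n_terms} terms"
        )
    fit = model.fit()
    table = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    table.index.name = "term"
    return RegressionResult(table=table, n=int(fit.nobs))


def median_split(pheno: PhenotypeTable | pd.DataFrame, column: str) -> pd.Series:
    """Assign 'low' (value <= median) / 'high' strata on a numeric column.

    The median is computed on non-missing values; ties go to 'low'
    (deterministic). Samples with missing values get NaN.
    """
    frame = pheno.frame if isinstance(pheno, PhenotypeTable) else pheno
    vals = pd.to_numeric(frame[column], errors="coerce")
    if vals.isna().all():
        raise ValidationError(f"column {column!r} has no non-missing values")
    med = vals.median()
    out = pd.Series(
        np.where(vals <= med, "low", "high"), index=frame.index, name=f"{column}_stratum"
    )
    out[vals.isna()] = np.nan
    return out


def abuse_strata(
    pheno: PhenotypeTable | pd.DataFrame,
    sexual_col: str = "ctq_sexual",
    physical_col: str = "ctq_physical",
    sexual_cutoff: float = 8,
    physical_cutoff: float = 10,
) -> pd.Series:
    """Childhood-abuse strata from CTQ subscale cutoffs.

    'moderate_extreme' when sexual-abuse score >= ``sexual_cutoff`` (default
    8) OR physical-abuse score >= ``physical_cutoff`` (default 10), else
    'none_mild'. Samples missing either subscale get NaN.
    """
    frame = pheno.frame if isinstance(pheno, PhenotypeTable) else pheno
    for col in (sexual_col, physical_col):
        if col not in frame.columns:
            raise ValidationError(f"missing CTQ subscale column {col!r}")
    sex = pd.to_numeric(frame[sexual_col], errors="coerce")
    phys = pd.to_numeric(frame[physical_col], errors="coerce")
    severe = (sex >= sexual_cutoff) | (phys >= physical_cutoff)
    out = pd.Series(
        np.where(severe, "moderate_extreme", "none_mild"),
        index=frame.index,
        name="abuse_stratum",
    )
    out[sex.isna() | phys.isna()] = np.nan
    return out


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t test; returns ``(t, df, p)``.

    ``variant='pooled'`` assumes equal variances (df = n1 + n2 - 2);
    ``'welch'`` uses the Welch-Satterthwaite df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown variant {variant!r}")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.isclose(x.mean(), y.mean()):
        raise DegenerateInputError("zero variance in both groups with equal means")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for the difference of two independent correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``; returns
    ``(|z|, p)`` with a two-tailed normal p-value. The magnitude is reported
    because the comparison is direction-free.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValidationError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("each correlation needs n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(abs(z)), float(p)
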
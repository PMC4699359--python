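"""DNA-methylation age prediction and age-acceleration utilities.

The clock maps a weighted sum of CpG beta values through a calibrated age
transform that is logarithmic during development and linear in adulthood:

    F(age)   = log(age + 1) - log(adult_age + 1)        for age <= adult_age
    F(age)   = (age - adult_age) / (adult_age + 1)      for age >  adult_age

``dnam_age = F^{-1}(intercept + sum_i w_i * beta_i)``; age acceleration
(delta-age) is ``dnam_age - chronological age``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClockModel, MethylationMatrix, PhenotypeTable
from .errors import ConfigurationError, DegenerateInputError, ValidationError

__all__ = [
    "transform_age",
    "inverse_transform_age",
    "predict_dnam_age",
    "replicate_summary",
    "grubbs_test",
    "ReplicateSummary",
    "GrubbsResult",
]

MISSING_POLICIES = ("mean", "zero", "error")


def transform_age(age, adult_age: float = 20.0):
    """Calibrated age transform; log-linear with a knee at ``adult_age``.

    Continuous and monotone increasing on (-1, inf); vectorized over arrays.
    Raises for ages <= -1 where the logarithm is undefined.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1):
        raise ValidationError("transform_age requires age > -1")
    adult = float(adult_age)
    with np.errstate(invalid="ignore"):
        out = np.where(
            a <= adult,
            np.log1p(a) - np.log1p(adult),
            (a - adult) / (adult + 1.0),
        )
    return out.item() if np.isscalar(age) or out.ndim == 0 else out


def inverse_transform_age(t, adult_age: float = 20.0):
    """Inverse of :func:`transform_age`: years from the transformed scale."""
    x = np.asarray(t, dtype=float)
    adult = float(adult_age)
    out = np.where(
        x <= 0,
        np.expm1(x + np.log1p(adult)),
        x * (adult + 1.0) + adult,
    )
    return out.item() if np.isscalar(t) or out.ndim == 0 else out


def predict_dnam_age(
    m: MethylationMatrix,
    clock: ClockModel,
    pheno: PhenotypeTable | None = None,
    missing_policy: str = "mean",
) -> pd.DataFrame:
    """Predict DNAM-age per sample and, when ages are known, delta-age.

    The linear score ``intercept + sum w_i * beta_i`` runs over clock probes
    present in the matrix; probes absent from the matrix are dropped from the
    score and counted in ``n_probes_missing``. NaN betas at present probes
    are handled per ``missing_policy``:

    * ``'mean'`` (default) — impute with the probe's cohort mean;
    * ``'zero'`` — impute with 0;
    * ``'error'`` — raise.

    Returns a DataFrame indexed by sample id with columns ``dnam_age``,
    ``delta_age``, ``n_probes_used``, ``n_probes_missing``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigurationError(
            f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}"
        )
    present = [p for p in clock.probe_ids if p in m.betas.columns]
    if not present:
        raise ValidationError("no clock probes present in the methylation matrix")
    sub = m.betas[present].to_numpy(dtype=float)
    nan_mask = np.isnan(sub)
    n_nan_per_sample = nan_mask.sum(axis=1)
    if nan_mask.any():
        if missing_policy == "error":
            raise ValidationError("missing betas at clock probes with missing_policy='error'")
        if missing_policy == "mean":
            col_mean = np.nanmean(sub, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            fill = np.broadcast_to(col_mean, sub.shape)
        else:
            fill = np.zeros_like(sub)
        sub = np.where(nan_mask, fill, sub)
    w = clock.weights.loc[present].to_numpy(dtype=float)
    score = clock.intercept + sub @ w
    dnam = inverse_transform_age(score, clock.adult_age)
    n_absent = clock.size - len(present)
    out = pd.DataFrame(
        {
            "dnam_age": np.atleast_1d(dnam),
            "delta_age": np.nan,
            "n_probes_used": len(present) - n_nan_per_sample,
            "n_probes_missing": n_absent + n_nan_per_sample,
        },
        index=pd.Index(m.sample_ids, name="sample_id"),
    )
    if pheno is not None and "age" in pheno.frame.columns:
        age = pd.to_numeric(pheno.frame["age"], errors="coerce").reindex(out.index)
        out["delta_age"] = out["dnam_age"] - age
    return out


@dataclass
class ReplicateSummary:
    mean_dnam_age: float
    sd_dnam_age: float
    mean_pairwise_r: float
    n_replicates: int


def replicate_summary(m: MethylationMatrix, clock: ClockModel) -> ReplicateSummary:
    """Technical-replicate robustness: spread of predictions and beta agreement.

    Computes the mean and sample SD of DNAM-age across replicate samples and
    the mean pairwise Pearson correlation between replicate beta vectors
    restricted to clock probes. Requires >= 2 replicates.
    """
    if m.n_samples < 2:
        raise ValidationError("replicate_summary needs >= 2 replicate samples")
    pred = predict_dnam_age(m, clock)
    ages = pred["dnam_age"].to_numpy()
    present = [p for p in clock.probe_ids if p in m.betas.columns]
    vecs = m.betas[present].to_numpy(dtype=float)
    n = len(vecs)
    rs = []
    for i in range(n):
        for j in range(i + 1, n):
            sx, sy = np.std(vecs[i]), np.std(vecs[j])
            if sx == 0 or sy == 0:
                rs.append(1.0 if np.allclose(vecs[i], vecs[j]) else np.nan)
            else:
                rs.append(float(np.corrcoef(vecs[i], vecs[j])[0, 1]))
    return ReplicateSummary(
        mean_dnam_age=float(np.mean(ages)),
        sd_dnam_age=float(np.std(ages, ddof=1)),
        mean_pairwise_r=float(np.nanmean(rs)),
        n_replicates=n,
    )


@dataclass
class GrubbsResult:
    g: float
    index: int
    critical: float
    p_bound: float
    significant: bool


def grubbs_test(x, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier.

    ``G = max_i |x_i - mean| / sd`` (sample SD). Significance is assessed
    against the classical t-based critical value

        G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)),
        t = t_{alpha/(2n), n-2},

    and the reported ``p_bound`` is the matching upper bound
    ``min(1, 2n * P(T_{n-2} > t(G)))``.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n < 3:
        raise ValidationError("Grubbs test requires n >= 3")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise DegenerateInputError("Grubbs test undefined for a constant vector")
    dev = np.abs(arr - arr.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    tcrit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))
    # invert G -> t to obtain the p bound
    c = g**2 * n / (n - 1) ** 2
    if c >= 1:
        p_bound = 0.0
    else:
        t_of_g = np.sqrt(c * (n - 2) / (1 - c))
        p_bound = float(min(1.0, 2 * n * stats.t.sf(t_of_g, n - 2)))
    return GrubbsResult(
        g=g, index=idx, critical=float(g_crit), p_bound=p_bound, significant=g > g_crit
    )
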
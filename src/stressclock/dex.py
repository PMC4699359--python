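"""Paired baseline / post-glucocorticoid differential testing.

Subjects are sampled twice — at baseline and a few hours after ingestion of
the glucocorticoid receptor agonist dexamethasone (DEX) — and each feature
(CpG beta value or expression probe) is tested for a condition effect with a
Gaussian likelihood-ratio test on within-subject differences:

    d_i = post_i - baseline_i
    full:    d ~ 1 + covariates
    reduced: d ~ 0 + covariates
    LRT = n * ln(RSS_reduced / RSS_full),  p ~ chi2(1)

Taking differences absorbs subject-level effects (equivalent to subject
fixed effects with two time points); covariates stay in both models so the
test isolates the condition effect. Multiple testing is controlled with
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MethylationMatrix, PhenotypeTable
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PairedDesign",
    "paired_lrt",
    "bh_fdr",
    "direction_summary",
    "paired_t_dnam_age",
    "filter_expressed",
    "PairedAgeTest",
]


@dataclass
class PairedDesign:
    """Pairing of baseline and post samples per subject, with covariates.

    ``frame`` is indexed by subject id with columns ``baseline_sample``,
    ``post_sample`` and any per-subject covariates (gender, age, BMI,
    disease status, cell fractions, ...).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("baseline_sample", "post_sample"):
            if col not in self.frame.columns:
                raise ValidationError(f"paired design missing column {col!r}")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate subject ids in paired design")
        both = pd.concat([self.frame["baseline_sample"], self.frame["post_sample"]])
        if both.duplicated().any():
            raise ValidationError("a sample id occurs in more than one pairing slot")

    @classmethod
    def from_phenotypes(
        cls,
        pheno: PhenotypeTable | pd.DataFrame,
        subject_col: str = "subject_id",
        condition_col: str = "condition",
        baseline_label: str = "baseline",
        post_label: str = "post",
        covariates: list | None = None,
    ) -> "PairedDesign":
        frame = pheno.frame if isinstance(pheno, PhenotypeTable) else pheno
        rows = {}
        for subj, grp in frame.groupby(subject_col):
            conds = grp[condition_col]
            base = grp.index[conds == baseline_label]
            post = grp.index[conds == post_label]
            if len(base) != 1 or len(post) != 1:
                raise ValidationError(
                    f"subject {subj!r} must have exactly one {baseline_label!r} "
                    f"and one {post_label!r} sample"
                )
            row = {"baseline_sample": base[0], "post_sample": post[0]}
            for cov in covariates or []:
                row[cov] = grp.loc[base[0], cov]
            rows[subj] = row
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "subject_id"
        return cls(out)

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def baseline_samples(self) -> list:
        return list(self.frame["baseline_sample"])

    @property
    def post_samples(self) -> list:
        return list(self.frame["post_sample"])


def _covariate_matrix(design: PairedDesign, covariates) -> np.ndarray:
    """Numeric covariate matrix, centered (categoricals expanded first).

    Centering makes the intercept-free reduced model independent of the
    covariates' origin, so the test is invariant under affine covariate
    rescaling and the full-model intercept reads as the adjusted mean
    paired difference.
    """
    if not covariates:
        return np.empty((design.n_subjects, 0))
    missing = [c for c in covariates if c not in design.frame.columns]
    if missing:
        raise ValidationError(f"covariates missing from design: {missing}")
    block = design.frame[list(covariates)]
    block = pd.get_dummies(block, drop_first=True, dtype=float)
    z = block.to_numpy(dtype=float)
    return z - z.mean(axis=0)


def paired_lrt(
    values: MethylationMatrix | pd.DataFrame,
    design: PairedDesign,
    covariates: list | None = None,
) -> pd.DataFrame:
    """Per-feature likelihood-ratio test for a paired condition effect.

    ``values`` holds both baseline and post samples (rows) by feature
    (columns). Returns a DataFrame indexed by feature with columns
    ``effect`` (mean paired difference adjusted for covariates — the full
    model's intercept), ``lrt``, ``p``, ``q`` (BH-FDR) and ``direction``
    ('down' for negative effects, else 'up'). Features with zero full-model
    residual sum of squares are flagged ``degenerate`` and assigned p = 0
    with a warning.
    """
    df = values.betas if isinstance(values, MethylationMatrix) else values
    for col, what in (("baseline_samples", "baseline"), ("post_samples", "post")):
        missing = [s for s in getattr(design, col) if s not in df.index]
        if missing:
            raise ValidationError(f"{what} samples absent from matrix: {missing[:5]}")
    covariates = list(covariates or [])
    n = design.n_subjects
    if n < len(covariates) + 3:
        raise ValidationError(
            f"paired LRT needs >= {len(covariates) + 3} subjects, got {n}"
        )
    d = (
        df.loc[design.post_samples].to_numpy(dtype=float)
        - df.loc[design.baseline_samples].to_numpy(dtype=float)
    )
    z = _covariate_matrix(design, covariates)
    x_full = np.column_stack([np.ones(n), z])
    beta_full, *_ = np.linalg.lstsq(x_full, d, rcond=None)
    rss_full = np.sum((d - x_full @ beta_full) ** 2, axis=0)
    if z.shape[1]:
        beta_red, *_ = np.linalg.lstsq(z, d, rcond=None)
        rss_red = np.sum((d - z @ beta_red) ** 2, axis=0)
    else:
        rss_red = np.sum(d**2, axis=0)
    # RSS_full = 0 with signal in the reduced model means a perfect fit
    # (degenerate); RSS_full = RSS_red = 0 means d == 0 (no effect, p = 1).
    degenerate = (rss_full <= 0) & (rss_red > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero residual variance; p set to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(np.where(degenerate, np.inf, rss_red / rss_full))
    lrt = np.where(rss_red <= rss_full, 0.0, lrt)  # numerical guard
    lrt = np.where(degenerate, np.inf, lrt)
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(degenerate, 0.0, p)
    effect = beta_full[0]
    out = pd.DataFrame(
        {
            "effect": effect,
            "lrt": lrt,
            "p": p,
            "q": bh_fdr(p),
            "direction": np.where(effect < 0, "down", "up"),
            "degenerate": degenerate,
        },
        index=pd.Index(df.columns, name="feature_id"),
    )
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def direction_summary(results: pd.DataFrame, q_thresh: float = 0.05) -> tuple[int, int, int]:
    """Counts of significant features by effect direction.

    Returns ``(n_sig, n_down, n_up)`` among features with ``q < q_thresh``.
    """
    sig = results[results["q"] < q_thresh]
    n_down = int((sig["effect"] < 0).sum())
    n_up = int((sig["effect"] >= 0).sum())
    return n_down + n_up, n_down, n_up


@dataclass
class PairedAgeTest:
    t: float
    df: int
    p: float
    mean_baseline: float
    mean_post: float


def paired_t_dnam_age(
    pred_baseline: pd.DataFrame, pred_post: pd.DataFrame, design: PairedDesign
) -> PairedAgeTest:
    """Paired t test of DNAM-age between baseline and post conditions.

    One-sample t on per-subject differences (post - baseline), df = n - 1,
    two-tailed p. Identical predictions give t = 0, p = 1; non-zero constant
    differences (zero SD) are a degenerate input.
    """
    base = pred_baseline["dnam_age"].reindex(design.baseline_samples).to_numpy(dtype=float)
    post = pred_post["dnam_age"].reindex(design.post_samples).to_numpy(dtype=float)
    if np.isnan(base).any() or np.isnan(post).any():
        raise ValidationError("predictions missing for some paired samples")
    n = len(base)
    if n < 2:
        raise ValidationError("paired t test needs n >= 2 pairs")
    d = post - base
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedAgeTest(0.0, n - 1, 1.0, float(base.mean()), float(post.mean()))
        raise DegenerateInputError("constant non-zero paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedAgeTest(float(t), n - 1, float(p), float(base.mean()), float(post.mean()))


def filter_expressed(
    expr: pd.DataFrame,
    detection_p: pd.DataFrame,
    p_thresh: float = 0.05,
    min_frac: float = 0.50,
) -> pd.DataFrame:
    """Keep expression probes detected above background.

    A probe is kept when the fraction of samples with detection
    ``p < p_thresh`` is at least ``min_frac`` (strict inequality, matching
    array-detection convention for expression). ``min_frac=0`` is the
    identity.
    """
    det = detection_p.reindex(index=expr.index, columns=expr.columns)
    frac = (det.to_numpy() < p_thresh).mean(axis=0)
    keep = frac >= min_frac
    return expr.loc[:, keep]
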
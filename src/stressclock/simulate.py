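"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the pipeline is built to
detect, with every planted quantity recorded in a :class:`GroundTruth`:

* a toy linear clock whose noiseless weighted score reproduces the
  transformed age exactly, so delta-age is identically zero without noise;
* methylation cohorts where a stress score adds ``gamma_stress`` years of
  age acceleration per stress unit (entering on the transformed-age scale
  divided by ``adult_age + 1`` so the parameter reads directly as years of
  delta-age per unit above the knee);
* paired baseline / post-DEX matrices with an asymmetric down/up direction
  mix among affected probes;
* interval (peak) sets with controllable per-probe membership rates for
  query vs. background probes;
* expression matrices with planted regulation and a silent (undetected)
  gene fraction.

Defaults mirror the cohort regime the pipeline targets: n = 400 samples,
ages 18-77, right-skewed integer stress scores around 10, ~70 % female,
an 89 %/11 % down/up DEX direction mix over ~31 % of clock probes, peak
membership 24 % for clock probes vs 13.8 % for the background (the
85-of-353 vs 48.8-of-353 co-localization regime) and peak lengths around
746 bp.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import inverse_transform_age, transform_age
from .datatypes import ClockModel, IntervalSet, MethylationMatrix, PhenotypeTable, ProbeManifest
from .dex import PairedDesign
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ToyClock",
    "generate_toy_clock",
    "generate_manifest",
    "generate_cohort",
    "generate_dex_pair",
    "generate_peaks",
    "generate_tss",
    "generate_expression",
    "generate_gene_sets",
]

_CHROMS = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimulationConfig:
    """All tunable knobs of the generators, with cohort-regime defaults."""

    n_samples: int = 400
    n_clock_probes: int = 50
    n_background_probes: int = 2000
    adult_age: float = 20.0
    age_range: tuple = (18.0, 77.0)
    gamma_stress: float = 0.3  # years of delta-age per stress unit
    beta_noise_sd: float = 0.05
    stress_mean: float = 10.0
    frac_female: float = 0.7
    n_batches: int = 4
    frac_dex_affected: float = 110 / 353
    dex_down_frac: float = 0.89
    dex_effect_size: float = 0.10  # beta units
    dex_noise_sd: float = 0.01
    n_dex_pairs: int = 124
    enrich_frac_query: float = 0.24
    enrich_frac_background: float = 0.138
    peak_length_mean: float = 746.3
    peak_length_sd: float = 370.6
    probe_spacing: int = 5000
    frac_on_21k: float = 0.25
    tss_frac_linked: float = 0.95
    tss_max_offset: int = 1423
    expr_frac_regulated: float = 0.8
    expr_up_frac: float = 0.58
    expr_effect_size: float = 1.0
    expr_noise_sd: float = 0.3
    expr_silent_frac: float = 0.49
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "frac_female",
            "frac_dex_affected",
            "dex_down_frac",
            "enrich_frac_query",
            "enrich_frac_background",
            "frac_on_21k",
            "tss_frac_linked",
            "expr_frac_regulated",
            "expr_up_frac",
            "expr_silent_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_clock_probes > self.n_background_probes:
            raise ValidationError("n_clock_probes must be <= n_background_probes")


class GroundTruth(dict):
    """JSON-serializable record of every planted quantity."""

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=1, sort_keys=True, default=_jsonify)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(json.load(fh))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _probe_ids(n: int) -> list:
    return [f"cg{i:06d}" for i in range(n)]


@dataclass
class ToyClock:
    """A generated clock plus the per-probe means/loadings that realize it."""

    model: ClockModel
    probes: pd.DataFrame  # index probe_id; columns mean, loading


def generate_toy_clock(config: SimulationConfig, seed=None) -> ToyClock:
    """Construct a clock whose noiseless score equals the transformed age.

    Probe baseline means are drawn in (0.3, 0.7) and loadings (beta change
    per unit of transformed age) in +/-(0.02, 0.08); weights are the
    loadings scaled by 1/||loading||^2 and the intercept cancels the means,
    so ``intercept + w . beta(a) = F(a)`` exactly. Raises when the implied
    betas would leave [0, 1] anywhere over ``age_range``.
    """
    if config.n_clock_probes < 2:
        raise ValidationError("need >= 2 clock probes")
    rng = _rng(seed if seed is not None else config.seed)
    n = config.n_clock_probes
    means = rng.uniform(0.3, 0.7, size=n)
    loadings = rng.uniform(0.02, 0.08, size=n) * rng.choice([-1.0, 1.0], size=n)
    t_lo = transform_age(config.age_range[0], config.adult_age)
    t_hi = transform_age(config.age_range[1], config.adult_age)
    extremes = np.stack([means + loadings * t_lo, means + loadings * t_hi])
    if (extremes < 0).any() or (extremes > 1).any():
        raise ValidationError("loading scale infeasible: betas leave [0, 1] over age_range")
    weights = loadings / np.dot(loadings, loadings)
    intercept = -float(np.dot(weights, means))
    ids = _probe_ids(n)
    model = ClockModel(
        intercept=intercept,
        weights=pd.Series(weights, index=ids),
        adult_age=config.adult_age,
    )
    probes = pd.DataFrame(
        {"mean": means, "loading": loadings}, index=pd.Index(ids, name="probe_id")
    )
    return ToyClock(model=model, probes=probes)


def generate_manifest(config: SimulationConfig, seed=None) -> ProbeManifest:
    """Probe manifest for clock + background probes.

    Probes are laid out round-robin over chr1-chr22 with ``probe_spacing``
    bp between consecutive probes on a chromosome (far enough apart that
    generated peaks rarely span two probes). The first ``n_clock_probes``
    ids are the clock probes; all probes are on the 450K-style background
    and the 21K subset contains every clock probe plus a random
    ``frac_on_21k`` of the rest.
    """
    rng = _rng(seed if seed is not None else config.seed)
    n = config.n_background_probes
    ids = _probe_ids(n)
    chrom_idx = np.arange(n) % len(_CHROMS)
    rank_on_chrom = np.arange(n) // len(_CHROMS)
    pos = (rank_on_chrom + 1) * config.probe_spacing + 1  # 1-based
    on_21k = rng.random(n) < config.frac_on_21k
    on_21k[: config.n_clock_probes] = True
    frame = pd.DataFrame(
        {
            "chrom": [_CHROMS[i] for i in chrom_idx],
            "pos": pos,
            "on_21k": on_21k,
            "on_450k": True,
            "is_sex_chrom": False,
        },
        index=pd.Index(ids, name="probe_id"),
    )
    return ProbeManifest(frame)


def generate_cohort(
    toy: ToyClock, config: SimulationConfig, seed=None, manifest: ProbeManifest | None = None
) -> tuple[MethylationMatrix, PhenotypeTable, GroundTruth]:
    """Methylation cohort with a planted stress -> age-acceleration effect.

    Ages are uniform over ``age_range``; stress scores are Poisson integers
    around ``stress_mean``. The latent transformed age is

        t_i = F(age_i) + gamma_stress * stress_i / (adult_age + 1)

    and clock betas are ``mean + loading * t_i + N(0, beta_noise_sd)``,
    clipped to [0, 1] with the clip count logged (warn above 10 %, error
    above 50 %). Background probes carry mean + noise only. Covariates
    (sex, CD4/CD8/NK cell fractions, batch) are generated independently.
    """
    rng = _rng(seed if seed is not None else config.seed)
    n = config.n_samples
    ages = rng.uniform(*config.age_range, size=n)
    stress = rng.poisson(config.stress_mean, size=n)
    current = rng.binomial(stress, 0.25)
    ctq_sexual = rng.poisson(5.5, size=n)
    ctq_physical = rng.poisson(7.0, size=n)
    sex = np.where(rng.random(n) < config.frac_female, "F", "M")
    cells = rng.dirichlet([40, 20, 10], size=n)
    batch = rng.integers(config.n_batches, size=n)

    t = transform_age(ages, config.adult_age) + config.gamma_stress * stress / (
        config.adult_age + 1.0
    )
    means = toy.probes["mean"].to_numpy()
    loadings = toy.probes["loading"].to_numpy()
    clock_betas = means + np.outer(t, loadings)
    clock_betas = clock_betas + rng.normal(0, config.beta_noise_sd, size=clock_betas.shape)

    if manifest is not None:
        bg_ids = [p for p in manifest.probe_ids if p not in toy.probes.index]
    else:
        bg_ids = _probe_ids(config.n_background_probes)[config.n_clock_probes :]
    bg_means = rng.uniform(0.1, 0.9, size=len(bg_ids))
    bg_betas = bg_means + rng.normal(0, config.beta_noise_sd, size=(n, len(bg_ids)))

    betas = np.concatenate([clock_betas, bg_betas], axis=1)
    n_clipped = int(((betas < 0) | (betas > 1)).sum())
    frac_clipped = n_clipped / betas.size
    if frac_clipped > 0.5:
        raise ValidationError(f"{frac_clipped:.0%} of betas clipped; noise scale infeasible")
    if frac_clipped > 0.1:
        warnings.warn(f"{frac_clipped:.1%} of betas clipped to [0, 1]", stacklevel=2)
    betas = np.clip(betas, 0.0, 1.0)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    columns = list(toy.probes.index) + list(bg_ids)
    matrix = MethylationMatrix(
        pd.DataFrame(betas, index=pd.Index(sample_ids, name="sample_id"), columns=columns)
    )
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "age": ages,
                "sex": sex,
                "life_stress": stress,
                "current_stress": current,
                "ctq_sexual": ctq_sexual,
                "ctq_physical": ctq_physical,
                "cd4": cells[:, 0],
                "cd8": cells[:, 1],
                "nk": cells[:, 2],
                "batch": [f"b{b}" for b in batch],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(
        {
            "kind": "cohort",
            "gamma_stress": config.gamma_stress,
            "beta_noise_sd": config.beta_noise_sd,
            "ages": ages,
            "stress": stress,
            "delta_age_true": config.gamma_stress * stress,
            "n_clipped": n_clipped,
            "frac_clipped": frac_clipped,
        }
    )
    return matrix, pheno, truth


def generate_dex_pair(
    baseline: MethylationMatrix, config: SimulationConfig, seed=None
) -> tuple[MethylationMatrix, PairedDesign, GroundTruth]:
    """Post-treatment matrix with planted per-probe effects and pairing.

    ``frac_dex_affected`` of the probes receive a shift of magnitude
    ``dex_effect_size``, directed down with probability ``dex_down_frac``;
    every probe additionally gets N(0, dex_noise_sd) re-measurement noise.
    Post sample ids are ``<baseline id>_post``; per-subject covariates
    (gender, age, BMI, disease status, CD4 fraction) are generated for the
    design.
    """
    rng = _rng(seed if seed is not None else config.seed)
    b = baseline.betas.to_numpy(dtype=float)
    n, m = b.shape
    affected = rng.random(m) < config.frac_dex_affected
    down = rng.random(m) < config.dex_down_frac
    effect = np.where(affected, np.where(down, -1.0, 1.0) * config.dex_effect_size, 0.0)
    post = b + effect + rng.normal(0, config.dex_noise_sd, size=b.shape)
    post = np.clip(post, 0.0, 1.0)
    base_ids = baseline.sample_ids
    post_ids = [f"{s}_post" for s in base_ids]
    post_matrix = MethylationMatrix(
        pd.DataFrame(post, index=pd.Index(post_ids, name="sample_id"), columns=baseline.probe_ids)
    )
    design = PairedDesign(
        pd.DataFrame(
            {
                "baseline_sample": base_ids,
                "post_sample": post_ids,
                "gender": np.where(rng.random(n) < 0.35, "F", "M"),
                "age": rng.uniform(21, 71, size=n),
                "bmi": rng.normal(25, 4, size=n),
                "status": np.where(rng.random(n) < 0.5, "case", "control"),
                "cd4": rng.dirichlet([40, 30], size=n)[:, 0],
            },
            index=pd.Index([f"subj{i:04d}" for i in range(n)], name="subject_id"),
        )
    )
    truth = GroundTruth(
        {
            "kind": "dex",
            "affected": affected,
            "effect": effect,
            "dex_effect_size": config.dex_effect_size,
            "dex_noise_sd": config.dex_noise_sd,
            "frac_dex_affected": config.frac_dex_affected,
            "dex_down_frac": config.dex_down_frac,
            "probe_ids": list(baseline.probe_ids),
        }
    )
    return post_matrix, design, truth


def generate_peaks(
    manifest: ProbeManifest,
    config: SimulationConfig,
    query_probes=None,
    seed=None,
) -> tuple[IntervalSet, GroundTruth]:
    """Interval set with planted per-probe membership.

    Each probe in ``query_probes`` falls inside a peak with probability
    ``enrich_frac_query``; every other manifest probe with probability
    ``enrich_frac_background``. One peak is placed around each selected
    CpG, length ~ N(peak_length_mean, peak_length_sd) clipped at 50 bp,
    CpG at a uniform offset. With the manifest's default probe spacing,
    peaks rarely reach a neighboring probe; actual membership is recomputed
    and recorded, and an error is raised if collisions push more than 5 %
    of non-selected probes into peaks.
    """
    from .enrichment import _membership, _probe_positions

    rng = _rng(seed if seed is not None else config.seed)
    ids = manifest.probe_ids
    query = set(query_probes) if query_probes is not None else set(ids[: config.n_clock_probes])
    p_member = np.array(
        [config.enrich_frac_query if p in query else config.enrich_frac_background for p in ids]
    )
    selected = rng.random(len(ids)) < p_member
    sub = manifest.frame.loc[np.asarray(ids)[selected]]
    lengths = np.maximum(
        rng.normal(config.peak_length_mean, config.peak_length_sd, size=len(sub)), 50
    ).astype(np.int64)
    offsets = (rng.random(len(sub)) * lengths).astype(np.int64)
    pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
    starts = np.maximum(pos0 - offsets, 0)
    ends = starts + lengths
    peaks = IntervalSet(
        pd.DataFrame({"chrom": sub["chrom"].to_numpy(), "start": starts, "end": ends})
    )
    chroms, allpos0 = _probe_positions(ids, manifest)
    actual = _membership(chroms, allpos0, peaks, 0)
    collisions = actual & ~selected
    if selected.sum() < len(ids) and collisions.sum() / max((~selected).sum(), 1) > 0.05:
        raise ValidationError(
            "peak placement collides with too many non-selected probes; "
            "increase probe_spacing or reduce peak lengths"
        )
    truth = GroundTruth(
        {
            "kind": "peaks",
            "requested_member": selected,
            "actual_member": actual,
            "probe_ids": list(ids),
            "enrich_frac_query": config.enrich_frac_query,
            "enrich_frac_background": config.enrich_frac_background,
        }
    )
    return peaks, truth


def generate_tss(
    manifest: ProbeManifest, config: SimulationConfig, query_probes=None, seed=None
) -> pd.DataFrame:
    """TSS table placing a gene near most query CpGs.

    A fraction ``tss_frac_linked`` of the query probes get a gene whose TSS
    sits 1..``tss_max_offset`` bp away on a random side. Returns columns
    ``gene``, ``chrom``, ``tss_pos`` (1-based).
    """
    rng = _rng(seed if seed is not None else config.seed)
    ids = list(query_probes) if query_probes is not None else manifest.probe_ids[: config.n_clock_probes]
    sub = manifest.frame.loc[ids]
    rows = []
    for i, (pid, row) in enumerate(sub.iterrows()):
        if rng.random() >= config.tss_frac_linked:
            continue
        offset = int(rng.integers(1, config.tss_max_offset + 1))
        side = -1 if rng.random() < 0.5 else 1
        tss = max(int(row["pos"]) + side * offset, 1)
        rows.append((f"GENE{i:04d}", row["chrom"], tss))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss_pos"])


def generate_expression(
    gene_links: pd.DataFrame, design: PairedDesign, config: SimulationConfig, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Expression + detection-p matrices for genes linked to clock CpGs.

    One probe per unique gene in ``gene_links``. Baseline expression is
    Gaussian per gene; ``expr_frac_regulated`` of the *detected* genes get a
    post-treatment shift of ``expr_effect_size`` (up with probability
    ``expr_up_frac``). A fraction ``expr_silent_frac`` of genes are silent:
    large detection p-values in all samples so the detection filter removes
    them. Row index covers baseline then post sample ids.
    """
    rng = _rng(seed if seed is not None else config.seed)
    genes = list(dict.fromkeys(gene_links["gene"]))
    n_g = len(genes)
    n = design.n_subjects
    silent = rng.random(n_g) < config.expr_silent_frac
    regulated = (rng.random(n_g) < config.expr_frac_regulated) & ~silent
    up = rng.random(n_g) < config.expr_up_frac
    shift = np.where(regulated, np.where(up, 1.0, -1.0) * config.expr_effect_size, 0.0)
    gene_mean = rng.normal(7.0, 1.0, size=n_g)
    subj_effect = rng.normal(0, 0.5, size=(n, 1))
    base = gene_mean + subj_effect + rng.normal(0, config.expr_noise_sd, size=(n, n_g))
    post = (
        gene_mean
        + subj_effect
        + shift
        + rng.normal(0, config.expr_noise_sd, size=(n, n_g))
    )
    index = pd.Index(design.baseline_samples + design.post_samples, name="sample_id")
    cols = pd.Index([f"pr_{g}" for g in genes], name="probe_id")
    expr = pd.DataFrame(np.vstack([base, post]), index=index, columns=cols)
    det = np.where(
        silent,
        rng.uniform(0.06, 1.0, size=(2 * n, n_g)),
        rng.uniform(0.0, 0.01, size=(2 * n, n_g)),
    )
    detection = pd.DataFrame(det, index=index, columns=cols)
    truth = GroundTruth(
        {
            "kind": "expression",
            "genes": genes,
            "silent": silent,
            "regulated": regulated,
            "shift": shift,
            "expr_effect_size": config.expr_effect_size,
            "expr_up_frac": config.expr_up_frac,
        }
    )
    return expr, detection, truth


def generate_gene_sets(
    genes, config: SimulationConfig, regulated_genes=None, seed=None, n_sets: int = 6
) -> dict:
    """Small GMT-style collection; one set enriched in ``regulated_genes``.

    The first set ('AGING_DISEASE') draws ~80 % of its members from the
    regulated genes so downstream over-representation analysis has a
    planted positive; the rest are uniform draws.
    """
    rng = _rng(seed if seed is not None else config.seed)
    genes = list(genes)
    sets: dict = {}
    if regulated_genes:
        reg = list(regulated_genes)
        k = max(5, min(15, len(reg)))
        n_reg = min(len(reg), int(round(0.8 * k)))
        members = list(rng.choice(reg, size=n_reg, replace=False))
        others = [g for g in genes if g not in set(members)]
        if others and k - n_reg > 0:
            members += list(rng.choice(others, size=min(k - n_reg, len(others)), replace=False))
        sets["AGING_DISEASE"] = members
    for i in range(n_sets - len(sets)):
        k = int(rng.integers(5, max(6, min(20, len(genes)))))
        sets[f"SET{i:02d}"] = list(rng.choice(genes, size=min(k, len(genes)), replace=False))
    return sets
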
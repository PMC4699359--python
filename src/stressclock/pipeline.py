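"""End-to-end orchestration: clock -> association -> DEX -> enrichment -> ORA.

A single YAML/dict config drives either a fully simulated run (the default;
every input is generated with known ground truth) or a file-driven run on
user-supplied matrices. One global seed fans out to per-stage child seeds
via :class:`numpy.random.SeedSequence`, so toggling one stage does not shift
another stage's randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clock, dex, enrichment, io, simulate
from .errors import ConfigurationError

__all__ = ["RunConfig", "validate_config", "run_all"]

_DEFAULTS = {
    "seed": 0,
    "outdir": "stressclock_out",
    "formula": "delta_age ~ life_stress + age + sex + cd4 + cd8",
    "q_thresh": 0.05,
    "n_perm": 1000,
    "pad": 0,
    "tss_max_dist": 1500,
    "ora_min_set": 5,
    "stages": {
        "association": True,
        "dex": True,
        "enrichment": True,
        "expression": True,
    },
    "simulate": {},  # SimulationConfig overrides
    "inputs": None,  # file-driven mode: paths for betas/pheno/clock/...
}

_STAGE_NAMES = ("association", "dex", "enrichment", "expression")


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    options: dict

    def __getitem__(self, key):
        return self.options[key]


def validate_config(config: dict | str | Path) -> RunConfig:
    """Check keys and ranges, fill defaults, and echo the result.

    Accepts a dict or a path to a YAML file. Unknown keys are rejected by
    name; thresholds are range-checked before any stage runs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(config) - set(_DEFAULTS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    opts = {**_DEFAULTS, **config}
    stages = {**_DEFAULTS["stages"], **(config.get("stages") or {})}
    bad_stage = set(stages) - set(_STAGE_NAMES)
    if bad_stage:
        raise ConfigurationError(f"unknown stage toggles: {sorted(bad_stage)}")
    opts["stages"] = stages
    if not 0 < opts["q_thresh"] <= 1:
        raise ConfigurationError(f"q_thresh must lie in (0, 1], got {opts['q_thresh']}")
    if int(opts["n_perm"]) < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {opts['n_perm']}")
    if int(opts["pad"]) < 0:
        raise ConfigurationError("pad must be >= 0")
    sim_overrides = opts.get("simulate") or {}
    known_sim = set(simulate.SimulationConfig.__dataclass_fields__)
    bad_sim = set(sim_overrides) - known_sim
    if bad_sim:
        raise ConfigurationError(f"unknown simulate keys: {sorted(bad_sim)}")
    if opts["inputs"] is not None:
        # paired-DEX and expression stages draw their subjects from the
        # simulator; in file-driven mode they are off unless explicitly
        # requested (which is rejected as unsupported).
        explicit = config.get("stages") or {}
        for name in ("dex", "expression"):
            if explicit.get(name):
                raise ConfigurationError(
                    f"stage {name!r} is not available in file-driven mode"
                )
            stages[name] = False
        opts["stages"] = stages
        inp = opts["inputs"]
        for key in ("betas", "pheno", "clock"):
            if key not in inp:
                raise ConfigurationError(f"inputs mode requires {key!r} path")
            if not Path(inp[key]).exists():
                raise ConfigurationError(f"input file not found: {inp[key]}")
        if stages["enrichment"] and not ("peaks" in inp and "manifest" in inp):
            raise ConfigurationError(
                "enrichment stage requires 'peaks' and 'manifest' inputs"
            )
    return RunConfig(options=opts)


def run_all(config: RunConfig | dict | str | Path) -> dict:
    """Execute every enabled stage; write tables, a summary and a log.

    Returns the machine-readable summary (also written as
    ``summary.json``). Partial outputs are retained on stage failure; the
    raised error names the failing stage.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    opts = cfg.options
    outdir = Path(opts["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(int(opts["seed"]))
    child = {
        name: s
        for name, s in zip(
            ("clockgen", "manifest", "cohort", "dexpair", "peaks", "tss", "expr", "gmt", "perm"),
            ss.spawn(9),
        )
    }
    summary: dict = {"seed": int(opts["seed"]), "stages": {}}
    log: list[str] = [f"seed={opts['seed']}"]

    stage = "setup"
    try:
        if opts["inputs"] is None:
            sim_cfg = simulate.SimulationConfig(**(opts.get("simulate") or {}))
            toy = simulate.generate_toy_clock(sim_cfg, seed=child["clockgen"])
            manifest = simulate.generate_manifest(sim_cfg, seed=child["manifest"])
            matrix, pheno, cohort_truth = simulate.generate_cohort(
                toy, sim_cfg, seed=child["cohort"], manifest=manifest
            )
            clock_model = toy.model
            cohort_truth.save(outdir / "ground_truth_cohort.json")
        else:
            inp = opts["inputs"]
            matrix = io.read_beta_matrix(inp["betas"])
            pheno = io.read_phenotypes(inp["pheno"])
            clock_model = io.read_clock(inp["clock"])
            manifest = io.read_manifest(inp["manifest"]) if "manifest" in inp else None
            sim_cfg = None
            toy = None

        stage = "clock"
        pred = clock.predict_dnam_age(matrix, clock_model, pheno)
        pred.to_csv(outdir / "pred.tsv", sep="\t", float_format="%.6g")
        r = float(
            pd.Series(pred["dnam_age"]).corr(pd.to_numeric(pheno.frame["age"], errors="coerce"))
        )
        summary["stages"]["clock"] = {
            "n_samples": int(len(pred)),
            "r_dnam_age_vs_age": r,
            "mean_delta_age": float(pred["delta_age"].mean()),
            "sd_delta_age": float(pred["delta_age"].std(ddof=1)),
        }
        log.append(f"clock: r={r:.4f}")

        if opts["stages"]["association"]:
            stage = "association"
            fit = association.fit_delta_age_model(pred, pheno, opts["formula"])
            fit.table.to_csv(outdir / "assoc.tsv", sep="\t", float_format="%.6g")
            stress_term = next(
                (t for t in fit.terms if "stress" in t.lower()), fit.terms[-1]
            )
            summary["stages"]["association"] = {
                "formula": opts["formula"],
                "n": fit.n,
                "stress_term": stress_term,
                "beta_stress": fit.beta(stress_term),
                "se_stress": fit.se(stress_term),
                "p_stress": fit.p(stress_term),
            }
            log.append(f"association: beta({stress_term})={fit.beta(stress_term):.4f}")

        if opts["stages"]["dex"]:
            stage = "dex"
            if opts["inputs"] is not None:
                raise ConfigurationError("file-driven DEX stage not configured")
            dex_cfg = simulate.SimulationConfig(
                **{**(opts.get("simulate") or {}), "n_samples": sim_cfg.n_dex_pairs}
            )
            base_m, base_pheno, _ = simulate.generate_cohort(
                toy, dex_cfg, seed=child["dexpair"], manifest=None
            )
            base_clock = base_m.select_probes(clock_model.probe_ids)
            post_m, design, dex_truth = simulate.generate_dex_pair(
                base_clock, dex_cfg, seed=child["dexpair"]
            )
            dex_truth.save(outdir / "ground_truth_dex.json")
            both = pd.concat([base_clock.betas, post_m.betas])
            res = dex.paired_lrt(both, design, covariates=["gender", "age", "bmi", "status", "cd4"])
            res.to_csv(outdir / "dex.tsv", sep="\t", float_format="%.6g")
            n_sig, n_down, n_up = dex.direction_summary(res, opts["q_thresh"])
            pred_base = clock.predict_dnam_age(base_clock, clock_model)
            pred_post = clock.predict_dnam_age(post_m, clock_model)
            paired = dex.paired_t_dnam_age(pred_base, pred_post, design)
            summary["stages"]["dex"] = {
                "n_pairs": design.n_subjects,
                "n_probes": int(len(res)),
                "n_sig": n_sig,
                "n_down": n_down,
                "n_up": n_up,
                "frac_down": (n_down / n_sig) if n_sig else float("nan"),
                "paired_t": paired.t,
                "paired_t_df": paired.df,
                "paired_t_p": paired.p,
                "mean_dnam_age_baseline": paired.mean_baseline,
                "mean_dnam_age_post": paired.mean_post,
            }
            log.append(f"dex: {n_sig} significant ({n_down} down / {n_up} up)")

        if opts["stages"]["enrichment"]:
            stage = "enrichment"
            if opts["inputs"] is None:
                query = list(clock_model.probe_ids)
                peaks, peak_truth = simulate.generate_peaks(
                    manifest, sim_cfg, query_probes=query, seed=child["peaks"]
                )
                peak_truth.save(outdir / "ground_truth_peaks.json")
                io.write_bed(peaks, outdir / "peaks.bed")
            else:
                peaks = io.read_bed(opts["inputs"]["peaks"])
                query = list(clock_model.probe_ids)
            comp = enrichment.nested_background_compare(
                query,
                manifest.probes_on("21k"),
                manifest.probes_on("450k"),
                manifest,
                peaks,
                n_perm=int(opts["n_perm"]),
                seed=child["perm"],
                pad=int(opts["pad"]),
            )
            dist = enrichment.distance_to_nearest(query, manifest, peaks)
            dist.to_csv(outdir / "distance.tsv", sep="\t", float_format="%.6g")
            within_1kb = int((dist["distance_bp"].abs() <= 1000).sum())
            summary["stages"]["enrichment"] = {
                "vs_450k": comp.vs_outer.as_dict(),
                "vs_21k": comp.vs_inner.as_dict(),
                "rate_21k": comp.inner_rate,
                "rate_450k": comp.outer_rate,
                "p_21k_vs_450k": comp.inner_vs_outer_p,
                "n_within_1kb": within_1kb,
            }
            with open(outdir / "enrich.json", "w") as fh:
                json.dump(summary["stages"]["enrichment"], fh, indent=1)
            log.append(
                f"enrichment: observed={comp.vs_outer.observed} "
                f"null_mean={comp.vs_outer.null_mean:.1f} p={comp.vs_outer.p_perm:.4g}"
            )

        if opts["stages"]["expression"]:
            stage = "expression"
            if opts["inputs"] is not None:
                raise ConfigurationError("file-driven expression stage not configured")
            tss = simulate.generate_tss(
                manifest, sim_cfg, query_probes=clock_model.probe_ids, seed=child["tss"]
            )
            ann = enrichment.annotate_tss(
                clock_model.probe_ids, manifest, tss, max_dist=int(opts["tss_max_dist"])
            )
            # reuse DEX pairing from the dex stage config for expression subjects
            expr_cfg = simulate.SimulationConfig(
                **{**(opts.get("simulate") or {}), "n_samples": sim_cfg.n_dex_pairs}
            )
            base_m, _, _ = simulate.generate_cohort(
                toy, expr_cfg, seed=child["expr"], manifest=None
            )
            _, design, _ = simulate.generate_dex_pair(
                base_m.select_probes(clock_model.probe_ids), expr_cfg, seed=child["expr"]
            )
            expr, det, expr_truth = simulate.generate_expression(
                ann.links, design, expr_cfg, seed=child["expr"]
            )
            expr_truth.save(outdir / "ground_truth_expression.json")
            expressed = dex.filter_expressed(expr, det)
            res = dex.paired_lrt(expressed, design, covariates=["gender", "age", "bmi"])
            res.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
            n_sig, n_down, n_up = dex.direction_summary(res, opts["q_thresh"])
            regulated = [
                c.removeprefix("pr_") for c in res.index[res["q"] < opts["q_thresh"]]
            ]
            universe = [c.removeprefix("pr_") for c in expressed.columns]
            gmt = simulate.generate_gene_sets(
                universe, expr_cfg, regulated_genes=regulated, seed=child["gmt"]
            )
            ora = enrichment.ora_hypergeometric(
                regulated, universe, gmt, min_set=int(opts["ora_min_set"]),
                fdr_thresh=opts["q_thresh"],
            )
            ora.to_csv(outdir / "ora.tsv", sep="\t", float_format="%.6g")
            summary["stages"]["expression"] = {
                "n_linked_genes": len(ann.genes),
                "mean_tss_distance": ann.mean_distance,
                "n_expressed_probes": int(expressed.shape[1]),
                "n_sig": n_sig,
                "n_up": n_up,
                "n_down": n_down,
                "frac_up": (n_up / n_sig) if n_sig else float("nan"),
                "n_ora_sets_tested": int(len(ora)),
                "n_ora_significant": int(ora["significant"].sum()) if len(ora) else 0,
            }
            log.append(f"expression: {n_sig} significant ({n_up} up / {n_down} down)")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
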
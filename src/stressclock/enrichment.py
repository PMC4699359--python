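"""Co-localization of CpG sets with genomic intervals (GRE ChIP-seq peaks).

The core statistic counts query CpGs whose coordinate falls inside any
interval (point-in-interval on 0-based coordinates, half-open), and compares
the observed count against a permutation null built by repeatedly drawing
same-sized CpG sets without replacement from a background probe list (the
full 450K-style array, or the 21K subset the clock was trained from).
Distance profiles, TSS-proximity gene linkage, Fisher's exact test and
hypergeometric over-representation analysis round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import IntervalSet, ProbeManifest
from .errors import ValidationError

__all__ = [
    "count_overlap",
    "permutation_enrichment",
    "nested_background_compare",
    "distance_to_nearest",
    "annotate_tss",
    "fisher_exact_2x2",
    "ora_hypergeometric",
    "EnrichmentResult",
    "NestedComparison",
    "TssAnnotation",
]


def _probe_positions(query, manifest: ProbeManifest):
    """0-based CpG coordinates for probes; the single 1-based -> 0-based hop."""
    query = list(query)
    idx = manifest.frame.index
    missing = [p for p in query if p not in idx]
    if missing:
        raise ValidationError(f"probes absent from manifest: {missing[:5]}")
    sub = manifest.frame.loc[query]
    if sub["pos"].isna().any():
        bad = list(sub.index[sub["pos"].isna()])[:5]
        raise ValidationError(f"probes without coordinates: {bad}")
    return sub["chrom"].to_numpy(), sub["pos"].to_numpy(dtype=np.int64) - 1


def _membership(chroms, pos0, peaks: IntervalSet, pad: int = 0) -> np.ndarray:
    """Boolean: is each 0-based position inside any (padded) interval?"""
    merged = peaks.merged(pad)
    out = np.zeros(len(pos0), dtype=bool)
    for chrom in np.unique(chroms):
        entry = merged.get(chrom)
        if entry is None:
            continue
        starts, ends = entry
        mask = chroms == chrom
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.maximum(idx, 0)])
        out[mask] = inside
    return out


def count_overlap(query, manifest: ProbeManifest, peaks: IntervalSet, pad: int = 0) -> int:
    """Number of query CpGs inside any interval, padded by ``pad`` bp.

    A CpG at 0-based position ``x`` counts when ``start - pad <= x < end + pad``
    for some interval on its chromosome.
    """
    chroms, pos0 = _probe_positions(query, manifest)
    return int(_membership(chroms, pos0, peaks, pad).sum())


@dataclass
class EnrichmentResult:
    """Observed overlap vs. a permutation null of same-sized random CpG sets."""

    observed: int
    n_query: int
    null_mean: float
    null_sd: float
    null_min: int
    null_max: int
    n_perm: int
    p_perm: float

    @property
    def observed_pct(self) -> float:
        return 100.0 * self.observed / self.n_query

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_query": self.n_query,
            "observed_pct": self.observed_pct,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_min": self.null_min,
            "null_max": self.null_max,
            "n_perm": self.n_perm,
            "p_perm": self.p_perm,
        }


def _null_counts(member: np.ndarray, k: int, n_perm: int, rng) -> np.ndarray:
    n_bg = len(member)
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        take = rng.choice(n_bg, size=k, replace=False)
        counts[i] = member[take].sum()
    return counts


def permutation_enrichment(
    query,
    background,
    manifest: ProbeManifest,
    peaks: IntervalSet,
    n_perm: int = 1000,
    seed=None,
    pad: int = 0,
) -> EnrichmentResult:
    """Permutation test for CpG-interval co-localization (upper tail).

    Draws ``n_perm`` sets of size ``len(query)`` uniformly without
    replacement from ``background``; the null is their overlap counts and

        p_perm = (1 + #{null >= observed}) / (n_perm + 1)

    (add-one estimator, so the smallest reportable p is 1/(n_perm+1) — a
    bound matching "p < 1/n_perm"-style reporting). The query need not be a
    subset of the background; a warning flags stray probes.
    """
    query = list(query)
    background = list(background)
    if len(background) < len(query):
        raise ValidationError(
            f"background ({len(background)}) smaller than query ({len(query)})"
        )
    bg_index = set(background)
    stray = [p for p in query if p not in bg_index]
    if stray:
        warnings.warn(
            f"{len(stray)} query probe(s) not in background, e.g. {stray[:3]}",
            stacklevel=2,
        )
    observed = count_overlap(query, manifest, peaks, pad)
    chroms, pos0 = _probe_positions(background, manifest)
    member = _membership(chroms, pos0, peaks, pad)
    rng = np.random.default_rng(seed)
    null = _null_counts(member, len(query), n_perm, rng)
    p_perm = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed=observed,
        n_query=len(query),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        null_min=int(null.min()),
        null_max=int(null.max()),
        n_perm=n_perm,
        p_perm=p_perm,
    )


@dataclass
class NestedComparison:
    """Enrichment of one CpG set against two nested backgrounds.

    ``vs_outer`` / ``vs_inner``: the set's overlap against permutations from
    the outer (e.g. 450K) and inner (e.g. 21K) backgrounds.
    ``inner_vs_outer_p``: permutation p for the inner background's own
    overlap rate (scaled to the query size) against the outer null — the
    "is the training background itself enriched?" comparison.
    """

    vs_outer: EnrichmentResult
    vs_inner: EnrichmentResult
    inner_rate: float
    outer_rate: float
    inner_vs_outer_p: float


def nested_background_compare(
    set_a,
    bg_inner,
    bg_outer,
    manifest: ProbeManifest,
    peaks: IntervalSet,
    n_perm: int = 1000,
    seed=None,
    pad: int = 0,
) -> NestedComparison:
    """Evaluate a CpG set against an inner and an outer background at once.

    Enables the three-way comparison pattern (clock vs. full array, clock
    vs. training background, training background vs. full array) through one
    interface. Child seeds are derived deterministically from ``seed``.
    """
    set_a = list(set_a)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_outer, seed_inner = ss.spawn(2)
    vs_outer = permutation_enrichment(
        set_a, bg_outer, manifest, peaks, n_perm=n_perm, seed=seed_outer, pad=pad
    )
    vs_inner = permutation_enrichment(
        set_a, bg_inner, manifest, peaks, n_perm=n_perm, seed=seed_inner, pad=pad
    )
    inner_count = count_overlap(bg_inner, manifest, peaks, pad)
    outer_count = count_overlap(bg_outer, manifest, peaks, pad)
    inner_rate = inner_count / len(list(bg_inner))
    outer_rate = outer_count / len(list(bg_outer))
    # the inner background's rate projected onto a query-sized set, against
    # the outer null
    projected = inner_rate * len(set_a)
    rng = np.random.default_rng(ss.spawn(1)[0])
    chroms, pos0 = _probe_positions(list(bg_outer), manifest)
    member = _membership(chroms, pos0, peaks, pad)
    null = _null_counts(member, len(set_a), n_perm, rng)
    inner_vs_outer_p = (1 + int((null >= projected).sum())) / (n_perm + 1)
    return NestedComparison(
        vs_outer=vs_outer,
        vs_inner=vs_inner,
        inner_rate=inner_rate,
        outer_rate=outer_rate,
        inner_vs_outer_p=inner_vs_outer_p,
    )


def distance_to_nearest(query, manifest: ProbeManifest, peaks: IntervalSet) -> pd.DataFrame:
    """Signed distance from each CpG to its nearest interval edge.

    0 inside an interval; positive when the CpG lies right of (after) the
    nearest interval, negative when left of it; NaN when the CpG's
    chromosome carries no interval. Distances to the last covered base
    (``end - 1``) on the right, to ``start`` on the left.
    """
    chroms, pos0 = _probe_positions(query, manifest)
    merged = peaks.merged(0)
    dist = np.full(len(pos0), np.nan)
    for chrom in np.unique(chroms):
        entry = merged.get(chrom)
        if entry is None:
            continue
        starts, ends = entry
        mask = chroms == chrom
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.maximum(idx, 0)])
        # gap to interval on the left of the CpG (CpG right of it): positive
        left_gap = np.where(idx >= 0, p - (ends[np.maximum(idx, 0)] - 1), np.inf)
        # gap to interval on the right of the CpG: negative sign
        nxt = idx + 1
        right_gap = np.where(
            nxt < len(starts), p - starts[np.minimum(nxt, len(starts) - 1)], -np.inf
        )
        d = np.where(np.abs(left_gap) <= np.abs(right_gap), left_gap, right_gap)
        d = np.where(inside, 0.0, d)
        dist[mask] = d
    return pd.DataFrame(
        {"distance_bp": dist}, index=pd.Index(list(query), name="probe_id")
    )


@dataclass
class TssAnnotation:
    links: pd.DataFrame  # probe_id, gene, distance_bp (absolute)
    genes: list
    mean_distance: float
    sd_distance: float
    min_distance: float
    max_distance: float


def annotate_tss(
    query, manifest: ProbeManifest, tss_table: pd.DataFrame, max_dist: int = 1500
) -> TssAnnotation:
    """Link CpGs to genes whose TSS lies within ``max_dist`` bp.

    ``tss_table`` needs columns ``gene``, ``chrom``, ``tss_pos`` (1-based).
    Every gene within range is linked (a CpG may link several genes and vice
    versa). Distance statistics are over absolute linked distances.
    """
    query = list(query)
    sub = manifest.frame.loc[query]
    links = []
    for chrom, genes in tss_table.groupby("chrom"):
        probes = sub[sub["chrom"] == chrom]
        if probes.empty:
            continue
        tss_pos = genes["tss_pos"].to_numpy(dtype=np.int64)
        for pid, pos in probes["pos"].items():
            d = np.abs(int(pos) - tss_pos)
            hit = d <= max_dist
            for g, dd in zip(genes["gene"].to_numpy()[hit], d[hit]):
                links.append((pid, g, int(dd)))
    frame = pd.DataFrame(links, columns=["probe_id", "gene", "distance_bp"])
    if frame.empty:
        return TssAnnotation(frame, [], float("nan"), float("nan"), float("nan"), float("nan"))
    d = frame["distance_bp"].to_numpy(dtype=float)
    return TssAnnotation(
        links=frame,
        genes=sorted(frame["gene"].unique()),
        mean_distance=float(d.mean()),
        sd_distance=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        min_distance=float(d.min()),
        max_distance=float(d.max()),
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` — the conditional maximum-likelihood odds
    ratio and the exact p (two-sided: sum of table probabilities <= the
    observed table's probability; 'greater'/'less' also available).
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if table.sum() == 0:
        raise ValidationError("all-zero 2x2 table")
    _, p = stats.fisher_exact(table, alternative=alternative)
    or_res = stats.contingency.odds_ratio(table, kind="conditional")
    return float(or_res.statistic), float(p)


def ora_hypergeometric(
    query_genes,
    universe_genes,
    gene_sets: dict,
    min_set: int = 5,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis against gene sets.

    Each set is restricted to the universe; sets with fewer than ``min_set``
    universe members are skipped. Upper-tail p = P(overlap >= observed)
    under drawing ``len(query)`` genes from the universe; BH-FDR across
    tested sets. Query genes outside the universe are dropped with a
    warning.
    """
    universe = list(dict.fromkeys(universe_genes))
    if not universe:
        raise ValidationError("empty gene universe")
    uset = set(universe)
    query = list(dict.fromkeys(query_genes))
    stray = [g for g in query if g not in uset]
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe dropped, e.g. {stray[:3]}",
            stacklevel=2,
        )
        query = [g for g in query if g in uset]
    qset = set(query)
    big_m, big_n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        in_univ = [g for g in dict.fromkeys(members) if g in uset]
        if len(in_univ) < min_set:
            continue
        k = len(qset.intersection(in_univ))
        p = float(stats.hypergeom.sf(k - 1, big_m, len(in_univ), big_n))
        expected = big_n * len(in_univ) / big_m
        rows.append((name, len(in_univ), k, expected, k / expected if expected else np.nan, p))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "expected", "ratio", "p"]
    ).set_index("set")
    if len(out):
        from .dex import bh_fdr

        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_thresh
        out = out.sort_values("p")
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
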
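"""Cross-call-set comparison, discovery saturation, and SV burden near loci.

Population-scale long-read cohorts discover structural variants faster than
short-read cohorts but saturate: as more genomes are sequenced, the number of
new common variants per genome falls toward zero while rare variants keep
accumulating roughly linearly.  This module quantifies that behaviour with
down-sampling curves and a binomial detection model for extrapolation, and
counts SV burden near anchor loci (GWAS lead SNVs, disease genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, VariantCallSet, allele_frequencies

__all__ = [
    "MergeReport",
    "SaturationCurve",
    "merge_callsets",
    "saturation_curve",
    "extrapolate_saturation",
    "locus_burden",
]


@dataclass
class MergeReport:
    """Pairing of two call sets: shared and technology-unique counts per type."""

    pairs: list[tuple[str, str]]
    shared_count: dict
    unique_a: dict
    unique_b: dict

    def summary(self) -> pd.DataFrame:
        types = sorted(
            set(self.shared_count) | set(self.unique_a) | set(self.unique_b)
        )
        return pd.DataFrame(
            {
                "vtype": types,
                "shared": [self.shared_count.get(t, 0) for t in types],
                "unique_a": [self.unique_a.get(t, 0) for t in types],
                "unique_b": [self.unique_b.get(t, 0) for t in types],
            }
        )


def merge_callsets(
    a: VariantCallSet,
    b: VariantCallSet,
    pos_tol_bp: int = 500,
    min_size_ratio: float = 0.7,
) -> MergeReport:
    """Pair records across two call sets by type, start proximity and size.

    Two records pair iff they share chrom and vtype, their starts differ by
    at most ``pos_tol_bp`` (inclusive), and min(len)/max(len) >=
    ``min_size_ratio``.  Matching is greedy by nearest start difference, each
    record pairing at most once.
    """
    pairs: list[tuple[str, str]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    groups_a: dict[tuple[str, str], list[int]] = {}
    groups_b: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(a.records):
        groups_a.setdefault((r.chrom, r.vtype), []).append(i)
    for j, r in enumerate(b.records):
        groups_b.setdefault((r.chrom, r.vtype), []).append(j)
    for key, ia in groups_a.items():
        ib = groups_b.get(key, [])
        cand: list[tuple[int, int, str, str, int, int]] = []
        for i in ia:
            ra = a.records[i]
            for j in ib:
                rb = b.records[j]
                d = abs(ra.start - rb.start)
                if d > pos_tol_bp:
                    continue
                la, lb = max(ra.length, 1), max(rb.length, 1)
                if min(la, lb) / max(la, lb) < min_size_ratio:
                    continue
                # stable greedy order: distance, then ids
                cand.append((d, 0, ra.id, rb.id, i, j))
        for d, _, ida, idb, i, j in sorted(cand):
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((ida, idb))
    shared: dict[str, int] = {}
    ua: dict[str, int] = {}
    ub: dict[str, int] = {}
    for i, r in enumerate(a.records):
        (shared if i in used_a else ua).setdefault(r.vtype, 0)
        if i in used_a:
            shared[r.vtype] = shared.get(r.vtype, 0) + 1
        else:
            ua[r.vtype] = ua.get(r.vtype, 0) + 1
    for j, r in enumerate(b.records):
        if j not in used_b:
            ub[r.vtype] = ub.get(r.vtype, 0) + 1
    return MergeReport(pairs=pairs, shared_count=shared, unique_a=ua, unique_b=ub)


@dataclass
class SaturationCurve:
    """Mean cumulative-discovery curve per AF stratum.

    ``curves`` maps stratum label -> array of mean distinct-variant counts at
    n = 1..N genomes; ``saturation_n`` maps stratum -> genome count at which
    the marginal discovery rate stays below the threshold (None if never);
    ``marginal_rates`` maps stratum -> new variants per genome at the end of
    the curve.
    """

    curves: dict
    saturation_n: dict
    marginal_rates: dict
    af_bins: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, curve in self.curves.items():
            for n, c in enumerate(curve, start=1):
                rows.append({"stratum": label, "n_genomes": n, "mean_distinct": c})
        return pd.DataFrame(rows)


def _stratum_labels(af_bins: list[tuple[float, float]]) -> list[str]:
    return [f"af_{lo:g}_{hi:g}" for lo, hi in af_bins]


def saturation_curve(
    callset: VariantCallSet,
    af_bins: list[tuple[float, float]] | None = None,
    n_orders: int = 100,
    seed: int = 0,
    rate_threshold: float = 0.5,
    lookahead: int = 20,
) -> SaturationCurve:
    """Down-sampling discovery curve, stratified by allele frequency.

    For each of ``n_orders`` random genome orderings, accumulate the number
    of distinct variants carried (dosage >= 1) by at least one sampled
    genome; report the mean curve per AF stratum.  ``saturation_n`` is the
    smallest n after which the mean marginal gain stays below
    ``rate_threshold`` new variants/genome over a ``lookahead``-genome
    window.  AF bins are half-open ``(lo, hi]`` over (0, 0.5].
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    if af_bins is None:
        af_bins = [(0.0, 0.5)]
    rng = np.random.default_rng(seed)
    carrier = callset.genotypes >= 1  # samples x variants
    af = allele_frequencies(callset)["maf"].to_numpy()
    labels = _stratum_labels(af_bins)
    masks = [(af > lo) & (af <= hi) for lo, hi in af_bins]
    n = callset.n_samples
    sums = {lab: np.zeros(n) for lab in labels}
    for _ in range(n_orders):
        order = rng.permutation(n)
        seen = np.zeros(callset.n_variants, dtype=bool)
        cum = np.empty((n, callset.n_variants), dtype=bool)
        for k, s in enumerate(order):
            seen = seen | carrier[s]
            cum[k] = seen
        for lab, m in zip(labels, masks):
            sums[lab] += cum[:, m].sum(axis=1)
    curves = {lab: sums[lab] / n_orders for lab in labels}
    saturation_n: dict[str, int | None] = {}
    marginal: dict[str, float] = {}
    for lab, curve in curves.items():
        gains = np.diff(curve, prepend=0.0)
        marginal[lab] = float(gains[-1]) if len(gains) else 0.0
        sat = None
        for i in range(1, n + 1):
            hi = min(i + lookahead, n)
            if hi <= i:
                break
            window = gains[i:hi]
            if len(window) and np.all(window < rate_threshold):
                sat = i
                break
        saturation_n[lab] = sat
    return SaturationCurve(
        curves=curves, saturation_n=saturation_n, marginal_rates=marginal,
        af_bins=af_bins,
    )


def extrapolate_saturation(
    af_values: np.ndarray,
    target_af: float,
    undiscovered_max: float = 0.01,
    n_max: int = 1_000_000,
) -> int:
    """Project the cohort size needed to saturate variants above ``target_af``.

    Under a binomial detection model a variant of allele frequency f is seen
    in n diploid genomes with probability 1 - (1-f)^(2n).  Integrating over
    the empirical AF density above ``target_af``, returns the smallest n at
    which the expected undiscovered fraction drops below
    ``undiscovered_max``.  Returns 0 when no variant exceeds ``target_af``.
    """
    af = np.asarray(af_values, dtype=float)
    af = af[af > target_af]
    if af.size == 0:
        return 0
    if np.any((af <= 0) | (af > 1)):
        raise ValueError("allele frequencies must lie in (0, 1]")
    log_miss = 2.0 * np.log1p(-np.minimum(af, 1 - 1e-12))
    lo, hi = 1, 1
    def undiscovered(n: int) -> float:
        return float(np.mean(np.exp(n * log_miss)))
    while undiscovered(hi) >= undiscovered_max:
        hi *= 2
        if hi > n_max:
            raise ValueError("projection exceeds n_max; degenerate AF density")
    while lo < hi:
        mid = (lo + hi) // 2
        if undiscovered(mid) < undiscovered_max:
            hi = mid
        else:
            lo = mid + 1
    return lo


def locus_burden(
    callset: VariantCallSet,
    anchors: pd.DataFrame,
    distances: list[int],
    rare_maf: float = 0.01,
    lr_specific: dict | None = None,
) -> pd.DataFrame:
    """Count SVs whose interval lies within each distance of each anchor.

    ``anchors`` needs columns chrom/start/end (points: start == end) and
    ``name``.  An SV counts toward an anchor at distance d iff the gap
    between the SV interval and the anchor interval is <= d (0 when they
    overlap; boundary inclusive).  Counts are stratified by MAF class
    (rare < ``rare_maf``) and, when ``lr_specific`` (variant_id -> bool) is
    given, by long-read specificity.
    """
    aft = allele_frequencies(callset)
    maf = aft["maf"]
    rows = []
    for _, anc in anchors.iterrows():
        gaps = {}
        for rec in callset.records:
            g = rec.gap_to(str(anc["chrom"]), int(anc["start"]), int(anc["end"]))
            if g is not None:
                gaps[rec.id] = g
        for d in distances:
            hits = [vid for vid, g in gaps.items() if g <= d]
            n_rare = sum(1 for v in hits if maf.get(v, np.nan) < rare_maf)
            row = {
                "anchor": anc["name"],
                "distance": d,
                "n_svs": len(hits),
                "n_rare": n_rare,
                "n_common": len(hits) - n_rare,
            }
            if lr_specific is not None:
                row["n_lr_specific"] = sum(
                    1 for v in hits if lr_specific.get(v, False)
                )
            rows.append(row)
    return pd.DataFrame(rows)
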
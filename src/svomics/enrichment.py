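"""Fisher-exact enrichment machinery and the rare-SV prioritization cascade.

The unit of analysis throughout is the (feature, sample) pair: a pair is
*exposed* when the sample carries a rare SV near the feature, and an
*outcome* when the pair is a molecular outlier.  Odds ratios use the sample
(cross-product) estimator with a Haldane +0.5 correction when any cell is
zero; p-values come from the two-sided exact hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .variants import VariantCallSet, allele_frequencies

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "rare_sv_outlier_enrichment",
    "cross_omic_concordance",
    "prioritize_rare_svs",
]


@dataclass
class EnrichmentResult:
    """2x2 enrichment: a = exposed&outcome, b = exposed&not, c = unexposed&outcome,
    d = unexposed&not."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    stratum: dict = field(default_factory=dict)
    haldane: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def to_dict(self) -> dict:
        return {
            **self.stratum,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        }


def fisher_enrichment(
    exposure: np.ndarray, outcome: np.ndarray, stratum: dict | None = None
) -> EnrichmentResult:
    """Fisher's exact enrichment of ``outcome`` given ``exposure``.

    OR is the cross-product (a*d)/(b*c), Haldane +0.5 applied to all cells
    iff any cell is zero; the 95% CI is exp(log OR +/- 1.96 * sqrt(sum of
    reciprocal cells)); p is two-sided exact.
    """
    e = np.asarray(exposure, dtype=bool)
    o = np.asarray(outcome, dtype=bool)
    if e.shape != o.shape or e.size == 0:
        raise ValueError("exposure and outcome must be equal-length, nonempty")
    a = int(np.sum(e & o))
    b = int(np.sum(e & ~o))
    c = int(np.sum(~e & o))
    d = int(np.sum(~e & ~o))
    return fisher_from_table(a, b, c, d, stratum)


def fisher_from_table(
    a: int, b: int, c: int, d: int, stratum: dict | None = None
) -> EnrichmentResult:
    cells = np.array([a, b, c, d], dtype=float)
    haldane = bool((cells == 0).any())
    if haldane:
        cells = cells + 0.5
    orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = float(np.sqrt(np.sum(1.0 / cells)))
    ci_low = float(np.exp(np.log(orr) - 1.96 * se))
    ci_high = float(np.exp(np.log(orr) + 1.96 * se))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        a=a, b=b, c=c, d=d, odds_ratio=float(orr),
        ci_low=ci_low, ci_high=ci_high, p=float(p),
        stratum=stratum or {}, haldane=haldane,
    )


def _exposure_matrix(
    sv_callset: VariantCallSet,
    feature_anchors: pd.DataFrame,
    window_bp: int,
    variant_mask: np.ndarray,
) -> np.ndarray:
    """samples x features boolean: sample carries a masked SV within window of
    the feature anchor interval (gap-based, inclusive)."""
    trees: dict[str, IntervalTree] = {}
    for j in np.flatnonzero(variant_mask):
        rec = sv_callset.records[j]
        a, b = rec.interval
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            a - window_bp, b + window_bp + 1, j
        )
    carrier = sv_callset.genotypes >= 1
    out = np.zeros((sv_callset.n_samples, len(feature_anchors)), dtype=bool)
    for f, (_, row) in enumerate(feature_anchors.iterrows()):
        tree = trees.get(str(row["chrom"]))
        if tree is None:
            continue
        hits = tree.overlap(int(row["start"]), int(row["end"]) + 1)
        if not hits:
            continue
        cols = [h.data for h in hits]
        out[:, f] = carrier[:, cols].any(axis=1)
    return out


def rare_sv_outlier_enrichment(
    sv_callset: VariantCallSet,
    zmatrix: pd.DataFrame,
    feature_anchors: pd.DataFrame,
    window_bp: int = 100_000,
    af_thresholds: tuple = (0.01,),
    directions: tuple = ("both", "under", "over"),
    z_thresholds: tuple = (2.0,),
    singleton: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment of molecular outliers among carriers of nearby rare SVs.

    ``zmatrix`` is samples x features (z-scores); ``feature_anchors`` is
    indexed by feature with chrom/start/end.  A (feature, sample) pair is
    exposed iff the sample carries (dosage >= 1) a rare SV (AF < threshold,
    or allele count 1 when ``singleton``) whose interval is within
    ``window_bp`` of the feature anchor; the outcome is outlier status in
    the stated direction at the stated z threshold.  One result per
    (af_threshold | singleton) x direction x z_threshold stratum.
    """
    feats = [f for f in zmatrix.columns if f in feature_anchors.index]
    anchors = feature_anchors.loc[feats]
    sv_sub = sv_callset.subset_samples(list(zmatrix.index))
    aft = allele_frequencies(sv_sub)
    Z = zmatrix[feats].to_numpy(dtype=float)
    results: list[EnrichmentResult] = []
    af_specs: list[tuple[str, np.ndarray]] = []
    if singleton:
        af_specs.append(("singleton", (aft["allele_count"] == 1).to_numpy()))
    for thr in af_thresholds:
        af_specs.append((f"af<{thr:g}", (aft["af"] < thr).to_numpy()))
    for label, mask in af_specs:
        if mask.sum() == 0:
            warnings.warn(f"stratum {label}: no qualifying SVs", RuntimeWarning)
            continue
        exposed = _exposure_matrix(sv_sub, anchors, window_bp, mask).ravel()
        if exposed.sum() == 0:
            warnings.warn(f"stratum {label}: no exposed pairs", RuntimeWarning)
            continue
        for z_thr in z_thresholds:
            for direction in directions:
                if direction == "both":
                    outcome = np.abs(Z) >= z_thr
                elif direction == "under":
                    outcome = Z <= -z_thr
                elif direction == "over":
                    outcome = Z >= z_thr
                else:
                    raise ValueError(f"unknown direction {direction!r}")
                results.append(
                    fisher_enrichment(
                        exposed,
                        outcome.ravel(),
                        stratum={
                            "af": label,
                            "direction": direction,
                            "z_threshold": z_thr,
                            "window_bp": window_bp,
                        },
                    )
                )
    return results


def cross_omic_concordance(
    zA: pd.DataFrame,
    zB: pd.DataFrame,
    thresholds: tuple = (-2.0, 2.0),
    feature_map: pd.DataFrame | None = None,
) -> list[EnrichmentResult]:
    """Concordance of outliers between two omes on linked features.

    ``feature_map`` has columns feature_a/feature_b (defaults to identity on
    shared columns).  Signed thresholds: a negative x means outlier iff
    z < x (under); positive means z > x (over).  One result per (discovery
    threshold, outcome threshold) pair over shared samples.
    """
    if feature_map is None:
        shared = [f for f in zA.columns if f in zB.columns]
        feature_map = pd.DataFrame({"feature_a": shared, "feature_b": shared})
    if len(feature_map) == 0:
        raise ValueError("empty feature map")
    samples = [s for s in zA.index if s in zB.index]
    A = zA.loc[samples, feature_map["feature_a"]].to_numpy(dtype=float)
    B = zB.loc[samples, feature_map["feature_b"]].to_numpy(dtype=float)
    out = []
    for ta in thresholds:
        flag_a = (A < ta) if ta < 0 else (A > ta)
        for tb in thresholds:
            flag_b = (B < tb) if tb < 0 else (B > tb)
            out.append(
                fisher_enrichment(
                    flag_a.ravel(), flag_b.ravel(),
                    stratum={"threshold_a": ta, "threshold_b": tb},
                )
            )
    return out


def prioritize_rare_svs(
    sv_gene_pairs: pd.DataFrame,
    outlier_z: dict,
    posterior_scores: dict | None = None,
    risk_genes: set | None = None,
    posterior_min: float = 0.6,
    z_min: float = 2.0,
) -> pd.DataFrame:
    """Triage rare SV-gene pairs through the prioritization cascade.

    ``sv_gene_pairs`` has columns sv_id/feature/sample; ``outlier_z`` maps
    (sample, feature) -> z; ``posterior_scores`` maps (sv_id, feature) -> a
    functional posterior in [0,1] (externally computed, e.g. by a
    hierarchical outlier-integration model).  Tiers:

    1. rare SV near gene (every input pair);
    2. tier 1 + the gene is an outlier (|z| > ``z_min``) in the carrier;
    3. tier 2 + the gene is in the risk-gene list;
    4. tier 1 + posterior score > ``posterior_min`` (strict);
    5. tier 4 + risk gene.
    """
    posterior_scores = posterior_scores or {}
    risk_genes = risk_genes or set()
    for v in posterior_scores.values():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"posterior score {v} outside [0,1]")
    rows = []
    for _, p in sv_gene_pairs.iterrows():
        z = outlier_z.get((p["sample"], p["feature"]))
        score = posterior_scores.get((p["sv_id"], p["feature"]))
        is_outlier = z is not None and abs(z) > z_min
        is_risk = p["feature"] in risk_genes
        high_score = score is not None and score > posterior_min
        rows.append(
            {
                "sv_id": p["sv_id"],
                "feature": p["feature"],
                "sample": p["sample"],
                "z": z,
                "score": score,
                "tier1_rare_sv": True,
                "tier2_outlier": is_outlier,
                "tier3_outlier_risk_gene": is_outlier and is_risk,
                "tier4_high_posterior": high_score,
                "tier5_posterior_risk_gene": high_score and is_risk,
            }
        )
    return pd.DataFrame(rows)
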
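"""Enumeration-based GWAS-QTL colocalization from p-value summary statistics.

Given summary statistics for two traits over a shared locus, each variant's
evidence of association is summarized by a Wakefield approximate Bayes
factor (ABF) computed from its p-value, allele frequency and sample size
under a normal effect-size prior.  Enumerating causal configurations with
at most one causal variant per trait yields posterior probabilities for
five hypotheses:

    H0 — no association with either trait
    H1 / H2 — association with trait 1 / trait 2 only
    H3 — both traits, two distinct causal variants
    H4 — both traits, one shared causal variant

All sums run in log space (log-sum-exp) for numerical stability.

Loci are defined by 100 kb windows around variants passing per-dataset
significance thresholds; overlapping windows merge, and only loci holding
both a GWAS and a QTL signal are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ColocResult",
    "define_loci",
    "abf_from_pvalue",
    "ColocModel",
    "coloc_abf",
    "coloc_report",
]

REQUIRED_COLS = ("variant_id", "chrom", "pos", "p", "maf", "n")


def _check_stats(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(REQUIRED_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{name} summary statistics missing columns {missing}")
    return df


def define_loci(
    gwas: pd.DataFrame,
    qtl: pd.DataFrame,
    window_bp: int = 100_000,
    p_gwas: float = 1e-5,
    p_qtl: float = 1e-4,
) -> pd.DataFrame:
    """Merged windows around significant variants containing both signals.

    Windows of +/- ``window_bp`` are placed around every GWAS variant with
    p < ``p_gwas`` and every QTL variant with p < ``p_qtl``; overlapping
    windows merge; a merged locus is retained iff it contains at least one
    qualifying variant from each dataset.
    """
    _check_stats(gwas, "gwas")
    _check_stats(qtl, "qtl")
    hits = []
    for df, thr, src in ((gwas, p_gwas, "gwas"), (qtl, p_qtl, "qtl")):
        sig = df.loc[df["p"] < thr]
        for _, r in sig.iterrows():
            hits.append((str(r["chrom"]), int(r["pos"]) - window_bp,
                         int(r["pos"]) + window_bp, src))
    if not hits:
        return pd.DataFrame(columns=["chrom", "start", "end", "has_gwas",
                                     "has_qtl"])
    hits.sort()
    loci = []
    cur = None
    for chrom, start, end, src in hits:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(src)
        else:
            if cur is not None:
                loci.append(cur)
            cur = [chrom, start, end, {src}]
    loci.append(cur)
    out = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e,
             "has_gwas": "gwas" in srcs, "has_qtl": "qtl" in srcs}
            for c, s, e, srcs in loci
        ]
    )
    return out.loc[out["has_gwas"] & out["has_qtl"]].reset_index(drop=True)


def abf_from_pvalue(
    p: float,
    maf: float,
    n: float,
    trait_type: str = "quant",
    prior_sd: float | None = None,
    case_fraction: float | None = None,
) -> float:
    """Log Wakefield approximate Bayes factor from a two-sided p-value.

    The sampling variance of the effect estimate is approximated by
    V = 1 / (2 N f (1-f)) for a quantitative trait (divided additionally by
    s(1-s) for case-control with case fraction s); with shrinkage
    r = W / (W + V) for prior effect variance W = prior_sd^2,

        log ABF = 0.5 log(1 - r) + 0.5 z^2 r.

    p = 0 inputs are clipped to the smallest positive float.  Default prior
    SD: 0.15 (quant), 0.2 (cc).
    """
    if prior_sd is None:
        prior_sd = 0.15 if trait_type == "quant" else 0.2
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"MAF {maf} outside (0, 0.5]")
    if n <= 0:
        raise ValueError("N must be positive")
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    z = stats.norm.isf(p / 2.0)  # sign-free: only z^2 enters
    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if trait_type == "cc":
        s = case_fraction if case_fraction is not None else 0.5
        V /= s * (1.0 - s)
    W = prior_sd**2
    r = W / (W + V)
    return float(0.5 * np.log1p(-r) + 0.5 * z * z * r)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    chrom: str
    start: int
    end: int
    n_variants: int
    pp: dict  # {"H0": .., ..., "H4": ..}
    top_gwas: str
    top_qtl: str
    sv_in_credible_set: bool = False
    sv_is_lead: bool = False
    feature: str = ""

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]

    def summary(self) -> str:
        lines = [
            f"colocalization locus {self.chrom}:{self.start}-{self.end} "
            f"({self.n_variants} shared variants)",
            "-" * 50,
        ]
        for h in ("H0", "H1", "H2", "H3", "H4"):
            lines.append(f"PP.{h}: {self.pp[h]:.4f}")
        lines.append(f"top GWAS variant: {self.top_gwas}")
        lines.append(f"top QTL variant:  {self.top_qtl}")
        return "\n".join(lines)


class ColocModel:
    """Pairwise colocalization of one GWAS and one QTL locus.

    Variants are matched across datasets by (chrom, pos), falling back to
    variant id.  ``fit`` enumerates causal configurations and returns a
    :class:`ColocResult`.
    """

    def __init__(
        self,
        gwas_locus: pd.DataFrame,
        qtl_locus: pd.DataFrame,
        gwas_type: str = "cc",
        qtl_type: str = "quant",
        gwas_prior_sd: float | None = None,
        qtl_prior_sd: float | None = None,
    ):
        g = _check_stats(gwas_locus, "gwas").copy()
        q = _check_stats(qtl_locus, "qtl").copy()
        for df, name in ((g, "gwas"), (q, "qtl")):
            if df["variant_id"].duplicated().any():
                raise ValueError(f"duplicated variant ids in {name} locus")
        g["_key"] = list(zip(g["chrom"].astype(str), g["pos"].astype(int)))
        q["_key"] = list(zip(q["chrom"].astype(str), q["pos"].astype(int)))
        merged = g.merge(q, on="_key", suffixes=("_g", "_q"))
        if len(merged) < 2:
            merged = g.merge(q, left_on="variant_id", right_on="variant_id",
                             suffixes=("_g", "_q"))
            if len(merged) < 2:
                raise ValueError("fewer than 2 shared variants in locus")
            merged["variant_id_g"] = merged["variant_id"]
            merged["variant_id_q"] = merged["variant_id"]
        self.merged = merged
        self.gwas_type = gwas_type
        self.qtl_type = qtl_type
        self.gwas_prior_sd = gwas_prior_sd
        self.qtl_prior_sd = qtl_prior_sd

    def fit(self, p1: float = 1e-4, p2: float = 1e-4,
            p12: float = 1e-5) -> ColocResult:
        m = self.merged
        l1 = np.array([
            abf_from_pvalue(r["p_g"], r["maf_g"], r["n_g"], self.gwas_type,
                            self.gwas_prior_sd,
                            r.get("case_fraction_g"))
            for _, r in m.iterrows()
        ])
        l2 = np.array([
            abf_from_pvalue(r["p_q"], r["maf_q"], r["n_q"], self.qtl_type,
                            self.qtl_prior_sd,
                            r.get("case_fraction_q"))
            for _, r in m.iterrows()
        ])
        pp = _posteriors_from_log_abfs(l1, l2, p1, p2, p12)
        chrom = str(m["chrom_g"].iloc[0])
        return ColocResult(
            chrom=chrom,
            start=int(m["pos_g"].min()),
            end=int(m["pos_g"].max()),
            n_variants=len(m),
            pp=pp,
            top_gwas=str(m.loc[m["p_g"].idxmin(), "variant_id_g"]),
            top_qtl=str(m.loc[m["p_q"].idxmin(), "variant_id_q"]),
        )


def _posteriors_from_log_abfs(l1, l2, p1, p2, p12) -> dict:
    """Enumerate H0..H4 in log space from per-variant log ABFs."""
    lp1, lp2, lp12 = np.log(p1), np.log(p2), np.log(p12)
    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lh0 = 0.0
    lh1 = lp1 + lsum1
    lh2 = lp2 + lsum2
    # H3: distinct causal pairs = sum_i sum_{j != i} ABF1_i ABF2_j
    lsum12 = logsumexp(l1 + l2)
    lpairs_all = lsum1 + lsum2
    # subtract the diagonal in log space
    if lsum12 >= lpairs_all:  # degenerate: diagonal carries all mass
        lh3 = -np.inf
    else:
        lh3 = lp1 + lp2 + lpairs_all + np.log1p(-np.exp(lsum12 - lpairs_all))
    lh4 = lp12 + lsum12
    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    denom = logsumexp(logs)
    pp = np.exp(logs - denom)
    return {f"H{i}": float(v) for i, v in enumerate(pp)}


def coloc_abf(
    gwas_locus: pd.DataFrame,
    qtl_locus: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    **kwargs,
) -> ColocResult:
    """Functional wrapper: ``ColocModel(gwas, qtl, **kwargs).fit(p1, p2, p12)``."""
    return ColocModel(gwas_locus, qtl_locus, **kwargs).fit(p1=p1, p2=p2, p12=p12)


def coloc_report(
    results: list[ColocResult],
    credible_sets: dict | None = None,
    pp4_min: float = 0.5,
    gene_of_feature: dict | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Retain colocalizations with PP.H4 strictly above ``pp4_min``; derive
    risk genes.

    ``credible_sets`` maps feature -> list of CredibleSet with ``vclass``
    labels, used to flag whether an SV sits in (or leads) the colocalized
    QTL's credible set.  The risk-gene list contains genes whose maximum
    PP.H4 across contexts exceeds 0.5.
    """
    rows = []
    gene_best: dict[str, float] = {}
    for res in results:
        gene = (gene_of_feature or {}).get(res.feature, res.feature)
        gene_best[gene] = max(gene_best.get(gene, 0.0), res.pp_h4)
        if res.pp_h4 <= pp4_min:
            continue
        sv_in_cs = sv_lead = False
        if credible_sets and res.feature in credible_sets:
            for cs in credible_sets[res.feature]:
                if cs.vclass in ("SV-led", "contains-SV"):
                    sv_in_cs = True
                if cs.vclass == "SV-led":
                    sv_lead = True
        rows.append(
            {
                "feature": res.feature,
                "chrom": res.chrom, "start": res.start, "end": res.end,
                "n_variants": res.n_variants,
                **{f"pp_{h.lower()}": res.pp[h] for h in
                   ("H0", "H1", "H2", "H3", "H4")},
                "top_gwas": res.top_gwas, "top_qtl": res.top_qtl,
                "sv_in_credible_set": sv_in_cs, "sv_is_lead": sv_lead,
            }
        )
    risk_genes = sorted(g for g, v in gene_best.items() if v > 0.5)
    return pd.DataFrame(rows), risk_genes
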
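"""CpG segmentation into correlated clusters and methylation outlier calling.

Neighbouring CpGs on the same regulatory element are highly correlated
across individuals, so per-CpG beta values (fraction methylated, in [0,1])
are aggregated into segments before outlier testing.  Segmentation here is a
greedy left-to-right scan: a CpG joins the open segment while it stays
correlated with the segment's running mean profile and close enough in
genomic distance.

Variable segments are selected with a mean-variance trend on the transform
``t = logit(1 - |0.5 - beta|)``, which symmetrizes hyper- and
hypomethylation: betas near 0 or 1 map to t near 0, high-variance segments
with mean betas near 0.5 map to large positive t.

Outliers require both an absolute z-score >= 2.5 and an absolute beta delta
(sample beta minus cohort median) >= 0.25 — the delta gate stops
low-variance segments from producing large-z but biologically negligible
calls.  Samples above the Tukey fence of total outlier counts are removed
as global outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MethylationSegmentSet",
    "MethylationOutlier",
    "segment_cpgs",
    "segment_betas",
    "variability_filter",
    "methylation_outliers",
    "symmetric_logit",
]

_EPS = 1e-3


@dataclass(frozen=True)
class MethylationOutlier:
    sample: str
    segment: str
    z: float
    delta: float
    direction: str  # "hyper" | "hypo"


@dataclass
class MethylationSegmentSet:
    """Segments (chrom, start, end, member CpG indices) plus segment betas."""

    segments: pd.DataFrame  # segment_id, chrom, start, end, cpg_indices
    betas: pd.DataFrame | None = None  # samples x segments
    variable: pd.Series | None = None


def segment_cpgs(
    beta_matrix: pd.DataFrame,
    positions: pd.DataFrame,
    r_min: float = 0.5,
    max_gap_bp: int = 1000,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Greedy correlation-based segmentation of CpGs.

    ``beta_matrix`` is samples x CpGs (columns align with ``positions``
    rows, which carry chrom/pos).  Scanning each chromosome left to right, a
    CpG joins the open segment iff its Pearson correlation across samples
    with the segment's running mean profile is >= ``r_min`` (inclusive) and
    its gap to the previous CpG is <= ``max_gap_bp``; otherwise a new
    segment opens.  Singletons are allowed.
    """
    if list(beta_matrix.columns) != list(positions.index):
        raise ValueError("beta columns must align with positions index")
    segs = []
    chroms = positions["chrom"].to_numpy()
    pos = positions["pos"].to_numpy()
    B = beta_matrix.to_numpy(dtype=float)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError(f"unsorted CpG positions on {chrom}")
        if autosomes_only and str(chrom).lstrip("chr") in ("X", "Y", "M", "MT"):
            continue
        current: list[int] = []
        profile: np.ndarray | None = None
        for i in idx:
            join = False
            if current:
                gap = pos[i] - pos[current[-1]]
                if gap <= max_gap_bp:
                    r = _safe_corr(profile, B[:, i])
                    join = r is not None and r >= r_min
            if join:
                current.append(i)
                profile = B[:, current].mean(axis=1)
            else:
                if current:
                    segs.append((chrom, current))
                current = [i]
                profile = B[:, i].copy()
        if current:
            segs.append((chrom, current))
    rows = []
    for k, (chrom, members) in enumerate(segs):
        rows.append(
            {
                "segment_id": f"seg_{k}",
                "chrom": chrom,
                "start": int(pos[members[0]]),
                "end": int(pos[members[-1]]),
                "cpg_indices": tuple(int(m) for m in members),
            }
        )
    return pd.DataFrame(rows)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float | None:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return None
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def segment_betas(
    beta_matrix: pd.DataFrame, segments: pd.DataFrame
) -> pd.DataFrame:
    """Per sample per segment, mean beta over member CpGs (ignoring NaNs).

    Cells where every member CpG is missing stay NaN and are flagged.
    """
    B = beta_matrix.to_numpy(dtype=float)
    out = np.empty((B.shape[0], len(segments)))
    for j, members in enumerate(segments["cpg_indices"]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, j] = np.nanmean(B[:, list(members)], axis=1)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        warnings.warn(f"{n_missing} all-missing segment cells", RuntimeWarning)
    return pd.DataFrame(
        out, index=beta_matrix.index, columns=segments["segment_id"].to_list()
    )


def symmetric_logit(beta: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """t = logit(1 - |0.5 - beta|), clamped away from the logit(1) singularity.

    Maps beta near 0 or 1 to t near 0 and beta = 0.5 to the clamp ceiling;
    symmetric under beta -> 1 - beta.
    """
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    arg = np.clip(1.0 - np.abs(0.5 - b), eps, 1 - eps)
    return np.log(arg / (1.0 - arg))


def variability_filter(
    seg_betas: pd.DataFrame,
    sd_resid: float = 3.0,
    min_per_bin: int = 15,
) -> pd.Series:
    """Flag variable segments via a CV^2 mean-variance trend on transformed betas.

    Each beta is transformed with :func:`symmetric_logit`; per segment the
    CV^2 of the transform across samples is compared against a local trend
    of log CV^2 on log mean, estimated as a running median over quantile
    bins of the mean.  The bin medians track the smooth mean-dependence of
    the transform's sensitivity while staying immune to the variable tail
    (a minority within any bin cannot move its median).  Segments whose
    MAD-standardized residual exceeds ``sd_resid`` are variable.
    """
    if seg_betas.shape[1] < 50:
        raise ValueError("need >= 50 segments to fit the variability trend")
    T = symmetric_logit(seg_betas.to_numpy(dtype=float))
    mean = np.nanmean(T, axis=0)
    var = np.nanvar(T, axis=0, ddof=1)
    mean = np.maximum(mean, _EPS)
    cv2 = np.maximum(var / mean**2, 1e-12)
    lx = np.log(mean)
    ly = np.log(cv2)
    if np.ptp(lx) < 1e-10:
        raise ValueError("degenerate trend: constant segment means")
    p = len(lx)
    nbins = int(np.clip(p // min_per_bin, 4, 30))
    edges = np.quantile(lx, np.linspace(0.0, 1.0, nbins + 1))
    edges[-1] += 1e-9
    which = np.clip(np.searchsorted(edges, lx, side="right") - 1, 0,
                    nbins - 1)
    bx, by = [], []
    for b in range(nbins):
        m = which == b
        if m.sum() >= 2:
            bx.append(float(np.median(lx[m])))
            by.append(float(np.median(ly[m])))
    if len(bx) < 2:
        raise ValueError("degenerate trend: too few populated bins")
    order = np.argsort(bx)
    trend = np.interp(lx, np.asarray(bx)[order], np.asarray(by)[order])
    resid = ly - trend
    mad = np.median(np.abs(resid - np.median(resid)))
    sd = 1.4826 * mad if mad > 0 else resid.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate trend: zero residual spread")
    flags = pd.Series(resid / sd > sd_resid, index=seg_betas.columns,
                      name="variable")
    return flags


def methylation_outliers(
    seg_betas: pd.DataFrame,
    variable_flags: pd.Series | None = None,
    z_min: float = 2.5,
    delta_min: float = 0.25,
    fence_k: float = 1.5,
) -> tuple[list[MethylationOutlier], list[str]]:
    """Call methylation outliers on variable segments; drop global-outlier samples.

    Per segment, z-scores come from scaled/centred betas and delta is the
    sample beta minus the cohort median.  A call requires |z| >= ``z_min``
    AND |delta| >= ``delta_min``.  Samples whose total call count exceeds
    the upper Tukey fence (Q3 + ``fence_k``*IQR) are removed and the calls
    re-emitted without them.
    """
    if variable_flags is not None:
        cols = variable_flags.index[variable_flags]
        seg_betas = seg_betas[cols]
    def _call(betas: pd.DataFrame) -> list[MethylationOutlier]:
        X = betas.to_numpy(dtype=float)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=0)
        sd[sd == 0] = np.inf
        z = (X - mu) / sd
        med = np.nanmedian(X, axis=0)
        delta = X - med
        hit = (np.abs(z) >= z_min) & (np.abs(delta) >= delta_min)
        hit &= ~np.isnan(X)
        calls = []
        samples = list(betas.index)
        segs = list(betas.columns)
        for i, j in zip(*np.nonzero(hit)):
            calls.append(
                MethylationOutlier(
                    sample=samples[i],
                    segment=segs[j],
                    z=float(z[i, j]),
                    delta=float(delta[i, j]),
                    direction="hyper" if delta[i, j] > 0 else "hypo",
                )
            )
        return calls

    calls = _call(seg_betas)
    counts = pd.Series(0, index=seg_betas.index, dtype=int)
    for c in calls:
        counts[c.sample] += 1
    removed: list[str] = []
    if len(counts) >= 8:
        q1, q3 = np.percentile(counts, [25, 75])
        fence = q3 + fence_k * (q3 - q1)
        if q3 == 0 and q1 == 0:
            # most samples have no calls: the fence is degenerate at 0 and
            # would remove every sample with a single call
            warnings.warn("degenerate outlier-count distribution: "
                          "global-sample removal skipped", RuntimeWarning)
        else:
            removed = list(counts.index[counts > fence])
    if removed:
        calls = _call(seg_betas.drop(index=removed))
    return calls, removed
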
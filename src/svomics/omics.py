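"""Expression/protein normalization, rank-normalization and outlier calling.

Two normalization tracks are kept deliberately separate, mirroring how
molecular-outlier and QTL analyses treat the same matrix differently:

* QTL track: raw counts -> library-size + log normalization -> per-feature
  inverse-normal rank transform (the response for cis-QTL linear models).
* Outlier track: log-normalized values -> per-feature z-scores -> removal of
  hidden structure (top principal components) and covariates (age, sex) by
  per-feature OLS residualization -> re-standardized z-scores, from which
  under/over outliers are called at an absolute z threshold.

Samples with an excessive burden of outlier features are "global outliers"
(technical failures, sample swaps) and are removed with a Tukey fence on the
per-sample outlier count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OmicsMatrix",
    "OutlierCall",
    "pseudobulk_aggregate",
    "filter_features",
    "log_normalize",
    "rank_normalize",
    "outlier_zscores",
    "remove_global_outlier_samples",
    "call_outliers",
]

_STATES = ("raw_counts", "log_norm", "rank_norm", "zscore")
_ALLOWED = {
    "raw_counts": {"log_norm"},
    "log_norm": {"rank_norm", "zscore"},
    "rank_norm": set(),
    "zscore": set(),
}


@dataclass
class OmicsMatrix:
    """Samples x features matrix with genomic feature anchors and a state tag.

    ``values`` is a DataFrame indexed by sample id with feature-id columns.
    ``anchors`` maps feature id -> (chrom, start, end); features without an
    anchor are allowed but skipped by position-aware analyses.  The state
    tag tracks normalization and only advances along
    raw_counts -> log_norm -> {rank_norm | zscore}.
    """

    values: pd.DataFrame
    anchors: pd.DataFrame | None = None
    state: str = "raw_counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.anchors is not None:
            missing = {"chrom", "start", "end"} - set(self.anchors.columns)
            if missing:
                raise ValueError(f"anchors missing columns {missing}")
        if self.state != "raw_counts" and self.values.isna().any().any():
            raise ValueError(f"NaNs not allowed in {self.state} matrix")

    def _advance(self, new_state: str, values: pd.DataFrame, **meta) -> "OmicsMatrix":
        if new_state not in _ALLOWED[self.state]:
            raise ValueError(f"cannot go from {self.state} to {new_state}")
        return OmicsMatrix(
            values=values,
            anchors=self.anchors,
            state=new_state,
            meta={**self.meta, **meta},
        )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def anchor_of(self, feature: str):
        if self.anchors is None or feature not in self.anchors.index:
            return None
        row = self.anchors.loc[feature]
        return str(row["chrom"]), int(row["start"]), int(row["end"])


@dataclass(frozen=True)
class OutlierCall:
    sample: str
    feature: str
    z: float
    direction: str  # "under" | "over"
    ome: str = ""


def pseudobulk_aggregate(
    cell_counts: pd.DataFrame,
    barcode_to_sample: pd.Series,
    anchors: pd.DataFrame | None = None,
) -> OmicsMatrix:
    """Sum single-cell counts into per-sample pseudobulk profiles.

    ``cell_counts`` is barcodes x genes.  Barcodes absent from the mapping
    are counted and excluded.  When a sample id appears with multiple
    time-point suffixes (``sample::tp``), only the time point with the
    largest library size is retained under the bare sample id.
    """
    mapped = cell_counts.index.isin(barcode_to_sample.index)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        warnings.warn(f"{n_unmapped} unmapped barcodes excluded", RuntimeWarning)
    cc = cell_counts.loc[mapped]
    groups = barcode_to_sample.loc[cc.index]
    bulk = cc.groupby(groups.to_numpy()).sum()
    # collapse time points: keep the largest library per base sample
    base = pd.Series(
        [s.split("::")[0] for s in bulk.index], index=bulk.index, name="base"
    )
    libsize = bulk.sum(axis=1)
    keep_rows = libsize.groupby(base).idxmax()
    bulk = bulk.loc[keep_rows.to_numpy()]
    bulk.index = keep_rows.index
    bulk = bulk.sort_index()
    return OmicsMatrix(values=bulk, anchors=anchors, state="raw_counts",
                       meta={"n_unmapped_barcodes": n_unmapped})


def filter_features(
    matrix: OmicsMatrix,
    kind: str,
    min_frac: float = 0.2,
    min_count: float = 1.0,
    cv2_sd: float = 0.0,
) -> list[str]:
    """Feature retention list for expression counts or protein intensities.

    Expression: a gene is dropped only when it fails BOTH the CV^2 trend
    test (log CV^2 residual above the trend fitted on log mean by more than
    ``cv2_sd`` standard deviations) and the minimum-expression rule
    (detected at >= ``min_count`` in >= ``min_frac`` of samples).  Protein
    intensities use the minimum-expression rule alone.
    """
    X = matrix.values.to_numpy(dtype=float)
    feats = np.asarray(matrix.features)
    detected = (X >= min_count).mean(axis=0) >= min_frac
    if kind != "expression":
        return list(feats[detected])
    if X.shape[1] < 50:
        raise ValueError("need >= 50 features to fit the CV^2 trend")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    ok = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(ok, var / np.maximum(mean, 1e-300) ** 2, np.nan)
    usable = ok & (cv2 > 0)
    if usable.sum() < 50 or np.ptp(np.log(mean[usable])) < 1e-8:
        raise ValueError("degenerate mean spread: CV^2 trend cannot be fit")
    lx = np.log(mean[usable])
    ly = np.log(cv2[usable])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate CV^2 trend: zero residual spread")
    above = np.zeros(len(feats), dtype=bool)
    above[np.flatnonzero(usable)] = resid > cv2_sd * sd
    keep = above | detected
    return list(feats[keep])


def log_normalize(matrix: OmicsMatrix, scale: float = 1e4) -> OmicsMatrix:
    """Library-size normalize counts and log-transform: log1p(scale * c / lib)."""
    if matrix.state != "raw_counts":
        raise ValueError("log_normalize expects raw counts")
    X = matrix.values.to_numpy(dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    out = pd.DataFrame(
        np.log1p(scale * X / lib), index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return matrix._advance("log_norm", out, log_scale=scale)


def rank_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Per-feature inverse-normal transform: Phi^{-1}((rank - 0.5) / n).

    Ties get the average rank.  Constant features map to all-zero columns
    and are flagged in the output metadata.
    """
    if matrix.state != "log_norm":
        raise ValueError("rank_normalize expects log-normalized input")
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[0]
    ranks = stats.rankdata(X, axis=0, method="average")
    out = stats.norm.ppf((ranks - 0.5) / n)
    const = np.ptp(X, axis=0) == 0
    out[:, const] = 0.0
    flagged = list(np.asarray(matrix.features)[const])
    if flagged:
        warnings.warn(f"{len(flagged)} constant features rank to zero", RuntimeWarning)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix._advance(
        "rank_norm", df, rank_offset="(r-0.5)/n", constant_features=flagged
    )


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def outlier_zscores(
    matrix: OmicsMatrix,
    covariates: pd.DataFrame | None = None,
    n_pcs: int = 0,
    covariate_cols: tuple = ("age", "sex"),
) -> OmicsMatrix:
    """Covariate/PC-residualized, re-standardized z-scores per feature.

    Features are scaled/centred, the top ``n_pcs`` principal components of
    the standardized matrix are computed by SVD, every feature is
    residualized by OLS against those PCs plus the named covariates, and the
    residuals are re-standardized.
    """
    if matrix.state != "log_norm":
        raise ValueError("outlier_zscores expects log-normalized input")
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n_pcs >= n:
        raise ValueError(f"n_pcs={n_pcs} must be < n_samples={n}")
    Z = _standardize(X)
    design = [np.ones((n, 1))]
    if n_pcs > 0:
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        design.append(U[:, :n_pcs] * s[:n_pcs])
    if covariates is not None:
        cov = covariates.loc[matrix.values.index]
        for c in covariate_cols:
            if c in cov.columns:
                design.append(cov[c].to_numpy(dtype=float).reshape(-1, 1))
    D = np.hstack(design)
    beta, *_ = np.linalg.lstsq(D, Z, rcond=None)
    resid = Z - D @ beta
    out = _standardize(resid)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix._advance("zscore", df, n_pcs=n_pcs)


def remove_global_outlier_samples(
    zmatrix: OmicsMatrix,
    abs_z: float = 3.0,
    fence_k: float = 1.5,
) -> tuple[OmicsMatrix, list[str]]:
    """Drop samples with an excessive burden of |z| > ``abs_z`` features.

    The per-sample count of outlier features is compared with the upper
    Tukey fence Q3 + ``fence_k`` * IQR; samples above the fence are removed.
    With fewer than 8 samples the fence is unstable: a warning is issued and
    nothing is removed.
    """
    if zmatrix.state != "zscore":
        raise ValueError("expects z-score matrix")
    Z = zmatrix.values.to_numpy(dtype=float)
    if Z.shape[1] == 0:
        return zmatrix, []
    counts = (np.abs(Z) > abs_z).sum(axis=1)
    if Z.shape[0] < 8:
        warnings.warn("fewer than 8 samples: global-outlier fence skipped",
                      RuntimeWarning)
        return zmatrix, []
    q1, q3 = np.percentile(counts, [25, 75])
    fence = q3 + fence_k * (q3 - q1)
    if q1 == 0 and q3 == 0:
        warnings.warn("degenerate outlier-count distribution: "
                      "global-outlier removal skipped", RuntimeWarning)
        return zmatrix, []
    drop = counts > fence
    removed = list(np.asarray(zmatrix.samples)[drop])
    kept = zmatrix.values.loc[~drop]
    out = OmicsMatrix(values=kept, anchors=zmatrix.anchors, state="zscore",
                      meta={**zmatrix.meta, "global_outliers_removed": removed})
    return out, removed


def call_outliers(
    zmatrix: OmicsMatrix, abs_z: float = 2.0, ome: str = ""
) -> list[OutlierCall]:
    """One call per (sample, feature) with \\|z\\| >= ``abs_z``."""
    if zmatrix.state != "zscore":
        raise ValueError("expects z-score matrix")
    Z = zmatrix.values.to_numpy(dtype=float)
    rows, cols = np.nonzero(np.abs(Z) >= abs_z)
    samples = zmatrix.samples
    feats = zmatrix.features
    return [
        OutlierCall(
            sample=samples[i],
            feature=feats[j],
            z=float(Z[i, j]),
            direction="over" if Z[i, j] > 0 else "under",
            ome=ome,
        )
        for i, j in zip(rows, cols)
    ]
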
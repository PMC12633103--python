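"""Synthetic cohort generator with known ground truth.

Generates every input the downstream stages consume — diploid SV/SNV
genotype matrices with a rare-skewed MAF spectrum and configurable SV-SNV
LD, molecular phenotypes with planted cis effects, hidden factors and
covariate structure, segmented CpG methylation, and GWAS summary statistics
under shared- or distinct-causal-variant configurations — so that every
analysis stage can be tested against planted truth without any external
data.

Key modelling choices
---------------------
* Genotypes are binomial dosages at a per-variant MAF drawn from a
  beta-shaped density over [maf_min, 0.5]; roughly 40% of SVs fall below
  1% MAF at the defaults, matching a long-read cohort's rare-heavy
  spectrum.
* SV lengths come from a mixture with mobile-element modes near 300 bp
  (Alu), 2.5 kb (SVA) and 6 kb (LINE-1) over a long-tailed background.
* LD between an SV and its tagging SNV is induced by copy-then-perturb:
  the tag starts as a copy of the SV dosages and entries are resampled
  until the realized r^2 matches the target.  Tag SNVs therefore share the
  SV's MAF unless overridden; an explicit override is checked against the
  comonotone feasibility bound r^2 <= p1(1-p2) / (p2(1-p1)).
* Phenotypes follow the additive model
  ``y = sum beta * std(g) + covariates + factor loadings . factors + noise``
  with the residual variance chosen so the total phenotype variance equals
  ``noise_sd^2`` (default 1): planted betas are then directly the
  standardized effect sizes the QTL mapper estimates.  Expression is
  mapped to counts through a log-normal latent mean and a Poisson draw.
* Every planted effect is recorded exactly once in :class:`GroundTruth`.

The seed fully determines all output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import _exposure_matrix
from .omics import OmicsMatrix
from .variants import MISSING, VariantCallSet, VariantRecord, allele_frequencies

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "plant_rare_outliers",
    "simulate_methylation",
    "simulate_gwas_summary",
    "ld_feasibility_bound",
    "write_fixture_dir",
]


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    Cohort size defaults to 551 (the long-read cohort scale); ages are
    uniform over 55-90, sex is balanced, and diagnosis is categorical over
    healthy controls and disease groups.  ``noise_sd`` is the target total
    phenotype SD; planted effects, covariates and hidden factors carve
    their variance out of it.
    """

    n_samples: int = 551
    n_svs: int = 200
    n_snvs: int = 400
    maf_beta: tuple = (0.4, 1.5)  # beta density shape over [maf_min, 0.5]
    maf_min: float = 0.001
    ld_targets: list = field(default_factory=list)  # (sv_id, snv_id, r2)
    maf_overrides: dict = field(default_factory=dict)
    sv_length_modes: tuple = ((300, 0.45), (2500, 0.12), (6000, 0.08))
    sv_length_background: tuple = (50, 100_000)
    missing_rate: float = 0.02
    genome_size: int = 50_000_000
    chrom: str = "chr1"
    # phenotypes
    n_genes: int = 300
    n_proteins: int = 300
    qtl_effects: list = field(default_factory=list)  # (variant_id, feature_id, beta)
    rare_outlier_effects: list = field(default_factory=list)
    n_hidden_factors: int = 5
    factor_var_frac: float = 0.3
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.1, "sex": 0.1, "dx": 0.15}
    )
    noise_sd: float = 1.0
    expression_log_base_mean: float = 3.0
    # methylation
    n_segments: int = 120
    cpgs_per_segment: tuple = (3, 8)
    segment_latent_sd: float = 0.02       # flat (non-variable) segments
    frac_variable_segments: float = 0.15
    variable_latent_sd: float = 0.08
    inter_segment_gap_bp: tuple = (5_000, 20_000)
    cpg_noise_sd: float = 0.03
    mqtl_effects: list = field(default_factory=list)  # (variant_id, segment, delta/allele)
    methylation_outliers: list = field(default_factory=list)  # (sample_idx, segment, delta)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        for sv, snv, r2 in self.ld_targets:
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"target r2 {r2} outside [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class GroundTruth:
    """Planted truth: causal pairs, outlier carriers, segments, GWAS causals."""

    qtl_effects: list = field(default_factory=list)
    rare_outlier_pairs: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    variable_segments: list = field(default_factory=list)
    segment_means: list = field(default_factory=list)
    methylation_outliers: list = field(default_factory=list)
    mqtl_effects: list = field(default_factory=list)
    gwas_causal: dict = field(default_factory=dict)
    clip_count: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=lambda o: list(o)
                          if isinstance(o, (tuple, np.ndarray)) else o, indent=1)


def ld_feasibility_bound(maf1: float, maf2: float) -> float:
    """Maximum attainable r^2 between two biallelic variants with the given
    minor allele frequencies (comonotone haplotype coupling)."""
    p1, p2 = sorted((maf1, maf2))
    return (p1 * (1 - p2)) / ((1 - p1) * p2)


def _draw_mafs(rng, n, cfg: SimulationConfig) -> np.ndarray:
    a, b = cfg.maf_beta
    return cfg.maf_min + rng.beta(a, b, size=n) * (0.5 - cfg.maf_min)


def _draw_sv_lengths(rng, n, cfg: SimulationConfig) -> np.ndarray:
    modes = cfg.sv_length_modes
    w_bg = 1.0 - sum(w for _, w in modes)
    probs = [w for _, w in modes] + [w_bg]
    comp = rng.choice(len(probs), size=n, p=probs)
    out = np.empty(n)
    for k, (mode, _) in enumerate(modes):
        m = comp == k
        out[m] = np.exp(rng.normal(np.log(mode), 0.08, size=m.sum()))
    bg = comp == len(modes)
    lo, hi = cfg.sv_length_background
    out[bg] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=bg.sum()))
    return np.maximum(out.astype(int), 50)


def _realized_r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _ld_tag(rng, g_sv: np.ndarray, maf_snv: float, target_r2: float,
            tol: float = 0.02, max_rounds: int = 200) -> np.ndarray:
    """Copy-then-perturb: start from the SV dosages, resample entries until
    the realized r^2 matches the target."""
    n = len(g_sv)
    if target_r2 >= 1.0 - 1e-12:
        return g_sv.copy()
    g = g_sv.copy()
    q = 1.0 - np.sqrt(max(target_r2, 0.0))
    k0 = int(round(q * n))
    if k0 > 0:
        idx = rng.choice(n, size=k0, replace=False)
        g[idx] = rng.binomial(2, maf_snv, size=k0)
    if target_r2 <= 0.0:
        return g
    step = max(1, n // 100)
    for _ in range(max_rounds):
        r2 = _realized_r2(g_sv, g)
        if np.isnan(r2) or abs(r2 - target_r2) <= tol:
            break
        idx = rng.choice(n, size=step, replace=False)
        if r2 > target_r2:
            g[idx] = rng.binomial(2, maf_snv, size=step)
        else:
            g[idx] = g_sv[idx]
    return g


def simulate_genotypes(
    config: SimulationConfig, self_check: bool = True
) -> tuple[VariantCallSet, VariantCallSet]:
    """Generate SV and SNV call sets with the configured MAF spectrum and LD.

    Raises on infeasible LD targets (target r^2 above the bound implied by
    the two variants' MAFs).  With ``self_check`` the realized MAFs and LD
    targets are verified within tolerance (3 binomial SEs on the mean AF;
    +/-0.1 per LD target at n >= 500) before returning.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sv_ids = [f"sv_{i+1}" for i in range(config.n_svs)]
    snv_ids = [f"snv_{i+1}" for i in range(config.n_snvs)]
    ld_by_snv = {snv: (sv, r2) for sv, snv, r2 in config.ld_targets}
    for sv, snv, r2 in config.ld_targets:
        if sv not in sv_ids or snv not in snv_ids:
            raise ValueError(f"LD target references unknown variant {sv}/{snv}")

    sv_mafs = _draw_mafs(rng, config.n_svs, config)
    snv_mafs = _draw_mafs(rng, config.n_snvs, config)
    for vid, maf in config.maf_overrides.items():
        if vid in sv_ids:
            sv_mafs[sv_ids.index(vid)] = maf
        elif vid in snv_ids:
            snv_mafs[snv_ids.index(vid)] = maf
    # tag SNVs share the SV's MAF unless explicitly overridden
    for snv, (sv, r2) in ld_by_snv.items():
        j, i = snv_ids.index(snv), sv_ids.index(sv)
        if snv in config.maf_overrides:
            bound = ld_feasibility_bound(sv_mafs[i], snv_mafs[j])
            if r2 > bound + 1e-9:
                raise ValueError(
                    f"LD target r2={r2} between {sv} (MAF {sv_mafs[i]:.3f}) and "
                    f"{snv} (MAF {snv_mafs[j]:.3f}) exceeds the feasibility "
                    f"bound {bound:.3f} implied by the two MAFs"
                )
        else:
            snv_mafs[j] = sv_mafs[i]

    G_sv = rng.binomial(2, sv_mafs, size=(n, config.n_svs)).astype(np.int8)
    G_snv = np.empty((n, config.n_snvs), dtype=np.int8)
    for j, snv in enumerate(snv_ids):
        if snv in ld_by_snv:
            sv, r2 = ld_by_snv[snv]
            G_snv[:, j] = _ld_tag(rng, G_sv[:, sv_ids.index(sv)].astype(np.int8),
                                  snv_mafs[j], r2)
        else:
            G_snv[:, j] = rng.binomial(2, snv_mafs[j], size=n)

    # genomic layout: SVs spread along the chromosome; tag SNVs placed nearby
    sv_starts = np.sort(rng.integers(1_000, config.genome_size,
                                     size=config.n_svs))
    lengths = _draw_sv_lengths(rng, config.n_svs, config)
    types = rng.choice(["DEL", "INS", "DUP", "INV"], size=config.n_svs,
                       p=[0.42, 0.45, 0.07, 0.06])
    sv_records = []
    for i, vid in enumerate(sv_ids):
        start = int(sv_starts[i])
        if types[i] == "INS":
            rec = VariantRecord(id=vid, chrom=config.chrom, start=start,
                                end=start, vtype="INS", length=int(lengths[i]))
        else:
            rec = VariantRecord(id=vid, chrom=config.chrom, start=start,
                                end=start + int(lengths[i]), vtype=types[i])
        sv_records.append(rec)
    snv_pos = {}
    for j, snv in enumerate(snv_ids):
        if snv in ld_by_snv:
            sv, _ = ld_by_snv[snv]
            anchor = sv_starts[sv_ids.index(sv)]
            snv_pos[snv] = int(anchor + rng.integers(-10_000, 10_000))
        else:
            snv_pos[snv] = int(rng.integers(1_000, config.genome_size))
    snv_records = [
        VariantRecord(id=snv, chrom=config.chrom, start=max(snv_pos[snv], 1),
                      end=max(snv_pos[snv], 1), vtype="SNV", length=1)
        for snv in snv_ids
    ]

    if config.missing_rate > 0:
        for G in (G_sv, G_snv):
            mask = rng.random(G.shape) < config.missing_rate
            # keep at least half the calls per variant
            G[mask] = MISSING

    svs = VariantCallSet(records=sv_records, genotypes=G_sv, sample_ids=[
        f"S{i+1:04d}" for i in range(n)])
    snvs = VariantCallSet(records=snv_records, genotypes=G_snv,
                          sample_ids=list(svs.sample_ids))
    if self_check:
        _self_check(svs, snvs, sv_mafs, snv_mafs, config)
    return svs, snvs


def _self_check(svs, snvs, sv_mafs, snv_mafs, config: SimulationConfig):
    n = config.n_samples
    for cs, drawn in ((svs, sv_mafs), (snvs, snv_mafs)):
        if cs.n_variants == 0:
            continue
        realized = allele_frequencies(cs)["af"].to_numpy()
        drawn_mean = float(np.mean(drawn))
        se = float(np.sqrt(np.mean(drawn * (1 - drawn)) / (2 * n * len(drawn))))
        if abs(np.nanmean(realized) - drawn_mean) > 4 * se + 1e-6:
            raise RuntimeError("self-check failed: realized MAF spectrum drifted")
    if n >= 500:
        for sv, snv, r2 in config.ld_targets:
            a = svs.column(sv).astype(float)
            b = snvs.column(snv).astype(float)
            ok = (a != MISSING) & (b != MISSING)
            realized = _realized_r2(a[ok], b[ok])
            if abs(realized - r2) > 0.1:
                raise RuntimeError(
                    f"self-check failed: LD target {sv}-{snv} r2={r2} "
                    f"realized {realized:.3f}"
                )


def _standardized_dosage(callset: VariantCallSet, vid: str) -> np.ndarray:
    g = callset.column(vid).astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g)
    g = np.where(np.isnan(g), mu, g)
    sd = g.std()
    if sd == 0:
        raise ValueError(f"planted effect on monomorphic variant {vid}")
    return (g - mu) / sd


def simulate_covariates(rng, n: int) -> pd.DataFrame:
    """Age ~ U(55, 90); sex ~ Bernoulli(0.5); diagnosis over HC/MCI/AD/PD."""
    return pd.DataFrame(
        {
            "age": rng.uniform(55, 90, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "dx": rng.choice(["HC", "MCI", "AD", "PD"], size=n,
                             p=[0.5, 0.2, 0.2, 0.1]),
        },
        index=[f"S{i+1:04d}" for i in range(n)],
    )


def simulate_phenotypes(
    genotypes: VariantCallSet,
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame, GroundTruth]:
    """Expression counts and protein log-abundances with planted cis effects.

    Every feature gets a genomic anchor on the simulated chromosome (QTL
    target features are anchored near their causal variant so they form cis
    pairs).  Returns (expression raw counts, protein log-abundance,
    covariates, ground truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_samples
    if n != config.n_samples:
        raise ValueError("genotype sample count does not match config")
    gene_ids = [f"gene_{i+1}" for i in range(config.n_genes)]
    prot_ids = [f"prot_{i+1}" for i in range(config.n_proteins)]
    all_feats = set(gene_ids) | set(prot_ids)
    for vid, fid, beta in config.qtl_effects:
        if fid not in all_feats:
            raise ValueError(f"planted effect references unknown feature {fid}")
        if vid not in genotypes.variant_ids:
            raise ValueError(f"planted effect references unknown variant {vid}")

    cov = simulate_covariates(rng, n)
    cov_std = pd.DataFrame(
        {
            "age": (cov["age"] - cov["age"].mean()) / cov["age"].std(),
            "sex": cov["sex"] - cov["sex"].mean(),
            "dx": (cov["dx"] != "HC").astype(float),
        }
    )
    cov_std["dx"] -= cov_std["dx"].mean()

    truth = GroundTruth()
    vmeta = {r.id: r for r in genotypes.records}

    def _latent(feature_ids: list[str]) -> np.ndarray:
        F = len(feature_ids)
        Y = np.zeros((n, F))
        explained = np.zeros(F)
        effects_by_feat: dict[str, list] = {}
        for vid, fid, beta in config.qtl_effects:
            if fid in feature_ids:
                effects_by_feat.setdefault(fid, []).append((vid, beta))
        for f, fid in enumerate(feature_ids):
            for vid, beta in effects_by_feat.get(fid, []):
                Y[:, f] += beta * _standardized_dosage(genotypes, vid)
                explained[f] += beta**2
                truth.qtl_effects.append(
                    {"variant_id": vid, "feature": fid, "beta": float(beta)}
                )
        # covariates, with per-feature random signs
        for cname, cbeta in config.covariate_effects.items():
            if cbeta == 0 or cname not in cov_std:
                continue
            signs = rng.choice([-1.0, 1.0], size=F)
            x = cov_std[cname].to_numpy()
            xs = x / (x.std() if x.std() > 0 else 1.0)
            Y += np.outer(xs, signs * cbeta)
            explained += cbeta**2
        # hidden factors with fixed per-feature variance fraction
        if config.n_hidden_factors > 0 and config.factor_var_frac > 0:
            factors = rng.normal(size=(n, config.n_hidden_factors))
            load = rng.normal(size=(config.n_hidden_factors, F))
            load /= np.linalg.norm(load, axis=0, keepdims=True)
            load *= np.sqrt(config.factor_var_frac)
            Y += factors @ load
            explained += config.factor_var_frac
        resid_var = np.maximum(config.noise_sd**2 - explained, 0.0)
        over = explained > config.noise_sd**2 + 1e-9
        if over.any() and config.noise_sd > 0:
            warnings.warn(
                f"{int(over.sum())} features exceed the variance budget; "
                "residual noise floored at 0", RuntimeWarning,
            )
        Y += rng.normal(size=(n, F)) * np.sqrt(resid_var)
        return Y

    expr_latent = _latent(gene_ids)
    prot_latent = _latent(prot_ids)

    # anchors: QTL features near their variant, the rest uniform
    anchor_pos: dict[str, int] = {}
    for vid, fid, beta in config.qtl_effects:
        rec = vmeta[vid]
        anchor_pos.setdefault(fid, rec.start + int(rng.integers(-50_000, 50_000)))
    for fid in gene_ids + prot_ids:
        anchor_pos.setdefault(fid, int(rng.integers(1_000, config.genome_size)))
    def _anchors(ids):
        return pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": [max(anchor_pos[f], 1) for f in ids],
                "end": [max(anchor_pos[f], 1) + 1_000 for f in ids],
            },
            index=ids,
        )

    base = rng.normal(config.expression_log_base_mean, 0.5, size=config.n_genes)
    lam = np.exp(base + 0.5 * expr_latent)
    counts = rng.poisson(lam)
    samples = list(genotypes.sample_ids)
    expression = OmicsMatrix(
        values=pd.DataFrame(counts, index=samples, columns=gene_ids),
        anchors=_anchors(gene_ids),
        state="raw_counts",
        meta={"latent": "log-normal + Poisson"},
    )
    protein = OmicsMatrix(
        values=pd.DataFrame(prot_latent, index=samples, columns=prot_ids),
        anchors=_anchors(prot_ids),
        state="log_norm",
        meta={"scale": "log-abundance"},
    )
    cov.index = samples
    return expression, protein, cov, truth


def plant_rare_outliers(
    genotypes: VariantCallSet,
    matrix: OmicsMatrix,
    target_or: float | None = None,
    pairs: list | None = None,
    window_bp: int = 100_000,
    af_rare: float = 0.01,
    z_threshold: float = 2.0,
    shift: float = 6.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, GroundTruth]:
    """Plant rare-SV outlier effects into a log-scale phenotype matrix.

    Two modes:

    * ``pairs`` — explicit (variant_id, feature, z_shift) effects: every
      carrier of the variant gets the shift (in feature-SD units) on the
      feature.
    * ``target_or`` — calibrated enrichment: among (feature, sample) pairs
      exposed to a rare SV (AF < ``af_rare``, interval within ``window_bp``
      of the feature anchor), a random subset is shifted so that the
      expected exposure-outlier odds ratio at ``z_threshold`` equals the
      target.  Raises when the requested OR is unreachable (would require
      outlier probability > 1).
    """
    rng = np.random.default_rng(seed)
    sub = genotypes.subset_samples(list(matrix.values.index))
    X = matrix.values.to_numpy(dtype=float).copy()
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    truth = GroundTruth()
    feats = list(matrix.values.columns)
    fpos = {f: j for j, f in enumerate(feats)}
    if pairs:
        for vid, fid, zshift in pairs:
            if fid not in fpos:
                raise ValueError(f"unknown feature {fid}")
            carriers = np.flatnonzero(sub.column(vid) >= 1)
            X[carriers, fpos[fid]] += zshift * sds[fpos[fid]]
            for c in carriers:
                truth.rare_outlier_pairs.append(
                    {"variant_id": vid, "feature": fid,
                     "sample": matrix.samples[c], "z_shift": float(zshift)}
                )
    if target_or is not None:
        from scipy.stats import norm
        p0 = 2.0 * norm.sf(z_threshold)
        if not np.isfinite(target_or) or target_or <= 0:
            raise ValueError(f"odds ratio {target_or} unreachable")
        odds1 = target_or * p0 / (1.0 - p0)
        p1 = odds1 / (1.0 + odds1)
        q = (p1 - p0) / (1.0 - p0)
        if q < -1e-12:
            raise ValueError("target odds ratio below 1 cannot be planted "
                             "by adding outliers")
        q = max(q, 0.0)
        aft = allele_frequencies(sub)
        rare = (aft["af"] < af_rare).to_numpy()
        anchors = matrix.anchors.loc[[f for f in feats
                                      if f in matrix.anchors.index]]
        exposed = _exposure_matrix(sub, anchors, window_bp, rare)
        if q > 0 and exposed.sum() == 0:
            raise ValueError(
                f"odds ratio {target_or} unreachable: no carrier of a rare "
                f"SV (AF < {af_rare}) lies within {window_bp} bp of any "
                "feature"
            )
        hit = exposed & (rng.random(exposed.shape) < q)
        signs = rng.choice([-1.0, 1.0], size=hit.shape)
        acols = [fpos[f] for f in anchors.index]
        for i, j in zip(*np.nonzero(hit)):
            col = acols[j]
            X[i, col] += signs[i, j] * shift * sds[col]
            truth.rare_outlier_pairs.append(
                {"feature": feats[col], "sample": matrix.samples[i],
                 "z_shift": float(signs[i, j] * shift)}
            )
    out = OmicsMatrix(
        values=pd.DataFrame(X, index=matrix.values.index,
                            columns=matrix.values.columns),
        anchors=matrix.anchors, state=matrix.state,
        meta={**matrix.meta, "planted_outliers": len(truth.rare_outlier_pairs)},
    )
    return out, truth


def simulate_methylation(
    config: SimulationConfig,
    genotypes: VariantCallSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-CpG beta matrix with correlated segments and planted outliers.

    CpGs within a true segment share a per-sample latent level (clipped to
    [0,1]) plus CpG-level noise; segments are separated by gaps larger than
    any within-segment spacing.  Planted mQTL effects shift the latent by
    genotype dosage; planted outliers shift one sample's latent by a
    configured delta.  Values pushed outside [0,1] are clipped and the clip
    count reported on the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_samples
    samples = [f"S{i+1:04d}" for i in range(n)]
    truth = GroundTruth()
    pos_cursor = 10_000
    cpg_pos: list[int] = []
    seg_members: list[list[int]] = []
    lo, hi = config.cpgs_per_segment
    for s in range(config.n_segments):
        k = int(rng.integers(lo, hi + 1))
        members = []
        for _ in range(k):
            members.append(len(cpg_pos))
            cpg_pos.append(pos_cursor)
            pos_cursor += int(rng.integers(20, 200))
        seg_members.append(members)
        truth.segments.append(tuple(members))
        glo, ghi = config.inter_segment_gap_bp
        pos_cursor += int(rng.integers(glo, ghi))
    n_cpgs = len(cpg_pos)

    seg_mean = np.empty(config.n_segments)
    comp = rng.choice(3, size=config.n_segments, p=[0.4, 0.2, 0.4])
    seg_mean[comp == 0] = rng.beta(2, 10, size=(comp == 0).sum())
    seg_mean[comp == 1] = rng.beta(8, 8, size=(comp == 1).sum())
    seg_mean[comp == 2] = rng.beta(10, 2, size=(comp == 2).sum())

    variable = rng.random(config.n_segments) < config.frac_variable_segments
    truth.variable_segments = [int(i) for i in np.flatnonzero(variable)]
    truth.segment_means = [float(m) for m in seg_mean]
    seg_sd = np.where(variable, config.variable_latent_sd,
                      config.segment_latent_sd)
    latent = seg_mean[None, :] + rng.normal(size=(n, config.n_segments)) * seg_sd
    for vid, seg, delta in config.mqtl_effects:
        if genotypes is None:
            raise ValueError("mQTL effects require genotypes")
        g = genotypes.column(vid).astype(float)
        g[g == MISSING] = np.nanmean(np.where(g == MISSING, np.nan, g))
        latent[:, seg] += delta * g
        truth.mqtl_effects.append({"variant_id": vid, "segment": int(seg),
                                   "delta_per_allele": float(delta)})
    for sample_idx, seg, delta in config.methylation_outliers:
        latent[sample_idx, seg] += delta
        truth.methylation_outliers.append(
            {"sample": samples[sample_idx], "segment": int(seg),
             "delta": float(delta)}
        )
    n_clip = int(np.sum((latent < 0) | (latent > 1)))
    latent = np.clip(latent, 0.0, 1.0)

    B = np.empty((n, n_cpgs))
    for s, members in enumerate(seg_members):
        for m in members:
            B[:, m] = latent[:, s] + rng.normal(0, config.cpg_noise_sd, size=n)
    n_clip += int(np.sum((B < 0) | (B > 1)))
    B = np.clip(B, 0.0, 1.0)
    truth.clip_count = n_clip

    betas = pd.DataFrame(B, index=samples,
                         columns=[f"cpg_{i+1}" for i in range(n_cpgs)])
    positions = pd.DataFrame(
        {"chrom": config.chrom, "pos": cpg_pos},
        index=betas.columns,
    )
    return betas, positions, truth


def simulate_gwas_summary(
    R: np.ndarray,
    causal_lambda: dict | np.ndarray,
    n: int,
    seed: int = 0,
    maf: np.ndarray | None = None,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    spacing: int = 2_000,
    variant_ids: list | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """GWAS summary statistics under an LD-aware z-score model.

    Joint z-scores are drawn from N(R @ lambda, R) where lambda holds the
    non-centrality at causal variants (zero elsewhere); two-sided p-values
    follow.  ``R`` must be a positive semi-definite correlation matrix.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be a square symmetric matrix")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise ValueError(f"R is not positive semi-definite (min eig {w.min():.2e})")
    w = np.maximum(w, 0.0)
    lam = np.zeros(p)
    if isinstance(causal_lambda, dict):
        for idx, v in causal_lambda.items():
            lam[int(idx)] = v
    else:
        lam = np.asarray(causal_lambda, dtype=float)
    rng = np.random.default_rng(seed)
    z = R @ lam + (V * np.sqrt(w)) @ rng.normal(size=p)
    from scipy.stats import norm
    pvals = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    if maf is None:
        maf = np.full(p, 0.25)
    ids = variant_ids or [f"rs{i+1}" for i in range(p)]
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(p),
            "p": pvals,
            "maf": maf,
            "n": n,
            "z": z,
        }
    )
    truth = GroundTruth(gwas_causal={ids[i]: float(lam[i])
                                     for i in np.flatnonzero(lam)})
    return df, truth


def write_fixture_dir(out_dir: str, config: SimulationConfig) -> dict:
    """Generate a full fixture set and write it as plain-text files.

    Writes SV/SNV VCFs, expression/protein matrices, covariates, CpG betas
    and ground truth JSON; returns the path map.
    """
    import os
    from .variants import write_variant_vcf

    os.makedirs(out_dir, exist_ok=True)
    svs, snvs = simulate_genotypes(config)
    expr, prot, cov, truth = simulate_phenotypes(svs, config)
    betas, positions, mtruth = simulate_methylation(config, svs)
    paths = {}
    paths["sv_vcf"] = os.path.join(out_dir, "svs.vcf")
    write_variant_vcf(svs, paths["sv_vcf"])
    paths["snv_vcf"] = os.path.join(out_dir, "snvs.vcf")
    write_variant_vcf(snvs, paths["snv_vcf"])
    paths["expression"] = os.path.join(out_dir, "expression_counts.tsv")
    expr.values.to_csv(paths["expression"], sep="\t")
    paths["protein"] = os.path.join(out_dir, "protein_log_abundance.tsv")
    prot.values.to_csv(paths["protein"], sep="\t")
    paths["covariates"] = os.path.join(out_dir, "covariates.tsv")
    cov.to_csv(paths["covariates"], sep="\t")
    paths["methylation"] = os.path.join(out_dir, "cpg_betas.tsv")
    pd.concat([positions, betas.T], axis=1).to_csv(paths["methylation"],
                                                   sep="\t")
    paths["ground_truth"] = os.path.join(out_dir, "ground_truth.json")
    with open(paths["ground_truth"], "w") as fh:
        fh.write(truth.to_json())
        fh.write("\n")
    with open(os.path.join(out_dir, "ground_truth_methylation.json"), "w") as fh:
        fh.write(mtruth.to_json())
        fh.write("\n")
    return paths
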
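"""Variant data model, VCF I/O, allele frequencies, filtering, imputation and LD.

Structural variants (SVs) are genomic alterations of at least 50 bp —
deletions, insertions, duplications, inversions.  The data model keeps the
VCF convention throughout: 1-based POS, closed intervals ``[start, end]``.
For insertions the interval spans ``start .. start + inserted_length`` and
``length`` stores the inserted-sequence length; for all other types
``length = end - start``.

Genotypes are diploid alternate-allele dosages in ``{0, 1, 2}`` with ``-1``
marking a missing call.  The genotype matrix is samples x variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SV_TYPES = ("INS", "DEL", "DUP", "INV")
VALID_TYPES = SV_TYPES + ("SNV",)
MISSING = -1

__all__ = [
    "VariantRecord",
    "VariantCallSet",
    "sv_length",
    "allele_frequencies",
    "filter_callset",
    "impute_genotypes_pca",
    "genotype_r2",
    "best_tag_snv",
    "read_variant_vcf",
    "write_variant_vcf",
]


@dataclass(frozen=True)
class VariantRecord:
    """A single SV or SNV call.

    ``start``/``end`` are 1-based inclusive genomic coordinates matching VCF
    POS.  ``length`` is the inserted-sequence length for INS and
    ``end - start`` otherwise; SV types require length >= 50, SNVs have
    length 1.
    """

    id: str
    chrom: str
    start: int
    end: int
    vtype: str
    length: int | None = None
    alt_allele: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.vtype not in VALID_TYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.end < self.start:
            raise ValueError(f"{self.id}: end {self.end} < start {self.start}")
        if self.length is None:
            if self.vtype == "SNV":
                object.__setattr__(self, "length", 1)
            elif self.vtype == "INS":
                object.__setattr__(self, "length", self.end - self.start)
            else:
                object.__setattr__(self, "length", self.end - self.start)
        if self.vtype == "SNV":
            if self.length != 1:
                raise ValueError(f"{self.id}: SNV must have length 1")
        elif self.length < 50:
            raise ValueError(
                f"{self.id}: SV length {self.length} < 50 bp minimum"
            )

    @property
    def interval(self) -> tuple[int, int]:
        """Closed genomic interval occupied by the variant."""
        if self.vtype == "INS":
            return (self.start, self.start + self.length)
        return (self.start, self.end)

    def gap_to(self, chrom: str, start: int, end: int) -> int | None:
        """Gap in bp to the closed interval [start, end]; 0 if overlapping.

        Returns None when on a different chromosome.
        """
        if chrom != self.chrom:
            return None
        a, b = self.interval
        if b < start:
            return start - b
        if end < a:
            return a - end
        return 0


def sv_length(record: VariantRecord) -> int:
    """Length in bp: ``end - start`` for DEL/DUP/INV, inserted length for INS."""
    if record.vtype == "INS":
        return record.length
    if record.vtype == "SNV":
        return 1
    return record.end - record.start


@dataclass
class VariantCallSet:
    """Ordered variant records plus a samples x variants dosage matrix."""

    records: list[VariantRecord]
    genotypes: np.ndarray  # int matrix, samples x variants, -1 = missing
    sample_ids: list[str]

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.sample_ids), len(self.records)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.records)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variant_ids.index(variant_id)
        return self.genotypes[:, idx]

    def subset_variants(self, keep: np.ndarray) -> "VariantCallSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantCallSet(
            records=[self.records[i] for i in keep],
            genotypes=self.genotypes[:, keep],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: list[str]) -> "VariantCallSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return VariantCallSet(
            records=list(self.records),
            genotypes=self.genotypes[idx, :],
            sample_ids=list(sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """Variant annotation table (one row per record)."""
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "start": [r.start for r in self.records],
                "end": [r.end for r in self.records],
                "vtype": [r.vtype for r in self.records],
                "length": [r.length for r in self.records],
            }
        )


def allele_frequencies(callset: VariantCallSet) -> pd.DataFrame:
    """Per-variant AF, MAF and call rate.

    AF = sum of dosages / (2 x non-missing count); MAF = min(AF, 1 - AF);
    call_rate = 1 - missing fraction.  All-missing variants get NaN AF and
    are flagged in the ``defined`` column.
    """
    g = callset.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_obs > 0, alt / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(af, 1.0 - af)
    return pd.DataFrame(
        {
            "variant_id": callset.variant_ids,
            "af": af,
            "maf": maf,
            "call_rate": n_obs / g.shape[0] if g.shape[0] else np.nan,
            "allele_count": alt,
            "defined": n_obs > 0,
        }
    ).set_index("variant_id")


def filter_callset(
    callset: VariantCallSet,
    max_missing: float = 0.5,
    maf_min: float = 0.0,
) -> VariantCallSet:
    """Drop variants missing in more than ``max_missing`` of samples or with
    MAF below ``maf_min`` (both boundaries inclusive-for-retention). Order
    preserved."""
    aft = allele_frequencies(callset)
    missing_frac = 1.0 - aft["call_rate"].to_numpy()
    maf = aft["maf"].to_numpy()
    keep = (missing_frac <= max_missing) & (maf >= maf_min) & aft["defined"].to_numpy()
    return callset.subset_variants(keep)


def impute_genotypes_pca(
    matrix: np.ndarray,
    n_components: int = 10,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """Iterative low-rank (PCA) imputation of missing dosages.

    Missing cells (``-1`` or NaN) are initialised at column means, then the
    matrix is repeatedly centred, approximated by its rank-``n_components``
    truncated SVD, and the missing cells refilled from the reconstruction,
    until the largest refill change falls below ``tol``.  Observed cells are
    never altered; imputed cells are clipped to [0, 2].
    """
    X = np.asarray(matrix, dtype=float).copy()
    X[X == MISSING] = np.nan
    miss = np.isnan(X)
    if n_components >= min(X.shape):
        raise ValueError(
            f"n_components={n_components} must be < min(matrix shape)={min(X.shape)}"
        )
    if not miss.any():
        return X
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + mu
        new_vals = np.clip(recon[miss], 0.0, 2.0)
        delta = np.max(np.abs(new_vals - X[miss]))
        X[miss] = new_vals
        if delta < tol:
            break
    return X


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete entries.

    Missing entries (``-1`` or NaN) in either vector are dropped.  Returns
    NaN (flagged via warning) when either vector is constant on the joint
    support.
    """
    a = np.asarray(g1, dtype=float).copy()
    b = np.asarray(g2, dtype=float).copy()
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    a[a == MISSING] = np.nan
    b[b == MISSING] = np.nan
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need >= 3 jointly non-missing entries")
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("constant genotype vector: r2 undefined", RuntimeWarning)
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def best_tag_snv(
    sv: VariantRecord,
    sv_genotypes: np.ndarray,
    snv_callset: VariantCallSet,
    window_bp: int = 1_000_000,
) -> tuple[str, float] | None:
    """LD proxy: the SNV with the highest genotype r2 to the SV.

    Candidate SNVs must lie within ``window_bp`` of the SV interval.  Ties in
    r2 break by smaller distance to the SV interval, then lexicographic id.
    Returns None (with a warning) when no SNV falls in the window.
    """
    cands: list[tuple[float, int, str, int]] = []
    for j, rec in enumerate(snv_callset.records):
        gap = sv.gap_to(rec.chrom, *rec.interval)
        if gap is None or gap > window_bp:
            continue
        cands.append((gap, j, rec.id, gap))
    if not cands:
        warnings.warn(f"no SNV within {window_bp} bp of {sv.id}", RuntimeWarning)
        return None
    best: tuple[float, int, str] | None = None  # (-r2, gap, id)
    best_j = -1
    for gap, j, rid, _ in cands:
        try:
            r2 = genotype_r2(sv_genotypes, snv_callset.genotypes[:, j])
        except ValueError:
            continue
        if np.isnan(r2):
            continue
        key = (-r2, gap, rid)
        if best is None or key < best:
            best = key
            best_j = j
    if best is None:
        return None
    return snv_callset.records[best_j].id, -best[0]


# ---------------------------------------------------------------------------
# VCF I/O (minimal 4.2 dialect: SVTYPE/SVLEN/END INFO keys, GT format)
# ---------------------------------------------------------------------------

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def read_variant_vcf(path: str) -> VariantCallSet:
    """Read SV or SNV calls from a VCF into a :class:`VariantCallSet`.

    Honours SVTYPE/SVLEN/END INFO keys: INS length = \\|SVLEN\\|; DEL/DUP/INV
    length = END - POS when SVLEN is absent.  Records with symbolic ALT but
    unknown SVTYPE, or END < POS, are skipped with a warning count.
    Multi-allelic rows are split into biallelic records (``<id>_alt<k>``),
    with each split genotype counting only its own allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for i, v in enumerate(vcf):
        alts = v.ALT or ["<UNK>"]
        gts = v.genotypes  # list of [a0, a1, phased]
        for k, alt in enumerate(alts, start=1):
            vid = v.ID or f"var_{i + 1}"
            if len(alts) > 1:
                vid = f"{vid}_alt{k}"
            try:
                rec = _parse_record(v, alt, vid)
            except ValueError:
                skipped += 1
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for si, gt in enumerate(gts):
                a = [x for x in gt[:-1]]
                if any(x is None or x < 0 for x in a):
                    col[si] = MISSING
                else:
                    col[si] = sum(1 for x in a if x == k)
            records.append(rec)
            columns.append(col)
    if skipped:
        warnings.warn(f"skipped {skipped} unparseable VCF records", RuntimeWarning)
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return VariantCallSet(records=records, genotypes=geno, sample_ids=samples)


def _parse_record(v, alt: str, vid: str) -> VariantRecord:
    pos = v.POS
    svtype = v.INFO.get("SVTYPE")
    svlen = v.INFO.get("SVLEN")
    end = v.INFO.get("END")
    if svtype is None:
        if alt.startswith("<") and alt.endswith(">"):
            svtype = alt.strip("<>")
        elif len(v.REF) == 1 and len(alt) == 1:
            svtype = "SNV"
        elif len(alt) > len(v.REF):
            svtype = "INS"
            svlen = svlen if svlen is not None else len(alt) - len(v.REF)
        else:
            svtype = "DEL"
            svlen = svlen if svlen is not None else len(v.REF) - len(alt)
    if svtype not in VALID_TYPES:
        raise ValueError(f"unknown SVTYPE {svtype}")
    if svtype == "SNV":
        return VariantRecord(
            id=vid, chrom=v.CHROM, start=pos, end=pos, vtype="SNV", length=1,
            alt_allele=alt,
        )
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]
    if svtype == "INS":
        length = abs(int(svlen)) if svlen is not None else None
        if length is None:
            raise ValueError("INS without SVLEN")
        return VariantRecord(
            id=vid, chrom=v.CHROM, start=pos, end=pos, vtype="INS", length=length,
        )
    if end is None:
        if svlen is None:
            raise ValueError(f"{svtype} without END or SVLEN")
        end = pos + abs(int(svlen))
    end = int(end)
    if end < pos:
        raise ValueError("END < POS")
    return VariantRecord(id=vid, chrom=v.CHROM, start=pos, end=end, vtype=svtype)


def write_variant_vcf(callset: VariantCallSet, path: str) -> None:
    """Write the minimal VCF dialect read by :func:`read_variant_vcf`."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = sorted({r.chrom for r in callset.records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(callset.sample_ids)
            + "\n"
        )
        order = sorted(
            range(len(callset.records)),
            key=lambda i: (chroms.index(callset.records[i].chrom),
                           callset.records[i].start),
        )
        for i in order:
            r = callset.records[i]
            if r.vtype == "SNV":
                ref = "A"
                alt = r.alt_allele or "G"
                info = "SVTYPE=SNV"
            else:
                ref = "N"
                alt = f"<{r.vtype}>"
                info = f"SVTYPE={r.vtype};SVLEN={r.length};END={r.end}"
            gts = "\t".join(gt_str[int(g)] for g in callset.genotypes[:, i])
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.id}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def to_bed_frame(callset: VariantCallSet) -> pd.DataFrame:
    """Export records as BED (0-based half-open) columns."""
    df = callset.to_frame()
    iv = [r.interval for r in callset.records]
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": [a - 1 for a, _ in iv],
            "end": [b for _, b in iv],
            "name": df["id"],
            "score": 0,
            "strand": ".",
        }
    )
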
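"""Variant data model, allele frequencies, imputation, LD and VCF round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svomics.variants import (
    MISSING,
    VariantCallSet,
    VariantRecord,
    allele_frequencies,
    best_tag_snv,
    filter_callset,
    genotype_r2,
    impute_genotypes_pca,
    read_variant_vcf,
    sv_length,
    write_variant_vcf,
)

from conftest import del_record, make_callset


class TestVariantRecord:
    @pytest.mark.parametrize(
        "chrom,start,end,vtype,length,expected",
        [
            ("chr16", 72057133, 72058849, "DEL", None, 1716),
            ("chr2", 203034349, 203039584, "DEL", None, 5235),
            ("chr7", 12242079, 12242079, "INS", 322, 322),
            ("chr17", 46237502, 46238226, "DEL", None, 724),
        ],
    )
    def test_sv_length_breakpoint_arithmetic(self, chrom, start, end, vtype,
                                             length, expected):
        rec = VariantRecord(id="v", chrom=chrom, start=start, end=end,
                            vtype=vtype, length=length)
        assert sv_length(rec) == expected

    def test_insertion_interval_spans_inserted_length(self):
        rec = VariantRecord(id="v", chrom="chr7", start=12242079,
                            end=12242079, vtype="INS", length=322)
        assert rec.interval == (12242079, 12242401)

    def test_rejects_sub_50bp_sv(self):
        with pytest.raises(ValueError, match="50"):
            VariantRecord(id="v", chrom="chr1", start=100, end=120,
                          vtype="DEL")

    def test_rejects_end_before_start(self):
        with pytest.raises(ValueError):
            VariantRecord(id="v", chrom="chr1", start=200, end=100,
                          vtype="DEL")

    def test_snv_has_unit_length(self):
        rec = VariantRecord(id="v", chrom="chr1", start=500, end=500,
                            vtype="SNV")
        assert rec.length == 1

    def test_gap_to_is_zero_on_overlap_and_counts_bases_otherwise(self):
        rec = del_record("v", "chr1", 1000, 2000)
        assert rec.gap_to("chr1", 1500, 1600) == 0
        assert rec.gap_to("chr1", 2501, 2600) == 501
        assert rec.gap_to("chr1", 100, 400) == 600
        assert rec.gap_to("chr2", 1500, 1600) is None


class TestAlleleFrequencies:
    def test_simple_af(self):
        cs = make_callset([del_record("v1", "chr1", 100, 200)],
                          [[0], [1], [2]])
        aft = allele_frequencies(cs)
        assert aft.loc["v1", "af"] == 0.5
        assert aft.loc["v1", "call_rate"] == 1.0

    def test_af_with_missing_uses_nonmissing_denominator(self):
        cs = make_callset([del_record("v1", "chr1", 100, 200)],
                          [[0], [2], [MISSING]])
        aft = allele_frequencies(cs)
        assert aft.loc["v1", "af"] == 0.5
        assert aft.loc["v1", "call_rate"] == pytest.approx(2 / 3)

    def test_monomorphic_af_zero(self):
        cs = make_callset([del_record("v1", "chr1", 100, 200)],
                          [[0], [0], [0]])
        aft = allele_frequencies(cs)
        assert aft.loc["v1", "af"] == 0.0
        assert aft.loc["v1", "maf"] == 0.0

    def test_all_missing_flagged_undefined(self):
        cs = make_callset([del_record("v1", "chr1", 100, 200)],
                          [[MISSING], [MISSING]])
        aft = allele_frequencies(cs)
        assert not aft.loc["v1", "defined"]
        assert np.isnan(aft.loc["v1", "af"])

    def test_af_invariant_under_sample_reordering_and_maf_bounded(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(40, 5))
        recs = [del_record(f"v{i}", "chr1", 100 * i + 100, 100 * i + 200)
                for i in range(5)]
        cs = make_callset(recs, g)
        perm = rng.permutation(40)
        cs2 = VariantCallSet(records=recs, genotypes=g[perm],
                             sample_ids=[cs.sample_ids[i] for i in perm])
        a1, a2 = allele_frequencies(cs), allele_frequencies(cs2)
        assert np.allclose(a1["af"], a2["af"])
        assert (a1["maf"] <= 0.5).all()


class TestFilterCallset:
    def _cs(self):
        rng = np.random.default_rng(1)
        n = 100
        g = np.column_stack([
            rng.binomial(2, 0.3, n),          # common, complete
            rng.binomial(2, 0.3, n),          # will get 51% missing
            rng.binomial(2, 0.005, n),        # very rare
        ])
        g[:51, 1] = MISSING
        recs = [del_record(f"v{i}", "chr1", 1000 * i + 100, 1000 * i + 300)
                for i in range(3)]
        return make_callset(recs, g)

    def test_high_missingness_dropped(self):
        kept = filter_callset(self._cs(), max_missing=0.5, maf_min=0.0)
        assert "v1" not in kept.variant_ids
        assert "v0" in kept.variant_ids

    def test_maf_boundary_inclusive(self):
        g = np.zeros((100, 1), dtype=int)
        g[:4, 0] = 1  # AF = 0.02 exactly
        cs = make_callset([del_record("v", "chr1", 100, 200)], g)
        kept = filter_callset(cs, maf_min=0.02)
        assert kept.n_variants == 1

    def test_identity_when_thresholds_trivial(self):
        cs = self._cs()
        kept = filter_callset(cs, max_missing=1.0, maf_min=0.0)
        assert kept.variant_ids == cs.variant_ids


class TestImputation:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.4, size=(30, 8)).astype(float)
        out = impute_genotypes_pca(X, n_components=2)
        assert np.array_equal(out, X)

    def test_rank1_completion_recovers_masked_cell(self):
        u = np.linspace(0.2, 1.8, 40)
        v = np.linspace(0.5, 1.0, 6)
        X = np.outer(u, v)
        truth = X[10, 3]
        X_miss = X.copy()
        X_miss[10, 3] = np.nan
        out = impute_genotypes_pca(X_miss, n_components=1, tol=1e-9,
                                   max_iter=500)
        assert out[10, 3] == pytest.approx(truth, abs=1e-6)
        # observed cells untouched
        mask = ~np.isnan(X_miss)
        assert np.array_equal(out[mask], X[mask])

    def test_beats_column_mean_on_ld_structured_genotypes(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.4, size=(300, 1)).astype(float)
        # 12 highly correlated columns + noise columns
        X = np.repeat(base, 12, axis=1)
        flip = rng.random(X.shape) < 0.05
        X[flip] = rng.binomial(2, 0.4, size=flip.sum())
        truth = X.copy()
        miss = rng.random(X.shape) < 0.10
        X[miss] = np.nan
        out = impute_genotypes_pca(X, n_components=3)
        rmse = np.sqrt(np.mean((out[miss] - truth[miss]) ** 2))
        col_sd = truth.std(axis=0).mean()
        assert rmse < col_sd
        assert out.min() >= 0.0 and out.max() <= 2.0

    def test_rejects_excess_components(self):
        with pytest.raises(ValueError):
            impute_genotypes_pca(np.ones((5, 4)), n_components=4)


class TestGenotypeR2:
    def test_identical_and_flipped_vectors(self):
        g = np.array([0, 1, 2, 0, 1, 2])
        assert genotype_r2(g, g) == pytest.approx(1.0)
        assert genotype_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_zero_covariance(self):
        assert genotype_r2([0, 0, 1, 1, 2, 2],
                           [0, 1, 0, 1, 0, 1]) == pytest.approx(0.0)

    def test_constant_vector_flagged_nan(self):
        with pytest.warns(RuntimeWarning):
            r2 = genotype_r2([1, 1, 1, 1], [0, 1, 2, 1])
        assert np.isnan(r2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.5, 3.0), b=st.floats(-2.0, 2.0),
        seed=st.integers(0, 1000),
    )
    def test_symmetric_and_affine_invariant(self, a, b, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.integers(0, 3, 20).astype(float)
        g2 = rng.integers(0, 3, 20).astype(float)
        if g1.std() == 0 or g2.std() == 0:
            return
        r = genotype_r2(g1, g2)
        assert genotype_r2(g2, g1) == pytest.approx(r)
        assert genotype_r2(a * g1 + b, g2) == pytest.approx(r, abs=1e-10)


class TestBestTag:
    def _snvs(self, columns, positions):
        recs = [VariantRecord(id=f"snv{i}", chrom="chr1", start=p, end=p,
                              vtype="SNV") for i, p in enumerate(positions)]
        return make_callset(recs, np.column_stack(columns))

    def test_duplicate_genotypes_win(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, 50)
        sv = del_record("sv", "chr1", 10_000, 10_500)
        snvs = self._snvs([g, rng.binomial(2, 0.3, 50)], [12_000, 13_000])
        tag = best_tag_snv(sv, g, snvs, window_bp=100_000)
        assert tag == ("snv0", pytest.approx(1.0))

    def test_tie_broken_by_distance(self):
        g = np.array([0, 1, 2] * 10)
        sv = del_record("sv", "chr1", 10_000, 10_500)
        # identical columns: equal r2, nearer one must win
        snvs = self._snvs([g, g], [50_000, 20_000])
        tag = best_tag_snv(sv, g, snvs, window_bp=100_000)
        assert tag[0] == "snv1"

    def test_independent_snvs_report_low_r2(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, 2000)
        sv = del_record("sv", "chr1", 10_000, 10_500)
        cols = [rng.binomial(2, 0.3, 2000) for _ in range(5)]
        snvs = self._snvs(cols, [11_000, 12_000, 13_000, 14_000, 15_000])
        tag = best_tag_snv(sv, g, snvs, window_bp=100_000)
        assert tag[1] < 0.05

    def test_empty_window_flagged(self):
        g = np.array([0, 1, 2] * 10)
        sv = del_record("sv", "chr1", 10_000, 10_500)
        snvs = self._snvs([g], [10_000_000])
        with pytest.warns(RuntimeWarning):
            assert best_tag_snv(sv, g, snvs, window_bp=1000) is None


class TestVcfIO:
    def test_round_trip_preserves_everything(self, tmp_path, small_cohort):
        cs = small_cohort["svs"]
        path = str(tmp_path / "svs.vcf")
        write_variant_vcf(cs, path)
        back = read_variant_vcf(path)
        assert back.n_variants == cs.n_variants
        assert back.sample_ids == cs.sample_ids
        orig = {r.id: r for r in cs.records}
        for j, rec in enumerate(back.records):
            o = orig[rec.id]
            assert (rec.chrom, rec.start, rec.end, rec.vtype, rec.length) == \
                (o.chrom, o.start, o.end, o.vtype, o.length)
            col = cs.column(rec.id)
            assert np.array_equal(back.genotypes[:, j], col)

    def test_del_length_from_end_minus_pos(self, tmp_path):
        path = tmp_path / "one.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr16>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr16\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1816\tGT\t0/1\t./.\n"
        )
        cs = read_variant_vcf(str(path))
        assert cs.records[0].length == 1716
        assert cs.genotypes[0, 0] == 1
        assert cs.genotypes[1, 0] == MISSING

    def test_multiallelic_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t500\tm1\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/1\n"
        )
        cs = read_variant_vcf(str(path))
        assert cs.n_variants == 2
        assert cs.variant_ids == ["m1_alt1", "m1_alt2"]
        assert list(cs.genotypes[0]) == [1, 1]
        assert list(cs.genotypes[1]) == [1, 0]
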
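"""BED codec round-trips, normalization, and keyed-table reading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from masklmm.plinkio import (
    NormalizationPolicy,
    PlinkFormatError,
    open_bed,
    read_covariates,
    read_phenotype,
    stream_blocks,
    write_bed,
)

from conftest import make_samples, make_variants


class TestBedCodec:
    def test_roundtrip_exhaustive_codes(self, tmp_path):
        """All four two-bit codes survive a write/read cycle exactly."""
        dosages = np.array([[0, 1], [1, -1], [2, 0], [-1, 2], [0, 0]], dtype=np.int8)
        prefix = tmp_path / "codes"
        write_bed(dosages, make_variants(2), make_samples(5), prefix)
        src = open_bed(prefix)
        assert src.n == 5 and src.m == 2
        np.testing.assert_array_equal(src.dosages(), dosages)

    def test_roundtrip_random_matrix(self, random_bed):
        prefix, dosages = random_bed
        src = open_bed(prefix)
        np.testing.assert_array_equal(src.dosages(), dosages)

    def test_single_sample_single_snp_payload(self, tmp_path):
        prefix = tmp_path / "one"
        write_bed(np.array([[2]], dtype=np.int8), make_variants(1), make_samples(1), prefix)
        assert prefix.with_suffix(".bed").stat().st_size == 4  # 3-byte header + 1 byte

    def test_tiny_fixture_metadata(self, tiny_bed):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        assert (src.n, src.m) == (4, 3)
        stats = src.allele_stats()
        assert stats.missing_frac[1] == 1.0
        assert stats.freq[0] == pytest.approx(0.5)  # dosages (0,1,2,1)

    def test_bad_magic_rejected(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        data = bytearray(prefix.with_suffix(".bed").read_bytes())
        data[0] = 0x00
        bad = tmp_path / "bad"
        for ext in (".bim", ".fam"):
            bad.with_suffix(ext).write_text(prefix.with_suffix(ext).read_text())
        bad.with_suffix(".bed").write_bytes(bytes(data))
        with pytest.raises(PlinkFormatError, match="magic"):
            open_bed(bad)

    def test_individual_major_rejected(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        data = bytearray(prefix.with_suffix(".bed").read_bytes())
        data[2] = 0x00
        bad = tmp_path / "imaj"
        for ext in (".bim", ".fam"):
            bad.with_suffix(ext).write_text(prefix.with_suffix(ext).read_text())
        bad.with_suffix(".bed").write_bytes(bytes(data))
        with pytest.raises(PlinkFormatError, match="SNP-major"):
            open_bed(bad)

    def test_payload_length_mismatch(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        bad = tmp_path / "short"
        for ext in (".bim", ".fam"):
            bad.with_suffix(ext).write_text(prefix.with_suffix(ext).read_text())
        bad.with_suffix(".bed").write_bytes(prefix.with_suffix(".bed").read_bytes()[:-1])
        with pytest.raises(PlinkFormatError, match="payload"):
            open_bed(bad)

    def test_missing_file_named(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nothere"):
            open_bed(tmp_path / "nothere")

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        hnp.arrays(
            np.int8,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=9),
            elements=st.sampled_from([0, 1, 2, -1]),
        )
    )
    def test_roundtrip_property(self, dosages):
        """Any dosage matrix (any shape, any code mix) round-trips bit-exactly."""
        import tempfile

        n, m = dosages.shape
        with tempfile.TemporaryDirectory() as d:
            prefix = f"{d}/p"
            write_bed(dosages, make_variants(m), make_samples(n), prefix)
            np.testing.assert_array_equal(open_bed(prefix).dosages(), dosages)

    def test_empty_variant_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_bed(np.empty((3, 0), dtype=np.int8), [], make_samples(3), tmp_path / "x")


class TestStreaming:
    def test_normalized_column_closed_form(self, tmp_path):
        """Dosages (0,1,2,1) at p=0.5 normalize to (-sqrt2, 0, sqrt2, 0)."""
        dosages = np.array([[0], [1], [2], [1]], dtype=np.int8)
        prefix = tmp_path / "cf"
        write_bed(dosages, make_variants(1), make_samples(4), prefix)
        src = open_bed(prefix)
        (block,) = stream_blocks(src, NormalizationPolicy(maf_min=0.0), block_size=8)
        expected = np.array([-np.sqrt(2), 0.0, np.sqrt(2), 0.0])
        np.testing.assert_allclose(block.data[:, 0], expected, atol=1e-12)

    def test_monomorphic_and_all_missing_excluded(self, tmp_path):
        dosages = np.array([[2, 0, -1], [2, 1, -1], [2, 2, -1], [2, 1, -1]], dtype=np.int8)
        prefix = tmp_path / "mono"
        write_bed(dosages, make_variants(3), make_samples(4), prefix)
        src = open_bed(prefix)
        blocks = list(stream_blocks(src, NormalizationPolicy(maf_min=0.0), block_size=8))
        kept = np.concatenate([b.marker_indices for b in blocks])
        np.testing.assert_array_equal(kept, [1])

    def test_block_partition_widths(self, random_bed):
        prefix, _ = random_bed
        src = open_bed(prefix)
        policy = NormalizationPolicy(maf_min=0.0)
        n_kept = src.retained_markers(policy).size
        widths = [b.data.shape[1] for b in stream_blocks(src, policy, block_size=7)]
        assert sum(widths) == n_kept
        assert all(w == 7 for w in widths[:-1]) and 1 <= widths[-1] <= 7

    @pytest.mark.parametrize("block_size", [1, 3, 17, 200])
    def test_stream_invariance(self, random_bed, block_size):
        """Any block partition concatenates to the full-matrix normalization."""
        prefix, _ = random_bed
        src = open_bed(prefix)
        policy = NormalizationPolicy()
        full = np.hstack([b.data for b in stream_blocks(src, policy, block_size=200)])
        parts = np.hstack([b.data for b in stream_blocks(src, policy, block_size=block_size)])
        np.testing.assert_allclose(parts, full, atol=1e-12)
        assert np.abs(full.mean(axis=0)).max() < 1e-8

    def test_bad_block_size(self, random_bed):
        prefix, _ = random_bed
        src = open_bed(prefix)
        with pytest.raises(ValueError, match="block_size"):
            next(stream_blocks(src, NormalizationPolicy(), block_size=0))


def _write_pheno(path, rows, header="FID IID TRAIT"):
    lines = ([header] if header else []) + rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestPhenotype:
    def test_centered_and_scaled(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(tmp_path / "p.txt", [f"F{i} I{i} {i}" for i in range(1, 5)])
        ph = read_phenotype(p, src)
        assert ph.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert ph.values.var() == pytest.approx(1.0)
        np.testing.assert_array_equal(ph.sample_indices, np.arange(4))

    def test_order_invariance(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        rows = [f"F{i} I{i} {i * 1.5}" for i in range(1, 5)]
        a = read_phenotype(_write_pheno(tmp_path / "a.txt", rows), src)
        b = read_phenotype(_write_pheno(tmp_path / "b.txt", rows[::-1]), src)
        np.testing.assert_allclose(a.values, b.values)

    def test_missing_code_dropped(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(tmp_path / "p.txt", ["F1 I1 1", "F2 I2 -9", "F3 I3 3", "F4 I4 5"])
        ph = read_phenotype(p, src)
        assert ph.n_missing == 1
        np.testing.assert_array_equal(ph.sample_indices, [0, 2, 3])

    def test_constant_phenotype_rejected(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(tmp_path / "p.txt", [f"F{i} I{i} 2.0" for i in range(1, 5)])
        with pytest.raises(ValueError, match="zero variance"):
            read_phenotype(p, src)

    def test_non_numeric_rejected(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(tmp_path / "p.txt", ["F1 I1 1", "F2 I2 oops", "F3 I3 3", "F4 I4 4"])
        with pytest.raises(ValueError, match="oops"):
            read_phenotype(p, src)

    def test_no_overlap_rejected(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(tmp_path / "p.txt", ["X1 Y1 1", "X2 Y2 2"])
        with pytest.raises(ValueError, match="overlap"):
            read_phenotype(p, src)


class TestCovariates:
    def test_two_columns_aligned(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(
            tmp_path / "c.txt",
            ["F2 I2 30 1", "F1 I1 20 2", "F3 I3 40 1", "F4 I4 50 2"],
            header="FID IID AGE SEX",
        )
        C, labels = read_covariates(p, src)
        assert labels == ["AGE", "SEX"]
        np.testing.assert_allclose(C[:, 0], [20, 30, 40, 50])

    def test_missing_cell_located(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(
            tmp_path / "c.txt",
            ["F1 I1 20", "F2 I2 30", "F3 I3 40"],
            header="FID IID AGE",
        )
        with pytest.raises(ValueError, match="F4 I4"):
            read_covariates(p, src)

    def test_zero_columns_accepted(self, tiny_bed, tmp_path):
        prefix, _ = tiny_bed
        src = open_bed(prefix)
        p = _write_pheno(tmp_path / "c.txt", [f"F{i} I{i}" for i in range(1, 5)], header="FID IID")
        C, labels = read_covariates(p, src)
        assert C.shape == (4, 0) and labels == []
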
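import numpy as np
import pytest

from masklmm.plinkio import SampleRecord, VariantRecord, write_bed


def make_variants(m, chrom="1"):
    return [VariantRecord(chrom, f"snp{j + 1}", 0.0, j + 1, "A", "G") for j in range(m)]


def make_samples(n):
    return [SampleRecord(f"F{i + 1}", f"I{i + 1}") for i in range(n)]


@pytest.fixture
def tiny_bed(tmp_path):
    """4 samples x 3 SNPs; SNP 2 (index 1) is coded all-missing."""
    dosages = np.array(
        [
            [0, -1, 2],
            [1, -1, 2],
            [2, -1, 1],
            [1, -1, 0],
        ],
        dtype=np.int8,
    )
    prefix = tmp_path / "tiny"
    write_bed(dosages, make_variants(3), make_samples(4), prefix)
    return prefix, dosages


@pytest.fixture
def random_bed(tmp_path):
    """50 samples x 200 SNPs with scattered missing calls."""
    rng = np.random.default_rng(42)
    dosages = rng.integers(0, 3, size=(50, 200)).astype(np.int8)
    miss = rng.random((50, 200)) < 0.02
    dosages[miss] = -1
    prefix = tmp_path / "rand"
    write_bed(dosages, make_variants(200), make_samples(50), prefix)
    return prefix, dosages
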
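import numpy as np
import pandas as pd
import pytest

from rohpipe import vcf_io


@pytest.fixture
def three_record_table() -> vcf_io.VariantTable:
    """Two samples, three biallelic sites with depths."""
    return vcf_io.VariantTable.from_records(
        chrom=["1", "1", "2"],
        pos=[100, 250, 40],
        ref=["A", "G", "T"],
        alt=["C", "T", "A"],
        genotypes={"s1": [1, 0, 2], "s2": [0, 1, -1]},
        depths={"s1": [10, 12, 8], "s2": [9, 11, -1]},
    )


@pytest.fixture
def vcf_file(tmp_path, three_record_table):
    path = tmp_path / "three.vcf"
    vcf_io.write_vcf(three_record_table, path, {"1": 1000, "2": 1000})
    return path


def make_track(scaled, covered=None, chrom="1", bin_size=10_000, retained=None) -> pd.DataFrame:
    """Build a bin track directly from scaled SNP counts."""
    scaled = np.asarray(scaled, dtype=float)
    n = len(scaled)
    covered = np.full(n, bin_size) if covered is None else np.asarray(covered)
    track = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "covered_sites": covered,
            "raw_snp_count": scaled.astype(int),
            "scaled_snp_count": scaled,
            "retained": np.ones(n, dtype=bool) if retained is None else np.asarray(retained),
        }
    )
    return track
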
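import numpy as np
import pandas as pd
import pytest

from methdrift.matrix import CpGCountMatrix, GroupCounts


def make_matrix(records, groups):
    """Build a CpGCountMatrix from [(chrom, pos, {group: (meth_list, total_list)})]."""
    records = sorted(records, key=lambda r: (r[0], r[1]))
    chrom = np.array([r[0] for r in records], dtype=object)
    pos = np.array([r[1] for r in records], dtype=np.int64)
    meth = {g: np.array([r[2][g][0] for r in records], dtype=np.int64) for g in groups}
    total = {g: np.array([r[2][g][1] for r in records], dtype=np.int64) for g in groups}
    return CpGCountMatrix(chrom, pos, meth, total)


@pytest.fixture
def two_site_matrix():
    """Two strongly differential CpGs: per replicate 8/10 (A) vs 2/10 (B)."""
    recs = [
        ("chr1", 100, {"A": ([8] * 5, [10] * 5), "B": ([2] * 5, [10] * 5)}),
        ("chr1", 300, {"A": ([8] * 5, [10] * 5), "B": ([2] * 5, [10] * 5)}),
    ]
    return make_matrix(recs, ["A", "B"])


def group(meth, total):
    return GroupCounts(np.asarray(meth), np.asarray(total))
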
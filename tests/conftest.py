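"""Shared fixtures: tiny alignments and a toy coding sequence."""

import numpy as np
import pytest

from coevomut.msa_io import Alignment

# 60-codon toy CDS assembled from a fixed codon cycle; GC-rich enough that
# 33-mers centred on interior codons clear the QuikChange Tm guideline.
_CODONS = ["GCC", "GGT", "CTG", "GAC", "CAC", "ACC", "AAC", "GAG", "CGC", "TCC"]
TOY_CDS = "".join(_CODONS[i % 10] for i in range(60))


@pytest.fixture
def toy_cds() -> str:
    return TOY_CDS


@pytest.fixture
def small_alignment() -> Alignment:
    """4 sequences x 6 columns, no gaps; query = first row."""
    return Alignment(
        ids=("query", "s1", "s2", "s3"),
        rows=("ACDEFG", "ACDEFG", "AVDEYG", "AVDKYG"),
        query_id="query",
    )


@pytest.fixture
def gapped_alignment() -> Alignment:
    """5 x 8 with gaps concentrated in two sequences and two columns."""
    return Alignment(
        ids=("query", "s1", "s2", "s3", "s4"),
        rows=(
            "ACDEFGHI",
            "ACDEFGHI",
            "AC-EFG-I",
            "ACDEF--I",
            "A-DEFGHI",
        ),
        query_id="query",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_alignment(
    rng: np.random.Generator, n_seqs: int, n_cols: int, gap_rate: float = 0.0
) -> Alignment:
    """Uniform-residue random alignment helper used across test modules."""
    from coevomut.msa_io import AA20

    letters = np.array(list(AA20))
    chars = letters[rng.integers(0, 20, size=(n_seqs, n_cols))]
    if gap_rate > 0:
        mask = rng.random((n_seqs, n_cols)) < gap_rate
        mask[0] = False
        chars = np.where(mask, "-", chars)
    rows = tuple("".join(r) for r in chars)
    ids = ("query",) + tuple(f"s{i}" for i in range(1, n_seqs))
    return Alignment(ids, rows, "query")
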
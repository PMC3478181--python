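"""Coevolving-site detection via row-and-column-weighted mutual information.

For two alignment columns A and B, mutual information is

    MI(A:B) = sum_i sum_j P(a_i, b_j) * log20[ P(a_i, b_j) / (P(a_i) P(b_j)) ]

with frequencies observed over the rows that carry a standard residue at
*both* columns (gaps and X excluded pairwise).  The base-20 logarithm makes
1 the ceiling for a 20-letter alphabet: MI(A:B) <= min(H(A), H(B)) <= 1,
where H is column entropy in the same base.

Raw MI confounds genuine inter-site covariation with columns that score
promiscuously high against everything (high entropy, shared phylogenetic
signal).  The row-column-weighted score damps those:

    RCW(A:B) = MI_AB / [ (MI_A. + MI_.B - 2 MI_AB) / (n - 1) ]

i.e. MI divided by the average MI that A and B achieve against all *other*
columns.  The diagonal is never computed and row/column sums run over
off-diagonal entries only.  The normalisation count n (number of alignment
sequences, or optionally number of columns) is a common positive factor,
so pair *ranking* does not depend on the convention chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .errors import (
    InsufficientDataError,
    InsufficientSitesError,
    InvalidNError,
    MissingCoordinateError,
)
from .msa_io import AA20, Alignment, ColumnMap

_LOG20 = np.log(20.0)
_CODE = {aa: k for k, aa in enumerate(AA20)}


def encode_alignment(aln: Alignment) -> np.ndarray:
    """(n_seqs, n_cols) int8 matrix; residues 0..19, gap/X -> -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for aa, k in _CODE.items():
        lut[ord(aa)] = k
    arr = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(aln.n_seqs, aln.n_cols)


@dataclass(frozen=True)
class FrequencyTable:
    """Observed residue frequencies for one column."""

    frequencies: np.ndarray  # length 20, sums to 1 when effective_count > 0
    effective_count: int  # rows with a standard residue


@dataclass(frozen=True)
class PairFrequencyTable:
    """Joint frequencies for a column pair, on rows valid at both columns."""

    joint: np.ndarray  # (20, 20)
    effective_count: int

    @property
    def marginal_a(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def column_frequencies(aln: Alignment, col: int) -> FrequencyTable:
    """Per-column residue frequencies, 0-based column index."""
    codes = encode_alignment(aln)[:, col]
    codes = codes[codes >= 0]
    counts = np.bincount(codes, minlength=20).astype(float)
    n = int(counts.sum())
    freqs = counts / n if n else counts
    return FrequencyTable(frequencies=freqs, effective_count=n)


def pair_frequencies(aln: Alignment, col_a: int, col_b: int) -> PairFrequencyTable:
    """Joint frequencies of a column pair on rows complete at both."""
    enc = encode_alignment(aln)
    return _pair_frequencies_encoded(enc[:, col_a], enc[:, col_b])


def _pair_frequencies_encoded(a: np.ndarray, b: np.ndarray) -> PairFrequencyTable:
    valid = (a >= 0) & (b >= 0)
    a, b = a[valid].astype(np.int64), b[valid].astype(np.int64)
    n = a.size
    joint = np.bincount(a * 20 + b, minlength=400).astype(float).reshape(20, 20)
    return PairFrequencyTable(joint=joint / n if n else joint, effective_count=n)


def column_entropy(aln: Alignment, col: int) -> float:
    """Shannon entropy of a column, base 20 (gap/X excluded)."""
    p = column_frequencies(aln, col).frequencies
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / _LOG20)


def _mi_from_joint(pair: PairFrequencyTable) -> float:
    pj = pair.joint
    pa, pb = pair.marginal_a, pair.marginal_b
    nz = pj > 0
    prod = np.outer(pa, pb)
    mi = (pj[nz] * (np.log(pj[nz]) - np.log(prod[nz]))).sum() / _LOG20
    return float(max(mi, 0.0))  # clip tiny negative rounding residue


def mutual_information(aln: Alignment, col_a: int, col_b: int) -> float:
    """Base-20 mutual information between two columns (0-based indices).

    Rows with a gap or X at either column are excluded; fewer than two
    usable rows raises :class:`InsufficientDataError`.
    """
    pair = pair_frequencies(aln, col_a, col_b)
    if pair.effective_count < 2:
        raise InsufficientDataError(
            f"columns {col_a},{col_b}: fewer than 2 complete rows"
        )
    return _mi_from_joint(pair)


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric column-pair MI matrix; diagonal is NaN by convention.

    Pairs with fewer than two complete rows are recorded in ``missing``
    and stored as NaN rather than raising.
    """

    values: np.ndarray  # (n_cols, n_cols), NaN diagonal
    missing: tuple[tuple[int, int], ...]

    @property
    def n_cols(self) -> int:
        return self.values.shape[0]


def mi_matrix(aln: Alignment) -> MIMatrix:
    """Score every unordered column pair; symmetric by construction."""
    enc = encode_alignment(aln)
    m = aln.n_cols
    vals = np.full((m, m), np.nan)
    missing: list[tuple[int, int]] = []
    for i in range(m):
        for j in range(i + 1, m):
            pair = _pair_frequencies_encoded(enc[:, i], enc[:, j])
            if pair.effective_count < 2:
                missing.append((i, j))
                continue
            vals[i, j] = vals[j, i] = _mi_from_joint(pair)
    return MIMatrix(values=vals, missing=tuple(missing))


@dataclass(frozen=True)
class RCWMatrix:
    """Row-column-weighted MI with the quantities entering the weighting."""

    values: np.ndarray  # (n_cols, n_cols), NaN diagonal
    row_sums: np.ndarray  # off-diagonal MI row sums (== column sums)
    n: int
    n_mode: str  # "sequences" or "columns"

    @property
    def n_cols(self) -> int:
        return self.values.shape[0]


def rcw_matrix(mi: MIMatrix, n: int, n_mode: str = "sequences") -> RCWMatrix:
    """Weight each MI entry by the mean off-diagonal MI of its row/column.

    ``n`` is the normalisation count: the number of alignment sequences
    (default convention) or of columns; it scales all entries by the same
    (n-1) factor and leaves the ranking untouched.  A zero denominator
    yields RCW = 0 (no signal anywhere in the row and column); if MI
    itself is positive there — only possible in degenerate geometries such
    as a two-column matrix — a warning is emitted.
    """
    if n_mode not in ("sequences", "columns"):
        raise ValueError(f"unknown n_mode {n_mode!r}")
    if n < 2:
        raise InvalidNError(f"n must be >= 2, got {n}")
    v = mi.values
    row_sums = np.nansum(v, axis=1)  # diagonal NaN excluded
    denom = (row_sums[:, None] + row_sums[None, :] - 2.0 * v) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rcw = v / denom
    zero_den = np.isfinite(v) & (denom <= 0)
    if np.any(zero_den & (v > 0)):
        warnings.warn(
            "zero RCW denominator with positive MI; score set to 0 "
            "(degenerate geometry, e.g. only two scored columns)",
            stacklevel=2,
        )
    rcw[zero_den] = 0.0
    np.fill_diagonal(rcw, np.nan)
    return RCWMatrix(values=rcw, row_sums=row_sums, n=n, n_mode=n_mode)


@dataclass(frozen=True)
class CoevolvingPair:
    """A selected site pair in query-residue numbering."""

    site_a: int
    site_b: int
    wt_a: str
    wt_b: str
    mi_score: float
    rcw_score: float
    rank: int


def _offdiag_values(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    v = values[iu]
    return v[np.isfinite(v)]


def select_coevolving_pairs(
    rcw: RCWMatrix,
    cmap: ColumnMap,
    query_seq: str,
    mi: MIMatrix | None = None,
    rule: str = "zscore",
    z: float = 2.0,
    top_k: int | None = None,
) -> tuple[list[CoevolvingPair], list[int]]:
    """Rank column pairs by RCW and report those passing the selection rule.

    ``rule="zscore"`` keeps pairs scoring above mean + z·SD of all finite
    off-diagonal RCW values (z defaults to 2); ``rule="topk"`` keeps the
    ``top_k`` best.  Pairs are sorted by descending RCW, ties broken by
    (site_a, site_b).  Sites are reported in 1-based query numbering with
    wild-type residues from ``query_seq``; pairs whose columns do not map
    to the query (query gap) are skipped.  Returns the pairs and the
    sorted unique-site list they induce.
    """
    if rule not in ("zscore", "topk"):
        raise ValueError(f"unknown selection rule {rule!r}")
    m = rcw.n_cols
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            score = rcw.values[i, j]
            if not np.isfinite(score):
                continue
            ra = cmap.residue_for_column(i + 1)
            rb = cmap.residue_for_column(j + 1)
            if ra is None or rb is None:
                continue
            sa, sb = sorted((ra, rb))
            mi_score = float(mi.values[i, j]) if mi is not None else float("nan")
            candidates.append((float(score), sa, sb, mi_score))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    if rule == "topk":
        k = 0 if top_k is None else max(top_k, 0)
        chosen = candidates[:k]
    else:
        pool = _offdiag_values(rcw.values)
        if pool.size == 0:
            chosen = []
        else:
            cutoff = float(pool.mean() + z * pool.std(ddof=0))
            chosen = [c for c in candidates if c[0] > cutoff]

    pairs = [
        CoevolvingPair(
            site_a=sa,
            site_b=sb,
            wt_a=query_seq[sa - 1],
            wt_b=query_seq[sb - 1],
            mi_score=mi_score,
            rcw_score=score,
            rank=r,
        )
        for r, (score, sa, sb, mi_score) in enumerate(chosen, start=1)
    ]
    sites = sorted({s for p in pairs for s in (p.site_a, p.site_b)})
    return pairs, sites


def pair_ranking(rcw: RCWMatrix) -> list[tuple[int, int]]:
    """All finite off-diagonal pairs as 0-based (i, j), best RCW first."""
    m = rcw.n_cols
    scored = [
        (float(rcw.values[i, j]), i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if np.isfinite(rcw.values[i, j])
    ]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(i, j) for _, i, j in scored]


def site_distance_stats(
    sites: Sequence[int], coords: Mapping[int, Iterable[float]]
) -> tuple[float, float]:
    """Mean and sample SD of pairwise Cα-Cα distances between sites (Å)."""
    if len(sites) < 2:
        raise InsufficientSitesError("need at least 2 sites for distances")
    missing = [s for s in sites if s not in coords]
    if missing:
        raise MissingCoordinateError(f"no coordinates for sites {missing}")
    xyz = np.array([list(coords[s]) for s in sites], dtype=float)
    d = pdist(xyz)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def read_ca_coordinates(path: str | Path, chain: str | None = None) -> dict[int, np.ndarray]:
    """Cα coordinates per residue number from a PDB file (first model)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure("s", str(path))))
    coords: dict[int, np.ndarray] = {}
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if "CA" in res:
                coords[res.id[1]] = res["CA"].coord.astype(float)
        if chain is None:  # default: first chain only
            break
    return coords


def write_matrix_tsv(values: np.ndarray, path: str | Path) -> None:
    """Square matrix as TSV with 1-based column headers, 6 decimals."""
    m = values.shape[0]
    with open(path, "w") as fh:
        fh.write("col\t" + "\t".join(str(c + 1) for c in range(m)) + "\n")
        for i in range(m):
            cells = (
                "nan" if not np.isfinite(values[i, j]) else f"{values[i, j]:.6f}"
                for j in range(m)
            )
            fh.write(str(i + 1) + "\t" + "\t".join(cells) + "\n")


def write_pairs_tsv(pairs: Sequence[CoevolvingPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_a\twt_a\tsite_b\twt_b\tmi\trcw\trank\n")
        for p in pairs:
            fh.write(
                f"{p.site_a}\t{p.wt_a}\t{p.site_b}\t{p.wt_b}"
                f"\t{p.mi_score:.6f}\t{p.rcw_score:.6f}\t{p.rank}\n"
            )
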
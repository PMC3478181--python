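"""Gap reduction before coevolution scoring.

Mutual information over alignment columns is only as good as the columns
it sees: heavily gapped columns carry few usable rows.  Two complementary
steps are provided.

``maxalign_reduce`` drops whole *sequences* to maximise the alignment
"area" — the number of kept sequences times the number of columns that are
gap-free across all kept sequences.  This is the objective popularised by
the MaxAlign procedure; here it is optimised by greedy steepest-ascent
removal, with an exhaustive-subset optimiser available for small inputs as
an independent check.

``drop_gapped_columns`` then removes residual *columns* whose gap fraction
exceeds a threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .errors import EmptyAlignmentError, TooFewSequencesError
from .msa_io import GAP, Alignment


@dataclass(frozen=True)
class ReductionReport:
    """What maxalign_reduce did and how the area objective moved."""

    removed_ids: tuple[str, ...]
    gap_free_columns_before: int
    gap_free_columns_after: int
    area_before: int
    area_after: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _gap_matrix(aln: Alignment) -> np.ndarray:
    """Boolean (n_seqs, n_cols) matrix, True where gapped."""
    arr = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    return (arr == ord(GAP)).reshape(aln.n_seqs, aln.n_cols)


def _area(gaps: np.ndarray, keep: np.ndarray) -> tuple[int, int]:
    """(gap-free column count, area) for a boolean keep-mask over rows."""
    n_kept = int(keep.sum())
    if n_kept == 0:
        return 0, 0
    gap_free = int((~gaps[keep].any(axis=0)).sum())
    return gap_free, n_kept * gap_free


def _best_removal(
    gaps: np.ndarray, keep: np.ndarray, qi: int
) -> tuple[int, int]:
    """(row index, resulting area) of the steepest single removal."""
    best_i, best_area = -1, -1
    for i in np.flatnonzero(keep):
        if i == qi:
            continue
        keep[i] = False
        _, cand = _area(gaps, keep)
        keep[i] = True
        if cand > best_area:  # ties -> lowest index (first seen)
            best_i, best_area = int(i), cand
    return best_i, best_area


def maxalign_reduce(
    aln: Alignment, min_seqs: int = 10
) -> tuple[Alignment, ReductionReport]:
    """Greedily drop sequences to maximise kept-rows × gap-free-columns.

    Steepest-descent peel: starting from the full alignment, the single
    removal (query excluded) yielding the largest area is applied
    repeatedly until only ``min_seqs`` sequences remain, and the
    best-scoring state along that path is returned.  Tracking the best
    state lets the peel walk through area plateaus (common when several
    fragmentary sequences jointly spoil the same columns) that a
    stop-at-first-non-improvement rule cannot cross; the returned area is
    never below the input's.

    Raises
    ------
    TooFewSequencesError
        If a strictly improving removal exists from the returned state
        but would shrink the alignment below ``min_seqs`` sequences.
    """
    gaps = _gap_matrix(aln)
    keep = np.ones(aln.n_seqs, dtype=bool)
    qi = aln.ids.index(aln.query_id)
    gap_free_before, area_before = _area(gaps, keep)
    removal_path: list[int] = []
    best_keep, best_area, best_step = keep.copy(), area_before, 0

    while int(keep.sum()) > max(min_seqs, 1):
        i, _ = _best_removal(gaps, keep, qi)
        if i < 0:
            break
        keep[i] = False
        removal_path.append(i)
        _, area = _area(gaps, keep)
        if area > best_area:
            best_keep, best_area, best_step = keep.copy(), area, len(removal_path)

    # the peel explored every removal from states above the floor, so an
    # improving-but-blocked removal can only exist at/below min_seqs
    if int(best_keep.sum()) <= min_seqs:
        _, blocked_area = _best_removal(gaps, best_keep, qi)
        if blocked_area > best_area:
            raise TooFewSequencesError(
                f"reduction would leave fewer than {min_seqs} sequences"
            )

    removed = [aln.ids[i] for i in removal_path[:best_step]]
    gap_free_after, area_after = _area(gaps, best_keep)
    reduced = aln.subset([aln.ids[i] for i in np.flatnonzero(best_keep)])
    report = ReductionReport(
        removed_ids=tuple(str(r) for r in removed),
        gap_free_columns_before=gap_free_before,
        gap_free_columns_after=gap_free_after,
        area_before=area_before,
        area_after=area_after,
    )
    return reduced, report


def exhaustive_reduce(
    aln: Alignment, min_seqs: int = 2, max_seqs: int = 20
) -> tuple[Alignment, int]:
    """Exact optimiser of the area objective by subset enumeration.

    Exponential in the number of sequences; intended as an independent
    check of the greedy heuristic on small alignments.  Returns the best
    alignment (query always kept) and its area.  Ties go to the subset
    keeping more sequences, then to lexicographically earlier removals.
    """
    if aln.n_seqs > max_seqs:
        raise ValueError(f"exhaustive search limited to {max_seqs} sequences")
    gaps = _gap_matrix(aln)
    qi = aln.ids.index(aln.query_id)
    others = [i for i in range(aln.n_seqs) if i != qi]
    best_keep, best_area, best_size = None, -1, -1
    for r in range(len(others) + 1):
        for drop in combinations(others, r):
            keep = np.ones(aln.n_seqs, dtype=bool)
            keep[list(drop)] = False
            if int(keep.sum()) < min_seqs:
                continue
            _, area = _area(gaps, keep)
            size = int(keep.sum())
            if area > best_area or (area == best_area and size > best_size):
                best_keep, best_area, best_size = keep.copy(), area, size
    assert best_keep is not None
    best = aln.subset([aln.ids[i] for i in np.flatnonzero(best_keep)])
    return best, best_area


def drop_gapped_columns(aln: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Remove columns whose gap fraction strictly exceeds the threshold.

    ``max_gap_fraction=0`` removes every column containing any gap;
    ``max_gap_fraction=1`` removes only all-gap columns (fraction 1.0 is
    not strictly greater than 1, but such columns carry no data and are
    dropped regardless).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    gaps = _gap_matrix(aln)
    frac = gaps.mean(axis=0)
    keep = [
        c
        for c in range(aln.n_cols)
        if frac[c] <= max_gap_fraction and frac[c] < 1.0
    ]
    if not keep:
        raise EmptyAlignmentError("no columns left after gap filtering")
    return aln.take_columns(keep)
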
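"""Alignment reading/writing and column-to-query-residue mapping.

An :class:`Alignment` holds equal-length gapped amino-acid rows over the
20-letter alphabet plus ``-`` (gap) and ``X`` (missing / non-standard
residue).  One row is designated the *query*: its ungapped positions define
the residue numbering in which coevolving sites and mutagenesis targets are
reported (e.g. "G89").

Parsing of FASTA and CLUSTAL files is delegated to Biopython's
``Bio.AlignIO``; this module adds the normalisation and validation rules
the downstream scoring assumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    DuplicateIdError,
    EmptyInputError,
    EmptyQueryError,
)

#: The 20 standard amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"

_ALPHABET = set(AA20) | {GAP, MISSING}
# Non-standard residue letters normalised to X: ambiguity codes (B, Z, J),
# selenocysteine/pyrrolysine (U, O), explicit unknowns (X, *).
_TO_MISSING = set("BZJUOX*")


def normalize_row(row: str) -> str:
    """Uppercase a row, map ``.`` to ``-`` and non-standard letters to X."""
    out = []
    for ch in row.upper():
        if ch == ".":
            ch = GAP
        elif ch in _TO_MISSING:
            ch = MISSING
        if ch not in _ALPHABET:
            raise AlignmentFormatError(f"illegal alignment character {ch!r}")
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """An immutable protein multiple sequence alignment with a query row.

    Rows are normalised on construction (uppercase, ``.``→``-``,
    non-standard letters→``X``) and the core invariants are enforced:
    equal row lengths, unique ids, query present.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    query_id: str

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise EmptyInputError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise DuplicateIdError(f"duplicate sequence id {dup!r}")
        rows = tuple(normalize_row(r) for r in self.rows)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "ids", tuple(self.ids))
        ncol = len(rows[0])
        if any(len(r) != ncol for r in rows):
            raise AlignmentFormatError("rows have unequal lengths")
        if self.query_id not in self.ids:
            raise AlignmentFormatError(
                f"query id {self.query_id!r} not among sequence ids"
            )

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.ids.index(self.query_id)]

    @property
    def query_sequence(self) -> str:
        """The ungapped query sequence."""
        return self.query_row.replace(GAP, "")

    def subset(self, keep_ids: list[str] | tuple[str, ...]) -> "Alignment":
        """Row subset (order preserved); the query must be kept."""
        keep = set(keep_ids)
        ids = tuple(i for i in self.ids if i in keep)
        rows = tuple(r for i, r in zip(self.ids, self.rows) if i in keep)
        return Alignment(ids, rows, self.query_id)

    def take_columns(self, cols: list[int]) -> "Alignment":
        """Column subset by 0-based index (order preserved)."""
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Alignment(self.ids, rows, self.query_id)


def _infer_format(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            head = line.strip()
            if head.startswith(">"):
                return "fasta"
            if head.upper().startswith(("CLUSTAL", "MUSCLE")):
                return "clustal"
            break
    raise AlignmentFormatError("cannot infer alignment format (fasta/clustal)")


def read_alignment(
    path: str | Path,
    format: str | None = None,
    query_id: str | None = None,
) -> Alignment:
    """Read an aligned FASTA or CLUSTAL file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"fasta"`` or ``"clustal"``; inferred from the first line when
        omitted.
    query_id:
        Identifier of the query row; defaults to the first sequence.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise EmptyInputError(f"empty alignment file: {path}")
    fmt = format or _infer_format(text)
    if fmt not in ("fasta", "clustal"):
        raise AlignmentFormatError(f"unsupported format {fmt!r}")
    try:
        msa = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    ids = tuple(rec.id for rec in msa)
    rows = tuple(str(rec.seq) for rec in msa)
    return Alignment(ids, rows, query_id if query_id is not None else ids[0])


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment (aligned FASTA by default, or CLUSTAL)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), format)


def drop_duplicate_sequences(aln: Alignment) -> Alignment:
    """Remove rows whose sequence string duplicates an earlier row.

    The query row is always kept. Off by default in the pipeline; identical
    homologs inflate pair counts without adding evolutionary information.
    """
    seen: set[str] = set()
    keep: list[str] = []
    for sid, row in zip(aln.ids, aln.rows):
        if sid == aln.query_id or row not in seen:
            keep.append(sid)
            seen.add(row)
    return aln.subset(keep)


@dataclass(frozen=True)
class ColumnMap:
    """Bijection between alignment columns and query residue numbers.

    ``pairs`` holds (1-based alignment column, 1-based query residue)
    tuples, strictly increasing in both coordinates. Columns where the
    query row is gapped are absent.
    """

    pairs: tuple[tuple[int, int], ...]
    _col_to_res: dict[int, int] = field(init=False, repr=False, compare=False)
    _res_to_col: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_col_to_res", dict(self.pairs))
        object.__setattr__(self, "_res_to_col", {r: c for c, r in self.pairs})

    def residue_for_column(self, col: int) -> int | None:
        """Query residue number at a 1-based alignment column, or None."""
        return self._col_to_res.get(col)

    def column_for_residue(self, res: int) -> int | None:
        """1-based alignment column of a query residue number, or None."""
        return self._res_to_col.get(res)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tquery_residue\n")
            for col, res in self.pairs:
                fh.write(f"{col}\t{res}\n")


def column_to_query_map(aln: Alignment) -> ColumnMap:
    """Map alignment columns to 1-based query residue numbers.

    Every ungapped query position appears exactly once; the largest residue
    number equals the query's ungapped length.
    """
    pairs = []
    res = 0
    for col0, ch in enumerate(aln.query_row):
        if ch != GAP:
            res += 1
            pairs.append((col0 + 1, res))
    if not pairs:
        raise EmptyQueryError(f"query row {aln.query_id!r} is entirely gaps")
    return ColumnMap(tuple(pairs))
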
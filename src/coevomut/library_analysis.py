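"""Post-screening sequence analysis of combinatorial mutant libraries.

Sequenced survivors of a two-site NNK library fall into four classes:
both designed sites still encode the wild-type residue (DNA-identical or
synonymous — the library's built-in "false positive" class), a missense
change at exactly one site, missense changes at both, or a stop codon at
a designed site.  Tallies per site mirror the standard reporting layout:
for each observed amino-acid substitution, its codon(s), count, and the
minimum number of nucleotide changes separating each codon from wild type.

Residue identity in a tally is taken from the record when supplied (what
the sequencing report states) and recomputed from the codon otherwise;
where a supplied residue disagrees with the codon's translation the entry
is kept as recorded and flagged, so typographic conflicts in upstream
tables surface instead of silently reshaping the counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    EmptyInputError,
    IncompleteRecordError,
    InconsistentRecordsError,
)
from .mutagenesis import STOP, min_codon_changes, translate_codon

UNCHANGED = "unchanged_or_synonymous"
SINGLE = "single_missense"
DOUBLE = "double_missense"
CONTAINS_STOP = "contains_stop"
CLASSES = (UNCHANGED, SINGLE, DOUBLE, CONTAINS_STOP)


@dataclass(frozen=True)
class VariantRecord:
    """Observed codons of one sequenced variant at the designed sites."""

    variant_id: str
    codons: Mapping[int, str]  # site -> observed codon
    wt_codons: Mapping[int, str]  # site -> wild-type codon
    residues: Mapping[int, str] = field(default_factory=dict)  # optional, as reported

    def sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.codons))


def classify_variant(v: VariantRecord) -> str:
    """Class of a variant by translated changes at the designed sites."""
    missing = [s for s in v.wt_codons if s not in v.codons]
    if missing:
        raise IncompleteRecordError(
            f"variant {v.variant_id!r} missing sites {missing}"
        )
    changed = 0
    for site in sorted(v.wt_codons):
        aa = translate_codon(v.codons[site])
        if aa == STOP:
            return CONTAINS_STOP
        if aa != translate_codon(v.wt_codons[site]):
            changed += 1
    if changed == 0:
        return UNCHANGED
    if changed == 1:
        return SINGLE
    return DOUBLE


@dataclass(frozen=True)
class TallyTable:
    """Per-site substitution counts in the standard reporting layout.

    ``entries`` has one row per (site, amino_acid, codon) with columns
    site, wt_codon, amino_acid, codon, count, min_changes,
    translation_conflict — sorted by (site, amino_acid, codon) so output
    is deterministic.
    """

    entries: pd.DataFrame
    sites: tuple[int, ...]
    wt_codons: Mapping[int, str]

    def type_counts(self) -> dict[int, int]:
        """Distinct amino acids observed per site among non-WT codons.

        Entries with a synonymous (same-residue, different-codon) change
        count toward diversity, matching how library reports enumerate
        "kinds of amino acids" at a site; stop entries do not (a stop is
        not an amino acid).
        """
        counts = {s: 0 for s in self.sites}
        aa_entries = self.entries[self.entries["amino_acid"] != STOP]
        if not aa_entries.empty:
            got = aa_entries.groupby("site")["amino_acid"].nunique()
            counts.update({int(s): int(c) for s, c in got.items()})
        return counts

    def substitution_totals(self) -> dict[int, int]:
        """Total substitution observations per site (column sums)."""
        totals = {s: 0 for s in self.sites}
        if not self.entries.empty:
            got = self.entries.groupby("site")["count"].sum()
            totals.update({int(s): int(c) for s, c in got.items()})
        return totals

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


_COLUMNS = [
    "site",
    "wt_codon",
    "amino_acid",
    "codon",
    "count",
    "min_changes",
    "translation_conflict",
]


def _finish_entries(rows: list[dict], sites: Iterable[int], wt: Mapping[int, str]) -> TallyTable:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df = df.sort_values(["site", "amino_acid", "codon"], kind="stable").reset_index(
        drop=True
    )
    return TallyTable(entries=df, sites=tuple(sorted(sites)), wt_codons=dict(wt))


def tally_table(variants: Sequence[VariantRecord]) -> TallyTable:
    """Tally observed substitutions (codon != wild type) across a pool.

    All records must share one designed-site set.  An empty pool yields an
    empty table with zero type counts.
    """
    if not variants:
        return _finish_entries([], (), {})
    site_set = variants[0].sites()
    wt = dict(variants[0].wt_codons)
    counts: Counter[tuple[int, str, str]] = Counter()
    for v in variants:
        if v.sites() != site_set:
            raise InconsistentRecordsError(
                f"variant {v.variant_id!r} has sites {v.sites()}, expected {site_set}"
            )
        for site in site_set:
            codon = v.codons[site].upper()
            if codon == wt[site].upper():
                continue
            aa = v.residues.get(site) or translate_codon(codon)
            counts[(site, aa, codon)] += 1
    rows = [
        {
            "site": site,
            "wt_codon": wt[site],
            "amino_acid": aa,
            "codon": codon,
            "count": n,
            "min_changes": min_codon_changes(wt[site], codon),
            "translation_conflict": translate_codon(codon) != aa,
        }
        for (site, aa, codon), n in counts.items()
    ]
    return _finish_entries(rows, site_set, wt)


def tally_from_entries(entries: pd.DataFrame) -> TallyTable:
    """Build a tally from pre-aggregated (site, amino_acid, codon, count) rows.

    The layout sequencing reports print: one row per substitution with its
    count.  ``wt_codon`` per site is required; residues are taken as
    recorded and conflicts with the codon translation flagged.
    """
    required = {"site", "wt_codon", "amino_acid", "codon", "count"}
    missing = required - set(entries.columns)
    if missing:
        raise ValueError(f"entries missing columns {sorted(missing)}")
    wt = {int(s): str(c) for s, c in zip(entries["site"], entries["wt_codon"])}
    rows = [
        {
            "site": int(r["site"]),
            "wt_codon": str(r["wt_codon"]),
            "amino_acid": str(r["amino_acid"]),
            "codon": str(r["codon"]).upper(),
            "count": int(r["count"]),
            "min_changes": min_codon_changes(str(r["wt_codon"]), str(r["codon"])),
            "translation_conflict": translate_codon(str(r["codon"]))
            != str(r["amino_acid"]),
        }
        for r in entries.to_dict("records")
    ]
    return _finish_entries(rows, wt.keys(), wt)


def site_diversity(t: TallyTable) -> tuple[dict[int, int], int | None]:
    """Per-site distinct amino-acid counts and the most diverse site.

    Ties on the maximum go to the lower residue number; an empty table
    returns (empty counts, None).
    """
    counts = t.type_counts()
    if not counts:
        return counts, None
    best = min(
        (s for s in counts), key=lambda s: (-counts[s], s)
    )
    return counts, best


def summary_fractions(classes: Sequence[str]) -> dict[str, float]:
    """Percentage of each class, rounded half-up to one decimal."""
    if not classes:
        raise EmptyInputError("no class labels supplied")
    total = len(classes)
    counts = Counter(classes)
    return {
        label: float(
            (Decimal(100 * counts[label]) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for label in CLASSES
        if counts[label]
    }


def read_variants_tsv(path: str | Path, wt_codons: Mapping[int, str]) -> list[VariantRecord]:
    """Read variant records from TSV with columns id, site, codon."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "site", "codon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns {sorted(missing)}")
    records = []
    for vid, grp in df.groupby("id", sort=True):
        codons = {
            int(s): str(c).upper() for s, c in zip(grp["site"], grp["codon"])
        }
        records.append(
            VariantRecord(variant_id=str(vid), codons=codons, wt_codons=dict(wt_codons))
        )
    return records


def variants_from_cds(
    mutant_cds: Mapping[str, str], wt_cds: str, sites: Sequence[int]
) -> list[VariantRecord]:
    """Extract designed-site codons from full-length mutant CDS sequences."""
    wt_cds = wt_cds.upper()
    wt = {s: wt_cds[(s - 1) * 3 : s * 3] for s in sites}
    records = []
    for vid, seq in mutant_cds.items():
        seq = seq.upper()
        if len(seq) != len(wt_cds):
            raise IncompleteRecordError(
                f"variant {vid!r}: CDS length {len(seq)} != wild type {len(wt_cds)}"
            )
        codons = {s: seq[(s - 1) * 3 : s * 3] for s in sites}
        records.append(VariantRecord(variant_id=vid, codons=codons, wt_codons=wt))
    return records


def load_amy7c_tallies() -> TallyTable:
    """The bundled per-site substitution records for the Amy7C library screen.

    Ninety-eight rescreened α-amylase variants from a two-site NNK library
    campaign over the six coevolving sites G89, D95, H100, D144, T147 and
    N197; residue labels are kept exactly as reported (translation
    conflicts, where present, are flagged in the table).
    """
    with resources.files("coevomut.data").joinpath("amy7c_table.tsv").open() as fh:
        entries = pd.read_csv(fh, sep="\t")
    return tally_from_entries(entries)
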
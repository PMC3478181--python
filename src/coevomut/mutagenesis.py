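"""Degenerate-codon algebra and saturation-mutagenesis primer design.

A combinatorial library randomises each chosen site with an NNK codon
(N = A/C/G/T at positions 1-2, K = G/T at position 3): 32 codons covering
all 20 amino acids with a single stop (TAG).  Randomising two sites
simultaneously therefore spans 32 × 32 = 1024 codon combinations.  For
each site a complementary primer pair 33-35 nt long carries the degenerate
codon in frame at its centre, flanked by bases copied from the coding
sequence — the QuikChange-style whole-plasmid mutagenesis format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import FlankTooShortError, FrameError, InvalidCodeError, InvalidCodonError

#: IUPAC nucleotide codes mapped to the set of concrete bases.
IUPAC = {code: set(bases) for code, bases in ambiguous_dna_values.items()}

STOP = "*"


def expand_degenerate_codon(code: str) -> tuple[str, ...]:
    """All concrete DNA triplets matching a 3-letter IUPAC code.

    Deterministic lexicographic order; size equals the product of the
    per-position degeneracies (e.g. NNK -> 4*4*2 = 32).
    """
    code = code.upper()
    if len(code) != 3:
        raise InvalidCodeError(f"degenerate codon must have 3 letters: {code!r}")
    for ch in code:
        if ch not in IUPAC:
            raise InvalidCodeError(f"not an IUPAC nucleotide code: {ch!r}")
    return tuple(
        a + b + c
        for a in sorted(IUPAC[code[0]])
        for b in sorted(IUPAC[code[1]])
        for c in sorted(IUPAC[code[2]])
    )


def _check_concrete(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(ch not in "ACGT" for ch in codon):
        raise InvalidCodonError(f"not a concrete DNA triplet: {codon!r}")
    return codon


def translate_codon_set(codons: Iterable[str]) -> tuple[frozenset[str], frozenset[str]]:
    """(amino acids encoded, stop codons) under the standard genetic code."""
    aas: set[str] = set()
    stops: set[str] = set()
    for codon in codons:
        codon = _check_concrete(codon)
        aa = str(Seq(codon).translate())
        if aa == STOP:
            stops.add(codon)
        else:
            aas.add(aa)
    return frozenset(aas), frozenset(stops)


def translate_codon(codon: str) -> str:
    """One-letter residue (or ``*`` for stop) of a concrete triplet."""
    return str(Seq(_check_concrete(codon)).translate())


def min_codon_changes(codon_wt: str, codon_mut: str) -> int:
    """Positionwise Hamming distance between two concrete codons (0-3).

    The minimum number of nucleotide substitutions separating the mutant
    codon from wild type; values >= 2 mark substitutions essentially out
    of reach of error-prone PCR, which the combinatorial library accesses
    directly.
    """
    a, b = _check_concrete(codon_wt), _check_concrete(codon_mut)
    return sum(x != y for x, y in zip(a, b))


def expected_gc_fraction(primer: str) -> float:
    """GC fraction of a possibly-degenerate primer.

    Degenerate positions contribute the expected GC over their expansion
    (N -> 0.5, K -> 0.5, S -> 1.0, ...).
    """
    total = 0.0
    for ch in primer.upper():
        bases = IUPAC.get(ch)
        if not bases:
            raise InvalidCodeError(f"not an IUPAC nucleotide code: {ch!r}")
        total += sum(b in "GC" for b in bases) / len(bases)
    return total / len(primer)


def melting_temperature(primer: str) -> float:
    """QuikChange-manual Tm estimate: 81.5 + 0.41*(%GC) - 675/N (°C)."""
    n = len(primer)
    return 81.5 + 0.41 * (100.0 * expected_gc_fraction(primer)) - 675.0 / n


#: Tm the QuikChange protocol recommends primers meet or exceed.
TM_RECOMMENDED = 78.0

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC degeneracy codes."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Complementary mutagenic oligos carrying one degenerate codon."""

    target_site: int  # 1-based residue/codon number in the CDS
    forward: str
    reverse: str
    degenerate_position: int  # 0-based offset of the codon in `forward`
    melting_temperature: float

    @property
    def length(self) -> int:
        return len(self.forward)


def design_primer_pair(
    cds: str,
    site: int,
    code: str = "NNK",
    length: int = 33,
) -> PrimerPair:
    """Design a complementary primer pair replacing one codon with ``code``.

    The degenerate codon sits in frame at the centre of the forward
    primer; when the flanking length (length - 3) is odd the extra base
    goes 5'.  Flanks are copied verbatim from the CDS and the reverse
    primer is the exact reverse complement of the forward.

    Raises
    ------
    FrameError
        CDS length not a multiple of 3.
    FlankTooShortError
        Target codon too close to a CDS end for the requested length.
    """
    cds = cds.upper().replace("\n", "").replace(" ", "")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    if not 33 <= length <= 35:
        raise ValueError(f"primer length must be in [33, 35], got {length}")
    expand_degenerate_codon(code)  # validates the code
    n_codons = len(cds) // 3
    if not 1 <= site <= n_codons:
        raise FlankTooShortError(f"site {site} outside CDS of {n_codons} codons")
    start = (site - 1) * 3
    flank = length - 3
    left = flank - flank // 2  # extra base 5' when flank is odd
    right = flank // 2
    if start - left < 0 or start + 3 + right > len(cds):
        raise FlankTooShortError(
            f"site {site}: needs {left}+{right} flanking bases inside the CDS"
        )
    forward = cds[start - left : start] + code.upper() + cds[start + 3 : start + 3 + right]
    return PrimerPair(
        target_site=site,
        forward=forward,
        reverse=reverse_complement(forward),
        degenerate_position=left,
        melting_temperature=melting_temperature(forward),
    )


@dataclass(frozen=True)
class LibraryDesign:
    """A combinatorial library randomising a set of sites with one code."""

    sites: tuple[int, ...]
    code: str
    wt_codons: tuple[str, ...]
    primers: tuple[PrimerPair, ...]
    codon_combinations: int
    amino_acid_combinations: int
    stop_containing_fraction: float

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["stop_containing_fraction"] = round(
            self.stop_containing_fraction, 6
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def design_library(
    cds: str,
    sites: Sequence[int],
    code: str = "NNK",
    length: int = 33,
) -> LibraryDesign:
    """One primer pair per site plus the library's combinatorial accounting.

    Sites are randomised independently, so the theoretical codon space is
    the product of per-site expansion sizes (1024 for two NNK sites) and
    the amino-acid space the product of per-site residue counts.
    """
    sites = tuple(sorted(sites))
    expansion = expand_degenerate_codon(code)
    aas, stops = translate_codon_set(expansion)
    primers = tuple(design_primer_pair(cds, s, code, length) for s in sites)
    wt = tuple(cds.upper()[(s - 1) * 3 : s * 3] for s in sites)
    k = len(sites)
    stop_free = (1.0 - len(stops) / len(expansion)) ** k
    return LibraryDesign(
        sites=sites,
        code=code.upper(),
        wt_codons=wt,
        primers=primers,
        codon_combinations=len(expansion) ** k,
        amino_acid_combinations=len(aas) ** k,
        stop_containing_fraction=1.0 - stop_free,
    )


def library_coverage(
    design: LibraryDesign | int, clones_screened: int
) -> tuple[float, float]:
    """Expected distinct codon combinations among screened clones.

    Under uniform sampling of V variants, E[distinct] = V(1 - (1-1/V)^L)
    for L clones; completeness is that expectation over V.  Accepts a
    LibraryDesign or the variant count V directly.
    """
    v = design.codon_combinations if isinstance(design, LibraryDesign) else int(design)
    if v < 1:
        raise ValueError("variant count must be >= 1")
    if clones_screened < 0:
        raise ValueError("clones_screened must be >= 0")
    expected = v * (1.0 - (1.0 - 1.0 / v) ** clones_screened)
    return expected, expected / v


def write_primers_tsv(primers: Sequence[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tforward\treverse\tlength\ttm\tdegenerate_offset\n")
        for p in primers:
            fh.write(
                f"{p.target_site}\t{p.forward}\t{p.reverse}"
                f"\t{p.length}\t{p.melting_temperature:.2f}\t{p.degenerate_position}\n"
            )
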
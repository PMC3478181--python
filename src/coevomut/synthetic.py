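"""Synthetic alignments with planted coevolving pairs and NNK variant pools.

The alignment generator draws each background column independently from a
residue profile (uniform over the 20 amino acids by default); for each
planted column pair, the second column is — with probability ``coupling``
— a fixed random bijection of the first, and an independent draw
otherwise.  Under a bijection at coupling 1 the pair's mutual information
equals the first column's empirical entropy, which gives the detector an
analytically known target.  Rows are independent: no phylogenetic tree
relates the sequences, so the shared-ancestry bias that RCW weighting is
meant to damp in real families is absent here by construction.

Gaps are injected independently per cell at ``gap_rate`` in every row
except the query, which stays gap-free so that planted columns always map
to query residue numbers.

The variant-pool generator draws each designed site's codon uniformly from
the degenerate expansion — the idealised product a saturation-mutagenesis
protocol aims for — and records the generating tallies as ground truth.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .library_analysis import VariantRecord
from .msa_io import AA20, Alignment
from .mutagenesis import LibraryDesign, expand_degenerate_codon

QUERY_ID = "query"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic family alignment.

    Defaults are the standard recovery test-bed: 300 sequences by 50
    columns with uniform background, no gaps, full coupling.
    """

    n_seqs: int = 300
    n_cols: int = 50
    planted_pairs: tuple[tuple[int, int], ...] = ()  # 0-based column pairs
    coupling: float = 1.0
    profile: tuple[float, ...] | None = None  # length 20, sums to 1; None=uniform
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 2 or self.n_cols < 2:
            raise ConfigError("need n_seqs >= 2 and n_cols >= 2")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must be in [0, 1]")
        if not 0.0 <= self.gap_rate <= 1.0:
            raise ConfigError("gap_rate must be in [0, 1]")
        used: set[int] = set()
        for a, b in self.planted_pairs:
            if a == b or not (0 <= a < self.n_cols and 0 <= b < self.n_cols):
                raise ConfigError(f"bad planted pair ({a}, {b})")
            if a in used or b in used:
                raise ConfigError("planted pairs must use distinct columns")
            used.update((a, b))
        if self.profile is not None:
            p = np.asarray(self.profile, dtype=float)
            if p.shape != (20,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError("profile must be 20 nonnegative values summing to 1")


def simulate_coevolving_alignment(
    cfg: SimulationConfig,
) -> tuple[Alignment, dict]:
    """Generate an alignment and its ground truth, reproducibly from seed."""
    rng = np.random.default_rng(cfg.seed)
    p = (
        np.full(20, 1.0 / 20)
        if cfg.profile is None
        else np.asarray(cfg.profile, dtype=float)
    )
    codes = rng.choice(20, size=(cfg.n_seqs, cfg.n_cols), p=p)
    bijections: dict[str, list[int]] = {}
    for a, b in cfg.planted_pairs:
        perm = rng.permutation(20)
        coupled = rng.random(cfg.n_seqs) < cfg.coupling
        codes[coupled, b] = perm[codes[coupled, a]]
        bijections[f"{a},{b}"] = perm.tolist()

    letters = np.frombuffer(AA20.encode("ascii"), dtype=np.uint8)
    chars = letters[codes]
    if cfg.gap_rate > 0:
        gaps = rng.random((cfg.n_seqs, cfg.n_cols)) < cfg.gap_rate
        gaps[0, :] = False  # query row stays gap-free
        chars = np.where(gaps, ord("-"), chars)
    rows = tuple(
        bytes(chars[i].astype(np.uint8)).decode("ascii") for i in range(cfg.n_seqs)
    )
    ids = (QUERY_ID,) + tuple(f"seq{i}" for i in range(1, cfg.n_seqs))
    truth = {
        "planted_pairs": [list(pr) for pr in cfg.planted_pairs],
        "coupling": cfg.coupling,
        "gap_rate": cfg.gap_rate,
        "seed": cfg.seed,
        "bijections": bijections,
    }
    return Alignment(ids, rows, QUERY_ID), truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_variant_pool(
    design: LibraryDesign, n_variants: int, seed: int = 0
) -> tuple[list[VariantRecord], dict[int, Counter]]:
    """Draw a variant pool uniformly from the library's codon expansions.

    Returns the records and the generating per-site codon tallies (all
    draws, wild-type codons included).
    """
    if n_variants < 0:
        raise ConfigError("n_variants must be >= 0")
    rng = np.random.default_rng(seed)
    expansion = expand_degenerate_codon(design.code)
    wt = dict(zip(design.sites, design.wt_codons))
    truth: dict[int, Counter] = {s: Counter() for s in design.sites}
    records = []
    for k in range(n_variants):
        codons = {}
        for site in design.sites:
            codon = expansion[rng.integers(len(expansion))]
            codons[site] = codon
            truth[site][codon] += 1
        records.append(
            VariantRecord(variant_id=f"v{k:05d}", codons=codons, wt_codons=wt)
        )
    return records, truth
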
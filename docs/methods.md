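# Methods

## Mutual information on alignment columns

For columns A and B of a protein family alignment, the score is

    MI(A:B) = Σᵢ Σⱼ P(aᵢ,bⱼ) · log₂₀ [ P(aᵢ,bⱼ) / (P(aᵢ) P(bⱼ)) ]

with all frequencies observed (no pseudocounts) over the rows that carry a
standard residue at *both* columns. Conventions, and why:

- **Base-20 logarithm.** 20 is the alphabet size, so column entropy and MI
  are bounded by 1; a bijective pairing of 20 equifrequent residues scores
  exactly 1.
- **Pairwise gap/missing exclusion.** Gaps (`-`, `.`) and non-standard
  letters (B, Z, J, U, O, normalised to X on input) are not part of the
  20-letter alphabet the logarithm base presumes, so rows carrying them at
  either column are excluded from that pair's counts only. Marginals are
  therefore recomputed per pair on the shared row subset, which keeps the
  joint's marginals exactly consistent with the per-column frequencies.
  A pair with fewer than two complete rows is recorded as missing in the
  matrix (NaN) rather than scored.
- **0·log 0 = 0**; tiny negative rounding residues are clipped at 0.

## Row-column weighting (RCW)

    RCW(A:B) = MI_AB / [ (MI_A· + MI_·B − 2 MI_AB) / (n − 1) ]

The denominator is the average MI that A and B achieve against all *other*
columns, which damps high-entropy or phylogenetically biased columns that
correlate with everything.

- **Diagonal convention.** MI_ii is never computed; row and column sums
  run over off-diagonal entries only, and subtracting 2·MI_AB removes the
  pair's own score from its normalisation. Self-information in the sums
  would reward exactly the promiscuous columns the weighting exists to
  damp.
- **The count n** defaults to the number of alignment sequences, with a
  `columns` option (the convention in the corrected-MI literature). Since
  (n−1) is one positive factor applied to every entry, the pair *ranking*
  is provably identical under both; tests assert this.
- **Zero denominator ⇒ RCW = 0**: if a pair's row and column carry no MI
  anywhere, there is no evidence of coevolution. The only way MI_AB > 0
  can co-occur with a zero denominator is degenerate geometry (exactly two
  scored columns, where the denominator is identically zero); that case
  warns and still returns 0, and RCW should simply not be used below three
  columns.
- **Selection rule.** Default: RCW > mean + 2·SD of all finite
  off-diagonal values; `topk` override available. Ties in the descending
  sort break on (site_a, site_b) so output is deterministic. Sites are
  reported in 1-based query-residue numbering; pairs involving columns
  where the query is gapped cannot be named and are skipped.

## Alignment preparation

Sequence reduction maximises the area objective: (kept sequences) ×
(columns gap-free across all kept sequences). The optimiser is a
steepest-descent *peel*: repeatedly apply the single removal (query
protected) that yields the largest area, down to the configured minimum
sequence count (default 10), and return the best state encountered. A
plain stop-at-first-non-improvement ascent was rejected: when several
fragmentary sequences jointly spoil the same columns, every single removal
sits on an area plateau and strict ascent stalls; tracking the best state
along the full peel walks through such plateaus, still never returns an
area below the input's, and stays within 90% of the exhaustive-subset
optimum on seeded fragmentary-family fixtures (the exhaustive optimiser is
part of the package, usable up to ~20 sequences). A too-few-sequences
error is raised only when a strictly improving removal exists from the
returned state but the minimum-count floor blocks it. Note that under
*diffuse* per-cell gaps no removal creates gap-free columns, so the
reduction correctly keeps everything and column filtering plus pairwise
exclusion carry the load.

Column filtering removes columns whose gap fraction strictly exceeds
`max_gap_fraction` (default 0.5, a balance between retaining signal and
starving pair counts); all-gap columns are always dropped.

Optional exact-duplicate sequence removal is off by default: duplicates
inflate counts without adding information, but deduplication is not part
of the reference workflow, so it is opt-in.

## Library design

- NNK (N = A/C/G/T at codon positions 1–2, K = G/T at position 3) is the
  default saturation code: 32 codons, all 20 amino acids, one stop (TAG).
  Any 3-letter IUPAC code is accepted; expansion size is the product of
  per-letter degeneracies.
- Primers are 33–35 nt (default 33) with the degenerate codon in frame at
  the centre; when the flank total is odd the extra base goes 5′. Flanks
  are copied verbatim from the CDS and the reverse primer is the exact
  reverse complement (IUPAC-aware: complement of K is M).
- Melting temperature uses the QuikChange manual estimate
  Tm = 81.5 + 0.41·(%GC) − 675/N, with degenerate positions contributing
  their expected GC over the expansion (N and K both 0.5). Primers below
  78 °C are warned about, not rejected — the threshold is a protocol
  guideline, not a physical limit.
- Two-site accounting treats sites as independent draws: 32² = 1024 codon
  combinations, 20² amino-acid combinations, stop-containing fraction
  1 − (31/32)². Expected screening coverage of V combinations by L clones
  is V(1 − (1 − 1/V)^L), monotone in L.

## Screen analysis

Variants are classified by translated residues at the designed sites:
no change at any site (DNA-identical and synonymous lumped together —
the class a screen reads as "false positives"), single missense, double
missense, or stop-containing. Percentages round half-up to one decimal.

Tallies count, per site, every observed codon differing from wild type,
keyed by amino acid, with the Hamming distance to the wild-type codon
attached (the minimum number of nucleotide changes a conventional
mutagenesis method would have needed). Diversity ("kinds of amino acids
per site") counts distinct amino-acid labels among those entries —
synonymous-to-wild-type entries included, stops excluded. When records
carry an explicitly reported residue it takes precedence over the codon's
translation and disagreements are flagged per entry rather than silently
rewritten; the bundled Amy7C screen table contains three such conflicts,
which are preserved exactly as reported.

## Synthetic data

`simulate_coevolving_alignment` draws each background column iid from a
residue profile (uniform over 20 by default); for each planted pair the
second column is, with probability `coupling`, a fixed random bijection of
the first, else an independent draw. The bijection mechanism was chosen
over a Potts-style model because its MI is analytically known at the
endpoints: at coupling 1 the pair's MI equals the first column's empirical
entropy, at coupling 0 it is background. Gaps are injected independently
per cell at `gap_rate` in every row except the query, which stays gap-free
so planted columns always map to query residues. Defaults (300 sequences,
50 columns) are the standard recovery test-bed used throughout the tests
and the acceptance script.

What the generator deliberately does not emulate: phylogenetic relatedness
between rows (sequences are independent), column-specific conservation
profiles, or structured gap patterns (indel blocks). Passing recovery
tests therefore demonstrates correctness of the estimator and the ranking
machinery, not robustness to shared-ancestry confounding — the main reason
real-data MI studies add corrections in the first place.

`simulate_variant_pool` draws each designed site's codon uniformly from
the degenerate expansion (the idealised library) and returns the
generating tallies, so tally round-trips can assert exact recovery.

## Numerical and determinism choices

- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed yields byte-identical alignments, pools and CLI outputs.
- Matrices are written with six decimals, scores likewise; ties in every
  ranking break on ascending site indices.
- Frequency tables sum to 1 within 1e-12; MI oracle agreement is asserted
  at 1e-12.

## Known limitations

- No correction for phylogenetic relatedness beyond RCW weighting (no APC,
  no DCA); detected pairs on real families inherit MI's known bias toward
  shared-ancestry signal.
- Finite-sample MI bias (~(19·19)/(2 n ln 20) at uniform columns) is not
  subtracted; with few sequences the background floor rises and the z-score
  selection becomes conservative.
- The two-column RCW geometry is degenerate (see above).
- Primer design assumes a plain CDS with the target codon at
  3·(site−1): no intron, vector or codon-offset handling.
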
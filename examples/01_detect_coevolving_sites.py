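"""Detect coevolving site pairs in a family alignment.

Builds a synthetic protein family (300 sequences, 50 columns) with three
planted covarying column pairs, trims it, scores every column pair with
base-20 mutual information, applies row-column weighting, and prints the
selected pairs in query-residue numbering.
"""

from coevomut import (
    column_to_query_map,
    drop_gapped_columns,
    maxalign_reduce,
    mi_matrix,
    rcw_matrix,
    select_coevolving_pairs,
)
from coevomut.synthetic import SimulationConfig, simulate_coevolving_alignment

cfg = SimulationConfig(
    n_seqs=300,
    n_cols=50,
    planted_pairs=((3, 17), (5, 30), (10, 44)),  # 0-based columns
    coupling=0.9,
    gap_rate=0.05,
    seed=42,
)
aln, truth = simulate_coevolving_alignment(cfg)
print(f"family: {aln.n_seqs} sequences x {aln.n_cols} columns")

# With diffuse per-cell gaps no single sequence spoils whole columns, so
# the area-maximising reduction rightly keeps everything; it earns its
# keep on families with fragmentary rows.  Pairwise gap exclusion inside
# MI handles the residual gaps.
aln, report = maxalign_reduce(aln, min_seqs=250)
aln = drop_gapped_columns(aln, max_gap_fraction=0.5)
print(
    f"after trimming: {aln.n_seqs} sequences, {aln.n_cols} columns "
    f"({len(report.removed_ids)} sequence(s) removed)"
)

mi = mi_matrix(aln)
rcw = rcw_matrix(mi, n=aln.n_seqs)  # ranking identical under n_mode="columns"
pairs, sites = select_coevolving_pairs(
    rcw, column_to_query_map(aln), aln.query_sequence, mi=mi, rule="zscore"
)

print(f"\nselected {len(pairs)} pair(s) over {len(sites)} unique site(s):")
print("rank  site_a  site_b   MI      RCW")
for p in pairs:
    print(
        f"{p.rank:>4}  {p.wt_a}{p.site_a:<6} {p.wt_b}{p.site_b:<6} "
        f"{p.mi_score:.4f}  {p.rcw_score:8.2f}"
    )
print(f"\nplanted column pairs (1-based): "
      f"{[(a + 1, b + 1) for a, b in truth['planted_pairs']]}")
print(
    "Each selected pair scores above mean + 2 SD of all off-diagonal RCW\n"
    "values; at coupling 0.9 the three planted pairs dominate the ranking."
)
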
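"""MI / RCW scoring, pair selection and site geometry.

The matrix implementation is checked entry-for-entry against a deliberately
naive per-pair oracle (plain-dict counting, no numpy), and on gap-free
fixtures against scikit-learn's ``mutual_info_score`` rescaled to base 20.
"""

import math
from collections import Counter

import numpy as np
import pytest

from conftest import random_alignment
from coevomut.coevolution import (
    MIMatrix,
    column_entropy,
    mi_matrix,
    mutual_information,
    pair_frequencies,
    pair_ranking,
    rcw_matrix,
    select_coevolving_pairs,
    site_distance_stats,
)
from coevomut.errors import (
    InsufficientDataError,
    InsufficientSitesError,
    InvalidNError,
    MissingCoordinateError,
)
from coevomut.msa_io import Alignment, column_to_query_map


def oracle_mi(aln: Alignment, a: int, b: int) -> float:
    """Brute-force Eq.-style MI: dict counting, pairwise gap/X exclusion."""
    pairs = [
        (ra[a], ra[b])
        for ra in aln.rows
        if ra[a] not in "-X" and ra[b] not in "-X"
    ]
    n = len(pairs)
    joint = Counter(pairs)
    pa = Counter(x for x, _ in pairs)
    pb = Counter(y for _, y in pairs)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * math.log(pxy / ((pa[x] / n) * (pb[y] / n)), 20)
    return total


class TestMutualInformation:
    def test_constant_column_gives_zero(self):
        aln = Alignment(("q", "b", "c", "d"), ("AD", "AE", "AD", "AE"), "q")
        assert mutual_information(aln, 0, 1) == 0.0

    def test_twenty_distinct_residues_bijective_pair_is_one(self):
        col = "ACDEFGHIKLMNPQRSTVWY"
        rows = tuple(ch + ch for ch in col)
        aln = Alignment(tuple(f"s{i}" for i in range(20)), rows, "s0")
        assert mutual_information(aln, 0, 1) == pytest.approx(1.0, abs=1e-12)

    def test_two_block_pair_equals_log20_two(self):
        aln = Alignment(("q", "b", "c", "d"), ("AD", "AD", "CE", "CE"), "q")
        expected = math.log(2, 20)  # 0.23137...
        assert mutual_information(aln, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_insufficient_complete_rows(self):
        aln = Alignment(("q", "b", "c"), ("A-", "-D", "AD"), "q")
        with pytest.raises(InsufficientDataError):
            mutual_information(aln, 0, 1)

    def test_gap_rows_excluded_pairwise(self):
        # the gapped 4th row must not contribute to the pair counts
        full = Alignment(("q", "b", "c"), ("AD", "AD", "CE"), "q")
        gapped = Alignment(("q", "b", "c", "d"), ("AD", "AD", "CE", "A-"), "q")
        assert mutual_information(gapped, 0, 1) == mutual_information(full, 0, 1)

    def test_joint_marginals_match_column_frequencies_on_shared_rows(self, rng):
        aln = random_alignment(rng, 40, 6, gap_rate=0.15)
        pf = pair_frequencies(aln, 1, 4)
        assert pf.joint.min() >= 0
        assert pf.joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert pf.marginal_a.sum() == pytest.approx(1.0, abs=1e-12)


class TestMIMatrix:
    def test_matches_bruteforce_oracle_on_random_fixtures(self, rng):
        for gap_rate in (0.0, 0.2):
            aln = random_alignment(rng, 30, 10, gap_rate=gap_rate)
            mat = mi_matrix(aln)
            for i in range(10):
                for j in range(i + 1, 10):
                    assert mat.values[i, j] == pytest.approx(
                        oracle_mi(aln, i, j), abs=1e-12
                    )
                    assert mat.values[i, j] == mat.values[j, i]

    def test_matches_sklearn_on_gapfree_fixture(self, rng):
        from sklearn.metrics import mutual_info_score

        aln = random_alignment(rng, 60, 5)
        mat = mi_matrix(aln)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = mutual_info_score(
                    [r[i] for r in aln.rows], [r[j] for r in aln.rows]
                ) / math.log(20)
                assert mat.values[i, j] == pytest.approx(ref, abs=1e-12)

    def test_bounds_and_symmetry_on_random_pairs(self, rng):
        aln = random_alignment(rng, 25, 12, gap_rate=0.1)
        mat = mi_matrix(aln)
        for i in range(12):
            for j in range(i + 1, 12):
                v = mat.values[i, j]
                bound = min(column_entropy(aln, i), column_entropy(aln, j))
                assert 0.0 <= v <= bound + 1e-12 <= 1.0 + 1e-12

    def test_uninformative_pair_recorded_missing_not_crash(self):
        aln = Alignment(("q", "b", "c"), ("A-C", "-DC", "ADC"), "q")
        mat = mi_matrix(aln)
        assert (0, 1) in mat.missing
        assert np.isnan(mat.values[0, 1])

    def test_constant_columns_give_all_zero(self):
        aln = Alignment(("q", "b"), ("ACD", "ACD"), "q")
        mat = mi_matrix(aln)
        off = mat.values[np.triu_indices(3, k=1)]
        assert np.all(off == 0.0)


class TestRCW:
    def test_hand_worked_three_column_example(self):
        v = np.full((3, 3), np.nan)
        v[0, 1] = v[1, 0] = 0.4
        v[0, 2] = v[2, 0] = 0.2
        v[1, 2] = v[2, 1] = 0.1
        rcw = rcw_matrix(MIMatrix(v, ()), n=10)
        # RCW(1,2) = 0.4 / ((0.6 + 0.5 - 0.8) / 9) = 12.0
        assert rcw.values[0, 1] == pytest.approx(12.0, abs=1e-12)

    def test_zero_mi_gives_zero_rcw(self):
        v = np.full((3, 3), np.nan)
        v[0, 1] = v[1, 0] = 0.0
        v[0, 2] = v[2, 0] = 0.3
        v[1, 2] = v[2, 1] = 0.2
        rcw = rcw_matrix(MIMatrix(v, ()), n=5)
        assert rcw.values[0, 1] == 0.0

    def test_equal_mi_gives_equal_rcw(self):
        v = np.full((4, 4), 0.25)
        np.fill_diagonal(v, np.nan)
        rcw = rcw_matrix(MIMatrix(v, ()), n=7)
        off = rcw.values[np.triu_indices(4, k=1)]
        assert np.allclose(off, off[0])

    def test_invalid_n(self):
        v = np.full((3, 3), 0.1)
        np.fill_diagonal(v, np.nan)
        with pytest.raises(InvalidNError):
            rcw_matrix(MIMatrix(v, ()), n=1)

    def test_ranking_invariant_to_n_convention(self, rng):
        aln = random_alignment(rng, 40, 12)
        mi = mi_matrix(aln)
        by_seqs = pair_ranking(rcw_matrix(mi, n=40, n_mode="sequences"))
        by_cols = pair_ranking(rcw_matrix(mi, n=12, n_mode="columns"))
        assert by_seqs == by_cols

    def test_two_column_degenerate_geometry_warns_and_zeroes(self):
        v = np.full((2, 2), np.nan)
        v[0, 1] = v[1, 0] = 0.5
        with pytest.warns(UserWarning):
            rcw = rcw_matrix(MIMatrix(v, ()), n=10)
        assert rcw.values[0, 1] == 0.0


class TestSelection:
    def _setup(self, rng):
        from coevomut.synthetic import SimulationConfig, simulate_coevolving_alignment

        cfg = SimulationConfig(
            n_seqs=120, n_cols=12, planted_pairs=((2, 7),), coupling=1.0, seed=7
        )
        aln, _ = simulate_coevolving_alignment(cfg)
        mi = mi_matrix(aln)
        rcw = rcw_matrix(mi, n=aln.n_seqs)
        return aln, mi, rcw

    def test_topk_one_returns_best_pair(self, rng):
        aln, mi, rcw = self._setup(rng)
        cmap = column_to_query_map(aln)
        pairs, sites = select_coevolving_pairs(
            rcw, cmap, aln.query_sequence, mi=mi, rule="topk", top_k=1
        )
        assert len(pairs) == 1
        assert (pairs[0].site_a, pairs[0].site_b) == (3, 8)  # 1-based residues
        assert pairs[0].rank == 1
        assert sites == [3, 8]
        assert pairs[0].wt_a == aln.query_sequence[2]

    def test_threshold_above_max_selects_nothing(self, rng):
        aln, mi, rcw = self._setup(rng)
        cmap = column_to_query_map(aln)
        pairs, sites = select_coevolving_pairs(
            rcw, cmap, aln.query_sequence, mi=mi, rule="zscore", z=1e9
        )
        assert pairs == [] and sites == []

    def test_zscore_rule_finds_the_planted_pair(self, rng):
        aln, mi, rcw = self._setup(rng)
        cmap = column_to_query_map(aln)
        pairs, _ = select_coevolving_pairs(
            rcw, cmap, aln.query_sequence, mi=mi, rule="zscore"
        )
        assert {(p.site_a, p.site_b) for p in pairs} >= {(3, 8)}
        assert pairs == sorted(
            pairs, key=lambda p: (-p.rcw_score, p.site_a, p.site_b)
        )

    def test_pair_count_vs_unique_site_count_shape(self):
        """10 selected pairs over 6 unique sites yields a site set of 6."""
        from coevomut.coevolution import CoevolvingPair

        sites6 = [89, 95, 100, 144, 147, 197]
        combos = [
            (89, 95), (89, 100), (89, 144), (89, 147), (95, 100),
            (95, 147), (100, 144), (100, 197), (144, 197), (147, 197),
        ]
        pairs = [
            CoevolvingPair(a, b, "G", "D", 0.5, 5.0, r)
            for r, (a, b) in enumerate(combos, 1)
        ]
        unique = sorted({s for p in pairs for s in (p.site_a, p.site_b)})
        assert len(pairs) == 10 and unique == sites6


class TestShuffledColumnsLoseSignal:
    def test_shuffled_planted_pair_falls_to_permutation_null(self, rng):
        """Destroying row pairing drops planted MI below the null 95th pct."""
        from coevomut.synthetic import SimulationConfig, simulate_coevolving_alignment

        cfg = SimulationConfig(
            n_seqs=150, n_cols=20, planted_pairs=((0, 1),), coupling=1.0, seed=11
        )
        aln, _ = simulate_coevolving_alignment(cfg)
        background = [
            mutual_information(aln, i, j)
            for i in range(2, 20)
            for j in range(i + 1, 20)
        ]
        null95 = np.quantile(background, 0.95)
        assert mutual_information(aln, 0, 1) > null95  # intact signal clears it
        shuffled_mis = []
        col0 = list(aln.rows)
        for _ in range(100):
            perm = rng.permutation(aln.n_seqs)
            rows = tuple(
                aln.rows[perm[k]][0] + aln.rows[k][1:] for k in range(aln.n_seqs)
            )
            shuf = Alignment(aln.ids, rows, aln.query_id)
            shuffled_mis.append(mutual_information(shuf, 0, 1))
        assert np.mean(shuffled_mis) < null95


class TestSiteDistances:
    def test_two_sites(self):
        coords = {1: (0.0, 0.0, 0.0), 9: (3.0, 4.0, 0.0)}
        assert site_distance_stats([1, 9], coords) == (5.0, 0.0)

    def test_three_four_five_triangle(self):
        coords = {1: (0, 0, 0), 2: (3, 0, 0), 3: (0, 4, 0)}
        mean, sd = site_distance_stats([1, 2, 3], coords)
        assert mean == pytest.approx(4.0)
        assert sd == pytest.approx(1.0)

    def test_single_site_raises(self):
        with pytest.raises(InsufficientSitesError):
            site_distance_stats([5], {5: (0, 0, 0)})

    def test_missing_coordinate_raises(self):
        with pytest.raises(MissingCoordinateError):
            site_distance_stats([1, 2], {1: (0, 0, 0)})
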
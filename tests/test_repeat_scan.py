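"""Windowed repeat scan: window arithmetic, fragment comparison, chaining,
and set-level equivalence with the all-diagonals brute-force scan."""

import random

import pytest

from oracles import brute_repeat_scan, kadane_best_segment, maximal_scoring_segments, rc
from planting import plant_plain_repeats
from dgrhunt.core import Contig
from dgrhunt.repeat_scan import (
    chain_and_merge,
    compare_fragments,
    find_repeat_pairs,
    fragment_windows,
    make_fragments,
    scan_flanks,
)
from dgrhunt.rt_search import RTHit


def _hit(contig_id, s, e, L):
    return RTHit(contig_id, "+", 0, (s, e), (0, (e - s) // 3), "ref", 100.0, 1e-20)


class TestFragmentWindows:
    def test_full_window_count_10kb(self):
        windows = fragment_windows((0, 10_000), 200, 50)
        full = [w for w in windows if w[1] - w[0] == 200]
        assert len(full) == 197  # floor((10000-200)/50)+1

    def test_degenerate_region_single_window(self):
        assert fragment_windows((100, 300), 200, 50) == [(100, 300)]
        assert fragment_windows((0, 30), 200, 50) == [(0, 30)]

    @pytest.mark.parametrize("seed", range(5))
    def test_windows_cover_region(self, seed):
        rng = random.Random(seed)
        start = rng.randint(0, 1000)
        end = start + rng.randint(1, 3000)
        windows = fragment_windows((start, end), 200, 50)
        assert windows[0][0] == start
        covered = set()
        for s, e in windows:
            covered.update(range(s, e))
        assert covered == set(range(start, end))
        starts = [s for s, _ in windows]
        assert all(b - a == 50 for a, b in zip(starts, starts[1:]))

    def test_invalid_window_step(self):
        with pytest.raises(ValueError):
            fragment_windows((0, 100), 50, 200)


class TestScanFlanks:
    def test_interior_hit(self):
        c = Contig("c", "A" * 50_000)
        assert scan_flanks(c, _hit("c", 20_000, 21_000, 50_000)) == (10_000, 31_000)

    def test_clipped_at_contig_start(self):
        c = Contig("c", "A" * 15_000)
        assert scan_flanks(c, _hit("c", 100, 1_000, 15_000)) == (0, 11_000)

    def test_zero_flank_is_rt_interval(self):
        c = Contig("c", "A" * 15_000)
        assert scan_flanks(c, _hit("c", 100, 1_000, 15_000), flank=0) == (100, 1_000)


class TestCompareFragments:
    def test_exact_repeat_direct_match(self):
        rng = random.Random(0)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        unit = bg(200)
        seq = bg(1000) + unit + bg(5000) + unit + bg(1000)
        contig = Contig("c", seq)
        frags = make_fragments(contig, (0, len(seq)))
        matches = compare_fragments(frags, contig)
        exact = [m for m in matches if m.identity == 1.0 and m.orientation == "direct"
                 and m.aligned_columns >= 150]
        assert exact, "planted exact repeat not matched"

    def test_inverted_repeat_detected(self):
        rng = random.Random(1)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        unit = bg(260)
        seq = bg(800) + unit + bg(2000) + rc(unit) + bg(800)
        contig = Contig("c", seq)
        matches = compare_fragments(make_fragments(contig, (0, len(seq))), contig)
        assert any(m.orientation == "inverted" and m.identity == 1.0 for m in matches)

    def test_overlapping_fragments_excluded(self):
        # tandem A-runs make every window identical, but overlapping window
        # pairs must not be reported
        contig = Contig("c", "ACGT" * 100)
        matches = compare_fragments(make_fragments(contig, (0, 400)), contig)
        for m in matches:
            assert m.interval_a[1] <= m.interval_b[0]


class TestChainAndMerge:
    def test_exact_300bp_repeat_merges_to_one_pair(self):
        rng = random.Random(2)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        unit = bg(300)
        seq = bg(700) + unit + bg(3000) + unit + bg(700)
        contig = Contig("c", seq)
        pairs = find_repeat_pairs(contig)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.identity == 1.0
        # spans the planted 300 bp within a few chance-match bases
        assert abs((p.interval_a[1] - p.interval_a[0]) - 300) <= 10
        assert abs(p.interval_a[0] - 700) <= 5 and abs(p.interval_b[0] - 4000) <= 5

    def test_two_unrelated_repeats_stay_separate(self):
        rng = random.Random(3)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        u1, u2 = bg(250), bg(250)
        seq = bg(500) + u1 + bg(1500) + u2 + bg(1500) + u1 + bg(1000) + u2 + bg(500)
        pairs = find_repeat_pairs(Contig("c", seq))
        assert len(pairs) == 2

    def test_no_matches_no_pairs(self):
        assert chain_and_merge([], Contig("c", "ACGT" * 50)) == []

    def test_mirrored_construction_symmetry(self):
        """Swapping the two planted copies mirrors intervals but leaves the
        pair count and identity unchanged."""
        seq, truth = plant_plain_repeats(3_000, 1, seed=10)
        (a, b, orient) = truth[0]
        contig = Contig("c", seq)
        swapped = list(seq)
        swapped[a[0]:a[1]], swapped[b[0]:b[1]] = seq[b[0]:b[1]], seq[a[0]:a[1]]
        pairs = find_repeat_pairs(contig)
        pairs_sw = find_repeat_pairs(Contig("c", "".join(swapped)))
        assert len(pairs) == len(pairs_sw) == 1
        assert pairs[0].identity == pytest.approx(pairs_sw[0].identity)
        assert pairs[0].interval_a == pairs_sw[0].interval_a


class TestSegmentOracle:
    """Vetting of the Ruzzo–Tompa enumeration used by the brute-force scan."""

    @pytest.mark.parametrize("seed", range(10))
    def test_segments_disjoint_positive_and_contain_optimum(self, seed):
        rng = random.Random(seed)
        scores = [rng.choice([2.0, -3.0]) for _ in range(200)]
        segs = sorted(maximal_scoring_segments(scores))
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            assert e1 <= s2
        sums = [sum(scores[s:e]) for s, e in segs]
        assert all(v > 0 for v in sums)
        best = kadane_best_segment(scores)
        assert best == pytest.approx(max(sums, default=0.0))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_windowed_scan_equals_brute_force(self, seed):
        """On small contigs the windowed scan recovers exactly the repeat-pair
        set of the independent all-diagonals scan (pairs >= window length)."""
        n_rep = seed % 4
        seq, _ = plant_plain_repeats(4_000, n_rep, seed=100 + seed)
        contig = Contig("c", seq)
        detected = {
            (p.interval_a[0], p.interval_a[1], p.interval_b[0], p.interval_b[1],
             p.orientation)
            for p in find_repeat_pairs(contig)
            if p.aligned_columns >= 200
        }
        expected = brute_repeat_scan(seq, min_len=200, min_identity=0.8)
        assert detected == expected
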
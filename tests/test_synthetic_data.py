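"""Generator correctness: reverse translation, mutagenesis bookkeeping,
feature placement, and composition-preserving shuffles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import dinucleotide_counts
from dgrhunt.core import CODON_TO_AA, revcomp, translate_dna
from dgrhunt.synthetic_data import (
    GeneratorConfig,
    make_null_contig,
    make_rt_gene,
    mutagenize_tr,
    plant_dgr,
    swap_repeat_copies,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestMakeRtGene:
    @pytest.mark.parametrize("protein,expected", [("M", "ATG"), ("MW", "ATGTGG")])
    def test_unique_codon_amino_acids(self, protein, expected):
        assert make_rt_gene(protein, seed=0) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA20, min_size=1, max_size=60), st.integers(0, 2**20))
    def test_round_trip(self, protein, seed):
        assert translate_dna(make_rt_gene(protein, seed)) == protein

    def test_deterministic_in_seed(self):
        p = "MKLVSTANQRW"
        assert make_rt_gene(p, seed=7) == make_rt_gene(p, seed=7)

    def test_rejects_nonstandard_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            make_rt_gene("MKBX", seed=0)


class TestMutagenizeTr:
    def test_identity_when_no_substitutions(self):
        vr, subs = mutagenize_tr("AAAA", 0, 0, imh_length=0, seed=0)
        assert vr == "AAAA" and subs == []

    def test_ninety_percent_identity_regime(self):
        # 8 substitutions over 90 bp leaves ~91 % identity, the typical
        # TR/VR divergence of natural elements
        rng = np.random.default_rng(3)
        tr = "".join(rng.choice(list("ACGT"), 90))
        vr, subs = mutagenize_tr(tr, 7, 1, imh_length=10, seed=4)
        ident = sum(a == b for a, b in zip(tr, vr)) / 90
        assert len(subs) == 8
        assert ident == pytest.approx((90 - 8) / 90)

    @pytest.mark.parametrize("seed", range(8))
    def test_recount_oracle(self, seed):
        """Recounting column types from the two strings reproduces the
        requested substitution counts exactly."""
        rng = np.random.default_rng(seed)
        tr = "".join(rng.choice(list("AACGT"), 120))  # A-rich
        n_a, n_n = int(rng.integers(0, 9)), int(rng.integers(0, 4))
        vr, subs = mutagenize_tr(tr, n_a, n_n, imh_length=15, seed=seed + 100)
        assert len(vr) == len(tr)
        got_a = sum(1 for a, b in zip(tr, vr) if a != b and a == "A")
        got_n = sum(1 for a, b in zip(tr, vr) if a != b and a != "A")
        assert (got_a, got_n) == (n_a, n_n)
        # no substitution ever writes an A, so classification stays symmetric
        assert all(v != "A" for _, _, v in subs)
        assert subs == sorted(subs)
        assert tr[-15:] == vr[-15:]

    def test_rejects_impossible_budget(self):
        with pytest.raises(ValueError, match="adenine"):
            mutagenize_tr("CCCCCCCCCC", 1, 0, imh_length=0, seed=0)

    def test_frame_aware_substitution_avoids_stops(self):
        # TAT -> TAG would create a stop; with frame=0 it must be avoided
        for seed in range(20):
            vr, _ = mutagenize_tr("TATTATTAT", 0, 3, imh_length=0, seed=seed, frame=0)
            assert "*" not in translate_dna(vr)


class TestPlantDgr:
    def test_deterministic(self):
        cfg = GeneratorConfig(contig_length=8_000, seed=5)
        c1, t1 = plant_dgr(cfg)
        c2, t2 = plant_dgr(cfg)
        assert c1.seq == c2.seq and t1 == t2

    def test_extraction_oracle(self, planted):
        """Aligning the planted TR/VR substrings gaplessly reproduces the
        generator's substitution list exactly."""
        contig, truth = planted
        tr = contig.seq[truth.tr_interval[0]:truth.tr_interval[1]]
        vr = contig.seq[truth.vr_interval[0]:truth.vr_interval[1]]
        observed = tuple(
            (i, a, b) for i, (a, b) in enumerate(zip(tr, vr)) if a != b
        )
        assert observed == truth.substituted_positions

    def test_identity_bookkeeping(self, planted):
        contig, truth = planted
        tr_len = truth.tr_interval[1] - truth.tr_interval[0]
        ident = 1 - len(truth.substituted_positions) / tr_len
        tr = contig.seq[truth.tr_interval[0]:truth.tr_interval[1]]
        vr = contig.seq[truth.vr_interval[0]:truth.vr_interval[1]]
        assert sum(a == b for a, b in zip(tr, vr)) / tr_len == pytest.approx(ident)

    def test_feature_order_and_layout(self, planted):
        contig, truth = planted
        assert truth.vr_interval[1] <= truth.hairpin_interval[0]
        assert truth.hairpin_interval[1] <= truth.tr_interval[0]
        assert truth.tr_interval[1] <= truth.rt_interval[0]
        # everything within 10 kb of the RT gene
        assert truth.rt_interval[0] - truth.vr_interval[0] <= 10_000
        # VR ORF is stop-free in the VR frame
        vr = contig.seq[truth.vr_interval[0]:truth.vr_interval[1]]
        assert "*" not in translate_dna(vr)

    def test_hairpin_is_palindrome(self, planted):
        contig, truth = planted
        hp = contig.seq[truth.hairpin_interval[0]:truth.hairpin_interval[1]]
        stem = (len(hp) - 6) // 2
        assert hp[:stem] == revcomp(hp[-stem:])

    def test_rejects_oversized_features(self):
        with pytest.raises(ValueError):
            plant_dgr(GeneratorConfig(contig_length=2_000, seed=0))

    def test_swap_repeat_copies_swaps_labels_only(self, planted):
        contig, truth = planted
        swapped, struth = swap_repeat_copies(contig, truth)
        assert len(swapped) == len(contig)
        assert struth.tr_interval == truth.vr_interval
        assert struth.vr_interval == truth.tr_interval
        tr_seq = contig.seq[truth.tr_interval[0]:truth.tr_interval[1]]
        assert swapped.seq[truth.vr_interval[0]:truth.vr_interval[1]] == tr_seq


class TestMakeNullContig:
    def test_exact_shuffle_preserves_dinucleotides(self, planted):
        contig, _ = planted
        null = make_null_contig(len(contig), contig, seed=9)
        assert len(null) == len(contig)
        assert dinucleotide_counts(null.seq) == dinucleotide_counts(contig.seq)
        assert sorted(null.seq) == sorted(contig.seq)

    def test_shuffle_actually_shuffles(self, planted):
        contig, _ = planted
        null = make_null_contig(len(contig), contig, seed=9)
        assert null.seq != contig.seq

    def test_markov_path_for_other_lengths(self, planted):
        contig, _ = planted
        null = make_null_contig(1_000, contig, seed=2)
        assert len(null) == 1_000
        assert set(null.seq) <= set("ACGTN")

    def test_deterministic(self, planted):
        contig, _ = planted
        assert make_null_contig(500, contig, 3).seq == make_null_contig(500, contig, 3).seq

    def test_rejects_nonpositive_length(self, planted):
        with pytest.raises(ValueError):
            make_null_contig(0, planted[0], seed=0)
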
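import numpy as np
import pytest
from conftest import mutate_seq, random_seq
from oracles import cigar_reconstructs, cigar_stats, edit_distance_dp

from sdparalog.formats import SdparalogError, revcomp
from sdparalog.synteny import (
    Anchor,
    align_regions,
    block_identity,
    chain_anchors,
    extract_indels,
    find_anchors,
    identity_matrix,
    load_chm13_table,
    longest_syntenic_block,
    read_blocks_tsv,
    window_identity,
    write_blocks_tsv,
)


class TestAnchors:
    def test_identical_sequences_give_one_full_anchor(self, rng):
        seq = random_seq(rng, 1000)
        anchors = find_anchors(seq, seq, k=21)
        assert len(anchors) == 1
        assert (anchors[0].q_start, anchors[0].length, anchors[0].strand) == (
            0,
            1000,
            "+",
        )

    def test_reverse_complement_anchors_on_minus_only(self, rng):
        seq = random_seq(rng, 800)
        anchors = find_anchors(seq, revcomp(seq))
        assert anchors and all(a.strand == "-" for a in anchors)
        assert max(a.length for a in anchors) == 800

    def test_single_substitution_splits_into_flanking_anchors(self, rng):
        seq = random_seq(rng, 2000)
        mutated = seq[:1000] + "ACGT"["TACG".index(seq[1000])] + seq[1001:]
        anchors = find_anchors(seq, mutated)
        plus = [a for a in anchors if a.strand == "+"]
        assert len(plus) == 2
        assert plus[0].q_end == 1000 and plus[1].q_start == 1001

    def test_small_k_rejected(self, rng):
        with pytest.raises(SdparalogError):
            find_anchors("ACGTACGTACGT", "ACGTACGTACGT", k=7)


class TestChaining:
    def test_single_anchor_single_block(self):
        blocks = chain_anchors([Anchor(0, 0, 1500, "+")], min_chain=1000)
        assert len(blocks) == 1
        assert len(blocks[0].query_interval) == 1500

    def test_small_gap_chains_into_one_block(self):
        anchors = [Anchor(0, 0, 1200, "+"), Anchor(1300, 1300, 1200, "+")]
        blocks = chain_anchors(anchors, max_gap=10_000)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 2

    def test_gap_over_max_gap_splits_blocks(self):
        anchors = [Anchor(0, 0, 2000, "+"), Anchor(52_000, 52_000, 2000, "+")]
        blocks = chain_anchors(anchors, max_gap=10_000)
        assert len(blocks) == 2


class TestBlockIdentity:
    def test_identical_sequences_identity_100(self, rng):
        seq = random_seq(rng, 1500)
        (block,) = align_regions(seq, seq)
        assert block.identity == 100.0
        assert block.matches == 1500

    def test_ten_substitutions_in_2000bp_is_99_50(self, rng):
        seq = random_seq(rng, 2000)
        mutated = mutate_seq(seq, 10, rng)
        span, ident = longest_syntenic_block(seq, mutated)
        assert span == 2000
        assert ident == pytest.approx(99.50, abs=1e-9)

    def test_20bp_deletion_costs_one_column_per_base(self, rng):
        # query 2000 bp, target missing 20 bp: 1980 matches / 2000 columns
        query = random_seq(rng, 2000)
        target = query[:1000] + query[1020:]
        (block,) = align_regions(query, target)
        assert block.aligned_columns == 2000
        assert block.matches == 1980
        assert block.identity == pytest.approx(99.0)

    @pytest.mark.parametrize("case", range(40))
    def test_alignment_is_optimal_full_dp(self, case):
        """Block alignment cost equals the independent full-matrix DP edit
        distance and the path reconstructs both sequences exactly."""
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(300, 2000))
        query = random_seq(rng, n)
        target = mutate_seq(query, int(rng.integers(0, n // 50 + 1)), rng)
        # sprinkle indels
        for _ in range(int(rng.integers(0, 4))):
            pos = int(rng.integers(0, len(target)))
            if rng.random() < 0.5:
                target = target[:pos] + random_seq(rng, int(rng.integers(1, 30))) + target[pos:]
            else:
                target = target[:pos] + target[pos + int(rng.integers(1, 30)) :]
        blocks = align_regions(query, target, min_chain=200)
        assert len(blocks) == 1
        block = blocks[0]
        stats = cigar_stats(block.cigar)
        qs, qe = block.query_interval.start, block.query_interval.end
        ts, te = block.target_interval.start, block.target_interval.end
        assert cigar_reconstructs(block.cigar, query[qs:qe], target[ts:te])
        assert stats["X"] + stats["I"] + stats["D"] == edit_distance_dp(
            query[qs:qe], target[ts:te]
        )
        assert block.identity == pytest.approx(
            100.0 * stats["="] / sum(stats.values())
        )


class TestLongestBlock:
    def test_region_vs_itself(self, rng):
        seq = random_seq(rng, 3000)
        assert longest_syntenic_block(seq, seq) == (3000, 100.0)

    def test_disjoint_random_sequences(self, rng):
        a, b = random_seq(rng, 3000), random_seq(rng, 3000)
        span, ident = longest_syntenic_block(a, b)
        assert (span, ident) == (0, None)

    def test_shared_segment_inside_unrelated_flanks(self, rng):
        shared = random_seq(rng, 8000)
        a = random_seq(rng, 3000) + shared + random_seq(rng, 3000)
        b = random_seq(rng, 2000) + mutate_seq(shared, 24, rng) + random_seq(rng, 4000)
        span, ident = longest_syntenic_block(a, b)
        assert abs(span - 8000) <= 80  # within 1%
        assert ident == pytest.approx(100 * (1 - 24 / 8000), abs=0.05)


class TestIdentityMatrix:
    def test_two_identical_regions(self, rng):
        seq = random_seq(rng, 2500)
        m = identity_matrix([("a", seq), ("b", seq)])
        assert m.identity[0, 1] == 100.0
        assert m.length[0, 1] == 2500

    def test_duplicate_labels_rejected(self, rng):
        seq = random_seq(rng, 1200)
        with pytest.raises(SdparalogError):
            identity_matrix([("a", seq), ("a", seq)])

    def test_symmetry_on_simulated_pairs(self, rng):
        a = random_seq(rng, 4000)
        b = mutate_seq(a, 30, rng)
        sab = longest_syntenic_block(a, b)
        sba = longest_syntenic_block(b, a)
        assert sab[1] == pytest.approx(sba[1], abs=1e-9)
        assert abs(sab[0] - sba[0]) <= 21  # within one anchor seed length

    def test_packaged_homology_table_statistics(self):
        table = load_chm13_table()
        assert table.mean_offdiagonal_length() == pytest.approx(286_958.7)
        assert table.max_offdiagonal_identity() == 99.7

    def test_monotonicity_substitutions_never_increase_identity(self, rng):
        base = random_seq(rng, 3000)
        prev_identity = 100.0
        current = base
        for _ in range(4):
            current = mutate_seq(current, 15, rng)
            _, ident = longest_syntenic_block(base, current)
            assert ident <= prev_identity + 1e-9
            prev_identity = ident


class TestWindowProfile:
    def test_self_candidate_all_windows_assigned(self, rng):
        seq = random_seq(rng, 5000)
        profile = window_identity(seq, {"self": seq})
        assert all(i == 100.0 for i in profile.identity["self"])
        assert profile.assigned == ["self"] * 5

    def test_chimera_first_5kb_assigned_to_donor(self, rng):
        donor = random_seq(rng, 10_000)
        diverged = mutate_seq(donor, 200, rng)  # 2% diverged elsewhere
        acceptor = donor[:5000] + diverged[5000:]
        profile = window_identity(acceptor, {"A": donor}, window_size=1000)
        assert profile.assigned[:5] == ["A"] * 5
        assert all(lab is None for lab in profile.assigned[5:])

    def test_weighted_window_mean_equals_block_identity(self, rng):
        a = random_seq(rng, 8000)
        b = mutate_seq(a, 60, rng)
        profile = window_identity(a, {"b": b}, window_size=1000)
        (block,) = align_regions(a, b)
        assert profile.weighted_mean_identity("b") == pytest.approx(
            block.identity, abs=0.1
        )

    def test_window_larger_than_acceptor_gives_single_window(self, rng):
        seq = random_seq(rng, 500)
        profile = window_identity(seq, {"s": seq}, window_size=1000)
        assert len(profile.windows) == 1


class TestIndels:
    def test_identical_sequences_no_indels(self, rng):
        seq = random_seq(rng, 2000)
        (block,) = align_regions(seq, seq)
        assert extract_indels(block) == []

    def test_100bp_insertion_reported_with_position(self, rng):
        target = random_seq(rng, 4000)
        query = target[:2000] + random_seq(rng, 100) + target[2000:]
        (block,) = align_regions(query, target)
        indels = extract_indels(block, min_len=50)
        assert len(indels) == 1
        kind, pos, length = indels[0]
        assert kind == "INS" and length == 100
        assert abs(pos - 2000) <= 5  # gap placement within a co-optimal shift

    def test_indel_below_min_len_suppressed(self, rng):
        target = random_seq(rng, 4000)
        query = target[:2000] + random_seq(rng, 40) + target[2000:]
        (block,) = align_regions(query, target)
        assert extract_indels(block, min_len=50) == []


def test_blocks_tsv_round_trip(tmp_path, rng):
    a = random_seq(rng, 3000)
    b = mutate_seq(a, 12, rng)
    blocks = align_regions(a, b, query_id="qA", target_id="tB")
    path = tmp_path / "blocks.tsv"
    write_blocks_tsv(path, blocks)
    back = read_blocks_tsv(path)
    assert len(back) == len(blocks)
    assert back[0].query_interval == blocks[0].query_interval
    assert back[0].matches == blocks[0].matches
    assert back[0].cigar == blocks[0].cigar
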
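import numpy as np
import pytest

from mirevol import curation
from mirevol.curation import (
    MirnaLocus,
    ReadStack,
    classify_known,
    curate_locus,
    duplex_evidence,
    fold_hairpin,
    is_mirna_like,
    merge_candidates,
    rescue_low_coverage,
    revcomp,
)
from mirevol.io_formats import GenomicInterval
from mirevol.synthetic import simulate_hairpin_locus, simulate_read_stacks

from _oracles import enumerate_nested_structures


def iv(seq_id, start, end, strand="+"):
    return GenomicInterval(seq_id, start, end, strand)


class TestMergeCandidates:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # overlap merge
            ([iv("chr1", 10, 50)], [iv("chr1", 40, 80)], [iv("chr1", 10, 80)]),
            # book-ended merge (bedtools-merge semantics)
            ([iv("chr1", 10, 50)], [iv("chr1", 50, 80)], [iv("chr1", 10, 80)]),
            # strand separation
            (
                [iv("chr1", 10, 50, "+")],
                [iv("chr1", 40, 80, "-")],
                [iv("chr1", 10, 80 - 30, "+"), iv("chr1", 40, 80, "-")],
            ),
        ],
    )
    def test_merge_semantics(self, a, b, expected):
        assert merge_candidates(a, b) == expected

    def test_output_sorted_and_minimal(self):
        a = [iv("chr2", 5, 15), iv("chr1", 100, 150)]
        b = [iv("chr1", 140, 160), iv("chr1", 10, 20)]
        merged = merge_candidates(a, b)
        assert merged == [
            iv("chr1", 10, 20),
            iv("chr1", 100, 160),
            iv("chr2", 5, 15),
        ]


class TestFoldHairpin:
    def test_matches_exhaustive_enumeration(self):
        # oracle: all nested structures over WC+GU with min loop 3
        seq = "GGGGAAAACCCC"
        structures = enumerate_nested_structures(seq)
        best_pairs = max(n for n, _ in structures)
        struct, score = fold_hairpin(seq + "A" * 28)  # pad to min length
        assert struct[:12].count("(") == best_pairs == 4
        assert struct[:12] == "((((....))))"

    def test_unpairable_sequence_all_dots(self):
        struct, _ = fold_hairpin("A" * 40)
        assert struct == "." * 40

    def test_deterministic(self, rng):
        hp, _ = simulate_hairpin_locus(rng)
        assert fold_hairpin(hp) == fold_hairpin(hp)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            fold_hairpin("ACGX" * 10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fold_hairpin("ACGT" * 5)

    def test_balanced_dot_bracket(self, rng):
        for _ in range(5):
            hp, _ = simulate_hairpin_locus(rng, mismatches=3)
            struct, _ = fold_hairpin(hp)
            assert len(struct) == len(hp)
            curation.pair_table(struct)  # raises if unbalanced


class TestIsMirnaLike:
    def test_perfect_hairpin_accepted(self, rng):
        hp, arms = simulate_hairpin_locus(rng, mismatches=0)
        ok, reason = is_mirna_like(fold_hairpin(hp), arms)
        assert ok, reason

    def test_two_terminal_loops_is_multiloop(self):
        # two independent stems -> two terminal loops
        struct = "(((((.....)))))(((((.....)))))"
        ok, reason = is_mirna_like((struct, 0.0), ((0, 5), (25, 30)))
        assert not ok and reason == "multiloop"

    def test_low_pairing_fraction_rejected(self):
        # single hairpin but arms mostly unpaired
        struct = "(((....)))" + "." * 30
        ok, reason = is_mirna_like((struct, 0.0), ((0, 10), (30, 40)))
        assert not ok and reason == "pairing fraction"

    def test_arms_outside_sequence_rejected(self, rng):
        hp, _ = simulate_hairpin_locus(rng)
        with pytest.raises(ValueError, match="arm"):
            is_mirna_like(fold_hairpin(hp), ((0, 22), (50, 80)))


class TestDuplexEvidence:
    def _locus(self, hp, arms):
        return MirnaLocus(
            locus_id="l1",
            interval=iv("chr1", 0, len(hp)),
            hairpin_seq=hp,
            arm_5p=arms[0],
            arm_3p=arms[1],
        )

    def _stacks(self, hp, arms, n5, n3):
        reads = []
        if n5:
            reads.append(ReadStack(hp[arms[0][0] : arms[0][1]], n5, arms[0][0]))
        if n3:
            reads.append(ReadStack(hp[arms[1][0] : arms[1][1]], n3, arms[1][0]))
        return reads

    @pytest.mark.parametrize(
        "n5,n3,expected",
        [
            (6, 6, True),  # total 12 >= 10, both arms
            (9, 0, False),  # one arm silent
            (5, 4, False),  # total 9 < 10
            (1, 9, True),
        ],
    )
    def test_filter_thresholds(self, rng, n5, n3, expected):
        hp, arms = simulate_hairpin_locus(rng)
        locus = self._locus(hp, arms)
        r5, r3, total, ok = duplex_evidence(locus, self._stacks(hp, arms, n5, n3))
        assert (r5, r3, total) == (n5, n3, n5 + n3)
        assert ok is expected

    def test_wobbled_reads_still_assigned(self, rng, config):
        hp, arms = simulate_hairpin_locus(rng)
        stacks = simulate_read_stacks(hp, arms, config, rng, depth_5p=10, depth_3p=10)
        r5, r3, total, ok = duplex_evidence(
            MirnaLocus("l", iv("c", 0, len(hp)), hp, arms[0], arms[1]), stacks
        )
        assert ok and r5 == 10 and r3 == 10

    def test_loop_read_assigned_to_neither_arm(self, rng):
        hp, arms = simulate_hairpin_locus(rng, arm_len=22, loop_len=8)
        # read centred on the loop overlaps both arms partially
        loop_read = ReadStack(hp[14:36], 5, 14)
        r5, r3, total, _ = duplex_evidence(
            MirnaLocus("l", iv("c", 0, len(hp)), hp, arms[0], arms[1]), [loop_read]
        )
        assert (r5, r3) == (0, 0) and total == 5


class TestClassifyKnown:
    def _locus(self, hp):
        return MirnaLocus("l", iv("c", 0, len(hp)), hp, (0, 22), (30, 52))

    def test_exact_substring_is_known(self, rng):
        hp, arms = simulate_hairpin_locus(rng)
        mature = hp[: 22]
        assert classify_known(self._locus(hp), {"m": mature}) == "known"

    def test_one_mismatch_is_known(self, rng):
        hp, _ = simulate_hairpin_locus(rng)
        mature = list(hp[:22])
        mature[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mature[10]]
        assert classify_known(self._locus(hp), {"m": "".join(mature)}) == "known"

    def test_two_mismatches_is_novel_vs_sliding_oracle(self, rng):
        # oracle: exhaustive sliding-window mismatch count
        hp, _ = simulate_hairpin_locus(rng)
        mature = list(hp[:22])
        for p in (5, 15):
            mature[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mature[p]]
        mature = "".join(mature)
        best = min(
            sum(1 for a, b in zip(mature, hp[o : o + 22]) if a != b)
            for o in range(len(hp) - 21)
        )
        best_rc = min(
            sum(1 for a, b in zip(revcomp(mature), hp[o : o + 22]) if a != b)
            for o in range(len(hp) - 21)
        )
        assert min(best, best_rc) == 2
        assert classify_known(self._locus(hp), {"m": mature}) == "novel"

    def test_reverse_complement_mature_matches(self, rng):
        hp, _ = simulate_hairpin_locus(rng)
        assert classify_known(self._locus(hp), {"m": revcomp(hp[:22])}) == "known"


class TestRescue:
    def _rejected(self, lid, r5, r3):
        l = MirnaLocus(lid, iv("c", 0, 52), "A" * 52, (0, 22), (30, 52))
        l.status = "rejected"
        l.reads_5p, l.reads_3p, l.total_reads = r5, r3, r5 + r3
        return l

    def test_rescued_with_homolog_and_processing(self):
        l = self._rejected("x", 3, 3)
        out = rescue_low_coverage([l], {"x": {"acc1"}}, {"acc1"})
        assert out == [l] and l.status == "rescued"

    def test_no_homolog_stays_rejected(self):
        l = self._rejected("x", 3, 3)
        assert rescue_low_coverage([l], {"x": {"other"}}, {"acc1"}) == []
        assert l.status == "rejected"

    def test_missing_arm_evidence_not_rescued(self):
        l = self._rejected("x", 6, 0)
        assert rescue_low_coverage([l], {"x": {"acc1"}}, {"acc1"}) == []


class TestPipelineProperties:
    def test_calibration_positives_and_shuffled_negatives(self, config):
        """>=95% of well-formed loci accepted; <=10% of shuffled negatives."""
        from mirevol.synthetic import dinucleotide_shuffle

        rng = np.random.default_rng(7)
        accepted_pos = accepted_neg = 0
        n = 100
        for i in range(n):
            hp, arms = simulate_hairpin_locus(rng)
            stacks = simulate_read_stacks(hp, arms, config, rng)
            locus = MirnaLocus(f"p{i}", iv("c", 0, len(hp)), hp, arms[0], arms[1])
            curate_locus(locus, stacks)
            accepted_pos += locus.status in ("known", "novel")

            shuffled = dinucleotide_shuffle(hp, rng)
            neg = MirnaLocus(f"n{i}", iv("c", 0, len(hp)), shuffled, arms[0], arms[1])
            curate_locus(neg, stacks)
            accepted_neg += neg.status in ("known", "novel")
        assert accepted_pos >= 95
        assert accepted_neg <= 10

    def test_statuses_partition_candidates(self, config):
        rng = np.random.default_rng(3)
        statuses = []
        for i in range(20):
            hp, arms = simulate_hairpin_locus(rng, mismatches=int(rng.integers(0, 3)))
            stacks = simulate_read_stacks(hp, arms, config, rng)
            locus = MirnaLocus(f"l{i}", iv("c", 0, len(hp)), hp, arms[0], arms[1])
            curate_locus(locus, stacks, mature_db={"m": hp[:22]})
            statuses.append(locus.status)
        assert set(statuses) <= {"known", "novel", "rejected"}

    def test_filter_order_independent(self, config):
        """Structure-then-duplex equals duplex-then-structure."""
        rng = np.random.default_rng(11)
        for i in range(10):
            hp, arms = simulate_hairpin_locus(rng, mismatches=int(rng.integers(0, 4)))
            stacks = simulate_read_stacks(
                hp, arms, config, rng,
                depth_5p=int(rng.integers(0, 12)), depth_3p=int(rng.integers(0, 12)),
            )
            locus = MirnaLocus(f"l{i}", iv("c", 0, len(hp)), hp, arms[0], arms[1])
            ok_s, _ = is_mirna_like(fold_hairpin(hp), arms)
            _, _, _, ok_d = duplex_evidence(locus, stacks)
            # both orders of applying the two filters give the same verdict
            assert (ok_s and ok_d) == (ok_d and ok_s)
            curate_locus(locus, stacks)
            assert (locus.status != "rejected") == (ok_s and ok_d)
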
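import numpy as np
import pytest

from mirevol import (
    SimulationConfig,
    simulate_annotation_and_repeats,
    simulate_dollo_histories,
    simulate_hairpin_locus,
    simulate_read_stacks,
    simulate_utr_alignments,
)
from mirevol.curation import revcomp
from mirevol.synthetic import dinucleotide_shuffle
from mirevol.tree import DatedTree


class TestDolloHistories:
    def test_no_losses_means_clade_presence(self, five_leaf_tree):
        cfg = SimulationConfig(rng_seed=5, n_orthogroups=50, loss_rate=0.0)
        histories, matrix = simulate_dollo_histories(five_leaf_tree, cfg)
        for h in histories:
            clade = five_leaf_tree.leaves_below(h.gain_branch)
            assert {sp for sp, v in h.leaf_presence.items() if v} == clade
            assert h.loss_branches == set()

    def test_terminal_gain_single_presence(self, five_leaf_tree):
        cfg = SimulationConfig(rng_seed=5, n_orthogroups=200)
        histories, _ = simulate_dollo_histories(five_leaf_tree, cfg)
        terminal = [h for h in histories if h.gain_branch in five_leaf_tree.leaf_names]
        assert terminal, "expected some terminal-branch gains"
        for h in terminal:
            assert sum(h.leaf_presence.values()) == 1

    def test_seeded_determinism(self, five_leaf_tree):
        cfg = SimulationConfig(rng_seed=9, n_orthogroups=40)
        h1, m1 = simulate_dollo_histories(five_leaf_tree, cfg)
        h2, m2 = simulate_dollo_histories(five_leaf_tree, cfg)
        assert m1.rows == m2.rows
        assert [(h.gain_branch, h.loss_branches) for h in h1] == [
            (h.gain_branch, h.loss_branches) for h in h2
        ]

    def test_histories_are_dollo_consistent(self, five_leaf_tree):
        cfg = SimulationConfig(rng_seed=13, n_orthogroups=200, loss_rate=0.005)
        histories, matrix = simulate_dollo_histories(five_leaf_tree, cfg)
        assert len(histories) == 200
        for h in histories:
            assert any(h.leaf_presence.values()), "all-absent rows must be discarded"
            for b in h.loss_branches:
                assert five_leaf_tree.is_strictly_below(b, h.gain_branch)
            # leaf presence = gain clade minus lost subtrees
            expect = five_leaf_tree.leaves_below(h.gain_branch)
            for b in h.loss_branches:
                expect -= five_leaf_tree.leaves_below(b)
            assert {sp for sp, v in h.leaf_presence.items() if v} == expect
            assert matrix.rows[h.orthogroup_id] == h.leaf_presence

    def test_tiny_tree_rejected(self):
        one_leaf = DatedTree.from_newick("(A:1,B:1);")
        # two leaves is the documented minimum; a degenerate tree errors
        cfg = SimulationConfig(rng_seed=1, n_orthogroups=5)
        histories, _ = simulate_dollo_histories(one_leaf, cfg)
        assert len(histories) == 5


class TestHairpins:
    def test_construction_geometry(self, rng):
        hp, arms = simulate_hairpin_locus(rng, arm_len=22, loop_len=8, mismatches=0)
        assert len(hp) == 52
        assert arms == ((0, 22), (30, 52))
        assert hp[30:] == revcomp(hp[:22])

    @pytest.mark.parametrize("mm", [1, 3])
    def test_mismatch_count_exact(self, rng, mm):
        hp, arms = simulate_hairpin_locus(rng, mismatches=mm)
        arm3 = hp[arms[1][0] : arms[1][1]]
        dist = sum(1 for a, b in zip(arm3, revcomp(hp[:22])) if a != b)
        assert dist == mm

    def test_bad_geometry_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_hairpin_locus(rng, arm_len=10)
        with pytest.raises(ValueError):
            simulate_hairpin_locus(rng, loop_len=2)

    def test_dinucleotide_shuffle_preserves_composition(self, rng):
        hp, _ = simulate_hairpin_locus(rng)
        sh = dinucleotide_shuffle(hp, rng)
        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert dinucs(sh) == dinucs(hp)
        assert sh != hp


class TestReadStacks:
    def test_clean_reads_match_arms(self, rng):
        cfg = SimulationConfig(rng_seed=1, read_error_rate=0.0)
        hp, arms = simulate_hairpin_locus(rng)
        stacks = simulate_read_stacks(hp, arms, cfg, rng, wobble=False,
                                      depth_5p=5, depth_3p=5)
        seqs = {s.seq for s in stacks}
        assert seqs == {hp[0:22], hp[30:52]}
        assert sum(s.count for s in stacks) == 10

    def test_zero_depth_arm_fails_duplex_downstream(self, rng):
        from mirevol.curation import MirnaLocus, duplex_evidence
        from mirevol.io_formats import GenomicInterval

        cfg = SimulationConfig(rng_seed=1)
        hp, arms = simulate_hairpin_locus(rng)
        stacks = simulate_read_stacks(hp, arms, cfg, rng, depth_5p=20, depth_3p=0)
        locus = MirnaLocus("l", GenomicInterval("c", 0, 52, "+"), hp, *arms)
        *_, ok = duplex_evidence(locus, stacks)
        assert not ok

    def test_seeded_byte_identical(self):
        cfg = SimulationConfig(rng_seed=2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(8)
            hp, arms = simulate_hairpin_locus(rng)
            out.append(simulate_read_stacks(hp, arms, cfg, rng))
        assert out[0] == out[1]

    def test_expected_depth(self):
        cfg = SimulationConfig(rng_seed=2, read_depth_per_arm=25)
        rng = np.random.default_rng(3)
        hp, arms = simulate_hairpin_locus(rng)
        totals = []
        for _ in range(50):
            stacks = simulate_read_stacks(hp, arms, cfg, rng)
            totals.append(sum(s.count for s in stacks))
        assert np.mean(totals) == pytest.approx(50, rel=0.1)


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(rng_seed=21)
    return simulate_annotation_and_repeats(cfg)


class TestPlantedGenome:

    def test_mirtron_reciprocal_overlap(self, planted):
        genome, genes, repeats, loci = planted
        mirtron = next(p for p in loci if "mirtron" in p.origin_flags)
        introns = [iv for g in genes for iv in g.introns()]
        best = max(
            min(
                mirtron.interval.overlap_len(i) / len(mirtron.interval),
                mirtron.interval.overlap_len(i) / len(i),
            )
            for i in introns
            if i.strand == mirtron.interval.strand
        )
        assert best >= 0.9

    def test_antisense_pair_full_overlap(self, planted):
        *_, loci = planted
        pair = [p for p in loci if "antisense_pair" in p.origin_flags]
        assert len(pair) == 2
        a, b = pair
        assert a.interval.seq_id == b.interval.seq_id
        assert a.interval.strand != b.interval.strand
        ov = a.interval.overlap_len(b.interval)
        assert ov / len(a.interval) == 1.0 and ov / len(b.interval) == 1.0

    def test_repeat_derived_share_30nt_block(self, planted):
        _, _, repeats, loci = planted
        rd = [p for p in loci if "repeat_derived" in p.origin_flags]
        assert rd
        for p in rd:
            rep = repeats[p.source_repeat]
            shared = any(
                p.hairpin_seq[i : i + 30] in rep
                for i in range(len(p.hairpin_seq) - 29)
            )
            assert shared

    def test_genome_carries_locus_sequences(self, planted):
        genome, _, _, loci = planted
        for p in loci:
            segment = genome[p.interval.seq_id][p.interval.start : p.interval.end]
            expected = p.hairpin_seq if p.interval.strand == "+" else revcomp(p.hairpin_seq)
            assert segment == expected

    def test_ground_truth_labels_complete(self, planted):
        *_, loci = planted
        assert all(p.context in {"intron", "intergenic", "utr5", "utr3"} for p in loci)
        ids = [p.locus_id for p in loci]
        assert len(ids) == len(set(ids))

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_annotation_and_repeats(SimulationConfig(rng_seed=1), genome_len=1000)


class TestUtrAlignments:
    def test_planted_sites_discoverable(self):
        from mirevol.targets import find_sites

        cfg = SimulationConfig(rng_seed=31)
        alignments, track, sites = simulate_utr_alignments(cfg, n_genes=3)
        assert sites
        for s in sites:
            aligned = alignments[s.gene_id][s.species]
            ungapped = aligned.replace("-", "")
            found = find_sites(ungapped, s.seed7)
            assert any(
                f.utr_offset == s.utr_offset and f.site_type == "8mer" for f in found
            )

    def test_no_gaps_inside_planted_sites(self):
        cfg = SimulationConfig(rng_seed=31)
        alignments, _, sites = simulate_utr_alignments(cfg, n_genes=3)
        for s in sites:
            cols = alignments[s.gene_id][s.species][s.msa_columns[0] : s.msa_columns[1]]
            assert "-" not in cols

    def test_site_scores_elevated(self):
        cfg = SimulationConfig(rng_seed=31)
        _, track, sites = simulate_utr_alignments(cfg, n_genes=10)
        ref_sites = [s for s in sites if s.species == "human"]
        site_vals, bg_vals = [], []
        for s in ref_sites:
            for p in range(s.utr_offset, s.utr_offset + 8):
                site_vals.append(track.get(s.gene_id, p))
            for p in range(0, 50):
                bg_vals.append(track.get(s.gene_id, p))
        assert np.mean(site_vals) > np.mean(bg_vals) + 0.3

    def test_null_configuration_flat(self):
        cfg = SimulationConfig(
            rng_seed=31, site_conservation_mean=0.35, background_conservation_mean=0.35
        )
        _, track, sites = simulate_utr_alignments(cfg, n_genes=10)
        ref_sites = [s for s in sites if s.species == "human"]
        site_vals = [
            track.get(s.gene_id, p)
            for s in ref_sites
            for p in range(s.utr_offset, s.utr_offset + 8)
        ]
        bg_vals = [track.get(s.gene_id, p) for s in ref_sites for p in range(0, 50)]
        assert abs(np.mean(site_vals) - np.mean(bg_vals)) < 0.05

    def test_seeded_identical(self):
        cfg = SimulationConfig(rng_seed=12)
        a1, _, s1 = simulate_utr_alignments(cfg, n_genes=2)
        a2, _, s2 = simulate_utr_alignments(cfg, n_genes=2)
        assert a1 == a2
        assert [(s.gene_id, s.species, s.utr_offset) for s in s1] == [
            (s.gene_id, s.species, s.utr_offset) for s in s2
        ]
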
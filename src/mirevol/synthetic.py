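"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of ``(config, seed)``: identical seeds
give identical outputs.  Ground-truth labels (gain/loss histories, planted
origin flags, planted target sites) are emitted alongside every simulated
object so downstream tests never re-derive truth.

The default five-species tree mirrors a Laurasiatheria-plus-rabbit
phylogeny with approximate divergence times in Myr; orthogroup histories
are simulated under the enforced Dollo regime (exactly one gain, losses
only below it), read stacks mimic Drosha/Dicer arm processing with +/-1 nt
end wobble, conservation scores are Beta-distributed in [0, 1] like
phastCons, and the planted genome carries labelled miRtron, intronic,
intergenic, antisense, tandem-duplicate and repeat-derived loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curation import MirnaLocus, ReadStack, revcomp
from .io_formats import GeneModel, GenomicInterval, ScoreTrack
from .orthogroups import OrthogroupMatrix
from .tree import DatedTree, TreeNode

#: five-species dated tree (Myr): ((cow,pig),(dog,horse)) with rabbit outgroup
DEFAULT_TREE_NEWICK = (
    "(((cow:60,pig:60):25,(dog:78,horse:78):7):5,rabbit:90);"
)

DEFAULT_SPECIES = ["cow", "pig", "dog", "horse", "rabbit"]

_NT = np.array(list("ACGT"))


def default_tree() -> DatedTree:
    return DatedTree.from_newick(DEFAULT_TREE_NEWICK)


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults define the standard conditions."""

    rng_seed: int = 17
    n_orthogroups: int = 500
    gain_rate: float = 0.01  # events/Myr (relative weight of gain placement)
    loss_rate: float = 0.002  # events/Myr along lineages below the gain
    read_depth_per_arm: int = 30  # expected reads per arm
    read_error_rate: float = 0.005  # per-base substitution rate in reads
    n_repeat_families: int = 3
    site_conservation_mean: float = 0.9
    background_conservation_mean: float = 0.35

    def __post_init__(self):
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.read_error_rate < 0.5):
            raise ValueError("read_error_rate must be in [0, 0.5)")
        for m in (self.site_conservation_mean, self.background_conservation_mean):
            if not (0 <= m <= 1):
                raise ValueError("conservation means must be in [0, 1]")


@dataclass
class TrueHistory:
    """Ground-truth gain/loss history of one simulated orthogroup."""

    orthogroup_id: str
    gain_branch: str
    loss_branches: set[str]
    leaf_presence: dict[str, int]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NT, size=n))


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Altschul–Erikson).

    Builds the edge multigraph of adjacent nucleotide pairs and samples a
    random Eulerian walk with the same start/end states.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random last edge per vertex (except the terminal state) that
    # forms a tree toward ``last``; rejection-sample for connectivity
    for _ in range(1000):
        lasts = {}
        for v, outs in edges.items():
            if v != last:
                lasts[v] = outs[rng.integers(len(outs))]
        ok = True
        for v in lasts:
            seen = set()
            u = v
            while u != last and u in lasts and u not in seen:
                seen.add(u)
                u = lasts[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        return mononucleotide_shuffle(seq, rng)

    pools = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in lasts:
            rest.remove(lasts[v])
        idx = rng.permutation(len(rest))
        pools[v] = [rest[i] for i in idx]

    out = [seq[0]]
    counts = {v: 0 for v in edges}
    while len(out) < len(seq):
        v = out[-1]
        if counts[v] < len(pools[v]):
            nxt = pools[v][counts[v]]
            counts[v] += 1
        else:
            nxt = lasts[v]
        out.append(nxt)
    return "".join(out)


# ---------------------------------------------------------------------------
# Dollo histories
# ---------------------------------------------------------------------------


def simulate_dollo_histories(
    tree: DatedTree, config: SimulationConfig
) -> tuple[list[TrueHistory], OrthogroupMatrix]:
    """Simulate Dollo-consistent presence–absence histories.

    Each orthogroup gains exactly once, on a branch drawn with probability
    proportional to branch length; losses then occur along lineages below
    the gain as a Poisson process at ``loss_rate``/Myr (a lost lineage
    cannot lose again).  Histories whose leaves are all absent are
    discarded and redrawn, so every matrix row has at least one presence.
    """
    if len(tree.leaf_names) < 2:
        raise ValueError("tree must have >= 2 leaves")
    rng = np.random.default_rng(config.rng_seed)
    branches = [n for n in tree.preorder() if n is not tree.root]
    lengths = np.array([n.length for n in branches])
    weights = lengths / lengths.sum()

    histories: list[TrueHistory] = []
    matrix = OrthogroupMatrix(species=list(tree.leaf_names))
    og_index = 0
    while len(histories) < config.n_orthogroups:
        gain_node = branches[rng.choice(len(branches), p=weights)]
        losses: set[str] = set()
        present: set[str] = set()

        def descend(node: TreeNode) -> None:
            if node.is_leaf:
                present.add(node.label)
                return
            for child in node.children:
                p_loss = 1.0 - np.exp(-config.loss_rate * child.length)
                if rng.random() < p_loss:
                    losses.add(child.label)
                else:
                    descend(child)

        descend(gain_node)
        if not present:
            continue  # all-absent: discard and redraw
        og_index += 1
        og_id = f"og{og_index:04d}"
        leaf_presence = {
            sp: (1 if sp in present else 0) for sp in tree.leaf_names
        }
        histories.append(
            TrueHistory(
                orthogroup_id=og_id,
                gain_branch=gain_node.label,
                loss_branches=losses,
                leaf_presence=leaf_presence,
            )
        )
        matrix.rows[og_id] = dict(leaf_presence)
        for sp, v in leaf_presence.items():
            matrix.evidence[(og_id, sp)] = "annotated" if v else "absent"
    return histories, matrix


# ---------------------------------------------------------------------------
# hairpins and read stacks
# ---------------------------------------------------------------------------


def simulate_hairpin_locus(
    rng: np.random.Generator,
    arm_len: int = 22,
    loop_len: int = 8,
    mismatches: int = 0,
) -> tuple[str, tuple[tuple[int, int], tuple[int, int]]]:
    """One stem-loop hairpin: 5p arm + loop + revcomp(5p arm) with mismatches.

    Returns ``(sequence, (arm_5p, arm_3p))`` with arm offsets half-open on
    the hairpin.
    """
    if not (18 <= arm_len <= 25):
        raise ValueError("arm_len must be in [18, 25]")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    arm5 = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len)
    arm3 = list(revcomp(arm5))
    if mismatches:
        pos = rng.choice(arm_len, size=mismatches, replace=False)
        for p in pos:
            others = [c for c in "ACGT" if c != arm3[p]]
            arm3[p] = others[rng.integers(3)]
    seq = arm5 + loop + "".join(arm3)
    arms = ((0, arm_len), (arm_len + loop_len, arm_len + loop_len + arm_len))
    return seq, arms


def simulate_read_stacks(
    hairpin: str,
    arms: tuple[tuple[int, int], tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
    wobble: bool = True,
    depth_5p: int | None = None,
    depth_3p: int | None = None,
) -> list[ReadStack]:
    """Draw arm reads with +/-1 nt end wobble and per-base error.

    Per-arm totals are Poisson with mean ``read_depth_per_arm`` unless an
    explicit depth is given; identical (sequence, offset) draws aggregate
    into one :class:`ReadStack` with a summed count.
    """
    stacks: dict[tuple[str, int], int] = {}
    for arm, depth in zip(arms, (depth_5p, depth_3p)):
        n = (
            int(rng.poisson(config.read_depth_per_arm))
            if depth is None
            else depth
        )
        for _ in range(n):
            s, e = arm
            if wobble:
                s = max(0, s + int(rng.integers(-1, 2)))
                e = min(len(hairpin), e + int(rng.integers(-1, 2)))
            read = list(hairpin[s:e])
            if config.read_error_rate > 0:
                err = rng.random(len(read)) < config.read_error_rate
                for i in np.flatnonzero(err):
                    others = [c for c in "ACGT" if c != read[i]]
                    read[i] = others[rng.integers(3)]
            key = ("".join(read), s)
            stacks[key] = stacks.get(key, 0) + 1
    return [
        ReadStack(seq=seq, count=c, offset=off)
        for (seq, off), c in sorted(stacks.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    ]


# ---------------------------------------------------------------------------
# planted genome: genes, repeats, labelled loci
# ---------------------------------------------------------------------------


@dataclass
class PlantedLocus:
    """A simulated locus with its ground-truth origin labels."""

    locus_id: str
    interval: GenomicInterval
    hairpin_seq: str
    arms: tuple[tuple[int, int], tuple[int, int]]
    context: str  # intron | intergenic | utr5 | utr3
    origin_flags: set[str] = field(default_factory=set)
    partner_id: str | None = None
    source_repeat: str | None = None

    def as_mirna_locus(self) -> MirnaLocus:
        return MirnaLocus(
            locus_id=self.locus_id,
            interval=self.interval,
            hairpin_seq=self.hairpin_seq,
            arm_5p=self.arms[0],
            arm_3p=self.arms[1],
        )


def _make_gene(
    gene_id: str,
    contig: str,
    start: int,
    strand: str,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    utr5_len: int,
    utr3_len: int,
) -> GeneModel:
    """Gene model from exon/intron lengths; UTRs trimmed off the CDS ends."""
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(contig, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    gene_iv = GenomicInterval(contig, start, pos, strand)
    # CDS: exonic minus utr5 at the 5' end and utr3 at the 3' end
    five_first = strand == "+"
    cds = []
    skip5, skip3 = utr5_len, utr3_len
    ordered = exons if five_first else exons[::-1]
    trimmed = []
    for e in ordered:
        s, t = e.start, e.end
        if skip5 > 0:
            cut = min(skip5, t - s)
            if five_first:
                s += cut
            else:
                t -= cut
            skip5 -= cut
        if s < t:
            trimmed.append([s, t, e])
    for item in reversed(trimmed):
        s, t, _ = item
        if skip3 > 0:
            cut = min(skip3, t - s)
            if five_first:
                item[1] -= cut
            else:
                item[0] += cut
            skip3 -= cut
    for s, t, e in trimmed:
        if s < t:
            cds.append(GenomicInterval(contig, s, t, strand))
    return GeneModel(gene_id=gene_id, interval=gene_iv, exons=exons, cds=cds)


def simulate_annotation_and_repeats(
    config: SimulationConfig,
    genome_len: int = 60_000,
) -> tuple[dict[str, str], list[GeneModel], dict[str, str], list[PlantedLocus]]:
    """Planted genome with labelled miRNA loci of every genomic origin.

    Returns ``(genome, gene_models, repeat_library, planted_loci)``.  The
    planted set contains a miRtron (locus == intron), a plain intronic
    locus, intergenic loci, a perfectly overlapping antisense pair, a
    tandem duplicate pair (same contig, 10 kb apart), a cross-contig
    duplicate pair, a 3'UTR locus, repeat-derived loci sharing a 30-nt
    exact block with a repeat consensus, and unlabelled random negatives.
    """
    if config.n_repeat_families < 1:
        raise ValueError("need at least one repeat family")
    if genome_len < 40_000:
        raise ValueError("genome too short to place the requested features")
    rng = np.random.default_rng(config.rng_seed + 1)
    chr1 = list(_random_seq(rng, genome_len))
    chr2 = list(_random_seq(rng, 6_000))

    repeats = {
        f"repeat{i + 1}": _random_seq(rng, 200)
        for i in range(config.n_repeat_families)
    }

    genes = [
        # gene1: miRtron host; intron1 (between exon1 and exon2) is 60 nt
        _make_gene("gene1", "chr1", 2_000, "+", [200, 200, 200], [60, 300], 100, 60),
        # gene2: plain intronic host with a 300 nt intron
        _make_gene("gene2", "chr1", 6_000, "+", [150, 150, 150], [300, 120], 50, 50),
        # gene3: minus-strand gene supplying a 3'UTR
        _make_gene("gene3", "chr1", 10_000, "-", [250, 250], [150], 80, 120),
        # gene4: far-downstream gene (keeps intergenic space unambiguous)
        _make_gene("gene4", "chr1", 40_000, "+", [300, 300], [200], 60, 60),
    ]

    planted: list[PlantedLocus] = []

    def write_locus(
        locus_id: str,
        contig: list[str],
        contig_name: str,
        start: int,
        strand: str,
        context: str,
        flags: set[str],
        hairpin: str | None = None,
        arms=None,
        arm_len: int = 22,
        loop_len: int = 8,
        **extra,
    ) -> PlantedLocus:
        if hairpin is None:
            hairpin, arms = simulate_hairpin_locus(rng, arm_len, loop_len)
        genomic = hairpin if strand == "+" else revcomp(hairpin)
        contig[start : start + len(hairpin)] = list(genomic)
        pl = PlantedLocus(
            locus_id=locus_id,
            interval=GenomicInterval(contig_name, start, start + len(hairpin), strand),
            hairpin_seq=hairpin,
            arms=arms,
            context=context,
            origin_flags=flags,
            **extra,
        )
        planted.append(pl)
        return pl

    # miRtron: hairpin spanning gene1's first intron exactly (60 nt)
    intron = genes[0].introns()[0]
    hp, arms = simulate_hairpin_locus(rng, arm_len=25, loop_len=10)
    write_locus(
        "mirtron1", chr1, "chr1", intron.start, "+", "intron",
        {"mirtron"}, hairpin=hp, arms=arms,
    )
    # plain intronic locus: 52 nt inside gene2's 300 nt intron
    intron2 = genes[1].introns()[0]
    write_locus(
        "intronic1", chr1, "chr1", intron2.start + 120, "+", "intron", set()
    )
    # 3'UTR locus inside gene3's UTR3 (minus strand: UTR3 at interval start)
    write_locus("utr1", chr1, "chr1", 10_004, "-", "utr3", set())

    # intergenic singletons
    write_locus("intergenic1", chr1, "chr1", 20_000, "+", "intergenic", set())
    write_locus("intergenic2", chr1, "chr1", 21_000, "-", "intergenic", set())

    # antisense couple: identical span, opposite strands
    pa = write_locus(
        "anti_a", chr1, "chr1", 22_000, "+", "intergenic",
        {"antisense_pair"}, partner_id="anti_b",
    )
    pb = PlantedLocus(
        locus_id="anti_b",
        interval=GenomicInterval("chr1", 22_000, 22_000 + len(pa.hairpin_seq), "-"),
        hairpin_seq=revcomp(pa.hairpin_seq),
        arms=pa.arms,
        context="intergenic",
        origin_flags={"antisense_pair"},
        partner_id="anti_a",
    )
    planted.append(pb)

    # tandem duplicates: identical hairpin 10 kb apart on chr1
    td = write_locus(
        "tandem_a", chr1, "chr1", 25_000, "+", "intergenic",
        {"duplicated", "tandem"}, partner_id="tandem_b",
    )
    write_locus(
        "tandem_b", chr1, "chr1", 35_000, "+", "intergenic",
        {"duplicated", "tandem"},
        hairpin=td.hairpin_seq, arms=td.arms, partner_id="tandem_a",
    )
    # dispersed duplicates: identical hairpin on different contigs
    dd = write_locus(
        "dispersed_a", chr1, "chr1", 30_000, "+", "intergenic",
        {"duplicated"}, partner_id="dispersed_b",
    )
    write_locus(
        "dispersed_b", chr2, "chr2", 2_000, "+", "intergenic",
        {"duplicated"},
        hairpin=dd.hairpin_seq, arms=dd.arms, partner_id="dispersed_a",
    )

    # repeat-derived loci: 30 nt of the consensus embedded in the hairpin
    for i, (rep_id, rep_seq) in enumerate(list(repeats.items())[:2]):
        hp, arms = simulate_hairpin_locus(rng, arm_len=25, loop_len=10)
        block = rep_seq[50:80]
        hp = block + hp[30:]
        write_locus(
            f"repeat_mir{i + 1}", chr1, "chr1", 27_000 + i * 500, "+",
            "intergenic", {"repeat_derived"},
            hairpin=hp, arms=arms, source_repeat=rep_id,
        )

    # unlabelled negatives
    for i in range(3):
        write_locus(f"neg{i + 1}", chr1, "chr1", 45_000 + i * 500, "+",
                    "intergenic", set())

    genome = {"chr1": "".join(chr1), "chr2": "".join(chr2)}
    return genome, genes, repeats, planted


# ---------------------------------------------------------------------------
# UTR alignments, conservation tracks, planted target sites
# ---------------------------------------------------------------------------


def _beta_scores(
    rng: np.random.Generator, means: np.ndarray, concentration: float = 20.0
) -> np.ndarray:
    means = np.clip(means, 1e-3, 1 - 1e-3)
    return rng.beta(means * concentration, (1 - means) * concentration)


def simulate_utr_alignments(
    config: SimulationConfig,
    n_genes: int = 20,
    species_list: Sequence[str] | None = None,
    aln_len: int = 600,
    divergence: float = 0.05,
    seed7: str = "TACAATA",
    site_offset: int = 300,
    flank_decay: int = 7,
):
    """Per-gene UTR alignments with planted 8mer sites and score tracks.

    Returns ``(alignments, score_track, planted_sites)`` where
    ``alignments`` maps gene -> species -> aligned sequence (the first
    species is the ungapped reference whose coordinates index the score
    track, one pseudo-contig per gene), and planted sites are
    :class:`~mirevol.targets.TargetSite` records for every carrier species.
    Per-base scores are Beta-distributed with mean
    ``site_conservation_mean`` inside a planted site, decaying linearly to
    ``background_conservation_mean`` over ``flank_decay`` nt.
    """
    from .targets import TargetSite  # local import to avoid a cycle

    if species_list is None:
        species_list = ["human", "mouse"] + DEFAULT_SPECIES
    if len(species_list) < 2:
        raise ValueError("need at least two species")
    if aln_len < 500:
        raise ValueError("gene alignment length must be >= 500")
    rng = np.random.default_rng(config.rng_seed + 2)
    site_seq = revcomp(seed7) + "A"  # 8mer site
    site_len = len(site_seq)

    alignments: dict[str, dict[str, str]] = {}
    track = ScoreTrack()
    planted: list[TargetSite] = []

    for g in range(n_genes):
        gene_id = f"gene{g + 1:03d}"
        ancestor = list(_random_seq(rng, aln_len))
        ancestor[site_offset : site_offset + site_len] = list(site_seq)
        per_species: dict[str, str] = {}
        for si, sp in enumerate(species_list):
            seq = list(ancestor)
            if si > 0:
                sub = rng.random(aln_len) < divergence
                for i in np.flatnonzero(sub):
                    if site_offset <= i < site_offset + site_len:
                        continue  # sites stay intact in carrier species
                    others = [c for c in "ACGT" if c != seq[i]]
                    seq[i] = others[rng.integers(3)]
                # a few short deletions, never inside the planted site
                for _ in range(int(rng.integers(1, 4))):
                    dstart = int(rng.integers(0, aln_len - 3))
                    dlen = int(rng.integers(1, 4))
                    if dstart + dlen > site_offset and dstart < site_offset + site_len:
                        continue
                    for i in range(dstart, min(dstart + dlen, aln_len)):
                        seq[i] = "-"
            per_species[sp] = "".join(seq)
        alignments[gene_id] = per_species

        # score track in reference (ungapped first species) coordinates
        means = np.full(aln_len, config.background_conservation_mean)
        lo, hi = site_offset, site_offset + site_len
        means[lo:hi] = config.site_conservation_mean
        for d in range(1, flank_decay + 1):
            w = 1 - d / (flank_decay + 1)
            val = (
                config.background_conservation_mean
                + w
                * (config.site_conservation_mean - config.background_conservation_mean)
            )
            if lo - d >= 0:
                means[lo - d] = val
            if hi - 1 + d < aln_len:
                means[hi - 1 + d] = val
        scores = _beta_scores(rng, means)
        for pos, v in enumerate(scores):
            track.set(gene_id, pos, float(v))

        for sp in species_list:
            aligned = per_species[sp]
            if aligned[site_offset : site_offset + site_len] != site_seq:
                continue
            ungapped_offset = site_offset - aligned[:site_offset].count("-")
            planted.append(
                TargetSite(
                    gene_id=gene_id,
                    species=sp,
                    utr_offset=ungapped_offset,
                    site_type="8mer",
                    seed7=seed7,
                    msa_columns=(site_offset, site_offset + site_len),
                )
            )
    return alignments, track, planted
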
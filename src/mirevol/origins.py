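"""Genomic origins of miRNA loci.

Classifies each locus by genomic context (3'UTR, 5'UTR, intron,
intergenic) and flags the mechanisms that can seed new miRNA genes:

* **repeat-derived** — similarity to a repeat consensus exceeding a
  shuffle-based null: every repeat with any original hit is shuffled many
  times, all miRNAs are re-aligned against the shuffles, and the maximum
  bit score observed becomes the calling threshold (combined with a 30-nt
  minimum alignment length);
* **antisense couples** — two loci on opposite strands overlapping >= 95%
  of at least one of them, with a cross-mapping check that looks for
  <= 1-mismatch read pairs that could be sequencing-error artifacts;
* **miRtrons** — >= 90% reciprocal overlap with an intron on the same
  strand, plus Drosha/Dicer processing evidence;
* **duplications** — orthogroups with >= 2 paralogous copies in one
  species, flagged *tandem* when two copies lie within 100 kb on one
  contig.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import bit_score, local_hit_record, local_score
from .curation import MirnaLocus, ReadStack
from .io_formats import GeneModel, GenomicInterval, HitRecord
from .orthogroups import Orthogroup

MIN_REPEAT_ALIGN_LEN = 30
ANTISENSE_MIN_OVERLAP = 0.95
MIRTRON_RECIPROCAL_OVERLAP = 0.9
TANDEM_WINDOW = 100_000
CONTEXT_PRECEDENCE = ("utr3", "utr5", "intron", "intergenic")


@dataclass
class OriginCall:
    """Context plus origin flags for one locus, with per-flag support."""

    locus_id: str
    context: str
    flags: set[str] = field(default_factory=set)
    support: dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# repeat-derived calling
# ---------------------------------------------------------------------------


def shuffle_null_threshold(
    mirna_seqs: Mapping[str, str],
    repeat_seqs: Mapping[str, str],
    n_shuffles: int = 1000,
    rng_seed: int = 0,
    dinucleotide: bool = False,
) -> float:
    """Maximum bit score of miRNAs against shuffled repeats.

    ``repeat_seqs`` should contain only the repeats that had an original
    hit.  Each repeat is shuffled ``n_shuffles`` times (mononucleotide
    permutation by default) with a per-(repeat, index) seed stream, so the
    first *k* shuffles are identical for any ``n_shuffles >= k`` — the
    threshold is therefore non-decreasing in ``n_shuffles`` under a fixed
    seed.  Returns the largest bit score observed; when no alignment has a
    positive raw score, the minimum reportable bit score (raw score 1).
    """
    if not mirna_seqs or not repeat_seqs:
        raise ValueError("mirna_seqs and repeat_seqs must be non-empty")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    from .synthetic import dinucleotide_shuffle, mononucleotide_shuffle

    shuffle = dinucleotide_shuffle if dinucleotide else mononucleotide_shuffle
    best_raw = 0.0
    mirnas = [mirna_seqs[k] for k in sorted(mirna_seqs)]
    for rep_idx, rep_id in enumerate(sorted(repeat_seqs)):
        rep = repeat_seqs[rep_id]
        for i in range(n_shuffles):
            rng = np.random.default_rng(
                np.random.SeedSequence([rng_seed, rep_idx, i])
            )
            shuffled = shuffle(rep, rng)
            for m in mirnas:
                s = local_score(m, shuffled)
                if s > best_raw:
                    best_raw = s
    return bit_score(max(best_raw, 1.0))


def classify_repeat_derived(
    hits: Sequence[HitRecord],
    threshold: float,
    min_len: int = MIN_REPEAT_ALIGN_LEN,
) -> set[str]:
    """Loci with a repeat hit of length >= 30 and bit score > threshold."""
    return {
        h.query_id
        for h in hits
        if h.align_len >= min_len and h.bit_score > threshold
    }


def repeat_hits(
    mirna_seqs: Mapping[str, str], repeat_seqs: Mapping[str, str]
) -> list[HitRecord]:
    """Best local-alignment hit of every miRNA against every repeat."""
    out = []
    for mid in sorted(mirna_seqs):
        for rid in sorted(repeat_seqs):
            rec = local_hit_record(mid, mirna_seqs[mid], rid, repeat_seqs[rid])
            if rec is not None:
                out.append(rec)
    return out


# ---------------------------------------------------------------------------
# antisense couples
# ---------------------------------------------------------------------------


def find_antisense_pairs(
    loci: Sequence[MirnaLocus],
    min_overlap: float = ANTISENSE_MIN_OVERLAP,
) -> list[tuple[str, str, float]]:
    """Opposite-strand couples overlapping >= 95% of at least one locus.

    Each unordered pair is reported once, with the larger of the two
    overlap fractions; output is invariant under input ordering.
    """
    out = []
    ordered = sorted(loci, key=lambda l: l.locus_id)
    for a, b in itertools.combinations(ordered, 2):
        ia, ib = a.interval, b.interval
        if ia.seq_id != ib.seq_id or ia.strand == ib.strand:
            continue
        ov = ia.overlap_len(ib)
        if ov == 0:
            continue
        frac = max(ov / len(ia), ov / len(ib))
        if frac >= min_overlap:
            out.append((a.locus_id, b.locus_id, frac))
    return out


def cross_mapping_check(
    reads_a: Iterable[ReadStack],
    reads_b: Iterable[ReadStack],
    max_flag_mismatches: int = 1,
) -> list[dict]:
    """Compare reads across an antisense couple for near-identical pairs.

    Reads of equal length are compared position-wise (ungapped); pairs at
    <= 1 mismatch are flagged as potential cross-mapping artifacts (a
    single sequencing error in an abundant miRNA can map to the opposite
    strand), with the abundance ratio attached.  Unequal-length pairs are
    skipped with a note rather than an error.
    """
    results = []
    for ra in reads_a:
        for rb in reads_b:
            if len(ra.seq) != len(rb.seq):
                results.append(
                    {
                        "read_a": ra.seq,
                        "read_b": rb.seq,
                        "mismatches": None,
                        "note": "unequal lengths, skipped",
                        "flagged": False,
                    }
                )
                continue
            mm = sum(1 for x, y in zip(ra.seq, rb.seq) if x != y)
            flagged = mm <= max_flag_mismatches
            rec = {
                "read_a": ra.seq,
                "read_b": rb.seq,
                "mismatches": mm,
                "count_a": ra.count,
                "count_b": rb.count,
                "flagged": flagged,
            }
            if flagged:
                rec["abundance_ratio"] = (
                    ra.count / rb.count if rb.count else float("inf")
                )
            results.append(rec)
    return results


# ---------------------------------------------------------------------------
# miRtrons
# ---------------------------------------------------------------------------


def detect_mirtrons(
    loci: Sequence[MirnaLocus],
    gene_models: Sequence[GeneModel],
    duplex_pass: Mapping[str, bool],
    min_reciprocal: float = MIRTRON_RECIPROCAL_OVERLAP,
) -> set[str]:
    """Loci with >= 90% reciprocal same-strand intron overlap plus
    processing evidence (``duplex_pass``)."""
    introns = [iv for g in gene_models for iv in g.introns()]
    flagged = set()
    for locus in loci:
        if not duplex_pass.get(locus.locus_id, False):
            continue
        li = locus.interval
        for intron in introns:
            if intron.strand != li.strand:
                continue
            ov = li.overlap_len(intron)
            if ov / len(li) >= min_reciprocal and ov / len(intron) >= min_reciprocal:
                flagged.add(locus.locus_id)
                break
    return flagged


# ---------------------------------------------------------------------------
# duplications
# ---------------------------------------------------------------------------


def find_duplications(
    orthogroups: Sequence[Orthogroup],
    loci_by_id: Mapping[str, MirnaLocus],
    tandem_window: int = TANDEM_WINDOW,
) -> dict[str, dict]:
    """Duplication status per orthogroup.

    Duplicated iff some species contributes >= 2 member loci forming at
    least one genuine copy pair (opposite-strand couples overlapping >=
    95% are reverse-complement couples, not duplications, and are
    excluded); tandem iff a copy pair lies within ``tandem_window`` on
    one contig (strand-agnostic otherwise).
    """
    def is_antisense_couple(a: GenomicInterval, b: GenomicInterval) -> bool:
        # one genomic span read on both strands is a reverse-complement
        # couple, not a pair of paralogous copies
        if a.seq_id != b.seq_id or a.strand == b.strand:
            return False
        ov = a.overlap_len(b)
        return ov and max(ov / len(a), ov / len(b)) >= ANTISENSE_MIN_OVERLAP

    out = {}
    for og in orthogroups:
        dup_species: list[str] = []
        tandem = False
        for sp, ids in og.members.items():
            ivs = [loci_by_id[i].interval for i in ids if i in loci_by_id]
            pairs = [
                (a, b)
                for a, b in itertools.combinations(ivs, 2)
                if not is_antisense_couple(a, b)
            ]
            if not pairs:
                continue
            dup_species.append(sp)
            for a, b in pairs:
                if a.seq_id == b.seq_id:
                    gap = max(a.start, b.start) - min(a.end, b.end)
                    if gap <= tandem_window:
                        tandem = True
        out[og.og_id] = {
            "duplicated": bool(dup_species),
            "tandem": tandem,
            "species": sorted(dup_species),
        }
    return out


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------


def _utr_regions(gene: GeneModel) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """(utr5, utr3) exonic regions outside the CDS, strand-aware."""
    if not gene.cds:
        return [], []
    cds_lo = min(c.start for c in gene.cds)
    cds_hi = max(c.end for c in gene.cds)
    before, after = [], []
    for e in gene.exons:
        if e.start < cds_lo:
            before.append(
                GenomicInterval(e.seq_id, e.start, min(e.end, cds_lo), e.strand)
            )
        if e.end > cds_hi:
            after.append(
                GenomicInterval(e.seq_id, max(e.start, cds_hi), e.end, e.strand)
            )
    if gene.interval.strand == "+":
        return before, after
    return after, before


def genomic_context(
    locus: GenomicInterval, gene_models: Sequence[GeneModel]
) -> str:
    """Majority-overlap context with precedence UTR3 > UTR5 > intron on ties.

    Intergenic means no gene overlap at all; a locus overlapping only
    coding exons falls back to the containing gene's intron category so
    that the four categories stay a partition.
    """
    overlap = {"utr3": 0, "utr5": 0, "intron": 0}
    gene_overlap = 0
    for g in gene_models:
        gene_overlap = max(gene_overlap, locus.overlap_len(g.interval))
        u5, u3 = _utr_regions(g)
        for iv in u5:
            overlap["utr5"] += locus.overlap_len(iv)
        for iv in u3:
            overlap["utr3"] += locus.overlap_len(iv)
        for iv in g.introns():
            overlap["intron"] += locus.overlap_len(iv)
    if gene_overlap == 0:
        return "intergenic"
    best = max(overlap.values())
    if best == 0:
        return "intron"
    for cat in CONTEXT_PRECEDENCE[:3]:
        if overlap[cat] == best:
            return cat
    return "intergenic"  # pragma: no cover


def classify_origins(
    loci: Sequence[MirnaLocus],
    gene_models: Sequence[GeneModel],
    orthogroups: Sequence[Orthogroup] | None = None,
    repeat_flags: set[str] | None = None,
    duplex_pass: Mapping[str, bool] | None = None,
) -> dict[str, OriginCall]:
    """Convenience wrapper combining all origin classifiers per locus."""
    duplex_pass = duplex_pass or {l.locus_id: True for l in loci}
    calls = {
        l.locus_id: OriginCall(
            locus_id=l.locus_id,
            context=genomic_context(l.interval, gene_models),
        )
        for l in loci
    }
    for a, b, frac in find_antisense_pairs(loci):
        for x, y in ((a, b), (b, a)):
            calls[x].flags.add("antisense_pair")
            calls[x].support["antisense_pair"] = {"partner": y, "overlap": frac}
    for lid in detect_mirtrons(loci, gene_models, duplex_pass):
        calls[lid].flags.add("mirtron")
        calls[lid].support["mirtron"] = {"reciprocal_overlap": ">=0.9"}
    if repeat_flags:
        for lid in repeat_flags & set(calls):
            calls[lid].flags.add("repeat_derived")
    if orthogroups:
        loci_by_id = {l.locus_id: l for l in loci}
        dup = find_duplications(orthogroups, loci_by_id)
        for og in orthogroups:
            info = dup[og.og_id]
            if info["duplicated"]:
                for lid in og.member_ids():
                    if lid in calls:
                        calls[lid].flags.add("duplicated")
                        if info["tandem"]:
                            calls[lid].flags.add("tandem")
                        calls[lid].support["duplicated"] = {
                            "orthogroup": og.og_id,
                            "species": info["species"],
                        }
    return calls
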
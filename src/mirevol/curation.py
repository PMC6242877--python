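"""Curation of candidate miRNA loci from merged computational predictions.

The filters mirror manual small-RNA curation practice: a candidate hairpin
is accepted when (i) its fold looks like a pre-miRNA stem-loop — a single
terminal loop with the two annotated arms on opposite sides of it and most
arm bases paired — and (ii) the read stacks show Drosha/Dicer duplex
evidence: at least one read on each arm and at least 10 reads in total.
Accepted loci are classified *known* when a reference mature sequence
aligns ungapped within the hairpin with at most one mismatch, otherwise
*novel*.  Low-coverage rejects can be rescued later when they show both
arm-processing evidence and homology to an accepted locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval

_COMP = str.maketrans("ACGTN", "TGCAN")

# thresholds, overridable per call
MIN_TOTAL_READS = 10
MIN_ARM_PAIRED_FRACTION = 0.6
ARM_ASSIGN_SPAN_FRACTION = 0.8
ARM_ASSIGN_SLACK_NT = 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadStack:
    """A distinct small-RNA read aligned to a hairpin."""

    seq: str
    count: int
    offset: int  # 0-based start on the hairpin


@dataclass
class MirnaLocus:
    """A hairpin locus with arm annotations and read-support summary."""

    locus_id: str
    interval: GenomicInterval
    hairpin_seq: str
    arm_5p: tuple[int, int]  # nt offsets on the hairpin, half-open
    arm_3p: tuple[int, int]
    total_reads: int = 0
    reads_5p: int = 0
    reads_3p: int = 0
    status: str = "candidate"  # known | novel | rejected | rescued | candidate
    fold: tuple[str, float] | None = None

    def __post_init__(self):
        if self.arm_5p[1] > self.arm_3p[0]:
            raise ValueError(
                f"{self.locus_id}: arms overlap or 3p precedes 5p "
                f"({self.arm_5p} vs {self.arm_3p})"
            )


# ---------------------------------------------------------------------------
# candidate merging
# ---------------------------------------------------------------------------


def merge_candidates(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Merge two prediction sets into maximal non-overlapping intervals.

    Overlapping or book-ended intervals on the same contig and strand are
    merged (bedtools-merge semantics); output sorted by (contig, start).
    """
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in list(set_a) + list(set_b):
        by_key.setdefault((iv.seq_id, iv.strand), []).append(iv)

    merged: list[GenomicInterval] = []
    for (seq_id, strand), ivs in by_key.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(seq_id, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(seq_id, cur_s, cur_e, strand))
    merged.sort(key=lambda x: (x.seq_id, x.start, x.end, x.strand))
    return merged


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_LOOP = 3


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def _nussinov(seq: str) -> str:
    """Deterministic maximum-pairing fold (Watson–Crick + GU, min loop 3)."""
    n = len(seq)
    E = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i][j - 1]  # j unpaired
            for k in range(i, j - MIN_LOOP):
                if _can_pair(seq[k], seq[j]):
                    left = E[i][k - 1] if k > i else 0
                    cand = left + 1 + E[k + 1][j - 1]
                    if cand > best:
                        best = cand
            E[i][j] = best

    structure = ["."] * n

    def trace(i: int, j: int) -> None:
        while j > i:
            if E[i][j] == (E[i][j - 1] if j - 1 >= i else 0):
                j -= 1
                continue
            for k in range(i, j - MIN_LOOP):
                if _can_pair(seq[k], seq[j]):
                    left = E[i][k - 1] if k > i else 0
                    if left + 1 + E[k + 1][j - 1] == E[i][j]:
                        structure[k] = "("
                        structure[j] = ")"
                        trace(k + 1, j - 1)
                        j = k - 1
                        break
            else:  # pragma: no cover - DP guarantees a branch above
                raise AssertionError("traceback failed")

    trace(0, n - 1)
    return "".join(structure)


def fold_hairpin(sequence: str, engine: str = "nussinov") -> tuple[str, float]:
    """Fold a candidate hairpin into a dot-bracket structure.

    ``engine="nussinov"`` (default) uses the built-in deterministic
    maximum-pairing fold and reports the negated pair count as the score;
    ``engine="vienna"`` uses the ViennaRNA bindings (minimum free energy in
    kcal/mol) when the ``RNA`` module is importable.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 40:
        raise ValueError(f"sequence too short to fold ({len(seq)} < 40 nt)")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if engine == "vienna":
        import RNA  # noqa: import guarded by caller choice

        struct, mfe = RNA.fold(seq.replace("T", "U"))
        return struct, float(mfe)
    if engine != "nussinov":
        raise ValueError(f"unknown folding engine {engine!r}")
    struct = _nussinov(seq)
    return struct, -float(struct.count("("))


def pair_table(structure: str) -> list[int | None]:
    """Partner index per position (None if unpaired) from dot-bracket."""
    stack: list[int] = []
    table: list[int | None] = [None] * len(structure)
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return table


def _hairpin_loops(table: list[int | None]) -> list[tuple[int, int]]:
    """Terminal (hairpin) loops: pairs (i, j) with no pairs strictly inside."""
    loops = []
    for i, j in enumerate(table):
        if j is None or j <= i:
            continue
        if all(table[k] is None for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


#: shortest helix treated as structure; isolated 1-2-pair helices are noise
MIN_HELIX = 3


def _drop_short_helices(
    table: list[int | None], min_helix: int = MIN_HELIX
) -> list[int | None]:
    """Unpair helices shorter than ``min_helix`` stacked pairs.

    A maximum-pairing fold happily adds isolated pairs that no stable
    structure would hold; removing them before loop counting keeps the
    terminal-loop criterion about the dominant stem, not pairing noise.
    """
    pairs = sorted((i, j) for i, j in enumerate(table) if j is not None and i < j)
    helices: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    for p in pairs:
        if cur and p == (cur[-1][0] + 1, cur[-1][1] - 1):
            cur.append(p)
        else:
            if cur:
                helices.append(cur)
            cur = [p]
    if cur:
        helices.append(cur)
    cleaned: list[int | None] = [None] * len(table)
    for helix in helices:
        if len(helix) >= min_helix:
            for i, j in helix:
                cleaned[i], cleaned[j] = j, i
    return cleaned


def is_mirna_like(
    fold: tuple[str, float],
    arms: tuple[tuple[int, int], tuple[int, int]],
    min_arm_paired: float = MIN_ARM_PAIRED_FRACTION,
) -> tuple[bool, str]:
    """miRNA-likeness of a fold given annotated (5p, 3p) arm offsets.

    Criteria: exactly one terminal loop; >= ``min_arm_paired`` of arm bases
    paired; the two arms flank the loop; no arm base pairs within its own
    arm.  Returns ``(ok, reason)`` where ``reason`` names the first failed
    criterion (empty when ok).
    """
    structure, _ = fold
    (a5s, a5e), (a3s, a3e) = arms
    n = len(structure)
    if not (0 <= a5s < a5e <= n and 0 <= a3s < a3e <= n):
        raise ValueError("arm offsets outside the folded sequence")

    table = _drop_short_helices(pair_table(structure))
    loops = _hairpin_loops(table)
    if len(loops) != 1:
        return False, "multiloop"

    arm_positions = list(range(a5s, a5e)) + list(range(a3s, a3e))
    paired = sum(1 for k in arm_positions if table[k] is not None)
    if paired < min_arm_paired * len(arm_positions):
        return False, "pairing fraction"

    # arms must sit on opposite sides of the single terminal loop; a few nt
    # of slack tolerates mismatch-shifted closing pairs near the loop
    loop_i, loop_j = loops[0]
    slack = 4
    if not (a5e <= loop_i + 1 + slack and a3s >= loop_j - slack):
        return False, "arms not flanking loop"

    for k in range(a5s, a5e):
        p = table[k]
        if p is not None and a5s <= p < a5e:
            return False, "intra-arm pairing"
    for k in range(a3s, a3e):
        p = table[k]
        if p is not None and a3s <= p < a3e:
            return False, "intra-arm pairing"
    return True, ""


# ---------------------------------------------------------------------------
# read-based filters
# ---------------------------------------------------------------------------


def _arm_read_fraction(read_start: int, read_end: int, arm: tuple[int, int]) -> float:
    lo = arm[0] - ARM_ASSIGN_SLACK_NT
    hi = arm[1] + ARM_ASSIGN_SLACK_NT
    ov = max(0, min(read_end, hi) - max(read_start, lo))
    return ov / (read_end - read_start)


def duplex_evidence(
    locus: MirnaLocus,
    read_stacks: Iterable[ReadStack],
    min_total: int = MIN_TOTAL_READS,
) -> tuple[int, int, int, bool]:
    """Assign reads to arms and apply the duplex-evidence filter.

    A read belongs to an arm when >= 80% of its span lies within the arm
    extended by 3 nt.  The locus passes iff both arms have >= 1 read and
    the total read count is >= ``min_total``.
    Returns ``(reads_5p, reads_3p, total_reads, pass)``.
    """
    r5 = r3 = total = 0
    for rs in read_stacks:
        start, end = rs.offset, rs.offset + len(rs.seq)
        total += rs.count
        if _arm_read_fraction(start, end, locus.arm_5p) >= ARM_ASSIGN_SPAN_FRACTION:
            r5 += rs.count
        elif _arm_read_fraction(start, end, locus.arm_3p) >= ARM_ASSIGN_SPAN_FRACTION:
            r3 += rs.count
    ok = r5 >= 1 and r3 >= 1 and total >= min_total
    return r5, r3, total, ok


def _best_ungapped_mismatches(needle: str, hay: str) -> int:
    """Minimum mismatch count of ``needle`` over all ungapped placements."""
    best = len(needle) + 1
    for off in range(len(hay) - len(needle) + 1):
        mm = sum(1 for a, b in zip(needle, hay[off : off + len(needle)]) if a != b)
        best = min(best, mm)
        if best == 0:
            return 0
    return best


def classify_known(locus: MirnaLocus, mature_db: Mapping[str, str]) -> str:
    """``known`` iff a reference mature maps ungapped with <= 1 mismatch.

    Both orientations of each mature are slid along the hairpin sense
    strand; gaps are not allowed.
    """
    hp = locus.hairpin_seq.upper().replace("U", "T")
    for mature in mature_db.values():
        m = mature.upper().replace("U", "T")
        if len(m) > len(hp):
            continue
        for cand in (m, revcomp(m)):
            if _best_ungapped_mismatches(cand, hp) <= 1:
                return "known"
    return "novel"


def rescue_low_coverage(
    rejected_loci: Sequence[MirnaLocus],
    homology_orthologs: Mapping[str, set[str]],
    accepted_ids: set[str],
) -> list[MirnaLocus]:
    """Rescue low-coverage rejects with processing evidence plus homology.

    A rejected locus is rescued iff it has >= 1 read on each arm (Drosha/
    Dicer processing evidence) and ``homology_orthologs`` links it to at
    least one accepted locus.  Rescued loci get status ``rescued``.
    """
    rescued = []
    for locus in rejected_loci:
        if locus.status != "rejected":
            continue
        if locus.reads_5p < 1 or locus.reads_3p < 1:
            continue
        partners = homology_orthologs.get(locus.locus_id, set())
        if partners & accepted_ids:
            locus.status = "rescued"
            rescued.append(locus)
    return rescued


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def curate_locus(
    locus: MirnaLocus,
    read_stacks: Iterable[ReadStack],
    mature_db: Mapping[str, str] | None = None,
    engine: str = "nussinov",
) -> MirnaLocus:
    """Run structure + duplex filters on one locus and set its status.

    The two filters commute; both always run so diagnostics are complete.
    """
    fold = fold_hairpin(locus.hairpin_seq, engine=engine)
    locus.fold = fold
    ok_structure, _reason = is_mirna_like(fold, (locus.arm_5p, locus.arm_3p))
    r5, r3, total, ok_duplex = duplex_evidence(locus, read_stacks)
    locus.reads_5p, locus.reads_3p, locus.total_reads = r5, r3, total
    if ok_structure and ok_duplex:
        locus.status = (
            classify_known(locus, mature_db) if mature_db is not None else "novel"
        )
    else:
        locus.status = "rejected"
    return locus
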
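"""Pairwise alignment helpers.

Two distinct alignment regimes are used by the pipeline:

* global identity counting for greedy clustering — Needleman–Wunsch with
  match 1 / mismatch 0 / indel 0, so the optimal score *is* the number of
  identically aligned positions;
* gapped local alignment for repeat-similarity calls, with raw scores
  converted to bit scores by the Karlin–Altschul transform
  ``bits = (lambda * S - ln K) / ln 2`` using the published ungapped
  parameters for the +1/−2 nucleotide scheme (lambda = 1.28, K = 0.46),
  the same scheme blastn reports for its default scoring.

Both delegate the dynamic programming to ``Bio.Align.PairwiseAligner``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .io_formats import HitRecord

# Karlin-Altschul ungapped parameters for match +1 / mismatch -2
KA_LAMBDA = 1.28
KA_K = 0.46

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2


def _identity_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = 0
    al.open_gap_score = 0
    al.extend_gap_score = 0
    return al


def _local_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


_IDENTITY = _identity_aligner()
_LOCAL = _local_aligner()


def identity_fraction(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical positions / length of the shorter.

    This is the CD-HIT global-identity convention used for orthogroup
    clustering.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    matches = _IDENTITY.score(seq_a, seq_b)
    return matches / min(len(seq_a), len(seq_b))


def bit_score(raw_score: float) -> float:
    """Karlin–Altschul bit score for an ungapped-parameter raw score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def local_score(query: str, subject: str) -> float:
    """Raw local-alignment score only (fast path for shuffle nulls)."""
    return _LOCAL.score(query, subject)


@dataclass
class LocalHit:
    raw_score: float
    bit_score: float
    align_len: int
    identity_pct: float
    query_span: tuple[int, int]  # 0-based half-open
    subject_span: tuple[int, int]


def local_align(query: str, subject: str) -> LocalHit | None:
    """Best gapped local alignment of ``query`` against ``subject``.

    Returns ``None`` when no positive-scoring alignment exists.
    """
    score = _LOCAL.score(query, subject)
    if score <= 0:
        return None
    aln = _LOCAL.align(query, subject)[0]
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    ss, se = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
    matches = 0
    length = 0
    for (qa, qb), (sa, sb) in zip(aln.aligned[0], aln.aligned[1]):
        for i in range(qb - qa):
            length += 1
            if query[qa + i] == subject[sa + i]:
                matches += 1
    # count gap columns between aligned blocks as alignment length
    for k in range(1, len(aln.aligned[0])):
        length += (aln.aligned[0][k][0] - aln.aligned[0][k - 1][1]) + (
            aln.aligned[1][k][0] - aln.aligned[1][k - 1][1]
        )
    return LocalHit(
        raw_score=float(score),
        bit_score=bit_score(float(score)),
        align_len=length,
        identity_pct=100.0 * matches / length if length else 0.0,
        query_span=(qs, qe),
        subject_span=(ss, se),
    )


def local_hit_record(
    query_id: str, query: str, subject_id: str, subject: str
) -> HitRecord | None:
    """Best local alignment as a :class:`HitRecord` (1-based spans), or None."""
    hit = local_align(query, subject)
    if hit is None:
        return None
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=hit.identity_pct,
        align_len=hit.align_len,
        evalue=0.0,
        bit_score=hit.bit_score,
        query_span=(hit.query_span[0] + 1, hit.query_span[1]),
        subject_span=(hit.subject_span[0] + 1, hit.subject_span[1]),
    )
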
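"""Orthogroup construction: greedy identity clustering, homology-hit
filtering, synteny support, and the presence–absence matrix.

Clustering follows CD-HIT semantics: sequences are sorted longest first,
each unassigned sequence either joins the first existing cluster whose
representative it matches at or above the identity threshold, or seeds a
new cluster.  Identity is identical positions in a global alignment
divided by the length of the shorter sequence (CD-HIT's global-identity
default).  Ties in the ordering break lexicographically by ID, which makes
the output independent of input insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import identity_fraction
from .io_formats import GeneModel, GenomicInterval, HitRecord

MAX_EVALUE = 1e-6
MIN_ALIGN_LEN = 40
IDENTITY_THRESHOLD = 0.8


@dataclass
class Orthogroup:
    """A cluster of homologous miRNA loci across species."""

    og_id: str
    members: dict[str, list[str]] = field(default_factory=dict)  # species -> ids
    representative: str = ""
    composition: str = "novel_only"  # mirbase_only | novel_only | mixed

    def member_ids(self) -> list[str]:
        return [m for ids in self.members.values() for m in ids]


@dataclass
class OrthogroupMatrix:
    """Orthogroup × species presence matrix with per-cell evidence source."""

    species: list[str]
    rows: dict[str, dict[str, int]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def presence(self, og_id: str, species: str) -> int:
        return self.rows[og_id][species]

    def present_species(self, og_id: str) -> set[str]:
        return {sp for sp, v in self.rows[og_id].items() if v == 1}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def greedy_cluster(
    sequences: Mapping[str, str],
    identity_threshold: float = IDENTITY_THRESHOLD,
    species_of: Mapping[str, str] | None = None,
    known_ids: set[str] | None = None,
) -> list[Orthogroup]:
    """Greedy incremental clustering at a global-identity threshold.

    ``species_of`` maps locus IDs to species (defaults to one pseudo-species);
    ``known_ids`` marks reference-annotated members for the composition label.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not (0.5 <= identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in [0.5, 1.0]")

    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    clusters: list[tuple[str, list[str]]] = []  # (representative, members)
    for sid in order:
        seq = sequences[sid]
        for rep, members in clusters:
            if identity_fraction(seq, sequences[rep]) >= identity_threshold:
                members.append(sid)
                break
        else:
            clusters.append((sid, [sid]))

    out = []
    for idx, (rep, members) in enumerate(clusters, 1):
        og = Orthogroup(og_id=f"og{idx:04d}", representative=rep)
        for m in members:
            sp = species_of[m] if species_of else "sp"
            og.members.setdefault(sp, []).append(m)
        if known_ids is not None:
            n_known = sum(1 for m in members if m in known_ids)
            if n_known == len(members):
                og.composition = "mirbase_only"
            elif n_known == 0:
                og.composition = "novel_only"
            else:
                og.composition = "mixed"
        out.append(og)
    return out


# ---------------------------------------------------------------------------
# homology-hit filtering and synteny
# ---------------------------------------------------------------------------


def filter_hits(
    hits: Sequence[HitRecord],
    max_evalue: float = MAX_EVALUE,
    min_len: int = MIN_ALIGN_LEN,
) -> list[HitRecord]:
    """Keep hits with e-value <= ``max_evalue`` and length >= ``min_len``."""
    return [h for h in hits if h.evalue <= max_evalue and h.align_len >= min_len]


def _flanking_genes(
    locus: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str | None, str | None]:
    """Nearest protein-coding gene up/downstream (strand-normalised).

    A gene containing the locus counts as both flanks.  "Upstream" is in
    the locus's transcription direction.
    """
    left = right = None  # in forward-genome coordinates
    left_end = -1
    right_start = None
    for g in genes:
        if g.biotype != "protein_coding" or g.interval.seq_id != locus.seq_id:
            continue
        gi = g.interval
        if gi.start <= locus.start and gi.end >= locus.end:
            return g.gene_id, g.gene_id
        if gi.end <= locus.start and gi.end > left_end:
            left, left_end = g.gene_id, gi.end
        if gi.start >= locus.end and (right_start is None or gi.start < right_start):
            right, right_start = g.gene_id, gi.start
    if locus.strand == "+":
        return left, right
    return right, left


def synteny_support(
    hit: HitRecord,
    query_locus: GenomicInterval,
    subject_locus: GenomicInterval,
    query_genes: Sequence[GeneModel],
    subject_genes: Sequence[GeneModel],
    homolog_map: Mapping[str, str],
) -> bool:
    """True iff at least one flank-gene pair is homologous in matching
    orientation.

    The nearest protein-coding gene upstream and downstream of the query
    locus and of the subject hit location are compared (the containing
    gene counts as both flanks for intragenic loci); support requires
    ``homolog_map`` to link the query's upstream gene to the subject's
    upstream gene, or downstream to downstream, after strand
    normalisation.
    """
    q_up, q_down = _flanking_genes(query_locus, query_genes)
    s_up, s_down = _flanking_genes(subject_locus, subject_genes)
    for q_gene, s_gene in ((q_up, s_up), (q_down, s_down)):
        if q_gene is None or s_gene is None:
            continue
        if homolog_map.get(q_gene) == s_gene or homolog_map.get(s_gene) == q_gene:
            return True
    return False


# ---------------------------------------------------------------------------
# presence-absence matrix
# ---------------------------------------------------------------------------

_EVIDENCE_PRIORITY = ("annotated", "synteny_homolog", "unaligned_read")


def build_matrix(
    orthogroups: Sequence[Orthogroup],
    species: Sequence[str],
    syntenic_hits: Mapping[tuple[str, str], bool] | None = None,
    unaligned_read_matches: Mapping[tuple[str, str], bool] | None = None,
) -> OrthogroupMatrix:
    """Assemble the presence–absence matrix with per-cell evidence.

    Presence in (orthogroup, species) holds when the species has an
    annotated member, a synteny-supported homology hit, or a match among
    unaligned reads; the evidence field records the strongest source in
    that order.  Rows with no presence anywhere are excluded.
    """
    syntenic_hits = syntenic_hits or {}
    unaligned_read_matches = unaligned_read_matches or {}
    matrix = OrthogroupMatrix(species=list(species))
    for og in orthogroups:
        row = {}
        ev_row = {}
        for sp in species:
            if og.members.get(sp):
                row[sp], ev_row[sp] = 1, "annotated"
            elif syntenic_hits.get((og.og_id, sp)):
                row[sp], ev_row[sp] = 1, "synteny_homolog"
            elif unaligned_read_matches.get((og.og_id, sp)):
                row[sp], ev_row[sp] = 1, "unaligned_read"
            else:
                row[sp], ev_row[sp] = 0, "absent"
        if not any(row.values()):
            continue
        matrix.rows[og.og_id] = row
        for sp in species:
            matrix.evidence[(og.og_id, sp)] = ev_row[sp]
    return matrix
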
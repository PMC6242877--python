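"""Seed families, target-site discovery and conservation profiling.

The mature miRNA's *seed* (nucleotides 2–8) defines its canonical target
sites in 3'UTRs, named by the TargetScan taxonomy: with ``m`` the reverse
complement of the 7-nt seed,

* **8mer** — ``m`` followed by an A (pairing to positions 2–8 plus the
  t1 adenosine);
* **7mer-m8** — ``m`` not followed by an A;
* **7mer-A1** — the 6-nt match to positions 2–7 followed by an A, and not
  preceded by the position-8 match (which would make it an 8mer).

UTR windows are the 5 kb downstream of a gene's last exon, trimmed at the
first overlapping downstream CDS and kept only when >= 500 nt remain.
Conservation around sites is profiled in consecutive 7-nt bins tiling the
site +/- 49 nt (15 bins, the site occupying the central one), reporting
the median across sites of per-site bin means with a seeded bootstrap
percentile confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .curation import revcomp
from .io_formats import GeneModel, GenomicInterval, ScoreTrack

logger = logging.getLogger(__name__)

UTR_WINDOW = 5000
UTR_MIN_LEN = 500
DEFAULT_FLANK = 49
DEFAULT_BIN = 7
MIN_CONTEXT = -0.1
DEFAULT_OUTGROUP = "rabbit"


@dataclass
class SeedFamily:
    """Matures sharing one exact 7-nt seed (positions 2–8)."""

    seed7: str
    members: list[str] = field(default_factory=list)
    species_span: set[str] = field(default_factory=set)


@dataclass
class TargetSite:
    """One seed-match occurrence in a 3'UTR."""

    gene_id: str
    species: str
    utr_offset: int  # 0-based on the ungapped UTR
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1
    seed7: str
    context_score: float | None = None
    msa_columns: tuple[int, int] | None = None


@dataclass
class ConservationProfile:
    bin_offsets: list[int]
    median: list[float]
    ci_low: list[float]
    ci_high: list[float]
    n_sites: int


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------


def extract_seed(mature_sequence: str) -> tuple[str, str]:
    """(seed7, seed6) = mature positions 2–8 and 2–7 (1-based)."""
    seq = mature_sequence.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"mature too short for a seed ({len(seq)} < 8 nt)")
    return seq[1:8], seq[1:7]


def seed_families(
    matures: Mapping[str, str],
    species_of: Mapping[str, str] | None = None,
) -> dict[str, SeedFamily]:
    """Group matures into exact-seed families."""
    fams: dict[str, SeedFamily] = {}
    for mid in sorted(matures):
        seed7, _ = extract_seed(matures[mid])
        fam = fams.setdefault(seed7, SeedFamily(seed7=seed7))
        fam.members.append(mid)
        if species_of and mid in species_of:
            fam.species_span.add(species_of[mid])
    return fams


# ---------------------------------------------------------------------------
# UTR windows
# ---------------------------------------------------------------------------


def build_utr_windows(
    gene_models: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    window: int = UTR_WINDOW,
    min_len: int = UTR_MIN_LEN,
) -> dict[str, GenomicInterval]:
    """Strand-aware 3'UTR windows downstream of each gene's last exon.

    The window spans ``window`` nt beyond the 3'-most exon end, is trimmed
    at the first overlapping CDS of any other gene, clipped at the contig
    end, and dropped when shorter than ``min_len``.
    """
    all_cds = [(c, g.gene_id) for g in gene_models for c in g.cds]
    out: dict[str, GenomicInterval] = {}
    for g in gene_models:
        iv = g.interval
        if not g.exons:
            continue
        if iv.strand == "+":
            start = max(e.end for e in g.exons)
            end = min(start + window, contig_lengths.get(iv.seq_id, start + window))
            for c, owner in all_cds:
                if owner == g.gene_id or c.seq_id != iv.seq_id:
                    continue
                if start < c.end and c.start < end:
                    end = min(end, max(c.start, start))
        else:
            end = min(e.start for e in g.exons)
            start = max(0, end - window)
            for c, owner in all_cds:
                if owner == g.gene_id or c.seq_id != iv.seq_id:
                    continue
                if c.start < end and c.end > start:
                    start = max(start, min(c.end, end))
        if end - start >= min_len:
            out[g.gene_id] = GenomicInterval(iv.seq_id, start, end, iv.strand)
    return out


# ---------------------------------------------------------------------------
# site discovery
# ---------------------------------------------------------------------------


def find_sites(
    utr_sequence: str,
    seed7: str,
    gene_id: str = "",
    species: str = "",
) -> list[TargetSite]:
    """All canonical seed-match sites in one ungapped UTR sequence.

    Overlapping occurrences are all reported; offsets are 0-based starts
    of the site's seed match in the UTR.
    """
    utr = utr_sequence.upper().replace("U", "T")
    if len(seed7) != 7:
        raise ValueError("seed must be exactly 7 nt")
    m = revcomp(seed7)  # t8..t2 match
    m7a1 = m[1:]  # t7..t2 match for 7mer-A1
    sites = []
    for off in range(len(utr) - 6):
        if utr[off : off + 7] == m:
            stype = "8mer" if utr[off + 7 : off + 8] == "A" else "7mer-m8"
            sites.append(
                TargetSite(gene_id, species, off, stype, seed7)
            )
        if (
            utr[off : off + 6] == m7a1
            and utr[off + 6 : off + 7] == "A"
            and (off == 0 or utr[off - 1] != m[0])
        ):
            sites.append(TargetSite(gene_id, species, off, "7mer-A1", seed7))
    return sites


def filter_sites(
    sites: Sequence[TargetSite],
    min_context: float = MIN_CONTEXT,
    outgroup: str = DEFAULT_OUTGROUP,
    min_supporting_species: int = 1,
) -> list[TargetSite]:
    """Keep site groups predicted in the outgroup plus supporting species.

    Sites group by (gene, homologous position, seed), where the position
    key is the MSA column span when available and the raw UTR offset
    otherwise.  A group survives when the outgroup carries it along with
    at least ``min_supporting_species`` other species; a site with a
    context++ score above ``min_context`` is dropped individually.  When
    no site carries a score the context filter is skipped with a notice.
    """
    has_scores = any(s.context_score is not None for s in sites)
    if not has_scores:
        logger.info("no context++ scores provided; context filter skipped")

    def passes_context(s: TargetSite) -> bool:
        if not has_scores or s.context_score is None:
            return True
        return s.context_score <= min_context

    groups: dict[tuple, list[TargetSite]] = {}
    for s in sites:
        poskey = s.msa_columns if s.msa_columns is not None else s.utr_offset
        groups.setdefault((s.gene_id, poskey, s.seed7), []).append(s)

    kept: list[TargetSite] = []
    for members in groups.values():
        surviving = [s for s in members if passes_context(s)]
        species = {s.species for s in surviving}
        if outgroup not in species:
            continue
        if len(species - {outgroup}) < min_supporting_species:
            continue
        kept.extend(surviving)
    return kept


# ---------------------------------------------------------------------------
# MSA coordinate lifting
# ---------------------------------------------------------------------------


def lift_through_msa(
    msa: Mapping[str, str],
    species: str,
    ungapped_interval: tuple[int, int],
) -> tuple[tuple[int, int], dict[str, tuple[int, int, bool]]]:
    """Map an ungapped interval to MSA columns and project to all species.

    Returns ``(msa_columns, projections)`` where each projection is
    ``(start, end, gap_flag)`` in that species' ungapped coordinates; the
    flag marks projections interrupted by gap columns.
    """
    if species not in msa:
        raise KeyError(f"species {species!r} not in alignment")
    aligned = msa[species]
    start, end = ungapped_interval
    ungapped_len = len(aligned) - aligned.count("-")
    if not (0 <= start < end <= ungapped_len):
        raise ValueError(
            f"interval {ungapped_interval} outside ungapped length {ungapped_len}"
        )
    col_of: list[int] = [i for i, ch in enumerate(aligned) if ch != "-"]
    col_start, col_end = col_of[start], col_of[end - 1] + 1

    projections: dict[str, tuple[int, int, bool]] = {}
    src_block = aligned[col_start:col_end]
    for sp, seq in msa.items():
        before = sum(1 for ch in seq[:col_start] if ch != "-")
        inside = sum(1 for ch in seq[col_start:col_end] if ch != "-")
        # interrupted = gap pattern differs from the source species inside
        # the lifted columns (a deletion or insertion relative to it)
        gap_flag = any(
            (x == "-") != (y == "-")
            for x, y in zip(src_block, seq[col_start:col_end])
        )
        projections[sp] = (before, before + inside, gap_flag)
    return (col_start, col_end), projections


def pairwise_site_similarity(
    msa_site_block: Mapping[str, str],
    species_a: str,
    species_b: str,
    seed6_columns: tuple[int, int] | None = None,
) -> float:
    """Identity over the 6 seed-match columns of a site block.

    The block is the aligned site plus 2 nt of flank each side; by default
    the seed6 columns are block columns 3–8 (skipping the 2-nt flank and
    the position-8 match).  A gap in either species counts as
    non-identical.
    """
    for sp in (species_a, species_b):
        if sp not in msa_site_block:
            raise KeyError(f"species {sp!r} absent from site block")
    a, b = msa_site_block[species_a], msa_site_block[species_b]
    if seed6_columns is None:
        seed6_columns = (3, 9)
    lo, hi = seed6_columns
    if hi - lo != 6:
        raise ValueError("seed6 spans exactly 6 columns")
    same = sum(
        1
        for x, y in zip(a[lo:hi], b[lo:hi])
        if x == y and x != "-"
    )
    return same / 6


# ---------------------------------------------------------------------------
# conservation profiles
# ---------------------------------------------------------------------------


def conservation_profile(
    sites: Sequence[tuple[str, int]],
    score_track: ScoreTrack,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
    site_len: int = 7,
    bootstrap_B: int = 1000,
    rng_seed: int = 0,
    statistic: str = "per_site_means",
) -> ConservationProfile:
    """Binned conservation profile around target sites.

    ``sites`` are ``(contig, site_start)`` positions on the score track.
    The window (site +/- flank) is tiled into consecutive ``bin_size``-nt
    bins with the site in the central bin.  Per bin the default statistic
    is the median across sites of per-site bin means (``statistic=
    "pooled"`` pools per-position scores instead), with a seeded bootstrap
    percentile 95% CI of the median.  Missing positions drop out of the
    per-site mean; sites with a fully missing bin drop out of that bin's
    median.
    """
    if not sites:
        raise ValueError("no sites to profile")
    if (2 * flank + site_len) % bin_size != 0:
        raise ValueError("window (site + 2*flank) must tile into whole bins")
    if statistic not in ("per_site_means", "pooled"):
        raise ValueError(f"unknown statistic {statistic!r}")
    n_bins = (2 * flank + site_len) // bin_size
    rng = np.random.default_rng(rng_seed)

    # per site and bin: either the mean of available positions, or the raw
    # position values (pooled mode); sites with a fully missing bin drop out
    site_bin_vals: list[list[list[float]]] = []
    for contig, start in sites:
        w0 = start - flank
        rows = []
        for b in range(n_bins):
            rows.append(
                [
                    v
                    for p in range(w0 + b * bin_size, w0 + (b + 1) * bin_size)
                    if (v := score_track.get(contig, p)) is not None
                ]
            )
        site_bin_vals.append(rows)

    medians, lows, highs = [], [], []
    for b in range(n_bins):
        contributing = [sv[b] for sv in site_bin_vals if sv[b]]
        if not contributing:
            medians.append(float("nan"))
            lows.append(float("nan"))
            highs.append(float("nan"))
            continue
        if statistic == "per_site_means":
            samples = [[float(np.mean(vals))] for vals in contributing]
        else:
            samples = contributing
        flat = np.concatenate([np.asarray(s) for s in samples])
        medians.append(float(np.median(flat)))
        # bootstrap resamples sites (the exchangeable unit), then re-pools
        n = len(samples)
        boots = np.empty(bootstrap_B)
        for rep in range(bootstrap_B):
            pick = rng.integers(0, n, size=n)
            boots[rep] = np.median(
                np.concatenate([np.asarray(samples[i]) for i in pick])
            )
        lows.append(float(np.percentile(boots, 2.5)))
        highs.append(float(np.percentile(boots, 97.5)))

    offsets = [b * bin_size - flank for b in range(n_bins)]
    return ConservationProfile(
        bin_offsets=offsets,
        median=medians,
        ci_low=lows,
        ci_high=highs,
        n_sites=len(sites),
    )
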
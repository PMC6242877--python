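"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based half-open on the forward strand.  BED is
read as-is (already 0-based half-open); GFF3 (1-based inclusive) is converted
on read; hit tables keep their 1-based inclusive spans inside
:class:`HitRecord` because they mirror BLAST ``outfmt 6`` rows, with subject
orientation inferred from the coordinate order.

All readers reject malformed records with an error naming the file and line;
nothing is silently repaired.  ``U`` is normalised to ``T`` on FASTA read so
genomic and small-RNA sequence space share one alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .tree import DatedTree

_VALID_NT = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Located, stranded span: 0-based half-open on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """Gene with exon/CDS structure; introns are the gaps between sorted exons."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(
                    f"exon {e.start}-{e.end} outside gene {self.gene_id} "
                    f"span {self.interval.start}-{self.interval.end}"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(
                        self.interval.seq_id, a.end, b.start, self.interval.strand
                    )
                )
        return out


@dataclass
class HitRecord:
    """One BLAST-style tabular hit (outfmt 6 semantics, 1-based spans)."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    evalue: float
    bit_score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    orientation: str = "forward"  # forward | reverse, on the subject

    def __post_init__(self):
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


class ScoreTrack:
    """Sparse per-contig score track (e.g. phastCons).

    Positions without data return ``None`` from :meth:`get`, never 0 —
    conservation tracks have gaps and a missing score must not be mistaken
    for an unconserved base.
    """

    def __init__(self):
        self._data: dict[str, dict[int, float]] = {}

    def set(self, seq_id: str, pos: int, value: float) -> None:
        self._data.setdefault(seq_id, {})[pos] = value

    def get(self, seq_id: str, pos: int) -> float | None:
        return self._data.get(seq_id, {}).get(pos)

    def contigs(self) -> list[str]:
        return sorted(self._data)

    def n_positions(self) -> int:
        return sum(len(d) for d in self._data.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``; ``U``→``T``; IDs are the first token."""
    path = Path(path)
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def flush():
        if current is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: empty sequence for ID {current!r}")
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"{path}: invalid characters {sorted(bad)} in sequence {current!r}"
            )
        seqs[current] = seq

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                if current in seqs:
                    raise ValueError(f"{path}:{lineno}: duplicate ID {current!r}")
                chunks = []
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                chunks.append(line)
    flush()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED6 rows as ``(interval, name, score)`` in file order."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: need >= 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            score = float(score_s) if score_s not in (".", "") else 0.0
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def write_bed(
    records: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv, name, score in records:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
    return path


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def _gff_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a GFF3-like annotation (gene/exon/CDS) into :class:`GeneModel` s.

    GFF coordinates (1-based inclusive) convert to internal 0-based
    half-open as ``start-1, end``.  Exons and CDS attach to their gene via
    ``Parent`` (or ``gene_id``) attributes.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    children: list[tuple[int, str, str, GenomicInterval]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: need 9 GFF columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = (
                fields[:9]
            )
            start, end = int(start_s) - 1, int(end_s)
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            iv = GenomicInterval(seqid, start, end, strand)
            attrs = _gff_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if not gid:
                    raise ValueError(f"{path}:{lineno}: gene without ID/gene_id")
                genes[gid] = {
                    "interval": iv,
                    "exons": [],
                    "cds": [],
                    "biotype": attrs.get("biotype", "protein_coding"),
                }
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent") or attrs.get("gene_id")
                if not parent:
                    raise ValueError(f"{path}:{lineno}: {ftype} without Parent")
                children.append((lineno, ftype, parent, iv))

    for lineno, ftype, parent, iv in children:
        if parent not in genes:
            raise ValueError(f"{path}:{lineno}: {ftype} Parent {parent!r} unknown")
        genes[parent]["exons" if ftype == "exon" else "cds"].append(iv)

    out = []
    for gid in order:
        g = genes[gid]
        try:
            out.append(
                GeneModel(
                    gene_id=gid,
                    interval=g["interval"],
                    exons=g["exons"],
                    cds=g["cds"],
                    biotype=g["biotype"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: gene {gid}: {exc}") from None
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.seq_id}\tmirevol\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.seq_id}\tmirevol\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={g.gene_id}\n"
                )
            for c in g.cds:
                fh.write(
                    f"{c.seq_id}\tmirevol\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t.\tParent={g.gene_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# hit tables (outfmt 6)
# ---------------------------------------------------------------------------

_OUTFMT6_COLS = 12


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table (BLAST ``outfmt 6`` layout)."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                ident = float(fields[2])
                alen = int(fields[3])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                ev = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            orientation = "forward" if ss <= se else "reverse"
            if orientation == "reverse":
                ss, se = se, ss
            out.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_pct=ident,
                    align_len=alen,
                    evalue=ev,
                    bit_score=bits,
                    query_span=(qs, qe),
                    subject_span=(ss, se),
                    orientation=orientation,
                )
            )
    return out


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.subject_span
            if h.orientation == "reverse":
                ss, se = se, ss
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        h.align_len,
                        0,
                        0,
                        h.query_span[0],
                        h.query_span[1],
                        ss,
                        se,
                        f"{h.evalue:.2g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Newick / score tracks / presence-absence matrix
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> DatedTree:
    """Read a rooted, dated Newick tree (bifurcating root required)."""
    return DatedTree.from_newick(Path(path).read_text())


def read_scores(path: str | Path) -> ScoreTrack:
    """Read bedGraph or fixed-step wiggle into a sparse :class:`ScoreTrack`."""
    path = Path(path)
    track = ScoreTrack()
    mode = "bedgraph"
    chrom, pos, step = "", 0, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                continue
            if mode == "wig":
                track.set(chrom, pos, float(line))
                pos += step
            else:
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: need 4 bedGraph columns")
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if s >= e:
                    raise ValueError(f"{path}:{lineno}: start {s} >= end {e}")
                for p in range(s, e):
                    track.set(c, p, v)
    return track


def read_matrix(path: str | Path):
    """Read a TSV presence–absence matrix (rows = orthogroups, cols = species)."""
    from .orthogroups import OrthogroupMatrix

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}:1: header needs >= 2 columns")
        species = header[1:]
        rows: dict[str, dict[str, int]] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            og = fields[0]
            vec = {}
            for sp, cell in zip(species, fields[1:]):
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"{path}:{lineno}: cell {cell!r} not in {{0,1}}"
                    )
                vec[sp] = int(cell)
            rows[og] = vec
    return OrthogroupMatrix(species=species, rows=rows)


def write_matrix(matrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("orthogroup\t" + "\t".join(matrix.species) + "\n")
        for og in sorted(matrix.rows):
            vec = matrix.rows[og]
            fh.write(og + "\t" + "\t".join(str(vec[sp]) for sp in matrix.species) + "\n")
    return path


def gff_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF 1-based inclusive span -> internal 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open span -> GFF 1-based inclusive."""
    return start + 1, end
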
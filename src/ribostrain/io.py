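"""Sequence and annotation I/O plus the ortholog gene set.

All internal coordinates are 0-based half-open; GFF3 I/O (1-based closed)
is the only conversion boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")
_BASE_ORDER = "ATGC"  # order of the nucleotide-frequency vector components


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence restricted to the A/C/G/T/N alphabet."""

    name: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.name!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A stranded multi-interval CDS annotation on a named sequence.

    ``intervals`` are 0-based half-open and sorted in genomic order;
    they never overlap.  For a minus-strand gene the transcript runs
    from the last interval's end backwards.
    """

    gene_id: str
    seqname: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    source: str = "ribostrain"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        for a, b in ivs:
            if b <= a or a < 0:
                raise ValueError(f"{self.gene_id}: bad interval ({a},{b})")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: intervals overlap or unsorted")
        object.__setattr__(self, "intervals", ivs)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def genomic_positions(self) -> np.ndarray:
        """CDS genomic positions in transcript (5'->3') order."""
        pos = np.concatenate([np.arange(a, b) for a, b in self.intervals])
        return pos if self.strand == "+" else pos[::-1]

    def cds_sequence(self, genome: str | GenomeSequence) -> str:
        seq = genome.sequence if isinstance(genome, GenomeSequence) else genome
        s = "".join(seq[a:b] for a, b in self.intervals)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def to_transcript_coord(self, genomic_pos: int) -> int | None:
        """Map a genomic position to a transcript offset, or None if outside
        the CDS.  Offset 0 is the first CDS base in reading direction."""
        off = 0
        for a, b in self.intervals:
            if a <= genomic_pos < b:
                t = off + (genomic_pos - a)
                return t if self.strand == "+" else self.cds_length - 1 - t
            off += b - a
        return None


@dataclass(frozen=True)
class OrthologPair:
    """Two linked genes with mappable lengths and base compositions."""

    gene_b: str
    gene_y: str
    length_b: int
    length_y: int
    pi_b: tuple[float, float, float, float]
    pi_y: tuple[float, float, float, float]

    def __post_init__(self):
        for L in (self.length_b, self.length_y):
            if L <= 0:
                raise ValueError("mappable lengths must be positive")
        for pi in (self.pi_b, self.pi_y):
            v = np.asarray(pi, dtype=float)
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"nucleotide frequencies invalid: {pi}")

    def swapped(self) -> "OrthologPair":
        return OrthologPair(self.gene_y, self.gene_b, self.length_y,
                            self.length_b, self.pi_y, self.pi_b)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[GenomeSequence]:
    """Read FASTA records, upper-casing sequences; duplicate names are an
    error, as are characters outside A/C/G/T/N."""
    out, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(path, sequences) -> None:
    recs = [SeqRecord(Seq(s.sequence), id=s.name, description="")
            for s in sequences]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path) -> list[GeneModel]:
    """Read gene models from GFF3 (CDS features grouped by Parent).

    GFF 1-based closed coordinates become 0-based half-open.  Lines other
    than CDS features are used only to pick up gene sources.
    """
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seqname, source, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            m = re.search(r"(?:Parent|ID)=([^;]+)", attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: CDS without Parent/ID")
            gid = m.group(1)
            g = groups.setdefault(gid, {"seqname": seqname, "strand": strand,
                                        "source": source, "ivs": []})
            g["ivs"].append((start_i - 1, end_i))
    models = []
    for gid, g in groups.items():
        ivs = sorted(g["ivs"])
        models.append(GeneModel(gid, g["seqname"], g["strand"], tuple(ivs),
                                source=g["source"]))
    return models


def write_gff(path, models) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write("\t".join([m.seqname, m.source, "gene", str(m.start + 1),
                                str(m.end), ".", m.strand, ".",
                                f"ID={m.gene_id}"]) + "\n")
            for a, b in m.intervals:
                fh.write("\t".join([m.seqname, m.source, "CDS", str(a + 1),
                                    str(b), ".", m.strand, "0",
                                    f"Parent={m.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# Ortholog table

def read_ortholog_table(path) -> list[tuple[str, str]]:
    """TSV with header columns gene_b, gene_y."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            ib, iy = header.index("gene_b"), header.index("gene_y")
        except ValueError as e:
            raise ValueError("ortholog table needs gene_b and gene_y columns") from e
        for line in fh:
            if line.strip():
                parts = line.rstrip("\n").split("\t")
                pairs.append((parts[ib], parts[iy]))
    return pairs


def write_ortholog_table(path, pairs) -> None:
    with open(path, "w") as fh:
        fh.write("gene_b\tgene_y\n")
        for b, y in pairs:
            fh.write(f"{b}\t{y}\n")


# ---------------------------------------------------------------------------
# Ortholog curation and composition

def dedup_orthologs(pairs, models_b, models_y):
    """Retain pairs whose members occupy a unique chromosome location.

    A gene fails if its genomic footprint (start, end on its sequence)
    intersects any other gene's footprint in the same strain, on either
    strand.  A pair is removed if either member fails.
    """
    def overlapping_ids(models):
        bad = set()
        by_seq: dict[str, list] = {}
        for m in models:
            by_seq.setdefault(m.seqname, []).append(m)
        for ms in by_seq.values():
            ms.sort(key=lambda m: m.start)
            for i, m in enumerate(ms):
                for other in ms[i + 1:]:
                    if other.start >= m.end:
                        break
                    bad.add(m.gene_id)
                    bad.add(other.gene_id)
        return bad

    idx_b = {m.gene_id for m in models_b}
    idx_y = {m.gene_id for m in models_y}
    for b, y in pairs:
        if b not in idx_b or y not in idx_y:
            raise KeyError(f"ortholog pair ({b},{y}) references a missing gene")
    bad_b = overlapping_ids(models_b)
    bad_y = overlapping_ids(models_y)
    return [(b, y) for b, y in pairs if b not in bad_b and y not in bad_y]


def nucleotide_freq(sequence: str):
    """Marginal nucleotide frequencies in (A, T, G, C) order.

    N bases are excluded from the denominator; an all-N (or empty)
    sequence is an error.
    """
    seq = sequence.upper()
    counts = np.array([seq.count(b) for b in _BASE_ORDER], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return tuple(counts / total)


def build_ortholog_pairs(pairs, models_b, models_y, genome_b, genome_y):
    """Assemble OrthologPair records with lengths and compositions taken
    over each member's CDS."""
    gb = {g.name: g.sequence for g in genome_b}
    gy = {g.name: g.sequence for g in genome_y}
    mb = {m.gene_id: m for m in models_b}
    my = {m.gene_id: m for m in models_y}
    out = []
    for b, y in pairs:
        sb = mb[b].cds_sequence(gb[mb[b].seqname])
        sy = my[y].cds_sequence(gy[my[y].seqname])
        out.append(OrthologPair(b, y, len(sb), len(sy),
                                nucleotide_freq(sb), nucleotide_freq(sy)))
    return out
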
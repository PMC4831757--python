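"""Read alignment and 5'-end feature assignment.

The aligner is a seed-free exact scan with a mismatch budget, intended
for toy genomes (up to ~1 Mb); real data enters as externally produced
SAM, to which only trimming bookkeeping and assignment apply.  Footprint
reads carry spurious 3' adenines, so mapping is iterative: the 3'-most
base is removed one at a time until the remaining read aligns, down to a
minimum of 23 nt with at most two mismatches.  Only unique best
alignments are reported; reads are assigned to genomic features by the
position of their 5'-most nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import revcomp, seq_to_array
from .io import GeneModel, GenomeSequence


@dataclass(frozen=True)
class ReadAlignment:
    """A unique alignment; ``pos5`` is the genomic 0-based position of the
    read's 5'-most nucleotide (the rightmost aligned base on minus)."""

    read_id: str
    seqname: str
    pos5: int
    strand: str
    length: int
    mismatches: int
    trimmed: int = 0


class NaiveAligner:
    """Iterative 3'-trimming aligner over small genomes."""

    def __init__(self, genome: list[GenomeSequence], min_len: int = 23,
                 max_mismatch: int = 2):
        self.min_len = min_len
        self.max_mismatch = max_mismatch
        self._seqs = [(g.name, seq_to_array(g.sequence)) for g in genome]

    def _hits(self, query: str):
        """All (seqname, start, strand, mismatches) placements of the query
        on the forward strand of each sequence, for the query and its
        reverse complement."""
        hits = []
        for qseq, strand in ((query, "+"), (revcomp(query), "-")):
            q = seq_to_array(qseq)
            m = len(q)
            for name, arr in self._seqs:
                if len(arr) < m:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(arr, m)
                mm = (win != q).sum(axis=1)
                for start in np.nonzero(mm <= self.max_mismatch)[0]:
                    hits.append((name, int(start), strand, int(mm[start])))
        return hits

    def align(self, read_id: str, sequence: str,
              iterative: bool = True) -> ReadAlignment | None:
        """Align, trimming the 3'-most base one at a time (when
        ``iterative``) until a placement survives.  Returns the unique
        minimum-mismatch alignment at the fewest trims, or None when the
        read is unmapped or multi-mapping."""
        sequence = sequence.upper()
        if len(sequence) < self.min_len:
            raise ValueError(
                f"read {read_id!r} shorter than min_len={self.min_len}")
        max_trim = len(sequence) - self.min_len if iterative else 0
        for trimmed in range(max_trim + 1):
            sub = sequence[:len(sequence) - trimmed]
            hits = self._hits(sub)
            if not hits:
                continue
            best = min(h[3] for h in hits)
            top = [h for h in hits if h[3] == best]
            if len(top) > 1:
                return None  # multi-mapper at the first mappable length
            name, start, strand, mm = top[0]
            pos5 = start if strand == "+" else start + len(sub) - 1
            return ReadAlignment(read_id, name, pos5, strand,
                                 len(sub), mm, trimmed)
        return None


def iterative_trim_align(sequence: str, genome: list[GenomeSequence],
                         min_len: int = 23, max_mismatch: int = 2,
                         read_id: str = "read") -> ReadAlignment | None:
    return NaiveAligner(genome, min_len, max_mismatch).align(read_id, sequence)


# ---------------------------------------------------------------------------
# feature assignment

@dataclass(frozen=True)
class FeatureWindows:
    """5'-end assignment windows, in transcript-oriented coordinates where
    0 is the first CDS base.  A read belongs to the CDS when its 5' end
    falls in [-cds_upstream, L - cds_end_upstream); the 5' UTR ends
    (exclusive) at -utr5_end_upstream; the 3' UTR runs from
    L - utr3_start_upstream to transcript end - utr3_end_upstream; an
    intron claims [gap start, gap end - intron_end_upstream).  Defaults
    follow the ribosome-profiling offsets of the assignment contract."""

    cds_upstream: int = 16
    cds_end_upstream: int = 14
    utr5_end_upstream: int = 16
    intron_end_upstream: int = 8
    utr3_start_upstream: int = 13
    utr3_end_upstream: int = 28

    def __post_init__(self):
        if self.utr5_end_upstream < self.cds_upstream:
            raise ValueError("5'UTR window overlaps the CDS window")
        if self.utr3_start_upstream > self.cds_end_upstream:
            raise ValueError("3'UTR window overlaps the CDS window")


def _transcript_offset(alignment: ReadAlignment, model: GeneModel):
    """Signed transcript-oriented offset of the 5' end relative to the CDS
    start, or ('intron', gap offset, gap length) inside an annotated gap."""
    p = alignment.pos5
    t = model.to_transcript_coord(p)
    if t is not None:
        return t
    ivs = model.intervals
    for (a1, b1), (a2, _) in zip(ivs, ivs[1:]):
        if b1 <= p < a2:  # annotated intron gap
            off = p - b1 if model.strand == "+" else a2 - 1 - p
            return ("intron", off, a2 - b1)
    if model.strand == "+":
        d = p - model.start if p < model.start else model.cds_length + (p - model.end)
    else:
        d = model.end - 1 - p if p >= model.end else \
            model.cds_length + (model.start - 1 - p)
    return d


def assign_to_feature(alignment: ReadAlignment, model: GeneModel,
                      windows: FeatureWindows = FeatureWindows(),
                      utr5_len: int = 0, utr3_len: int = 0) -> str:
    """Label an alignment CDS / intron / 5UTR / 3UTR / unassigned from its
    5'-most nucleotide alone."""
    if alignment.seqname != model.seqname:
        return "unassigned"
    t = _transcript_offset(alignment, model)
    L = model.cds_length
    if isinstance(t, tuple):
        _, off, gap_len = t
        return "intron" if off < gap_len - windows.intron_end_upstream \
            else "unassigned"
    if -windows.cds_upstream <= t < L - windows.cds_end_upstream:
        return "CDS"
    if -utr5_len <= t < -windows.utr5_end_upstream:
        return "5UTR"
    if L - windows.utr3_start_upstream <= t < L + utr3_len - windows.utr3_end_upstream:
        return "3UTR"
    return "unassigned"


# ---------------------------------------------------------------------------
# quantification

CDS_READ_MIN = 50  # genes below this CDS read count are excluded


def cds_read_count(model: GeneModel, alignments,
                   windows: FeatureWindows = FeatureWindows()) -> int:
    return sum(1 for a in alignments
               if assign_to_feature(a, model, windows) == "CDS")


def base_coverage(model: GeneModel, alignments,
                  windows: FeatureWindows = FeatureWindows()) -> np.ndarray:
    """Per-base 5'-end counts over the CDS in transcript orientation.

    CDS-assigned reads whose 5' end sits in the upstream/downstream
    margin of the CDS window are clamped to the nearest CDS base so that
    sum(coverage) equals cds_read_count."""
    L = model.cds_length
    cov = np.zeros(L, dtype=np.int64)
    for a in alignments:
        if assign_to_feature(a, model, windows) != "CDS":
            continue
        t = _transcript_offset(a, model)
        cov[min(max(int(t), 0), L - 1)] += 1
    return cov


def gene_is_quantifiable(count: int, min_reads: int = CDS_READ_MIN) -> bool:
    return count >= min_reads


# ---------------------------------------------------------------------------
# SAM / TSV interchange

def read_sam(path, trimmed_tag: str = "XT") -> list[ReadAlignment]:
    """Read alignments from SAM (text); the optional integer tag named by
    ``trimmed_tag`` carries the number of trimmed 3' bases."""
    import pysam
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            length = rec.query_alignment_length or len(rec.query_sequence or "")
            pos5 = rec.reference_start if strand == "+" \
                else rec.reference_end - 1
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            trimmed = rec.get_tag(trimmed_tag) if rec.has_tag(trimmed_tag) else 0
            out.append(ReadAlignment(rec.query_name, rec.reference_name,
                                     pos5, strand, length, nm, trimmed))
    return out


def write_alignment_tsv(path, alignments) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tseqname\tpos5\tstrand\tlength\tmismatches\ttrimmed\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.seqname}\t{a.pos5}\t{a.strand}"
                     f"\t{a.length}\t{a.mismatches}\t{a.trimmed}\n")


def read_alignment_tsv(path) -> list[ReadAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("alignment TSV must start with its header line")
        for line in fh:
            rid, name, pos5, strand, length, mm, tr = line.rstrip("\n").split("\t")
            out.append(ReadAlignment(rid, name, int(pos5), strand,
                                     int(length), int(mm), int(tr)))
    return out
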
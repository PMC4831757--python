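"""Translated 5' extensions and 3' stop-codon read-through.

Candidates are purely sequence-determined: a 5' extension needs an
in-frame ATG within 180 bp (60 codons) upstream of the annotated start
with no in-frame stop between it and the start (the 5'-most qualifying
ATG is reported, i.e. the maximal extension); a 3' read-through region
runs from the annotated stop (exclusive) to the first in-frame stop
within 180 bp downstream (inclusive).  A candidate is confirmed when
both the mRNA and the footprint library place >= 10 reads in the region
and those reads cover >= 80% of its bases (full aligned span, not the
5' end alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .codons import STOP_CODONS, revcomp
from .io import GeneModel, GenomeSequence

logger = logging.getLogger(__name__)

SEARCH_SPAN_NT = 180


@dataclass(frozen=True)
class ExtensionCandidate:
    gene_id: str
    n_codons: int
    seqname: str
    strand: str
    atg_pos: int                # genomic 0-based leftmost base of the new ATG
    region: tuple[int, int]     # genomic half-open; new ATG .. annotated start


@dataclass(frozen=True)
class ReadthroughCandidate:
    gene_id: str
    n_codons: int               # sense codons added before the new stop
    seqname: str
    strand: str
    stop_pos: int               # genomic 0-based leftmost base of the new stop
    region: tuple[int, int]     # annotated stop (excl) .. new stop (incl)


@dataclass(frozen=True)
class VariantCall:
    candidate: ExtensionCandidate | ReadthroughCandidate
    mrna_reads: int
    rfp_reads: int
    mrna_cov_frac: float
    rfp_cov_frac: float
    accepted: bool


def _flank(model: GeneModel, seq: str, span: int, side: str) -> str | None:
    """Transcript-oriented flanking sequence (5' upstream or 3' downstream),
    or None when the gene sits too close to the sequence edge."""
    upstream = side == "up"
    left = (model.strand == "+") == upstream
    if left:
        if model.start < span:
            return None
        s = seq[model.start - span:model.start]
    else:
        if model.end + span > len(seq):
            return None
        s = seq[model.end:model.end + span]
    return s if model.strand == "+" else revcomp(s)


def find_extension_candidate(model: GeneModel, genome: list[GenomeSequence],
                             span: int = SEARCH_SPAN_NT
                             ) -> ExtensionCandidate | None:
    """The 5'-most in-frame upstream ATG with no intervening in-frame stop."""
    if span % 3:
        raise ValueError("span must be a multiple of 3")
    seq = {g.name: g.sequence for g in genome}[model.seqname]
    up = _flank(model, seq, span, "up")
    if up is None:
        logger.info("%s: too close to the sequence edge for a %d nt "
                    "upstream scan", model.gene_id, span)
        return None
    best = None
    for j in range(1, span // 3 + 1):  # j codons upstream of the start
        codon = up[span - 3 * j:span - 3 * j + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            best = j
    if best is None:
        return None
    k = best
    if model.strand == "+":
        region = (model.start - 3 * k, model.start)
        atg = region[0]
    else:
        region = (model.end, model.end + 3 * k)
        atg = region[1] - 3
    return ExtensionCandidate(model.gene_id, k, model.seqname, model.strand,
                              atg, region)


def find_readthrough_candidate(model: GeneModel, genome: list[GenomeSequence],
                               span: int = SEARCH_SPAN_NT
                               ) -> ReadthroughCandidate | None:
    """Region to the first in-frame stop within ``span`` nt downstream of
    the annotated stop; an immediately following stop (zero added
    codons) or no stop at all yields None."""
    if span % 3:
        raise ValueError("span must be a multiple of 3")
    seq = {g.name: g.sequence for g in genome}[model.seqname]
    down = _flank(model, seq, span, "down")
    if down is None:
        logger.info("%s: too close to the sequence edge for a %d nt "
                    "downstream scan", model.gene_id, span)
        return None
    stop_j = None
    for j in range(1, span // 3 + 1):
        if down[3 * (j - 1):3 * j] in STOP_CODONS:
            stop_j = j
            break
    if stop_j is None or stop_j == 1:
        return None
    if model.strand == "+":
        region = (model.end, model.end + 3 * stop_j)
        stop = region[1] - 3
    else:
        region = (model.start - 3 * stop_j, model.start)
        stop = region[0]
    return ReadthroughCandidate(model.gene_id, stop_j - 1, model.seqname,
                                model.strand, stop, region)


# ---------------------------------------------------------------------------
# expression evidence

def _region_evidence(region, seqname, strand, alignments):
    """(read count by 5' end, fraction of region bases covered by full
    aligned spans) for one library."""
    start, end = region
    occupancy = np.zeros(end - start, dtype=bool)
    n_reads = 0
    for a in alignments:
        if a.seqname != seqname or a.strand != strand:
            continue
        span = (a.pos5, a.pos5 + a.length) if a.strand == "+" \
            else (a.pos5 - a.length + 1, a.pos5 + 1)
        if start <= a.pos5 < end:
            n_reads += 1
        lo, hi = max(span[0], start), min(span[1], end)
        if lo < hi:
            occupancy[lo - start:hi - start] = True
    return n_reads, occupancy.mean()


def confirm_expression(region: tuple[int, int], seqname: str, strand: str,
                       mrna_alignments, rfp_alignments,
                       min_reads: int = 10, min_cov_frac: float = 0.8):
    """Evidence check for a candidate region in both assays.

    Returns (accepted, mrna_reads, rfp_reads, mrna_frac, rfp_frac).
    Reads are counted by 5'-end position inside the region; coverage is
    the fraction of region bases touched by any aligned span.
    """
    if region[1] <= region[0]:
        raise ValueError("empty candidate region")
    mr, mf = _region_evidence(region, seqname, strand, mrna_alignments)
    rr, rf_ = _region_evidence(region, seqname, strand, rfp_alignments)
    ok = (mr >= min_reads and rr >= min_reads
          and mf >= min_cov_frac and rf_ >= min_cov_frac)
    return ok, mr, rr, mf, rf_


def _call(candidates, mrna_alignments, rfp_alignments, min_reads,
          min_cov_frac):
    calls = []
    for c in candidates:
        ok, mr, rr, mf, rf_ = confirm_expression(
            c.region, c.seqname, c.strand, mrna_alignments, rfp_alignments,
            min_reads, min_cov_frac)
        calls.append(VariantCall(c, mr, rr, mf, rf_, ok))
    return calls


def call_extensions(models, genome, mrna_alignments, rfp_alignments,
                    span: int = SEARCH_SPAN_NT, min_reads: int = 10,
                    min_cov_frac: float = 0.8) -> list[VariantCall]:
    cands = filter(None, (find_extension_candidate(m, genome, span)
                          for m in models))
    return _call(cands, mrna_alignments, rfp_alignments, min_reads,
                 min_cov_frac)


def call_readthroughs(models, genome, mrna_alignments, rfp_alignments,
                      span: int = SEARCH_SPAN_NT, min_reads: int = 10,
                      min_cov_frac: float = 0.8) -> list[VariantCall]:
    cands = filter(None, (find_readthrough_candidate(m, genome, span)
                          for m in models))
    return _call(cands, mrna_alignments, rfp_alignments, min_reads,
                 min_cov_frac)


def write_calls_tsv(path, calls) -> None:
    """TSV with coordinates in both 0-based half-open and 1-based closed
    (GFF) conventions."""
    with open(path, "w") as fh:
        fh.write("gene_id\tkind\tn_codons\tseqname\tstrand"
                 "\tregion_start0\tregion_end0\tregion_start1\tregion_end1"
                 "\tmrna_reads\trfp_reads\tmrna_cov_frac\trfp_cov_frac"
                 "\taccepted\n")
        for v in calls:
            c = v.candidate
            kind = "extension-5p" if isinstance(c, ExtensionCandidate) \
                else "readthrough-3p"
            a, b = c.region
            fh.write(f"{c.gene_id}\t{kind}\t{c.n_codons}\t{c.seqname}"
                     f"\t{c.strand}\t{a}\t{b}\t{a + 1}\t{b}"
                     f"\t{v.mrna_reads}\t{v.rfp_reads}"
                     f"\t{v.mrna_cov_frac:.4f}\t{v.rfp_cov_frac:.4f}"
                     f"\t{v.accepted}\n")
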
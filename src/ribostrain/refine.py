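"""Evidence-based gene-model refinement.

De-novo predicted gene models (from any external predictor, ingested as
GFF) are compared with an existing annotation and accepted or rejected
from mRNA + footprint (RFP) coverage:

* new gene: >= 50 mRNA and >= 50 RFP reads on the predicted CDS and a
  CDS of at least 150 nt;
* extension of an existing gene: >= 20 reads of each assay on the added
  region, and the extended model must carry its own start and stop
  codons;
* trimming of an existing gene: retained only when the removed region
  carries zero reads of either assay.

Reads are counted by the position of their 5'-most nucleotide, matching
the feature-assignment rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import STOP_CODONS
from .io import GeneModel, GenomeSequence

KINDS = ("new", "extended", "trimmed", "unchanged", "ambiguous")


@dataclass(frozen=True)
class RefinementDecision:
    gene_id: str
    kind: str
    accepted: bool
    mrna_reads: int
    rfp_reads: int
    start_codon: bool
    stop_codon: bool
    region: tuple[tuple[int, int], ...]  # intervals the evidence was read on
    reason: str = ""


def five_prime_track(alignments, genome: list[GenomeSequence]
                     ) -> dict[str, np.ndarray]:
    """Per-sequence counts of alignment 5'-end positions."""
    track = {g.name: np.zeros(len(g.sequence), dtype=np.int64) for g in genome}
    for a in alignments:
        track[a.seqname][a.pos5] += 1
    return track


def _subtract(minuend, subtrahend):
    """Interval-set difference (0-based half-open, both sorted)."""
    out = []
    for a, b in minuend:
        cur = [(a, b)]
        for c, d in subtrahend:
            nxt = []
            for x, y in cur:
                if d <= x or c >= y:
                    nxt.append((x, y))
                    continue
                if x < c:
                    nxt.append((x, c))
                if d < y:
                    nxt.append((d, y))
            cur = nxt
        out.extend(cur)
    return tuple(sorted(out))


def classify_prediction(prediction: GeneModel, existing: list[GeneModel]
                        ) -> tuple[str, GeneModel | None]:
    """Classify a predicted model against the annotation.

    Returns (kind, matched existing model).  Predictions overlapping two
    or more annotated genes, or one gene ambiguously (opposite strand,
    or equal length with different coordinates), are 'ambiguous' and not
    refined further.
    """
    overl = [m for m in existing
             if m.seqname == prediction.seqname
             and m.start < prediction.end and prediction.start < m.end]
    if not overl:
        return "new", None
    if len(overl) > 1:
        return "ambiguous", None
    m = overl[0]
    if m.strand != prediction.strand:
        return "ambiguous", m
    if prediction.intervals == m.intervals:
        return "unchanged", m
    if prediction.cds_length > m.cds_length:
        return "extended", m
    if prediction.cds_length < m.cds_length:
        return "trimmed", m
    return "ambiguous", m


def _region_counts(track: dict[str, np.ndarray], seqname: str, intervals,
                   genome_len: int) -> int:
    total = 0
    for a, b in intervals:
        if a < 0 or b > genome_len:
            raise ValueError(f"region ({a},{b}) outside genome bounds")
        total += int(track[seqname][a:b].sum())
    return total


def _complete_orf(model: GeneModel, seq: str) -> tuple[bool, bool]:
    cds = model.cds_sequence(seq)
    return cds[:3] == "ATG", cds[-3:] in STOP_CODONS


def confirm_refinement(kind: str, prediction: GeneModel,
                       existing: GeneModel | None,
                       mrna_track: dict[str, np.ndarray],
                       rfp_track: dict[str, np.ndarray],
                       genome: list[GenomeSequence],
                       min_new_reads: int = 50, min_new_len: int = 150,
                       min_ext_reads: int = 20) -> RefinementDecision:
    """Apply the kind-specific evidence rule to one classified prediction."""
    seqs = {g.name: g.sequence for g in genome}
    seq = seqs[prediction.seqname]
    glen = len(seq)
    has_start, has_stop = _complete_orf(prediction, seq)

    if kind == "new":
        region = prediction.intervals
        mr = _region_counts(mrna_track, prediction.seqname, region, glen)
        rr = _region_counts(rfp_track, prediction.seqname, region, glen)
        ok = (mr >= min_new_reads and rr >= min_new_reads
              and prediction.cds_length >= min_new_len
              and has_start and has_stop)
        reason = "" if ok else "insufficient coverage, length or ORF structure"
    elif kind == "extended":
        region = _subtract(prediction.intervals, existing.intervals)
        mr = _region_counts(mrna_track, prediction.seqname, region, glen)
        rr = _region_counts(rfp_track, prediction.seqname, region, glen)
        ok = (mr >= min_ext_reads and rr >= min_ext_reads
              and has_start and has_stop)
        reason = "" if ok else "insufficient added-region coverage or missing codons"
    elif kind == "trimmed":
        region = _subtract(existing.intervals, prediction.intervals)
        mr = _region_counts(mrna_track, prediction.seqname, region, glen)
        rr = _region_counts(rfp_track, prediction.seqname, region, glen)
        ok = mr == 0 and rr == 0 and has_start and has_stop
        reason = "" if ok else "reads observed on the removed region"
    elif kind in ("unchanged", "ambiguous"):
        region = ()
        mr = rr = 0
        ok = False
        reason = "identical to existing annotation" if kind == "unchanged" \
            else "overlaps multiple or conflicting annotations"
    else:
        raise ValueError(f"unknown refinement kind {kind!r}")
    return RefinementDecision(prediction.gene_id, kind, ok, mr, rr,
                              has_start, has_stop, tuple(region), reason)


def refine_annotation(existing: list[GeneModel], predicted: list[GeneModel],
                      mrna_track, rfp_track, genome: list[GenomeSequence],
                      **thresholds):
    """Run classification + confirmation over all predictions.

    Returns (refined model list, decisions).  Accepted new models are
    added; accepted extensions/trims replace their matched gene;
    everything else leaves the existing annotation untouched.
    """
    decisions = []
    replaced: dict[str, GeneModel] = {}
    added = []
    for pred in predicted:
        kind, match = classify_prediction(pred, existing)
        d = confirm_refinement(kind, pred, match, mrna_track, rfp_track,
                               genome, **thresholds)
        decisions.append(d)
        if d.accepted:
            if kind == "new":
                added.append(pred)
            else:
                replaced[match.gene_id] = GeneModel(
                    match.gene_id, pred.seqname, pred.strand,
                    pred.intervals, source="refined")
    refined = [replaced.get(m.gene_id, m) for m in existing] + added
    return refined, decisions


def write_decisions_tsv(path, decisions) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tkind\taccepted\tmrna_reads\trfp_reads"
                 "\tstart_codon\tstop_codon\tregion\treason\n")
        for d in decisions:
            region = ";".join(f"{a}-{b}" for a, b in d.region)
            fh.write(f"{d.gene_id}\t{d.kind}\t{d.accepted}\t{d.mrna_reads}"
                     f"\t{d.rfp_reads}\t{d.start_codon}\t{d.stop_codon}"
                     f"\t{region}\t{d.reason}\n")
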
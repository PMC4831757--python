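"""Synthetic two-strain data with known ground truth.

Emulates the two-strain ribosome-profiling design: a pair of ortholog
genomes diverged by point substitutions, per-base 5'-end read counts for
mRNA and footprint (RFP) libraries with negative-binomial overdispersion
and injected between-strain fold changes, footprint placement with
codon-specific dwell multipliers, and genes carrying upstream in-frame
start-codon extensions or downstream shifted stop codons.

All randomness flows from one root seed through named substreams
(genome, coverage, footprints), so each layer can be regenerated
independently and every output is bit-identical for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import io as rio
from .codons import (
    ATG_INDEX,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    STOP_INDICES,
    array_to_seq,
    codon_indices,
    revcomp_array,
    seq_to_array,
)

ASSAYS = ("mrna", "rfp")
STRAINS = ("B", "Y")

_UPSTREAM_NT = 180   # planted-variant search context, 60 codons
_DOWNSTREAM_NT = 180
_PAD_NT = 60         # intergenic spacer between gene blocks

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _substream(root_seed: int, *key) -> np.random.Generator:
    """Named, order-independent child stream of the root seed."""
    ints = [int(root_seed)]
    for k in key:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class SimConfig:
    """Simulation knobs; defaults are the package's study conditions.

    ``mean_depth`` is the expected read count per gene and library;
    ``dispersion`` is the negative-binomial size parameter
    (variance = mu + mu^2/dispersion); ``positional_sigma`` is the
    log-normal sd of sequence-driven per-base rate multipliers shared
    between strains and replicates; ``fold_change_spec`` entries are
    (gene index, assay, log2 fold change of strain Y over strain B),
    applied symmetrically (B x 2^-l/2, Y x 2^+l/2).
    """

    n_genes: int = 50
    gene_length_range: tuple[int, int] = (300, 600)
    gc_content: tuple[float, float] = (0.38, 0.38)
    mean_depth: float = 500.0
    dispersion: float = 2.0
    positional_sigma: float = 0.3
    substitution_rate: float = 0.02
    fold_change_spec: list[tuple[int, str, float]] = field(default_factory=list)
    dwell_spec: dict[str, tuple[int, float]] = field(default_factory=dict)
    orf_variant_spec: list[tuple[int, str, int]] = field(default_factory=list)
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo < 51:
            raise ValueError("gene lengths must be multiples of 3 and >= 51 nt")
        if hi < lo:
            raise ValueError("empty gene_length_range")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for gc in self.gc_content:
            if not 0.0 <= gc <= 1.0:
                raise ValueError("gc_content must lie in [0, 1]")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("at least two replicates are required")
        for g, assay, _ in self.fold_change_spec:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"fold_change_spec references gene {g}")
            if assay not in ASSAYS:
                raise ValueError(f"unknown assay {assay!r}")
        validate_dwell_spec(self.dwell_spec)
        max_ext = _UPSTREAM_NT // 3 - 1  # room for a blocking stop codon
        for g, kind, k in self.orf_variant_spec:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"orf_variant_spec references gene {g}")
            if kind not in ("extension-5p", "readthrough-3p"):
                raise ValueError(f"unknown variant kind {kind!r}")
            if not 1 <= k <= max_ext:
                raise ValueError(
                    f"variant of {k} codons does not fit the {_UPSTREAM_NT} nt "
                    f"context (1..{max_ext} codons)")


def validate_dwell_spec(dwell_spec) -> None:
    for codon, (pos, mult) in dwell_spec.items():
        if codon not in SENSE_CODONS:
            raise ValueError(f"{codon!r} is not a sense codon")
        if not 1 <= pos <= 9:
            raise ValueError("dwell window position must be 1..9")
        if mult <= 0:
            raise ValueError("dwell multipliers must be > 0")


@dataclass(frozen=True)
class PlantedVariant:
    gene_index: int
    kind: str                 # extension-5p | readthrough-3p
    n_codons: int
    seqname: str
    strand: str
    region: tuple[int, int]   # genomic 0-based half-open, both strains


@dataclass
class SimTruth:
    """Ground truth of every planted effect."""

    fold_changes: dict[tuple[int, str], float]
    dwell: dict[str, tuple[int, float]]
    variants: list[PlantedVariant]


@dataclass
class StrainPair:
    """Simulated two-strain dataset: genomes, gene models, ortholog table."""

    genome_b: list[rio.GenomeSequence]
    genome_y: list[rio.GenomeSequence]
    models_b: list[rio.GeneModel]
    models_y: list[rio.GeneModel]
    orthologs: list[tuple[str, str]]
    truth: SimTruth
    config: SimConfig

    def genome(self, strain):
        return self.genome_b if strain == "B" else self.genome_y

    def models(self, strain):
        return self.models_b if strain == "B" else self.models_y

    def cds_sequences(self, strain) -> dict[str, str]:
        seqs = {g.name: g.sequence for g in self.genome(strain)}
        return {m.gene_id: m.cds_sequence(seqs[m.seqname])
                for m in self.models(strain)}

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rio.write_fasta(out / "genome_B.fasta", self.genome_b)
        rio.write_fasta(out / "genome_Y.fasta", self.genome_y)
        rio.write_gff(out / "annotation_B.gff3", self.models_b)
        rio.write_gff(out / "annotation_Y.gff3", self.models_y)
        rio.write_ortholog_table(out / "orthologs.tsv", self.orthologs)
        with open(out / "truth_variants.tsv", "w") as fh:
            fh.write("gene_index\tkind\tn_codons\tseqname\tstrand\tstart\tend\n")
            for v in self.truth.variants:
                fh.write(f"{v.gene_index}\t{v.kind}\t{v.n_codons}\t{v.seqname}"
                         f"\t{v.strand}\t{v.region[0]}\t{v.region[1]}\n")
        with open(out / "truth_fold_changes.tsv", "w") as fh:
            fh.write("gene_index\tassay\tlog2fc\n")
            for (g, assay), l in self.truth.fold_changes.items():
                fh.write(f"{g}\t{assay}\t{l}\n")


# ---------------------------------------------------------------------------
# genome construction

def _random_bases(rng, n, gc) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_ACGT, size=n, p=p)


def _random_sense_codons(rng, n, gc, forbid_atg=False) -> np.ndarray:
    """n random codons, stop-free (optionally ATG-free), as a (n,3) array."""
    out = _random_bases(rng, 3 * n, gc).reshape(n, 3)
    while True:
        idx = codon_indices(array_to_seq(out.ravel()))
        bad = np.isin(idx, list(STOP_INDICES))
        if forbid_atg:
            bad |= idx == ATG_INDEX
        if not bad.any():
            return out
        k = int(bad.sum())
        out[bad] = _random_bases(rng, 3 * k, gc).reshape(k, 3)


def _stop_codon(rng) -> np.ndarray:
    return seq_to_array(STOP_CODONS[rng.integers(3)])


def simulate_strain_pair(config: SimConfig) -> StrainPair:
    """Build the two ortholog genomes, annotations and truth tables.

    Strain B is drawn fresh; strain Y is a point-substituted copy (no
    indels, so ortholog coordinates coincide).  Planted ORF-variant
    context codons, start and stop codons are protected from mutation,
    and substitutions never create an in-frame stop inside a CDS.
    """
    rng = _substream(config.seed, "genome")
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = 3 * rng.integers(lo // 3, hi // 3 + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    variant_by_gene: dict[int, tuple[str, int]] = {}
    for g, kind, k in config.orf_variant_spec:
        if g in variant_by_gene:
            raise ValueError(f"gene {g} given more than one ORF variant")
        variant_by_gene[g] = (kind, k)

    chrom_b, chrom_y = [], []
    models_b, models_y, orthologs, variants = [], [], [], []
    offset = 0
    gc_b, gc_y = config.gc_content
    seqname = "chrI"

    for g in range(n):
        L = int(lengths[g])
        n_codons = L // 3
        # transcript-oriented block: pad | upstream | CDS | downstream
        pad = _random_bases(rng, _PAD_NT, gc_b)
        up = _random_bases(rng, _UPSTREAM_NT, gc_b)
        down = _random_bases(rng, _DOWNSTREAM_NT, gc_b)
        body = _random_sense_codons(rng, n_codons - 2, gc_b)
        cds = np.concatenate([seq_to_array("ATG"), body.ravel(), _stop_codon(rng)])

        protect = np.zeros(_PAD_NT + _UPSTREAM_NT + L + _DOWNSTREAM_NT, dtype=bool)
        cds_off = _PAD_NT + _UPSTREAM_NT
        protect[cds_off:cds_off + 3] = True          # start codon
        protect[cds_off + L - 3:cds_off + L] = True  # stop codon

        kind_k = variant_by_gene.get(g)
        region_t = None  # transcript-oriented (start, end) within the block
        if kind_k is not None:
            kind, k = kind_k
            if kind == "extension-5p":
                # upstream codons -k..-1 form the extension; -(k+1) blocks it
                ext = _random_sense_codons(rng, k - 1, gc_b, forbid_atg=True)
                planted = np.concatenate(
                    [_stop_codon(rng), seq_to_array("ATG"), ext.ravel()])
                a = _UPSTREAM_NT - 3 * (k + 1)
                up[a:] = planted
                protect[_PAD_NT + a:_PAD_NT + _UPSTREAM_NT] = True
                region_t = (cds_off - 3 * k, cds_off)
            else:  # readthrough-3p
                ext = _random_sense_codons(rng, k, gc_b)
                planted = np.concatenate([ext.ravel(), _stop_codon(rng)])
                down[:3 * (k + 1)] = planted
                protect[cds_off + L:cds_off + L + 3 * (k + 1)] = True
                region_t = (cds_off + L, cds_off + L + 3 * (k + 1))

        block_b = np.concatenate([pad, up, cds, down])
        block_y = _mutate_block(block_b, protect, config.substitution_rate,
                                gc_y, rng)
        _revert_cds_stops(block_y, block_b, cds_off, L)

        strand = str(strands[g])
        if strand == "+":
            g_start = offset + cds_off
            out_b, out_y = block_b, block_y
            region = None if region_t is None else (
                offset + region_t[0], offset + region_t[1])
        else:
            blen = len(block_b)
            out_b, out_y = revcomp_array(block_b), revcomp_array(block_y)
            g_start = offset + blen - (cds_off + L)
            region = None if region_t is None else (
                offset + blen - region_t[1], offset + blen - region_t[0])
        chrom_b.append(out_b)
        chrom_y.append(out_y)

        gid_b, gid_y = f"gB{g:04d}", f"gY{g:04d}"
        models_b.append(rio.GeneModel(gid_b, seqname, strand,
                                      ((g_start, g_start + L),)))
        models_y.append(rio.GeneModel(gid_y, seqname, strand,
                                      ((g_start, g_start + L),)))
        orthologs.append((gid_b, gid_y))
        if kind_k is not None:
            variants.append(PlantedVariant(g, kind_k[0], kind_k[1],
                                           seqname, strand, region))
        offset += len(block_b)

    tail_b = _random_bases(rng, _PAD_NT, gc_b)
    tail_y = _mutate_block(tail_b, np.zeros(_PAD_NT, bool),
                           config.substitution_rate, gc_y, rng)
    chrom_b.append(tail_b)
    chrom_y.append(tail_y)

    genome_b = [rio.GenomeSequence(seqname, array_to_seq(np.concatenate(chrom_b)))]
    genome_y = [rio.GenomeSequence(seqname, array_to_seq(np.concatenate(chrom_y)))]
    truth = SimTruth(
        fold_changes={(g, a): l for g, a, l in config.fold_change_spec},
        dwell=dict(config.dwell_spec),
        variants=variants,
    )
    return StrainPair(genome_b, genome_y, models_b, models_y,
                      orthologs, truth, config)


def _mutate_block(block: np.ndarray, protect: np.ndarray, rate: float,
                  gc_target: float, rng) -> np.ndarray:
    """Point-substitute unprotected positions at the given rate; the
    replacement base is drawn from the target GC composition restricted
    to the three non-identical bases."""
    out = block.copy()
    hit = (rng.random(len(block)) < rate) & ~protect
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return out
    w = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
                  (1 - gc_target) / 2])
    cur = np.searchsorted(_ACGT, out[idx])  # ACGT are ascending byte values
    wmat = np.tile(w, (len(idx), 1))
    wmat[np.arange(len(idx)), cur] = 0.0
    wmat /= wmat.sum(axis=1, keepdims=True)
    u = rng.random(len(idx))
    pick = (wmat.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out[idx] = _ACGT[pick]
    return out


def _revert_cds_stops(block_y, block_b, cds_off, L) -> None:
    """Undo any substitution that created an in-frame stop inside the CDS."""
    cds = block_y[cds_off:cds_off + L]
    idx = codon_indices(array_to_seq(cds))
    bad = np.nonzero(np.isin(idx[1:-1], list(STOP_INDICES)))[0] + 1
    for c in bad:
        cds[3 * c:3 * c + 3] = block_b[cds_off + 3 * c:cds_off + 3 * c + 3]


# ---------------------------------------------------------------------------
# base-level coverage

def simulate_base_coverage(length: int, mean_depth: float, dispersion: float,
                           seed, positional_multipliers=None) -> np.ndarray:
    """Per-base 5'-end counts for one gene and library.

    Counts are negative binomial with per-base mean
    ``mean_depth / length`` (times optional positional multipliers) and
    variance mu + mu^2/dispersion; ``dispersion=inf`` gives Poisson.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mu = np.full(length, mean_depth / length)
    if positional_multipliers is not None:
        mult = np.asarray(positional_multipliers, dtype=float)
        if mult.shape != (length,):
            raise ValueError("positional multiplier length mismatch")
        mu = mu * mult
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


@dataclass
class CoverageSet:
    """Per-library base coverage: coverage[(strain, assay, replicate)] maps
    gene id -> per-base 5'-end count vector in transcript orientation."""

    coverage: dict[tuple[str, str, int], dict[str, np.ndarray]]
    library_size: dict[tuple[str, str, int], int]


def simulate_coverage(pair: StrainPair, assays=ASSAYS) -> CoverageSet:
    """Simulate all libraries for a strain pair under its config.

    Positional rate multipliers (log-normal, sd ``positional_sigma``,
    unit mean) model sequence-driven coverage bias and are shared
    between strains and replicates; planted fold changes split
    symmetrically between the strains.
    """
    cfg = pair.config
    rng = _substream(cfg.seed, "coverage")
    lengths = {m.gene_id: m.cds_length for m in pair.models_b}
    coverage = {}
    sizes = {}
    sigma = cfg.positional_sigma
    mult = {}
    for g, (gid_b, _) in enumerate(pair.orthologs):
        L = lengths[gid_b]
        for assay in assays:
            m = (rng.lognormal(-sigma * sigma / 2, sigma, size=L)
                 if sigma > 0 else np.ones(L))
            mult[(g, assay)] = m
    for strain in STRAINS:
        sgn = -0.5 if strain == "B" else 0.5
        for assay in assays:
            for rep in range(1, cfg.n_replicates + 1):
                lib = {}
                total = 0
                for g, pair_ids in enumerate(pair.orthologs):
                    gid = pair_ids[0] if strain == "B" else pair_ids[1]
                    L = lengths[pair_ids[0]]
                    lfc = pair.truth.fold_changes.get((g, assay), 0.0)
                    depth = cfg.mean_depth * 2.0 ** (sgn * lfc)
                    vec = simulate_base_coverage(
                        L, depth, cfg.dispersion, rng,
                        positional_multipliers=mult[(g, assay)])
                    lib[gid] = vec
                    total += int(vec.sum())
                key = (strain, assay, rep)
                coverage[key] = lib
                sizes[key] = total
    return CoverageSet(coverage, sizes)


# ---------------------------------------------------------------------------
# footprints

@dataclass
class FootprintSet:
    """Pre-aligned ribosome footprints in codon coordinates: footprint i
    starts at the first base of codon ``codon_start[i]`` of gene
    ``gene_ids[gene_index[i]]`` and spans ``read_length`` nt."""

    gene_ids: list[str]
    gene_index: np.ndarray
    codon_start: np.ndarray
    read_length: int

    def __len__(self):
        return len(self.gene_index)

    def __iter__(self):
        for gi, cs in zip(self.gene_index, self.codon_start):
            yield self.gene_ids[gi], int(cs)

    def start_counts(self, n_codons: dict[str, int]) -> dict[str, np.ndarray]:
        """Footprint 5'-end counts per codon start site, per gene."""
        out = {}
        for gi, gid in enumerate(self.gene_ids):
            sel = self.codon_start[self.gene_index == gi]
            out[gid] = np.bincount(sel, minlength=n_codons[gid])
        return out


def simulate_footprints(cds_sequences: dict[str, str], dwell_spec,
                        n_reads: int, read_length: int = 27,
                        seed=0) -> FootprintSet:
    """Place footprints on CDSs with codon-specific dwell multipliers.

    A footprint of ``read_length`` nt covers read_length/3 codons; the
    probability of starting at codon s is proportional to the product of
    multipliers of the codons it covers at their specified window
    positions (position p = the codon at s + p - 1).  An empty
    dwell_spec gives uniform placement.
    """
    if read_length < 27 or read_length % 3:
        raise ValueError("read_length must be a multiple of 3 and >= 27")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    validate_dwell_spec(dwell_spec)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    span = read_length // 3
    logw = np.zeros((span, 64))
    for codon, (pos, mlt) in dwell_spec.items():
        if pos <= span:
            logw[pos - 1, CODON_INDEX[codon]] = np.log(mlt)

    gene_ids = sorted(cds_sequences)
    all_w, gene_of_site, site_codon = [], [], []
    for gi, gid in enumerate(gene_ids):
        seq = cds_sequences[gid]
        if len(seq) < read_length:
            raise ValueError(f"{gid}: CDS shorter than the read length")
        cods = codon_indices(seq)
        n_sites = len(cods) - span + 1
        lw = np.zeros(n_sites)
        for p in range(span):
            lw += logw[p, cods[p:p + n_sites]]
        all_w.append(np.exp(lw))
        gene_of_site.append(np.full(n_sites, gi))
        site_codon.append(np.arange(n_sites))
    w = np.concatenate(all_w)
    gene_of_site = np.concatenate(gene_of_site)
    site_codon = np.concatenate(site_codon)

    if n_reads == 0:
        picks = np.empty(0, dtype=np.int64)
    else:
        picks = rng.choice(len(w), size=n_reads, p=w / w.sum())
    return FootprintSet(gene_ids, gene_of_site[picks], site_codon[picks],
                        read_length)


def footprint_reads(cds_sequences: dict[str, str], footprints: FootprintSet,
                    seed=0, max_spurious_a: int = 3) -> list[tuple[str, str]]:
    """Raw read sequences for a FootprintSet, each carrying 0..max
    spurious 3' adenines (the library artefact the iterative trimmer
    removes).  Returns (read id, sequence) pairs."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    reads = []
    for i, (gid, cs) in enumerate(footprints):
        s = cds_sequences[gid][3 * cs:3 * cs + footprints.read_length]
        n_a = int(rng.integers(0, max_spurious_a + 1))
        reads.append((f"fp{i:06d}", s + "A" * n_a))
    return reads
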
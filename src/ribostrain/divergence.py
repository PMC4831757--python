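"""Resampling tests for between-strain expression and translation divergence.

For each ortholog pair the null distribution of the log2 expression
ratio is built by composition-matched bootstrap: base-level 5'-end
counts of ONE source gene are resampled with replacement, drawing, for
each target gene, a number of positions equal to the target's mappable
length L partitioned across the four bases in proportion to the
target's marginal nucleotide frequencies pi.  This keeps sequencing
bias tied to base composition and gene length inside the null.  The
observed log2(Y/B) per replicate is compared with the nulls from both
source strains and both replicates (four two-sided empirical P values);
the maximum is retained and Benjamini-Hochberg adjusted across genes.

Translation-efficiency (TE) divergence compares the observed mRNA ratio
with a null built from each strain's own footprint (RFP) counts and
vice versa (reciprocal tests); the maximum P is kept only when the TE
direction agrees across replicates.

The public surface is statsmodels-like: ``DivergenceModel(...).fit()``
and ``TranslationEfficiencyModel(...).fit()`` return Results objects
with a per-gene frame and ``summary()``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .codons import seq_to_array
from .io import OrthologPair

_BASE_ORDER = b"ATGC"
REGULATORY_CATEGORIES = ("mRNA-only", "TE-only", "both", "neither")


# ---------------------------------------------------------------------------
# containers

@dataclass
class OrthologCounts:
    """Per-ortholog base coverage across libraries.

    ``coverage[(strain, assay, replicate)]`` is the per-base 5'-end
    count vector of that strain's gene (length = that strain's mappable
    length); ``library_size`` holds total CDS-assigned reads of each
    library.  ``sequence_b``/``sequence_y`` are the CDS sequences used
    to stratify resampling by base identity.
    """

    pair: OrthologPair
    sequence_b: str
    sequence_y: str
    coverage: dict[tuple[str, str, int], np.ndarray]
    library_size: dict[tuple[str, str, int], float]

    def replicates(self, assay) -> list[int]:
        return sorted({k[2] for k in self.coverage if k[1] == assay})

    def swapped(self) -> "OrthologCounts":
        """Strain labels exchanged (for symmetry checks)."""
        swap = {"B": "Y", "Y": "B"}
        return OrthologCounts(
            self.pair.swapped(), self.sequence_y, self.sequence_b,
            {(swap[s], a, r): v for (s, a, r), v in self.coverage.items()},
            {(swap[s], a, r): v for (s, a, r), v in self.library_size.items()},
        )


def counts_from_simulation(pair, coverage_set, assays=("mrna", "rfp")):
    """Bundle a simulated StrainPair + CoverageSet into OrthologCounts."""
    seqs_b = pair.cds_sequences("B")
    seqs_y = pair.cds_sequences("Y")
    from .io import nucleotide_freq
    out = []
    for gid_b, gid_y in pair.orthologs:
        sb, sy = seqs_b[gid_b], seqs_y[gid_y]
        op = OrthologPair(gid_b, gid_y, len(sb), len(sy),
                          nucleotide_freq(sb), nucleotide_freq(sy))
        cov, libs = {}, {}
        for (strain, assay, rep), lib in coverage_set.coverage.items():
            if assay not in assays:
                continue
            gid = gid_b if strain == "B" else gid_y
            cov[(strain, assay, rep)] = lib[gid]
            libs[(strain, assay, rep)] = coverage_set.library_size[(strain, assay, rep)]
        out.append(OrthologCounts(op, sb, sy, cov, libs))
    return out


# ---------------------------------------------------------------------------
# resampling primitives

def _largest_remainder(total: int, probs: np.ndarray) -> np.ndarray:
    """Partition ``total`` into integer quotas proportional to ``probs``
    (which sum to 1), assigning leftovers by largest fractional part;
    ties break on index order."""
    raw = total * probs
    quotas = np.floor(raw).astype(np.int64)
    short = total - quotas.sum()
    if short:
        order = np.lexsort((np.arange(len(probs)), -(raw - quotas)))
        quotas[order[:short]] += 1
    return quotas


def _positions_by_base(sequence: str) -> dict[int, np.ndarray]:
    arr = seq_to_array(sequence)
    return {i: np.nonzero(arr == b)[0] for i, b in enumerate(_BASE_ORDER)}


def stratified_resample_total(coverage, sequence, L_target, pi_target,
                              seed, size: int = 1):
    """Composition-matched bootstrap totals.

    Draws, with replacement, n_b positions carrying base b from the
    source gene, where {n_b} partitions ``L_target`` proportionally to
    ``pi_target`` (largest-remainder rounding); base classes absent from
    the source have their quota reallocated proportionally among present
    classes.  Returns the sum of counts at drawn positions — an array of
    ``size`` totals (scalar when size=1).
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.size == 0:
        raise ValueError("empty coverage")
    if len(sequence) != cov.size:
        raise ValueError("coverage/sequence length mismatch")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    by_base = _positions_by_base(sequence)
    pi = np.asarray(pi_target, dtype=float)
    present = np.array([len(by_base[i]) > 0 for i in range(4)])
    if not present.any():
        raise ValueError("source sequence has no A/C/G/T positions")
    eff = np.where(present, pi, 0.0)
    if eff.sum() == 0:  # target mass entirely on absent classes
        eff = present.astype(float)
    eff = eff / eff.sum()
    quotas = _largest_remainder(int(L_target), eff)
    totals = np.zeros(size)
    for b in range(4):
        nb = int(quotas[b])
        if nb == 0:
            continue
        pos = by_base[b]
        idx = rng.integers(0, len(pos), size=(size, nb))
        totals += cov[pos[idx]].sum(axis=1)
    return totals if size > 1 else float(totals[0])


def _gene_stream(root_seed, *parts) -> np.random.Generator:
    ints = [int(root_seed)] + [
        zlib.crc32(str(p).encode()) if isinstance(p, str) else int(p)
        for p in parts]
    return np.random.default_rng(np.random.SeedSequence(ints))


def empirical_p_two_sided(null: np.ndarray, observed: float) -> float:
    """min(1, 2*min(#{null<=obs}+1, #{null>=obs}+1)/(N+1)); never 0."""
    n = len(null)
    lo = int((null <= observed).sum()) + 1
    hi = int((null >= observed).sum()) + 1
    return min(1.0, 2.0 * min(lo, hi) / (n + 1))


def _log2_ratio(num_total, num_scale, den_total, den_scale):
    return np.log2((np.asarray(num_total) * num_scale + 0.5)
                   / (np.asarray(den_total) * den_scale + 0.5))


def null_log2_distribution(counts: OrthologCounts, assay: str, replicate: int,
                           source_strain: str, n_resamples: int,
                           seed: int, normalize: bool = True) -> np.ndarray:
    """Null log2(Y/B) ratios for one (source strain, replicate) component.

    Both pseudo totals are resampled from the SAME source gene's
    coverage — pseudo_B with (L_B, pi_B), pseudo_Y with (L_Y, pi_Y) —
    after scaling the source library to the assay's mean library size,
    then combined as log2((pseudo_Y + 0.5)/(pseudo_B + 0.5)).
    """
    p = counts.pair
    key = (source_strain, assay, replicate)
    cov = counts.coverage[key].astype(float)
    if normalize:
        cov = cov * _lib_factor(counts, assay)[key]
    seq = counts.sequence_b if source_strain == "B" else counts.sequence_y
    src_gene = p.gene_b if source_strain == "B" else p.gene_y
    pseudo_b = stratified_resample_total(
        cov, seq, p.length_b, p.pi_b,
        _gene_stream(seed, assay, replicate, src_gene, p.gene_b),
        size=n_resamples)
    pseudo_y = stratified_resample_total(
        cov, seq, p.length_y, p.pi_y,
        _gene_stream(seed, assay, replicate, src_gene, p.gene_y),
        size=n_resamples)
    return _log2_ratio(pseudo_y, 1.0, pseudo_b, 1.0)


def _lib_factor(counts: OrthologCounts, assay: str) -> dict:
    """Per-library scale factors: mean library size / library size."""
    keys = [k for k in counts.library_size if k[1] == assay]
    mean = np.mean([counts.library_size[k] for k in keys])
    return {k: mean / counts.library_size[k] for k in keys}


def observed_log2_ratio(counts: OrthologCounts, assay: str, replicate: int,
                        normalize: bool = True) -> float:
    """Observed library-size-normalized log2(Y/B) in one replicate."""
    f = _lib_factor(counts, assay) if normalize else \
        {k: 1.0 for k in counts.library_size}
    tb = counts.coverage[("B", assay, replicate)].sum()
    ty = counts.coverage[("Y", assay, replicate)].sum()
    return float(_log2_ratio(ty, f[("Y", assay, replicate)],
                             tb, f[("B", assay, replicate)]))


# ---------------------------------------------------------------------------
# the divergence test

@dataclass
class DivergenceRow:
    gene_b: str
    gene_y: str
    assay: str
    log2_ratio: float            # mean over replicates of observed log2(Y/B)
    log2_ratio_reps: tuple
    p_components: tuple          # (source strain, replicate) grid
    p_max: float
    tested: bool
    skip_reason: str = ""


def divergence_test(counts: OrthologCounts, assay: str,
                    n_resamples: int = 10000, seed: int = 0,
                    min_cds_reads: int = 50,
                    normalize: bool = True) -> DivergenceRow:
    """Resampling divergence test for one ortholog pair and assay.

    Each (source strain x replicate) component compares the observed
    per-replicate ratio to its null; the maximum of the four two-sided
    empirical P values is retained.
    """
    reps = counts.replicates(assay)
    if len(reps) < 2:
        raise ValueError(
            f"{counts.pair.gene_b}: both replicates required in {assay}")
    totals = {s: sum(counts.coverage[(s, assay, r)].sum() for r in reps)
              for s in ("B", "Y")}
    if min(totals.values()) < min_cds_reads:
        return DivergenceRow(counts.pair.gene_b, counts.pair.gene_y, assay,
                             np.nan, (), (), np.nan, False,
                             f"fewer than {min_cds_reads} CDS reads")
    obs = {r: observed_log2_ratio(counts, assay, r, normalize) for r in reps}
    ps = []
    for src in ("B", "Y"):
        for r in reps:
            null = null_log2_distribution(counts, assay, r, src,
                                          n_resamples, seed, normalize)
            ps.append(empirical_p_two_sided(null, obs[r]))
    obs_list = tuple(obs[r] for r in reps)
    return DivergenceRow(counts.pair.gene_b, counts.pair.gene_y, assay,
                         float(np.mean(obs_list)), obs_list,
                         tuple(ps), max(ps), True)


# ---------------------------------------------------------------------------
# the TE test

@dataclass
class TERow:
    gene_b: str
    gene_y: str
    log2_rfp_by: float           # observed log2[RFP(B/Y)], replicate mean
    log2_mrna_by: float
    log2_te_ratio: float         # log2_rfp_by - log2_mrna_by
    p_components: tuple
    direction_agrees: bool
    p_max: float
    tested: bool
    skip_reason: str = ""


def _te_null(counts: OrthologCounts, assay: str, replicate: int,
             n_resamples: int, seed: int, normalize: bool) -> np.ndarray:
    """Null log2(B/Y) built from each strain's OWN coverage in ``assay``."""
    p = counts.pair
    f = _lib_factor(counts, assay) if normalize else \
        {k: 1.0 for k in counts.library_size if k[1] == assay}
    cov_b = counts.coverage[("B", assay, replicate)] * f[("B", assay, replicate)]
    cov_y = counts.coverage[("Y", assay, replicate)] * f[("Y", assay, replicate)]
    pseudo_b = stratified_resample_total(
        cov_b, counts.sequence_b, p.length_b, p.pi_b,
        _gene_stream(seed, "te", assay, replicate, p.gene_b), size=n_resamples)
    pseudo_y = stratified_resample_total(
        cov_y, counts.sequence_y, p.length_y, p.pi_y,
        _gene_stream(seed, "te", assay, replicate, p.gene_y), size=n_resamples)
    return _log2_ratio(pseudo_b, 1.0, pseudo_y, 1.0)


def te_test(counts: OrthologCounts, n_resamples: int = 10000, seed: int = 0,
            min_cds_reads: int = 50, normalize: bool = True) -> TERow:
    """Reciprocal resampling test of translation-efficiency divergence.

    The observed log2[mRNA(B/Y)] is compared with nulls resampled from
    footprint counts, and the observed log2[RFP(B/Y)] with nulls
    resampled from mRNA counts, in each replicate.  The maximum P is
    retained only if the TE direction agrees across replicates;
    otherwise the gene is called non-significant (P = 1).
    """
    gid_b, gid_y = counts.pair.gene_b, counts.pair.gene_y
    reps = counts.replicates("mrna")
    if reps != counts.replicates("rfp") or len(reps) < 2:
        raise ValueError(f"{gid_b}: both replicates required in both assays")
    for assay in ("mrna", "rfp"):
        tot = {s: sum(counts.coverage[(s, assay, r)].sum() for r in reps)
               for s in ("B", "Y")}
        if min(tot.values()) < min_cds_reads:
            return TERow(gid_b, gid_y, np.nan, np.nan, np.nan, (), False,
                         np.nan, False,
                         f"fewer than {min_cds_reads} CDS reads in {assay}")
    # observed per-replicate ratios, B over Y
    obs = {assay: {r: -observed_log2_ratio(counts, assay, r, normalize)
                   for r in reps} for assay in ("mrna", "rfp")}
    ps = []
    for r in reps:
        null_rfp = _te_null(counts, "rfp", r, n_resamples, seed, normalize)
        ps.append(empirical_p_two_sided(null_rfp, obs["mrna"][r]))
        null_mrna = _te_null(counts, "mrna", r, n_resamples, seed, normalize)
        ps.append(empirical_p_two_sided(null_mrna, obs["rfp"][r]))
    d = [obs["rfp"][r] - obs["mrna"][r] for r in reps]
    agrees = all(x > 0 for x in d) or all(x < 0 for x in d)
    p_max = max(ps) if agrees else 1.0
    rfp_by = float(np.mean([obs["rfp"][r] for r in reps]))
    mrna_by = float(np.mean([obs["mrna"][r] for r in reps]))
    return TERow(gid_b, gid_y, rfp_by, mrna_by, rfp_by - mrna_by,
                 tuple(ps), agrees, p_max, True)


# ---------------------------------------------------------------------------
# multiple testing and classification

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("P values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regulation(mrna_significant: bool, te_significant: bool) -> str:
    """Four regulatory categories from the two FDR<=5% significance flags."""
    return {(True, False): "mRNA-only", (False, True): "TE-only",
            (True, True): "both", (False, False): "neither"}[
        (bool(mrna_significant), bool(te_significant))]


# ---------------------------------------------------------------------------
# Model / Results surface

class _ResamplingModel:
    def __init__(self, counts: list[OrthologCounts], min_cds_reads: int = 50,
                 normalize: bool = True):
        self.counts = list(counts)
        self.min_cds_reads = min_cds_reads
        self.normalize = normalize


class DivergenceModel(_ResamplingModel):
    """Per-ortholog divergence in one assay across a cohort of pairs."""

    def __init__(self, counts, assay: str = "mrna", min_cds_reads: int = 50,
                 normalize: bool = True):
        super().__init__(counts, min_cds_reads, normalize)
        if assay not in ("mrna", "rfp"):
            raise ValueError("assay must be 'mrna' or 'rfp'")
        self.assay = assay

    def fit(self, n_resamples: int = 10000, seed: int = 0,
            fdr: float = 0.05) -> "DivergenceResults":
        rows = [divergence_test(c, self.assay, n_resamples, seed,
                                self.min_cds_reads, self.normalize)
                for c in self.counts]
        return DivergenceResults(self, rows, n_resamples, seed, fdr)


class TranslationEfficiencyModel(_ResamplingModel):
    """Per-ortholog translation-efficiency divergence across a cohort."""

    def fit(self, n_resamples: int = 10000, seed: int = 0,
            fdr: float = 0.05) -> "TEResults":
        rows = [te_test(c, n_resamples, seed, self.min_cds_reads,
                        self.normalize) for c in self.counts]
        return TEResults(self, rows, n_resamples, seed, fdr)


def _attach_q(frame: pd.DataFrame, fdr: float) -> pd.DataFrame:
    frame = frame.copy()
    frame["q"] = np.nan
    tested = frame["tested"].to_numpy(bool)
    if tested.any():
        frame.loc[tested, "q"] = bh_adjust(frame.loc[tested, "p_max"])
    frame["significant"] = frame["q"] <= fdr
    frame.loc[~tested, "significant"] = False
    return frame


class DivergenceResults:
    """Per-gene divergence estimates, empirical P values and BH q."""

    def __init__(self, model, rows, n_resamples, seed, fdr):
        self.model = model
        self.n_resamples = n_resamples
        self.seed = seed
        self.fdr = fdr
        frame = pd.DataFrame([{
            "gene_b": r.gene_b, "gene_y": r.gene_y, "assay": r.assay,
            "log2_ratio": r.log2_ratio,
            "log2_ratio_reps": r.log2_ratio_reps,
            "p_components": r.p_components, "p_max": r.p_max,
            "tested": r.tested, "skip_reason": r.skip_reason,
        } for r in rows])
        self.frame = _attach_q(frame, fdr)

    @property
    def significant(self) -> pd.Series:
        return self.frame["significant"]

    def summary(self) -> str:
        f = self.frame
        n_test = int(f["tested"].sum())
        n_sig = int(f["significant"].sum())
        lines = [
            f"Divergence test ({self.model.assay}), "
            f"{len(f)} ortholog pairs, {self.n_resamples} resamples",
            f"  tested: {n_test}  skipped: {len(f) - n_test}",
            f"  significant at FDR<={self.fdr:g}: {n_sig} "
            f"({100 * n_sig / max(n_test, 1):.1f}% of tested)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        f = self.frame.copy()
        f["p_components"] = f["p_components"].map(
            lambda t: ",".join(f"{p:.6g}" for p in t))
        f["log2_ratio_reps"] = f["log2_ratio_reps"].map(
            lambda t: ",".join(f"{x:.6g}" for x in t))
        f.to_csv(path, sep="\t", index=False)


class TEResults:
    """Per-gene TE divergence with the reciprocal max-P rule applied."""

    def __init__(self, model, rows, n_resamples, seed, fdr):
        self.model = model
        self.n_resamples = n_resamples
        self.seed = seed
        self.fdr = fdr
        frame = pd.DataFrame([{
            "gene_b": r.gene_b, "gene_y": r.gene_y,
            "log2_rfp_by": r.log2_rfp_by, "log2_mrna_by": r.log2_mrna_by,
            "log2_te_ratio": r.log2_te_ratio,
            "p_components": r.p_components,
            "direction_agrees": r.direction_agrees,
            "p_max": r.p_max, "tested": r.tested,
            "skip_reason": r.skip_reason,
        } for r in rows])
        self.frame = _attach_q(frame, fdr)

    @property
    def significant(self) -> pd.Series:
        return self.frame["significant"]

    def categories(self, mrna_results: DivergenceResults) -> pd.Series:
        """Regulatory category per gene, combining mRNA and TE calls."""
        m = mrna_results.frame.set_index("gene_b")["significant"]
        return pd.Series(
            [classify_regulation(bool(m.get(g, False)), bool(s))
             for g, s in zip(self.frame["gene_b"], self.frame["significant"])],
            index=self.frame.index, name="category")

    def summary(self) -> str:
        f = self.frame
        n_test = int(f["tested"].sum())
        n_sig = int(f["significant"].sum())
        return "\n".join([
            f"Translation-efficiency test, {len(f)} ortholog pairs, "
            f"{self.n_resamples} resamples",
            f"  tested: {n_test}  skipped: {len(f) - n_test}",
            f"  direction agreement: "
            f"{int(f.loc[f['tested'], 'direction_agrees'].sum())}/{n_test}",
            f"  significant at FDR<={self.fdr:g}: {n_sig}",
        ])

    def to_tsv(self, path) -> None:
        f = self.frame.copy()
        f["p_components"] = f["p_components"].map(
            lambda t: ",".join(f"{p:.6g}" for p in t))
        f.to_csv(path, sep="\t", index=False)
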
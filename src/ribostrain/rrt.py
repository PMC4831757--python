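"""Ribosome residence time (RRT) per codon and window position.

For each of the 61 sense codons, every 17-codon window of the coding
genome in which the codon occurs uniquely at the middle is collected.
A footprint of >= 27 nt whose 5' end lies on a codon boundary covers
nine codons, so the central codon of a window can sit at nine positions
(1..9) of a footprint; the A-, P- and E-sites map to positions 6, 5 and
4.  Window footprint counts over the nine positions are normalized to
relative frequencies (RF), averaged across windows, and divided by the
uniform expectation 1/9 to give RRT.  Significance comes from permuting
the nine position labels within each window; the stalling filter
requires max(RRT, 1/RRT) >= 1.2, P <= 1e-4 and >= 300 windows.

``ResidenceTimeModel(...).fit()`` returns a ``ResidenceTimeResults``
with the full 61 x 9 table; ``strain_rrt_ratio_test`` compares two
fitted strains position by position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import CODON_INDEX, SENSE_CODONS, codon_indices
from .simulate import FootprintSet

SITE_FLAGS = {6: "A", 5: "P", 4: "E"}
WINDOW_CODONS = 17
MIN_FOOTPRINT_NT = 27


def eligible_positions(window_codons: int = WINDOW_CODONS,
                       read_length: int = MIN_FOOTPRINT_NT) -> int:
    """Number of window positions at which the central codon can appear
    in a footprint, given the window size and the minimum retained read
    length (reads longer than ``read_length`` are truncated to their
    5'-most read_length/3 codons for positioning)."""
    if window_codons % 2 == 0 or window_codons < 1:
        raise ValueError("window size must be odd")
    if read_length % 3 or read_length < 3:
        raise ValueError("read length must be a positive multiple of 3")
    f = read_length // 3
    h = window_codons // 2
    lo = max(-h, 1 - f)       # footprint start relative to the center
    hi = min(0, h - f + 1)
    return max(0, hi - lo + 1)


def uniform_expected_rf(window_codons: int = WINDOW_CODONS,
                        read_length: int = MIN_FOOTPRINT_NT) -> float:
    """Expected per-position RF under no codon preference."""
    return 1.0 / eligible_positions(window_codons, read_length)


N_POSITIONS = eligible_positions()


# ---------------------------------------------------------------------------
# footprints and windows

def in_frame_footprints(alignments, models, min_len: int = MIN_FOOTPRINT_NT
                        ) -> FootprintSet:
    """Retain alignments of length >= min_len whose 5'-most nucleotide
    falls on the first base of a codon; emit codon-coordinate placements."""
    gene_ids = sorted({m.gene_id for m in models})
    gidx = {g: i for i, g in enumerate(gene_ids)}
    by_seq: dict[str, list] = {}
    for m in models:
        by_seq.setdefault(m.seqname, []).append(m)
    gi, cs = [], []
    for a in alignments:
        if a.length < min_len:
            continue
        for m in by_seq.get(a.seqname, ()):
            if m.strand != a.strand:
                continue
            t = m.to_transcript_coord(a.pos5)
            if t is None or t % 3:
                continue
            gi.append(gidx[m.gene_id])
            cs.append(t // 3)
            break
    return FootprintSet(gene_ids, np.asarray(gi, dtype=np.int64),
                        np.asarray(cs, dtype=np.int64), min_len)


def build_windows(codon_seq: np.ndarray, codon: str) -> list[int]:
    """Center indices of all 17-codon windows of one CDS in which
    ``codon`` occurs uniquely at the middle position.

    ``codon_seq`` is the CDS as codon indices (codons.codon_indices).
    """
    ci = CODON_INDEX[codon]
    n = len(codon_seq)
    half = WINDOW_CODONS // 2
    hits = codon_seq == ci
    centers = []
    for c in np.nonzero(hits)[0]:
        if c < half or c >= n - half:
            continue
        if hits[c - half:c + half + 1].sum() == 1:
            centers.append(int(c))
    return centers


@dataclass
class CodonWindows:
    """All windows of one codon: per-window footprint counts over the
    nine eligible positions (column p-1 = footprints whose 5' end starts
    at center - (p - 1))."""

    codon: str
    counts: np.ndarray  # (n_windows, 9) ints, zero-footprint rows removed

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def rf(self) -> np.ndarray:
        """Per-window relative-frequency rows (each sums to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)


def _window_counts(codon_seqs: dict[str, np.ndarray],
                   start_counts: dict[str, np.ndarray],
                   codon: str) -> CodonWindows:
    rows = []
    for gid, cods in codon_seqs.items():
        centers = build_windows(cods, codon)
        if not centers:
            continue
        starts = start_counts[gid]
        for c in centers:
            rows.append(starts[c - N_POSITIONS + 1:c + 1][::-1])
    if rows:
        m = np.asarray(rows, dtype=np.int64)
        m = m[m.sum(axis=1) > 0]
    else:
        m = np.empty((0, N_POSITIONS), dtype=np.int64)
    return CodonWindows(codon, m)


def _null_mean_rf(rf: np.ndarray, n_perm: int, rng,
                  max_chunk_elems: int = 4_000_000) -> np.ndarray:
    """Null mean-RF vectors from per-window label permutations."""
    n_w = rf.shape[0]
    out = np.empty((n_perm, rf.shape[1]))
    chunk = max(1, max_chunk_elems // (n_w * rf.shape[1]))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        arr = np.tile(rf, (k, 1, 1))
        rng.permuted(arr, axis=-1, out=arr)
        out[done:done + k] = arr.mean(axis=1)
        done += k
    return out


def empirical_p_two_sided(null: np.ndarray, observed) -> np.ndarray:
    """Columnwise two-sided empirical P with the (+1)/(N+1) estimator."""
    n = null.shape[0]
    lo = (null <= observed).sum(axis=0) + 1
    hi = (null >= observed).sum(axis=0) + 1
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi) / (n + 1))


# ---------------------------------------------------------------------------
# model / results

class ResidenceTimeModel:
    """RRT analysis of one strain's footprint data.

    Parameters
    ----------
    cds_sequences : mapping gene id -> CDS nucleotide sequence
    footprints : FootprintSet (codon-coordinate placements), e.g. from
        the simulator or ``in_frame_footprints``.
    """

    def __init__(self, cds_sequences: dict[str, str],
                 footprints: FootprintSet, min_len: int = MIN_FOOTPRINT_NT):
        if footprints.read_length < min_len:
            raise ValueError("footprints shorter than the retained minimum")
        self.codon_seqs = {g: codon_indices(s)
                           for g, s in cds_sequences.items()}
        self.footprints = footprints
        n_codons = {g: len(c) for g, c in self.codon_seqs.items()}
        missing = set(footprints.gene_ids) - set(n_codons)
        if missing:
            raise KeyError(f"footprints on unknown genes: {sorted(missing)}")
        self.start_counts = footprints.start_counts(n_codons)

    def windows(self, codon: str) -> CodonWindows:
        return _window_counts(self.codon_seqs, self.start_counts, codon)

    def fit(self, permutations: int = 10000, seed: int = 0,
            codons=SENSE_CODONS) -> "ResidenceTimeResults":
        rows = []
        windows = {}
        for codon in codons:
            cw = self.windows(codon)
            windows[codon] = cw
            if cw.n_windows == 0:
                for p in range(1, N_POSITIONS + 1):
                    rows.append((codon, p, np.nan, np.nan, 0, np.nan))
                continue
            rf = cw.rf()
            mean_rf = rf.mean(axis=0)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, CODON_INDEX[codon]]))
            null = _null_mean_rf(rf, permutations, rng)
            pvals = empirical_p_two_sided(null, mean_rf)
            for p in range(1, N_POSITIONS + 1):
                rows.append((codon, p, mean_rf[p - 1],
                             mean_rf[p - 1] * N_POSITIONS,
                             cw.n_windows, pvals[p - 1]))
        table = pd.DataFrame(
            rows, columns=["codon", "position", "rf", "rrt", "n_windows", "p"])
        table["site"] = table["position"].map(SITE_FLAGS).fillna("")
        return ResidenceTimeResults(self, table, windows, permutations, seed)


class ResidenceTimeResults:
    """The 61-codon x 9-position RRT table with permutation P values."""

    def __init__(self, model, table, windows, permutations, seed):
        self.model = model
        self.table = table
        self.windows = windows
        self.permutations = permutations
        self.seed = seed

    def significant_stalling(self, rrt_thresh: float = 1.2,
                             p_thresh: float = 1e-4,
                             min_windows: int = 300) -> pd.DataFrame:
        """Codon-position pairs passing the stalling filter.

        RRT is a positive ratio, so the effect criterion is symmetric:
        max(RRT, 1/RRT) >= rrt_thresh, catching both over- and
        under-represented occupancy; ``direction`` records which.
        """
        t = self.table.dropna(subset=["rrt", "p"])
        effect = np.maximum(t["rrt"], 1.0 / t["rrt"])
        keep = ((effect >= rrt_thresh) & (t["p"] <= p_thresh)
                & (t["n_windows"] >= min_windows))
        out = t[keep].copy()
        out["direction"] = np.where(out["rrt"] >= 1.0, "over", "under")
        return out.reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        called = self.significant_stalling()
        ok = t.dropna(subset=["rrt"])
        lines = [
            f"Ribosome residence time, {len(self.model.footprints)} footprints, "
            f"{self.permutations} permutations",
            f"  codons with windows: {ok['codon'].nunique()}/{t['codon'].nunique()}",
            f"  stalling calls (max(RRT,1/RRT)>=1.2, P<=1e-4, >=300 windows): "
            f"{len(called)}",
        ]
        for _, r in called.iterrows():
            lines.append(f"    {r.codon} position {r.position} "
                         f"({r.site or '-'}-site) RRT={r.rrt:.3f} p={r.p:.2g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# between-strain comparison

def strain_rrt_ratio_test(results_b: ResidenceTimeResults,
                          results_y: ResidenceTimeResults,
                          permutations: int = 10000, seed: int = 0,
                          rrt_thresh: float = 1.2, p_thresh: float = 1e-4,
                          min_windows: int = 300) -> pd.DataFrame:
    """Per codon-position RRT(B)/RRT(Y) with joint-permutation P values.

    For each permutation both strains' window labels are shuffled and
    the ratio of the permuted mean RFs recomputed; the observed ratio is
    compared two-sided against these nulls.  Significance uses the same
    criteria as the stalling filter, with the window requirement applied
    to both strains.  Codons missing in either strain are skipped.
    """
    rows = []
    codons = [c for c in results_b.windows
              if c in results_y.windows
              and results_b.windows[c].n_windows > 0
              and results_y.windows[c].n_windows > 0]
    for codon in codons:
        rf_b = results_b.windows[codon].rf()
        rf_y = results_y.windows[codon].rf()
        obs_b, obs_y = rf_b.mean(axis=0), rf_y.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_ratio = obs_b / obs_y
        # permutation streams keyed by window content, not strain label,
        # so a label swap inverts ratios with identical P values
        null_b = _null_mean_rf(rf_b, permutations, _content_rng(seed, codon, rf_b))
        null_y = _null_mean_rf(rf_y, permutations, _content_rng(seed, codon, rf_y))
        with np.errstate(divide="ignore", invalid="ignore"):
            null_ratio = null_b / null_y
        pvals = empirical_p_two_sided(null_ratio, obs_ratio)
        nb = results_b.windows[codon].n_windows
        ny = results_y.windows[codon].n_windows
        for p in range(1, N_POSITIONS + 1):
            r = obs_ratio[p - 1]
            effect = max(r, 1.0 / r) if r > 0 else np.inf
            rows.append((codon, p, SITE_FLAGS.get(p, ""), r, nb, ny,
                         pvals[p - 1],
                         bool(effect >= rrt_thresh
                              and pvals[p - 1] <= p_thresh
                              and min(nb, ny) >= min_windows)))
    return pd.DataFrame(rows, columns=[
        "codon", "position", "site", "rrt_ratio",
        "n_windows_b", "n_windows_y", "p", "significant"])


def _content_rng(seed, codon, rf) -> np.random.Generator:
    import zlib
    return np.random.default_rng(np.random.SeedSequence(
        [seed, 7, CODON_INDEX[codon], zlib.crc32(np.ascontiguousarray(rf).tobytes())]))
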
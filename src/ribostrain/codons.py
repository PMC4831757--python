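"""Codon tables and byte-level sequence helpers shared across modules."""

from __future__ import annotations

import itertools

import numpy as np

BASES = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

_BASE2CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE2CODE[ord(_b)] = _i

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


def seq_to_array(seq: str) -> np.ndarray:
    """Sequence string -> uint8 byte array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def revcomp(seq: str) -> str:
    return array_to_seq(revcomp_array(seq_to_array(seq)))


def codon_indices(seq: str) -> np.ndarray:
    """Codon index (0..63, base-4 over A,C,G,T) for each codon of an
    in-frame sequence; length must be a multiple of 3.  Codons containing
    non-ACGT characters get index -1."""
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    codes = _BASE2CODE[seq_to_array(seq)].astype(np.int64)
    cod = codes.reshape(-1, 3)
    bad = (cod < 0).any(axis=1)
    idx = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    idx[bad] = -1
    return idx


STOP_INDICES = frozenset(CODON_INDEX[c] for c in STOP_CODONS)
ATG_INDEX = CODON_INDEX["ATG"]
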
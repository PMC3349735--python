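"""Shared helpers: seed fan-out, IUPAC alphabet, reverse complement."""

from __future__ import annotations

import hashlib

import numpy as np

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (case-insensitive, returns upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def derive_seed(seed: int, *labels: str) -> int:
    """Stable per-stage seed below 2**31, derived from a global seed and stage labels.

    Uses blake2s so that the fan-out is independent of PYTHONHASHSEED and of
    platform int hashing; each stage of the pipeline gets an independent,
    reproducible stream.
    """
    key = ":".join([str(int(seed)), *labels]).encode()
    digest = hashlib.blake2s(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *labels))
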
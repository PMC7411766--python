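"""Low-level nucleotide helpers shared across the package.

Sequences are stored internally as DNA (``U`` is converted to ``T`` on
ingest); report-facing code converts back to RNA where the field prints
RNA (sequence logos, candidate tables).
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGTN"

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_U2T = str.maketrans("Uu", "Tt")

#: byte -> 2-bit code; A=0 C=1 G=2 T=3, anything else (incl. N) = 4.
#: Code 4 is a sentinel that never matches a real base.
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODE[ord(_b)] = _i
    BASE_CODE[ord(_b.lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def to_dna(seq: str) -> str:
    """Normalize to uppercase DNA (U -> T)."""
    return seq.translate(_U2T).upper()


def to_rna(seq: str) -> str:
    """Render a DNA-stored sequence as RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (sentinel 4 decodes to N)."""
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def encode_revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; the N sentinel stays 4."""
    rc = np.where(codes == 4, np.uint8(4), (3 - codes).astype(np.uint8))
    return rc[::-1]


def is_valid_read(seq: str) -> bool:
    """True when the sequence contains only A/C/G/T (no N, no junk)."""
    return bool((encode(seq) < 4).all()) if seq else False


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    ea, eb = encode(a), encode(b)
    return int(np.count_nonzero((ea != eb) | (ea == 4) | (eb == 4)))
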
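"""Low-level nucleotide helpers shared across the pipeline.

The whole package works on plain upper-case strings over {A, C, G, T, N};
numpy byte encodings are used only inside hot loops.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte codes: A=0 C=1 G=2 T=3, everything else (incl. N) = 4 so that an
# ambiguous base never equals a reference base in vectorised comparisons
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def sanitize(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and normalise to the {A,C,G,T,N} alphabet.

    IUPAC ambiguity codes (and the gap characters occasionally left in
    flat files) are collapsed to N; anything non-alphabetic raises.
    """
    up = str(seq).upper().replace("-", "N").replace(".", "N")
    if not up.isalpha() and up != "":
        bad = sorted({c for c in up if not c.isalpha()})
        raise ValueError(f"{context}: invalid characters {bad!r}")
    return "".join(c if c in VALID else "N" for c in up)


def hamming_matches(a: str, b: str) -> int:
    """Number of positions where equal and neither base is N."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x == y and x != "N" for x, y in zip(a, b))
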
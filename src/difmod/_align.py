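"""Pairwise alignment identities via edlib.

Identity is defined as matched columns / total alignment columns of an
optimal edit-distance alignment (global for whole-sequence comparisons,
infix for catalog-vs-module matching).
"""
from __future__ import annotations

import re

import edlib

from ._seq import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_identity(cigar: str) -> float:
    matches = columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches / columns if columns else 0.0


def _identity(query: str, target: str, mode: str) -> float:
    res = edlib.align(query, target, mode=mode, task="path")
    return _cigar_identity(res["cigar"])


def global_identity(a: str, b: str, orientation_normalize: bool = True) -> float:
    """Global (Needleman-Wunsch) alignment identity of two sequences.

    With orientation normalisation, the better of forward and
    reverse-complement comparisons is returned.
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    fwd = _identity(a, b, "NW")
    if not orientation_normalize:
        return fwd
    return max(fwd, _identity(a, revcomp(b), "NW"))


def infix_identity(query: str, target: str, orientation_normalize: bool = True):
    """Best infix (query-in-target) alignment identity and its start in target.

    Returns ``(identity, start0)`` where ``start0`` is the 0-based start of
    the best placement on the forward strand of ``target`` (for a
    reverse-complement hit, the forward-strand start of the hit interval).
    """
    if not query or not target:
        raise ValueError("infix_identity requires non-empty sequences")
    res = edlib.align(query, target, mode="HW", task="path")
    best = (_cigar_identity(res["cigar"]), res["locations"][0][0])
    if orientation_normalize:
        rc = edlib.align(revcomp(query), target, mode="HW", task="path")
        cand = (_cigar_identity(rc["cigar"]), rc["locations"][0][0])
        if cand[0] > best[0]:
            best = cand
    return best
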
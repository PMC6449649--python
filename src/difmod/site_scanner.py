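"""Fixed-length similarity scanning for 28-bp dif/pdif sites.

A dif site is a 28-bp locus bound by the XerC and XerD tyrosine
recombinases: an 11-bp XerC arm, a 6-bp central region and an 11-bp XerD
arm. A site can sit on the forward strand in CD (XerC/XerD) or DC
(XerD/XerC) arm order. Detection is an exhaustive sliding-window scan of
every forward-strand 28-mer against the packaged (or user-supplied)
reference pair, scored by ungapped Hamming identity; this is deterministic
and, at this scale, exactly equivalent to local alignment of an ungapped
28-bp motif.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import encode, hamming_matches, revcomp
from .io_formats import Replicon, ReferenceSite, load_dif1_reference, load_reference_sites

logger = logging.getLogger(__name__)

SITE_LEN = 28
XERC_SLICE = slice(0, 11)
CENTRAL_SLICE = slice(11, 17)
XERD_SLICE = slice(17, 28)

DEFAULT_MIN_IDENTITY = 0.75


@dataclass(frozen=True)
class DifSite:
    """A located, oriented, identity-scored 28-bp site.

    Coordinates are 1-based inclusive on the forward strand; for sites that
    wrap the origin of a circular replicon, ``end`` exceeds the replicon
    length and is read modulo the length. ``sequence`` is the forward-strand
    28-mer; the three arms are reported in site-intrinsic orientation
    (DC-oriented hits are reverse-complemented before decomposition).
    """

    replicon_id: str
    start: int
    end: int
    orientation: str            # "CD" or "DC" as read on the forward strand
    identity: float             # Hamming matches / 28
    matched_reference: str      # label of the best-scoring packaged reference
    sequence: str               # forward-strand 28-mer
    xerC_arm: str
    central: str
    xerD_arm: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != SITE_LEN:
            raise ValueError(f"site span must be {SITE_LEN} bp, got {self.end - self.start + 1}")

    @property
    def intrinsic_sequence(self) -> str:
        """The site read in CD arm order (reverse complement of DC hits)."""
        return self.sequence if self.orientation == "CD" else revcomp(self.sequence)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ChromosomalSiteClassification:
    """Main dif1 site (if any) vs additional chromosomal dif sites."""

    main_dif1: Optional[DifSite]
    additional_sites: list[DifSite] = field(default_factory=list)


def decompose_arms(sequence: str, orientation: str) -> tuple[str, str, str]:
    """Split a 28-mer into (XerC arm, central, XerD arm) in intrinsic orientation."""
    if len(sequence) != SITE_LEN:
        raise ValueError(f"expected {SITE_LEN} bp, got {len(sequence)}")
    intrinsic = sequence if orientation == "CD" else revcomp(sequence)
    return intrinsic[XERC_SLICE], intrinsic[CENTRAL_SLICE], intrinsic[XERD_SLICE]


def identity28(window: str, ref: str) -> float:
    """Ungapped identity between two 28-mers: equal non-N positions / 28."""
    if len(window) != SITE_LEN or len(ref) != SITE_LEN:
        raise ValueError(f"identity28 requires two {SITE_LEN}-bp strings "
                         f"(got {len(window)} and {len(ref)})")
    return hamming_matches(window, ref) / SITE_LEN


def _motif_table(refs: tuple[ReferenceSite, ReferenceSite]):
    """Forward-strand comparison motifs.

    Each packaged reference is scanned in both arrangements: the CD reference
    read forward is a CD occurrence and its reverse complement a DC
    occurrence (vice versa for the DC reference). CD entries precede DC so
    argmax ties resolve CD-first.
    """
    cd, dc = refs
    if {cd.label, dc.label} != {"CD", "DC"}:
        raise ValueError("reference pair must carry labels CD and DC")
    if cd.label != "CD":
        cd, dc = dc, cd
    return [
        (cd.sequence, "CD", cd.label),
        (revcomp(dc.sequence), "CD", dc.label),
        (dc.sequence, "DC", dc.label),
        (revcomp(cd.sequence), "DC", cd.label),
    ]


def _intervals_overlap(a: DifSite, b: DifSite, length: int, circular: bool) -> bool:
    shifts = (0,) if not circular else (-length, 0, length)
    for sh in shifts:
        if a.start + sh <= b.end and b.start <= a.end + sh:
            return True
    return False


def scan_replicon(
    replicon: Replicon,
    refs: Optional[tuple[ReferenceSite, ReferenceSite]] = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    wrap: Optional[bool] = None,
) -> list[DifSite]:
    """Scan every forward-strand 28-bp window against the reference pair.

    Hits at or above ``min_identity`` are collected; overlapping hits are
    resolved keeping the highest identity (ties: leftmost, then CD before
    DC). With ``wrap`` (default: on for circular replicons) the scan crosses
    the origin by virtually appending the first 27 bases.
    """
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError(f"min_identity must be in [0.5, 1.0], got {min_identity}")
    if refs is None:
        refs = load_reference_sites()
    if wrap is None:
        wrap = replicon.topology == "circular"

    L = replicon.length
    if L < SITE_LEN:
        return []
    seq = replicon.sequence + (replicon.sequence[:SITE_LEN - 1] if wrap else "")
    arr = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)
    n_win = L if wrap else L - SITE_LEN + 1
    windows = windows[:n_win]

    motifs = _motif_table(refs)
    scores = np.empty((len(motifs), n_win), dtype=np.int16)
    for k, (motif, _, _) in enumerate(motifs):
        scores[k] = (windows == encode(motif)[None, :]).sum(axis=1)
    best_k = scores.argmax(axis=0)          # first max -> CD preferred on ties
    best = scores[best_k, np.arange(n_win)]

    min_matches = int(np.ceil(min_identity * SITE_LEN - 1e-9))
    hits: list[DifSite] = []
    for i in np.flatnonzero(best >= min_matches):
        k = int(best_k[i])
        _, orientation, ref_label = motifs[k]
        window = seq[i:i + SITE_LEN]
        xc, ce, xd = decompose_arms(window, orientation)
        hits.append(DifSite(
            replicon_id=replicon.id, start=int(i) + 1, end=int(i) + SITE_LEN,
            orientation=orientation, identity=float(best[i]) / SITE_LEN,
            matched_reference=ref_label, sequence=window,
            xerC_arm=xc, central=ce, xerD_arm=xd,
        ))

    # overlap resolution: one physical locus -> one call
    order = sorted(hits, key=lambda s: (-s.identity, s.start, s.orientation))
    accepted: list[DifSite] = []
    for cand in order:
        if not any(_intervals_overlap(cand, a, L, wrap) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda s: s.start)
    return accepted


def count_by_orientation(sites: Sequence[DifSite]) -> tuple[int, int]:
    """(n_CD, n_DC) counts for one replicon's sites."""
    n_cd = sum(1 for s in sites if s.orientation == "CD")
    return n_cd, len(sites) - n_cd


def classify_chromosomal_sites(
    sites: Sequence[DifSite],
    dif1_reference: Optional[str] = None,
    dif1_min_identity: float = 0.90,
) -> ChromosomalSiteClassification:
    """Separate the main chromosomal dif1 site from additional dif sites.

    The main site is the single detected site whose intrinsic sequence is
    most similar to the dif1 reference (ties: lowest start); if no site
    reaches ``dif1_min_identity`` the main site is absent (warning logged)
    and every detected site counts as additional.
    """
    if dif1_reference is None:
        dif1_reference = load_dif1_reference()
    sites = list(sites)
    if not sites:
        return ChromosomalSiteClassification(main_dif1=None, additional_sites=[])
    scored = [(identity28(s.intrinsic_sequence, dif1_reference), -s.start, s) for s in sites]
    best_id, _, best_site = max(scored, key=lambda t: (t[0], t[1]))
    if best_id < dif1_min_identity:
        logger.warning("no candidate reaches dif1 identity %.2f (best %.3f); main dif1 absent",
                       dif1_min_identity, best_id)
        return ChromosomalSiteClassification(main_dif1=None, additional_sites=sites)
    additional = [s for s in sites if s is not best_site]
    return ChromosomalSiteClassification(main_dif1=best_site, additional_sites=additional)
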
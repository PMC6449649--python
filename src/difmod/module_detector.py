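"""Calling dif modules: cargo-carrying spans between consecutive pdif sites.

A dif module is the DNA segment bounded by two adjacent sites, measured
INCLUSIVE of both flanking 28-bp sites, that carries at least one cargo
open reading frame. Modules are candidates for Xer-mediated horizontal
mobility; labelling against an adaptive-cargo catalog gives them the
field's usual names (terC_dif, add_dif, ...).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from ._align import infix_identity
from ._seq import revcomp
from .io_formats import Replicon
from .site_scanner import SITE_LEN, DifSite

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_MAX_MODULE_LEN = 20_000
DEFAULT_MIN_ORF_LEN = 150
DEFAULT_CARGO_MIN_IDENTITY = 0.90
MIN_MODULE_LEN = 2 * SITE_LEN


@dataclass(frozen=True)
class OpenReadingFrame:
    """A start-to-stop ORF; length includes the stop codon."""

    start: int        # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str       # "+" or "-"
    length: int
    translation: str

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ValueError(f"ORF length must be a codon multiple, got {self.length}")


@dataclass(frozen=True)
class CargoCatalogEntry:
    name: str
    function_class: str
    reference_sequence: str


@dataclass
class DifModule:
    replicon_id: str
    left_site: DifSite
    right_site: DifSite
    cargo_orfs: list[OpenReadingFrame] = field(default_factory=list)
    label: str = "unlabeled"
    module_sequence: str = ""

    @property
    def start(self) -> int:
        return self.left_site.start

    @property
    def end(self) -> int:
        return self.right_site.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.module_sequence and len(self.module_sequence) != self.length:
            raise ValueError("module_sequence length does not match span")


def _orfs_in_frame(seq: str, frame: int, min_len: int) -> list[tuple[int, int]]:
    """Longest ORF per stop codon in one forward frame; 0-based [start, end)."""
    out = []
    start: Optional[int] = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            if start is not None and (i + 3 - start) >= min_len:
                out.append((start, i + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = i
    return out


def find_orfs(replicon: Replicon, min_len: int = DEFAULT_MIN_ORF_LEN,
              wrap: Optional[bool] = None) -> list[OpenReadingFrame]:
    """All ORFs on six frames with starts {ATG,GTG,TTG} and stops {TAA,TAG,TGA}.

    Longest-ORF-per-stop; with ``wrap`` (default: circular topology) ORFs may
    cross the origin (coordinates then extend past the replicon length,
    modulo convention) and are capped at the replicon length.
    """
    if min_len < 60:
        raise ValueError(f"min_len must be >= 60, got {min_len}")
    if wrap is None:
        wrap = replicon.topology == "circular"
    L = replicon.length
    fwd = replicon.sequence + (replicon.sequence if wrap else "")
    rev = revcomp(fwd)
    orfs: list[OpenReadingFrame] = []
    seen: set[tuple[int, int, str]] = set()
    for strand, seq in (("+", fwd), ("-", rev)):
        for frame in range(3):
            for s0, e0 in _orfs_in_frame(seq, frame, min_len):
                if e0 - s0 > L:
                    continue
                if strand == "+":
                    start, end = s0 + 1, e0
                else:
                    start, end = len(seq) - e0 + 1, len(seq) - s0
                if wrap and start > L:
                    # second-copy duplicate; canonicalise to start within [1, L]
                    start, end = start - L, end - L
                key = (start, end, strand)
                if key in seen:
                    continue
                seen.add(key)
                aa = str(Seq(seq[s0:e0]).translate())
                orfs.append(OpenReadingFrame(start=start, end=end, strand=strand,
                                             length=e0 - s0, translation=aa))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def wrap_needed(start: int, end: int, length: int) -> bool:
    return end > length


def module_span(left: DifSite, right: DifSite, replicon_length: int, wraps: bool) -> int:
    """Inclusive span between two flanking sites; circular-aware."""
    if wraps:
        return right.end + replicon_length - left.start + 1
    return right.end - left.start + 1


def call_modules(
    sites: Sequence[DifSite],
    replicon: Replicon,
    max_len: int = DEFAULT_MAX_MODULE_LEN,
    require_orf: bool = True,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
) -> list[DifModule]:
    """One candidate module per pair of consecutive sites within the length cap.

    The span is inclusive of both flanking sites. On circular replicons the
    pair wrapping the origin is also considered. With ``require_orf``,
    candidates lacking any cargo ORF of at least ``min_orf_len`` are dropped.
    """
    sites = sorted(sites, key=lambda s: s.start)
    for a, b in zip(sites, sites[1:]):
        if b.start <= a.end:
            raise ValueError(f"overlapping sites at {a.start} and {b.start} "
                             "(scanner contract violation)")
    if len(sites) < 2:
        return []
    L = replicon.length
    circular = replicon.topology == "circular"
    pairs: list[tuple[DifSite, DifSite, bool]] = [(a, b, False) for a, b in zip(sites, sites[1:])]
    if circular and len(sites) >= 2:
        pairs.append((sites[-1], sites[0], True))

    doubled = replicon.sequence * 2
    out: list[DifModule] = []
    for left, right, wraps in pairs:
        span = module_span(left, right, L, wraps)
        if span < MIN_MODULE_LEN or span > max_len or span > L:
            continue
        start = left.start
        end = start + span - 1    # may exceed L for wrapping modules
        seq = doubled[start - 1:end]
        interior = Replicon(id=f"{replicon.id}|module", sequence=seq, topology="linear",
                            category=replicon.category)
        orfs = find_orfs(interior, min_len=min_orf_len, wrap=False)
        orfs = [OpenReadingFrame(start=o.start + start - 1, end=o.end + start - 1,
                                 strand=o.strand, length=o.length, translation=o.translation)
                for o in orfs]
        if require_orf and not orfs:
            continue
        right_adj = right
        if wraps:
            right_adj = DifSite(replicon_id=right.replicon_id, start=right.start + L,
                                end=right.end + L, orientation=right.orientation,
                                identity=right.identity, matched_reference=right.matched_reference,
                                sequence=right.sequence, xerC_arm=right.xerC_arm,
                                central=right.central, xerD_arm=right.xerD_arm)
        out.append(DifModule(replicon_id=replicon.id, left_site=left, right_site=right_adj,
                             cargo_orfs=orfs, module_sequence=seq))
    return out


def label_module(
    module: DifModule,
    catalog: Sequence[CargoCatalogEntry],
    min_identity: float = DEFAULT_CARGO_MIN_IDENTITY,
) -> str:
    """Label a module by catalog entries matching its cargo.

    Catalog reference sequences are infix-aligned (both orientations)
    against the module sequence; names of entries at or above
    ``min_identity`` are joined in coordinate order and suffixed ``_dif``;
    a module matching nothing is ``unlabeled``.
    """
    if not catalog:
        raise ValueError("cargo catalog is empty")
    matched: list[tuple[int, str]] = []
    for entry in catalog:
        if len(entry.reference_sequence) > len(module.module_sequence):
            continue
        ident, start0 = infix_identity(entry.reference_sequence, module.module_sequence)
        if ident >= min_identity:
            matched.append((start0, entry.name))
    if not matched:
        return "unlabeled"
    matched.sort()
    return "-".join(name for _, name in matched) + "_dif"


def call_and_label_modules(sites, replicon, catalog, **kwargs) -> list[DifModule]:
    """Convenience wrapper: call modules then attach catalog labels."""
    modules = call_modules(sites, replicon, **kwargs)
    for m in modules:
        m.label = label_module(m, catalog)
    return modules
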
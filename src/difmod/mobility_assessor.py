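"""Horizontal-mobility assessment for dif module families.

The mobility criterion: near-identical copies of a module (global identity
at or above a threshold, default 0.98) occurring in different sequence
contexts (dissimilar flanking DNA) on different replicons are taken as
evidence of horizontal transfer. Species difference is recorded and can be
enforced in strict mode, but is not required by default because species
labels are frequently absent on contigs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._align import global_identity
from ._seq import revcomp
from .io_formats import Replicon
from .module_detector import DifModule

DEFAULT_FLANK_LEN = 500
DEFAULT_MIN_MODULE_IDENTITY = 0.98
DEFAULT_MAX_CONTEXT_IDENTITY = 0.80
DEFAULT_MIN_INFORMATIVE_FLANK = 100
DEFAULT_FAMILY_THRESHOLD = 0.95


@dataclass
class ModuleOccurrence:
    """One module copy plus its flanking context outside the module span."""

    module: DifModule
    left_flank: str
    right_flank: str
    replicon_id: str
    species_label: Optional[str] = None


@dataclass
class SupportingPair:
    """One occurrence pair evaluated for the mobility criterion."""

    index_a: int
    index_b: int
    module_identity: float
    context_different: Optional[bool]   # None = indeterminate (flanks too short)
    different_replicons: bool
    different_species: Optional[bool]

    @property
    def supports(self) -> bool:
        return bool(self.context_different) and self.different_replicons


@dataclass
class MobilityCall:
    family_label: str
    occurrences: list[ModuleOccurrence]
    is_mobile: bool
    supporting_pairs: list[SupportingPair] = field(default_factory=list)


def extract_occurrence(module: DifModule, replicon: Replicon,
                       flank_len: int = DEFAULT_FLANK_LEN) -> ModuleOccurrence:
    """Take up to ``flank_len`` bp outside each module boundary.

    On circular replicons flanks wrap the origin (but never into the module
    itself); on linear replicons they truncate at the ends.
    """
    L = replicon.length
    outside = max(0, L - (module.length if module.length <= L else L))
    flank = min(flank_len, outside // 2 if replicon.topology == "circular" else flank_len)
    doubled = replicon.sequence * 3
    # coordinates into the tripled sequence, offset by L to allow left wrap
    s = module.start + L
    e = module.end + L
    if replicon.topology == "circular":
        left = doubled[s - 1 - flank:s - 1]
        right = doubled[e:e + flank]
    else:
        left = replicon.sequence[max(0, module.start - 1 - flank_len):module.start - 1]
        right = replicon.sequence[module.end:module.end + flank_len]
    return ModuleOccurrence(module=module, left_flank=left, right_flank=right,
                            replicon_id=replicon.id, species_label=replicon.species_label)


def module_identity(a: DifModule, b: DifModule) -> float:
    """Orientation-normalised global alignment identity of two module sequences."""
    return global_identity(a.module_sequence, b.module_sequence)


def context_different(
    a: ModuleOccurrence,
    b: ModuleOccurrence,
    max_context_identity: float = DEFAULT_MAX_CONTEXT_IDENTITY,
    min_informative: int = DEFAULT_MIN_INFORMATIVE_FLANK,
) -> Optional[bool]:
    """True iff the best flank pairing identity is below ``max_context_identity``.

    Pairings tried: forward (left-left, right-right) and swapped/
    reverse-complement (left vs revcomp(right)), covering a module copied in
    inverted orientation. Returns None (indeterminate) when no flank
    comparison has both sequences at the informative minimum length.
    """
    pairings = [
        (a.left_flank, b.left_flank), (a.right_flank, b.right_flank),
        (a.left_flank, revcomp(b.right_flank)), (a.right_flank, revcomp(b.left_flank)),
    ]
    identities = [global_identity(x, y, orientation_normalize=False)
                  for x, y in pairings
                  if len(x) >= min_informative and len(y) >= min_informative]
    if not identities:
        return None
    return max(identities) < max_context_identity


def assess_mobility(
    occurrences: Sequence[ModuleOccurrence],
    min_module_identity: float = DEFAULT_MIN_MODULE_IDENTITY,
    max_context_identity: float = DEFAULT_MAX_CONTEXT_IDENTITY,
    min_informative: int = DEFAULT_MIN_INFORMATIVE_FLANK,
    require_species_difference: bool = False,
) -> MobilityCall:
    """Evaluate the mobility criterion over all occurrence pairs of one family."""
    occurrences = list(occurrences)
    labels = [o.module.label for o in occurrences if o.module.label != "unlabeled"]
    family_label = max(set(labels), key=labels.count) if labels else "unlabeled"
    pairs: list[SupportingPair] = []
    for i in range(len(occurrences)):
        for j in range(i + 1, len(occurrences)):
            a, b = occurrences[i], occurrences[j]
            ident = module_identity(a.module, b.module)
            if ident < min_module_identity:
                continue
            ctx = context_different(a, b, max_context_identity, min_informative)
            diff_rep = a.replicon_id != b.replicon_id
            if a.species_label and b.species_label:
                diff_sp: Optional[bool] = a.species_label != b.species_label
            else:
                diff_sp = None
            pairs.append(SupportingPair(i, j, ident, ctx, diff_rep, diff_sp))
    if require_species_difference:
        is_mobile = any(p.supports and p.different_species for p in pairs)
    else:
        is_mobile = any(p.supports for p in pairs)
    return MobilityCall(family_label=family_label, occurrences=occurrences,
                        is_mobile=is_mobile,
                        supporting_pairs=[p for p in pairs if p.supports])


def group_families(
    occurrences: Sequence[ModuleOccurrence],
    family_threshold: float = DEFAULT_FAMILY_THRESHOLD,
) -> list[list[ModuleOccurrence]]:
    """Single-linkage grouping of occurrences at module identity >= threshold."""
    n = len(occurrences)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if module_identity(occurrences[i].module, occurrences[j].module) >= family_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[ModuleOccurrence]] = {}
    for i, occ in enumerate(occurrences):
        groups.setdefault(find(i), []).append(occ)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0].replicon_id, g[0].module.start))


def assess_all(occurrences: Sequence[ModuleOccurrence],
               family_threshold: float = DEFAULT_FAMILY_THRESHOLD,
               **kwargs) -> list[MobilityCall]:
    """Group occurrences into families, then assess each family."""
    return [assess_mobility(group, **kwargs) for group in group_families(occurrences, family_threshold)]
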
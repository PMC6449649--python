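"""Synthetic replicon datasets with planted sites, modules and ground truth.

The generator emulates the statistical structure the analysis assumes: a
collection of circular/linear replicons (log-uniform lengths, i.i.d.
background at a given GC), a per-replicon site-burden distribution matching
the observed plasmid burden (40% zero, 43% one-to-four, 10% five-to-eight,
7% more), planted 28-bp sites at controlled divergence from the packaged
references, planted cargo modules at the field-typical spans, and transfer
events that copy a module onto a second replicon with a fresh random
context and <=1% cargo mutation.

Placement rules that make recovery testing exact: planted features are
spaced at least ``min_feature_gap`` apart (default 21 kb, above the module
length cap, so the only consecutive site pair within the cap is a planted
module), and replicons shorter than ``min_site_replicon_length`` (default
6 kb) never carry sites — mirroring the empirical absence of sites from
very small plasmids.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io_formats import Replicon, load_reference_sites, read_catalog, write_fasta
from .site_scanner import SITE_LEN

DEFAULT_CATEGORY_PROBS = {"0": 0.40, "1-4": 0.43, "5-8": 0.10, ">8": 0.07}
BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ModuleTemplate:
    """Blueprint of a plantable module: label, ordered cargo genes, total span
    (inclusive of both flanking 28-bp sites) and flank orientations."""

    label: str
    cargo_names: tuple[str, ...]
    total_span: int
    left_orientation: str = "CD"
    right_orientation: str = "DC"


def default_module_templates() -> list[ModuleTemplate]:
    """The seven adaptive-module blueprints at their characteristic spans."""
    return [
        ModuleTemplate("chrAB_dif", ("chrA", "chrB"), 3011),
        ModuleTemplate("terC_dif", ("terC",), 1221),
        ModuleTemplate("kup_dif", ("kup", "orfY"), 2549),
        ModuleTemplate("ohr1_dif", ("ohr", "ohrR"), 1063),
        ModuleTemplate("sulP_dif", ("sulP", "orfX"), 2159),
        ModuleTemplate("sulP_uspA_dif", ("sulP", "uspA"), 2739),
        ModuleTemplate("add_dif", ("add_toxin", "add_antitoxin"), 768),
    ]


@dataclass
class SimulationSpec:
    """Generator parameters; the defaults are the study conditions."""

    n_replicons: int = 50
    length_bounds: tuple[int, int] = (2_000, 400_000)
    topology: str = "circular"
    gc_content: float = 0.40
    category_probs: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    divergence_choices: tuple[int, ...] = (0, 1, 2, 3)
    module_templates: Optional[list[ModuleTemplate]] = None
    n_transfer_events: int = 3
    n_single_modules: int = 2      # planted once only; must never be called mobile
    transfer_mutation_rate: float = 0.005
    min_feature_gap: int = 21_000
    min_site_replicon_length: int = 6_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category probabilities must sum to 1, got {total}")
        if self.module_templates is None:
            self.module_templates = default_module_templates()


@dataclass
class RealizedTemplate:
    """A template with concrete interior sequence for one dataset."""

    template: ModuleTemplate
    left_site: str
    right_site: str
    interior: str

    @property
    def sequence(self) -> str:
        return self.left_site + self.interior + self.right_site

    @property
    def span(self) -> int:
        return len(self.left_site) + len(self.interior) + len(self.right_site)


@dataclass
class Dataset:
    spec: SimulationSpec
    replicons: list[Replicon]
    truth_sites: pd.DataFrame
    truth_modules: pd.DataFrame
    categories: dict               # replicon id -> realized burden category

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.replicons, out / "replicons.fasta")
        self.truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.truth_modules.to_csv(out / "truth_modules.tsv", sep="\t", index=False)
        spec_dict = asdict(self.spec)
        spec_dict["module_templates"] = [asdict(t) for t in self.spec.module_templates]
        with open(out / "simulation_spec.json", "w") as fh:
            json.dump(spec_dict, fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# primitive operations

def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(BASES, size=length, p=probs))


def scrub_chance_sites(seq: str, rng: np.random.Generator,
                       circular: bool = True, max_matches: int = 19) -> str:
    """Remove chance dif-like windows from a background sequence.

    I.i.d. background of megabase volume occasionally contains 28-mers at
    >= 21/28 identity to a reference arrangement. The generator guarantees a
    site-free backbone (so its ground truth is complete), so any window
    exceeding ``max_matches`` against either reference in either arrangement
    is degraded by substituting matching positions until it falls below.
    """
    from ._seq import encode
    from .site_scanner import _motif_table

    motifs = [encode(m) for m, _, _ in _motif_table(load_reference_sites())]
    chars = list(seq)
    L = len(chars)
    if L < SITE_LEN:
        return seq
    for _ in range(10):
        ext = "".join(chars) + ("".join(chars[:SITE_LEN - 1]) if circular else "")
        arr = encode(ext)
        win = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)
        n_win = L if circular else L - SITE_LEN + 1
        win = win[:n_win]
        dirty = False
        for enc_motif in motifs:
            scores = (win == enc_motif[None, :]).sum(axis=1)
            for i in np.flatnonzero(scores > max_matches):
                dirty = True
                matched = [p for p in range(SITE_LEN)
                           if arr[i + p] == enc_motif[p]]
                flip = rng.choice(matched, size=int(scores[i]) - max_matches,
                                  replace=False)
                for p in flip:
                    pos = (int(i) + int(p)) % L
                    alternatives = [b for b in "ACGT"
                                    if b != chars[pos] and b != "ACGT"[enc_motif[p]]]
                    chars[pos] = alternatives[rng.integers(len(alternatives))]
        if not dirty:
            break
    return "".join(chars)


def mutate_site(ref: str, k_mismatches: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``k_mismatches`` positions to a different base, so
    identity to the reference is exactly (28 - k) / 28."""
    if not 0 <= k_mismatches <= len(ref):
        raise ValueError(f"k_mismatches must be in [0, {len(ref)}], got {k_mismatches}")
    out = list(ref)
    for pos in rng.choice(len(ref), size=k_mismatches, replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def realize_template(template: ModuleTemplate, catalog: dict,
                     gc: float, rng: np.random.Generator) -> RealizedTemplate:
    """Fill a template blueprint with its cargo ORFs and random spacers."""
    cd_ref, dc_ref = load_reference_sites()
    left = cd_ref.sequence if template.left_orientation == "CD" else dc_ref.sequence
    right = dc_ref.sequence if template.right_orientation == "DC" else cd_ref.sequence
    cargo = [catalog[name] for name in template.cargo_names]
    interior_len = template.total_span - 2 * SITE_LEN
    spacer_total = interior_len - sum(len(c) for c in cargo)
    if spacer_total < 0:
        raise ValueError(f"{template.label}: cargo exceeds interior span")
    n_gaps = len(cargo) + 1
    base, rem = divmod(spacer_total, n_gaps)
    pieces = []
    for i in range(n_gaps):
        pieces.append(random_background(base + (1 if i < rem else 0), gc, rng))
        if i < len(cargo):
            pieces.append(cargo[i])
    interior = "".join(pieces)
    assert len(interior) == interior_len
    return RealizedTemplate(template=template, left_site=left, right_site=right,
                            interior=interior)


def _paste(seq: list, start0: int, insert: str) -> None:
    """Overwrite (circularly) starting at 0-based position start0."""
    L = len(seq)
    for i, ch in enumerate(insert):
        seq[(start0 + i) % L] = ch


def plant_module(background: Replicon, template, position: int,
                 rng: np.random.Generator,
                 existing: Sequence[tuple[int, int]] = (),
                 catalog: Optional[dict] = None,
                 gc: float = 0.40):
    """Plant one module at a 1-based position (replacing background bases).

    ``template`` may be a blueprint (realized here with ``rng``) or an
    already-realized template. Returns the updated replicon plus ground-truth
    rows for the module and its two flanking sites. Overlap with a span in
    ``existing`` raises.
    """
    if isinstance(template, ModuleTemplate):
        if catalog is None:
            catalog = {e.name: e.reference_sequence for e in read_catalog()}
        template = realize_template(template, catalog, gc, rng)
    span = template.span
    L = background.length
    if span > L:
        raise ValueError("module does not fit on replicon")
    end = position + span - 1
    for (s0, e0) in existing:
        for shift in (-L, 0, L):
            if position + shift <= e0 and s0 <= end + shift:
                raise ValueError(f"module at {position} overlaps existing feature ({s0}, {e0})")
    if background.topology != "circular" and end > L:
        raise ValueError("module extends beyond linear replicon end")
    seq = list(background.sequence)
    _paste(seq, position - 1, template.sequence)
    replicon = Replicon(id=background.id, sequence="".join(seq),
                        topology=background.topology, category=background.category,
                        description=background.description,
                        species_label=background.species_label)
    t = template.template
    module_row = {"replicon": background.id, "label": t.label, "start": position,
                  "end": end, "span": span, "transfer_event": -1}
    site_rows = _flank_site_rows(background.id, position, end, t, L)
    return replicon, module_row, site_rows


def _flank_site_rows(rid: str, start: int, end: int, t: ModuleTemplate, L: int) -> list[dict]:
    """Ground-truth rows for a module's two flanking sites, with starts
    canonicalised into [1, L] (the scanner's wrap convention)."""
    rows = []
    for s_raw, orient in ((start, t.left_orientation),
                          (end - SITE_LEN + 1, t.right_orientation)):
        s = (s_raw - 1) % L + 1
        rows.append({"replicon": rid, "start": s, "end": s + SITE_LEN - 1,
                     "orientation": orient, "mismatches": 0, "source": "module_flank"})
    return rows


def _mutate_interior(realized: RealizedTemplate, rate: float,
                     rng: np.random.Generator) -> RealizedTemplate:
    """Copy a realized template with random interior substitutions (the
    flanking sites are left intact so the copy remains detectable)."""
    interior = list(realized.interior)
    k = rng.binomial(len(interior), rate)
    for pos in rng.choice(len(interior), size=k, replace=False):
        alternatives = [b for b in "ACGT" if b != interior[pos]]
        interior[pos] = alternatives[rng.integers(len(alternatives))]
    return RealizedTemplate(template=realized.template, left_site=realized.left_site,
                            right_site=realized.right_site, interior="".join(interior))


# ---------------------------------------------------------------------------
# dataset generation

def _draw_count(category: str, rng: np.random.Generator) -> int:
    if category == "0":
        return 0
    if category == "1-4":
        return int(rng.integers(1, 5))
    if category == "5-8":
        return int(rng.integers(5, 9))
    return int(rng.integers(9, 17))


def generate_dataset(spec: SimulationSpec, out_dir=None) -> Dataset:
    """Generate replicons, plant features, and emit full ground truth.

    Deterministic for a fixed ``spec.seed`` (byte-identical outputs).
    """
    rng = np.random.default_rng(spec.seed)
    cd_ref, dc_ref = load_reference_sites()
    catalog = {e.name: e.reference_sequence for e in read_catalog()}
    templates = list(spec.module_templates)
    if spec.n_transfer_events > len(templates):
        raise ValueError("n_transfer_events exceeds the number of module templates")

    realized = [realize_template(t, catalog, spec.gc_content, rng) for t in templates]

    # per-replicon burden plan
    cats = list(spec.category_probs)
    probs = [spec.category_probs[c] for c in cats]
    drawn = [cats[i] for i in rng.choice(len(cats), size=spec.n_replicons, p=probs)]
    counts = [_draw_count(c, rng) for c in drawn]

    # transfer events place one template on two distinct replicons; single-copy
    # modules use further templates and one replicon each
    n_needed_templates = spec.n_transfer_events + spec.n_single_modules
    if n_needed_templates > len(templates):
        raise ValueError("n_transfer_events + n_single_modules exceeds available templates")
    tmpl_order = rng.choice(len(realized), size=n_needed_templates, replace=False)
    event_templates = [realized[i] for i in tmpl_order[:spec.n_transfer_events]]
    single_templates = [realized[i] for i in tmpl_order[spec.n_transfer_events:]]

    remaining = list(counts)

    def pick_hosts(n: int, exclude: set[int] = frozenset()) -> list[int]:
        eligible = [i for i, r in enumerate(remaining) if r >= 2 and i not in exclude]
        if len(eligible) < n:
            raise ValueError("not enough multi-site replicons to host the planted modules")
        picked = [int(h) for h in rng.choice(eligible, size=n, replace=False)]
        for h in picked:
            remaining[h] -= 2
        return picked

    module_plan: dict[int, list[tuple[int, RealizedTemplate]]] = {}
    for e, tmpl in enumerate(event_templates):
        host_a, host_b = pick_hosts(2)
        module_plan.setdefault(host_a, []).append((e, tmpl))
        module_plan.setdefault(host_b, []).append(
            (e, _mutate_interior(tmpl, spec.transfer_mutation_rate, rng)))
    for tmpl in single_templates:
        (host,) = pick_hosts(1)
        module_plan.setdefault(host, []).append((-1, tmpl))

    lo, hi = spec.length_bounds
    replicons: list[Replicon] = []
    site_rows: list[dict] = []
    module_rows: list[dict] = []
    categories: dict[str, str] = {}

    for i in range(spec.n_replicons):
        rid = f"synthetic_replicon_{i + 1:03d}"
        modules = module_plan.get(i, [])
        n_standalone = counts[i] - 2 * len(modules)
        widths = [m.span for _, m in modules] + [SITE_LEN] * n_standalone
        n_feat = len(widths)
        if n_feat >= 2:
            needed = sum(widths) + (n_feat + 1) * spec.min_feature_gap
        elif n_feat == 1:
            needed = max(widths[0] + 2_000, spec.min_site_replicon_length)
        else:
            needed = lo
        if counts[i] > 0:
            needed = max(needed, spec.min_site_replicon_length)
        if needed > hi:
            raise ValueError(f"{rid}: cannot fit {n_feat} features within length bound {hi}")
        length = int(round(np.exp(rng.uniform(np.log(max(lo, needed)), np.log(hi)))))
        length = min(max(length, needed), hi)

        circular = spec.topology == "circular"
        seq = list(scrub_chance_sites(random_background(length, spec.gc_content, rng),
                                      rng, circular=circular))

        # feature placement with the minimum gap (circular-aware)
        order = rng.permutation(n_feat)
        widths_perm = [widths[j] for j in order]
        starts0: list[int] = []
        if n_feat == 1:
            starts0 = [int(rng.integers(0, length if circular else length - widths_perm[0] + 1))]
        elif n_feat >= 2:
            n_gaps = n_feat if circular else n_feat + 1
            slack = length - sum(widths_perm) - n_feat * spec.min_feature_gap
            extra = rng.multinomial(slack, [1.0 / n_gaps] * n_gaps)
            # circular: random rotation; linear: the extra n_feat+1-th gap leads
            offset = int(rng.integers(0, length)) if circular else int(extra[-1])
            pos = offset
            for j in range(n_feat):
                starts0.append(pos % length)
                pos += widths_perm[j] + spec.min_feature_gap + int(extra[j])

        # realize features in permuted order
        feature_kinds: list[tuple[str, object]] = [("module", mv) for mv in modules] \
            + [("site", None)] * n_standalone
        for j, start0 in zip(order, starts0):
            kind, payload = feature_kinds[j]
            start1 = start0 + 1
            if kind == "module":
                event, copy = payload
                _paste(seq, start0, copy.sequence)
                end1 = start1 + copy.span - 1
                module_rows.append({"replicon": rid, "label": copy.template.label,
                                    "start": start1, "end": end1, "span": copy.span,
                                    "transfer_event": event})
                site_rows.extend(_flank_site_rows(rid, start1, end1,
                                                  copy.template, length))
            else:
                orientation = "CD" if rng.random() < 0.5 else "DC"
                ref = cd_ref.sequence if orientation == "CD" else dc_ref.sequence
                k = int(rng.choice(spec.divergence_choices))
                _paste(seq, start0, mutate_site(ref, k, rng))
                site_rows.append({"replicon": rid, "start": start1,
                                  "end": start1 + SITE_LEN - 1, "orientation": orientation,
                                  "mismatches": k, "source": "standalone"})

        replicons.append(Replicon(id=rid, sequence="".join(seq), topology=spec.topology,
                                  category="plasmid",
                                  description=f"synthetic replicon (planted sites: {counts[i]})"))
        categories[rid] = _category_of(counts[i])

    sites_df = pd.DataFrame(site_rows, columns=["replicon", "start", "end", "orientation",
                                                "mismatches", "source"])
    modules_df = pd.DataFrame(module_rows, columns=["replicon", "label", "start", "end",
                                                    "span", "transfer_event"])
    sites_df = sites_df.sort_values(["replicon", "start"]).reset_index(drop=True)
    modules_df = modules_df.sort_values(["replicon", "start"]).reset_index(drop=True)
    ds = Dataset(spec=spec, replicons=replicons, truth_sites=sites_df,
                 truth_modules=modules_df, categories=categories)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def _category_of(n: int) -> str:
    if n == 0:
        return "0"
    if n <= 4:
        return "1-4"
    if n <= 8:
        return "5-8"
    return ">8"
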
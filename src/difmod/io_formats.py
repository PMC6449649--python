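"""Reading replicons, reference sites and cargo catalogs; writing pipeline outputs.

Coordinate convention: all in-memory coordinates are 1-based inclusive on the
forward strand of the deposited sequence. BED export converts to 0-based
half-open. Features that wrap the origin of a circular replicon keep
``end = start + length - 1`` even when that exceeds the replicon length;
positions beyond ``L`` are understood modulo ``L`` (GFF3 export splits such
features into two segments sharing one ID).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from ._seq import revcomp, sanitize

TOPOLOGIES = ("circular", "linear")
CATEGORIES = ("plasmid", "chromosome", "contig")

SITE_TSV_COLUMNS = (
    "replicon", "start", "end", "orientation", "identity", "sequence",
    "xerC_arm", "central", "xerD_arm", "matched_reference",
)


@dataclass
class Replicon:
    """One input sequence record (plasmid, chromosome or contig)."""

    id: str
    sequence: str
    topology: str = "circular"
    category: str = "plasmid"
    description: str = ""
    species_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.sequence = sanitize(self.sequence, context=f"replicon {self.id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSite:
    """A 28-bp reference site in CD (XerC/XerD) or DC (XerD/XerC) arrangement."""

    label: str          # "CD" or "DC"
    sequence: str       # 28 bp, forward strand as scanned
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("CD", "DC"):
            raise ValueError(f"reference label must be CD or DC, got {self.label!r}")
        object.__setattr__(self, "sequence", sanitize(self.sequence, context="reference site"))
        if len(self.sequence) != 28:
            raise ValueError(f"reference site must be 28 bp, got {len(self.sequence)}")


# ---------------------------------------------------------------------------
# readers

def read_fasta(
    path,
    topology: str = "circular",
    category: str = "plasmid",
    species_label: Optional[str] = None,
) -> list[Replicon]:
    """Read a FASTA file into a list of replicons.

    All records receive the same topology/category; ids must be unique.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty or malformed input)")
    out: list[Replicon] = []
    seen: set[str] = set()
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(Replicon(
            id=rec.id, sequence=str(rec.seq), topology=topology,
            category=category, description=rec.description,
            species_label=species_label,
        ))
    return out


def _infer_category(description: str) -> str:
    low = description.lower()
    if "plasmid" in low:
        return "plasmid"
    if "chromosome" in low or "complete genome" in low:
        return "chromosome"
    return "contig"


def read_genbank(path, category: Optional[str] = None) -> list[Replicon]:
    """Read a GenBank flat file.

    Topology comes from the LOCUS line; category is inferred from the
    definition line ("plasmid ..." -> plasmid) unless overridden.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed GenBank record "
                         f"(truncated or missing ORIGIN sequence): {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    out: list[Replicon] = []
    seen: set[str] = set()
    for rec in records:
        try:
            seq = str(rec.seq)
        except Exception as exc:  # undefined sequence (no ORIGIN)
            raise ValueError(f"{path}: record {rec.id!r} has no ORIGIN sequence") from exc
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has no ORIGIN sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        topo = rec.annotations.get("topology", "linear")
        if topo not in TOPOLOGIES:
            topo = "linear"
        cat = category if category is not None else _infer_category(rec.description)
        species = rec.annotations.get("organism") or None
        out.append(Replicon(
            id=rec.id, sequence=seq, topology=topo, category=cat,
            description=rec.description, species_label=species,
        ))
    return out


def read_reference_sites(path) -> tuple[ReferenceSite, ReferenceSite]:
    """Read a CD/DC reference pair from a FASTA with headers ``CD`` and ``DC``."""
    recs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    missing = {"CD", "DC"} - recs.keys()
    if missing:
        raise ValueError(f"{path}: reference FASTA must contain records 'CD' and 'DC' (missing {sorted(missing)})")
    return (ReferenceSite("CD", recs["CD"], source=str(path)),
            ReferenceSite("DC", recs["DC"], source=str(path)))


def load_reference_sites() -> tuple[ReferenceSite, ReferenceSite]:
    """Packaged synthetic CD/DC pdif reference pair.

    Synthetic stand-ins with the canonical 11-6-11 architecture: the DC
    reference is the reverse complement of a near-identical sister of the CD
    reference, so the pair is reverse-complement compatible in arm order.
    """
    with resources.as_file(resources.files("difmod.data") / "synthetic_reference_sites.fasta") as p:
        return read_reference_sites(p)


def load_dif1_reference() -> str:
    """Packaged synthetic Proteobacteria-consensus-style chromosomal dif1 (28 bp)."""
    with resources.as_file(resources.files("difmod.data") / "synthetic_dif1_reference.fasta") as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    return str(rec.seq)


def read_catalog(path=None):
    """Read an adaptive-cargo catalog FASTA (headers ``name|function_class``).

    With no path, loads the packaged synthetic catalog.
    """
    from .module_detector import CargoCatalogEntry

    if path is None:
        with resources.as_file(resources.files("difmod.data") / "synthetic_cargo_catalog.fasta") as p:
            return read_catalog(p)
    entries = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, func = rec.id.partition("|")
        if name in seen:
            raise ValueError(f"{path}: duplicate catalog entry {name!r}")
        seen.add(name)
        entries.append(CargoCatalogEntry(
            name=name, function_class=func or "unknown",
            reference_sequence=sanitize(str(rec.seq), context=f"catalog {name}"),
        ))
    if not entries:
        raise ValueError(f"{path}: empty cargo catalog")
    return entries


# ---------------------------------------------------------------------------
# site tables

def write_sites(sites: Sequence, path, format: str = "tsv") -> None:
    """Write detected sites as TSV (1-based inclusive) or BED (0-based half-open).

    BED strand is ``+`` for CD-oriented sites and ``-`` for DC-oriented sites.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(SITE_TSV_COLUMNS)
            for s in sites:
                w.writerow([s.replicon_id, s.start, s.end, s.orientation,
                            f"{s.identity:.6f}", s.sequence,
                            s.xerC_arm, s.central, s.xerD_arm, s.matched_reference])
    elif format == "bed":
        with open(path, "w", newline="") as fh:
            for s in sites:
                strand = "+" if s.orientation == "CD" else "-"
                score = min(1000, int(round(s.identity * 1000)))
                fh.write(f"{s.replicon_id}\t{s.start - 1}\t{s.end}\t"
                         f"pdif_{s.orientation}\t{score}\t{strand}\n")
    else:
        raise ValueError(f"unknown site format {format!r}")


def read_sites(path) -> list:
    """Read a site TSV written by :func:`write_sites` back into DifSite objects."""
    from .site_scanner import DifSite

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(DifSite(
                replicon_id=row["replicon"], start=int(row["start"]), end=int(row["end"]),
                orientation=row["orientation"], identity=float(row["identity"]),
                matched_reference=row["matched_reference"], sequence=row["sequence"],
                xerC_arm=row["xerC_arm"], central=row["central"], xerD_arm=row["xerD_arm"],
            ))
    return out


# ---------------------------------------------------------------------------
# GFF3 modules

def _gff_escape(s: str) -> str:
    return s.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _segments(start: int, end: int, length: int) -> list[tuple[int, int]]:
    """Split a (possibly origin-wrapping) 1-based inclusive span into linear segments."""
    if end <= length:
        return [(start, end)]
    return [(start, length), (1, end - length)]


def write_modules(modules: Sequence, path, replicons: Optional[Mapping[str, Replicon]] = None) -> None:
    """Write called modules as GFF3: one parent mobile_genetic_element feature
    with child recombination_site features (the flanking sites) and CDS
    features (cargo ORFs).

    Origin-wrapping features on circular replicons are emitted as two lines
    sharing one ID (the GFF3 discontinuous-feature convention). For linear
    replicons, coordinates beyond the replicon length raise.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("##gff-version 3\n")
        for k, m in enumerate(modules, start=1):
            rep = replicons.get(m.replicon_id) if replicons else None
            length = rep.length if rep is not None else None
            circular = rep is None or rep.topology == "circular"
            mid = f"module{k:05d}"

            def emit(ftype: str, start: int, end: int, strand: str, attrs: str) -> None:
                if length is not None:
                    if end > length and not circular:
                        raise ValueError(
                            f"{m.replicon_id}: feature end {end} beyond linear replicon length {length}")
                    segs = _segments(start, end, length) if end > length else [(start, end)]
                else:
                    segs = [(start, end)]
                for s0, e0 in segs:
                    fh.write(f"{m.replicon_id}\tdifmod\t{ftype}\t{s0}\t{e0}\t.\t{strand}\t.\t{attrs}\n")

            emit("mobile_genetic_element", m.start, m.end, "+",
                 f"ID={mid};Name={_gff_escape(m.label)};length={m.length}")
            for tag, site in (("left", m.left_site), ("right", m.right_site)):
                emit("recombination_site", site.start, site.end,
                     "+" if site.orientation == "CD" else "-",
                     f"ID={mid}.site_{tag};Parent={mid};orientation={site.orientation};"
                     f"identity={site.identity:.4f}")
            for j, orf in enumerate(m.cargo_orfs, start=1):
                emit("CDS", orf.start, orf.end, orf.strand,
                     f"ID={mid}.orf{j};Parent={mid};orf_length={orf.length}")


def read_modules(path, replicons: Mapping[str, Replicon]) -> list:
    """Read a GFF3 written by :func:`write_modules` back into DifModule objects."""
    from .module_detector import DifModule, OpenReadingFrame
    from .site_scanner import DifSite, decompose_arms

    parents: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            start, end = int(start), int(end)
            if ftype == "mobile_genetic_element":
                rec = parents.setdefault(a["ID"], {"replicon": seqid, "label": a.get("Name", "unlabeled"),
                                                   "segs": [], "sites": {}, "orfs": {}})
                rec["segs"].append((start, end))
            elif ftype == "recombination_site":
                pid = a["Parent"]
                tag = "left" if a["ID"].endswith("left") else "right"
                segs = parents[pid]["sites"].setdefault(tag, {"segs": [], "orientation": a["orientation"],
                                                              "identity": float(a.get("identity", 1.0))})
                segs["segs"].append((start, end))
            elif ftype == "CDS":
                entry = parents[a["Parent"]]["orfs"].setdefault(
                    a["ID"], {"segs": [], "strand": strand})
                entry["segs"].append((start, end))

    def join(segs: list[tuple[int, int]], L: int) -> tuple[int, int]:
        # re-join a possibly split discontinuous feature into wrap coordinates
        segs = sorted(segs)
        if len(segs) == 1:
            return segs[0]
        (s1, e1), (s2, e2) = segs[-1], segs[0]  # wrap: (start..L) + (1..end)
        return s1, e2 + L

    out = []
    for rec in parents.values():
        rep = replicons[rec["replicon"]]
        L = rep.length
        start, end = join(rec["segs"], L)
        doubled = rep.sequence * 2
        seq = doubled[start - 1:end]
        sites = {}
        for tag, sd in rec["sites"].items():
            s0, e0 = join(sd["segs"], L)
            site_seq = doubled[s0 - 1:e0]
            xc, ce, xd = decompose_arms(site_seq, sd["orientation"])
            sites[tag] = DifSite(replicon_id=rec["replicon"], start=s0, end=e0,
                                 orientation=sd["orientation"], identity=sd["identity"],
                                 matched_reference="CD", sequence=site_seq,
                                 xerC_arm=xc, central=ce, xerD_arm=xd)
        orfs = []
        for od in rec["orfs"].values():
            s0, e0 = join(od["segs"], L)
            orfs.append(OpenReadingFrame(start=s0, end=e0, strand=od["strand"],
                                         length=e0 - s0 + 1, translation=""))
        orfs.sort(key=lambda o: (o.start, o.end))
        out.append(DifModule(replicon_id=rec["replicon"], left_site=sites["left"],
                             right_site=sites["right"], cargo_orfs=orfs,
                             label=rec["label"], module_sequence=seq))
    out.sort(key=lambda m: (m.replicon_id, m.start))
    return out


def write_fasta(replicons: Iterable[Replicon], path, width: int = 70) -> None:
    """Write replicons as FASTA (wrapped at ``width`` columns)."""
    with open(path, "w", newline="") as fh:
        for rep in replicons:
            desc = f" {rep.description}" if rep.description else ""
            fh.write(f">{rep.id}{desc}\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i:i + width] + "\n")
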
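"""Summary artifacts: site-burden tables, size histograms, multi-site
replicon lists and per-replicon site-position maps."""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_formats import Replicon
from .site_scanner import DifSite

BURDEN_CATEGORIES = ("0", "1-4", "5-8", ">8")
DEFAULT_BIN_EDGES_KB = (0, 6, 10, 20, 30, 50, 100, 200, 400)
DEFAULT_CLUSTER_GAP = 5_000


def site_count_category(n: int) -> str:
    """Burden category for a per-replicon site count."""
    if n < 0:
        raise ValueError("negative site count")
    if n == 0:
        return "0"
    if n <= 4:
        return "1-4"
    if n <= 8:
        return "5-8"
    return ">8"


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (printed-table style)."""
    if total == 0:
        return 0.0
    exact = Decimal(count) * 100 / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def burden_table(site_counts: Mapping[str, int],
                 groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-group counts and percentages of replicons by site-count category.

    Categories are {0, 1-4, 5-8, >8}; a Total row aggregates all groups.
    Percentages are count / group total x 100, half-up to one decimal.
    """
    missing = set(site_counts) - set(groups)
    if missing:
        raise ValueError(f"replicons without group assignment: {sorted(missing)[:5]}")
    rows = []
    group_order = list(dict.fromkeys(groups[r] for r in site_counts))
    by_group: dict[str, list[int]] = {g: [] for g in group_order}
    for rep, n in site_counts.items():
        by_group[groups[rep]].append(n)
    all_counts: list[int] = list(site_counts.values())
    for g in group_order + ["Total"]:
        counts = all_counts if g == "Total" else by_group[g]
        total = len(counts)
        row: dict = {"group": g, "total": total}
        for cat in BURDEN_CATEGORIES:
            c = sum(1 for n in counts if site_count_category(n) == cat)
            row[f"n_{cat}"] = c
            row[f"pct_{cat}"] = _pct(c, total)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def size_histogram(
    replicons: Sequence[Replicon],
    site_presence: Mapping[str, bool],
    bin_edges_kb: Sequence[float] = DEFAULT_BIN_EDGES_KB,
) -> pd.DataFrame:
    """Replicon size histogram split into with/without detected sites.

    Bins are [edge_i, edge_{i+1}) in kb; replicons beyond the last edge fall
    into an overflow bin.
    """
    edges = list(bin_edges_kb)
    if any(b >= a for a, b in zip(edges[1:], edges)):
        raise ValueError("bin edges must be strictly increasing")
    labels = [f"{a}-{b}" for a, b in zip(edges, edges[1:])] + [f">{edges[-1]}"]
    total = [0] * len(labels)
    with_sites = [0] * len(labels)
    for rep in replicons:
        kb = rep.length / 1000.0
        idx = len(labels) - 1
        for i, (a, b) in enumerate(zip(edges, edges[1:])):
            if a <= kb < b:
                idx = i
                break
        total[idx] += 1
        if site_presence.get(rep.id, False):
            with_sites[idx] += 1
    return pd.DataFrame({"bin_kb": labels, "total": total, "with_sites": with_sites})


def multi_site_report(scans: Sequence[Mapping], cutoff: int = 10) -> pd.DataFrame:
    """Replicons whose total site count (CD + DC) exceeds ``cutoff``.

    ``scans`` rows need keys: strain, replicon, length, n_CD, n_DC and
    optionally accession. Output is sorted by strain then replicon.
    """
    rows = [dict(r) for r in scans if int(r["n_CD"]) + int(r["n_DC"]) > cutoff]
    cols = ["strain", "replicon", "length", "n_CD", "n_DC", "accession"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    if "accession" not in df.columns:
        df["accession"] = ""
    return df[cols].sort_values(["strain", "replicon"]).reset_index(drop=True)


@dataclass
class PositionMap:
    replicon_id: str
    positions: list[float]                  # site midpoints, sorted
    backbone_intervals: Optional[list[tuple[int, int]]]
    backbone_fraction: Optional[float]      # fraction of sites inside backbone
    n_clusters: int                         # site-dense regions (gap rule)


def position_map(
    replicon: Replicon,
    sites: Sequence[DifSite],
    backbone_intervals: Optional[Sequence[tuple[int, int]]] = None,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
) -> PositionMap:
    """Site midpoints, backbone occupancy and site-dense cluster count.

    Clusters are maximal runs of sites whose neighbour gap (circular-aware)
    is at most ``cluster_gap``.
    """
    L = replicon.length
    if backbone_intervals:
        for a, b in backbone_intervals:
            if not (1 <= a <= b <= L):
                raise ValueError(f"backbone interval ({a}, {b}) outside replicon bounds")
    mids = sorted(((s.start + s.end) / 2.0) % L or L for s in sites)
    fraction: Optional[float] = None
    if backbone_intervals is not None and sites:
        inside = sum(1 for m in mids if any(a <= m <= b for a, b in backbone_intervals))
        fraction = inside / len(mids)
    elif backbone_intervals is not None:
        fraction = 0.0

    if not mids:
        n_clusters = 0
    elif len(mids) == 1:
        n_clusters = 1
    else:
        gaps = [b - a for a, b in zip(mids, mids[1:])]
        if replicon.topology == "circular":
            gaps.append(mids[0] + L - mids[-1])
            breaks = sum(1 for g in gaps if g > cluster_gap)
            n_clusters = breaks if breaks > 0 else 1
        else:
            n_clusters = 1 + sum(1 for g in gaps if g > cluster_gap)
    return PositionMap(replicon_id=replicon.id, positions=mids,
                       backbone_intervals=list(map(tuple, backbone_intervals)) if backbone_intervals else None,
                       backbone_fraction=fraction, n_clusters=n_clusters)
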
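"""Per-position nucleotide profiles, information content and group comparison.

For a group of orientation-normalised 28-bp sites, the profile holds
per-position base counts, frequencies, information content
``IC(p) = 2 - H(p)`` (bits, where ``H`` is the Shannon entropy of the
position's base frequencies) and a consensus string. Groups (plasmid pdif
vs chromosomal main dif1 vs additional chromosomal sites) are compared by
per-position Jensen-Shannon divergence, summarised over the fixed site
regions: XerC arm = positions 1-11, central = 12-17, XerD arm = 18-28 in
site-intrinsic orientation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .site_scanner import CENTRAL_SLICE, SITE_LEN, XERC_SLICE, XERD_SLICE, DifSite

BASES = "ACGT"
REGIONS = {"xerC_arm": XERC_SLICE, "central": CENTRAL_SLICE, "xerD_arm": XERD_SLICE}

# two-letter then multi-letter IUPAC codes for consensus ties
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class PositionProfile:
    group_label: str
    n_sites: int
    counts: np.ndarray        # (28, 4) ints; N-containing sites excluded per position
    frequencies: np.ndarray   # (28, 4); rows sum to 1 where any base observed
    info_content: np.ndarray  # (28,) bits in [0, 2]
    consensus: str            # 28 chars; ties as IUPAC ambiguity codes


def _entropy_bits(freq_rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq_rows > 0, freq_rows * np.log2(freq_rows), 0.0)
    return -terms.sum(axis=-1)


def build_profile(
    sites: Sequence[Union[DifSite, str]],
    group_label: str = "",
    small_sample_correction: bool = False,
) -> PositionProfile:
    """Build a per-position profile from orientation-normalised sites.

    Accepts DifSite objects (their intrinsic sequences are used) or raw
    28-mers. Sites with N at a position are excluded from that position's
    denominator. The optional small-sample correction subtracts the standard
    (K-1)/(2 ln 2 n) entropy bias term per position.
    """
    seqs = [s if isinstance(s, str) else s.intrinsic_sequence for s in sites]
    if not seqs:
        raise ValueError("cannot build a profile from zero sites")
    if any(len(s) != SITE_LEN for s in seqs):
        raise ValueError(f"all sites must be {SITE_LEN} bp")
    counts = np.zeros((SITE_LEN, 4), dtype=int)
    for s in seqs:
        for p, b in enumerate(s):
            if b in BASES:
                counts[p, BASES.index(b)] += 1
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, counts / np.maximum(denom, 1), 0.0)
    ic = 2.0 - _entropy_bits(freqs)
    ic[denom[:, 0] == 0] = 0.0
    if small_sample_correction:
        n_eff = np.maximum(denom[:, 0], 1)
        ic = ic - 3.0 / (2.0 * np.log(2.0) * n_eff)
    ic = np.clip(ic, 0.0, 2.0)

    consensus = []
    for p in range(SITE_LEN):
        if denom[p, 0] == 0:
            consensus.append("N")
            continue
        top = counts[p].max()
        tied = frozenset(BASES[b] for b in range(4) if counts[p, b] == top)
        consensus.append(_IUPAC[tied])
    return PositionProfile(group_label=group_label, n_sites=len(seqs), counts=counts,
                           frequencies=freqs, info_content=ic, consensus="".join(consensus))


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Base-2 Jensen-Shannon divergence between frequency rows; in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def _kl(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(a > 0, a * (np.log2(np.maximum(a, 1e-300)) -
                                         np.log2(np.maximum(b, 1e-300))), 0.0)
        return terms.sum(axis=-1)

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


@dataclass
class ProfileComparison:
    label_a: str
    label_b: str
    per_position_jsd: np.ndarray   # (28,)
    region_means: dict             # region -> mean JSD

    @property
    def mean_jsd(self) -> float:
        return float(self.per_position_jsd.mean())


def compare_profiles(a: PositionProfile, b: PositionProfile) -> ProfileComparison:
    """Per-position JSD between two profiles plus per-region means."""
    jsd = jensen_shannon_divergence(a.frequencies, b.frequencies)
    region_means = {name: float(jsd[sl].mean()) for name, sl in REGIONS.items()}
    return ProfileComparison(label_a=a.group_label, label_b=b.group_label,
                             per_position_jsd=jsd, region_means=region_means)


def similarity_report(reference: PositionProfile,
                      others: Sequence[PositionProfile]) -> list[tuple[str, float]]:
    """Rank other groups by similarity to a reference group.

    Returns (group_label, mean per-position JSD) sorted most-similar first.
    """
    if len(others) < 2:
        raise ValueError("similarity ordering requires at least two comparison groups")
    scored = [(o.group_label, compare_profiles(reference, o).mean_jsd) for o in others]
    return sorted(scored, key=lambda t: t[1])


def conservation_ranking(profile: PositionProfile) -> dict:
    """Mean information content per region and the canonical ordering check.

    The expected conservation ordering for dif sites is
    XerD arm >= XerC arm >= central region.
    """
    means = {name: float(profile.info_content[sl].mean()) for name, sl in REGIONS.items()}
    ordering_holds = means["xerD_arm"] >= means["xerC_arm"] >= means["central"]
    return {"region_means": means, "expected_ordering_holds": bool(ordering_holds)}


def profile_to_dict(profile: PositionProfile) -> dict:
    """JSON-serialisable form of a profile."""
    return {
        "group_label": profile.group_label,
        "n_sites": profile.n_sites,
        "counts": profile.counts.tolist(),
        "frequencies": profile.frequencies.round(6).tolist(),
        "info_content": profile.info_content.round(6).tolist(),
        "consensus": profile.consensus,
    }


def render_logo(profile: PositionProfile, path) -> None:
    """Minimal information-content logo as a stacked bar chart (optional output;
    the tested surface is the numeric profile)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(10, 2.5))
    x = np.arange(1, SITE_LEN + 1)
    heights = profile.frequencies * profile.info_content[:, None]
    bottom = np.zeros(SITE_LEN)
    order = np.argsort(profile.frequencies, axis=1)
    for rank in range(4):
        idx = order[:, rank]
        h = heights[np.arange(SITE_LEN), idx]
        cols = [colors[BASES[i]] for i in idx]
        ax.bar(x, h, bottom=bottom, color=cols, width=0.8)
        bottom += h
    for boundary in (11.5, 17.5):
        ax.axvline(boundary, color="grey", ls="--", lw=0.8)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    ax.set_title(f"{profile.group_label} (n={profile.n_sites})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
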
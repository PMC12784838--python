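"""Clustering of filtered 3'-end sites into polyadenylation-site clusters.

Primary clustering is a 24-nt iterative greedy scheme: repeatedly seed a
cluster at the unassigned site with the highest summed count (ties broken
toward the 5'-most site in transcription order) and absorb all unassigned
sites within ±width nt of the seed. The resulting PACs are optionally
refined by weighted density-peak clustering (triangular kernel), which
splits multimodal clusters at density valleys. Each PAC is represented by
its center PAS, the member with the maximal summed count.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from longapa.io import EndSite

DEFAULT_WIDTH = 24


@dataclass
class PAC:
    """A polyadenylation-site cluster.

    Members are stored sorted by genomic position; ``center`` is the
    representative (highest-count) member position. Gene, region and
    known/novel status are attached later by the annotation stage.
    """

    chrom: str
    strand: str
    members: list[EndSite] = field(default_factory=list)
    center: int = -1

    def __post_init__(self) -> None:
        self.members.sort(key=lambda s: s.position)
        if self.center < 0 and self.members:
            self.center = select_center(self)

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].position, self.members[-1].position)

    @property
    def counts(self) -> dict[str, int]:
        agg: dict[str, int] = {}
        for m in self.members:
            for samp, n in m.counts.items():
                agg[samp] = agg.get(samp, 0) + n
        return agg

    @property
    def total(self) -> int:
        return sum(m.total for m in self.members)


def select_center(pac: PAC) -> int:
    """Position of the member with maximal summed count.

    Ties are broken toward the 5'-most member in transcription order
    (lowest coordinate on '+', highest on '-').
    """
    if not pac.members:
        raise ValueError("empty PAC has no center")
    if pac.strand == "+":
        best = max(pac.members, key=lambda m: (m.total, -m.position))
    else:
        best = max(pac.members, key=lambda m: (m.total, m.position))
    return best.position


def cluster_primary(sites: Sequence[EndSite], width: int = DEFAULT_WIDTH) -> list[PAC]:
    """Iterative greedy clustering with a ±``width`` nt absorption radius.

    Deterministic and independent of input order: sites are grouped per
    (chrom, strand) and seeds are taken by decreasing summed count with a
    5'-most tie-break.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    groups: dict[tuple[str, str], list[EndSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)

    pacs: list[PAC] = []
    for (chrom, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda s: s.position)
        pos = [s.position for s in group]
        sign = 1 if strand == "+" else -1
        seed_order = sorted(
            range(len(group)),
            key=lambda i: (-group[i].total, sign * group[i].position),
        )
        assigned = [False] * len(group)
        for i in seed_order:
            if assigned[i]:
                continue
            lo = bisect_left(pos, pos[i] - width)
            hi = bisect_right(pos, pos[i] + width)
            members = []
            for j in range(lo, hi):
                if not assigned[j]:
                    assigned[j] = True
                    members.append(group[j])
            pacs.append(PAC(chrom=chrom, strand=strand, members=members))
    pacs.sort(key=lambda p: (p.chrom, p.span[0], p.strand))
    return pacs


def refine_subpacs(
    pac: PAC,
    bandwidth: float = 8.0,
    min_peak_frac: float = 0.1,
    min_sep: float = 8.0,
) -> list[PAC]:
    """Split a PAC into sub-PACs by weighted density-peak clustering.

    Per member i the weighted density is
    ``rho_i = sum_j count_j * max(0, 1 - |pos_i - pos_j| / bandwidth)``
    (triangular kernel). Peak candidates are members whose density exceeds
    ``min_peak_frac`` of the maximum and whose distance to every
    higher-density member is at least ``min_sep``. Each member is assigned
    to its nearest peak (ties toward the 5'-most peak in transcription
    order). A unimodal PAC is returned unchanged.
    """
    n = len(pac.members)
    if n <= 1:
        return [pac]
    positions = np.array([m.position for m in pac.members], dtype=float)
    counts = np.array([m.total for m in pac.members], dtype=float)
    dist = np.abs(positions[:, None] - positions[None, :])
    rho = (counts[None, :] * np.maximum(0.0, 1.0 - dist / bandwidth)).sum(axis=1)

    # transcription-order rank used to break density ties deterministically
    sign = 1.0 if pac.strand == "+" else -1.0
    order_key = sign * positions
    higher = (rho[None, :] > rho[:, None]) | (
        (rho[None, :] == rho[:, None]) & (order_key[None, :] < order_key[:, None])
    )
    delta = np.where(higher, dist, np.inf).min(axis=1)

    peak_mask = (rho > min_peak_frac * rho.max()) & (delta >= min_sep)
    peaks = np.flatnonzero(peak_mask)
    if len(peaks) <= 1:
        return [pac]

    peak_pos = positions[peaks]
    # assign to nearest peak; tie -> the more 5' peak in transcription order
    d_to_peak = np.abs(positions[:, None] - peak_pos[None, :])
    tie_break = sign * peak_pos[None, :] * 1e-9
    assign = np.argmin(d_to_peak + tie_break, axis=1)

    subpacs = []
    for k in range(len(peaks)):
        members = [pac.members[i] for i in np.flatnonzero(assign == k)]
        if members:
            subpacs.append(PAC(chrom=pac.chrom, strand=pac.strand, members=members))
    subpacs.sort(key=lambda p: p.span[0])
    return subpacs


def cluster_sites(
    sites: Sequence[EndSite],
    width: int = DEFAULT_WIDTH,
    refine: bool = True,
    bandwidth: float = 8.0,
    min_peak_frac: float = 0.1,
    min_sep: float = 8.0,
) -> list[PAC]:
    """Primary clustering followed by optional sub-PAC refinement."""
    pacs = cluster_primary(sites, width=width)
    if not refine:
        return pacs
    refined: list[PAC] = []
    for pac in pacs:
        refined.extend(refine_subpacs(pac, bandwidth, min_peak_frac, min_sep))
    refined.sort(key=lambda p: (p.chrom, p.span[0], p.strand))
    return refined
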
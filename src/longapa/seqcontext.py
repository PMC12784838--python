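"""Sequence-context quality control of polyadenylation sites.

Genuine cleavage sites carry a hexamer polyadenylation signal (canonical
AATAAA, variant ATTAAA) typically 20-30 nt upstream, and a characteristic
nucleotide composition around the cleavage base. This module extracts
strand-oriented upstream flanks, profiles base composition around center
PASs, and scores exact k-mer enrichment (k = 4..6) against dinucleotide-
shuffled backgrounds — a transparent containment statistic standing in
for PWM-based motif discovery, with the positional density of the
canonical signal reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from longapa.io import revcomp

FLANK_LENGTH = 50
PROFILE_HALFWIDTH = 100
CANONICAL_SIGNAL = "AATAAA"
VARIANT_SIGNAL = "ATTAAA"


@dataclass
class FlankSet:
    """Strand-oriented upstream flank sequences, one per PAS."""

    sequences: list[str] = field(default_factory=list)
    clipped: list[bool] = field(default_factory=list)
    length: int = FLANK_LENGTH


def extract_flanks(
    sites: Sequence[tuple[str, str, int]],
    genome: Mapping[str, str],
    length: int = FLANK_LENGTH,
) -> FlankSet:
    """Extract the ``length``-nt sense-strand sequence upstream of each PAS.

    The flank excludes the cleavage base itself: on '+' it is
    ``genome[pos-length:pos]``, on '-' the reverse complement of
    ``genome[pos+1:pos+1+length]``. Chromosome-boundary flanks are
    truncated and flagged clipped.
    """
    flanks = FlankSet(length=length)
    for chrom, strand, pos in sites:
        seq = genome[chrom]
        if strand == "+":
            lo, hi = pos - length, pos
            sub = seq[max(lo, 0):hi]
            clipped = lo < 0
        else:
            lo, hi = pos + 1, pos + 1 + length
            sub = revcomp(seq[lo:min(hi, len(seq))])
            clipped = hi > len(seq)
        flanks.sequences.append(sub.upper())
        flanks.clipped.append(clipped)
    return flanks


def nt_profile(
    sites: Sequence[tuple[str, str, int]],
    genome: Mapping[str, str],
    halfwidth: int = PROFILE_HALFWIDTH,
) -> pd.DataFrame:
    """Base-frequency matrix over offsets [-halfwidth, +halfwidth].

    Offset 0 is the cleavage base; negative offsets are upstream in
    transcription orientation. Frequencies are normalized per offset over
    A/C/G/T (N excluded), so each row sums to 1 wherever any base was
    observed.
    """
    width = 2 * halfwidth + 1
    counts = {b: np.zeros(width, dtype=int) for b in "ACGT"}
    for chrom, strand, pos in sites:
        seq = genome[chrom]
        n = len(seq)
        for k in range(width):
            off = k - halfwidth
            g = pos + off if strand == "+" else pos - off
            if 0 <= g < n:
                base = seq[g].upper()
                if strand == "-":
                    base = revcomp(base)
                if base in counts:
                    counts[base][k] += 1
    mat = pd.DataFrame(counts, index=pd.Index(range(-halfwidth, halfwidth + 1), name="offset"))
    totals = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = mat.div(totals.replace(0, np.nan), axis=0)
    return freq


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson Euler-path shuffle: edges of the dinucleotide
    multigraph are permuted, one randomly chosen last-edge per vertex is
    retained so that a walk from the first to the last symbol exists.
    """
    if len(seq) < 3:
        return seq
    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)

    # pick a random "last edge" per vertex (except the terminal one) such
    # that following last-edges from every vertex reaches the terminal
    for _ in range(1000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen, cur = {v}, v
            while ok and cur != last:
                nxt = last_edge.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                elif nxt == last or nxt in edges:
                    seen.add(nxt)
                    cur = nxt
                else:
                    ok = False
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - cannot happen for connected sequences
        return seq

    out_lists = {}
    for v in vertices:
        remaining = list(edges[v])
        if v != last:
            remaining.remove(last_edge[v])
        perm = rng.permutation(len(remaining))
        shuffled = [remaining[i] for i in perm]
        if v != last:
            shuffled.append(last_edge[v])
        out_lists[v] = shuffled

    result = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def _containment(seqs: Sequence[str], kmers: Sequence[str]) -> dict[str, int]:
    present = {k: 0 for k in kmers}
    lens = sorted({len(k) for k in kmers})
    for seq in seqs:
        seen = set()
        for L in lens:
            for i in range(len(seq) - L + 1):
                seen.add(seq[i:i + L])
        for k in kmers:
            if k in seen:
                present[k] += 1
    return present


def kmer_enrichment(
    flanks: FlankSet,
    k_min: int = 4,
    k_max: int = 6,
    n_shuffles: int = 10,
    seed: int = 0,
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exact k-mer containment enrichment over upstream flanks.

    For every k-mer (k in [k_min, k_max]) the foreground fraction of
    flanks containing it is tested one-sidedly (binomial, greater)
    against the containment rate in the background — by default
    ``n_shuffles`` seeded dinucleotide shuffles of each flank. The report
    is ranked by log survival p-value (ties by foreground fraction, then
    background fraction, then k-mer). Needs ≥10 flanks; an empty flank
    set yields an empty report.
    """
    seqs = list(flanks.sequences)
    if not seqs:
        return pd.DataFrame(
            columns=["kmer", "k", "fg_frac", "bg_frac", "p", "log10_p", "q"]
        )
    if len(seqs) < 10:
        raise ValueError(f"kmer_enrichment needs >= 10 flanks, got {len(seqs)}")

    if background is None:
        rng = np.random.default_rng(seed)
        background = [
            dinucleotide_shuffle(s, rng) for s in seqs for _ in range(n_shuffles)
        ]
    background = list(background)

    kmers = [
        "".join(t)
        for k in range(k_min, k_max + 1)
        for t in product("ACGT", repeat=k)
    ]
    fg = _containment(seqs, kmers)
    bg = _containment(background, kmers)
    n_fg, n_bg = len(seqs), len(background)

    rows = []
    for kmer in kmers:
        k_obs = fg[kmer]
        p0 = (bg[kmer] + 1) / (n_bg + 2)  # Laplace-smoothed background rate
        logsf = stats.binom.logsf(k_obs - 1, n_fg, p0)
        pval = float(np.exp(logsf))
        rows.append(
            {
                "kmer": kmer,
                "k": len(kmer),
                "fg_frac": k_obs / n_fg,
                "bg_frac": bg[kmer] / n_bg,
                "p": pval,
                "log10_p": float(logsf / np.log(10)),
            }
        )
    report = pd.DataFrame(rows)
    report["q"] = stats.false_discovery_control(
        report["p"].clip(lower=0.0, upper=1.0), method="bh"
    )
    report = report.sort_values(
        ["log10_p", "fg_frac", "bg_frac", "kmer"],
        ascending=[True, False, True, True],
    ).reset_index(drop=True)
    return report


def signal_density(flanks: FlankSet, motif: str = CANONICAL_SIGNAL) -> pd.DataFrame:
    """Positional histogram of motif starts upstream of the PAS.

    Offsets are motif start minus PAS position in sense orientation
    (upstream = negative), covering [-length, -1]; every occurrence in
    every flank is counted.
    """
    length = flanks.length
    counts = np.zeros(length, dtype=int)  # index 0 -> offset -length
    m = len(motif)
    for seq in flanks.sequences:
        shift = length - len(seq)  # clipped flanks start later
        for i in range(len(seq) - m + 1):
            if seq[i:i + m] == motif:
                counts[i + shift] += 1
    return pd.DataFrame(
        {"offset": np.arange(-length, 0), "count": counts}
    )
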
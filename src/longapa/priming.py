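"""Internal-priming artifact detection.

Oligo(dT) primers can anneal to genomically encoded A-rich stretches inside
a transcript, producing spurious 3'-end signals. A raw end site is flagged
as an internal-priming artifact when the sense-strand sequence spanning
10 nt upstream and downstream of the site (a 21-nt window including the
site base) contains ≥6 consecutive adenines, or ≥7 adenines within any
10-nt sliding window. The scan runs on the transcription-strand sequence,
so genomic T-runs under minus-strand genes are caught as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from longapa.io import EndSite, revcomp

#: thresholds of the A-content rules
RUN_THRESHOLD = 6
WINDOW_COUNT_THRESHOLD = 7
WINDOW_SIZE = 10
FLANK = 10  # nt on each side of the site base


@dataclass
class PrimingVerdict:
    """Classification of one end site under the A-content rules."""

    site: EndSite
    window_sequence: str
    max_A_run: int
    max_A_in_10nt: int
    is_artifact: bool
    clipped: bool = False


def extract_window(
    site: EndSite, genome: Mapping[str, str], flank: int = FLANK
) -> tuple[str, bool]:
    """Sense-strand sequence ``flank`` nt up- and downstream of the site.

    Returns ``(sequence, clipped)``; the window is truncated (and flagged
    clipped) at chromosome boundaries. Minus-strand windows are
    reverse-complemented so the returned string always reads 5'→3' in
    transcription orientation.
    """
    try:
        chrom_seq = genome[site.chrom]
    except KeyError:
        raise KeyError(f"chromosome {site.chrom!r} not present in genome") from None
    n = len(chrom_seq)
    lo, hi = site.position - flank, site.position + flank + 1
    clipped = lo < 0 or hi > n
    seq = chrom_seq[max(lo, 0): min(hi, n)].upper()
    if site.strand == "-":
        seq = revcomp(seq)
    return seq, clipped


def classify_priming(
    seq: str,
    run_threshold: int = RUN_THRESHOLD,
    window_count_threshold: int = WINDOW_COUNT_THRESHOLD,
    window_size: int = WINDOW_SIZE,
) -> tuple[int, int, bool]:
    """Apply the A-content rules to a window sequence.

    Returns ``(max_A_run, max_A_in_10nt, is_artifact)``. Only uppercase
    'A' counts as adenine (N and soft-masked bases never do). Sequences
    shorter than the sliding window are scanned as a single window.
    """
    seq = seq.upper()
    max_run = run = 0
    for base in seq:
        run = run + 1 if base == "A" else 0
        max_run = max(max_run, run)

    is_a = [1 if b == "A" else 0 for b in seq]
    if len(seq) <= window_size:
        max_in_win = sum(is_a)
    else:
        cur = sum(is_a[:window_size])
        max_in_win = cur
        for i in range(window_size, len(seq)):
            cur += is_a[i] - is_a[i - window_size]
            max_in_win = max(max_in_win, cur)
    artifact = max_run >= run_threshold or max_in_win >= window_count_threshold
    return max_run, max_in_win, artifact


def filter_sites(
    sites: Sequence[EndSite],
    genome: Mapping[str, str],
    run_threshold: int = RUN_THRESHOLD,
    window_count_threshold: int = WINDOW_COUNT_THRESHOLD,
) -> tuple[list[EndSite], list[EndSite], pd.DataFrame]:
    """Partition sites into (kept, artifacts) and tabulate the verdicts.

    The partition is exhaustive and disjoint; the verdict table has one
    row per input site.
    """
    kept: list[EndSite] = []
    artifacts: list[EndSite] = []
    rows = []
    for site in sites:
        seq, clipped = extract_window(site, genome)
        max_run, max_in_win, is_art = classify_priming(
            seq, run_threshold, window_count_threshold
        )
        (artifacts if is_art else kept).append(site)
        rows.append(
            (site.chrom, site.strand, site.position, seq, max_run, max_in_win,
             is_art, clipped)
        )
    verdicts = pd.DataFrame(
        rows,
        columns=["chrom", "strand", "position", "window_sequence", "max_A_run",
                 "max_A_in_10nt", "is_artifact", "clipped"],
    )
    return kept, artifacts, verdicts
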
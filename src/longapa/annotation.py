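"""Genomic annotation of PACs and matching against a reference PAS table.

Each PAC is assigned to a gene and a genomic region by the position of its
center PAS; overlapping annotations resolve with precedence
3UTR > exon/CDS > intron > 5UTR (polyadenylation evidence most plausibly
terminates a 3'UTR). Centers up to ``extension`` nt downstream of an
annotated transcript end are treated as unannotated distal 3UTR sites.
Known/novel status comes from the signed distance to the nearest
same-strand reference PAS (PolyA_DB-style table).
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from longapa.clustering import PAC
from longapa.io import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_EXON,
    REGION_INTERGENIC,
    REGION_INTRON,
    GeneModel,
)

DEFAULT_MATCH_WINDOW = 24
DEFAULT_EXTENSION = 1000

_PRECEDENCE = {REGION_3UTR: 0, REGION_EXON: 1, REGION_INTRON: 2, REGION_5UTR: 3}

STATUS_EXACT = "exact_match"
STATUS_MATCHED = "matched"
STATUS_NOVEL = "novel"


@dataclass
class AnnotatedPAC:
    """A PAC with gene/region assignment and reference-matching status."""

    pac: PAC
    gene_id: str | None
    region: str
    nearest_ref_distance: float = math.inf
    status: str = STATUS_NOVEL


class GeneIndex:
    """Per-(chrom, strand) interval index over gene spans (with extension)."""

    def __init__(self, models: Sequence[GeneModel], extension: int = DEFAULT_EXTENSION):
        self.extension = extension
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            lo, hi = m.span
            if m.strand == "+":
                hi += extension
            else:
                lo -= extension
            tree = self.trees.setdefault((m.chrom, m.strand), IntervalTree())
            tree[max(lo, 0): hi] = m

    def candidates(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        tree = self.trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]


def _region_in_gene(model: GeneModel, pos: int, extension: int) -> str | None:
    """Region label of ``pos`` within one gene, or None if outside."""
    lo, hi = model.span
    if lo <= pos < hi:
        for a, b, lab in model.intervals:
            if a <= pos < b:
                return REGION_EXON if lab == "CDS" else lab
        return None
    # downstream extension: unannotated distal 3'UTR
    if model.strand == "+" and 0 < pos - model.tx_end <= extension:
        return REGION_3UTR
    if model.strand == "-" and 0 < model.tx_end - pos <= extension:
        return REGION_3UTR
    return None


def assign_region(
    pac: PAC, index: GeneIndex, extension: int | None = None
) -> tuple[str | None, str]:
    """Assign ``(gene_id, region)`` to a PAC by its center position.

    When several same-strand genes cover the center, the label with the
    highest precedence wins; remaining ties resolve to the
    lexicographically smallest gene id for determinism.
    """
    ext = index.extension if extension is None else extension
    best: tuple[int, str, str] | None = None
    for model in index.candidates(pac.chrom, pac.strand, pac.center):
        region = _region_in_gene(model, pac.center, ext)
        if region is None:
            continue
        key = (_PRECEDENCE[region], model.gene_id, region)
        if best is None or key < best:
            best = key
    if best is None:
        return None, REGION_INTERGENIC
    return best[1], best[2]


def match_reference(
    pacs: Sequence[AnnotatedPAC],
    refs: Sequence[tuple[str, str, int]],
    match_window: int = DEFAULT_MATCH_WINDOW,
) -> pd.DataFrame:
    """Set known/novel status in place and return a distance histogram.

    ``nearest_ref_distance`` is the signed transcription-order distance
    from the center PAS to the closest same-strand reference site
    (positive = center lies downstream of the reference). Status is
    ``exact_match`` at distance 0, ``matched`` within ±``match_window``,
    ``novel`` otherwise (or with an empty reference).
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, pos in refs:
        by_key.setdefault((chrom, strand), []).append(pos)
    for positions in by_key.values():
        positions.sort()

    distances = []
    for ap in pacs:
        positions = by_key.get((ap.pac.chrom, ap.pac.strand))
        if not positions:
            ap.nearest_ref_distance = math.inf
            ap.status = STATUS_NOVEL
            continue
        center = ap.pac.center
        i = bisect_left(positions, center)
        # candidates around the insertion point; tie -> the more 5' reference
        cand = []
        if i > 0:
            cand.append(positions[i - 1])
        if i < len(positions):
            cand.append(positions[i])
        sign = 1 if ap.pac.strand == "+" else -1
        ref = min(cand, key=lambda r: (abs(center - r), sign * r))
        d = sign * (center - ref)
        ap.nearest_ref_distance = d
        if d == 0:
            ap.status = STATUS_EXACT
        elif abs(d) <= match_window:
            ap.status = STATUS_MATCHED
        else:
            ap.status = STATUS_NOVEL
        distances.append(d)

    hist = (
        pd.Series(distances, dtype=float)
        .value_counts()
        .rename_axis("distance")
        .sort_index()
        .rename("n_pacs")
        .reset_index()
    )
    return hist


def annotate_pacs(
    pacs: Sequence[PAC],
    models: Sequence[GeneModel],
    refs: Sequence[tuple[str, str, int]] | None = None,
    match_window: int = DEFAULT_MATCH_WINDOW,
    extension: int = DEFAULT_EXTENSION,
) -> tuple[list[AnnotatedPAC], pd.DataFrame]:
    """Assign gene/region to every PAC and match against the reference."""
    index = GeneIndex(models, extension=extension)
    annotated = []
    for pac in pacs:
        gene, region = assign_region(pac, index)
        annotated.append(AnnotatedPAC(pac=pac, gene_id=gene, region=region))
    hist = match_reference(annotated, refs or [], match_window=match_window)
    return annotated, hist
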
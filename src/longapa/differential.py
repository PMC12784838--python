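"""Differential PAS-usage statistics: PSU, DPUI, Wald test, RED, patterns.

For one comparison (treatment stage vs control stage):

* a gene is retained when it has at least ``min_pas`` PACs whose summed
  read count exceeds ``min_reads`` in *each* group;
* PSU (percentage of site usage) of a PAC in a sample is its count divided
  by the summed count of all retained PACs of the same gene in that sample;
* DPUI = mean PSU over treatment replicates − mean PSU over control
  replicates, per PAC;
* significance is a two-proportion Wald test on group-pooled counts;
  events with |DPUI| ≥ 0.05 and p ≤ 0.05 are differential APA events;
* for genes with ≥2 3'UTR PACs and a significant 3'UTR event, the two
  PACs with the largest |DPUI| give RED = DPUI_distal − DPUI_proximal;
  RED ≥ 0.05 calls 3'UTR lengthening, RED ≤ −0.05 shortening;
* across two ordered comparisons, genes fall into four dynamic patterns:
  1 = (lengthening, lengthening), 2 = (lengthening, shortening),
  3 = (shortening, shortening), 4 = (shortening, lengthening).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from longapa.annotation import AnnotatedPAC
from longapa.io import REGION_3UTR, GeneModel

DPUI_THRESHOLD = 0.05
P_THRESHOLD = 0.05
RED_THRESHOLD = 0.05
MIN_READS = 5
MIN_PAS = 2

LENGTHENING = "lengthening"
SHORTENING = "shortening"
UNCLASSIFIED = "unclassified"

#: (direction in comparison 1, direction in comparison 2) -> pattern label
PATTERN_MAP = {
    (LENGTHENING, LENGTHENING): "1",
    (LENGTHENING, SHORTENING): "2",
    (SHORTENING, SHORTENING): "3",
    (SHORTENING, LENGTHENING): "4",
}


def pac_count_table(pacs: Sequence[AnnotatedPAC], samples: Sequence[str]) -> pd.DataFrame:
    """Per-PAC count table with gene/region metadata.

    Intergenic PACs (no gene) are excluded from gene-level statistics.
    Index is (gene, center); columns are region/chrom/strand plus one count
    column per sample.
    """
    rows = []
    for ap in pacs:
        if ap.gene_id is None:
            continue
        counts = ap.pac.counts
        rows.append(
            {
                "gene": ap.gene_id,
                "center": ap.pac.center,
                "region": ap.region,
                "chrom": ap.pac.chrom,
                "strand": ap.pac.strand,
                "status": ap.status,
                **{s: counts.get(s, 0) for s in samples},
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "center", "region", "chrom", "strand", "status", *samples]
        ).set_index(["gene", "center"])
    df = pd.DataFrame(rows).sort_values(["gene", "center"])
    return df.set_index(["gene", "center"])


def retain_genes(
    table: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    min_reads: int = MIN_READS,
    min_pas: int = MIN_PAS,
) -> pd.DataFrame:
    """Rows qualifying for one comparison.

    A PAC qualifies when its summed count strictly exceeds ``min_reads``
    in each of the two groups; a gene is retained when it has at least
    ``min_pas`` qualifying PACs. Returns the qualifying rows of retained
    genes.
    """
    ka = table[list(samples_a)].sum(axis=1)
    kb = table[list(samples_b)].sum(axis=1)
    qual = table[(ka > min_reads) & (kb > min_reads)]
    n_per_gene = qual.groupby(level="gene").size()
    keep = n_per_gene[n_per_gene >= min_pas].index
    return qual[qual.index.get_level_values("gene").isin(keep)]


def compute_psu(table: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Per-sample PSU matrix over the rows of ``table``.

    PSU = count / gene total in that sample; a zero gene total leaves the
    PSU missing (NaN), excluded from group means downstream.
    """
    counts = table[list(samples)].astype(float)
    totals = counts.groupby(level="gene").transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psu = counts / totals
    return psu


def wald_test(k1, n1, k2, n2):
    """Two-sided two-proportion Wald test on pooled group counts.

    ``z = (k1/n1 - k2/n2) / sqrt(v1 + v2)`` with unpooled variance terms
    ``v = p(1-p)/n``; degenerate proportions (k = 0 or k = n) enter the
    variance as 0.5/n (resp. 1 - 0.5/n) so the test remains defined.
    Vectorized; returns NaN where a group total is zero.
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = k1 / n1
        p2 = k2 / n2
        pv1 = np.where((k1 <= 0) | (k1 >= n1), 0.5 / n1, p1)
        pv2 = np.where((k2 <= 0) | (k2 >= n2), 0.5 / n2, p2)
        v = pv1 * (1 - pv1) / n1 + pv2 * (1 - pv2) / n2
        z = (p1 - p2) / np.sqrt(v)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where((n1 <= 0) | (n2 <= 0), np.nan, p)
    if p.ndim == 0:
        return float(p)
    return p


def call_events(
    table: pd.DataFrame,
    samples_by_stage: Mapping[str, Sequence[str]],
    treat: str,
    ctrl: str,
    min_reads: int = MIN_READS,
    min_pas: int = MIN_PAS,
    dpui_threshold: float = DPUI_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Differential APA events for one comparison (``treat`` vs ``ctrl``).

    Returns one row per retained (gene, PAC): DPUI, raw Wald p-value, a
    BH-adjusted q-value (reported as an extra column; the significance
    call uses the raw p, mirroring the headline thresholds), and the
    boolean ``significant``.
    """
    s_treat = list(samples_by_stage[treat])
    s_ctrl = list(samples_by_stage[ctrl])
    retained = retain_genes(table, s_treat, s_ctrl, min_reads, min_pas)
    if retained.empty:
        return pd.DataFrame(
            columns=["region", "chrom", "strand", "status", "dpui", "p", "q",
                     "significant"],
            index=retained.index,
        )
    psu = compute_psu(retained, s_treat + s_ctrl)
    dpui = psu[s_treat].mean(axis=1, skipna=True) - psu[s_ctrl].mean(axis=1, skipna=True)

    k1 = retained[s_treat].sum(axis=1).to_numpy()
    k2 = retained[s_ctrl].sum(axis=1).to_numpy()
    n1 = retained[s_treat].sum(axis=1).groupby(retained.index.get_level_values("gene")).transform("sum").to_numpy()
    n2 = retained[s_ctrl].sum(axis=1).groupby(retained.index.get_level_values("gene")).transform("sum").to_numpy()
    p = wald_test(k1, n1, k2, n2)

    events = retained[["region", "chrom", "strand", "status"]].copy()
    events["dpui"] = dpui
    events["p"] = p
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = stats.false_discovery_control(p[finite], method="bh")
    events["q"] = q
    events["significant"] = (
        (events["dpui"].abs() >= dpui_threshold) & (events["p"] <= p_threshold)
    ).fillna(False)
    return events


def _tx_distance_to_terminal(center: int, model: GeneModel) -> float:
    """Transcription-order distance from a 3'UTR center to the terminal-exon
    anchor (3' end of the last CDS; transcript 5' end for non-coding genes)."""
    anchor = model.cds_anchor
    if anchor is None:
        anchor = model.span[0] if model.strand == "+" else model.span[1] - 1
    return (center - anchor) if model.strand == "+" else (anchor - center)


def call_red(
    events: pd.DataFrame,
    models: Mapping[str, GeneModel],
    red_threshold: float = RED_THRESHOLD,
) -> pd.DataFrame:
    """RED-based 3'UTR lengthening/shortening calls, one row per gene.

    Considers genes with ≥2 3'UTR PACs and at least one significant 3'UTR
    event; selects the two PACs with the largest |DPUI| (ties toward the
    transcriptionally 5' PAC), orients them proximal/distal by distance to
    the terminal exon, and applies the ±``red_threshold`` direction rule.
    """
    rows = []
    utr = events[events["region"] == REGION_3UTR]
    for gene, sub in utr.groupby(level="gene", sort=True):
        if len(sub) < 2 or not sub["significant"].any():
            continue
        model = models[gene]
        sub = sub.reset_index()
        sign = 1 if model.strand == "+" else -1
        sub = sub.sort_values(
            ["dpui", "center"],
            key=lambda col: -col.abs() if col.name == "dpui" else sign * col,
        )
        top2 = sub.iloc[:2]
        d = top2["center"].map(lambda c: _tx_distance_to_terminal(int(c), model))
        prox = top2.loc[d.idxmin()]
        dist = top2.loc[d.idxmax()]
        red = float(dist["dpui"] - prox["dpui"])
        if red >= red_threshold:
            direction = LENGTHENING
        elif red <= -red_threshold:
            direction = SHORTENING
        else:
            direction = UNCLASSIFIED
        rows.append(
            {
                "gene": gene,
                "proximal_center": int(prox["center"]),
                "distal_center": int(dist["center"]),
                "dpui_proximal": float(prox["dpui"]),
                "dpui_distal": float(dist["dpui"]),
                "red": red,
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "proximal_center", "distal_center", "dpui_proximal",
                 "dpui_distal", "red", "direction"],
    )


def classify_patterns(red1: pd.DataFrame, red2: pd.DataFrame) -> pd.DataFrame:
    """Four-pattern classification across two ordered comparisons.

    Pattern "1" = persistent lengthening, "2" = lengthening then
    shortening, "3" = persistent shortening, "4" = shortening then
    lengthening; genes lacking a lengthening/shortening call in either
    comparison get "none". The five labels partition the gene universe.
    """
    d1 = red1.set_index("gene")["direction"] if len(red1) else pd.Series(dtype=object)
    d2 = red2.set_index("gene")["direction"] if len(red2) else pd.Series(dtype=object)
    genes = sorted(set(d1.index) | set(d2.index))
    rows = []
    for gene in genes:
        dir1 = d1.get(gene, None)
        dir2 = d2.get(gene, None)
        pattern = PATTERN_MAP.get((dir1, dir2), "none")
        rows.append({"gene": gene, "direction_1": dir1, "direction_2": dir2,
                     "pattern": pattern})
    return pd.DataFrame(rows, columns=["gene", "direction_1", "direction_2", "pattern"])
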
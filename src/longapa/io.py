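"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
All positions are stored 0-based internally. BED input/output is 0-based
half-open (the BED standard); GTF input/output is 1-based inclusive and is
converted exactly once at the file boundary. An end site's ``position`` is
the genomic coordinate of the transcriptionally *last* base of the read:
for minus-strand reads that is the genomic 5'-most base, so proximal/distal
comparisons are strand-uniform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: region labels, in the precedence order used for overlapping annotations
REGION_3UTR = "3UTR"
REGION_EXON = "exon"
REGION_INTRON = "intron"
REGION_5UTR = "5UTR"
REGION_INTERGENIC = "intergenic"


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class EndSite:
    """One observed read 3'-end position with per-sample counts."""

    chrom: str
    strand: str
    position: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def key(self) -> tuple[str, str, int]:
        return (self.chrom, self.strand, self.position)


@dataclass
class GeneModel:
    """One gene, represented by a single representative transcript.

    ``intervals`` are ``(start, end, label)`` triples, 0-based half-open
    genomic coordinates, listed in transcription order (5'→3'); labels are
    ``5UTR``/``CDS``/``intron``/``3UTR`` for coding genes, ``exon``/``intron``
    for non-coding ones. ``tx_end`` is the genomic coordinate of the
    transcriptionally last base; ``cds_anchor`` the transcription-order 3'
    end of the last CDS (None for non-coding genes).
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int, str]]
    terminal_exon: tuple[int, int]
    tx_end: int
    coding: bool
    cds_anchor: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        starts = [a for a, _, _ in self.intervals]
        ends = [b for _, b, _ in self.intervals]
        return (min(starts), max(ends))


# ---------------------------------------------------------------------------
# genome FASTA

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a dict chrom → uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(genome[c]), id=c, description="") for c in sorted(genome)]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# end-site BED

def _parse_bed6(path: str | Path, need_score: bool) -> Iterable[tuple[int, str, int, int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(f)}")
            try:
                start = int(f[1])
                score = int(f[4]) if need_score else 0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            strand = f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative position {start}")
            if need_score and score < 0:
                raise ValueError(f"{path}:{lineno}: negative count {score}")
            yield lineno, f[0], start, score, strand


def read_endsites(path: str | Path, sample_id: str) -> list[EndSite]:
    """Read one sample's 3'-end BED (score column = read count).

    Duplicate (chrom, strand, position) records are merged by summing
    counts; zero-count sites are dropped. Returns sites sorted by
    (chrom, position, strand).
    """
    merged: dict[tuple[str, str, int], int] = {}
    for _, chrom, start, score, strand in _parse_bed6(path, need_score=True):
        key = (chrom, strand, start)
        merged[key] = merged.get(key, 0) + score
    sites = [
        EndSite(c, s, p, {sample_id: n})
        for (c, s, p), n in merged.items()
        if n > 0
    ]
    sites.sort(key=lambda x: (x.chrom, x.position, x.strand))
    return sites


def merge_endsites(collections: Iterable[Sequence[EndSite]]) -> list[EndSite]:
    """Merge per-sample site collections into one multi-sample collection."""
    merged: dict[tuple[str, str, int], dict[str, int]] = {}
    for coll in collections:
        for site in coll:
            counts = merged.setdefault(site.key(), {})
            for samp, n in site.counts.items():
                counts[samp] = counts.get(samp, 0) + n
    out = [EndSite(c, s, p, counts) for (c, s, p), counts in merged.items()]
    out.sort(key=lambda x: (x.chrom, x.position, x.strand))
    return out


def write_endsites(sites: Sequence[EndSite], path: str | Path, sample_id: str | None = None) -> None:
    """Write sites as BED6; score = count of ``sample_id`` (or the total)."""
    rows = sorted(sites, key=lambda x: (x.chrom, x.position, x.strand))
    with open(path, "w") as fh:
        for s in rows:
            n = s.counts.get(sample_id, 0) if sample_id is not None else s.total
            name = sample_id if sample_id is not None else "."
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{name}\t{n}\t{s.strand}\n")


# ---------------------------------------------------------------------------
# reference PAS BED

def read_refpas(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a reference PAS BED into deduplicated (chrom, strand, position)."""
    seen = set()
    for _, chrom, start, _, strand in _parse_bed6(path, need_score=False):
        seen.add((chrom, strand, start))
    return sorted(seen)


def write_refpas(refs: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, strand, pos in sorted(set(refs)):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# gene-model GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_genemodels(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into one :class:`GeneModel` per gene.

    The representative transcript per gene is the one with the 3'-most
    annotated end in transcription order (ties broken by span length).
    Introns are derived as gaps between consecutive exons; exon stretches
    are split into 5UTR/CDS/3UTR using the transcript's UTR and CDS
    features when present, otherwise labeled plain ``exon`` and the gene
    is flagged non-coding.
    """
    # transcript_id -> feature -> list of (start0, end0)
    tx_feats: dict[str, dict[str, list[tuple[int, int]]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attr = f[:9]
            if feature in ("gene", "transcript"):
                continue
            attrs = _parse_attrs(attr)
            tx = attrs.get("transcript_id")
            gene = attrs.get("gene_id")
            if tx is None or gene is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id")
            tx_meta[tx] = (gene, chrom, strand)
            tx_feats.setdefault(tx, {}).setdefault(feature, []).append(
                (int(start) - 1, int(end))
            )

    # choose representative transcript per gene
    by_gene: dict[str, list[str]] = {}
    for tx, (gene, _, _) in tx_meta.items():
        by_gene.setdefault(gene, []).append(tx)

    models = []
    for gene in sorted(by_gene):
        def _rank(tx: str) -> tuple[int, int, str]:
            exons = sorted(tx_feats[tx].get("exon", []))
            if not exons:
                return (-(10**12), 0, tx)
            strand = tx_meta[tx][2]
            lo, hi = exons[0][0], exons[-1][1]
            end3 = hi - 1 if strand == "+" else -lo  # bigger = more 3'
            return (end3, hi - lo, tx)

        tx = max(sorted(by_gene[gene]), key=_rank)
        _, chrom, strand = tx_meta[tx]
        feats = tx_feats[tx]
        exons = sorted(feats.get("exon", []))
        if not exons:
            continue
        cds = sorted(feats.get("CDS", []))
        utr5 = sorted(feats.get("five_prime_utr", []))
        utr3 = sorted(feats.get("three_prime_utr", []))
        coding = bool(cds)

        labeled: list[tuple[int, int, str]] = []
        for a, b in exons:
            pieces = []
            for lab, ivs in ((REGION_5UTR, utr5), ("CDS", cds), (REGION_3UTR, utr3)):
                for s, e in ivs:
                    s2, e2 = max(a, s), min(b, e)
                    if s2 < e2:
                        pieces.append((s2, e2, lab))
            if not pieces:
                pieces = [(a, b, REGION_EXON)]
            else:
                # fill unannotated exon gaps
                pieces.sort()
                filled, cur = [], a
                for s, e, lab in pieces:
                    if s > cur:
                        filled.append((cur, s, REGION_EXON))
                    filled.append((s, e, lab))
                    cur = max(cur, e)
                if cur < b:
                    filled.append((cur, b, REGION_EXON))
                pieces = filled
            labeled.extend(pieces)
        # introns from exon gaps
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 > b1:
                labeled.append((b1, a2, REGION_INTRON))
        labeled.sort()
        if strand == "-":
            labeled = labeled[::-1]

        terminal_exon = exons[-1] if strand == "+" else exons[0]
        tx_end = exons[-1][1] - 1 if strand == "+" else exons[0][0]
        cds_anchor = None
        if coding:
            cds_anchor = cds[-1][1] - 1 if strand == "+" else cds[0][0]
        models.append(
            GeneModel(
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                intervals=labeled,
                terminal_exon=terminal_exon,
                tx_end=tx_end,
                coding=coding,
                cds_anchor=cds_anchor,
            )
        )
    return models


def write_gtf(records: Sequence[tuple[str, str, int, int, str, str]], path: str | Path) -> None:
    """Write GTF rows given as (chrom, feature, start0, end0, strand, attributes).

    Coordinates are converted to 1-based inclusive here, exactly once.
    """
    with open(path, "w") as fh:
        for chrom, feature, start0, end0, strand, attrs in records:
            fh.write(
                f"{chrom}\tlongapa\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"
            )
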
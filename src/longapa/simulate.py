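"""Synthetic long-read 3'-end data with full ground truth.

The generator emulates the data-generating process behind oligo(dT)-primed
long-read 3'-end sequencing across ordered differentiation stages:

* genes with 5'UTR / CDS exons / intron / 3'UTR structure on both strands;
* one to three true PASs per gene inside the 3'UTR, with stage-specific
  usage proportions that plant the four 3'UTR dynamic patterns
  (persistent lengthening, lengthening→shortening, persistent shortening,
  shortening→lengthening) plus stable genes;
* a canonical AATAAA signal planted a fixed offset upstream of every
  non-artifact true PAS on the sense strand;
* optionally, a constant-usage intronic PAS in a subset of genes
  (upstream-region APA), exercising intron annotation downstream;
* internal-priming traps: a subset of genes carries an extra site sitting
  in a genomic A-run, guaranteed to fail the priming filter;
* per-replicate read sampling: Poisson gene depth, multinomial allocation
  across sites by stage usage, and discretized Gaussian jitter of the
  read end around the true PAS.

Outputs are a genome FASTA, a gene-model GTF, a reference-PAS BED
containing a configurable subset of the true sites, per-sample 3'-end
BEDs, and a :class:`TruthTable` with per-site usage and per-gene expected
direction/pattern labels — a deterministic function of the planted usage
fractions under the RED thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from longapa.differential import (
    LENGTHENING,
    PATTERN_MAP,
    RED_THRESHOLD,
    SHORTENING,
    UNCLASSIFIED,
)
from longapa.io import (
    GeneModel,
    revcomp,
    write_endsites,
    write_genome,
    write_gtf,
    write_refpas,
)

#: planted proximal-PAS usage trajectory per dynamic label (3 stages)
PATTERN_PROXIMAL_USAGE: dict[str, tuple[float, float, float]] = {
    "1": (0.80, 0.50, 0.20),  # persistent lengthening
    "2": (0.65, 0.35, 0.65),  # lengthening then shortening
    "3": (0.20, 0.50, 0.80),  # persistent shortening
    "4": (0.35, 0.65, 0.35),  # shortening then lengthening
    "stable": (0.50, 0.50, 0.50),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a three-stage design (hESC → NSC → NPC) with two
    replicates per stage, moderate depth, and realistic end-scatter.
    """

    n_genes: int = 100
    stages: tuple[str, ...] = ("hESC", "NSC", "NPC")
    replicates_per_stage: int = 2
    pas_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.5, 3: 0.2}
    )
    usage_by_stage: Mapping[str, Mapping[str, Sequence[float]]] | None = None
    reads_per_gene: float = 150.0
    jitter_sd: float = 3.0
    artifact_rate: float = 0.15
    artifact_usage: float = 0.15
    intronic_pas_rate: float = 0.1
    intronic_usage: float = 0.1
    motif_offset: int = 21
    known_frac: float = 0.5
    pattern_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"stable": 0.2, "1": 0.2, "2": 0.2, "3": 0.2, "4": 0.2}
    )
    pas_spacing: int = 80
    seed: int = 0
    # gene architecture (nt)
    utr5_len: int = 100
    cds1_len: int = 150
    intron_len: int = 100
    cds2_len: int = 150
    first_pas_offset: int = 60
    utr3_margin: int = 30
    genes_per_chrom: int = 25
    intergenic_len: int = 300
    chrom_pad: int = 150
    dirichlet_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates_per_stage < 1:
            raise ValueError("n_genes and replicates_per_stage must be >= 1")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not math.isclose(sum(self.pas_per_gene.values()), 1.0, abs_tol=1e-9):
            raise ValueError("pas_per_gene probabilities must sum to 1")
        if any(k not in (1, 2, 3) for k in self.pas_per_gene):
            raise ValueError("pas_per_gene supports 1-3 sites per gene")
        if not math.isclose(sum(self.pattern_fractions.values()), 1.0, abs_tol=1e-9):
            raise ValueError("pattern_fractions must sum to 1")
        if not 0 <= self.artifact_rate <= 1 or not 0 < self.artifact_usage < 1:
            raise ValueError("artifact_rate in [0,1], artifact_usage in (0,1)")
        if not 0 <= self.intronic_pas_rate <= 1 or not 0 < self.intronic_usage < 1:
            raise ValueError("intronic_pas_rate in [0,1], intronic_usage in (0,1)")
        if self.intronic_pas_rate > 0 and self.intron_len < 100:
            raise ValueError(
                "gene too short to host requested structure: intron_len must be "
                ">= 100 nt to place a mid-intron PAS clear of the exon boundaries"
            )
        if self.first_pas_offset < self.motif_offset + 10:
            raise ValueError(
                "gene too short to host requested structure: first_pas_offset "
                f"({self.first_pas_offset}) must be >= motif_offset + 10 "
                f"({self.motif_offset + 10}) so the planted signal fits in the 3'UTR"
            )
        if self.pas_spacing < 30:
            raise ValueError(
                "gene too short to host requested structure: pas_spacing must be "
                ">= 30 nt so sites do not share clustering windows"
            )
        if len(self.stages) != 3 and any(
            k != "stable" and v > 0 for k, v in self.pattern_fractions.items()
        ):
            raise ValueError("dynamic patterns require exactly three stages")
        if self.usage_by_stage is not None:
            for gene, by_stage in self.usage_by_stage.items():
                for stage, props in by_stage.items():
                    if not math.isclose(sum(props), 1.0, abs_tol=1e-9):
                        raise ValueError(
                            f"usage_by_stage[{gene}][{stage}] must sum to 1"
                        )

    @property
    def samples(self) -> list[str]:
        return [
            f"{stage}_rep{r}"
            for stage in self.stages
            for r in range(1, self.replicates_per_stage + 1)
        ]

    @property
    def samples_by_stage(self) -> dict[str, list[str]]:
        return {
            stage: [
                f"{stage}_rep{r}" for r in range(1, self.replicates_per_stage + 1)
            ]
            for stage in self.stages
        }


@dataclass
class TruthTable:
    """Ground truth of one synthetic dataset.

    ``sites``: one row per planted site (true PASs and artifact traps)
    with genomic location, region, per-stage usage and the artifact flag.
    ``genes``: per gene the expected lengthening/shortening direction for
    every consecutive stage comparison and the expected dynamic pattern.
    """

    sites: pd.DataFrame
    genes: pd.DataFrame
    chrom_sizes: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


@dataclass
class SyntheticGenome:
    """In-memory result of :func:`simulate_genome`."""

    genome: dict[str, str]
    models: list[GeneModel]
    gtf_records: list[tuple[str, str, int, int, str, str]]
    ref_pas: list[tuple[str, str, int]]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, outdir / "genome.fa")
        write_gtf(self.gtf_records, outdir / "annotation.gtf")
        write_refpas(self.ref_pas, outdir / "ref_pas.bed")
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# sequence helpers

def _sanitize_a_content(
    seq: np.ndarray, protected: np.ndarray, lo: int, hi: int,
    max_run: int = 4, max_in10: int = 5,
) -> None:
    """Deterministically cap A-content in ``seq[lo:hi]`` in place.

    Keeps every A-run at ≤``max_run`` and every 10-nt window at
    ≤``max_in10`` adenines (comfortably below the priming-filter
    thresholds of 6 and 7), never mutating protected positions (the
    planted signal). Used around non-artifact true PASs so no genuine
    site is lost to the filter by accident.
    """
    lo, hi = max(lo, 0), min(hi, len(seq))
    # cap runs
    i = lo
    while i < hi:
        if seq[i] == "A":
            j = i
            while j < hi and seq[j] == "A":
                j += 1
            if j - i > max_run:
                kept = 0
                for t in range(i, j):
                    if protected[t]:
                        kept += 1
                        continue
                    kept += 1
                    if kept > max_run:
                        seq[t] = "C"
                        kept = 0
            i = j
        else:
            i += 1
    # cap 10-nt windows
    for w0 in range(lo, max(lo, hi - 9)):
        w1 = min(w0 + 10, hi)
        while True:
            idx = [t for t in range(w0, w1) if seq[t] == "A"]
            if len(idx) <= max_in10:
                break
            mutable = [t for t in idx if not protected[t]]
            if not mutable:
                break
            seq[mutable[-1]] = "C"


def _largest_remainder_quota(fracs: Mapping[str, float], n: int) -> dict[str, int]:
    labels = sorted(fracs)
    raw = {lab: fracs[lab] * n for lab in labels}
    counts = {lab: int(math.floor(raw[lab])) for lab in labels}
    rem = n - sum(counts.values())
    order = sorted(labels, key=lambda lab: (-(raw[lab] - counts[lab]), lab))
    for lab in order[:rem]:
        counts[lab] += 1
    return counts


def true_direction(
    dpui: Sequence[float],
    tx_rank: Sequence[int],
    threshold: float = RED_THRESHOLD,
) -> str:
    """Expected RED direction given per-site true DPUI values.

    Mirrors the analysis rule on noise-free usage fractions: take the two
    sites with the largest |DPUI| (ties toward the transcriptionally 5'
    site), orient proximal/distal by transcription rank, and threshold
    RED = DPUI_distal − DPUI_proximal.
    """
    order = sorted(range(len(dpui)), key=lambda i: (-abs(dpui[i]), tx_rank[i]))
    a, b = order[0], order[1]
    prox, dist = (a, b) if tx_rank[a] < tx_rank[b] else (b, a)
    red = dpui[dist] - dpui[prox]
    if red >= threshold:
        return LENGTHENING
    if red <= -threshold:
        return SHORTENING
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# genome simulation

def simulate_genome(config: SimConfig, outdir: str | Path | None = None) -> SyntheticGenome:
    """Generate genome, gene models, reference PAS table and ground truth.

    Identical configs (same seed) produce byte-identical outputs.
    """
    rng = np.random.default_rng([config.seed, 11])

    # per-gene structure draws
    ks = sorted(config.pas_per_gene)
    probs = np.array([config.pas_per_gene[k] for k in ks], dtype=float)
    n_pas = rng.choice(np.array(ks), size=config.n_genes, p=probs / probs.sum())
    has_artifact = rng.random(config.n_genes) < config.artifact_rate
    has_intronic = rng.random(config.n_genes) < config.intronic_pas_rate

    # dynamic-label assignment over multi-PAS genes: exact quotas,
    # seeded permutation order
    multi = np.flatnonzero(n_pas >= 2)
    quotas = _largest_remainder_quota(dict(config.pattern_fractions), len(multi))
    labels = np.array(["single"] * config.n_genes, dtype=object)
    pool: list[str] = []
    for lab in sorted(quotas):
        pool.extend([lab] * quotas[lab])
    perm = rng.permutation(len(multi))
    for idx, lab_i in zip(multi[perm], range(len(pool))):
        labels[idx] = pool[lab_i]

    n_stages = len(config.stages)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    gtf_records: list[tuple[str, str, int, int, str, str]] = []
    ref_pas: list[tuple[str, str, int]] = []
    site_rows: list[dict] = []
    gene_rows: list[dict] = []

    n_chroms = math.ceil(config.n_genes / config.genes_per_chrom)
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        parts: list[np.ndarray] = []
        cursor = 0

        def _random_seq(n: int) -> np.ndarray:
            return _BASES[rng.integers(0, 4, size=n)]

        pad = _random_seq(config.chrom_pad)
        parts.append(pad)
        cursor += config.chrom_pad

        genes_here = min(config.genes_per_chrom, config.n_genes - gi)
        for _ in range(genes_here):
            strand = "+" if gi % 2 == 0 else "-"
            k = int(n_pas[gi])
            art = bool(has_artifact[gi])
            intr = bool(has_intronic[gi])
            lab = labels[gi]
            gene_id = f"G{gi + 1:04d}"

            utr3_len = (
                config.first_pas_offset
                + (k - 1) * config.pas_spacing
                + (60 if art else 0)
                + config.utr3_margin
            )
            utr5 = config.utr5_len
            e1_end = utr5 + config.cds1_len
            i_end = e1_end + config.intron_len
            cds2_end = i_end + config.cds2_len
            L = cds2_end + utr3_len
            utr3_start = cds2_end

            sense = _random_seq(L)
            protected = np.zeros(L, dtype=bool)

            pas_local = [
                utr3_start + config.first_pas_offset + j * config.pas_spacing
                for j in range(k)
            ]
            art_local = pas_local[-1] + 60 if art else None
            intron_local = e1_end + config.intron_len // 2 if intr else None

            genuine = ([intron_local] if intr else []) + pas_local
            motif = np.array(list("AATAAA"))
            for p in genuine:
                m0 = p - config.motif_offset
                sense[m0:m0 + 6] = motif
                protected[m0:m0 + 6] = True
            for p in genuine:
                _sanitize_a_content(sense, protected, p - 14, p + 15)
            # 15-nt A-run centered on the trap: any read jittered within the
            # ±4 sd clip keeps >= 6 run bases inside its 21-nt filter window
            if art is True and art_local is not None:
                sense[art_local - 7:art_local + 8] = "A"

            # usage per stage over the gene's 3'UTR sites; the constant-usage
            # intronic site (prepended) and artifact trap (appended) take
            # fixed shares, with the 3'UTR block rescaled to keep the sum 1
            if config.usage_by_stage is not None and gene_id in config.usage_by_stage:
                by_stage = config.usage_by_stage[gene_id]
                utr3_usage = np.array(
                    [list(by_stage[s]) for s in config.stages], dtype=float
                )
            elif k == 1:
                utr3_usage = np.ones((n_stages, 1))
            else:
                prox = PATTERN_PROXIMAL_USAGE.get(lab, (0.5,) * n_stages)
                if n_stages != 3:
                    prox = (0.5,) * n_stages
                cols = []
                for s in range(n_stages):
                    p_use = prox[s]
                    if k == 2:
                        cols.append([p_use, 1.0 - p_use])
                    else:
                        cols.append([0.8 * p_use, 0.2, 0.8 * (1.0 - p_use)])
                utr3_usage = np.array(cols, dtype=float)

            extra = (config.intronic_usage if intr else 0.0) + (
                config.artifact_usage if art else 0.0
            )
            blocks = []
            if intr:
                blocks.append(np.full((n_stages, 1), config.intronic_usage))
            blocks.append(utr3_usage * (1.0 - extra))
            if art:
                blocks.append(np.full((n_stages, 1), config.artifact_usage))
            usage = np.hstack(blocks)

            # genomic placement
            g0 = cursor
            if strand == "+":
                parts.append(sense)
            else:
                parts.append(np.array(list(revcomp("".join(sense)))))
            cursor += L
            spacer = _random_seq(config.intergenic_len)
            parts.append(spacer)
            cursor += config.intergenic_len

            def _pt(i: int) -> int:
                return g0 + i if strand == "+" else g0 + L - 1 - i

            def _iv(a: int, b: int) -> tuple[int, int]:
                return (g0 + a, g0 + b) if strand == "+" else (g0 + L - b, g0 + L - a)

            tx = f"{gene_id}.t1"
            attrs = f'gene_id "{gene_id}"; transcript_id "{tx}";'
            exon1 = _iv(0, e1_end)
            exon2 = _iv(i_end, L)
            feats = [
                ("gene", _iv(0, L)),
                ("transcript", _iv(0, L)),
                ("exon", exon1),
                ("exon", exon2),
                ("five_prime_utr", _iv(0, utr5)),
                ("CDS", _iv(utr5, e1_end)),
                ("CDS", _iv(i_end, cds2_end)),
                ("three_prime_utr", _iv(utr3_start, L)),
            ]
            for feature, (a, b) in sorted(feats, key=lambda x: (x[1][0], x[0])):
                gtf_records.append((chrom, feature, a, b, strand, attrs))

            intervals = [
                (*_iv(0, utr5), "5UTR"),
                (*_iv(utr5, e1_end), "CDS"),
                (*_iv(e1_end, i_end), "intron"),
                (*_iv(i_end, cds2_end), "CDS"),
                (*_iv(utr3_start, L), "3UTR"),
            ]
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    intervals=intervals,
                    terminal_exon=_iv(i_end, L),
                    tx_end=_pt(L - 1),
                    coding=True,
                    cds_anchor=_pt(cds2_end - 1),
                )
            )

            locals_all = (
                ([(intron_local, "intron")] if intr else [])
                + [(p, "3UTR") for p in pas_local]
                + ([(art_local, "3UTR")] if art else [])
            )
            for rank, (p, region) in enumerate(locals_all):
                is_art = art and p == art_local
                if not is_art and rng.random() < config.known_frac:
                    known = True
                    ref_pas.append((chrom, strand, _pt(p)))
                else:
                    known = False
                row = {
                    "gene_id": gene_id,
                    "site_id": f"{gene_id}.p{rank + 1}",
                    "chrom": chrom,
                    "strand": strand,
                    "position": _pt(p),
                    "tx_rank": rank,
                    "region": region,
                    "is_artifact": is_art,
                    "in_reference": known,
                }
                for s, stage in enumerate(config.stages):
                    row[f"usage_{stage}"] = usage[s, rank]
                site_rows.append(row)

            # expected per-comparison directions and pattern on the 3'UTR
            # non-artifact sites, renormalized
            off = 1 if intr else 0
            true_usage = usage[:, off:off + k]
            true_usage = true_usage / true_usage.sum(axis=1, keepdims=True)
            dirs = []
            for s in range(n_stages - 1):
                if k >= 2:
                    dpui = true_usage[s + 1] - true_usage[s]
                    dirs.append(true_direction(list(dpui), list(range(k))))
                else:
                    dirs.append(UNCLASSIFIED)
            if n_stages == 3:
                pattern = PATTERN_MAP.get((dirs[0], dirs[1]), "none")
            else:
                pattern = "none"
            grow = {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "n_pas": k,
                "has_artifact": art,
                "has_intronic": intr,
                "planted_label": lab,
                "expected_pattern": pattern,
            }
            for s in range(n_stages - 1):
                cmp_name = f"{config.stages[s + 1]}_vs_{config.stages[s]}"
                grow[f"direction_{cmp_name}"] = dirs[s]
            gene_rows.append(grow)
            gi += 1

        parts.append(_random_seq(config.chrom_pad))
        genome[chrom] = "".join("".join(p) for p in parts)

    sites = pd.DataFrame(site_rows)
    genes = pd.DataFrame(gene_rows)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    truth = TruthTable(sites=sites, genes=genes, chrom_sizes=chrom_sizes)
    result = SyntheticGenome(
        genome=genome,
        models=models,
        gtf_records=gtf_records,
        ref_pas=sorted(set(ref_pas)),
        truth=truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(
    config: SimConfig,
    truth: TruthTable,
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample aggregated 3'-end positions with counts.

    Per sample and gene: total reads ~ Poisson(reads_per_gene), allocated
    multinomially across the gene's sites by stage usage (optionally
    Dirichlet-perturbed per replicate), each read's end jittered by
    round(N(0, jitter_sd)) clipped at ±4·jitter_sd and to the chromosome.
    Identical (chrom, strand, position) reads aggregate to one record.
    """
    rng = np.random.default_rng([config.seed, 23])
    sites = truth.sites.sort_values(["gene_id", "tx_rank"])
    genes = sites["gene_id"].to_numpy()
    gene_starts: dict[str, np.ndarray] = {
        g: np.flatnonzero(genes == g) for g in pd.unique(genes)
    }
    max_jit = int(math.ceil(4 * config.jitter_sd))

    out: dict[str, pd.DataFrame] = {}
    for stage in config.stages:
        usage_col = sites[f"usage_{stage}"].to_numpy(dtype=float)
        for rep in range(1, config.replicates_per_stage + 1):
            sample = f"{stage}_rep{rep}"
            agg: dict[tuple[str, str, int], int] = {}
            for g in pd.unique(genes):
                idx = gene_starts[g]
                props = usage_col[idx]
                props = props / props.sum()
                total = int(rng.poisson(config.reads_per_gene))
                if total == 0:
                    continue
                if config.dirichlet_concentration is not None:
                    alpha = np.maximum(props * config.dirichlet_concentration, 1e-9)
                    props = rng.dirichlet(alpha)
                alloc = rng.multinomial(total, props)
                for j, n_reads in zip(idx, alloc):
                    if n_reads == 0:
                        continue
                    pos0 = int(sites["position"].iat[j])
                    chrom = sites["chrom"].iat[j]
                    strand = sites["strand"].iat[j]
                    if config.jitter_sd > 0:
                        offs = np.rint(
                            rng.normal(0.0, config.jitter_sd, size=n_reads)
                        ).astype(int)
                        offs = np.clip(offs, -max_jit, max_jit)
                    else:
                        offs = np.zeros(n_reads, dtype=int)
                    positions = np.clip(
                        pos0 + offs, 0, truth.chrom_sizes[chrom] - 1
                    )
                    vals, cnts = np.unique(positions, return_counts=True)
                    for p, c in zip(vals, cnts):
                        key = (chrom, strand, int(p))
                        agg[key] = agg.get(key, 0) + int(c)
            df = pd.DataFrame(
                [(c, s, p, n) for (c, s, p), n in sorted(agg.items())],
                columns=["chrom", "strand", "position", "count"],
            )
            out[sample] = df
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, df in out.items():
            path = outdir / f"ends_{sample}.bed"
            with open(path, "w") as fh:
                for row in df.itertuples(index=False):
                    fh.write(
                        f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                        f"{sample}\t{row.count}\t{row.strand}\n"
                    )
    return out


def reads_to_endsites(reads: Mapping[str, pd.DataFrame]):
    """Convert :func:`simulate_reads` output to a merged EndSite collection."""
    from longapa.io import EndSite, merge_endsites

    collections = []
    for sample, df in reads.items():
        collections.append(
            [
                EndSite(r.chrom, r.strand, int(r.position), {sample: int(r.count)})
                for r in df.itertuples(index=False)
            ]
        )
    return merge_endsites(collections)
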
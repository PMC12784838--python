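# Methods

## Scope and data model

`longapa` analyzes aggregated read 3′-end positions — one record per
(chromosome, strand, position) with a count per sample — across two or
more ordered stages with replicates. All coordinates are 0-based
internally; BED I/O is 0-based half-open, GTF I/O 1-based inclusive,
converted exactly once at the file boundary. An end site's position is
the transcriptionally last base of the read (on the minus strand, the
genomic 5′-most base), so proximal/distal reasoning is strand-uniform
throughout.

One representative transcript is kept per gene — the one with the 3′-most
annotated end, ties broken by span length — because usage statistics are
per gene and need a single terminal-exon anchor. Introns are derived as
gaps between consecutive exons; exon stretches are split into
5′UTR/CDS/3′UTR using the transcript's UTR and CDS features, and genes
without CDS are carried as non-coding with plain exon/intron labels.

## Internal-priming filter

The filter scans the sense-strand (transcription-orientation) sequence of
a 21-nt window: 10 nt upstream, the site base, 10 nt downstream. A site
is an artifact when the window contains ≥6 consecutive adenines or ≥7
adenines within any 10-nt sliding window (stride 1). Only uppercase `A`
counts; `N` never does. Windows truncated at chromosome ends are scanned
as-is and flagged clipped; sequences shorter than 10 nt are treated as a
single window.

Two deliberate readings are recorded here because the rule as usually
stated is ambiguous: (i) the window *includes* the site base (21 nt, the
only symmetric, self-consistent reading; the thresholds are insensitive
to the one-base alternative); (ii) the scan is on the sense strand, so
genomic T-runs under minus-strand genes — A-runs in the mRNA, which is
what oligo(dT) actually anneals to — are caught.

## PAC clustering

Primary clustering is greedy and count-ordered within each (chromosome,
strand): repeatedly seed at the unassigned site with the highest summed
count (ties → the 5′-most site in transcription order) and absorb every
unassigned site within ±24 nt. This realization is order-independent
(membership is invariant under input permutation) and consistent with
taking the highest peak as the cluster representative. The width (24 nt)
matches the unimodal scatter of long-read 3′ ends around a true PAS.

Refinement splits multimodal PACs by weighted density-peak clustering:
member density ρᵢ = Σⱼ cⱼ · max(0, 1 − |pᵢ − pⱼ|/h) with a triangular
kernel of bandwidth h = 8 nt; peak candidates must exceed 10% of the
maximum density and lie ≥8 nt from any higher-density member; members
join their nearest peak (ties → the 5′ peak). The three parameters are
not canonical — they are chosen so sub-PACs are finer than the 24-nt
primary scale — and are exposed in the CLI config. A unimodal PAC is
returned unchanged, and membership is conserved under splitting.

The center PAS is the member with the maximal summed count; ties resolve
to the transcriptionally 5′-most member on either strand.

## Annotation

Region assignment uses the center PAS against gene spans (interval tree
per chromosome and strand, same-strand only). Overlapping annotations
resolve with precedence 3′UTR > exon/CDS > intron > 5′UTR:
polyadenylation evidence most plausibly terminates a 3′UTR. Centers up
to 1,000 nt downstream of an annotated transcript end are treated as
unannotated distal 3′UTR sites (CLI-exposed). Remaining ties resolve to
the lexicographically smallest gene id, for determinism.

Known/novel status is the signed transcription-order distance to the
nearest same-strand reference PAS (positive = center downstream of the
reference): `exact_match` at 0, `matched` within ±24 nt (the clustering
scale; reported separately from exact matches because reference catalogs
are typically single-base), `novel` otherwise. A distance histogram is
emitted for QC.

## Differential usage statistics

For a comparison (treat vs ctrl), a PAC qualifies when its summed count
strictly exceeds 5 reads in *each* group, and a gene is retained with ≥2
qualifying PACs; the strict per-group threshold keeps a site absent from
one condition out of the test. PSU is computed per sample over the
qualifying PACs (per gene and sample they sum to 1); a zero gene total
leaves that sample's PSU missing and excluded from group means.

DPUI is the difference of group-mean PSUs (arithmetic mean over
replicates). Significance is a two-sided two-proportion Wald test on
counts pooled across replicates within each group:

z = (k₁/n₁ − k₂/n₂) / √(p̂₁(1−p̂₁)/n₁ + p̂₂(1−p̂₂)/n₂)

with unpooled variance terms. Pooling is a declared choice: with two
replicates a replicate-level variance estimate is degenerate. When a
proportion is degenerate (k = 0 or k = n) it enters the variance as
0.5/n (resp. 1 − 0.5/n) — the standard continuity fix; a literal
variance floor of 0.5/n would exceed the maximum possible p(1−p)/n ≤
0.25/n, so that reading is rejected. Events with |DPUI| ≥ 0.05 and raw
p ≤ 0.05 are called differential; no multiple-testing correction enters
the headline call, but BH q-values are emitted as an extra column.

RED calls consider genes with ≥2 3′UTR PACs and at least one significant
3′UTR event: the two PACs with the largest |DPUI| (ties → the
transcriptionally 5′ PAC) are oriented proximal/distal by distance from
the center to the 3′ end of the last CDS in transcription order (a
strand-uniform terminal-exon anchor, defined for every coding gene;
non-coding genes fall back to transcription order). RED =
DPUI(distal) − DPUI(proximal), with lengthening at ≥0.05, shortening at
≤−0.05, otherwise unclassified. All statistics are antisymmetric under
swapping the groups.

Patterns intersect the RED directions of two ordered comparisons; genes
lacking a lengthening/shortening call in either comparison are "none",
so the five labels partition the gene universe.

## Sequence-context QC

Flanks are the 50 nt upstream of the PAS in sense orientation, excluding
the cleavage base. Offsets are motif start minus PAS position (upstream
negative). The nucleotide profile covers ±100 nt with per-offset
frequencies over A/C/G/T.

K-mer enrichment replaces PWM-based motif discovery with a transparent
statistic: for every k-mer (k = 4..6), the fraction of flanks containing
it is tested one-sidedly (binomial) against its containment rate in 10
seeded dinucleotide-preserving shuffles (Altschul–Erickson Euler-path
shuffle) of the same flanks, with Laplace smoothing of the background
rate. Ranking uses the log survival function rather than the p-value
itself because containment p-values underflow to zero for strong
signals; ties resolve by foreground fraction, background fraction, then
k-mer. This answers the same question — is AATAAA (and variants)
enriched, and where — without re-implementing a motif-discovery tool;
per-category percentages from such tools are tool-specific and are not
comparable surfaces.

## Synthetic-data generator

The generator is first-class, tested code defining the study conditions.
Genes carry 5′UTR (100 nt), two CDS exons (150 nt each), one intron
(100 nt) and a 3′UTR sized to hold 1–3 true PASs spaced 80 nt apart
(first PAS 60 nt into the 3′UTR), laid out with 300-nt intergenic
spacers and equal numbers of plus- and minus-strand genes — forcing
strand-correctness everywhere downstream. Defaults describe a
three-stage design (hESC → NSC → NPC), two replicates per stage, and a
mean depth of 150 reads per gene per sample.

Planted structure:

* **Signal.** AATAAA starts 21 nt upstream of every genuine PAS (sense
  strand), the canonical 20–30-nt positioning.
* **Usage dynamics.** Multi-PAS genes receive one of five labels with
  exact largest-remainder quotas (default 20% each): the four dynamic
  patterns and "stable". Proximal-PAS usage trajectories are
  0.80/0.50/0.20 (persistent lengthening), 0.65/0.35/0.65
  (lengthening→shortening), and mirrored for patterns 3 and 4 — a
  per-comparison usage shift of 0.3, large against the 0.05 RED
  threshold but small enough that sampling noise matters at realistic
  depth. Three-PAS genes hold the middle site at 0.2.
* **Internal-priming traps.** A configurable fraction of genes (default
  15%) carries an extra 3′UTR site centered in a planted 15-nt A-run
  with a fixed 15% usage share. The run is symmetric around the site so
  that every jittered read within the jitter clip keeps ≥6 run bases
  inside its 21-nt window: trap removal is guaranteed by construction,
  not by luck.
* **Intronic APA.** A fraction of genes (default 10%) carries a
  constant-usage (10%) mid-intron PAS, so intron annotation and
  upstream-region events are exercised; it never affects the planted
  3′UTR dynamics, which are computed on the renormalized 3′UTR sites.
* **Reference table.** Each genuine PAS enters the reference BED with
  probability 50% ("known"); the rest stay novel.

Read sampling per sample and gene: Poisson total around the configured
depth, multinomial allocation across the gene's sites by stage usage
(optionally Dirichlet-perturbed per replicate; off by default, the
simplest model under which the Wald test's nominal behavior can be
checked), and end-position jitter of round(N(0, σ)) with σ = 3 nt by
default, clipped at ±4σ and at chromosome bounds. The clip is what makes
the artifact-trap guarantee above exact; it affects ~0.006% of reads.
Because accidental A-runs in random background could silence a genuine
site, the ±14 nt around every genuine PAS is deterministically sanitized
(A-runs capped at 4, ≤5 A per 10-nt window — comfortably inside the 6/7
thresholds) without touching the planted signal.

The ground truth records every site (position, region, per-stage usage,
artifact flag) and, per gene, the expected direction per comparison and
expected pattern — a deterministic function of the planted usage
fractions under the RED thresholds, computed by the same top-2-|DPUI|
rule the analysis uses but on noise-free fractions.

**What the generator does not emulate:** basecalling error profiles,
poly(A)-tail lengths, isoform-level splicing, expression differences
between genes, batch effects, or overlapping gene architectures (those
are covered by targeted unit tests instead). Passing tests therefore
demonstrate correctness of the statistical machinery and planted-feature
recovery under idealized noise, not performance on real ONT libraries.

## Determinism and numerical choices

Every random draw flows from a single integer seed (generator streams
are split per stage of the pipeline); identical configs give
byte-identical files, and the CLI writes sorted outputs only. Ties are
broken deterministically everywhere (documented per operation above).
Degenerate inputs: empty site collections yield empty outputs; an empty
reference makes every PAC novel at infinite distance; a gene with a
single qualifying PAC is silently dropped from differential analysis;
empty flank sets yield empty motif reports, and fewer than 10 flanks are
rejected for enrichment.

## Problem sizes used in checks

The bundled verification runs use 150–500 genes (300–1,000 planted
sites), 2,000 simulated null genes for Wald calibration, 500 genes for
direction recovery, and 50 genes per planted pattern — sizes at which
every recovery property is measured with comfortable binomial margins
while the whole suite stays fast on a laptop.

## Known limitations

* The Wald test is asymptotic; at the 5-read retention floor its
  calibration is approximate (the null-calibration check runs at 100
  reads per group, where it is accurate to within a percentage point).
* RED uses only the top-2 |DPUI| 3′UTR PACs; genes with >2 shifting
  sites are summarized by their two strongest movers.
* Annotation is gene-level against one representative transcript;
  transcript-level assignment is out of scope.
* The k-mer statistic measures containment enrichment, not positional
  PWMs; motif *position* is reported separately via the signal-density
  histogram.
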
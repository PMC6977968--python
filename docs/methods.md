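# Methods

## The measurement model

Nascent transcription is measured as counts of newly synthesized RNA per
gene per sample, with a fixed-ratio foreign-genome spike-in added before
RNA purification. Because the spike-in channel experiences the same
capture and sequencing losses as the experimental channel, the ratio

    signal(g, s) = counts(g, s) / spike_total(s) × C        (C = 10000)

is an absolute between-sample measure: jointly rescaling a sample's counts
and spike total is an exact no-op. The constant C is an arbitrary display
scale with no effect on any downstream log-ratio. The same logic drives the
ChEC normalization (per-bp cleavage / spike total × C) and the ChIP
normalization, which additionally multiplies by the spike-to-experimental
read ratio of the matched input sample to correct for differences in the
chromatin mix between IPs.

## Filtering cascade

1. Genes whose ORF class is dubious, pseudogene or transposable element
   are flagged and excluded from analysis (they stay in the annotation).
2. Genes with zero signal in *any* sample of the designated filter set are
   removed. The default filter set spans the TFIID-degron, SAGA-degron and
   SPT-deletion experiments plus their controls; double-degron samples are
   excluded from the filter, so log2 changes for those contrasts drop
   (rather than error on) the rare gene whose double-degron mean is zero.
3. Genes are ranked by mean length-normalized signal over baseline (WT and
   vehicle) samples. The lowest-expressed fraction f is removed, with
   ⌊f·N + 0.5⌋ genes dropped (round half up). The default f = 0.05 is the
   point of largest relative decrease in the mean replicate coefficient of
   variation, as computed by `cv_profile` (CV per gene within each
   replicate group, averaged over genes, then over groups).

Log2 changes are log2(mean_treated / mean_control) of replicate-mean
normalized signal, with no pseudocount: zeros are excluded upstream by
design, and a zero mean in a retained gene is treated as a filter
misconfiguration.

## Class discovery

Genes are clustered by k-means (squared-Euclidean, k-means++
initialization, 10 restarts, fixed seed) on unscaled log2-change features.
The headline feature set is the three SPT-deletion contrasts plus the
three Taf-degron contrasts; the SAGA-degron contrasts are held out and
used for a stability re-clustering, with agreement scored after optimal
label matching. The number of clusters is chosen by mean silhouette score
over k = 2..6 (ties to the smaller k). Replicate-mean contrast columns are
used as features rather than per-replicate columns. The cluster with the
more negative mean log2 change over the Taf-degron contrasts is labeled
TFIID-dependent; under the modeled conditions this is also the larger
cluster, and if the two criteria ever disagree the label follows Taf
sensitivity and a warning is logged.

## Promoter motifs

Promoters are TSS-relative [-400, +100] windows read 5'→3' along the gene
strand (minus-strand windows reverse-complemented); windows clipped at a
chromosome end are flagged. A motif is present when a full IUPAC-consensus
match *starts* inside the motif's search range, endpoints inclusive: TATA
(`TATAWAW`) within [-200, 0], Msn2/4 (`VAGGGG`) within [-300, -50].
Scanning is sense-strand-only by default (config-switchable to both
strands; the stress-response element is functional on either strand, but
single-strand scanning keeps calls position-exact and reproducible).
Missing TSS annotations are imputed 100 bp upstream of the start codon,
strand-aware. Class×motif tables carry two-sided Fisher exact p-values.

## ChEC-seq peak calling and consensus

The caller scores fixed sliding windows (150 bp, step 50 bp) of
spike-normalized sample signal against a free-MNase control. The expected
window signal is the control sum floored at a pseudocount of 1 and scaled
so genome-wide totals match; significance is a Poisson upper-tail p-value
with Benjamini–Hochberg control at FDR 0.001 across all windows. Windows
must additionally be ≥2-fold over the scaled control and ≥2-fold over the
local background, defined as the mean of sample and scaled-control signal
over ±1 kb flanks excluding the window. Significant windows are merged
when overlapping or adjacent; the merged region is the peak and the summit
is the mid-range of its borders, rounding down. A fixed-window caller was
chosen over variable-width region growing because promoter-proximal ChEC
peaks are narrow (on the order of 100–200 bp) and the scientific content
lies in the enrichment thresholds and promoter-assignment rules, not the
region-finding heuristic.

Summits are assigned to a promoter when they fall in [-300, +100] of its
TSS (strand-aware); with several candidates the summit closest to the TSS
wins, and an exact distance tie goes upstream. A promoter is
consensus-bound when bound in at least ⌈0.75·n⌉ of n replicates (3 of 4 at
the default). For consensus promoters lacking a peak in some replicate,
the position of that replicate's strongest signal within the TSS window
stands in as its summit. Per-replicate promoter signal is the normalized
per-bp sum over the 300 bp window [summit-150, summit+149]; the reported
signal is the replicate mean.

## ChIP-seq mark quantification

Per-gene promoter mark signal is the normalized per-bp sum over the
TSS-relative window [-200, +300], 501 bp inclusive, which captures the +1
nucleosome carrying most promoter acetylation. Genes with zero signal in
any sample of a contrast's comparison set are excluded from that contrast
only. Changes are replicate-mean log2 ratios.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
writes a truth table next to every dataset. Defaults define the emulated
study conditions:

- **Design**: 5000 genes, 13% coactivator-redundant; degron conditions
  (Taf13/Taf7/Taf1, Spt3/20, Spt3/7, and the Taf13+Spt3 / Taf13+Spt7
  doubles) with IAA and DMSO arms, SPT deletions with a shared WT control;
  3 replicates per arm.
- **Effects** (mean log2 fold change per class per condition): Taf degrons
  −log2 4.5 (TFIID-dependent) / −log2 2.0 (CR); Spt3/20 degron 0 /
  −log2 1.6; Spt3/7 degron 0 / −log2 1.5; spt3Δ −log2 2.7 / −log2 3.5;
  spt7Δ and spt20Δ −log2 2.0 / −log2 3.0; double degrons −log2 4.5 /
  −log2 5.7. The Taf-degron CR effect, the Spt3/7-degron CR effect and the
  spt7Δ/spt20Δ magnitudes are interpolated from qualitative descriptions
  of the modeled study design; the remainder encode its reported averages.
  A per-gene, per-condition Normal(0, 0.4) deviation is added once and
  shared across replicates.
- **Counts**: negative binomial with dispersion 0.05 around
  baseline × 2^effect × capture, where per-sample capture efficiencies are
  log-normal (sd 0.3) and spike totals are proportional to them, so the
  spike channel absorbs capture exactly. Baseline expression is a per-bp
  log-normal density (sd 1.1) times ORF length times 0.1 counts/bp
  (median ≈ 150 counts per gene, a moderate sequencing depth); CR genes
  draw from a heavier-tailed component (45% weight, median 8× higher)
  so the top expressers are CR-enriched, as the modeled design requires.
- **Genome**: genes of 600–2400 bp with 1.2–1.6 kb intergenic gaps (wide
  enough that planted promoter windows never collide) on ≥2 chromosomes;
  15% of genes lack a TSS annotation and exercise the imputation rule;
  5% carry excluded ORF classes. Promoter windows are i.i.d. background
  with motifs planted per class frequency (TATA 0.65/0.25, Msn2/4
  0.26/0.14 for CR/TFIID-dependent) inside the correct search windows;
  sequences are redrawn until scanning matches the plan, so planted
  fractions are exact rather than inflated by background hits.
- **ChEC**: two factors, 70% of analyzed promoters bound, 90% co-binding;
  Gaussian peaks (FWHM 120 bp, 8-fold over a flat Poisson background of
  0.5 counts/bp) centered at a random offset in [-250, +50] of the TSS;
  four replicates plus a free-MNase control.
- **ChIP**: +1-nucleosome Gaussian bumps (sd 40 bp, center TSS+150)
  with log-normal amplitudes over a low background, scaled per genotype
  (10-fold loss in gcn5Δ and spt7Δ, 3.3-fold in spt3Δ, 1.7-fold after
  rapid Spt3/7 depletion); duplicate IPs with input-sidecar read totals.

What the generator does **not** model: correlated effects across
conditions within a gene, expression-dependent dispersion trends, mapping
artifacts and mappability gaps, MNase sequence bias and accessibility
structure in the free-MNase control, nucleosome positioning beyond a
single +1 bump, or batch effects. Passing recovery tests therefore show
that the pipeline is correct and quantitative under the declared
statistical model, not that it is robust to every failure mode of real
sequencing data.

## Numerical and scale choices

- Internal coordinates are 1-based inclusive everywhere; bedGraph I/O
  converts at the boundary (0-based half-open on disk).
- Expression-rank ties break lexicographically by gene id; the k-means
  seed defaults to 0 and every stochastic step is reproducible from the
  configuration.
- Gene length for ranking is the annotated ORF length (end − start + 1).
- The multi-seed stability of silhouette model selection is checked over
  20 seeds on a 1200-gene design in the test suite; the full 5000-gene
  selection is run once in the acceptance suite. Recovery tests at
  moderate sizes (200–1500 genes) exercise every module; the acceptance
  checks use the full 5000-gene design.
- k-means with two unequal classes places its boundary slightly inside
  the majority class, so the minority-cluster share runs ~1–2 percentage
  points above the true CR share under the default noise; the class-label
  agreement with truth remains ≥ 95%.

## Known limitations

- The peak caller is validated on synthetic tracks only; its local
  background definition is a declared approximation, and real ChEC data
  with structured MNase background may need the window/flank parameters
  retuned via the configuration.
- Fisher tests in the motif tables are descriptive plumbing; no
  multiple-testing correction is applied across motifs.
- The CLI stages expect the dataset-directory layout the generator
  writes; real data must be arranged into the same TSV/bedGraph/FASTA
  formats.
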
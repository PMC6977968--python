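# nascentclass

Quantitative analysis of coactivator dependence from spike-in-normalized
nascent RNA-seq, for researchers studying how the budding-yeast
transcription coactivators **TFIID** and **SAGA** divide the genome between
them.

Newly synthesized (4-thioU-labeled) RNA measured after rapid depletion of a
coactivator subunit reports direct transcriptional dependence, free of
mRNA-stability confounds. With a fixed-ratio *S. pombe* spike-in, signal
per gene is comparable in absolute terms across samples, so genome-wide
shutdowns are measurable rather than normalized away. `nascentclass`
implements the full analysis chain around this idea:

- **Spike-in normalization and filtering** — per-gene signal
  `counts / spike_total × 10000`; genes with no measurable signal in any
  designated sample are dropped; genes are ranked by length-normalized
  baseline expression and the lowest-expressed fraction (default 5%,
  chosen via a coefficient-of-variation profile) is removed; replicates
  are averaged and per-gene log2 changes computed per contrast
  (IAA vs DMSO for degrons, mutant vs WT for deletions).
- **Two-class discovery** — k-means on the log2-change matrix over SAGA
  deletion and TFIID-degron experiments with silhouette model selection;
  the cluster most sensitive to Taf depletion is labeled *TFIID-dependent*
  and the other *coactivator-redundant* (CR). Stability re-clustering,
  expression-quintile composition, TFIID-vs-SAGA sensitivity differences
  and double-depletion additivity checks are included.
- **Promoter motif classification** — strand-aware TSS-relative
  [-400, +100] promoter windows; directed consensus search for the TATA
  box (`TATAWAW` in [-200, 0]) and the Msn2/4 stress-response element
  (`(A/C/G)AGGGG` in [-300, -50]) with per-class Fisher tests.
- **ChEC-seq promoter mapping** — spike-normalized MNase-fusion cleavage
  tracks, sliding-window peak calling against a free-MNase control
  (≥2-fold over control and local background, 0.1% FDR), summit assignment
  to promoters within [-300, +100] of the TSS, 3-of-4 replicate consensus
  with strongest-signal summit rescue, per-promoter signal and factor
  co-binding overlap.
- **ChIP-seq mark quantification** — dual spike-in normalization
  (`/ ip_spike × input_spike/input_experimental × 10000`), per-gene
  promoter mark signal over [-200, +300] (the +1 nucleosome), and
  mutant-vs-control log2 changes.
- **Synthetic-data generator** — emits every input the pipeline consumes
  (counts + sample sheet, annotation + TSS tables, genome FASTA with
  planted motifs, ChEC and ChIP bedGraphs with spike sidecars) with a
  truth table, enabling end-to-end parameter-recovery tests.

## Worked example

```python
from nascentclass import classify
from nascentclass.pipeline import analyze_counts
from nascentclass.simulate import FEATURES_PRIMARY, TAF_DEGRONS, GeneratorParams, simulate

ds = simulate(GeneratorParams(n_genes=1500, seed=0), components=("counts",))
res = analyze_counts(ds.count_matrix, ds.gene_table)
k, _ = classify.select_k(res["lct"], FEATURES_PRIMARY, range(2, 7), seed=0)
clusters = classify.cluster_genes(res["lct"], FEATURES_PRIMARY, k=2, seed=0)
assignment = classify.label_clusters(clusters, res["lct"], TAF_DEGRONS)
```

Running `python examples/01_simulate_and_classify.py` prints:

```
genes analyzed after filtering: 1280
silhouette-selected number of clusters: k=2
TFIID-dependent share: 83.7%
coactivator-redundant share: 16.3%
agreement with generator truth: 97.5%
mean fold decrease, TFIID_dependent genes under taf13_deg: 4.54x
mean fold decrease, coactivator_redundant genes under spt3_20_deg: 1.51x
```

Silhouette analysis selects two clusters; the majority class is strongly
Taf-dependent (~4.5-fold transcription decrease upon Taf13 depletion) while
the CR minority responds modestly to rapid SAGA depletion (~1.5-fold) —
the planted study structure, recovered by the pipeline. The other scripts
under `examples/` demonstrate the motif scan, the ChEC binding map and the
ChIP mark quantification, each printing the numbers it computes and what
they mean.

A thin CLI mirrors the stages over a dataset directory:

```sh
nascentclass all --seed 0 --outdir results    # simulate + every stage
nascentclass simulate|normalize|classify|motifs|chec|chip --config run.yaml
```

## Layout

```
src/nascentclass/
  annotation.py   gene coordinates, ORF classes, TSS imputation
  io.py           count-matrix / bedGraph / FASTA readers and writers
  nascent.py      spike normalization, filtering, log2 changes
  classify.py     k-means class discovery and class summaries
  motifs.py       promoter windows and consensus motif scanning
  chec.py         ChEC-seq peak calling and promoter binding consensus
  chip.py         ChIP-seq dual spike-in mark quantification
  simulate.py     synthetic-data generator with truth table
  config.py       run configuration (every threshold is a config field)
  pipeline.py     file-based stage orchestration
  cli.py          click-based command-line interface
docs/methods.md   model, parameters, numerical choices, limitations
examples/         one narrative script per capability
```
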
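"""Stage orchestration over a dataset directory.

Each stage reads the files a simulated (or real, identically formatted)
dataset directory provides, runs the corresponding module, and writes TSV
outputs under the configured output directory.  Outputs are first written
with a ``.partial`` suffix and renamed once the stage completes, so an
aborted stage never leaves files that look final.  Gene counts at every
filter step are logged so runs can be audited.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from nascentclass import annotation as ann
from nascentclass import chec as chec_mod
from nascentclass import chip as chip_mod
from nascentclass import classify as cls_mod
from nascentclass import motifs as motif_mod
from nascentclass import nascent
from nascentclass.config import RunConfig
from nascentclass.io import read_count_matrix, read_coverage, read_fasta
from nascentclass.simulate import GeneratorParams, generate_dataset

logger = logging.getLogger(__name__)


class _StageWriter:
    """Writes stage outputs atomically: .partial files renamed on success."""

    def __init__(self, outdir: Path):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.pending: list[tuple[Path, Path]] = []

    def write(self, frame: pd.DataFrame, name: str, index: bool = True) -> None:
        final = self.outdir / name
        partial = final.with_suffix(final.suffix + ".partial")
        frame.to_csv(partial, sep="\t", index=index)
        self.pending.append((partial, final))

    def commit(self) -> None:
        for partial, final in self.pending:
            partial.rename(final)
        self.pending.clear()


def _chrom_lengths(data_dir: Path) -> dict[str, int]:
    table = pd.read_csv(data_dir / "chrom_lengths.tsv", sep="\t")
    return dict(zip(table["chrom"].astype(str), table["length"].astype(int)))


def _load_annotation(cfg: RunConfig) -> pd.DataFrame:
    data_dir = Path(cfg.data_dir)
    tss = data_dir / "tss.tsv"
    return ann.read_annotation(
        data_dir / "annotation.tsv", tss_path=tss if tss.exists() else None
    )


def stage_simulate(cfg: RunConfig, **param_overrides) -> dict:
    params = GeneratorParams(seed=cfg.seed, **param_overrides)
    logger.info("simulate: n_genes=%d seed=%d", params.n_genes, params.seed)
    return generate_dataset(params, cfg.data_dir)


def stage_normalize(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    data_dir = Path(cfg.data_dir)
    cm = read_count_matrix(data_dir / "counts.tsv", data_dir / "samples.tsv")
    annotation = _load_annotation(cfg)
    analyzed = ann.analyzed_genes(annotation).intersection(cm.genes)
    logger.info(
        "normalize: %d genes total, %d after ORF-class exclusion",
        len(cm.genes), len(analyzed),
    )

    nm = nascent.spike_normalize(cm, cfg.norm_constant).loc[analyzed]
    groups = cm.samples["group"]
    filter_samples = list(groups.index[groups.isin(cfg.filter_groups)])
    baseline_samples = list(groups.index[groups.isin(cfg.baseline_groups)])
    nonzero = nascent.filter_nonzero(nm, filter_samples)

    lengths = annotation["end"] - annotation["start"] + 1
    ranking = nascent.rank_expression(nm.loc[nonzero], baseline_samples, lengths)
    cv = nascent.cv_profile(
        nm.loc[nonzero],
        groups.loc[filter_samples].to_dict(),
        cfg.cv_candidate_fractions,
        ranking,
    )
    retained = nascent.apply_expression_cutoff(nonzero, ranking, cfg.cutoff_fraction)
    logger.info(
        "filter cascade: %d -> %d (nonzero) -> %d (expression cutoff)",
        len(analyzed), len(nonzero), len(retained),
    )

    means = nascent.average_replicates(nm.loc[retained], groups.to_dict())
    contrasts = {k: tuple(v) for k, v in cfg.contrasts.items()}
    covered = {k: v for k, v in contrasts.items() if k not in cfg.unfiltered_contrasts}
    uncovered = {k: v for k, v in contrasts.items() if k in cfg.unfiltered_contrasts}
    lct = nascent.log2_change(means, covered, on_zero="error")
    if uncovered:
        lct = lct.join(nascent.log2_change(means, uncovered, on_zero="drop"))

    writer = _StageWriter(Path(cfg.outdir))
    writer.write(nm, "normalized.tsv")
    writer.write(ranking, "ranking.tsv")
    writer.write(cv, "cv_profile.tsv", index=False)
    writer.write(pd.DataFrame(index=retained), "retained_genes.tsv")
    writer.write(means, "condition_means.tsv")
    writer.write(lct, "log2_change.tsv")
    writer.commit()
    return {"normalized": nm, "ranking": ranking, "lct": lct, "means": means}


def _read_lct(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    lct = pd.read_csv(outdir / "log2_change.tsv", sep="\t", index_col="gene_id")
    ranking = pd.read_csv(outdir / "ranking.tsv", sep="\t", index_col="gene_id")
    return lct, ranking


def stage_classify(cfg: RunConfig) -> cls_mod.ClassAssignment:
    lct, ranking = _read_lct(cfg)
    k, scores = cls_mod.select_k(
        lct, cfg.feature_contrasts, cfg.k_range, seed=cfg.seed,
        n_init=cfg.kmeans_restarts,
    )
    logger.info("select_k: silhouette scores %s -> k=%d", scores, k)
    clusters = cls_mod.cluster_genes(
        lct, cfg.feature_contrasts, k=2, seed=cfg.seed, n_init=cfg.kmeans_restarts
    )
    assignment = cls_mod.label_clusters(
        clusters, lct, cfg.taf_contrasts, k_selected=k,
        silhouette_by_k=scores, seed=cfg.seed,
    )
    alt = cls_mod.cluster_genes(
        lct, cfg.alt_feature_contrasts, k=2, seed=cfg.seed, n_init=cfg.kmeans_restarts
    )
    alt_assignment = cls_mod.label_clusters(alt, lct, cfg.taf_contrasts, seed=cfg.seed)
    overlap = cls_mod.stability_overlap(assignment.labels, alt_assignment.labels)
    logger.info("stability overlap vs alternative feature set: %.4f", overlap)

    quintiles = cls_mod.quintile_composition(
        ranking, assignment, cfg.n_quantile_bins, cfg.top_percent
    )
    cr_genes = assignment.gene_set(cls_mod.COACTIVATOR_REDUNDANT)
    sens = cls_mod.sensitivity_difference(
        lct, "taf13_deg", "spt3_7_deg", ranking, subset=cr_genes
    )
    addit = cls_mod.additivity_check(
        lct, "taf13_deg", "spt3_20_deg", "taf13_spt3_deg", assignment
    )

    writer = _StageWriter(Path(cfg.outdir))
    class_table = lct.copy()
    class_table.insert(0, "class", assignment.labels)
    writer.write(class_table, "class_table.tsv")
    writer.write(
        pd.DataFrame(
            {"k": list(assignment.silhouette_by_k), "silhouette": list(assignment.silhouette_by_k.values())}
        ).assign(selected=lambda d: d["k"] == assignment.k_selected),
        "silhouette.tsv",
        index=False,
    )
    writer.write(quintiles, "quintile_table.tsv")
    writer.write(sens, "sensitivity_difference.tsv")
    writer.write(addit, "additivity.tsv")
    writer.write(
        pd.DataFrame([{"stability_overlap": overlap}]), "stability.tsv", index=False
    )
    writer.commit()
    return assignment


def stage_motifs(cfg: RunConfig) -> pd.DataFrame:
    data_dir = Path(cfg.data_dir)
    genome = read_fasta(data_dir / "genome.fa")
    annotation = _load_annotation(cfg)
    class_path = Path(cfg.outdir) / "class_table.tsv"
    if class_path.exists():
        classes = pd.read_csv(class_path, sep="\t", index_col="gene_id")["class"]
        genes = classes.index
    else:
        genes = ann.analyzed_genes(annotation)
        classes = None
    windows = motif_mod.extract_promoters(
        genome, annotation.loc[genes], cfg.promoter_upstream, cfg.promoter_downstream
    )
    catalogue = {
        name: (spec["consensus"], tuple(spec["range"])) for name, spec in cfg.motifs.items()
    }
    calls = motif_mod.scan_all(windows, catalogue, cfg.scan_both_strands)
    writer = _StageWriter(Path(cfg.outdir))
    writer.write(calls, "motif_calls.tsv")
    if classes is not None:
        table = motif_mod.class_motif_table(calls, classes)
        writer.write(table, "class_motif_table.tsv", index=False)
    writer.commit()
    return calls


def stage_chec(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    data_dir = Path(cfg.data_dir)
    chec_dir = data_dir / "chec"
    sheet = pd.read_csv(chec_dir / "chec_samples.tsv", sep="\t")
    lengths = _chrom_lengths(data_dir)
    annotation = _load_annotation(cfg)
    analyzed = annotation.loc[ann.analyzed_genes(annotation)]

    control_row = sheet[sheet["factor"] == "control"].iloc[0]
    control = chec_mod.normalize_chec(
        read_coverage(
            chec_dir / f"{control_row['track']}.bedgraph",
            int(control_row["spike_total"]), lengths, label=str(control_row["track"]),
        ),
        cfg.norm_constant,
    )
    tables: dict[str, pd.DataFrame] = {}
    writer = _StageWriter(Path(cfg.outdir))
    for factor, rows in sheet[sheet["factor"] != "control"].groupby("factor"):
        assignments, tracks = [], []
        for row in rows.itertuples():
            track = chec_mod.normalize_chec(
                read_coverage(
                    chec_dir / f"{row.track}.bedgraph", int(row.spike_total),
                    lengths, label=str(row.track),
                ),
                cfg.norm_constant,
            )
            peaks = chec_mod.call_peaks(
                track, control,
                window=cfg.chec_window, step=cfg.chec_step,
                fold_min=cfg.chec_fold_min, local_fold_min=cfg.chec_local_fold_min,
                local_flank=cfg.chec_local_flank, fdr=cfg.chec_fdr,
            )
            logger.info("chec %s: %d peaks", row.track, len(peaks))
            assignments.append(
                chec_mod.assign_peaks_to_promoters(peaks, analyzed, tuple(cfg.assign_window))
            )
            tracks.append(track)
        table = chec_mod.replicate_consensus(
            assignments, analyzed, tracks,
            assign_window=tuple(cfg.assign_window),
            signal_window=cfg.signal_window,
            consensus_fraction=cfg.consensus_fraction,
        )
        logger.info(
            "chec %s: %d consensus-bound promoters",
            factor, int(table["consensus_bound"].sum()),
        )
        tables[str(factor)] = table
        writer.write(table, f"chec_binding_{factor}.tsv")
    if len(tables) > 1:
        writer.write(chec_mod.factor_overlap(tables), "chec_overlap.tsv", index=False)
    writer.commit()
    return tables


def stage_chip(cfg: RunConfig) -> pd.DataFrame:
    data_dir = Path(cfg.data_dir)
    chip_dir = data_dir / "chip"
    sheet = pd.read_csv(chip_dir / "chip_samples.tsv", sep="\t")
    lengths = _chrom_lengths(data_dir)
    annotation = _load_annotation(cfg)
    analyzed = annotation.loc[ann.analyzed_genes(annotation)]

    signals = {}
    groups = {}
    for row in sheet.itertuples():
        sample = chip_mod.ChipSample(
            ip_track=read_coverage(
                chip_dir / f"{row.track}.bedgraph", int(row.ip_spike_total),
                lengths, label=str(row.track),
            ),
            ip_spike_total=int(row.ip_spike_total),
            input_spike_total=int(row.input_spike_total),
            input_experimental_total=int(row.input_experimental_total),
            label=str(row.track),
        )
        track = chip_mod.normalize_chip(sample, cfg.norm_constant)
        signals[row.track] = chip_mod.gene_mark_signal(
            track, analyzed, tuple(cfg.chip_gene_window)
        )
        groups[row.track] = str(row.genotype)
    signal_df = pd.DataFrame(signals)
    contrasts = {k: tuple(v) for k, v in cfg.chip_contrasts.items()}
    changes = chip_mod.mark_log2_change(signal_df, groups, contrasts)

    writer = _StageWriter(Path(cfg.outdir))
    writer.write(signal_df, "chip_gene_signal.tsv")
    writer.write(changes, "chip_log2_change.tsv")
    writer.commit()
    return changes


def recovery_report(cfg: RunConfig) -> pd.DataFrame:
    """Compare pipeline estimates with the generator truth table."""
    truth = pd.read_csv(Path(cfg.data_dir) / "truth.tsv", sep="\t", index_col="gene_id")
    class_table = pd.read_csv(
        Path(cfg.outdir) / "class_table.tsv", sep="\t", index_col="gene_id"
    )
    rows = []
    common = class_table.index.intersection(truth.index)
    agree = (
        class_table.loc[common, "class"] == truth.loc[common, "true_class"]
    ).mean()
    rows.append({"metric": "class_label_agreement", "value": float(agree)})
    for cond in [c for c in class_table.columns if c != "class"]:
        col = f"effect_{cond}"
        if col not in truth.columns:
            continue
        for cls, sub in class_table.groupby("class"):
            genes = sub.index.intersection(truth.index[truth["true_class"] == cls])
            est = class_table.loc[genes, cond].dropna().mean()
            true = truth.loc[genes, col].mean()
            rows.append(
                {
                    "metric": f"mean_log2fc[{cond},{cls}]",
                    "value": float(est),
                    "truth": float(true),
                    "abs_error": float(abs(est - true)),
                }
            )
    report = pd.DataFrame(rows)
    writer = _StageWriter(Path(cfg.outdir))
    writer.write(report, "recovery_report.tsv", index=False)
    writer.commit()
    return report


STAGES = {
    "normalize": stage_normalize,
    "classify": stage_classify,
    "motifs": stage_motifs,
    "chec": stage_chec,
    "chip": stage_chip,
}


def run_all(cfg: RunConfig, **simulate_overrides) -> None:
    stage_simulate(cfg, **simulate_overrides)
    for name, stage in STAGES.items():
        logger.info("stage %s", name)
        stage(cfg)
    recovery_report(cfg)


def analyze_counts(
    cm,
    gene_table: pd.DataFrame,
    contrasts: dict[str, tuple[str, str]] | None = None,
    cutoff_fraction: float = 0.05,
    unfiltered_contrasts: tuple[str, ...] | None = None,
    norm_constant: float = 10000.0,
) -> dict:
    """In-memory normalization chain: counts -> filtered log2-change table.

    Convenience wrapper used by recovery analyses and the worked examples;
    the file-based stages above expose the same computation over a dataset
    directory.
    """
    from nascentclass.simulate import (
        BASELINE_GROUPS,
        CONTRASTS,
        DOUBLE_DEGRONS,
        FILTER_GROUPS,
    )

    contrasts = dict(CONTRASTS if contrasts is None else contrasts)
    if unfiltered_contrasts is None:
        unfiltered_contrasts = tuple(DOUBLE_DEGRONS)
    analyzed = ann.analyzed_genes(gene_table).intersection(cm.genes)
    nm = nascent.spike_normalize(cm, norm_constant).loc[analyzed]
    groups = cm.samples["group"]
    filter_samples = list(groups.index[groups.isin(FILTER_GROUPS)])
    baseline_samples = list(groups.index[groups.isin(BASELINE_GROUPS)])
    nonzero = nascent.filter_nonzero(nm, filter_samples)
    lengths = gene_table["end"] - gene_table["start"] + 1
    ranking = nascent.rank_expression(nm.loc[nonzero], baseline_samples, lengths)
    retained = nascent.apply_expression_cutoff(nonzero, ranking, cutoff_fraction)
    means = nascent.average_replicates(nm.loc[retained], groups.to_dict())
    covered = {k: v for k, v in contrasts.items() if k not in unfiltered_contrasts}
    uncovered = {k: v for k, v in contrasts.items() if k in unfiltered_contrasts}
    lct = nascent.log2_change(means, covered, on_zero="error")
    if uncovered:
        lct = lct.join(nascent.log2_change(means, uncovered, on_zero="drop"))
    return {
        "normalized": nm,
        "ranking": ranking,
        "retained": retained,
        "means": means,
        "lct": lct,
    }
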
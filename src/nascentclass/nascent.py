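"""Spike-in normalization of nascent RNA counts and per-gene log2 changes.

The quantification chain: divide each gene's counts by the sample's
spike-in total and multiply by a constant (default 10000); drop genes with
no measurable signal in any of the designated filter samples; rank genes by
length-normalized baseline expression and remove the lowest-expressed
fraction (default 5%, selected by the coefficient-of-variation profile);
average biological replicates; and compute log2(treated/control) per gene
per contrast.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Arbitrary scaling constant applied after spike division.
DEFAULT_NORM_CONSTANT = 10000.0
#: Fraction of lowest-expressed genes removed by the expression cutoff.
DEFAULT_CUTOFF_FRACTION = 0.05


def spike_normalize(cm, C: float = DEFAULT_NORM_CONSTANT) -> pd.DataFrame:
    """Per-sample spike-in normalization: counts / spike_total * C.

    Joint rescaling of a sample's counts and spike total cancels exactly, so
    the result is independent of sequencing depth and capture efficiency.
    """
    if C <= 0:
        raise ValueError("normalization constant must be positive")
    spikes = cm.spike_totals.astype(float)
    nm = cm.counts.astype(float).div(spikes, axis=1) * C
    nm.attrs["norm_constant"] = float(C)
    return nm


def filter_nonzero(nm: pd.DataFrame, filter_samples: Sequence[str]) -> pd.Index:
    """Genes with signal > 0 in *every* listed sample.

    A single zero among the filter samples excludes the gene; this mirrors a
    no-measurable-signal filter applied across all relevant experiments.
    """
    filter_samples = list(filter_samples)
    if not filter_samples:
        raise ValueError("empty filter sample set is degenerate")
    missing = [s for s in filter_samples if s not in nm.columns]
    if missing:
        raise KeyError(f"filter sample(s) not in matrix: {missing}")
    keep = (nm[filter_samples] > 0).all(axis=1)
    logger.info("nonzero filter: %d of %d genes retained", int(keep.sum()), len(nm))
    return nm.index[keep]


def rank_expression(
    nm: pd.DataFrame,
    baseline_samples: Sequence[str],
    lengths: pd.Series,
) -> pd.DataFrame:
    """Rank genes by mean length-normalized signal over baseline samples.

    Returns a DataFrame with ``mean_signal`` (per-bp normalized signal
    averaged over the baseline samples) and ``rank`` (1 = most expressed;
    ties broken by gene_id lexicographic order).
    """
    baseline_samples = list(baseline_samples)
    missing_genes = nm.index.difference(lengths.index)
    if len(missing_genes):
        raise KeyError(f"missing length for gene(s): {list(missing_genes[:5])}")
    lens = lengths.loc[nm.index].astype(float)
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0][:5])
        raise ValueError(f"non-positive length for gene(s): {bad}")
    mean_signal = nm[baseline_samples].mean(axis=1) / lens
    order = mean_signal.to_frame("mean_signal")
    order = order.sort_values(
        by=["mean_signal"], ascending=False, kind="mergesort"
    )
    # stable sort on descending value; break remaining ties lexicographically
    order = (
        order.reset_index()
        .sort_values(by=["mean_signal", "gene_id"], ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
    )
    order["rank"] = np.arange(1, len(order) + 1)
    return order


def apply_expression_cutoff(
    genes: Iterable[str],
    ranking: pd.DataFrame,
    f: float = DEFAULT_CUTOFF_FRACTION,
) -> pd.Index:
    """Drop the lowest-expressed fraction ``f`` of ``genes``.

    The number removed is floor(f*N + 0.5) (round half up), so 5% of 5158
    genes removes 258 and retains 4900.
    """
    if not 0 <= f < 1:
        raise ValueError("cutoff fraction must lie in [0, 1)")
    genes = pd.Index(genes)
    missing = genes.difference(ranking.index)
    if len(missing):
        raise KeyError(f"gene(s) absent from ranking: {list(missing[:5])}")
    n_remove = int(np.floor(f * len(genes) + 0.5))
    if n_remove == 0:
        return genes
    ranks = ranking.loc[genes, "rank"].sort_values()
    kept = ranks.index[: len(genes) - n_remove]
    logger.info(
        "expression cutoff f=%.3g: removed %d of %d genes, retained %d",
        f, n_remove, len(genes), len(kept),
    )
    return pd.Index(kept)


def cv_profile(
    nm: pd.DataFrame,
    replicate_groups: Mapping[str, str],
    candidate_fractions: Sequence[float],
    ranking: pd.DataFrame,
) -> pd.DataFrame:
    """Mean replicate coefficient of variation after low-expression filtering.

    For each candidate fraction ``f`` the bottom ``f`` of genes (by
    ``ranking``) is removed; the CV (sd/mean across replicates) is computed
    per gene within each replicate group, averaged over genes within each
    group and then over groups.  The row with the largest relative CV
    decrease versus the previous candidate is marked ``best``.  Used to pick
    the expression cutoff (the study design settles on 5%).
    """
    groups: dict[str, list[str]] = {}
    for sample, group in replicate_groups.items():
        groups.setdefault(group, []).append(sample)
    for group, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"replicate group {group!r} has fewer than 2 members")

    rows = []
    for f in candidate_fractions:
        if not 0 <= f < 1:
            raise ValueError(f"fraction {f} outside [0, 1)")
        kept = apply_expression_cutoff(nm.index, ranking, f)
        sub = nm.loc[kept]
        group_cvs = []
        for members in groups.values():
            block = sub[members]
            mean = block.mean(axis=1)
            sd = block.std(axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = (sd / mean).replace([np.inf, -np.inf], np.nan)
            group_cvs.append(float(cv.mean()))
        rows.append({"fraction": float(f), "mean_cv": float(np.mean(group_cvs))})
    table = pd.DataFrame(rows)
    prev = table["mean_cv"].shift(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (prev - table["mean_cv"]) / prev
    table["relative_decrease"] = rel.replace([np.inf, -np.inf], np.nan)
    table["best"] = False
    if len(table) > 1 and table["relative_decrease"].notna().any():
        table.loc[table["relative_decrease"].idxmax(skipna=True), "best"] = True
    return table


def average_replicates(
    nm: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean of normalized values within each replicate group.

    ``groups`` maps sample_id -> group name (e.g. condition+treatment);
    returns genes x groups.
    """
    missing = [s for s in groups if s not in nm.columns]
    if missing:
        raise KeyError(f"sample(s) not in matrix: {missing}")
    frame = nm[list(groups)]
    return frame.T.groupby(pd.Series(groups)).mean().T


def log2_change(
    means: pd.DataFrame,
    contrasts: Mapping[str, tuple[str, str]],
    on_zero: str = "error",
) -> pd.DataFrame:
    """log2(mean_treated / mean_control) per gene per contrast.

    ``contrasts`` maps contrast name -> (treated group, control group).
    Zero means among retained genes normally signal a filter
    misconfiguration and raise; ``on_zero="drop"`` instead excludes the
    offending genes from the affected contrast (reported via logging), for
    contrasts whose samples are outside the zero-filter set.
    """
    if on_zero not in {"error", "drop"}:
        raise ValueError("on_zero must be 'error' or 'drop'")
    out = {}
    for name, (treated, control) in contrasts.items():
        for group in (treated, control):
            if group not in means.columns:
                raise KeyError(f"contrast {name!r}: unknown group {group!r}")
        t = means[treated].astype(float)
        c = means[control].astype(float)
        bad = (t <= 0) | (c <= 0)
        if bad.any():
            if on_zero == "error":
                genes = list(means.index[bad][:5])
                raise ValueError(
                    f"contrast {name!r}: non-positive mean for gene(s) {genes}; "
                    "check the zero filter configuration"
                )
            logger.info(
                "contrast %s: dropped %d gene(s) with zero mean", name, int(bad.sum())
            )
        ratio = pd.Series(np.where(bad, np.nan, t / c), index=means.index)
        out[name] = np.log2(ratio)
    table = pd.DataFrame(out, index=means.index)
    if on_zero == "drop":
        return table
    return table
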
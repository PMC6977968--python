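"""Two-class discovery on the log2-change matrix and class-level analyses.

Genes are clustered by k-means on their log2 transcription changes across
coactivator perturbations (SAGA subunit deletions plus TFIID-subunit
degrons).  Silhouette analysis selects the number of clusters; with the
study's statistical structure two clusters separate best.  The cluster most
sensitive to Taf depletion is labeled TFIID-dependent, the other
coactivator-redundant (CR).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

TFIID_DEPENDENT = "TFIID_dependent"
COACTIVATOR_REDUNDANT = "coactivator_redundant"

DEFAULT_K_RANGE = range(2, 7)
DEFAULT_N_INIT = 10


def _feature_matrix(lct: pd.DataFrame, feature_contrasts: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in feature_contrasts if c not in lct.columns]
    if missing:
        raise KeyError(f"unknown feature contrast(s): {missing}")
    feats = lct[list(feature_contrasts)]
    if feats.isna().any().any():
        raise ValueError("missing values in feature columns; filter genes first")
    return feats


def cluster_genes(
    lct: pd.DataFrame,
    feature_contrasts: Sequence[str],
    k: int,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
) -> pd.Series:
    """k-means cluster assignment on unscaled log2-change features.

    Squared-Euclidean objective, k-means++ initialization, ``n_init``
    restarts with the best-objective run returned; deterministic for a given
    seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    feats = _feature_matrix(lct, feature_contrasts)
    n_distinct = len(np.unique(feats.to_numpy(), axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct feature rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(feats.to_numpy())
    out = pd.Series(labels, index=feats.index, name="cluster")
    out.attrs["inertia"] = float(km.inertia_)
    return out


def select_k(
    lct: pd.DataFrame,
    feature_contrasts: Sequence[str],
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
) -> tuple[int, dict[int, float]]:
    """Silhouette model selection over ``k_range``; ties go to the smaller k."""
    feats = _feature_matrix(lct, feature_contrasts).to_numpy()
    scores: dict[int, float] = {}
    for k in k_range:
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(feats)
        scores[k] = float(silhouette_score(feats, labels))
    best = max(sorted(scores), key=lambda k: scores[k])
    # sorted() + max keeps the smallest k among exact ties
    return best, scores


@dataclass
class ClassAssignment:
    """Per-gene class labels with clustering diagnostics."""

    labels: pd.Series
    k_selected: int
    silhouette_by_k: dict[int, float]
    cluster_means: pd.DataFrame
    seed: int
    size_consistent: bool = True

    @property
    def genes(self) -> pd.Index:
        return self.labels.index

    def gene_set(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def label_clusters(
    clusters: pd.Series,
    lct: pd.DataFrame,
    taf_contrasts: Sequence[str],
    k_selected: int = 2,
    silhouette_by_k: dict[int, float] | None = None,
    seed: int = 0,
) -> ClassAssignment:
    """Name the two clusters by Taf-degron sensitivity.

    The cluster with the more negative mean log2 change over the Taf-degron
    contrasts becomes TFIID-dependent.  With the study's structure this is
    also the larger cluster; if the two criteria disagree, labeling follows
    Taf sensitivity and a warning is logged.
    """
    uniq = sorted(pd.unique(clusters))
    if len(uniq) != 2:
        raise ValueError(f"expected 2 clusters, got {len(uniq)}")
    means = lct.loc[clusters.index].groupby(clusters).mean()
    taf_mean = means[list(taf_contrasts)].mean(axis=1)
    tfiid_cluster = taf_mean.idxmin()
    sizes = clusters.value_counts()
    size_consistent = sizes.idxmax() == tfiid_cluster
    if not size_consistent:
        logger.warning(
            "Taf-sensitive cluster (%s) is not the larger cluster; "
            "labeling follows Taf sensitivity", tfiid_cluster
        )
    labels = clusters.map(
        lambda c: TFIID_DEPENDENT if c == tfiid_cluster else COACTIVATOR_REDUNDANT
    ).rename("class")
    means.index = [
        TFIID_DEPENDENT if c == tfiid_cluster else COACTIVATOR_REDUNDANT
        for c in means.index
    ]
    return ClassAssignment(
        labels=labels,
        k_selected=k_selected,
        silhouette_by_k=silhouette_by_k or {},
        cluster_means=means,
        seed=seed,
        size_consistent=size_consistent,
    )


def stability_overlap(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Fraction of genes with identical labels under optimal label matching.

    Used to check clustering robustness when re-clustering with an
    alternative feature set; the matching resolves arbitrary label swaps.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two assignments")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    cats_a, cats_b = list(pd.unique(a)), list(pd.unique(b))
    best = 0.0
    for perm in itertools.permutations(cats_b, len(cats_b)):
        mapping = dict(zip(cats_a, perm))
        agree = float((a.map(mapping) == b).mean())
        best = max(best, agree)
    return best


def quintile_composition(
    ranking: pd.DataFrame,
    assignment: ClassAssignment,
    n_bins: int = 5,
    top_percent: float = 10.0,
) -> pd.DataFrame:
    """Class counts per expression quantile bin.

    Genes are split into ``n_bins`` near-equal bins by expression rank (bin
    ``n_bins`` holds the most-expressed genes; bin sizes differ by at most
    one).  A ``top`` row reports the top ``top_percent``% of expressed
    genes.
    """
    genes = assignment.genes.intersection(ranking.index)
    ranks = ranking.loc[genes, "rank"].sort_values()  # rank 1 = most expressed
    ordered = ranks.index  # most expressed first
    chunks = np.array_split(np.asarray(ordered), n_bins)
    rows = []
    for i, chunk in enumerate(chunks):
        bin_id = n_bins - i  # highest bin number = most expressed
        labels = assignment.labels.loc[chunk]
        row = {"bin": bin_id, "n": len(chunk)}
        for cls in (TFIID_DEPENDENT, COACTIVATOR_REDUNDANT):
            row[cls] = int((labels == cls).sum())
        row["cr_fraction"] = row[COACTIVATOR_REDUNDANT] / max(len(chunk), 1)
        rows.append(row)
    n_top = max(1, int(round(len(ordered) * top_percent / 100.0)))
    top = assignment.labels.loc[ordered[:n_top]]
    rows.append(
        {
            "bin": "top",
            "n": n_top,
            TFIID_DEPENDENT: int((top == TFIID_DEPENDENT).sum()),
            COACTIVATOR_REDUNDANT: int((top == COACTIVATOR_REDUNDANT).sum()),
            "cr_fraction": float((top == COACTIVATOR_REDUNDANT).mean()),
        }
    )
    table = pd.DataFrame(rows).set_index("bin")
    return table.sort_index(key=lambda idx: [99 if b == "top" else b for b in idx])


def sensitivity_difference(
    lct: pd.DataFrame,
    contrast_taf: str,
    contrast_saga: str,
    ranking: pd.DataFrame,
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene difference in sensitivity to rapid TFIID vs SAGA depletion.

    delta = log2FC(Taf degron) - log2FC(SAGA degron); negative delta means
    the gene is more Taf-sensitive.  ``subset`` restricts the table (the
    headline analysis uses CR genes only).  Summary statistics live in
    ``DataFrame.attrs``.
    """
    genes = pd.Index(subset) if subset is not None else lct.index
    delta = lct.loc[genes, contrast_taf] - lct.loc[genes, contrast_saga]
    out = pd.DataFrame({"delta": delta})
    out["rank"] = ranking["rank"].reindex(genes)
    out.attrs["fraction_taf_more_sensitive"] = float((delta < 0).mean())
    out.attrs["mean_delta"] = float(delta.mean())
    return out


def additivity_check(
    lct: pd.DataFrame,
    single_contrast_1: str,
    single_contrast_2: str,
    double_contrast: str,
    assignment: ClassAssignment | None = None,
) -> pd.DataFrame:
    """Excess defect of simultaneous depletion over the sum of single depletions.

    excess = log2FC(double) - [log2FC(single1) + log2FC(single2)]; a
    negative class mean indicates a synergistic (greater-than-additive)
    transcription defect.  Per-class means are in ``DataFrame.attrs``.
    """
    excess = lct[double_contrast] - (lct[single_contrast_1] + lct[single_contrast_2])
    out = pd.DataFrame({"excess": excess})
    if assignment is not None:
        out["class"] = assignment.labels.reindex(out.index)
        out.attrs["class_mean_excess"] = (
            out.dropna().groupby("class")["excess"].mean().to_dict()
        )
    return out
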
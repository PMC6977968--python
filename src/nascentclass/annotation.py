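"""Gene annotation: coordinates, ORF classification and transcription start sites.

Internal genomic coordinates are uniformly 1-based and inclusive, matching
the SGD/GFF convention.  An annotation set is a :class:`pandas.DataFrame`
indexed by ``gene_id`` with columns ``chrom``, ``start``, ``end``,
``strand``, ``orf_class``, ``tss`` and ``tss_imputed``.

Genes classified as dubious, pseudogene or transposable element are retained
in the table but flagged via :func:`analyzed_genes`, which returns the gene
set the downstream analysis actually uses.  Genes lacking an annotated TSS
receive one imputed 100 bp upstream of the start codon (strand-aware).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ORF_CLASSES = frozenset(
    {"verified", "uncharacterized", "dubious", "pseudogene", "transposable_element"}
)
#: ORF classes excluded from the analyzed gene set.
EXCLUDED_ORF_CLASSES = frozenset({"dubious", "pseudogene", "transposable_element"})

#: Distance upstream of the start codon at which a missing TSS is imputed.
TSS_IMPUTE_OFFSET = 100

_REQUIRED_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "orf_class"]


def _normalize_orf_class(value: str) -> str:
    v = str(value).strip().lower().replace(" ", "_").replace("orf|", "")
    aliases = {
        "transposable_element_gene": "transposable_element",
        "pseudogene": "pseudogene",
    }
    return aliases.get(v, v)


def _from_gff3(path: Path) -> pd.DataFrame:
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    # pyranges uses 0-based half-open starts; internal convention is 1-based.
    out = pd.DataFrame(
        {
            "gene_id": df["ID"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int) + 1,
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str),
            "orf_class": df.get("orf_classification", pd.Series(["verified"] * len(df))),
        }
    )
    if "Feature" in df.columns:
        out = out[df["Feature"].isin(["gene", "ORF"]).to_numpy()]
    return out


def read_annotation(
    path: str | Path,
    tss_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a gene annotation table (TSV or GFF3) and merge/impute TSSs.

    Parameters
    ----------
    path:
        Either a TSV with columns ``gene_id chrom start end strand orf_class``
        or a GFF3 file whose records carry ``ID`` and ``orf_classification``
        attributes.
    tss_path:
        Optional TSV with columns ``gene_id tss`` (and optionally ``chrom``,
        used for a consistency check).  Genes absent from the table get an
        imputed TSS 100 bp upstream of the start codon.

    Returns
    -------
    pandas.DataFrame indexed by ``gene_id``.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        table = _from_gff3(path)
    else:
        table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"annotation {path} lacks required columns: {missing}")

    table = table.copy()
    table["orf_class"] = table["orf_class"].map(_normalize_orf_class)
    unknown = set(table["orf_class"]) - ORF_CLASSES
    if unknown:
        raise ValueError(f"unknown orf_class values: {sorted(unknown)}")
    bad_strand = set(table["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"unknown strand symbol(s): {sorted(bad_strand)}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id(s) in annotation: {dups[:5]}")
    if (table["start"] > table["end"]).any():
        bad = table.loc[table["start"] > table["end"], "gene_id"].tolist()
        raise ValueError(f"start > end for gene(s): {bad[:5]}")

    table = table.set_index("gene_id")
    table["start"] = table["start"].astype(int)
    table["end"] = table["end"].astype(int)

    tss = pd.Series(pd.NA, index=table.index, dtype="Int64")
    if tss_path is not None:
        tss_table = pd.read_csv(tss_path, sep="\t", dtype={"gene_id": str, "chrom": str})
        if not {"gene_id", "tss"} <= set(tss_table.columns):
            raise ValueError("TSS table needs columns gene_id and tss")
        tss_table = tss_table.set_index("gene_id")
        common = tss_table.index.intersection(table.index)
        if "chrom" in tss_table.columns:
            mismatch = common[
                tss_table.loc[common, "chrom"].astype(str).to_numpy()
                != table.loc[common, "chrom"].astype(str).to_numpy()
            ]
            if len(mismatch):
                raise ValueError(
                    f"TSS on wrong chromosome for gene(s): {list(mismatch[:5])}"
                )
        tss.loc[common] = tss_table.loc[common, "tss"].astype(int).to_numpy()
    table["tss"] = tss
    return impute_tss(table)


def impute_tss(annotation: pd.DataFrame, offset: int = TSS_IMPUTE_OFFSET) -> pd.DataFrame:
    """Fill missing TSSs at ``offset`` bp upstream of the start codon.

    Plus-strand genes get ``start - offset``; minus-strand genes ``end +
    offset``.  Adds/updates the boolean ``tss_imputed`` column; explicit TSS
    values always win.
    """
    table = annotation.copy()
    missing = table["tss"].isna()
    plus = table["strand"] == "+"
    table["tss_imputed"] = missing
    table.loc[missing & plus, "tss"] = table.loc[missing & plus, "start"] - offset
    table.loc[missing & ~plus, "tss"] = table.loc[missing & ~plus, "end"] + offset
    table["tss"] = table["tss"].astype(int)
    n_imputed = int(missing.sum())
    if n_imputed:
        logger.info("imputed TSS at -%d bp for %d gene(s)", offset, n_imputed)
    return table


def analyzed_genes(annotation: pd.DataFrame) -> pd.Index:
    """Gene ids whose ORF class is not dubious/pseudogene/transposable element."""
    keep = ~annotation["orf_class"].isin(EXCLUDED_ORF_CLASSES)
    return annotation.index[keep]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()
    cols = [c for c in ["gene_id", "chrom", "start", "end", "strand", "orf_class", "tss", "tss_imputed"] if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)
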
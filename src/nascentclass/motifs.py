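"""Strand-aware promoter windows and consensus motif classification.

A promoter is the TSS-relative window [-400, +100] read 5'->3' along the
gene's strand.  Consensus motifs are IUPAC strings; a promoter contains a
motif if at least one full match *starts* inside the motif's search range.
Two motifs matter for the gene-class analysis: the TATA box (TATAWAW,
searched from 200 bp upstream to the TSS) and the Msn2/4 stress-response
element ((A/C/G)AGGGG, searched 300 to 50 bp upstream).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

PROMOTER_UPSTREAM = 400
PROMOTER_DOWNSTREAM = 100

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: name -> (IUPAC consensus, TSS-relative search range, inclusive)
MOTIFS: dict[str, tuple[str, tuple[int, int]]] = {
    "TATA": ("TATAWAW", (-200, 0)),
    "MSN24": ("VAGGGG", (-300, -50)),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC consensus into an overlap-aware regex."""
    parts = []
    for base in motif.upper():
        if base not in IUPAC:
            raise ValueError(f"invalid IUPAC code {base!r} in motif {motif!r}")
        expansion = IUPAC[base]
        parts.append(base if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass
class PromoterWindow:
    """Promoter sequence in TSS-relative coordinates along the gene's strand.

    ``rel_start`` is the TSS-relative position of the first base of
    ``sequence`` (-400 for a full window); ``truncated`` flags windows
    clipped at a chromosome end.
    """

    gene_id: str
    tss: int
    strand: str
    sequence: str
    rel_start: int = -PROMOTER_UPSTREAM
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifCall:
    gene_id: str
    motif_name: str
    present: bool
    hits: list[int]  # TSS-relative start positions

    def __post_init__(self) -> None:
        assert self.present == bool(self.hits)


def extract_promoters(
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> dict[str, PromoterWindow]:
    """Extract TSS-relative [-upstream, +downstream] windows for every gene.

    Plus-strand genes read the genomic span [tss-upstream, tss+downstream];
    minus-strand genes read [tss-downstream, tss+upstream] and are
    reverse-complemented so the returned sequence runs 5'->3' along the
    gene.  Windows that run off a chromosome end are truncated and flagged.
    """
    windows: dict[str, PromoterWindow] = {}
    for gene_id, row in annotation.iterrows():
        chrom = row["chrom"]
        if chrom not in genome:
            raise KeyError(f"gene {gene_id}: chromosome {chrom!r} not in genome")
        seq = genome[chrom]
        tss = int(row["tss"])
        strand = row["strand"]
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        clipped_lo, clipped_hi = max(lo, 1), min(hi, len(seq))
        sub = seq[clipped_lo - 1 : clipped_hi]
        truncated = (clipped_lo != lo) or (clipped_hi != hi)
        if strand == "+":
            rel_start = clipped_lo - tss
        else:
            sub = reverse_complement(sub)
            rel_start = tss - clipped_hi
        windows[gene_id] = PromoterWindow(
            gene_id=str(gene_id),
            tss=tss,
            strand=strand,
            sequence=sub,
            rel_start=rel_start,
            truncated=truncated,
        )
    return windows


def scan_motif(
    window: PromoterWindow,
    motif: str,
    search_range: tuple[int, int],
    both_strands: bool = False,
) -> MotifCall:
    """Find consensus matches whose first base lies inside ``search_range``.

    Range endpoints are TSS-relative and inclusive; matching is on the
    promoter's sense strand unless ``both_strands`` is set, in which case a
    reverse-strand match is reported at the sense-strand position of its
    leftmost base.
    """
    lo, hi = search_range
    if lo > hi:
        raise ValueError("search range start exceeds end")
    pattern = iupac_regex(motif)
    hits: set[int] = set()
    for m in pattern.finditer(window.sequence):
        rel = m.start() + window.rel_start
        if lo <= rel <= hi:
            hits.add(rel)
    if both_strands:
        rc = reverse_complement(window.sequence)
        n = len(window.sequence)
        for m in pattern.finditer(rc):
            # leftmost sense-strand base of the reverse-strand match
            sense_index = n - (m.start() + len(motif))
            rel = sense_index + window.rel_start
            if lo <= rel <= hi:
                hits.add(rel)
    ordered = sorted(hits)
    return MotifCall(
        gene_id=window.gene_id,
        motif_name=motif,
        present=bool(ordered),
        hits=ordered,
    )


def scan_all(
    windows: Mapping[str, PromoterWindow],
    motifs: Mapping[str, tuple[str, tuple[int, int]]] = MOTIFS,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Presence table (genes x motifs) for a motif catalogue."""
    rows = {}
    for gene_id, window in windows.items():
        rows[gene_id] = {
            name: scan_motif(window, consensus, rng, both_strands).present
            for name, (consensus, rng) in motifs.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


def class_motif_table(
    calls: pd.DataFrame,
    labels: pd.Series,
) -> pd.DataFrame:
    """Per-class motif counts and fractions with a Fisher exact test.

    ``calls`` is the genes x motifs boolean table from :func:`scan_all`;
    ``labels`` maps gene_id -> class.  For each motif a two-sided Fisher
    exact test is run on the 2x2 class-by-presence table.
    """
    genes = calls.index.intersection(labels.index)
    calls = calls.loc[genes]
    labels = labels.loc[genes]
    classes = sorted(pd.unique(labels))
    rows = []
    for motif in calls.columns:
        present = calls[motif]
        counts = {cls: int(present[labels == cls].sum()) for cls in classes}
        totals = {cls: int((labels == cls).sum()) for cls in classes}
        if len(classes) == 2:
            a, b = classes
            table2x2 = [
                [counts[a], totals[a] - counts[a]],
                [counts[b], totals[b] - counts[b]],
            ]
            _, pval = fisher_exact(table2x2, alternative="two-sided")
        else:
            pval = float("nan")
        for cls in classes:
            rows.append(
                {
                    "motif": motif,
                    "class": cls,
                    "n_genes": totals[cls],
                    "n_with_motif": counts[cls],
                    "fraction": counts[cls] / totals[cls] if totals[cls] else 0.0,
                    "fisher_p": pval,
                }
            )
    return pd.DataFrame(rows)
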
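"""Readers and writers for the tabular and genomic formats the pipeline touches.

Count matrices and sample sheets are plain TSV; coverage is bedGraph
(0-based half-open on disk, converted to dense 1-based-inclusive per-bp
vectors internally); sequences are FASTA via Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ["sample_id", "strain", "condition", "treatment", "replicate", "media", "group", "spike_total"]
TREATMENTS = {"IAA", "DMSO", "none"}


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample spike-in totals.

    ``counts`` is indexed by gene_id with one column per sample_id;
    ``samples`` is indexed by sample_id and carries the descriptors
    (strain, condition, treatment, replicate, media, group) plus
    ``spike_total`` (spike-in mapped reads, > 0).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows disagree")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample descriptors")
        if "spike_total" not in self.samples.columns:
            raise ValueError("sample sheet lacks spike_total")
        spikes = self.samples["spike_total"]
        if spikes.isna().any():
            bad = list(self.samples.index[spikes.isna()])
            raise ValueError(f"missing spike total for sample(s): {bad}")
        if (spikes <= 0).any():
            bad = list(self.samples.index[spikes <= 0])
            raise ValueError(f"non-positive spike total for sample(s): {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def spike_totals(self) -> pd.Series:
        return self.samples["spike_total"]


def read_count_matrix(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample sheet.

    The count TSV has a ``gene_id`` column and one integer column per
    sample.  The sample sheet maps each count column to its descriptors and
    spike-in total.  A missing spike total or a non-integer count is a hard
    error naming the offender.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in raw.columns:
        raise ValueError(f"{path}: no gene_id column")
    raw = raw.set_index("gene_id")
    raw.columns.name = "sample_id"
    for col in raw.columns:
        values = raw[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-integer count at gene {row!r}, sample {col!r}")
        raw[col] = numeric.astype(int)

    sheet = pd.read_csv(sample_sheet, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in sheet.columns:
        raise ValueError(f"{sample_sheet}: no sample_id column")
    sheet = sheet.set_index("sample_id")
    missing = [s for s in raw.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"sample sheet lacks row(s) for sample(s): {missing}")
    sheet = sheet.loc[list(raw.columns)]
    if "spike_total" not in sheet.columns or sheet["spike_total"].isna().any():
        bad = (
            list(sheet.index[sheet["spike_total"].isna()])
            if "spike_total" in sheet.columns
            else list(sheet.index)
        )
        raise ValueError(f"missing spike total for sample(s): {bad}")
    sheet["spike_total"] = sheet["spike_total"].astype(int)
    return CountMatrix(counts=raw, samples=sheet)


def write_count_matrix(cm: CountMatrix, path: str | Path, sample_sheet: str | Path) -> None:
    cm.counts.reset_index().to_csv(path, sep="\t", index=False)
    cm.samples.reset_index().to_csv(sample_sheet, sep="\t", index=False)


@dataclass
class CoverageTrack:
    """Dense per-base-pair signal per chromosome plus a spike-in total.

    ``data[chrom][i]`` holds the value at 1-based position ``i + 1``.
    """

    data: dict[str, np.ndarray]
    spike_total: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.spike_total <= 0:
            raise ValueError(f"track {self.label!r}: spike_total must be > 0")
        for chrom, vec in self.data.items():
            if (np.asarray(vec) < 0).any():
                raise ValueError(f"track {self.label!r}: negative signal on {chrom}")

    def scaled(self, factor: float, label: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            data={c: v * factor for c, v in self.data.items()},
            spike_total=self.spike_total,
            label=self.label if label is None else label,
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


def read_coverage(
    path: str | Path,
    spike_total: int,
    chrom_lengths: dict[str, int],
    label: str = "",
) -> CoverageTrack:
    """Read a bedGraph into a dense per-bp track.

    bedGraph intervals are 0-based half-open; a record ``chrI 0 3 5.0``
    covers internal 1-based positions 1..3.  Overlapping records and
    intervals beyond the declared chromosome length are errors; uncovered
    bases are 0.
    """
    data = {c: np.zeros(int(n), dtype=float) for c, n in chrom_lengths.items()}
    path = Path(path)
    if path.stat().st_size > 0:
        frame = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str},
        )
        frame = frame[~frame["chrom"].str.startswith("track")]
        last_end: dict[str, int] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            if chrom not in data:
                raise ValueError(f"{path}: unknown chromosome {chrom!r}")
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=int)
            ends = sub["end"].to_numpy(dtype=int)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{path}: overlapping bedGraph records on {chrom}")
            if ends[-1] > len(data[chrom]) or (starts < 0).any():
                raise ValueError(
                    f"{path}: interval beyond chromosome length on {chrom}"
                )
            values = sub["value"].to_numpy(dtype=float)
            vec = data[chrom]
            for s, e, v in zip(starts, ends, values):
                vec[s:e] = v
            last_end[chrom] = int(ends[-1])
    return CoverageTrack(data=data, spike_total=int(spike_total), label=label or path.stem)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a dense track as bedGraph, merging runs of equal value, skipping zeros."""
    with open(path, "w") as fh:
        for chrom in track.data:
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
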
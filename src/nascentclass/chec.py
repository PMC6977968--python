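"""ChEC-seq: spike-normalized cleavage tracks, peak calling, promoter assignment.

MNase fused to a chromatin factor cleaves DNA near its binding sites; a
free-MNase track is the control.  Tracks are normalized to spike-in
(D. melanogaster) read totals.  Peaks are called with a fixed
sliding-window scorer honoring the study's thresholds: windows must be
enriched at least 2-fold over the scaled control and 2-fold over the local
background, with a Benjamini-Hochberg FDR of 0.1% on Poisson upper-tail
p-values.  Peak summits are assigned to promoters whose TSS-relative window
[-300, +100] contains them, and per-factor binding calls require a
consensus across replicates (3 of 4, generalized to ceil(0.75 n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson, false_discovery_control

from nascentclass.io import CoverageTrack

DEFAULT_NORM_CONSTANT = 10000.0
DEFAULT_WINDOW = 150
DEFAULT_STEP = 50
DEFAULT_FOLD_MIN = 2.0
DEFAULT_LOCAL_FOLD_MIN = 2.0
DEFAULT_LOCAL_FLANK = 1000
DEFAULT_FDR = 0.001
#: TSS-relative promoter window used for summit assignment and rescue.
ASSIGN_WINDOW = (-300, 100)
#: Width of the summit-centered window used for per-promoter signal.
SIGNAL_WINDOW = 300
#: Fraction of replicates in which a promoter must be bound.
CONSENSUS_FRACTION = 0.75


def normalize_chec(track: CoverageTrack, C: float = DEFAULT_NORM_CONSTANT) -> CoverageTrack:
    """Per-bp signal / spike_total * C."""
    if C <= 0:
        raise ValueError("normalization constant must be positive")
    factor = C / float(track.spike_total)
    return track.scaled(factor)


@dataclass
class Peak:
    """A called enrichment region (1-based inclusive) with its summit."""

    chrom: str
    start: int
    end: int
    summit: int
    fold_vs_control: float
    fold_vs_local: float
    q_value: float

    def __post_init__(self) -> None:
        assert self.start <= self.summit <= self.end


def call_peaks(
    sample: CoverageTrack,
    control: CoverageTrack,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    fold_min: float = DEFAULT_FOLD_MIN,
    local_fold_min: float = DEFAULT_LOCAL_FOLD_MIN,
    local_flank: int = DEFAULT_LOCAL_FLANK,
    fdr: float = DEFAULT_FDR,
) -> list[Peak]:
    """Sliding-window peak calling against a free-MNase control.

    Both tracks must be normalized to the same constant.  Window scores are
    sample sums tested against the control sum (floored at a pseudocount of
    1 and rescaled so genome-wide totals match) with a Poisson upper tail;
    q-values are Benjamini-Hochberg across all windows.  Significant
    windows passing both fold filters are merged when overlapping or
    adjacent; the merged region is the peak and its summit is the midpoint
    (mid-range of the peak borders).
    """
    if window < step:
        raise ValueError("window must be >= step")
    if not sample.data or all(len(v) == 0 for v in sample.data.values()):
        raise ValueError("empty genome")
    total_sample = sample.total()
    total_control = control.total()
    scale = total_sample / total_control if total_control > 0 else 1.0

    win_rows = []
    for chrom, svec in sample.data.items():
        cvec = control.data.get(chrom)
        if cvec is None or len(cvec) != len(svec):
            raise ValueError(f"control track missing or mismatched on {chrom}")
        n = len(svec)
        if n < window:
            continue
        s_cum = np.concatenate([[0.0], np.cumsum(svec)])
        c_cum = np.concatenate([[0.0], np.cumsum(cvec)])
        starts = np.arange(0, n - window + 1, step)  # 0-based window starts
        ends = starts + window
        s_sum = s_cum[ends] - s_cum[starts]
        c_sum = c_cum[ends] - c_cum[starts]
        expected = np.maximum(c_sum, 1.0) * scale

        # local background: combined sample+scaled-control mean over +-flank
        lo = np.maximum(starts - local_flank, 0)
        hi = np.minimum(ends + local_flank, n)
        flank_len = (starts - lo) + (hi - ends)
        s_flank = (s_cum[starts] - s_cum[lo]) + (s_cum[hi] - s_cum[ends])
        c_flank = (c_cum[starts] - c_cum[lo]) + (c_cum[hi] - c_cum[ends])
        with np.errstate(divide="ignore", invalid="ignore"):
            local_mean = np.where(
                flank_len > 0, (s_flank + c_flank * scale) / (2.0 * flank_len), 0.0
            )
        window_mean = s_sum / window
        local_floor = np.maximum(local_mean, 1.0 / window)
        fold_local = window_mean / local_floor
        fold_control = s_sum / expected

        pvals = poisson.sf(np.ceil(s_sum) - 1, expected)
        for i in range(len(starts)):
            win_rows.append(
                (chrom, int(starts[i]) + 1, int(ends[i]), float(fold_control[i]),
                 float(fold_local[i]), float(pvals[i]))
            )

    if not win_rows:
        return []
    frame = pd.DataFrame(
        win_rows, columns=["chrom", "start", "end", "fold_control", "fold_local", "p"]
    )
    frame["q"] = false_discovery_control(frame["p"].to_numpy(), method="bh")
    sig = frame[
        (frame["q"] <= fdr)
        & (frame["fold_control"] >= fold_min)
        & (frame["fold_local"] >= local_fold_min)
    ]

    peaks: list[Peak] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples():
            if cur is not None and row.start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], row.end)
                cur["fold_control"] = max(cur["fold_control"], row.fold_control)
                cur["fold_local"] = max(cur["fold_local"], row.fold_local)
                cur["q"] = min(cur["q"], row.q)
            else:
                if cur is not None:
                    peaks.append(_finish_peak(chrom, cur))
                cur = {
                    "start": row.start,
                    "end": row.end,
                    "fold_control": row.fold_control,
                    "fold_local": row.fold_local,
                    "q": row.q,
                }
        if cur is not None:
            peaks.append(_finish_peak(chrom, cur))
    return peaks


def _finish_peak(chrom: str, cur: dict) -> Peak:
    return Peak(
        chrom=chrom,
        start=int(cur["start"]),
        end=int(cur["end"]),
        summit=(int(cur["start"]) + int(cur["end"])) // 2,
        fold_vs_control=float(cur["fold_control"]),
        fold_vs_local=float(cur["fold_local"]),
        q_value=float(cur["q"]),
    )


def _tss_relative(summit: int, tss: int, strand: str) -> int:
    return summit - tss if strand == "+" else tss - summit


def assign_peaks_to_promoters(
    peaks: Sequence[Peak],
    annotation: pd.DataFrame,
    assign_window: tuple[int, int] = ASSIGN_WINDOW,
) -> dict[str, Peak]:
    """Map each promoter to the peak whose summit lies in [-300, +100] of its TSS.

    When several peaks land in one promoter window the summit closest to
    the TSS wins; an exact distance tie goes to the upstream peak.
    """
    lo, hi = assign_window
    by_chrom: dict[str, list[Peak]] = {}
    for peak in peaks:
        by_chrom.setdefault(peak.chrom, []).append(peak)
    out: dict[str, Peak] = {}
    for gene_id, row in annotation.iterrows():
        candidates = []
        for peak in by_chrom.get(row["chrom"], []):
            rel = _tss_relative(peak.summit, int(row["tss"]), row["strand"])
            if lo <= rel <= hi:
                candidates.append((abs(rel), rel, peak))
        if not candidates:
            continue
        # nearest summit; equidistant tie -> upstream (more negative rel)
        candidates.sort(key=lambda t: (t[0], t[1]))
        out[str(gene_id)] = candidates[0][2]
    return out


def _window_signal(track: CoverageTrack, chrom: str, summit: int, width: int = SIGNAL_WINDOW) -> float:
    """Sum of per-bp signal over [summit - width/2, summit + width/2 - 1]."""
    vec = track.data[chrom]
    half = width // 2
    lo = max(summit - half, 1)
    hi = min(summit + half - 1, len(vec))
    if hi < lo:
        return 0.0
    return float(vec[lo - 1 : hi].sum())


def replicate_consensus(
    assignments: Sequence[Mapping[str, Peak]],
    annotation: pd.DataFrame,
    tracks: Sequence[CoverageTrack],
    assign_window: tuple[int, int] = ASSIGN_WINDOW,
    signal_window: int = SIGNAL_WINDOW,
    consensus_fraction: float = CONSENSUS_FRACTION,
) -> pd.DataFrame:
    """Consensus promoter binding across replicates with summit rescue.

    A promoter is consensus-bound when it has a peak in at least
    ceil(consensus_fraction * n) replicates (3 of 4 at the default).  For a
    consensus promoter lacking a peak in some replicate, the position of
    the strongest normalized signal within the TSS window stands in as that
    replicate's summit.  Per-replicate signal is the normalized per-bp sum
    over the summit-centered window; ``mean_signal`` averages replicates.
    """
    if len(assignments) != len(tracks):
        raise ValueError("one track per replicate assignment required")
    n_rep = len(assignments)
    threshold = math.ceil(consensus_fraction * n_rep)
    lo, hi = assign_window
    rows = []
    for gene_id, row in annotation.iterrows():
        gene_id = str(gene_id)
        bound_flags = [gene_id in a for a in assignments]
        n_bound = sum(bound_flags)
        consensus = n_bound >= threshold
        rec: dict = {"gene_id": gene_id, "n_bound": n_bound, "consensus_bound": consensus}
        signals = []
        for i, (assign, track) in enumerate(zip(assignments, tracks)):
            if gene_id in assign:
                summit = assign[gene_id].summit
                rescued = False
            elif consensus:
                chrom = row["chrom"]
                tss, strand = int(row["tss"]), row["strand"]
                if strand == "+":
                    g_lo, g_hi = tss + lo, tss + hi
                else:
                    g_lo, g_hi = tss - hi, tss - lo
                vec = track.data[chrom]
                g_lo, g_hi = max(g_lo, 1), min(g_hi, len(vec))
                summit = int(np.argmax(vec[g_lo - 1 : g_hi])) + g_lo
                rescued = True
            else:
                rec[f"rep{i + 1}_bound"] = bound_flags[i]
                continue
            sig = _window_signal(track, row["chrom"], summit, signal_window)
            signals.append(sig)
            rec[f"rep{i + 1}_bound"] = bound_flags[i]
            rec[f"rep{i + 1}_summit"] = summit
            rec[f"rep{i + 1}_rescued"] = rescued
            rec[f"rep{i + 1}_signal"] = sig
        rec["mean_signal"] = float(np.mean(signals)) if consensus else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


def factor_overlap(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise overlap of consensus-bound promoter sets across factors."""
    sets = {
        name: set(tbl.index[tbl["consensus_bound"]]) for name, tbl in tables.items()
    }
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = sets[a] & sets[b]
            smaller = min(len(sets[a]), len(sets[b]))
            rows.append(
                {
                    "factor_a": a,
                    "factor_b": b,
                    "n_a": len(sets[a]),
                    "n_b": len(sets[b]),
                    "n_intersection": len(inter),
                    "n_a_only": len(sets[a] - sets[b]),
                    "n_b_only": len(sets[b] - sets[a]),
                    "fraction_of_a": len(inter) / len(sets[a]) if sets[a] else 0.0,
                    "fraction_of_b": len(inter) / len(sets[b]) if sets[b] else 0.0,
                    "fraction_of_smaller": len(inter) / smaller if smaller else 0.0,
                }
            )
    return pd.DataFrame(rows)


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """Write peaks as BED (0-based half-open), summit in column 7."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\tpeak_{i + 1}\t"
                f"{p.fold_vs_control:.3f}\t.\t{p.summit}\n"
            )
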
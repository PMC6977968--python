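"""Synthetic-data generator emulating the coactivator-depletion study design.

The generator emits every input the pipeline consumes — spike-in count
matrices with sample sheets, gene annotation and TSS tables, a genome FASTA
with planted promoter motifs, ChEC-seq cleavage tracks with a free-MNase
control, and ChIP-seq tracks with input-sidecar read totals — together with
a truth table for parameter-recovery tests.

The statistical structure mirrors the study:

* two gene classes (87% TFIID-dependent, 13% coactivator-redundant) with
  class-by-condition mean log2 transcription effects anchored to the
  reported fold averages (e.g. 4.5-fold TFIID-class decrease under Taf
  degrons, 1.6-fold CR decrease under the Spt3/20 degron, 5.7-fold CR
  decrease under the double degron);
* heavy-tailed baseline expression with CR genes over-represented among
  the top expressers;
* negative-binomial replicate counts under per-sample capture efficiencies
  that the spike-in channel absorbs exactly;
* promoter sequences with class-specific TATA and Msn2/4 motif
  frequencies planted inside the correct search windows;
* ChEC tracks with Gaussian promoter-proximal peaks over a flat
  free-MNase-like background;
* ChIP tracks with +1-nucleosome-localized mark signal scaled by
  per-genotype fold effects.

Effects the study reports only qualitatively (the CR-class Taf-degron
effect, the Spt3/7-degron CR effect, the spt7/spt20 deletion magnitudes)
are interpolated defaults; see docs/methods.md.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from nascentclass.io import CountMatrix, CoverageTrack, write_count_matrix, write_coverage, write_fasta
from nascentclass.annotation import write_annotation
from nascentclass.chip import ChipSample
from nascentclass.classify import TFIID_DEPENDENT, COACTIVATOR_REDUNDANT
from nascentclass.motifs import MOTIFS, iupac_regex, reverse_complement

TAF_DEGRONS = ["taf13_deg", "taf7_deg", "taf1_deg"]
SAGA_DEGRONS = ["spt3_20_deg", "spt3_7_deg"]
DOUBLE_DEGRONS = ["taf13_spt3_deg", "taf13_spt7_deg"]
DELETIONS = ["spt3_del", "spt7_del", "spt20_del"]
DEGRON_CONDITIONS = TAF_DEGRONS + SAGA_DEGRONS + DOUBLE_DEGRONS
CONDITIONS = DEGRON_CONDITIONS + DELETIONS

#: contrast name -> (treated group, control group)
CONTRASTS: dict[str, tuple[str, str]] = {
    **{c: (f"{c}_IAA", f"{c}_DMSO") for c in DEGRON_CONDITIONS},
    **{c: (c, "WT") for c in DELETIONS},
}

#: headline clustering features: SPT deletions + Taf degrons
FEATURES_PRIMARY = DELETIONS + TAF_DEGRONS
#: stability re-clustering features: SAGA degrons + Taf degrons
FEATURES_ALT = SAGA_DEGRONS + TAF_DEGRONS

#: replicate groups whose samples enter the no-zero filter
FILTER_GROUPS = (
    [g for c in TAF_DEGRONS + SAGA_DEGRONS for g in (f"{c}_IAA", f"{c}_DMSO")]
    + DELETIONS
    + ["WT"]
)
#: replicate groups averaged for the baseline expression ranking
BASELINE_GROUPS = ["WT"] + [f"{c}_DMSO" for c in DEGRON_CONDITIONS]


def _log2(x: float) -> float:
    return math.log2(x)


#: true mean log2 change per condition: (TFIID-dependent, coactivator-redundant)
DEFAULT_EFFECTS: dict[str, tuple[float, float]] = {
    "taf13_deg": (-_log2(4.5), -_log2(2.0)),
    "taf7_deg": (-_log2(4.5), -_log2(2.0)),
    "taf1_deg": (-_log2(4.5), -_log2(2.0)),
    "spt3_20_deg": (0.0, -_log2(1.6)),
    "spt3_7_deg": (0.0, -_log2(1.5)),
    "taf13_spt3_deg": (-_log2(4.5), -_log2(5.7)),
    "taf13_spt7_deg": (-_log2(4.5), -_log2(5.7)),
    "spt3_del": (-_log2(2.7), -_log2(3.5)),
    "spt7_del": (-_log2(2.0), -_log2(3.0)),
    "spt20_del": (-_log2(2.0), -_log2(3.0)),
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GeneratorParams:
    """Generator defaults define the emulated study conditions."""

    n_genes: int = 5000
    n_chroms: int | None = None  # auto: ~650 genes per chromosome, >= 2
    cr_fraction: float = 0.13
    replicates: int = 3
    effect_sd: float = 0.4  # per-gene per-condition log2 effect spread
    nb_dispersion: float = 0.05
    capture_sd: float = 0.3  # log-normal sd of per-sample capture efficiency
    counts_scale: float = 0.1  # mean counts per ORF bp at unit density
    spike_base: int = 20000
    baseline_sigma: float = 1.1
    cr_tail_fraction: float = 0.45  # CR genes drawn from the heavy tail
    cr_tail_log_mean: float = math.log(8.0)
    cr_tail_sigma: float = 0.8
    effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    # annotation geometry
    gene_length: tuple[int, int] = (600, 2400)
    intergenic_gap: tuple[int, int] = (1200, 1600)
    tss_offset: tuple[int, int] = (30, 150)
    tss_missing_fraction: float = 0.15
    orf_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "verified": 0.90,
            "uncharacterized": 0.05,
            "dubious": 0.03,
            "pseudogene": 0.02,
        }
    )
    # promoter motifs: (TFIID-dependent, CR) planted frequencies
    tata_freq: tuple[float, float] = (0.25, 0.65)
    msn24_freq: tuple[float, float] = (0.14, 0.26)
    # ChEC
    chec_factors: tuple[str, ...] = ("Taf7", "Spt7")
    chec_replicates: int = 4
    chec_bound_fraction: float = 0.7
    chec_cobind: float = 0.9  # fraction of the 2nd factor's sites shared
    chec_peak_fold: float = 8.0
    chec_peak_width: float = 120.0  # FWHM in bp
    chec_background: float = 0.5  # mean cleavage counts per bp
    # ChIP
    chip_replicates: int = 2
    chip_folds: dict[str, float] = field(
        default_factory=lambda: {
            "gcn5_del": 10.0,
            "spt7_del": 10.0,
            "spt3_del": 3.3,
            "spt3_7_deg": 1.7,
        }
    )
    chip_background: float = 0.005
    chip_amp_log_mean: float = math.log(10.0)
    chip_amp_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cr_fraction", "tss_missing_fraction", "cr_tail_fraction",
                     "chec_bound_fraction", "chec_cobind"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for pair in (self.tata_freq, self.msn24_freq):
            if not all(0 <= f <= 1 for f in pair):
                raise ValueError("motif frequencies must lie in [0, 1]")
        missing = set(CONTRASTS) - set(self.effects)
        if missing:
            raise ValueError(f"effect matrix lacks condition(s): {sorted(missing)}")


@dataclass
class SimulatedDataset:
    """In-memory bundle of generated inputs plus the truth table."""

    params: GeneratorParams
    gene_table: pd.DataFrame  # annotation incl. tss (all genes)
    tss_table: pd.DataFrame  # only genes with an explicit (non-imputed) TSS
    truth: pd.DataFrame
    count_matrix: CountMatrix | None = None
    genome: dict[str, str] | None = None
    chrom_lengths: dict[str, int] | None = None
    chec_tracks: dict[str, list[CoverageTrack]] | None = None
    chec_control: CoverageTrack | None = None
    chip_samples: dict[str, list[ChipSample]] | None = None


# ---------------------------------------------------------------------------
# gene geometry and classes


def _simulate_genes(p: GeneratorParams, rng: np.random.Generator):
    n = p.n_genes
    n_chroms = p.n_chroms or max(2, math.ceil(n / 650))
    ids = np.array([f"G{i:05d}" for i in range(1, n + 1)])

    n_cr = int(round(n * p.cr_fraction))
    classes = np.full(n, TFIID_DEPENDENT, dtype=object)
    cr_idx = rng.choice(n, size=n_cr, replace=False)
    classes[cr_idx] = COACTIVATOR_REDUNDANT

    orf_names = list(p.orf_class_probs)
    orf_class = rng.choice(orf_names, size=n, p=list(p.orf_class_probs.values()))
    lengths = rng.integers(p.gene_length[0], p.gene_length[1] + 1, size=n)
    gaps = rng.integers(p.intergenic_gap[0], p.intergenic_gap[1] + 1, size=n)
    strands = rng.choice(["+", "-"], size=n)
    offsets = rng.integers(p.tss_offset[0], p.tss_offset[1] + 1, size=n)
    has_tss = rng.random(n) >= p.tss_missing_fraction

    chrom_of = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=int)
    pad = 1500
    chrom_lengths: dict[str, int] = {}
    for ci, idx in enumerate(np.array_split(np.arange(n), n_chroms)):
        chrom = f"chr{ci + 1}"
        cursor = pad
        for g in idx:
            chrom_of[g] = chrom
            starts[g] = cursor
            cursor = cursor + lengths[g] - 1 + gaps[g]
        chrom_lengths[chrom] = cursor + pad

    ends = starts + lengths - 1
    tss = np.where(strands == "+", starts - offsets, ends + offsets)
    # the pipeline imputes missing TSSs at -100; the generator plants
    # promoters at the position the pipeline will actually use
    tss_eff = np.where(
        has_tss, tss, np.where(strands == "+", starts - 100, ends + 100)
    )

    gene_table = pd.DataFrame(
        {
            "chrom": chrom_of,
            "start": starts,
            "end": ends,
            "strand": strands,
            "orf_class": orf_class,
            "tss": tss_eff,
            "tss_imputed": ~has_tss,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    tss_table = pd.DataFrame(
        {
            "gene_id": ids[has_tss],
            "chrom": chrom_of[has_tss],
            "tss": tss[has_tss],
        }
    )

    is_cr = classes == COACTIVATOR_REDUNDANT
    density = rng.lognormal(0.0, p.baseline_sigma, size=n)
    tail = rng.lognormal(p.cr_tail_log_mean, p.cr_tail_sigma, size=n)
    use_tail = is_cr & (rng.random(n) < p.cr_tail_fraction)
    density = np.where(use_tail, tail, density)

    truth = pd.DataFrame(
        {"true_class": classes, "density": density},
        index=gene_table.index,
    )
    return gene_table, tss_table, truth, chrom_lengths


# ---------------------------------------------------------------------------
# counts


def _sample_table(p: GeneratorParams) -> pd.DataFrame:
    rows = []
    for cond in DEGRON_CONDITIONS:
        for treatment in ("IAA", "DMSO"):
            for r in range(1, p.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{treatment}_r{r}",
                        "strain": cond,
                        "condition": cond,
                        "treatment": treatment,
                        "replicate": r,
                        "media": "SC",
                        "group": f"{cond}_{treatment}",
                    }
                )
    for cond in DELETIONS + ["WT"]:
        for r in range(1, p.replicates + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_r{r}",
                    "strain": cond,
                    "condition": cond,
                    "treatment": "none",
                    "replicate": r,
                    "media": "SC",
                    "group": cond,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _simulate_counts(
    p: GeneratorParams,
    gene_table: pd.DataFrame,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    samples = _sample_table(p)
    n = len(gene_table)
    lengths = (gene_table["end"] - gene_table["start"] + 1).to_numpy()
    base_mean = truth["density"].to_numpy() * lengths * p.counts_scale
    is_cr = (truth["true_class"] == COACTIVATOR_REDUNDANT).to_numpy()

    truth = truth.copy()
    realized: dict[str, np.ndarray] = {}
    for cond in CONTRASTS:
        tf_eff, cr_eff = p.effects[cond]
        eta = rng.normal(0.0, p.effect_sd, size=n)
        effect = np.where(is_cr, cr_eff, tf_eff) + eta
        realized[cond] = effect
        truth[f"effect_{cond}"] = effect

    eff_s = rng.lognormal(0.0, p.capture_sd, size=len(samples))
    spike_totals = np.maximum(np.round(p.spike_base * eff_s).astype(int), 1)

    r = 1.0 / p.nb_dispersion
    counts = np.empty((n, len(samples)), dtype=int)
    for j, (sample_id, row) in enumerate(samples.iterrows()):
        cond = row["condition"]
        treated = (cond in DEGRON_CONDITIONS and row["treatment"] == "IAA") or (
            cond in DELETIONS
        )
        mult = np.exp2(realized[cond]) if treated else 1.0
        mean = base_mean * mult * eff_s[j]
        prob = r / (r + mean)
        counts[:, j] = rng.negative_binomial(r, prob)

    samples = samples.copy()
    samples["spike_total"] = spike_totals
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_table.index, columns=samples.index),
        samples=samples,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# promoter sequences and genome


def _realize_motif(name: str, rng: np.random.Generator) -> str:
    if name == "TATA":
        w = rng.choice(["A", "T"], size=2)
        return f"TATA{w[0]}A{w[1]}"
    if name == "MSN24":
        v = rng.choice(["A", "C", "G"])
        return f"{v}AGGGG"
    raise KeyError(name)


def _design_promoter(
    rng: np.random.Generator,
    want_tata: bool,
    want_msn: bool,
    upstream: int = 400,
    downstream: int = 100,
    max_tries: int = 200,
) -> tuple[str, int | None, int | None]:
    """A promoter window whose motif content matches the plan exactly.

    Sequences are redrawn until a scan of each search window agrees with
    the wanted presence flags, so planted fractions are exact by
    construction (no accidental background hits).
    """
    length = upstream + downstream + 1
    tata_re = iupac_regex(MOTIFS["TATA"][0])
    msn_re = iupac_regex(MOTIFS["MSN24"][0])
    (t_lo, t_hi) = MOTIFS["TATA"][1]
    (m_lo, m_hi) = MOTIFS["MSN24"][1]
    for _ in range(max_tries):
        seq = _BASES[rng.integers(0, 4, size=length)].copy()
        tata_pos = msn_pos = None
        if want_tata:
            tata_pos = int(rng.integers(t_lo, t_hi + 1))
        if want_msn:
            for _ in range(50):
                msn_pos = int(rng.integers(m_lo, m_hi + 1))
                if tata_pos is None or msn_pos >= tata_pos + 7 or tata_pos >= msn_pos + 6:
                    break
        if tata_pos is not None:
            motif = _realize_motif("TATA", rng)
            i = tata_pos + upstream
            seq[i : i + 7] = np.frombuffer(motif.encode(), dtype="S1")
        if msn_pos is not None:
            motif = _realize_motif("MSN24", rng)
            i = msn_pos + upstream
            seq[i : i + 6] = np.frombuffer(motif.encode(), dtype="S1")
        text = seq.tobytes().decode()
        has_tata = any(
            t_lo <= m.start() - upstream <= t_hi for m in tata_re.finditer(text)
        )
        has_msn = any(
            m_lo <= m.start() - upstream <= m_hi for m in msn_re.finditer(text)
        )
        if has_tata == want_tata and has_msn == want_msn:
            return text, tata_pos, msn_pos
    raise RuntimeError("could not realize promoter motif plan")


def _simulate_promoters(
    p: GeneratorParams,
    gene_table: pd.DataFrame,
    truth: pd.DataFrame,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[str, str], pd.DataFrame]:
    genome = {
        chrom: _BASES[rng.integers(0, 4, size=length)].copy()
        for chrom, length in chrom_lengths.items()
    }
    truth = truth.copy()
    is_cr = (truth["true_class"] == COACTIVATOR_REDUNDANT).to_numpy()
    want_tata = rng.random(len(truth)) < np.where(is_cr, p.tata_freq[1], p.tata_freq[0])
    want_msn = rng.random(len(truth)) < np.where(is_cr, p.msn24_freq[1], p.msn24_freq[0])

    tata_pos = np.full(len(truth), np.nan)
    msn_pos = np.full(len(truth), np.nan)
    for i, (gene_id, row) in enumerate(gene_table.iterrows()):
        seq, tpos, mpos = _design_promoter(rng, bool(want_tata[i]), bool(want_msn[i]))
        tss, strand, chrom = int(row["tss"]), row["strand"], row["chrom"]
        if strand == "+":
            lo, hi = tss - 400, tss + 100
            planted = seq
        else:
            lo, hi = tss - 100, tss + 400
            planted = reverse_complement(seq)
        if lo < 1 or hi > len(genome[chrom]):
            raise RuntimeError(f"promoter window off chromosome for {gene_id}")
        genome[chrom][lo - 1 : hi] = np.frombuffer(planted.encode(), dtype="S1")
        if tpos is not None:
            tata_pos[i] = tpos
        if mpos is not None:
            msn_pos[i] = mpos

    truth["tata"] = want_tata
    truth["msn24"] = want_msn
    truth["tata_pos"] = tata_pos
    truth["msn24_pos"] = msn_pos
    return {c: v.tobytes().decode() for c, v in genome.items()}, truth


# ---------------------------------------------------------------------------
# ChEC tracks


def _gauss_bump(vec: np.ndarray, center: int, amp: float, sd: float) -> None:
    """Add amp * exp(-(x-center)^2 / (2 sd^2)) in place (1-based center)."""
    reach = int(4 * sd)
    lo = max(center - reach, 1)
    hi = min(center + reach, len(vec))
    x = np.arange(lo, hi + 1)
    vec[lo - 1 : hi] += amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _simulate_chec(
    p: GeneratorParams,
    gene_table: pd.DataFrame,
    truth: pd.DataFrame,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
):
    from nascentclass.annotation import analyzed_genes

    analyzed = analyzed_genes(gene_table)
    n_bound = int(p.chec_bound_fraction * len(analyzed))
    truth = truth.copy()

    bound_sets: dict[str, pd.Index] = {}
    first = p.chec_factors[0]
    bound_sets[first] = pd.Index(
        rng.choice(analyzed, size=n_bound, replace=False)
    )
    for factor in p.chec_factors[1:]:
        n_shared = int(round(p.chec_cobind * n_bound))
        shared = rng.choice(bound_sets[first], size=n_shared, replace=False)
        rest_pool = analyzed.difference(bound_sets[first])
        extra = rng.choice(rest_pool, size=n_bound - n_shared, replace=False)
        bound_sets[factor] = pd.Index(np.concatenate([shared, extra]))

    sd = p.chec_peak_width / 2.355  # FWHM -> Gaussian sd
    amp = (p.chec_peak_fold - 1.0) * p.chec_background

    tracks: dict[str, list[CoverageTrack]] = {}
    for factor in p.chec_factors:
        bound = bound_sets[factor]
        offsets = rng.integers(-250, 51, size=len(bound))
        summits = {}
        lam = {c: np.full(length, p.chec_background) for c, length in chrom_lengths.items()}
        for gene_id, off in zip(bound, offsets):
            row = gene_table.loc[gene_id]
            center = int(row["tss"]) + (int(off) if row["strand"] == "+" else -int(off))
            _gauss_bump(lam[row["chrom"]], center, amp, sd)
            summits[gene_id] = center
        truth[f"bound_{factor}"] = truth.index.isin(bound)
        truth[f"summit_{factor}"] = pd.Series(summits).reindex(truth.index)

        reps = []
        for r in range(p.chec_replicates):
            depth = rng.lognormal(0.0, p.capture_sd)
            data = {c: rng.poisson(v * depth).astype(float) for c, v in lam.items()}
            reps.append(
                CoverageTrack(
                    data=data,
                    spike_total=max(int(round(p.spike_base * depth)), 1),
                    label=f"{factor}_rep{r + 1}",
                )
            )
        tracks[factor] = reps

    depth = rng.lognormal(0.0, p.capture_sd)
    control = CoverageTrack(
        data={
            c: rng.poisson(np.full(length, p.chec_background * depth)).astype(float)
            for c, length in chrom_lengths.items()
        },
        spike_total=max(int(round(p.spike_base * depth)), 1),
        label="free_mnase",
    )
    return tracks, control, truth


# ---------------------------------------------------------------------------
# ChIP tracks


def _simulate_chip(
    p: GeneratorParams,
    gene_table: pd.DataFrame,
    truth: pd.DataFrame,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
):
    truth = truth.copy()
    amp = rng.lognormal(p.chip_amp_log_mean, p.chip_amp_sigma, size=len(gene_table))
    truth["chip_amp"] = amp

    genotype_folds: dict[str, float] = {"WT": 1.0}
    for cond, fold in p.chip_folds.items():
        if cond.endswith("_deg"):
            genotype_folds[f"{cond}_IAA"] = fold
            genotype_folds[f"{cond}_DMSO"] = 1.0
        else:
            genotype_folds[cond] = fold

    centers = np.where(
        gene_table["strand"] == "+",
        gene_table["tss"] + 150,
        gene_table["tss"] - 150,
    )
    chroms = gene_table["chrom"].to_numpy()

    samples: dict[str, list[ChipSample]] = {}
    input_exp_total = 1_000_000
    for genotype, fold in genotype_folds.items():
        lam = {c: np.full(length, p.chip_background) for c, length in chrom_lengths.items()}
        for chrom, center, a in zip(chroms, centers, amp):
            _gauss_bump(lam[chrom], int(center), a / fold, 40.0)
        reps = []
        for r in range(p.chip_replicates):
            depth = rng.lognormal(0.0, p.capture_sd)
            chrom_ratio = rng.lognormal(math.log(0.1), 0.2)
            data = {c: rng.poisson(v * depth).astype(float) for c, v in lam.items()}
            ip_spike = max(int(round(p.spike_base * depth * chrom_ratio)), 1)
            reps.append(
                ChipSample(
                    ip_track=CoverageTrack(
                        data=data, spike_total=ip_spike, label=f"{genotype}_rep{r + 1}"
                    ),
                    ip_spike_total=ip_spike,
                    input_spike_total=max(int(round(input_exp_total * chrom_ratio)), 1),
                    input_experimental_total=input_exp_total,
                    label=f"{genotype}_rep{r + 1}",
                )
            )
        samples[genotype] = reps
    return samples, truth


# ---------------------------------------------------------------------------
# public entry points


def simulate(
    p: GeneratorParams,
    components: tuple[str, ...] = ("counts",),
) -> SimulatedDataset:
    """Generate the requested components deterministically from ``p.seed``.

    Components: ``counts``, ``promoters`` (implies a genome), ``chec``,
    ``chip``.  Each component draws from its own child RNG stream, so a
    component's output does not depend on which others are requested.
    """
    ss = np.random.SeedSequence(p.seed)
    keys = ["genes", "counts", "promoters", "chec", "chip"]
    streams = dict(zip(keys, [np.random.default_rng(c) for c in ss.spawn(len(keys))]))

    gene_table, tss_table, truth, chrom_lengths = _simulate_genes(p, streams["genes"])
    ds = SimulatedDataset(
        params=p,
        gene_table=gene_table,
        tss_table=tss_table,
        truth=truth,
        chrom_lengths=chrom_lengths,
    )
    if "counts" in components:
        ds.count_matrix, ds.truth = _simulate_counts(p, gene_table, ds.truth, streams["counts"])
    if "promoters" in components:
        ds.genome, ds.truth = _simulate_promoters(
            p, gene_table, ds.truth, chrom_lengths, streams["promoters"]
        )
    if "chec" in components:
        ds.chec_tracks, ds.chec_control, ds.truth = _simulate_chec(
            p, gene_table, ds.truth, chrom_lengths, streams["chec"]
        )
    if "chip" in components:
        ds.chip_samples, ds.truth = _simulate_chip(
            p, gene_table, ds.truth, chrom_lengths, streams["chip"]
        )
    return ds


def small_fixture(
    components: tuple[str, ...] = ("counts", "promoters", "chec", "chip"),
    **overrides,
) -> SimulatedDataset:
    """Miniature dataset (200 genes, 2 chromosomes) for fast tests."""
    defaults = dict(n_genes=200, n_chroms=2)
    defaults.update(overrides)
    return simulate(GeneratorParams(**defaults), components=components)


def generate_dataset(
    p: GeneratorParams,
    outdir: str | Path,
    components: tuple[str, ...] = ("counts", "promoters", "chec", "chip"),
) -> dict[str, Path]:
    """Write a complete dataset (and its truth table) under ``outdir``."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate(p, components=components)
    paths: dict[str, Path] = {}

    write_annotation(ds.gene_table.drop(columns=["tss", "tss_imputed"]), outdir / "annotation.tsv")
    ds.tss_table.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    ds.truth.reset_index().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"chrom": list(ds.chrom_lengths), "length": list(ds.chrom_lengths.values())}
    ).to_csv(outdir / "chrom_lengths.tsv", sep="\t", index=False)
    paths.update(
        annotation=outdir / "annotation.tsv",
        tss=outdir / "tss.tsv",
        truth=outdir / "truth.tsv",
        chrom_lengths=outdir / "chrom_lengths.tsv",
    )

    if ds.count_matrix is not None:
        write_count_matrix(ds.count_matrix, outdir / "counts.tsv", outdir / "samples.tsv")
        paths.update(counts=outdir / "counts.tsv", samples=outdir / "samples.tsv")
    if ds.genome is not None:
        write_fasta(ds.genome, outdir / "genome.fa")
        paths["genome"] = outdir / "genome.fa"
    if ds.chec_tracks is not None:
        chec_dir = outdir / "chec"
        chec_dir.mkdir(exist_ok=True)
        rows = []
        for factor, reps in ds.chec_tracks.items():
            for track in reps:
                write_coverage(track, chec_dir / f"{track.label}.bedgraph")
                rows.append(
                    {"track": track.label, "factor": factor, "spike_total": track.spike_total}
                )
        write_coverage(ds.chec_control, chec_dir / "free_mnase.bedgraph")
        rows.append(
            {
                "track": "free_mnase",
                "factor": "control",
                "spike_total": ds.chec_control.spike_total,
            }
        )
        pd.DataFrame(rows).to_csv(chec_dir / "chec_samples.tsv", sep="\t", index=False)
        paths["chec"] = chec_dir
    if ds.chip_samples is not None:
        chip_dir = outdir / "chip"
        chip_dir.mkdir(exist_ok=True)
        rows = []
        for genotype, reps in ds.chip_samples.items():
            for s in reps:
                write_coverage(s.ip_track, chip_dir / f"{s.label}.bedgraph")
                rows.append(
                    {
                        "track": s.label,
                        "genotype": genotype,
                        "ip_spike_total": s.ip_spike_total,
                        "input_spike_total": s.input_spike_total,
                        "input_experimental_total": s.input_experimental_total,
                    }
                )
        pd.DataFrame(rows).to_csv(chip_dir / "chip_samples.tsv", sep="\t", index=False)
        paths["chip"] = chip_dir

    serializable = asdict(p)
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(serializable, fh, sort_keys=True)
    paths["params"] = outdir / "params.yaml"
    return paths


def filter_samples_for(cm: CountMatrix) -> list[str]:
    """Samples whose replicate group participates in the no-zero filter."""
    return list(cm.samples.index[cm.samples["group"].isin(FILTER_GROUPS)])


def baseline_samples_for(cm: CountMatrix) -> list[str]:
    """WT and vehicle (DMSO) samples used for the expression ranking."""
    return list(cm.samples.index[cm.samples["group"].isin(BASELINE_GROUPS)])
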
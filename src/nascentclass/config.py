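"""Run configuration: inputs, contrasts and every analysis threshold.

Every threshold the pipeline uses is a config field with a default, never a
hidden constant: the normalization constant, the zero-filter sample
selection, the expression-cutoff fraction, clustering feature sets and
seed, motif consensus/search windows, the ChEC caller parameters and
consensus rule, and the ChIP gene window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from nascentclass.simulate import (
    CONTRASTS,
    FEATURES_PRIMARY,
    FEATURES_ALT,
    FILTER_GROUPS,
    BASELINE_GROUPS,
    TAF_DEGRONS,
    DOUBLE_DEGRONS,
)


@dataclass
class RunConfig:
    # input paths (a simulated dataset directory provides all of them)
    data_dir: str = "."
    outdir: str = "results"
    seed: int = 0

    # nascent normalization and filtering
    norm_constant: float = 10000.0
    filter_groups: list[str] = field(default_factory=lambda: list(FILTER_GROUPS))
    baseline_groups: list[str] = field(default_factory=lambda: list(BASELINE_GROUPS))
    cutoff_fraction: float = 0.05
    cv_candidate_fractions: list[float] = field(
        default_factory=lambda: [0.0, 0.01, 0.025, 0.05, 0.075, 0.10]
    )
    contrasts: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in CONTRASTS.items()}
    )
    #: contrasts whose samples sit outside the zero filter; zero means there
    #: drop the gene from that contrast instead of raising
    unfiltered_contrasts: list[str] = field(default_factory=lambda: list(DOUBLE_DEGRONS))

    # classification
    feature_contrasts: list[str] = field(default_factory=lambda: list(FEATURES_PRIMARY))
    alt_feature_contrasts: list[str] = field(default_factory=lambda: list(FEATURES_ALT))
    taf_contrasts: list[str] = field(default_factory=lambda: list(TAF_DEGRONS))
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    kmeans_restarts: int = 10
    n_quantile_bins: int = 5
    top_percent: float = 10.0

    # promoter motifs
    promoter_upstream: int = 400
    promoter_downstream: int = 100
    motifs: dict[str, dict] = field(
        default_factory=lambda: {
            "TATA": {"consensus": "TATAWAW", "range": [-200, 0]},
            "MSN24": {"consensus": "VAGGGG", "range": [-300, -50]},
        }
    )
    scan_both_strands: bool = False

    # ChEC
    chec_window: int = 150
    chec_step: int = 50
    chec_fold_min: float = 2.0
    chec_local_fold_min: float = 2.0
    chec_local_flank: int = 1000
    chec_fdr: float = 0.001
    assign_window: list[int] = field(default_factory=lambda: [-300, 100])
    signal_window: int = 300
    consensus_fraction: float = 0.75

    # ChIP
    chip_gene_window: list[int] = field(default_factory=lambda: [-200, 300])
    chip_contrasts: dict[str, list[str]] = field(
        default_factory=lambda: {
            "gcn5_del": ["gcn5_del", "WT"],
            "spt7_del": ["spt7_del", "WT"],
            "spt3_del": ["spt3_del", "WT"],
            "spt3_7_deg": ["spt3_7_deg_IAA", "spt3_7_deg_DMSO"],
        }
    )

    def validate(self) -> None:
        for name, pair in self.contrasts.items():
            if len(pair) != 2:
                raise ValueError(f"contrast {name!r} must be a (treated, control) pair")
        for group in self.feature_contrasts + self.alt_feature_contrasts + self.taf_contrasts:
            if group not in self.contrasts:
                raise ValueError(f"unknown contrast referenced: {group!r}")
        if not 0 <= self.cutoff_fraction < 1:
            raise ValueError("cutoff_fraction outside [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
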
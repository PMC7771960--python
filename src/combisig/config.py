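"""Pipeline and synthetic-dataset configuration.

Every tunable of the analysis lives here with the default used throughout
the package; stages read their parameters from a :class:`PipelineConfig`
so a run is a pure function of (inputs, config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

SIGNALS = ("control", "control_low_density", "control_high_density",
           "signalA", "signalB", "both")
DOSES = ("none", "low", "medium", "high")
TREATMENT_DOSES = ("low", "medium", "high")
EXPERIMENTAL_SIGNALS = ("signalA", "signalB", "both")
EXTRA_CONTROL_SIGNALS = ("control_low_density", "control_high_density")
REFERENCE_SIGNAL = "control"


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid range."""


@dataclass
class PipelineConfig:
    """Tunables of the combined-response analysis.

    Defaults are the values the analysis was designed around: an 80%
    confidence interval for the classifier, a 100 kb TSS window for
    peak-gene linking, a 50x50 empirical-FDR grid with a 0.25% per-cell
    threshold, and 250 bp peak merging.
    """

    # classifier
    ci_level: float = 0.80
    # master set of upregulated genes
    master_log2fc: float = 0.5
    master_padj: float = 0.05
    # reliability filter on the interaction scale dA*dB/x0
    reliability_min_tpm: float = 2.0
    # null simulations
    n_sims_gene: int = 250
    n_sims_peak: int = 10
    hist_bin_width: float = 0.25
    hist_step: float = 0.125
    residual_fit_range: tuple[float, float] = (-4.0, 5.0)
    poisson_n_reps: int = 1000
    poisson_exclusion: tuple[float, float] = (-0.3, 0.3)
    # peak caller
    consensus_width: int = 150
    consensus_min_support: int = 2
    fc_grid: tuple[float, float, int] = (1.1, 10.0, 50)
    count_grid: tuple[float, float, int] = (10.0, 237.0, 50)
    fdr_cell_threshold: float = 0.0025
    merge_distance_bp: int = 250
    second_round_min_fc: float = 1.5
    second_round_min_count: float = 30.0
    # integration
    window_bp: int = 100_000
    dominance_threshold: float = 0.9
    n_bootstrap_genes: int = 10_000
    n_bootstrap_peaks: int = 1000
    bootstrap_ci_level: float = 0.90
    n_shuffles: int = 1000
    # randomness
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if not 0.0 < self.bootstrap_ci_level < 1.0:
            raise ConfigError(
                f"bootstrap_ci_level must be in (0, 1), got {self.bootstrap_ci_level}")
        if self.window_bp < 0:
            raise ConfigError("window_bp must be non-negative")
        if not 0.0 <= self.fdr_cell_threshold <= 1.0:
            raise ConfigError("fdr_cell_threshold must be a fraction")
        if self.merge_distance_bp < 0:
            raise ConfigError("merge_distance_bp must be non-negative")
        if self.hist_bin_width <= 0:
            raise ConfigError("hist_bin_width must be positive")
        if self.hist_step > self.hist_bin_width:
            raise ConfigError("hist_step must not exceed hist_bin_width")
        for lo, hi, n in (self.fc_grid, self.count_grid):
            if not (0 < lo < hi and n >= 2):
                raise ConfigError("threshold grids need 0 < lo < hi and n >= 2")
        if not 0.5 <= self.dominance_threshold <= 1.0:
            raise ConfigError("dominance_threshold must be in [0.5, 1]")
        for name in ("n_sims_gene", "n_sims_peak", "poisson_n_reps",
                     "n_bootstrap_genes", "n_bootstrap_peaks", "n_shuffles",
                     "consensus_width", "consensus_min_support"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("residual_fit_range", "poisson_exclusion", "fc_grid",
                    "count_grid", "seeds"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SynthConfig:
    """Ground-truth generator settings.

    The defaults emulate the study conditions the analysis assumes:
    three replicates, three doses of each signal alone and combined,
    per-feature Gaussian noise with a dose-shared CV drawn uniform in
    [0.05, 0.3], gene baselines log-uniform in [1, 500] TPM, and
    individual-signal effects with fold-changes spanning the weakly to
    strongly induced regime (delta/baseline log-uniform in [0.1, 2]).
    """

    n_genes: int = 500
    n_peaks: int = 1000
    n_replicates: int = 3
    dose_multipliers: tuple[float, float, float] = (0.5, 1.0, 1.5)
    cv_range: tuple[float, float] = (0.05, 0.3)
    gene_baseline_range: tuple[float, float] = (1.0, 500.0)      # TPM, log-uniform
    peak_baseline_range: tuple[float, float] = (30.0, 300.0)     # norm. counts, log-uniform
    delta_ratio_range: tuple[float, float] = (0.1, 2.0)          # delta/baseline, log-uniform
    # fraction of peaks that respond to the signals at all; the rest are a
    # static background, as in real accessibility landscapes where
    # differential peaks are a minority (reads-in-peaks normalization
    # assumes such a composition-stable universe)
    frac_responsive_peaks: float = 0.25
    # c_true: mixture of Gaussians (weight, mean, sd); default emulates the
    # additive + multiplicative bimodality of combined responses
    c_mixture: tuple[tuple[float, float, float], ...] = ((0.5, 0.0, 0.2), (0.5, 1.0, 0.2))
    d_sd: float = 0.1          # d_true ~ Normal(0, d_sd): addition as default operation
    extra_controls: bool = True
    # toy genome
    genome_length: int = 50_000_000
    chrom: str = "chrS"
    peak_width_range: tuple[int, int] = (150, 600)
    summit_jitter_sd: float = 15.0
    summit_dropout: float = 0.1
    # sequencing-depth factors applied to raw counts, undone by normalization
    depth_factor_range: tuple[float, float] = (0.6, 1.4)
    # motifs
    motif_mean_matches: float = 1.0
    motif_clustering: float = 0.0   # 0 = Poisson; >0 concentrates matches in few peaks
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cv_range
        if not (0 <= lo <= hi):  # lo == hi == 0 is the exact zero-noise limit
            raise ConfigError("cv_range must satisfy 0 <= lo <= hi")
        lo, hi = self.depth_factor_range
        if not (0 < lo <= hi):  # lo == hi == 1 turns depth variation off
            raise ConfigError("depth_factor_range must satisfy 0 < lo <= hi")
        for name in ("gene_baseline_range", "peak_baseline_range",
                     "delta_ratio_range", "peak_width_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ConfigError(f"{name} must satisfy 0 < lo < hi")
        if not 0.0 <= self.frac_responsive_peaks <= 1.0:
            raise ConfigError("frac_responsive_peaks must be in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 for CV estimation")
        if not 0.0 <= self.summit_dropout < 1.0:
            raise ConfigError("summit_dropout must be in [0, 1)")
        if abs(sum(w for w, _, _ in self.c_mixture) - 1.0) > 1e-9:
            raise ConfigError("c_mixture weights must sum to 1")
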
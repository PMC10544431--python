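"""Configuration objects for the simulator and the analysis pipeline.

Both configs are plain frozen dataclasses with eager validation, round-trip
YAML serialisation and a stable field order, so that a config + seed fully
determines every byte the pipeline writes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

__all__ = ["SimulationConfig", "PipelineConfig", "load_yaml", "dump_yaml"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic three-way admixed case-control cohort.

    The defaults emulate a Colombian-style study: three ancestral populations
    (Native American, European, African), Dirichlet individual admixture with
    mean proportions roughly (0.44, 0.49, 0.07) and an SD of the Native
    American proportion near 10 percentage points (interquartile range
    ~36-49%), a protective causal odds ratio of 0.974 per 1% Native American
    ancestry, and a continuous non-genetic risk factor that may be correlated
    with ancestry.

    Parameters
    ----------
    n_snps
        Number of unlinked biallelic SNPs simulated genome-wide.
    n_ref_per_pop
        Reference-panel sizes per ancestral population, ordered as
        ``pop_names``. Defaults mirror a small Native American panel plus
        1000-Genomes-sized European/African panels.
    fst
        Per-population Balding-Nichols drift from the shared ancestral
        frequency; Native American populations are the most drifted.
    dirichlet_alpha
        Concentration parameters of the individual admixture proportions.
    beta_anc
        Causal log-odds of disease per +1 percentage point of Native American
        ancestry (default ln 0.974).
    beta_conf
        Log-odds per 1 SD of the non-genetic confounder U.
    conf_anc_corr
        Correlation between U and the standardized Native American ancestry
        percentage. 0 makes U a purely non-genetic outcome-side risk factor.
    beta_age
        Log-odds per year of age (centred at 50); small and known so age
        adjustment is testable.
    baseline_prev
        Population disease prevalence; the logistic intercept is calibrated
        to it by bisection (tolerance 1e-6).
    pool_size
        Size of the population pool cases/controls are sampled from.
    subtype_effects
        Optional ``(beta_er_pos, beta_er_neg)`` per-1% log-odds for two
        competing disease processes; used to plant subtype-specific causal
        effects. ``None`` uses the single-process model.
    frac_phewas_flagged
        Fraction of SNPs flagged with a sub-genome-wide-significant entry in
        the synthetic PheWAS catalog.
    """

    n_snps: int = 5000
    n_ref_per_pop: tuple[int, ...] = (30, 107, 108)
    fst: tuple[float, ...] = (0.25, 0.15, 0.10)
    dirichlet_alpha: tuple[float, ...] = (10.0, 11.0, 1.5)
    n_cases: int = 700
    n_controls: int = 700
    pool_size: int = 20000
    beta_anc: float = math.log(0.974)
    beta_conf: float = math.log(1.5)
    conf_anc_corr: float = -0.3
    beta_age: float = 0.01
    baseline_prev: float = 0.08
    frac_phewas_flagged: float = 0.1
    seed: int = 0
    pop_names: tuple[str, ...] = ("NAM", "EUR", "AFR")
    # age model: N(age_mean, age_sd^2) truncated to age_range
    age_mean: float = 50.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (25.0, 80.0)
    # case attribute model
    er_pos_frac: float = 0.65
    er_anc_slope: float = 0.0
    pr_pos_given_er: tuple[float, float] = (0.85, 0.25)
    her2_pos_frac: float = 0.2
    fam_hist_case: float = 0.15
    fam_hist_control: float = 0.05
    subtype_effects: Optional[tuple[float, float]] = None
    # optional LD blocks: consecutive SNPs within a block are noisy copies of
    # the block leader (exercises LD pruning; default = unlinked SNPs)
    ld_block_size: int = 1
    ld_block_flip: float = 0.05

    def __post_init__(self) -> None:
        k = len(self.pop_names)
        if k < 2:
            raise ValueError("need at least two ancestral populations")
        if len(self.n_ref_per_pop) != k or len(self.fst) != k or len(self.dirichlet_alpha) != k:
            raise ValueError("n_ref_per_pop, fst and dirichlet_alpha must all have length K")
        for name, val in [
            ("n_snps", self.n_snps),
            ("n_cases", self.n_cases),
            ("n_controls", self.n_controls),
            ("pool_size", self.pool_size),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be a positive count, got {val}")
        if any(n <= 0 for n in self.n_ref_per_pop):
            raise ValueError("reference panel sizes must be positive")
        if any(not (0.0 < f < 1.0) for f in self.fst):
            raise ValueError(f"fst values must lie in (0, 1), got {self.fst}")
        if any(a <= 0.0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if not (0.0 < self.baseline_prev < 1.0):
            raise ValueError("baseline_prev must lie in (0, 1)")
        if not (-1.0 <= self.conf_anc_corr <= 1.0):
            raise ValueError("conf_anc_corr must lie in [-1, 1]")
        if not (0.0 <= self.frac_phewas_flagged <= 1.0):
            raise ValueError("frac_phewas_flagged must lie in [0, 1]")
        if not math.isfinite(self.beta_anc):
            raise ValueError("beta_anc must be finite")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @property
    def k(self) -> int:
        return len(self.pop_names)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly plain types
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for key in (
            "n_ref_per_pop",
            "fst",
            "dirichlet_alpha",
            "pop_names",
            "age_range",
            "pr_pos_given_er",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("subtype_effects") is not None:
            kwargs["subtype_effects"] = tuple(kwargs["subtype_effects"])
        return cls(**kwargs)


#: default strata mirroring the stratified analyses: early diagnosis,
#: familial disease, hormone-receptor subtypes
DEFAULT_STRATA: tuple[str, ...] = (
    "diag_le_45",
    "familial",
    "er_pos",
    "er_neg",
    "triple_negative",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, stage options and provenance for an end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gwas_p: float = 5e-8
    phewas_p: float = 5e-8
    ld_r2: float = 0.01
    radial_p: float = 0.1
    top_k: int = 20000
    em_tol: float = 1e-6
    em_max_iter: int = 2000
    n_boot_wm: int = 1000
    strata: tuple[str, ...] = DEFAULT_STRATA
    min_stratum_cases: int = 30
    random_effects: bool = False

    def __post_init__(self) -> None:
        for name in ("gwas_p", "phewas_p", "ld_r2", "radial_p"):
            val = getattr(self, name)
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValueError("invalid EM settings")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["strata"] = list(self.strata)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], Mapping):
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        if "strata" in kwargs:
            kwargs["strata"] = tuple(kwargs["strata"])
        return cls(**kwargs)


def dump_yaml(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_yaml(path, kind: str = "pipeline"):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if kind == "simulation":
        return SimulationConfig.from_dict(d)
    return PipelineConfig.from_dict(d)
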
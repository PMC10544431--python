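"""Synthetic admixed case-control cohorts with known causal structure.

The generative model:

* Balding-Nichols drift: each SNP has an ancestral frequency p ~ U(0.05, 0.95)
  and per-subpopulation frequencies p_k ~ Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k).
* Reference panels: dosages ~ Binomial(2, p_k) per SNP and individual.
* Admixture at the genotype level: individual proportions q ~ Dirichlet(alpha),
  dosage ~ Binomial(2, sum_k q_k p_k). Global proportions (the exposure) are
  therefore exact by construction; no local-ancestry segments are simulated.
* Disease: logit P(case) = c + beta_anc * q_NA% + beta_conf * U + beta_age * (age - 50),
  with U = rho * z(q_NA%) + sqrt(1 - rho^2) * N(0,1) a continuous non-genetic
  risk factor (rho = conf_anc_corr) that downstream modules never observe, and
  the intercept c calibrated by bisection so the population prevalence equals
  baseline_prev. Cases and controls are then sampled from the pool.
* Optionally two competing disease processes (ER-positive / ER-negative) with
  separate ancestry effects, for planting subtype heterogeneity.

All randomness flows from ``SimulationConfig.seed`` through fixed-purpose
``numpy.random.SeedSequence`` children, so identical configs give identical
outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .aims import FrequencyTable
from .config import SimulationConfig
from .instruments import CONFOUNDER_PHENOTYPES

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "simulate_ancestral_frequencies",
    "simulate_reference_panel",
    "simulate_admixed_cohort",
    "simulate_outcome",
    "simulate_phewas_catalog",
    "simulate_case_control_study",
]

# fixed stream labels so each operation draws from an independent,
# reproducible stream of config.seed
_STREAMS = {
    "freqs": 101,
    "alleles": 102,
    "panel": 201,
    "cohort": 301,
    "outcome": 401,
    "genotypes": 501,
    "phewas": 601,
}

_BASES = np.array(list("ACGT"))


def _rng(config: SimulationConfig, stream: str, rng: Optional[np.random.Generator]):
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), _STREAMS[stream])))


@dataclass(frozen=True)
class Cohort:
    """Genotypes plus (optionally) phenotypes for a set of individuals.

    ``genotypes`` holds ALT-allele dosages in {0, 1, 2} with shape
    (n_individuals, n_snps); ``true_q`` the generating ancestry simplex.
    ``phenotypes`` is None until :func:`simulate_outcome` assigns case-control
    status and covariates.
    """

    genotypes: np.ndarray
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    true_q: np.ndarray
    pop_names: tuple[str, ...]
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        if not np.isin(np.unique(g), [0, 1, 2]).all():
            raise ValueError("dosages must be integers in {0, 1, 2}")
        if self.true_q.shape != (g.shape[0], len(self.pop_names)):
            raise ValueError("true_q must be (n_individuals, K)")
        if np.any(self.true_q < -1e-12) or np.max(np.abs(self.true_q.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("each true_q row must lie on the probability simplex")
        if self.phenotypes is not None and len(self.phenotypes) != g.shape[0]:
            raise ValueError("phenotypes must align with genotypes")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def q_na_percent(self) -> np.ndarray:
        """True Native American (first population) proportion on the 0-100 scale."""
        return 100.0 * self.true_q[:, 0]

    @property
    def status(self) -> np.ndarray:
        if self.phenotypes is None:
            raise ValueError("cohort has no phenotypes yet; run simulate_outcome")
        return self.phenotypes["status"].to_numpy(int)

    @property
    def age(self) -> np.ndarray:
        if self.phenotypes is None:
            raise ValueError("cohort has no phenotypes yet; run simulate_outcome")
        return self.phenotypes["age"].to_numpy(float)

    def take(self, idx: np.ndarray) -> "Cohort":
        return replace(
            self,
            genotypes=self.genotypes[idx],
            sample_ids=self.sample_ids[idx],
            true_q=self.true_q[idx],
            phenotypes=None
            if self.phenotypes is None
            else self.phenotypes.iloc[idx].reset_index(drop=True),
        )


def simulate_ancestral_frequencies(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> FrequencyTable:
    """Draw ancestral and per-subpopulation allele frequencies.

    Ancestral ALT frequency per SNP ~ U(0.05, 0.95); subpopulation k drifts
    away following the Balding-Nichols Beta with parameter F_k. Frequencies
    are clipped into the open interval to remain strictly in (0, 1).
    """
    if config.k < 2:
        raise ValueError("need K >= 2 subpopulations")
    rng = _rng(config, "freqs", rng)
    m = config.n_snps
    anc = rng.uniform(0.05, 0.95, size=m)
    freqs = np.empty((m, config.k))
    for i, f in enumerate(config.fst):
        lam = (1.0 - f) / f
        freqs[:, i] = rng.beta(anc * lam, (1.0 - anc) * lam)
    eps = 1e-9
    freqs = np.clip(freqs, eps, 1.0 - eps)
    if config.ld_block_size > 1:
        # block members inherit the leader's frequencies so genotype copying
        # (below) preserves marginal frequencies
        leaders = (np.arange(m) // config.ld_block_size) * config.ld_block_size
        freqs = freqs[leaders]
        anc = anc[leaders]
    snp_ids = np.array([f"rs{i + 1:06d}" for i in range(m)])
    allele_rng = _rng(config, "alleles", None)
    ref = _BASES[allele_rng.integers(0, 4, size=m)]
    shift = allele_rng.integers(1, 4, size=m)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    tbl = FrequencyTable(snp_ids=snp_ids, freqs=freqs, pop_names=config.pop_names, ancestral=anc)
    # stash alleles for VCF export without widening the FrequencyTable contract
    object.__setattr__(tbl, "_ref", ref)
    object.__setattr__(tbl, "_alt", alt)
    return tbl


def _alleles(freqs: FrequencyTable, config: SimulationConfig):
    ref = getattr(freqs, "_ref", None)
    alt = getattr(freqs, "_alt", None)
    if ref is None:
        m = freqs.n_snps
        ref = np.array(["A"] * m)
        alt = np.array(["G"] * m)
    return ref, alt


def _draw_dosages(
    rng: np.random.Generator, probs: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Binomial(2, p) dosages, with optional LD-block copying."""
    g = rng.binomial(2, probs).astype(np.int8)
    if config.ld_block_size > 1:
        m = probs.shape[-1]
        leaders = (np.arange(m) // config.ld_block_size) * config.ld_block_size
        keep_own = rng.random(g.shape) < config.ld_block_flip
        g = np.where(keep_own, g, g[..., leaders]).astype(np.int8)
    return g


def simulate_reference_panel(
    freqs: FrequencyTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, np.ndarray]:
    """Unadmixed reference-panel dosage matrices, one per subpopulation."""
    if any(n < 1 for n in config.n_ref_per_pop):
        raise ValueError("panel sizes must be >= 1")
    rng = _rng(config, "panel", rng)
    panels = {}
    for i, pop in enumerate(freqs.pop_names):
        n_i = config.n_ref_per_pop[i]
        p = np.broadcast_to(freqs.freqs[:, i], (n_i, freqs.n_snps))
        panels[pop] = _draw_dosages(rng, p, config)
    return panels


def simulate_admixed_cohort(
    freqs: FrequencyTable,
    config: SimulationConfig,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Admixed individuals: q ~ Dirichlet(alpha), dosage ~ Binomial(2, q'p)."""
    if len(config.dirichlet_alpha) != freqs.k:
        raise ValueError("dirichlet_alpha must have length K")
    rng = _rng(config, "cohort", rng)
    n = config.pool_size if n is None else int(n)
    q = rng.dirichlet(config.dirichlet_alpha, size=n)
    x = q @ freqs.freqs.T
    g = _draw_dosages(rng, x, config)
    ref, alt = _alleles(freqs, config)
    return Cohort(
        genotypes=g,
        snp_ids=freqs.snp_ids.copy(),
        sample_ids=np.array([f"ind{i + 1:06d}" for i in range(n)]),
        true_q=q,
        pop_names=freqs.pop_names,
        ref=ref,
        alt=alt,
    )


def _truncated_ages(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    u = rng.random(n)
    return truncnorm.ppf(u, a, b, loc=config.age_mean, scale=config.age_sd)


def _calibrate_intercept(risk_at, prev: float, tol: float = 1e-6) -> float:
    """Bisection on the intercept so the mean disease probability equals prev.

    ``risk_at(c)`` must return the mean probability at intercept c and be
    increasing in c.
    """
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = risk_at(mid)
        if abs(val - prev) < tol:
            return mid
        if val < prev:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _pool_disease(
    q_pct: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Confounder, age, disease status and (optionally) subtype for a pool."""
    n = q_pct.size
    sd = q_pct.std()
    z = (q_pct - q_pct.mean()) / sd if sd > 0 else np.zeros(n)
    rho = config.conf_anc_corr
    u = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    age = _truncated_ages(rng, n, config)
    age_term = config.beta_age * (age - config.age_mean)
    out = {"u": u, "age": age}
    if config.subtype_effects is None:
        h = config.beta_anc * q_pct + config.beta_conf * u + age_term
        c = _calibrate_intercept(lambda c: expit(c + h).mean(), config.baseline_prev)
        p = expit(c + h)
        out["p_case"] = p
        out["status"] = (rng.random(n) < p).astype(int)
        out["er_process"] = None
    else:
        b_pos, b_neg = config.subtype_effects
        h_pos = b_pos * q_pct + config.beta_conf * u + age_term
        h_neg = b_neg * q_pct + config.beta_conf * u + age_term
        off_pos = np.log(config.er_pos_frac)
        off_neg = np.log(1.0 - config.er_pos_frac)

        def total(c):
            p1 = expit(c + off_pos + h_pos)
            p2 = expit(c + off_neg + h_neg)
            return (1.0 - (1.0 - p1) * (1.0 - p2)).mean()

        c = _calibrate_intercept(total, config.baseline_prev)
        p_pos = expit(c + off_pos + h_pos)
        p_neg = expit(c + off_neg + h_neg)
        hit_pos = rng.random(n) < p_pos
        hit_neg = rng.random(n) < p_neg
        both = hit_pos & hit_neg
        pick_pos = rng.random(n) < p_pos / np.maximum(p_pos + p_neg, 1e-30)
        er_pos = np.where(both, pick_pos, hit_pos)
        out["p_case"] = 1.0 - (1.0 - p_pos) * (1.0 - p_neg)
        out["status"] = (hit_pos | hit_neg).astype(int)
        out["er_process"] = er_pos
    return out


def _case_attributes(
    n: int,
    is_case: np.ndarray,
    q_pct: np.ndarray,
    age: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    er_process: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assign age at diagnosis, family history and receptor labels."""
    sd = q_pct.std()
    z = (q_pct - q_pct.mean()) / sd if sd > 0 else np.zeros(n)
    if er_process is not None:
        er_pos = er_process.astype(bool)
    else:
        p_er = expit(logit(config.er_pos_frac) + config.er_anc_slope * z)
        er_pos = rng.random(n) < p_er
    p_pr = np.where(er_pos, config.pr_pos_given_er[0], config.pr_pos_given_er[1])
    pr_pos = rng.random(n) < p_pr
    her2_pos = rng.random(n) < config.her2_pos_frac
    fam_p = np.where(is_case, config.fam_hist_case, config.fam_hist_control)
    fam = (rng.random(n) < fam_p).astype(int)
    aad = np.clip(age - rng.uniform(0.0, 4.0, size=n), config.age_range[0], None)

    df = pd.DataFrame(
        {
            "status": is_case.astype(int),
            "age": age,
            "age_at_diagnosis": np.where(is_case, aad, np.nan),
            "family_history": fam,
            "er": np.where(is_case, np.where(er_pos, "+", "-"), None),
            "pr": np.where(is_case, np.where(pr_pos, "+", "-"), None),
            "her2": np.where(is_case, np.where(her2_pos, "+", "-"), None),
        }
    )
    return df


def _sample_case_control(
    status: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    if case_idx.size < config.n_cases:
        raise ValueError(
            f"only {case_idx.size} cases generated but {config.n_cases} requested; "
            "increase pool_size or baseline_prev"
        )
    if ctrl_idx.size < config.n_controls:
        raise ValueError(
            f"only {ctrl_idx.size} controls generated but {config.n_controls} requested; "
            "increase pool_size"
        )
    take_cases = rng.permutation(case_idx)[: config.n_cases]
    take_ctrls = rng.permutation(ctrl_idx)[: config.n_controls]
    return np.sort(np.concatenate([take_cases, take_ctrls]))


def simulate_outcome(
    cohort: Cohort, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Cohort:
    """Assign disease status to a pool cohort and sample cases and controls.

    Returns a new :class:`Cohort` of exactly ``n_cases + n_controls``
    individuals with phenotypes attached. Raises if the pool produced fewer
    cases (or controls) than requested.
    """
    rng = _rng(config, "outcome", rng)
    q_pct = cohort.q_na_percent
    dis = _pool_disease(q_pct, config, rng)
    status = dis["status"]
    keep = _sample_case_control(status, config, rng)
    pheno = _case_attributes(
        cohort.n, status.astype(bool), q_pct, dis["age"], config, rng, dis["er_process"]
    )
    sub = cohort.take(keep)
    ph = pheno.iloc[keep].reset_index(drop=True)
    ph.insert(0, "sample_id", sub.sample_ids)
    return replace(sub, phenotypes=ph)


def simulate_phewas_catalog(
    snp_ids: Sequence[str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Synthetic PheWAS catalog: flagged SNPs get confounder-phenotype hits.

    Each flagged SNP (fraction ``frac_phewas_flagged``) receives at least one
    row with a phenotype drawn from :data:`CONFOUNDER_PHENOTYPES` and a
    p-value log-uniform below 5e-8. Unflagged SNPs are absent.
    """
    rng = _rng(config, "phewas", rng)
    snp_ids = np.asarray(snp_ids, dtype=str)
    flagged = rng.random(snp_ids.size) < config.frac_phewas_flagged
    rows = []
    log_cut = np.log10(5e-8)
    for snp in snp_ids[flagged]:
        n_rows = min(1 + rng.poisson(0.5), len(CONFOUNDER_PHENOTYPES))
        phenos = rng.choice(CONFOUNDER_PHENOTYPES, size=n_rows, replace=False)
        for ph in np.atleast_1d(phenos):
            pval = 10.0 ** rng.uniform(-20.0, log_cut)
            rows.append((snp, str(ph), pval))
    return pd.DataFrame(rows, columns=["snp_id", "phenotype", "pval"])


def simulate_case_control_study(
    config: SimulationConfig,
) -> tuple[Cohort, dict[str, np.ndarray], FrequencyTable, pd.DataFrame]:
    """End-to-end study generator used by the pipeline.

    Equivalent to simulate_ancestral_frequencies -> simulate_reference_panel ->
    simulate_admixed_cohort -> simulate_outcome -> simulate_phewas_catalog,
    but genotypes are only materialised for the sampled cases and controls
    (disease depends on ancestry, not on genotypes given ancestry), which makes
    replicate studies cheap.

    Returns (cohort, panels, true_frequency_table, phewas_catalog).
    """
    freqs = simulate_ancestral_frequencies(config)
    panels = simulate_reference_panel(freqs, config)

    rng_cohort = _rng(config, "cohort", None)
    n = config.pool_size
    q = rng_cohort.dirichlet(config.dirichlet_alpha, size=n)
    q_pct = 100.0 * q[:, 0]

    rng_outcome = _rng(config, "outcome", None)
    dis = _pool_disease(q_pct, config, rng_outcome)
    keep = _sample_case_control(dis["status"], config, rng_outcome)
    pheno = _case_attributes(
        n, dis["status"].astype(bool), q_pct, dis["age"], config, rng_outcome, dis["er_process"]
    )

    rng_geno = _rng(config, "genotypes", None)
    q_sel = q[keep]
    x = q_sel @ freqs.freqs.T
    g = _draw_dosages(rng_geno, x, config)
    ref, alt = _alleles(freqs, config)
    sample_ids = np.array([f"ind{i + 1:06d}" for i in keep])
    ph = pheno.iloc[keep].reset_index(drop=True)
    ph.insert(0, "sample_id", sample_ids)
    cohort = Cohort(
        genotypes=g,
        snp_ids=freqs.snp_ids.copy(),
        sample_ids=sample_ids,
        true_q=q_sel,
        pop_names=freqs.pop_names,
        ref=ref,
        alt=alt,
        phenotypes=ph,
    )
    catalog = simulate_phewas_catalog(freqs.snp_ids, config)
    return cohort, panels, freqs, catalog
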
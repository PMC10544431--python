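"""Two-sample Mendelian randomization estimators and diagnostics.

Per instrument j the harmonised set carries the SNP-exposure effect gamma_j
(percentage points of Native American ancestry per effect allele, estimated in
the controls), the SNP-outcome effect Gamma_j (log odds ratio per allele,
estimated in cases plus controls), their standard errors, the Wald ratio
beta_j = Gamma_j / gamma_j and the first-order inverse-variance weight
w_j = (sigma_Gamma_j / gamma_j)^-2. First-order weights (which ignore the
exposure-side uncertainty and keep the type-I error rate under the causal
null) are used everywhere: IVW, Cochran's Q and the radial outlier filter.

Estimators: inverse-variance-weighted (fixed-effect by default), MR-Egger
(weighted regression with a free intercept; a non-zero intercept flags
directional pleiotropy) and the interpolated weighted median (consistent when
at least half the weight comes from valid instruments), plus Cochran's Q
heterogeneity, iterative radial outlier exclusion, odds-ratio-per-1% reporting
helpers and a closed-form power calculation for binary outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "MRResult",
    "harmonize",
    "ivw",
    "cochran_q",
    "radial_outlier_filter",
    "mr_egger",
    "weighted_median",
    "or_per_percent",
    "quartile_risk_difference",
    "mr_power_binary",
]


@dataclass(frozen=True)
class InstrumentSet:
    """Harmonised per-instrument exposure/outcome summary statistics."""

    snp_ids: np.ndarray
    gamma: np.ndarray  # SNP-exposure effect, per-1% scale
    se_gamma: np.ndarray
    big_gamma: np.ndarray  # SNP-outcome log-OR
    se_big_gamma: np.ndarray
    n_flipped: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.gamma == 0):
            raise ValueError("retained instruments must have non-zero exposure effects")
        if np.any(self.se_big_gamma <= 0) or np.any(self.se_gamma < 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_iv(self) -> int:
        return self.snp_ids.size

    @property
    def ratio(self) -> np.ndarray:
        """Per-instrument Wald ratios beta_j = Gamma_j / gamma_j."""
        return self.big_gamma / self.gamma

    @property
    def weights(self) -> np.ndarray:
        """First-order weights w_j = (sigma_Gamma_j / gamma_j)^-2."""
        return (self.gamma / self.se_big_gamma) ** 2

    def take(self, mask: np.ndarray) -> "InstrumentSet":
        return replace(
            self,
            snp_ids=self.snp_ids[mask],
            gamma=self.gamma[mask],
            se_gamma=self.se_gamma[mask],
            big_gamma=self.big_gamma[mask],
            se_big_gamma=self.se_big_gamma[mask],
        )

    def oriented(self) -> "InstrumentSet":
        """Flip alleles so every exposure effect is positive (for Egger)."""
        sign = np.sign(self.gamma)
        return replace(self, gamma=self.gamma * sign, big_gamma=self.big_gamma * sign)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "Gamma": self.big_gamma,
                "se_Gamma": self.se_big_gamma,
                "ratio": self.ratio,
                "weight": self.weights,
            }
        )


@dataclass(frozen=True)
class MRResult:
    """One causal estimate with heterogeneity diagnostics."""

    method: str
    beta_hat: float  # log-OR per 1% ancestry
    se: float
    pval: float
    n_iv: int
    odds_ratio: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    cochran_q: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    r2_cumulative: Optional[float] = None
    f_stat: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "odds_ratio", float(np.exp(self.beta_hat)))
        object.__setattr__(self, "ci_low", float(np.exp(self.beta_hat - 1.959963984540054 * self.se)))
        object.__setattr__(self, "ci_high", float(np.exp(self.beta_hat + 1.959963984540054 * self.se)))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta_hat": self.beta_hat,
            "se": self.se,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_iv": self.n_iv,
            "cochran_q": self.cochran_q,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_pval": self.egger_intercept_pval,
            "r2_cumulative": self.r2_cumulative,
            "f_stat": self.f_stat,
        }


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Swapped effect/other alleles flip the outcome beta sign (and eaf);
    incompatible allele pairs are dropped with a warning. Both inputs are
    GWAS-style summary-statistic frames.
    """
    merged = exposure.merge(outcome, on="snp_id", suffixes=("_exp", "_out"))
    if merged.empty:
        raise ValueError("no overlapping SNPs between exposure and outcome statistics")
    same = (merged["effect_allele_exp"] == merged["effect_allele_out"]) & (
        merged["other_allele_exp"] == merged["other_allele_out"]
    )
    swapped = (merged["effect_allele_exp"] == merged["other_allele_out"]) & (
        merged["other_allele_exp"] == merged["effect_allele_out"]
    )
    drop = ~(same | swapped)
    if drop.any():
        logger.warning(
            "dropping %d SNP(s) with incompatible alleles: %s",
            int(drop.sum()),
            ", ".join(merged.loc[drop, "snp_id"].head(5)),
        )
        merged = merged[~drop]
        same, swapped = same[~drop], swapped[~drop]
    sign = np.where(swapped, -1.0, 1.0)
    zero = merged["beta_exp"].to_numpy() == 0
    if zero.any():
        merged = merged[~zero]
        sign = sign[~zero]
    return InstrumentSet(
        snp_ids=merged["snp_id"].to_numpy(str),
        gamma=merged["beta_exp"].to_numpy(float),
        se_gamma=merged["se_exp"].to_numpy(float),
        big_gamma=merged["beta_out"].to_numpy(float) * sign,
        se_big_gamma=merged["se_out"].to_numpy(float),
        n_flipped=int(swapped.sum()),
        n_dropped=int(drop.sum()) + int(zero.sum()),
    )


def cochran_q(instruments: InstrumentSet, beta_hat: float) -> tuple[float, int, float]:
    """Cochran's Q with first-order weights: Q = sum w_j (beta_j - beta_hat)^2."""
    if instruments.n_iv < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    w = instruments.weights
    q = float(np.sum(w * (instruments.ratio - beta_hat) ** 2))
    df = instruments.n_iv - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(instruments: InstrumentSet, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate with first-order weights.

    beta_hat = sum w_j beta_j / sum w_j, se = (sum w_j)^-1/2 — identical to
    the slope of the zero-intercept weighted regression of Gamma on gamma.
    ``random_effects`` applies the multiplicative heterogeneity inflation
    max(1, sqrt(Q / df)) to the standard error.
    """
    if instruments.n_iv < 1:
        raise ValueError("IVW needs at least one instrument")
    w = instruments.weights
    beta = float(np.sum(w * instruments.ratio) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = df = qp = None
    if instruments.n_iv >= 2:
        q, df, qp = cochran_q(instruments, beta)
        if random_effects:
            se *= max(1.0, np.sqrt(q / df))
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MRResult(
        method="IVW", beta_hat=beta, se=se, pval=float(pval), n_iv=instruments.n_iv,
        cochran_q=q, q_df=df, q_pval=qp,
    )


def radial_outlier_filter(
    instruments: InstrumentSet, alpha: float = 0.1, max_rounds: int = 20
) -> tuple[InstrumentSet, np.ndarray]:
    """Iterative radial-MR outlier exclusion.

    Each round fits IVW, computes per-instrument contributions
    Q_j = w_j (beta_j - beta_hat)^2 with chi-square(1) p-values and removes
    every instrument with p_j < alpha; rounds repeat until nothing is removed,
    at most 3 instruments would remain, or ``max_rounds`` is hit.
    """
    if instruments.n_iv < 3:
        raise ValueError("radial filtering needs at least 3 instruments")
    removed: list[str] = []
    current = instruments
    for _ in range(max_rounds):
        w = current.weights
        beta = float(np.sum(w * current.ratio) / np.sum(w))
        q_j = w * (current.ratio - beta) ** 2
        p_j = stats.chi2.sf(q_j, 1)
        out = p_j < alpha
        if not out.any():
            break
        if out.all():
            raise ValueError("radial filtering removed every instrument; inspect the inputs")
        removed.extend(current.snp_ids[out])
        current = current.take(~out)
        if current.n_iv <= 3:
            break
    return current, np.array(removed, dtype=str)


def mr_egger(instruments: InstrumentSet) -> MRResult:
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    Exposure effects are first oriented positive; weights are 1/sigma_Gamma^2.
    The slope is the causal estimate, the intercept the average directional
    pleiotropy; p-values are t-based with n_iv - 2 degrees of freedom.
    """
    if instruments.n_iv < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    inst = instruments.oriented()
    x, y = inst.gamma, inst.big_gamma
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all exposure effects identical")
    w = 1.0 / inst.se_big_gamma**2
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(design, sw * y, rcond=None)
    resid = sw * y - design @ coef
    dof = inst.n_iv - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, dof)
    p_inter = 2.0 * stats.t.sf(abs(inter) / max(se_inter, 1e-300), dof)
    q, dfq, qp = cochran_q(inst, slope)
    return MRResult(
        method="Egger", beta_hat=slope, se=se_slope, pval=float(p_slope),
        n_iv=inst.n_iv, cochran_q=q, q_df=dfq, q_pval=qp,
        egger_intercept=inter, egger_intercept_pval=float(p_inter),
    )


def _interp_weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order] / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(b[0])
    if s[-1] <= 0.5:
        return float(b[-1])
    k = int(np.searchsorted(s, 0.5))
    return float(b[k - 1] + (b[k] - b[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(
    instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Interpolated weighted median of the Wald ratios.

    The estimate interpolates the ordered ratios where the normalised
    cumulative weight crosses one half; the standard error comes from a
    seeded parametric bootstrap with beta_j* ~ Normal(beta_j, w_j^-1/2).
    """
    if instruments.n_iv < 3:
        raise ValueError("the weighted median needs at least 3 instruments")
    b, w = instruments.ratio, instruments.weights
    est = _interp_weighted_median(b, w)
    rng = np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(w)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _interp_weighted_median(b + sd * rng.standard_normal(b.size), w)
    se = float(boots.std(ddof=1))
    pval = 2.0 * stats.norm.sf(abs(est) / max(se, 1e-300))
    q, df, qp = cochran_q(instruments, est)
    return MRResult(
        method="WM", beta_hat=est, se=se, pval=float(pval), n_iv=instruments.n_iv,
        cochran_q=q, q_df=df, q_pval=qp,
    )


def or_per_percent(beta_hat: float, se: float) -> dict:
    """Report a log-OR per 1% ancestry as OR, 95% CI and percent risk decrease."""
    z = 1.959963984540054
    or_ = float(np.exp(beta_hat))
    return {
        "odds_ratio": or_,
        "ci_low": float(np.exp(beta_hat - z * se)),
        "ci_high": float(np.exp(beta_hat + z * se)),
        "percent_decrease": 100.0 * (1.0 - or_),
    }


def quartile_risk_difference(
    percent_decrease_per_1pct: float, q_low: float, q_high: float
) -> float:
    """Expected risk difference (%) between ancestry quantiles q_low and q_high.

    Linear extrapolation of the per-1% risk decrease across the interquartile
    spread of the ancestry distribution, both on the percent scale.
    """
    if q_high < q_low:
        raise ValueError("q_high must be >= q_low")
    return (q_high - q_low) * percent_decrease_per_1pct


def mr_power_binary(
    n: int,
    case_fraction: float,
    r2: float,
    or_per_sd: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power of an MR study with a binary outcome.

    Non-centrality follows the standard two-stage approximation: with
    b = ln(or_per_sd) (log-OR per SD of the exposure), instrument strength r2
    (fraction of exposure variance explained) and case fraction K,

        z = |b| * sqrt(n * r2 * K * (1 - K)),
        power = Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2}).
    """
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must lie in (0, 1)")
    if not (0.0 < case_fraction < 1.0) or n <= 0 or not (0.0 < alpha < 1.0):
        raise ValueError("invalid power-calculation arguments")
    b = np.log(or_per_sd)
    z = abs(b) * np.sqrt(n * r2 * case_fraction * (1.0 - case_fraction))
    zcrit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(z - zcrit) + stats.norm.cdf(-z - zcrit))
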
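"""Instrument selection: association scans, PheWAS exclusion, LD pruning.

Candidate instruments are ancestry-informative markers that (1) predict the
exposure (Native American ancestry percentage) at genome-wide significance in
the controls, (2) carry no known association with potential confounder
phenotypes in a PheWAS catalog, and (3) are pairwise in linkage equilibrium,
keeping the marker with the highest explained variance within each correlated
group. Instrument strength is summarised by the cumulative explained variance
and F-statistics.

Summary statistics are exchanged as pandas DataFrames with the GWAS-style
columns (snp_id, effect_allele, other_allele, eaf, beta, se, pval, n); the
effect allele is the VCF ALT allele throughout this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "CONFOUNDER_PHENOTYPES",
    "InstrumentReport",
    "linear_scan_ancestry",
    "logistic_scan_outcome",
    "phewas_filter",
    "explained_variance",
    "ld_r2",
    "greedy_ld_prune",
    "instrument_strength",
]

#: Phenotype groups whose catalog associations disqualify an instrument:
#: reproductive, lifestyle, socio-economic and metabolic traits plus the
#: outcome itself.
CONFOUNDER_PHENOTYPES: tuple[str, ...] = (
    "menopause",
    "pregnancy outcomes",
    "tobacco or cigarette smoking",
    "alcohol consumption",
    "educational level",
    "contraceptives",
    "hormone-replacement therapy",
    "diabetes",
    "body circumferences",
    "breast cancer",
)

_SUMMARY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]


def _as_alleles(snp_ids, effect, other):
    m = len(snp_ids)
    if effect is None:
        effect = np.array(["ALT"] * m)
    if other is None:
        other = np.array(["REF"] * m)
    return np.asarray(effect, dtype=str), np.asarray(other, dtype=str)


def linear_scan_ancestry(
    genotypes: np.ndarray,
    q_na_percent: np.ndarray,
    age: np.ndarray,
    snp_ids: np.ndarray,
    effect_allele: np.ndarray | None = None,
    other_allele: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of the ancestry percentage on dosage plus age (controls).

    Fits q_NA% ~ 1 + dosage + age independently for every SNP by batched
    closed-form least squares; beta is the per-effect-allele change in the
    exposure (percentage points), with t-based two-sided p-values.
    Monomorphic SNPs are dropped with a warning.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(q_na_percent, dtype=float)
    a = np.asarray(age, dtype=float)
    n, m = g.shape
    if n < 3:
        raise ValueError("need at least 3 individuals for the exposure scan")
    poly = g.std(axis=0) > 0
    if not poly.all():
        logger.warning("dropping %d monomorphic SNP(s) from the exposure scan", int((~poly).sum()))
    g = g[:, poly]
    snp_ids = np.asarray(snp_ids, dtype=str)[poly]
    effect_allele, other_allele = _as_alleles(
        snp_ids,
        None if effect_allele is None else np.asarray(effect_allele)[poly],
        None if other_allele is None else np.asarray(other_allele)[poly],
    )
    m = g.shape[1]
    use_age = np.ptp(a) > 0  # a constant age column would be collinear
    d = 3 if use_age else 2

    # batched normal equations; X_j = [1, g_j (, age)]
    xtx = np.empty((m, d, d))
    xtx[:, 0, 0] = n
    xtx[:, 0, 1] = xtx[:, 1, 0] = g.sum(axis=0)
    xtx[:, 1, 1] = (g * g).sum(axis=0)
    xty = np.empty((m, d))
    xty[:, 0] = y.sum()
    xty[:, 1] = g.T @ y
    if use_age:
        xtx[:, 0, 2] = xtx[:, 2, 0] = a.sum()
        xtx[:, 1, 2] = xtx[:, 2, 1] = g.T @ a
        xtx[:, 2, 2] = float(a @ a)
        xty[:, 2] = float(a @ y)
    coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
    fitted_ss = np.einsum("mk,mk->m", coef, xty)
    dof = n - d
    sigma2 = np.maximum(float(y @ y) - fitted_ss, 0.0) / dof
    inv11 = np.linalg.inv(xtx)[:, 1, 1]
    se = np.sqrt(np.maximum(sigma2 * inv11, 1e-300))
    beta = coef[:, 1]
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": g.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "pval": np.clip(pval, np.finfo(float).tiny, 1.0),
            "n": n,
        }
    )


def _batch_logistic(g, y, age=None, max_iter=30, tol=1e-8):
    """Newton fits of status ~ 1 + dosage (+ age) for every SNP at once.

    ``age`` is dropped automatically when absent or constant (it would be
    collinear with the intercept).
    """
    n, m = g.shape
    use_age = age is not None and np.ptp(age) > 0
    d = 3 if use_age else 2
    gt = g.T  # (m, n)
    ybar = y.mean()
    beta = np.zeros((m, d))
    beta[:, 0] = np.log(ybar / (1.0 - ybar))
    ok = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = beta[:, 0][:, None] + beta[:, 1][:, None] * gt
        if use_age:
            eta = eta + beta[:, 2][:, None] * age[None, :]
        mu = expit(eta)  # (m, n)
        w = mu * (1.0 - mu)
        r = y[None, :] - mu
        grad = np.empty((m, d))
        grad[:, 0] = r.sum(axis=1)
        grad[:, 1] = (r * gt).sum(axis=1)
        h = np.empty((m, d, d))
        h[:, 0, 0] = w.sum(axis=1)
        h[:, 0, 1] = h[:, 1, 0] = (w * gt).sum(axis=1)
        h[:, 1, 1] = (w * gt**2).sum(axis=1)
        if use_age:
            grad[:, 2] = r @ age
            h[:, 0, 2] = h[:, 2, 0] = w @ age
            h[:, 1, 2] = h[:, 2, 1] = (w * gt) @ age
            h[:, 2, 2] = w @ age**2
        # guard singular Hessians (separation / monomorphic)
        det = np.linalg.det(h)
        bad = ~np.isfinite(det) | (np.abs(det) < 1e-12)
        ok &= ~bad
        h[bad] = np.eye(d)
        step = np.linalg.solve(h, grad[..., None])[..., 0]
        step[bad] = 0.0
        beta += step
        converged = np.max(np.abs(step), axis=1) < tol
        if (converged | ~ok).all():
            break
    # quasi-complete separation shows up as runaway dosage coefficients
    ok &= converged & (np.abs(beta[:, 1]) < 12.0) & np.isfinite(beta).all(axis=1)
    hinv = np.linalg.inv(np.where(ok[:, None, None], h, np.eye(d)[None]))
    se1 = np.sqrt(np.maximum(hinv[:, 1, 1], 1e-300))
    return beta, se1, ok


def logistic_scan_outcome(
    genotypes: np.ndarray,
    status: np.ndarray,
    age: np.ndarray | None,
    snp_ids: np.ndarray,
    effect_allele: np.ndarray | None = None,
    other_allele: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP logistic regression of case status on dosage plus age.

    Fitted by Newton / iteratively reweighted least squares vectorised across
    SNPs; beta is the per-effect-allele log odds ratio with a Wald normal
    p-value. SNPs with quasi-complete separation (or failed convergence) are
    flagged and dropped. ``age`` may be None (unadjusted scan).
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(status, dtype=float)
    a = None if age is None else np.asarray(age, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("status is constant; need both cases and controls")
    poly = g.std(axis=0) > 0
    g = g[:, poly]
    snp_ids = np.asarray(snp_ids, dtype=str)[poly]
    effect_allele, other_allele = _as_alleles(
        snp_ids,
        None if effect_allele is None else np.asarray(effect_allele)[poly],
        None if other_allele is None else np.asarray(other_allele)[poly],
    )
    beta, se, ok = _batch_logistic(g, y, a)
    if not ok.all():
        logger.warning(
            "dropping %d SNP(s) from the outcome scan (separation or non-convergence)",
            int((~ok).sum()),
        )
    z = beta[:, 1] / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": g.mean(axis=0) / 2.0,
            "beta": beta[:, 1],
            "se": se,
            "pval": np.clip(pval, np.finfo(float).tiny, 1.0),
            "n": len(y),
        }
    )
    return df[ok].reset_index(drop=True)


def phewas_filter(
    snp_ids,
    catalog: pd.DataFrame | None,
    threshold: float = 5e-8,
    phenotypes: tuple[str, ...] = CONFOUNDER_PHENOTYPES,
) -> np.ndarray:
    """Exclude SNPs with a catalog association to a confounder phenotype.

    A SNP is excluded iff any catalog row for it names one of ``phenotypes``
    (case-insensitive) with p below ``threshold``. An empty or None catalog
    leaves the set unchanged. Malformed rows raise with their line number.
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    if catalog is None or len(catalog) == 0:
        return snp_ids.copy()
    required = {"snp_id", "phenotype", "pval"}
    if not required.issubset(catalog.columns):
        raise ValueError(f"PheWAS catalog must have columns {sorted(required)}")
    pvals = pd.to_numeric(catalog["pval"], errors="coerce")
    bad = pvals.isna() | (pvals <= 0) | (pvals > 1) | catalog["snp_id"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based, after header
        raise ValueError(f"malformed PheWAS catalog row at line {line}")
    listed = {p.lower() for p in phenotypes}
    hits = catalog.loc[
        catalog["phenotype"].str.lower().isin(listed) & (pvals < threshold), "snp_id"
    ]
    flagged = set(hits.astype(str))
    keep = np.array([s not in flagged for s in snp_ids])
    return snp_ids[keep]


def explained_variance(beta, eaf) -> np.ndarray | float:
    """Per-SNP exposure variance contribution beta^2 * 2 * MAF * (1 - MAF).

    ``beta`` must be on a variance-standardised exposure scale for the result
    to be a genuine fraction of exposure variance (divide the per-allele
    effect by the exposure SD before calling); MAF is folded from the
    effect-allele frequency.
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie strictly inside (0, 1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    out = beta**2 * 2.0 * maf * (1.0 - maf)
    return float(out) if out.ndim == 0 else out


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation between two dosage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have the same length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def greedy_ld_prune(
    snp_ids,
    ev: np.ndarray,
    genotypes: np.ndarray,
    r2_threshold: float = 0.01,
) -> np.ndarray:
    """Greedy LD pruning retaining the highest-explained-variance markers.

    Candidates are processed in explained-variance-descending order (ties by
    snp_id ascending); a SNP is retained iff its squared dosage correlation
    with every already-retained SNP does not exceed ``r2_threshold``.
    ``genotypes`` columns align with ``snp_ids`` (controls are the intended
    LD reference sample).
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    ev = np.asarray(ev, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if g.shape[1] != snp_ids.size or ev.size != snp_ids.size:
        raise ValueError("snp_ids, ev and genotype columns must align")
    n = g.shape[0]
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance dosage vector among candidates")
    z = (g - mu) / sd
    order = np.lexsort((snp_ids, -ev))
    kept: list[int] = []
    for idx in order:
        if kept:
            r = z[:, kept].T @ z[:, idx] / n
            if np.max(r * r) > r2_threshold:
                continue
        kept.append(int(idx))
    kept_arr = np.array(sorted(kept))
    return snp_ids[kept_arr]


@dataclass(frozen=True)
class InstrumentReport:
    """Instrument-strength summary for a retained IV set.

    ``f_stat`` is the cumulative-R^2 F statistic ((n-k-1)/k)(R^2/(1-R^2));
    ``f_mean_per_iv`` the mean of the per-instrument F values
    (n-2) R^2_j / (1 - R^2_j), a common alternative strength summary.
    """

    snp_ids: np.ndarray
    explained_variance: np.ndarray
    r2_cumulative: float
    f_stat: float
    f_mean_per_iv: float
    n: int
    k: int
    stage_counts: dict = field(default_factory=dict)


def instrument_strength(
    snp_ids,
    ev: np.ndarray,
    n: int,
    stage_counts: dict | None = None,
    exposure_variance: float | None = None,
) -> InstrumentReport:
    """Cumulative explained variance and F statistics of the retained IVs.

    ``ev`` are per-SNP beta^2 * 2 * MAF * (1 - MAF) contributions; their sum is
    the cumulative explained variance R^2 feeding the cumulative F. When
    ``exposure_variance`` (the variance of the exposure in the scan sample, on
    the same scale as the betas) is supplied, the mean per-instrument F is
    computed on true per-SNP variance fractions ev_j / exposure_variance;
    otherwise the ev values are used as fractions directly.
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    ev = np.asarray(ev, dtype=float)
    k = snp_ids.size
    if k < 1:
        raise ValueError("need at least one retained instrument")
    if np.any(ev < 0):
        raise ValueError("explained variances must be non-negative")
    r2 = float(ev.sum())
    if r2 >= 1.0:
        raise ValueError(
            f"cumulative explained variance {r2:.3f} >= 1; exposure betas are mis-scaled"
        )
    f_stat = ((n - k - 1) / k) * (r2 / (1.0 - r2))
    frac = ev / exposure_variance if exposure_variance else ev
    frac = np.clip(frac, 0.0, 1.0 - 1e-12)
    f_per = (n - 2) * frac / (1.0 - frac)
    return InstrumentReport(
        snp_ids=snp_ids,
        explained_variance=ev,
        r2_cumulative=r2,
        f_stat=float(f_stat),
        f_mean_per_iv=float(f_per.mean()),
        n=int(n),
        k=int(k),
        stage_counts=dict(stage_counts or {}),
    )
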
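"""Supervised ancestry estimation and genotype principal components.

Supervised estimation fixes the reference-panel allele frequencies f_ik and
maximises, independently per individual, the binomial log-likelihood

    L(q) = sum_i [ g_i ln x_i + (2 - g_i) ln(1 - x_i) ],   x_i = sum_k q_k f_ik

over the ancestry simplex. The EM update

    q_k <- (1 / 2M) sum_i [ g_i q_k f_ik / x_i + (2 - g_i) q_k (1 - f_ik) / (1 - x_i) ]

is run from the uniform start; L is concave in q for fixed f, so no restarts
are needed and the log-likelihood is non-decreasing at every iteration.

The PCA follows the eigenstrat convention: dosage columns centred by twice the
sample allele frequency and scaled by the binomial standard deviation, scores
from the singular value decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aims import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryVector",
    "PcaResult",
    "supervised_ancestry_em",
    "estimate_cohort_ancestry",
    "ancestry_summary",
    "eigenstrat_pca",
]

_FREQ_CLIP = 1e-6


@dataclass(frozen=True)
class AncestryVector:
    """Estimated ancestry proportions for one individual."""

    sample_id: str
    q: np.ndarray
    pop_names: tuple[str, ...]
    loglik: float
    n_iter: int
    converged: bool

    @property
    def q_na_percent(self) -> float:
        return 100.0 * float(self.q[0])


def _em_map(q, g0, g1, f, fc, m_eff):
    """One EM update of the ancestry simplex for every row."""
    x = q @ f.T
    np.clip(x, _FREQ_CLIP / 2, 1.0 - _FREQ_CLIP / 2, out=x)
    r = (g0 / x) @ f + (g1 / (1.0 - x)) @ fc
    qn = q * r / (2.0 * m_eff[:, None])
    qn /= qn.sum(axis=1, keepdims=True)  # guard floating-point drift
    return qn


def _loglik(q, g0, g1, f):
    x = q @ f.T
    np.clip(x, _FREQ_CLIP / 2, 1.0 - _FREQ_CLIP / 2, out=x)
    return (g0 * np.log(x) + g1 * np.log1p(-x)).sum(axis=1)


def _em_batch(
    genotypes: np.ndarray,
    freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
    return_trace: bool = False,
    accelerate: bool = True,
):
    """Vectorised supervised EM over a batch of individuals.

    Parameters
    ----------
    genotypes
        (N, M) dosages in {0, 1, 2}; NaN marks missing and is skipped.
    freqs
        (M, K) panel frequencies, clipped to [1e-6, 1 - 1e-6].
    accelerate
        Use squared-extrapolation (SQUAREM-style) cycles with a monotone
        guard: an extrapolated candidate is only accepted when it does not
        decrease the log-likelihood, so the fixed point and the monotonicity
        property are those of plain EM. Disabled automatically when a trace
        is requested.

    Returns
    -------
    q : (N, K), loglik : (N,), n_iter : (N,) EM-map evaluations used,
    converged : (N,) and, when ``return_trace``, the per-iteration
    log-likelihood trace of plain EM.
    """
    g = np.asarray(genotypes, dtype=float)
    single = g.ndim == 1
    if single:
        g = g[None, :]
    f = np.clip(np.asarray(freqs, dtype=float), _FREQ_CLIP, 1.0 - _FREQ_CLIP)
    n, m = g.shape
    if f.shape[0] != m:
        raise ValueError("genotypes and panel frequencies disagree on SNP count")
    k = f.shape[1]
    miss = np.isnan(g)
    if miss.all(axis=1).any():
        raise ValueError("individual with all genotypes missing")
    g0 = np.where(miss, 0.0, g)  # ALT-allele counts
    g1 = np.where(miss, 0.0, 2.0 - g)  # REF-allele counts
    m_eff = (~miss).sum(axis=1).astype(float)
    fc = 1.0 - f

    q = np.full((n, k), 1.0 / k)
    ll = _loglik(q, g0, g1, f)
    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    trace = [ll.copy()] if return_trace else None

    if return_trace or not accelerate:
        it = 0
        while it < max_iter and not converged.all():
            q_new = _em_map(q, g0, g1, f, fc, m_eff)
            ll_new = _loglik(q_new, g0, g1, f)
            it += 1
            if return_trace:
                trace.append(ll_new.copy())
            newly = (~converged) & (np.abs(ll_new - ll) < tol)
            n_iter[np.where(~converged)[0]] = it
            converged |= newly
            q, ll = q_new, ll_new
    else:
        active = np.arange(n)
        budget = max_iter
        while active.size and budget > 0:
            qa = q[active]
            ga0, ga1, fa_m = g0[active], g1[active], m_eff[active]
            q1 = _em_map(qa, ga0, ga1, f, fc, fa_m)
            q2 = _em_map(q1, ga0, ga1, f, fc, fa_m)
            r = q1 - qa
            v = q2 - q1 - r
            vv = np.einsum("ik,ik->i", v, v)
            rr = np.einsum("ik,ik->i", r, r)
            alpha = -np.sqrt(rr / np.maximum(vv, 1e-300))
            # bounded step; a positive floor keeps coordinates off the
            # absorbing zero face of the multiplicative EM map
            alpha = np.clip(alpha, -6.0, -1.0)[:, None]
            qs = qa - 2.0 * alpha * r + alpha**2 * v
            np.clip(qs, 1e-8, None, out=qs)
            qs /= qs.sum(axis=1, keepdims=True)
            qs = _em_map(qs, ga0, ga1, f, fc, fa_m)  # stabilisation step
            ll2 = _loglik(q2, ga0, ga1, f)
            lls = _loglik(qs, ga0, ga1, f)
            take = lls >= ll2  # monotone guard
            q_new = np.where(take[:, None], qs, q2)
            ll_new = np.where(take, lls, ll2)
            q[active] = q_new
            n_iter[active] += 3
            budget -= 3
            done = np.abs(ll_new - ll[active]) < tol
            ll[active] = ll_new
            converged[active[done]] = True
            active = active[~done]
    if not converged.all():
        logger.warning("EM did not converge for %d individual(s)", int((~converged).sum()))
    out = (q, ll, n_iter, converged)
    if single:
        out = (q[0], float(ll[0]), int(n_iter[0]), bool(converged[0]))
    return out + (np.array(trace),) if return_trace else out


def supervised_ancestry_em(
    genotypes: np.ndarray,
    panel_freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
    sample_id: str = "sample",
    pop_names: tuple[str, ...] | None = None,
) -> AncestryVector:
    """Maximum-likelihood ancestry proportions for a single individual.

    ``genotypes`` is the individual's dosage vector over M SNPs (NaN =
    missing); ``panel_freqs`` the (M, K) fixed reference frequencies.
    Convergence is declared when the log-likelihood improves by less than
    ``tol``; non-convergence is flagged on the result, not hidden.
    """
    q, ll, n_it, conv = _em_batch(genotypes, panel_freqs, tol=tol, max_iter=max_iter)
    if pop_names is None:
        pop_names = tuple(f"pop{i + 1}" for i in range(q.size))
    return AncestryVector(
        sample_id=sample_id, q=q, pop_names=pop_names, loglik=ll, n_iter=n_it, converged=conv
    )


def estimate_cohort_ancestry(
    genotypes: np.ndarray,
    snp_ids: np.ndarray,
    sample_ids: np.ndarray,
    freq_table: FrequencyTable,
    restrict_to: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Supervised ancestry estimates for every cohort member.

    The genotype columns are intersected with the frequency table (optionally
    further restricted to ``restrict_to``, e.g. a preselected AIM union); the
    estimate is invariant to SNP order.
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    wanted = set(freq_table.snp_ids)
    if restrict_to is not None:
        wanted &= set(np.asarray(restrict_to, dtype=str))
    mask = np.fromiter((s in wanted for s in snp_ids), bool, snp_ids.size)
    if not mask.any():
        raise ValueError("no overlap between cohort SNPs and panel frequencies")
    used = snp_ids[mask]
    # align frequency rows to the cohort's column order
    pos = {s: i for i, s in enumerate(freq_table.snp_ids)}
    f = freq_table.freqs[[pos[s] for s in used]]
    q, ll, n_it, conv = _em_batch(genotypes[:, mask], f, tol=tol, max_iter=max_iter)
    df = pd.DataFrame({"sample_id": np.asarray(sample_ids, dtype=str)})
    for i, pop in enumerate(freq_table.pop_names):
        df[f"q_{pop}"] = q[:, i]
    df["q_NA_percent"] = 100.0 * q[:, 0]
    df["loglik"] = ll
    df["n_iter"] = n_it
    df["converged"] = conv
    return df


def ancestry_summary(q_na_percent: np.ndarray, controls: np.ndarray | None = None) -> dict:
    """Median and interquartile range of the ancestry exposure (controls)."""
    x = np.asarray(q_na_percent, dtype=float)
    if controls is not None:
        x = x[np.asarray(controls, dtype=bool)]
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {"median": float(q50), "iqr_low": float(q25), "iqr_high": float(q75)}


@dataclass(frozen=True)
class PcaResult:
    """Sample scores and explained-variance fractions of genotype PCs."""

    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_fraction: np.ndarray  # (n_components,)
    kept_snps: np.ndarray

    def __post_init__(self) -> None:
        ev = self.explained_variance_fraction
        if np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-12) or ev.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must be non-negative, "
                             "non-increasing and sum to at most 1")


def eigenstrat_pca(
    genotypes: np.ndarray,
    n_components: int = 10,
    snp_ids: np.ndarray | None = None,
    bayesian_freq: bool = False,
) -> PcaResult:
    """Eigenstrat-normalised genotype PCA.

    Columns are centred by 2 p-hat and scaled by sqrt(p-hat (1 - p-hat)); by
    default p-hat is the plain mean dosage / 2, with the Bayesian-smoothed
    (1 + sum g) / (2 + 2n) variant behind ``bayesian_freq``. Monomorphic SNPs
    are dropped. Scores come from the SVD of the normalised matrix, and the
    explained-variance fraction of each component is its squared singular
    value over the total.
    """
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if snp_ids is None:
        snp_ids = np.arange(m)
    if n < n_components:
        raise ValueError(f"cannot extract {n_components} components from {n} samples")
    p_plain = g.mean(axis=0) / 2.0
    poly = (p_plain > 0.0) & (p_plain < 1.0)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs")
    p_hat = (1.0 + g.sum(axis=0)) / (2.0 + 2.0 * n) if bayesian_freq else p_plain
    z = (g[:, poly] - 2.0 * p_plain[poly]) / np.sqrt(p_hat[poly] * (1.0 - p_hat[poly]))
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    total = float((s**2).sum())
    n_components = min(n_components, s.size)
    scores = u[:, :n_components] * s[:n_components]
    frac = s[:n_components] ** 2 / total
    return PcaResult(
        scores=scores,
        explained_variance_fraction=frac,
        kept_snps=np.asarray(snp_ids)[poly],
    )
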
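"""Independent oracle implementations used to cross-check the package.

Everything here deliberately avoids the code paths it validates: brute-force
counting, grid searches, dense linear algebra, statsmodels fits and explicit
textbook formulas.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import entropy


def informativeness_kl(p: np.ndarray) -> float:
    """I_n as the mean Kullback-Leibler divergence of each subpopulation's
    allele distribution from the average distribution (equivalent algebraic
    form of the assignment-informativeness measure)."""
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    dists = np.stack([p, 1.0 - p], axis=-1)  # (K, 2)
    mean = dists.mean(axis=0)
    return float(np.mean([entropy(dists[i], mean) for i in range(k)]))


def allele_freq_counting(panel: np.ndarray) -> np.ndarray:
    """Brute-force ALT allele frequency by explicit allele counting."""
    n_ind, m = panel.shape
    out = np.empty(m)
    for j in range(m):
        alt = tot = 0
        for i in range(n_ind):
            d = panel[i, j]
            if not np.isnan(d):
                alt += int(d)
                tot += 2
        out[j] = alt / tot
    return out


def preselect_union_bruteforce(snp_ids, i_n_by_comparison, top_k):
    """Sort-and-union oracle for AIM preselection (ties: I_n desc, id asc)."""
    union = set()
    for i_n in i_n_by_comparison:
        order = sorted(range(len(snp_ids)), key=lambda i: (-i_n[i], snp_ids[i]))
        union |= {snp_ids[i] for i in order[:top_k]}
    return union


def em_grid_oracle(genotypes: np.ndarray, freqs: np.ndarray, step: float = 0.001) -> float:
    """Grid-search maximiser of the K=2 supervised likelihood over q1."""
    g = np.asarray(genotypes, float)
    f = np.clip(np.asarray(freqs, float), 1e-6, 1 - 1e-6)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    x = grid[:, None] * f[None, :, 0] + (1 - grid[:, None]) * f[None, :, 1]
    x = np.clip(x, 1e-12, 1 - 1e-12)
    ll = (g[None, :] * np.log(x) + (2 - g[None, :]) * np.log1p(-x)).sum(axis=1)
    return float(grid[np.argmax(ll)])


def ivw_wls_oracle(gamma, big_gamma, se_big_gamma):
    """Zero-intercept weighted least squares of Gamma on gamma with first-order
    weights; returns (slope, se)."""
    w = (np.asarray(gamma) / np.asarray(se_big_gamma)) ** 2
    x, y = np.asarray(gamma, float), np.asarray(big_gamma, float)
    # weights on the ratio scale translate to sigma^-2 on the regression scale
    wls_w = 1.0 / np.asarray(se_big_gamma, float) ** 2
    slope = np.sum(wls_w * x * y) / np.sum(wls_w * x * x)
    se = np.sqrt(1.0 / np.sum(wls_w * x * x))
    assert np.isclose(np.sum(w), np.sum(wls_w * x * x))
    return float(slope), float(se)


def weighted_median_oracle(b, w):
    """Independent interpolated weighted median (explicit loop form)."""
    b = np.asarray(b, float)
    w = np.asarray(w, float)
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order] / w.sum()
    s = []
    acc = 0.0
    for j in range(len(b)):
        s.append(acc + w[j] / 2.0)
        acc += w[j]
    s = np.asarray(s)
    if s[0] >= 0.5:
        return float(b[0])
    if s[-1] <= 0.5:
        return float(b[-1])
    for j in range(1, len(b)):
        if s[j] >= 0.5:
            return float(b[j - 1] + (b[j] - b[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))
    return float(b[-1])


def prune_is_valid(retained_ids, all_ids, ev, genotypes, threshold):
    """Exhaustive verification of the greedy pruning contract.

    Every retained pair must respect the threshold, and every dropped SNP must
    violate it against some retained SNP with higher explained variance
    (ties broken by snp_id ascending).
    """
    ids = list(map(str, all_ids))
    idx = {s: j for j, s in enumerate(ids)}
    g = np.asarray(genotypes, float)
    r = np.corrcoef(g.T)
    retained = [str(s) for s in retained_ids]
    rank = {s: (-ev[idx[s]], s) for s in ids}
    for a in retained:
        for b in retained:
            if a < b and r[idx[a], idx[b]] ** 2 > threshold + 1e-12:
                return False
    dropped = [s for s in ids if s not in set(retained)]
    for s in dropped:
        better = [t for t in retained if rank[t] < rank[s]]
        if not any(r[idx[s], idx[t]] ** 2 > threshold for t in better):
            return False
    return True


def logistic_2x2_logor(a, b, c, d):
    """Log odds ratio from a 2x2 table (cases: a exposed, b unexposed)."""
    return float(np.log((a * d) / (b * c)))


def mr_power_mc(n, case_fraction, r2, or_per_sd, alpha=0.05, n_reps=2000, seed=0):
    """Two-stage Monte-Carlo power: instrument score -> exposure -> logistic
    disease; rejection = Wald test of the instrument-outcome association
    (statsmodels fit, independent of the analytic formula)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    b = np.log(or_per_sd)
    # intercept for population prevalence = case_fraction (Gauss-Hermite over x)
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    wts = weights / weights.sum()

    def prev(c):
        return float(np.sum(wts * expit(c + b * nodes)))

    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = (lo + hi) / 2
        if prev(mid) < case_fraction:
            lo = mid
        else:
            hi = mid
    c = (lo + hi) / 2
    rej = 0
    for _ in range(n_reps):
        z = rng.standard_normal(n)
        x = np.sqrt(r2) * z + np.sqrt(1 - r2) * rng.standard_normal(n)
        y = (rng.random(n) < expit(c + b * x)).astype(float)
        if y.min() == y.max():
            continue
        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        rej += fit.pvalues[1] < alpha
    return rej / n_reps
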
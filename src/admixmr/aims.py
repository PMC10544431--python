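"""Ancestry-informative marker (AIM) selection.

Implements the informativeness-for-assignment measure

    I_n(Q, J) = sum_j [ -p_j log p_j + sum_i (p_ij / K) log p_ij ]

for biallelic SNPs (j = 1, 2 alleles; i = 1..K subpopulations), where p_ij is
the frequency of allele j in subpopulation i and p_j the unweighted average of
p_ij across the K subpopulations. I_n is the mutual information (in nats)
between the subpopulation of origin Q of a random allele and the allele J
itself, assuming equal prior weight on the subpopulations. It is 0 when all
subpopulations share the same frequency and attains its maximum log K when the
allele fully determines the population.

AIMs are preselected per ordered population pair (here the Native American
panel against each other panel), ranking SNPs by I_n computed with K = 2, and
retaining the union of the per-comparison top lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyTable",
    "AimPanel",
    "allele_frequencies",
    "informativeness",
    "preselect_aims",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Per-SNP alternate-allele frequencies in K reference subpopulations.

    ``freqs[m, i]`` is the frequency of the ALT allele of SNP ``m`` in
    subpopulation ``i``; the REF allele frequency is its complement.
    ``ancestral`` optionally records the pre-drift ancestral frequency used by
    the simulator.
    """

    snp_ids: np.ndarray
    freqs: np.ndarray
    pop_names: tuple[str, ...]
    ancestral: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.pop_names):
            raise ValueError("freqs must be (n_snps, K) matching pop_names")
        if len(self.snp_ids) != self.freqs.shape[0]:
            raise ValueError("snp_ids and freqs disagree on the number of SNPs")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.pop_names)

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[0]

    def mean_freq(self) -> np.ndarray:
        """Unweighted average ALT frequency p_j across the K subpopulations."""
        return self.freqs.mean(axis=1)

    def subset(self, snp_ids: Sequence[str]) -> "FrequencyTable":
        keep = set(map(str, snp_ids))
        mask = np.fromiter((s in keep for s in self.snp_ids), bool, self.n_snps)
        return FrequencyTable(
            snp_ids=self.snp_ids[mask],
            freqs=self.freqs[mask],
            pop_names=self.pop_names,
            ancestral=None if self.ancestral is None else self.ancestral[mask],
        )

    def pair(self, pop_a: str, pop_b: str) -> np.ndarray:
        """(n_snps, 2) frequency columns for an ordered population pair."""
        ia, ib = self.pop_names.index(pop_a), self.pop_names.index(pop_b)
        return self.freqs[:, [ia, ib]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids})
        for i, pop in enumerate(self.pop_names):
            df[f"f_{pop}"] = self.freqs[:, i]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencyTable":
        pops = tuple(c[2:] for c in df.columns if c.startswith("f_"))
        freqs = df[[f"f_{p}" for p in pops]].to_numpy(float)
        return cls(snp_ids=df["snp_id"].to_numpy(str), freqs=freqs, pop_names=pops)


def allele_frequencies(
    panels: Mapping[str, np.ndarray], snp_ids: Sequence[str]
) -> FrequencyTable:
    """Estimate per-subpopulation ALT allele frequencies from panel dosages.

    Parameters
    ----------
    panels
        Mapping of population name to an (n_individuals, n_snps) dosage matrix
        with values in {0, 1, 2}; NaN marks missing genotypes.
    snp_ids
        SNP identifiers, aligned with the dosage columns.

    SNPs with all genotypes missing in any subpopulation are dropped with a
    logged warning.
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    pops = tuple(panels)
    freqs = []
    valid = np.ones(len(snp_ids), dtype=bool)
    for pop in pops:
        g = np.asarray(panels[pop], dtype=float)
        if g.ndim != 2 or g.shape[1] != len(snp_ids):
            raise ValueError(f"panel {pop!r} has shape {g.shape}, expected (*, {len(snp_ids)})")
        n_obs = np.sum(~np.isnan(g), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(g, axis=0) / (2.0 * np.maximum(n_obs, 1))
        valid &= n_obs > 0
        freqs.append(p)
    freq = np.column_stack(freqs)
    if not valid.all():
        dropped = snp_ids[~valid]
        logger.warning(
            "dropping %d SNP(s) with all genotypes missing in some panel: %s%s",
            dropped.size,
            ", ".join(dropped[:5]),
            "..." if dropped.size > 5 else "",
        )
    return FrequencyTable(snp_ids=snp_ids[valid], freqs=freq[valid], pop_names=pops)


def informativeness(p: np.ndarray) -> np.ndarray | float:
    """Informativeness for assignment I_n (nats) of biallelic SNPs.

    Parameters
    ----------
    p
        Array of shape (..., K): frequency of one designated allele in each of
        K subpopulations (the other allele has frequency 1 - p). The result is
        invariant to which allele is designated.

    Returns
    -------
    I_n with shape ``p.shape[:-1]`` (a scalar for 1-D input). Uses the
    convention 0 * log 0 = 0; non-negative, bounded by log K.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    k = p.shape[-1]
    out = 0.0
    for pj in (p, 1.0 - p):
        pbar = pj.mean(axis=-1)
        out = out - xlogy(pbar, pbar) + xlogy(pj, pj).sum(axis=-1) / k
    # guard tiny negative round-off for (near-)uninformative SNPs
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AimPanel:
    """Per-comparison I_n rankings and the retained union of top markers."""

    comparisons: tuple[tuple[str, str], ...]
    rankings: pd.DataFrame  # columns: snp_id, comparison, I_n, rank
    union: np.ndarray  # retained snp_ids (table order, no duplicates)

    @property
    def n_retained(self) -> int:
        return len(self.union)


def preselect_aims(
    table: FrequencyTable,
    comparisons: Sequence[tuple[str, str]] | None = None,
    top_k: int = 20000,
) -> AimPanel:
    """Rank SNPs by pairwise I_n and retain the union of the top lists.

    Each comparison is an ordered pair of subpopulation labels; I_n is
    computed with K = 2 (two populations at a time). Per comparison the
    ``top_k`` SNPs with the highest I_n are kept (ties broken by snp_id
    ascending for determinism) and the union over comparisons is returned.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if comparisons is None:
        ref = table.pop_names[0]
        comparisons = [(ref, other) for other in table.pop_names[1:]]
    comparisons = tuple((a, b) for a, b in comparisons)
    if top_k > table.n_snps:
        logger.info(
            "top_k=%d exceeds the %d available SNPs; retaining all", top_k, table.n_snps
        )
    frames = []
    union_mask = np.zeros(table.n_snps, dtype=bool)
    for pop_a, pop_b in comparisons:
        i_n = informativeness(table.pair(pop_a, pop_b))
        df = pd.DataFrame({"snp_id": table.snp_ids, "I_n": i_n, "_idx": np.arange(table.n_snps)})
        df = df.sort_values(["I_n", "snp_id"], ascending=[False, True], kind="mergesort")
        df = df.head(top_k).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        df["comparison"] = f"{pop_a}_vs_{pop_b}"
        union_mask[df["_idx"].to_numpy()] = True
        frames.append(df[["snp_id", "comparison", "I_n", "rank"]])
    rankings = pd.concat(frames, ignore_index=True)
    return AimPanel(
        comparisons=comparisons,
        rankings=rankings,
        union=table.snp_ids[union_mask].copy(),
    )
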
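"""Weir–Goudet allele-sharing (matching) machinery.

The matching proportion M_ij between two diploid individuals at a site is
the probability that one allele drawn from each matches:

    m = (x_i * x_j + (2 - x_i)(2 - x_j)) / 4

with x the alt-allele dosage.  Averaging m over sites gives the matching
matrix, from which population-specific FST, pairwise FST and individual
relatedness (beta) all derive as (M - baseline) / (1 - baseline) for the
appropriate baseline.  This moment, model-free estimator family is what the
genome scans here are built on: an "island-specific" FST contrasts mean
matching among island individuals with mean island-mainland matching, so a
window where all islanders resemble each other more than they resemble the
mainland stands out regardless of substructure among islands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "MatchingMatrix",
    "GroupContrast",
    "RelatednessMatrix",
    "matching_matrix",
    "group_specific_fst",
    "pairwise_fst",
    "beta_relatedness",
]


@dataclass
class MatchingMatrix:
    """Symmetric matrix of pairwise matching proportions.

    ``M[i, j]`` is the mean per-site matching between individuals i and j
    over their pairwise-complete sites (NaN when no usable site).
    ``self_matching[i]`` is the per-individual probability that its own two
    alleles match (1 at a homozygous site, 0 at a heterozygous one, averaged
    over the individual's non-missing sites).
    """

    samples: list[str]
    M: np.ndarray
    self_matching: np.ndarray
    n_sites_used: np.ndarray

    def indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matching matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.samples)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.samples[i], self.samples[j],
                             self.M[i, j], self.n_sites_used[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "M", "n_sites"])


@dataclass
class GroupContrast:
    target: tuple[str, ...]
    reference: tuple[str, ...]
    M_within: float
    M_between: float
    fst_specific: float


@dataclass
class RelatednessMatrix:
    samples: list[str]
    beta: np.ndarray
    baseline: float


def matching_matrix(gm: GenotypeMatrix, samples=None,
                    min_snps: int = 1) -> MatchingMatrix:
    """Compute the allele-sharing matrix for a (subset of a) genotype matrix.

    Per pair, the average runs over sites where both genotypes are called
    (ratio of sums); pairs with fewer than ``min_snps`` usable sites are
    reported as NaN.
    """
    if samples is not None:
        gm = gm.subset_samples(list(samples))
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = gm.dosage.astype(np.float64)
    V = (gm.dosage != MISSING).astype(np.float64)
    Y = X * V  # missing entries zeroed

    # Sum over pairwise-complete sites of m = 1 - (x_i + x_j)/2 + x_i x_j / 2
    n_pair = V.T @ V
    s_cross = Y.T @ Y
    s_i = Y.T @ V  # (i,j): sum of x_i over sites where j is also called
    with np.errstate(invalid="ignore", divide="ignore"):
        M = (n_pair - 0.5 * (s_i + s_i.T) + 0.5 * s_cross) / n_pair
    M[n_pair < max(min_snps, 1)] = np.nan

    n_self = V.sum(axis=0)
    hom = ((gm.dosage != 1) & (gm.dosage != MISSING)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        self_m = hom / n_self
    np.fill_diagonal(M, self_m)  # diagonal kept consistent with M_ii usage
    return MatchingMatrix(list(gm.samples), M, self_m,
                          n_pair.astype(np.int64))


def _pair_mean(M: np.ndarray, idx: np.ndarray) -> float:
    """Mean matching over unordered pairs of distinct individuals in idx."""
    if len(idx) < 2:
        return np.nan
    sub = M[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.nanmean(sub[iu]))


def _cross_mean(M: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    return float(np.nanmean(M[np.ix_(idx_a, idx_b)]))


def group_specific_fst(M: MatchingMatrix, target, reference) -> GroupContrast:
    """Population/group-specific FST of ``target`` against ``reference``.

    M_within averages matching over all unordered pairs of distinct target
    individuals (cross-population pairs inside the target group included);
    M_between over all target x reference pairs.  The statistic is
    (M_within - M_between) / (1 - M_between).
    """
    target = tuple(target)
    reference = tuple(reference)
    if set(target) & set(reference):
        raise ValueError("target and reference overlap")
    if len(target) < 2:
        raise ValueError("need >= 2 target individuals")
    if len(reference) < 1:
        raise ValueError("need >= 1 reference individual")
    ti = M.indices(target)
    ri = M.indices(reference)
    m_w = _pair_mean(M.M, ti)
    m_b = _cross_mean(M.M, ti, ri)
    if np.isclose(m_b, 1.0):
        warnings.warn("between-group matching is 1; specific FST undefined")
        fst = np.nan
    else:
        fst = (m_w - m_b) / (1.0 - m_b)
    return GroupContrast(target, reference, m_w, m_b, fst)


def pairwise_fst(M: MatchingMatrix, popA, popB) -> float:
    """Pairwise FST between two populations from the matching matrix.

    M_w is the unweighted average of the two within-population mean
    matchings, M_b the mean cross-population matching;
    FST = (M_w - M_b) / (1 - M_b).
    """
    ai = M.indices(tuple(popA))
    bi = M.indices(tuple(popB))
    if len(ai) < 2 or len(bi) < 2:
        raise ValueError("each population needs >= 2 individuals")
    m_w = 0.5 * (_pair_mean(M.M, ai) + _pair_mean(M.M, bi))
    m_b = _cross_mean(M.M, ai, bi)
    if np.isclose(m_b, 1.0):
        warnings.warn("between-population matching is 1; FST undefined")
        return np.nan
    return float((m_w - m_b) / (1.0 - m_b))


def beta_relatedness(M: MatchingMatrix) -> RelatednessMatrix:
    """Individual pairwise relatedness beta_ij = (M_ij - Mb) / (1 - Mb).

    The baseline Mb is the mean matching over all distinct pairs in the
    analysed panel, so beta averages to 0 over pairs by construction.
    """
    n = len(M.samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    iu = np.triu_indices(n, k=1)
    baseline = float(np.nanmean(M.M[iu]))
    beta = (M.M - baseline) / (1.0 - baseline)
    return RelatednessMatrix(list(M.samples), beta, baseline)
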
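"""Outlying Mean Index (OMI) niche-separation analysis.

The OMI of a species is the squared distance between its niche centroid —
the occurrence-weighted mean of the (standardized) environmental conditions
at its sites — and the origin of the environmental space, which represents
the average habitat available in the study area (the niche of a hypothetical
ubiquitous species).  Each species' environmental inertia decomposes exactly
into marginality (OMI), tolerance along the marginality direction (Tol, a
niche-breadth term) and residual tolerance (Rtol).  Ordination axes come
from the eigen-decomposition of the weighted cross-product of the species
centroid matrix, each axis carrying a percentage of the total marginality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnvTable",
    "OccurrenceTable",
    "NicheResult",
    "standardize_env",
    "drop_redundant",
    "omi_analysis",
    "omi_permutation_test",
]


@dataclass
class EnvTable:
    """Sites x environmental-variables table with site weights summing to 1."""

    values: pd.DataFrame  # index: site ids, columns: variable names
    site_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("environment table contains missing values")
        if len(self.values) < 2:
            raise ValueError("need >= 2 sites")
        if self.site_weights is None:
            n = len(self.values)
            self.site_weights = np.full(n, 1.0 / n)
        self.site_weights = np.asarray(self.site_weights, dtype=float)
        if (self.site_weights < 0).any():
            raise ValueError("negative site weight")
        total = self.site_weights.sum()
        if not np.isclose(total, 1.0):
            self.site_weights = self.site_weights / total


@dataclass
class OccurrenceTable:
    """Species x sites non-negative occurrence weights (presence counts)."""

    counts: pd.DataFrame  # index: species, columns: site ids

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative occurrence weight")
        if (self.counts.sum(axis=1) <= 0).any():
            bad = self.counts.index[self.counts.sum(axis=1) <= 0].tolist()
            raise ValueError(f"species with no occurrences: {bad}")


@dataclass
class NicheResult:
    species: list[str]
    marginality: pd.DataFrame        # species x variables (centroids)
    omi: pd.Series                   # squared marginality length
    tol: pd.Series
    rtol: pd.Series
    inertia: pd.Series
    eigenvalues: np.ndarray
    axis_percent: np.ndarray         # sums to 100
    axes: pd.DataFrame               # variables x axes (loadings)
    species_scores: pd.DataFrame     # species x axes
    site_scores: pd.DataFrame        # sites x axes


def drop_redundant(env: EnvTable, tol: float = 1e-12) -> EnvTable:
    """Remove later variables perfectly correlated (|r| = 1) with an earlier
    one — duplicates carry no information and break standardization-based
    rank assumptions."""
    df = env.values
    keep: list[str] = []
    for col in df.columns:
        dup = False
        x = df[col].to_numpy(dtype=float)
        for kept in keep:
            y = df[kept].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if abs(r) >= 1.0 - tol:
                dup = True
                break
        if not dup:
            keep.append(col)
    return EnvTable(df[keep].copy(), env.site_weights.copy())


def standardize_env(env: EnvTable) -> EnvTable:
    """Center and scale each variable to weighted mean 0, weighted variance 1
    under the site weights.  A zero-variance variable is an error (drop it
    first with :func:`drop_redundant` or by hand)."""
    w = env.site_weights
    X = env.values.to_numpy(dtype=float)
    mean = w @ X
    var = w @ (X - mean) ** 2
    zero = np.flatnonzero(var <= 0)
    if len(zero):
        names = [env.values.columns[i] for i in zero]
        raise ValueError(f"zero-variance variable(s): {names}")
    Z = (X - mean) / np.sqrt(var)
    return EnvTable(pd.DataFrame(Z, index=env.values.index,
                                 columns=env.values.columns),
                    w.copy())


def omi_analysis(env: EnvTable, occ: OccurrenceTable,
                 n_axes: int = 2) -> NicheResult:
    """Run the OMI decomposition on a standardized environment table.

    Species centroids are occurrence-weighted means of the standardized
    site rows; OMI is the squared Euclidean norm of the centroid.  Axes are
    eigenvectors of A = sum_k W_k c_k c_k^T / sum_k W_k (W_k the species'
    total occurrence weight); per-axis percentages are eigenvalue shares.
    Axis signs are fixed by making each axis' largest-magnitude loading
    positive.
    """
    sites = list(env.values.index)
    if list(occ.counts.columns) != sites:
        try:
            occ = OccurrenceTable(occ.counts[sites])
        except KeyError as e:
            raise ValueError("occurrence table sites do not match "
                             "environment table") from e
    Z = env.values.to_numpy(dtype=float)
    Wmat = occ.counts.to_numpy(dtype=float)
    totals = Wmat.sum(axis=1)
    P = Wmat / totals[:, None]                       # per-species site profile
    C = P @ Z                                        # species centroids
    omi = (C ** 2).sum(axis=1)
    inertia = P @ (Z ** 2).sum(axis=1)

    # tolerance along each species' own marginality direction
    tol = np.zeros(len(C))
    for k in range(len(C)):
        norm = np.sqrt(omi[k])
        if norm == 0:
            tol[k] = 0.0
            continue
        u = C[k] / norm
        scores = Z @ u
        tol[k] = P[k] @ (scores - norm) ** 2
    rtol = inertia - omi - tol

    wtot = totals.sum()
    A = (C.T * (totals / wtot)) @ C
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    rank = int((evals > evals[0] * 1e-12).sum()) if evals[0] > 0 else 0
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncated")
        n_axes = max(rank, 1)
    evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    for a in range(evecs.shape[1]):  # deterministic sign
        j = np.argmax(np.abs(evecs[:, a]))
        if evecs[j, a] < 0:
            evecs[:, a] = -evecs[:, a]
    total_ev = (np.linalg.eigvalsh(A).clip(0).sum()) or 1.0
    axis_percent = evals / total_ev * 100.0

    species = list(occ.counts.index)
    axis_names = [f"OMI{i+1}" for i in range(len(evals))]
    variables = list(env.values.columns)
    return NicheResult(
        species=species,
        marginality=pd.DataFrame(C, index=species, columns=variables),
        omi=pd.Series(omi, index=species, name="OMI"),
        tol=pd.Series(tol, index=species, name="Tol"),
        rtol=pd.Series(rtol, index=species, name="Rtol"),
        inertia=pd.Series(inertia, index=species, name="inertia"),
        eigenvalues=evals,
        axis_percent=axis_percent,
        axes=pd.DataFrame(evecs, index=variables, columns=axis_names),
        species_scores=pd.DataFrame(C @ evecs, index=species, columns=axis_names),
        site_scores=pd.DataFrame(Z @ evecs, index=sites, columns=axis_names),
    )


def omi_permutation_test(env: EnvTable, occ: OccurrenceTable,
                         n_perm: int = 999, seed: int = 0) -> pd.Series:
    """Permutation p-values for each species' OMI (off by default in the
    pipeline): site rows of the environment table are randomly permuted,
    breaking the occurrence-environment link while preserving both margins.
    """
    rng = np.random.default_rng(seed)
    obs = omi_analysis(env, occ, n_axes=1).omi
    n = len(env.values)
    exceed = np.zeros(len(obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        shuffled = EnvTable(pd.DataFrame(env.values.to_numpy()[perm],
                                         index=env.values.index,
                                         columns=env.values.columns),
                            env.site_weights)
        om = omi_analysis(shuffled, occ, n_axes=1).omi
        exceed += (om.to_numpy() >= obs.to_numpy())
    return pd.Series((exceed + 1) / (n_perm + 1), index=obs.index,
                     name="p_omi")
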
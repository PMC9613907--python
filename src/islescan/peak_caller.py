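"""Outlier-region calling from window statistics.

A window supports a peak when its statistic lies strictly above a
genome-wide threshold (mean + k*SD; the scans use k = 5, a cut whose
one-sided normal tail probability is ~3e-7, about one random window in 3.5
million).  Supporting windows whose genomic spans overlap are chained into
clusters; clusters with at least ``min_windows`` windows become regions
spanning the union of their windows.  A dual-criteria mode additionally
requires a population-specific statistic above its genome-wide 99th
quantile, the design used for contrasting two sister populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import GeneAnnotation

__all__ = [
    "Region",
    "sigma_threshold",
    "tail_probability",
    "call_regions",
    "call_regions_dual",
    "annotate_regions",
    "regions_to_frame",
]


@dataclass
class Region:
    scaffold: str
    start: int  # 0-based half-open union of supporting windows
    end: int
    n_support_windows: int
    peak_value: float
    genes: list[str] = field(default_factory=list)


def sigma_threshold(values, k: float = 5.0) -> float:
    """mean + k * sample SD (ddof=1) over the non-missing values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need >= 2 non-missing values for a threshold")
    return float(v.mean() + k * v.std(ddof=1))


def tail_probability(k: float) -> float:
    """One-sided upper-tail probability of the standard normal at k SD."""
    if k <= 0 and k != 0:
        raise ValueError("k must be positive")
    return float(norm.sf(k))


def _cluster(sub: pd.DataFrame, min_windows: int, statistic: str) -> list[Region]:
    """Chain overlapping above-threshold windows of one scaffold, sorted."""
    regions = []
    cur_start = cur_end = None
    cur_vals: list[float] = []
    def flush():
        if cur_start is not None and len(cur_vals) >= min_windows:
            regions.append(Region(sub["scaffold"].iloc[0], int(cur_start),
                                  int(cur_end), len(cur_vals),
                                  float(max(cur_vals))))
    for _, row in sub.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if cur_start is None or s >= cur_end:  # half-open: no overlap
            flush()
            cur_start, cur_end, cur_vals = s, e, [row[statistic]]
        else:
            cur_end = max(cur_end, e)
            cur_vals.append(row[statistic])
    flush()
    return regions


def call_regions(rows: pd.DataFrame, statistic: str, threshold: float,
                 min_windows: int = 2) -> list[Region]:
    """Call regions where ``statistic`` exceeds ``threshold``.

    Windows strictly above the threshold are clustered by genomic-span
    overlap within a scaffold; clusters supported by at least
    ``min_windows`` windows are returned as regions covering the union of
    their windows.
    """
    if statistic not in rows.columns:
        raise KeyError(f"unknown statistic {statistic!r}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hits = rows[rows[statistic] > threshold]
    regions = []
    for scaf in sorted(hits["scaffold"].unique()):
        sub = hits[hits["scaffold"] == scaf].sort_values("start")
        regions.extend(_cluster(sub, min_windows, statistic))
    return regions


def call_regions_dual(rows: pd.DataFrame, pair_stat: str,
                      pair_threshold: float, pop_stat: str,
                      pop_quantile: float = 0.99,
                      min_windows: int = 2) -> tuple[list[Region], float]:
    """Conjunction caller: pairwise stat above its five-sigma threshold AND
    a population-specific stat above its genome-wide quantile.

    Returns the regions and the quantile threshold actually used (quantile
    with linear interpolation over non-missing windows).
    """
    for col in (pair_stat, pop_stat):
        if col not in rows.columns:
            raise KeyError(f"unknown statistic {col!r}")
    vals = rows[pop_stat].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError(f"no non-missing values of {pop_stat!r}")
    q_thr = float(np.quantile(vals, pop_quantile))
    mask = (rows[pair_stat] > pair_threshold) & (rows[pop_stat] > q_thr)
    hits = rows[mask]
    regions = []
    for scaf in sorted(hits["scaffold"].unique()):
        sub = hits[hits["scaffold"] == scaf].sort_values("start")
        regions.extend(_cluster(sub, min_windows, pop_stat))
    return regions, q_thr


def annotate_regions(regions: list[Region], genes: GeneAnnotation
                     ) -> pd.DataFrame:
    """Attach overlapping genes (>= 1 bp overlap, half-open) to regions.

    Mutates each region's ``genes`` list (deduplicated, position order) and
    returns a flat table (region id, gene id, gene name, overlap bp).
    """
    if len(genes.genes) == 0:
        warnings.warn("empty gene annotation; regions will carry no genes")
    rows = []
    for ridx, reg in enumerate(regions):
        sub = genes.on_scaffold(reg.scaffold)
        hit = sub[(sub["start"] < reg.end) & (sub["end"] > reg.start)]
        hit = hit.sort_values("start").drop_duplicates("gene_id")
        reg.genes = list(hit["name"])
        for _, g in hit.iterrows():
            overlap = min(reg.end, g["end"]) - max(reg.start, g["start"])
            rows.append((f"region_{ridx}", g["gene_id"], g["name"], overlap))
    return pd.DataFrame(rows, columns=["region", "gene_id", "gene_name",
                                       "overlap_bp"])


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    cols = ["scaffold", "start", "end", "n_support_windows", "peak_value",
            "name", "genes"]
    return pd.DataFrame(
        [{"scaffold": r.scaffold, "start": r.start, "end": r.end,
          "n_support_windows": r.n_support_windows,
          "peak_value": r.peak_value,
          "name": f"region_{i}",
          "genes": ",".join(r.genes) if r.genes else "NA"}
         for i, r in enumerate(regions)], columns=cols)
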
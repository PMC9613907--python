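"""Sliding-window genome scan: group-specific FST, pairwise FST, dxy, pi, LD.

Windows are fixed-size (default 100 kb) with a fixed step (default 20 kb);
trailing partial windows are never emitted.  Per window the allele-sharing
matrix is recomputed on the window's SNPs and the configured contrasts are
evaluated on it; nucleotide diversity and absolute divergence use per-group
allele frequencies with the window length in bp as denominator (positions
absent from the SNP table count as invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_sharing import group_specific_fst, matching_matrix, pairwise_fst
from .genotype_io import MISSING, GenotypeMatrix, SampleSheet

__all__ = [
    "Window",
    "ScanConfig",
    "LDBlockMatrix",
    "make_windows",
    "window_pi",
    "window_dxy",
    "scan",
    "ld_blocks",
]


@dataclass(frozen=True)
class Window:
    scaffold: str
    start: int  # 0-based half-open
    end: int


@dataclass
class ScanConfig:
    """Named contrasts for the scan, in population labels.

    ``specific`` maps a statistic name to (target populations, reference
    populations) for group-specific FST, e.g. ``{"fst_can": (("EC", "WC"),
    ("MA", "PT", "IS"))}``.  ``pairwise`` is the same shape for pooled
    pairwise FST, ``dxy`` for absolute divergence between two pooled groups
    and ``pi`` maps a name to the populations pooled into one group.
    """

    specific: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    dxy: dict = field(default_factory=dict)
    pi: dict = field(default_factory=dict)

    def validate(self, sheet: SampleSheet) -> None:
        known = set(sheet.populations)
        def check(pops):
            bad = set(pops) - known
            if bad:
                raise ValueError(f"unknown population label(s) {sorted(bad)}")
        for tgt, ref in self.specific.values():
            check(tgt); check(ref)
        for a, b in self.pairwise.values():
            check(a); check(b)
        for a, b in self.dxy.values():
            check(a); check(b)
        for pops in self.pi.values():
            check(pops)


def make_windows(contig_lengths: dict[str, int], size: int = 100_000,
                 step: int = 20_000) -> list[Window]:
    """Sliding windows per scaffold; only full-length windows are emitted."""
    if not (size >= step >= 1):
        raise ValueError("need size >= step >= 1")
    out = []
    for scaf, length in contig_lengths.items():
        start = 0
        while start + size <= length:
            out.append(Window(scaf, start, start + size))
            start += step
    return out


def _group_freq(dos: np.ndarray, cols: np.ndarray):
    """Alt frequency and allele count (2 x called) per site for a group."""
    sub = dos[:, cols]
    called = (sub != MISSING)
    n = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
    return p, n


def window_pi(dos: np.ndarray, cols: np.ndarray, window_bp: int) -> float:
    """Per-bp nucleotide diversity of a group over one window's SNPs.

    pi = sum over sites of 2 p (1-p) n/(n-1), divided by the window length;
    n is the allele count (2 x non-missing genotypes), and sites with n < 2
    are skipped.  Returns NaN when no site is usable and SNPs are present.
    """
    if dos.shape[0] == 0:
        return 0.0
    p, n = _group_freq(dos, cols)
    ok = n >= 2
    if not ok.any():
        return np.nan
    p, n = p[ok], n[ok]
    return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)) / window_bp)


def window_dxy(dos: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray,
               window_bp: int) -> float:
    """Per-bp absolute divergence: sum of pA(1-pB) + pB(1-pA) over sites,
    divided by window length.  Sites lacking data in either group are
    skipped; NaN if none usable (and SNPs present)."""
    if dos.shape[0] == 0:
        return 0.0
    pa, na = _group_freq(dos, cols_a)
    pb, nb = _group_freq(dos, cols_b)
    ok = (na >= 1) & (nb >= 1)
    if not ok.any():
        return np.nan
    pa, pb = pa[ok], pb[ok]
    return float(np.sum(pa * (1.0 - pb) + pb * (1.0 - pa)) / window_bp)


def scan(gm: GenotypeMatrix, sheet: SampleSheet, config: ScanConfig,
         windows: list[Window] | None = None, min_snps: int = 10,
         window_size: int = 100_000, step: int = 20_000) -> pd.DataFrame:
    """Evaluate all configured statistics in sliding windows.

    Returns one row per window sorted by (scaffold, start) with columns
    ``scaffold, start, end, n_snps`` plus one column per named statistic;
    windows with fewer than ``min_snps`` SNPs keep their row but have all
    statistics missing.
    """
    sheet.validate(gm)
    config.validate(sheet)
    if windows is None:
        windows = make_windows(gm.contig_lengths, window_size, step)

    def cols_of(pops):
        names = [s for p in pops for s in sheet.samples_of(p)]
        return gm.sample_indices(names), names

    spec = {k: (cols_of(t), cols_of(r)) for k, (t, r) in config.specific.items()}
    pairw = {k: (cols_of(a), cols_of(b)) for k, (a, b) in config.pairwise.items()}
    dxy_groups = {k: (cols_of(a)[0], cols_of(b)[0]) for k, (a, b) in config.dxy.items()}
    pi_groups = {k: cols_of(p)[0] for k, p in config.pi.items()}

    scaffolds = gm.sites["scaffold"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    # per-scaffold index ranges for fast window slicing
    bounds = {}
    for scaf in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaf)
        bounds[scaf] = (idx[0], idx[-1] + 1)

    stat_names = (list(config.specific) + list(config.pairwise)
                  + [f"dxy_{k}" for k in config.dxy]
                  + [f"pi_{k}" for k in config.pi])
    rows = []
    for w in windows:
        rec = {"scaffold": w.scaffold, "start": w.start, "end": w.end}
        if w.scaffold in bounds:
            lo, hi = bounds[w.scaffold]
            p = pos0[lo:hi]
            a, b = np.searchsorted(p, [w.start, w.end])
            idx = np.arange(lo + a, lo + b)
        else:
            idx = np.arange(0)
        rec["n_snps"] = len(idx)
        if len(idx) < min_snps:
            rec.update({k: np.nan for k in stat_names})
            rows.append(rec)
            continue
        dos = gm.dosage[idx]
        sub = GenotypeMatrix(gm.sites.iloc[idx].reset_index(drop=True),
                             gm.samples, dos, gm.contig_lengths)
        wlen = w.end - w.start
        if spec or pairw:
            M = matching_matrix(sub)
        for name, ((ti, tn), (ri, rn)) in spec.items():
            rec[name] = group_specific_fst(M, tn, rn).fst_specific
        for name, ((ai, an), (bi, bn)) in pairw.items():
            rec[name] = pairwise_fst(M, an, bn)
        for name, (ca, cb) in dxy_groups.items():
            rec[f"dxy_{name}"] = window_dxy(dos, ca, cb, wlen)
        for name, cg in pi_groups.items():
            rec[f"pi_{name}"] = window_pi(dos, cg, wlen)
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df.sort_values(["scaffold", "start"], kind="stable").reset_index(drop=True)


@dataclass
class LDBlockMatrix:
    """Mean pairwise r^2 between non-overlapping blocks of consecutive SNPs."""

    scaffold: str
    block_bounds: list[tuple[int, int]]  # bp span (0-based half-open) per block
    block_sizes: list[int]
    mean_r2: np.ndarray  # symmetric, n_blocks x n_blocks
    partial_last: bool


def _block_r2(Y, V, Ysq, iu, iv):
    """Mean r^2 between SNP sets iu and iv (pairwise-complete Pearson)."""
    n = V[iu].astype(float) @ V[iv].T
    sx = Y[iu] @ V[iv].T
    sy = (V[iu].astype(float) @ Y[iv].T)
    sxy = Y[iu] @ Y[iv].T
    sxx = Ysq[iu] @ V[iv].T
    syy = V[iu].astype(float) @ Ysq[iv].T
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx**2) * (n * syy - sy**2)
        r2 = num**2 / den
    r2[(den <= 0) | (n < 2)] = np.nan
    return r2


def ld_blocks(gm: GenotypeMatrix, group_samples, maf_min: float = 0.05,
              block_snps: int = 100) -> list[LDBlockMatrix]:
    """Blocked LD summary for one group of individuals.

    SNPs whose minor-allele frequency in the group is not strictly above
    ``maf_min`` are excluded, the rest are grouped into consecutive blocks
    of ``block_snps`` per scaffold, and every block pair gets the mean r^2
    over its SNP pairs (within-block: distinct pairs only).  The final block
    of a scaffold may be partial and is flagged.
    """
    cols = gm.sample_indices(list(group_samples))
    if len(cols) < 2:
        raise ValueError("LD needs >= 2 samples in the group")
    p, n = _group_freq(gm.dosage, cols)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = (n >= 2) & (maf > maf_min)

    scaffolds = gm.sites["scaffold"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    out = []
    for scaf in pd.unique(scaffolds):
        idx = np.flatnonzero((scaffolds == scaf) & keep)
        if len(idx) == 0:
            continue
        X = gm.dosage[np.ix_(idx, cols)].astype(np.float64)
        V = (gm.dosage[np.ix_(idx, cols)] != MISSING)
        Y = np.where(V, X, 0.0)
        Ysq = Y * Y
        starts = list(range(0, len(idx), block_snps))
        blocks = [np.arange(s, min(s + block_snps, len(idx))) for s in starts]
        nb = len(blocks)
        mean_r2 = np.full((nb, nb), np.nan)
        for u in range(nb):
            for v in range(u, nb):
                r2 = _block_r2(Y, V, Ysq, blocks[u], blocks[v])
                if u == v:
                    iu_t = np.triu_indices(len(blocks[u]), k=1)
                    vals = r2[iu_t]
                else:
                    vals = r2.ravel()
                with np.errstate(invalid="ignore"):
                    m = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
                mean_r2[u, v] = mean_r2[v, u] = m
        bounds = [(int(pos0[idx[b[0]]]), int(pos0[idx[b[-1]]]) + 1) for b in blocks]
        out.append(LDBlockMatrix(scaf, bounds, [len(b) for b in blocks],
                                 mean_r2, len(blocks[-1]) < block_snps))
    return out
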
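"""End-to-end validation runs on synthetic data: parameter recovery,
planted-sweep recovery with its co-occurring signature, null false-positive
sweeps, and the dual-criteria east-west design.

These drive the full pipeline (simulate -> scan -> threshold -> call) and
measure how well it recovers what was planted; they back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import peak_caller as pc
from . import synthetic_data as sd
from . import window_scan as ws
from .allele_sharing import matching_matrix, pairwise_fst

ISLAND = ("EC", "WC")
MAINLAND = ("MA", "PT", "IS")


def island_mainland_config() -> ws.ScanConfig:
    """The island-vs-mainland scan: FST^Can (island-specific), the pooled
    island-vs-mainland pairwise FST, island-island dxy and per-group pi."""
    return ws.ScanConfig(
        specific={"fst_can": (ISLAND, MAINLAND)},
        pairwise={"fst_ilvsml": (ISLAND, MAINLAND)},
        dxy={"ec_wc": (("EC",), ("WC",))},
        pi={"island": ISLAND, "mainland": MAINLAND})


def ld_region_contrast(gm, samples, region, maf_min: float = 0.0,
                       block_snps: int = 100) -> tuple[float, float]:
    """Mean within-block r^2 for blocks inside vs outside a region on its
    scaffold.  Blocks are classified by the midpoint of their bp span (SNP
    blocks need not align with region boundaries).  NaN when a side has no
    blocks."""
    blocks = ws.ld_blocks(gm, samples, maf_min=maf_min, block_snps=block_snps)
    bm = [b for b in blocks if b.scaffold == region.scaffold]
    if not bm:
        return np.nan, np.nan
    bm = bm[0]
    diag = np.array([bm.mean_r2[u, u] for u in range(len(bm.block_sizes))])
    mid = np.array([(s + e) / 2 for s, e in bm.block_bounds])
    inside = (mid >= region.start) & (mid < region.end)
    inside_mean = float(np.nanmean(diag[inside])) if inside.any() else np.nan
    outside_mean = float(np.nanmean(diag[~inside])) if (~inside).any() else np.nan
    return inside_mean, outside_mean


def parameter_recovery(seed: int, F: float = 0.10, n_snps: int = 20_000,
                       n_per_pop: int = 10) -> float:
    """Genome-wide pairwise FST between two Balding–Nichols populations
    simulated with drift parameter F (the estimator should recover F)."""
    cfg = sd.SimConfig(pop_sizes={"A": n_per_pop, "B": n_per_pop},
                       pop_F={"A": F, "B": F},
                       group_of_pop={"A": "island", "B": "mainland"},
                       n_snps=n_snps, contigs={"c1": 20_000_000}, seed=seed)
    gm, sheet, _ = sd.simulate_neutral(cfg)
    M = matching_matrix(gm)
    return pairwise_fst(M, sheet.samples_of("A"), sheet.samples_of("B"))


def planted_recovery(seed: int) -> dict:
    """Full default planted-sweep run: scan, five-sigma call, truth overlap
    and the sweep signature (pi drop, dxy drop, LD elevation on islands)."""
    gm, sheet, truth = sd.simulate_study(seed=seed)
    reg = truth.planted
    rows = ws.scan(gm, sheet, island_mainland_config())
    thr = pc.sigma_threshold(rows["fst_can"], 5.0)
    regions = pc.call_regions(rows, "fst_can", thr)

    overlap = 0.0
    if regions:
        best = max(regions, key=lambda r: min(r.end, reg.end) - max(r.start, reg.start))
        if best.scaffold == reg.scaffold:
            overlap = max(0, min(best.end, reg.end) - max(best.start, reg.start)) \
                / (reg.end - reg.start)

    inside = ((rows["scaffold"] == reg.scaffold) & (rows["start"] >= reg.start)
              & (rows["end"] <= reg.end))
    med = lambda col, m: float(np.nanmedian(rows.loc[m, col]))
    signature = {
        "fst_can_inside": med("fst_can", inside),
        "fst_can_outside": med("fst_can", ~inside),
        "pi_island_inside": med("pi_island", inside),
        "pi_island_outside": med("pi_island", ~inside),
        "dxy_ec_wc_inside": med("dxy_ec_wc", inside),
        "dxy_ec_wc_outside": med("dxy_ec_wc", ~inside),
    }
    # LD contrast measured without the MAF cut: at the default sweep
    # frequency the swept sites sit below 5% MAF in islanders, exactly the
    # regime the unfiltered correlation is needed to see (cf. methods note)
    for label, samples in [("island", sheet.samples_of_group("island")),
                           ("mainland", sheet.samples_of_group("mainland"))]:
        inside_m, outside_m = ld_region_contrast(gm, samples, reg)
        signature[f"ld_{label}_inside"] = inside_m
        signature[f"ld_{label}_outside"] = outside_m
    return {"n_regions": len(regions), "overlap_fraction": overlap,
            "threshold": thr, "regions": regions, "windows": rows,
            "signature": signature}


def null_region_count(seed: int) -> int:
    """Regions called on a no-sweep background (scaled null: 4 x 2 Mb
    contigs, 8,000 SNPs, ~370 windows)."""
    cfg = sd.default_config(seed=seed, n_snps=8_000, n_contigs=4,
                            contig_len=2_000_000, planted=False)
    gm, sheet, _ = sd.simulate_study(cfg, seed=seed)
    rows = ws.scan(gm, sheet,
                   ws.ScanConfig(specific={"fst_can": (ISLAND, MAINLAND)}))
    thr = pc.sigma_threshold(rows["fst_can"], 5.0)
    return len(pc.call_regions(rows, "fst_can", thr))


def null_sweep(base_seed: int, n_seeds: int = 100) -> float:
    """Fraction of null replicates with zero called regions."""
    zero = sum(null_region_count(base_seed + k) == 0 for k in range(n_seeds))
    return zero / n_seeds


def dual_recovery(seed: int) -> dict:
    """East-vs-west dual-criteria run on the two-region fixture.

    Returns, per island population, the called regions and whether they
    recover that population's planted region and nothing else."""
    gm, sheet, reg_ec, reg_wc = sd.east_west_fixture(seed=seed)
    gmi = gm.subset_samples(sheet.samples_of_group("island"))
    cfg = ws.ScanConfig(pairwise={"fst_ec_wc": (("EC",), ("WC",))},
                        specific={"fst_ec": (("EC",), ("WC",)),
                                  "fst_wc": (("WC",), ("EC",))})
    rows = ws.scan(gmi, sheet, cfg)
    thr = pc.sigma_threshold(rows["fst_ec_wc"], 5.0)

    def overlaps(r, reg):
        return (r.scaffold == reg.scaffold and r.start < reg.end
                and r.end > reg.start)

    out = {"threshold": thr}
    for label, pop_stat, own, other in [("EC", "fst_ec", reg_ec, reg_wc),
                                        ("WC", "fst_wc", reg_wc, reg_ec)]:
        regions, q_thr = pc.call_regions_dual(rows, "fst_ec_wc", thr,
                                              pop_stat, 0.99)
        out[label] = {
            "regions": regions,
            "quantile_threshold": q_thr,
            "recovers_own": any(overlaps(r, own) for r in regions),
            "hits_other": any(overlaps(r, other) for r in regions),
            "all_in_own": all(overlaps(r, own) for r in regions),
        }
    return out
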
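"""Island-vs-mainland genome scan: island-specific FST (FST^Can), pooled
island-vs-mainland pairwise FST, island-island dxy and per-group pi in
100-kb windows with 20-kb steps, plus blocked LD for islanders and
mainlanders.

Windows go to scratch/ (one row per window); a Manhattan-style figure of
FST^Can goes to scratch/figures/.
"""

import pathlib
import sys

import numpy as np

from islescan import evaluation as ev
from islescan import genotype_io as gio
from islescan import window_scan as ws

FIX = pathlib.Path("scratch/fixtures")
SCRATCH = pathlib.Path("scratch")


def main() -> int:
    gm = gio.read_vcf(FIX / "filtered.vcf")
    sheet = gio.SampleSheet.read(FIX / "samples.tsv")
    rows = ws.scan(gm, sheet, ev.island_mainland_config())
    gio.write_tsv(rows, SCRATCH / "windows_island_mainland.tsv")
    ok = rows["n_snps"] >= 10
    print(f"{len(rows)} windows ({ok.sum()} with >=10 SNPs); "
          f"median FST^Can = {np.nanmedian(rows['fst_can']):.4f}, "
          f"median island pi = {np.nanmedian(rows['pi_island']):.6f}/bp")

    for group in ("island", "mainland"):
        blocks = ws.ld_blocks(gm, sheet.samples_of_group(group),
                              maf_min=0.05, block_snps=100)
        mean_r2 = np.nanmean([b.mean_r2[u, u] for b in blocks
                              for u in range(len(b.block_sizes))])
        print(f"mean within-block r^2 ({group}, MAF>5%): {mean_r2:.4f}")

    fig_dir = SCRATCH / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(rows))
    scafs = rows["scaffold"].astype("category").cat.codes
    ax.scatter(x, rows["fst_can"], s=4, c=scafs % 2, cmap="Greys",
               vmin=-0.5, vmax=1.5)
    from islescan.peak_caller import sigma_threshold
    thr = sigma_threshold(rows["fst_can"], 5.0)
    ax.axhline(thr, ls="--", c="red", lw=0.8)
    ax.set_xlabel("window index")
    ax.set_ylabel(r"island-specific $F_{ST}$")
    fig.tight_layout()
    fig.savefig(fig_dir / "fst_can_scan.png", dpi=150)
    print(f"five-sigma threshold: {thr:.4f}; figure in {fig_dir}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
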
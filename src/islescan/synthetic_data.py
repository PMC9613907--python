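"""Synthetic genotype, annotation and niche data with the structure the
analysis assumes: an island/mainland Balding–Nichols background, one planted
multi-megabase swept haplotype shared by all island individuals, tiled
fixture genes, and a hot-arid niche specialist versus a generalist.

The neutral background draws, per SNP, an ancestral frequency
p ~ Uniform(0.05, 0.95) and per-population frequencies from the
Balding–Nichols beta distribution Beta(p(1-F)/F, (1-p)(1-F)/F), then
genotypes Binomial(2, p_pop) per individual — sites are unlinked, so LD
exists only where the sweep is planted, making the LD contrast a clean
signature.  Defaults mirror the study conditions: five populations (EC 10,
WC 9, MA 3, PT 9, IS 9) in island/mainland groups, drift of order
F = 0.05-0.10, 30,000 SNPs over ten 5-Mb scaffolds, and one 1-Mb planted
region where the island haplotype sits at frequency 0.97.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SampleSheet, write_vcf

__all__ = [
    "PlantedRegion",
    "SimConfig",
    "TruthRecord",
    "default_config",
    "simulate_neutral",
    "plant_sweep",
    "simulate_niche",
    "make_fixture_gff",
    "simulate_study",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PlantedRegion:
    scaffold: str
    start: int          # 0-based half-open, bp
    end: int
    island_freq: float = 0.97   # frequency of the swept haplotype on islands
    mainland_freq: float = 0.0  # kept for bookkeeping; mainland untouched
    populations: tuple[str, ...] | None = None  # default: the island group


@dataclass
class SimConfig:
    pop_sizes: dict[str, int]
    pop_F: dict[str, float]
    group_of_pop: dict[str, str]
    n_snps: int = 30_000
    contigs: dict[str, int] = field(default_factory=dict)
    planted: PlantedRegion | None = None
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        for p, f in self.pop_F.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"F for {p} must be in (0,1), got {f}")
        if self.planted is not None:
            if self.planted.scaffold not in self.contigs:
                raise ValueError("planted region on undeclared contig")
            if not (0 <= self.planted.start < self.planted.end
                    <= self.contigs[self.planted.scaffold]):
                raise ValueError("planted region outside its contig")
            if not 0.0 <= self.planted.island_freq <= 1.0:
                raise ValueError("island haplotype frequency outside [0,1]")


@dataclass
class TruthRecord:
    pop_freqs: pd.DataFrame            # sites x populations, simulated freqs
    planted: PlantedRegion | None
    pop_of: dict[str, str]
    swept_allele: np.ndarray | None = None   # per planted-region SNP, dosage allele
    swept_copies: pd.DataFrame | None = None  # individuals x 1, copies carried


def default_config(seed: int = 0, n_snps: int = 30_000,
                   n_contigs: int = 10, contig_len: int = 5_000_000,
                   planted: bool = True) -> SimConfig:
    """The study-shaped default: Table-1 sample sizes, island/mainland
    groups, drift F in the 0.05-0.10 band, one 1-Mb planted region."""
    contigs = {f"Super-Scaffold_{i+1}": contig_len for i in range(n_contigs)}
    region = PlantedRegion("Super-Scaffold_1", 2_000_000, 3_000_000) if planted else None
    return SimConfig(
        pop_sizes={"EC": 10, "WC": 9, "MA": 3, "PT": 9, "IS": 9},
        pop_F={"EC": 0.10, "WC": 0.09, "MA": 0.05, "PT": 0.05, "IS": 0.07},
        group_of_pop={"EC": "island", "WC": "island",
                      "MA": "mainland", "PT": "mainland", "IS": "mainland"},
        n_snps=n_snps, contigs=contigs, planted=region, seed=seed)


def _sample_sheet(cfg: SimConfig) -> SampleSheet:
    pop_of = {}
    for pop, size in cfg.pop_sizes.items():
        for i in range(size):
            pop_of[f"{pop}{i+1:02d}"] = pop
    return SampleSheet(pop_of, cfg.group_of_pop)


def simulate_neutral(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleSheet, TruthRecord]:
    """Draw the unlinked Balding–Nichols background.  Fully seeded: the same
    config yields bit-identical output."""
    if not cfg.contigs:
        raise ValueError("no contigs declared")
    rng = np.random.default_rng(cfg.seed)
    sheet = _sample_sheet(cfg)
    lo, hi = cfg.freq_bounds
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)

    # positions: uniform over the concatenated genome, distinct per contig
    names = list(cfg.contigs)
    lengths = np.array([cfg.contigs[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    contig_idx = rng.choice(len(names), size=cfg.n_snps, p=probs)
    scaf_col, pos_col = [], []
    for ci, name in enumerate(names):
        k = int((contig_idx == ci).sum())
        n_avail = cfg.contigs[name]
        if k > n_avail:
            raise ValueError(f"more SNPs than positions on {name}")
        pos = np.sort(rng.choice(n_avail, size=k, replace=False)) + 1
        scaf_col.extend([name] * k)
        pos_col.extend(pos.tolist())
    refs = rng.choice(4, size=cfg.n_snps)
    alt_off = rng.integers(1, 4, size=cfg.n_snps)
    sites = pd.DataFrame({
        "scaffold": scaf_col, "pos": pos_col,
        "ref": [_BASES[r] for r in refs],
        "alt": [_BASES[(r + o) % 4] for r, o in zip(refs, alt_off)]})

    pops = list(cfg.pop_sizes)
    freqs = np.empty((cfg.n_snps, len(pops)))
    dosage = np.empty((cfg.n_snps, sum(cfg.pop_sizes.values())), dtype=np.int8)
    col = 0
    for j, pop in enumerate(pops):
        F = cfg.pop_F[pop]
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pf = rng.beta(a, b)
        freqs[:, j] = pf
        n = cfg.pop_sizes[pop]
        dosage[:, col:col + n] = rng.binomial(
            2, pf[:, None], size=(cfg.n_snps, n)).astype(np.int8)
        col += n
    gm = GenotypeMatrix(sites, sheet.samples, dosage, dict(cfg.contigs))
    # GenotypeMatrix sorts sites lexicographically; keep truth aligned
    truth_freqs = pd.DataFrame(freqs, columns=pops)
    truth_freqs["scaffold"] = sites["scaffold"].to_numpy()
    truth_freqs["pos"] = sites["pos"].to_numpy()
    order = np.lexsort((truth_freqs["pos"], truth_freqs["scaffold"]))
    truth_freqs = truth_freqs.iloc[order].reset_index(drop=True)
    truth = TruthRecord(truth_freqs, cfg.planted, dict(sheet.pop_of))
    return gm, sheet, truth


def plant_sweep(gm: GenotypeMatrix, sheet: SampleSheet, truth: TruthRecord,
                region: PlantedRegion | None = None,
                seed: int = 0) -> tuple[GenotypeMatrix, TruthRecord]:
    """Overwrite the planted region with a shared swept haplotype.

    Of the target group's 2N chromosomes, round(f * 2N) (f =
    ``island_freq``) are replaced by copies of one swept haplotype,
    assigned to individuals by a seeded random shuffle — so the realized
    haplotype frequency equals the configured one in every replicate,
    rather than being binomially dispersed (which at these sample sizes
    would often fix the haplotype outright and erase the residual
    within-region variation).  The per-individual copy number is shared
    across all SNPs of the region, which is what generates region-wide LD,
    low within-group diversity and low island-island divergence.
    Non-target populations are untouched.
    """
    region = region or truth.planted
    if region is None:
        raise ValueError("no planted region specified")
    idx = gm.window_slice(region.scaffold, region.start, region.end)
    if len(idx) == 0:
        raise ValueError("planted region contains no SNPs; "
                         "increase SNP density or widen the region")
    rng = np.random.default_rng(seed + 1_000_003)
    if region.populations is not None:
        targets = [s for p in region.populations for s in sheet.samples_of(p)]
    else:
        targets = sheet.samples_of_group("island")
    tcols = gm.sample_indices(targets)

    # the swept haplotype's allele at each region SNP
    p_anc = truth.pop_freqs.iloc[idx][list(dict.fromkeys(sheet.pop_of.values()))]
    hap = (rng.random(len(idx)) < p_anc.mean(axis=1).to_numpy()).astype(np.int8)

    f = region.island_freq
    n_chrom = 2 * len(tcols)
    n_swept = int(round(f * n_chrom))
    slots = np.zeros(n_chrom, dtype=np.int8)
    slots[:n_swept] = 1
    rng.shuffle(slots)
    copies = slots.reshape(len(tcols), 2).sum(axis=1)

    dosage = gm.dosage.copy()
    for t, k in zip(tcols, copies):
        if k == 0:
            continue
        old = dosage[idx, t]
        # keep (2-k) randomly retained background alleles, add k swept copies
        retained = np.clip(old, 0, 2 - k)
        if k == 2:
            retained = np.zeros_like(old)
        else:  # k == 1: one background allele survives, drawn from the two
            keep_hi = rng.random(len(idx)) < old / 2.0
            retained = np.where(old == 2, 1, np.where(old == 0, 0,
                                keep_hi.astype(np.int8)))
        newd = retained + k * hap
        miss = old < 0
        dosage[idx, t] = np.where(miss, old, newd.astype(np.int8))
    out = GenotypeMatrix(gm.sites.copy(), gm.samples, dosage,
                         dict(gm.contig_lengths))
    new_truth = TruthRecord(truth.pop_freqs, region, truth.pop_of,
                            swept_allele=hap,
                            swept_copies=pd.DataFrame(
                                {"copies": copies}, index=targets))
    return out, new_truth


def simulate_study(cfg: SimConfig | None = None, seed: int = 0
                   ) -> tuple[GenotypeMatrix, SampleSheet, TruthRecord]:
    """Neutral background plus the planted sweep when configured."""
    cfg = cfg if cfg is not None else default_config(seed)
    if cfg.seed != seed:
        cfg = replace(cfg, seed=seed)
    gm, sheet, truth = simulate_neutral(cfg)
    if cfg.planted is not None:
        gm, truth = plant_sweep(gm, sheet, truth, cfg.planted, seed=cfg.seed)
    return gm, sheet, truth


def east_west_fixture(seed: int = 0, region_bp: int = 1_000_000
                      ) -> tuple[GenotypeMatrix, SampleSheet,
                                 PlantedRegion, PlantedRegion]:
    """Two-island fixture for the dual-criteria caller: one region swept in
    EC only, another in WC only, on the neutral five-population background.

    Each 1-Mb region spans ~2% of scan windows, so each population's
    99th-quantile F threshold lands inside its own swept windows — far
    above the mild elevation the *other* population's sweep induces in the
    focal population's F (a single shared haplotype makes the
    between-population matching term noisier there).  This keeps the
    conjunction caller's two lists cleanly separated at desk scale, where
    a genome of a few thousand windows cannot push the quantile as deep
    into the tail as a full-size scan does.
    """
    cfg = default_config(seed=seed, planted=False)
    gm, sheet, truth = simulate_study(cfg, seed=seed)
    reg_ec = PlantedRegion("Super-Scaffold_2", 1_000_000, 1_000_000 + region_bp,
                           populations=("EC",))
    reg_wc = PlantedRegion("Super-Scaffold_5", 3_000_000, 3_000_000 + region_bp,
                           populations=("WC",))
    gm, _ = plant_sweep(gm, sheet, truth, reg_ec, seed=seed)
    gm, _ = plant_sweep(gm, sheet, truth, reg_wc, seed=seed + 500_009)
    return gm, sheet, reg_ec, reg_wc


def make_fixture_gff(cfg: SimConfig, path) -> pd.DataFrame:
    """Deterministic gene tiling: one 20-kb gene every 100 kb per contig.

    Returns the gene table that was written (1-based inclusive in the file,
    as GFF3 requires)."""
    rows = []
    for scaf, length in cfg.contigs.items():
        start = 0
        i = 0
        while start + 20_000 <= length:
            i += 1
            rows.append((scaf, start, start + 20_000, f"gene_{scaf}_{i}"))
            start += 100_000
    genes = pd.DataFrame(rows, columns=["scaffold", "start", "end", "name"])
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf, length in cfg.contigs.items():
            fh.write(f"##sequence-region {scaf} 1 {length}\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['name']};Name={g['name']}"
            fh.write(f"{g.scaffold}\tislescan\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t+\t.\t{attrs}\n")
    return genes


def simulate_niche(n_sites: int = 300, n_vars: int = 13,
                   specialist_offset: np.ndarray | None = None,
                   records: tuple[int, int] = (73, 79),
                   seed: int = 0):
    """Environment + occurrence tables with a displaced specialist niche.

    Site environments are i.i.d. standard normal.  The specialist samples
    sites with probability proportional to exp(z . offset), concentrating
    it at one extreme of the offset direction (the hot-arid corner when the
    offset loads positively on a temperature-like variable and negatively
    on a precipitation-like one); the generalist samples sites uniformly.
    Returns (EnvTable, OccurrenceTable, truth dict).
    """
    from .niche_omi import EnvTable, OccurrenceTable

    rng = np.random.default_rng(seed)
    if specialist_offset is None:
        specialist_offset = np.zeros(n_vars)
        specialist_offset[0] = 2.0          # temperature-like axis, hot
        if n_vars > 7:
            specialist_offset[7] = -2.0     # precipitation-like axis, arid
    specialist_offset = np.asarray(specialist_offset, dtype=float)
    if len(specialist_offset) != n_vars:
        raise ValueError("offset length must equal n_vars")

    Z = rng.standard_normal((n_sites, n_vars))
    logits = Z @ specialist_offset
    w = np.exp(logits - logits.max())
    w = w / w.sum()
    site_ids = [f"site_{i+1}" for i in range(n_sites)]
    var_ids = [f"bio_{j+1}" for j in range(n_vars)]
    env = EnvTable(pd.DataFrame(Z, index=site_ids, columns=var_ids))

    n_spec, n_gen = records
    spec_draw = rng.choice(n_sites, size=n_spec, p=w)
    gen_draw = rng.choice(n_sites, size=n_gen)
    counts = np.zeros((2, n_sites))
    np.add.at(counts[0], spec_draw, 1)
    np.add.at(counts[1], gen_draw, 1)
    occ = OccurrenceTable(pd.DataFrame(counts, index=["specialist", "generalist"],
                                       columns=site_ids))
    truth = {"offset": specialist_offset, "site_weights": w}
    return env, occ, truth


def write_fixture_set(cfg: SimConfig, out_dir, seed: int = 0) -> dict[str, str]:
    """Write VCF + sample sheet + truth + GFF + niche tables to a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    gm, sheet, truth = simulate_study(cfg, seed=seed)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth": os.path.join(out_dir, "truth_freqs.tsv"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "env": os.path.join(out_dir, "env.tsv"),
        "occ": os.path.join(out_dir, "occ.tsv"),
    }
    write_vcf(gm, paths["vcf"])
    sheet.write(paths["samples"])
    truth.pop_freqs.to_csv(paths["truth"], sep="\t", index=False)
    make_fixture_gff(cfg, paths["gff"])
    env, occ, _ = simulate_niche(seed=seed)
    env.values.to_csv(paths["env"], sep="\t")
    occ.counts.to_csv(paths["occ"], sep="\t")
    return paths
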
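"""Genotype and annotation I/O: VCF reading/writing, site filters, GFF3 genes.

The internal representation of genotypes is a sites x samples matrix of
alt-allele dosages (0, 1, 2; -1 for missing).  Phase is discarded on read —
nothing downstream uses it.  All interval coordinates are held 0-based
half-open internally; VCF (1-based) and GFF3 (1-based inclusive) are
converted at the boundary.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

MISSING = -1

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_gff",
    "hwe_exact_test",
    "filter_sites",
    "ld_prune",
    "pairwise_r2",
    "write_tsv",
    "write_bed",
]


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP. ``position`` is 1-based, as printed in a VCF."""

    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site metadata.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``scaffold``, ``pos`` (1-based), ``ref``, ``alt``; one row
        per SNP, sorted by (scaffold, pos), no duplicate positions.
    samples : list of str
    dosage : ndarray of shape (n_sites, n_samples), int8
        Count of alt alleles per genotype; ``MISSING`` (-1) for no call.
    contig_lengths : dict mapping scaffold -> length in bp
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        key = self.sites[["scaffold", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup.scaffold}:{dup.pos}")
        order = np.lexsort((self.sites["pos"].to_numpy(),
                            self.sites["scaffold"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[order]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(self.sites.copy(), list(names),
                              self.dosage[:, idx], dict(self.contig_lengths))

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.sites[mask].reset_index(drop=True),
                              list(self.samples), self.dosage[mask],
                              dict(self.contig_lengths))

    def window_slice(self, scaffold: str, start: int, end: int) -> np.ndarray:
        """Row indices of sites with 0-based position in [start, end)."""
        on = self.sites["scaffold"].to_numpy() == scaffold
        pos0 = self.sites["pos"].to_numpy() - 1
        return np.flatnonzero(on & (pos0 >= start) & (pos0 < end))


class SampleSheet:
    """Individual -> population and population -> group (island/mainland)."""

    def __init__(self, pop_of: dict[str, str],
                 group_of_pop: dict[str, str] | None = None) -> None:
        self.pop_of = dict(pop_of)
        self.group_of_pop = dict(group_of_pop or {})
        unknown = set(self.pop_of.values()) - set(self.group_of_pop) if self.group_of_pop else set()
        if unknown:
            raise ValueError(f"populations without a group: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.pop_of)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_of.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        if population not in set(self.pop_of.values()):
            raise KeyError(f"unknown population {population!r}")
        return [s for s, p in self.pop_of.items() if p == population]

    def samples_of_group(self, group: str) -> list[str]:
        pops = [p for p, g in self.group_of_pop.items() if g == group]
        if not pops:
            raise KeyError(f"unknown or empty group {group!r}")
        return [s for s, p in self.pop_of.items() if p in pops]

    def validate(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.pop_of]
        if missing:
            raise ValueError(f"samples absent from sheet: {missing}")

    @classmethod
    def read(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        needed = {"individual", "population"}
        if not needed.issubset(df.columns):
            raise ValueError(f"sample sheet needs columns {sorted(needed)}")
        if df["individual"].duplicated().any():
            raise ValueError("duplicate individuals in sample sheet")
        pop_of = dict(zip(df["individual"], df["population"]))
        groups = None
        if "group" in df.columns:
            groups = (df.drop_duplicates("population")
                        .set_index("population")["group"].to_dict())
        return cls(pop_of, groups)

    def write(self, path) -> None:
        rows = [{"individual": s, "population": p,
                 "group": self.group_of_pop.get(p, "NA")}
                for s, p in self.pop_of.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, with scaffold and name."""

    genes: pd.DataFrame  # scaffold, start, end, strand, gene_id, name

    def __post_init__(self) -> None:
        if len(self.genes) and not (self.genes["start"] < self.genes["end"]).all():
            raise ValueError("gene with start >= end")

    def on_scaffold(self, scaffold: str) -> pd.DataFrame:
        return self.genes[self.genes["scaffold"] == scaffold]


def read_vcf(path, exclude_scaffolds=frozenset()) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; records on ``exclude_scaffolds``
    (e.g. the sex-linked super-scaffolds 13 and 42) are dropped.  Dosage is
    the count of alt alleles; phased and unphased genotypes are treated the
    same, and ``./.`` becomes missing.
    """
    exclude = set(exclude_scaffolds)
    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample names in {path}")
    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqnames else {}
    contig_lengths = {k: v for k, v in contig_lengths.items() if k not in exclude}

    recs, rows = [], []
    for v in vcf:
        if v.CHROM in exclude:
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            continue
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gt = v.gt_types.astype(np.int8)  # 0 homref / 1 het / 2 homalt / 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()

    sites = pd.DataFrame(recs, columns=["scaffold", "pos", "ref", "alt"])
    dosage = (np.vstack(rows) if rows
              else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(sites, samples, dosage, contig_lengths)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write GT-only VCF v4.2 (uncompressed) for the matrix."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in gm.contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        scaf = gm.sites["scaffold"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        for i in range(gm.n_sites):
            gts = "\t".join(code[int(d)] for d in gm.dosage[i])
            fh.write(f"{scaf[i]}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_gff(path) -> GeneAnnotation:
    """Load gene features from a GFF3 file.

    Coordinates are converted from GFF's 1-based inclusive convention to
    0-based half-open.  The gene name is taken from the ``Name`` attribute,
    falling back on ``ID``; records with neither are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(os.fspath(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [None])[0]
        name = g.attributes.get("Name", [None])[0] or gid
        if name is None:
            warnings.warn(f"gene at {g.seqid}:{g.start}-{g.end} lacks ID and Name; skipped")
            continue
        rows.append((g.seqid, g.start - 1, g.end, g.strand, gid or name, name))
    if not rows:
        warnings.warn(f"no gene features found in {path}")
    genes = pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                        "strand", "gene_id", "name"])
    return GeneAnnotation(genes)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy–Weinberg test p-value (Levene's conditional distribution).

    Conditional on the observed allele counts, the number of heterozygotes h
    follows

        P(h) = n! / (n_AA! h! n_aa!) * 2^h * n_A! n_a! / (2n)!

    over h with the parity of n_A.  The p-value sums the probabilities of
    all outcomes no more probable than the observed one, the convention of
    the classical exact test.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty sample")
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    hs = np.arange(nA % 2, min(nA, na) + 1, 2)
    if len(hs) == 0:  # monomorphic
        return 1.0
    log_p = (gammaln(n + 1) - gammaln((nA - hs) / 2 + 1) - gammaln(hs + 1)
             - gammaln((na - hs) / 2 + 1) + hs * np.log(2)
             + gammaln(nA + 1) + gammaln(na + 1) - gammaln(2 * n + 1))
    probs = np.exp(log_p)
    p_obs = probs[hs == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_distribution(n_AA: int, n_Aa: int, n_aa: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote outcomes and their exact probabilities (for checking)."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    hs = np.arange(nA % 2, min(nA, na) + 1, 2)
    log_p = (gammaln(n + 1) - gammaln((nA - hs) / 2 + 1) - gammaln(hs + 1)
             - gammaln((na - hs) / 2 + 1) + hs * np.log(2)
             + gammaln(nA + 1) + gammaln(na + 1) - gammaln(2 * n + 1))
    return hs, np.exp(log_p)


@dataclass
class FilterReport:
    n_input: int
    n_dropped_missing: int
    n_dropped_hwe: int
    n_output: int


def filter_sites(gm: GenotypeMatrix, max_missing: float = 0.05,
                 hwe_alpha: float = 0.05, apply_hwe: bool = False
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop sites by missingness (and optionally HWE departure).

    A site is kept when its missing fraction is strictly below
    ``max_missing`` — "less than 5% missing" keeps, 5% or more drops.  With
    ``apply_hwe``, sites whose exact HWE p (all samples pooled) falls below
    ``hwe_alpha`` are also removed, mirroring the neutral-structure dataset.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must be in [0,1], got {max_missing}")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = (gm.dosage == MISSING).mean(axis=1)
    keep = miss_frac < max_missing
    n_miss = int((~keep).sum())
    n_hwe = 0
    if apply_hwe:
        idx = np.flatnonzero(keep)
        for i in idx:
            row = gm.dosage[i]
            row = row[row != MISSING]
            p = hwe_exact_test(int((row == 0).sum()), int((row == 1).sum()),
                               int((row == 2).sum()))
            if p < hwe_alpha:
                keep[i] = False
                n_hwe += 1
    out = gm.subset_sites(keep)
    return out, FilterReport(gm.n_sites, n_miss, n_hwe, out.n_sites)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN when undefined (monomorphic or <2 obs)."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.1) -> GenotypeMatrix:
    """Greedy LD pruning, plink ``--indep-pairwise`` style.

    Per scaffold, within each ``window_snps``-SNP window, pairs are visited
    in position order; whenever a pair of still-kept SNPs has r² exceeding
    ``r2_max`` the later-positioned SNP is removed.  The window then advances
    by ``step_snps``.  Deterministic given input order.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    keep = np.ones(gm.n_sites, dtype=bool)
    scaffolds = gm.sites["scaffold"].to_numpy()
    for scaf in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaf)
        start = 0
        while start < len(idx):
            win = idx[start:start + window_snps]
            changed = True
            while changed:
                changed = False
                live = [i for i in win if keep[i]]
                for a in range(len(live)):
                    if not keep[live[a]]:
                        continue
                    for b in range(a + 1, len(live)):
                        if not keep[live[b]]:
                            continue
                        r2 = pairwise_r2(gm.dosage[live[a]], gm.dosage[live[b]])
                        if np.isfinite(r2) and r2 > r2_max:
                            keep[live[b]] = False
                            changed = True
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return gm.subset_sites(keep)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Tab-separated with header, missing as NA."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_bed(df: pd.DataFrame, path, name_col="name", score_col=None) -> None:
    """BED3+name(+score); start/end are already 0-based half-open."""
    cols = df[["scaffold", "start", "end"]].copy()
    cols["name"] = df[name_col] if name_col in df else "."
    if score_col is not None and score_col in df:
        cols["score"] = df[score_col]
    cols.to_csv(path, sep="\t", index=False, header=False)
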
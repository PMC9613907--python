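"""Population diversity summaries: observed heterozygosity, private alleles
(raw and rarefied), and allele-sharing inbreeding coefficients (FIS, FIT)
plus the overall FST.

All F coefficients use the matching framework: an individual's
self-matching (1 at homozygous sites, 0 at heterozygous, averaged over its
called sites) is contrasted against a mean-matching baseline, panel-wide
for FIT and within-population for FIS.  Overall FST contrasts mean
within-population pair matching against the mean between-population pair
matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .allele_sharing import matching_matrix
from .genotype_io import MISSING, GenotypeMatrix, SampleSheet

__all__ = [
    "observed_heterozygosity",
    "private_alleles",
    "rarefied_private_alleles",
    "inbreeding_coefficients",
    "diversity_table",
]


def observed_heterozygosity(gm: GenotypeMatrix, sheet: SampleSheet
                            ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-individual H_O (fraction of called sites that are heterozygous)
    and the per-population mean and SD over its individuals."""
    sheet.validate(gm)
    called = gm.dosage != MISSING
    het = gm.dosage == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = het.sum(axis=0) / called.sum(axis=0)
    per_ind = pd.Series(ho, index=gm.samples, name="H_O")
    rows = []
    for pop in sheet.populations:
        vals = per_ind[sheet.samples_of(pop)]
        rows.append({"population": pop, "n": len(vals),
                     "H_O_mean": vals.mean(),
                     "H_O_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan})
    return per_ind, pd.DataFrame(rows)


def _observed_allele_masks(gm: GenotypeMatrix, cols: np.ndarray):
    """Per site: is the alt (resp. ref) allele observed in these columns?
    Missing genotypes carry no evidence."""
    sub = gm.dosage[:, cols]
    called = sub != MISSING
    alt_seen = (called & (sub > 0)).any(axis=1)
    ref_seen = (called & (sub < 2)).any(axis=1)
    return alt_seen, ref_seen


def private_alleles(gm: GenotypeMatrix, sheet: SampleSheet,
                    populations=None) -> pd.Series:
    """Count alleles observed in exactly one population.

    Both alleles of a site can be private (to different populations); an
    allele observed nowhere is private to none.
    """
    sheet.validate(gm)
    pops = list(populations) if populations is not None else sheet.populations
    masks = {}
    for pop in pops:
        cols = gm.sample_indices(sheet.samples_of(pop))
        masks[pop] = _observed_allele_masks(gm, cols)
    alt_total = np.sum([m[0] for m in masks.values()], axis=0)
    ref_total = np.sum([m[1] for m in masks.values()], axis=0)
    counts = {}
    for pop, (alt_seen, ref_seen) in masks.items():
        priv_alt = alt_seen & (alt_total == 1)
        priv_ref = ref_seen & (ref_total == 1)
        counts[pop] = int(priv_alt.sum() + priv_ref.sum())
    return pd.Series(counts, name="private_alleles")


def rarefied_private_alleles(gm: GenotypeMatrix, sheet: SampleSheet,
                             g: int = 9, reps: int = 1000, seed: int = 0,
                             merge: dict[str, str] | None = None,
                             exhaustive: bool = False) -> pd.DataFrame:
    """Private-allele counts rarefied to ``g`` individuals per population.

    ``merge`` maps population labels onto merged labels before rarefaction
    (e.g. ``{"PT": "PTMA", "MA": "PTMA"}`` to pool two populations too small
    to subsample alone).  Monte-Carlo by default (``reps`` draws without
    replacement, seeded); ``exhaustive`` enumerates every g-subset
    combination instead — only feasible on toy panels.
    """
    sheet.validate(gm)
    pop_of = {s: (merge or {}).get(p, p) for s, p in sheet.pop_of.items()}
    pops: dict[str, list[str]] = {}
    for s, p in pop_of.items():
        pops.setdefault(p, []).append(s)
    too_small = [p for p, ss in pops.items() if len(ss) < g]
    if too_small:
        raise ValueError(f"population(s) smaller than g={g}: {too_small}")

    merged_sheet = SampleSheet(pop_of)
    labels = list(pops)

    def count_for(chosen: dict[str, list[str]]) -> pd.Series:
        keep = [s for ss in chosen.values() for s in ss]
        sub = gm.subset_samples(keep)
        sub_sheet = SampleSheet({s: pop_of[s] for s in keep})
        return private_alleles(sub, sub_sheet, populations=labels)

    if exhaustive:
        draws = []
        pools = [list(combinations(pops[p], g)) for p in labels]
        from itertools import product
        for combo in product(*pools):
            draws.append(count_for({p: list(c) for p, c in zip(labels, combo)}))
    else:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(reps):
            chosen = {p: list(rng.choice(pops[p], size=g, replace=False))
                      for p in labels}
            draws.append(count_for(chosen))
    mat = pd.DataFrame(draws)
    return pd.DataFrame({"population": labels,
                         "rarefied_mean": [mat[p].mean() for p in labels],
                         "rarefied_sd": [mat[p].std(ddof=1) for p in labels]})


@dataclass
class InbreedingResult:
    f_it: pd.Series                  # per individual
    f_is: pd.Series                  # per individual, within-pop baseline
    f_is_pop: pd.DataFrame           # population mean/SD
    overall_fst: float
    baseline_panel: float


def inbreeding_coefficients(gm: GenotypeMatrix, sheet: SampleSheet
                            ) -> InbreedingResult:
    """FIS / FIT per individual and the overall allele-sharing FST.

    FIT_i = (Mself_i - Mb) / (1 - Mb), Mb the mean matching over all
    distinct pairs in the panel; FIS_i restricts the baseline to distinct
    pairs within i's population.  Overall FST = (mean within-population pair
    matching - Mb') / (1 - Mb'), Mb' the mean between-population matching.
    """
    sheet.validate(gm)
    for pop in sheet.populations:
        if len(sheet.samples_of(pop)) < 2:
            raise ValueError(f"population {pop} has < 2 individuals")
    M = matching_matrix(gm)
    n = len(M.samples)
    iu = np.triu_indices(n, k=1)
    mb_panel = float(np.nanmean(M.M[iu]))

    pop_idx = {p: M.indices(sheet.samples_of(p)) for p in sheet.populations}
    within_vals, between_mask = [], np.ones((n, n), dtype=bool)
    for p, idx in pop_idx.items():
        sub = M.M[np.ix_(idx, idx)]
        within_vals.append(sub[np.triu_indices(len(idx), k=1)])
        between_mask[np.ix_(idx, idx)] = False
    within_all = np.concatenate(within_vals)
    between_vals = M.M[np.triu_indices(n, k=1)][
        between_mask[np.triu_indices(n, k=1)]]
    m_within = float(np.nanmean(within_all))
    if len(between_vals) == 0:
        overall = mb_between = np.nan  # single population: FST undefined
    else:
        mb_between = float(np.nanmean(between_vals))
        overall = (np.nan if np.isclose(mb_between, 1.0)
                   else (m_within - mb_between) / (1.0 - mb_between))

    f_it = pd.Series(
        np.nan if np.isclose(mb_panel, 1.0)
        else (M.self_matching - mb_panel) / (1.0 - mb_panel),
        index=M.samples, name="F_IT")
    f_is = pd.Series(np.nan, index=M.samples, name="F_IS", dtype=float)
    pop_rows = []
    for p, idx in pop_idx.items():
        sub = M.M[np.ix_(idx, idx)]
        base = float(np.nanmean(sub[np.triu_indices(len(idx), k=1)]))
        if np.isclose(base, 1.0):
            vals = pd.Series(np.nan, index=idx)
        else:
            vals = (M.self_matching[idx] - base) / (1.0 - base)
        for i, v in zip(idx, np.atleast_1d(vals)):
            f_is.iloc[i] = v
        arr = np.asarray(vals, dtype=float)
        pop_rows.append({"population": p, "F_IS_mean": np.nanmean(arr),
                         "F_IS_sd": np.nanstd(arr, ddof=1) if len(arr) > 1 else np.nan})
    return InbreedingResult(f_it, f_is, pd.DataFrame(pop_rows),
                            float(overall), mb_panel)


def diversity_table(gm: GenotypeMatrix, sheet: SampleSheet, g: int = 9,
                    reps: int = 1000, seed: int = 0,
                    merge: dict[str, str] | None = None) -> pd.DataFrame:
    """Assemble the per-population summary (n, H_O, #PA, #rPA, FIS, FIT)."""
    _, ho_pop = observed_heterozygosity(gm, sheet)
    pa = private_alleles(gm, sheet)
    rpa = rarefied_private_alleles(gm, sheet, g=g, reps=reps, seed=seed,
                                   merge=merge)
    inb = inbreeding_coefficients(gm, sheet)
    out = ho_pop.set_index("population")
    out["private_alleles"] = pa
    merged_of = {p: (merge or {}).get(p, p) for p in out.index}
    rpa_idx = rpa.set_index("population")
    out["rarefied_pa_mean"] = [rpa_idx.loc[merged_of[p], "rarefied_mean"]
                               for p in out.index]
    out["rarefied_pa_sd"] = [rpa_idx.loc[merged_of[p], "rarefied_sd"]
                             for p in out.index]
    fis = inb.f_is_pop.set_index("population")
    out["F_IS_mean"] = fis["F_IS_mean"]
    out["F_IS_sd"] = fis["F_IS_sd"]
    fit_mean, fit_sd = {}, {}
    for p in out.index:
        vals = inb.f_it[sheet.samples_of(p)]
        fit_mean[p] = vals.mean()
        fit_sd[p] = vals.std(ddof=1) if len(vals) > 1 else np.nan
    out["F_IT_mean"] = pd.Series(fit_mean)
    out["F_IT_sd"] = pd.Series(fit_sd)
    out.attrs["overall_fst"] = inb.overall_fst
    return out.reset_index()
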
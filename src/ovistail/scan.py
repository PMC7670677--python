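"""Per-breed-pair F_ST / dDAF selection scan with consensus candidate calling.

For each group comparison (a set of fat-tailed vs a set of thin-tailed
breeds), both statistics are computed for every fat x thin breed pair at
every SNP and averaged over pairs.  The top 1% of each averaged statistic is
flagged, a SNP is "positively selected" in a comparison when it is flagged
by both tests, and the final consensus set is the intersection across all
comparisons, further filtered for worldwide breed consistency of the
derived-allele frequency and annotated with genes within a +-150 kb window.

F_ST is the Weir & Cockerham (1984) variance-components estimator theta,
computed per SNP for two populations from genotype counts including
heterozygotes; pairs where both breeds are monomorphic for the same allele
are undefined and excluded from the average (not counted as 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, BreedPanel, GeneAnnotation, GenotypeMatrix
from .polarize import PolarizedFrequencyTable


@dataclass
class GroupComparison:
    name: str
    fat_breeds: list[str]
    thin_breeds: list[str]

    def __post_init__(self) -> None:
        if not self.fat_breeds or not self.thin_breeds:
            raise ValueError(f"{self.name}: both breed lists must be non-empty")
        if set(self.fat_breeds) & set(self.thin_breeds):
            raise ValueError(f"{self.name}: breed lists overlap")


@dataclass
class ScanResult:
    comparison: GroupComparison
    table: pd.DataFrame       # index snp_id; fst_avg, ddaf_avg, n_pairs_*, flags
    fst_cutoff: float
    ddaf_cutoff: float
    quantile: float

    @property
    def selected_snps(self) -> list[str]:
        return sorted(self.table.index[self.table["positively_selected"]])


@dataclass
class CandidateSet:
    consensus: list[str]
    post_filter: list[str]
    genes_per_snp: dict[str, list[str]] = field(default_factory=dict)

    @property
    def gene_union(self) -> list[str]:
        return sorted({g for gs in self.genes_per_snp.values() for g in gs})


# --------------------------------------------------------------------------
# Weir-Cockerham theta
# --------------------------------------------------------------------------

def _breed_counts(gm: GenotypeMatrix, panel: BreedPanel, breed: str):
    samples = [s for s in panel.samples_of(breed) if s in set(gm.samples)]
    idx = gm.sample_index(samples)
    calls = gm.calls[idx]
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)              # genotypes called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, calls, 0).sum(axis=0)
                     / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, np.where(called, calls == 1, False).sum(axis=0)
                     / np.maximum(n, 1), np.nan)
    return n, p, h


def fst_wc84(n1, p1, h1, n2, p2, h2) -> np.ndarray:
    """Vectorized WC84 theta for two populations from per-SNP summaries.

    ``n``: genotype counts, ``p``: allele frequencies, ``h``: observed
    heterozygote frequencies.  Returns NaN where undefined (a+b+c = 0, a
    breed with no calls, or fewer than 2 genotypes on average).
    """
    n1, p1, h1, n2, p2, h2 = map(np.asarray, (n1, p1, h1, n2, p2, h2))
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / 2.0
        n_c = 2.0 * n_bar - (n1 ** 2 + n2 ** 2) / (2.0 * n_bar)
        p_bar = (n1 * p1 + n2 * p2) / (2.0 * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (n1 * h1 + n2 * h2) / (2.0 * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 / 2.0 - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 / 2.0
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    bad = (n1 == 0) | (n2 == 0) | (n_bar <= 1) | (n_c <= 0) | ~np.isfinite(denom)
    return np.where(bad, np.nan, theta)


def fst_pair_all(gm: GenotypeMatrix, panel: BreedPanel,
                 breed1: str, breed2: str) -> np.ndarray:
    """Per-SNP WC84 theta between two breeds (NaN where undefined)."""
    n1, p1, h1 = _breed_counts(gm, panel, breed1)
    n2, p2, h2 = _breed_counts(gm, panel, breed2)
    return fst_wc84(n1, p1, h1, n2, p2, h2)


def fst_pair(gm: GenotypeMatrix, panel: BreedPanel, breed1: str, breed2: str,
             snp_id: str) -> float:
    """Scalar WC84 theta for one SNP; NaN when undefined."""
    j = gm.snp_ids.index(snp_id)
    return float(fst_pair_all(gm.take_snps(np.array([j])), panel,
                              breed1, breed2)[0])


# --------------------------------------------------------------------------
# dDAF and averaging
# --------------------------------------------------------------------------

def ddaf_pair(freq_table: PolarizedFrequencyTable, fat_breed: str,
              thin_breed: str, snp_id: str) -> float:
    """Signed DAF(fat) - DAF(thin) for one SNP; NaN when either undefined."""
    return float(freq_table.daf.loc[snp_id, fat_breed]
                 - freq_table.daf.loc[snp_id, thin_breed])


def average_over_pairs(per_pair: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean over breed pairs (rows), skipping undefined entries.

    Returns (mean, n_pairs_used); the mean is NaN where no pair is defined.
    """
    defined = ~np.isnan(per_pair)
    n_used = defined.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_pair, axis=0)
    return np.where(n_used > 0, mean, np.nan), n_used


def top_percentile_flags(values: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, float]:
    """Flag the top-q fraction of defined values, ties at the cutoff included.

    The cutoff is the value at rank ceil(q * N) from the top among the N
    defined values; every value >= cutoff is flagged.  NaN entries are never
    flagged.  Returns (flags, cutoff).
    """
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    n = int(defined.sum())
    if n == 0:
        return np.zeros(values.shape, dtype=bool), np.nan
    if n < 100 and q <= 0.01:
        warnings.warn(f"only {n} defined values: top-{q:.0%} cutoff is coarse",
                      stacklevel=2)
    ranked = np.sort(values[defined])[::-1]
    k = max(1, math.ceil(q * n))
    cutoff = ranked[k - 1]
    if ranked[0] == ranked[-1]:
        warnings.warn("all values equal: every SNP flagged", stacklevel=2)
    flags = defined & (values >= cutoff)
    return flags, float(cutoff)


def intersect_tests(sig_fst: np.ndarray, sig_ddaf: np.ndarray) -> np.ndarray:
    """A SNP is positively selected when flagged by both tests."""
    return np.asarray(sig_fst, bool) & np.asarray(sig_ddaf, bool)


# --------------------------------------------------------------------------
# Per-comparison scan and cross-comparison consensus
# --------------------------------------------------------------------------

def scan_comparison(gm: GenotypeMatrix, freq_table: PolarizedFrequencyTable,
                    panel: BreedPanel, comparison: GroupComparison,
                    quantile: float = 0.01) -> ScanResult:
    """Full scan for one group comparison: averaged F_ST and dDAF with flags."""
    snp_ids = freq_table.snp_ids
    keep = np.isin(gm.snp_ids, snp_ids)
    gm = gm.take_snps(np.flatnonzero(keep))  # only polarized SNPs are scanned
    order = gm.snp_ids
    daf = freq_table.daf.loc[order]

    counts = {b: _breed_counts(gm, panel, b)
              for b in comparison.fat_breeds + comparison.thin_breeds}
    fst_rows, ddaf_rows = [], []
    for fat in comparison.fat_breeds:
        n1, p1, h1 = counts[fat]
        for thin in comparison.thin_breeds:
            n2, p2, h2 = counts[thin]
            fst_rows.append(fst_wc84(n1, p1, h1, n2, p2, h2))
            ddaf_rows.append(daf[fat].to_numpy(float) - daf[thin].to_numpy(float))
    fst_avg, n_fst = average_over_pairs(np.vstack(fst_rows))
    ddaf_avg, n_ddaf = average_over_pairs(np.vstack(ddaf_rows))
    sig_fst, fst_cut = top_percentile_flags(fst_avg, quantile)
    sig_ddaf, ddaf_cut = top_percentile_flags(ddaf_avg, quantile)
    selected = intersect_tests(sig_fst, sig_ddaf)

    table = pd.DataFrame({
        "chrom": [s.chrom for s in gm.snps],
        "pos_bp": [s.pos_bp for s in gm.snps],
        "fst_avg": fst_avg,
        "ddaf_avg": ddaf_avg,
        "n_pairs_fst": n_fst,
        "n_pairs_ddaf": n_ddaf,
        "sig_fst": sig_fst,
        "sig_ddaf": sig_ddaf,
        "positively_selected": selected,
    }, index=pd.Index(order, name="snp_id"))
    return ScanResult(comparison, table, fst_cut, ddaf_cut, quantile)


def consensus_across_comparisons(scans: list[ScanResult]) -> list[str]:
    """SNPs positively selected in every comparison (sorted ids)."""
    if len(scans) < 2:
        raise ValueError("consensus needs at least two comparisons")
    sets = [set(s.selected_snps) for s in scans]
    consensus = set.intersection(*sets)
    return sorted(consensus)


def breed_consistency_filter(consensus: list[str],
                             freq_table: PolarizedFrequencyTable,
                             thin_breeds_all: list[str],
                             fat_breeds_all: list[str],
                             frac: float = 0.30
                             ) -> tuple[list[str], int, int]:
    """Remove consensus SNPs whose DAF pattern is inconsistent worldwide.

    A SNP is removed when DAF > 0.5 in more than floor(frac * n_thin)
    thin-tailed breeds, or DAF < 0.5 in more than floor(frac * n_fat)
    fat-tailed breeds.  With 18 thin and 14 fat breeds the thresholds are 5
    and 4.  Breeds with undefined DAF at a SNP are excluded from both the
    count and the group total for that SNP.

    Returns (retained snp_ids, b_thin, b_fat).
    """
    b_thin = math.floor(frac * len(thin_breeds_all))
    b_fat = math.floor(frac * len(fat_breeds_all))
    retained = []
    for snp in consensus:
        thin_daf = freq_table.daf.loc[snp, thin_breeds_all].to_numpy(float)
        fat_daf = freq_table.daf.loc[snp, fat_breeds_all].to_numpy(float)
        n_thin_hi = int(np.nansum(thin_daf > 0.5))
        n_fat_lo = int(np.nansum(fat_daf < 0.5))
        if n_thin_hi > b_thin or n_fat_lo > b_fat:
            continue
        retained.append(snp)
    return retained, b_thin, b_fat


def annotate_candidates(filtered: list[str], consensus: list[str],
                        gm: GenotypeMatrix, annotation: GeneAnnotation,
                        window_bp: int = 150_000) -> CandidateSet:
    """Attach genes overlapping [pos - window, pos + window] to each candidate."""
    pos = {s.snp_id: (s.chrom, s.pos_bp) for s in gm.snps}
    genes_per_snp: dict[str, list[str]] = {}
    for snp_id in filtered:
        chrom, p = pos[snp_id]
        lo, hi = p - window_bp, p + window_bp
        hits = [g.gene_id for g in annotation.on_chrom(chrom)
                if g.start_bp <= hi and g.end_bp >= lo]
        genes_per_snp[snp_id] = sorted(hits)
    return CandidateSet(list(consensus), list(filtered), genes_per_snp)
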
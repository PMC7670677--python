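"""Sequence-level follow-up inside candidate genes.

Given sequence variants (from a VCF) and a fat/thin sample panel, this
module computes the absolute group allele-frequency difference |dAF| per
variant, clusters consecutive high-|dAF| variants into elevated regions,
exports the phased haplotype matrix over a region, and applies the
high-confidence candidate rule (|dAF| > 0.8 and derived allele frequency in
the fat group > 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, BreedPanel, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class RegionCandidate:
    chrom: str
    start_bp: int
    end_bp: int
    member_snps: list[str]          # above-threshold variants defining the region
    n_above_threshold: int
    haplotypes: np.ndarray | None = None     # (2*n_samples) x n_region_variants
    hap_variant_ids: list[str] = field(default_factory=list)
    hap_group_labels: list[str] = field(default_factory=list)  # per haplotype row

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


class UnphasedError(RuntimeError):
    pass


def _group_indices(gm: GenotypeMatrix, panel: BreedPanel):
    fat = [s for s in gm.samples
           if panel.breeds[panel.breed_of(s)].tail_type == "fat"]
    thin = [s for s in gm.samples
            if panel.breeds[panel.breed_of(s)].tail_type == "thin"]
    return fat, thin


def group_delta_af(gm: GenotypeMatrix, panel: BreedPanel) -> pd.DataFrame:
    """Per-variant |AF(fat) - AF(thin)| pooling each group's samples.

    Variants where either group has zero calls are dropped with a logged
    count.  ``daf_fat`` (the fat group's derived-allele frequency) is filled
    where the variant carries an ancestral assignment, else NaN.
    """
    fat, thin = _group_indices(gm, panel)
    if not fat or not thin:
        raise ValueError("panel must contain fat and thin samples present in the data")

    def _af(sample_ids):
        idx = gm.sample_index(sample_ids)
        calls = gm.calls[idx]
        called = calls != MISSING
        n = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, np.where(called, calls, 0).sum(axis=0)
                            / np.maximum(n, 1), np.nan), n

    af_fat, n_fat = _af(fat)
    af_thin, n_thin = _af(thin)
    ok = (n_fat > 0) & (n_thin > 0)
    dropped = int((~ok).sum())
    if dropped:
        log.info("group_delta_af: dropped %d variants with an uncalled group", dropped)

    daf_fat = np.full(gm.n_snps, np.nan)
    for j, snp in enumerate(gm.snps):
        if snp.ancestral == snp.allele_a:       # derived = alt
            daf_fat[j] = af_fat[j]
        elif snp.ancestral == snp.allele_b:     # derived = ref
            daf_fat[j] = 1.0 - af_fat[j]

    table = pd.DataFrame({
        "chrom": [s.chrom for s in gm.snps],
        "pos_bp": [s.pos_bp for s in gm.snps],
        "ref": [s.allele_a for s in gm.snps],
        "alt": [s.allele_b for s in gm.snps],
        "af_fat": af_fat,
        "af_thin": af_thin,
        "delta_af": np.abs(af_fat - af_thin),
        "daf_fat": daf_fat,
    }, index=pd.Index(gm.snp_ids, name="snp_id"))
    return table[ok]


def detect_elevated_region(table: pd.DataFrame, delta_threshold: float = 0.6,
                           max_gap_bp: int = 5_000,
                           min_snps: int = 5) -> list[RegionCandidate]:
    """Cluster consecutive high-|dAF| variants into candidate regions.

    Variants with delta_af > ``delta_threshold`` join one cluster while the
    gap to the previous above-threshold variant is <= ``max_gap_bp``;
    clusters with at least ``min_snps`` members become regions spanning
    [min pos, max pos] of their members.
    """
    regions: list[RegionCandidate] = []
    hot = table[table["delta_af"] > delta_threshold]
    for chrom, sub in hot.groupby("chrom", sort=True):
        sub = sub.sort_values("pos_bp")
        pos = sub["pos_bp"].to_numpy(int)
        ids = list(sub.index)
        cluster: list[int] = []
        for i in range(len(pos)):
            if cluster and pos[i] - pos[cluster[-1]] > max_gap_bp:
                if len(cluster) >= min_snps:
                    regions.append(RegionCandidate(
                        str(chrom), int(pos[cluster[0]]), int(pos[cluster[-1]]),
                        [ids[k] for k in cluster], len(cluster)))
                cluster = []
            cluster.append(i)
        if len(cluster) >= min_snps:
            regions.append(RegionCandidate(
                str(chrom), int(pos[cluster[0]]), int(pos[cluster[-1]]),
                [ids[k] for k in cluster], len(cluster)))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def extract_haplotype_matrix(gm: GenotypeMatrix, haplotypes: np.ndarray | None,
                             region: RegionCandidate, panel: BreedPanel,
                             allow_unphased: bool = False) -> RegionCandidate:
    """Fill a region with its haplotype matrix over ALL polymorphic variants
    in the region span (not only the above-threshold members).

    Rows are phased haplotypes (two per sample) grouped fat-first by
    phenotype label; columns are variants in strictly increasing position.
    Without phased input, ``allow_unphased=True`` substitutes a genotype-
    dosage pseudo-haplotype split (heterozygotes contribute one 0 and one 1
    row in arbitrary phase); otherwise an error directs the user to supply
    a phased VCF.
    """
    in_span = [j for j, s in enumerate(gm.snps)
               if s.chrom == region.chrom and region.start_bp <= s.pos_bp <= region.end_bp]
    in_span.sort(key=lambda j: gm.snps[j].pos_bp)
    # polymorphic within the samples at hand
    freqs = gm.allele_b_freq()
    in_span = [j for j in in_span
               if not np.isnan(freqs[j]) and 0.0 < freqs[j] < 1.0]

    fat, thin = _group_indices(gm, panel)
    ordered_samples = fat + thin
    labels = ["fat"] * len(fat) + ["thin"] * len(thin)
    sidx = gm.sample_index(ordered_samples)

    if haplotypes is None:
        if not allow_unphased:
            raise UnphasedError(
                "haplotype extraction needs phased genotypes: supply a phased "
                "VCF, or pass allow_unphased=True for a genotype-dosage fallback")
        calls = gm.calls[sidx][:, in_span]
        rows = np.full((2 * len(ordered_samples), len(in_span)), MISSING, np.int8)
        rows[0::2] = np.where(calls == MISSING, MISSING, (calls >= 1).astype(np.int8))
        rows[1::2] = np.where(calls == MISSING, MISSING, (calls == 2).astype(np.int8))
    else:
        hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in sidx])
        rows = haplotypes[hap_rows][:, in_span]

    region.haplotypes = rows
    region.hap_variant_ids = [gm.snps[j].snp_id for j in in_span]
    region.hap_group_labels = [lab for lab in labels for _ in range(2)]
    return region


def select_high_confidence_snps(table: pd.DataFrame, delta_af_min: float = 0.8,
                                daf_fat_min: float = 0.8) -> pd.DataFrame:
    """Variants with |dAF| and fat-group DAF both strictly above their floors.

    Variants lacking an ancestral assignment (NaN daf_fat) are excluded with
    a logged count; the result is sorted by delta_af descending.
    """
    polarized = table[table["daf_fat"].notna()]
    dropped = len(table) - len(polarized)
    if dropped:
        log.info("select_high_confidence_snps: %d unpolarized variants excluded",
                 dropped)
    hits = polarized[(polarized["delta_af"] > delta_af_min)
                     & (polarized["daf_fat"] > daf_fat_min)]
    return hits.sort_values("delta_af", ascending=False, kind="mergesort")


def write_haplotype_tsv(region: RegionCandidate, path) -> None:
    if region.haplotypes is None:
        raise ValueError("region has no haplotype matrix; run extract_haplotype_matrix")
    df = pd.DataFrame(region.haplotypes, columns=region.hap_variant_ids)
    df.insert(0, "group", region.hap_group_labels)
    df.to_csv(path, sep="\t", index_label="haplotype")


def haplotype_heatmap(region: RegionCandidate, path) -> None:
    """Render the Fig.-2b-style haplotype matrix (alt alleles dark) to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if region.haplotypes is None:
        raise ValueError("region has no haplotype matrix")
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(region.haplotypes, aspect="auto", cmap="Blues",
              interpolation="nearest")
    n_fat = sum(1 for g in region.hap_group_labels if g == "fat")
    ax.axhline(n_fat - 0.5, color="red", lw=1)
    ax.set_xlabel(f"{len(region.hap_variant_ids)} variants "
                  f"({region.chrom}:{region.start_bp}-{region.end_bp})")
    ax.set_ylabel("phased haplotypes (fat above line, thin below)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
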
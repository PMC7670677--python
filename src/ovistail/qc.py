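"""SNP-, sample-, and relatedness-level quality control.

Filter semantics follow the published pipeline conventions for array data:
SNPs are removed when call rate <= 0.90 or MAF <= 0.05 (inclusive), samples
when their call rate falls strictly below 0.90, and one member of any
within-breed pair with PI-HAT > 0.3 is dropped.  MAF is pooled over all
non-outgroup samples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import MISSING, BreedPanel, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class QcReport:
    removed_snps_callrate: int = 0
    removed_snps_maf: int = 0
    removed_samples_callrate: int = 0
    removed_samples_ibd: list[str] = field(default_factory=list)
    n_snps_retained: int = 0
    n_samples_retained: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class IbdEstimate:
    sample1: str
    sample2: str
    z0: float
    z1: float
    z2: float

    @property
    def pi_hat(self) -> float:
        return self.z2 + self.z1 / 2.0


def _nonoutgroup_idx(gm: GenotypeMatrix, panel: BreedPanel | None) -> np.ndarray | None:
    if panel is None:
        return None
    study = [s for s in gm.samples if s in set(panel.study_samples)]
    return gm.sample_index(study)


def filter_snps(gm: GenotypeMatrix, max_missing_rate: float = 0.10,
                min_maf: float = 0.05,
                panel: BreedPanel | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with call rate <= 1 - max_missing_rate or MAF <= min_maf.

    Both removals are inclusive of the threshold value.  When a breed panel
    is given, call rate and MAF are computed over non-outgroup samples only.
    """
    if not (0 <= max_missing_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    idx = _nonoutgroup_idx(gm, panel)
    sub = gm if idx is None else gm.take_samples(idx)
    call_rate = sub.snp_call_rate()
    maf = np.nan_to_num(sub.maf(), nan=0.0)
    fail_cr = call_rate <= (1.0 - max_missing_rate)
    fail_maf = maf <= min_maf
    keep = ~(fail_cr | fail_maf)
    report = QcReport(
        removed_snps_callrate=int(fail_cr.sum()),
        removed_snps_maf=int((fail_maf & ~fail_cr).sum()),
        n_snps_retained=int(keep.sum()),
        n_samples_retained=gm.n_samples,
    )
    if not keep.any():
        warnings.warn("filter_snps removed every SNP", stacklevel=2)
    return gm.take_snps(np.flatnonzero(keep)), report


def filter_samples(gm: GenotypeMatrix,
                   min_call_rate: float = 0.90) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples whose average call rate is strictly below the threshold."""
    if not 0 <= min_call_rate <= 1:
        raise ValueError("min_call_rate must lie in [0, 1]")
    call_rate = gm.sample_call_rate()
    keep = call_rate >= min_call_rate
    report = QcReport(
        removed_samples_callrate=int((~keep).sum()),
        n_snps_retained=gm.n_snps,
        n_samples_retained=int(keep.sum()),
    )
    if not keep.any():
        warnings.warn("filter_samples removed every sample", stacklevel=2)
    return gm.take_samples(np.flatnonzero(keep)), report


# --------------------------------------------------------------------------
# IBD (PI-HAT) by method of moments
# --------------------------------------------------------------------------

def _ibs_expectations(counts_b: np.ndarray, counts_total: np.ndarray):
    """Per-SNP E[P(IBS state | IBD state)] with finite-sample corrections.

    Uses without-replacement allele products so that the expectations are
    unbiased when allele frequencies are estimated from the same sample
    (Purcell et al. 2007 style).  x = allele_b count, y = allele_a count,
    w = total alleles observed within the breed.
    """
    x = counts_b.astype(float)
    w = counts_total.astype(float)
    y = w - x
    d4 = w * (w - 1) * (w - 2) * (w - 3)
    d3 = w * (w - 1) * (w - 2)
    e00 = 2 * x * (x - 1) * y * (y - 1) / d4
    e10 = (4 * x * (x - 1) * (x - 2) * y + 4 * x * y * (y - 1) * (y - 2)) / d4
    e20 = (x * (x - 1) * (x - 2) * (x - 3) + y * (y - 1) * (y - 2) * (y - 3)
           + 4 * x * (x - 1) * y * (y - 1)) / d4
    e11 = (2 * x * (x - 1) * y + 2 * x * y * (y - 1)) / d3
    e21 = (x * (x - 1) * (x - 2) + y * (y - 1) * (y - 2)
           + x * (x - 1) * y + x * y * (y - 1)) / d3
    return e00, e10, e20, e11, e21


def estimate_ibd(gm: GenotypeMatrix, panel: BreedPanel, breed: str,
                 min_maf: float = 0.01) -> list[IbdEstimate]:
    """Pairwise IBD (z0, z1, z2, PI-HAT) within one breed.

    Method-of-moments in the style of PLINK ``--genome``: observed IBS-state
    counts are equated to their expectations given within-breed allele
    frequencies and solved for the IBD-state proportions, which are clamped
    to [0, 1] and renormalized.  SNPs with within-breed MAF < ``min_maf``
    are excluded to avoid degenerate moments.
    """
    samples = sorted(panel.samples_of(breed))
    samples = [s for s in samples if s in set(gm.samples)]
    if len(samples) < 2:
        return []
    idx = gm.sample_index(samples)
    calls = gm.calls[idx]
    called = calls != MISSING
    counts_total = 2 * called.sum(axis=0)
    counts_b = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts_total > 0, counts_b / np.maximum(counts_total, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    usable = (counts_total >= 4) & (maf >= min_maf)
    if not usable.any():
        log.warning("estimate_ibd: breed %s has no usable SNPs", breed)
        return []
    calls = calls[:, usable]
    e00, e10, e20, e11, e21 = _ibs_expectations(counts_b[usable],
                                                counts_total[usable])
    estimates = []
    for (i, s1), (j, s2) in combinations(enumerate(samples), 2):
        both = (calls[i] != MISSING) & (calls[j] != MISSING)
        if both.sum() == 0:
            continue
        diff = np.abs(calls[i][both].astype(int) - calls[j][both].astype(int))
        n0 = int((diff == 2).sum())
        n1 = int((diff == 1).sum())
        n2 = int((diff == 0).sum())
        n = n0 + n1 + n2
        s00, s10, s20 = e00[both].sum(), e10[both].sum(), e20[both].sum()
        s11, s21 = e11[both].sum(), e21[both].sum()
        z0 = n0 / s00 if s00 > 0 else 0.0
        z1 = (n1 - z0 * s10) / s11 if s11 > 0 else 0.0
        z2 = (n2 - z0 * s20 - z1 * s21) / n
        z = np.clip([z0, z1, z2], 0.0, 1.0)
        total = z.sum()
        if total == 0:
            z = np.array([1.0, 0.0, 0.0])
        else:
            z = z / total
        estimates.append(IbdEstimate(s1, s2, *map(float, z)))
    return estimates


def prune_related(estimates: list[IbdEstimate], gm: GenotypeMatrix,
                  threshold: float = 0.3) -> list[str]:
    """Greedy removal of one member of every pair with PI-HAT > threshold.

    While any retained pair exceeds the threshold, the member with the
    higher missing-call rate is dropped (ties broken toward the
    lexicographically smaller sample id).
    """
    miss = dict(zip(gm.samples, 1.0 - gm.sample_call_rate()))
    dropped: set[str] = set()
    active = [e for e in estimates if e.pi_hat > threshold]
    while True:
        live = [e for e in active
                if e.sample1 not in dropped and e.sample2 not in dropped]
        if not live:
            break
        # drop the sample involved in the most violating pairs first; among
        # those, prefer higher missingness then smaller id (deterministic)
        degree: dict[str, int] = {}
        for e in live:
            degree[e.sample1] = degree.get(e.sample1, 0) + 1
            degree[e.sample2] = degree.get(e.sample2, 0) + 1
        victim = sorted(degree, key=lambda s: (-degree[s], -miss.get(s, 0.0), s))[0]
        dropped.add(victim)
    return sorted(dropped)


def apply_qc(gm: GenotypeMatrix, panel: BreedPanel,
             max_missing_rate: float = 0.10, min_maf: float = 0.05,
             min_sample_call_rate: float = 0.90,
             pihat_threshold: float = 0.3) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC cascade: SNP filters, sample filter, per-breed IBD pruning,
    then a re-applied MAF filter so frequencies stay valid after sample loss."""
    gm1, r1 = filter_snps(gm, max_missing_rate, min_maf, panel)
    gm2, r2 = filter_samples(gm1, min_sample_call_rate)
    panel2 = panel.restrict(gm2.samples)
    to_drop: list[str] = []
    for breed in sorted(panel2.breeds):
        if panel2.breeds[breed].tail_type == "outgroup":
            continue
        est = estimate_ibd(gm2, panel2, breed)
        to_drop += prune_related(est, gm2, pihat_threshold)
    gm3 = gm2.drop_samples(to_drop)
    gm4, r4 = filter_snps(gm3, max_missing_rate=1.0, min_maf=min_maf,
                          panel=panel.restrict(gm3.samples))
    report = QcReport(
        removed_snps_callrate=r1.removed_snps_callrate,
        removed_snps_maf=r1.removed_snps_maf + r4.removed_snps_maf,
        removed_samples_callrate=r2.removed_samples_callrate,
        removed_samples_ibd=to_drop,
        n_snps_retained=gm4.n_snps,
        n_samples_retained=gm4.n_samples,
    )
    return gm4, report
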
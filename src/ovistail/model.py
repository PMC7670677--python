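"""Core data containers for the fat-tail selection-signature pipeline.

Genotypes are held as a dense samples x SNPs dosage matrix counting copies
of ``allele_b`` (0/1/2), with ``-1`` marking a missing call.  Coordinates are
1-based inclusive everywhere inside the package; format-specific conventions
(BED half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

TAIL_TYPES = ("thin", "fat", "outgroup")


@dataclass
class SnpRecord:
    """A biallelic array SNP with optional ancestral-state annotation."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str
    ancestral: str = "unknown"  # one of allele_a, allele_b, or "unknown"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ ({self.allele_a})")

    @property
    def derived(self) -> str:
        """The non-ancestral allele; raises if the SNP is unpolarized."""
        if self.ancestral == self.allele_a:
            return self.allele_b
        if self.ancestral == self.allele_b:
            return self.allele_a
        raise ValueError(f"{self.snp_id}: ancestral state not resolved")


class GenotypeMatrix:
    """Diploid call matrix: ``calls[i, j]`` counts allele_b copies of sample i at SNP j."""

    def __init__(self, snps: Sequence[SnpRecord], samples: Sequence[str],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(snps)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs")
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype entries outside {{-1,0,1,2}}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        self.snps = list(snps)
        self.samples = list(samples)
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    # --- per-axis summaries -------------------------------------------------

    def snp_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def allele_b_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele_b per SNP over non-missing calls (NaN if none)."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        b_count = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, b_count / np.maximum(n_alleles, 1), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_b_freq(sample_idx)
        return np.minimum(p, 1.0 - p)

    # --- subsetting ---------------------------------------------------------

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.snps[i] for i in idx], self.samples,
                              self.calls[:, idx])

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.snps, [self.samples[i] for i in idx],
                              self.calls[idx, :])

    def drop_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.samples) if s not in drop]
        return self.take_samples(np.array(keep, dtype=int))


@dataclass
class BreedInfo:
    tail_type: str
    region: str = ""

    def __post_init__(self) -> None:
        if self.tail_type not in TAIL_TYPES:
            raise ValueError(f"tail_type must be one of {TAIL_TYPES}, got {self.tail_type!r}")


@dataclass
class BreedPanel:
    """Sample -> breed assignment plus breed-level tail-type / region labels."""

    sample_breed: dict[str, str]
    breeds: dict[str, BreedInfo]

    def __post_init__(self) -> None:
        unknown = {b for b in self.sample_breed.values() if b not in self.breeds}
        if unknown:
            raise ValueError(f"samples assigned to undeclared breeds: {sorted(unknown)}")

    def breed_of(self, sample_id: str) -> str:
        return self.sample_breed[sample_id]

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in self.sample_breed.items() if b == breed]

    def breeds_by_tail(self, tail_type: str) -> list[str]:
        return sorted(b for b, info in self.breeds.items() if info.tail_type == tail_type)

    @property
    def outgroup_samples(self) -> list[str]:
        out = set(self.breeds_by_tail("outgroup"))
        return [s for s, b in self.sample_breed.items() if b in out]

    @property
    def study_samples(self) -> list[str]:
        """Non-outgroup samples: the ones breed frequencies and QC act on."""
        out = set(self.breeds_by_tail("outgroup"))
        return [s for s, b in self.sample_breed.items() if b not in out]

    def restrict(self, sample_ids: Iterable[str]) -> "BreedPanel":
        keep = set(sample_ids)
        sb = {s: b for s, b in self.sample_breed.items() if s in keep}
        return BreedPanel(sb, dict(self.breeds))

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.sample_breed]
        if missing:
            raise ValueError(f"{len(missing)} samples absent from breed panel, "
                             f"e.g. {missing[:3]}")


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start {self.start_bp} > end {self.end_bp}")


@dataclass
class GeneAnnotation:
    genes: list[GeneRecord] = field(default_factory=list)

    def on_chrom(self, chrom: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chrom == chrom]
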
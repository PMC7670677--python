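"""Ancestral/derived allele assignment and per-breed derived allele frequencies.

The wild outgroup (Mouflon) carries the ancestral state: unless a provided
ancestral-allele table lists a SNP, the ancestral allele is the strict
majority allele among non-missing outgroup calls.  An exact 50/50 split, or
zero outgroup calls, leaves the SNP unresolved — such SNPs are excluded from
all downstream scans, since an arbitrary choice would flip the sign of dDAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, BreedPanel, GenotypeMatrix, SnpRecord

log = logging.getLogger(__name__)

SOURCES = ("provided", "outgroup_major", "unresolved")


@dataclass
class PolarizedFrequencyTable:
    """Derived-allele frequency per breed (columns) and SNP (rows).

    ``daf`` holds NaN where a breed has zero called alleles at a SNP;
    ``n_alleles`` the non-missing allele counts; ``ancestral`` / ``source``
    index the per-SNP polarization outcome.
    """

    daf: pd.DataFrame
    n_alleles: pd.DataFrame
    ancestral: pd.Series
    source: pd.Series

    @property
    def snp_ids(self) -> list[str]:
        return list(self.daf.index)

    @property
    def breeds(self) -> list[str]:
        return list(self.daf.columns)

    def to_tsv(self, path) -> None:
        out = self.daf.copy()
        out.insert(0, "ancestral", self.ancestral)
        out.insert(1, "polarization_source", self.source)
        out.to_csv(path, sep="\t", index_label="snp_id")


def infer_ancestral(gm: GenotypeMatrix, panel: BreedPanel,
                    provided: dict[str, str] | None = None
                    ) -> tuple[GenotypeMatrix, pd.Series]:
    """Annotate every SNP with its ancestral allele and a provenance label.

    A provided table entry wins over the outgroup majority.  Returns a new
    matrix with annotated :class:`SnpRecord` objects plus a per-SNP source
    series over {provided, outgroup_major, unresolved}.
    """
    provided = provided or {}
    out_samples = [s for s in panel.outgroup_samples if s in set(gm.samples)]
    if not out_samples and not provided:
        raise ValueError("no outgroup samples in panel and no provided "
                         "ancestral table: cannot polarize")
    out_idx = gm.sample_index(out_samples) if out_samples else None

    if out_idx is not None:
        calls = gm.calls[out_idx]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        b_count = np.where(called, calls, 0).sum(axis=0)
        a_count = n_alleles - b_count
    else:
        n_alleles = np.zeros(gm.n_snps, dtype=int)
        a_count = b_count = n_alleles

    new_snps: list[SnpRecord] = []
    sources: list[str] = []
    for j, snp in enumerate(gm.snps):
        if snp.snp_id in provided:
            anc = provided[snp.snp_id]
            if anc not in (snp.allele_a, snp.allele_b):
                raise ValueError(
                    f"provided ancestral allele {anc!r} for {snp.snp_id} is not "
                    f"one of its alleles {snp.allele_a}/{snp.allele_b}")
            src = "provided"
        elif n_alleles[j] > 0 and a_count[j] != b_count[j]:
            anc = snp.allele_a if a_count[j] > b_count[j] else snp.allele_b
            src = "outgroup_major"
        else:  # tie or no outgroup calls
            anc = "unknown"
            src = "unresolved"
        new_snps.append(SnpRecord(snp.snp_id, snp.chrom, snp.pos_bp,
                                  snp.allele_a, snp.allele_b, ancestral=anc))
        sources.append(src)
    n_unres = sources.count("unresolved")
    if n_unres:
        log.info("infer_ancestral: %d of %d SNPs unresolved", n_unres, gm.n_snps)
    source = pd.Series(sources, index=gm.snp_ids, name="polarization_source")
    return GenotypeMatrix(new_snps, gm.samples, gm.calls), source


def derived_allele_frequencies(gm: GenotypeMatrix, panel: BreedPanel,
                               source: pd.Series | None = None
                               ) -> PolarizedFrequencyTable:
    """Per-breed DAF over all resolved SNPs; outgroup breeds are excluded.

    A breed with zero called alleles at a SNP gets NaN (undefined), never 0.
    """
    resolved = np.array([s.ancestral in (s.allele_a, s.allele_b) for s in gm.snps])
    if not resolved.all():
        gm = gm.take_snps(np.flatnonzero(resolved))
    snp_ids = gm.snp_ids
    # derived freq = freq(allele_b) when ancestral is allele_a, else 1 - freq
    flip = np.array([s.ancestral == s.allele_b for s in gm.snps])

    breeds = (panel.breeds_by_tail("thin") + panel.breeds_by_tail("fat"))
    present = set(gm.samples)
    daf_cols, n_cols, kept_breeds = [], [], []
    for breed in breeds:
        samples = [s for s in panel.samples_of(breed) if s in present]
        if not samples:
            continue
        idx = gm.sample_index(samples)
        calls = gm.calls[idx]
        called = calls != MISSING
        n_all = 2 * called.sum(axis=0)
        b_count = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_b = np.where(n_all > 0, b_count / np.maximum(n_all, 1), np.nan)
        daf_cols.append(np.where(flip, 1.0 - p_b, p_b))
        n_cols.append(n_all)
        kept_breeds.append(breed)

    daf = pd.DataFrame(np.column_stack(daf_cols) if daf_cols else [],
                       index=snp_ids, columns=kept_breeds)
    n_alleles = pd.DataFrame(np.column_stack(n_cols) if n_cols else [],
                             index=snp_ids, columns=kept_breeds)
    ancestral = pd.Series([s.ancestral for s in gm.snps], index=snp_ids,
                          name="ancestral")
    if source is None:
        source = pd.Series("outgroup_major", index=snp_ids,
                           name="polarization_source")
    else:
        source = source.reindex(snp_ids)
    return PolarizedFrequencyTable(daf, n_alleles, ancestral, source)


def read_ancestral_table(path) -> dict[str, str]:
    """Read a two-column TSV (snp_id, ancestral_base) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "ancestral_base"} <= set(df.columns):
        raise ValueError(f"{path}: need columns snp_id, ancestral_base")
    return dict(zip(df["snp_id"], df["ancestral_base"]))
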
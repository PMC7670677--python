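"""Readers/writers and panel merging for the formats the pipeline touches.

PLINK text PED/MAP is the native array format: dosages count ``allele_b``
copies, where ``allele_a`` is the first allele encountered in the PED column
for that SNP (deterministic registration, independent of allele frequency).
VCF is read through cyvcf2; BED intervals are converted to 1-based inclusive
at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (MISSING, BreedInfo, BreedPanel, GeneAnnotation,
                    GeneRecord, GenotypeMatrix, SnpRecord)

log = logging.getLogger(__name__)

STRAND_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


class ParseError(ValueError):
    pass


class MergeError(ValueError):
    pass


# --------------------------------------------------------------------------
# PLINK text PED/MAP
# --------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Genotype "0 0" becomes a missing call; any SNP with more than two
    observed alleles raises :class:`ParseError`.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP columns, "
                                 f"got {len(parts)}")
            chrom, snp_id, _cm, pos = parts[:4]
            map_rows.append((chrom, snp_id, int(pos)))

    n_snps = len(map_rows)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    # per-SNP observed alleles, in first-seen order
    alleles: list[list[str]] = [[] for _ in range(n_snps)]
    raw_gts: list[list[tuple[str, str]]] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                    f"({n_snps} SNPs), got {len(parts)}")
            samples.append(parts[1])
            gts = []
            for j in range(n_snps):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                gts.append((a1, a2))
                for a in (a1, a2):
                    if a != "0" and a not in alleles[j]:
                        alleles[j].append(a)
                        if len(alleles[j]) > 2:
                            raise ParseError(
                                f"{ped_path}:{lineno}: SNP {map_rows[j][1]} has "
                                f">2 alleles: {alleles[j]}")
            raw_gts.append(gts)

    snps = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        obs = alleles[j]
        a = obs[0] if len(obs) >= 1 else "A"
        b = obs[1] if len(obs) >= 2 else "0"  # "0": second allele never observed
        snps.append(SnpRecord(snp_id, chrom, pos, a, b))

    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for i, gts in enumerate(raw_gts):
        for j, (a1, a2) in enumerate(gts):
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == snps[j].allele_b) + (a2 == snps[j].allele_b)
    return GenotypeMatrix(snps, samples, calls)


def write_plink_text(gm: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` / ``<prefix>.map``; missing calls become "0 0"."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    coding = {0: None, 1: None, 2: None}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, snp in enumerate(gm.snps):
                d = int(gm.calls[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [snp.allele_a, snp.allele_a]
                elif d == 1:
                    fields += [snp.allele_a, snp.allele_b]
                else:
                    fields += [snp.allele_b, snp.allele_b]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def read_vcf(path: str | Path, min_maf: float = 0.0,
             min_call_rate: float = 0.0) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Read biallelic SNPs from a VCF, applying call-rate / MAF filters.

    Records with call rate <= ``min_call_rate`` or MAF <= ``min_maf`` are
    removed (the removal is inclusive of the threshold).  Multi-allelic and
    indel records are dropped with a logged count.

    Returns the genotype matrix plus a phased haplotype matrix of shape
    ``(2 * n_samples, n_snps)`` with 0=ref, 1=alt, -1=missing — or ``None``
    if any retained call is unphased.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    snps, dosage_cols, hap_cols = [], [], []
    n_dropped_nonbiallelic = n_dropped_filter = 0
    all_phased = True

    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped_nonbiallelic += 1
            continue
        gts = var.genotypes  # list of [a0, a1, phased]
        if gts is None or len(gts) != n:
            raise ParseError(f"{path}: record {var.CHROM}:{var.POS} lacks GT field")
        dos = np.full(n, MISSING, dtype=np.int8)
        haps = np.full(2 * n, MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                continue
            dos[i] = a0 + a1
            haps[2 * i], haps[2 * i + 1] = a0, a1
            if not g[2]:
                all_phased = False
        called = dos != MISSING
        call_rate = called.mean() if n else 0.0
        n_alleles = 2 * called.sum()
        p = dos[called].sum() / n_alleles if n_alleles else np.nan
        maf = min(p, 1 - p) if n_alleles else 0.0
        if call_rate <= min_call_rate or maf <= min_maf:
            n_dropped_filter += 1
            continue
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(snp_id, str(var.CHROM), int(var.POS),
                              var.REF, var.ALT[0]))
        dosage_cols.append(dos)
        hap_cols.append(haps)

    if n_dropped_nonbiallelic:
        log.info("read_vcf: dropped %d non-biallelic/indel records",
                 n_dropped_nonbiallelic)
    if n_dropped_filter:
        log.info("read_vcf: dropped %d records by call-rate/MAF filter",
                 n_dropped_filter)
    calls = (np.stack(dosage_cols, axis=1) if dosage_cols
             else np.zeros((n, 0), dtype=np.int8))
    gm = GenotypeMatrix(snps, samples, calls)
    haps_mat = (np.stack(hap_cols, axis=1) if hap_cols
                else np.zeros((2 * n, 0), dtype=np.int8))
    return gm, (haps_mat if all_phased else None)


# --------------------------------------------------------------------------
# Panel merging
# --------------------------------------------------------------------------

def _is_strand_ambiguous(a: str, b: str) -> bool:
    return {a, b} in STRAND_AMBIGUOUS


def merge_panels(gms: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge genotype panels on their shared SNP ids.

    Allele registration is reconciled by id + allele match: a panel coded
    B/A relative to the first panel's A/B has its dosages flipped (x -> 2-x).
    SNPs with irreconcilable allele pairs, and strand-ambiguous (A/T, C/G)
    SNPs whose registration conflicts across panels, are dropped with a
    logged count.  Sample ids must be globally unique.
    """
    if len(gms) < 2:
        raise MergeError("merge_panels needs at least two panels")
    seen: set[str] = set()
    for gm in gms:
        dup = seen & set(gm.samples)
        if dup:
            raise MergeError(f"duplicate sample ids across panels: {sorted(dup)[:5]}")
        seen |= set(gm.samples)

    common = set(gms[0].snp_ids)
    for gm in gms[1:]:
        common &= set(gm.snp_ids)
    # keep the first panel's SNP order
    order = [s for s in gms[0].snp_ids if s in common]

    id_to_col = [{s: j for j, s in enumerate(gm.snp_ids)} for gm in gms]
    kept_snps: list[SnpRecord] = []
    blocks: list[list[np.ndarray]] = [[] for _ in gms]
    n_dropped = 0

    for snp_id in order:
        ref = gms[0].snps[id_to_col[0][snp_id]]
        a, b = ref.allele_a, ref.allele_b
        cols, ok = [], True
        for k, gm in enumerate(gms):
            snp = gm.snps[id_to_col[k][snp_id]]
            col = gm.calls[:, id_to_col[k][snp_id]]
            pa, pb = snp.allele_a, snp.allele_b
            if pb == "0":  # monomorphic in this panel: match on allele_a only
                if pa == a:
                    cols.append(col)
                elif pa == b or b == "0":
                    cols.append(np.where(col == MISSING, MISSING, 2 - col).astype(np.int8))
                else:
                    ok = False
                    break
                continue
            if b == "0":  # reference panel monomorphic: adopt this panel's pair
                if pa == a:
                    b = pb
                    cols.append(col)
                elif pb == a:
                    b = pa
                    cols.append(np.where(col == MISSING, MISSING, 2 - col).astype(np.int8))
                else:
                    ok = False
                    break
                continue
            if (pa, pb) == (a, b):
                cols.append(col)
            elif (pa, pb) == (b, a):
                if _is_strand_ambiguous(a, b):
                    ok = False  # flip vs strand error undecidable
                    break
                cols.append(np.where(col == MISSING, MISSING, 2 - col).astype(np.int8))
            else:
                ok = False
                break
        if not ok:
            n_dropped += 1
            continue
        kept_snps.append(SnpRecord(snp_id, ref.chrom, ref.pos_bp, a, b,
                                   ancestral=ref.ancestral))
        for k, col in enumerate(cols):
            blocks[k].append(col)

    if n_dropped:
        log.info("merge_panels: dropped %d SNPs with conflicting or "
                 "strand-ambiguous registration", n_dropped)

    samples = [s for gm in gms for s in gm.samples]
    if kept_snps:
        calls = np.concatenate(
            [np.stack(cols, axis=1) for cols in blocks], axis=0)
    else:
        calls = np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(kept_snps, samples, calls)


# --------------------------------------------------------------------------
# Gene annotation (BED / GFF3)
# --------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, fmt: str) -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based)."""
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {fmt!r}; use BED or GFF3")
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if fmt == "BED":
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
                chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end}"
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(GeneRecord(name, chrom, start0 + 1, end, strand))
            else:
                if len(parts) < 9:
                    raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
                if parts[2].lower() != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
                name = attrs.get("ID", attrs.get("Name", f"gene_{lineno}"))
                genes.append(GeneRecord(name, parts[0], int(parts[3]),
                                        int(parts[4]), parts[6]))
    return GeneAnnotation(genes)


# --------------------------------------------------------------------------
# Breed panel TSV
# --------------------------------------------------------------------------

def read_breed_panel(path: str | Path) -> BreedPanel:
    """Read a sample table with columns sample_id, breed, tail_type, region."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "tail_type", "region"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: breed panel needs columns {sorted(required)}")
    sample_breed = dict(zip(df["sample_id"], df["breed"]))
    breeds: dict[str, BreedInfo] = {}
    for _, row in df.iterrows():
        info = BreedInfo(row["tail_type"], row["region"] if pd.notna(row["region"]) else "")
        prev = breeds.setdefault(row["breed"], info)
        if prev.tail_type != info.tail_type:
            raise ParseError(f"{path}: breed {row['breed']} has conflicting tail types")
    return BreedPanel(sample_breed, breeds)


def write_breed_panel(panel: BreedPanel, path: str | Path) -> None:
    rows = [{"sample_id": s, "breed": b,
             "tail_type": panel.breeds[b].tail_type,
             "region": panel.breeds[b].region}
            for s, b in panel.sample_breed.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
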
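"""PED/MAP round trips, VCF filtering semantics, panel merging, annotation I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovistail import io as gio
from ovistail.model import MISSING, GenotypeMatrix, SnpRecord

from conftest import make_matrix


# --------------------------------------------------------------------------
# PED/MAP
# --------------------------------------------------------------------------

def test_single_homozygote_dosage_zero(tmp_path):
    """'A A' at a SNP whose first-seen allele is A is dosage 0 (allele_a)."""
    (tmp_path / "x.ped").write_text("1 S1 0 0 0 -9 A A\n")
    (tmp_path / "x.map").write_text("1 snp1 0 100\n")
    gm = gio.read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert gm.calls.shape == (1, 1)
    assert gm.calls[0, 0] == 0
    assert gm.snps[0].allele_a == "A"


def test_zero_zero_is_missing(tmp_path):
    (tmp_path / "x.ped").write_text("1 S1 0 0 0 -9 0 0 A G\n")
    (tmp_path / "x.map").write_text("1 snp1 0 100\n1 snp2 0 200\n")
    gm = gio.read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert gm.calls[0, 0] == MISSING
    assert gm.calls[0, 1] == 1


def test_heterozygote_written_a_then_b(tmp_path):
    gm = make_matrix([[1]], alleles=[("A", "G")])
    ped, _ = gio.write_plink_text(gm, tmp_path / "out")
    assert ped.read_text().strip().endswith("A G")


def test_empty_matrix_round_trip(tmp_path):
    gm = make_matrix(np.zeros((0, 3), dtype=np.int8))
    ped, mp = gio.write_plink_text(gm, tmp_path / "empty")
    back = gio.read_plink_text(ped, mp)
    assert back.n_samples == 0 and back.n_snps == 3
    assert [s.pos_bp for s in back.snps] == [100, 200, 300]


@settings(deadline=None, derandomize=True, max_examples=15)
@given(seed=st.integers(0, 2 ** 31 - 1))
def test_round_trip_identity_random(seed):
    """Write-then-read reproduces calls, ids and positions exactly."""
    import tempfile
    from pathlib import Path
    rng = np.random.default_rng(seed)
    calls = rng.choice([MISSING, 0, 1, 2], size=(20, 50),
                       p=[0.05, 0.4, 0.3, 0.25]).astype(np.int8)
    gm = make_matrix(calls)
    with tempfile.TemporaryDirectory() as td:
        out = Path(td) / "panel"
        ped, mp = gio.write_plink_text(gm, out)
        back = gio.read_plink_text(ped, mp)
    assert back.samples == gm.samples
    assert back.snp_ids == gm.snp_ids
    assert [s.pos_bp for s in back.snps] == [s.pos_bp for s in gm.snps]
    # registration may flip where allele_b was seen first in PED column order
    for j in range(gm.n_snps):
        got, want = back.calls[:, j], gm.calls[:, j]
        flipped = np.where(want == MISSING, MISSING, 2 - want)
        assert np.array_equal(got, want) or np.array_equal(got, flipped)
        p_got = back.allele_b_freq()[j]
        p_want = gm.allele_b_freq()[j]
        if not np.isnan(p_want):
            assert np.isclose(p_got, p_want) or np.isclose(p_got, 1 - p_want)


def test_malformed_ped_names_line(tmp_path):
    (tmp_path / "x.ped").write_text("1 S1 0 0 0 -9 A\n")
    (tmp_path / "x.map").write_text("1 snp1 0 100\n")
    with pytest.raises(gio.ParseError, match=":1"):
        gio.read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")


def test_triallelic_snp_rejected(tmp_path):
    (tmp_path / "x.ped").write_text("1 S1 0 0 0 -9 A G\n1 S2 0 0 0 -9 A C\n")
    (tmp_path / "x.map").write_text("1 snp1 0 100\n")
    with pytest.raises(gio.ParseError, match="alleles"):
        gio.read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def write_vcf(path, records, samples, phased=True):
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, ref, alt, gts in records:
            cols = [sep.join("." if a is None else str(a) for a in g)
                    for g in gts]
            fh.write(f"1\t{pos}\tv{pos}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(cols) + "\n")


def test_vcf_call_rate_boundary_removed(tmp_path):
    """A record called in exactly 90% of samples is removed at threshold 0.9."""
    samples = [f"s{i}" for i in range(10)]
    gts = [(0, 0)] * 9 + [(None, None)]
    write_vcf(tmp_path / "a.vcf", [(100, "A", "G", gts),
                                   (200, "A", "G", [(0, 1)] * 10)], samples)
    gm, _ = gio.read_vcf(tmp_path / "a.vcf", min_maf=0.0, min_call_rate=0.9)
    assert gm.snp_ids == ["v200"]


def test_vcf_maf_boundary_removed(tmp_path):
    """MAF exactly 0.05 is removed (inclusive threshold)."""
    samples = [f"s{i}" for i in range(10)]
    maf05 = [(0, 1)] + [(0, 0)] * 9          # 1/20 alleles alt -> MAF 0.05
    kept = [(0, 1)] * 5 + [(0, 0)] * 5       # MAF 0.25
    write_vcf(tmp_path / "b.vcf", [(100, "A", "G", maf05),
                                   (200, "A", "G", kept)], samples)
    gm, _ = gio.read_vcf(tmp_path / "b.vcf", min_maf=0.05, min_call_rate=0.0)
    assert gm.snp_ids == ["v200"]


def test_vcf_phased_haplotypes(tmp_path):
    write_vcf(tmp_path / "c.vcf", [(100, "A", "G", [(0, 1), (1, 1)])],
              ["s1", "s2"], phased=True)
    gm, haps = gio.read_vcf(tmp_path / "c.vcf")
    assert haps is not None and haps.shape == (4, 1)
    assert list(haps[:, 0]) == [0, 1, 1, 1]
    assert gm.calls[0, 0] == 1 and gm.calls[1, 0] == 2


def test_vcf_unphased_gives_no_haplotypes(tmp_path):
    write_vcf(tmp_path / "d.vcf", [(100, "A", "G", [(0, 1)])], ["s1"],
              phased=False)
    _, haps = gio.read_vcf(tmp_path / "d.vcf")
    assert haps is None


def test_vcf_drops_indels_and_multiallelic(tmp_path):
    with open(tmp_path / "e.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")
        fh.write("1\t100\tindel\tA\tAT\t.\tPASS\t.\tGT\t0|1\n")
        fh.write("1\t200\tmulti\tA\tG,C\t.\tPASS\t.\tGT\t0|1\n")
        fh.write("1\t300\tsnp\tA\tG\t.\tPASS\t.\tGT\t0|1\n")
    gm, _ = gio.read_vcf(tmp_path / "e.vcf")
    assert gm.snp_ids == ["snp"]


# --------------------------------------------------------------------------
# Merging
# --------------------------------------------------------------------------

def test_merge_restricts_to_shared_ids():
    rng = np.random.default_rng(0)
    gm1 = make_matrix(rng.integers(0, 3, (4, 15)), sample_prefix="A")
    gm2 = make_matrix(rng.integers(0, 3, (4, 10)), sample_prefix="B")
    merged = gio.merge_panels([gm1, gm2])
    assert merged.n_snps == 10
    assert merged.n_samples == 8


def test_merge_flips_swapped_registration():
    """A/G vs G/A: dosages recoded so pooled frequency matches pre-merge."""
    gm1 = make_matrix([[0], [1]], alleles=[("A", "G")], sample_prefix="A")
    gm2 = make_matrix([[2], [1]], alleles=[("G", "A")], sample_prefix="B")
    merged = gio.merge_panels([gm1, gm2])
    # pooled allele-G frequency: gm1 gives (0+1)/4, gm2 (G is allele_a) (2+1)/4
    # -> G count = 1 + (4 - 3) = 2 of 8
    assert np.isclose(merged.allele_b_freq()[0], 2 / 8)
    assert list(merged.calls[:, 0]) == [0, 1, 0, 1]


def test_merge_drops_irreconcilable_and_ambiguous():
    gm1 = make_matrix([[1], [1]], alleles=[("A", "G")], sample_prefix="A")
    gm2 = make_matrix([[1], [1]], alleles=[("A", "C")], sample_prefix="B")
    assert gio.merge_panels([gm1, gm2]).n_snps == 0
    # strand-ambiguous A/T with conflicting registration: dropped, not flipped
    gm3 = make_matrix([[1], [1]], alleles=[("A", "T")], sample_prefix="C")
    gm4 = make_matrix([[1], [1]], alleles=[("T", "A")], sample_prefix="D")
    assert gio.merge_panels([gm3, gm4]).n_snps == 0


def test_merge_duplicate_sample_id_errors():
    gm1 = make_matrix([[1]], sample_prefix="X")
    gm2 = make_matrix([[1]], sample_prefix="X")
    with pytest.raises(gio.MergeError, match="duplicate"):
        gio.merge_panels([gm1, gm2])


def test_merge_pooled_frequency_invariant():
    """Pooled allele frequency after merge equals the pre-merge pooled value."""
    rng = np.random.default_rng(42)
    calls1 = rng.integers(0, 3, (10, 8)).astype(np.int8)
    calls2 = rng.integers(0, 3, (6, 8)).astype(np.int8)
    gm1 = make_matrix(calls1, sample_prefix="A")
    # second panel has swapped registration at even SNPs
    alleles2 = [("G", "A") if j % 2 == 0 else ("A", "G") for j in range(8)]
    calls2_coded = calls2.copy()
    calls2_coded[:, ::2] = 2 - calls2_coded[:, ::2]
    gm2 = make_matrix(calls2_coded, alleles=alleles2, sample_prefix="B")
    merged = gio.merge_panels([gm1, gm2])
    pooled_g = (calls1.sum(axis=0) + calls2.sum(axis=0)) / (2 * 16.0)
    assert np.allclose(merged.allele_b_freq(), pooled_g)


# --------------------------------------------------------------------------
# Gene annotation
# --------------------------------------------------------------------------

def test_bed_coordinates_converted(tmp_path):
    (tmp_path / "g.bed").write_text("15\t3854062\t3860894\tPDGFD\n")
    ann = gio.read_gene_annotation(tmp_path / "g.bed", "BED")
    g = ann.genes[0]
    assert (g.start_bp, g.end_bp, g.gene_id) == (3854063, 3860894, "PDGFD")


def test_gff3_taken_one_based(tmp_path):
    (tmp_path / "g.gff3").write_text(
        "##gff-version 3\n15\tsrc\tgene\t100\t200\t.\t+\t.\tID=geneX\n"
        "15\tsrc\texon\t100\t150\t.\t+\t.\tID=exon1\n")
    ann = gio.read_gene_annotation(tmp_path / "g.gff3", "GFF3")
    assert len(ann.genes) == 1
    assert (ann.genes[0].start_bp, ann.genes[0].end_bp) == (100, 200)


def test_empty_annotation_ok(tmp_path):
    (tmp_path / "empty.bed").write_text("")
    assert gio.read_gene_annotation(tmp_path / "empty.bed", "BED").genes == []


def test_unknown_format_rejected(tmp_path):
    (tmp_path / "g.bed").write_text("1\t0\t10\tg\n")
    with pytest.raises(ValueError, match="unknown annotation format"):
        gio.read_gene_annotation(tmp_path / "g.bed", "GTF")
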
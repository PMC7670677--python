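"""Weir-Cockerham theta against an independent oracle, dDAF, percentile
flagging, consensus logic, the breed-consistency filter, and gene windows."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ovistail.model import GeneAnnotation, GeneRecord
from ovistail.polarize import PolarizedFrequencyTable
from ovistail.scan import (GroupComparison, annotate_candidates,
                           average_over_pairs, breed_consistency_filter,
                           consensus_across_comparisons, ddaf_pair,
                           fst_pair_all, fst_wc84, intersect_tests,
                           scan_comparison, top_percentile_flags)

from conftest import make_matrix, make_panel


# --------------------------------------------------------------------------
# Independent WC84 oracle: scalar, generic number of populations, written
# straight from the variance-component definitions on genotype COUNTS.
# --------------------------------------------------------------------------

def wc84_oracle(pop_counts):
    """theta from per-population genotype counts [(n_AA, n_Aa, n_aa), ...]."""
    r = len(pop_counts)
    n = [naa + nab + nbb for naa, nab, nbb in pop_counts]
    p = [(2 * naa + nab) / (2 * ni) for (naa, nab, nbb), ni in zip(pop_counts, n)]
    h = [nab / ni for (naa, nab, nbb), ni in zip(pop_counts, n)]
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni ** 2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar)
                               - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def _counts_to_matrix(counts1, counts2):
    """Two breeds' genotype counts -> GenotypeMatrix + panel (1 SNP)."""
    dosages = []
    for counts in (counts1, counts2):
        col = [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
        dosages.append(col)
    calls = np.array(dosages[0] + dosages[1], dtype=np.int8).reshape(-1, 1)
    gm = make_matrix(calls)
    n1 = sum(counts1)
    breed_of = {s: ("b1" if i < n1 else "b2") for i, s in enumerate(gm.samples)}
    panel = make_panel(gm, breed_of, tail_of={"b1": "fat", "b2": "thin"})
    return gm, panel


def test_fst_complete_fixation_is_one():
    gm, panel = _counts_to_matrix((0, 0, 10), (10, 0, 0))
    theta = fst_pair_all(gm, panel, "b1", "b2")[0]
    assert theta == 1.0


def test_fst_identical_counts_nonpositive():
    """Same genotype distribution in both breeds: theta <= 0 (no divergence)."""
    gm, panel = _counts_to_matrix((5, 10, 5), (5, 10, 5))
    theta = fst_pair_all(gm, panel, "b1", "b2")[0]
    oracle = wc84_oracle([(5, 10, 5), (5, 10, 5)])
    assert theta <= 0
    assert theta == pytest.approx(oracle, abs=1e-12)


def test_fst_monomorphic_both_undefined():
    gm, panel = _counts_to_matrix((10, 0, 0), (8, 0, 0))
    assert np.isnan(fst_pair_all(gm, panel, "b1", "b2")[0])


def test_fst_matches_oracle_200_random_configs():
    """Implementation equals the independently coded WC84 evaluation to 1e-12."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 200:
        c1 = tuple(rng.integers(0, 15, 3))
        c2 = tuple(rng.integers(0, 15, 3))
        if sum(c1) < 2 or sum(c2) < 2:
            continue
        expected = wc84_oracle([c1, c2])
        gm, panel = _counts_to_matrix(c1, c2)
        theta = fst_pair_all(gm, panel, "b1", "b2")[0]
        if np.isnan(expected):
            assert np.isnan(theta)
        else:
            assert theta == pytest.approx(expected, abs=1e-12)
        checked += 1


def test_fst_vectorized_handles_missing():
    """Missing calls only shrink the per-breed sample; theta matches the
    oracle computed on the called genotypes."""
    gm, panel = _counts_to_matrix((3, 4, 3), (6, 2, 2))
    calls = gm.calls.copy()
    calls[0, 0] = -1   # drop one AA genotype from breed 1
    gm2 = make_matrix(calls.reshape(-1, 1))
    gm2.samples = gm.samples
    theta = fst_pair_all(gm2, panel, "b1", "b2")[0]
    assert theta == pytest.approx(wc84_oracle([(2, 4, 3), (6, 2, 2)]), abs=1e-12)


# --------------------------------------------------------------------------
# dDAF and averaging
# --------------------------------------------------------------------------

def _freq_table(daf_dict):
    daf = pd.DataFrame(daf_dict)
    daf.index = [f"snp{i+1}" for i in range(len(daf))]
    n = daf.notna().astype(int) * 10
    anc = pd.Series("A", index=daf.index)
    src = pd.Series("outgroup_major", index=daf.index)
    return PolarizedFrequencyTable(daf, n, anc, src)


def test_ddaf_signed_values():
    ft = _freq_table({"fatb": [1.0, 0.3], "thinb": [0.0, 0.8]})
    assert ddaf_pair(ft, "fatb", "thinb", "snp1") == pytest.approx(1.0)
    assert ddaf_pair(ft, "fatb", "thinb", "snp2") == pytest.approx(-0.5)
    # antisymmetry under role swap
    assert ddaf_pair(ft, "thinb", "fatb", "snp2") == pytest.approx(0.5)


def test_average_over_pairs_mean_and_undefined():
    vals = np.array([[0.2, 0.2], [0.4, np.nan]])
    mean, n_used = average_over_pairs(vals)
    assert mean[0] == pytest.approx(0.3)
    assert mean[1] == pytest.approx(0.2)
    assert list(n_used) == [2, 1]
    all_nan, n0 = average_over_pairs(np.array([[np.nan], [np.nan]]))
    assert np.isnan(all_nan[0]) and n0[0] == 0


def test_top_percentile_exact_and_ties():
    vals = np.arange(1000, dtype=float)
    flags, cutoff = top_percentile_flags(vals, 0.01)
    assert flags.sum() == 10 and cutoff == 990.0
    tied = vals.copy()
    tied[[0, 1]] = 990.0            # 3-way tie at the cutoff
    flags2, _ = top_percentile_flags(tied, 0.01)
    assert flags2.sum() == 12


def test_top_percentile_all_equal_warns():
    with pytest.warns(UserWarning, match="all values equal"):
        flags, _ = top_percentile_flags(np.full(200, 0.5), 0.01)
    assert flags.all()


def test_intersect_bound():
    rng = np.random.default_rng(0)
    f1 = rng.random(500) < 0.05
    f2 = rng.random(500) < 0.05
    sel = intersect_tests(f1, f2)
    assert sel.sum() <= min(f1.sum(), f2.sum())
    assert not (sel & ~f1).any() and not (sel & ~f2).any()


# --------------------------------------------------------------------------
# Consensus and filters
# --------------------------------------------------------------------------

class _FakeScan:
    def __init__(self, ids):
        self.selected_snps = sorted(ids)


def test_consensus_requires_all_comparisons():
    scans = [_FakeScan({"a", "b", "c"}), _FakeScan({"b", "c"}),
             _FakeScan({"c", "d"})]
    assert consensus_across_comparisons(scans) == ["c"]
    # removing a comparison can only grow the consensus
    assert set(consensus_across_comparisons(scans)) <= \
        set(consensus_across_comparisons(scans[:2]))


def test_breed_consistency_printed_thresholds():
    """The 30% rule gives 'more than five' of 18 thin and 'more than four'
    of 14 fat breeds; removal/retention at the printed boundaries."""
    thin = [f"t{i}" for i in range(18)]
    fat = [f"f{i}" for i in range(14)]

    def snp_row(n_thin_high, n_fat_low):
        row = {}
        for i, b in enumerate(thin):
            row[b] = 0.9 if i < n_thin_high else 0.1
        for i, b in enumerate(fat):
            row[b] = 0.1 if i < n_fat_low else 0.9
        return row

    daf = pd.DataFrame([snp_row(6, 0), snp_row(5, 0), snp_row(0, 5),
                        snp_row(0, 4)],
                       index=["s_6thin", "s_5thin", "s_5fat", "s_4fat"])
    ft = PolarizedFrequencyTable(daf, daf.notna().astype(int),
                                 pd.Series("A", index=daf.index),
                                 pd.Series("outgroup_major", index=daf.index))
    retained, b_thin, b_fat = breed_consistency_filter(
        list(daf.index), ft, thin, fat)
    assert (b_thin, b_fat) == (5, 4)
    assert retained == ["s_5thin", "s_4fat"]


def test_breed_consistency_undefined_breed_excluded():
    thin = ["t0", "t1", "t2"]
    fat = ["f0", "f1", "f2"]
    daf = pd.DataFrame([{"t0": np.nan, "t1": 0.9, "t2": 0.9,
                         "f0": 0.9, "f1": 0.9, "f2": 0.9}], index=["s"])
    ft = PolarizedFrequencyTable(daf, daf.notna().astype(int),
                                 pd.Series("A", index=daf.index),
                                 pd.Series("outgroup_major", index=daf.index))
    # floor(0.3*3)=0: >0 thin breeds with DAF>0.5 removes; NaN breed ignored
    retained, b_thin, b_fat = breed_consistency_filter(["s"], ft, thin, fat)
    assert (b_thin, b_fat) == (0, 0)
    assert retained == []


# --------------------------------------------------------------------------
# Gene-window annotation
# --------------------------------------------------------------------------

def test_annotation_window_boundaries():
    calls = np.zeros((1, 1), dtype=np.int8)
    gm = make_matrix(calls, start_pos=1_000_000)
    ann = GeneAnnotation([
        GeneRecord("touching", "1", 1_140_000, 1_200_000),
        GeneRecord("just_out", "1", 1_150_001, 1_200_000),
        GeneRecord("containing", "1", 999_000, 1_001_000),
        GeneRecord("other_chrom", "2", 1_000_000, 1_001_000),
    ])
    cand = annotate_candidates(["snp1"], ["snp1"], gm, ann, window_bp=150_000)
    assert cand.genes_per_snp["snp1"] == ["containing", "touching"]
    assert cand.gene_union == ["containing", "touching"]


# --------------------------------------------------------------------------
# Full comparison scan on a constructed panel
# --------------------------------------------------------------------------

def test_scan_comparison_pair_enumeration_and_sign(small_sim):
    """All fat x thin pairs are used, and planting derived alleles in fat
    breeds yields positive averaged dDAF at the planted loci."""
    from ovistail.polarize import derived_allele_frequencies, infer_ancestral
    gm, panel, truth = small_sim
    gm_pol, src = infer_ancestral(gm, panel)
    resolved = (src != "unresolved").to_numpy().nonzero()[0]
    ft = derived_allele_frequencies(gm_pol.take_snps(resolved), panel,
                                    src.iloc[resolved])
    fat = panel.breeds_by_tail("fat")[:3]
    thin = panel.breeds_by_tail("thin")[:4]
    comp = GroupComparison("test", fat, thin)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scan_comparison(gm_pol, ft, panel, comp)
    assert res.table["n_pairs_ddaf"].max() == len(fat) * len(thin)
    planted = [s for s in truth.selected_snp_ids if s in res.table.index]
    assert (res.table.loc[planted, "ddaf_avg"] > 0.5).all()
    assert res.table.loc[planted, "positively_selected"].all()
    # order of breed-pair enumeration does not matter
    comp_r = GroupComparison("rev", fat[::-1], thin[::-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_r = scan_comparison(gm_pol, ft, panel, comp_r)
    assert np.allclose(res.table["fst_avg"], res_r.table["fst_avg"],
                       equal_nan=True)
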
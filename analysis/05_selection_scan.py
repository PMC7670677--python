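"""The core scan: per-breed-pair F_ST and dDAF, consensus candidate calling.

For each of the three group comparisons (Middle-East fat vs South-Asian
thin, Middle-East fat vs European thin, Chinese fat vs South-Asian thin)
both statistics are averaged over all fat x thin breed pairs, the top 1% of
each is flagged, dual-test hits are intersected across comparisons, and the
worldwide breed-consistency DAF filter is applied.  Reports how many of the
planted loci were recovered.  Writes results/scan/.
"""

from pathlib import Path

import pandas as pd

from ovistail import io as gio
from ovistail.polarize import derived_allele_frequencies, infer_ancestral
from ovistail.scan import (breed_consistency_filter,
                           consensus_across_comparisons, scan_comparison)
from ovistail.simulate import default_comparisons

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "results" / "qc"
    out = ROOT / "results" / "scan"
    out.mkdir(parents=True, exist_ok=True)
    gm = gio.read_plink_text(src / "qc.ped", src / "qc.map")
    panel = gio.read_breed_panel(src / "qc_panel.tsv")
    gm_pol, source = infer_ancestral(gm, panel)
    resolved = (source != "unresolved").to_numpy().nonzero()[0]
    ft = derived_allele_frequencies(gm_pol.take_snps(resolved), panel,
                                    source.iloc[resolved])

    scans = []
    for comp in default_comparisons(panel):
        res = scan_comparison(gm_pol, ft, panel, comp)
        res.table.to_csv(out / f"scan_{comp.name}.tsv", sep="\t")
        scans.append(res)
        print(f"{comp.name}: {len(res.selected_snps)} positively selected "
              f"SNPs (F_ST cutoff {res.fst_cutoff:.3f}, "
              f"dDAF cutoff {res.ddaf_cutoff:.3f})")

    consensus = consensus_across_comparisons(scans)
    filtered, b_thin, b_fat = breed_consistency_filter(
        consensus, ft, panel.breeds_by_tail("thin"),
        panel.breeds_by_tail("fat"))
    pd.Series(consensus, name="snp_id").to_csv(out / "consensus.tsv",
                                               sep="\t", index=False)
    pd.Series(filtered, name="snp_id").to_csv(out / "candidates.tsv",
                                              sep="\t", index=False)

    truth = pd.read_csv(ROOT / "results" / "panel" / "truth.snps.tsv", sep="\t")
    planted = set(truth.loc[truth["is_selected"], "snp_id"])
    print(f"consensus across all comparisons: {len(consensus)} loci; "
          f"{len(filtered)} survive the breed-consistency filter "
          f"(> {b_thin} thin with DAF>0.5 or > {b_fat} fat with DAF<0.5 "
          f"removes)")
    print(f"planted-locus recovery: {len(planted & set(filtered))}/"
          f"{len(planted)}; neutral false positives in consensus: "
          f"{len(set(consensus) - planted)}")


if __name__ == "__main__":
    main()
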
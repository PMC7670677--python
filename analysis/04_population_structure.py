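"""Structure sanity checks on the QC'd panel: LD pruning, PCA, breed tree.

Prunes to a quasi-independent SNP set (50-SNP window, step 5, r2 > 0.2),
runs a standardized-genotype PCA with per-breed outlier flags, and builds a
neighbor-joining tree over breeds from Nei's standard distance on the DAF
table.  Writes results/structure/.
"""

import pandas as pd
from pathlib import Path

from ovistail import io as gio
from ovistail.structure import nj_tree, prune_ld, run_pca

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "results" / "qc"
    out = ROOT / "results" / "structure"
    out.mkdir(parents=True, exist_ok=True)
    gm = gio.read_plink_text(src / "qc.ped", src / "qc.map")
    panel = gio.read_breed_panel(src / "qc_panel.tsv")

    pruned = prune_ld(gm)
    pca = run_pca(pruned, k=10, panel=panel)
    pca.to_tsv(out / "pca.tsv")

    daf = pd.read_csv(ROOT / "results" / "polarize" / "daf_table.tsv",
                      sep="\t", index_col="snp_id")
    freq_cols = daf.drop(columns=["ancestral", "polarization_source"])
    tree = nj_tree(freq_cols)
    tree.write(str(out / "breed_tree.nwk"))
    print(f"pruned {gm.n_snps} -> {pruned.n_snps} SNPs; "
          f"{int(pca.outlier.sum())} PCA outlier(s) flagged; "
          f"NJ tree over {len(freq_cols.columns)} breeds -> {out}")


if __name__ == "__main__":
    main()
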
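"""Polarize alleles against the wild outgroup and tabulate per-breed DAF.

The ancestral allele at each SNP is the outgroup majority allele; exact
ties are left unresolved and excluded from the scans.  Writes the SNP x
breed derived-allele-frequency table to results/polarize/daf_table.tsv.
"""

from pathlib import Path

from ovistail import io as gio
from ovistail.polarize import derived_allele_frequencies, infer_ancestral

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "results" / "qc"
    out = ROOT / "results" / "polarize"
    out.mkdir(parents=True, exist_ok=True)
    gm = gio.read_plink_text(src / "qc.ped", src / "qc.map")
    panel = gio.read_breed_panel(src / "qc_panel.tsv")
    gm_pol, source = infer_ancestral(gm, panel)
    resolved = (source != "unresolved").to_numpy().nonzero()[0]
    table = derived_allele_frequencies(gm_pol.take_snps(resolved), panel,
                                       source.iloc[resolved])
    table.to_tsv(out / "daf_table.tsv")
    print(f"polarized {len(resolved)}/{gm.n_snps} SNPs "
          f"({gm.n_snps - len(resolved)} unresolved ties dropped); "
          f"DAF table covers {len(table.breeds)} breeds")


if __name__ == "__main__":
    main()
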
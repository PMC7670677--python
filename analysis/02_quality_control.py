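"""Apply the array QC cascade to the simulated panel.

SNPs with call rate <= 90% or MAF <= 0.05 are removed, samples with call
rate below 90% are discarded, and one member of every within-breed pair
with PI-HAT > 0.3 is pruned.  Writes the filtered panel and a QC report to
results/qc/.
"""

from pathlib import Path

from ovistail import io as gio
from ovistail.qc import apply_qc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "results" / "panel"
    out = ROOT / "results" / "qc"
    out.mkdir(parents=True, exist_ok=True)
    gm = gio.read_plink_text(src / "panel.ped", src / "panel.map")
    panel = gio.read_breed_panel(src / "panel.tsv")
    gm_qc, report = apply_qc(gm, panel)
    gio.write_plink_text(gm_qc, out / "qc")
    gio.write_breed_panel(panel.restrict(gm_qc.samples), out / "qc_panel.tsv")
    (out / "qc_report.json").write_text(report.to_json())
    print(f"QC: {gm.n_snps} -> {gm_qc.n_snps} SNPs "
          f"({report.removed_snps_callrate} by call rate, "
          f"{report.removed_snps_maf} by MAF); "
          f"{gm.n_samples} -> {gm_qc.n_samples} samples "
          f"({len(report.removed_samples_ibd)} by relatedness)")


if __name__ == "__main__":
    main()
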
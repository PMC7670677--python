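"""Generate the synthetic worldwide breed panel the downstream scans consume.

Emulates a merged 50K-array study: 18 thin-tailed and 14 fat-tailed breeds
(25 samples each), 8 wild outgroup individuals, 20,000 neutral SNPs plus 20
planted loci where the derived allele is near-fixed only in fat-tailed
breeds.  Writes PED/MAP, the breed panel and the truth tables under
results/panel/.
"""

import argparse
from pathlib import Path

from ovistail import io as gio
from ovistail.simulate import SimulationParams, simulate_panel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    out = ROOT / "results" / "panel"
    out.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(seed=args.seed)
    gm, panel, truth = simulate_panel(params)
    gio.write_plink_text(gm, out / "panel")
    gio.write_breed_panel(panel, out / "panel.tsv")
    truth.write(out / "truth")
    n_sel = truth.snps["is_selected"].sum()
    print(f"simulated {gm.n_snps} SNPs ({n_sel} planted selected) x "
          f"{gm.n_samples} samples across "
          f"{len(panel.breeds_by_tail('thin'))} thin / "
          f"{len(panel.breeds_by_tail('fat'))} fat breeds -> {out}")


if __name__ == "__main__":
    main()
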
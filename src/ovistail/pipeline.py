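"""End-to-end orchestration: merge -> QC -> polarize -> scan -> filter -> annotate.

A single validated :class:`RunConfig` drives every stage; each stage writes
its tables plus a JSON manifest (parameters, input hashes, in/out counts)
into the output directory, and a mandatory seed plus stable sorts make
reruns byte-identical — empirical-percentile methods are brittle to
ordering, so determinism is part of the contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as gio
from . import qc as gqc
from .model import BreedPanel, GenotypeMatrix
from .polarize import (derived_allele_frequencies, infer_ancestral,
                       read_ancestral_table)
from .scan import (GroupComparison, annotate_candidates,
                   breed_consistency_filter, consensus_across_comparisons,
                   scan_comparison)
from .simulate import SimulationParams, default_comparisons, simulate_panel
from .structure import nj_tree, prune_ld, run_pca

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_KNOWN_KEYS = {
    "seed", "out_dir", "inputs", "simulate", "qc", "comparisons",
    "scan_quantile", "consistency_fraction", "annotation_window_bp",
    "structure", "region",
}
_QC_KEYS = {"max_missing_rate", "min_maf", "min_sample_call_rate",
            "pihat_threshold"}
_INPUT_KEYS = {"ped", "map", "panel", "ancestral_table", "annotation",
               "annotation_format"}
_STRUCTURE_KEYS = {"enabled", "window_snps", "step_snps", "r2_max", "pca_k",
                   "outlier_sd"}
_REGION_KEYS = {"vcf", "min_maf", "min_call_rate", "delta_threshold",
                "max_gap_bp", "min_snps", "delta_af_min", "daf_fat_min"}


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    qc: dict[str, float] = field(default_factory=dict)
    comparisons: list[dict[str, Any]] | str = "auto"
    scan_quantile: float = 0.01
    consistency_fraction: float = 0.30
    annotation_window_bp: int = 150_000
    structure: dict[str, Any] = field(default_factory=dict)
    region: dict[str, Any] | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in (("qc", _QC_KEYS), ("inputs", _INPUT_KEYS),
                             ("structure", _STRUCTURE_KEYS),
                             ("region", _REGION_KEYS)):
            sub = raw.get(key) or {}
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
        if "seed" not in raw:
            raise ConfigError("config requires an explicit seed")
        if "out_dir" not in raw:
            raise ConfigError("config requires out_dir")
        if "comparisons" not in raw and not raw.get("simulate"):
            raise ConfigError("config requires a comparisons block "
                              "(or simulate:, which supplies defaults)")
        cfg = cls(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS})
        if not cfg.simulate and not ({"ped", "map", "panel"} <= set(cfg.inputs)):
            raise ConfigError("either simulate: or inputs.{ped,map,panel} required")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest(out_dir: Path, stage: str, payload: dict[str, Any]) -> None:
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def _build_comparisons(cfg: RunConfig, panel: BreedPanel) -> list[GroupComparison]:
    if cfg.comparisons == "auto":
        return default_comparisons(panel)
    comps = []
    for entry in cfg.comparisons:
        missing = {"name", "fat_breeds", "thin_breeds"} - set(entry)
        if missing:
            raise ConfigError(f"comparison entry missing keys: {sorted(missing)}")
        comps.append(GroupComparison(entry["name"], list(entry["fat_breeds"]),
                                     list(entry["thin_breeds"])))
    if not comps:
        raise ConfigError("comparisons block is empty")
    return comps


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage in order and return the result directory."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- acquire data ------------------------------------------------------
    if cfg.simulate is not None:
        params = SimulationParams(**{**cfg.simulate, "seed": cfg.seed})
        gm, panel, truth = simulate_panel(params)
        truth.write(out_dir / "truth")
        gio.write_plink_text(gm, out_dir / "simulated")
        gio.write_breed_panel(panel, out_dir / "simulated_panel.tsv")
        _manifest(out_dir, "simulate", {"params": asdict(params),
                                        "n_snps": gm.n_snps,
                                        "n_samples": gm.n_samples})
    else:
        gm = gio.read_plink_text(cfg.inputs["ped"], cfg.inputs["map"])
        panel = gio.read_breed_panel(cfg.inputs["panel"])
        _manifest(out_dir, "load", {
            "hashes": {k: _hash_file(v) for k, v in cfg.inputs.items()
                       if k in ("ped", "map", "panel")},
            "n_snps": gm.n_snps, "n_samples": gm.n_samples})
    panel.validate_against(gm)

    # --- QC ---------------------------------------------------------------
    gm_qc, report = gqc.apply_qc(gm, panel, **cfg.qc)
    panel_qc = panel.restrict(gm_qc.samples)
    with open(out_dir / "qc_report.json", "w") as fh:
        fh.write(report.to_json())
    _manifest(out_dir, "qc", {"in_snps": gm.n_snps, "out_snps": gm_qc.n_snps,
                              "in_samples": gm.n_samples,
                              "out_samples": gm_qc.n_samples,
                              "params": cfg.qc})

    # --- polarization ------------------------------------------------------
    provided = (read_ancestral_table(cfg.inputs["ancestral_table"])
                if cfg.inputs.get("ancestral_table") else None)
    gm_pol, source = infer_ancestral(gm_qc, panel_qc, provided)
    resolved = source != "unresolved"
    freq_table = derived_allele_frequencies(
        gm_pol.take_snps(resolved.to_numpy().nonzero()[0]), panel_qc,
        source[resolved])
    freq_table.to_tsv(out_dir / "daf_table.tsv")
    _manifest(out_dir, "polarize", {"in_snps": gm_qc.n_snps,
                                    "resolved_snps": int(resolved.sum())})

    # --- optional structure ------------------------------------------------
    struct = dict(cfg.structure)
    if struct.pop("enabled", False):
        pruned = prune_ld(gm_pol,
                          window_snps=struct.get("window_snps", 50),
                          step_snps=struct.get("step_snps", 5),
                          r2_max=struct.get("r2_max", 0.2))
        pca = run_pca(pruned, k=struct.get("pca_k", 10), panel=panel_qc,
                      outlier_sd=struct.get("outlier_sd", 3.0))
        pca.to_tsv(out_dir / "pca.tsv")
        tree = nj_tree(freq_table.daf)
        tree.write(str(out_dir / "breed_tree.nwk"))
        _manifest(out_dir, "structure", {"pruned_snps": pruned.n_snps,
                                         "n_outliers": int(pca.outlier.sum())})

    # --- scans -------------------------------------------------------------
    comparisons = _build_comparisons(cfg, panel_qc)
    scans = []
    for comp in comparisons:
        res = scan_comparison(gm_pol, freq_table, panel_qc, comp,
                              cfg.scan_quantile)
        res.table.to_csv(out_dir / f"scan_{comp.name}.tsv", sep="\t")
        scans.append(res)
        _manifest(out_dir, f"scan_{comp.name}", {
            "fst_cutoff": res.fst_cutoff, "ddaf_cutoff": res.ddaf_cutoff,
            "n_selected": len(res.selected_snps)})

    # --- consensus + consistency filter ------------------------------------
    consensus = consensus_across_comparisons(scans)
    if not consensus:
        log.info("run_pipeline: empty consensus set (valid outcome)")
    thin_all = panel_qc.breeds_by_tail("thin")
    fat_all = panel_qc.breeds_by_tail("fat")
    filtered, b_thin, b_fat = breed_consistency_filter(
        consensus, freq_table, thin_all, fat_all, cfg.consistency_fraction)
    _manifest(out_dir, "consensus", {
        "n_consensus": len(consensus), "n_post_filter": len(filtered),
        "b_thin": b_thin, "b_fat": b_fat})

    # --- annotation --------------------------------------------------------
    genes_per_snp: dict[str, list[str]] = {}
    if cfg.inputs.get("annotation"):
        ann = gio.read_gene_annotation(cfg.inputs["annotation"],
                                       cfg.inputs.get("annotation_format", "BED"))
        cand = annotate_candidates(filtered, consensus, gm_pol, ann,
                                   cfg.annotation_window_bp)
        genes_per_snp = cand.genes_per_snp

    pos = {s.snp_id: s for s in gm_pol.snps}
    with open(out_dir / "candidates.tsv", "w") as fh:
        fh.write("snp_id\tchrom\tpos_bp\tin_consensus\tpost_filter\tgenes\n")
        for snp_id in consensus:
            s = pos[snp_id]
            fh.write(f"{snp_id}\t{s.chrom}\t{s.pos_bp}\t1\t"
                     f"{int(snp_id in set(filtered))}\t"
                     f"{','.join(genes_per_snp.get(snp_id, []))}\n")

    # --- optional region analysis ------------------------------------------
    if cfg.region and cfg.region.get("vcf"):
        from .region import (detect_elevated_region, extract_haplotype_matrix,
                             group_delta_af, select_high_confidence_snps,
                             write_haplotype_tsv)
        rcfg = dict(cfg.region)
        gm_seq, haps = gio.read_vcf(rcfg.pop("vcf"),
                                    min_maf=rcfg.pop("min_maf", 0.05),
                                    min_call_rate=rcfg.pop("min_call_rate", 0.90))
        seq_panel = panel_qc if set(gm_seq.samples) <= set(panel_qc.sample_breed) \
            else panel
        table = group_delta_af(gm_seq, seq_panel)
        table.to_csv(out_dir / "region_delta_af.tsv", sep="\t")
        regions = detect_elevated_region(
            table, delta_threshold=rcfg.pop("delta_threshold", 0.6),
            max_gap_bp=rcfg.pop("max_gap_bp", 5_000),
            min_snps=rcfg.pop("min_snps", 5))
        with open(out_dir / "regions.tsv", "w") as fh:
            fh.write("chrom\tstart_bp\tend_bp\tlength_bp\tn_snps\n")
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t"
                         f"{r.length_bp}\t{r.n_above_threshold}\n")
        for i, r in enumerate(regions):
            if haps is not None:
                extract_haplotype_matrix(gm_seq, haps, r, seq_panel)
                write_haplotype_tsv(r, out_dir / f"region_{i+1}_haplotypes.tsv")
        hi = select_high_confidence_snps(
            table, delta_af_min=rcfg.pop("delta_af_min", 0.8),
            daf_fat_min=rcfg.pop("daf_fat_min", 0.8))
        hi.to_csv(out_dir / "high_confidence_snps.tsv", sep="\t")
        _manifest(out_dir, "region", {"n_variants": len(table),
                                      "n_regions": len(regions),
                                      "n_high_confidence": len(hi)})
    return out_dir
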
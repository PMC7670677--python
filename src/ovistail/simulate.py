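"""Synthetic multi-breed genotype panels and regional haplotypes.

The generator emulates the data regime of a worldwide sheep-breed array
study: many breeds in two tail-type groups diverged by drift from a shared
ancestral allele-frequency distribution (Balding-Nichols Beta model), a
small set of planted loci with high derived-allele frequency only in the
fat-tailed group, a wild outgroup carrying mostly ancestral alleles, plus
optional missingness and cryptic relatedness.  Defaults mirror the study
design the scan targets: 18 thin-tailed breeds (5 South Asian, 6 European,
3 American, 4 Nepalese), 14 fat-tailed breeds (6 Middle Eastern, 4 African,
4 Chinese), 25 samples per breed and 8 outgroup individuals.

No linkage disequilibrium is simulated among array SNPs: the scan statistics
are per-SNP, and frequency-level Balding-Nichols draws reproduce exactly the
between-breed differentiation they consume, with closed-form expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MISSING, BreedInfo, BreedPanel, GenotypeMatrix, SnpRecord
from .scan import GroupComparison

ANCESTRAL, DERIVED = "A", "G"

THIN_REGIONS = [("south_asia", 5), ("europe", 6), ("americas", 3), ("nepal", 4)]
FAT_REGIONS = [("middle_east", 6), ("africa", 4), ("china", 4)]


@dataclass
class SimulationParams:
    n_snps_neutral: int = 20_000
    n_snps_selected: int = 20
    n_thin_breeds: int = 18
    n_fat_breeds: int = 14
    n_outgroup_samples: int = 8
    samples_per_breed: int = 25
    drift_f: float = 0.1
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    selected_mean_fat: float = 0.9
    selected_mean_thin: float = 0.1
    selected_concentration: float = 20.0
    missing_rate: float = 0.02
    n_related_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.drift_f < 1:
            raise ValueError("drift_f must lie in (0, 1)")
        for name in ("ancestral_freq_low", "ancestral_freq_high",
                     "selected_mean_fat", "selected_mean_thin", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ancestral_freq_low > self.ancestral_freq_high:
            raise ValueError("ancestral_freq_low > ancestral_freq_high")
        for name in ("n_snps_neutral", "n_thin_breeds", "n_fat_breeds",
                     "samples_per_breed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_snps_selected < 0 or self.n_outgroup_samples < 0:
            raise ValueError("counts must be non-negative")
        if self.selected_concentration <= 0:
            raise ValueError("selected_concentration must be positive")
        if self.n_related_pairs < 0:
            raise ValueError("n_related_pairs must be non-negative")


@dataclass
class TruthTable:
    snps: pd.DataFrame      # snp_id, is_selected, ancestral, mean_fat, mean_thin
    samples: pd.DataFrame   # sample_id, breed, role

    @property
    def selected_snp_ids(self) -> list[str]:
        return sorted(self.snps.loc[self.snps["is_selected"], "snp_id"])

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.snps.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)
        self.samples.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index=False)


def _allocate_regions(n: int, template: list[tuple[str, int]]) -> list[str]:
    """Distribute n breeds over region labels proportionally to the template."""
    total = sum(w for _, w in template)
    if n == total:
        return [name for name, w in template for _ in range(w)]
    raw = [(name, n * w / total) for name, w in template]
    counts = {name: int(x) for name, x in raw}
    rem = sorted(raw, key=lambda t: t[1] - int(t[1]), reverse=True)
    short = n - sum(counts.values())
    for name, _ in rem[:short]:
        counts[name] += 1
    return [name for name, w in template for _ in range(counts[name])]


def simulate_panel(params: SimulationParams
                   ) -> tuple[GenotypeMatrix, BreedPanel, TruthTable]:
    """Draw a full array panel under the Balding-Nichols breed model.

    Neutral SNP j: ancestral derived frequency p_j ~ Uniform(low, high); each
    breed's frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F).  Planted (selected)
    SNPs instead center fat breeds at ``selected_mean_fat`` and thin breeds
    at ``selected_mean_thin`` with the given Beta concentration.  Outgroup
    genotypes are drawn at derived frequency min(p, 0.05) so that majority
    polarization recovers the truth (while still exercising tie paths).
    Genotypes are Binomial(2, p_breed); missingness is i.i.d.; related pairs
    replace one breed member by a gamete-dropped child of another.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_snps = params.n_snps_neutral + params.n_snps_selected

    # interleave planted loci at random map positions
    is_selected = np.zeros(n_snps, dtype=bool)
    sel_idx = rng.choice(n_snps, size=params.n_snps_selected, replace=False)
    is_selected[sel_idx] = True

    p_anc = rng.uniform(params.ancestral_freq_low, params.ancestral_freq_high,
                        size=n_snps)

    thin_regions = _allocate_regions(params.n_thin_breeds, THIN_REGIONS)
    fat_regions = _allocate_regions(params.n_fat_breeds, FAT_REGIONS)
    breed_names, breed_infos = [], {}
    for i, reg in enumerate(thin_regions):
        name = f"thin_{i+1:02d}"
        breed_names.append(name)
        breed_infos[name] = BreedInfo("thin", reg)
    for i, reg in enumerate(fat_regions):
        name = f"fat_{i+1:02d}"
        breed_names.append(name)
        breed_infos[name] = BreedInfo("fat", reg)
    breed_infos["outgroup"] = BreedInfo("outgroup", "wild")

    f = params.drift_f
    shape = (1 - f) / f
    c = params.selected_concentration
    freq_rows, mean_fat_col, mean_thin_col = {}, [], []
    for j in range(n_snps):
        mean_fat_col.append(params.selected_mean_fat if is_selected[j] else p_anc[j])
        mean_thin_col.append(params.selected_mean_thin if is_selected[j] else p_anc[j])
    mean_fat_col = np.array(mean_fat_col)
    mean_thin_col = np.array(mean_thin_col)

    for name in breed_names:
        is_fat = breed_infos[name].tail_type == "fat"
        mean = mean_fat_col if is_fat else mean_thin_col
        conc = np.where(is_selected, c, shape)
        a = np.clip(mean * conc, 1e-6, None)
        b = np.clip((1 - mean) * conc, 1e-6, None)
        freq_rows[name] = rng.beta(a, b)

    samples, breed_of, roles, calls_rows = [], {}, [], []
    for name in breed_names:
        p_breed = freq_rows[name]
        geno = rng.binomial(2, p_breed,
                            size=(params.samples_per_breed, n_snps)).astype(np.int8)
        ids = [f"{name}_s{k+1:03d}" for k in range(params.samples_per_breed)]
        for sid in ids:
            breed_of[sid] = name
            roles.append((sid, name, "independent"))
        samples.extend(ids)
        calls_rows.append(geno)

    calls = np.concatenate(calls_rows, axis=0)
    roles = {sid: role for sid, _, role in roles}

    # cryptic relatedness: child = one gamete from a stored parent + one from
    # the breed frequency; the child replaces its breed's last sample
    for k in range(params.n_related_pairs):
        breed = breed_names[k % len(breed_names)]
        members = [i for i, s in enumerate(samples) if breed_of[s] == breed]
        if len(members) < 2:
            continue
        parent_i, child_i = members[0], members[-1]
        parent = calls[parent_i]
        from_parent = np.where(parent == 1, rng.integers(0, 2, n_snps), parent // 2)
        from_pop = rng.binomial(1, freq_rows[breed])
        calls[child_i] = (from_parent + from_pop).astype(np.int8)
        roles[samples[child_i]] = f"child_of:{samples[parent_i]}"

    # outgroup at low derived frequency
    if params.n_outgroup_samples:
        p_out = np.minimum(p_anc, 0.05)
        geno = rng.binomial(2, p_out,
                            size=(params.n_outgroup_samples, n_snps)).astype(np.int8)
        ids = [f"outgroup_s{k+1:03d}" for k in range(params.n_outgroup_samples)]
        for sid in ids:
            breed_of[sid] = "outgroup"
            roles[sid] = "outgroup"
        samples.extend(ids)
        calls = np.concatenate([calls, geno], axis=0)

    if params.missing_rate > 0:
        mask = rng.random(calls.shape) < params.missing_rate
        calls[mask] = MISSING

    snps = []
    for j in range(n_snps):
        chrom = str(j % 26 + 1)
        pos = (j // 26 + 1) * 5_000
        snps.append(SnpRecord(f"snp{j+1:06d}", chrom, pos, ANCESTRAL, DERIVED,
                              ancestral="unknown"))
    gm = GenotypeMatrix(snps, samples, calls)
    panel = BreedPanel(breed_of, breed_infos)

    truth_snps = pd.DataFrame({
        "snp_id": [s.snp_id for s in snps],
        "chrom": [s.chrom for s in snps],
        "pos_bp": [s.pos_bp for s in snps],
        "is_selected": is_selected,
        "ancestral": ANCESTRAL,
        "mean_fat": mean_fat_col,
        "mean_thin": mean_thin_col,
    })
    truth_samples = pd.DataFrame(
        [(s, breed_of[s], roles[s]) for s in samples],
        columns=["sample_id", "breed", "role"])
    return gm, panel, TruthTable(truth_snps, truth_samples)


def default_comparisons(panel: BreedPanel) -> list[GroupComparison]:
    """The three analogue group comparisons: Middle-East fat vs South-Asian
    thin, Middle-East fat vs European thin, Chinese fat vs South-Asian thin."""
    def by_region(tail: str, region: str) -> list[str]:
        return sorted(b for b, info in panel.breeds.items()
                      if info.tail_type == tail and info.region == region)

    mef = by_region("fat", "middle_east")
    chf = by_region("fat", "china")
    sat = by_region("thin", "south_asia")
    eut = by_region("thin", "europe")
    return [
        GroupComparison("MEF_vs_SAT", mef, sat),
        GroupComparison("MEF_vs_EUT", mef, eut),
        GroupComparison("CHF_vs_SAT", chf, sat),
    ]


# --------------------------------------------------------------------------
# Regional phased haplotypes
# --------------------------------------------------------------------------

def simulate_region_haplotypes(n_fat: int, n_thin: int, n_sites: int,
                               span_bp: int, divergent_block: list[int],
                               seed: int, out_dir: str | Path,
                               chrom: str = "15", start_bp: int = 3_854_063,
                               block_start_bp: int | None = None,
                               block_end_bp: int | None = None,
                               p_background_fat: float = 0.9,
                               p_background_thin: float = 0.1,
                               ) -> tuple[Path, BreedPanel, dict]:
    """Write a phased VCF of a candidate region with a divergent haplotype block.

    ``divergent_block`` lists 1-based site indices (after position sorting)
    that differ between the two haplotype backgrounds; fat haplotypes carry
    the alternative background with probability ``p_background_fat``, thin
    with ``p_background_thin``.  Non-block sites are i.i.d. at shared
    frequencies.  When ``block_start_bp``/``block_end_bp`` are given, the
    first and last block sites are pinned to those coordinates so the
    planted span is exact.

    Returns (vcf_path, panel, truth) where truth records the planted block
    span and per-haplotype background assignments.
    """
    if n_sites > span_bp:
        raise ValueError(f"n_sites {n_sites} exceeds span_bp {span_bp}")
    block = sorted(divergent_block)
    if block and not (1 <= block[0] and block[-1] <= n_sites):
        raise ValueError("divergent_block indices must lie in [1, n_sites]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    positions = np.sort(rng.choice(span_bp, size=n_sites, replace=False)) + start_bp
    if len(block) >= 2 and block_start_bp is not None and block_end_bp is not None:
        # pin block sites inside the requested sub-interval, endpoints included
        inner = np.sort(rng.choice(
            np.arange(block_start_bp + 1, block_end_bp),
            size=len(block) - 2, replace=False))
        block_pos = np.concatenate([[block_start_bp], inner, [block_end_bp]])
        non_block_idx = [i for i in range(n_sites) if (i + 1) not in set(block)]
        pool = np.setdiff1d(np.arange(start_bp, start_bp + span_bp), block_pos)
        other = np.sort(rng.choice(pool, size=len(non_block_idx), replace=False))
        positions = np.empty(n_sites, dtype=int)
        for k, i in enumerate(sorted(set(block))):
            positions[i - 1] = block_pos[k]
        for k, i in enumerate(non_block_idx):
            positions[i] = other[k]
        order = np.argsort(positions)
        rank = {old: new for new, old in enumerate(order)}
        positions = positions[order]
        block = sorted(rank[i - 1] + 1 for i in block)

    in_block = np.zeros(n_sites, dtype=bool)
    for i in block:
        in_block[i - 1] = True

    n_hap_fat, n_hap_thin = 2 * n_fat, 2 * n_thin
    bg_fat = rng.random(n_hap_fat) < p_background_fat
    bg_thin = rng.random(n_hap_thin) < p_background_thin
    backgrounds = np.concatenate([bg_fat, bg_thin])      # True = alt background

    shared_p = rng.uniform(0.05, 0.95, size=n_sites)
    haps = (rng.random((n_hap_fat + n_hap_thin, n_sites))
            < shared_p[None, :]).astype(np.int8)
    # every emitted site must be polymorphic (it is a discovered variant):
    # redraw columns fixed for one allele by chance
    for j in np.flatnonzero(~in_block):
        while haps[:, j].min() == haps[:, j].max():
            haps[:, j] = (rng.random(haps.shape[0]) < shared_p[j]).astype(np.int8)
    haps[:, in_block] = backgrounds[:, None].astype(np.int8)

    sample_ids = ([f"fat_{i+1:03d}" for i in range(n_fat)]
                  + [f"thin_{i+1:03d}" for i in range(n_thin)])
    vcf_path = out_dir / "region.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(n_sites):
            gts = [f"{haps[2*i, j]}|{haps[2*i+1, j]}"
                   for i in range(n_fat + n_thin)]
            fh.write(f"{chrom}\t{positions[j]}\tvar{j+1:04d}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")

    breed_of = {s: ("fat_pool" if s.startswith("fat") else "thin_pool")
                for s in sample_ids}
    panel = BreedPanel(breed_of, {"fat_pool": BreedInfo("fat", "pooled"),
                                  "thin_pool": BreedInfo("thin", "pooled")})
    truth = {
        "positions": positions.tolist(),
        "block_sites": block,
        "block_start_bp": int(positions[block[0] - 1]) if block else None,
        "block_end_bp": int(positions[block[-1] - 1]) if block else None,
        "backgrounds": backgrounds.astype(int).tolist(),
    }
    return vcf_path, panel, truth
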
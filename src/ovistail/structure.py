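"""Population-structure utilities: LD pruning, PCA, and a breed tree.

These reproduce the sanity analyses run on the merged panel before the
selection scan: a pruned quasi-independent SNP set, a standardized-genotype
PCA with per-breed outlier flagging, and a neighbor-joining tree over breeds
built from Nei's standard genetic distance on allele frequencies.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .model import MISSING, BreedPanel, GenotypeMatrix


def prune_ld(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.2) -> GenotypeMatrix:
    """Sliding-window greedy LD pruning on genotype correlation.

    Within each window, while any retained pair has r^2 > ``r2_max``, the
    member with the lower MAF is dropped (tie broken toward the later map
    position).  Missing dosages are mean-imputed for the correlation.
    """
    n = gm.n_snps
    if n == 0:
        return gm
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    col_mean = np.nan_to_num(col_mean)
    imputed = np.where(np.isnan(calls), col_mean, calls)
    maf = np.nan_to_num(gm.maf(), nan=0.0)
    keep = np.ones(n, dtype=bool)

    for start in range(0, n, step_snps):
        idx = np.flatnonzero(keep[start:start + window_snps]) + start
        if len(idx) < 2:
            continue
        block = imputed[:, idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(block, rowvar=False)
        r2 = np.nan_to_num(r ** 2)
        np.fill_diagonal(r2, 0.0)
        alive = np.ones(len(idx), dtype=bool)
        while True:
            sub = np.where(np.outer(alive, alive), r2, 0.0)
            ii, jj = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[ii, jj] <= r2_max:
                break
            gi, gj = idx[ii], idx[jj]
            if maf[gi] < maf[gj]:
                victim = ii
            elif maf[gj] < maf[gi]:
                victim = jj
            else:  # tie: drop the later map position
                victim = ii if gm.snps[gi].pos_bp >= gm.snps[gj].pos_bp else jj
            alive[victim] = False
            keep[idx[victim]] = False
    return gm.take_snps(np.flatnonzero(keep))


@dataclass
class PcaResult:
    samples: list[str]
    coords: np.ndarray          # n_samples x k
    eigenvalues: np.ndarray     # k, non-increasing
    outlier: np.ndarray         # n_samples bool

    def to_tsv(self, path) -> None:
        k = self.coords.shape[1]
        df = pd.DataFrame(self.coords, index=self.samples,
                          columns=[f"PC{i+1}" for i in range(k)])
        df["outlier_flag"] = self.outlier.astype(int)
        df.to_csv(path, sep="\t", index_label="sample_id")


def run_pca(gm: GenotypeMatrix, k: int = 10,
            panel: BreedPanel | None = None,
            outlier_sd: float = 3.0) -> PcaResult:
    """PCA of the standardized-genotype relationship matrix.

    Missing dosages are mean-imputed; each SNP is centered by its mean
    dosage 2p and scaled by sqrt(2p(1-p)) (GCTA convention).  When a breed
    panel is supplied, a sample is flagged as an outlier if it sits farther
    than ``outlier_sd`` robust standard deviations (1.4826 * MAD) from its
    own breed's centroid on any of the top components.
    """
    n, m = gm.n_samples, gm.n_snps
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    mean = np.nan_to_num(np.nanmean(calls, axis=0))
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    scale[scale == 0] = 1.0
    x = (np.where(np.isnan(calls), mean, calls) - mean) / scale

    rank = min(n, m)
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; reduced", stacklevel=2)
        k = max(rank, 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = (u[:, :k] * s[:k]) / np.sqrt(max(m, 1))
    eigenvalues = (s[:k] ** 2) / max(m, 1)

    outlier = np.zeros(n, dtype=bool)
    if panel is not None and n:
        breeds = np.array([panel.breed_of(s) for s in gm.samples])
        span = np.abs(coords).max() or 1.0
        for breed in np.unique(breeds):
            rows = np.flatnonzero(breeds == breed)
            block = coords[rows]
            center = np.median(block, axis=0)
            mad = np.median(np.abs(block - center), axis=0)
            robust_sd = np.maximum(1.4826 * mad, 1e-9 * span)
            z = np.abs(block - center) / robust_sd
            outlier[rows] = (z > outlier_sd).any(axis=1)
    return PcaResult(list(gm.samples), coords, eigenvalues, outlier)


def nei_distance(freqs: pd.DataFrame) -> pd.DataFrame:
    """Nei's standard genetic distance between breeds.

    ``freqs``: SNP x breed table of one allele's frequency (NaN = undefined).
    For each pair, loci defined in both breeds contribute
    J_xy = mean(p_x p_y + q_x q_y); D = -ln(J_xy / sqrt(J_x J_y)).
    """
    breeds = list(freqs.columns)
    d = pd.DataFrame(0.0, index=breeds, columns=breeds)
    for i, x in enumerate(breeds):
        for y in breeds[i + 1:]:
            px, py = freqs[x].to_numpy(float), freqs[y].to_numpy(float)
            ok = ~(np.isnan(px) | np.isnan(py))
            if not ok.any():
                raise ValueError(f"no shared defined loci between {x} and {y}")
            px, py = px[ok], py[ok]
            qx, qy = 1 - px, 1 - py
            jxy = np.mean(px * py + qx * qy)
            jx = np.mean(px ** 2 + qx ** 2)
            jy = np.mean(py ** 2 + qy ** 2)
            val = -np.log(jxy / np.sqrt(jx * jy)) if jxy > 0 else np.inf
            d.loc[x, y] = d.loc[y, x] = max(val, 0.0)
    return d


def nj_from_distances(dmat: pd.DataFrame) -> TreeNode:
    """Canonical neighbor-joining on a symmetric distance table.

    Negative branch lengths are clamped to zero.  Two taxa give a single
    edge; ties (zero distances) resolve in id order.
    """
    breeds = sorted(dmat.columns)
    if len(breeds) < 2:
        raise ValueError("need at least two breeds for a tree")
    if len(breeds) == 2:
        a, b = breeds
        half = dmat.loc[a, b] / 2.0
        return TreeNode.read(_io.StringIO(f"({a}:{half},{b}:{half});"))
    dm = DistanceMatrix(dmat.loc[breeds, breeds].to_numpy(float), ids=breeds)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def nj_tree(freqs: pd.DataFrame) -> TreeNode:
    """Neighbor-joining breed tree from Nei's standard distance on a
    SNP x breed allele-frequency table; Newick-serializable."""
    return nj_from_distances(nei_distance(freqs))
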
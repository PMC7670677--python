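import numpy as np
import pytest

from ovistail.model import BreedInfo, BreedPanel, GenotypeMatrix, SnpRecord
from ovistail.simulate import SimulationParams, simulate_panel


def make_matrix(calls, alleles=None, chrom="1", start_pos=100, spacing=100,
                sample_prefix="S", ancestral=None):
    """Build a GenotypeMatrix from a dosage array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = []
    for j in range(m):
        a, b = alleles[j] if alleles else ("A", "G")
        anc = ancestral[j] if ancestral else "unknown"
        snps.append(SnpRecord(f"snp{j+1}", chrom, start_pos + j * spacing,
                              a, b, ancestral=anc))
    samples = [f"{sample_prefix}{i+1}" for i in range(n)]
    return GenotypeMatrix(snps, samples, calls)


def make_panel(gm, breed_of=None, tail_of=None):
    """Panel assigning every sample of gm to a breed (default: one per sample)."""
    breed_of = breed_of or {s: f"b_{s}" for s in gm.samples}
    breeds = {}
    for b in set(breed_of.values()):
        tail = (tail_of or {}).get(b, "thin")
        breeds[b] = BreedInfo(tail)
    return BreedPanel(dict(breed_of), breeds)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic panel shared across tests."""
    params = SimulationParams(n_snps_neutral=2_000, n_snps_selected=10,
                              samples_per_breed=12, missing_rate=0.02, seed=11)
    return simulate_panel(params)
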
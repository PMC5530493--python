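import numpy as np
import pytest

from chipdesign.catalog import AnnotationVector, Catalog, GenotypeMatrix, VariantSite


def make_sites(positions, chrom="1", ref="A", alt="G", quals=None, groups=None,
               vqslods=None):
    """Build a Catalog from bare positions (1-based), optional per-site extras."""
    sites = []
    for i, pos in enumerate(positions):
        sites.append(VariantSite(
            chrom=chrom, pos=int(pos), ref=ref, alt=alt,
            qual=None if quals is None else float(quals[i]),
            groups_observed=frozenset() if groups is None else frozenset(groups[i]),
            vqslod=None if vqslods is None else float(vqslods[i]),
        ))
    return Catalog(sites)


def make_gm(dosage, positions=None, chrom="1", samples=None):
    """GenotypeMatrix from a (sites x samples) list/array; -1 = missing."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if positions is None:
        positions = range(1, n_sites + 1)
    keys = [(chrom, int(p), "A", "G") for p in positions]
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n_samples)]
    return GenotypeMatrix(keys, list(samples), dosage)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multi-breed simulated cohort shared across tests."""
    from chipdesign.simulate import SimConfig, simulate_population
    cfg = SimConfig(seed=11, n_sites=400, n_breeds=3, samples_per_breed=6)
    return simulate_population(cfg)
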
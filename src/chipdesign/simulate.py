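"""Seeded multi-breed diploid population simulator.

Generates everything the design pipeline consumes, with no external data:
haplotypes with block LD structure and breed differentiation, per-site
read-level annotations that differ between true and artifactual sites,
array genotyping error and missingness, and probe-design recommendation
classes.

Haplotypes are built by mosaic copying: each simulated haplotype walks along
the chromosome copying from a shared pool of base haplotypes, switching
template with a probability proportional to physical distance (a
Li-Stephens-flavoured resampling).  Low recombination yields long shared
blocks and hence high local LD; breed differentiation comes from each breed
drawing its templates from a drift-dependent subsample of the base pool.
Artifactual ("false") sites carry no haplotype structure: their alleles are
independent low-frequency noise, and their annotations are drawn from
shifted distributions (lower QD, higher FS, displaced rank sums) so that
annotation-based recalibration can separate the classes while the QUAL
score alone separates them only weakly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import (ANNOTATIONS, AnnotationVector, BreedGroupMap, Catalog,
                      GenomeLayout, GenotypeMatrix, VariantSite)
from .windows import ProbeRecommendation, RecClass


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults describe a desk-scale multi-breed cohort: 8 breeds of 8
    diploids each on two 1 Mb chromosomes, 2000 segregating sites drawn
    from a 24-haplotype ancestral pool, moderate breed drift and a
    recombination rate giving multi-kb LD blocks.  Array noise defaults
    (0.5% genotype error, 2% missingness) match the high cross-platform
    concordance regimes seen on real arrays.
    """

    seed: int = 0
    n_breeds: int = 8
    samples_per_breed: int = 8
    n_sites: int = 2000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 1_000_000, "2": 1_000_000})
    base_pool_size: int = 24
    n_founders: int = 4               # deep founders behind the base pool
    founder_switch_rate: float = 2e-6  # per bp, fixes the ancestral block scale
    pool_mutation_rate: float = 0.01
    drift: float = 0.3
    recombination_rate: float = 1e-6  # per bp per copying step
    false_site_fraction: float = 0.05
    # annotation distributions: (true-class mean, false-class mean, sd)
    ann_params: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "DP": (1500.0, 1400.0, 300.0),
        "QD": (20.0, 8.0, 5.0),
        "FS": (3.0, 12.0, 4.0),
        "MQRankSum": (0.0, -2.5, 1.2),
        "ReadPosRankSum": (0.0, -2.0, 1.2),
    })
    qual_class_shift: float = 1.0  # shift (in sd units) of log-QUAL between classes
    ranksum_missing_rate: float = 0.05
    array_error_rate: float = 0.005
    array_missing_rate: float = 0.02
    n_calling_groups: int = 8

    def __post_init__(self) -> None:
        for name in ("drift", "recombination_rate", "false_site_fraction",
                     "array_error_rate", "array_missing_rate", "ranksum_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_pool_size < 2:
            raise ValueError("base haplotype pool must contain at least 2 haplotypes")


@dataclass
class SimResult:
    """Everything the simulator knows about the generated cohort."""

    catalog: Catalog
    genotypes: GenotypeMatrix          # with phased haplotypes
    group_map: BreedGroupMap
    layout: GenomeLayout
    truth_is_true_site: np.ndarray     # bool per site; False = artifactual
    breed_haplotypes: dict[str, np.ndarray]  # breed -> (n_sites, 2*n) haplotype panel


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    chroms = list(cfg.chrom_lengths)
    total = sum(cfg.chrom_lengths.values())
    per_chrom = {c: max(1, round(cfg.n_sites * cfg.chrom_lengths[c] / total)) for c in chroms}
    # adjust rounding drift on the last chromosome
    per_chrom[chroms[-1]] += cfg.n_sites - sum(per_chrom.values())
    out = []
    for c in chroms:
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_lengths[c] + 1),
                                 size=per_chrom[c], replace=False))
        out.extend((c, int(p)) for p in pos)
    return out


def _mosaic_haplotype(pool: np.ndarray, dists: np.ndarray, rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Copy one haplotype from ``pool`` (n_sites, k) with distance-based switches."""
    n_sites, k = pool.shape
    switch = 1.0 - np.exp(-rate * dists)  # per-step template switch probability
    tmpl = rng.integers(k)
    out = np.empty(n_sites, dtype=np.int8)
    out[0] = pool[0, tmpl]
    u = rng.random(n_sites - 1)
    for t in range(1, n_sites):
        if u[t - 1] < switch[t - 1]:
            tmpl = rng.integers(k)
        out[t] = pool[t, tmpl]
    return out


def simulate_population(cfg: SimConfig) -> SimResult:
    """Simulate the cohort: haplotype panels per breed, genotypes, truth labels."""
    root = np.random.SeedSequence(cfg.seed)
    rng_sites, rng_pool, rng_hap, rng_ann, rng_rec = (
        np.random.default_rng(s) for s in root.spawn(5))

    positions = _site_positions(cfg, rng_sites)
    n_sites = len(positions)
    chrom_arr = np.array([c for c, _ in positions])
    pos_arr = np.array([p for _, p in positions])
    # distances between consecutive sites; chromosome breaks get infinite distance
    dists = np.empty(max(n_sites - 1, 0))
    for i in range(n_sites - 1):
        dists[i] = (pos_arr[i + 1] - pos_arr[i]
                    if chrom_arr[i + 1] == chrom_arr[i] else np.inf)

    # base pool: a handful of deep founders carry the allele-frequency
    # spectrum; pool haplotypes are founder mosaics (long shared blocks plus
    # rare private mutations), so nearby sites are genuinely correlated and
    # sample-level recombination has structure to erode
    base_freq = rng_pool.beta(0.8, 2.2, size=n_sites)
    founders = (rng_pool.random((n_sites, cfg.n_founders)) < base_freq[:, None]).astype(np.int8)
    pool = np.empty((n_sites, cfg.base_pool_size), dtype=np.int8)
    for j in range(cfg.base_pool_size):
        pool[:, j] = _mosaic_haplotype(founders, dists, cfg.founder_switch_rate, rng_pool)
    mut = rng_pool.random(pool.shape) < cfg.pool_mutation_rate
    pool[mut] = 1 - pool[mut]

    # artifactual sites: overwrite pool rows with rare iid noise (no LD, low MAF)
    is_true = rng_pool.random(n_sites) >= cfg.false_site_fraction
    false_idx = np.flatnonzero(~is_true)
    pool[false_idx] = (rng_pool.random((false_idx.size, cfg.base_pool_size)) < 0.08).astype(np.int8)

    breeds = [f"breed{i + 1}" for i in range(cfg.n_breeds)]
    sample_names, sample_groups = [], {}
    hap_cols = []
    breed_panels: dict[str, np.ndarray] = {}
    pool_idx = np.arange(cfg.base_pool_size)
    for b, breed in enumerate(breeds):
        sub_size = max(2, round(cfg.base_pool_size * (1.0 - cfg.drift)))
        sub = (pool_idx if cfg.drift == 0.0
               else np.sort(rng_hap.choice(pool_idx, size=sub_size, replace=False)))
        breed_pool = pool[:, sub]
        panel = np.empty((n_sites, 2 * cfg.samples_per_breed), dtype=np.int8)
        for j in range(2 * cfg.samples_per_breed):
            panel[:, j] = _mosaic_haplotype(breed_pool, dists, cfg.recombination_rate, rng_hap)
        breed_panels[breed] = panel
        for s in range(cfg.samples_per_breed):
            name = f"{breed}_s{s + 1}"
            sample_names.append(name)
            sample_groups[name] = breed
        hap_cols.append(panel)

    haps = np.concatenate(hap_cols, axis=1)  # (n_sites, 2*n_samples)
    n_samples = len(sample_names)
    haplotypes = haps.reshape(n_sites, n_samples, 2)
    dosage = haplotypes.sum(axis=2).astype(np.int8)

    # calling groups: breeds double as calling groups (capped at n_calling_groups);
    # a site is observed in a group when the alt allele segregates there
    group_of_breed = {b: f"group{(i % cfg.n_calling_groups) + 1}"
                      for i, b in enumerate(breeds)}
    sites = []
    col0 = 0
    breed_cols = {}
    for breed in breeds:
        breed_cols[breed] = slice(col0, col0 + cfg.samples_per_breed)
        col0 += cfg.samples_per_breed
    for i, (chrom, pos) in enumerate(positions):
        groups = frozenset(group_of_breed[b] for b in breeds
                           if dosage[i, breed_cols[b]].sum() > 0)
        ref, alt = rng_rec.choice(list("ACGT"), size=2, replace=False)
        sites.append(VariantSite(chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
                                 groups_observed=groups))
    catalog = Catalog(sites)
    simulate_annotations(catalog, is_true, cfg, rng_ann)
    simulate_probe_recommendations(catalog, cfg, rng_rec)

    gm = GenotypeMatrix(catalog.keys(), sample_names, dosage, haplotypes)
    gmap = BreedGroupMap(sample_groups, frozenset())
    layout = GenomeLayout(dict(cfg.chrom_lengths))
    return SimResult(catalog, gm, gmap, layout, is_true, breed_panels)


def simulate_annotations(catalog: Catalog, is_true: np.ndarray, cfg: SimConfig,
                         rng: np.random.Generator | None = None) -> None:
    """Attach QUAL and the five annotations, class-shifted for false sites.

    True sites draw from the clean distributions and false sites from the
    shifted ones; QUAL is log-normal with a deliberately small class shift
    so that ranking by QUAL alone is an imperfect classifier.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = len(catalog)
    vals = {}
    for name in ANNOTATIONS:
        mu_t, mu_f, sd = cfg.ann_params[name]
        mu = np.where(is_true, mu_t, mu_f)
        v = rng.normal(mu, sd)
        if name in ("DP", "FS"):
            v = np.clip(v, 0.0, None)
        vals[name] = v
    # rank sums missing at random (sites with no usable het reads)
    rs_missing = rng.random(n) < cfg.ranksum_missing_rate
    log_qual = rng.normal(np.where(is_true, 5.0, 5.0 - cfg.qual_class_shift), 1.0)
    qual = np.exp(log_qual)
    for i, site in enumerate(catalog):
        site.qual = float(qual[i])
        site.annotations = AnnotationVector(
            DP=float(vals["DP"][i]),
            QD=float(vals["QD"][i]),
            FS=float(vals["FS"][i]),
            MQRankSum=None if rs_missing[i] else float(vals["MQRankSum"][i]),
            ReadPosRankSum=None if rs_missing[i] else float(vals["ReadPosRankSum"][i]),
        )


_REC_CLASSES = [RecClass.RECOMMENDED, RecClass.NEUTRAL,
                RecClass.NOT_RECOMMENDED, RecClass.NOT_POSSIBLE]
_REC_PROBS = [0.55, 0.25, 0.15, 0.05]


def simulate_probe_recommendations(catalog: Catalog, cfg: SimConfig,
                                   rng: np.random.Generator | None = None) -> None:
    """Attach per-strand probe design recommendation classes to every site."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    for site in catalog:
        fwd, rev = rng.choice(len(_REC_CLASSES), size=2, p=_REC_PROBS)
        site.probe_rec = ProbeRecommendation(
            forward=_REC_CLASSES[fwd], reverse=_REC_CLASSES[rev],
            needs_two_probes={site.ref, site.alt} in ({"A", "T"}, {"C", "G"}),
        )


def simulate_array_genotyping(gm: GenotypeMatrix, error_rate: float,
                              missing_rate: float, seed: int) -> GenotypeMatrix:
    """Corrupt a genotype matrix the way an array assay would.

    Each call is independently flipped to one of the two other dosages with
    probability ``error_rate`` and set missing with probability
    ``missing_rate`` (missingness applied after errors).  Haplotypes are
    dropped from the result: array output is unphased.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = gm.dosage.copy()
    obs = dosage != GenotypeMatrix.MISSING
    flip = (rng.random(dosage.shape) < error_rate) & obs
    shift = rng.integers(1, 3, size=dosage.shape).astype(np.int8)  # +1 or +2 mod 3
    dosage[flip] = (dosage[flip] + shift[flip]) % 3
    miss = rng.random(dosage.shape) < missing_rate
    dosage[miss] = GenotypeMatrix.MISSING
    return GenotypeMatrix(gm.sites, gm.samples, dosage)


def write_truth_table(result: SimResult, path: str) -> None:
    """Write per-site truth labels (chrom, pos, ref, alt, is_true) as TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tis_true\n")
        for site, t in zip(result.catalog, result.truth_is_true_site):
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{int(t)}\n")
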
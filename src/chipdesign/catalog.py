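"""Variant catalogs, genotype matrices, genome layout, and VCF/BED/TSV I/O.

The catalog is the central container of the toolkit: a table of bi-allelic
SNVs keyed by ``(chrom, pos, ref, alt)`` carrying the caller QUAL score, the
five read-level annotations used for quality recalibration (DP, QD, FS,
MQRankSum, ReadPosRankSum), the set of calling groups each site was observed
in, the composite VQSLOD score once computed, and the filter flags applied
along the design pipeline.  Positions are 1-based (VCF convention)
throughout; genomic windows use half-open 0-based intervals internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

#: canonical order of the recalibration annotations (VCF INFO keys)
ANNOTATIONS = ("DP", "QD", "FS", "MQRankSum", "ReadPosRankSum")

BASES = frozenset("ACGT")

#: a site key: (chrom, pos, ref, alt), pos 1-based
Key = tuple[str, int, str, str]


class CatalogError(ValueError):
    pass


@dataclass
class AnnotationVector:
    """Read-level site annotations; ``None`` marks a missing value.

    DP is the total unfiltered depth, QD the quality by depth, FS the
    Fisher strand bias (phred-scaled, >= 0), and the two rank sums test
    mapping quality and read position of alt-supporting reads.  Rank sums
    are legitimately absent at sites with no heterozygote and are tracked
    as missing, never zero-filled.
    """

    DP: float | None = None
    QD: float | None = None
    FS: float | None = None
    MQRankSum: float | None = None
    ReadPosRankSum: float | None = None

    def __post_init__(self) -> None:
        if self.DP is not None and self.DP < 0:
            raise CatalogError(f"DP must be >= 0, got {self.DP}")
        if self.FS is not None and self.FS < 0:
            raise CatalogError(f"FS must be >= 0, got {self.FS}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [np.nan if getattr(self, a) is None else float(getattr(self, a)) for a in ANNOTATIONS]
        )


@dataclass
class VariantSite:
    """A single bi-allelic SNV with its annotations and pipeline state."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    annotations: AnnotationVector = field(default_factory=AnnotationVector)
    groups_observed: frozenset[str] = frozenset()
    vqslod: float | None = None
    filter_flags: set[str] = field(default_factory=set)
    probe_rec: object | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CatalogError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise CatalogError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise CatalogError(f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.ref, self.alt)


class Catalog:
    """Ordered collection of :class:`VariantSite`, indexable by site key."""

    def __init__(self, sites: list[VariantSite] | None = None):
        self.sites: list[VariantSite] = list(sites) if sites else []
        self._index: dict[Key, int] = {s.key: i for i, s in enumerate(self.sites)}
        if len(self._index) != len(self.sites):
            raise CatalogError("duplicate site keys in catalog")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __contains__(self, key: Key) -> bool:
        return key in self._index

    def __getitem__(self, key: Key) -> VariantSite:
        return self.sites[self._index[key]]

    def keys(self) -> list[Key]:
        return [s.key for s in self.sites]

    def subset(self, keys) -> "Catalog":
        keyset = set(keys)
        return Catalog([s for s in self.sites if s.key in keyset])

    def candidates(self) -> "Catalog":
        """Sites not removed by any filter so far."""
        return Catalog([s for s in self.sites if not s.filter_flags])

    def annotation_matrix(self) -> np.ndarray:
        """(n_sites, 5) array of annotations with NaN for missing."""
        return np.array([s.annotations.as_array() for s in self.sites])

    def qual_array(self) -> np.ndarray:
        return np.array([np.nan if s.qual is None else s.qual for s in self.sites])

    def vqslod_array(self) -> np.ndarray:
        return np.array([np.nan if s.vqslod is None else s.vqslod for s in self.sites])

    def sorted_by_position(self) -> "Catalog":
        return Catalog(sorted(self.sites, key=lambda s: (s.chrom, s.pos, s.ref, s.alt)))


# ---------------------------------------------------------------------------
# genotype matrix


class GenotypeMatrix:
    """sites x samples diploid alt-dosage calls; -1 encodes missing.

    ``haplotypes`` (optional) is an int8 array of shape (n_sites, n_samples, 2)
    with per-sample phased alt-allele indicators; where present and the call
    is non-missing, the dosage must equal the haplotype sum.
    """

    MISSING = -1

    def __init__(self, sites: list[Key], samples: list[str], dosage: np.ndarray,
                 haplotypes: np.ndarray | None = None):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(sites), len(samples)):
            raise CatalogError(
                f"dosage shape {dosage.shape} != ({len(sites)}, {len(samples)})"
            )
        bad = ~np.isin(dosage, [-1, 0, 1, 2])
        if bad.any():
            raise CatalogError(f"invalid dosage values: {np.unique(dosage[bad])}")
        self.sites = list(sites)
        self.samples = list(samples)
        self.dosage = dosage
        self.haplotypes = None
        if haplotypes is not None:
            haplotypes = np.asarray(haplotypes, dtype=np.int8)
            if haplotypes.shape != (len(sites), len(samples), 2):
                raise CatalogError("haplotype array shape mismatch")
            hsum = haplotypes.sum(axis=2)
            obs = dosage != self.MISSING
            if not np.array_equal(hsum[obs], dosage[obs]):
                raise CatalogError("dosage inconsistent with haplotype sums")
            self.haplotypes = haplotypes
        self._site_index = {k: i for i, k in enumerate(self.sites)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def site_row(self, key: Key) -> np.ndarray:
        return self.dosage[self._site_index[key]]

    def site_pos(self, key: Key) -> int:
        return self._site_index[key]

    def subset_sites(self, keys) -> "GenotypeMatrix":
        idx = [self._site_index[k] for k in keys]
        hap = self.haplotypes[idx] if self.haplotypes is not None else None
        return GenotypeMatrix(list(keys), self.samples, self.dosage[idx], hap)

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in names]
        hap = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeMatrix(self.sites, list(names), self.dosage[:, idx], hap)

    def copy(self) -> "GenotypeMatrix":
        hap = self.haplotypes.copy() if self.haplotypes is not None else None
        return GenotypeMatrix(self.sites, self.samples, self.dosage.copy(), hap)


def allele_stats(genotypes: GenotypeMatrix, site: Key) -> dict:
    """Allele frequency summary for one site, excluding missing calls.

    Returns ``alt_freq``, ``maf``, ``minor_allele_count`` (observed copies of
    the rarer allele) and ``n_called``.  Raises if every call is missing.
    """
    row = genotypes.site_row(site)
    called = row[row != GenotypeMatrix.MISSING]
    if called.size == 0:
        raise CatalogError(f"all calls missing at {site}; allele frequency undefined")
    n_called = int(called.size)
    alt_count = int(called.sum())
    total = 2 * n_called
    alt_freq = alt_count / total
    minor_count = min(alt_count, total - alt_count)
    return {
        "alt_freq": alt_freq,
        "maf": min(alt_freq, 1.0 - alt_freq),
        "minor_allele_count": minor_count,
        "n_called": n_called,
    }


def maf_array(genotypes: GenotypeMatrix) -> np.ndarray:
    """Vector of per-site MAF (NaN where all calls are missing)."""
    d = genotypes.dosage
    obs = d != GenotypeMatrix.MISSING
    n = obs.sum(axis=1)
    alt = np.where(obs, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n)
    maf = np.minimum(freq, 1.0 - freq)
    maf[n == 0] = np.nan
    return maf


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class GenomeLayout:
    """Chromosome lengths plus the window size used for density targets."""

    chrom_lengths: dict[str, int]
    window_size: int = 50_000

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise CatalogError("window size must be positive")
        for c, ln in self.chrom_lengths.items():
            if ln <= 0:
                raise CatalogError(f"non-positive length for chromosome {c}: {ln}")


def partition_windows(layout: GenomeLayout) -> list[tuple[str, int, int]]:
    """Tile each chromosome with half-open ``[start, start+size)`` windows.

    Internal coordinates are 0-based; a 1-based position ``pos`` falls in the
    window containing ``pos - 1``.  The final window of a chromosome may be
    shorter than ``window_size``.
    """
    out = []
    size = layout.window_size
    for chrom, length in layout.chrom_lengths.items():
        for start in range(0, length, size):
            out.append((chrom, start, min(start + size, length)))
    return out


def window_of(layout: GenomeLayout, chrom: str, pos: int) -> tuple[str, int, int]:
    """Window containing 1-based position ``pos``."""
    size = layout.window_size
    start = ((pos - 1) // size) * size
    return (chrom, start, min(start + size, layout.chrom_lengths[chrom]))


# ---------------------------------------------------------------------------
# breed group map


@dataclass
class BreedGroupMap:
    """Sample -> tagging-group assignment with priority-class annotations.

    ``priority_groups`` marks groups whose discoveries get priority in LD
    pruning (historically under-represented draft and pony groups).
    """

    sample_to_group: dict[str, str]
    priority_groups: frozenset[str] = frozenset()

    def groups(self) -> list[str]:
        return sorted(set(self.sample_to_group.values()))

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]


def read_group_map(path: str, priority_groups=()) -> BreedGroupMap:
    """Read a two-column (sample, group) tab-separated map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str,
                     comment="#")
    return BreedGroupMap(dict(zip(df["sample"], df["group"])),
                         frozenset(priority_groups))


def write_group_map(gmap: BreedGroupMap, path: str) -> None:
    with open(path, "w") as fh:
        for s, g in gmap.sample_to_group.items():
            fh.write(f"{s}\t{g}\n")


def read_layout(path: str, window_size: int = 50_000) -> GenomeLayout:
    """Read a two-column chrom/length text file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeLayout(dict(zip(df["chrom"].astype(str), df["length"].astype(int))),
                        window_size)


# ---------------------------------------------------------------------------
# catalog set operations


def intersect_caller_sites(catalog_a: Catalog, catalog_b: Catalog) -> tuple[Catalog, dict]:
    """Sites called by both callers, annotations carried from ``catalog_a``.

    The first argument is the primary caller: surviving sites keep its QUAL
    and annotations.  Sites sharing (chrom, pos, ref) but disagreeing on the
    alt allele are excluded and counted in the report.
    """
    keys_b = set(catalog_b.keys())
    loci_b = {(c, p, r) for c, p, r, _ in keys_b}
    kept, mismatches = [], 0
    for site in catalog_a:
        if site.key in keys_b:
            kept.append(site)
        elif (site.chrom, site.pos, site.ref) in loci_b:
            mismatches += 1
    report = {
        "n_a": len(catalog_a),
        "n_b": len(catalog_b),
        "n_intersection": len(kept),
        "n_allele_mismatch": mismatches,
    }
    return Catalog(kept), report


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def _vcf_header(catalog: Catalog, samples=(), layout: GenomeLayout | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if layout is not None:
        for chrom, length in layout.chrom_lengths.items():
            header.contigs.add(chrom, length=length)
    else:
        seen = {}
        for s in catalog:
            seen[s.chrom] = max(seen.get(s.chrom, 0), s.pos)
        for chrom, maxpos in seen.items():
            header.contigs.add(chrom, length=maxpos + 1)
    header.info.add("DP", 1, "Integer", "Total unfiltered depth")
    header.info.add("QD", 1, "Float", "Quality by depth")
    header.info.add("FS", 1, "Float", "Fisher strand bias (phred)")
    header.info.add("MQRankSum", 1, "Float", "Mapping quality rank sum")
    header.info.add("ReadPosRankSum", 1, "Float", "Read position rank sum")
    header.info.add("VQSLOD", 1, "Float", "Composite recalibrated quality (log10 odds)")
    header.info.add("GROUPS", ".", "String", "Calling groups observing the site")
    flags = sorted({f for s in catalog for f in s.filter_flags})
    for f in flags:
        header.filters.add(f, None, None, f"removed by {f} filter")
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        for name in samples:
            header.add_sample(name)
    return header


def write_vcf(catalog: Catalog, path: str, genotypes: GenotypeMatrix | None = None,
              layout: GenomeLayout | None = None) -> None:
    """Write the catalog (and optionally genotypes) as an uncompressed VCF."""
    samples = genotypes.samples if genotypes is not None else ()
    header = _vcf_header(catalog, samples, layout)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in catalog:
            rec = out.new_record(contig=site.chrom, start=site.pos - 1,
                                 alleles=(site.ref, site.alt))
            if site.qual is not None:
                rec.qual = site.qual
            ann = site.annotations
            if ann.DP is not None:
                rec.info["DP"] = int(ann.DP)
            for k in ("QD", "FS", "MQRankSum", "ReadPosRankSum"):
                v = getattr(ann, k)
                if v is not None:
                    rec.info[k] = float(v)
            if site.vqslod is not None:
                rec.info["VQSLOD"] = float(site.vqslod)
            if site.groups_observed:
                rec.info["GROUPS"] = ",".join(sorted(site.groups_observed))
            if site.filter_flags:
                for f in sorted(site.filter_flags):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            if genotypes is not None:
                row = genotypes.site_row(site.key)
                for j, name in enumerate(samples):
                    d = int(row[j])
                    rec.samples[name]["GT"] = gt_codes.get(d, (None, None))
            out.write(rec)


def read_vcf(path: str) -> tuple[Catalog, GenotypeMatrix | None, dict]:
    """Read a VCF into a catalog (+ genotype matrix if samples present).

    Only bi-allelic SNVs are retained; multi-allelic records and indels are
    skipped with a count in the report, never an error.  Malformed records
    raise with line context (pysam reports the offending record).
    """
    sites: list[VariantSite] = []
    dosage_rows: list[list[int]] = []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref is None or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or rec.ref not in BASES or alts[0] not in BASES:
                skipped += 1
                continue
            info = rec.info
            ann = AnnotationVector(
                DP=float(info["DP"]) if "DP" in info else None,
                QD=float(info["QD"]) if "QD" in info else None,
                FS=float(info["FS"]) if "FS" in info else None,
                MQRankSum=float(info["MQRankSum"]) if "MQRankSum" in info else None,
                ReadPosRankSum=float(info["ReadPosRankSum"]) if "ReadPosRankSum" in info else None,
            )
            groups = frozenset()
            if "GROUPS" in info:
                raw = info["GROUPS"]
                if not isinstance(raw, tuple):
                    raw = (raw,)
                groups = frozenset(g for part in raw for g in str(part).split(","))
            flags = {f for f in rec.filter.keys() if f != "PASS"}
            site = VariantSite(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alts[0],
                qual=None if rec.qual is None else float(rec.qual),
                annotations=ann, groups_observed=groups,
                vqslod=float(info["VQSLOD"]) if "VQSLOD" in info else None,
                filter_flags=flags,
            )
            sites.append(site)
            if samples:
                row = []
                for name in samples:
                    gt = rec.samples[name].get("GT", (None, None))
                    if gt is None or any(a is None for a in gt):
                        row.append(GenotypeMatrix.MISSING)
                    else:
                        row.append(int(sum(gt)))
                dosage_rows.append(row)
    catalog = Catalog(sites)
    gm = None
    if samples:
        dosage = np.array(dosage_rows, dtype=np.int8).reshape(len(sites), len(samples))
        gm = GenotypeMatrix(catalog.keys(), samples, dosage)
    report = {"n_retained": len(sites), "n_skipped": skipped}
    if skipped:
        warnings.warn(f"{skipped} non-SNV/multi-allelic records skipped in {path}")
    return catalog, gm, report


def read_catalog(path: str) -> Catalog:
    """Catalog-only convenience wrapper around :func:`read_vcf`."""
    return read_vcf(path)[0]
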
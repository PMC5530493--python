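"""Array-compatibility filters and priority-aware LD pruning.

Four marginal filters remove sites that are poor probe targets: repeats
(interval overlap with a repeat mask), proximity (another variant within a
flanking radius, evaluated against the full consensus catalog since any
real nearby polymorphism interferes with the probe), rarity (fewer than a
minimum number of observed minor-allele copies), and fixed non-reference
sites (alt frequency 1.0, i.e. likely reference-assembly errors).  A
windowed LD prune then thins redundant pairs (r² above a threshold within a
bp window), preferring sites discovered in priority calling groups
(historically draft and pony) and breaking ties by VQSLOD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import Catalog, GenotypeMatrix, Key, allele_stats


class FilterError(ValueError):
    pass


@dataclass
class FilterReport:
    """Bookkeeping for one or more filters applied to a catalog.

    Per-filter counts may overlap (a site can fail several filters), so
    their sum can exceed ``unique removed``; the accounting identity
    ``surviving + unique_removed == input_size`` always holds.
    """

    input_size: int
    per_filter: dict[str, int] = field(default_factory=dict)
    removed_keys: set[Key] = field(default_factory=set)
    log: list[str] = field(default_factory=list)

    @property
    def unique_removed(self) -> int:
        return len(self.removed_keys)

    @property
    def surviving(self) -> int:
        return self.input_size - self.unique_removed

    def merge(self, other: "FilterReport") -> "FilterReport":
        if other.input_size != self.input_size:
            raise FilterError("cannot merge reports over different catalogs")
        merged = FilterReport(self.input_size, dict(self.per_filter),
                              set(self.removed_keys), list(self.log))
        for name, n in other.per_filter.items():
            merged.per_filter[name] = merged.per_filter.get(name, 0) + n
        merged.removed_keys |= other.removed_keys
        merged.log += other.log
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.per_filter.items()]
        rows.append({"filter": "unique_removed", "removed": self.unique_removed})
        rows.append({"filter": "surviving", "removed": self.surviving})
        return pd.DataFrame(rows)


def _flag(catalog: Catalog, keys: set[Key], name: str) -> None:
    for key in keys:
        catalog[key].filter_flags.add(name)


def read_bed(path: str) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FilterError(f"malformed BED line {lineno}: {line!r}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FilterError(f"malformed BED line {lineno}: {line!r}") from exc
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def filter_repeats(catalog: Catalog, repeat_trees: dict[str, IntervalTree],
                   flag: str = "repeat") -> FilterReport:
    """Remove sites inside repeat-mask intervals (BED half-open convention)."""
    removed = set()
    for site in catalog:
        tree = repeat_trees.get(site.chrom)
        if tree is not None and tree.overlaps_point(site.pos - 1):
            removed.add(site.key)
    _flag(catalog, removed, flag)
    rep = FilterReport(len(catalog), {flag: len(removed)}, removed)
    rep.log.append(f"{flag}: removed {len(removed)}")
    return rep


def filter_proximity(catalog: Catalog, radius: int = 20,
                     full_catalog: Catalog | None = None,
                     flag: str = "proximity") -> FilterReport:
    """Remove any site with another variant within ``radius`` bp.

    Distance is center-to-center and the removal is symmetric: both members
    of a close pair go.  Proximity is evaluated against ``full_catalog``
    (default: the catalog itself) — the complete consensus catalog including
    sites removed by other filters — since probe interference comes from any
    real variant, not just surviving candidates.
    """
    reference = full_catalog if full_catalog is not None else catalog
    by_chrom: dict[str, list[int]] = {}
    for site in reference:
        by_chrom.setdefault(site.chrom, []).append(site.pos)
    close: dict[str, set[int]] = {}
    for chrom, positions in by_chrom.items():
        positions = sorted(positions)
        flagged = set()
        for i in range(len(positions) - 1):
            if positions[i + 1] - positions[i] <= radius:
                flagged.add(positions[i])
                flagged.add(positions[i + 1])
        close[chrom] = flagged
    removed = {s.key for s in catalog if s.pos in close.get(s.chrom, ())}
    _flag(catalog, removed, flag)
    rep = FilterReport(len(catalog), {flag: len(removed)}, removed)
    rep.log.append(f"{flag}: removed {len(removed)} (radius {radius} bp)")
    return rep


def filter_rare(catalog: Catalog, genotypes: GenotypeMatrix,
                min_minor_obs: int = 2, flag: str = "rare") -> FilterReport:
    """Remove sites with fewer than ``min_minor_obs`` observed minor alleles.

    Sites where every call is missing cannot be assessed; they are removed
    with a separate "uncallable" flag and counted separately.
    """
    removed, uncallable = set(), set()
    for site in catalog:
        try:
            stats = allele_stats(genotypes, site.key)
        except Exception:
            uncallable.add(site.key)
            continue
        if stats["minor_allele_count"] < min_minor_obs:
            removed.add(site.key)
    _flag(catalog, removed, flag)
    _flag(catalog, uncallable, "uncallable")
    rep = FilterReport(len(catalog), {flag: len(removed), "uncallable": len(uncallable)},
                       removed | uncallable)
    rep.log.append(f"{flag}: removed {len(removed)}; uncallable {len(uncallable)}")
    return rep


def filter_fixed_nonreference(catalog: Catalog, genotypes: GenotypeMatrix,
                              flag: str = "fixed_nonref") -> FilterReport:
    """Remove sites fixed for the alternative allele among non-missing calls.

    Such sites are reference-error candidates (every sequenced individual
    carries the alternative base) and cannot be assayed as polymorphisms.
    """
    removed = set()
    for site in catalog:
        try:
            stats = allele_stats(genotypes, site.key)
        except Exception:
            continue
        if stats["alt_freq"] == 1.0:
            removed.add(site.key)
    _flag(catalog, removed, flag)
    rep = FilterReport(len(catalog), {flag: len(removed)}, removed)
    rep.log.append(f"{flag}: removed {len(removed)} reference-error candidates")
    return rep


def pairwise_r2(genotypes: GenotypeMatrix, site_a: Key, site_b: Key) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples.

    Returns NaN (undefined) when fewer than two shared samples remain or
    either dosage vector is constant on the shared samples; callers treat
    undefined as "not in LD".
    """
    a = genotypes.site_row(site_a).astype(float)
    b = genotypes.site_row(site_b).astype(float)
    both = (a != GenotypeMatrix.MISSING) & (b != GenotypeMatrix.MISSING)
    a, b = a[both], b[both]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_priority_prune(catalog: Catalog, genotypes: GenotypeMatrix,
                      window: int = 10_000, r2_max: float = 0.90,
                      priority_groups: frozenset[str] = frozenset({"draft", "pony"}),
                      flag: str = "ld_prune") -> FilterReport:
    """Greedy left-to-right LD prune within a bp window.

    For every surviving pair closer than ``window`` with r² above
    ``r2_max``, the member observed in more priority calling groups is kept;
    ties keep the higher VQSLOD, then the left (lower-position) site.  The
    loser is removed immediately and takes no further part in comparisons,
    so no surviving pair within the window exceeds the threshold.
    """
    sites = sorted(catalog.sites, key=lambda s: (s.chrom, s.pos))
    alive = [True] * len(sites)

    def rank(site):
        prio = len(site.groups_observed & priority_groups)
        vq = site.vqslod if site.vqslod is not None else float("-inf")
        return (prio, vq)

    removed = set()
    for i, si in enumerate(sites):
        if not alive[i]:
            continue
        j = i + 1
        while j < len(sites) and sites[j].chrom == si.chrom \
                and sites[j].pos - si.pos <= window:
            if alive[j]:
                r2 = pairwise_r2(genotypes, si.key, sites[j].key)
                if not np.isnan(r2) and r2 > r2_max:
                    if rank(sites[j]) > rank(si):
                        alive[i] = False
                        removed.add(si.key)
                        break
                    alive[j] = False
                    removed.add(sites[j].key)
            j += 1
    _flag(catalog, removed, flag)
    rep = FilterReport(len(catalog), {flag: len(removed)}, removed)
    rep.log.append(f"{flag}: removed {len(removed)} (window {window} bp, r2 > {r2_max})")
    return rep


def apply_design_filters(catalog: Catalog, genotypes: GenotypeMatrix,
                         repeat_trees: dict[str, IntervalTree] | None = None,
                         radius: int = 20, min_minor_obs: int = 2,
                         ld_window: int = 10_000, r2_max: float = 0.90,
                         priority_groups: frozenset[str] = frozenset()) -> FilterReport:
    """Run the full candidate-reduction stage; returns the merged report.

    The marginal filters (repeats, proximity, rarity, fixed non-reference)
    are order-independent; LD pruning runs last, on the surviving sites.
    """
    report = FilterReport(len(catalog))
    if repeat_trees:
        report = report.merge(filter_repeats(catalog, repeat_trees))
    report = report.merge(filter_proximity(catalog, radius=radius))
    report = report.merge(filter_rare(catalog, genotypes, min_minor_obs=min_minor_obs))
    report = report.merge(filter_fixed_nonreference(catalog, genotypes))
    survivors = catalog.candidates()
    prune = ld_priority_prune(survivors, genotypes, window=ld_window,
                              r2_max=r2_max, priority_groups=priority_groups)
    for key in prune.removed_keys:
        catalog[key].filter_flags.add("ld_prune")
    merged = FilterReport(len(catalog), dict(report.per_filter),
                          set(report.removed_keys), list(report.log) + list(prune.log))
    merged.per_filter["ld_prune"] = len(prune.removed_keys)
    merged.removed_keys |= prune.removed_keys
    return merged
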
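"""Windowed quota selection for the high-density design set.

The genome is tiled into fixed-size windows (50 kb by default) and a quota
of SNPs per window (37 by default) is filled greedily by selection tier:

1. legacy-array VIP SNPs (regardless of probe recommendation or strand)
2. Mendelian-trait VIP SNPs (likewise)
3. 'recommended' probes designable with a single probe
4. 'neutral' probes designable with a single probe
5. any remaining SNP inside the designated MHC region
6. SNPs requiring two probes (A/T and C/G alleles)
7. fallback: remaining designable single-probe sites ('not recommended')

VIP and MHC sites are always included, even when that exceeds the quota;
they count against the quota otherwise.  Sites whose probes are 'not
possible' on both strands and that are not VIP are unselectable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .catalog import Catalog, GenomeLayout, Key, window_of


class RecClass(enum.IntEnum):
    """Probe design recommendation classes, best first."""

    RECOMMENDED = 0
    NEUTRAL = 1
    NOT_RECOMMENDED = 2
    NOT_POSSIBLE = 3


class Strand(enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class ProbeRecommendation:
    forward: RecClass
    reverse: RecClass
    needs_two_probes: bool


#: tier labels, index 1..7 (see module docstring)
TIER_LABELS = {
    1: "legacy_vip",
    2: "mendelian_vip",
    3: "recommended_single",
    4: "neutral_single",
    5: "mhc",
    6: "multi_probe",
    7: "not_recommended_single",
}

UNSELECTABLE = None


def resolve_strand(rec: ProbeRecommendation) -> Strand:
    """Pick the strand with the better recommendation class; ties go forward."""
    if rec.reverse < rec.forward:
        return Strand.REVERSE
    return Strand.FORWARD


def _best_class(rec: ProbeRecommendation) -> RecClass:
    return min(rec.forward, rec.reverse)


def in_region(region: tuple[str, int, int] | None, chrom: str, pos: int) -> bool:
    """Half-open bp region (chrom, start, end) containment for 1-based pos."""
    if region is None:
        return False
    rchrom, start, end = region
    return chrom == rchrom and start <= pos - 1 < end


def assign_tier(site, rec: ProbeRecommendation | None, legacy_vip: set[Key],
                mendelian_vip: set[Key], mhc_region: tuple[str, int, int] | None):
    """Lowest applicable selection tier for a candidate, or None if unselectable."""
    key = site.key
    if key in legacy_vip:
        return 1
    if key in mendelian_vip:
        return 2
    if rec is None or _best_class(rec) == RecClass.NOT_POSSIBLE:
        # MHC membership rescues sites with any designable probe, not these
        return UNSELECTABLE
    if not rec.needs_two_probes:
        if _best_class(rec) == RecClass.RECOMMENDED:
            return 3
        if _best_class(rec) == RecClass.NEUTRAL:
            return 4
    if in_region(mhc_region, site.chrom, site.pos):
        return 5
    if rec.needs_two_probes:
        return 6
    return 7


def select_per_window(catalog: Catalog, layout: GenomeLayout, quota: int = 37,
                      legacy_vip: set[Key] | None = None,
                      mendelian_vip: set[Key] | None = None,
                      mhc_region: tuple[str, int, int] | None = None) -> list[dict]:
    """Greedy per-window quota selection over candidate sites.

    Returns one record per selected site: key, window, tier, chosen strand.
    Selection within a tier is ordered by VQSLOD descending then position,
    so the output is independent of candidate input order.
    """
    legacy_vip = legacy_vip or set()
    mendelian_vip = mendelian_vip or set()
    by_window: dict[tuple[str, int, int], list] = {}
    for site in catalog:
        win = window_of(layout, site.chrom, site.pos)
        by_window.setdefault(win, []).append(site)

    selected: list[dict] = []
    for win in sorted(by_window):
        entries = []
        for site in by_window[win]:
            rec = site.probe_rec
            tier = assign_tier(site, rec, legacy_vip, mendelian_vip, mhc_region)
            if tier is UNSELECTABLE:
                continue
            vq = site.vqslod if site.vqslod is not None else float("-inf")
            entries.append((tier, -vq, site.pos, site, rec))
        entries.sort(key=lambda e: e[:3])
        forced = [e for e in entries
                  if e[0] in (1, 2) or in_region(mhc_region, e[3].chrom, e[3].pos)]
        forced_keys = {e[3].key for e in forced}
        chosen = list(forced)
        for e in entries:
            if len(chosen) >= quota:
                break
            if e[3].key not in forced_keys:
                chosen.append(e)
        chosen.sort(key=lambda e: e[2])
        for tier, _negvq, pos, site, rec in chosen:
            strand = resolve_strand(rec) if rec is not None else Strand.FORWARD
            selected.append({
                "key": site.key, "chrom": site.chrom, "pos": pos,
                "window_start": win[1], "tier": tier,
                "tier_label": TIER_LABELS[tier], "strand": strand.value,
                "two_probe": bool(rec.needs_two_probes) if rec else False,
            })
    return selected
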
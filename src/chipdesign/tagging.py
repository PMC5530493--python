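"""r²-based tag-SNP selection and assembly of the final array.

A tag SNP predicts the genotypes of other SNPs: site ``t`` is covered by
tag ``s`` when the squared dosage correlation r²(s, t) meets a threshold.
Within one population this is a set-cover problem, solved greedily
(repeatedly take the site covering the most uncovered targets).  Across
populations a near-minimal spanning subset is found by greedily picking the
SNP that serves as an admissible tag in the most populations still needing
coverage.  The final array is assembled from six inclusion criteria applied
in precedence order: Inter (cross-population tags), Intra (tags in enough
breed groups), Diverse (tags in enough of the designated high-diversity
groups), MHC (region membership), Density (window fill), and VIP
(backwards-compatibility sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (Catalog, GenomeLayout, GenotypeMatrix, Key, maf_array,
                      partition_windows, window_of)
from .windows import in_region


class TaggingError(ValueError):
    pass


def dosage_r2_matrix(gm: GenotypeMatrix, keys: list[Key] | None = None) -> np.ndarray:
    """Pairwise squared dosage correlation with pairwise-complete samples."""
    if keys is None:
        keys = gm.sites
    sub = gm.subset_sites(keys)
    x = sub.dosage.astype(float)
    x[sub.dosage == GenotypeMatrix.MISSING] = np.nan
    corr = pd.DataFrame(x.T).corr(min_periods=2).to_numpy()
    return corr ** 2


@dataclass
class TagSet:
    """Result of tagging one population.

    ``coverage`` maps each target to the tag rule that covers it (a tuple of
    one or two tag keys) and the achieved r²; ``alternatives`` lists every
    admissible single tag per target (used by the multi-population pass).
    """

    population: str
    tags: list[Key]
    coverage: dict[Key, tuple[tuple[Key, ...], float]]
    alternatives: dict[Key, set[Key]]
    uncoverable: list[Key]
    maf_min: float
    r2_min: float
    max_markers: int = 1


def _two_marker_r2(gm: GenotypeMatrix, target: Key, pair: tuple[Key, Key]) -> float:
    """R² of the OLS fit of target dosage on two tag dosages (joint rule)."""
    y = gm.site_row(target).astype(float)
    x1 = gm.site_row(pair[0]).astype(float)
    x2 = gm.site_row(pair[1]).astype(float)
    ok = (y != GenotypeMatrix.MISSING) & (x1 != GenotypeMatrix.MISSING) \
        & (x2 != GenotypeMatrix.MISSING)
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    if y.size < 3 or np.all(y == y[0]):
        return float("nan")
    design = np.column_stack([np.ones(y.size), x1, x2])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - resid @ resid / tss)


def find_tags_greedy(gm: GenotypeMatrix, maf_min: float, r2_min: float,
                     max_markers: int = 1, population: str = "all") -> TagSet:
    """Greedy set-cover tagging of all sites with MAF >= ``maf_min``.

    A site covers itself and every target whose pairwise r² reaches
    ``r2_min``.  With ``max_markers=2``, a target left uncovered by the
    chosen single tags may instead be covered by a pair of already-selected
    tags whose joint regression R² reaches the threshold.
    """
    maf = maf_array(gm)
    eligible_idx = [i for i, m in enumerate(maf) if not np.isnan(m) and m >= maf_min]
    if not eligible_idx:
        raise TaggingError(f"no site passes maf_min={maf_min}")
    keys = [gm.sites[i] for i in eligible_idx]
    r2 = dosage_r2_matrix(gm, keys)
    n = len(keys)
    covers = [set(np.flatnonzero(np.nan_to_num(r2[i]) >= r2_min)) | {i} for i in range(n)]

    uncovered = set(range(n))
    tags: list[int] = []
    coverage: dict[Key, tuple[tuple[Key, ...], float]] = {}
    while uncovered:
        best = max(range(n), key=lambda i: (len(covers[i] & uncovered), -i))
        gained = covers[best] & uncovered
        if not gained:
            break
        tags.append(best)
        for t in gained:
            achieved = 1.0 if t == best else float(r2[best, t])
            coverage[keys[t]] = ((keys[best],), achieved)
        uncovered -= gained

    if max_markers >= 2 and uncovered and len(tags) >= 2:
        still = set()
        for t in sorted(uncovered):
            hit = None
            for a in range(len(tags)):
                for b in range(a + 1, len(tags)):
                    pair = (keys[tags[a]], keys[tags[b]])
                    rr = _two_marker_r2(gm, keys[t], pair)
                    if not np.isnan(rr) and rr >= r2_min:
                        hit = (pair, rr)
                        break
                if hit:
                    break
            if hit:
                coverage[keys[t]] = hit
                uncovered.discard(t)
            else:
                still.add(t)
        uncovered = still

    alternatives = {
        keys[t]: {keys[s] for s in range(n) if s == t or np.nan_to_num(r2[s, t]) >= r2_min}
        for t in range(n)
    }
    return TagSet(
        population=population,
        tags=[keys[i] for i in tags],
        coverage=coverage,
        alternatives=alternatives,
        uncoverable=[keys[t] for t in sorted(uncovered)],
        maf_min=maf_min, r2_min=r2_min, max_markers=max_markers,
    )


def multi_pop_tag_select(tagsets: dict[str, TagSet]) -> tuple[set[Key], dict[str, dict[Key, Key]]]:
    """Near-minimal SNP set spanning several populations' tagging contracts.

    Iteratively picks the SNP admissible as a tag in the most populations
    that still have uncovered targets (ties: most targets covered, then site
    key), then rebuilds the remaining requirements.  Returns the spanning
    set and, per population, the target -> chosen-tag assignment.
    """
    needs: dict[str, dict[Key, set[Key]]] = {}
    for pop, ts in tagsets.items():
        if not ts.tags and not ts.alternatives:
            import warnings
            warnings.warn(f"population {pop} has an empty tag set; skipped")
            continue
        needs[pop] = {t: set(alts) for t, alts in ts.alternatives.items()
                      if t in ts.coverage or t not in ts.uncoverable}
    chosen: set[Key] = set()
    assignment: dict[str, dict[Key, Key]] = {pop: {} for pop in needs}

    def candidates():
        score: dict[Key, tuple[int, int]] = {}
        for pop, targets in needs.items():
            pop_snp_targets: dict[Key, int] = {}
            for t, alts in targets.items():
                for s in alts:
                    pop_snp_targets[s] = pop_snp_targets.get(s, 0) + 1
            for s, cnt in pop_snp_targets.items():
                p, c = score.get(s, (0, 0))
                score[s] = (p + 1, c + cnt)
        return score

    while any(needs.values()):
        score = candidates()
        if not score:
            break
        snp = min(score, key=lambda s: (-score[s][0], -score[s][1], s))
        chosen.add(snp)
        for pop in list(needs):
            covered = [t for t, alts in needs[pop].items() if snp in alts]
            for t in covered:
                assignment[pop][t] = snp
                del needs[pop][t]
    return chosen, assignment


#: final-array inclusion labels in precedence order
INCLUSION_ORDER = ("Inter", "Intra", "Diverse", "MHC", "Density", "VIP")


def assemble_array(candidates: Catalog, inter_tags: set[Key],
                   per_pop_tags: dict[str, set[Key]],
                   diverse_groups: list[str],
                   mhc_region: tuple[str, int, int] | None,
                   layout: GenomeLayout,
                   vip_sites: set[Key],
                   window_density_min: int = 8,
                   intra_min_groups: int = 5,
                   diverse_min_groups: int = 3) -> pd.DataFrame:
    """Assemble the final array and label every SNP by inclusion criterion.

    Criteria are applied in precedence order; each selected SNP carries the
    first label that admitted it.  The Density pass fills each genomic
    window to at least ``window_density_min`` SNPs from the remaining
    candidates, highest VQSLOD first; windows without enough candidates are
    reported, not fatal.
    """
    labels: dict[Key, str] = {}
    cand_keys = candidates.keys()
    cand_set = set(cand_keys)

    for key in cand_keys:
        if key in inter_tags:
            labels[key] = "Inter"
    pop_membership = {key: sum(key in tags for tags in per_pop_tags.values())
                      for key in cand_keys}
    for key in cand_keys:
        if key not in labels and pop_membership[key] >= intra_min_groups:
            labels[key] = "Intra"
    diverse_sets = [per_pop_tags[g] for g in diverse_groups if g in per_pop_tags]
    for key in cand_keys:
        if key not in labels and sum(key in s for s in diverse_sets) >= diverse_min_groups:
            labels[key] = "Diverse"
    for key in cand_keys:
        if key not in labels and in_region(mhc_region, key[0], key[1]):
            labels[key] = "MHC"

    # density fill per window
    window_count: dict[tuple, int] = {w: 0 for w in partition_windows(layout)}
    for key in labels:
        window_count[window_of(layout, key[0], key[1])] += 1
    remaining_by_window: dict[tuple, list] = {}
    for site in candidates:
        if site.key in labels:
            continue
        win = window_of(layout, site.chrom, site.pos)
        vq = site.vqslod if site.vqslod is not None else float("-inf")
        remaining_by_window.setdefault(win, []).append((-vq, site.pos, site.key))
    underfilled = []
    for win in sorted(window_count):
        need = window_density_min - window_count[win]
        if need <= 0:
            continue
        pool = sorted(remaining_by_window.get(win, []))
        for _negvq, _pos, key in pool[:need]:
            labels[key] = "Density"
            window_count[win] += 1
        if window_count[win] < window_density_min:
            underfilled.append(win)

    for key in cand_keys:
        if key not in labels and key in vip_sites:
            labels[key] = "VIP"

    rows = [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "label": labels[k]}
            for k in cand_keys if k in labels]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "label"])
    df.attrs["underfilled_windows"] = underfilled
    df.attrs["label_counts"] = df["label"].value_counts().to_dict() if len(df) else {}
    assert sum(df.attrs["label_counts"].values()) == len(df)
    missing_vip = (vip_sites & cand_set) - set(labels)
    assert not missing_vip, "VIP candidates must always be included"
    return df
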
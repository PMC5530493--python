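"""Array property reports: spacing, informativeness, frequencies, LD decay,
and gene-model overlap.

These are the descriptive statistics used to characterize a finished array:
inter-SNP distance at a ladder of MAF cutoffs (spacing degrades as rare
SNPs are excluded), the count of informative SNPs (at least one
heterozygote), alternate-allele frequency summaries per sample split, the
mean-r² LD decay curve by distance bin (optionally within sample groups),
and how many SNPs fall inside annotated gene models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import GenotypeMatrix, Key, maf_array

DEFAULT_MAF_CUTOFFS = (0.0, 0.01, 0.03, 0.05, 0.10)


def _per_site_arrays(gm: GenotypeMatrix):
    d = gm.dosage
    obs = d != GenotypeMatrix.MISSING
    n = obs.sum(axis=1)
    alt = np.where(obs, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n)
    freq[n == 0] = np.nan
    return freq, np.minimum(freq, 1.0 - freq)


def inter_snp_distance(gm: GenotypeMatrix,
                       maf_cutoffs=DEFAULT_MAF_CUTOFFS) -> pd.DataFrame:
    """Mean/median gap between consecutive surviving SNPs per MAF cutoff.

    The first row ("all") keeps every site including monomorphic ones; each
    cutoff row keeps sites with MAF strictly above the cutoff.  Gaps are
    computed within chromosomes only.  With fewer than two survivors on
    every chromosome the distances are undefined (NaN) but the count is
    still reported.
    """
    _freq, maf = _per_site_arrays(gm)
    chrom = np.array([k[0] for k in gm.sites])
    pos = np.array([k[1] for k in gm.sites])
    order = np.lexsort((pos, chrom))
    rows = []
    cases = [("all", np.ones(len(gm.sites), dtype=bool))]
    cases += [(f"maf>{c:g}", maf > c) for c in maf_cutoffs]
    for label, keep in cases:
        idx = order[keep[order]]
        gaps = []
        for c in np.unique(chrom):
            p = pos[idx[chrom[idx] == c]]
            if p.size >= 2:
                gaps.append(np.diff(p))
        gaps = np.concatenate(gaps) if gaps else np.array([])
        rows.append({
            "cutoff": label,
            "mean": float(gaps.mean()) if gaps.size else np.nan,
            "median": float(np.median(gaps)) if gaps.size else np.nan,
            "n_snps": int(keep.sum()),
        })
    df = pd.DataFrame(rows)
    # sanity: SNP counts non-increasing, mean spacing non-decreasing with cutoff
    counts = df["n_snps"].to_numpy()
    assert (np.diff(counts) <= 0).all(), "SNP counts must not increase with MAF cutoff"
    return df


def informativeness(gm: GenotypeMatrix) -> dict:
    """SNPs with at least one (non-missing) heterozygous call."""
    het = (gm.dosage == 1).any(axis=1)
    return {"informative": int(het.sum()), "total": len(gm.sites),
            "per_site": het}


def alt_freq_summary(gm: GenotypeMatrix,
                     sample_splits: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Mean/median alternate-allele frequency per sample split."""
    splits = sample_splits or {"all": gm.samples}
    rows = []
    for name, samples in splits.items():
        freq, _maf = _per_site_arrays(gm.subset_samples(samples))
        ok = ~np.isnan(freq)
        rows.append({"split": name,
                     "mean_alt_freq": float(freq[ok].mean()),
                     "median_alt_freq": float(np.median(freq[ok])),
                     "n_snps": int(ok.sum())})
    return pd.DataFrame(rows)


def ld_decay(gm: GenotypeMatrix, max_dist: int = 1_000_000, maf_min: float = 0.05,
             bin_size: int = 25_000, samples: list[str] | None = None) -> pd.DataFrame:
    """Mean r² per distance bin over qualifying pairs within ``max_dist``.

    Qualifying sites have MAF above ``maf_min`` in the chosen sample set
    (all samples by default; pass a group's samples for within-breed
    curves).  Pairs with undefined r² are skipped; empty bins are reported
    with NaN.
    """
    sub = gm.subset_samples(samples) if samples is not None else gm
    _freq, maf = _per_site_arrays(sub)
    keep = np.flatnonzero(~np.isnan(maf) & (maf > maf_min))
    chrom = np.array([k[0] for k in sub.sites])
    pos = np.array([k[1] for k in sub.sites])
    x = sub.dosage.astype(float)
    x[sub.dosage == GenotypeMatrix.MISSING] = np.nan
    n_bins = int(np.ceil(max_dist / bin_size))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for ii, i in enumerate(keep):
        for j in keep[ii + 1:]:
            if chrom[j] != chrom[i]:
                continue
            d = abs(int(pos[j]) - int(pos[i]))
            if d > max_dist or d == 0:
                continue
            a, b = x[i], x[j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 2:
                continue
            av, bv = a[ok], b[ok]
            if np.all(av == av[0]) or np.all(bv == bv[0]):
                continue
            r = np.corrcoef(av, bv)[0, 1]
            b_idx = min((d - 1) // bin_size, n_bins - 1)
            sums[b_idx] += r * r
            counts[b_idx] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "dist_lo": np.arange(n_bins) * bin_size,
        "dist_hi": np.minimum((np.arange(n_bins) + 1) * bin_size, max_dist),
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })


def read_gff_genes(path: str, feature: str = "gene") -> dict[str, IntervalTree]:
    """Gene intervals from GFF3 (1-based closed, converted to half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5 or parts[2] != feature:
                continue
            chrom, start, end = parts[0], int(parts[3]), int(parts[4])
            trees.setdefault(chrom, IntervalTree()).addi(start - 1, end,
                                                         data=f"{chrom}:{start}-{end}")
    return trees


def gene_overlap(sites: list[Key], gene_trees: dict[str, IntervalTree]) -> dict:
    """SNPs inside gene models and gene models containing at least one SNP.

    A SNP inside several overlapping genes counts once; each of those genes
    counts as hit.
    """
    snps_in = 0
    genes_hit = set()
    for chrom, pos, _ref, _alt in sites:
        tree = gene_trees.get(chrom)
        if tree is None:
            continue
        hits = tree[pos - 1]
        if hits:
            snps_in += 1
            for iv in hits:
                genes_hit.add((chrom, iv.begin, iv.end))
    total_genes = sum(len(t) for t in gene_trees.values())
    return {"snps_in_genes": snps_in, "genes_with_snps": len(genes_hit),
            "n_snps": len(sites), "n_genes": total_genes}
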
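"""Cross-platform genotype agreement and quality-ranked precision curves.

Concordance is the proportion of genotype calls, non-missing on both
platforms, that agree.  Comparison is on diploid dosage, so phase is
irrelevant (ref/alt equals alt/ref).  Precision curves rank shared sites by
a per-site score (QUAL or VQSLOD) and report, at each rank, the cumulative
proportion of agreeing genotype cells over the top-ranked sites — the
pooled-over-genotypes convention, not a per-site average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import GenotypeMatrix, Key


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceResult:
    samples: list[str]
    matched: np.ndarray            # per-sample agreeing calls
    compared: np.ndarray           # per-sample calls non-missing on both
    per_site_mismatch: dict[Key, int]
    shared_sites: list[Key]

    @property
    def per_individual(self) -> dict[str, float | None]:
        out = {}
        for s, m, c in zip(self.samples, self.matched, self.compared):
            out[s] = (m / c) if c > 0 else None
        return out

    @property
    def overall_precision(self) -> float:
        total = int(self.compared.sum())
        if total == 0:
            raise ConcordanceError("no shared non-missing genotype calls")
        return float(self.matched.sum()) / total


def _aligned(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix):
    shared_sites = [k for k in gm_a.sites if k in gm_b._site_index]
    shared_samples = [s for s in gm_a.samples if s in gm_b._sample_index]
    if not shared_sites or not shared_samples:
        raise ConcordanceError("no shared sites/samples between platforms")
    a = gm_a.subset_sites(shared_sites).subset_samples(shared_samples)
    b = gm_b.subset_sites(shared_sites).subset_samples(shared_samples)
    return shared_sites, shared_samples, a.dosage, b.dosage


def per_individual_concordance(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> ConcordanceResult:
    """Phase-insensitive per-individual concordance over shared sites.

    Calls missing on either platform are excluded from both numerator and
    denominator; an individual with no comparable calls is reported as
    undefined (None), not zero.
    """
    sites, samples, da, db = _aligned(gm_a, gm_b)
    both = (da != GenotypeMatrix.MISSING) & (db != GenotypeMatrix.MISSING)
    agree = both & (da == db)
    mism_counts = (both & (da != db)).sum(axis=1)
    return ConcordanceResult(
        samples=samples,
        matched=agree.sum(axis=0),
        compared=both.sum(axis=0),
        per_site_mismatch={k: int(m) for k, m in zip(sites, mism_counts)},
        shared_sites=sites,
    )


@dataclass
class PrecisionCurve:
    site_order: list[Key]          # sites by decreasing score
    cumulative_precision: np.ndarray
    compared_per_site: np.ndarray
    score_name: str = "score"

    @property
    def final_precision(self) -> float:
        return float(self.cumulative_precision[-1])

    def precision_at_fraction(self, frac: float) -> float:
        """Cumulative precision at the top ``frac`` of ranked sites."""
        k = max(1, int(round(frac * len(self.site_order))))
        return float(self.cumulative_precision[k - 1])


def cumulative_precision_curve(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix,
                               site_scores: dict[Key, float],
                               score_name: str = "score") -> PrecisionCurve:
    """Rank shared sites by decreasing score and accumulate pooled precision.

    Ties are broken by (chrom, pos) so the curve is reproducible.  Every
    compared site must carry a score.
    """
    sites, _samples, da, db = _aligned(gm_a, gm_b)
    missing_scores = [k for k in sites if k not in site_scores]
    if missing_scores:
        raise ConcordanceError(f"{len(missing_scores)} shared sites lack a score")
    order = sorted(range(len(sites)),
                   key=lambda i: (-site_scores[sites[i]], sites[i][0], sites[i][1]))
    both = (da != GenotypeMatrix.MISSING) & (db != GenotypeMatrix.MISSING)
    agree = both & (da == db)
    matched = agree.sum(axis=1)[order]
    compared = both.sum(axis=1)[order]
    cum_m = np.cumsum(matched)
    cum_c = np.cumsum(compared)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(cum_c > 0, cum_m / np.maximum(cum_c, 1), np.nan)
    return PrecisionCurve([sites[i] for i in order], prec, compared, score_name)


def compare_rankings(curve_a: PrecisionCurve, curve_b: PrecisionCurve,
                     quantiles=(0.1,)) -> dict:
    """Precision of two rankings of the same comparison set at top quantiles.

    Returns per-quantile precisions and whether ``curve_b`` dominates (is at
    least as precise as) ``curve_a`` at every requested quantile.
    """
    if set(curve_a.site_order) != set(curve_b.site_order):
        raise ConcordanceError("curves computed on different site sets")
    if len(curve_a.site_order) != len(curve_b.site_order):
        raise ConcordanceError("curves of different lengths")
    rows = []
    for q in quantiles:
        pa = curve_a.precision_at_fraction(q)
        pb = curve_b.precision_at_fraction(q)
        rows.append({"quantile": q, curve_a.score_name: pa,
                     curve_b.score_name: pb, "difference": pb - pa})
    return {
        "quantiles": rows,
        "b_dominates": all(r["difference"] >= 0 for r in rows),
        "final_precision": curve_a.final_precision,
    }
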
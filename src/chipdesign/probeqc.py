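"""Probe conversion classification, best-probe selection, and sample QC.

Each array probe is classified from its genotype calls across samples:
``PolyHighResolution`` (good clusters, at least two minor-allele copies and
a minor homozygote present), ``NoMinorHom`` (good clusters, minor alleles
present but no minor homozygote), ``MonoHighResolution`` (good clusters,
fewer than two minor-allele copies), ``CallRateBelowThreshold``, or
``Other`` (poor clustering, off-target variation and similar failures,
signalled by the caller via the ``cluster_ok`` flag).  SNPs assayed by
several probes get a best probe by category order, with the guard that a
NoMinorHom probe showing extreme Hardy-Weinberg departure (chi-squared
p <= 1e-5) is ineligible.  Sample QC is two-stage: a per-sample call-rate
floor, then per-plate pass-rate floors that differ by tissue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class QCError(ValueError):
    pass


class ConversionCategory(enum.Enum):
    POLY_HIGH_RESOLUTION = "PolyHighResolution"
    MONO_HIGH_RESOLUTION = "MonoHighResolution"
    NO_MINOR_HOM = "NoMinorHom"
    CALL_RATE_BELOW_THRESHOLD = "CallRateBelowThreshold"
    OTHER = "Other"


#: best-first order for best-probe selection
CATEGORY_RANK = {
    ConversionCategory.POLY_HIGH_RESOLUTION: 0,
    ConversionCategory.MONO_HIGH_RESOLUTION: 1,
    ConversionCategory.NO_MINOR_HOM: 2,
}


def genotype_counts(calls) -> tuple[int, int, int]:
    """(hom_ref, het, hom_alt) counts, ignoring missing (-1) calls."""
    calls = np.asarray(calls)
    calls = calls[calls != -1]
    return (int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum()))


def classify_conversion(calls, call_rate: float, cluster_ok: bool,
                        call_rate_min: float = 0.97) -> ConversionCategory:
    """Pure-function conversion category from one probe's calls."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise QCError("cannot classify a probe with no calls")
    if call_rate < call_rate_min:
        return ConversionCategory.CALL_RATE_BELOW_THRESHOLD
    if not cluster_ok:
        return ConversionCategory.OTHER
    aa, ab, bb = genotype_counts(calls)
    alt = ab + 2 * bb
    total = 2 * (aa + ab + bb)
    alt_is_minor = alt * 2 <= total
    minor_hom = bb if alt_is_minor else aa
    # "examples of the minor allele" = samples carrying at least one copy
    minor_samples = ab + (bb if alt_is_minor else aa)
    if minor_samples < 2:
        return ConversionCategory.MONO_HIGH_RESOLUTION
    if minor_hom == 0:
        return ConversionCategory.NO_MINOR_HOM
    return ConversionCategory.POLY_HIGH_RESOLUTION


def hwe_chisq(counts: tuple[int, int, int]) -> dict:
    """1-df chi-squared test of Hardy-Weinberg proportions.

    ``counts`` are (hom_ref, het, hom_alt) observed genotype counts; the
    expectation uses allele frequencies estimated from the same sample.
    Monomorphic input returns chi2 = 0, p = 1.
    """
    aa, ab, bb = counts
    n = aa + ab + bb
    if n <= 0:
        raise QCError("total genotype count must be positive")
    p = (2 * aa + ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return {"chi2": 0.0, "p": 1.0}
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([aa, ab, bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return {"chi2": chi2, "p": float(sps.chi2.sf(chi2, df=1))}


@dataclass
class ProbeResult:
    probe_id: str
    category: ConversionCategory
    call_rate: float
    counts: tuple[int, int, int]


def best_probe(probes: list[ProbeResult], hwe_p_max: float = 1e-5) -> ProbeResult | None:
    """Best probe for a SNP, or None if no probe is eligible (SNP dropped).

    Eligible categories in order: PolyHighResolution, MonoHighResolution,
    NoMinorHom — but a NoMinorHom probe with HWE p <= ``hwe_p_max`` is
    ineligible.  Ties within a category go to the higher call rate, then
    the lower probe index.
    """
    eligible = []
    for idx, probe in enumerate(probes):
        if probe.category not in CATEGORY_RANK:
            continue
        if probe.category is ConversionCategory.NO_MINOR_HOM:
            if hwe_chisq(probe.counts)["p"] <= hwe_p_max:
                continue
        eligible.append((CATEGORY_RANK[probe.category], -probe.call_rate, idx, probe))
    if not eligible:
        return None
    return min(eligible)[3]


def sample_qc(call_rates: dict[str, float], plate_map: dict[str, tuple[str, str]],
              call_rate_min: float = 0.97,
              plate_pass_min: dict[str, float] | None = None) -> dict:
    """Two-stage sample QC: call-rate floor, then plate pass-rate by tissue.

    ``plate_map`` assigns each sample (plate, tissue); default plate floors
    are 0.95 for blood and 0.93 for hair.  A plate below its tissue's floor
    is dropped whole.  Unknown tissue labels are an error.
    """
    plate_pass_min = plate_pass_min or {"blood": 0.95, "hair": 0.93}
    for sample, (_plate, tissue) in plate_map.items():
        if tissue not in plate_pass_min:
            raise QCError(f"unknown tissue {tissue!r} for sample {sample}")
    stage1_pass = {s for s, r in call_rates.items() if r >= call_rate_min}
    stage1_fail = set(call_rates) - stage1_pass

    plates: dict[tuple[str, str], list[str]] = {}
    for sample in call_rates:
        plate, tissue = plate_map[sample]
        plates.setdefault((plate, tissue), []).append(sample)
    dropped_plates = []
    failed_by_plate = set()
    for (plate, tissue), members in sorted(plates.items()):
        rate = sum(1 for m in members if m in stage1_pass) / len(members)
        if rate < plate_pass_min[tissue]:
            dropped_plates.append(plate)
            failed_by_plate |= set(members)
    passed = sorted(stage1_pass - failed_by_plate)
    return {
        "passed": passed,
        "failed_call_rate": sorted(stage1_fail),
        "failed_plate": sorted(failed_by_plate & stage1_pass),
        "dropped_plates": dropped_plates,
    }
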
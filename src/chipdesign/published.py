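"""Published design bookkeeping for the MNEc equine arrays.

The toolkit's methods were developed for the MNEc2M / MNEc670k horse
genotyping arrays; the printed design counts for those arrays are bundled
here as reference inputs so that the arithmetic of the published design —
inclusion-group totals, probe conversion rate, genic fractions, window
tiling, legacy-array overlap — can be recomputed and checked without the
underlying cohort data (which is not redistributable at desk scale).
"""

from __future__ import annotations

#: unique-site counts of the SNP sets at each design stage
SET_SIZES = {
    "discovered": 22_557_988,        # intersection of the two callers
    "array_compatible": 11_435_936,  # after repeat/proximity/rarity filters
    "array_candidate": 5_443_950,    # after LD pruning / priority selection
    "test_array": 2_001_826,         # high-density design set
    "test_array_converted": 1_846_988,
    "commercial_array": 670_805,
}

#: per-caller discovery counts feeding the two-caller intersection
CALLER_COUNTS = {"samtools": 26_884_885, "gatk": 31_506_364}

#: commercial-array inclusion-criteria counts (label -> SNPs admitted)
INCLUSION_COUNTS = {
    "Inter": 355_903,
    "Intra": 206_822,
    "Diverse": 13_993,
    "MHC": 7_394,
    "Density": 16_398,
    "VIP": 70_295,
}

#: SNPs inside annotated gene models (array -> (snps_in_genes, genes_with_snps))
GENIC_COUNTS = {
    "test_array": (591_521, 17_128),
    "commercial_array": (192_681, 14_758),
    "legacy": (20_950, 8_249),
}
N_GENE_MODELS = 26_991

#: legacy-array backwards compatibility
LEGACY_UNIQUE_SNPS = 74_056
LEGACY_IN_COMPATIBLE_SET = 48_485

#: genome layout used for the high-density design
GENOME_SIZE_BP = 2_700_000_000
WINDOW_SIZE_BP = 50_000
WINDOW_QUOTA = 37
DENSITY_MIN_PER_WINDOW = 8

#: marginal filter removal counts (overlapping; not additive)
FILTER_COUNTS = {"repeat": 780, "proximity": 9_342_733, "rare": 4_858_273}
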
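"""Masking plans, the haplotype-copying imputer, and accuracy metrics."""

import numpy as np
import pytest

from chipdesign.catalog import BreedGroupMap, GenotypeMatrix
from chipdesign.impute import (ImputationError, evaluate_imputation,
                               impute_reference, major_genotype_baseline,
                               make_masking_plan, mask_matrix,
                               reference_panel, run_masked_imputation)
from chipdesign.simulate import SimConfig, simulate_population
from conftest import make_gm


def group_map(n_per_group: dict[str, int]) -> tuple[list[str], BreedGroupMap]:
    samples, mapping = [], {}
    for g, n in n_per_group.items():
        for i in range(n):
            name = f"{g}_{i}"
            samples.append(name)
            mapping[name] = g
    return samples, BreedGroupMap(mapping)


class TestMaskingPlan:
    def test_one_third_held_out(self):
        samples, gmap = group_map({"a": 15})
        keys = [("1", i, "A", "G") for i in range(1, 10)]
        plan = make_masking_plan(samples, gmap, keys[:3], keys, seed=1)
        assert len(plan.held_out["a"]) == 5

    def test_same_seed_same_plan(self):
        samples, gmap = group_map({"a": 9, "b": 7})
        keys = [("1", i, "A", "G") for i in range(1, 10)]
        p1 = make_masking_plan(samples, gmap, keys[:3], keys, seed=4)
        p2 = make_masking_plan(samples, gmap, keys[:3], keys, seed=4)
        assert p1.held_out == p2.held_out

    def test_tiny_group_warns_and_holds_one(self):
        samples, gmap = group_map({"a": 2})
        keys = [("1", i, "A", "G") for i in range(1, 5)]
        with pytest.warns(UserWarning):
            plan = make_masking_plan(samples, gmap, keys[:2], keys, seed=0)
        assert len(plan.held_out["a"]) == 1

    def test_retained_must_be_subset(self):
        samples, gmap = group_map({"a": 3})
        keys = [("1", i, "A", "G") for i in range(1, 5)]
        with pytest.raises(ImputationError):
            make_masking_plan(samples, gmap, [("9", 1, "A", "G")], keys, seed=0)

    def test_json_round_trip(self, tmp_path):
        samples, gmap = group_map({"a": 6})
        keys = [("1", i, "A", "G") for i in range(1, 7)]
        plan = make_masking_plan(samples, gmap, keys[:2], keys, seed=2)
        path = str(tmp_path / "plan.json")
        plan.to_json(path)
        from chipdesign.impute import MaskingPlan
        back = MaskingPlan.from_json(path)
        assert back.held_out == plan.held_out
        assert back.retained_sites == plan.retained_sites


def test_leakage_guard_reference_excludes_held_out(small_cohort):
    gm = small_cohort.genotypes
    low = [k for i, k in enumerate(gm.sites) if i % 2 == 0]
    plan = make_masking_plan(gm.samples, small_cohort.group_map, low,
                             list(gm.sites), seed=5)
    ref = reference_panel(gm, plan)
    assert not set(ref.samples) & set(plan.all_held_out())
    masked = mask_matrix(gm, plan)
    # masked sites carry no information for held-out individuals
    retained = set(plan.retained_sites)
    for i, key in enumerate(masked.sites):
        if key not in retained:
            assert (masked.dosage[i] == GenotypeMatrix.MISSING).all()


class TestImputer:
    def test_clone_of_reference_individual_is_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n_sites = 60
        hap = rng.integers(0, 2, size=(n_sites, 10), dtype=np.int8)
        dosage = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
        ref = GenotypeMatrix([("1", i + 1, "A", "G") for i in range(n_sites)],
                             [f"r{j}" for j in range(5)], dosage,
                             hap.reshape(n_sites, 5, 2))
        target = dosage[:, [2]].copy()
        target[1::2] = GenotypeMatrix.MISSING  # mask every other site
        masked = GenotypeMatrix(ref.sites, ["t"], target)
        imputed, _ = impute_reference(masked, ref, switch_rate=0.001,
                                      error_rate=0.001)
        assert np.array_equal(imputed.dosage[:, 0], dosage[:, 2])

    def test_monomorphic_site_imputes_to_fixed_allele(self):
        n = 20
        dosage = np.zeros((n, 6), dtype=np.int8)
        dosage[5, :] = 2  # fixed alt site
        ref = make_gm(dosage)
        target = np.full((n, 1), GenotypeMatrix.MISSING, dtype=np.int8)
        target[0, 0] = 0
        masked = GenotypeMatrix(ref.sites, ["t"], target)
        imputed, _ = impute_reference(masked, ref)
        assert imputed.dosage[5, 0] == 2
        assert (imputed.dosage[np.arange(n) != 5, 0] == 0).all()

    def test_empty_reference_rejected(self):
        gm = make_gm(np.zeros((4, 2), dtype=int))
        empty = gm.subset_samples([])
        with pytest.raises(ImputationError):
            impute_reference(gm, empty)


class TestTwoRegimes:
    def _run(self, recombination_rate, seed=5, **kw):
        cfg = SimConfig(seed=seed, n_sites=300, n_breeds=3, samples_per_breed=10,
                        recombination_rate=recombination_rate,
                        false_site_fraction=0.0, **kw)
        res = simulate_population(cfg)
        gm = res.genotypes
        low = [k for i, k in enumerate(gm.sites) if i % 3 == 0]
        plan, report = run_masked_imputation(gm, res.group_map, low, seed=11)
        ref = reference_panel(gm, plan)
        base = major_genotype_baseline(ref)
        truth = gm.subset_samples(plan.all_held_out()).subset_sites(plan.masked_sites())
        idx = [ref.site_pos(k) for k in plan.masked_sites()]
        ok = truth.dosage != GenotypeMatrix.MISSING
        baseline = float(np.mean((truth.dosage == base[idx][:, None])[ok]))
        return report.overall_concordance, baseline

    def test_strong_ld_beats_major_genotype_baseline(self):
        imputed, baseline = self._run(1e-7)
        assert imputed > baseline + 0.05

    def test_without_ld_converges_to_baseline(self):
        imputed, baseline = self._run(1.0)
        assert abs(imputed - baseline) < 0.10

    def test_accuracy_non_decreasing_in_panel_size(self):
        cfg = SimConfig(seed=8, n_sites=250, n_breeds=1, samples_per_breed=30,
                        recombination_rate=1e-6, false_site_fraction=0.0)
        res = simulate_population(cfg)
        gm = res.genotypes
        low = [k for i, k in enumerate(gm.sites) if i % 3 == 0]
        target = gm.subset_samples(gm.samples[:4])
        masked_d = target.dosage.copy()
        retained = set(low)
        for i, key in enumerate(target.sites):
            if key not in retained:
                masked_d[i] = GenotypeMatrix.MISSING
        masked = GenotypeMatrix(target.sites, target.samples, masked_d)
        accs = []
        for n_ref in (4, 12, 26):
            ref = gm.subset_samples(gm.samples[4:4 + n_ref])
            imputed, _ = impute_reference(masked, ref)
            m = np.array([k not in retained for k in target.sites])
            accs.append(float((imputed.dosage[m] == target.dosage[m]).mean()))
        assert accs[2] >= accs[0] - 0.02
        assert max(accs) == pytest.approx(accs[2], abs=0.03)


class TestEvaluate:
    def _plan(self, keys, retained, held):
        return type("P", (), {
            "held_out": held,
            "retained_sites": retained,
            "full_sites": keys,
            "all_held_out": lambda self=None: [s for g in sorted(held)
                                               for s in held[g]],
            "masked_sites": lambda self=None: [k for k in keys
                                               if k not in set(retained)],
        })()

    def test_perfect_imputation_scores_one_everywhere(self, small_cohort):
        gm = small_cohort.genotypes
        low = [k for i, k in enumerate(gm.sites) if i % 2 == 0]
        plan = make_masking_plan(gm.samples, small_cohort.group_map, low,
                                 list(gm.sites), seed=3)
        held = plan.all_held_out()
        imputed = gm.subset_samples(held)
        ref = reference_panel(gm, plan)
        report = evaluate_imputation(gm, imputed, plan, small_cohort.group_map,
                                     reference=ref)
        assert all(v == 1.0 for v in report.per_individual.values())
        assert (report.group_summary["mean"] == 1.0).all()
        valid = report.dose_correlation.dropna(subset=["r"])
        assert (valid["r"] > 0.999).all()

    def test_hand_counted_concordance(self):
        keys = [("1", i, "A", "G") for i in range(1, 6)]
        truth = GenotypeMatrix(keys, ["x"], np.array([[0], [1], [2], [1], [0]],
                                                     dtype=np.int8))
        imputed_d = np.array([[0], [1], [2], [0], [0]], dtype=np.int8)
        imputed = GenotypeMatrix(keys[1:], ["x"], imputed_d[1:])
        samples, gmap = group_map({"g": 1})
        plan = make_masking_plan(["x"], BreedGroupMap({"x": "g"}),
                                 keys[:1], keys, seed=0)
        report = evaluate_imputation(truth, imputed, plan, gmap)
        # 4 masked sites, one wrong -> 0.75
        assert report.per_individual["x"] == pytest.approx(0.75)

    def test_constant_truth_bin_reports_nan(self):
        keys = [("1", i, "A", "G") for i in range(1, 5)]
        truth = GenotypeMatrix(keys, ["x"], np.zeros((4, 1), dtype=np.int8))
        imputed = GenotypeMatrix(keys[1:], ["x"], np.zeros((3, 1), dtype=np.int8))
        ref = GenotypeMatrix(keys, ["r1", "r2"],
                             np.array([[0, 1], [0, 1], [0, 1], [0, 1]], dtype=np.int8))
        plan = make_masking_plan(["x"], BreedGroupMap({"x": "g"}),
                                 keys[:1], keys, seed=0)
        report = evaluate_imputation(truth, imputed, plan,
                                     BreedGroupMap({"x": "g"}), reference=ref)
        with_cells = report.dose_correlation[report.dose_correlation.n_cells > 0]
        assert with_cells["r"].isna().all()


def test_low_mac_bins_show_lower_dose_correlation():
    """Rare variants impute worse than common ones on a realistic cohort."""
    cfg = SimConfig(seed=6, n_sites=500, n_breeds=3, samples_per_breed=10,
                    recombination_rate=2e-6)
    res = simulate_population(cfg)
    gm = res.genotypes
    low = [k for i, k in enumerate(gm.sites) if i % 3 == 0]
    _plan, report = run_masked_imputation(gm, res.group_map, low, seed=11)
    dc = report.dose_correlation.dropna(subset=["r"])
    low_bins = dc[dc.mac_lo <= 2]["r"].mean()
    high_bins = dc[dc.mac_lo >= 9]["r"].mean()
    assert low_bins < high_bins
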
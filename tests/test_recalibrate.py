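"""Gold-standard construction, Gaussian recalibration, VQSLOD behaviour."""

import numpy as np
import pytest

from chipdesign.catalog import ANNOTATIONS, AnnotationVector, Catalog, VariantSite
from chipdesign.recalibrate import (GoldStandardSpec, RecalModel,
                                    RecalibrationError, build_gold_standard,
                                    score_logistic, score_vqslod,
                                    train_logistic_recalibrator,
                                    train_recalibrator)
from chipdesign.simulate import SimConfig, simulate_population
from conftest import make_sites


class TestGoldStandard:
    def test_multi_group_threshold(self):
        catalog = make_sites([100, 200, 300],
                             groups=[{"g1", "g2", "g3", "g4", "g5"},
                                     {"g1", "g2", "g3"},
                                     {"g1", "g2", "g3", "g4"}])
        gold = build_gold_standard(catalog, GoldStandardSpec(mode="multi_group", k_groups=4))
        assert gold == {("1", 100, "A", "G"), ("1", 300, "A", "G")}

    def test_qual_percentile_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(42)
        quals = rng.exponential(100, size=1000)
        catalog = make_sites(range(1, 1001), quals=quals)
        gold = build_gold_standard(
            catalog, GoldStandardSpec(mode="qual_top_percentile", percentile=1.0))
        oracle = {catalog.sites[i].key for i in np.argsort(-quals)[:10]}
        assert gold == oracle and len(gold) == 10

    def test_legacy_mode_requires_sites(self):
        catalog = make_sites([100])
        with pytest.raises(RecalibrationError):
            build_gold_standard(catalog, GoldStandardSpec(mode="legacy_overlap"))
        gold = build_gold_standard(
            catalog, GoldStandardSpec(mode="legacy_overlap",
                                      legacy_sites={("1", 100, "A", "G")}))
        assert gold == {("1", 100, "A", "G")}

    def test_spec_validation(self):
        with pytest.raises(RecalibrationError):
            GoldStandardSpec(mode="nope")
        with pytest.raises(RecalibrationError):
            GoldStandardSpec(percentile=60.0)


def _two_class_catalog(n=600, shift=4.0, seed=0, chroms=("1", "2", "3")):
    """Half gold sites at +shift/2, half background at -shift/2 (unit sd)."""
    rng = np.random.default_rng(seed)
    sites, gold = [], set()
    for i in range(n):
        is_gold = i % 2 == 0
        mu = shift / 2.0 if is_gold else -shift / 2.0
        vals = rng.normal(mu, 1.0, size=5)
        site = VariantSite(chrom=chroms[i % len(chroms)], pos=10 * i + 10,
                           ref="A", alt="G", qual=50.0,
                           annotations=AnnotationVector(
                               DP=abs(vals[0]) + 1, QD=vals[1], FS=abs(vals[2]),
                               MQRankSum=vals[3], ReadPosRankSum=vals[4]))
        sites.append(site)
        if is_gold:
            gold.add(site.key)
    return Catalog(sites), gold


class TestTraining:
    def test_parameter_recovery_on_gaussian_annotations(self):
        rng = np.random.default_rng(1)
        true_mu = np.array([30.0, 20.0, 5.0, 0.5, -0.5])
        sd = np.array([5.0, 4.0, 2.0, 1.0, 1.0])
        n = 800
        sites = []
        for i in range(n):
            v = rng.normal(true_mu, sd)
            sites.append(VariantSite("1", i + 1, "A", "G", qual=10.0,
                                     annotations=AnnotationVector(
                                         DP=max(v[0], 0), QD=v[1], FS=max(v[2], 0),
                                         MQRankSum=v[3], ReadPosRankSum=v[4])))
        catalog = Catalog(sites)
        gold = set(catalog.keys())
        model = train_recalibrator(catalog, gold)
        recovered = model.standardize_mean + model.pos_mean * model.standardize_std
        se = sd / np.sqrt(n)
        assert (np.abs(recovered - true_mu) < 3 * se + 0.2).all()

    def test_training_chromosome_metadata(self):
        catalog, gold = _two_class_catalog()
        model = train_recalibrator(catalog, gold, training_chroms=["2", "3"],
                                   min_gold=50)
        assert model.training_chroms == ["2", "3"]

    def test_constant_annotations_error(self):
        sites = [VariantSite("1", i + 1, "A", "G", qual=1.0,
                             annotations=AnnotationVector(DP=10, QD=5, FS=1,
                                                          MQRankSum=0, ReadPosRankSum=0))
                 for i in range(300)]
        catalog = Catalog(sites)
        with pytest.raises(RecalibrationError), pytest.warns(UserWarning):
            train_recalibrator(catalog, set(catalog.keys()), min_gold=10)

    def test_too_few_gold_sites_error(self):
        catalog, gold = _two_class_catalog(n=100)
        with pytest.raises(RecalibrationError):
            train_recalibrator(catalog, gold, min_gold=100)


class TestScoring:
    def test_signs_at_class_means(self):
        catalog, gold = _two_class_catalog()
        model = train_recalibrator(catalog, gold, min_gold=50)
        scores = score_vqslod(model, catalog, write=False)
        gold_mask = np.array([s.key in gold for s in catalog])
        assert scores[gold_mask].mean() > 0
        assert scores[~gold_mask].mean() < 0
        assert np.isfinite(scores).all()
        assert (np.abs(scores) <= model.clip).all()

    def test_missing_annotations_marginalized(self):
        catalog, gold = _two_class_catalog()
        model = train_recalibrator(catalog, gold, min_gold=50)
        full = score_vqslod(model, catalog, write=False)
        for site in catalog:
            site.annotations.MQRankSum = None
        partial = score_vqslod(model, catalog, write=False)
        assert np.isfinite(partial).all()
        # marginal scores track full scores but are not identical
        assert np.corrcoef(full, partial)[0, 1] > 0.9
        assert not np.allclose(full, partial)

    def test_affine_rescaling_of_one_annotation_is_absorbed(self):
        catalog, gold = _two_class_catalog()
        model = train_recalibrator(catalog, gold, min_gold=50)
        base = score_vqslod(model, catalog, write=False)
        for site in catalog:
            site.annotations.QD = 7.0 * site.annotations.QD + 3.0
        model2 = train_recalibrator(catalog, gold, min_gold=50)
        rescaled = score_vqslod(model2, catalog, write=False)
        assert rescaled == pytest.approx(base, abs=1e-6)

    def test_out_of_chromosome_scores_unchanged_by_holdout_choice(self):
        catalog, gold = _two_class_catalog(n=900)
        m_23 = train_recalibrator(catalog, gold, training_chroms=["2", "3"],
                                  min_gold=50)
        chrom1 = catalog.subset([s.key for s in catalog if s.chrom == "1"])
        s1 = score_vqslod(m_23, chrom1, write=False)
        assert np.isfinite(s1).all()
        # the evaluation chromosome's sites never entered training
        assert "1" not in m_23.training_chroms


class TestRankingDominance:
    def test_vqslod_dominates_qual_on_labeled_sites(self):
        cfg = SimConfig(seed=13, n_sites=2500, n_breeds=6, samples_per_breed=4,
                        false_site_fraction=0.25)
        res = simulate_population(cfg)
        gold = build_gold_standard(res.catalog,
                                   GoldStandardSpec(mode="multi_group", k_groups=4))
        model = train_recalibrator(res.catalog, gold, min_gold=50)
        vq = score_vqslod(model, res.catalog, write=False)
        qual = res.catalog.qual_array()
        y = res.truth_is_true_site
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, vq) >= roc_auc_score(y, qual)
        # cumulative precision at every decile of the ranking
        order_v = np.argsort(-vq)
        order_q = np.argsort(-qual)
        n = len(y)
        for decile in range(1, 11):
            k = int(n * decile / 10)
            prec_v = y[order_v[:k]].mean()
            prec_q = y[order_q[:k]].mean()
            assert prec_v >= prec_q - 1e-12

    def test_logistic_backend_agrees_qualitatively(self):
        catalog, gold = _two_class_catalog()
        model = train_logistic_recalibrator(catalog, gold, min_gold=50)
        scores = score_logistic(model, catalog)
        gold_mask = np.array([s.key in gold for s in catalog])
        assert scores[gold_mask].mean() > scores[~gold_mask].mean()


def test_model_json_round_trip(tmp_path):
    catalog, gold = _two_class_catalog()
    model = train_recalibrator(catalog, gold, min_gold=50)
    path = str(tmp_path / "model.json")
    model.to_json(path)
    back = RecalModel.from_json(path)
    assert back.features == model.features
    assert np.allclose(back.pos_cov, model.pos_cov)
    assert score_vqslod(back, catalog, write=False) == pytest.approx(
        score_vqslod(model, catalog, write=False))
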
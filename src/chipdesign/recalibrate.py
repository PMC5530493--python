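"""Composite variant quality recalibration (VQSLOD scores).

A trusted ("gold standard") subset of the catalog anchors a positive class:
a multivariate Gaussian is fit to its standardized annotations
(DP, QD, FS, MQRankSum, ReadPosRankSum).  A negative class is fit to the
sites least plausible under the positive model (the lowest-density tail).
Each site's VQSLOD is the log10 ratio of positive to negative class density
at its annotation vector; missing annotations are marginalized out of both
Gaussians (a zero rank sum is a meaningful value, so missing values are
never imputed to zero).

Gold standards can come from a legacy-array site list, from recurrence
across independent calling groups (default: seen in 4+ groups), or from the
top percentile of QUAL scores.  Models record which chromosomes they were
trained on so evaluation can be held strictly out-of-chromosome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from .catalog import ANNOTATIONS, Catalog, Key


class RecalibrationError(ValueError):
    pass


@dataclass
class GoldStandardSpec:
    """How to construct the trusted training subset.

    Exactly one mode is active: ``legacy_overlap`` (membership in a supplied
    legacy site list), ``multi_group`` (observed in ``k_groups`` or more
    calling groups), or ``qual_top_percentile`` (top ``percentile`` % of the
    catalog's QUAL distribution).
    """

    mode: str = "multi_group"
    k_groups: int = 4
    percentile: float = 1.0
    legacy_sites: set[Key] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("legacy_overlap", "multi_group", "qual_top_percentile"):
            raise RecalibrationError(f"unknown gold-standard mode {self.mode!r}")
        if self.k_groups < 2:
            raise RecalibrationError("k_groups must be >= 2")
        if not 0.0 < self.percentile <= 50.0:
            raise RecalibrationError("percentile must be in (0, 50]")


def build_gold_standard(catalog: Catalog, spec: GoldStandardSpec) -> set[Key]:
    """Return the site keys satisfying the gold-standard specification."""
    if spec.mode == "legacy_overlap":
        if not spec.legacy_sites:
            raise RecalibrationError("legacy_overlap mode requires a non-empty legacy site list")
        legacy = set(spec.legacy_sites)
        return {s.key for s in catalog if s.key in legacy}
    if spec.mode == "multi_group":
        return {s.key for s in catalog if len(s.groups_observed) >= spec.k_groups}
    # qual_top_percentile: take the top round(n * p / 100) sites by QUAL,
    # ties broken by genomic position for determinism
    scored = [(s.qual, s.key) for s in catalog if s.qual is not None]
    if not scored:
        raise RecalibrationError("no QUAL scores in catalog")
    k = max(1, round(len(scored) * spec.percentile / 100.0))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return {key for _, key in scored[:k]}


@dataclass
class RecalModel:
    """Two-Gaussian density-ratio model over standardized annotations."""

    features: list[str]
    standardize_mean: np.ndarray
    standardize_std: np.ndarray
    pos_mean: np.ndarray
    pos_cov: np.ndarray
    neg_mean: np.ndarray
    neg_cov: np.ndarray
    training_chroms: list[str]
    clip: float = 20.0

    def to_json(self, path: str) -> None:
        payload = {
            "format_version": 1,
            "features": self.features,
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_std": self.standardize_std.tolist(),
            "pos_mean": self.pos_mean.tolist(),
            "pos_cov": self.pos_cov.tolist(),
            "neg_mean": self.neg_mean.tolist(),
            "neg_cov": self.neg_cov.tolist(),
            "training_chroms": self.training_chroms,
            "clip": self.clip,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "RecalModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            features=p["features"],
            standardize_mean=np.array(p["standardize_mean"]),
            standardize_std=np.array(p["standardize_std"]),
            pos_mean=np.array(p["pos_mean"]),
            pos_cov=np.array(p["pos_cov"]),
            neg_mean=np.array(p["neg_mean"]),
            neg_cov=np.array(p["neg_cov"]),
            training_chroms=p["training_chroms"],
            clip=p["clip"],
        )


def _regularized_cov(x: np.ndarray, reg: float) -> np.ndarray:
    cov = np.atleast_2d(np.cov(x, rowvar=False))
    cov = cov + reg * max(np.trace(cov), 1e-12) * np.eye(cov.shape[0])
    return cov


def train_recalibrator(catalog: Catalog, gold_sites: set[Key],
                       training_chroms=None, min_gold: int = 100,
                       neg_tail_fraction: float = 0.05,
                       reg: float = 1e-6) -> RecalModel:
    """Fit the positive/negative Gaussian pair on the training chromosomes.

    The positive class is fit to gold sites with complete annotations; the
    negative class to the ``neg_tail_fraction`` of all training sites with
    the lowest density under the positive model.  Zero-variance annotations
    are dropped with a warning; if none remain, training fails.
    """
    if training_chroms is not None:
        training_chroms = [str(c) for c in training_chroms]
        train_sites = [s for s in catalog if s.chrom in training_chroms]
    else:
        train_sites = list(catalog.sites)
        training_chroms = sorted({s.chrom for s in train_sites})
    ann = np.array([s.annotations.as_array() for s in train_sites])
    complete = ~np.isnan(ann).any(axis=1)
    gold_mask = np.array([s.key in gold_sites for s in train_sites])

    keep = []
    for j, name in enumerate(ANNOTATIONS):
        col = ann[complete, j]
        if col.size and np.std(col) > 0:
            keep.append(j)
        else:
            warnings.warn(f"annotation {name} is constant on training data; dropped")
    if not keep:
        raise RecalibrationError("no trainable annotation: all features constant")
    features = [ANNOTATIONS[j] for j in keep]
    x = ann[:, keep]
    complete = ~np.isnan(x).any(axis=1)

    mean = np.nanmean(x, axis=0)
    std = np.nanstd(x, axis=0)
    z = (x - mean) / std

    pos = z[complete & gold_mask]
    if pos.shape[0] < min_gold:
        raise RecalibrationError(
            f"only {pos.shape[0]} fully-annotated gold sites on training "
            f"chromosomes; need >= {min_gold}")
    pos_mean = pos.mean(axis=0)
    pos_cov = _regularized_cov(pos, reg)

    all_complete = z[complete]
    dens = multivariate_normal(pos_mean, pos_cov).logpdf(all_complete)
    n_tail = max(2, int(np.ceil(neg_tail_fraction * all_complete.shape[0])))
    tail = all_complete[np.argsort(dens)[:n_tail]]
    neg_mean = tail.mean(axis=0)
    neg_cov = _regularized_cov(tail, reg)

    return RecalModel(features, mean, std, pos_mean, pos_cov,
                      neg_mean, neg_cov, training_chroms)


def _marginal_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                     dims: np.ndarray) -> np.ndarray:
    sub_mean = mean[dims]
    sub_cov = cov[np.ix_(dims, dims)]
    return multivariate_normal(sub_mean, sub_cov).logpdf(x[:, dims])


def score_vqslod(model: RecalModel, catalog: Catalog, write: bool = True) -> np.ndarray:
    """VQSLOD = log10 positive/negative density ratio per site.

    Sites with missing annotations are scored on the marginal distribution
    over their observed dimensions; a site with no observed annotation gets
    a score of 0 (uninformative).  Scores are clipped to ±``model.clip``.
    """
    feat_idx = [ANNOTATIONS.index(f) for f in model.features]
    ann = catalog.annotation_matrix()[:, feat_idx]
    z = (ann - model.standardize_mean) / model.standardize_std
    n = z.shape[0]
    scores = np.zeros(n)
    observed = ~np.isnan(z)
    # group sites by missingness pattern; patterns are few in practice
    patterns: dict[tuple, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(tuple(observed[i]), []).append(i)
    ln10 = np.log(10.0)
    for pat, idx in patterns.items():
        idx = np.asarray(idx)
        dims = np.flatnonzero(np.array(pat))
        if dims.size == 0:
            continue
        xi = np.nan_to_num(z[idx])
        lp = _marginal_logpdf(xi, model.pos_mean, model.pos_cov, dims)
        ln = _marginal_logpdf(xi, model.neg_mean, model.neg_cov, dims)
        scores[idx] = np.clip((lp - ln) / ln10, -model.clip, model.clip)
    if write:
        for site, sc in zip(catalog, scores):
            site.vqslod = float(sc)
    return scores


# ---------------------------------------------------------------------------
# alternative backend: regularized logistic regression (gold vs rest)


@dataclass
class LogisticRecalModel:
    features: list[str]
    standardize_mean: np.ndarray
    standardize_std: np.ndarray
    coef: np.ndarray  # intercept first
    training_chroms: list[str]
    clip: float = 20.0


def train_logistic_recalibrator(catalog: Catalog, gold_sites: set[Key],
                                training_chroms=None, l2: float = 1e-3,
                                min_gold: int = 100) -> LogisticRecalModel:
    """Logistic-regression alternative to the Gaussian density-ratio model."""
    if training_chroms is not None:
        training_chroms = [str(c) for c in training_chroms]
        train_sites = [s for s in catalog if s.chrom in training_chroms]
    else:
        train_sites = list(catalog.sites)
        training_chroms = sorted({s.chrom for s in train_sites})
    ann = np.array([s.annotations.as_array() for s in train_sites])
    complete = ~np.isnan(ann).any(axis=1)
    y = np.array([s.key in gold_sites for s in train_sites])[complete].astype(float)
    if y.sum() < min_gold:
        raise RecalibrationError("too few fully-annotated gold sites for logistic fit")
    x = ann[complete]
    mean, std = x.mean(axis=0), x.std(axis=0)
    std[std == 0] = 1.0
    z = np.column_stack([np.ones(x.shape[0]), (x - mean) / std])

    def loss(w):
        eta = z @ w
        return (np.logaddexp(0.0, eta) - y * eta).sum() + l2 * (w[1:] ** 2).sum()

    res = minimize(loss, np.zeros(z.shape[1]), method="L-BFGS-B")
    return LogisticRecalModel(list(ANNOTATIONS), mean, std, res.x, training_chroms)


def score_logistic(model: LogisticRecalModel, catalog: Catalog) -> np.ndarray:
    """Log10-odds scores from the logistic backend (missing set to column mean)."""
    ann = catalog.annotation_matrix()
    z = (ann - model.standardize_mean) / model.standardize_std
    z = np.nan_to_num(z)  # column mean after standardization is 0
    eta = model.coef[0] + z @ model.coef[1:]
    return np.clip(eta / np.log(10.0), -model.clip, model.clip)
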
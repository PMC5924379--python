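"""Desk-scale replica of the study design: repeated stratified CV with
kappa-NN disease-incidence prediction under three data-sharing regimes.

* open system — sites pool raw data freely and fit one central model;
* closed system — each site fits and evaluates on its own data only, and
  the reported number is the unweighted mean over sites;
* federated — the distributed fit: shared hash functions, local codes.

Codes can be multi-hash (one block per feature domain), uni-hash (a single
function over the concatenated features with b = sum b_k), or skipped
entirely in favor of raw-feature distance baselines (euclidean, cityblock,
cosine, correlation). For a given seed every regime sees byte-identical
fold assignments, so comparisons are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from fedsimhash.cohort import SitePartitionPlan, partition_sites
from fedsimhash.errors import ConfigurationError
from fedsimhash.features import SiteDataset, as_uni_domain, pool_sites
from fedsimhash.federation import FederationConfig, federated_fit
from fedsimhash.hashcore import HashConfig, encode, fit_hash_model
from fedsimhash.simsearch import knn_vote_matrix

logger = logging.getLogger(__name__)

SYSTEMS = ("open", "closed", "federated")
CODE_MODES = ("multi", "uni", "raw")
BASELINE_METRICS = ("euclidean", "cityblock", "cosine", "correlation")


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation design and the regime under evaluation."""

    folds: int = 5
    repeats: int = 10
    kappa: tuple[int, ...] = (1, 3, 9)
    system: str = "federated"
    code_mode: str = "multi"
    baseline_metric: str = "cosine"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if any(k < 1 for k in self.kappa):
            raise ConfigurationError("kappa values must be >= 1")
        if self.system not in SYSTEMS:
            raise ConfigurationError(f"system must be one of {SYSTEMS}")
        if self.code_mode not in CODE_MODES:
            raise ConfigurationError(f"code_mode must be one of {CODE_MODES}")
        if self.baseline_metric not in BASELINE_METRICS:
            raise ConfigurationError(f"baseline_metric must be one of {BASELINE_METRICS}")


@dataclass
class MetricReport:
    """Per-repeat AUCs with summary statistics and threshold metrics.

    ``per_site`` carries the closed system's site-level AUC means; the
    headline closed-system number is their unweighted average. Sites whose
    test labels are single-class get NaN AUC and are flagged.
    """

    system: str
    code_mode: str
    kappa: int
    per_repeat_auc: list[float] = field(default_factory=list)
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    f1: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    per_site: dict[int, float] = field(default_factory=dict)
    undefined_sites: list[int] = field(default_factory=list)

    def summarize(self) -> None:
        vals = [v for v in self.per_repeat_auc if np.isfinite(v)]
        if vals:
            self.auc_mean = float(np.mean(vals))
            self.auc_sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "system": self.system,
            "code_mode": self.code_mode,
            "kappa": self.kappa,
            "per_repeat_auc": self.per_repeat_auc,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_site": {str(k): v for k, v in self.per_site.items()},
            "undefined_sites": self.undefined_sites,
        }


def compute_metrics(probs, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUC (rank statistic), F1, sensitivity, specificity at a threshold.

    AUC is the probability a random positive outranks a random negative;
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), F1 the harmonic
    mean of precision and recall.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ConfigurationError("probs and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("AUC undefined: labels contain a single class")
    auc = float(roc_auc_score(labels, probs))
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"auc": auc, "f1": f1, "sensitivity": sens, "specificity": spec}


def _fold_assignments(sites: Sequence[SiteDataset], folds: int, seed: int) -> list[np.ndarray]:
    """Per-site fold labels, stratified within site; deterministic in seed."""
    out = []
    for s in sites:
        fold_of = np.empty(s.n_patients, dtype=int)
        if len(np.unique(s.labels)) < 2:
            rng = np.random.default_rng(seed + s.site_index)
            fold_of[:] = rng.permutation(np.arange(s.n_patients) % folds)
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + s.site_index) % 2**31)
            for f, (_, test_idx) in enumerate(skf.split(np.zeros(s.n_patients), s.labels)):
                fold_of[test_idx] = f
        out.append(fold_of)
    return out


def _codes_matrix(model, site: SiteDataset) -> dict[str, np.ndarray]:
    return encode(model, site.P).codes


def _raw_votes(train: SiteDataset, test: SiteDataset, metric: str, kappa: int) -> np.ndarray:
    Xtr = np.concatenate([train.P[t] for t, _ in train.spec.domains], axis=0).T
    Xte = np.concatenate([test.P[t] for t, _ in test.spec.domains], axis=0).T
    D = cdist(Xte, Xtr, metric=metric)
    D = np.nan_to_num(D, nan=np.inf)  # constant vectors under correlation/cosine
    order = np.argsort(D, axis=1, kind="stable")[:, :kappa]
    return train.labels.astype(float)[order].mean(axis=1)


def _fit_for_system(system: str, train_sites: list[SiteDataset], cfg: HashConfig):
    """Fit the hash model under the given sharing regime; closed returns one per site."""
    if system == "open":
        pooled = pool_sites(train_sites)
        model, _, _ = fit_hash_model([pooled], cfg)
        return model
    if system == "federated":
        model, _, _ = federated_fit(train_sites, cfg, FederationConfig(M=len(train_sites)))
        return model
    raise ConfigurationError(system)


def _predict_fold(
    system: str,
    code_mode: str,
    train_sites: list[SiteDataset],
    test_sites: list[SiteDataset],
    cfg: HashConfig,
    eval_cfg: EvalConfig,
    kappa: int,
):
    """Vote probabilities and labels for one fold; closed yields per-site lists."""
    if code_mode == "uni":
        uni_bits = sum(cfg.bits_for(train_sites[0].spec))
        train_sites = [as_uni_domain(s) for s in train_sites]
        test_sites = [as_uni_domain(s) for s in test_sites]
        cfg = replace(cfg, bits_per_domain=(uni_bits,))

    if code_mode == "raw":
        if system in ("open", "federated"):
            train = pool_sites(train_sites)
            test = pool_sites(test_sites)
            votes = _raw_votes(train, test, eval_cfg.baseline_metric, kappa)
            return votes, test.labels, None
        per_site = []
        for tr, te in zip(train_sites, test_sites):
            per_site.append((_raw_votes(tr, te, eval_cfg.baseline_metric, kappa), te.labels))
        return None, None, per_site

    if system in ("open", "federated"):
        model = _fit_for_system(system, train_sites, cfg)
        ref_codes = _codes_matrix(model, pool_sites(train_sites))
        ref_labels = np.concatenate([s.labels for s in train_sites])
        test = pool_sites(test_sites)
        votes = knn_vote_matrix(_codes_matrix(model, test), ref_codes, ref_labels, kappa)
        return votes, test.labels, None

    # closed: per-site fit, per-site evaluation
    per_site = []
    for tr, te in zip(train_sites, test_sites):
        if len(np.unique(tr.labels)) < 2:
            per_site.append((None, te.labels))
            continue
        model, _, _ = fit_hash_model([tr], cfg)
        votes = knn_vote_matrix(_codes_matrix(model, te), _codes_matrix(model, tr), tr.labels, kappa)
        per_site.append((votes, te.labels))
    return None, None, per_site


def run_experiment(
    sites: Sequence[SiteDataset],
    cfg: HashConfig,
    eval_cfg: EvalConfig,
    kappa: int | None = None,
) -> MetricReport:
    """Repeated stratified CV of one system/code-mode configuration.

    Per repeat, each patient is predicted exactly once (when their fold is
    the test fold); AUC is computed over the repeat's full vote-probability
    vector. Fold assignments depend only on (labels, seed, repeat), so
    different systems evaluated at the same seed are paired.
    """
    kappa = kappa if kappa is not None else eval_cfg.kappa[min(1, len(eval_cfg.kappa) - 1)]
    sites = list(sites)
    report = MetricReport(system=eval_cfg.system, code_mode=eval_cfg.code_mode, kappa=kappa)
    site_aucs: dict[int, list[float]] = {s.site_index: [] for s in sites}
    thr_metrics: list[dict[str, float]] = []

    for rep in range(eval_cfg.repeats):
        folds = _fold_assignments(sites, eval_cfg.folds, seed=eval_cfg.seed * 1000 + rep)
        pooled_votes: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        per_site_votes: dict[int, list] = {s.site_index: [] for s in sites}
        for f in range(eval_cfg.folds):
            train_sites = [s.subset(np.flatnonzero(fold != f)) for s, fold in zip(sites, folds)]
            test_sites = [s.subset(np.flatnonzero(fold == f)) for s, fold in zip(sites, folds)]
            votes, labels, per_site = _predict_fold(
                eval_cfg.system, eval_cfg.code_mode, train_sites, test_sites, cfg, eval_cfg, kappa
            )
            if per_site is None:
                pooled_votes.append(votes)
                pooled_labels.append(labels)
            else:
                for s, (v, lab) in zip(sites, per_site):
                    per_site_votes[s.site_index].append((v, lab))
        if pooled_votes:
            votes = np.concatenate(pooled_votes)
            labels = np.concatenate(pooled_labels)
            m = compute_metrics(votes, labels, eval_cfg.threshold)
            report.per_repeat_auc.append(m["auc"])
            thr_metrics.append(m)
        else:
            aucs = []
            for idx, chunks in per_site_votes.items():
                usable = [(v, lab) for v, lab in chunks if v is not None]
                if not usable:
                    if idx not in report.undefined_sites:
                        report.undefined_sites.append(idx)
                    continue
                v = np.concatenate([c[0] for c in usable])
                lab = np.concatenate([c[1] for c in usable])
                if len(np.unique(lab)) < 2:
                    if idx not in report.undefined_sites:
                        report.undefined_sites.append(idx)
                    site_aucs[idx].append(float("nan"))
                    continue
                m = compute_metrics(v, lab, eval_cfg.threshold)
                site_aucs[idx].append(m["auc"])
                aucs.append(m["auc"])
                thr_metrics.append(m)
            report.per_repeat_auc.append(float(np.mean(aucs)) if aucs else float("nan"))

    report.per_site = {
        idx: (float(np.nanmean(v)) if v else float("nan")) for idx, v in site_aucs.items() if v
    }
    if thr_metrics:
        for key, attr in (("f1", "f1"), ("sensitivity", "sensitivity"), ("specificity", "specificity")):
            vals = [m[key] for m in thr_metrics if np.isfinite(m[key])]
            setattr(report, attr, float(np.mean(vals)) if vals else float("nan"))
    report.summarize()
    return report


def imbalance_experiment(
    cohort,
    spec,
    cfg: HashConfig,
    eval_cfg: EvalConfig,
    gamma: float = 0.01,
    target_code: str = "d_TARGET",
    site_size: int = 125,
    ratios: Sequence[float] = (0.1, 0.3, 0.5),
) -> dict[str, MetricReport]:
    """Balanced vs skewed site composition, same cohort and seeds.

    The balanced arm inherits the cohort's class rate at every site; the
    skewed arm assigns each site the requested positive fraction. Both
    arms run the same system/code-mode at the same evaluation seed.
    """
    from fedsimhash.features import assemble_site

    M = len(ratios)
    arms = {
        "balanced": SitePartitionPlan(M=M, per_site_sizes=(site_size,) * M),
        "imbalanced": SitePartitionPlan(
            M=M, per_site_sizes=(site_size,) * M, per_site_positive_fraction=tuple(ratios)
        ),
    }
    out = {}
    for name, plan in arms.items():
        parts = partition_sites(cohort, plan, seed=eval_cfg.seed)
        sites = [
            assemble_site(part, spec, gamma, target_code, site_index=i)
            for i, part in enumerate(parts)
        ]
        out[name] = run_experiment(sites, cfg, eval_cfg)
    return out
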
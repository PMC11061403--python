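"""Augmentation performance-evaluation protocol.

A deliberately data-starved *inverse* k-fold cross-validation trains on one
fold and validates on the rest, quantifying how much an augmentation strategy
recovers of the accuracy lost to the small training set; a regular k-fold on
the full data provides the ceiling.  Improvements are tested across subjects
with a paired t-test, after excluding subjects whose data the protocol cannot
speak to (chance-level performers and those whom shrinking the training set
did not hurt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CtmaugError, LengthMismatch, TooFewEpochs
from .pipeline import (
    EpochSet,
    apply_csp,
    balanced_accuracy,
    bandpass,
    extract_features,
    fit_csp,
    predict,
    train_classifier,
)

__all__ = [
    "PipelineConfig",
    "SubjectResult",
    "EvalReport",
    "inverse_cv",
    "full_cv",
    "filter_subjects",
    "paired_improvement_test",
    "proficiency_grid_search",
    "run_benchmark",
]


@dataclass
class PipelineConfig:
    """Settings shared by every train/validate split."""

    feature: str = "TP"
    hfd_n_max: int = 10
    band: tuple[float, float] = (8.0, 30.0)
    filter_order: int = 4
    prefiltered: bool = False    # set True when epochs are already band-passed


@dataclass
class SubjectResult:
    subject_id: str
    ac_full: float
    ac_small: float
    ac_strategy: dict = field(default_factory=dict)  # strategy name -> accuracy


@dataclass
class EvalReport:
    """Per-strategy cohort summary in the shape of a results table."""

    table: pd.DataFrame
    retained: list[str]
    excluded: dict
    subject_results: list[SubjectResult]
    proficiency_threshold: float | None = None


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator):
    """Random partition into k folds, separately per condition."""
    folds = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise TooFewEpochs(f"condition {c}: {idx.size} epochs < {k} folds")
        idx = rng.permutation(idx)
        for i, chunk in enumerate(np.array_split(idx, k)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def _evaluate_split(e_bp: EpochSet, train_idx: np.ndarray, val_idx: np.ndarray,
                    cfg: PipelineConfig, augmenter=None, seed: int = 0) -> float:
    """Fit the whole pipeline on the training indices, score the validation ones."""
    assert np.intersect1d(train_idx, val_idx).size == 0
    train = e_bp.select(train_idx)
    val = e_bp.select(val_idx)
    csp = fit_csp(train)
    src_train = apply_csp(csp, train)
    src_val = apply_csp(csp, val)
    feats_train = extract_features(src_train, cfg.feature, cfg.hfd_n_max)
    if augmenter is not None:
        feats_train = augmenter.training_features(
            train, csp, src_train, feats_train, cfg.feature, cfg.hfd_n_max, seed)
    feats_val = extract_features(src_val, cfg.feature, cfg.hfd_n_max)
    clf = train_classifier(feats_train)
    return balanced_accuracy(val.labels, predict(clf, feats_val))


def _prepared(e: EpochSet, cfg: PipelineConfig) -> EpochSet:
    if cfg.prefiltered:
        return e
    return bandpass(e, cfg.band[0], cfg.band[1], cfg.filter_order)


def inverse_cv(e: EpochSet, cfg: PipelineConfig | None = None,
               augmenter=None, k: int = 3, seed: int = 0) -> float:
    """Inverse k-fold CV: train on one fold, validate on the other k-1.

    Each fold serves once as the (small) training set; CSP fitting,
    augmentation and the classifier see only that fold.  Returns the mean
    balanced accuracy over the k rotations.
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    e_bp = _prepared(e, cfg)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(e_bp.labels, k, rng)
    accs = []
    for i, fold in enumerate(folds):
        rest = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        accs.append(_evaluate_split(e_bp, fold, rest, cfg, augmenter,
                                    seed=seed * 1000 + i))
    return float(np.mean(accs))


def full_cv(e: EpochSet, cfg: PipelineConfig | None = None,
            k: int = 7, seed: int = 0) -> float:
    """Regular stratified k-fold CV (train on k-1 folds)."""
    cfg = cfg if cfg is not None else PipelineConfig()
    e_bp = _prepared(e, cfg)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(e_bp.labels, k, rng)
    accs = []
    for i, fold in enumerate(folds):
        rest = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        accs.append(_evaluate_split(e_bp, rest, fold, cfg, seed=seed * 1000 + i))
    return float(np.mean(accs))


def filter_subjects(results: list[SubjectResult]) -> list[SubjectResult]:
    """Drop subjects for whom the protocol is uninformative.

    Exclusion criteria: full-set accuracy <= 0.5 (not separable), small-set
    accuracy <= 0.5 (chance-level baseline), or small-set accuracy above the
    full-set accuracy (shrinking the training set did not hurt).
    """
    keep = []
    for r in results:
        if r.ac_full <= 0.5 or r.ac_small <= 0.5 or r.ac_small > r.ac_full:
            continue
        keep.append(r)
    return keep


def paired_improvement_test(baseline, treated) -> tuple[float, float]:
    """Paired two-sided t-test on per-subject accuracy differences.

    Returns (mean difference, p-value); identical inputs give p = 1.
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.shape != b.shape:
        raise LengthMismatch("paired samples must have equal length")
    if a.size < 3:
        raise LengthMismatch("need at least 3 pairs")
    d = b - a
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    t = stats.ttest_rel(b, a)
    return float(d.mean()), float(t.pvalue)


def proficiency_grid_search(results: list[SubjectResult], strategies: list[str],
                            thresholds) -> float:
    """Baseline-accuracy threshold maximizing the number of successful strategies.

    For each candidate threshold, keeps subjects whose small-set accuracy is at
    least the threshold and counts strategies with a significant positive mean
    improvement (paired p < 0.05).  Ties resolve to the lowest threshold.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    best_thr, best_count = None, -1
    for thr in sorted(thresholds):
        subset = [r for r in results if r.ac_small >= thr]
        if len(subset) < 3:
            continue
        count = 0
        for s in strategies:
            base = [r.ac_small for r in subset]
            trt = [r.ac_strategy[s] for r in subset]
            delta, p = paired_improvement_test(base, trt)
            if delta > 0 and p < 0.05:
                count += 1
        if count > best_count:
            best_thr, best_count = thr, count
    if best_thr is None:
        raise ValueError("no threshold retains >= 3 subjects")
    return float(best_thr)


def run_benchmark(subjects: list[EpochSet], strategies: list,
                  cfg: PipelineConfig | None = None,
                  k_inverse: int = 3, k_full: int = 7,
                  seed: int = 0, n_repeats: int = 1) -> EvalReport:
    """Full cohort evaluation of augmentation strategies.

    Per subject: full-set k-fold accuracy, small-set inverse-CV baseline, and
    one inverse-CV run per strategy (augmentation applied inside each training
    fold only).  Subjects failing the exclusion criteria are dropped before
    the per-strategy paired tests.

    ``n_repeats`` re-randomizes the fold partition and averages the
    accuracies per subject; within each repeat the baseline and every
    strategy share the partition seed, so the treated/untreated comparison
    stays paired at the fold level while partition noise averages out.
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    ss = np.random.SeedSequence([int(seed), 0xEFA1])
    results = []
    failed: dict = {}
    for subj in subjects:
        states = ss.spawn(1)[0].generate_state(2 * n_repeats)
        try:
            fulls, smalls = [], []
            strat_accs: dict = {s.name: [] for s in strategies}
            for rep in range(n_repeats):
                small_seed = int(states[2 * rep + 1] % 2**31)
                fulls.append(full_cv(subj, cfg, k=k_full,
                                     seed=int(states[2 * rep] % 2**31)))
                smalls.append(inverse_cv(subj, cfg, None, k=k_inverse,
                                         seed=small_seed))
                for strat in strategies:
                    strat_accs[strat.name].append(inverse_cv(
                        subj, cfg, strat, k=k_inverse, seed=small_seed))
        except CtmaugError as exc:
            warnings.warn(f"subject {subj.subject_id} failed and is excluded: "
                          f"{type(exc).__name__}: {exc}")
            failed[subj.subject_id] = f"{type(exc).__name__}: {exc}"
            continue
        res = SubjectResult(
            subject_id=subj.subject_id,
            ac_full=float(np.mean(fulls)),
            ac_small=float(np.mean(smalls)),
            ac_strategy={k: float(np.mean(v)) for k, v in strat_accs.items()},
        )
        results.append(res)

    retained = filter_subjects(results)
    excluded = {r.subject_id: (r.ac_full, r.ac_small)
                for r in results if r not in retained}
    excluded.update(failed)
    rows = []
    base = [r.ac_small for r in retained]
    full = [r.ac_full for r in retained]
    for strat in strategies:
        trt = [r.ac_strategy[strat.name] for r in retained]
        d_small, p_small = paired_improvement_test(base, trt)
        d_full, p_full = paired_improvement_test(full, trt)
        rows.append({
            "strategy": strat.name,
            "augmented_ac": float(np.mean(trt)),
            "delta_vs_small": d_small,
            "p_vs_small": p_small,
            "delta_vs_full": d_full,
            "p_vs_full": p_full,
        })
    table = pd.DataFrame(
        rows, columns=["strategy", "augmented_ac", "delta_vs_small",
                       "p_vs_small", "delta_vs_full", "p_vs_full"])
    return EvalReport(
        table=table,
        retained=[r.subject_id for r in retained],
        excluded=excluded,
        subject_results=results,
    )
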
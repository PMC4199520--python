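"""Leave-one-out cross-validation harness and all reported metrics.

Every patient is predicted once by a model that never saw them: the variance
filter, the rank-sum feature ranking, any internal hyperparameter tuning and
the classifier fit are re-run inside each fold on the remaining patients
only.  This strict nesting is what makes the held-out probabilities a fair
estimate of predictive ability — fitting the feature selection on the full
cohort inflates apparent performance even on pure noise (the harness can
demonstrate this on request via ``unsafe_global_selection``, which exists
only as a diagnostic).

Metrics follow the clinical-reporting conventions for a two-class test:
ROC/AUC (Mann-Whitney ranking probability, ties at 1/2), a Youden-optimal
probability threshold, sensitivity and specificity with exact
Clopper-Pearson binomial intervals, a stratified-bootstrap AUC interval,
probability/covariate correlation, and summary report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .classifiers import ClassifierSpec, fit_classifier, predict_probabilities
from .io import LABEL_CD, LABEL_IBS, FaimsSample
from .pipeline_core import (
    SelectionModel,
    WaveletConfig,
    fit_variance_filter,
    select_top_k,
    transform_cohort,
    variance_cutoff,
)

logger = logging.getLogger("faimsvoc")

PROBABILITY_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class CvPrediction:
    """Held-out probability of CD for one patient."""

    patient_id: str
    true_label: str
    prob_cd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_cd <= 1.0:
            raise ValueError("prob_cd must lie in [0, 1]")

    @property
    def y(self) -> int:
        return 1 if self.true_label == LABEL_CD else 0


@dataclass
class RocResult:
    """ROC curve with AUC, chosen operating point, and all intervals."""

    points: list[tuple[float, float, float]]      # (FPR, TPR, threshold)
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis end to end."""

    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    variance_mode: str = "quantile"       # "quantile" (keep top fraction) | "absolute"
    variance_value: float = 0.05
    select_k: int = 30
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        wav = raw.get("wavelet", {})
        var = raw.get("variance", {})
        sel = raw.get("select", {})
        clf = raw.get("classifier", {})
        return cls(
            wavelet=WaveletConfig(
                order=wav.get("order", 4),
                boundary=wav.get("boundary", "periodic"),
                levels=wav.get("levels", "max"),
            ),
            variance_mode=var.get("mode", "quantile"),
            variance_value=var.get("value", 0.05),
            select_k=sel.get("k", 30),
            classifier=ClassifierSpec(
                kind=clf.get("kind", "sparse_logistic"),
                hyperparameters=clf.get("hyperparameters", {}),
                seed=clf.get("seed", raw.get("seed", 0)),
            ),
            seed=raw.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# LOO-CV harness
# ---------------------------------------------------------------------------

def _fit_selection(train: np.ndarray, train_y: np.ndarray,
                   config: PipelineConfig) -> SelectionModel:
    cutoff = variance_cutoff(train, config.variance_mode, config.variance_value)
    mask = fit_variance_filter(train, cutoff)
    return select_top_k(train, train_y, config.select_k, mask)


def run_loo_cv(cohort: Sequence[FaimsSample], pipeline: PipelineConfig,
               unsafe_global_selection: bool = False) -> list[CvPrediction]:
    """Leave-one-out cross-validation over patients.

    Returns one held-out CD probability per patient, in cohort order.
    Replicate aggregation and the wavelet transform are per-sample
    operations and are precomputed; all data-adaptive fitting happens on
    the ``n - 1`` training patients of each fold.

    ``unsafe_global_selection`` fits the variance filter and rank-sum
    selection once on the *entire* cohort — a deliberately leaky variant
    retained solely to quantify selection bias; never use it for reporting.
    """
    y = np.array([s.y for s in cohort])
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least two patients of each class")
    matrix, _ = transform_cohort(cohort, pipeline.wavelet)
    n = len(cohort)
    global_sel = _fit_selection(matrix, y, pipeline) if unsafe_global_selection else None
    predictions: list[CvPrediction] = []
    for i in range(n):
        train_rows = np.arange(n) != i
        train_y = y[train_rows]
        if np.unique(train_y).size < 2:
            raise ValueError(f"training fold {i} lost a class")
        sel = global_sel if global_sel is not None else _fit_selection(
            matrix[train_rows], train_y, pipeline)
        cols = sel.selected
        logger.info("fold %d (%s): %d features selected",
                    i, cohort[i].patient_id, cols.size)
        model = fit_classifier(pipeline.classifier, matrix[np.ix_(train_rows, cols)],
                               train_y)
        prob = float(predict_probabilities(model, matrix[i, cols])[0])
        predictions.append(CvPrediction(cohort[i].patient_id, cohort[i].label, prob))
    return predictions


def fold_selected_features(cohort: Sequence[FaimsSample], pipeline: PipelineConfig,
                           fold: int) -> np.ndarray:
    """Indices selected by the given LOO fold (diagnostic; used to verify
    that the held-out patient cannot influence feature choice)."""
    y = np.array([s.y for s in cohort])
    matrix, _ = transform_cohort(cohort, pipeline.wavelet)
    rows = np.arange(len(cohort)) != fold
    return _fit_selection(matrix[rows], y[rows], pipeline).selected


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _scores(predictions: Sequence[CvPrediction]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([p.y for p in predictions])
    s = np.array([p.prob_cd for p in predictions])
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    return y, s


def auc_score(predictions: Sequence[CvPrediction]) -> float:
    """Probability that a random CD patient outranks a random D-IBS patient.

    Ties count one half — exactly the Mann-Whitney U statistic divided by
    the number of case/control pairs.
    """
    y, s = _scores(predictions)
    ranks = stats.rankdata(s)                     # midranks
    n1 = int(np.sum(y == 1))
    n0 = y.size - n1
    u = float(np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2.0)
    return u / (n1 * n0)


def roc_points(predictions: Sequence[CvPrediction]) -> list[tuple[float, float, float]]:
    """Full ROC staircase from (0, 0) to (1, 1) with thresholds.

    A point at threshold t is the (FPR, TPR) of calling CD when
    ``prob_cd >= t``; the leading point carries an unattainable threshold
    above every score.
    """
    y, s = _scores(predictions)
    n1 = np.sum(y == 1)
    n0 = y.size - n1
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    pts = [(0.0, 0.0, float(s_sorted[0]) + 1.0)]
    tp = fp = 0
    i = 0
    while i < y.size:                             # advance one tie-group at a time
        j = i
        while j < y.size and s_sorted[j] == s_sorted[i]:
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        pts.append((fp / n0, tp / n1, float(s_sorted[i])))
        i = j
    return pts


def trapezoidal_auc(points: Sequence[tuple[float, float, float]]) -> float:
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def sensitivity_specificity(predictions: Sequence[CvPrediction],
                            threshold: float) -> tuple[float, float]:
    """Operating characteristics of the rule ``prob_cd >= threshold -> CD``."""
    y, s = _scores(predictions)
    call = s >= threshold
    sens = float(np.sum(call & (y == 1)) / np.sum(y == 1))
    spec = float(np.sum(~call & (y == 0)) / np.sum(y == 0))
    return sens, spec


def choose_threshold(predictions: Sequence[CvPrediction]) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    A single operating point giving good values for both characteristics;
    ties are broken toward the smaller threshold.
    """
    _, s = _scores(predictions)
    best = None
    for t in np.unique(s):                        # ascending => first win is smallest
        sens, spec = sensitivity_specificity(predictions, float(t))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), sens, spec)
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson interval from Beta distribution quantiles.

    Guaranteed coverage at least ``level``; the lower bound is 0 when no
    successes are observed and the upper bound 1 when all trials succeed.
    """
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError("require 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lower, upper


def auc_confidence_interval(predictions: Sequence[CvPrediction],
                            method: str = "bootstrap", reps: int = 2000,
                            seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval for the AUC over class-stratified bootstrap resamples.

    Stratification resamples cases and controls separately, so every
    resample contains both classes and the AUC is always defined.
    """
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    y, s = _scores(predictions)
    cases, controls = s[y == 1], s[y == 0]
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    for b in range(reps):
        ca = rng.choice(cases, cases.size, replace=True)
        co = rng.choice(controls, controls.size, replace=True)
        ranks = stats.rankdata(np.concatenate([ca, co]))
        u = np.sum(ranks[: ca.size]) - ca.size * (ca.size + 1) / 2.0
        aucs[b] = u / (ca.size * co.size)
    alpha = 1.0 - level
    return (float(np.quantile(aucs, alpha / 2)),
            float(np.quantile(aucs, 1 - alpha / 2)))


def evaluate(predictions: Sequence[CvPrediction], ci_reps: int = 2000,
             seed: int = 0) -> RocResult:
    """Complete Table-style evaluation of one cross-validated prediction set."""
    y, _ = _scores(predictions)
    pts = roc_points(predictions)
    auc = auc_score(predictions)
    thr, sens, spec = choose_threshold(predictions)
    n1 = int(np.sum(y == 1))
    n0 = y.size - n1
    return RocResult(
        points=pts,
        auc=auc,
        auc_ci=auc_confidence_interval(predictions, reps=ci_reps, seed=seed),
        threshold=thr,
        sensitivity=sens,
        sensitivity_ci=binomial_ci(round(sens * n1), n1),
        specificity=spec,
        specificity_ci=binomial_ci(round(spec * n0), n0),
    )


# ---------------------------------------------------------------------------
# Covariate correlation and report tables
# ---------------------------------------------------------------------------

def correlate_probability(predictions: Sequence[CvPrediction],
                          covariate: Sequence[float],
                          exclude_above: Optional[float] = None) -> float:
    """Pearson correlation between held-out probabilities and a covariate.

    Pairs with a missing covariate are dropped; ``exclude_above`` removes
    outlying covariate values first (e.g. a TTG titre above 60 kU/L) and is
    logged when applied.
    """
    probs = np.array([p.prob_cd for p in predictions], dtype=float)
    cov = np.array([np.nan if c is None else float(c) for c in covariate])
    keep = np.isfinite(cov)
    if exclude_above is not None:
        excl = keep & (cov > exclude_above)
        if np.any(excl):
            logger.info("correlate_probability: excluding %d point(s) with "
                        "covariate > %g", int(np.sum(excl)), exclude_above)
        keep &= ~excl
    probs, cov = probs[keep], cov[keep]
    if probs.size < 3:
        raise ValueError("need at least 3 paired values after filtering")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; correlation undefined")
    return float(stats.pearsonr(probs, cov).statistic)


def probability_group_summary(predictions: Sequence[CvPrediction]) -> pd.DataFrame:
    """Box-and-whisker numbers per disease group.

    Whiskers show the data range but are truncated to at most twice the
    interquartile range beyond the quartiles.
    """
    rows = []
    for label in (LABEL_CD, LABEL_IBS):
        probs = np.array([p.prob_cd for p in predictions if p.true_label == label])
        q1, med, q3 = np.percentile(probs, [25, 50, 75])
        iqr = q3 - q1
        rows.append({
            "group": label, "n": probs.size,
            "q1": q1, "median": med, "q3": q3,
            "whisker_low": max(probs.min(), q1 - 2 * iqr),
            "whisker_high": min(probs.max(), q3 + 2 * iqr),
        })
    return pd.DataFrame(rows).set_index("group")


def probability_marsh_crosstab(predictions: Sequence[CvPrediction],
                               cohort: Sequence[FaimsSample]) -> pd.DataFrame:
    """Cross-tabulate CD probability bins against Marsh grade (CD patients).

    Bins are 0-0.2, ..., 0.8-1 with a right-closed upper bin; patients
    without a Marsh score are tallied in an ``unknown`` row.
    """
    marsh_by_id = {s.patient_id: s.marsh for s in cohort}
    recs = [(marsh_by_id.get(p.patient_id) or "unknown", p.prob_cd)
            for p in predictions if p.true_label == LABEL_CD]
    frame = pd.DataFrame(recs, columns=["marsh", "prob"])
    labels = [f"{lo:g}-{hi:g}" for lo, hi in
              zip(PROBABILITY_BINS[:-1], PROBABILITY_BINS[1:])]
    frame["bin"] = pd.cut(frame["prob"], bins=list(PROBABILITY_BINS),
                          labels=labels, include_lowest=True)
    table = pd.crosstab(frame["marsh"], frame["bin"], dropna=False)
    return table.reindex(columns=labels, fill_value=0)


def selected_feature_heatmap(cohort: Sequence[FaimsSample],
                             pipeline: PipelineConfig) -> pd.DataFrame:
    """Samples x selected-features matrix, rows sorted CD first.

    The selection here is refit on the full cohort: the heatmap is a
    descriptive display of the discriminating coefficients, not part of the
    cross-validated evaluation.
    """
    y = np.array([s.y for s in cohort])
    matrix, _ = transform_cohort(cohort, pipeline.wavelet)
    sel = _fit_selection(matrix, y, pipeline)
    order = np.argsort(-y, kind="stable")
    return pd.DataFrame(
        matrix[np.ix_(order, sel.selected)],
        index=[cohort[i].patient_id for i in order],
        columns=[f"w{j}" for j in sel.selected],
    )


def report(predictions: Sequence[CvPrediction], cohort: Sequence[FaimsSample],
           pipeline: PipelineConfig) -> dict:
    """Bundle of the summary artefacts for one completed CV run."""
    return {
        "heatmap": selected_feature_heatmap(cohort, pipeline),
        "group_summary": probability_group_summary(predictions),
        "crosstab": probability_marsh_crosstab(predictions, cohort),
    }
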
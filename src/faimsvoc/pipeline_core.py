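"""Deterministic feature pipeline for FAIMS scans.

The stages, in run order: replicate aggregation (per-patient mean of the
flattened positive+negative grids), 1-D Daubechies wavelet transform of the
resulting data vector, variance-threshold filtering of wavelet coefficients
(coefficients nearly constant across training samples carry noise, not
signal), and Wilcoxon rank-sum ranking to pick the coefficients most
informative of disease state.  The two fitting stages (variance filter and
rank-sum selection) operate on *training rows only*; in cross-validation the
harness refits them inside every fold so the held-out patient can never
influence feature choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import stats

from .io import FaimsSample

logger = logging.getLogger("faimsvoc")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """An ordered coefficient vector with its provenance.

    For wavelet-domain vectors ``index_map[i]`` is ``(level, position)``:
    level 0 is the deepest approximation band, levels ``1..L`` are detail
    bands from coarsest to finest.  ``orig_len`` records the pre-padding raw
    length so the inverse transform can strip the zero padding again.
    """

    values: np.ndarray
    provenance: str = "raw"                      # "raw" | "wavelet"
    index_map: Optional[list[tuple[int, int]]] = None
    orig_len: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature vector must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")
        if self.provenance not in ("raw", "wavelet"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "wavelet":
            if self.index_map is None or len(self.index_map) != self.values.size:
                raise ValueError("wavelet vector requires a full index_map")


@dataclass
class WaveletConfig:
    """Daubechies transform settings.

    ``order`` selects the db-N family member (db4 default — the family is
    the only constraint the method imposes; the order trades support length
    against smoothness).  ``boundary`` chooses the signal extension:
    ``"periodic"`` (orthonormal on power-of-two lengths, preserves energy)
    or ``"zero-pad"``.  ``levels`` is a decomposition depth or ``"max"``.
    """

    order: int = 4
    boundary: str = "periodic"                   # "periodic" | "zero-pad"
    levels: int | str = "max"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("Daubechies order must be >= 1")
        if self.boundary not in ("periodic", "zero-pad"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(f"db{self.order}")

    @property
    def mode(self) -> str:
        return "periodization" if self.boundary == "periodic" else "zero"

    def depth(self, n: int) -> int:
        max_level = pywt.dwt_max_level(n, self.wavelet.dec_len)
        if self.levels == "max":
            return max(1, max_level)
        return min(int(self.levels), max(1, max_level))


@dataclass
class SelectionModel:
    """Fitted feature-selection state: variance mask + rank-sum ordering."""

    variance_keep_mask: np.ndarray               # bool per coefficient
    ranked_indices: np.ndarray                   # masked features, p-ascending
    k: int
    pvalues: np.ndarray                          # per-feature; NaN if masked out

    @property
    def selected(self) -> np.ndarray:
        """Indices of the kept features: min(k, available) best by p."""
        return self.ranked_indices[: min(self.k, self.ranked_indices.size)]


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

def flatten_replicate(pair) -> np.ndarray:
    """Row-major flattening: positive-mode grid first, then negative."""
    return np.concatenate([pair.positive.current.ravel(order="C"),
                           pair.negative.current.ravel(order="C")])


def aggregate_replicates(sample: FaimsSample) -> FeatureVector:
    """Element-wise mean of the sample's flattened replicate scans.

    Averaging at the patient level (rather than carrying replicates as
    separate rows) keeps all information about one patient inside a single
    cross-validation unit, so replicates can never straddle folds.
    """
    flats = [flatten_replicate(rep) for rep in sample.replicates]
    lengths = {f.size for f in flats}
    if len(lengths) != 1:
        raise ValueError(f"replicates of {sample.patient_id} have mismatched shapes")
    return FeatureVector(np.mean(flats, axis=0), provenance="raw")


# ---------------------------------------------------------------------------
# Wavelet transform
# ---------------------------------------------------------------------------

def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def dwt_forward(vector: FeatureVector, config: WaveletConfig = WaveletConfig()) -> FeatureVector:
    """Daubechies analysis transform of a raw data vector.

    The vector is zero-padded to the next power of two (padding is recorded
    via ``orig_len``; since the pad is deterministic and data-independent it
    cannot leak class signal), then decomposed with :func:`pywt.wavedec`.
    The transform is linear and, under the periodic boundary, orthonormal.
    """
    if vector.provenance != "raw":
        raise ValueError("dwt_forward expects a raw vector")
    if vector.values.size == 0:
        raise ValueError("empty vector")
    x = vector.values
    n = _next_pow2(x.size)
    if n != x.size:
        x = np.pad(x, (0, n - x.size))
    coeffs = pywt.wavedec(x, config.wavelet, mode=config.mode,
                          level=config.depth(n))
    index_map: list[tuple[int, int]] = []
    for level, band in enumerate(coeffs):
        index_map.extend((level, pos) for pos in range(len(band)))
    return FeatureVector(np.concatenate(coeffs), provenance="wavelet",
                         index_map=index_map, orig_len=vector.values.size)


def dwt_inverse(vector: FeatureVector, config: WaveletConfig = WaveletConfig()) -> FeatureVector:
    """Inverse of :func:`dwt_forward`; strips the zero padding again."""
    if vector.provenance != "wavelet" or vector.index_map is None:
        raise ValueError("dwt_inverse requires a wavelet vector with index_map")
    bands: dict[int, int] = {}
    for level, _pos in vector.index_map:
        bands[level] = bands.get(level, 0) + 1
    coeffs = []
    start = 0
    for level in sorted(bands):
        stop = start + bands[level]
        coeffs.append(vector.values[start:stop])
        start = stop
    x = pywt.waverec(coeffs, config.wavelet, mode=config.mode)
    if vector.orig_len is not None:
        x = x[: vector.orig_len]
    return FeatureVector(x, provenance="raw")


def transform_cohort(cohort: Sequence[FaimsSample],
                     config: WaveletConfig = WaveletConfig()) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Aggregate and wavelet-transform every patient; rows align with ``cohort``.

    These are purely per-sample operations, so precomputing them once before
    cross-validation cannot leak information across folds.
    """
    vecs = [dwt_forward(aggregate_replicates(s), config) for s in cohort]
    matrix = np.vstack([v.values for v in vecs])
    return matrix, vecs[0].index_map


# ---------------------------------------------------------------------------
# Variance filter
# ---------------------------------------------------------------------------

def fit_variance_filter(train_matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask keeping coefficients whose sample variance >= threshold.

    Variance uses the unbiased (n-1) denominator and is computed on the
    training rows only; coefficients that barely vary across samples are
    dominated by instrument noise and are dropped.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.ndim != 2 or train_matrix.shape[0] < 2:
        raise ValueError("variance filter needs >= 2 training samples")
    variances = train_matrix.var(axis=0, ddof=1)
    return variances >= threshold


def variance_cutoff(train_matrix: np.ndarray, mode: str, value: float) -> float:
    """Resolve a variance threshold from config.

    ``mode="absolute"`` uses ``value`` directly; ``mode="quantile"`` keeps
    the top ``value`` fraction of coefficients by variance (default pipeline:
    top 5%), i.e. the cutoff is the ``1-value`` variance quantile of the
    training rows.
    """
    if mode == "absolute":
        return float(value)
    if mode == "quantile":
        if not 0 < value <= 1:
            raise ValueError("quantile fraction must be in (0, 1]")
        variances = np.asarray(train_matrix).var(axis=0, ddof=1)
        return float(np.quantile(variances, 1.0 - value))
    raise ValueError(f"unknown variance mode {mode!r}")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum ranking
# ---------------------------------------------------------------------------

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns ``(U, p)`` with U counted for ``x`` over ``y`` using midranks
    for ties.  The p-value is exact (full enumeration of label assignments)
    when the combined sample size is at most 12 and tie-free; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_sum_pvalues(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values for class A vs class B rows."""
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    n = xa.shape[0] + xb.shape[0]
    if n > 12:
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                 method="asymptotic", use_continuity=True, axis=0)
        return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    return np.array([rank_sum_test(xa[:, j], xb[:, j])[1]
                     for j in range(xa.shape[1])])


def select_top_k(train_matrix: np.ndarray, labels: Sequence[int], k: int,
                 mask: np.ndarray) -> SelectionModel:
    """Rank the masked coefficients by rank-sum p and keep the best ``k``.

    Ties in p are broken toward the lower coefficient index, making the
    selection fully deterministic.  If fewer than ``k`` features survive the
    variance mask, all of them are kept (with a warning).
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    masked_idx = np.flatnonzero(mask)
    pvalues = np.full(train_matrix.shape[1], np.nan)
    if masked_idx.size:
        sub = train_matrix[:, masked_idx]
        pvalues[masked_idx] = rank_sum_pvalues(sub[labels == 1], sub[labels == 0])
    order = masked_idx[np.lexsort((masked_idx, pvalues[masked_idx]))]
    if k > masked_idx.size:
        logger.warning("requested k=%d but only %d features pass the variance "
                       "mask; keeping all", k, masked_idx.size)
    return SelectionModel(np.asarray(mask, dtype=bool), order, k, pvalues)
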
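"""Synthetic FAIMS cohorts and GC-MS chromatograms with known class structure.

The study this package operationalises compared urinary volatile-organic-
compound profiles of 27 coeliac-disease (CD) patients against 20 patients
with diarrhoea-predominant IBS, three FAIMS scans per urine sample, but the
underlying patient data are not publicly deposited.  This module generates
cohorts with the same design so that every downstream stage — wavelet
compression, nested feature selection, cross-validated classification, and
the GC-MS unique-peak screen — can be exercised against a known ground truth.

Signal model
------------
Ion chemistry concentrates FAIMS response into localized peaks in the
(dispersion field, compensation voltage) plane, so a scan is modelled as a
sum of 2-D Gaussian blobs on a smooth background ridge:

* *shared* blobs appear in every patient with patient-specific amplitudes
  (common metabolites);
* *discriminative* blobs have a class-dependent mean amplitude: the CD mean
  exceeds the D-IBS mean by ``effect_size`` pooled between-patient standard
  deviations (Cohen's d scale);
* between-patient amplitude SD is larger in the D-IBS class by default,
  reflecting the larger patient-to-patient variation expected in IBS;
* replicates of one patient share the patient's latent amplitudes and differ
  only by i.i.d. measurement noise (``noise_sd``).

Randomness is drawn from one global seed split per patient by counter, so a
cohort is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gcms_screen import Chromatogram
from .io import (
    LABEL_CD,
    LABEL_IBS,
    FaimsSample,
    IonCurrentMatrix,
    MatrixPair,
    MARSH_GRADES,
)

# Table of common GC peaks (retention time min): planted in both classes.
COMMON_PEAK_RTS = (5.30, 7.63, 7.95, 9.76)
#: Retention time (min) of the CD-only marker peak.
UNIQUE_PEAK_RT = 4.67


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic FAIMS cohort.

    Defaults reproduce the study design: 27 CD vs 20 D-IBS patients, three
    replicate scan pairs each, a 51 x 512 (dispersion x compensation) grid
    per polarity, three class-discriminative signal regions, and twice the
    between-patient spread in the D-IBS class.
    """

    n_cd: int = 27
    n_ibs: int = 20
    replicates_per_sample: int = 3
    n_df: int = 51
    n_cv: int = 512
    n_signal_regions: int = 3
    n_shared_regions: int = 4
    effect_size: float = 2.0          # Cohen's d of blob amplitude between classes
    base_amplitude: float = 4.0       # mean blob amplitude, arbitrary ion-current units
    patient_sd_cd: float = 1.0        # between-patient amplitude SD, CD
    patient_sd_ibs: float = 2.0       # between-patient amplitude SD, D-IBS
    noise_sd: float = 0.5             # within-replicate measurement SD per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cd, self.n_ibs, self.replicates_per_sample) < 0:
            raise ValueError("counts must be >= 0")
        if self.replicates_per_sample < 1:
            raise ValueError("need at least one replicate per sample")
        if self.n_df < 1 or self.n_cv < 1:
            raise ValueError("zero-size grid")
        if min(self.patient_sd_cd, self.patient_sd_ibs, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def pooled_patient_sd(self) -> float:
        return float(np.sqrt((self.patient_sd_cd**2 + self.patient_sd_ibs**2) / 2.0))


# ---------------------------------------------------------------------------
# Blob geometry — deterministic functions of the config, not of the RNG
# ---------------------------------------------------------------------------

_GOLDEN = 0.6180339887498949


def _blob_sites(n: int, offset: float) -> list[tuple[float, float, int]]:
    """Fixed fractional (df, cv) centers and polarity index for ``n`` blobs."""
    sites = []
    for j in range(n):
        fdf = (offset + _GOLDEN * j) % 1.0
        fcv = (offset * 2.0 + 0.7548776662466927 * j) % 1.0
        # keep centers away from the grid edge
        sites.append((0.1 + 0.8 * fdf, 0.1 + 0.8 * fcv, j % 2))
    return sites


def _blob_kernel(n_df: int, n_cv: int, fdf: float, fcv: float) -> np.ndarray:
    """Unit-height 2-D Gaussian at fractional center, widths scaled to grid."""
    i = np.arange(n_df)[:, None]
    j = np.arange(n_cv)[None, :]
    s_df = max(1.0, 0.05 * n_df)
    s_cv = max(1.0, 0.02 * n_cv)
    return np.exp(
        -0.5 * (((i - fdf * (n_df - 1)) / s_df) ** 2
                + ((j - fcv * (n_cv - 1)) / s_cv) ** 2)
    )


class _CohortGeometry:
    """Precomputed kernels shared by all patients of one cohort."""

    def __init__(self, cfg: SyntheticConfig) -> None:
        self.df_axis = np.linspace(0.0, 100.0, cfg.n_df)
        self.cv_axis = np.linspace(-6.0, 6.0, cfg.n_cv)
        # broad background ridge present in every scan (reactant ion signal)
        i = np.arange(cfg.n_df)[:, None]
        j = np.arange(cfg.n_cv)[None, :]
        ridge = np.exp(-0.5 * ((j - 0.5 * (cfg.n_cv - 1)) / (0.25 * cfg.n_cv)) ** 2)
        self.background = [2.0 * ridge * (1.0 - 0.004 * i), 1.5 * ridge * (1.0 - 0.004 * i)]
        self.shared = [
            (_blob_kernel(cfg.n_df, cfg.n_cv, fdf, fcv), pol)
            for fdf, fcv, pol in _blob_sites(cfg.n_shared_regions, 0.23)
        ]
        self.signal = [
            (_blob_kernel(cfg.n_df, cfg.n_cv, fdf, fcv), pol)
            for fdf, fcv, pol in _blob_sites(cfg.n_signal_regions, 0.57)
        ]


def signal_region_centers(cfg: SyntheticConfig) -> list[tuple[int, float, float]]:
    """(polarity index, df %, cv V) of each planted discriminative region."""
    geom = _CohortGeometry(cfg)
    out = []
    for fdf, fcv, pol in _blob_sites(cfg.n_signal_regions, 0.57):
        out.append((pol, float(np.interp(fdf * (cfg.n_df - 1), np.arange(cfg.n_df), geom.df_axis)),
                    float(np.interp(fcv * (cfg.n_cv - 1), np.arange(cfg.n_cv), geom.cv_axis))))
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SyntheticConfig) -> list[FaimsSample]:
    """Generate ``cfg.n_cd + cfg.n_ibs`` patients with planted class structure.

    Replicates of one patient share the patient's latent blob amplitudes and
    differ only by measurement noise.  Identical config (including seed)
    yields an identical cohort.
    """
    geom = _CohortGeometry(cfg)
    delta = cfg.effect_size * cfg.pooled_patient_sd
    samples: list[FaimsSample] = []
    labels = [LABEL_CD] * cfg.n_cd + [LABEL_IBS] * cfg.n_ibs
    for idx, label in enumerate(labels):
        rng = np.random.default_rng([cfg.seed, idx])
        is_cd = label == LABEL_CD
        patient_sd = cfg.patient_sd_cd if is_cd else cfg.patient_sd_ibs
        shared_amp = cfg.base_amplitude + rng.normal(0.0, patient_sd, len(geom.shared))
        signal_mean = cfg.base_amplitude + (delta if is_cd else 0.0)
        signal_amp = signal_mean + rng.normal(0.0, patient_sd, len(geom.signal))
        latent = [geom.background[0].copy(), geom.background[1].copy()]
        for (kern, pol), amp in zip(geom.shared, shared_amp):
            latent[pol] += amp * kern
        for (kern, pol), amp in zip(geom.signal, signal_amp):
            latent[pol] += amp * kern
        reps = []
        for _ in range(cfg.replicates_per_sample):
            mats = []
            for pol, polarity in enumerate(("positive", "negative")):
                current = latent[pol] + rng.normal(0.0, cfg.noise_sd, latent[pol].shape)
                mats.append(IonCurrentMatrix(polarity, geom.df_axis, geom.cv_axis, current))
            reps.append(MatrixPair(*mats))
        ttg, marsh = _covariates(rng, is_cd)
        pid = f"{'CD' if is_cd else 'IBS'}{(idx if is_cd else idx - cfg.n_cd) + 1:02d}"
        samples.append(FaimsSample(pid, label, reps, ttg=ttg, marsh=marsh))
    return samples


def _covariates(rng: np.random.Generator, is_cd: bool) -> tuple[float, str | None]:
    """Clinical covariates: TTG titre (kU/L) and Marsh grade (CD only)."""
    if is_cd:
        ttg = float(np.round(np.exp(rng.normal(0.8, 1.2)), 1))
        marsh = str(rng.choice(MARSH_GRADES, p=[0.05, 0.05, 0.36, 0.24, 0.30]))
        return ttg, marsh
    return float(np.round(np.abs(rng.normal(0.3, 0.2)), 1)), None


def permute_labels(cohort: Sequence[FaimsSample], seed: int) -> list[FaimsSample]:
    """Randomly reassign the cohort's labels; matrices are untouched.

    The label multiset is preserved, making this a null-hypothesis generator:
    any class signal in the matrices is decoupled from the labels.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    labels = [s.label for s in cohort]
    perm = rng.permutation(len(labels))
    return [
        FaimsSample(s.patient_id, labels[perm[i]], s.replicates, s.ttg, s.marsh)
        for i, s in enumerate(cohort)
    ]


# ---------------------------------------------------------------------------
# GC-MS chromatograms
# ---------------------------------------------------------------------------

def generate_chromatograms(
    n_cd: int,
    n_ibs: int,
    unique_peak_rt: float = UNIQUE_PEAK_RT,
    seed: int = 0,
    rt_max: float = 12.0,
    rt_step: float = 0.005,
    peak_sigma: float = 0.02,
    noise_sd: float = 0.05,
    rt_jitter_sd: float = 0.015,
) -> tuple[list[Chromatogram], list[Chromatogram]]:
    """Per-class chromatogram lists with a planted CD-only marker peak.

    Both classes share common peaks at the retention times of the compounds
    seen in the majority of urine samples (5.30, 7.63, 7.95, 9.76 min) plus
    two sub-threshold bumps below the 1.8 MCps detection floor; only CD
    chromatograms additionally carry a peak near ``unique_peak_rt`` (default
    4.67 min) that clears the floor.  Retention times jitter by well under
    the 0.05 min binning tolerance.  Peaks are Gaussians (sigma 0.02 min) on
    a flat baseline with additive noise.
    """
    if n_cd < 1 or n_ibs < 1:
        raise ValueError("need at least one chromatogram per class")
    rt = np.arange(0.0, rt_max, rt_step)
    common = [(r, h) for r, h in zip(COMMON_PEAK_RTS, (4.0, 3.0, 3.5, 2.8))]
    weak = [(3.20, 0.9), (6.50, 1.1)]  # below the 1.8 MCps floor in every sample

    def make(sample_id: str, label: str, rng: np.random.Generator) -> Chromatogram:
        intensity = np.full_like(rt, 0.3)
        peaks = list(common) + list(weak)
        if label == LABEL_CD:
            peaks.append((unique_peak_rt, 2.6))
        for center, height in peaks:
            c = center + np.clip(rng.normal(0.0, rt_jitter_sd), -0.04, 0.04)
            h = height * float(np.exp(rng.normal(0.0, 0.08)))
            if height >= 1.8:
                h = max(h, height * 0.85)   # keep real peaks clear of the floor
            else:
                h = min(h, 1.5)             # keep weak bumps under it
            intensity += h * np.exp(-0.5 * ((rt - c) / peak_sigma) ** 2)
        intensity += rng.normal(0.0, noise_sd, rt.shape)
        return Chromatogram(sample_id, label, rt.copy(), intensity)

    cd = [make(f"CD{i + 1:02d}", LABEL_CD, np.random.default_rng([seed, 0, i]))
          for i in range(n_cd)]
    ibs = [make(f"IBS{i + 1:02d}", LABEL_IBS, np.random.default_rng([seed, 1, i]))
           for i in range(n_ibs)]
    return cd, ibs
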
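"""GC-MS chromatogram screening for class-unique peaks.

Chromatograms are screened in three steps: peak detection against the
1.8 MCps intensity floor (after rolling-median baseline subtraction, so slow
baseline drift does not masquerade as signal), greedy retention-time binning
across samples (peaks at the same retention time are tallied together), and
a prevalence rule that flags bins present in nearly all samples of one class
and in none of the other — the pattern of a disease-specific volatile such
as the marker peak near 4.67 min seen only in coeliac urine.

MCps is treated as an opaque detector intensity unit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

#: Detection floor (MCps): only clear peaks above this are reported.
DEFAULT_THRESHOLD = 1.8
#: Retention-time binning tolerance (min): merges run-to-run jitter without
#: merging distinct compounds reported to two decimals.
DEFAULT_TOLERANCE = 0.05
DEFAULT_MIN_PREVALENCE = 0.9
_BASELINE_WINDOW_MIN = 0.5


@dataclass
class Chromatogram:
    """One GC-MS trace: intensity (MCps) over retention time (min)."""

    sample_id: str
    label: str
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.rt.size != self.intensity.size:
            raise ValueError("rt and intensity must be 1-D and equal length")
        if not (np.all(np.isfinite(self.rt)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("non-finite chromatogram values")
        if np.any(self.rt < 0):
            raise ValueError("negative retention time")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("retention times must be strictly increasing")


@dataclass
class Peak:
    """A detected chromatogram peak (heights are baseline-subtracted)."""

    rt_apex: float
    height: float
    left: float
    right: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be > 0")
        if not self.left < self.rt_apex < self.right:
            raise ValueError("peak bounds must bracket the apex")


@dataclass
class PeakBin:
    """Peaks from different samples sharing one retention time."""

    center: float
    members: list[tuple[str, str, Peak]] = field(default_factory=list)
    unique_class: Optional[str] = None

    def prevalence(self, label: str, class_size: int) -> float:
        """Fraction of the class's samples contributing >=1 peak to this bin."""
        if class_size < 1:
            return 0.0
        ids = {sid for sid, lab, _ in self.members if lab == label}
        return len(ids) / class_size


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_peaks(chrom: Chromatogram,
                 threshold: float = DEFAULT_THRESHOLD) -> list[Peak]:
    """Local maxima clearing ``threshold`` after baseline subtraction.

    The baseline is a rolling median over a 0.5 min window — wide enough to
    ride under sharp chromatographic peaks while tracking slow drift.  A
    prominence requirement of half the threshold suppresses noise wiggles on
    the flank of a genuine peak.  Peaks are returned in retention-time order
    with bounds at 90% height drop.
    """
    if chrom.rt.size < 3:
        raise ValueError("need at least 3 points")
    dt = float(np.median(np.diff(chrom.rt)))
    win = max(3, int(round(_BASELINE_WINDOW_MIN / dt)) | 1)
    baseline = ndimage.median_filter(chrom.intensity, size=win, mode="nearest")
    net = chrom.intensity - baseline
    idx, props = signal.find_peaks(net, height=threshold,
                                   prominence=0.5 * threshold)
    strict = props["peak_heights"] > threshold
    idx = idx[strict]
    if idx.size == 0:
        return []
    widths = signal.peak_widths(net, idx, rel_height=0.9)
    peaks = []
    for k, i in enumerate(idx):
        left = float(np.interp(widths[2][k], np.arange(chrom.rt.size), chrom.rt))
        right = float(np.interp(widths[3][k], np.arange(chrom.rt.size), chrom.rt))
        apex = float(chrom.rt[i])
        left = min(left, apex - 1e-9)
        right = max(right, apex + 1e-9)
        peaks.append(Peak(apex, float(net[i]), left, right))
    return peaks


# ---------------------------------------------------------------------------
# Retention-time binning
# ---------------------------------------------------------------------------

def bin_retention_times(peaks: Sequence[tuple[str, str, Peak]],
                        tolerance: float = DEFAULT_TOLERANCE) -> list[PeakBin]:
    """Greedy agglomeration of peaks by apex retention time.

    Peaks are scanned in ascending apex order; a peak joins the current bin
    while it sits within ``tolerance`` of the running bin center and within
    ``2 * tolerance`` of the bin's first member, else it opens a new bin.
    Every peak lands in exactly one bin and each bin spans at most
    ``2 * tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    ordered = sorted(peaks, key=lambda t: t[2].rt_apex)
    bins: list[PeakBin] = []
    apexes: list[float] = []
    for item in ordered:
        rt = item[2].rt_apex
        if bins and (rt - np.mean(apexes) <= tolerance
                     and rt - apexes[0] <= 2 * tolerance):
            bins[-1].members.append(item)
            apexes.append(rt)
            bins[-1].center = float(np.mean(apexes))
        else:
            bins.append(PeakBin(center=rt, members=[item]))
            apexes = [rt]
    return bins


def find_class_unique_peaks(bins: Sequence[PeakBin], class_counts: dict[str, int],
                            min_prevalence: float = DEFAULT_MIN_PREVALENCE) -> list[PeakBin]:
    """Bins present in >= ``min_prevalence`` of one class and absent in the other.

    Strict absence is required: a peak seen even once in the other class is
    not class-unique.  Returned bins carry ``unique_class``.
    """
    labels = sorted(class_counts)
    if len(labels) != 2:
        raise ValueError("class_counts must name exactly two classes")
    hits = []
    for b in bins:
        prev = {lab: b.prevalence(lab, class_counts[lab]) for lab in labels}
        for lab, other in (labels, labels[::-1]):
            if prev[lab] >= min_prevalence and prev[other] == 0.0:
                b.unique_class = lab
                hits.append(b)
                break
    return hits


def screen_cohort(chromatograms: Sequence[Chromatogram],
                  threshold: float = DEFAULT_THRESHOLD,
                  tolerance: float = DEFAULT_TOLERANCE,
                  min_prevalence: float = DEFAULT_MIN_PREVALENCE,
                  ) -> tuple[list[PeakBin], list[PeakBin]]:
    """Detect, bin, and screen a whole chromatogram cohort.

    Returns ``(all_bins, class_unique_bins)``.
    """
    tagged = [(c.sample_id, c.label, p)
              for c in chromatograms for p in detect_peaks(c, threshold)]
    bins = bin_retention_times(tagged, tolerance)
    counts: dict[str, int] = {}
    for c in chromatograms:
        counts[c.label] = counts.get(c.label, 0) + 1
    return bins, find_class_unique_peaks(bins, counts, min_prevalence)


# ---------------------------------------------------------------------------
# Chromatogram CSV I/O
# ---------------------------------------------------------------------------

def write_chromatogram(chrom: Chromatogram, path) -> None:
    """CSV with header ``rt_min,intensity_mcps``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rt_min", "intensity_mcps"])
        for rt, inten in zip(chrom.rt, chrom.intensity):
            writer.writerow([format(rt, ".6g"), format(inten, ".6g")])


def read_chromatogram(path, sample_id: Optional[str] = None,
                      label: str = "CD") -> Chromatogram:
    path = Path(path)
    rt, inten = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rt.append(float(row["rt_min"]))
            inten.append(float(row["intensity_mcps"]))
    return Chromatogram(sample_id or path.stem, label, np.array(rt), np.array(inten))
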
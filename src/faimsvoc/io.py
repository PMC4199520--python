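"""Reading and writing the on-disk formats of the FAIMS pipeline.

A FAIMS scan is stored as a plain-text, tab-separated matrix
(``*.faims.tsv``): ``#``-prefixed comment lines carry the polarity and axis
units, the first data row is the compensation-voltage axis (V), the first
column of each subsequent row is the dispersion-field axis (% of maximum
field), and the remaining cells are ion current in arbitrary units.  Cohorts
are described by a CSV manifest with header
``patient_id,label,ttg_kU_L,marsh,replicate_paths``; each manifest row lists
the replicate scans of one patient (replicates separated by ``;``, the
positive/negative polarity files of one replicate by ``|``, paths relative
to the manifest).  Held-out cross-validation probabilities are exchanged as
CSV ``patient_id,label,prob_cd``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("faimsvoc")

#: The two diagnostic classes. CD is encoded 1 throughout, D-IBS 0.
LABEL_CD = "CD"
LABEL_IBS = "D-IBS"
LABELS = (LABEL_CD, LABEL_IBS)

POLARITIES = ("positive", "negative")

#: Histological grades of duodenal damage.
MARSH_GRADES = ("I", "II", "IIIa", "IIIb", "IIIc")

_FORMAT_TAG = "faimsvoc matrix v1"


class FaimsParseError(ValueError):
    """Raised when an on-disk file violates the matrix or manifest dialect."""


class ValidationError(ValueError):
    """Raised when an in-memory object violates its invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IonCurrentMatrix:
    """One FAIMS scan: ion current over (dispersion field, compensation voltage).

    Parameters
    ----------
    polarity
        Ion polarity of the scan, ``"positive"`` or ``"negative"``.
    df_axis
        Dispersion-field settings (% of maximum field), strictly increasing.
    cv_axis
        Compensation voltages (V), strictly increasing.
    current
        Ion current grid of shape ``(len(df_axis), len(cv_axis))``.
    """

    polarity: str
    df_axis: np.ndarray
    cv_axis: np.ndarray
    current: np.ndarray

    def __post_init__(self) -> None:
        self.df_axis = np.asarray(self.df_axis, dtype=float)
        self.cv_axis = np.asarray(self.cv_axis, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if self.df_axis.size == 0 or self.cv_axis.size == 0:
            raise ValidationError("empty axis")
        for name, ax in (("df_axis", self.df_axis), ("cv_axis", self.cv_axis)):
            if ax.ndim != 1 or not np.all(np.isfinite(ax)):
                raise ValidationError(f"{name} must be 1-D and finite")
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if self.current.shape != (self.df_axis.size, self.cv_axis.size):
            raise ValidationError(
                f"current shape {self.current.shape} inconsistent with axes "
                f"({self.df_axis.size}, {self.cv_axis.size})"
            )
        if not np.all(np.isfinite(self.current)):
            raise ValidationError("current contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.current.shape

    def __eq__(self, other: object) -> bool:  # value equality, for round trips
        if not isinstance(other, IonCurrentMatrix):
            return NotImplemented
        return (
            self.polarity == other.polarity
            and np.array_equal(self.df_axis, other.df_axis)
            and np.array_equal(self.cv_axis, other.cv_axis)
            and np.array_equal(self.current, other.current)
        )


@dataclass
class MatrixPair:
    """Positive- and negative-mode scans acquired from the same headspace draw."""

    positive: IonCurrentMatrix
    negative: IonCurrentMatrix

    def __post_init__(self) -> None:
        if self.positive.polarity != "positive" or self.negative.polarity != "negative":
            raise ValidationError("MatrixPair polarities are swapped or wrong")


@dataclass
class FaimsSample:
    """One patient: identity, diagnostic class, replicate scans, covariates."""

    patient_id: str
    label: str
    replicates: list[MatrixPair]
    ttg: Optional[float] = None
    marsh: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        if len(self.replicates) < 1:
            raise ValidationError("sample needs at least one replicate")
        if self.ttg is not None and self.ttg < 0:
            raise ValidationError("TTG titre must be >= 0 kU/L")
        if self.marsh is not None and self.marsh not in MARSH_GRADES:
            raise ValidationError(f"unknown Marsh grade {self.marsh!r}")
        ref = self.replicates[0]
        for rep in self.replicates[1:]:
            for pol in POLARITIES:
                a, b = getattr(ref, pol), getattr(rep, pol)
                if not (np.array_equal(a.df_axis, b.df_axis)
                        and np.array_equal(a.cv_axis, b.cv_axis)):
                    raise ValidationError(
                        f"replicates of {self.patient_id} do not share axes"
                    )

    @property
    def y(self) -> int:
        """Class encoding: CD = 1, D-IBS = 0."""
        return 1 if self.label == LABEL_CD else 0


@dataclass
class CohortManifest:
    """Parsed manifest rows, in file order."""

    entries: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FAIMS matrix files
# ---------------------------------------------------------------------------

def write_faims_matrix(matrix: IonCurrentMatrix, path: str | Path) -> None:
    """Write ``matrix`` to ``path`` in the canonical text dialect.

    Values are serialized with 6 significant digits; output bytes are
    deterministic for identical input.
    """
    matrix.validate()
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# polarity: {matrix.polarity}\n")
        fh.write("# df_unit: percent_of_max_field\n")
        fh.write("# cv_unit: V\n")
        fh.write("df\\cv\t" + "\t".join(_fmt(v) for v in matrix.cv_axis) + "\n")
        for df, row in zip(matrix.df_axis, matrix.current):
            fh.write(_fmt(df) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    logger.info("wrote FAIMS matrix %s shape=%s", path, matrix.shape)


def _fmt(v: float) -> str:
    return format(float(v), ".6g")


def read_faims_matrix(path: str | Path, polarity: Optional[str] = None) -> IonCurrentMatrix:
    """Read a ``*.faims.tsv`` matrix file.

    Parameters
    ----------
    path
        File in the dialect written by :func:`write_faims_matrix`.
    polarity
        If given, overrides / checks the polarity declared in the header.

    Raises
    ------
    FaimsParseError
        On malformed headers, non-numeric cells or ragged rows; the message
        names the offending line number.
    """
    path = Path(path)
    declared = None
    header_cv: Optional[np.ndarray] = None
    df_vals: list[float] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("polarity:"):
                    declared = body.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header_cv is None:
                if not fields[0].startswith("df"):
                    raise FaimsParseError(
                        f"{path}:{lineno}: expected axis header row, got {fields[0]!r}"
                    )
                try:
                    header_cv = np.array([float(v) for v in fields[1:]])
                except ValueError as exc:
                    raise FaimsParseError(f"{path}:{lineno}: non-numeric cv value ({exc})")
                continue
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise FaimsParseError(f"{path}:{lineno}: non-numeric cell ({exc})")
            if len(values) != header_cv.size + 1:
                raise FaimsParseError(
                    f"{path}:{lineno}: ragged row, expected {header_cv.size + 1} "
                    f"fields, got {len(values)}"
                )
            df_vals.append(values[0])
            rows.append(values[1:])
    if header_cv is None or not rows:
        raise FaimsParseError(f"{path}: no matrix data found")
    pol = polarity or declared
    if pol is None:
        raise FaimsParseError(f"{path}: polarity neither declared nor supplied")
    if polarity is not None and declared is not None and polarity != declared:
        raise FaimsParseError(
            f"{path}: declared polarity {declared!r} contradicts requested {polarity!r}"
        )
    try:
        matrix = IonCurrentMatrix(pol, np.array(df_vals), header_cv, np.array(rows))
    except ValidationError as exc:
        raise FaimsParseError(f"{path}: {exc}")
    logger.info("read FAIMS matrix %s shape=%s", path, matrix.shape)
    return matrix


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

MANIFEST_HEADER = ["patient_id", "label", "ttg_kU_L", "marsh", "replicate_paths"]


def read_cohort(manifest_path: str | Path) -> list[FaimsSample]:
    """Load a full cohort from a manifest CSV, preserving row order.

    Each ``replicate_paths`` cell lists replicates separated by ``;``; within
    a replicate the positive and negative matrix files are separated by ``|``.
    Paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    samples: list[FaimsSample] = []
    seen: set[str] = set()
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != MANIFEST_HEADER:
            raise FaimsParseError(
                f"{manifest_path}: manifest header must be "
                f"{','.join(MANIFEST_HEADER)}, got {reader.fieldnames}"
            )
        for row in reader:
            pid = row["patient_id"].strip()
            if pid in seen:
                raise FaimsParseError(f"{manifest_path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            reps: list[MatrixPair] = []
            for rep_spec in row["replicate_paths"].split(";"):
                parts = [p.strip() for p in rep_spec.split("|")]
                if len(parts) != 2:
                    raise FaimsParseError(
                        f"{manifest_path}: patient {pid}: replicate must list "
                        f"pos|neg paths, got {rep_spec!r}"
                    )
                mats = {}
                for pol, rel in zip(POLARITIES, parts):
                    fpath = base / rel
                    if not fpath.exists():
                        raise FaimsParseError(
                            f"{manifest_path}: patient {pid}: missing matrix file {fpath}"
                        )
                    mats[pol] = read_faims_matrix(fpath, polarity=pol)
                reps.append(MatrixPair(mats["positive"], mats["negative"]))
            ttg = float(row["ttg_kU_L"]) if row["ttg_kU_L"].strip() else None
            marsh = row["marsh"].strip() or None
            samples.append(FaimsSample(pid, row["label"].strip(), reps, ttg, marsh))
    logger.info("read cohort %s: %d samples", manifest_path, len(samples))
    return samples


def write_cohort(cohort: Sequence[FaimsSample], out_dir: str | Path) -> Path:
    """Write every matrix of ``cohort`` plus a manifest CSV under ``out_dir``.

    Returns the manifest path. File names are ``<patient>_r<k>.<pol>.faims.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for sample in cohort:
            rep_specs = []
            for k, rep in enumerate(sample.replicates):
                names = []
                for pol in POLARITIES:
                    name = f"{sample.patient_id}_r{k}.{pol[:3]}.faims.tsv"
                    write_faims_matrix(getattr(rep, pol), out_dir / name)
                    names.append(name)
                rep_specs.append("|".join(names))
            writer.writerow([
                sample.patient_id,
                sample.label,
                "" if sample.ttg is None else format(sample.ttg, ".4g"),
                sample.marsh or "",
                ";".join(rep_specs),
            ])
    logger.info("wrote cohort of %d samples to %s", len(cohort), out_dir)
    return manifest


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(predictions, path: str | Path) -> None:
    """Write held-out probabilities as CSV ``patient_id,label,prob_cd``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "prob_cd"])
        for p in predictions:
            writer.writerow([p.patient_id, p.true_label, format(p.prob_cd, ".6g")])
    logger.info("wrote %d predictions to %s", len(predictions), path)


def read_predictions(path: str | Path):
    """Read a predictions CSV back into :class:`~faimsvoc.evaluation.CvPrediction`."""
    from .evaluation import CvPrediction

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(CvPrediction(row["patient_id"], row["label"], float(row["prob_cd"])))
    return out
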
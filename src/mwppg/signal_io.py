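"""Plain-text I/O for multi-wavelength PPG recordings and cuff-BP labels.

The on-disk contract for the whole pipeline:

* **Signal files** are plain text, one row per sample time, four numeric
  columns in fixed channel order (Channel 1..4 = 660, 730, 850, 940 nm),
  whitespace- or comma-delimited.  Blank lines and ``#`` comments are
  ignored.  Values are raw sensor amplitudes in arbitrary units;
  normalisation is the preprocessing stage's job.
* **Labels** live in a separate CSV keyed by subject id with header
  ``subject_id,sbp,dbp`` (mmHg), one row per subject.  A subject is flagged
  hypertensive when SBP >= 130 mmHg or DBP >= 90 mmHg.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

WAVELENGTHS_NM = (660, 730, 850, 940)
N_CHANNELS = 4

#: Hypertension rule applied to cuff labels (mmHg).
HYPERTENSION_SBP = 130.0
HYPERTENSION_DBP = 90.0


def is_hypertensive(sbp: float, dbp: float) -> bool:
    """Apply the cohort's hypertension rule: SBP >= 130 or DBP >= 90 mmHg."""
    return sbp >= HYPERTENSION_SBP or dbp >= HYPERTENSION_DBP


@dataclass
class MWPPGRecord:
    """One subject's four-wavelength fingertip PPG recording.

    Attributes
    ----------
    subject_id : str
        Cohort-unique identifier.
    samples : ndarray, shape (4, n)
        Raw signal, channel order fixed 660/730/850/940 nm.
    fs : float
        Sampling rate in Hz (200 for the acquisition protocol emulated here).
    sbp, dbp : float or None
        Reference cuff pressures in mmHg; ``None`` for unlabeled recordings.
    """

    subject_id: str
    samples: np.ndarray
    fs: float
    sbp: float | None = None
    dbp: float | None = None
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValidationError(
                f"samples must have shape (4, n); got {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive; got {self.fs}")
        if self.sbp is not None and self.dbp is not None and self.sbp <= self.dbp:
            raise ValidationError(
                f"sbp must exceed dbp; got sbp={self.sbp}, dbp={self.dbp}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def labeled(self) -> bool:
        return self.sbp is not None and self.dbp is not None

    @property
    def hypertensive(self) -> bool | None:
        if not self.labeled:
            return None
        return is_hypertensive(self.sbp, self.dbp)


_DELIM = re.compile(r"[,\s]+")


def read_record(path, fs: float = 200.0, subject_id: str | None = None) -> MWPPGRecord:
    """Read a four-column plain-text signal file into an (unlabeled) record.

    Parameters
    ----------
    path : path-like
        Text file with one row per sample, four numeric columns in
        Channel 1..4 order.
    fs : float
        Sampling rate the file was recorded at (not stored in the file).
    subject_id : str, optional
        Defaults to the file stem.

    Raises
    ------
    FormatError
        If a data row does not have exactly four columns.
    ParseError
        If a field is not numeric; the error names the 1-based line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = _DELIM.split(stripped)
            if len(fields) != N_CHANNELS:
                raise FormatError(
                    f"expected 4 columns, found {len(fields)}",
                    path=path,
                    line_number=lineno,
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric field in row: {stripped!r}",
                    path=path,
                    line_number=lineno,
                ) from exc
    samples = (
        np.asarray(rows, dtype=float).T if rows else np.empty((N_CHANNELS, 0))
    )
    return MWPPGRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        samples=samples,
        fs=fs,
    )


def write_record(record: MWPPGRecord, path, precision: int = 6) -> Path:
    """Write a record in the dialect :func:`read_record` accepts.

    Floats are printed with ``precision`` decimals, so a write/read
    round trip reproduces samples to that precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# subject_id: {record.subject_id}\n"
        f"# fs_hz: {record.fs:g}\n"
        f"# columns: {' '.join(f'ch{i + 1}_{w}nm' for i, w in enumerate(record.wavelengths))}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fmt = f"%.{precision}f"
        np.savetxt(fh, record.samples.T, fmt=fmt, delimiter="\t")
    return path


def read_labels(path) -> pd.DataFrame:
    """Read the cuff-BP labels CSV (header ``subject_id,sbp,dbp``).

    Returns a DataFrame with columns subject_id, sbp, dbp and a derived
    boolean ``hypertensive`` column (SBP >= 130 or DBP >= 90 mmHg).

    Raises
    ------
    ValidationError
        On duplicate subject ids or any row with sbp <= dbp.
    FormatError
        If the required columns are missing.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "sbp", "dbp"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"labels file must have columns {sorted(required)}; got {list(df.columns)}",
            path=path,
        )
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate subject_id(s): {sorted(set(dupes))}")
    bad = df[df["sbp"] <= df["dbp"]]
    if len(bad):
        raise ValidationError(
            "sbp must exceed dbp for every subject; offending rows: "
            + ", ".join(str(s) for s in bad["subject_id"])
        )
    df = df.copy()
    df["hypertensive"] = (df["sbp"] >= HYPERTENSION_SBP) | (
        df["dbp"] >= HYPERTENSION_DBP
    )
    return df


def write_labels(labels: pd.DataFrame, path) -> Path:
    """Write a labels table (subject_id, sbp, dbp) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels[["subject_id", "sbp", "dbp"]].to_csv(path, index=False)
    return path


def attach_labels(records: list[MWPPGRecord], labels: pd.DataFrame) -> list[MWPPGRecord]:
    """Return new records with (sbp, dbp) filled in from a labels table."""
    table = labels.set_index("subject_id")
    out = []
    for rec in records:
        if rec.subject_id not in table.index:
            raise ValidationError(f"no label row for subject {rec.subject_id!r}")
        row = table.loc[rec.subject_id]
        out.append(
            MWPPGRecord(
                subject_id=rec.subject_id,
                samples=rec.samples,
                fs=rec.fs,
                sbp=float(row["sbp"]),
                dbp=float(row["dbp"]),
            )
        )
    return out
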
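"""Device-validation metrics: ME/SD/MAE/RMSE/R2, AAMI, BHS, Bland–Altman.

Error is defined as predicted minus reference (mmHg) throughout.

* ME  — mean error.
* SD  — *population* standard deviation of the errors (divide by n), so
  the identity RMSE^2 = ME^2 + SD^2 holds exactly.
* MAE — mean absolute error;  RMSE — root mean squared error.
* R^2 — 1 - SSE/SST with SST about the mean of the reference values.
* AAMI criterion: |ME| < 5 mmHg and SD < 8 mmHg (strict).
* BHS grading: cumulative percentages of |error| <= 5/10/15 mmHg; grade A
  requires (60, 85, 95), B (50, 75, 90), C (40, 65, 85), inclusive; D
  otherwise.
* Bland–Altman: mean difference with 95% limits of agreement
  ME +/- 1.96 * SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SampleSizeError, ShapeError

AAMI_ME_LIMIT = 5.0   # mmHg
AAMI_SD_LIMIT = 8.0   # mmHg
BHS_ERROR_THRESHOLDS = (5.0, 10.0, 15.0)   # mmHg
#: Minimum cumulative percentages (<=5, <=10, <=15 mmHg) per grade.
BHS_GRADE_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
LOA_MULTIPLIER = 1.96  # 95% limits of agreement


def aami_check(me: float, sd: float) -> bool:
    """AAMI verdict: |ME| < 5 mmHg and SD < 8 mmHg (strict inequalities)."""
    if not (np.isfinite(me) and np.isfinite(sd)):
        raise ShapeError("aami_check requires finite ME and SD")
    return bool(abs(me) < AAMI_ME_LIMIT and sd < AAMI_SD_LIMIT)


def rmse_from_me_sd(me: float, sd: float) -> float:
    """RMSE reconstructed from ME and (population) SD: sqrt(ME^2 + SD^2)."""
    return float(np.sqrt(me**2 + sd**2))


def limits_of_agreement(me: float, sd: float) -> tuple[float, float]:
    """95% Bland–Altman limits: ME -/+ 1.96*SD."""
    return (me - LOA_MULTIPLIER * sd, me + LOA_MULTIPLIER * sd)


@dataclass(frozen=True)
class BHSResult:
    """Cumulative error percentages and the resulting BHS grade."""

    pct5: float
    pct10: float
    pct15: float
    grade: str

    @property
    def percentages(self) -> tuple[float, float, float]:
        return (self.pct5, self.pct10, self.pct15)


def grade_from_percentages(pct5: float, pct10: float, pct15: float) -> str:
    """Best grade whose three thresholds are all met (inclusive); else D."""
    for grade in ("A", "B", "C"):
        t5, t10, t15 = BHS_GRADE_THRESHOLDS[grade]
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            return grade
    return "D"


def bhs_grade(abs_errors: np.ndarray) -> BHSResult:
    """Grade a set of absolute errors (mmHg) on the BHS scale."""
    abs_errors = np.asarray(abs_errors, dtype=float)
    if abs_errors.size == 0:
        raise SampleSizeError("bhs_grade requires at least one error")
    if np.any(abs_errors < 0):
        raise ShapeError("abs_errors must be non-negative")
    pcts = [
        100.0 * float(np.mean(abs_errors <= t)) for t in BHS_ERROR_THRESHOLDS
    ]
    return BHSResult(*pcts, grade=grade_from_percentages(*pcts))


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference, 95% limits of agreement, and the per-point table."""

    mean_diff: float
    loa_low: float
    loa_high: float
    means: tuple = ()
    diffs: tuple = ()


def bland_altman(y_true: np.ndarray, y_pred: np.ndarray) -> BlandAltman:
    """Bland–Altman agreement statistics for predicted vs reference BP."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise SampleSizeError("bland_altman requires n >= 2")
    diffs = y_pred - y_true
    me = float(diffs.mean())
    sd = float(diffs.std())  # population SD, consistent with compute_metrics
    lo, hi = limits_of_agreement(me, sd)
    return BlandAltman(
        mean_diff=me,
        loa_low=lo,
        loa_high=hi,
        means=tuple((y_pred + y_true) / 2.0),
        diffs=tuple(diffs),
    )


@dataclass(frozen=True)
class EvalReport:
    """Full evaluation of one target (SBP or DBP) on one sample set."""

    n: int
    me: float
    sd: float
    mae: float
    rmse: float
    r2: float
    aami_pass: bool
    bhs: BHSResult
    ba: BlandAltman

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "me": self.me,
            "sd": self.sd,
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "aami_pass": self.aami_pass,
            "bhs": {
                "pct5": self.bhs.pct5,
                "pct10": self.bhs.pct10,
                "pct15": self.bhs.pct15,
                "grade": self.bhs.grade,
            },
            "ba": {
                "mean_diff": self.ba.mean_diff,
                "loa_low": self.ba.loa_low,
                "loa_high": self.ba.loa_high,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            n=int(d["n"]),
            me=float(d["me"]),
            sd=float(d["sd"]),
            mae=float(d["mae"]),
            rmse=float(d["rmse"]),
            r2=float(d["r2"]),
            aami_pass=bool(d["aami_pass"]),
            bhs=BHSResult(
                pct5=float(d["bhs"]["pct5"]),
                pct10=float(d["bhs"]["pct10"]),
                pct15=float(d["bhs"]["pct15"]),
                grade=str(d["bhs"]["grade"]),
            ),
            ba=BlandAltman(
                mean_diff=float(d["ba"]["mean_diff"]),
                loa_low=float(d["ba"]["loa_low"]),
                loa_high=float(d["ba"]["loa_high"]),
            ),
        )


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """All evaluation indexes for one target on one sample set.

    ME, SD (population), MAE, RMSE, R^2, the AAMI verdict, BHS grading and
    Bland–Altman statistics; requires n >= 2 and equal-length inputs.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ShapeError(
            f"length mismatch: y_true {y_true.shape} vs y_pred {y_pred.shape}"
        )
    if y_true.size < 2:
        raise SampleSizeError("compute_metrics requires n >= 2")
    err = y_pred - y_true
    me = float(err.mean())
    sd = float(err.std())
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return EvalReport(
        n=int(y_true.size),
        me=me,
        sd=sd,
        mae=mae,
        rmse=rmse,
        r2=r2,
        aami_pass=aami_check(me, sd),
        bhs=bhs_grade(np.abs(err)),
        ba=bland_altman(y_true, y_pred),
    )


def render_report(
    report: EvalReport, out_dir, label: str = "SBP"
) -> dict[str, Path]:
    """Write a report as JSON + Bland–Altman plot + AAMI/BHS summary table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    json_path = out_dir / f"metrics_{label.lower()}.json"
    json_path.write_text(json.dumps({"schema": 1, "label": label, **report.to_dict()}, indent=2))
    paths["json"] = json_path

    fig, ax = plt.subplots(figsize=(5, 4))
    if report.ba.means:
        ax.scatter(report.ba.means, report.ba.diffs, s=10, alpha=0.6)
    for yv, style in (
        (report.ba.mean_diff, "-"),
        (report.ba.loa_low, "--"),
        (report.ba.loa_high, "--"),
    ):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of predicted and reference {label} (mmHg)")
    ax.set_ylabel("predicted - reference (mmHg)")
    ax.set_title(f"Bland-Altman, {label}")
    fig.tight_layout()
    plot_path = out_dir / f"bland_altman_{label.lower()}.png"
    fig.savefig(plot_path, dpi=100)
    plt.close(fig)
    paths["plot"] = plot_path

    lines = [
        f"{label}: n={report.n}",
        f"  ME={report.me:.3f}  SD={report.sd:.3f}  MAE={report.mae:.3f}  "
        f"RMSE={report.rmse:.3f}  R2={report.r2:.3f}",
        f"  AAMI (|ME|<{AAMI_ME_LIMIT:g}, SD<{AAMI_SD_LIMIT:g} mmHg): "
        + ("Yes" if report.aami_pass else "No"),
        "  BHS cumulative percentages (<=5, <=10, <=15 mmHg): "
        f"{report.bhs.pct5:.1f} {report.bhs.pct10:.1f} {report.bhs.pct15:.1f}"
        f" -> grade {report.bhs.grade}",
    ]
    lines.append("  BHS grade boundaries:")
    for g, t in BHS_GRADE_THRESHOLDS.items():
        lines.append(f"    Grade {g}: {t[0]:g} {t[1]:g} {t[2]:g}")
    lines.append(
        f"  Bland-Altman: mean {report.ba.mean_diff:.3f}, "
        f"LoA [{report.ba.loa_low:.3f}, {report.ba.loa_high:.3f}] mmHg"
    )
    table_path = out_dir / f"summary_{label.lower()}.txt"
    table_path.write_text("\n".join(lines) + "\n")
    paths["table"] = table_path
    return paths
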
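"""Aggregation and comparison of reporter-gene activity assays.

Beta-galactosidase reporter activity (mOD/min) is measured in a nested
hierarchy: each transformed fly line is assayed in 2-3 biological
replicates, each biological replicate in two technical replicates, each
assay on a fixed number of flies (five by convention). Aggregation follows
the hierarchy upward: technical replicates are averaged within a biological
replicate, biological-replicate means are averaged into the line mean, and
line means are the units of the X-vs-autosome comparison.

Assays run with a different fly count are rescaled to the reference count
before any averaging (an assay on six flies is multiplied by 5/6).

Negative-control (non-transgenic) measurements are summarised but never
subtracted from line activities: the control serves as an
expression-detection floor, not as background.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from collections.abc import Callable, Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chromosome_stats import rank_sum_test
from .data_io import ValidationError

__all__ = [
    "AssayMeasurement",
    "LineSummary",
    "ClassComparison",
    "RegressionResult",
    "read_reporter_table",
    "write_reporter_table",
    "summarize_line",
    "summarize_lines",
    "compare_classes",
    "suppression_ratio",
    "suppression_points",
    "suppression_vs_expression",
]

REPORTER_COLUMNS = (
    "line_id",
    "chromosome_class",
    "tissue",
    "bio_rep",
    "tech_rep",
    "activity_mOD_min",
    "flies_per_assay",
)

CHROMOSOME_CLASSES = ("X", "A", "control")


@dataclasses.dataclass(frozen=True)
class AssayMeasurement:
    """One technical-replicate activity measurement.

    ``activity`` may be negative: control assays hover around zero and the
    maximum-slope extraction can dip below it.
    """

    line_id: str
    chromosome_class: str  # "X" | "A" | "control"
    tissue: str
    bio_rep: str
    tech_rep: str
    activity: float
    flies_per_assay: int = 5

    def __post_init__(self) -> None:
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise ValidationError(
                f"line {self.line_id!r}: chromosome_class must be one of "
                f"{CHROMOSOME_CLASSES}, got {self.chromosome_class!r}"
            )
        if not math.isfinite(self.activity):
            raise ValidationError(f"line {self.line_id!r}: non-finite activity")
        if self.flies_per_assay < 1:
            raise ValidationError(
                f"line {self.line_id!r}: flies_per_assay must be >= 1"
            )


@dataclasses.dataclass(frozen=True)
class LineSummary:
    """Per-line activity: mean and sd over biological-replicate means."""

    line_id: str
    chromosome_class: str
    tissue: str
    n_bio_reps: int
    mean_activity: float
    sd_activity: float


@dataclasses.dataclass(frozen=True)
class ClassComparison:
    """Autosomal vs X-linked line activities in one tissue."""

    tissue: str
    n_a: int
    n_x: int
    mean_a: float
    median_a: float
    mean_x: float
    median_x: float
    p_value: float


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def read_reporter_table(path: str | Path) -> list[AssayMeasurement]:
    """Read a CSV/TSV of assay measurements (delimiter sniffed from header)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"line_id": str})
    missing = [c for c in REPORTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    measurements = [
        AssayMeasurement(
            line_id=str(r.line_id),
            chromosome_class=str(r.chromosome_class),
            tissue=str(r.tissue),
            bio_rep=str(r.bio_rep),
            tech_rep=str(r.tech_rep),
            activity=float(r.activity_mOD_min),
            flies_per_assay=int(r.flies_per_assay),
        )
        for r in df.itertuples(index=False)
    ]
    keys = [(m.line_id, m.tissue, m.bio_rep, m.tech_rep) for m in measurements]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{path}: duplicate (line, tissue, bio_rep, tech_rep)")
    return measurements


def write_reporter_table(
    measurements: Sequence[AssayMeasurement], path: str | Path
) -> None:
    rows = [
        {
            "line_id": m.line_id,
            "chromosome_class": m.chromosome_class,
            "tissue": m.tissue,
            "bio_rep": m.bio_rep,
            "tech_rep": m.tech_rep,
            "activity_mOD_min": m.activity,
            "flies_per_assay": m.flies_per_assay,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def summarize_line(
    measurements: Iterable[AssayMeasurement], normalize_to: int = 5
) -> LineSummary:
    """Aggregate one line's measurements in one tissue to a line mean.

    Activities from assays run on a fly count other than ``normalize_to``
    are rescaled by ``normalize_to / flies_per_assay`` before averaging.
    The sd is over biological-replicate means (0 for a single replicate).
    """
    ms = list(measurements)
    if not ms:
        raise ValidationError("summarize_line: no measurements")
    lines = {m.line_id for m in ms}
    tissues = {m.tissue for m in ms}
    classes = {m.chromosome_class for m in ms}
    if len(lines) != 1 or len(tissues) != 1 or len(classes) != 1:
        raise ValidationError(
            f"summarize_line: expected one line/tissue/class, got lines={sorted(lines)}, "
            f"tissues={sorted(tissues)}, classes={sorted(classes)}"
        )
    by_bio: dict[str, list[float]] = defaultdict(list)
    for m in ms:
        by_bio[m.bio_rep].append(m.activity * normalize_to / m.flies_per_assay)
    bio_means = np.array([np.mean(v) for v in by_bio.values()])
    sd = float(np.std(bio_means, ddof=1)) if bio_means.size > 1 else 0.0
    return LineSummary(
        line_id=lines.pop(),
        chromosome_class=classes.pop(),
        tissue=tissues.pop(),
        n_bio_reps=int(bio_means.size),
        mean_activity=float(np.mean(bio_means)),
        sd_activity=sd,
    )


def summarize_lines(
    measurements: Iterable[AssayMeasurement], normalize_to: int = 5
) -> list[LineSummary]:
    """Summaries for every (line, tissue) group present in the input."""
    groups: dict[tuple[str, str], list[AssayMeasurement]] = defaultdict(list)
    for m in measurements:
        groups[(m.line_id, m.tissue)].append(m)
    return [summarize_line(g, normalize_to=normalize_to) for g in groups.values()]


def compare_classes(
    summaries: Iterable[LineSummary],
    exclude_lines: set[str] | None = None,
) -> ClassComparison:
    """Rank-sum comparison of autosomal vs X-linked line means in one tissue.

    Control-class lines are ignored; ``exclude_lines`` supports explicit
    outlier reanalysis (exclusion is always user-supplied, never automatic).
    """
    exclude_lines = exclude_lines or set()
    ss = [
        s
        for s in summaries
        if s.chromosome_class != "control" and s.line_id not in exclude_lines
    ]
    tissues = {s.tissue for s in ss}
    if len(tissues) != 1:
        raise ValidationError(
            f"compare_classes: expected one tissue, got {sorted(tissues)}"
        )
    a = np.array([s.mean_activity for s in ss if s.chromosome_class == "A"])
    x = np.array([s.mean_activity for s in ss if s.chromosome_class == "X"])
    if a.size == 0 or x.size == 0:
        raise ValidationError(
            f"compare_classes: empty class (n_a={a.size}, n_x={x.size})"
        )
    return ClassComparison(
        tissue=tissues.pop(),
        n_a=int(a.size),
        n_x=int(x.size),
        mean_a=float(np.mean(a)),
        median_a=float(np.median(a)),
        mean_x=float(np.mean(x)),
        median_x=float(np.median(x)),
        p_value=rank_sum_test(x, a),
    )


def suppression_ratio(mean_a: float, mean_x: float) -> float:
    """Autosomal-to-X activity ratio of one construct; > 1 means suppression."""
    if not mean_x > 0:
        raise ValidationError(
            f"suppression_ratio: X-class mean must be positive, got {mean_x}"
        )
    return mean_a / mean_x


def _construct_prefix(line_id: str) -> str:
    return line_id.split(".", 1)[0]


def suppression_points(
    measurements: Iterable[AssayMeasurement],
    normalize_to: int = 5,
    construct_of: Callable[[str], str] = _construct_prefix,
) -> dict[str, tuple[float, float]]:
    """Per-construct (autosomal mean activity, suppression ratio) pairs.

    Lines are grouped into constructs by ``construct_of(line_id)`` (default:
    the prefix before the first '.'). Class means are means over line means.
    """
    by_construct: dict[str, list[AssayMeasurement]] = defaultdict(list)
    for m in measurements:
        if m.chromosome_class == "control":
            continue
        by_construct[construct_of(m.line_id)].append(m)
    points: dict[str, tuple[float, float]] = {}
    for construct, ms in sorted(by_construct.items()):
        summaries = summarize_lines(ms, normalize_to=normalize_to)
        a = [s.mean_activity for s in summaries if s.chromosome_class == "A"]
        x = [s.mean_activity for s in summaries if s.chromosome_class == "X"]
        if not a or not x:
            raise ValidationError(
                f"construct {construct!r}: needs lines of both classes"
            )
        mean_a = float(np.mean(a))
        points[construct] = (mean_a, suppression_ratio(mean_a, float(np.mean(x))))
    return points


def suppression_vs_expression(
    points: Sequence[tuple[float, float]], log_expression: bool = False
) -> RegressionResult:
    """OLS of suppression ratio on autosomal expression across constructs.

    A positive, significant slope indicates that more highly expressed
    constructs are more strongly suppressed when X-linked. ``log_expression``
    regresses on log(expression) instead of the raw scale.
    """
    if len(points) < 3:
        raise ValidationError("suppression_vs_expression: need at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if log_expression:
        if np.any(x <= 0):
            raise ValidationError("log_expression requires positive expression values")
        x = np.log(x)
    if np.ptp(x) == 0:
        raise ValidationError("suppression_vs_expression: constant predictor")
    if np.ptp(y) == 0:  # flat response: zero slope, no variance explained
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )
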
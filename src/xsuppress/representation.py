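"""Enrichment/depletion of X-linked genes across cumulative expression bins.

Genes are grouped into *cumulative* expression categories: the category at
threshold t holds every gene with mean FPKM >= t, so categories are nested
along an ascending threshold grid. Within each category the observed count
of X-linked genes is compared to the count expected from the genome-wide
proportion of X-linked genes with a one-degree-of-freedom chi-square
goodness-of-fit test:

    chi2 = (obs_X - p*n)^2 / (p*n) + (obs_A - (1-p)*n)^2 / ((1-p)*n)

where p is the expected X proportion and n the category size. A category is
flagged ``under`` (``over``) when the observed X count falls below (above)
expectation and the test is significant at the configured level.

The expected proportion is, by default, taken from the entire unfiltered
gene universe — not from the filtered per-tissue gene set — so depletion of
X-linked genes among highly expressed genes registers against a stable
genomic baseline.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats

from .chromosome_stats import dosage_correction
from .data_io import (
    AUTOSOME_LABELS,
    X_LABELS,
    GeneExpressionRecord,
    TissueTable,
    ValidationError,
)

__all__ = [
    "RepresentationResult",
    "DEFAULT_THRESHOLDS",
    "expected_x_proportion",
    "categorize_cumulative",
    "representation_test",
    "representation_profile",
    "significance_stars",
]

#: Default geometric grid of FPKM thresholds for cumulative categories.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1, 2, 5, 10, 20, 50, 100, 200, 500)

#: Expected-count floor below which the chi-square approximation is suspect.
MIN_EXPECTED = 5.0


def significance_stars(p_value: float) -> str:
    """Figure-legend stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p_value):
        return ""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclasses.dataclass(frozen=True)
class RepresentationResult:
    """Chi-square representation test for one cumulative expression category.

    ``tested`` is False for empty categories (no statistic computed);
    ``low_expectation`` marks categories where an expected count falls below
    the validity floor — the test is still computed but should be read with
    caution.
    """

    threshold: float
    n_x_obs: int
    n_total: int
    expected_proportion: float
    chi2_stat: float
    p_value: float
    direction: str  # "under" | "over" | "none"
    low_expectation: bool = False
    tested: bool = True

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if self.tested else ""


def expected_x_proportion(
    records: Iterable[GeneExpressionRecord],
    x_labels: frozenset[str] | set[str] = X_LABELS,
    autosome_labels: frozenset[str] | set[str] = AUTOSOME_LABELS,
) -> float:
    """Genome-wide X-linked gene proportion #X / (#X + #A).

    Counts distinct gene ids over the full (unfiltered) record collection;
    genes on chromosomes in neither label set are ignored.
    """
    x_labels, autosome_labels = frozenset(x_labels), frozenset(autosome_labels)
    classes: dict[str, str] = {}
    for rec in records:
        if rec.chromosome in x_labels:
            cls = "X"
        elif rec.chromosome in autosome_labels:
            cls = "A"
        else:
            continue
        prev = classes.setdefault(rec.gene_id, cls)
        if prev != cls:
            raise ValidationError(
                f"gene {rec.gene_id!r} assigned to both X and autosomes"
            )
    n_x = sum(1 for c in classes.values() if c == "X")
    n_a = len(classes) - n_x
    if n_x == 0 or n_a == 0:
        raise ValidationError(
            f"expected_x_proportion undefined: n_x={n_x}, n_a={n_a}"
        )
    return n_x / (n_x + n_a)


def categorize_cumulative(
    table: TissueTable, thresholds: Sequence[float]
) -> list[tuple[float, int, int]]:
    """Counts (threshold, n_x_obs, n_total) of genes with mean FPKM >= t.

    Categories are cumulative, so both counts are non-increasing along the
    (ascending) threshold grid.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError("thresholds must be strictly ascending")
    x, a = table.x_fpkm, table.a_fpkm
    return [
        (float(t), int((x >= t).sum()), int((x >= t).sum() + (a >= t).sum()))
        for t in thresholds
    ]


def representation_test(
    n_x_obs: int,
    n_total: int,
    expected_proportion: float,
    threshold: float = float("nan"),
    alpha: float = 0.05,
    min_expected: float = MIN_EXPECTED,
) -> RepresentationResult:
    """Chi-square goodness-of-fit of the observed X count in one category."""
    if n_total < 1:
        raise ValidationError("representation_test: n_total must be >= 1")
    if n_x_obs < 0 or n_x_obs > n_total:
        raise ValidationError("representation_test: need 0 <= n_x_obs <= n_total")
    if not 0 < expected_proportion < 1:
        raise ValidationError(
            f"expected_proportion must be in (0,1), got {expected_proportion}"
        )
    expected = np.array(
        [expected_proportion * n_total, (1 - expected_proportion) * n_total]
    )
    observed = np.array([n_x_obs, n_total - n_x_obs], dtype=float)
    chi2, p = stats.chisquare(observed, f_exp=expected)
    chi2, p = float(chi2), float(p)
    if n_x_obs < expected[0] and p < alpha:
        direction = "under"
    elif n_x_obs > expected[0] and p < alpha:
        direction = "over"
    else:
        direction = "none"
    return RepresentationResult(
        threshold=threshold,
        n_x_obs=n_x_obs,
        n_total=n_total,
        expected_proportion=expected_proportion,
        chi2_stat=chi2,
        p_value=p,
        direction=direction,
        low_expectation=bool(expected.min() < min_expected),
    )


def representation_profile(
    table: TissueTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    expected_proportion: float | None = None,
    correction_factor: float | None = None,
    alpha: float = 0.05,
    min_expected: float = MIN_EXPECTED,
) -> list[RepresentationResult]:
    """Representation tests across the cumulative threshold grid.

    If ``correction_factor`` is given, X-linked FPKMs are multiplied by it
    (dosage correction) before categorisation; filters are not re-applied.
    If ``expected_proportion`` is None, the proportion observed in the table
    itself is used (per-tissue baseline) — passing the genome-wide value is
    the standard analysis.
    Empty categories are emitted untested (NaN statistic, direction "none").
    """
    if correction_factor is not None:
        table = dosage_correction(table, correction_factor)
    if expected_proportion is None:
        expected_proportion = table.n_x / (table.n_x + table.n_a)
    results = []
    for t, n_x_obs, n_total in categorize_cumulative(table, thresholds):
        if n_total == 0:
            results.append(
                RepresentationResult(
                    threshold=t,
                    n_x_obs=0,
                    n_total=0,
                    expected_proportion=expected_proportion,
                    chi2_stat=float("nan"),
                    p_value=float("nan"),
                    direction="none",
                    low_expectation=True,
                    tested=False,
                )
            )
        else:
            results.append(
                representation_test(
                    n_x_obs,
                    n_total,
                    expected_proportion,
                    threshold=t,
                    alpha=alpha,
                    min_expected=min_expected,
                )
            )
    return results
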
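"""X/A median-ratio statistics and the dosage-correction transform.

Within one tissue and sex, the level of X-chromosome expression relative to
the autosomes is summarised by the ratio of median FPKMs,

    X/A = median(FPKM of X-linked genes) / median(FPKM of autosomal genes),

and the two expression distributions are compared with a two-sided
Wilcoxon rank-sum (Mann-Whitney U) test. An X/A ratio near 1 indicates
dosage-compensated (or two-dose) expression; in the male germline, where
chromosome-wide dosage compensation is absent, gene-specific buffering
leaves single-dose X genes at roughly 65% of autosomal expression.

``dosage_correction`` applies the counterfactual rescaling used to ask
whether a germline expression deficit is explained by dose alone: X-linked
FPKMs are multiplied by the inverse of the observed X/A ratio (e.g. 1/0.65
= 1.53) and downstream statistics are recomputed without re-filtering.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .data_io import TissueTable, ValidationError

__all__ = [
    "RatioResult",
    "rank_sum_test",
    "compare_xa_expression",
    "median_xa_ratio",
    "correction_factor",
    "dosage_correction",
    "DegenerateDataWarning",
]

#: Largest per-group size at which the exact rank-sum null is enumerated
#: (ties force the normal approximation regardless).
EXACT_LIMIT = 20


class DegenerateDataWarning(UserWarning):
    """All observations identical; a rank test carries no information."""


@dataclasses.dataclass(frozen=True)
class RatioResult:
    """One row of an X-vs-autosome comparison table.

    Medians and the ratio are stored unrounded; :meth:`rounded` gives the
    2-decimal presentation used in printed tables.
    """

    tissue: str
    sex: str
    n_x: int
    median_x: float
    n_a: int
    median_a: float
    xa_ratio: float
    p_value: float

    def rounded(self) -> dict[str, float | int | str]:
        """Table-style row: Tissue, X Genes, X Median, A Genes, A Median, X/A, p."""
        return {
            "Tissue": self.tissue,
            "X Genes": self.n_x,
            "X Median": round(self.median_x, 2),
            "A Genes": self.n_a,
            "A Median": round(self.median_a, 2),
            "X/A": round(self.xa_ratio, 2),
            "p": self.p_value,
        }


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    exact_limit: int = EXACT_LIMIT,
    continuity: bool = False,
) -> float:
    """Two-sided Mann-Whitney U p-value comparing two samples.

    The exact permutation null is used when the smaller group has at most
    ``exact_limit`` observations and the pooled data are tie-free; otherwise
    the normal approximation with midrank tie correction is used
    (no continuity correction unless ``continuity``). If every pooled value
    is identical the test is vacuous: p = 1 with a
    :class:`DegenerateDataWarning`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test: both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn(
            "all observations identical; rank-sum p-value set to 1",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= exact_limit and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(min(res.pvalue, 1.0))


def compare_xa_expression(
    table: TissueTable, exact_limit: int = EXACT_LIMIT, continuity: bool = False
) -> float:
    """Two-sided rank-sum p-value for X vs autosomal mean-FPKM distributions."""
    return rank_sum_test(
        table.x_fpkm, table.a_fpkm, exact_limit=exact_limit, continuity=continuity
    )


def median_xa_ratio(table: TissueTable) -> RatioResult:
    """Median X and A expression, their ratio, and the rank-sum p-value.

    Even-sized partitions use the midpoint median (mean of the central
    pair). The ratio is median_x/median_a, kept unrounded.
    """
    x, a = table.x_fpkm, table.a_fpkm
    if x.size == 0 or a.size == 0:
        raise ValidationError("median_xa_ratio: empty X or A partition")
    median_x = float(np.median(x))
    median_a = float(np.median(a))
    if median_a == 0:
        raise ValidationError("median_xa_ratio: autosomal median is zero")
    return RatioResult(
        tissue=table.tissue,
        sex=table.sex,
        n_x=int(x.size),
        median_x=median_x,
        n_a=int(a.size),
        median_a=median_a,
        xa_ratio=median_x / median_a,
        p_value=compare_xa_expression(table),
    )


def correction_factor(ratio: RatioResult | float) -> float:
    """Inverse of the X/A ratio: the multiplier that equalises the medians.

    Computed from the unrounded ratio; round the result to 2 decimals for
    reporting (e.g. a testis ratio of 8.16/12.46 gives a 1.53-fold factor).
    """
    value = ratio.xa_ratio if isinstance(ratio, RatioResult) else float(ratio)
    if value <= 0:
        raise ValidationError(f"correction_factor: ratio must be positive, got {value}")
    return 1.0 / value


def dosage_correction(table: TissueTable, factor: float) -> TissueTable:
    """Multiply all X-linked mean FPKMs by ``factor``; autosomes untouched.

    This is a counterfactual transform of the already-filtered gene set:
    expression filters are deliberately not re-applied afterwards.
    """
    if not factor > 0:
        raise ValidationError(f"dosage_correction: factor must be > 0, got {factor}")
    data = table.data.copy()
    on_x = data["chromosome_class"] == "X"
    data.loc[on_x, "mean_fpkm"] *= factor
    return dataclasses.replace(table, data=data, correction=factor)
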
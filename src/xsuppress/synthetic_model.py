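"""Generative threshold-suppression model of male X-linked expression.

The model is phenomenological at the FPKM level. Each gene draws a baseline
*two-dose* expression potential e from a log-normal distribution and is
X-linked with probability ``x_fraction``, otherwise autosomal. In males:

* autosomal genes express e;
* X-linked genes express e when chromosome-wide dosage compensation is on
  (soma), and b*e when it is off (germline), where b in [0.5, 1] is the
  single-dose buffering fraction — 0.5 is the naive halved dose, ~0.65 the
  empirically buffered level, 1.0 full compensation;
* X-linked expression is then multiplied by the suppression factor

      f(e) = min(1, (tau/e)**gamma),

  equal to 1 below the threshold tau and decreasing in e above it, so only
  genes with high autosomal expression potential are suppressed, and the
  more severely the higher that potential. gamma = 0 or tau = inf switches
  suppression off.

Replicates add independent multiplicative log-normal noise (median 1).
All randomness flows from a single integer seed; a given parameter set
regenerates its dataset exactly.

The same threshold model, applied on the activity scale, drives the
synthetic reporter-assay generator, which reproduces the nested
line -> biological replicate -> technical replicate structure of the
beta-galactosidase assays.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

import numpy as np

from .chromosome_stats import correction_factor, median_xa_ratio
from .data_io import (
    GeneExpressionRecord,
    ValidationError,
    build_tissue_table,
)
from .representation import (
    DEFAULT_THRESHOLDS,
    RepresentationResult,
    expected_x_proportion,
    representation_profile,
)
from .reporter_assay import AssayMeasurement

__all__ = [
    "SuppressionModelParams",
    "ReporterModelParams",
    "suppression_factor",
    "generate_expression_dataset",
    "recover_buffering",
    "recover_suppression_signal",
    "suppression_detected",
    "generate_reporter_dataset",
]

AUTOSOME_ARMS = ("2L", "2R", "3L", "3R", "4")
# The dot chromosome (4) carries ~1% of genes; the major arms split the rest.
AUTOSOME_ARM_WEIGHTS = (0.2475, 0.2475, 0.2475, 0.2475, 0.01)


@dataclasses.dataclass(frozen=True)
class SuppressionModelParams:
    """Parameters of the expression-level generative model.

    Defaults emulate a testis-like tissue: median baseline 10 FPKM with a
    log-normal spread wide enough that ~6% of genes exceed 90 FPKM, an
    X-linked gene fraction of 0.15, single-dose buffering b = 0.65, and
    three biological replicates with moderate multiplicative noise.
    """

    n_genes: int = 10_000
    x_fraction: float = 0.15
    log_mean: float = math.log(10.0)  # location of log-baseline (ln FPKM)
    log_sd: float = 1.4               # scale of log-baseline
    buffering_b: float = 0.65         # single-dose fraction of two-dose expression
    dosage_compensation: bool = False  # on: soma; off: germline
    suppression_threshold_tau: float = math.inf  # FPKM; inf = no suppression
    suppression_exponent_gamma: float = 0.0      # severity above threshold
    n_replicates: int = 3
    replicate_noise_sd: float = 0.25  # log-scale sd of replicate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 < self.x_fraction < 1:
            raise ValidationError("x_fraction must be in (0, 1)")
        if not self.log_sd > 0:
            raise ValidationError("log_sd must be positive")
        if not 0.5 <= self.buffering_b <= 1.0:
            raise ValidationError("buffering_b must be in [0.5, 1]")
        if not self.suppression_threshold_tau > 0:
            raise ValidationError("suppression_threshold_tau must be positive")
        if self.suppression_exponent_gamma < 0:
            raise ValidationError("suppression_exponent_gamma must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ValidationError("replicate_noise_sd must be >= 0")

    @property
    def suppression_off(self) -> bool:
        return (
            self.suppression_exponent_gamma == 0
            or math.isinf(self.suppression_threshold_tau)
        )


def suppression_factor(
    e: np.ndarray | float, tau: float, gamma: float
) -> np.ndarray | float:
    """Threshold suppression f(e) = min(1, (tau/e)**gamma).

    f is 1 for e <= tau, continuous and non-increasing in e, and always in
    (0, 1]. gamma = 0 (or tau = inf) gives f = 1 everywhere.
    """
    if not tau > 0:
        raise ValidationError("tau must be positive")
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr <= 0):
        raise ValidationError("expression values must be positive")
    if gamma == 0 or math.isinf(tau):
        f = np.ones_like(e_arr)
    else:
        with np.errstate(over="ignore"):
            f = np.minimum(1.0, (tau / e_arr) ** gamma)
    return float(f) if np.isscalar(e) else f


def generate_expression_dataset(
    params: SuppressionModelParams,
    tissue: str = "testis",
    sex: str = "male",
    gene_prefix: str = "SYN",
) -> list[GeneExpressionRecord]:
    """Draw a synthetic male expression dataset under the threshold model.

    Output conforms to the expression-table record type and feeds straight
    into ``build_tissue_table``; chromosome labels are "X" for X-linked
    genes and a random major arm (rarely "4") for autosomal genes. Each call
    simulates an independent gene set; give multi-tissue composites a
    distinct ``gene_prefix`` per call so gene ids stay unique.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    baseline = rng.lognormal(params.log_mean, params.log_sd, n)
    is_x = rng.random(n) < params.x_fraction
    arms = rng.choice(AUTOSOME_ARMS, size=n, p=AUTOSOME_ARM_WEIGHTS)

    expressed = baseline.copy()
    if not params.dosage_compensation:
        expressed[is_x] *= params.buffering_b
    expressed[is_x] *= suppression_factor(
        baseline[is_x],
        params.suppression_threshold_tau,
        params.suppression_exponent_gamma,
    )

    if params.replicate_noise_sd > 0:
        noise = rng.lognormal(0.0, params.replicate_noise_sd, (n, params.n_replicates))
    else:
        noise = np.ones((n, params.n_replicates))
    replicates = expressed[:, None] * noise

    return [
        GeneExpressionRecord(
            gene_id=f"{gene_prefix}{i:06d}",
            chromosome="X" if is_x[i] else str(arms[i]),
            tissue=tissue,
            sex=sex,
            replicate_fpkm=tuple(float(v) for v in replicates[i]),
        )
        for i in range(n)
    ]


def recover_buffering(params: SuppressionModelParams, min_fpkm: float = 0.0) -> float:
    """Estimate the buffering fraction b as the median X/A ratio.

    Valid only for a germline-style dataset (dosage compensation off, no
    suppression), where the X and A expression distributions differ exactly
    by the factor b. The ratio is taken on the unfiltered table by default:
    a fixed absolute FPKM filter truncates the b-shifted X distribution at a
    higher quantile than the autosomal one and biases the median ratio
    upward.
    """
    if params.dosage_compensation:
        raise ValidationError(
            "recover_buffering requires dosage_compensation off; with it on "
            "the X/A ratio estimates 1, not b"
        )
    if not params.suppression_off:
        raise ValidationError(
            "recover_buffering requires suppression off (gamma=0 or tau=inf)"
        )
    records = generate_expression_dataset(params)
    table = build_tissue_table(
        records, tissue="testis", sex="male", min_fpkm=min_fpkm
    )
    return median_xa_ratio(table).xa_ratio


def recover_suppression_signal(
    params: SuppressionModelParams,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    min_fpkm: float = 1.0,
    alpha: float = 0.05,
) -> list[RepresentationResult]:
    """Run the full representation pipeline on one synthetic dataset.

    Generates a germline dataset, computes the genome-wide expected X
    proportion from the unfiltered records, filters at ``min_fpkm``, applies
    dosage correction at 1/b, and returns the representation profile. With
    gamma > 0 the categories above tau should come out ``under``; with
    gamma = 0 they should not, beyond the nominal false-positive rate.
    """
    if params.dosage_compensation:
        raise ValidationError("recover_suppression_signal models the germline")
    records = generate_expression_dataset(params)
    expected = expected_x_proportion(records)
    table = build_tissue_table(records, tissue="testis", sex="male", min_fpkm=min_fpkm)
    return representation_profile(
        table,
        thresholds=thresholds,
        expected_proportion=expected,
        correction_factor=correction_factor(params.buffering_b),
        alpha=alpha,
    )


def suppression_detected(
    results: list[RepresentationResult], tau: float
) -> bool:
    """True if every adequately powered category above tau is flagged under.

    Categories with an expected X count below the chi-square validity floor
    (``low_expectation``) or no genes at all are excluded from the check;
    detection is vacuously False if no category above tau qualifies.
    """
    eligible = [
        r
        for r in results
        if r.threshold > tau and r.tested and not r.low_expectation
    ]
    return bool(eligible) and all(r.direction == "under" for r in eligible)


@dataclasses.dataclass(frozen=True)
class ReporterModelParams:
    """Parameters of the synthetic reporter-assay generator.

    Constructs are distinct reporter genes with different intrinsic activity
    (mOD/min); each gets independent autosomal and X-linked insertion lines.
    An X-linked line's activity is its autosomal-potential activity times
    the same threshold suppression factor, on the activity scale. Noise is
    multiplicative log-normal at the line (position effect), biological and
    technical levels. Default construct activities span the observed range
    from a low testis-expressed construct (~0.2) to strongly expressed ones.
    """

    construct_activities: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "c1": 0.2,
            "c2": 1.0,
            "c3": 3.0,
            "c4": 8.0,
            "c5": 16.0,
        }
    )
    suppression_threshold_tau: float = 0.5  # mOD/min
    suppression_exponent_gamma: float = 1.0
    n_lines_per_class: int = 6
    line_noise_sd: float = 0.3
    bio_noise_sd: float = 0.15
    tech_noise_sd: float = 0.05
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    flies_per_assay: int = 5
    normalize_to: int = 5
    n_control_lines: int = 1
    control_mean: float = -0.05
    control_sd: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.construct_activities:
            raise ValidationError("need at least one construct")
        if any(a <= 0 for a in self.construct_activities.values()):
            raise ValidationError("construct activities must be positive")
        if not self.suppression_threshold_tau > 0:
            raise ValidationError("suppression_threshold_tau must be positive")
        if self.suppression_exponent_gamma < 0:
            raise ValidationError("suppression_exponent_gamma must be >= 0")
        for name in ("n_lines_per_class", "n_bio_reps", "n_tech_reps",
                     "flies_per_assay", "normalize_to"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("line_noise_sd", "bio_noise_sd", "tech_noise_sd", "control_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def generate_reporter_dataset(
    params: ReporterModelParams, tissue: str = "testis"
) -> list[AssayMeasurement]:
    """Simulate a nested reporter-assay dataset under the threshold model.

    Line ids are ``<construct>.<class><i>`` (e.g. ``c3.X2``), so the
    default construct grouping of ``suppression_points`` applies. Raw
    recorded activities scale with the fly count (an assay on six flies
    reads 6/5 of the five-fly activity); downstream normalization undoes
    this. Control lines draw additive Gaussian activity around the
    detection floor and carry class ``control``.
    """
    rng = np.random.default_rng(params.seed)
    out: list[AssayMeasurement] = []

    def _ln(sd: float) -> float:
        return float(rng.lognormal(0.0, sd)) if sd > 0 else 1.0

    for construct, activity in params.construct_activities.items():
        for cls in ("A", "X"):
            for i in range(params.n_lines_per_class):
                potential = activity * _ln(params.line_noise_sd)
                true_line = potential
                if cls == "X":
                    true_line *= suppression_factor(
                        potential,
                        params.suppression_threshold_tau,
                        params.suppression_exponent_gamma,
                    )
                for b in range(params.n_bio_reps):
                    bio = true_line * _ln(params.bio_noise_sd)
                    for t in range(params.n_tech_reps):
                        tech = bio * _ln(params.tech_noise_sd)
                        measured = tech * params.flies_per_assay / params.normalize_to
                        out.append(
                            AssayMeasurement(
                                line_id=f"{construct}.{cls}{i + 1}",
                                chromosome_class=cls,
                                tissue=tissue,
                                bio_rep=f"b{b + 1}",
                                tech_rep=f"t{t + 1}",
                                activity=measured,
                                flies_per_assay=params.flies_per_assay,
                            )
                        )
    for i in range(params.n_control_lines):
        for b in range(params.n_bio_reps):
            for t in range(params.n_tech_reps):
                out.append(
                    AssayMeasurement(
                        line_id=f"yw.ctl{i + 1}",
                        chromosome_class="control",
                        tissue=tissue,
                        bio_rep=f"b{b + 1}",
                        tech_rep=f"t{t + 1}",
                        activity=float(
                            rng.normal(params.control_mean, params.control_sd)
                        ),
                        flies_per_assay=params.normalize_to,
                    )
                )
    return out
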
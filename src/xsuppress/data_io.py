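"""Reading, validation, filtering and partitioning of gene-expression tables.

Expression inputs are tidy tab-separated tables in FPKM units. Two layouts
are accepted:

* **wide** — one gene per row, replicate FPKMs in columns ``fpkm_r1`` ..
  ``fpkm_rK``;
* **long** — one replicate per row, with a single ``fpkm`` column.

Column names are remappable through a ``format_config`` dictionary (or a YAML
file fed to the CLI). Records are validated on construction: FPKMs must be
finite and non-negative, and ``(gene_id, tissue, sex)`` must be unique within
one table.

The central container is :class:`TissueTable`: the replicate-averaged,
expression-filtered gene set of one tissue and sex, partitioned into X-linked
and autosomal genes. Chromosome arms default to the Drosophila melanogaster
karyotype (X vs 2L/2R/3L/3R/4); anything else — Y, mitochondrial genome,
unplaced scaffolds — belongs to neither class and is excluded with a count.
"""

from __future__ import annotations

import dataclasses
import math
import re
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "GeneExpressionRecord",
    "TissueTable",
    "X_LABELS",
    "AUTOSOME_LABELS",
    "FLYATLAS2_FORMAT",
    "average_replicates",
    "read_expression_table",
    "write_expression_table",
    "read_flyatlas2_export",
    "build_tissue_table",
]

#: Chromosome arms counted as X-linked / autosomal by default.
X_LABELS = frozenset({"X"})
AUTOSOME_LABELS = frozenset({"2L", "2R", "3L", "3R", "4"})

DEFAULT_FORMAT: dict[str, str] = {
    "gene_id": "gene_id",
    "chromosome": "chromosome",
    "tissue": "tissue",
    "sex": "sex",
    "fpkm_prefix": "fpkm_r",  # wide layout: fpkm_r1, fpkm_r2, ...
    "fpkm": "fpkm",           # long layout: one replicate per row
}

#: Column map for a tabular export of the FlyAtlas2 database. The database
#: itself ships as a MySQL dump; this adapter consumes a pre-exported TSV.
FLYATLAS2_FORMAT: dict[str, str] = {
    "gene_id": "FlyBaseID",
    "chromosome": "Chromosome",
    "tissue": "Tissue",
    "sex": "Sex",
    "fpkm_prefix": "FPKM_rep",
    "fpkm": "FPKM",
}


class ConfigurationError(ValueError):
    """A required column or setting is missing or inconsistent."""


class ValidationError(ValueError):
    """Input data violate a structural invariant."""


@dataclasses.dataclass(frozen=True)
class GeneExpressionRecord:
    """One gene's replicate FPKM measurements in one tissue and sex."""

    gene_id: str
    chromosome: str
    tissue: str
    sex: str
    replicate_fpkm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_fpkm) == 0:
            raise ValidationError(f"gene {self.gene_id!r}: no replicate FPKM values")
        for v in self.replicate_fpkm:
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"gene {self.gene_id!r}: invalid FPKM value {v!r} "
                    "(must be finite and non-negative)"
                )


def average_replicates(record: GeneExpressionRecord) -> float:
    """Mean FPKM across a record's biological replicates."""
    return float(np.mean(record.replicate_fpkm))


@dataclasses.dataclass(frozen=True)
class TissueTable:
    """Filtered, replicate-averaged expression of one tissue/sex, split X vs A.

    ``data`` holds one row per retained gene with columns ``gene_id``,
    ``chromosome_class`` (``"X"`` or ``"A"``) and ``mean_fpkm``. ``excluded``
    counts genes dropped at each filtering step; retained + excluded equals
    the number of input genes for this tissue/sex. ``correction`` records a
    dosage-correction factor if one has been applied downstream.
    """

    tissue: str
    sex: str
    data: pd.DataFrame
    min_fpkm: float
    max_fpkm: float | None
    excluded: Mapping[str, int]
    correction: float | None = None

    @property
    def x_fpkm(self) -> np.ndarray:
        return self.data.loc[self.data["chromosome_class"] == "X", "mean_fpkm"].to_numpy()

    @property
    def a_fpkm(self) -> np.ndarray:
        return self.data.loc[self.data["chromosome_class"] == "A", "mean_fpkm"].to_numpy()

    @property
    def n_x(self) -> int:
        return int((self.data["chromosome_class"] == "X").sum())

    @property
    def n_a(self) -> int:
        return int((self.data["chromosome_class"] == "A").sum())

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _replicate_columns(columns: Sequence[str], prefix: str) -> list[str]:
    """Replicate columns matching ``prefix`` + integer, in numeric order."""
    pat = re.compile(re.escape(prefix) + r"(\d+)$")
    hits = [(int(m.group(1)), c) for c in columns if (m := pat.match(c))]
    return [c for _, c in sorted(hits)]


def read_expression_table(
    path: str | Path,
    format_config: Mapping[str, str] | None = None,
) -> list[GeneExpressionRecord]:
    """Read a TSV of gene expression into validated records.

    Wide layout (replicate columns named ``<fpkm_prefix>1..K``) is tried
    first; if no such columns exist, the long layout (one replicate per row,
    column ``<fpkm>``) is used. Malformed values are reported with their
    1-based file line numbers.

    Raises
    ------
    ConfigurationError
        If a required column is absent.
    ValidationError
        If any FPKM is negative/NaN or a ``(gene_id, tissue, sex)`` key is
        duplicated.
    """
    fmt = dict(DEFAULT_FORMAT)
    if format_config:
        fmt.update(format_config)
    df = pd.read_csv(path, sep="\t", dtype={fmt["gene_id"]: str})

    for key in ("gene_id", "chromosome", "tissue", "sex"):
        if fmt[key] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {fmt[key]!r} (for {key}) not found"
            )

    rep_cols = _replicate_columns(list(df.columns), fmt["fpkm_prefix"])
    long_layout = not rep_cols
    if long_layout and fmt["fpkm"] not in df.columns:
        raise ConfigurationError(
            f"{path}: no replicate columns {fmt['fpkm_prefix']}1.. and no "
            f"column {fmt['fpkm']!r} — cannot locate FPKM values"
        )

    problems: list[str] = []
    records: list[GeneExpressionRecord] = []
    seen: set[tuple[str, str, str]] = set()

    def _check_values(gene: str, values: Iterable[float], lines: Iterable[int]) -> bool:
        ok = True
        for v, ln in zip(values, lines):
            if not math.isfinite(v) or v < 0:
                problems.append(f"line {ln}: gene {gene!r} has invalid FPKM {v!r}")
                ok = False
        return ok

    if long_layout:
        grouped: dict[tuple[str, str, str], dict] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            r = row._asdict()
            key = (str(r[fmt["gene_id"]]), str(r[fmt["tissue"]]), str(r[fmt["sex"]]))
            entry = grouped.setdefault(
                key, {"chromosome": str(r[fmt["chromosome"]]), "fpkm": [], "lines": []}
            )
            entry["fpkm"].append(float(r[fmt["fpkm"]]))
            entry["lines"].append(i + 2)  # +2: header is line 1
        for (gene, tissue, sex), entry in grouped.items():
            if _check_values(gene, entry["fpkm"], entry["lines"]):
                records.append(
                    GeneExpressionRecord(
                        gene, entry["chromosome"], tissue, sex, tuple(entry["fpkm"])
                    )
                )
    else:
        for i, row in enumerate(df.itertuples(index=False)):
            r = row._asdict()
            line = i + 2
            gene = str(r[fmt["gene_id"]])
            key = (gene, str(r[fmt["tissue"]]), str(r[fmt["sex"]]))
            if key in seen:
                problems.append(
                    f"line {line}: duplicate (gene_id, tissue, sex) = {key}"
                )
                continue
            seen.add(key)
            values = [float(r[c]) for c in rep_cols]
            if _check_values(gene, values, [line] * len(values)):
                records.append(
                    GeneExpressionRecord(
                        gene, str(r[fmt["chromosome"]]), key[1], key[2], tuple(values)
                    )
                )

    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    # long layout: duplicates manifest as repeated groups, caught here
    keys = [(rec.gene_id, rec.tissue, rec.sex) for rec in records]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{path}: duplicate (gene_id, tissue, sex) keys")
    return records


def write_expression_table(
    records: Sequence[GeneExpressionRecord], path: str | Path
) -> None:
    """Write records as a wide TSV (long layout if replicate counts differ)."""
    counts = {len(r.replicate_fpkm) for r in records}
    if len(counts) == 1:
        k = counts.pop()
        rows = [
            {
                "gene_id": r.gene_id,
                "chromosome": r.chromosome,
                "tissue": r.tissue,
                "sex": r.sex,
                **{f"fpkm_r{i + 1}": r.replicate_fpkm[i] for i in range(k)},
            }
            for r in records
        ]
    else:
        rows = [
            {
                "gene_id": r.gene_id,
                "chromosome": r.chromosome,
                "tissue": r.tissue,
                "sex": r.sex,
                "fpkm": v,
            }
            for r in records
            for v in r.replicate_fpkm
        ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_flyatlas2_export(path: str | Path) -> list[GeneExpressionRecord]:
    """Read a tabular export of the FlyAtlas2 tissue-expression database.

    FlyAtlas2 is distributed as a MySQL dump; this adapter expects a
    pre-exported TSV with columns ``FlyBaseID``, ``Chromosome``, ``Tissue``,
    ``Sex`` and replicate FPKMs in ``FPKM_rep1..K`` (or a long-format
    ``FPKM`` column).
    """
    return read_expression_table(path, FLYATLAS2_FORMAT)


def build_tissue_table(
    records: Iterable[GeneExpressionRecord],
    tissue: str,
    sex: str,
    min_fpkm: float = 1.0,
    max_fpkm: float | None = None,
    x_labels: frozenset[str] | set[str] = X_LABELS,
    autosome_labels: frozenset[str] | set[str] = AUTOSOME_LABELS,
) -> TissueTable:
    """Average replicates, filter on mean FPKM, and partition X vs autosomes.

    A gene is retained when its replicate-mean FPKM is strictly greater than
    ``min_fpkm`` and, if ``max_fpkm`` is given, at most ``max_fpkm`` (the
    high-expression exclusion drops genes strictly above the cap). Genes on
    chromosomes in neither label set are excluded and counted under
    ``unclassified``. Filtering is per tissue and sex: only records matching
    ``tissue``/``sex`` are considered.
    """
    x_labels = frozenset(x_labels)
    autosome_labels = frozenset(autosome_labels)
    if x_labels & autosome_labels:
        raise ConfigurationError(
            f"x_labels and autosome_labels overlap: {sorted(x_labels & autosome_labels)}"
        )

    excluded = {"unclassified": 0, "below_min": 0, "above_max": 0}
    rows = []
    seen: set[str] = set()
    for rec in records:
        if rec.tissue != tissue or rec.sex != sex:
            continue
        if rec.gene_id in seen:
            raise ValidationError(
                f"duplicate gene {rec.gene_id!r} for tissue={tissue!r}, sex={sex!r}"
            )
        seen.add(rec.gene_id)
        if rec.chromosome in x_labels:
            cls = "X"
        elif rec.chromosome in autosome_labels:
            cls = "A"
        else:
            excluded["unclassified"] += 1
            continue
        mean = average_replicates(rec)
        if not mean > min_fpkm:
            excluded["below_min"] += 1
            continue
        if max_fpkm is not None and mean > max_fpkm:
            excluded["above_max"] += 1
            continue
        rows.append((rec.gene_id, cls, mean))

    data = pd.DataFrame(rows, columns=["gene_id", "chromosome_class", "mean_fpkm"])
    table = TissueTable(
        tissue=tissue,
        sex=sex,
        data=data,
        min_fpkm=min_fpkm,
        max_fpkm=max_fpkm,
        excluded=excluded,
    )
    if table.n_x == 0 or table.n_a == 0:
        raise ValidationError(
            f"tissue={tissue!r}, sex={sex!r}: empty partition after filtering "
            f"(n_x={table.n_x}, n_a={table.n_a}); X-vs-A statistics are undefined"
        )
    return table
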
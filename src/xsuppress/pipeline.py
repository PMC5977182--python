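"""End-to-end orchestration: configuration, full runs, report emission.

``run_full_analysis`` reproduces the complete table/figure computation for
one expression table (plus an optional reporter table): per-tissue X/A
ratio tables with and without the high-expression exclusion, cumulative
representation profiles with and without dosage correction, reporter
line summaries and class comparisons, and a JSON run manifest with a
config hash and gene-attrition counts.

Outputs contain no timestamps: rerunning the same config (and seed, for
simulation commands) regenerates every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .chromosome_stats import correction_factor, median_xa_ratio
from .data_io import (
    AUTOSOME_LABELS,
    X_LABELS,
    GeneExpressionRecord,
    build_tissue_table,
    read_expression_table,
)
from .representation import (
    DEFAULT_THRESHOLDS,
    expected_x_proportion,
    representation_profile,
)
from .reporter_assay import (
    compare_classes,
    read_reporter_table,
    summarize_lines,
)

__all__ = ["RunConfig", "run_full_analysis", "ratio_table", "profile_frame"]

logger = logging.getLogger("xsuppress")

RATIO_COLUMNS = ["Tissue", "X Genes", "X Median", "A Genes", "A Median", "X/A", "p"]


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    expression_input: str
    output_dir: str
    reporter_input: str | None = None
    min_fpkm: float = 1.0
    high_expression_cutoff: float | None = 90.0
    thresholds: list[float] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_THRESHOLDS)
    )
    x_labels: list[str] = dataclasses.field(default_factory=lambda: sorted(X_LABELS))
    autosome_labels: list[str] = dataclasses.field(
        default_factory=lambda: sorted(AUTOSOME_LABELS)
    )
    expected_from: str = "dataset"  # "dataset" | "tissue"
    correction: str = "auto"  # "auto" | "none" | numeric string
    tissues: list[str] | None = None
    sexes: list[str] | None = None
    alpha: float = 0.05
    normalize_to: int = 5
    exclude_lines: list[str] = dataclasses.field(default_factory=list)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def ratio_table(
    records: list[GeneExpressionRecord],
    groups: list[tuple[str, str]],
    config: RunConfig,
    max_fpkm: float | None,
    attrition: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """One ratio-table row per (tissue, sex) group, printed-table column order."""
    rows = []
    for tissue, sex in groups:
        table = build_tissue_table(
            records,
            tissue=tissue,
            sex=sex,
            min_fpkm=config.min_fpkm,
            max_fpkm=max_fpkm,
            x_labels=set(config.x_labels),
            autosome_labels=set(config.autosome_labels),
        )
        result = median_xa_ratio(table)
        row = result.rounded()
        row["Sex"] = sex
        rows.append(row)
        if attrition is not None:
            attrition[f"{tissue}/{sex}" + ("/high-excluded" if max_fpkm else "")] = {
                "retained": len(table),
                **dict(table.excluded),
            }
        logger.info(
            "ratios %s/%s max_fpkm=%s: n_x=%d n_a=%d X/A=%.4f p=%.3g",
            tissue, sex, max_fpkm, result.n_x, result.n_a,
            result.xa_ratio, result.p_value,
        )
    return pd.DataFrame(rows)[["Sex"] + RATIO_COLUMNS]


def profile_frame(results) -> pd.DataFrame:
    """Representation profile as a TSV-ready frame (one row per threshold)."""
    return pd.DataFrame(
        [
            {
                "threshold": r.threshold,
                "n_x": r.n_x_obs,
                "n_total": r.n_total,
                "expected_p": round(r.expected_proportion, 6),
                "chi2": round(r.chi2_stat, 4) if r.tested else "",
                "p": r.p_value if r.tested else "",
                "direction": r.direction,
                "stars": r.stars,
                "low_expectation": r.low_expectation,
            }
            for r in results
        ]
    )


def _groups_present(
    records: list[GeneExpressionRecord], config: RunConfig
) -> list[tuple[str, str]]:
    groups = sorted({(r.tissue, r.sex) for r in records})
    if config.tissues:
        groups = [g for g in groups if g[0] in config.tissues]
    if config.sexes:
        groups = [g for g in groups if g[1] in config.sexes]
    return groups


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run every analysis section the inputs allow; return the manifest.

    Emits, under ``config.output_dir``: ``ratios_all.tsv``,
    ``ratios_high_excluded.tsv``, per-group representation profiles
    (uncorrected and dosage-corrected), reporter summaries/comparisons when
    a reporter table is given, the effective config, and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "xsuppress_version": __version__,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "outputs": [],
        "gene_counts": {},
        "skipped": [],
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"].append(name)

    records = read_expression_table(config.expression_input)
    groups = _groups_present(records, config)
    logger.info("loaded %d records; groups: %s", len(records), groups)

    attrition = manifest["gene_counts"]
    attrition["input_records"] = len(records)
    _write(ratio_table(records, groups, config, None, attrition), "ratios_all.tsv")
    if config.high_expression_cutoff is not None:
        _write(
            ratio_table(
                records, groups, config, config.high_expression_cutoff, attrition
            ),
            "ratios_high_excluded.tsv",
        )

    expected = (
        expected_x_proportion(
            records, set(config.x_labels), set(config.autosome_labels)
        )
        if config.expected_from == "dataset"
        else None
    )
    for tissue, sex in groups:
        table = build_tissue_table(
            records,
            tissue=tissue,
            sex=sex,
            min_fpkm=config.min_fpkm,
            x_labels=set(config.x_labels),
            autosome_labels=set(config.autosome_labels),
        )
        base = representation_profile(
            table, config.thresholds, expected, None, config.alpha
        )
        _write(profile_frame(base), f"representation_{tissue}_{sex}.tsv")
        if config.correction != "none":
            factor = (
                correction_factor(median_xa_ratio(table))
                if config.correction == "auto"
                else float(config.correction)
            )
            corrected = representation_profile(
                table, config.thresholds, expected, factor, config.alpha
            )
            frame = profile_frame(corrected)
            frame.insert(0, "correction_factor", round(factor, 4))
            _write(frame, f"representation_{tissue}_{sex}_corrected.tsv")

    if config.reporter_input:
        measurements = read_reporter_table(config.reporter_input)
        summaries = summarize_lines(measurements, normalize_to=config.normalize_to)
        _write(
            pd.DataFrame([dataclasses.asdict(s) for s in summaries]),
            "reporter_lines.tsv",
        )
        comparisons = []
        for tissue in sorted({s.tissue for s in summaries}):
            in_tissue = [s for s in summaries if s.tissue == tissue]
            try:
                cmp_result = compare_classes(in_tissue, set(config.exclude_lines))
                comparisons.append(dataclasses.asdict(cmp_result))
            except ValueError as exc:  # single-class tissue: record and move on
                manifest["skipped"].append(f"reporter comparison {tissue}: {exc}")
        if comparisons:
            _write(pd.DataFrame(comparisons), "reporter_comparison.tsv")
    else:
        manifest["skipped"].append("reporter section: no reporter_input")

    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest["outputs"].append("config_used.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
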
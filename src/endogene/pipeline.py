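"""End-to-end analysis run: import -> roles -> outliers -> stability ->
differential expression, writing the full report bundle to disk."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diffexpr import delta_cq, diffexpr_report
from .normfinder import normfinder_stability
from .outliers import OutlierParams, iterate_outlier_removal
from .panel import assign_roles
from .refstats import (descriptive_stability, group_location_tests,
                       group_tests_frame, leave_one_out_evaluation)
from .tabio import CqTable, TableFormatOptions, read_cq_table, write_reports

logger = logging.getLogger("endogene")

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; serialized next to the reports."""

    input_path: str | Path
    out_dir: str | Path
    format_options: TableFormatOptions = field(default_factory=TableFormatOptions)
    targets: tuple[str, ...] = ()
    reference_subset: tuple[str, ...] | None = None
    outlier_params: OutlierParams = field(default_factory=OutlierParams)
    test_method: str = "auto"
    compare: tuple[str, str] | None = None  # (group_a, calibrator)
    equal_var: bool = False

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "input_path": str(self.input_path),
            "out_dir": str(self.out_dir),
            "delimiter": self.format_options.delimiter,
            "decimal_mark": self.format_options.decimal_mark,
            "targets": list(self.targets),
            "reference_subset": (list(self.reference_subset)
                                 if self.reference_subset else None),
            "sd_threshold": self.outlier_params.threshold,
            "outlier_mode": self.outlier_params.mode,
            "max_rounds": self.outlier_params.max_rounds,
            "test_method": self.test_method,
            "compare": list(self.compare) if self.compare else None,
            "equal_var": self.equal_var,
        }


def run_analysis(config: RunConfig) -> dict:
    """Run the whole workflow and write the report bundle.

    Reports: outliers.tsv, gene_reference_by_group.tsv,
    descriptive_stats.tsv, leave_one_out.tsv, normfinder.tsv,
    differential_expression.tsv, plus run_summary.json with the
    parameters and before/after sample counts.  Stages that are not
    applicable (no targets, a single group) are skipped with a log
    message and their reports are omitted.  Returns the run summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("reading %s", config.input_path)
    table = read_cq_table(config.input_path, config.format_options)
    panel = assign_roles(table, list(config.targets))
    refs = (list(config.reference_subset) if config.reference_subset
            else list(panel.reference_genes))
    logger.info("panel: %d reference candidates, %d targets",
                len(panel.reference_genes), len(panel.target_genes))

    n_before = table.n_samples
    cleaned, outlier_report = iterate_outlier_removal(
        table, panel, config.outlier_params)
    bundle: dict[str, pd.DataFrame] = {"outliers.tsv": outlier_report.to_frame()}
    logger.info("outliers: %d samples removed over %d round(s)",
                n_before - cleaned.n_samples, outlier_report.n_rounds)

    multi_group = len(cleaned.groups) >= 2
    if multi_group:
        tests = group_location_tests(cleaned, panel, subset=refs)
        bundle["gene_reference_by_group.tsv"] = group_tests_frame(tests)
    else:
        logger.warning("single group: skipping group-difference tests")
    bundle["descriptive_stats.tsv"] = descriptive_stability(
        cleaned, panel, subset=refs)
    if multi_group and len(panel.reference_genes) >= 2:
        bundle["leave_one_out.tsv"] = leave_one_out_evaluation(cleaned, panel)
    if multi_group and len(refs) >= 3:
        bundle["normfinder.tsv"] = normfinder_stability(cleaned, refs).table
    else:
        logger.warning("stability model needs >=3 reference genes and >=2 "
                       "groups: skipping")
    if panel.target_genes and multi_group:
        dct = delta_cq(cleaned, panel, subset=refs)
        bundle["differential_expression.tsv"] = diffexpr_report(
            dct,
            group_a=config.compare[0] if config.compare else None,
            group_b=config.compare[1] if config.compare else None,
            method=config.test_method, equal_var=config.equal_var,
        )
    elif not panel.target_genes:
        logger.info("no target genes: skipping differential expression")

    written = write_reports(bundle, out_dir)
    summary = {
        "config": config.to_dict(),
        "n_samples_before": n_before,
        "n_samples_after": cleaned.n_samples,
        "samples_removed": sorted(
            set(table.sample_ids) - set(cleaned.sample_ids)),
        "outlier_rounds": outlier_report.n_rounds,
        "groups": cleaned.groups,
        "reference_genes": refs,
        "target_genes": list(panel.target_genes),
        "reports": [p.name for p in written],
    }
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
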
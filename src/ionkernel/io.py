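"""CSV readers/writers and the end-to-end pipeline driver.

All tables are plain RFC-4180 CSV with a header row, UTF-8. Sample tables
are wide (one column per element); instrument run files are long
(run_id, position, sample_id, element, raw_signal, is_signal) so the schema
is element-agnostic. Floats are written with 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import outliers, partition, quantgen, synthetic
from .config import PipelineConfig
from .processing import process_runs
from .synthetic import (ContaminationSpec, DriftProcess, EffectModel,
                        FieldDesign, InstrumentRun, default_effect_model,
                        generate_cob_experiment, generate_field_experiment,
                        generate_sugary_experiment, render_instrument_runs)

logger = logging.getLogger("ionkernel.io")

FLOAT_FORMAT = "%.6g"

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "weight_g")
RUN_FILE_COLUMNS = ("run_id", "position", "sample_id", "element",
                    "raw_signal", "is_signal")


class TableValidationError(ValueError):
    """Raised when an input table is missing columns or malformed."""


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sample_table(
    path: str | Path,
    elements: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a seed-level sample table.

    Requires ``sample_id`` and ``weight_g``; if ``elements`` is given those
    columns must be present too. Errors name every missing column and list
    duplicated sample ids with their row numbers.
    """
    table = pd.read_csv(path)
    required = list(REQUIRED_SAMPLE_COLUMNS) + list(elements or ())
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing required columns: {', '.join(missing)}")
    dup = table["sample_id"].duplicated(keep=False)
    if dup.any():
        offenders = table.loc[dup, "sample_id"].unique()[:10]
        rows = (table.index[dup] + 2).tolist()[:20]  # header is line 1
        raise TableValidationError(
            f"{path}: duplicated sample_id values {list(offenders)} "
            f"at lines {rows}")
    return table


def write_run_files(runs: list[InstrumentRun], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runs:
        p = out_dir / f"{run.run_id}.csv"
        run.to_long().to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths.append(p)
    return paths


def read_run_file(path: str | Path) -> InstrumentRun:
    """Read one long-format run CSV back into an InstrumentRun."""
    path = Path(path)
    long = pd.read_csv(path)
    missing = [c for c in RUN_FILE_COLUMNS if c not in long.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing run-file columns: {', '.join(missing)}")
    run_ids = long["run_id"].unique()
    if len(run_ids) != 1:
        raise TableValidationError(
            f"{path}: expected a single run_id, found {list(run_ids)}")
    # re-mark controls: CONTROL sample ids are reserved
    long = long.copy()
    return InstrumentRun.from_long(str(run_ids[0]), long)


def read_calibration(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("element", "nominal_ppb", "signal")
               if c not in table.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing calibration columns: {', '.join(missing)}")
    return table


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int = 0,
    design: FieldDesign | None = None,
    effects: EffectModel | None = None,
    drift: DriftProcess | None = None,
    contamination: ContaminationSpec | None = None,
) -> dict[str, Path]:
    """simulate -> render -> process -> filter -> stats, writing all outputs.

    Returns a mapping of artifact name to file path. Deterministic for a
    fixed seed and configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    effects = effects or default_effect_model(config.elements)
    design = design or FieldDesign()
    drift = drift or DriftProcess()
    contamination = contamination or ContaminationSpec(spike_prob=0.002)
    elements = list(effects.elements)
    paths: dict[str, Path] = {}

    # --- simulate + render the NAM-like field experiment
    samples, _truth = generate_field_experiment(design, effects, seed)
    rendered = render_instrument_runs(
        samples, drift, contamination, config.normalization,
        run_size=config.run_size, control_interval=config.control_interval,
        seed=seed, elements=elements)
    paths["samples_true"] = out_dir / "samples_true.csv"
    write_table(samples, paths["samples_true"])
    paths["runs_dir"] = out_dir / "runs"
    write_run_files(rendered.runs, paths["runs_dir"])

    # --- process raw runs back to seed concentrations
    weights = samples.set_index("sample_id")["weight_g"]
    result = process_runs(rendered.runs, weights, config.normalization)
    measured = result.wide().merge(
        samples[["sample_id", "line", "year", "block", "weight_g"]],
        on="sample_id", how="left")
    paths["concentrations"] = out_dir / "concentrations.csv"
    write_table(result.table, paths["concentrations"])
    paths["audit"] = out_dir / "audit.csv"
    write_table(result.audit, paths["audit"])
    paths["exclusions"] = out_dir / "exclusions.csv"
    write_table(result.exclusions, paths["exclusions"])

    # --- outlier filter on the measured table
    filt = outliers.remove_outliers(measured, elements, config.outlier)
    paths["kept"] = out_dir / "seeds_kept.csv"
    write_table(filt.kept, paths["kept"])
    paths["removed"] = out_dir / "seeds_removed.csv"
    write_table(filt.removed, paths["removed"])

    # --- genotype/year statistics (one row per element)
    plot_means = quantgen.compute_plot_means(
        filt.kept, elements, exclude_lines=config.excluded_lines)
    paths["plot_means"] = out_dir / "plot_means.csv"
    write_table(plot_means, paths["plot_means"])
    table1 = quantgen.nam_summary_table(
        measured, plot_means, elements,
        alpha_adjusted=config.alpha_adjusted,
        n_jackknife=config.n_jackknife,
        jackknife_seed=config.jackknife_seed,
        exclude_lines=config.excluded_lines)
    paths["nam_summary"] = out_dir / "nam_summary.csv"
    write_table(table1, paths["nam_summary"])

    # --- cob-position experiment
    cob = generate_cob_experiment(effects, seed=seed)
    paths["cob_samples"] = out_dir / "cob_samples.csv"
    write_table(cob, paths["cob_samples"])
    table2 = partition.cob_summary_table(
        cob, elements, alpha_adjusted=config.alpha_adjusted,
        nam_plot_means=plot_means)
    paths["cob_summary"] = out_dir / "cob_summary.csv"
    write_table(table2, paths["cob_summary"])

    # --- sugary experiment
    sug = generate_sugary_experiment(effects, seed=seed)
    paths["sugary_samples"] = out_dir / "sugary_samples.csv"
    write_table(sug, paths["sugary_samples"])
    table3 = partition.sugary_summary_table(
        sug, elements, alpha_adjusted=config.alpha_adjusted)
    paths["sugary_summary"] = out_dir / "sugary_summary.csv"
    write_table(table3, paths["sugary_summary"])

    logger.info("pipeline complete: %d artifacts in %s", len(paths), out_dir)
    return paths
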
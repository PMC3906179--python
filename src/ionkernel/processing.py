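"""Raw ICP-MS readings to seed elemental concentrations.

The correction chain, in order:

1. optional linear calibration (instrument signal -> solution ppb),
2. internal-standard correction: every analyte at a position is scaled by
   nominal IS / observed IS, cancelling sample-introduction and dilution
   variability that affects all channels equally,
3. within-run drift correction: the matrix-matched control is measured every
   tenth position; the fractional change between consecutive controls is
   assumed to accrue linearly over the samples in between, so the first
   sample after a control receives one tenth of the bracket's drift; all
   values are re-anchored to the run's first control,
4. between-run correction: each run is scaled by the ratio of a reference
   control level to the run's own (drift-corrected) control level,
5. dilution-factor and seed-weight normalization to ppm (mg/kg seed).

Drift is treated multiplicatively (a sensitivity change), which preserves
positivity and makes the chain invariant to rescaling any single position.
Every multiplicative factor applied to a reading is retained in an audit
table, so output = raw x product of factors, exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NormalizationConfig
from .synthetic import InstrumentRun

logger = logging.getLogger("ionkernel.processing")

_MIN_FACTOR = 1e-12


class ProcessingError(ValueError):
    """Raised when a run cannot be corrected (e.g. too few controls)."""


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Per-element linear response: signal = slope * ppb + intercept."""

    slope: dict[str, float]
    intercept: dict[str, float]
    r2: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def to_ppb(self, element: str, signal: np.ndarray) -> np.ndarray:
        """Back-calculate solution concentration; negatives floored at 0."""
        conc = (np.asarray(signal, dtype=float) - self.intercept[element]) \
            / self.slope[element]
        if np.any(conc < 0):
            self.flags.append(f"floored_negative:{element}")
        return np.maximum(conc, 0.0)


def calibrate_from_standards(standards: pd.DataFrame) -> CalibrationCurve:
    """Fit per-element OLS calibration lines from a dilution series.

    ``standards`` has columns ``element, nominal_ppb, signal``. At least two
    distinct nominal levels per element are required; a non-positive fitted
    slope flags the element as unusable but keeps the fit.
    """
    slope: dict[str, float] = {}
    intercept: dict[str, float] = {}
    r2: dict[str, float] = {}
    flags: list[str] = []
    for el, grp in standards.groupby("element", sort=False):
        x = grp["nominal_ppb"].to_numpy(dtype=float)
        y = grp["signal"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ProcessingError(
                f"calibration for {el} needs >= 2 distinct nominal levels")
        b, a = np.polyfit(x, y, 1)
        slope[el], intercept[el] = float(b), float(a)
        resid = y - (a + b * x)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2[el] = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        if b <= 0:
            flags.append(f"nonpositive_slope:{el}")
            warnings.warn(f"calibration slope for {el} is not positive",
                          stacklevel=2)
    return CalibrationCurve(slope, intercept, r2, flags)


# ---------------------------------------------------------------------------
# internal standard
# ---------------------------------------------------------------------------

def apply_internal_standard_correction(
    readings: np.ndarray,
    is_observed: np.ndarray,
    is_nominal: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale analyte readings by nominal/observed internal standard.

    ``readings`` is (n positions x k elements); ``is_observed`` is the IS
    signal per position. Positions with non-positive IS get a NaN factor
    (caller excludes them). Returns (corrected readings, factors).
    """
    if is_nominal <= 0:
        raise ProcessingError("nominal internal-standard level must be > 0")
    is_observed = np.asarray(is_observed, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(is_observed > 0, is_nominal / is_observed, np.nan)
    corrected = np.asarray(readings, dtype=float) * factors[:, None]
    return corrected, factors


# ---------------------------------------------------------------------------
# within-run drift
# ---------------------------------------------------------------------------

@dataclass
class DriftCorrectionModel:
    """Control trajectories and the correction factors derived from them."""

    run_id: str
    control_positions: dict[str, np.ndarray]
    control_values: dict[str, np.ndarray]
    drift_factors: dict[str, np.ndarray]     # per element, per position
    run_level: dict[str, float]              # corrected control level per element
    run_factor: dict[str, float] = field(default_factory=dict)
    flagged_elements: list[str] = field(default_factory=list)


def interpolate_drift_factors(
    positions: np.ndarray,
    control_positions: np.ndarray,
    control_values: np.ndarray,
    allow_extrapolation: bool = False,
) -> np.ndarray:
    """Multiplicative drift factor at each position, first control = 1.

    The factor is the control trajectory, linear between control positions,
    divided by the first control's value: a sample j slots into an m-slot
    bracket gets 1 + (j/m)(c1/c0 - 1) relative to the bracket's opening
    control, chained to the run's first control. Positions outside the
    bracketed range are NaN unless ``allow_extrapolation``, in which case
    the nearest bracket's line is extended (floored at a tiny positive
    value to preserve positivity).
    """
    pos = np.asarray(positions, dtype=float)
    cp = np.asarray(control_positions, dtype=float)
    cv = np.asarray(control_values, dtype=float)
    if cp.size < 2:
        raise ProcessingError("within-run drift needs >= 2 controls")
    if np.any(cv <= 0):
        raise ProcessingError("control values must be positive")
    traj = np.interp(pos, cp, cv)
    outside_lo = pos < cp[0]
    outside_hi = pos > cp[-1]
    if allow_extrapolation:
        if cp.size >= 2:
            lo_slope = (cv[1] - cv[0]) / (cp[1] - cp[0])
            hi_slope = (cv[-1] - cv[-2]) / (cp[-1] - cp[-2])
            traj = np.where(outside_lo, cv[0] + lo_slope * (pos - cp[0]), traj)
            traj = np.where(outside_hi, cv[-1] + hi_slope * (pos - cp[-1]), traj)
        traj = np.maximum(traj, _MIN_FACTOR * cv[0])
    else:
        traj = np.where(outside_lo | outside_hi, np.nan, traj)
    return traj / cv[0]


def correct_within_run_drift(
    run_id: str,
    positions: np.ndarray,
    is_control: np.ndarray,
    values: pd.DataFrame,
    allow_extrapolation: bool = False,
) -> tuple[pd.DataFrame, DriftCorrectionModel]:
    """Divide each element column by its interpolated drift factor.

    ``values`` holds IS-corrected readings (rows = positions in order,
    columns = elements). Positions whose factor is undefined (outside the
    control bracket with extrapolation off) come back NaN. Elements whose
    controls are unusable (< 2 valid, or non-positive) are flagged and
    returned as all-NaN.
    """
    positions = np.asarray(positions)
    is_control = np.asarray(is_control, dtype=bool)
    corrected = pd.DataFrame(index=values.index, columns=values.columns,
                             dtype=float)
    cpos: dict[str, np.ndarray] = {}
    cval: dict[str, np.ndarray] = {}
    dfac: dict[str, np.ndarray] = {}
    level: dict[str, float] = {}
    flagged: list[str] = []
    for el in values.columns:
        v = values[el].to_numpy(dtype=float)
        ok = is_control & np.isfinite(v) & (v > 0)
        cp, cv = positions[ok], v[ok]
        if cp.size < 2:
            flagged.append(el)
            corrected[el] = np.nan
            dfac[el] = np.full(len(v), np.nan)
            cpos[el], cval[el] = cp, cv
            level[el] = np.nan
            logger.warning("run %s element %s: unusable controls, flagged",
                           run_id, el)
            continue
        factors = interpolate_drift_factors(positions, cp, cv,
                                            allow_extrapolation)
        corrected[el] = v / factors
        cpos[el], cval[el], dfac[el] = cp, cv, factors
        level[el] = float(np.mean(cv / factors[ok]))
    model = DriftCorrectionModel(run_id=run_id, control_positions=cpos,
                                 control_values=cval, drift_factors=dfac,
                                 run_level=level, flagged_elements=flagged)
    return corrected, model


# ---------------------------------------------------------------------------
# between-run drift
# ---------------------------------------------------------------------------

def correct_between_run_drift(
    models: list[DriftCorrectionModel],
    reference_level: pd.Series | dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-run, per-element scale factor mapping runs to a common reference.

    The run's control level is the mean of its drift-corrected controls.
    ``reference_level`` defaults to the first run's level (the project's
    reference run); after scaling, control levels agree across runs. The
    factors are stored on each model and returned keyed by run id.
    """
    if not models:
        raise ProcessingError("no runs to correct")
    if reference_level is None:
        reference_level = dict(models[0].run_level)
    else:
        reference_level = dict(reference_level)
    factors: dict[str, dict[str, float]] = {}
    for m in models:
        f: dict[str, float] = {}
        for el, lev in m.run_level.items():
            ref = reference_level.get(el, np.nan)
            if not np.isfinite(ref) or ref <= 0:
                raise ProcessingError(f"missing reference control level for {el}")
            f[el] = ref / lev if np.isfinite(lev) and lev > 0 else np.nan
        m.run_factor = f
        factors[m.run_id] = f
    return factors


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_seed(
    solution_ppb: float | np.ndarray,
    config: NormalizationConfig,
    weight_g: float,
) -> float | np.ndarray:
    """Solution ppb -> seed ppm (mg/kg) via dilution and seed weight."""
    if not np.isfinite(weight_g) or weight_g <= 0:
        raise ProcessingError("seed weight must be positive and finite")
    return solution_ppb * config.seed_ppm_per_solution_ppb(weight_g)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass
class ProcessResult:
    """Final concentrations with the complete per-reading audit trail.

    ``table`` is long (sample_id, element, ppm); ``audit`` records every
    multiplicative factor applied, so
    ``raw_signal * is_factor / drift_factor * run_factor * norm_factor``
    reproduces ``ppm`` exactly; ``exclusions`` lists readings dropped and
    why; ``models`` holds the per-run drift models.
    """

    table: pd.DataFrame
    audit: pd.DataFrame
    exclusions: pd.DataFrame
    models: list[DriftCorrectionModel]

    def wide(self) -> pd.DataFrame:
        return (self.table.pivot(index="sample_id", columns="element",
                                 values="ppm").rename_axis(columns=None)
                .reset_index())


_EXCL_COLS = ["run_id", "position", "sample_id", "element", "reason"]
_AUDIT_COLS = ["run_id", "position", "sample_id", "element", "raw_signal",
               "is_factor", "drift_factor", "run_factor", "norm_factor",
               "weight_g", "ppm"]


def process_runs(
    runs: list[InstrumentRun],
    weights: pd.Series | dict[str, float],
    config: NormalizationConfig | None = None,
    calibration: CalibrationCurve | None = None,
    reference_level: pd.Series | dict[str, float] | None = None,
    allow_extrapolation: bool = False,
) -> ProcessResult:
    """Run the full correction chain over a list of instrument runs.

    ``weights`` maps sample_id to seed weight in grams. Readings that cannot
    be corrected (dead internal standard, missing control bracket, missing
    or non-positive weight, flagged element) are excluded individually with
    a logged reason; everything else is processed.
    """
    config = config or NormalizationConfig()
    weights = pd.Series(weights, dtype=float)
    if not runs:
        return ProcessResult(
            table=pd.DataFrame(columns=["sample_id", "element", "ppm"]),
            audit=pd.DataFrame(columns=_AUDIT_COLS),
            exclusions=pd.DataFrame(columns=_EXCL_COLS), models=[])

    per_run: list[dict] = []
    models: list[DriftCorrectionModel] = []
    exclusions: list[dict] = []

    for run in runs:
        t = run.table
        pos = t["position"].to_numpy()
        ctrl = t["is_control"].to_numpy(dtype=bool)
        elements = list(run.elements)

        raw = t[elements].to_numpy(dtype=float)
        if calibration is not None:
            raw = np.column_stack([
                calibration.to_ppb(el, raw[:, j])
                for j, el in enumerate(elements)])

        corrected_is, is_factors = apply_internal_standard_correction(
            raw, t["is_signal"].to_numpy(dtype=float), config.is_nominal_ppb)
        dead = ~np.isfinite(is_factors)
        for i in np.flatnonzero(dead & ~ctrl):
            exclusions.append({"run_id": run.run_id, "position": pos[i],
                               "sample_id": t["sample_id"].iat[i],
                               "element": "ALL",
                               "reason": "dead internal standard"})

        values = pd.DataFrame(corrected_is, columns=elements)
        drifted, model = correct_within_run_drift(
            run.run_id, pos, ctrl & ~dead, values, allow_extrapolation)
        models.append(model)
        per_run.append({"run": run, "raw": raw, "is_factors": is_factors,
                        "drifted": drifted, "dead": dead})
        logger.info("run %s: %d positions, %d controls, %d dead IS, "
                    "%d flagged elements", run.run_id, len(pos),
                    int(ctrl.sum()), int(dead.sum()),
                    len(model.flagged_elements))

    run_factors = correct_between_run_drift(models, reference_level)

    audit_rows: list[pd.DataFrame] = []
    for item, model in zip(per_run, models):
        run = item["run"]
        t = run.table
        keep = ~t["is_control"].to_numpy(dtype=bool) & ~item["dead"]
        pos = t["position"].to_numpy()[keep]
        sids = t["sample_id"].to_numpy()[keep]
        w = weights.reindex(sids).to_numpy(dtype=float)
        bad_w = ~np.isfinite(w) | (w <= 0)
        for i in np.flatnonzero(bad_w):
            exclusions.append({"run_id": run.run_id, "position": pos[i],
                               "sample_id": sids[i], "element": "ALL",
                               "reason": "missing or non-positive weight"})
        norm_f = np.where(bad_w, np.nan, np.array([
            config.seed_ppm_per_solution_ppb(wi) if np.isfinite(wi) and wi > 0
            else np.nan for wi in w]))

        for j, el in enumerate(run.elements):
            if el in model.flagged_elements:
                for i in range(len(pos)):
                    exclusions.append({
                        "run_id": run.run_id, "position": pos[i],
                        "sample_id": sids[i], "element": el,
                        "reason": "unusable controls for element"})
                continue
            isf = item["is_factors"][keep]
            dftf = model.drift_factors[el][keep]
            rnf = run_factors[run.run_id][el]
            rawv = item["raw"][keep, j]
            ppm = rawv * isf / dftf * rnf * norm_f
            unbracketed = ~np.isfinite(dftf)
            for i in np.flatnonzero(unbracketed):
                exclusions.append({
                    "run_id": run.run_id, "position": pos[i],
                    "sample_id": sids[i], "element": el,
                    "reason": "outside control bracket"})
            audit_rows.append(pd.DataFrame({
                "run_id": run.run_id, "position": pos, "sample_id": sids,
                "element": el, "raw_signal": rawv, "is_factor": isf,
                "drift_factor": dftf, "run_factor": rnf,
                "norm_factor": norm_f, "weight_g": w, "ppm": ppm}))

    audit = (pd.concat(audit_rows, ignore_index=True) if audit_rows
             else pd.DataFrame(columns=_AUDIT_COLS))
    table = audit.loc[np.isfinite(audit["ppm"]),
                      ["sample_id", "element", "ppm"]].reset_index(drop=True)
    excl = pd.DataFrame(exclusions, columns=_EXCL_COLS)
    if len(excl):
        logger.info("excluded %d readings (%d samples affected)",
                    len(excl), excl["sample_id"].nunique())
    return ProcessResult(table=table, audit=audit, exclusions=excl,
                         models=models)
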
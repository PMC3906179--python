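"""Synthetic field experiments and raw ICP-MS runs with known ground truth.

The generators emulate the structure of a multi-year maize field trial
phenotyped one kernel at a time: a randomized complete block design of
inbred lines grown in two years with unequal replication, kernels sampled
from base/middle/tip positions of individual ears, and segregating
*sugary* (sweet corn) kernels within recombinant inbred lines. Elemental
effects are simulated on the log scale by default (concentrations are
positive and genotype differences are fold-like); an additive mode with a
positive floor is available for sensitivity checks.

Raw instrument runs are rendered from true seed concentrations through a
forward model of the measurement: dilution to solution concentrations,
a per-run response factor, smooth within-run sensitivity drift sampled at
the control positions (piecewise linear in between), a sample-introduction
recovery curve that multiplies analyte and internal-standard channels
alike, multiplicative noise, and rare contamination spikes. Matrix-matched
controls (a pooled bulk of the samples) are interleaved every tenth
position and bracket the run, so the processing module can invert the
drift exactly when noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_ELEMENTS, NormalizationConfig

#: Founder inbreds of the maize nested association mapping panel.
NAM_FOUNDERS: tuple[str, ...] = (
    "B73", "B97", "CML52", "CML69", "CML103", "CML228", "CML247", "CML277",
    "CML322", "CML333", "HP301", "IL14H", "KI3", "KI11", "KY21", "M37W",
    "M162W", "MO17", "MO18W", "MS71", "NC350", "NC358", "OH43", "OH7B",
    "P39", "TX303",
)

#: Typical maize kernel grand means, ppm (mg/kg seed).
ELEMENT_MEANS_PPM: dict[str, float] = {
    "B": 3.0, "Na": 20.0, "Mg": 1200.0, "Al": 3.0, "P": 3200.0,
    "S": 1200.0, "K": 3700.0, "Ca": 60.0, "Mn": 7.0, "Fe": 25.0,
    "Co": 0.01, "Ni": 0.5, "Cu": 2.0, "Zn": 25.0, "As": 0.01,
    "Se": 0.05, "Rb": 3.0, "Sr": 0.3, "Mo": 0.7, "Cd": 0.01,
}

#: Elements that are low-abundance and interference-prone in kernels;
#: simulated with weak genetic signal and noisy measurement.
LOW_HERITABILITY_ELEMENTS: tuple[str, ...] = ("B", "Na", "Al", "Se")

COB_SECTIONS: tuple[str, ...] = ("base", "middle", "tip")
SUGARY_CLASSES: tuple[str, ...] = ("su/su", "Su/+")

# rng stream keys so each generator draws from an independent substream
_STREAM_FIELD, _STREAM_COB, _STREAM_SUGARY, _STREAM_RENDER = 11, 13, 17, 19


class SyntheticValidationError(ValueError):
    """Raised when a design or effect model violates its invariants."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(stream), int(seed)])


# ---------------------------------------------------------------------------
# design / effect-model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldDesign:
    """Randomized complete block field trial layout."""

    n_lines: int = 26
    years: tuple[str, ...] = ("2010", "2011")
    blocks_per_year: Mapping[str, int] = field(
        default_factory=lambda: {"2010": 6, "2011": 5})
    seeds_per_plot: tuple[int, int] = (4, 6)
    line_names: tuple[str, ...] | None = NAM_FOUNDERS

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise SyntheticValidationError("n_lines must be >= 2")
        for yr in self.years:
            if self.blocks_per_year.get(yr, 0) < 1:
                raise SyntheticValidationError(f"year {yr} needs >= 1 block")
        lo, hi = self.seeds_per_plot
        if lo < 1 or lo > hi:
            raise SyntheticValidationError("seeds_per_plot range invalid")
        if self.line_names is not None and len(self.line_names) < self.n_lines:
            raise SyntheticValidationError("not enough line names for n_lines")

    @property
    def lines(self) -> tuple[str, ...]:
        if self.line_names is not None:
            return tuple(self.line_names[: self.n_lines])
        width = len(str(self.n_lines))
        return tuple(f"L{i + 1:0{width}d}" for i in range(self.n_lines))


@dataclass(frozen=True)
class ElementEffect:
    """Variance components for one element.

    In lognormal mode the variances live on the natural-log scale
    (dimensionless); in additive mode they are ppm^2. ``var_plot``
    is plot-to-plot (field heterogeneity) variance within line x year;
    ``var_e`` is the seed-to-seed residual within a plot.
    """

    mean_ppm: float
    var_g: float = 0.02
    var_y: float = 0.005
    var_gy: float = 0.008
    var_plot: float = 0.02
    var_e: float = 0.06

    def __post_init__(self) -> None:
        if self.mean_ppm <= 0:
            raise SyntheticValidationError("mean_ppm must be positive")
        for name in ("var_g", "var_y", "var_gy", "var_plot", "var_e"):
            if getattr(self, name) < 0:
                raise SyntheticValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EffectModel:
    """Per-element effect sizes plus cob-gradient and sugary shifts."""

    effects: Mapping[str, ElementEffect]
    cob_gradient: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict)
    sugary_shift: Mapping[str, float] = field(default_factory=dict)
    weight_mean_g: float = 0.25
    weight_cv: float = 0.15
    sugary_weight_shift: float = 0.75
    var_farm: float = 0.05
    var_field: float = 0.002
    var_ear: float = 0.01
    mode: str = "lognormal"
    additive_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.mode not in ("lognormal", "additive"):
            raise SyntheticValidationError("mode must be lognormal or additive")
        if self.weight_mean_g <= 0 or self.weight_cv < 0:
            raise SyntheticValidationError("invalid weight model")
        for el, g in self.cob_gradient.items():
            if len(g) != 3 or any(v <= 0 for v in g):
                raise SyntheticValidationError(
                    f"cob gradient for {el} must be 3 positive factors")
        for el, s in self.sugary_shift.items():
            if s <= 0:
                raise SyntheticValidationError(f"sugary shift for {el} must be > 0")

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.effects)

    def gradient(self, element: str) -> tuple[float, float, float]:
        return tuple(self.cob_gradient.get(element, (1.0, 1.0, 1.0)))

    def shift(self, element: str) -> float:
        return float(self.sugary_shift.get(element, 1.0))

    def analytic_h2(
        self,
        element: str,
        n_years: int,
        reps_per_year: Sequence[int],
        seeds_per_plot: int,
        scope: str = "combined",
    ) -> float:
        """Heritability implied by the generating components on plot means.

        Exact for the additive mode; a log-scale approximation for the
        lognormal mode. ``reps_per_year`` enters through its harmonic mean,
        matching the estimator used downstream.
        """
        e = self.effects[element]
        reps = np.asarray(reps_per_year, dtype=float)
        r_h = len(reps) / np.sum(1.0 / reps)
        resid = e.var_plot + e.var_e / seeds_per_plot
        if scope == "combined":
            denom = e.var_g + e.var_gy / n_years + resid / (r_h * n_years)
        elif scope == "single-year":
            denom = e.var_g + resid / r_h
        else:
            raise ValueError("scope must be 'combined' or 'single-year'")
        return e.var_g / denom if denom > 0 else 0.0


def default_effect_model(
    elements: Sequence[str] = DEFAULT_ELEMENTS,
    mode: str = "lognormal",
) -> EffectModel:
    """Effect model emulating a NAM-founders-like trial.

    Most elements get a strong genetic signal (two-year heritability around
    0.7); the low-abundance interference-prone elements (B, Na, Al, Se) get
    weak genetic signal and inflated noise. Cob gradients are applied to the
    elements with known base-to-tip accumulation patterns, and sugary
    (collapsed) kernels concentrate a subset of elements while losing weight.
    """
    effects: dict[str, ElementEffect] = {}
    for el in elements:
        mean = ELEMENT_MEANS_PPM.get(el, 1.0)
        if el in LOW_HERITABILITY_ELEMENTS:
            effects[el] = ElementEffect(
                mean_ppm=mean, var_g=0.005, var_y=0.02, var_gy=0.004,
                var_plot=0.05, var_e=0.15)
        else:
            effects[el] = ElementEffect(mean_ppm=mean)
    gradient = {
        "Na": (1.10, 1.00, 0.92), "S": (1.08, 1.00, 0.94),
        "Ca": (1.25, 1.00, 0.85), "Fe": (1.12, 1.00, 0.92),
        "Cu": (1.20, 1.00, 0.85), "Zn": (1.10, 1.00, 0.92),
        "Sr": (1.35, 1.00, 0.80),
    }
    shift = {el: 1.25 for el in ("P", "S", "K", "Ca", "Mn", "Fe", "As", "Se", "Rb")}
    gradient = {el: g for el, g in gradient.items() if el in elements}
    shift = {el: s for el, s in shift.items() if el in elements}
    return EffectModel(effects=effects, cob_gradient=gradient,
                       sugary_shift=shift, mode=mode)


# ---------------------------------------------------------------------------
# concentration assembly helpers
# ---------------------------------------------------------------------------

def _compose(mean_ppm: float, log_effects: np.ndarray, mode: str,
             floor: float) -> np.ndarray:
    """Combine a grand mean with summed effects under the chosen mode.

    In lognormal mode ``log_effects`` are log-scale deviations; in additive
    mode they are ppm deviations truncated at ``floor``.
    """
    if mode == "lognormal":
        return mean_ppm * np.exp(log_effects)
    return np.maximum(mean_ppm + log_effects, floor)


def _draw_weights(rng: np.random.Generator, n: int, mean_g: float,
                  cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean_g)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean_g) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))


# ---------------------------------------------------------------------------
# field experiment (NAM-founders-like)
# ---------------------------------------------------------------------------

def generate_field_experiment(
    design: FieldDesign,
    effects: EffectModel,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Simulate seed-level true concentrations for a two-year RCBD trial.

    Returns ``(samples, truth)``. ``samples`` has one row per kernel with
    columns ``sample_id, line, year, block, weight_g`` plus one true-ppm
    column per element. ``truth`` records the realized line / year /
    interaction effects per element so recovery of variance components and
    heritability can be scored against what was actually simulated.
    """
    rng = _rng(seed, _STREAM_FIELD)
    lines = design.lines
    elements = effects.elements

    rows: list[dict] = []
    for year in design.years:
        for block in range(1, design.blocks_per_year[year] + 1):
            for line in lines:
                lo, hi = design.seeds_per_plot
                n_seeds = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                for k in range(1, n_seeds + 1):
                    rows.append({"line": line, "year": year,
                                 "block": block, "seed": k})
    samples = pd.DataFrame(rows)
    n = len(samples)
    samples.insert(0, "sample_id", [f"S{i:06d}" for i in range(n)])
    samples["weight_g"] = _draw_weights(
        rng, n, effects.weight_mean_g, effects.weight_cv)

    li = pd.Categorical(samples["line"], categories=lines).codes
    yi = pd.Categorical(samples["year"], categories=design.years).codes
    plot_key = (samples["line"].astype(str) + "|" + samples["year"].astype(str)
                + "|" + samples["block"].astype(str))
    pi = pd.Categorical(plot_key).codes
    n_plots = pi.max() + 1

    truth: dict = {"seed": seed, "mode": effects.mode, "elements": {}}
    for el in elements:
        e = effects.effects[el]
        g = rng.normal(0.0, np.sqrt(e.var_g), size=len(lines))
        y = rng.normal(0.0, np.sqrt(e.var_y), size=len(design.years))
        gy = rng.normal(0.0, np.sqrt(e.var_gy),
                        size=(len(lines), len(design.years)))
        p = rng.normal(0.0, np.sqrt(e.var_plot), size=n_plots)
        eps = rng.normal(0.0, np.sqrt(e.var_e), size=n)
        total = g[li] + y[yi] + gy[li, yi] + p[pi] + eps
        samples[el] = _compose(e.mean_ppm, total, effects.mode,
                               effects.additive_floor)
        truth["elements"][el] = {
            "line_effects": pd.Series(g, index=list(lines)),
            "year_effects": pd.Series(y, index=list(design.years)),
            "gy_effects": pd.DataFrame(gy, index=list(lines),
                                       columns=list(design.years)),
        }
    return samples, truth


# ---------------------------------------------------------------------------
# cob-position experiment
# ---------------------------------------------------------------------------

def generate_cob_experiment(
    effects: EffectModel,
    n_farms: int = 4,
    ears_per_farm: int = 3,
    kernels_per_section: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate kernels sampled from base/middle/tip of individual ears.

    One genotype grown at ``n_farms`` locations; each ear contributes
    ``kernels_per_section`` kernels per cob section. Farm, field-position
    and ear effects are log-scale random deviations; section means follow
    ``effects.cob_gradient`` in expectation.
    """
    if min(n_farms, ears_per_farm, kernels_per_section) < 1:
        raise SyntheticValidationError("counts must be >= 1")
    rng = _rng(seed, _STREAM_COB)
    elements = effects.elements

    rows = []
    for f in range(1, n_farms + 1):
        for e_idx in range(1, ears_per_farm + 1):
            for section in COB_SECTIONS:
                for k in range(1, kernels_per_section + 1):
                    rows.append({
                        "farm": f"farm{f}", "field_pos": f"pos{e_idx}",
                        "ear": f"farm{f}_ear{e_idx}", "cob_section": section,
                        "kernel": k,
                    })
    table = pd.DataFrame(rows)
    n = len(table)
    table.insert(0, "sample_id", [f"C{i:05d}" for i in range(n)])
    table["weight_g"] = _draw_weights(
        rng, n, effects.weight_mean_g, effects.weight_cv)

    fi = pd.Categorical(table["farm"]).codes
    pi = pd.Categorical(table["farm"] + "|" + table["field_pos"]).codes
    ei = pd.Categorical(table["ear"]).codes
    si = pd.Categorical(table["cob_section"], categories=COB_SECTIONS).codes

    for el in elements:
        e = effects.effects[el]
        farm_eff = rng.normal(0.0, np.sqrt(effects.var_farm), size=fi.max() + 1)
        field_eff = rng.normal(0.0, np.sqrt(effects.var_field), size=pi.max() + 1)
        ear_eff = rng.normal(0.0, np.sqrt(effects.var_ear), size=ei.max() + 1)
        eps = rng.normal(0.0, np.sqrt(e.var_e), size=n)
        base = farm_eff[fi] + field_eff[pi] + ear_eff[ei] + eps
        grad = np.log(np.asarray(effects.gradient(el)))
        if effects.mode == "lognormal":
            table[el] = e.mean_ppm * np.exp(base + grad[si])
        else:
            table[el] = np.maximum(
                (e.mean_ppm + base) * np.exp(grad[si]), effects.additive_floor)
    return table


# ---------------------------------------------------------------------------
# sugary experiment
# ---------------------------------------------------------------------------

def generate_sugary_experiment(
    effects: EffectModel,
    n_lines: int = 7,
    seeds_per_class: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate segregating sweet-corn (su/su) vs plump (Su/+) kernels.

    Each recombinant inbred line contributes both kernel classes from the
    same plot; collapsed su/su kernels are scaled by ``effects.sugary_shift``
    per element and weigh less by ``effects.sugary_weight_shift``.
    """
    if n_lines < 1 or seeds_per_class < 1:
        raise SyntheticValidationError("counts must be >= 1")
    rng = _rng(seed, _STREAM_SUGARY)
    elements = effects.elements
    lines = [f"Z011E{i:02d}" for i in range(1, n_lines + 1)]

    rows = []
    for line in lines:
        for su in SUGARY_CLASSES:
            for k in range(1, seeds_per_class + 1):
                rows.append({"line": line, "su_genotype": su, "kernel": k})
    table = pd.DataFrame(rows)
    n = len(table)
    table.insert(0, "sample_id", [f"U{i:05d}" for i in range(n)])

    is_su = (table["su_genotype"] == "su/su").to_numpy()
    weights = _draw_weights(rng, n, effects.weight_mean_g, effects.weight_cv)
    weights[is_su] *= effects.sugary_weight_shift
    table["weight_g"] = weights

    li = pd.Categorical(table["line"], categories=lines).codes
    for el in elements:
        e = effects.effects[el]
        g = rng.normal(0.0, np.sqrt(e.var_g), size=len(lines))
        eps = rng.normal(0.0, np.sqrt(e.var_e), size=n)
        shift = np.where(is_su, np.log(effects.shift(el)), 0.0)
        if effects.mode == "lognormal":
            table[el] = e.mean_ppm * np.exp(g[li] + eps + shift)
        else:
            table[el] = np.maximum(
                (e.mean_ppm + g[li] + eps) * np.exp(shift),
                effects.additive_floor)
    return table


# ---------------------------------------------------------------------------
# instrument-run rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftProcess:
    """Forward model of instrument behaviour across and within runs.

    ``run_factor_sd`` is the lognormal sd of the per-run response factor;
    the first run is the project's calibration reference and keeps factor
    1.0. Within-run sensitivity drift is a multiplicative random walk
    sampled at control positions (step sd ``drift_step_sd``), linear in
    between, anchored at 1.0 at the run start. The sample-introduction
    recovery curve multiplies analyte and internal-standard channels
    identically (which is what makes internal-standard correction work);
    it is a random walk around its own lognormal starting level.
    """

    run_factor_sd: float = 0.08
    drift_step_sd: float = 0.02
    is_recovery_sd: float = 0.05
    is_recovery_step_sd: float = 0.01
    noise_cv: float = 0.02
    drift_clip: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for name in ("run_factor_sd", "drift_step_sd", "is_recovery_sd",
                     "is_recovery_step_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise SyntheticValidationError(f"{name} must be >= 0")
        if self.drift_clip[0] <= 0 or self.drift_clip[0] >= self.drift_clip[1]:
            raise SyntheticValidationError("drift_clip must be 0 < lo < hi")


@dataclass(frozen=True)
class ContaminationSpec:
    """Rare analytical spikes, expressed in MAD multiples above group median.

    A spike replaces the affected reading with median + ``mad_multiples`` x
    MAD of its group's clean values. Replacing a reading perturbs the very
    median and MAD an outlier filter will later compute, so when
    ``detect_threshold`` is set the magnitude is escalated (doubled, a few
    times at most) until the spike exceeds ``detect_threshold`` x MAD of the
    post-injection group — making "detectable" true by construction rather
    than only in expectation. Groups with zero spread use a tenth of the
    median as the spread unit.
    """

    spike_prob: float = 0.0
    mad_multiples: float = 25.0
    detect_threshold: float | None = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_prob <= 1.0:
            raise SyntheticValidationError("spike_prob must be in [0, 1]")
        if self.mad_multiples <= 0:
            raise SyntheticValidationError("mad_multiples must be positive")
        if self.detect_threshold is not None and self.detect_threshold <= 0:
            raise SyntheticValidationError("detect_threshold must be positive")


@dataclass
class InstrumentRun:
    """One ordered ICP-MS run: interleaved controls and samples.

    ``table`` has one row per injection in sequence order with columns
    ``position, sample_id, is_control, is_signal`` plus one analyte-signal
    column per element (instrument-reported concentration units).
    """

    run_id: str
    table: pd.DataFrame
    elements: tuple[str, ...]
    standards: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        pos = self.table["position"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise SyntheticValidationError("positions must be strictly ordered")

    @property
    def control_mask(self) -> np.ndarray:
        return self.table["is_control"].to_numpy(dtype=bool)

    def to_long(self) -> pd.DataFrame:
        long = self.table.melt(
            id_vars=["position", "sample_id", "is_control", "is_signal"],
            value_vars=list(self.elements), var_name="element",
            value_name="raw_signal")
        long.insert(0, "run_id", self.run_id)
        cols = ["run_id", "position", "sample_id", "element",
                "raw_signal", "is_signal"]
        long["sample_id"] = np.where(long["is_control"], "CONTROL",
                                     long["sample_id"])
        return long[cols].sort_values(["position", "element"],
                                      kind="stable").reset_index(drop=True)

    @classmethod
    def from_long(cls, run_id: str, long: pd.DataFrame,
                  standards: pd.DataFrame | None = None) -> "InstrumentRun":
        wide = long.pivot_table(index="position", columns="element",
                                values="raw_signal", sort=False)
        wide = wide.rename_axis(columns=None)
        meta = long.drop_duplicates("position").set_index("position")
        elements = tuple(wide.columns)
        table = wide.reset_index()
        table["sample_id"] = meta["sample_id"].reindex(table["position"]).to_numpy()
        table["is_control"] = table["sample_id"] == "CONTROL"
        table["is_signal"] = meta["is_signal"].reindex(table["position"]).to_numpy()
        order = ["position", "sample_id", "is_control", "is_signal",
                 *elements]
        return cls(run_id=run_id, table=table[order].sort_values("position")
                   .reset_index(drop=True), elements=elements,
                   standards=standards)


def control_layout(n_samples: int, control_interval: int) -> np.ndarray:
    """Boolean mask over injection positions; True marks a control slot.

    A control opens the run, one follows every ``control_interval``
    experimental samples, and one closes the run, so every sample sits
    between two controls and drift interpolation is total.
    """
    if control_interval < 2:
        raise SyntheticValidationError("control_interval must be >= 2")
    mask: list[bool] = [True]
    placed = 0
    while placed < n_samples:
        take = min(control_interval, n_samples - placed)
        mask.extend([False] * take)
        mask.append(True)
        placed += take
    return np.asarray(mask, dtype=bool)


@dataclass
class RenderResult:
    """Rendered runs plus the ground truth needed to score processing."""

    runs: list[InstrumentRun]
    control_ppb: pd.Series
    expected_ppm: pd.DataFrame      # sample_id, element, ppm after ideal processing
    spikes: pd.DataFrame            # sample_id, element, factor, spiked_ppm
    run_factors: pd.Series


def _piecewise_walk(rng: np.random.Generator, knots: np.ndarray,
                    n_pos: int, step_sd: float, start: float,
                    clip: tuple[float, float]) -> np.ndarray:
    """Multiplicative random walk at knot positions, linear in between."""
    steps = rng.normal(0.0, step_sd, size=len(knots))
    steps[0] = 0.0
    curve = start * np.exp(np.cumsum(steps))
    curve = np.clip(curve, clip[0], clip[1])
    return np.interp(np.arange(n_pos), knots, curve)


def render_instrument_runs(
    samples: pd.DataFrame,
    drift: DriftProcess,
    contamination: ContaminationSpec | None = None,
    norm: NormalizationConfig | None = None,
    run_size: int = 576,
    control_interval: int = 10,
    seed: int = 0,
    elements: Sequence[str] | None = None,
    plot_cols: Sequence[str] = ("line", "year", "block"),
) -> RenderResult:
    """Render raw instrument runs from a seed-level true-concentration table.

    Samples are loaded in table order into consecutive runs of at most
    ``run_size`` experimental samples, with bracketing controls every
    ``control_interval`` positions. The control solution is a fixed pool
    whose composition is the grand mean of the samples' solution
    concentrations, mirroring a matrix-matched bulk of the study samples.
    Contamination spikes are injected into the analyte channel after drift,
    so they pass through drift correction intact.
    """
    if run_size < 1:
        raise SyntheticValidationError("run_size must be >= 1")
    norm = norm or NormalizationConfig()
    contamination = contamination or ContaminationSpec()
    rng = _rng(seed, _STREAM_RENDER)
    if elements is None:
        meta_cols = {"sample_id", "line", "year", "block", "seed", "farm",
                     "field_pos", "ear", "cob_section", "kernel",
                     "su_genotype", "weight_g"}
        elements = [c for c in samples.columns if c not in meta_cols]
    elements = list(elements)

    # true solution concentrations (ppb) seen by the instrument
    ppm = samples[elements].to_numpy(dtype=float)
    factors = np.array([norm.seed_ppm_per_solution_ppb(w)
                        for w in samples["weight_g"].to_numpy(dtype=float)])
    ppb = ppm / factors[:, None]
    control_ppb = pd.Series(ppb.mean(axis=0), index=elements)

    # expected post-processing concentrations: truth, with spikes applied
    expected = samples[["sample_id", *elements]].copy()

    spike_rows: list[dict] = []
    if contamination.spike_prob > 0:
        if plot_cols and all(c in samples.columns for c in plot_cols):
            groups = samples.groupby(list(plot_cols), sort=False).indices
        else:
            groups = {"all": np.arange(len(samples))}
        hit = rng.random(size=ppm.shape) < contamination.spike_prob
        for idx in groups.values():
            idx = np.asarray(idx)
            for j, el in enumerate(elements):
                hits = np.flatnonzero(hit[idx, j])
                if hits.size == 0:
                    continue
                vals = ppm[idx, j].copy()
                med = float(np.median(vals))
                madv = float(np.median(np.abs(vals - med)))
                unit = madv if madv > 0 else 0.1 * med
                vals[hits] = med + contamination.mad_multiples * unit
                if contamination.detect_threshold is not None:
                    # escalate jointly until every spike clears the cutoff
                    # against the post-injection group statistics (spikes in
                    # the same group inflate each other's MAD)
                    k = contamination.detect_threshold
                    for _ in range(60):
                        m2 = float(np.median(vals))
                        mad2 = float(np.median(np.abs(vals - m2)))
                        if mad2 == 0:
                            break
                        under = hits[np.abs(vals[hits] - m2) <= k * mad2]
                        if under.size == 0:
                            break
                        vals[under] *= 2.0
                for w in hits:
                    i = idx[w]
                    spike_rows.append({
                        "sample_id": samples["sample_id"].iat[i],
                        "element": el, "clean_ppm": ppm[i, j],
                        "spiked_ppm": vals[w]})
                    expected.iloc[i, expected.columns.get_loc(el)] = vals[w]
                    ppb[i, j] = vals[w] / factors[i]
    spikes = pd.DataFrame(
        spike_rows, columns=["sample_id", "element", "clean_ppm", "spiked_ppm"])

    n = len(samples)
    n_runs = int(np.ceil(n / run_size)) if n else 0
    run_factors = np.ones(max(n_runs, 1))
    if drift.run_factor_sd > 0 and n_runs > 1:
        run_factors[1:n_runs] = np.exp(
            rng.normal(0.0, drift.run_factor_sd, size=n_runs - 1))

    runs: list[InstrumentRun] = []
    for r in range(n_runs):
        idx = np.arange(r * run_size, min((r + 1) * run_size, n))
        mask = control_layout(len(idx), control_interval)
        n_pos = len(mask)
        knots = np.flatnonzero(mask)

        d = _piecewise_walk(rng, knots, n_pos, drift.drift_step_sd,
                            1.0, drift.drift_clip)
        is_start = (np.exp(rng.normal(0.0, drift.is_recovery_sd))
                    if drift.is_recovery_sd > 0 else 1.0)
        rec = _piecewise_walk(rng, knots, n_pos, drift.is_recovery_step_sd,
                              is_start, drift.drift_clip)
        if r == 0:
            # reference run: accurately calibrated at its first control
            d[0] = 1.0
            rec[0] = 1.0

        true_ppb = np.empty((n_pos, len(elements)))
        true_ppb[mask] = control_ppb.to_numpy()
        true_ppb[~mask] = ppb[idx]

        signal = true_ppb * run_factors[r] * d[:, None] * rec[:, None]
        is_sig = norm.is_nominal_ppb * rec
        if drift.noise_cv > 0:
            signal = signal * np.exp(rng.normal(
                0.0, drift.noise_cv, size=signal.shape))
            is_sig = is_sig * np.exp(rng.normal(
                0.0, drift.noise_cv, size=n_pos))

        sample_ids = np.empty(n_pos, dtype=object)
        sample_ids[mask] = [f"CONTROL_{r:02d}_{i:02d}"
                            for i in range(mask.sum())]
        sample_ids[~mask] = samples["sample_id"].to_numpy()[idx]
        table = pd.DataFrame({"position": np.arange(n_pos),
                              "sample_id": sample_ids,
                              "is_control": mask,
                              "is_signal": is_sig})
        for j, el in enumerate(elements):
            table[el] = signal[:, j]
        runs.append(InstrumentRun(run_id=f"run{r:02d}", table=table,
                                  elements=tuple(elements)))

    expected_long = expected.melt(id_vars="sample_id", var_name="element",
                                  value_name="ppm")
    return RenderResult(
        runs=runs, control_ppb=control_ppb, expected_ppm=expected_long,
        spikes=spikes,
        run_factors=pd.Series(run_factors[:max(n_runs, 1)],
                              index=[f"run{r:02d}" for r in
                                     range(max(n_runs, 1))]))


def render_calibration_standards(
    elements: Sequence[str],
    max_ppb: Mapping[str, float] | float = 100.0,
    n_levels: int = 6,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Six-point dilution series of a multi-element stock, as (element,
    nominal_ppb, signal) rows, with an optional linear instrument response."""
    rng = _rng(seed, 23)
    rows = []
    for el in elements:
        top = max_ppb[el] if isinstance(max_ppb, Mapping) else max_ppb
        for lev in range(n_levels):
            nominal = top * lev / (n_levels - 1)
            sig = slope * nominal + intercept
            if noise_sd > 0:
                sig += rng.normal(0.0, noise_sd)
            rows.append({"element": el, "nominal_ppb": nominal, "signal": sig})
    return pd.DataFrame(rows)
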
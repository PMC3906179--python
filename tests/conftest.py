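import numpy as np
import pandas as pd
import pytest

import ionkernel as ik

ELEMENTS3 = ["Ca", "Zn", "Cu"]


@pytest.fixture(scope="session")
def effects3() -> ik.EffectModel:
    return ik.default_effect_model(ELEMENTS3)


@pytest.fixture(scope="session")
def small_design() -> ik.FieldDesign:
    return ik.FieldDesign(n_lines=6, blocks_per_year={"2010": 3, "2011": 3},
                          seeds_per_plot=(3, 3), line_names=None)


@pytest.fixture(scope="session")
def nam_design() -> ik.FieldDesign:
    """23 lines (popcorn/sweet-corn founders dropped), 6+5 blocks, 5 seeds."""
    names = tuple(n for n in ik.NAM_FOUNDERS
                  if n not in ("IL14H", "HP301", "P39"))
    return ik.FieldDesign(n_lines=23, seeds_per_plot=(5, 5), line_names=names)


@pytest.fixture
def no_drift() -> ik.DriftProcess:
    """Instrument behaving perfectly: no drift, no noise, unit recovery."""
    return ik.DriftProcess(run_factor_sd=0.0, drift_step_sd=0.0,
                           is_recovery_sd=0.0, is_recovery_step_sd=0.0,
                           noise_cv=0.0)


@pytest.fixture
def linear_drift() -> ik.DriftProcess:
    """Noiseless piecewise-linear drift with varying IS recovery."""
    return ik.DriftProcess(run_factor_sd=0.15, drift_step_sd=0.05,
                           is_recovery_sd=0.1, is_recovery_step_sd=0.02,
                           noise_cv=0.0)


def zero_variance_effects(elements=("Ca",), mean=50.0) -> ik.EffectModel:
    eff = {el: ik.ElementEffect(mean_ppm=mean, var_g=0, var_y=0, var_gy=0,
                                var_plot=0, var_e=0) for el in elements}
    return ik.EffectModel(effects=eff, weight_cv=0.0)


def toy_two_way(cell_means: dict, reps: int = 3, noise_sd: float = 0.0,
                seed: int = 0) -> pd.DataFrame:
    """Balanced line x year table from explicit cell means."""
    rng = np.random.default_rng(seed)
    rows = []
    for (line, year), mu in cell_means.items():
        for b in range(1, reps + 1):
            rows.append({"line": line, "year": year, "block": b,
                         "y": mu + (rng.normal(0, noise_sd) if noise_sd else 0.0)})
    return pd.DataFrame(rows)
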
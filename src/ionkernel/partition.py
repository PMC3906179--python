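"""Non-genetic structure in kernel ionomes: cob position and sugary effects.

Kernels fill at different times along the ear, so elemental accumulation
can run in gradients from base to tip. The cob analysis fits a fixed-effects
model with farm, field position and cob section terms, reports each term's
p-value and share of the total sum of squares, the within-ear dynamic range
(max/min section mean per ear, averaged over ears), and — for elements with
a significant section term — the base/middle/tip profile normalized to each
ear's mean. Ear identity is deliberately not a model term; it enters only
through the ear-wise averaging of ranges and gradients.

The sugary analysis compares collapsed (su/su) sweet-corn kernels with
plump (Su/+) siblings segregating within the same lines, with an additive
line + sugary model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linmod import AnovaResult, anova_fixed
from .synthetic import COB_SECTIONS

COB_TERMS = ("farm", "field_pos", "cob_section")


@dataclass
class VariancePartition:
    """Per-term p-values and SS fractions for one element."""

    element: str
    pvalue: dict[str, float]
    ss_fraction: dict[str, float]
    residual_fraction: float
    anova: AnovaResult


def cob_position_anova(
    table: pd.DataFrame,
    element: str,
    alpha_adjusted: float = 0.0005,
) -> VariancePartition:
    """ANOVA of one element on farm, field position and cob section.

    Terms with a single observed level are dropped with a warning (their SS
    fraction is reported as 0). SS fractions are shares of the total
    corrected SS and sum with the residual share to 1.
    """
    terms = []
    dropped = []
    for term in COB_TERMS:
        if table[term].nunique() > 1:
            terms.append(term)
        else:
            dropped.append(term)
    if not terms:
        raise ValueError("all model terms have a single level")
    res = anova_fixed(table, element, terms, typ=2)
    pv = {t: res.pvalue.get(t, np.nan) for t in COB_TERMS}
    frac = {t: res.ss_fraction.get(t, 0.0) for t in COB_TERMS}
    resid_frac = (res.ss_resid / res.ss_total) if res.ss_total > 0 else 1.0
    for t in dropped:
        res.flags.append(f"dropped_single_level:{t}")
    res.flags.append(f"alpha_adjusted={alpha_adjusted}")
    return VariancePartition(element, pv, frac, float(resid_frac), res)


def dynamic_range(
    values: pd.DataFrame,
    element: str,
    group: str,
    within: str | None = None,
) -> float:
    """Ratio of the largest to smallest group mean, optionally per unit.

    With ``within`` set (e.g. sections within each ear), the max/min ratio
    of group means is computed inside each unit and the ratios averaged
    over units; without it, one ratio over the whole table (e.g. line means
    within a year). Non-positive group minima make the ratio undefined.
    """
    df = values.dropna(subset=[element])

    def one(sub: pd.DataFrame) -> float:
        means = sub.groupby(group, observed=True)[element].mean()
        lo = means.min()
        if lo <= 0:
            raise ValueError(
                f"dynamic range undefined for {element}: non-positive mean")
        return float(means.max() / lo)

    if within is None:
        return one(df)
    ratios = [one(sub) for _, sub in df.groupby(within, observed=True)]
    return float(np.mean(ratios))


def normalized_gradient(
    table: pd.DataFrame,
    element: str,
) -> pd.Series:
    """Mean base/middle/tip profile, each ear normalized to its own mean.

    Per ear: section means divided by the ear's overall mean; the
    per-section values are then averaged across ears. Ears with a
    non-positive mean are skipped with a note. Intended for elements whose
    cob-section term passed the significance cutoff.
    """
    df = table.dropna(subset=[element])
    profiles = []
    for _, sub in df.groupby("ear", observed=True):
        ear_mean = sub[element].mean()
        if not np.isfinite(ear_mean) or ear_mean <= 0:
            continue
        sec = sub.groupby("cob_section", observed=True)[element].mean()
        profiles.append(sec / ear_mean)
    if not profiles:
        raise ValueError(f"no usable ears for {element}")
    out = pd.concat(profiles, axis=1).mean(axis=1)
    return out.reindex(list(COB_SECTIONS))


def sugary_anova(
    table: pd.DataFrame,
    element: str,
    alpha_adjusted: float = 0.0005,
) -> AnovaResult:
    """Additive two-term ANOVA of an element on line and sugary genotype."""
    if table["line"].nunique() < 2:
        raise ValueError("need >= 2 lines")
    if table["su_genotype"].nunique() < 2:
        raise ValueError("both sugary classes must be present")
    res = anova_fixed(table, element, ["line", "su_genotype"], typ=2)
    res.flags.append(f"alpha_adjusted={alpha_adjusted}")
    return res


def cob_summary_table(
    table: pd.DataFrame,
    elements: list[str],
    alpha_adjusted: float = 0.0005,
    nam_plot_means: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per element: dynamic ranges, term p-values and SS fractions.

    If NAM plot means are supplied, the per-year genotype dynamic range
    (max line mean / min line mean) is reported alongside the within-cob
    range for scale comparison.
    """
    rows = []
    for el in elements:
        part = cob_position_anova(table, el, alpha_adjusted)
        row = {"element": el,
               "dyn_range_cob": dynamic_range(table, el, "cob_section",
                                              within="ear")}
        if nam_plot_means is not None:
            for yr, sub in nam_plot_means.groupby("year", observed=True):
                lm = sub.groupby("line", observed=True)[el].mean()
                row[f"dyn_range_{yr}"] = (float(lm.max() / lm.min())
                                          if lm.min() > 0 else np.nan)
        for t in COB_TERMS:
            row[f"{t}_p"] = part.pvalue[t]
        for t in COB_TERMS:
            row[f"{t}_ss_frac"] = part.ss_fraction[t]
        row["residual_ss_frac"] = part.residual_fraction
        rows.append(row)
    return pd.DataFrame(rows)


def sugary_summary_table(
    table: pd.DataFrame,
    elements: list[str],
    alpha_adjusted: float = 0.0005,
) -> pd.DataFrame:
    """One row per element with line and sugary p-values."""
    rows = []
    for el in elements:
        res = sugary_anova(table, el, alpha_adjusted)
        rows.append({"element": el,
                     "p_line": res.pvalue["line"],
                     "p_su": res.pvalue["su_genotype"],
                     "alpha_adjusted": alpha_adjusted})
    return pd.DataFrame(rows)
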
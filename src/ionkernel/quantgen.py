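"""Genotype/year analysis of plot-mean ionomic phenotypes.

A two-way fixed-effects ANOVA (line, year, line x year) is fitted to plot
means per element. Heritability is estimated from the expected mean squares
on a line-mean basis:

    single year:  h2 = s2_G / (s2_G + s2_e / r)
    combined:     h2 = s2_G / (s2_G + s2_GY / y + s2_e / (r * y))

with s2_G = (MS_line - MS_LxY) / (r y), s2_GY = (MS_LxY - MS_resid) / r and
s2_e = MS_resid, components clamped at zero, r the harmonic mean number of
replicate plots per line-year cell and y the number of years. The material
is inbred lines, so although the output column is labelled h2 in the
customary way, the line-variance ratio is a broad-sense quantity.

The single-seed jackknife rebuilds the dataset many times by drawing one
kernel per plot (from the unfiltered data — the outlier rule is defined on
the within-plot distribution that single-seed sampling destroys), refits
the two-year model, and summarizes the genotype p-value and combined
heritability at their 5th percentiles: the value that 95% of single-seed
datasets beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import AnovaResult, anova_fixed

logger = logging.getLogger("ionkernel.quantgen")

_JACKKNIFE_STREAM = 29


# ---------------------------------------------------------------------------
# plot means
# ---------------------------------------------------------------------------

def compute_plot_means(
    seed_table: pd.DataFrame,
    elements: Sequence[str],
    exclude_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Arithmetic mean per plot (line x year x block) per element.

    NaN readings (removed outliers) are skipped; plots with no kept seeds
    for any element are dropped with a logged note. ``exclude_lines`` drops
    whole genotypes (e.g. popcorn and sweet corn entries whose low seed
    weights would bias the analysis).
    """
    t = seed_table[~seed_table["line"].isin(set(exclude_lines))]
    means = (t.groupby(["line", "year", "block"], sort=False, observed=True)
             [list(elements)].mean().reset_index())
    empty = means[list(elements)].isna().all(axis=1)
    if empty.any():
        logger.info("dropped %d plots with no kept seeds", int(empty.sum()))
        means = means[~empty].reset_index(drop=True)
    return means


# ---------------------------------------------------------------------------
# genotype/year ANOVA
# ---------------------------------------------------------------------------

def fit_genotype_year_model(
    plot_means: pd.DataFrame,
    element: str,
    alpha_adjusted: float = 0.0005,
) -> AnovaResult:
    """Two-way ANOVA of an element on line, year and their interaction.

    Sums of squares are Type II (each term adjusted for the others), which
    reduces to the sequential decomposition on balanced data; the unequal
    replication across years makes the distinction matter. Single-year
    tables fall back to the line-only model. The Bonferroni-adjusted cutoff
    is attached to the result for reporting.
    """
    years = plot_means["year"].nunique()
    if plot_means["line"].nunique() < 2:
        raise ValueError("need >= 2 lines")
    if years >= 2:
        res = anova_fixed(plot_means, element, ["line", "year"],
                          interaction=("line", "year"), typ=2)
    else:
        res = anova_fixed(plot_means, element, ["line"], typ=2)
    res.flags.append(f"alpha_adjusted={alpha_adjusted}")
    return res


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityResult:
    """Variance components and heritability for one element and scope."""

    element: str
    scope: str                      # "combined" or a year label
    var_g: float
    var_gy: float
    var_e: float
    h2: float
    r_harmonic: float
    n_years: int
    flags: list[str] = dc_field(default_factory=list)


def _harmonic_mean(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    return float(len(counts) / np.sum(1.0 / counts))


def estimate_heritability(
    plot_means: pd.DataFrame,
    element: str,
    scope: str = "combined",
) -> HeritabilityResult:
    """Method-of-moments heritability on a line-mean basis.

    ``scope`` is ``"combined"`` (all years, G x Y separated from error) or a
    single year label. Replication (>= 2 plots per line in scope) is
    required to separate the line variance from noise; unreplicated data
    should go through the single-seed jackknife instead.
    """
    df = plot_means.dropna(subset=[element])
    if scope != "combined":
        df = df[df["year"].astype(str) == str(scope)]
        if df.empty:
            raise ValueError(f"no data for year {scope!r}")
        reps = df.groupby("line", observed=True)[element].count()
        if (reps < 2).all():
            raise ValueError(
                "unreplicated design: heritability needs >= 2 plots per "
                "line — use the single-seed jackknife for r = 1 data")
        r = _harmonic_mean(reps.to_numpy())
        res = anova_fixed(df, element, ["line"], typ=2)
        ms_g = res.ss["line"] / res.df["line"]
        ms_e = res.ss_resid / res.df_resid
        var_g = max((ms_g - ms_e) / r, 0.0)
        var_e = ms_e
        denom = var_g + var_e / r
        h2 = var_g / denom if denom > 0 else 0.0
        return HeritabilityResult(element, str(scope), var_g, 0.0, var_e,
                                  float(np.clip(h2, 0.0, 1.0)), r, 1,
                                  list(res.flags))

    years = sorted(df["year"].astype(str).unique())
    y = len(years)
    if y < 2:
        raise ValueError("combined scope needs >= 2 years")
    cell_reps = (df.groupby(["line", "year"], observed=True)[element]
                 .count().to_numpy())
    if (cell_reps < 2).all():
        raise ValueError(
            "unreplicated design: heritability needs >= 2 plots per "
            "line-year cell — use the single-seed jackknife for r = 1 data")
    r = _harmonic_mean(cell_reps)
    res = anova_fixed(df, element, ["line", "year"],
                      interaction=("line", "year"), typ=2)
    var_g, var_gy, var_e, h2 = _combined_components(res, r, y)
    return HeritabilityResult(element, "combined", var_g, var_gy, var_e,
                              h2, r, y, list(res.flags))


def _combined_components(res: AnovaResult, r: float,
                         y: int) -> tuple[float, float, float, float]:
    """Variance components and combined h2 from a two-way ANOVA result."""
    ms_g = res.ss["line"] / res.df["line"]
    ms_gy = res.ss["line:year"] / res.df["line:year"]
    ms_e = res.ss_resid / res.df_resid
    var_g = max((ms_g - ms_gy) / (r * y), 0.0)
    var_gy = max((ms_gy - ms_e) / r, 0.0)
    var_e = ms_e
    denom = var_g + var_gy / y + var_e / (r * y)
    h2 = var_g / denom if denom > 0 else 0.0
    return var_g, var_gy, var_e, float(np.clip(h2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# between-year correlation
# ---------------------------------------------------------------------------

def year_correlation(
    plot_means: pd.DataFrame,
    element: str,
    years: tuple[str, str] | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation of per-line year means between two years.

    Plot means are averaged to one value per line per year; lines missing
    either year are dropped pairwise. Returns ``(r, p, n_lines)``; fewer
    than three shared lines yields ``(nan, nan, n)``.
    """
    lm = (plot_means.dropna(subset=[element])
          .groupby(["line", "year"], observed=True)[element].mean().unstack())
    if years is None:
        if lm.shape[1] != 2:
            raise ValueError("specify the two years to correlate")
        years = tuple(lm.columns)
    pair = lm[list(years)].dropna()
    n = len(pair)
    if n < 3:
        logger.warning("year correlation for %s undefined: %d shared lines",
                       element, n)
        return np.nan, np.nan, n
    r, p = stats.pearsonr(pair[years[0]], pair[years[1]])
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# single-seed jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeSummary:
    """Per-element resampling distribution of single-seed analyses.

    ``p5`` is the 5th percentile of the genotype p-values (95% of datasets
    were more significant); ``h2_5`` is the 5th percentile of the combined
    heritabilities (95% of datasets exceeded it). Quantiles use linear
    interpolation.
    """

    element: str
    pvalues: np.ndarray
    h2: np.ndarray
    p5: float
    h2_5: float
    n_datasets: int
    seed: int


def jackknife_single_seed(
    seed_table: pd.DataFrame,
    elements: Sequence[str],
    n_datasets: int = 100,
    seed: int = 7,
    exclude_lines: Sequence[str] = (),
) -> dict[str, JackknifeSummary]:
    """Resample one kernel per plot and refit the two-year model.

    Expects the unfiltered seed-level table: single-seed sampling removes
    the within-plot replication the outlier rule relies on, so outlier
    removal is deliberately not applied here. Each of ``n_datasets`` draws
    picks one seed uniformly at random from every plot, fits the line/year
    model and the combined heritability, and the per-element distributions
    are summarized at their 5th percentiles.
    """
    t = seed_table[~seed_table["line"].isin(set(exclude_lines))]
    t = t.reset_index(drop=True)
    groups = t.groupby(["line", "year", "block"], sort=False,
                       observed=True).indices
    plot_idx = [np.asarray(v) for v in groups.values()]
    if not plot_idx:
        raise ValueError("no plots in table")

    rng = np.random.default_rng([_JACKKNIFE_STREAM, int(seed)])
    meta = t[["line", "year", "block"]]
    # one observation per plot, so replication per line-year cell is the
    # block count — identical in every dataset
    first = np.array([idx[0] for idx in plot_idx])
    cell_reps = (meta.iloc[first].groupby(["line", "year"], observed=True)
                 .size().to_numpy())
    r = _harmonic_mean(cell_reps)
    y = meta["year"].nunique()
    pvals = {el: np.empty(n_datasets) for el in elements}
    h2s = {el: np.empty(n_datasets) for el in elements}
    for d in range(n_datasets):
        pick = np.array([idx[rng.integers(len(idx))] for idx in plot_idx])
        sub = pd.concat([meta.iloc[pick].reset_index(drop=True),
                         t.loc[pick, list(elements)].reset_index(drop=True)],
                        axis=1)
        for el in elements:
            res = fit_genotype_year_model(sub, el)
            pvals[el][d] = res.pvalue.get("line", np.nan)
            h2s[el][d] = _combined_components(res, r, y)[3]

    out: dict[str, JackknifeSummary] = {}
    for el in elements:
        out[el] = JackknifeSummary(
            element=el, pvalues=pvals[el], h2=h2s[el],
            p5=float(np.quantile(pvals[el], 0.05)),
            h2_5=float(np.quantile(h2s[el], 0.05)),
            n_datasets=n_datasets, seed=seed)
    return out


# ---------------------------------------------------------------------------
# full per-element summary (one row per element)
# ---------------------------------------------------------------------------

def nam_summary_table(
    seed_table_unfiltered: pd.DataFrame,
    plot_means: pd.DataFrame,
    elements: Sequence[str],
    alpha_adjusted: float = 0.0005,
    n_jackknife: int = 100,
    jackknife_seed: int = 7,
    exclude_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-element genotype/year p-values, heritabilities, correlation and
    jackknife summaries, one row per element."""
    years = sorted(plot_means["year"].astype(str).unique())
    jk = jackknife_single_seed(seed_table_unfiltered, elements,
                               n_datasets=n_jackknife, seed=jackknife_seed,
                               exclude_lines=exclude_lines)
    rows = []
    for el in elements:
        res = fit_genotype_year_model(plot_means, el, alpha_adjusted)
        row = {
            "element": el,
            "p_geno": res.pvalue.get("line", np.nan),
            "p_year": res.pvalue.get("year", np.nan),
            "p_gxy": res.pvalue.get("line:year", np.nan),
        }
        for i, yr in enumerate(years, start=1):
            row[f"h2_year{i}"] = estimate_heritability(plot_means, el, yr).h2
        row["h2_both"] = estimate_heritability(plot_means, el, "combined").h2
        r, p_r, _ = year_correlation(plot_means, el,
                                     (years[0], years[1]))
        row["corr"] = r
        row["corr_p"] = p_r
        row["jk5_p"] = jk[el].p5
        row["jk5_h2"] = jk[el].h2_5
        row["alpha_adjusted"] = alpha_adjusted
        rows.append(row)
    return pd.DataFrame(rows)
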
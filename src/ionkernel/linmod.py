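"""Fixed-effects ANOVA on categorical designs.

Sums of squares are computed by incremental residual-sum-of-squares
comparisons between nested ordinary-least-squares fits on explicit
treatment-coded design matrices. Type I (sequential) and Type II
(each term adjusted for all others of equal or lower order) are supported;
the two coincide on balanced designs. This route is kept deliberately
lightweight — the genetics analyses below refit the same small models
thousands of times during resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    """Per-term ANOVA decomposition for one response variable.

    ``ss``, ``df``, ``fvalue`` and ``pvalue`` are keyed by term name
    (a factor name or ``"A:B"`` for an interaction). ``ss_fraction`` is
    each term's share of the total (corrected) sum of squares.
    """

    terms: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    fvalue: dict[str, float]
    pvalue: dict[str, float]
    ss_resid: float
    df_resid: int
    ss_total: float
    flags: list[str] = field(default_factory=list)

    @property
    def ss_fraction(self) -> dict[str, float]:
        if self.ss_total <= 0:
            return {t: 0.0 for t in self.terms}
        return {t: self.ss[t] / self.ss_total for t in self.terms}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "ss": self.ss[t], "df": self.df[t],
             "F": self.fvalue[t], "p": self.pvalue[t]}
            for t in self.terms
        ]
        rows.append({"term": "Residual", "ss": self.ss_resid,
                     "df": self.df_resid, "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


def _dummies(series: pd.Series) -> np.ndarray:
    """Full-rank treatment-coded dummy columns (first level dropped)."""
    d = pd.get_dummies(series.astype("category"), drop_first=True, dtype=float)
    return d.to_numpy()


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise products of two dummy blocks."""
    if a.shape[1] == 0 or b.shape[1] == 0:
        return np.empty((a.shape[0], 0))
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)

def _rss(blocks: list[np.ndarray], y: np.ndarray) -> tuple[float, int]:
    """Residual SS and model rank for an OLS fit on [1 | blocks]."""
    n = y.shape[0]
    X = np.hstack([np.ones((n, 1))] + [b for b in blocks if b.size])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def anova_fixed(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    interaction: tuple[str, str] | None = None,
    typ: int = 2,
) -> AnovaResult:
    """Fixed-effects ANOVA of ``response`` on categorical ``factors``.

    Parameters
    ----------
    data : observations; factor columns are treated as categorical.
    response : name of the numeric response column.
    factors : main-effect factor names, in model order.
    interaction : optional pair of factor names whose crossed term is added
        after the main effects. If the interaction leaves zero residual
        degrees of freedom it is dropped with a warning.
    typ : 1 for sequential SS, 2 for each term adjusted for the others
        (identical on balanced data).
    """
    if typ not in (1, 2):
        raise ValueError("typ must be 1 or 2")
    df = data.dropna(subset=[response, *factors])
    y = df[response].to_numpy(dtype=float)
    n = y.shape[0]
    if n == 0:
        raise ValueError("no complete observations")

    blocks = {f: _dummies(df[f]) for f in factors}
    terms = list(factors)
    if interaction is not None:
        a, b = interaction
        terms.append(f"{a}:{b}")
        blocks[f"{a}:{b}"] = _interaction(blocks[a], blocks[b])

    flags: list[str] = []
    ss_total = float(np.sum((y - y.mean()) ** 2))

    def fit(term_list: list[str]) -> tuple[float, int]:
        return _rss([blocks[t] for t in term_list], y)

    rss_full, rank_full = fit(terms)
    df_resid = n - rank_full
    if df_resid == 0 and interaction is not None:
        warnings.warn(
            "interaction term leaves zero residual degrees of freedom; "
            "reduced to main effects", stacklevel=2)
        flags.append("interaction_dropped")
        terms = list(factors)
        rss_full, rank_full = fit(terms)
        df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")

    if ss_total <= 1e-300 * max(1.0, float(np.abs(y).max()) ** 2):
        # constant response: nothing to partition
        flags.append("constant_response")
        zero = {t: 0.0 for t in terms}
        return AnovaResult(terms, zero, {t: 0 for t in terms},
                           {t: np.nan for t in terms},
                           {t: 1.0 for t in terms},
                           0.0, df_resid, 0.0, flags)

    ss: dict[str, float] = {}
    dof: dict[str, int] = {}
    for i, term in enumerate(terms):
        if typ == 1:
            reduced = terms[:i]
            nested = terms[: i + 1]
        else:
            # Type II: adjust for all terms not containing this factor's
            # marginality violations (the interaction is excluded when
            # testing its own main effects).
            reduced = [t for t in terms if t != term and term not in t.split(":")]
            if ":" in term:
                reduced = [t for t in terms if t != term]
            nested = reduced + [term]
        rss_r, rank_r = fit(reduced)
        rss_n, rank_n = fit(nested)
        ss[term] = max(rss_r - rss_n, 0.0)
        dof[term] = rank_n - rank_r

    ms_resid = rss_full / df_resid
    fval: dict[str, float] = {}
    pval: dict[str, float] = {}
    for term in terms:
        if dof[term] == 0 or ms_resid <= 0:
            fval[term] = np.nan
            pval[term] = np.nan
            flags.append(f"degenerate:{term}")
            continue
        fval[term] = (ss[term] / dof[term]) / ms_resid
        pval[term] = float(stats.f.sf(fval[term], dof[term], df_resid))

    return AnovaResult(terms, ss, dof, fval, pval,
                       float(rss_full), int(df_resid), ss_total, flags)
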
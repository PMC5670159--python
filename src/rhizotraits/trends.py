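"""Chronosequence trend statistics.

CFU counts are log10-transformed and tested with a three-way main-effects
ANOVA (compartment, plant species, successional stage as categorical
factors, sequential sums of squares) with Tukey HSD pairwise comparisons per
factor.  Individual traits are regressed on stage age with a quadratic
polynomial by default -- the stage is numeric here but categorical in the
ANOVA, matching the two roles it plays in the study design -- and the fitted
parabola is classified as hump / U-shape / monotone / flat from its
curvature, vertex position and significance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import (
    CfuRecord,
    DegenerateDesignError,
    InsufficientDataError,
    RhizotraitsError,
)

# ---------------------------------------------------------------------------
# CFU
# ---------------------------------------------------------------------------


def log_cfu(cfu: Sequence[CfuRecord]) -> pd.DataFrame:
    """Tidy table of log10 CFU with the three design factors."""
    if not cfu:
        raise InsufficientDataError("empty CFU table")
    return pd.DataFrame(
        {
            "stage_years": [r.stage_years for r in cfu],
            "plant_species": [r.plant_species.value for r in cfu],
            "compartment": [r.compartment.value for r in cfu],
            "plot_id": [r.plot_id for r in cfu],
            "log10_cfu": [math.log10(r.cfu_per_g) for r in cfu],
        }
    )


@dataclass
class AnovaResult:
    table: pd.DataFrame  # factor, F, p
    tukey: dict[str, pd.DataFrame]  # per factor pairwise comparisons

    def f_for(self, factor: str) -> float:
        return float(self.table.loc[self.table["factor"] == factor, "F"].iloc[0])

    def p_for(self, factor: str) -> float:
        return float(self.table.loc[self.table["factor"] == factor, "p"].iloc[0])


_FACTORS = ("compartment", "plant_species", "stage_years")


def anova_cfu(table: pd.DataFrame, factors: Sequence[str] = _FACTORS) -> AnovaResult:
    """Three-way main-effects ANOVA on log10 CFU, type-I sums of squares."""
    for factor in factors:
        if table[factor].nunique() < 2:
            raise DegenerateDesignError(f"factor {factor!r} has a single level")
    formula = "log10_cfu ~ " + " + ".join(f"C({f})" for f in factors)
    model = ols(formula, data=table).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    rows = []
    for factor in factors:
        row = anova.loc[f"C({factor})"]
        rows.append({"factor": factor, "F": float(row["F"]), "p": float(row["PR(>F)"])})
    tukey = {}
    for factor in factors:
        res = pairwise_tukeyhsd(table["log10_cfu"], table[factor].astype(str))
        tukey[factor] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaResult(pd.DataFrame(rows), tukey)


# ---------------------------------------------------------------------------
# Polynomial trend fitting
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    trait_id: str
    compartment: str | None
    degree: int
    coefficients: tuple[float, ...]  # ascending powers
    r_squared: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(c * t**k for k, c in enumerate(self.coefficients))

    @property
    def vertex(self) -> float | None:
        """Stationary point -b/(2c) of a quadratic fit, else None."""
        if self.degree != 2 or self.coefficients[2] == 0:
            return None
        return -self.coefficients[1] / (2.0 * self.coefficients[2])


def fit_polynomial_trend(
    values: Sequence[float],
    stage_years: Sequence[float],
    degree: int = 2,
    trait_id: str = "",
    compartment: str | None = None,
) -> TrendFit:
    """OLS fit of a trait on powers of stage age, with overall-F p-value."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(stage_years, dtype=float)
    if len(y) != len(t):
        raise RhizotraitsError("values and stage_years differ in length")
    n = len(y)
    if n <= degree + 1:
        raise InsufficientDataError(
            f"polynomial degree {degree} needs n > {degree + 1}, got {n}"
        )
    design = np.vander(t, degree + 1, increasing=True)
    fit = sm.OLS(y, design).fit()
    # constant response: no variation to explain
    if np.ptp(y) == 0:
        coefs = [float(np.mean(y))] + [0.0] * degree
        return TrendFit(trait_id, compartment, degree, tuple(coefs), 0.0, 1.0, n)
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return TrendFit(
        trait_id,
        compartment,
        degree,
        tuple(float(c) for c in fit.params),
        float(fit.rsquared),
        p,
        n,
    )


def classify_trend_shape(
    fit: TrendFit, stage_domain: tuple[float, float] = (5.0, 105.0)
) -> str:
    """hump / u_shape / increasing / decreasing / flat from a quadratic fit."""
    if fit.degree != 2:
        raise RhizotraitsError("shape classification requires a degree-2 fit")
    if not fit.significant:
        return "flat"
    _, b, c = fit.coefficients
    lo, hi = stage_domain
    if c != 0:
        vertex = -b / (2.0 * c)
        if lo < vertex < hi:
            return "hump" if c < 0 else "u_shape"
    # monotone over the domain: sign of derivative at both ends agrees
    deriv_lo, deriv_hi = b + 2 * c * lo, b + 2 * c * hi
    if deriv_lo >= 0 and deriv_hi >= 0:
        return "increasing" if (deriv_lo > 0 or deriv_hi > 0) else "flat"
    if deriv_lo <= 0 and deriv_hi <= 0:
        return "decreasing" if (deriv_lo < 0 or deriv_hi < 0) else "flat"
    return "flat"


def trend_table(fits: Sequence[TrendFit], stage_domain=(5.0, 105.0)) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "trait_id": f.trait_id,
                "compartment": f.compartment or "all",
                "degree": f.degree,
                "coefficients": ";".join(f"{c:.6g}" for c in f.coefficients),
                "r_squared": f.r_squared,
                "p_value": f.p_value,
                "shape": classify_trend_shape(f, stage_domain) if f.degree == 2 else "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation for n > 9 and exact enumeration of
    all rank permutations for n <= 9 (where the approximation is poor).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise RhizotraitsError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RhizotraitsError("Spearman undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        perms = np.array(list(itertools.permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# Distribution diagnostics
# ---------------------------------------------------------------------------


def distribution_diagnostics(
    values: Sequence[float], groups: Sequence
) -> pd.DataFrame:
    """Per-group Shapiro-Wilk normality and overall Fligner-Killeen
    homogeneity-of-variance p-values.  Advisory: the pipeline proceeds
    regardless of the outcome.  Groups of fewer than 3 observations are
    skipped with a note."""
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    if frame["group"].nunique() < 2:
        raise InsufficientDataError("diagnostics need >=2 groups")
    rows = []
    usable = []
    for group, sub in frame.groupby("group", sort=True):
        if len(sub) < 3:
            rows.append(
                {"group": str(group), "n": len(sub), "shapiro_p": np.nan,
                 "note": "skipped (n < 3)"}
            )
            continue
        if np.ptp(sub["value"].values) == 0:
            shapiro_p = np.nan
            note = "constant group"
        else:
            shapiro_p = float(stats.shapiro(sub["value"]).pvalue)
            note = ""
        rows.append({"group": str(group), "n": len(sub), "shapiro_p": shapiro_p,
                     "note": note})
        usable.append(sub["value"].values)
    out = pd.DataFrame(rows)
    if len(usable) >= 2:
        fligner_p = float(stats.fligner(*usable).pvalue)
    else:
        fligner_p = np.nan
    out.attrs["fligner_p"] = fligner_p
    out["fligner_p"] = fligner_p
    return out
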
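"""Standard-curve calibration for the colorimetric assays.

Two analytes are calibrated: the CAS siderophore assay (absorbance at 630 nm
versus FeCl3 concentration in mM) and the Salkowski IAA assay (absorbance at
535 nm versus log10 molar IAA concentration).  Both use an ordinary
least-squares line, the minimal model consistent with Beer-Lambert behaviour
over the assayed range.

Siderophore production is expressed as consumed FeCl3: the CAS reaction
mixture starts at a reference 0.015 mM FeCl3 and iron chelated by secreted
siderophores no longer contributes to the dye signal, so

    consumed = reference − inferred remaining FeCl3,

clipped to [0, reference].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import DegenerateDesignError, InsufficientDataError, RhizotraitsError

#: Analyte whose x axis is fitted on a log10 scale.
_LOG_ANALYTES = frozenset({"iaa"})

VALID_ANALYTES = ("fecl3_cas", "iaa")


class UninvertibleCurveError(RhizotraitsError):
    """Fitted slope too close to zero for inversion."""


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS standard curve with forward and inverse evaluation.

    ``x_values`` are on the fitted scale: concentration in mM for the CAS
    curve, log10(molar concentration) for IAA.
    """

    analyte: str
    x_values: tuple[float, ...]
    y_values: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    x_domain: tuple[float, float]

    @property
    def log_scale(self) -> bool:
        return self.analyte in _LOG_ANALYTES

    def forward(self, concentration: float) -> float:
        """Predicted absorbance at a concentration (natural scale)."""
        x = np.log10(concentration) if self.log_scale else concentration
        return self.slope * x + self.intercept

    def invert(self, absorbance: float) -> float:
        return invert_curve(self, absorbance)

    def is_extrapolated(self, absorbance: float) -> bool:
        """True when the inverted x falls outside the fitted standards."""
        x = (absorbance - self.intercept) / self.slope
        lo, hi = self.x_domain
        return not (lo - 1e-12 <= x <= hi + 1e-12)


def fit_standard_curve(
    standards: Sequence[tuple[float, float]], analyte: str
) -> CalibrationCurve:
    """Fit an OLS line absorbance ~ concentration on the standards.

    For the IAA analyte, concentrations must be positive and are moved to a
    log10 scale before fitting (standards span 1e-6 to 1e-4 M).
    """
    if analyte not in VALID_ANALYTES:
        raise RhizotraitsError(f"unknown analyte {analyte!r}; expected {VALID_ANALYTES}")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absorb = np.asarray([s[1] for s in standards], dtype=float)
    if len(conc) < 3:
        raise InsufficientDataError(
            f"analyte {analyte}: need >=3 standards, got {len(conc)}"
        )
    if np.ptp(conc) == 0:
        raise DegenerateDesignError(f"analyte {analyte}: zero variance in x")
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError(
            f"analyte {analyte}: need >=3 distinct standard concentrations, "
            f"got {len(np.unique(conc))}"
        )
    if analyte in _LOG_ANALYTES:
        if (conc <= 0).any():
            raise RhizotraitsError(
                f"analyte {analyte}: concentrations must be > 0 for log10 fitting"
            )
        x = np.log10(conc)
    else:
        x = conc
    if np.ptp(x) < 1e-12:
        raise DegenerateDesignError(f"analyte {analyte}: zero variance in x")
    fit = stats.linregress(x, absorb)
    return CalibrationCurve(
        analyte=analyte,
        x_values=tuple(x),
        y_values=tuple(absorb),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        x_domain=(float(x.min()), float(x.max())),
    )


def invert_curve(curve: CalibrationCurve, absorbance: float) -> float:
    """Concentration (natural scale) producing a given absorbance."""
    if abs(curve.slope) <= 1e-12:
        raise UninvertibleCurveError(
            f"analyte {curve.analyte}: slope {curve.slope} too close to zero"
        )
    x = (absorbance - curve.intercept) / curve.slope
    if curve.is_extrapolated(absorbance):
        import logging

        logging.getLogger("rhizotraits").debug(
            "analyte %s: absorbance %.4g inverts outside the fitted domain %s",
            curve.analyte, absorbance, curve.x_domain,
        )
    return float(10.0**x) if curve.log_scale else float(x)


def siderophore_consumed_fe(
    sample_absorbance: float,
    curve: CalibrationCurve,
    reference_fe_mM: float = 0.015,
) -> float:
    """Consumed FeCl3 (mM) in the CAS mixture, the siderophore proxy."""
    if curve.analyte != "fecl3_cas":
        raise RhizotraitsError(
            f"siderophore quantification needs the fecl3_cas curve, got "
            f"{curve.analyte!r}"
        )
    remaining = invert_curve(curve, sample_absorbance)
    return float(np.clip(reference_fe_mM - remaining, 0.0, reference_fe_mM))


def fit_all_curves(standards_frame) -> dict[str, CalibrationCurve]:
    """Fit one curve per analyte present in a standards table."""
    curves: dict[str, CalibrationCurve] = {}
    for analyte, group in standards_frame.groupby("analyte", sort=True):
        pairs = list(zip(group["concentration"], group["absorbance"]))
        curves[str(analyte)] = fit_standard_curve(pairs, str(analyte))
    return curves


def calibration_report(curves: dict[str, CalibrationCurve]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "analyte": name,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "x_min": c.x_domain[0],
                "x_max": c.x_domain[1],
                "n_standards": len(c.x_values),
            }
            for name, c in sorted(curves.items())
        ]
    )
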
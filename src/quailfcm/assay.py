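"""Radioimmunoassay processing and analytical validation.

Implements the standard competitive-RIA workflow: percent binding
relative to the zero-dose (B0) tube after nonspecific-binding (NSB)
subtraction, log-logit standard curves, back-calculation of extract
concentrations, conversion to pg per mg dry feces, the parallelism
(homogeneity-of-slopes) F-test for serial dilutions, and intra-/inter-
assay coefficients of variation.

Conventions: dose is natural-log transformed (the base cancels in the
F-test); curve fits are ordinary least squares with no heteroscedasticity
weighting; duplicate-pair CVs use the n=2 sample SD (divisor n-1);
unknowns are assayed undiluted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InsufficientDataError, InvalidPlateError


def percent_binding(count: float, b0: float, nsb: float) -> float:
    """NSB-corrected binding fraction ``(count - nsb) / (b0 - nsb)``."""
    if b0 <= nsb:
        raise InvalidPlateError(f"B0 ({b0}) must exceed NSB ({nsb})")
    return (count - nsb) / (b0 - nsb)


def logit(p):
    p = np.asarray(p, float)
    return np.log(p / (1.0 - p))


@dataclass
class StandardCurve:
    """Fitted log-logit standard line: logit(B/B0) = intercept + slope * ln(dose)."""

    slope: float
    intercept: float
    r_squared: float
    dose_unit: str = "pg/mL"


class LogLogitStandardCurve(BaseEstimator, RegressorMixin):
    """OLS standard curve in logit-binding vs ln-dose space.

    ``fit`` takes doses and binding fractions; tubes with binding outside
    (0, 1) are excluded with a warning.  ``predict`` returns binding
    fractions for doses; ``inverse`` back-calculates dose from binding.
    """

    def fit(self, doses, binding_fractions):
        doses = np.asarray(doses, float)
        p = np.asarray(binding_fractions, float)
        if (doses <= 0).any():
            raise InvalidPlateError("standard doses must be strictly positive")
        ok = (p > 0.0) & (p < 1.0)
        if (~ok).any():
            warnings.warn(f"excluding {int((~ok).sum())} tube(s) with binding "
                          "outside (0, 1) from the standard curve")
        if ok.sum() < 3:
            raise InsufficientDataError(
                f"need >= 3 usable standards, have {int(ok.sum())}")
        x, yv = np.log(doses[ok]), logit(p[ok])
        slope, intercept = np.polyfit(x, yv, 1)
        resid = yv - (intercept + slope * x)
        tss = float(np.square(yv - yv.mean()).sum())
        r2 = 1.0 - float(np.square(resid).sum()) / tss if tss > 0 else 1.0
        if slope >= 0:
            warnings.warn(f"non-competitive standard curve (slope {slope:.3g} >= 0)")
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r_squared_ = r2
        return self

    def predict(self, doses):
        doses = np.asarray(doses, float)
        z = self.intercept_ + self.slope_ * np.log(doses)
        return 1.0 / (1.0 + np.exp(-z))

    def inverse(self, binding_fractions):
        p = np.asarray(binding_fractions, float)
        if ((p <= 0.0) | (p >= 1.0)).any():
            raise ValueError("binding fraction outside (0, 1) cannot be interpolated")
        if self.slope_ == 0:
            raise ValueError("flat standard curve; dose not identifiable")
        return np.exp((logit(p) - self.intercept_) / self.slope_)

    def as_curve(self) -> StandardCurve:
        return StandardCurve(self.slope_, self.intercept_, self.r_squared_)


def fit_standard_curve(doses, binding_fractions) -> StandardCurve:
    return LogLogitStandardCurve().fit(doses, binding_fractions).as_curve()


def interpolate_concentration(curve: StandardCurve, p: float) -> float:
    """Invert the standard curve: extract concentration (pg/mL) at binding ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"binding fraction {p} outside (0, 1)")
    if curve.slope == 0:
        raise ValueError("flat standard curve; dose not identifiable")
    return float(np.exp((float(logit(p)) - curve.intercept) / curve.slope))


@dataclass
class ExtractionSpec:
    """Mass/volume arithmetic of the extraction: 50 mg dry feces in 1 mL
    methanol, 100 uL of extract assayed."""

    feces_mass_mg: float = 50.0
    solvent_volume_ml: float = 1.0
    assay_volume_ml: float = 0.1

    def validate(self) -> None:
        if min(self.feces_mass_mg, self.solvent_volume_ml, self.assay_volume_ml) <= 0:
            raise ValueError("extraction spec fields must be strictly positive")
        if self.assay_volume_ml > self.solvent_volume_ml:
            raise ValueError("assay volume cannot exceed solvent volume")


def tube_to_fecal_concentration(extract_conc: float,
                                spec: ExtractionSpec | None = None) -> float:
    """pg/mL in the extract -> pg/mg dry feces.

    Removing an aliquot of supernatant leaves the concentration
    unchanged, so the conversion is just extract concentration times
    solvent volume over fecal mass; no recovery correction is applied.
    """
    spec = spec or ExtractionSpec()
    spec.validate()
    if extract_conc < 0:
        raise ValueError("extract concentration must be >= 0")
    return extract_conc * spec.solvent_volume_ml / spec.feces_mass_mg


# --------------------------------------------------------------------------
# Parallelism (homogeneity of slopes)

@dataclass
class ParallelismResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    slopes: tuple


def parallelism_test(lines: Sequence[np.ndarray]) -> ParallelismResult:
    """F-test for equality of slopes among regression lines.

    ``lines`` is a sequence of (n_i, 2) arrays of (log-dose,
    logit-binding) points.  The full model fits a separate slope and
    intercept per line; the reduced model a common slope with separate
    intercepts.  F = [(SSE_reduced - SSE_full)/(a-1)] /
    [SSE_full / sum_i (n_i - 2)], with a the number of lines.
    """
    if len(lines) < 2:
        raise InsufficientDataError("need >= 2 lines")
    arrs = [np.asarray(ln, float) for ln in lines]
    for ln in arrs:
        if ln.ndim != 2 or ln.shape[1] != 2 or ln.shape[0] < 3:
            raise InsufficientDataError("each line needs >= 3 (x, y) points")

    slopes, sxx_all, sse_full, syy_tot = [], [], 0.0, 0.0
    for ln in arrs:
        x, yv = ln[:, 0], ln[:, 1]
        xc, yc = x - x.mean(), yv - yv.mean()
        sxx, sxy = float(xc @ xc), float(xc @ yc)
        if sxx == 0:
            raise InsufficientDataError("a line has zero dose spread")
        b = sxy / sxx
        slopes.append(b)
        sxx_all.append(sxx)
        syy_tot += float(yc @ yc)
        sse_full += max(0.0, float(yc @ yc) - b * sxy)
    if sse_full <= 1e-12 * syy_tot:      # exact fit up to rounding
        sse_full = 0.0
    # common slope pools the within-line cross products (ANCOVA);
    # SSE_reduced - SSE_full = sum_i Sxx_i (b_i - b_common)^2, which is
    # exactly zero whenever the per-line slope estimates coincide
    b_common = float(np.dot(sxx_all, slopes) / np.sum(sxx_all))
    ss_slopes = float(np.dot(sxx_all, np.square(np.subtract(slopes, b_common))))
    if ss_slopes <= 1e-20 * (1.0 + b_common ** 2) * float(np.sum(sxx_all)):
        ss_slopes = 0.0                  # slope estimates coincide up to rounding

    a = len(arrs)
    df_num = a - 1
    df_den = sum(ln.shape[0] - 2 for ln in arrs)
    if sse_full <= 0:
        if ss_slopes > 0:
            warnings.warn("degenerate fit: zero residual variance with unequal slopes")
            return ParallelismResult(np.inf, df_num, df_den, 0.0, tuple(slopes))
        return ParallelismResult(0.0, df_num, df_den, 1.0, tuple(slopes))
    f = (ss_slopes / df_num) / (sse_full / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return ParallelismResult(float(f), df_num, df_den, p, tuple(slopes))


# --------------------------------------------------------------------------
# Assay-variation statistics

def intra_assay_cv(duplicate_pairs: Iterable[tuple]) -> float:
    """Mean percent CV over duplicate pairs (n=2 sample SD / pair mean x 100)."""
    pairs = [(float(a), float(b)) for a, b in duplicate_pairs]
    if not pairs:
        raise InsufficientDataError("need at least one duplicate pair")
    cvs = []
    for a, b in pairs:
        if a <= 0 or b <= 0:
            raise ValueError(f"nonpositive concentration in pair ({a}, {b})")
        sd = abs(a - b) / np.sqrt(2.0)   # sample SD of two values
        cvs.append(100.0 * sd / ((a + b) / 2.0))
    return float(np.mean(cvs))


def inter_assay_cv(control_values: Iterable[float]) -> float:
    """Percent CV of the shared control across plates."""
    vals = np.asarray(list(control_values), float)
    if vals.size < 2:
        raise InsufficientDataError("need controls from >= 2 plates")
    if (vals <= 0).any():
        raise ValueError("control concentrations must be positive")
    return float(100.0 * vals.std(ddof=1) / vals.mean())


# --------------------------------------------------------------------------
# Plate-table processing

def _plate_groups(plates: pd.DataFrame):
    required = {"plate_id", "tube_id", "role", "series_id", "dose_or_dilution", "count"}
    missing = required - set(plates.columns)
    if missing:
        raise InvalidPlateError(f"plate table missing column(s): {sorted(missing)}")
    return plates.groupby("plate_id", sort=True)


def plate_standard_curve(plate: pd.DataFrame) -> StandardCurve:
    """B0/NSB means and log-logit standard curve for one plate's rows."""
    b0 = plate.loc[plate["role"] == "B0", "count"].mean()
    nsb = plate.loc[plate["role"] == "NSB", "count"].mean()
    if not np.isfinite(b0) or not np.isfinite(nsb):
        raise InvalidPlateError("plate lacks B0 or NSB tubes")
    std = plate[plate["role"] == "standard"]
    p = [percent_binding(c, b0, nsb) for c in std["count"]]
    return fit_standard_curve(std["dose_or_dilution"].to_numpy(), p)


def validate_plates(plates: pd.DataFrame,
                    spec: ExtractionSpec | None = None) -> pd.DataFrame:
    """Full analytical-validation report for a plate table.

    Runs the parallelism F-test on the standard series plus every
    serial-dilution series (in log-logit space), computes the intra-assay
    CV from back-calculated duplicate unknowns and the inter-assay CV
    from the shared control across plates.  Returns a tidy report with
    columns ``statistic, value, df_num, df_den, p_value``.
    """
    spec = spec or ExtractionSpec()
    lines = []
    duplicates: list[tuple[float, float]] = []
    controls: list[float] = []
    for _, plate in _plate_groups(plates):
        b0 = plate.loc[plate["role"] == "B0", "count"].mean()
        nsb = plate.loc[plate["role"] == "NSB", "count"].mean()
        curve = plate_standard_curve(plate)

        std = plate[plate["role"] == "standard"]
        std_pts = np.column_stack([
            np.log(std["dose_or_dilution"].to_numpy(float)),
            logit([percent_binding(c, b0, nsb) for c in std["count"]])])
        if not lines:          # parallelism is assessed against one standard line
            lines.append(std_pts)
        for sid, ser in plate[plate["role"] == "dilution"].groupby("series_id"):
            pts = np.column_stack([
                np.log(ser["dose_or_dilution"].to_numpy(float)),
                logit([percent_binding(c, b0, nsb) for c in ser["count"]])])
            lines.append(pts)

        for sid, dup in plate[plate["role"] == "unknown"].groupby("series_id"):
            concs = [tube_to_fecal_concentration(
                interpolate_concentration(curve, percent_binding(c, b0, nsb)), spec)
                for c in dup["count"]]
            if len(concs) == 2:
                duplicates.append(tuple(concs))
        ctrl = plate[plate["role"] == "control"]
        if len(ctrl):
            controls.append(tube_to_fecal_concentration(
                interpolate_concentration(
                    curve, percent_binding(float(ctrl["count"].iloc[0]), b0, nsb)),
                spec))

    rows = []
    if len(lines) >= 2:
        par = parallelism_test(lines)
        rows.append(("parallelism_F", par.f_stat, par.df_num, par.df_den, par.p_value))
    if duplicates:
        rows.append(("intra_assay_cv", intra_assay_cv(duplicates), "", "", ""))
    if len(controls) >= 2:
        rows.append(("inter_assay_cv", inter_assay_cv(controls), "", "", ""))
    return pd.DataFrame(rows, columns=["statistic", "value", "df_num", "df_den", "p_value"])
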
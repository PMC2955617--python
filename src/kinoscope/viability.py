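"""Plate-reader viability analysis: vehicle normalization, four-parameter
logistic (4PL) dose-response fitting, censored absolute IC50, and Bliss
combination-enhancement statistics.

The curve model is the decreasing 4PL

    v(c) = lower + (upper - lower) / (1 + (c / ec50)^hill)

with viability expressed as a fraction of vehicle. The IC50 reported is the
*absolute* one — the concentration where fitted viability crosses 0.5 — and
is censored as NOT_REACHED when the curve never attains 0.5 inside the
tested dose range; a drug plateauing at 60% viability therefore has no
IC50, which is the published behaviour this pipeline reproduces.

Combination effects are quantified as Bliss excess (expected viability
under independence, v_a * v_b, minus observed combination viability) and
reported as "enhancement (Bliss excess)" — never as synergy, which a
censored monotherapy IC50 makes unassessable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ParameterError, ValidationError


class _NotReached:
    """Singleton sentinel for a censored IC50."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_REACHED"


NOT_REACHED = _NotReached()

#: Printed monotherapy dose grids.
DASATINIB_DOSES_NM = (50.0, 100.0, 200.0, 500.0, 1000.0, 5000.0)
TBB_DOSES_UM = (10.0, 20.0, 50.0, 100.0, 200.0, 500.0)


@dataclass
class DoseResponse:
    """Replicate viabilities (fraction of vehicle) on a strict dose grid."""

    drug: str
    doses: np.ndarray                 # strictly increasing, positive
    viabilities: pd.DataFrame         # long: dose, replicate, viability
    unit: str = ""
    vehicle_mean: float = float("nan")
    blank_mean: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        if self.doses.size == 0 or (self.doses <= 0).any():
            raise ParameterError(f"{self.drug}: doses must be positive")
        if not (np.diff(self.doses) > 0).all():
            raise ParameterError(f"{self.drug}: doses must be strictly increasing")
        if not np.isfinite(self.viabilities["viability"]).all():
            raise ValidationError(f"{self.drug}: non-finite viabilities")
        per_dose = self.viabilities.groupby("dose").size()
        missing = set(self.doses) - set(per_dose.index)
        if missing:
            raise ValidationError(f"{self.drug}: doses without replicates: {sorted(missing)}")

    def mean_viability(self) -> pd.Series:
        """Replicate mean per dose, aligned with ``doses``."""
        m = self.viabilities.groupby("dose")["viability"].mean()
        return m.reindex(self.doses)


@dataclass
class FitResult:
    """Fitted 4PL parameters plus a possibly censored absolute IC50."""

    lower: float
    upper: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    ic50: float | _NotReached = NOT_REACHED

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return four_pl(np.asarray(dose, float), self.lower, self.upper, self.ec50, self.hill)


@dataclass
class CombinationResult:
    """Per-dose Bliss bookkeeping for drug A titrated on fixed drug B."""

    drug_a: str
    drug_b: str
    table: pd.DataFrame  # dose, v_combo, v_mono_a, v_mono_b, bliss_expected, excess
    enhancement_flag: bool
    excess_threshold: float
    min_doses: int
    statistic: str = "enhancement (Bliss excess)"
    schedule_note: str = ""


def four_pl(dose, lower: float, upper: float, ec50: float, hill: float):
    """Decreasing four-parameter logistic."""
    dose = np.asarray(dose, float)
    return lower + (upper - lower) / (1.0 + (dose / ec50) ** hill)


# ---------------------------------------------------------------------------
# plate normalization

def normalize_plate(raw: pd.DataFrame, drug: str | None = None) -> DoseResponse:
    """Convert a long-format absorbance table into vehicle-normalized
    viabilities.

    ``raw`` needs columns ``drug, dose, replicate, absorbance, role`` with
    role in {blank, vehicle, treated} (``unit`` optional). Viability is
    (A - mean blank) / (mean vehicle - mean blank); replicates are kept,
    never pre-averaged. Wells darker than blank yield negative viabilities,
    which are retained (with a warning) so the fit sees them.
    """
    required = {"drug", "dose", "replicate", "absorbance", "role"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"plate table missing columns {sorted(missing)}")
    if drug is not None:
        raw = raw[(raw["drug"] == drug) | (raw["role"].isin(["blank", "vehicle"]))]
    blanks = raw.loc[raw["role"] == "blank", "absorbance"]
    vehicles = raw.loc[raw["role"] == "vehicle", "absorbance"]
    if blanks.empty or vehicles.empty:
        raise ValidationError("plate must contain blank and vehicle wells")
    blank_mean = float(blanks.mean())
    vehicle_mean = float(vehicles.mean())
    if vehicle_mean <= blank_mean:
        raise ValidationError(
            f"mean vehicle absorbance ({vehicle_mean:.3f}) <= mean blank "
            f"({blank_mean:.3f}): plate uninterpretable"
        )
    treated = raw[raw["role"] == "treated"].copy()
    if treated.empty:
        raise ValidationError("no treated wells on plate")
    drug_names = treated["drug"].unique()
    if len(drug_names) > 1:
        raise ValidationError(f"multiple drugs in treated wells: {list(drug_names)}; pass drug=")
    treated["viability"] = (treated["absorbance"] - blank_mean) / (vehicle_mean - blank_mean)
    if (treated["viability"] < 0).any():
        warnings.warn(
            "wells below blank produced negative viabilities; retained for fitting",
            stacklevel=2,
        )
    doses = np.sort(treated["dose"].unique().astype(float))
    unit = str(treated["unit"].iloc[0]) if "unit" in treated.columns else ""
    return DoseResponse(
        drug=str(drug_names[0]),
        doses=doses,
        viabilities=treated[["dose", "replicate", "viability"]].reset_index(drop=True),
        unit=unit,
        vehicle_mean=vehicle_mean,
        blank_mean=blank_mean,
    )


# ---------------------------------------------------------------------------
# 4PL fitting

_BOUNDS_LOWER = (0.0, 1.0)
_BOUNDS_UPPER = (0.5, 1.5)
_BOUNDS_HILL = (1e-3, 10.0)


def fit_4pl(dr: DoseResponse) -> FitResult:
    """Bounded least-squares 4PL fit with three deterministic starts.

    Bounds: lower in [0, 1], upper in [0.5, 1.5], ec50 in
    [min dose / 10, max dose * 10] (fitted on the log scale), hill in
    (0, 10]. The best of the three starts by residual sum of squares wins;
    on optimizer failure the best-effort parameters are returned with
    ``converged=False``. The absolute IC50 is then filled in via
    :func:`ic50_from_fit`.
    """
    if dr.doses.size < 4:
        raise ParameterError(f"{dr.drug}: need >= 4 distinct doses to fit a 4PL")
    x = dr.viabilities["dose"].to_numpy(float)
    y = dr.viabilities["viability"].to_numpy(float)
    if not np.isfinite(y).all():
        raise ValidationError(f"{dr.drug}: non-finite viabilities")

    lo_ec, hi_ec = dr.doses.min() / 10.0, dr.doses.max() * 10.0
    log_lo, log_hi = np.log(lo_ec), np.log(hi_ec)

    def residuals(theta):
        lower, upper, log_ec50, hill = theta
        return four_pl(x, lower, upper, np.exp(log_ec50), hill) - y

    y_lo = float(np.clip(np.min(y), *_BOUNDS_LOWER))
    y_hi = float(np.clip(np.max(y), *_BOUNDS_UPPER))
    mid = float(np.sqrt(dr.doses.min() * dr.doses.max()))
    starts = [
        (y_lo, y_hi, np.log(mid), 1.0),
        (y_lo, y_hi, np.log(np.clip(dr.doses.min(), lo_ec, hi_ec)), 2.0),
        (y_lo, y_hi, np.log(np.clip(dr.doses.max(), lo_ec, hi_ec)), 0.5),
    ]
    bounds = (
        [_BOUNDS_LOWER[0], _BOUNDS_UPPER[0], log_lo, _BOUNDS_HILL[0]],
        [_BOUNDS_LOWER[1], _BOUNDS_UPPER[1], log_hi, _BOUNDS_HILL[1]],
    )
    best = None
    any_success = False
    for theta0 in starts:
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            sol = least_squares(residuals, theta0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        any_success = any_success or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise ValidationError(f"{dr.drug}: 4PL optimization failed from all starts")
    rss, sol = best
    lower, upper, log_ec50, hill = sol.x
    fit = FitResult(
        lower=float(lower),
        upper=float(upper),
        ec50=float(np.exp(log_ec50)),
        hill=float(hill),
        rss=rss,
        converged=any_success and bool(sol.success),
    )
    fit.ic50 = ic50_from_fit(fit, (float(dr.doses.min()), float(dr.doses.max())))
    return fit


def ic50_from_fit(fit: FitResult, dose_range: tuple[float, float]) -> float | _NotReached:
    """Absolute IC50 in closed form, censored as NOT_REACHED when the fitted
    curve never crosses viability 0.5 inside ``dose_range`` (in particular
    whenever the lower asymptote is >= 0.5)."""
    lo, hi = dose_range
    if fit.lower >= 0.5 or fit.upper <= 0.5:
        return NOT_REACHED
    ratio = (fit.upper - 0.5) / (0.5 - fit.lower)
    ic50 = fit.ec50 * ratio ** (1.0 / fit.hill)
    if not (lo <= ic50 <= hi):
        return NOT_REACHED
    return float(ic50)


# ---------------------------------------------------------------------------
# combination analysis

def analyze_combination(
    mono_a: DoseResponse,
    mono_b_at_fixed: float,
    combo: DoseResponse,
    excess_threshold: float = 0.1,
    min_doses: int = 2,
    drug_b: str = "drug_b",
    schedule_note: str = "",
) -> CombinationResult:
    """Bliss-independence bookkeeping for drug A titrated on a fixed dose of
    drug B (``mono_b_at_fixed`` is B's monotherapy viability at that dose).

    Per shared dose: bliss_expected = v_mono_a * v_mono_b and
    excess = bliss_expected - v_combo. The enhancement flag is raised when
    excess exceeds ``excess_threshold`` at >= ``min_doses`` doses. The
    statistic is labelled "enhancement (Bliss excess)" — monotherapy IC50
    censoring can make a formal synergy analysis impossible.
    """
    shared = np.intersect1d(mono_a.doses, combo.doses)
    if shared.size == 0:
        raise ValidationError(
            f"no shared doses between {mono_a.drug} monotherapy and combination"
        )
    va = mono_a.mean_viability().reindex(shared)
    vc = combo.mean_viability().reindex(shared)
    bliss = va * mono_b_at_fixed
    excess = bliss - vc
    table = pd.DataFrame(
        {
            "dose": shared,
            "v_combo": vc.to_numpy(),
            "v_mono_a": va.to_numpy(),
            "v_mono_b": mono_b_at_fixed,
            "bliss_expected": bliss.to_numpy(),
            "excess": excess.to_numpy(),
        }
    )
    flag = bool((table["excess"] > excess_threshold).sum() >= min_doses)
    return CombinationResult(
        drug_a=mono_a.drug,
        drug_b=drug_b,
        table=table,
        enhancement_flag=flag,
        excess_threshold=excess_threshold,
        min_doses=min_doses,
        schedule_note=schedule_note,
    )
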
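"""Four-parameter logistic dose-response fitting and auxiliary calculations.

The 4PL model on log10 dose,

    r(d) = bottom + (top - bottom) / (1 + (EC50 / d)^hill),

is fit by bounded nonlinear least squares with data-driven initialization.
``top``/``bottom`` are unconstrained in order, so the same model serves
responses that rise with dose (phenotypic distance) and responses that
fall (percent viability). A fit is demoted to "no_fit" when the optimizer
fails, the dynamic range is indistinguishable from control noise, r² is
below 0.5, or the EC50 sits at a search bound — operationalizing the
"No fit" entries of screens where no credible EC50 can be established.

Also provides DMSO-normalized viability, the ΔΔCt fold-change calculation
and the organoid-line derivation ("take") rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ValidationError

R_SQUARED_MIN = 0.5          # strict: r² < 0.5 -> no_fit
DYNAMIC_RANGE_CONTROL_SD = 2.0   # |top-bottom| must exceed 2x control SD
EC50_BOUND_REL_TOL = 1.05    # within 5% of a bound counts as "at bound"


@dataclass
class DoseResponseCurve:
    """Per-well dose/response observations for one compound."""

    compound: str
    doses: np.ndarray        # nM, one entry per well (replicates repeat)
    responses: np.ndarray
    response_kind: str = "distance"   # or "viability_percent"
    control_sd: Optional[float] = None  # pooled SD of control-well responses

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValidationError("doses and responses differ in length")
        if np.any(self.doses <= 0):
            raise ValidationError("doses must be strictly positive")


@dataclass
class FitResult:
    compound: str = ""
    bottom: float = np.nan
    top: float = np.nan
    ec50: float = np.nan     # nM
    hill: float = np.nan
    r_squared: float = np.nan
    status: str = "no_fit"   # "fit" | "no_fit"
    reason: str = ""

    def as_dict(self) -> dict:
        return {"compound": self.compound, "bottom": self.bottom,
                "top": self.top, "ec50_nM": self.ec50, "hill": self.hill,
                "r_squared": self.r_squared, "status": self.status,
                "reason": self.reason}


def _model(log_d: np.ndarray, bottom: float, top: float,
           log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_ec50 - log_d)))


def fit_4pl(curve: DoseResponseCurve) -> FitResult:
    """Fit the 4PL model and classify the result as fit / no_fit.

    Requires ≥ 4 distinct doses. EC50 is bounded to [min dose / 10,
    max dose × 10]; initialization takes bottom/top from the extreme-dose
    means and the EC50 from the half-maximal crossing.
    """
    doses = curve.doses
    resp = curve.responses
    uniq = np.unique(doses)
    if uniq.size < 4:
        raise ValidationError("need >= 4 distinct doses for a 4PL fit")

    log_d = np.log10(doses)
    lo_mean = resp[doses == uniq[0]].mean()
    hi_mean = resp[doses == uniq[-1]].mean()
    mid = 0.5 * (lo_mean + hi_mean)
    # dose whose mean response is nearest the midpoint
    dose_means = np.array([resp[doses == d].mean() for d in uniq])
    ec50_init = float(uniq[np.argmin(np.abs(dose_means - mid))])

    lb_ec50, ub_ec50 = uniq[0] / 10.0, uniq[-1] * 10.0
    span = resp.max() - resp.min()
    pad = max(span, 1e-6)
    x0 = np.array([lo_mean, hi_mean, np.log10(ec50_init), 1.0])
    bounds = (np.array([resp.min() - pad, resp.min() - pad,
                        np.log10(lb_ec50), 0.1]),
              np.array([resp.max() + pad, resp.max() + pad,
                        np.log10(ub_ec50), 10.0]))
    x0 = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)

    def residuals(x):
        return _model(log_d, *x) - resp

    try:
        sol = least_squares(residuals, x0, bounds=bounds, method="trf")
    except Exception:
        return FitResult(compound=curve.compound, status="no_fit",
                         reason="optimizer failure")
    if not sol.success:
        return FitResult(compound=curve.compound, status="no_fit",
                         reason="non-convergence")

    bottom, top, log_ec50, hill = sol.x
    pred = _model(log_d, *sol.x)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fit = FitResult(compound=curve.compound, bottom=float(bottom),
                    top=float(top), ec50=float(10 ** log_ec50),
                    hill=float(hill), r_squared=r2, status="fit")
    return classify_fit(fit, curve)


def classify_fit(fit: FitResult, curve: DoseResponseCurve) -> FitResult:
    """Demote a converged fit to no_fit when it is not credible.

    Criteria: dynamic range below 2× the pooled control SD (when a control
    SD is supplied, else below 2× the pooled replicate SD); r² < 0.5;
    EC50 within 5% of a search bound.
    """
    if fit.status == "no_fit":
        return fit
    reasons = []
    noise = curve.control_sd
    if noise is None:
        reps = [curve.responses[curve.doses == d]
                for d in np.unique(curve.doses)]
        sds = [r.std(ddof=1) for r in reps if r.size > 1]
        noise = float(np.sqrt(np.mean(np.square(sds)))) if sds else 0.0
    if abs(fit.top - fit.bottom) < DYNAMIC_RANGE_CONTROL_SD * noise:
        reasons.append("dynamic range within control noise")
    if fit.r_squared < R_SQUARED_MIN:
        reasons.append(f"r_squared {fit.r_squared:.3f} < {R_SQUARED_MIN}")
    lb = curve.doses.min() / 10.0
    ub = curve.doses.max() * 10.0
    if fit.ec50 <= lb * EC50_BOUND_REL_TOL or \
            fit.ec50 >= ub / EC50_BOUND_REL_TOL:
        reasons.append("EC50 at search bound")
    if reasons:
        return FitResult(compound=fit.compound, bottom=fit.bottom,
                         top=fit.top, ec50=fit.ec50, hill=fit.hill,
                         r_squared=fit.r_squared, status="no_fit",
                         reason="; ".join(reasons))
    return fit


def curve_from_distances(distances: pd.DataFrame, compound: str,
                         control_label: str = "DMSO") -> DoseResponseCurve:
    """Build a per-well distance curve for one compound.

    ``distances``: the per-well table from phenoscore.score_wells with
    columns well, compound, dose_nM, distance. Control wells supply the
    pooled control SD used by the no-fit dynamic-range criterion.
    """
    treated = distances[(distances["compound"] == compound)
                        & (distances["dose_nM"] > 0)]
    controls = distances[(distances["compound"] == control_label)
                         | (distances["dose_nM"] == 0)]
    control_sd = (float(controls["distance"].std(ddof=1))
                  if len(controls) > 1 else None)
    return DoseResponseCurve(
        compound=compound,
        doses=treated["dose_nM"].to_numpy(),
        responses=treated["distance"].to_numpy(),
        response_kind="distance",
        control_sd=control_sd)


def fit_screen(distances: pd.DataFrame,
               control_label: str = "DMSO") -> pd.DataFrame:
    """Fit every compound in a per-well distance table; summary rows."""
    compounds = sorted(c for c in distances["compound"].unique()
                       if c != control_label)
    rows = []
    for comp in compounds:
        curve = curve_from_distances(distances, comp, control_label)
        rows.append(fit_4pl(curve).as_dict())
    return pd.DataFrame(rows)


def normalize_viability(raw: Sequence[float],
                        control_raw: Sequence[float]) -> np.ndarray:
    """Percent-of-control viability: 100 × raw / mean(control)."""
    control = np.asarray(control_raw, dtype=float)
    if control.size == 0:
        raise ValidationError("need at least one control well")
    mean_c = control.mean()
    if mean_c == 0:
        raise ValidationError("control mean is zero")
    return 100.0 * np.asarray(raw, dtype=float) / mean_c


def delta_delta_ct(ct_target_treated: float, ct_ref_treated: float,
                   ct_target_control: float, ct_ref_control: float,
                   ) -> float:
    """Relative expression fold change 2^(−ΔΔCt).

    ΔΔCt = (Ct_target,treated − Ct_ref,treated)
         − (Ct_target,control − Ct_ref,control); the reference gene is the
    housekeeping normalizer (e.g. GAPDH).
    """
    cts = (ct_target_treated, ct_ref_treated,
           ct_target_control, ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValidationError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) \
        - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def derivation_rate(established: int, collected: int) -> float:
    """Percent of collected samples successfully established in culture."""
    if collected <= 0:
        raise ValidationError("collected must be > 0")
    if not 0 <= established <= collected:
        raise ValidationError("established must lie in [0, collected]")
    return 100.0 * established / collected
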
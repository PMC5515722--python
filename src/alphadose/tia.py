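"""Time-integrated activity (TIA) per unit mass, by two routes.

The cumulated activity concentration, the integral of activity concentration
from injection to infinity, is the kinetic half of the absorbed-dose
calculation.  Two routes are provided:

* **fit** — for tissues whose kinetics support a sum-of-exponentials fit the
  integral is the closed form sum(A_i / lambda_i);
* **hybrid** — otherwise the integral is taken as a numerical (trapezoid)
  integration over the measured span plus an analytic exponential tail whose
  rate is the log-linear slope of the last two time points.

Concentrations are treated as decay-corrected (biological) curves; physical
decay of a candidate radionuclide is applied explicitly — and exactly once —
by :func:`substitute_radionuclide`, which weights the biological curve by
``exp(-lambda_phys * t)``.  Setting the physical decay constant to zero
recovers the biological TIA, and TIA is monotone non-increasing in
lambda_phys, so shorter-lived nuclides always integrate to less activity on
the same biology.

Edge rules (documented because sparse animal schedules hit them often):

* the span from t=0 to the first sample is filled by back-extrapolating the
  first-segment log-linear slope, floored at the first measured value, so a
  distribution-phase hour of blood activity is not discarded and a rising
  (uptake) first segment never has activity invented before it;
* a non-decreasing tail (continuing uptake) has no defined log-linear
  clearance rate: the biological tail is held constant and only physical
  decay terminates the integral.  The result is flagged ``conservative-tail``
  — an upper bound, the safe direction for prescription work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclides import Radionuclide
from .pk import MultiExponentialModel, TimeActivityCurve, auc

__all__ = [
    "TIAResult",
    "tia_from_fit",
    "tia_hybrid",
    "substitute_radionuclide",
    "organ_tia_table",
    "tia_ratio_table",
]


@dataclass(frozen=True)
class TIAResult:
    """Time-integrated activity concentration for one tissue.

    ``tia`` is in %IA*h/g (or, for daughter-activity curves measured in
    Bq/g, in Bq*h/g — the caller keeps track, and the dose step converts).
    ``tail_fraction`` is the share contributed by extrapolation beyond the
    last observation.  ``flags`` records edge-rule fallbacks.
    """

    organ_label: str
    tia: float
    method: str  # "fit" | "hybrid"
    tail_fraction: float = 0.0
    radionuclide_label: str = "none"
    flags: tuple[str, ...] = ()
    components: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.tia < 0:
            raise ValueError(f"{self.organ_label}: TIA must be non-negative")
        if not 0.0 <= self.tail_fraction <= 1.0 + 1e-12:
            raise ValueError(f"{self.organ_label}: tail fraction outside [0, 1]")
        if self.method not in ("fit", "hybrid"):
            raise ValueError(f"unknown TIA method {self.method!r}")


def tia_from_fit(
    model: MultiExponentialModel,
    last_observation_h: float | None = None,
    radionuclide_label: str = "none",
) -> TIAResult:
    """Closed-form TIA of a fitted model: sum(A_i / lambda_i).

    When ``last_observation_h`` is given, ``tail_fraction`` reports the share
    of the integral lying beyond it (the extrapolated part of the fit route).
    """
    total = auc(model)  # validates rates > 0
    tail_frac = 0.0
    if last_observation_h is not None and total > 0:
        tail = float(
            np.sum(
                model.amplitudes
                * np.exp(-model.rates * last_observation_h)
                / model.rates
            )
        )
        tail_frac = min(max(tail / total, 0.0), 1.0)
    return TIAResult(
        organ_label=model.organ_label,
        tia=total,
        method="fit",
        tail_fraction=tail_frac,
        radionuclide_label=radionuclide_label,
    )


def _leading_edge_area(t: np.ndarray, c: np.ndarray) -> float:
    """Integral over [0, t_1] by back-extrapolation of the first segment.

    The first-segment log-linear slope is extended backwards; values are
    floored at the first measured concentration, so a decaying first segment
    back-extrapolates upward (blood distribution phase) while a rising first
    segment contributes a constant c_1 rather than inventing earlier uptake.
    """
    t1 = float(t[0])
    if t1 <= 0:
        return 0.0
    c1, c2 = float(c[0]), float(c[1])
    if c1 <= 0 or c2 <= 0 or c1 <= c2:
        return c1 * t1  # rising or flat first segment: floor at c_1
    lam = math.log(c1 / c2) / (t[1] - t[0])
    return c1 * (math.exp(lam * t1) - 1.0) / lam


def tia_hybrid(
    curve: TimeActivityCurve,
    physical_decay: Radionuclide | None = None,
    leading_edge: str = "back-extrapolate",
    radionuclide_label: str = "none",
) -> TIAResult:
    """Hybrid TIA: trapezoid over the measured span plus an analytic tail.

    The tail beyond the last sample is ``c_k / lambda_tail`` with
    ``lambda_tail`` the log-linear slope of the last two points.  For a
    non-decreasing tail the biological level is held constant and the
    integral is terminated by physical decay alone (``physical_decay``
    required; result flagged ``conservative-tail``).

    Parameters
    ----------
    curve : TimeActivityCurve
    physical_decay : Radionuclide, optional
        Supplies lambda_phys for the flat-tail fallback only; routine
        physical-decay weighting belongs to :func:`substitute_radionuclide`.
    leading_edge : "back-extrapolate" or "none"
        Whether to include the [0, t_1] span (see module notes).
    """
    if len(curve) < 2:
        raise ValueError(f"{curve.organ_label}: hybrid TIA needs at least two time points")
    if leading_edge not in ("back-extrapolate", "none"):
        raise ValueError(f"unknown leading_edge {leading_edge!r}")
    t = curve.times_h
    c = np.asarray(curve.mean_conc, dtype=float)
    flags: list[str] = []

    measured = float(np.trapezoid(c, t))
    leading = _leading_edge_area(t, c) if leading_edge == "back-extrapolate" else 0.0

    ck_1, ck = float(c[-2]), float(c[-1])
    if ck == 0.0:
        tail = 0.0
        flags.append("zero-terminal")
    elif ck < ck_1:
        lam_tail = math.log(ck_1 / ck) / (t[-1] - t[-2])
        tail = ck / lam_tail
    else:
        if physical_decay is None:
            raise ValueError(
                f"{curve.organ_label}: non-decreasing tail has no log-linear "
                "clearance rate; supply physical_decay for the constant-tail fallback"
            )
        tail = ck / physical_decay.decay_constant_per_h
        flags.append("conservative-tail")

    total = leading + measured + tail
    return TIAResult(
        organ_label=curve.organ_label,
        tia=total,
        method="hybrid",
        tail_fraction=tail / total if total > 0 else 0.0,
        radionuclide_label=radionuclide_label,
        flags=tuple(flags),
        components={"leading": leading, "measured": measured, "tail": tail},
    )


def substitute_radionuclide(
    biological: MultiExponentialModel | TimeActivityCurve,
    nuclide: Radionuclide,
) -> TIAResult:
    """TIA of the biological kinetics under a candidate nuclide's decay.

    The biological (decay-corrected) curve or model is weighted by
    ``exp(-lambda_phys t)``.  For a fitted model the result is the closed
    form sum(A_i / (lambda_i + lambda_phys)); for a sampled curve the decay
    weighting is applied pointwise and the hybrid rule integrates the
    product (whose tail always decreases once physical decay is applied, so
    the fallback is exercised only by exactly flat biology and lambda_phys
    consistently terminates it).
    """
    lam_p = nuclide.decay_constant_per_h
    if lam_p < 0:
        raise ValueError("physical decay constant must be non-negative")
    if isinstance(biological, MultiExponentialModel):
        if np.any(biological.rates + lam_p <= 0):
            raise ValueError("divergent integral: biological rate + lambda_phys <= 0")
        total = float(np.sum(biological.amplitudes / (biological.rates + lam_p)))
        return TIAResult(
            organ_label=biological.organ_label,
            tia=total,
            method="fit",
            radionuclide_label=nuclide.label,
        )
    decayed = TimeActivityCurve(
        organ_label=biological.organ_label,
        times_h=biological.times_h,
        mean_conc=biological.mean_conc * np.exp(-lam_p * biological.times_h),
        sd_conc=None,
        n_animals=biological.n_animals,
        organ_mass_g=biological.organ_mass_g,
    )
    return tia_hybrid(decayed, physical_decay=nuclide, radionuclide_label=nuclide.label)


def organ_tia_table(
    dataset,
    method: str = "auto",
    nuclide: Radionuclide | None = None,
) -> list[TIAResult]:
    """Per-organ TIA for a whole dataset, recording the route used.

    ``method="auto"`` mirrors the usual practice: each organ is fitted with
    a sum of exponentials (uptake phases admitted) and integrated in closed
    form; organs whose data cannot support a fit fall back to the hybrid
    trapezoid-plus-tail rule.  The route actually taken is recorded on each
    result (``method`` field), since the assignment is a property of the
    data, not of the tissue.  When ``nuclide`` is given, its physical decay
    is applied (exactly once) via :func:`substitute_radionuclide`.
    """
    from .pk import FitError, fit_multiexponential  # local: avoid cycle at import

    if method not in ("fit", "hybrid", "auto"):
        raise ValueError(f"unknown method {method!r}")
    results = []
    for curve in dataset.curves:
        model = None
        if method in ("fit", "auto"):
            try:
                model = fit_multiexponential(curve, n_terms="auto", nonnegative=False)
            except FitError:
                if method == "fit":
                    raise
        if model is not None and (model.predict(0.0) >= 0) and auc(model) >= 0:
            if nuclide is not None:
                results.append(substitute_radionuclide(model, nuclide))
            else:
                results.append(tia_from_fit(model, last_observation_h=float(curve.times_h[-1])))
        else:
            if nuclide is not None:
                results.append(substitute_radionuclide(curve, nuclide))
            else:
                results.append(tia_hybrid(curve, physical_decay=nuclide))
    return results


def tia_ratio_table(
    tia_results: list[TIAResult],
    numerator_organ: str,
    denominator_organs: list[str],
) -> pd.DataFrame:
    """Dimensionless TIA ratios (e.g. tumor-to-blood) per radionuclide.

    Returns a DataFrame indexed by radionuclide label with one column
    ``<numerator>/<denominator>`` per requested denominator organ.
    """
    by_key = {(r.radionuclide_label, r.organ_label): r.tia for r in tia_results}
    nuclides = sorted({r.radionuclide_label for r in tia_results})
    rows = {}
    for nuc in nuclides:
        num = by_key.get((nuc, numerator_organ))
        if num is None:
            raise KeyError(f"no TIA for organ {numerator_organ!r} under {nuc!r}")
        row = {}
        for den_organ in denominator_organs:
            den = by_key.get((nuc, den_organ))
            if den is None:
                raise KeyError(f"no TIA for organ {den_organ!r} under {nuc!r}")
            if den == 0:
                raise ZeroDivisionError(f"zero TIA denominator for organ {den_organ!r}")
            row[f"{numerator_organ}/{den_organ}"] = num / den
        rows[nuc] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("radionuclide")
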
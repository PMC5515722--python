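"""Multi-exponential pharmacokinetic models for organ time-activity curves.

Biodistribution studies sample the activity concentration of a tissue
(percent injected activity per gram, %IA/g) at a handful of times after
injection.  Antibody clearance from well-perfused tissues is described by a
sum of exponentials

    c(t) = sum_i A_i * exp(-lambda_i * t)

whose amplitudes ``A_i`` (%IA/g) and rates ``lambda_i`` (1/h) summarise the
kinetics: the fraction 100*A_i/sum(A) of the initial concentration clears
with half-life ln(2)/lambda_i.  This module fits such models by weighted
nonlinear least squares and derives the standard summaries: percent/half-life
tables, the area under the curve from zero to infinity, and the terminal
clearance half-time from the last two samples.

Fitting uses variable projection: for trial rates the amplitudes are the
exact linear least-squares (or non-negative least-squares) solution, so the
outer search runs over the rates only.  Initial rates come from curve
peeling (log-linear tail, strip, log-linear remainder), refined from a small
deterministic multi-start set, and the winner is polished on the full
parameter vector.  On noise-free data generated by a two-term model this
recovers the generating parameters to well below 0.1% relative error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TimeActivityCurve",
    "MultiExponentialModel",
    "TerminalHalfLife",
    "FitError",
    "DegenerateModelError",
    "fit_multiexponential",
    "blood_pk_summary",
    "auc",
    "terminal_half_life",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best candidate found."""

    def __init__(self, message: str, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class DegenerateModelError(FitError):
    """The requested model order is not supported by the data."""


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity concentration of one tissue over time.

    Parameters
    ----------
    organ_label : str
    times_h : array of float
        Sampling times in hours, strictly increasing.
    mean_conc : array of float
        Mean concentration at each time, %IA/g (non-negative).
    sd_conc : array of float, optional
        Inter-animal standard deviation per time point.
    n_animals : array of int, optional
        Animals contributing at each time point.
    organ_mass_g : float, optional
        Organ mass; only needed when converting per-mass dose to organ dose.
    """

    organ_label: str
    times_h: np.ndarray
    mean_conc: np.ndarray
    sd_conc: np.ndarray | None = None
    n_animals: np.ndarray | None = None
    organ_mass_g: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.mean_conc, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "mean_conc", c)
        if t.ndim != 1 or t.size == 0:
            raise ValueError(f"{self.organ_label}: times must be a 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.organ_label}: times must be strictly increasing")
        if c.shape != t.shape:
            raise ValueError(f"{self.organ_label}: times and concentrations differ in length")
        if np.any(c < 0):
            raise ValueError(f"{self.organ_label}: concentrations must be non-negative")
        if self.sd_conc is not None:
            s = np.asarray(self.sd_conc, dtype=float)
            object.__setattr__(self, "sd_conc", s)
            if s.shape != t.shape:
                raise ValueError(f"{self.organ_label}: sd length mismatch")
            if np.any(s < 0):
                raise ValueError(f"{self.organ_label}: sd must be non-negative")
        if self.n_animals is not None:
            n = np.asarray(self.n_animals, dtype=int)
            object.__setattr__(self, "n_animals", n)
            if n.shape != t.shape:
                raise ValueError(f"{self.organ_label}: n length mismatch")

    def __len__(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class MultiExponentialModel:
    """Fitted (or constructed) sum-of-exponentials clearance model."""

    terms: tuple[tuple[float, float], ...]  # (amplitude %IA/g, rate 1/h)
    rss: float = 0.0
    organ_label: str = ""
    param_se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        terms = tuple((float(a), float(r)) for a, r in self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms:
            raise ValueError("model needs at least one exponential term")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.terms])

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.terms])

    @property
    def c0(self) -> float:
        """Model value at t=0 (sum of amplitudes)."""
        return float(self.amplitudes.sum())

    def predict(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.sum(
            self.amplitudes[:, None] * np.exp(-np.outer(self.rates, t_arr)), axis=0
        )
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass(frozen=True)
class TerminalHalfLife:
    """Terminal clearance half-time, or a non-clearing flag."""

    half_life_h: float | None
    non_clearing: bool = False


# ----------------------------------------------------------------------
# fitting internals

_RATE_LO = math.log(math.log(2.0) / 5000.0)  # half-life cap 5000 h
_RATE_HI = math.log(math.log(2.0) / 0.05)    # half-life floor 0.05 h


def _weights(curve: TimeActivityCurve, weighting: str) -> np.ndarray:
    if weighting not in ("auto", "none", "inverse-variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    use_iv = weighting == "inverse-variance" or (
        weighting == "auto"
        and curve.sd_conc is not None
        and np.all(curve.sd_conc > 0)
    )
    if use_iv:
        if curve.sd_conc is None or np.any(curve.sd_conc <= 0):
            raise ValueError("inverse-variance weighting needs positive SDs")
        return 1.0 / np.asarray(curve.sd_conc, dtype=float)
    return np.ones_like(curve.times_h)


def _solve_amplitudes(t, y, w, rates, nonnegative):
    X = np.exp(-np.outer(t, rates)) * w[:, None]
    yw = y * w
    if nonnegative:
        amps, _ = optimize.nnls(X, yw)
    else:
        amps, *_ = np.linalg.lstsq(X, yw, rcond=None)
    resid = X @ amps - yw
    return amps, float(resid @ resid)


def _peeling_start(t, y, n_terms):
    """Curve-peeling rates: log-linear tail, strip, log-linear remainder."""
    y = np.maximum(y, 1e-12)
    lam_tail = max(math.log(y[-2] / y[-1]) / (t[-1] - t[-2]), 1e-6) if y[-2] > y[-1] else 1e-3
    if n_terms == 1:
        return [lam_tail]
    a_tail = y[-1] * math.exp(lam_tail * t[-1])
    resid = np.maximum(y - a_tail * np.exp(-lam_tail * t), 1e-12)
    k = min(2, len(t) - 1)
    lam_fast = (
        math.log(resid[0] / resid[k]) / (t[k] - t[0]) if resid[0] > resid[k] else 10 * lam_tail
    )
    lam_fast = max(lam_fast, 2.0 * lam_tail)
    return [lam_fast, lam_tail]


def _fit_rates(t, y, w, n_terms, nonnegative):
    """Variable-projection fit; returns (amps, rates, rss)."""
    ln2 = math.log(2.0)
    starts: list[list[float]] = [_peeling_start(t, y, n_terms)]
    if n_terms == 1:
        starts += [[ln2 / h] for h in (2.0, 20.0, 150.0)]
    else:
        grid = (2.0, 10.0, 40.0, 150.0)
        starts += [
            [ln2 / hf, ln2 / hs] for hf in grid for hs in grid if hs > 3.0 * hf
        ]

    def objective(log_rates):
        _, rss = _solve_amplitudes(t, y, w, np.exp(log_rates), nonnegative)
        return rss

    best = None
    for s in starts:
        x0 = np.clip(np.log(s), _RATE_LO, _RATE_HI)
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(np.clip(best.x, _RATE_LO, _RATE_HI))
    amps, rss = _solve_amplitudes(t, y, w, rates, nonnegative)

    # full-parameter polish for machine-precision recovery on clean data
    def full_resid(p):
        a = p[:n_terms]
        lam = np.exp(p[n_terms:])
        return (np.sum(a[:, None] * np.exp(-np.outer(lam, t)), axis=0) - y) * w

    p0 = np.concatenate([amps, np.log(np.maximum(rates, 1e-12))])
    lb = np.concatenate(
        [np.zeros(n_terms) if nonnegative else -np.inf * np.ones(n_terms),
         _RATE_LO * np.ones(n_terms)]
    )
    ub = np.concatenate([np.inf * np.ones(n_terms), _RATE_HI * np.ones(n_terms)])
    try:
        ls = optimize.least_squares(
            full_resid, np.clip(p0, lb, ub), bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if ls.cost * 2.0 <= rss + 1e-30:
            amps = ls.x[:n_terms]
            rates = np.exp(ls.x[n_terms:])
            rss = float(2.0 * ls.cost)
    except Exception:  # polish is best-effort; varpro solution stands
        pass
    return np.asarray(amps, float), np.asarray(rates, float), float(rss)


def fit_multiexponential(
    curve: TimeActivityCurve,
    n_terms: int | str = "auto",
    weighting: str = "auto",
    nonnegative: bool = True,
) -> MultiExponentialModel:
    """Fit a mono- or bi-exponential clearance model to a time-activity curve.

    Parameters
    ----------
    curve : TimeActivityCurve
    n_terms : 1, 2 or "auto"
        Model order.  ``"auto"`` tries two terms and falls back to one when
        the two-term fit is degenerate (rate ratio < 1.2 or a fractional
        amplitude below 1%), mirroring the single-phase fallback used when a
        bi-phasic description is not supported.
    weighting : "auto", "none" or "inverse-variance"
        ``"auto"`` uses inverse-variance weights whenever per-point SDs are
        available and positive.
    nonnegative : bool
        Constrain amplitudes to be non-negative (clearance-only kinetics).
        Set False to admit a negative fast term describing an uptake phase.

    Raises
    ------
    DegenerateModelError
        If an explicit ``n_terms`` cannot be supported by the data (flat
        curve, collapsing rates, vanishing fraction) or there are fewer
        points than parameters.
    FitError
        If no start converges; carries the best candidate found.
    """
    if n_terms == "auto":
        try:
            return fit_multiexponential(curve, 2, weighting, nonnegative)
        except (DegenerateModelError, FitError):
            return fit_multiexponential(curve, 1, weighting, nonnegative)
    if n_terms not in (1, 2):
        raise ValueError("n_terms must be 1, 2 or 'auto'")
    t = curve.times_h
    y = np.asarray(curve.mean_conc, dtype=float)
    if len(t) < 2 * n_terms:
        raise DegenerateModelError(
            f"{curve.organ_label}: {len(t)} points cannot identify "
            f"{2 * n_terms} parameters"
        )
    w = _weights(curve, weighting)
    amps, rates, rss = _fit_rates(t, y, w, n_terms, nonnegative)

    # boundary / degeneracy checks
    hl_cap = math.log(2.0) / math.exp(_RATE_LO)
    if np.any(math.log(2.0) / np.maximum(rates, 1e-300) > 0.98 * hl_cap):
        raise DegenerateModelError(
            f"{curve.organ_label}: fitted rate at the non-clearing boundary "
            "(curve does not decay); model rejected",
            best_candidate=(amps, rates, rss),
        )
    order = np.argsort(rates)[::-1]  # fastest first
    amps, rates = amps[order], rates[order]
    if n_terms == 2:
        total = np.abs(amps).sum()
        ratio = rates[0] / rates[1] if rates[1] > 0 else np.inf
        if ratio < 1.2 or (total > 0 and np.min(np.abs(amps)) / total < 0.01):
            raise DegenerateModelError(
                f"{curve.organ_label}: two-term fit degenerate "
                f"(rate ratio {ratio:.3g}, amplitudes {amps})",
                best_candidate=(amps, rates, rss),
            )
    return MultiExponentialModel(
        terms=tuple(zip(amps.tolist(), rates.tolist())),
        rss=rss,
        organ_label=curve.organ_label,
    )


def blood_pk_summary(model: MultiExponentialModel) -> list[tuple[float, float]]:
    """Percent / half-life table for a blood clearance model.

    Returns ``[(percent_of_initial, half_life_h), ...]`` sorted fastest phase
    first; percents sum to 100.  Negative amplitudes (uptake phases) are not
    a blood clearance summary and raise ``ValueError``.
    """
    amps, rates = model.amplitudes, model.rates
    if np.any(amps < 0):
        raise ValueError("negative amplitude: uptake-phase model has no percent/half-life summary")
    total = amps.sum()
    if total <= 0:
        raise ValueError("all amplitudes zero; nothing to summarise")
    order = np.argsort(rates)[::-1]
    return [
        (100.0 * amps[i] / total, math.log(2.0) / rates[i]) for i in order
    ]


def auc(model: MultiExponentialModel) -> float:
    """Area under c(t) from zero to infinity, %IA*h/g: sum(A_i / lambda_i).

    Raises
    ------
    ValueError
        If any rate is non-positive (divergent integral).
    """
    if np.any(model.rates <= 0):
        raise ValueError("non-positive rate: AUC to infinity diverges")
    return float(np.sum(model.amplitudes / model.rates))


def terminal_half_life(curve: TimeActivityCurve) -> TerminalHalfLife:
    """Terminal clearance half-time from the last two measured points.

    Computes ``ln2 * (t_k - t_{k-1}) / ln(c_{k-1} / c_k)``.  If the last
    concentration is not below the second-to-last, the tissue is flagged
    non-clearing over the observed window instead.
    """
    if len(curve) < 2:
        raise ValueError(f"{curve.organ_label}: need at least two time points")
    c1, c2 = curve.mean_conc[-2], curve.mean_conc[-1]
    t1, t2 = curve.times_h[-2], curve.times_h[-1]
    if c2 <= 0 or c1 <= 0:
        raise ValueError(f"{curve.organ_label}: terminal concentrations must be positive")
    if c2 >= c1:
        return TerminalHalfLife(half_life_h=None, non_clearing=True)
    return TerminalHalfLife(
        half_life_h=math.log(2.0) * (t2 - t1) / math.log(c1 / c2),
        non_clearing=False,
    )
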
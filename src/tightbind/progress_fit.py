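"""Simultaneous (global) nonlinear regression of progress-curve families.

All curves of a family share one set of rate constants; the only thing that
differs between curves is the inhibitor concentration.  The objective is
unweighted least squares on the signal, minimized by Levenberg-Marquardt on
log10-transformed rates (which enforces positivity and conditions the
tight-binding objective), with a small multi-start over decade-shifted
initial values because the residual surface can have long curved valleys.

Initial values, when not supplied, come from a classical two-stage analysis:
each inhibited curve is first fit to the closed-form biphasic curve to get a
per-curve apparent rate ``kobs``, and ``kobs`` is then regressed linearly on
the protection-corrected inhibitor concentration to yield starting values
for ``k_on`` (slope) and ``k_off`` (intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import curve_fit

from .datasets import ValueWithError
from .kinetic_models import (
    CurveFamily,
    InvalidStateError,
    RateParameters,
    SchemeId,
    kobs_one_step,
    morrison_walsh_curve,
    simulate_progress,
)

__all__ = ["FitResult", "fit_family", "curve_r", "estimate_initial_rates"]

LOG10 = math.log(10.0)

# log10 bounds for free rate parameters; generous but finite so the
# optimizer cannot wander to regions where the ODE stiffens needlessly.
_BOUNDS = {
    "k_on": (0.0, 10.0),  # 1 .. 1e10 M^-1 s^-1
    "k_off": (-9.0, 2.0),
    "k_isom_f": (-6.0, 2.0),
    "k_isom_r": (-6.0, 2.0),
    "k_cat": (-3.0, 4.0),
}


@dataclass
class FitResult:
    """Outcome of one global fit of one scheme to one curve family."""

    scheme: SchemeId
    estimates: dict[str, ValueWithError]
    best_params: RateParameters
    rss: float
    n_obs: int
    n_params: int
    param_names: list[str]
    covariance: np.ndarray | None  # natural-scale covariance of free params
    converged: bool
    identifiable: bool
    n_evals: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params

    @property
    def sigma2(self) -> float:
        """Residual variance estimate rss/(n_obs - n_params)."""
        return self.rss / self.dof

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "estimates": {
                k: {"value": v.value, "se": v.se}
                for k, v in self.estimates.items()
            },
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "identifiable": self.identifiable,
        }


def _free_param_names(scheme: SchemeId, fit_turnover: bool) -> list[str]:
    names = ["k_on"]
    if scheme is not SchemeId.IRREVERSIBLE:
        names.append("k_off")
    if scheme is SchemeId.TWO_STEP:
        names += ["k_isom_f", "k_isom_r"]
    if fit_turnover:
        names.append("k_cat")
    return names


def estimate_initial_rates(
    family: CurveFamily, K_m: float, k_cat_E: float | None = None
) -> tuple[float, float]:
    """Two-stage classical estimate of (k_on, k_off) for starting values.

    Stage 1 fits each inhibited curve to the closed-form biphasic curve
    (free ``v0``, ``vs``, ``kobs``); stage 2 regresses ``kobs`` on
    ``I/(1 + S_0/K_m)``.  Not meant to be accurate under strong inhibitor
    depletion — only to land the global fit in the right decade.
    """
    t = family.times
    protection = 1.0 + family.S_0 / K_m
    xs, ys = [], []
    v0_guess = None
    for i, conc in enumerate(family.inhibitor_concs):
        y = family.signals[i] - family.baseline
        if conc == 0:
            v0_guess = max((y[-1] - y[0]) / (t[-1] - t[0]), 1e-300)
            continue
        vs0 = max((y[-1] - y[len(t) // 2]) / (t[-1] - t[len(t) // 2]), 0.0)
        v00 = v0_guess if v0_guess is not None else max(y[-1] / t[-1], 1e-300)

        def model(tt, v0, vs, kobs):
            return morrison_walsh_curve(v0, vs, abs(kobs), tt)

        try:
            popt, _ = curve_fit(
                model, t, y, p0=[v00, vs0, 5.0 / t[-1]], maxfev=2000
            )
            xs.append(conc / protection)
            ys.append(abs(popt[2]))
        except RuntimeError:
            continue
    if len(xs) >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        k_on = float(max(slope, 1e2))
        k_off = float(max(intercept, 1e-7))
    elif len(xs) == 1:
        k_on = float(max(ys[0] / xs[0], 1e2))
        k_off = 1e-4
    else:
        k_on = 1e6
        k_off = 1e-4
    return k_on, k_off


def _simulate_family(
    scheme: SchemeId, params: RateParameters, family: CurveFamily
) -> np.ndarray:
    out = np.empty_like(family.signals)
    for i in range(family.n_curves):
        out[i] = simulate_progress(scheme, params, family.conditions(i)).signal
    return out


def fit_family(
    family: CurveFamily,
    scheme: SchemeId | str,
    fixed: dict[str, float] | None = None,
    init: dict[str, float] | None = None,
    fit_turnover: bool = False,
    n_starts: int = 3,
    max_nfev: int = 400,
) -> FitResult:
    """Globally fit one scheme to every curve of *family* at once.

    Parameters
    ----------
    fixed : dict
        Values held constant (``k_cat``, ``K_m``, or any rate).  ``K_m`` and
        ``k_cat`` default to the documented assay defaults when absent.
    init : dict
        Starting values for free rates; missing entries are estimated from
        the data (see :func:`estimate_initial_rates`).
    fit_turnover : bool
        Free the shared turnover scale ``k_cat`` (the uninhibited velocity
        ``k_cat * E_total`` is then effectively one shared nuisance scale).
    n_starts : int
        Multi-start count; starts are decade-spaced around the initial
        rates, and the best converged start wins.

    Standard errors come from the Gauss-Newton covariance
    ``(J^T J)^-1 * rss/(n_obs - n_params)`` propagated from the log10 scale
    to the natural scale.
    """
    scheme = SchemeId.coerce(scheme)
    fixed = dict(fixed or {})
    init = dict(init or {})
    if family.n_curves < 2:
        raise InvalidStateError("global fit needs >= 2 curves")
    if not np.any(family.inhibitor_concs == 0):
        raise InvalidStateError("family must include an uninhibited (I=0) curve")

    defaults = RateParameters(k_on=1e6, k_off=1e-4)
    K_m = fixed.get("K_m", defaults.K_m)
    k_cat0 = fixed.get("k_cat", defaults.k_cat)
    free_names = _free_param_names(scheme, fit_turnover)
    free_names = [n for n in free_names if n not in fixed]
    if not free_names:
        raise InvalidStateError("no free parameters left to fit")

    if "k_on" not in init or "k_off" not in init:
        k_on_est, k_off_est = estimate_initial_rates(family, K_m)
        init.setdefault("k_on", k_on_est)
        init.setdefault("k_off", k_off_est)
    init.setdefault("k_isom_f", 1e-3)
    init.setdefault("k_isom_r", 1e-3)
    init.setdefault("k_cat", k_cat0)
    for name, value in init.items():
        if not (np.isfinite(value) and value > 0):
            raise InvalidStateError(f"initial value for {name} must be finite and > 0")

    def build_params(values: dict[str, float]) -> RateParameters:
        get = lambda n, d: fixed.get(n, values.get(n, d))
        return RateParameters(
            k_on=get("k_on", init["k_on"]),
            k_off=0.0 if scheme is SchemeId.IRREVERSIBLE else get("k_off", init["k_off"]),
            k_isom_f=get("k_isom_f", 0.0) if scheme is SchemeId.TWO_STEP else 0.0,
            k_isom_r=get("k_isom_r", 0.0) if scheme is SchemeId.TWO_STEP else 0.0,
            k_cat=get("k_cat", k_cat0),
            K_m=K_m,
        )

    obs = family.signals.ravel()
    n_evals = 0

    def residual(lmpars: lmfit.Parameters) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        values = {n: 10.0 ** lmpars[f"log10_{n}"].value for n in free_names}
        model = _simulate_family(scheme, build_params(values), family)
        return (model.ravel() - obs)

    best = None
    decade_shifts = [0.0, 1.0, -1.0, 2.0, -2.0][: max(1, n_starts)]
    for shift in decade_shifts:
        lmpars = lmfit.Parameters()
        for n in free_names:
            lo, hi = _BOUNDS[n]
            start = math.log10(init[n])
            if n in ("k_on", "k_off"):
                start += shift
            lmpars.add(f"log10_{n}", value=min(max(start, lo), hi), min=lo, max=hi)
        try:
            result = lmfit.minimize(
                residual, lmpars, method="leastsq", max_nfev=max_nfev
            )
        except Exception:  # singular step, overflow in a bad basin
            continue
        rss = float(np.sum(result.residual**2))
        if best is None or rss < best[0] - 1e-300:
            best = (rss, result)
    if best is None:
        raise InvalidStateError("all optimization starts failed")
    rss, result = best

    n_obs = obs.size
    n_params = len(free_names)
    log_values = {n: result.params[f"log10_{n}"].value for n in free_names}
    nat_values = {n: 10.0 ** v for n, v in log_values.items()}

    covar_nat = None
    identifiable = result.covar is not None
    estimates: dict[str, ValueWithError] = {}
    if identifiable:
        # d k / d log10 k = k * ln 10
        jac = np.diag([nat_values[n] * LOG10 for n in free_names])
        covar_nat = jac @ result.covar @ jac
        for i, n in enumerate(free_names):
            estimates[n] = ValueWithError(
                nat_values[n], float(math.sqrt(max(covar_nat[i, i], 0.0)))
            )
    else:
        for n in free_names:
            estimates[n] = ValueWithError(nat_values[n], float("nan"))

    converged = bool(result.success) and result.nfev < max_nfev
    return FitResult(
        scheme=scheme,
        estimates=estimates,
        best_params=build_params(nat_values),
        rss=rss,
        n_obs=n_obs,
        n_params=n_params,
        param_names=list(free_names),
        covariance=covar_nat,
        converged=converged,
        identifiable=identifiable,
        n_evals=n_evals,
        meta={"fixed": fixed, "enzyme": family.enzyme_name},
    )


def curve_r(fit: FitResult, family: CurveFamily) -> np.ndarray:
    """Per-curve Pearson correlation between observed and fitted signals.

    A constant observed curve has no defined correlation and yields NaN.
    """
    model = _simulate_family(fit.scheme, fit.best_params, family)
    rs = np.empty(family.n_curves)
    for i in range(family.n_curves):
        o, m = family.signals[i], model[i]
        if np.ptp(o) == 0.0 or np.ptp(m) == 0.0:
            rs[i] = np.nan
        else:
            rs[i] = float(np.corrcoef(o, m)[0, 1])
    return rs
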
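"""Model discrimination and derived inhibition constants.

Competing binding schemes fitted to the same progress-curve family are
discriminated by small-sample-corrected Akaike information (AICc) weights
together with the variance-ratio (F) test for the nested pair.  The selected
scheme's rate constants are then converted to the quantities practitioners
quote: the equilibrium dissociation constant ``Ki = k_off/k_on`` with its
error propagated from the coefficients of variation of the two rates,
``cv(Ki) = sqrt(cv(k_on)^2 + cv(k_off)^2)``, and association/dissociation
half-lives ``t1/2(on) = ln2/(k_on*[I])`` at a reference inhibitor
concentration (default 1 uM) and ``t1/2(off) = ln2/k_off`` (reported in
minutes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import RateConstantSet, ValueWithError
from .kinetic_models import CurveFamily, InvalidStateError, SchemeId
from .progress_fit import FitResult, fit_family

__all__ = [
    "ModelComparison",
    "InhibitionSummary",
    "akaike_compare",
    "variance_ratio_test",
    "ki_with_error",
    "half_lives",
    "selectivity_ratios",
    "summary_from_rates",
    "analyze_family",
    "summary_table",
]

LN2 = math.log(2.0)
DEFAULT_REFERENCE_I = 1e-6  # 1 uM, the conventional reporting concentration


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample corrected Akaike information criterion for LS fits."""
    if n - p - 1 <= 0:
        raise InvalidStateError("AICc undefined: n - p - 1 must be > 0")
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


@dataclass
class ModelComparison:
    """Per-scheme AICc/weights plus the nested-pair F test."""

    schemes: list[SchemeId]
    aicc_values: dict[SchemeId, float]
    akaike_weights: dict[SchemeId, float]
    f_statistic: float | None
    f_dof: tuple[int, int] | None
    p_value: float | None
    selected: SchemeId

    def to_dict(self) -> dict:
        return {
            "schemes": [s.value for s in self.schemes],
            "aicc": {s.value: v for s, v in self.aicc_values.items()},
            "akaike_weights": {s.value: v for s, v in self.akaike_weights.items()},
            "f_statistic": self.f_statistic,
            "f_dof": list(self.f_dof) if self.f_dof else None,
            "p_value": self.p_value,
            "selected": self.selected.value,
        }


def akaike_compare(fits: list[FitResult]) -> ModelComparison:
    """Compare scheme fits on one data set by AICc weight (and F test).

    The selection rule favours parsimony: the more complex scheme is
    selected only when its Akaike weight exceeds 0.5 *and* (for a nested
    pair) the F test rejects the simpler scheme at alpha = 0.05.
    """
    if len(fits) < 2:
        raise InvalidStateError("need >= 2 fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise InvalidStateError(f"fits have mismatched n_obs: {sorted(n_obs)}")

    aicc_values = {f.scheme: aicc(f.rss, f.n_obs, f.n_params) for f in fits}
    a = np.array([aicc_values[f.scheme] for f in fits])
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    weights = {f.scheme: float(wi) for f, wi in zip(fits, w)}

    # Parsimony-first selection: walk schemes from fewest to most free
    # parameters and accept a more complex scheme only when its Akaike
    # weight exceeds 0.5 and the nested F test rejects the current choice.
    by_p = sorted(fits, key=lambda f: f.n_params)
    current = by_p[0]
    f_stat = f_dof = p_value = None
    for candidate in by_p[1:]:
        if candidate.n_params == current.n_params:
            if aicc_values[candidate.scheme] < aicc_values[current.scheme]:
                current = candidate
            continue
        f_stat, f_dof, p_value = variance_ratio_test(current, candidate)
        if weights[candidate.scheme] > 0.5 and p_value < 0.05:
            current = candidate
    selected = current.scheme
    return ModelComparison(
        schemes=[f.scheme for f in fits],
        aicc_values=aicc_values,
        akaike_weights=weights,
        f_statistic=f_stat,
        f_dof=f_dof,
        p_value=p_value,
        selected=selected,
    )


def variance_ratio_test(
    fit_simple: FitResult, fit_complex: FitResult
) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F test for a nested pair of LS fits.

    ``F = ((rss1 - rss2)/(p2 - p1)) / (rss2/(n - p2))``; a complex fit that
    is worse than the simple one clamps F at 0 (with a warning) rather than
    reporting a negative statistic.
    """
    if fit_simple.n_obs != fit_complex.n_obs:
        raise InvalidStateError("fits must be on the same data (same n_obs)")
    if fit_complex.n_params <= fit_simple.n_params:
        raise InvalidStateError("fit_complex must have more free parameters")
    n = fit_simple.n_obs
    p1, p2 = fit_simple.n_params, fit_complex.n_params
    df = (p2 - p1, n - p2)
    num = (fit_simple.rss - fit_complex.rss) / df[0]
    den = fit_complex.rss / df[1]
    f_stat = num / den
    if f_stat < 0:
        warnings.warn(
            "complex fit has larger rss than the nested simple fit; F clamped at 0",
            stacklevel=2,
        )
        f_stat = 0.0
    p_value = float(stats.f.sf(f_stat, *df))
    return float(f_stat), df, p_value


def ki_with_error(k_on: ValueWithError, k_off: ValueWithError) -> ValueWithError:
    """``Ki = k_off/k_on`` with error from summed squared CVs."""
    if k_on.value <= 0:
        raise InvalidStateError("k_on must be > 0")
    if k_off.value == 0:
        return ValueWithError(0.0, 0.0)
    ki = k_off.value / k_on.value
    cv = math.sqrt(k_on.cv**2 + k_off.cv**2)
    return ValueWithError(ki, ki * cv)


def half_lives(
    k_on: float, k_off: float | None, reference_I: float = DEFAULT_REFERENCE_I
) -> tuple[float, float | None]:
    """(association half-life in s at ``reference_I``, dissociation half-life
    in minutes; ``None`` when dissociation is unmeasurable/zero)."""
    if reference_I <= 0:
        raise InvalidStateError("reference inhibitor concentration must be > 0")
    if k_on <= 0:
        raise InvalidStateError("k_on must be > 0")
    t_on = LN2 / (k_on * reference_I)
    t_off = None if not k_off else LN2 / k_off / 60.0
    return t_on, t_off


@dataclass
class InhibitionSummary:
    """One inhibitor/enzyme row of a kinetic-constants report."""

    inhibitor: str
    enzyme: str
    K_i: ValueWithError  # M
    k_on: ValueWithError  # M^-1 s^-1
    k_off: ValueWithError | None  # s^-1; None when irreversible
    t_half_on: float  # s at reference_I
    t_half_off: float | None  # min
    reference_I: float = DEFAULT_REFERENCE_I

    @property
    def irreversible(self) -> bool:
        return self.k_off is None

    def to_dict(self) -> dict:
        return {
            "inhibitor": self.inhibitor,
            "enzyme": self.enzyme,
            "Ki_nM": self.K_i.value * 1e9,
            "Ki_se_nM": self.K_i.se * 1e9,
            "k_on_per_M_s": self.k_on.value,
            "k_on_se": self.k_on.se,
            "k_off_per_s": None if self.k_off is None else self.k_off.value,
            "k_off_se": None if self.k_off is None else self.k_off.se,
            "t_half_on_s": self.t_half_on,
            "t_half_off_min": self.t_half_off,
            "reference_I_M": self.reference_I,
        }


def summary_from_rates(
    rates: RateConstantSet, reference_I: float = DEFAULT_REFERENCE_I
) -> InhibitionSummary:
    """Derived constants from a measured (k_on, k_off) pair.

    For an apparently irreversible pair (no measurable ``k_off``) the
    literature ``Ki`` is carried through with zero error and no
    dissociation half-life.
    """
    if rates.irreversible:
        ki = ValueWithError(rates.ki_literature_M or 0.0, 0.0)
        t_on, _ = half_lives(rates.k_on.value, None, reference_I)
        return InhibitionSummary(
            rates.inhibitor, rates.enzyme, ki, rates.k_on, None, t_on, None,
            reference_I,
        )
    ki = ki_with_error(rates.k_on, rates.k_off)
    t_on, t_off = half_lives(rates.k_on.value, rates.k_off.value, reference_I)
    return InhibitionSummary(
        rates.inhibitor, rates.enzyme, ki, rates.k_on, rates.k_off, t_on,
        t_off, reference_I,
    )


def summary_from_fit(
    fit: FitResult,
    inhibitor: str,
    enzyme: str,
    reference_I: float = DEFAULT_REFERENCE_I,
) -> InhibitionSummary:
    """Derived constants from a converged global fit."""
    k_on = fit.estimates["k_on"]
    k_off = fit.estimates.get("k_off")
    rates = RateConstantSet(inhibitor, enzyme, k_on=k_on, k_off=k_off)
    return summary_from_rates(rates, reference_I)


def selectivity_ratios(
    summaries: list[InhibitionSummary], on: str = "K_i"
) -> pd.DataFrame:
    """All pairwise fold ratios between inhibitor/enzyme pairs.

    ``on`` selects the compared quantity: ``K_i`` (default) or
    ``t_half_off``.  Ratios against an irreversible comparator (zero or
    missing denominator) are flagged infinite.
    """
    if len(summaries) < 2:
        raise InvalidStateError("need >= 2 summaries")

    def value(s: InhibitionSummary) -> float | None:
        if on == "K_i":
            return s.K_i.value
        if on == "t_half_off":
            return s.t_half_off
        raise InvalidStateError(f"unknown ratio quantity {on!r}")

    rows = []
    for a in summaries:
        for b in summaries:
            if a is b:
                continue
            va, vb = value(a), value(b)
            if va is None:
                continue
            ratio = math.inf if not vb else va / vb
            rows.append(
                {
                    "numerator": f"{a.inhibitor}/{a.enzyme}",
                    "denominator": f"{b.inhibitor}/{b.enzyme}",
                    "quantity": on,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def summary_table(summaries: list[InhibitionSummary]) -> pd.DataFrame:
    """Report table: one column per inhibitor/enzyme pair, rows Ki, k_on,
    k_off and the two half-lives (the layout practitioners expect)."""
    cols = {}
    for s in summaries:
        cols[f"{s.inhibitor}/{s.enzyme}"] = {
            "Ki_nM": s.K_i.value * 1e9,
            "Ki_se_nM": s.K_i.se * 1e9,
            "k_on_per_M_s": s.k_on.value,
            "k_on_se": s.k_on.se,
            "k_off_per_s": np.nan if s.k_off is None else s.k_off.value,
            "k_off_se": np.nan if s.k_off is None else s.k_off.se,
            "t_half_on_s": s.t_half_on,
            "t_half_off_min": np.nan if s.t_half_off is None else s.t_half_off,
        }
    return pd.DataFrame(cols)


def analyze_family(
    family: CurveFamily,
    schemes: list[SchemeId | str] = (SchemeId.ONE_STEP, SchemeId.TWO_STEP),
    fixed: dict[str, float] | None = None,
    reference_I: float = DEFAULT_REFERENCE_I,
    inhibitor: str = "inhibitor",
    **fit_kwargs,
) -> tuple[dict[SchemeId, FitResult], ModelComparison, InhibitionSummary]:
    """Fit the candidate schemes, discriminate, and summarize the winner.

    When the selected reversible fit leaves ``k_off`` essentially
    undetermined (cv > 100%), the family is automatically refit under the
    irreversible scheme (``k_off = 0``) and the comparison redone including
    it — the standard rescue for apparently irreversible inhibitors.
    """
    # Fit simple -> complex, warm-starting each scheme from the previous
    # solution (nested schemes share the rate constants, so the simpler
    # optimum is an excellent starting point for the richer scheme).
    order = {SchemeId.IRREVERSIBLE: 0, SchemeId.ONE_STEP: 1, SchemeId.TWO_STEP: 2}
    fits: dict[SchemeId, FitResult] = {}
    warm: dict[str, float] = {}
    for s in sorted((SchemeId.coerce(s) for s in schemes), key=order.get):
        kwargs = dict(fit_kwargs)
        if warm:
            kwargs.setdefault("init", dict(warm))
            kwargs.setdefault("n_starts", 1)
        fits[s] = fit_family(family, s, fixed=fixed, **kwargs)
        warm.update({k: v.value for k, v in fits[s].estimates.items()})

    comparison = akaike_compare(list(fits.values()))
    selected = fits[comparison.selected]

    k_off = selected.estimates.get("k_off")
    if k_off is not None and (not math.isfinite(k_off.cv) or k_off.cv > 1.0):
        irr = fit_family(
            family, SchemeId.IRREVERSIBLE, fixed=fixed, **fit_kwargs
        )
        fits[SchemeId.IRREVERSIBLE] = irr
        comparison = akaike_compare(list(fits.values()))
        selected = fits[comparison.selected]

    summary = summary_from_fit(
        selected, inhibitor, family.enzyme_name, reference_I
    )
    return fits, comparison, summary
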
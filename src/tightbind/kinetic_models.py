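"""Reaction schemes and deterministic dynamics for slow/tight-binding inhibition.

Progress-curve assays of tight-binding protease inhibitors (Kunitz/BPTI-type
inhibitors against plasmin, plasma kallikrein, trypsin) operate at inhibitor
concentrations comparable to the enzyme concentration, so the free-inhibitor
pool is depleted and the classical steady-state rate laws do not apply.  The
species balance must instead be integrated numerically.  This module defines
the competing binding schemes, their ODE right-hand sides, a stiff-capable
progress-curve simulator, and two closed-form limits used as oracles:

* ``kobs_one_step`` — the apparent first-order approach rate of the
  competitive slow-binding limit (valid when the inhibitor is in large
  excess over the enzyme so its depletion is negligible), and
* ``morrison_walsh_curve`` — the classical biphasic progress curve
  ``P(t) = vs*t + (v0 - vs)*(1 - exp(-kobs*t))/kobs``.

Schemes
-------
``one_step``      E + I <-> EI, association ``k_on`` (M^-1 s^-1) and
                  dissociation ``k_off`` (s^-1).
``two_step``      E + I <-> EI <-> EI*, the initial encounter complex
                  isomerizing to a tightened complex with first-order rates
                  ``k_isom_f`` / ``k_isom_r``.
``irreversible``  one_step with ``k_off`` fixed at zero.

Substrate turnover is competitive Michaelis-Menten on the free enzyme:
``dP/dt = k_cat * E_free * S / (K_m + S)``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SchemeId",
    "RateParameters",
    "AssayConditions",
    "AssayState",
    "ProgressCurve",
    "CurveFamily",
    "InvalidStateError",
    "SimulationError",
    "scheme_rhs",
    "simulate_progress",
    "kobs_one_step",
    "morrison_walsh_curve",
]

#: Relative tolerance of the stiff integrator (nanomolar species with
#: second-order association terms make the system stiff).
ODE_RTOL = 1e-8
#: Absolute tolerance, in molar.
ODE_ATOL = 1e-12


class InvalidStateError(ValueError):
    """A concentration or parameter violates its physical constraints."""


class SimulationError(RuntimeError):
    """The ODE integrator failed; carries the solver diagnostic message."""


class SchemeId(str, enum.Enum):
    """Identifier of a binding scheme."""

    ONE_STEP = "one_step"
    TWO_STEP = "two_step"
    IRREVERSIBLE = "irreversible"

    @classmethod
    def coerce(cls, value: "SchemeId | str") -> "SchemeId":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise InvalidStateError(
                f"unknown scheme {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of a binding scheme plus substrate-turnover constants.

    Parameters
    ----------
    k_on : float
        Second-order association rate constant (M^-1 s^-1).
    k_off : float
        First-order dissociation rate constant (s^-1).
    k_isom_f, k_isom_r : float
        Forward/reverse isomerization rates (s^-1); used only by the
        two-step scheme.
    k_cat : float
        Substrate turnover number (s^-1).
    K_m : float
        Michaelis constant of the chromogenic substrate (M).

    The substrate constants are assay configuration, not fit targets: the
    chromogenic substrates (S-2251, S-2765, S-2302) have unpublished kinetic
    constants for these enzyme preparations, so documented defaults are used
    and all excess-substrate analyses are insensitive to them.
    """

    k_on: float
    k_off: float
    k_isom_f: float = 0.0
    k_isom_r: float = 0.0
    k_cat: float = 10.0
    K_m: float = 200e-6

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_isom_f", "k_isom_r", "k_cat"):
            if getattr(self, name) < 0:
                raise InvalidStateError(f"{name} must be >= 0")
        if self.K_m <= 0:
            raise InvalidStateError("K_m must be > 0")

    def for_scheme(self, scheme: SchemeId | str) -> "RateParameters":
        """Return a copy with the constraints of *scheme* applied.

        The irreversible scheme forces ``k_off = 0``; the one-step scheme
        zeroes the isomerization rates.  The two-step scheme requires a
        strictly positive reverse isomerization rate (otherwise the tightened
        complex is an absorbing state and the scheme degenerates to an
        irreversible trap).
        """
        scheme = SchemeId.coerce(scheme)
        if scheme is SchemeId.IRREVERSIBLE:
            return replace(self, k_off=0.0, k_isom_f=0.0, k_isom_r=0.0)
        if scheme is SchemeId.ONE_STEP:
            return replace(self, k_isom_f=0.0, k_isom_r=0.0)
        if self.k_isom_r <= 0:
            raise InvalidStateError("two_step requires k_isom_r > 0")
        return self


@dataclass(frozen=True)
class AssayConditions:
    """One progress-curve condition: concentrations, signal model, time grid.

    ``signal = baseline + signal_coeff * P`` with ``signal_coeff`` in signal
    units per molar product; the default of 1 reports product concentration
    directly.
    """

    E_total: float
    I_total: float
    S_0: float
    times: np.ndarray
    signal_coeff: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if min(self.E_total, self.I_total, self.S_0) < 0:
            raise InvalidStateError("concentrations must be >= 0")
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise InvalidStateError("times must be a 1-D grid of >= 2 points")
        if times[0] != 0.0:
            raise InvalidStateError("times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise InvalidStateError("times must be strictly increasing")
        object.__setattr__(self, "times", times)


@dataclass(frozen=True)
class AssayState:
    """Species concentrations (M) at one instant."""

    E_free: float
    I_free: float
    EI: float
    EI_star: float
    S: float
    P: float

    def __post_init__(self) -> None:
        for name in ("E_free", "I_free", "EI", "EI_star", "S", "P"):
            if getattr(self, name) < 0:
                raise InvalidStateError(f"{name} must be >= 0")

    @property
    def E_total(self) -> float:
        return self.E_free + self.EI + self.EI_star

    @property
    def I_total(self) -> float:
        return self.I_free + self.EI + self.EI_star


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives of an :class:`AssayState` (M/s)."""

    dE_free: float
    dI_free: float
    dEI: float
    dEI_star: float
    dS: float
    dP: float


def scheme_rhs(
    scheme: SchemeId | str, params: RateParameters, state: AssayState
) -> StateDerivative:
    """Time derivatives of all species under *scheme*.

    All three schemes share one algebraic form — the one-step and
    irreversible schemes are the two-step scheme with the appropriate rates
    pinned to zero — so nested schemes produce bit-identical derivatives on
    identical states.  Mass is conserved exactly: ``dE_free + dEI + dEI_star
    = 0``, likewise for the inhibitor total, and ``dS + dP = 0``.
    """
    p = params.for_scheme(scheme)
    # Competitive QSSA: of the enzyme not bound by inhibitor, only the
    # substrate-free fraction K_m/(K_m + S) is available for association,
    # which is what produces the substrate-protection factor in kobs.
    bind = p.k_on * state.E_free * state.I_free / (1.0 + state.S / p.K_m)
    unbind = p.k_off * state.EI
    isom_f = p.k_isom_f * state.EI
    isom_r = p.k_isom_r * state.EI_star
    turnover = p.k_cat * state.E_free * state.S / (p.K_m + state.S)
    dEI = bind - unbind - isom_f + isom_r
    dEI_star = isom_f - isom_r
    return StateDerivative(
        dE_free=-(dEI + dEI_star),
        dI_free=-(dEI + dEI_star),
        dEI=dEI,
        dEI_star=dEI_star,
        dS=-turnover,
        dP=turnover,
    )


@dataclass(frozen=True)
class ProgressCurve:
    """A simulated or measured progress curve.

    Simulated curves carry the bound-complex trajectories so the
    conservation laws can be audited; measured curves leave them ``None``.
    """

    times: np.ndarray
    product: np.ndarray  # molar product concentration
    signal: np.ndarray  # baseline + signal_coeff * product
    EI: np.ndarray | None = None
    EI_star: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "signal": self.signal})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, signal_coeff: float = 1.0,
                 baseline: float = 0.0) -> "ProgressCurve":
        frame = pd.read_csv(path)
        times = frame["time_s"].to_numpy(dtype=float)
        signal = frame["signal"].to_numpy(dtype=float)
        product = (signal - baseline) / signal_coeff
        return cls(times=times, product=product, signal=signal)


def simulate_progress(
    scheme: SchemeId | str,
    params: RateParameters,
    cond: AssayConditions,
) -> ProgressCurve:
    """Integrate a progress curve with a stiff implicit method (LSODA).

    The integrated state is the reduced vector ``(EI, EI*, P)``; the free
    species are recovered from the conservation laws, so the totals are
    conserved to machine precision at every output time.
    """
    p = params.for_scheme(scheme)
    E_tot, I_tot, S0 = cond.E_total, cond.I_total, cond.S_0
    k_on, k_off = p.k_on, p.k_off
    k_f, k_r = p.k_isom_f, p.k_isom_r
    k_cat, K_m = p.k_cat, p.K_m

    # With k_isom_f = 0 the tightened complex is never populated, so the
    # EI* equation is dropped: nested schemes then integrate the identical
    # reduced system and their trajectories agree bit-for-bit.
    two_state = k_f == 0.0

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        if two_state:
            ei, prod = y
            ei_star = 0.0
        else:
            ei, ei_star, prod = y
        e_free = E_tot - ei - ei_star
        i_free = I_tot - ei - ei_star
        s = S0 - prod
        d_ei = (
            k_on * e_free * i_free / (1.0 + s / K_m)
            - k_off * ei - k_f * ei + k_r * ei_star
        )
        d_p = k_cat * e_free * s / (K_m + s)
        if two_state:
            return [d_ei, d_p]
        return [d_ei, k_f * ei - k_r * ei_star, d_p]

    sol = solve_ivp(
        rhs,
        (cond.times[0], cond.times[-1]),
        [0.0, 0.0] if two_state else [0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=cond.times,
        rtol=ODE_RTOL,
        atol=ODE_ATOL,
    )
    if not sol.success:
        raise SimulationError(
            f"integrator failed for scheme={SchemeId.coerce(scheme).value}, "
            f"E={E_tot:g} M, I={I_tot:g} M: {sol.message}"
        )
    if two_state:
        product = sol.y[1]
        ei_traj = sol.y[0]
        ei_star_traj = np.zeros_like(product)
    else:
        product = sol.y[2]
        ei_traj = sol.y[0]
        ei_star_traj = sol.y[1]
    # Clamp float-level dips so the non-decreasing contract holds exactly.
    product = np.maximum.accumulate(np.maximum(product, 0.0))
    signal = cond.baseline + cond.signal_coeff * product
    return ProgressCurve(
        times=cond.times.copy(),
        product=product,
        signal=signal,
        EI=ei_traj,
        EI_star=ei_star_traj,
    )


def kobs_one_step(params: RateParameters, I: float, S: float) -> float:
    """Apparent first-order approach rate of the competitive one-step limit.

    ``kobs = k_off + k_on * I / (1 + S/K_m)`` — valid when the inhibitor is
    in sufficient excess over the enzyme that its depletion is negligible.
    The substrate term expresses substrate protection of the active site.
    """
    if I < 0 or S < 0:
        raise InvalidStateError("I and S must be >= 0")
    return params.k_off + params.k_on * I / (1.0 + S / params.K_m)


def morrison_walsh_curve(
    v0: float, vs: float, k_obs: float, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Closed-form biphasic slow-binding progress curve.

    ``P(t) = vs*t + (v0 - vs) * (1 - exp(-k_obs*t)) / k_obs`` with initial
    velocity ``v0`` and steady-state velocity ``vs``.  For ``k_obs = 0`` the
    limit form ``v0*t`` is returned.
    """
    t = np.asarray(times, dtype=float)
    if k_obs < 0:
        raise InvalidStateError("k_obs must be >= 0")
    if k_obs == 0.0:
        return v0 * t
    return vs * t + (v0 - vs) * (1.0 - np.exp(-k_obs * t)) / k_obs


@dataclass
class CurveFamily:
    """Progress curves sharing enzyme/substrate conditions, one per inhibitor
    concentration.

    ``signals`` is an ``(n_curves, n_times)`` array aligned with
    ``inhibitor_concs``.
    """

    enzyme_name: str
    E_total: float
    S_0: float
    inhibitor_concs: np.ndarray
    times: np.ndarray
    signals: np.ndarray
    signal_coeff: float = 1.0
    baseline: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inhibitor_concs = np.asarray(self.inhibitor_concs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (self.inhibitor_concs.size, self.times.size):
            raise InvalidStateError(
                "signals must have shape (n_inhibitor_concs, n_times); got "
                f"{self.signals.shape}"
            )

    @property
    def n_curves(self) -> int:
        return int(self.inhibitor_concs.size)

    def conditions(self, index: int) -> AssayConditions:
        return AssayConditions(
            E_total=self.E_total,
            I_total=float(self.inhibitor_concs[index]),
            S_0=self.S_0,
            times=self.times,
            signal_coeff=self.signal_coeff,
            baseline=self.baseline,
        )

    def write(self, directory: str | Path) -> Path:
        """Write one CSV per curve plus a JSON manifest; return manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, conc in enumerate(self.inhibitor_concs):
            name = f"curve_{i:02d}.csv"
            pd.DataFrame(
                {"time_s": self.times, "signal": self.signals[i]}
            ).to_csv(directory / name, index=False)
            entries.append({"inhibitor_conc_M": float(conc), "path": name})
        manifest = {
            "enzyme_name": self.enzyme_name,
            "E_total_M": self.E_total,
            "S_0_M": self.S_0,
            "signal_coeff": self.signal_coeff,
            "baseline": self.baseline,
            "curves": entries,
            "meta": self.meta,
        }
        manifest_path = directory / "family.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest_path

    @classmethod
    def read(cls, manifest_path: str | Path) -> "CurveFamily":
        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        concs, signals = [], []
        times = None
        for entry in manifest["curves"]:
            frame = pd.read_csv(manifest_path.parent / entry["path"])
            t = frame["time_s"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif not np.array_equal(times, t):
                raise InvalidStateError(
                    f"curve {entry['path']} has a different time grid"
                )
            concs.append(entry["inhibitor_conc_M"])
            signals.append(frame["signal"].to_numpy(dtype=float))
        return cls(
            enzyme_name=manifest["enzyme_name"],
            E_total=manifest["E_total_M"],
            S_0=manifest["S_0_M"],
            inhibitor_concs=np.asarray(concs),
            times=times,
            signals=np.asarray(signals),
            signal_coeff=manifest.get("signal_coeff", 1.0),
            baseline=manifest.get("baseline", 0.0),
            meta=manifest.get("meta", {}),
        )
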
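"""Reference kinetic constants for the two Kunitz-type inhibitors.

Measured association/dissociation rate constants for textilinin-1 (a
Kunitz-type inhibitor from *Pseudonaja textilis* venom) and aprotinin (BPTI)
against human plasmin, human plasma kallikrein and bovine trypsin.  These
serve as the ground-truth parameter sets for the synthetic progress-curve
generator and as inputs to the derived-constant arithmetic (Ki, half-lives,
selectivity ratios).

Aprotinin inhibits trypsin apparently irreversibly on the assay timescale:
its dissociation rate is not measurable (``k_off`` is ``None``) and its
equilibrium constant is the literature value ``6e-5`` nM rather than a
``k_off/k_on`` ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ValueWithError", "RateConstantSet", "KINETIC_CONSTANTS"]


@dataclass(frozen=True)
class ValueWithError:
    """A measured value with its standard error (same units)."""

    value: float
    se: float

    @property
    def cv(self) -> float:
        """Coefficient of variation (se/value)."""
        return self.se / self.value


@dataclass(frozen=True)
class RateConstantSet:
    """Measured rate constants for one inhibitor/enzyme pair."""

    inhibitor: str
    enzyme: str
    k_on: ValueWithError  # M^-1 s^-1
    k_off: ValueWithError | None  # s^-1; None if apparently irreversible
    ki_literature_M: float | None = None  # used when k_off is unmeasurable

    @property
    def irreversible(self) -> bool:
        return self.k_off is None


KINETIC_CONSTANTS: dict[tuple[str, str], RateConstantSet] = {
    ("textilinin-1", "plasmin"): RateConstantSet(
        "textilinin-1", "plasmin",
        k_on=ValueWithError(1.72e6, 0.02e6),
        k_off=ValueWithError(7.50e-4, 0.11e-4),
    ),
    ("textilinin-1", "kallikrein"): RateConstantSet(
        "textilinin-1", "kallikrein",
        k_on=ValueWithError(1.26e4, 0.43e4),
        k_off=ValueWithError(2.35e-2, 0.18e-2),
    ),
    ("textilinin-1", "trypsin"): RateConstantSet(
        "textilinin-1", "trypsin",
        k_on=ValueWithError(8.60e5, 0.44e5),
        k_off=ValueWithError(3.60e-4, 0.51e-4),
    ),
    ("aprotinin", "plasmin"): RateConstantSet(
        "aprotinin", "plasmin",
        k_on=ValueWithError(2.45e6, 0.04e6),
        k_off=ValueWithError(2.39e-5, 0.25e-5),
    ),
    ("aprotinin", "kallikrein"): RateConstantSet(
        "aprotinin", "kallikrein",
        k_on=ValueWithError(3.03e4, 0.17e4),
        k_off=ValueWithError(5.76e-4, 0.60e-4),
    ),
    ("aprotinin", "trypsin"): RateConstantSet(
        "aprotinin", "trypsin",
        k_on=ValueWithError(4.13e2, 0.06e2),
        k_off=None,
        ki_literature_M=6e-14,  # 6e-5 nM
    ),
}
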
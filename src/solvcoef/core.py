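"""Abraham general solvation model: domain types and LFER arithmetic.

The Abraham model is a linear free-energy relationship (LFER) that writes the
base-10 logarithm of a solvent/water partition coefficient as a dot product of
five solvent coefficients with five solute descriptors plus an intercept::

    log P = c + e*E + s*S + a*A + b*B + v*V

and, under the same coefficients, transfers aqueous solubility into the organic
solvent::

    log Ss = log Sw + c + e*E + s*S + a*A + b*B + v*V

Both logarithms are base 10 and concentrations are molar.  The solute
descriptors are E (excess molar refractivity, (cm^3/mol)/10), S
(dipolarity/polarizability), A and B (summation hydrogen-bond acidity and
basicity) and V (McGowan characteristic volume, (cm^3/mol)/100).

Solvent coefficient rows come in two conventions: ``original`` (the published
regression with a floating intercept c) and ``zero_intercept`` (refit with
c constrained to 0 so solvents are directly comparable; see
:mod:`solvcoef.recalibration`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ORIGINAL",
    "ZERO_INTERCEPT",
    "COEFF_KEYS",
    "DESCRIPTOR_KEYS",
    "SoluteDescriptors",
    "SolventCoefficients",
    "DescriptorAverages",
    "DEFAULT_AVERAGES",
    "eval_logp",
    "eval_solubility",
]

from .errors import InvalidInputError

#: Convention tags for solvent coefficient rows.
ORIGINAL = "original"
ZERO_INTERCEPT = "zero_intercept"

#: Canonical order of the five LFER weights / descriptors.
COEFF_KEYS = ("e", "s", "a", "b", "v")
DESCRIPTOR_KEYS = ("E", "S", "A", "B", "V")


def _require_finite(owner: str, name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{owner}: field {name!r} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SoluteDescriptors:
    """Abraham solute descriptors (E, S, A, B, V) for one compound."""

    E: float
    S: float
    A: float
    B: float
    V: float
    name: str = ""

    def __post_init__(self) -> None:
        for key in DESCRIPTOR_KEYS:
            object.__setattr__(self, key, _require_finite("SoluteDescriptors", key, getattr(self, key)))
        if self.A < 0 or self.B < 0:
            raise InvalidInputError(
                f"SoluteDescriptors {self.name!r}: A and B are summation H-bond "
                f"strengths and cannot be negative (A={self.A}, B={self.B})"
            )
        if self.V <= 0:
            raise InvalidInputError(
                f"SoluteDescriptors {self.name!r}: McGowan volume V must be positive, got {self.V}"
            )

    def as_array(self) -> np.ndarray:
        """The descriptors as a length-5 array in (E, S, A, B, V) order."""
        return np.array([self.E, self.S, self.A, self.B, self.V], dtype=float)


@dataclass(frozen=True)
class SolventCoefficients:
    """One solvent's LFER weights.

    ``c`` may be ``None`` for zero-intercept rows, where the intercept is zero
    by construction.  ``name`` is kept verbatim (trimmed); matching elsewhere
    in the package is case-insensitive via :attr:`key`.  Mixture names such as
    ``ethanol/water(50:50)vol`` are opaque identifiers.
    """

    name: str
    e: float
    s: float
    a: float
    b: float
    v: float
    c: float | None = None
    convention: str = ORIGINAL
    provenance: str = "measured"

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", str(self.name).strip())
        for key in COEFF_KEYS:
            object.__setattr__(self, key, _require_finite(f"SolventCoefficients {self.name!r}", key, getattr(self, key)))
        if self.convention not in (ORIGINAL, ZERO_INTERCEPT):
            raise InvalidInputError(
                f"SolventCoefficients {self.name!r}: unknown convention {self.convention!r}"
            )
        if self.c is not None:
            object.__setattr__(self, "c", _require_finite(f"SolventCoefficients {self.name!r}", "c", self.c))
        if self.convention == ZERO_INTERCEPT and self.c not in (None, 0.0):
            raise InvalidInputError(
                f"SolventCoefficients {self.name!r}: zero_intercept rows must have c absent or 0, got c={self.c}"
            )

    @property
    def key(self) -> str:
        """Case-insensitive matching key."""
        return self.name.strip().lower()

    @property
    def intercept(self) -> float:
        """The intercept c, with an absent c evaluated as exactly 0."""
        return 0.0 if self.c is None else self.c

    def as_array(self) -> np.ndarray:
        """The five weights as an array in (e, s, a, b, v) order (no intercept)."""
        return np.array([self.e, self.s, self.a, self.b, self.v], dtype=float)


@dataclass(frozen=True)
class DescriptorAverages:
    """Population-mean solute descriptors used as weights in shift/RMSE scaling,
    the adjusted model error D, and the general replacement distance d.

    Defaults are the means of the 2144-compound open descriptor database the
    zero-intercept recalibration was built on.
    """

    E: float = 0.884
    S: float = 1.002
    A: float = 0.173
    B: float = 0.486
    V: float = 1.308

    def __post_init__(self) -> None:
        for key in DESCRIPTOR_KEYS:
            object.__setattr__(self, key, _require_finite("DescriptorAverages", key, getattr(self, key)))

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.S, self.A, self.B, self.V], dtype=float)

    def as_solute(self, name: str = "average solute") -> SoluteDescriptors:
        """The averages viewed as a (virtual) solute."""
        return SoluteDescriptors(self.E, self.S, self.A, self.B, self.V, name=name)

    def weight_for(self, coeff: str) -> float:
        """The average descriptor paired with LFER weight ``coeff`` (e->E, ..., v->V)."""
        return float(getattr(self, coeff.upper()[0]))


DEFAULT_AVERAGES = DescriptorAverages()


def eval_logp(coeffs: SolventCoefficients, solute: SoluteDescriptors) -> float:
    """Solvent/water partition coefficient log10 P for ``solute`` in ``coeffs``.

    Molarity standard state; an absent intercept is evaluated as 0 so the same
    evaluator serves both conventions.
    """
    return float(coeffs.intercept + coeffs.as_array() @ solute.as_array())


def eval_solubility(
    coeffs: SolventCoefficients, solute: SoluteDescriptors, log_sw: float
) -> float:
    """log10 molar solubility in the solvent given log10 aqueous solubility ``log_sw``."""
    log_sw = _require_finite("eval_solubility", "log_sw", log_sw)
    return log_sw + eval_logp(coeffs, solute)
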
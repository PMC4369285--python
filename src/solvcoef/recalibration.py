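"""Zero-intercept recalibration of Abraham solvent coefficients.

To compare solvents directly, published coefficient rows (with a floating
intercept c) are refit with the intercept constrained to zero: log P is
evaluated with the original row for every compound in a solute population and
the values are regressed, without intercept, on the [E S A B V] design::

    log P = e0*E + s0*S + a0*A + b0*B + v0*V

Because the target vector is c + X @ w, ordinary least squares without an
intercept gives exactly::

    w0 = w + c * beta,      beta = (X'X)^{-1} X' 1

so the shift in each coefficient is proportional to the original intercept,
with a proportionality vector ``beta`` (the no-intercept regression of the
constant 1 on the descriptors) that depends only on the population.  Two
consequences used here:

* a row whose c is already 0 is returned unchanged for *any* full-rank
  population (exact-fit property), and
* within a published paired table, every row's shifts must line up on a single
  ``beta`` — rows that do not are internally inconsistent transcriptions and
  can be flagged (see :func:`flag_inconsistent_pairs`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    COEFF_KEYS,
    DEFAULT_AVERAGES,
    ORIGINAL,
    ZERO_INTERCEPT,
    DescriptorAverages,
    SoluteDescriptors,
    SolventCoefficients,
    eval_logp,
)
from .errors import DegeneratePopulationError, InvalidInputError
from .io import PAIRED_COLUMNS

__all__ = [
    "SolutePopulation",
    "ShiftReport",
    "recalibrate_solvent",
    "recalibrate_table",
    "sign_shift_check",
    "shift_report",
    "flag_inconsistent_pairs",
]

_MIN_ROWS = 5


@dataclass(frozen=True)
class SolutePopulation:
    """A table of solute descriptors used as the regression design.

    ``source`` labels provenance (``packaged-synthetic`` or ``user-supplied``).
    """

    frame: pd.DataFrame
    source: str = "user-supplied"

    def __post_init__(self) -> None:
        required = ["name", "E", "S", "A", "B", "V"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise InvalidInputError(f"solute population missing columns {missing}")
        if len(self.frame) == 0:
            raise InvalidInputError("solute population is empty")
        if len(self.frame) < _MIN_ROWS:
            raise DegeneratePopulationError(
                f"solute population needs >= {_MIN_ROWS} rows, got {len(self.frame)}"
            )
        X = self.design_matrix
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("solute population contains non-finite descriptor values")
        if np.linalg.matrix_rank(X) < 5:
            raise DegeneratePopulationError("[E S A B V] design matrix is rank deficient")

    @property
    def design_matrix(self) -> np.ndarray:
        """n x 5 array of (E, S, A, B, V) rows."""
        return self.frame[["E", "S", "A", "B", "V"]].to_numpy(dtype=float)

    @classmethod
    def from_descriptors(cls, rows: Sequence[SoluteDescriptors], source: str = "user-supplied") -> "SolutePopulation":
        frame = pd.DataFrame(
            [{"name": r.name, "E": r.E, "S": r.S, "A": r.A, "B": r.B, "V": r.V} for r in rows]
        )
        return cls(frame, source=source)

    def __len__(self) -> int:
        return len(self.frame)


def recalibrate_solvent(orig: SolventCoefficients, pop: SolutePopulation) -> SolventCoefficients:
    """Refit one solvent's coefficients with the intercept constrained to zero.

    Zero-intercept rows are returned unchanged (the map is idempotent).
    """
    if orig.convention == ZERO_INTERCEPT:
        return orig
    X = pop.design_matrix
    y = np.array([
        eval_logp(orig, SoluteDescriptors(*row, name=str(name)))
        for row, name in zip(X, pop.frame["name"])
    ])
    w0, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SolventCoefficients(
        orig.name, *map(float, w0), c=None, convention=ZERO_INTERCEPT, provenance=orig.provenance
    )


def recalibrate_table(
    table: Sequence[SolventCoefficients], pop: SolutePopulation
) -> pd.DataFrame:
    """Recalibrate a whole table row-wise into a paired original/zero-intercept frame.

    Order and names are preserved; a failing row's error is re-raised with the
    solvent name attached.
    """
    records = []
    for row in table:
        if row.convention != ORIGINAL:
            raise InvalidInputError(
                f"recalibrate_table: row {row.name!r} is already {row.convention}; expected original"
            )
        try:
            refit = recalibrate_solvent(row, pop)
        except (InvalidInputError, DegeneratePopulationError) as exc:
            raise type(exc)(f"solvent {row.name!r}: {exc}") from None
        records.append({
            "name": row.name, "c": row.intercept,
            **{k: getattr(row, k) for k in COEFF_KEYS},
            **{k + "0": getattr(refit, k) for k in COEFF_KEYS},
        })
    return pd.DataFrame(records, columns=PAIRED_COLUMNS)


def sign_shift_check(paired: pd.DataFrame, atol: float = 0.0) -> pd.DataFrame:
    """Check the systematic direction of coefficient shifts across a paired table.

    Solvents with c < 0 must see e and b increase and s, a, v decrease under
    the zero-intercept refit; solvents with c > 0 the mirror image; c = 0 rows
    are exempt.  Returns a frame with ``name``, ``c``, ``exempt`` and
    ``passed`` columns.  ``atol`` loosens the inequalities to absorb rounding
    of published tables.
    """
    if len(paired) == 0:
        raise InvalidInputError("sign_shift_check: empty paired table")
    up_when_c_negative = ("e", "b")
    records = []
    for _, r in paired.iterrows():
        c = float(r["c"])
        if c == 0.0:
            records.append({"name": r["name"], "c": c, "exempt": True, "passed": True})
            continue
        ok = True
        for k in COEFF_KEYS:
            delta = float(r[k + "0"]) - float(r[k])
            expected_up = (k in up_when_c_negative) == (c < 0)
            direction = 1.0 if expected_up else -1.0
            ok &= direction * delta >= -atol
        records.append({"name": r["name"], "c": c, "exempt": False, "passed": bool(ok)})
    return pd.DataFrame(records)


@dataclass(frozen=True)
class ShiftReport:
    """Average absolute coefficient shifts, scaled by the average solute descriptors."""

    aae: dict[str, float]
    scaled: dict[str, float]
    ranking: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.scaled.values()):
            raise InvalidInputError("scaled shifts must be nonnegative")
        if sorted(self.ranking) != sorted(COEFF_KEYS):
            raise InvalidInputError("ranking must be a permutation of (e, s, a, b, v)")


def shift_report(
    paired: pd.DataFrame, averages: DescriptorAverages = DEFAULT_AVERAGES
) -> ShiftReport:
    """Mean absolute original-vs-zero-intercept shift per coefficient, scaled by
    the matching average descriptor and ranked descending."""
    if len(paired) == 0:
        raise InvalidInputError("shift_report: empty paired table")
    aae = {
        k: float((paired[k + "0"] - paired[k]).abs().mean()) for k in COEFF_KEYS
    }
    scaled = {k: aae[k] * averages.weight_for(k) for k in COEFF_KEYS}
    ranking = tuple(sorted(COEFF_KEYS, key=lambda k: -scaled[k]))
    return ShiftReport(aae=aae, scaled=scaled, ranking=ranking)


def flag_inconsistent_pairs(paired: pd.DataFrame, tol: float = 0.05) -> pd.Series:
    """Flag rows of a paired table whose shifts break the shared Delta = c*beta law.

    For rows recalibrated against one common population, the per-coefficient
    shift is exactly c times a population constant.  ``beta`` is estimated per
    coefficient by no-intercept least squares of the shifts on c over the whole
    table; a row is inconsistent when any coefficient's residual exceeds
    ``tol`` (default 0.05 log units, generous against 3-decimal rounding).
    Returns a boolean Series aligned to ``paired`` (True = inconsistent).
    """
    if len(paired) == 0:
        raise InvalidInputError("flag_inconsistent_pairs: empty paired table")
    c = paired["c"].to_numpy(dtype=float)
    flags = np.zeros(len(paired), dtype=bool)
    denom = float(c @ c)
    for k in COEFF_KEYS:
        delta = (paired[k + "0"] - paired[k]).to_numpy(dtype=float)
        beta_k = float(c @ delta) / denom if denom > 0 else 0.0
        flags |= np.abs(delta - beta_k * c) > tol
    return pd.Series(flags, index=paired.index, name="inconsistent")
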
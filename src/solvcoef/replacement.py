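"""Solvent-replacement screening via the d-distance.

For two solvents in the zero-intercept convention, the difference in predicted
log P (equivalently log molar solubility) of a solute is::

    d = log P1 - log P2

Evaluated at the average solute descriptors this is a general solvent
similarity distance::

    d = (e01-e02)*E_ave + (s01-s02)*S_ave + (a01-a02)*A_ave
        + (b01-b02)*B_ave + (v01-v02)*V_ave

A small |d| means the two solvents are predicted to dissolve the solute (or
the average solute) almost equally well, making one a candidate replacement
for the other.  d is reported signed: d > 0 means the query solvent 1 is the
better solubilizer.  Toxicity, price, boiling point and reactivity are
deliberately outside the model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .core import (
    DEFAULT_AVERAGES,
    ZERO_INTERCEPT,
    DescriptorAverages,
    SoluteDescriptors,
    SolventCoefficients,
    eval_logp,
)
from .errors import ConventionError, InvalidInputError

__all__ = ["ReplacementHit", "general_distance", "solute_distance", "screen_replacements"]


def _require_zero_intercept(*rows: SolventCoefficients) -> None:
    for row in rows:
        if row.convention != ZERO_INTERCEPT:
            raise ConventionError(
                f"solvent {row.name!r} has convention {row.convention!r}; distances "
                "compare zero-intercept rows only (original-convention intercepts "
                "would silently enter the difference)"
            )


@dataclass(frozen=True)
class ReplacementHit:
    """One candidate from a replacement screen, sorted by |d| then name."""

    query: str
    candidate: str
    d: float
    mode: str  # "general" or "solute-specific"
    solute: str | None = None
    candidate_provenance: str = "measured"

    @property
    def abs_d(self) -> float:
        return abs(self.d)


def general_distance(
    s1: SolventCoefficients,
    s2: SolventCoefficients,
    averages: DescriptorAverages = DEFAULT_AVERAGES,
) -> float:
    """Signed d between two solvents at the average solute."""
    _require_zero_intercept(s1, s2)
    return float((s1.as_array() - s2.as_array()) @ averages.as_array())


def solute_distance(
    s1: SolventCoefficients, s2: SolventCoefficients, solute: SoluteDescriptors
) -> float:
    """Signed d between two solvents for one specific solute."""
    _require_zero_intercept(s1, s2)
    return eval_logp(s1, solute) - eval_logp(s2, solute)


def screen_replacements(
    query: SolventCoefficients,
    candidates: Sequence[SolventCoefficients],
    threshold: float,
    solute: SoluteDescriptors | None = None,
    averages: DescriptorAverages = DEFAULT_AVERAGES,
) -> list[ReplacementHit]:
    """All candidates within |d| <= threshold of the query, sorted ascending by |d|.

    The query itself is excluded by name (case-insensitive).  With ``solute``
    given the solute-specific distance is used, otherwise the general distance
    at ``averages``.  ``threshold`` must be positive; ``math.inf`` returns the
    whole ranked table.  The comparison is inclusive, so candidates sitting
    exactly on the cutoff are kept.
    """
    if not (threshold > 0):
        raise InvalidInputError(f"threshold must be > 0, got {threshold!r}")
    mode = "general" if solute is None else "solute-specific"
    hits: list[ReplacementHit] = []
    for cand in candidates:
        if cand.key == query.key:
            continue
        if solute is None:
            d = general_distance(query, cand, averages)
        else:
            d = solute_distance(query, cand, solute)
        if abs(d) <= threshold:
            hits.append(
                ReplacementHit(
                    query=query.name,
                    candidate=cand.name,
                    d=d,
                    mode=mode,
                    solute=None if solute is None else solute.name,
                    candidate_provenance=cand.provenance,
                )
            )
    hits.sort(key=lambda h: (h.abs_d, h.candidate.lower()))
    return hits
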
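"""Model-quality diagnostics for predicted solvent coefficients.

Coefficient errors are not equivalent: in the LFER each weight is multiplied
by its solute descriptor, so an error in v matters more for a typical solute
(V_ave = 1.308) than the same error in a (A_ave = 0.173).  Two diagnostics
encode this:

* the scaled RMSE, the per-coefficient out-of-bag RMSE times the matching
  average descriptor, and
* the adjusted error D, a descriptor-weighted Euclidean distance between an
  observed and a predicted zero-intercept coefficient vector::

      D = sqrt( (e0-e0p)^2 E_ave^2 + (s0-s0p)^2 S_ave^2 + (a0-a0p)^2 A_ave^2
                + (b0-b0p)^2 B_ave^2 + (v0-v0p)^2 V_ave^2 )

  i.e. the error in predicted log P at the average solute if the per-term
  errors added in quadrature.  (A published form of this expression types the
  first term's weight as A_ave; that is inconsistent with the stated average
  list and with the d-distance, so E_ave is the default here.  Pass
  ``strict_as_printed=True`` to audit the literal variant.)

The chemical-space map places solvents on the first two principal components
of their five measured zero-intercept coefficients, carrying D for coloring
and flagging the top decile of D as model outliers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    COEFF_KEYS,
    DEFAULT_AVERAGES,
    ZERO_INTERCEPT,
    DescriptorAverages,
    SolventCoefficients,
)
from .errors import ConventionError, InsufficientDataError, InvalidInputError

__all__ = ["AdjustedError", "ChemSpaceMap", "adjusted_error", "scaled_rmse", "chem_space_map"]


@dataclass(frozen=True)
class AdjustedError:
    """Adjusted model error D for one solvent."""

    name: str
    observed: SolventCoefficients
    predicted: SolventCoefficients
    D: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise InvalidInputError("D must be nonnegative")


def adjusted_error(
    obs: SolventCoefficients,
    pred: SolventCoefficients,
    averages: DescriptorAverages = DEFAULT_AVERAGES,
    strict_as_printed: bool = False,
) -> float:
    """Descriptor-weighted distance D between observed and predicted coefficients."""
    for row in (obs, pred):
        if row.convention != ZERO_INTERCEPT:
            raise ConventionError(
                f"adjusted_error compares zero-intercept rows; {row.name!r} is {row.convention!r}"
            )
    weights = averages.as_array().copy()
    if strict_as_printed:
        weights[0] = averages.A  # literal published weighting of the e-term
    diff = obs.as_array() - pred.as_array()
    return float(np.sqrt(np.sum(diff**2 * weights**2)))


def scaled_rmse(
    rmse: Mapping[str, float] | Sequence[float],
    averages: DescriptorAverages = DEFAULT_AVERAGES,
) -> dict[str, float]:
    """Per-coefficient RMSE times the matching average descriptor.

    ``rmse`` maps coefficient names (e, s, a, b, v — a trailing 0 is accepted)
    to nonnegative values, or gives them as a sequence in canonical order.
    Values are returned at full precision; round to 2 decimals for reporting.
    """
    if not isinstance(rmse, Mapping):
        values = list(rmse)
        if len(values) != 5:
            raise InvalidInputError(f"expected 5 rmse values, got {len(values)}")
        rmse = dict(zip(COEFF_KEYS, values))
    else:
        rmse = {str(k).rstrip("0"): v for k, v in rmse.items()}
        if sorted(rmse) != sorted(COEFF_KEYS):
            raise InvalidInputError(f"rmse keys must be {COEFF_KEYS}, got {sorted(rmse)}")
    out = {}
    for k in COEFF_KEYS:
        value = float(rmse[k])
        if not (value >= 0):
            raise InvalidInputError(f"rmse[{k!r}] must be nonnegative, got {value}")
        out[k] = value * averages.weight_for(k)
    return out


@dataclass(frozen=True)
class ChemSpaceMap:
    """Solvents embedded in the plane of the first two principal components.

    ``scores`` has columns name, PC1, PC2 (and D, outlier when errors were
    given); ``loadings`` is 2 x 5 over (e, s, a, b, v); explained-variance
    fractions refer to the retained two components.
    """

    scores: pd.DataFrame
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    outliers: tuple[str, ...] = ()

    def plot(self, path=None, ax=None):
        """Scatter the map, colored by D when available (matplotlib optional)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        color = self.scores["D"] if "D" in self.scores else None
        sc = ax.scatter(self.scores["PC1"], self.scores["PC2"], c=color, cmap="coolwarm", s=30)
        if color is not None:
            plt.colorbar(sc, ax=ax, label="adjusted error D")
        ax.set_xlabel(f"PC1 ({self.explained_variance_ratio[0]:.0%})")
        ax.set_ylabel(f"PC2 ({self.explained_variance_ratio[1]:.0%})")
        for name in self.outliers:
            row = self.scores[self.scores["name"] == name]
            if len(row):
                ax.annotate(name, (row["PC1"].iloc[0], row["PC2"].iloc[0]), fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax


def chem_space_map(
    table: Sequence[SolventCoefficients],
    errors: Sequence[AdjustedError] | Mapping[str, float] | None = None,
    standardize: bool = True,
    outlier_fraction: float = 0.1,
) -> ChemSpaceMap:
    """PCA map of a zero-intercept coefficient table with optional D coloring.

    Columns are centered and (by default) scaled to unit variance before the
    decomposition; zero-variance columns are left unscaled.  When D values are
    supplied (by solvent name), the top ``outlier_fraction`` of D is flagged
    as model outliers.  Principal-component signs are fixed so the largest
    loading of each component is positive, making scores independent of row
    order.
    """
    if len(table) < 3:
        raise InsufficientDataError(f"chem_space_map needs >= 3 solvents, got {len(table)}")
    for row in table:
        if row.convention != ZERO_INTERCEPT:
            raise ConventionError(f"chem_space_map expects zero-intercept rows; {row.name!r} is not")
    names = [row.name for row in table]
    X = np.vstack([row.as_array() for row in table])
    X = X - X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        X = X / scale
    # SVD of the centered (scaled) matrix; deterministic sign convention.
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores2 = U[:, :2] * s[:2]
    total_var = float(np.sum(s**2))
    evr = (s[:2] ** 2 / total_var) if total_var > 0 else np.zeros(2)
    frame = pd.DataFrame({"name": names, "PC1": scores2[:, 0], "PC2": scores2[:, 1]})

    outliers: tuple[str, ...] = ()
    if errors is not None:
        if isinstance(errors, Mapping):
            d_by_key = {str(k).strip().lower(): float(v) for k, v in errors.items()}
        else:
            d_by_key = {e.name.strip().lower(): float(e.D) for e in errors}
        frame["D"] = [d_by_key.get(n.strip().lower(), np.nan) for n in names]
        with_d = frame.dropna(subset=["D"])
        n_out = max(1, int(np.ceil(outlier_fraction * len(with_d))))
        cut = with_d["D"].nlargest(n_out)
        outlier_names = set(with_d.loc[cut.index, "name"])
        frame["outlier"] = frame["name"].isin(outlier_names)
        outliers = tuple(sorted(outlier_names))
    return ChemSpaceMap(
        scores=frame, loadings=Vt[:2], explained_variance_ratio=evr, outliers=outliers
    )
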
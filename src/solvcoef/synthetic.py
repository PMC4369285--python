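"""Synthetic solute populations and descriptor->coefficient datasets.

The zero-intercept recalibration was originally carried out against a large
open database of compounds with measured Abraham descriptors.  That database
is external, so this module generates stand-in populations whose descriptor
means match the published averages (E 0.884, S 1.002, A 0.173, B 0.486,
V 1.308) exactly, with dispersion and distribution families chosen for
support correctness: normals for E and S (which may be negative), gammas for
the nonnegative H-bond descriptors A and B, and a log-normal for the strictly
positive McGowan volume V.  Only the means are pinned by data; the
correlation structure of real descriptor databases is not emulated.

For the coefficient-model training harness, :func:`make_qsar_dataset` builds
descriptor tables with known smooth ground-truth maps onto (e0..v0) so that
forest training can be validated by parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneratePopulationError, InvalidInputError
from .recalibration import SolutePopulation

__all__ = ["SynthesisConfig", "make_solute_population", "make_qsar_dataset"]

#: Published mean solute descriptors, in (E, S, A, B, V) order.
DEFAULT_MEANS = (0.884, 1.002, 0.173, 0.486, 1.308)

#: Default dispersion scales (standard deviations) per descriptor, chosen to
#: resemble the spread of organic-compound descriptor collections.
DEFAULT_SPREADS = (0.50, 0.45, 0.25, 0.30, 0.55)


@dataclass(frozen=True)
class SynthesisConfig:
    """Configuration for the synthetic generators.

    ``n`` is the population size (the emulated descriptor database held 2144
    compounds, the default); ``means``/``spreads`` are per-descriptor in
    (E, S, A, B, V) order; ``clip_nonnegative`` guards A, B, V support.  The
    QSPR fields control :func:`make_qsar_dataset`: ``n_descriptors`` total
    features of which ``n_informative`` drive each coefficient, plus Gaussian
    noise of standard deviation ``noise_sd``.
    """

    n: int = 2144
    seed: int = 0
    means: tuple[float, ...] = DEFAULT_MEANS
    spreads: tuple[float, ...] = DEFAULT_SPREADS
    clip_nonnegative: bool = True
    n_descriptors: int = 10
    n_informative: int = 3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 5:
            raise InvalidInputError(f"population size n must be >= 5, got {self.n}")
        if len(self.means) != 5 or len(self.spreads) != 5:
            raise InvalidInputError("means and spreads must each have 5 entries")
        if any(s <= 0 for s in self.spreads):
            raise InvalidInputError("dispersion scales must be positive")
        if any(m <= 0 for m in self.means[2:]):
            raise InvalidInputError("means for A, B, V must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 < self.n_informative <= self.n_descriptors):
            raise InvalidInputError("need 0 < n_informative <= n_descriptors")


def _draw_descriptors(cfg: SynthesisConfig, rng: np.random.Generator) -> np.ndarray:
    mE, mS, mA, mB, mV = cfg.means
    sE, sS, sA, sB, sV = cfg.spreads
    E = rng.normal(mE, sE, cfg.n)
    S = rng.normal(mS, sS, cfg.n)
    # gamma parameterized by mean/sd: shape = (m/s)^2, scale = s^2/m
    A = rng.gamma((mA / sA) ** 2, sA**2 / mA, cfg.n)
    B = rng.gamma((mB / sB) ** 2, sB**2 / mB, cfg.n)
    # log-normal with the requested arithmetic mean and sd
    sigma2 = np.log(1 + (sV / mV) ** 2)
    V = rng.lognormal(np.log(mV) - sigma2 / 2, np.sqrt(sigma2), cfg.n)
    X = np.column_stack([E, S, A, B, V])
    if cfg.clip_nonnegative:
        X[:, 2:] = np.clip(X[:, 2:], 0.0, None)
        X[:, 4] = np.maximum(X[:, 4], 1e-3)  # V strictly positive
    # pin sample means to the configured targets exactly; multiplicative for
    # the nonnegative columns, additive for E and S
    X[:, 0] += mE - X[:, 0].mean()
    X[:, 1] += mS - X[:, 1].mean()
    for j, m in zip(range(2, 5), (mA, mB, mV)):
        col_mean = X[:, j].mean()
        if col_mean <= 0:
            raise InvalidInputError("degenerate draw: nonnegative column collapsed to zero mean")
        X[:, j] *= m / col_mean
    return X


def make_solute_population(cfg: SynthesisConfig = SynthesisConfig()) -> SolutePopulation:
    """Draw a seed-deterministic solute population with the configured mean descriptors.

    Sample means match the targets exactly by construction; the [E S A B V]
    design is guaranteed full rank (re-drawn on failure).
    """
    for attempt in range(10):
        rng = np.random.default_rng(cfg.seed + 1009 * attempt)
        X = _draw_descriptors(cfg, rng)
        if np.linalg.matrix_rank(X) == 5:
            frame = pd.DataFrame(X, columns=["E", "S", "A", "B", "V"])
            frame.insert(0, "name", [f"synthetic-{i:05d}" for i in range(cfg.n)])
            return SolutePopulation(frame, source="packaged-synthetic")
    raise DegeneratePopulationError("could not draw a full-rank population in 10 attempts")


#: Ground-truth functional forms used by :func:`make_qsar_dataset`, centered
#: and scaled to sit in realistic coefficient ranges.
_QSAR_FORMS = {
    "e": ("0.35 + 0.30*tanh(x1) + 0.20*x2 - 0.10*x3", lambda x1, x2, x3: 0.35 + 0.30 * np.tanh(x1) + 0.20 * x2 - 0.10 * x3),
    "s": ("-0.60 + 0.50*x1 - 0.25*x2 + 0.15*tanh(x3)", lambda x1, x2, x3: -0.60 + 0.50 * x1 - 0.25 * x2 + 0.15 * np.tanh(x3)),
    "a": ("-1.20 + 0.90*x1 + 0.20*x2 + 0.20*x3", lambda x1, x2, x3: -1.20 + 0.90 * x1 + 0.20 * x2 + 0.20 * x3),
    "b": ("-4.50 + 0.60*x1 + 0.35*x2 - 0.20*tanh(x3)", lambda x1, x2, x3: -4.50 + 0.60 * x1 + 0.35 * x2 - 0.20 * np.tanh(x3)),
    "v": ("4.00 + 0.45*x1 + 0.30*x2 + 0.15*x3", lambda x1, x2, x3: 4.00 + 0.45 * x1 + 0.30 * x2 + 0.15 * x3),
}


def make_qsar_dataset(
    cfg: SynthesisConfig = SynthesisConfig(n=200),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Descriptor table, coefficient targets, and ground-truth description.

    Descriptors are independent standard normals named ``d01..``; each target
    coefficient is a documented smooth function of the first ``n_informative``
    descriptors assigned to it (cycling through the pool) plus Gaussian noise
    of standard deviation ``noise_sd``.
    """
    rng = np.random.default_rng(cfg.seed)
    X = rng.standard_normal((cfg.n, cfg.n_descriptors))
    columns = [f"d{j + 1:02d}" for j in range(cfg.n_descriptors)]
    descriptors = pd.DataFrame(X, columns=columns)
    descriptors.insert(0, "name", [f"molecule-{i:05d}" for i in range(cfg.n)])

    truth: dict = {"noise_sd": cfg.noise_sd, "targets": {}}
    targets = {}
    for i, (coeff, (formula, fn)) in enumerate(_QSAR_FORMS.items()):
        idx = [(i + j) % cfg.n_descriptors for j in range(min(3, cfg.n_informative))]
        # pad with repeats if fewer than 3 informative descriptors requested
        while len(idx) < 3:
            idx.append(idx[-1])
        x1, x2, x3 = (X[:, j] for j in idx)
        y = fn(x1, x2, x3)
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd, cfg.n)
        targets[coeff + "0"] = y
        truth["targets"][coeff + "0"] = {
            "formula": formula,
            "descriptors": [columns[j] for j in idx],
        }
    target_frame = pd.DataFrame(targets)
    target_frame.insert(0, "name", descriptors["name"])
    return descriptors, target_frame, truth
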
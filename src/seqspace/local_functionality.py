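"""Hyper-exponential models of local functionality decay around a wildtype.

Mutation-accumulation experiments show that the proportion of functional
variants at Hamming distance ``n`` from a wildtype protein decays faster than
exponentially when epistasis is negative.  The standard form is the decaying
hyper-exponential

    P_loc(n) = exp(-alpha * n - beta * n**2)

Setting ``P_loc(n)`` equal to the percolation threshold ``P_th`` and solving
for ``n`` gives ``n_max``, the largest Hamming distance at which the local
functional proportion still exceeds the threshold — i.e. the radius of the
region around the wildtype where extensive continuous functional paths can
exist.  An alternative, stepwise estimate multiplies per-mutation tolerated
fractions from round-by-round mutagenesis data until the running product
falls to ``P_th``.

This module provides the model, both ``n_max`` procedures, the rescaling of
raw all-mutation coefficients to nonsynonymous-only counts, and a
least-squares fitter for ``(alpha, beta)`` from observed ``(n, p)`` data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HyperExponentialModel",
    "MutationToleranceSchedule",
    "PlocObservation",
    "PlocFitResult",
    "p_loc",
    "n_max_from_model",
    "n_max_root",
    "n_max_from_schedule",
    "rescale_nonsynonymous",
    "fit_hyperexponential",
]

#: Fraction of random nucleotide mutations that change the amino-acid
#: sequence; used to rescale all-mutation decay coefficients.
NONSYNONYMOUS_FRACTION = 0.69


@dataclass(frozen=True)
class HyperExponentialModel:
    """Coefficients of P_loc(n) = exp(-alpha*n - beta*n^2).

    ``alpha`` may be negative (functionality initially flat or rising) as long
    as ``beta > 0`` guarantees decay at large ``n``; with ``beta == 0`` the
    model is a plain exponential and ``alpha`` must be positive.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0 or (self.beta == 0 and self.alpha <= 0):
            raise ValueError(
                f"model must decay for large n: need beta > 0 or "
                f"(beta == 0 and alpha > 0); got alpha={self.alpha}, beta={self.beta}"
            )

    def __call__(self, n):
        return p_loc(self, n)


@dataclass(frozen=True)
class MutationToleranceSchedule:
    """Per-mutation tolerated fractions from round-wise mutagenesis data.

    ``per_step[k-1]`` is the fraction of variants that remain functional when
    the k-th nonsynonymous mutation is added; steps beyond the list reuse the
    final entry.
    """

    per_step: tuple[float, ...]

    def __init__(self, per_step: Iterable[float]):
        steps = tuple(float(p) for p in per_step)
        if not steps:
            raise ValueError("schedule must contain at least one entry")
        if any(not 0.0 < p <= 1.0 for p in steps):
            raise ValueError(f"all tolerated fractions must be in (0, 1]: {steps}")
        object.__setattr__(self, "per_step", steps)

    def fraction_at(self, k: int) -> float:
        """Tolerated fraction for the k-th added mutation (1-based)."""
        if k < 1:
            raise ValueError(f"mutation index must be >= 1, got {k}")
        return self.per_step[min(k, len(self.per_step)) - 1]


@dataclass(frozen=True)
class PlocObservation:
    """Observed functional proportion ``p`` at Hamming distance ``n``."""

    n: int
    p: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must be in (0, 1], got {self.p}")


@dataclass(frozen=True)
class PlocFitResult:
    model: HyperExponentialModel
    rss: float
    n_used: int
    excluded: tuple[int, ...]


def p_loc(model: HyperExponentialModel, n) -> float | np.ndarray:
    """Evaluate P_loc(n) = exp(-alpha*n - beta*n^2); P_loc(0) is exactly 1."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("Hamming distance n must be non-negative")
    out = np.exp(-model.alpha * n - model.beta * n**2)
    return float(out) if out.ndim == 0 else out


def n_max_root(model: HyperExponentialModel, p_th: float) -> float:
    """Positive real root of beta*n^2 + alpha*n = -ln(P_th).

    Quadratic closed form; linear fallback when ``beta == 0``.
    """
    if not 0.0 < p_th < 1.0:
        raise ValueError(f"p_th must be in (0, 1), got {p_th}")
    c = -math.log(p_th)  # > 0
    if model.beta == 0.0:
        return c / model.alpha
    disc = model.alpha**2 + 4.0 * model.beta * c
    if disc < 0:
        raise ValueError("no real root: model never decays to p_th")
    root = (-model.alpha + math.sqrt(disc)) / (2.0 * model.beta)
    if root <= 0:
        raise ValueError(f"no positive root for alpha={model.alpha}, beta={model.beta}")
    return root


def n_max_from_model(model: HyperExponentialModel, p_th: float) -> int:
    """Maximum Hamming distance where P_loc still exceeds P_th.

    The continuous crossing point of the hyper-exponential with the threshold,
    rounded to the nearest integer.
    """
    return int(round(n_max_root(model, p_th)))


def n_max_from_schedule(schedule: MutationToleranceSchedule, p_th: float) -> int:
    """Largest n whose cumulative tolerated-fraction product exceeds P_th.

    Multiplies the per-mutation tolerated fractions stepwise; returns the last
    step at which the running product is still strictly above ``p_th``.  A
    schedule whose final entry is 1.0 never decays, so it cannot cross any
    threshold and is rejected.
    """
    if not 0.0 < p_th < 1.0:
        raise ValueError(f"p_th must be in (0, 1), got {p_th}")
    if schedule.per_step[-1] >= 1.0:
        raise ValueError("schedule never decays: final tolerated fraction is 1.0")
    product = 1.0
    n = 0
    while True:
        n += 1
        product *= schedule.fraction_at(n)
        if product <= p_th:
            return n - 1
        # beyond the listed steps the product is a geometric decay and must
        # cross; the loop always terminates since fraction_at(k) < 1 there


def rescale_nonsynonymous(
    alpha_raw: float,
    beta_raw: float,
    fraction: float = NONSYNONYMOUS_FRACTION,
) -> HyperExponentialModel:
    """Convert all-mutation decay coefficients to nonsynonymous-only counts.

    Replacing ``n`` by ``n / fraction`` in the hyper-exponential maps
    ``alpha -> alpha / fraction`` and ``beta -> beta / fraction**2``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"nonsynonymous fraction must be in (0, 1], got {fraction}")
    return HyperExponentialModel(alpha_raw / fraction, beta_raw / fraction**2)


def fit_hyperexponential(
    observations: Sequence[PlocObservation],
    exclude_n: Iterable[int] = (),
    log_space: bool = False,
) -> PlocFitResult:
    """Least-squares fit of (alpha, beta) to observed (n, p) decay data.

    By default the residuals are taken in linear p-space
    (``scipy.optimize.curve_fit`` on ``p = exp(-a*n - b*n^2)``).  Because the
    observations can span several decades, a log-space variant (ordinary
    polynomial regression of ``-ln p`` on ``n`` and ``n^2``) is available via
    ``log_space=True``.

    Parameters
    ----------
    observations :
        The (n, p) samples.
    exclude_n :
        Hamming distances to drop before fitting (e.g. a known outlier).
    """
    excluded = tuple(sorted(set(int(k) for k in exclude_n)))
    used = [o for o in observations if o.n not in excluded]
    if len(used) < 3:
        raise ValueError(
            f"need at least 3 observations after exclusion, have {len(used)}"
        )
    n = np.array([o.n for o in used], dtype=float)
    p = np.array([o.p for o in used], dtype=float)

    # log-space start values are also the log-space solution (linear algebra)
    y = -np.log(p)
    design = np.column_stack([n, n**2])
    (a0, b0), *_ = np.linalg.lstsq(design, y, rcond=None)

    if log_space:
        alpha, beta = float(a0), float(b0)
    else:
        def _model(nn, a, b):
            return np.exp(-a * nn - b * nn**2)

        try:
            (alpha, beta), _ = curve_fit(_model, n, p, p0=(a0, b0), maxfev=10000)
        except RuntimeError as exc:
            raise ValueError(f"hyper-exponential fit did not converge: {exc}") from exc
        alpha, beta = float(alpha), float(beta)

    resid = p - np.exp(-alpha * n - beta * n**2)
    return PlocFitResult(
        model=HyperExponentialModel(alpha, beta),
        rss=float(np.dot(resid, resid)),
        n_used=len(used),
        excluded=excluded,
    )
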
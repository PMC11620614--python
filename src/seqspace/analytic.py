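"""Closed-form percolation thresholds for protein sequence space.

The percolation threshold of a lattice is approximately the reciprocal of the
number of nearest neighbours of a site.  In amino-acid sequence space a
sequence of length ``L`` has on average ``A_t * L`` single-mutation
neighbours, where ``A_t`` is the average number of amino acids reachable from
one amino acid by a single nucleotide change (7.5 for the standard genetic
code).  Allowing up to ``n_m`` simultaneous mutations multiplies the
neighbourhood to ``(A_t * L) ** n_m / n_m!``, so the threshold is

    P_th = n_m! / (A_t * L) ** n_m

This module evaluates that threshold, the biasing ratio ``R_b = P_th / P_fs``
(how strongly functional sequences must be locally concentrated for extensive
continuous functional paths to exist), the smallest ``n_m`` at which the
threshold drops to the observed proportion of functional sequences, and the
corresponding sequence identity ``SI = 100 * (1 - n/L)``.

All threshold arithmetic is carried out in log space (log-factorial via
``lgamma``) so that ``n_m`` up to a few hundred and ``L`` up to 10**4 never
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_A_T",
    "ProteinRecord",
    "ThresholdParams",
    "ThresholdReport",
    "MinNmNotFoundError",
    "percolation_threshold",
    "log_percolation_threshold",
    "biasing_ratio",
    "order_of_magnitude",
    "min_nm",
    "sequence_identity",
    "build_table",
    "round_sig",
    "round_half_up",
    "format_proportion",
]

#: Average number of amino acids an amino acid can mutate into through a
#: single nucleotide substitution, averaged over the genetic code.
DEFAULT_A_T = 7.5


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: its length and reported proportion of functional sequences.

    Parameters
    ----------
    name :
        Display label.
    L :
        Number of amino acids (positive integer).
    p_fs :
        Proportion of sequences of length ``L`` that perform the protein's
        function, in ``(0, 1]``.  These are literature values, typically bare
        powers of ten.
    source :
        Free-text citation tag for the ``p_fs`` value.
    """

    name: str
    L: int
    p_fs: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"{self.name}: L must be >= 1, got {self.L}")
        if not 0.0 < self.p_fs <= 1.0:
            raise ValueError(f"{self.name}: p_fs must be in (0, 1], got {self.p_fs}")


@dataclass(frozen=True)
class ThresholdParams:
    """Neighbourhood parameters: transitions per mutation and mutation count."""

    A_t: float = DEFAULT_A_T
    n_m: int = 1

    def __post_init__(self) -> None:
        if self.A_t <= 0:
            raise ValueError(f"A_t must be positive, got {self.A_t}")
        if self.n_m < 1:
            raise ValueError(f"n_m must be >= 1, got {self.n_m}")


@dataclass(frozen=True)
class ThresholdReport:
    """Derived percolation quantities for one protein."""

    name: str
    L: int
    p_fs: float
    p_th: float
    r_b: float
    r_b_exponent: int
    n_min: int | None
    si: float | None  # percent, at n_min; None when n_min not found
    params: ThresholdParams = field(default_factory=ThresholdParams)

    @property
    def p_th_display(self) -> str:
        """Threshold at two significant figures, Table-style (``.0027``)."""
        return format_proportion(round_sig(self.p_th, 2))

    @property
    def r_b_display(self) -> str:
        return f"10^{self.r_b_exponent}"

    @property
    def si_display(self) -> str:
        if self.si is None:
            return "-"
        return f"{round_half_up(self.si)}%"


class MinNmNotFoundError(ValueError):
    """No mutation count within the search bound brings P_th down to P_fs."""


def log_percolation_threshold(L: int, A_t: float = DEFAULT_A_T, n_m: int = 1) -> float:
    """Natural log of the percolation threshold n_m! / (A_t * L)**n_m."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if A_t <= 0:
        raise ValueError(f"A_t must be positive, got {A_t}")
    if n_m < 1:
        raise ValueError(f"n_m must be >= 1, got {n_m}")
    return math.lgamma(n_m + 1) - n_m * math.log(A_t * L)


def percolation_threshold(L: int, A_t: float = DEFAULT_A_T, n_m: int = 1) -> float:
    """Percolation threshold for length-``L`` sequences with ``n_m``-mutation moves.

    For ``n_m = 1`` this is ``1 / (A_t * L)``, the reciprocal of the average
    neighbour count.  The value can exceed 1 for tiny neighbourhoods; no clamp
    is applied — the caller decides how to interpret a threshold above 1.
    """
    return math.exp(log_percolation_threshold(L, A_t, n_m))


def biasing_ratio(p_th: float, p_fs: float) -> float:
    """Ratio R_b = P_th / P_fs: the required local enrichment of functional
    sequences for extensive continuous functional paths to be possible."""
    if p_th <= 0:
        raise ValueError(f"p_th must be positive, got {p_th}")
    if p_fs <= 0:
        raise ValueError(f"p_fs must be positive, got {p_fs}")
    return p_th / p_fs


def order_of_magnitude(x: float) -> int:
    """floor(log10(x)) for positive x, exact on powers of ten.

    ``math.log10`` alone can land an ulp below an integer for exact powers of
    ten, so the floor is corrected by direct comparison with ``10**e``.
    """
    if x <= 0:
        raise ValueError(f"order_of_magnitude requires x > 0, got {x}")
    e = math.floor(math.log10(x))
    # correct off-by-one from floating log10
    if 10.0 ** (e + 1) <= x:
        e += 1
    elif 10.0 ** e > x:
        e -= 1
    return e


def min_nm(
    L: int,
    A_t: float,
    p_fs: float,
    max_nm: int = 200,
) -> int:
    """Smallest ``n_m`` whose threshold drops to or below ``p_fs`` (strict rule).

    Returns the first ``n_m`` with ``P_th(n_m) <= p_fs``; the comparison is in
    log space.  ``P_th`` is not monotone in ``n_m`` forever (the factorial
    eventually wins), so if no ``n_m <= max_nm`` satisfies the criterion a
    :class:`MinNmNotFoundError` is raised rather than silently returning the
    bound.
    """
    if not 0.0 < p_fs <= 1.0:
        raise ValueError(f"p_fs must be in (0, 1], got {p_fs}")
    if max_nm < 1:
        raise ValueError(f"max_nm must be >= 1, got {max_nm}")
    log_target = math.log(p_fs)
    for n_m in range(1, max_nm + 1):
        if log_percolation_threshold(L, A_t, n_m) <= log_target:
            return n_m
    raise MinNmNotFoundError(
        f"no n_m <= {max_nm} gives P_th <= {p_fs} for L={L}, A_t={A_t}"
    )


def sequence_identity(n: float, L: int) -> float:
    """Percent sequence identity at Hamming distance ``n``: 100 * (1 - n/L)."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if n < 0 or n > L:
        raise ValueError(f"Hamming distance must be in [0, L]={L}, got {n}")
    return 100.0 * (1.0 - n / L)


def build_table(
    records: list[ProteinRecord],
    params: ThresholdParams | None = None,
    max_nm: int = 200,
) -> list[ThresholdReport]:
    """Derive threshold, biasing ratio, n_min and SI for each protein record.

    ``params.n_m`` sets the mutation count used for the displayed ``P_th`` and
    ``R_b`` columns (the literature tables use ``n_m = 1``); ``n_min`` is
    always searched from 1.  Per-record domain errors are re-raised with the
    record name attached.
    """
    if not records:
        raise ValueError("build_table requires at least one record")
    params = params or ThresholdParams()
    reports: list[ThresholdReport] = []
    for rec in records:
        try:
            p_th = percolation_threshold(rec.L, params.A_t, params.n_m)
            r_b = biasing_ratio(p_th, rec.p_fs)
            try:
                n_min_val: int | None = min_nm(rec.L, params.A_t, rec.p_fs, max_nm)
                si: float | None = sequence_identity(n_min_val, rec.L)
            except MinNmNotFoundError:
                n_min_val, si = None, None
            reports.append(
                ThresholdReport(
                    name=rec.name,
                    L=rec.L,
                    p_fs=rec.p_fs,
                    p_th=p_th,
                    r_b=r_b,
                    r_b_exponent=order_of_magnitude(r_b),
                    n_min=n_min_val,
                    si=si,
                    params=params,
                )
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.name!r}: {exc}") from exc
    return reports


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - order_of_magnitude(abs(x)))


def round_half_up(x: float, decimals: int = 0) -> float | int:
    """Round with ties away from zero (the convention of the source tables)."""
    scale = 10.0 ** decimals
    v = math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
    return int(v) if decimals == 0 else v


def format_proportion(x: float, sig: int = 2) -> str:
    """Render a small proportion at ``sig`` significant figures the way the
    tables print it (``.0027``, ``.0010`` — trailing zeros kept)."""
    if x >= 1 or x <= 0:
        return f"{x:g}"
    decimals = max(sig - 1 - order_of_magnitude(x), 0)
    return f"{x:.{decimals}f}".lstrip("0")
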
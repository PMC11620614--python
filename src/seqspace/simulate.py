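"""Monte-Carlo site percolation over discrete protein sequence spaces.

A sequence space is the set of all ``A**L`` sequences of length ``L`` over an
``A``-letter amino-acid alphabet.  Two sequences are neighbours when they
differ at exactly one position and the substitution is allowed by the
transition rule (``full``: any of the other ``A - 1`` letters; ``restricted``:
``A_t < A - 1`` cyclic-offset targets).  Each sequence is independently
functional with probability ``P_fs``; a cluster is a connected component of
the functional subgraph, i.e. the set of sequences joined by continuous
functional paths (CFPs) of single mutations.

Functionality is assigned lazily: each sequence's uniform deviate is a
deterministic SplitMix64-style hash of ``(seed, sequence index)``, so the
2.8e8-sequence space at L=10, A=7 needs no materialised matrix, identical
configurations replay identically on any platform, and thresholding the same
deviates at two occupation probabilities yields a monotone coupling (the
functional set at the lower P_fs is a subset of the set at the higher one).

Cluster search is an iterative breadth-first traversal with an explicit
frontier (no recursion), capped by default at 20,000 functional sequences;
near the percolation threshold cluster sizes are strongly bimodal, so a
capped search cleanly separates small clusters from space-spanning ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpaceConfig",
    "ClusterOutcome",
    "ConnectivityOutcome",
    "SweepResult",
    "PowerLawFit",
    "DEFAULT_CAP",
    "functional",
    "functional_index",
    "uniform_deviates",
    "neighbors",
    "neighbor_indices",
    "encode",
    "decode",
    "cluster_from_start",
    "connect_to_target",
    "attempts_until_connected",
    "large_cluster_fraction",
    "sweep_transition",
    "cluster_size_distribution",
    "fit_power_law_tau",
]

#: Cluster-search cap: every observed cluster larger than this extends
#: throughout sequence space at the scales studied here.
DEFAULT_CAP = 20_000

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)


def _mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer, vectorised over uint64 (wrapping arithmetic)."""
    x = (x + _GOLDEN).astype(_U64)
    x = ((x ^ (x >> _U64(30))) * _MIX1).astype(_U64)
    x = ((x ^ (x >> _U64(27))) * _MIX2).astype(_U64)
    return x ^ (x >> _U64(31))


@dataclass(frozen=True)
class SpaceConfig:
    """Full specification of one simulated sequence space.

    Parameters
    ----------
    L, A :
        Sequence length and alphabet size.
    p_fs :
        Probability that a sequence is functional.
    seed :
        Integer seed; together with a sequence's index it determines the
        sequence's uniform deviate, hence the whole space.
    A_t :
        Allowed transitions per position.  ``None`` means the full rule
        (``A - 1``); a smaller value selects symmetric cyclic offsets.
    force_start_functional :
        Treat the start sequence as functional regardless of its deviate
        (a nonfunctional start would make every trial degenerate).
    require_functional_target_hit :
        A target hit must itself be functional (it terminates a CFP).
    """

    L: int
    A: int
    p_fs: float
    seed: int
    A_t: int | None = None
    force_start_functional: bool = True
    require_functional_target_hit: bool = True

    def __post_init__(self) -> None:
        if self.A < 2:
            raise ValueError(f"A must be >= 2, got {self.A}")
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if not 0.0 <= self.p_fs <= 1.0:
            raise ValueError(f"p_fs must be in [0, 1], got {self.p_fs}")
        if self.A_t is not None:
            if not 1 <= self.A_t <= self.A - 1:
                raise ValueError(f"A_t must be in [1, A-1], got {self.A_t}")
            if self.A_t < self.A - 1 and self.A_t % 2 == 1 and self.A % 2 == 1:
                raise ValueError(
                    "restricted odd A_t with odd A admits no symmetric "
                    "cyclic-offset rule (odd-degree circulant on an odd cycle)"
                )

    @property
    def effective_A_t(self) -> int:
        return self.A - 1 if self.A_t is None else self.A_t

    @property
    def full_rule(self) -> bool:
        return self.effective_A_t == self.A - 1

    @property
    def size(self) -> int:
        return self.A**self.L

    @property
    def start_index(self) -> int:
        """Index of the all-first-amino-acid start sequence."""
        return 0

    @property
    def target_index(self) -> int:
        """Index of the all-second-amino-acid target sequence."""
        return encode(np.ones(self.L, dtype=np.int64), self.A)

    def offsets(self) -> np.ndarray:
        """Cyclic code offsets realising the transition rule (negation-closed
        mod A, so the neighbour relation is symmetric)."""
        At, A = self.effective_A_t, self.A
        if self.full_rule:
            return np.arange(1, A, dtype=np.int64)
        if At % 2 == 0:
            k = At // 2
            offs = list(range(1, k + 1)) + [A - o for o in range(1, k + 1)]
        else:
            k = (At - 1) // 2  # plus the self-inverse half-turn offset A/2
            offs = list(range(1, k + 1)) + [A - o for o in range(1, k + 1)] + [A // 2]
        return np.array(sorted(offs), dtype=np.int64)


@dataclass(frozen=True)
class ClusterOutcome:
    """Size of the start sequence's cluster, possibly truncated at ``cap``."""

    size: int
    capped: bool
    is_large: bool


@dataclass(frozen=True)
class ConnectivityOutcome:
    """Number of freshly seeded spaces needed to find a start-to-target CFP."""

    attempts: int
    tol: int
    success: bool


@dataclass(frozen=True)
class SweepResult:
    """Per-P_fs percolation statistics from a monotone-coupled sweep."""

    p_fs_grid: tuple[float, ...]
    large_fraction: tuple[float, ...]
    mean_size: tuple[float, ...]
    critical_p_fs: float | None
    detect_fraction: float
    reps: int
    cap: int


@dataclass(frozen=True)
class PowerLawFit:
    """Cluster-size power-law exponent tau from log-binned regression."""

    tau: float
    stderr: float
    n_sizes: int
    n_bins: int


# ---------------------------------------------------------------------------
# indexing and lazy functionality


def encode(codes: np.ndarray, A: int) -> int | np.ndarray:
    """Map 0-based code vectors (…, L) to flat base-A indices."""
    codes = np.asarray(codes, dtype=np.int64)
    pows = A ** np.arange(codes.shape[-1], dtype=np.int64)
    out = (codes * pows).sum(axis=-1)
    return int(out) if out.ndim == 0 else out


def decode(indices, L: int, A: int) -> np.ndarray:
    """Inverse of :func:`encode`: flat indices to (…, L) code arrays."""
    idx = np.asarray(indices, dtype=np.int64)
    codes = np.empty(idx.shape + (L,), dtype=np.int64)
    for p in range(L):
        codes[..., p] = idx % A
        idx = idx // A
    return codes


def uniform_deviates(config: SpaceConfig, indices) -> np.ndarray:
    """Deterministic per-sequence uniforms in [0, 1) from (seed, index)."""
    idx = np.atleast_1d(np.asarray(indices)).astype(np.int64).astype(_U64)
    seeded = _mix64(np.array([config.seed], dtype=np.int64).astype(_U64))
    bits = _mix64(idx ^ seeded)
    return (bits >> _U64(11)).astype(np.float64) * 2.0**-53


def functional_index(config: SpaceConfig, indices) -> bool | np.ndarray:
    """Functionality of sequences given by flat index: u(seed, index) < P_fs.

    The start sequence is functional by construction when
    ``force_start_functional`` is set.
    """
    scalar = np.isscalar(indices) or np.asarray(indices).ndim == 0
    idx = np.atleast_1d(np.asarray(indices, dtype=np.int64))
    out = uniform_deviates(config, idx) < config.p_fs
    if config.force_start_functional:
        out = out | (idx == config.start_index)
    return bool(out[0]) if scalar else out


def functional(config: SpaceConfig, seq) -> bool | np.ndarray:
    """Whether code-vector sequence(s) are functional.

    ``seq`` is one length-``L`` code vector (returns bool) or an (m, L)
    array of them (returns a boolean array).
    """
    arr = np.asarray(seq, dtype=np.int64)
    if arr.ndim not in (1, 2) or arr.shape[-1] != config.L:
        raise ValueError(f"sequence must have length L={config.L}")
    if arr.size and (arr.min() < 0 or arr.max() >= config.A):
        raise ValueError("sequence codes out of range [0, A)")
    idx = encode(np.atleast_2d(arr), config.A)
    out = functional_index(config, idx)
    return bool(out[0]) if arr.ndim == 1 else out


def neighbor_indices(config: SpaceConfig, indices) -> np.ndarray:
    """Flat indices of all single-mutation neighbours, shape (m, L * A_t).

    In substitution space every sequence has exactly ``L * A_t`` neighbours —
    there are no boundary effects.
    """
    idx = np.atleast_1d(np.asarray(indices, dtype=np.int64))
    codes = decode(idx, config.L, config.A)  # (m, L)
    pows = config.A ** np.arange(config.L, dtype=np.int64)  # (L,)
    offs = config.offsets()  # (At,)
    new_codes = (codes[:, :, None] + offs[None, None, :]) % config.A  # (m, L, At)
    delta = (new_codes - codes[:, :, None]) * pows[None, :, None]
    out = idx[:, None, None] + delta
    return out.reshape(idx.shape[0], -1)


def neighbors(config: SpaceConfig, seq: Sequence[int]) -> np.ndarray:
    """Code vectors of all single-mutation neighbours of one sequence."""
    seq = np.asarray(seq, dtype=np.int64)
    if seq.shape != (config.L,):
        raise ValueError(f"sequence must have length L={config.L}")
    if seq.min() < 0 or seq.max() >= config.A:
        raise ValueError("sequence codes out of range [0, A)")
    nbr_idx = neighbor_indices(config, encode(seq, config.A))[0]
    return decode(nbr_idx, config.L, config.A)


# ---------------------------------------------------------------------------
# cluster search


def _bfs(
    config: SpaceConfig,
    start_index: int,
    cap: int | None,
    target_index: int | None = None,
    tol: int | None = None,
):
    """Iterative BFS over the functional subgraph from ``start_index``.

    Returns ``(size, capped, hit)`` where ``hit`` reports whether a sequence
    within Hamming distance ``tol`` of the target was reached (``None`` when
    no target was given); the search stops at the first hit.  Each sequence
    is counted once: cluster members are kept in a visited set, nonfunctional
    candidates are simply re-hashed when re-encountered.
    """
    if not functional_index(config, start_index):
        return 0, False, (False if target_index is not None else None)

    target_codes = None
    if target_index is not None:
        target_codes = decode(np.asarray([target_index]), config.L, config.A)[0]
        d0 = int((decode(np.asarray([start_index]), config.L, config.A)[0]
                  != target_codes).sum())
        if d0 <= tol:
            return 1, False, True

    def _hits(idx: np.ndarray) -> bool:
        dist = (decode(idx, config.L, config.A) != target_codes).sum(axis=1)
        return bool(np.any(dist <= tol))

    members = {int(start_index)}
    frontier = np.array([start_index], dtype=np.int64)
    capped = False
    while frontier.size:
        cand = np.unique(neighbor_indices(config, frontier).ravel())
        if target_codes is not None and not config.require_functional_target_hit:
            # a nonfunctional terminal may end the path one step early
            if _hits(cand):
                return len(members), False, True
        cand = cand[functional_index(config, cand)]
        new = np.array(
            [i for i in cand.tolist() if i not in members], dtype=np.int64
        )
        if new.size == 0:
            break
        if target_codes is not None and config.require_functional_target_hit:
            if _hits(new):
                return len(members) + int(new.size), False, True
        members.update(new.tolist())
        frontier = new
        if cap is not None and len(members) > cap:
            capped = True
            break
    size = min(len(members), cap) if cap is not None else len(members)
    return size, capped, (False if target_index is not None else None)


def cluster_from_start(
    config: SpaceConfig,
    start: Sequence[int] | None = None,
    cap: int | None = DEFAULT_CAP,
) -> ClusterOutcome:
    """Size of the cluster of functional sequences containing the start.

    Breadth-first over single-mutation moves; the search stops once the
    cluster exceeds ``cap`` sequences and the outcome is flagged both
    ``capped`` and ``is_large`` (at the scales studied, every cluster past
    the cap spans sequence space).
    """
    if cap is not None and cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    start_index = (
        config.start_index if start is None else encode(np.asarray(start), config.A)
    )
    size, capped, _ = _bfs(config, start_index, cap)
    return ClusterOutcome(size=size, capped=capped, is_large=capped)


def connect_to_target(
    config: SpaceConfig,
    start: Sequence[int] | None = None,
    target: Sequence[int] | None = None,
    tol: int = 0,
    cap: int | None = None,
) -> bool:
    """Whether a CFP joins the start to the target neighbourhood.

    True iff the start's cluster contains a functional sequence within
    Hamming distance ``tol`` of the target sequence; the search exits at the
    first hit.  ``cap`` optionally bounds the exploration (None = exhaustive).
    """
    if not 0 <= tol <= config.L:
        raise ValueError(f"tol must be in [0, L], got {tol}")
    start_index = (
        config.start_index if start is None else encode(np.asarray(start), config.A)
    )
    target_index = (
        config.target_index if target is None else encode(np.asarray(target), config.A)
    )
    _, _, hit = _bfs(config, start_index, cap, target_index, tol)
    return bool(hit)


def _spawned_seed(base_seed: int, stream: int) -> int:
    """Derive a child seed (< 2**31) from a base seed and stream number."""
    z = _mix64(np.array([base_seed], dtype=np.int64).astype(_U64) ^
               _mix64(np.array([stream + 1], dtype=np.int64).astype(_U64)))
    return int(z[0] & _U64(0x7FFFFFFF))


def attempts_until_connected(
    config_base: SpaceConfig,
    start: Sequence[int] | None = None,
    target: Sequence[int] | None = None,
    tol: int = 0,
    max_attempts: int = 1000,
    cap: int | None = None,
) -> ConnectivityOutcome:
    """Regenerate the space with fresh seeds until a start-target CFP appears.

    Mirrors the experimental protocol: draw spaces at the same ``P_fs`` until
    one contains a connecting CFP, and report the attempt count ``N_att``.
    """
    if max_attempts < 1:
        raise ValueError(f"max_attempts must be >= 1, got {max_attempts}")
    for attempt in range(1, max_attempts + 1):
        cfg = replace(config_base, seed=_spawned_seed(config_base.seed, attempt))
        if connect_to_target(cfg, start, target, tol, cap):
            return ConnectivityOutcome(attempts=attempt, tol=tol, success=True)
    return ConnectivityOutcome(attempts=max_attempts, tol=tol, success=False)


def large_cluster_fraction(
    config_base: SpaceConfig,
    reps: int = 100,
    cap: int = DEFAULT_CAP,
) -> float:
    """Fraction of independent replicate spaces whose start cluster is large."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    hits = 0
    for r in range(reps):
        cfg = replace(config_base, seed=_spawned_seed(config_base.seed, r))
        if cluster_from_start(cfg, cap=cap).is_large:
            hits += 1
    return hits / reps


def sweep_transition(
    config_base: SpaceConfig,
    p_fs_grid: Sequence[float],
    reps: int = 50,
    cap: int = DEFAULT_CAP,
    detect_fraction: float = 0.05,
) -> SweepResult:
    """Locate the percolation phase transition over an ascending P_fs grid.

    All grid points share each replicate's underlying uniforms (the same
    seed), thresholded at each P_fs: this monotone coupling makes the
    functional set, hence the start-cluster size and the large-cluster flag,
    non-decreasing in P_fs for every replicate.  The scan therefore ascends
    the grid and, once a replicate's cluster is large, credits all higher
    grid points without re-running (their size equals the cap).

    The critical P_fs is the smallest grid point whose large-cluster fraction
    reaches ``detect_fraction``; ``None`` if no point does.
    """
    grid = [float(p) for p in p_fs_grid]
    if grid != sorted(grid):
        raise ValueError("p_fs_grid must be ascending")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if not 0.0 < detect_fraction < 1.0:
        raise ValueError(f"detect_fraction must be in (0, 1), got {detect_fraction}")

    large_counts = np.zeros(len(grid), dtype=np.int64)
    size_sums = np.zeros(len(grid), dtype=np.float64)
    for r in range(reps):
        seed = _spawned_seed(config_base.seed, r)
        for i, p in enumerate(grid):
            cfg = replace(config_base, p_fs=p, seed=seed)
            out = cluster_from_start(cfg, cap=cap)
            size_sums[i] += out.size
            if out.is_large:
                large_counts[i:] += 1
                size_sums[i + 1:] += cap  # monotone coupling: large stays large
                break

    fractions = large_counts / reps
    critical = None
    for p, f in zip(grid, fractions):
        if f >= detect_fraction:
            critical = p
            break
    return SweepResult(
        p_fs_grid=tuple(grid),
        large_fraction=tuple(fractions.tolist()),
        mean_size=tuple((size_sums / reps).tolist()),
        critical_p_fs=critical,
        detect_fraction=detect_fraction,
        reps=reps,
        cap=cap,
    )


def cluster_size_distribution(
    config_base: SpaceConfig,
    reps: int,
    cap: int = DEFAULT_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Start-cluster sizes over independent replicates.

    Returns ``(sizes, capped)``; capped sizes must be excluded from
    power-law fitting (they are truncated, not observed).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    sizes = np.empty(reps, dtype=np.int64)
    capped = np.empty(reps, dtype=bool)
    for r in range(reps):
        cfg = replace(config_base, seed=_spawned_seed(config_base.seed, r))
        out = cluster_from_start(cfg, cap=cap)
        sizes[r] = out.size
        capped[r] = out.capped
    return sizes, capped


def fit_power_law_tau(
    sizes: Sequence[int],
    s_min: int = 1,
    bins_per_decade: int = 6,
    min_bin_count: int = 5,
) -> PowerLawFit:
    """Exponent tau of the cluster-size distribution N(s) ~ s**(-tau).

    Sizes at or above ``s_min`` are histogrammed in logarithmic bins; the
    count in each bin is divided by the bin width to estimate the density,
    and ``log10(density)`` is regressed on ``log10(size)``.  The returned
    ``tau`` is the magnitude of the slope.

    Three standard refinements of log-binned regression are applied: bins
    with fewer than ``min_bin_count`` sizes are excluded (their log-density
    is dominated by sampling noise and flattens the slope); each bin's
    abscissa is the mean of the sizes it contains rather than its geometric
    centre (the within-bin mass of a decaying law sits left of centre); and
    the regression is weighted by the square root of the bin count, the
    inverse-variance weight for a log-transformed Poisson count.  If the
    occupancy cut leaves fewer than three bins it is relaxed to occupied
    bins only.
    """
    s = np.asarray(sizes, dtype=np.float64)
    s = s[s >= s_min]
    if s.size < 20:
        raise ValueError(f"need at least 20 sizes >= s_min={s_min}, have {s.size}")
    if np.all(s == s[0]):
        raise ValueError("degenerate histogram: all sizes identical")
    lo, hi = np.log10(s.min()), np.log10(s.max())
    n_edges = max(int(np.ceil((hi - lo) * bins_per_decade)) + 1, 4)
    edges = np.logspace(lo, hi, n_edges)
    edges[-1] *= 1.0 + 1e-12  # keep the max size inside the last bin
    counts, _ = np.histogram(s, bins=edges)
    widths = np.diff(edges)
    keep = counts >= min_bin_count
    if keep.sum() < 3:
        keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("degenerate histogram: fewer than 3 occupied bins")
    which = np.digitize(s, edges) - 1
    centers = np.array(
        [s[which == i].mean() if counts[i] else np.nan for i in range(len(counts))]
    )
    density = counts[keep] / widths[keep]
    x = np.log10(centers[keep])
    y = np.log10(density)
    if keep.sum() >= 4:
        w = np.sqrt(counts[keep])
        (slope, _), cov = np.polyfit(x, y, 1, w=w, cov=True)
        slope, stderr = float(slope), float(np.sqrt(cov[0, 0]))
    else:  # too few bins for a scaled covariance; plain regression
        res = stats.linregress(x, y)
        slope, stderr = float(res.slope), float(res.stderr)
    return PowerLawFit(
        tau=float(-slope),
        stderr=stderr,
        n_sizes=int(s.size),
        n_bins=int(keep.sum()),
    )
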
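"""Backward interval PLS (BiPLS) variable selection.

The region-filtered spectral variables are split into contiguous intervals
(default 45). Starting from the full set, each round scores the exclusion of
every surviving interval by leave-one-out PRESS — with the number of latent
variables re-selected for every candidate fit — and permanently removes the
interval whose exclusion gives the lowest PRESS, until a single interval
remains. The round with the lowest RMSE_CV (including the full-spectrum
starting model, round 0) defines the final variable set, which is compared
against an all-variable PLS model via ΔR²_CV.

Tie-breaking, where the underlying statistics are exactly equal: the lowest
interval index is excluded, and the earliest round (more variables retained)
is preferred as the best model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pls import CVResult, loocv, select_n_lv

__all__ = [
    "IntervalPartition",
    "BiPLSRound",
    "BiPLSTrace",
    "ComparisonResult",
    "partition",
    "bipls_run",
    "compare_models",
]


@dataclass(frozen=True)
class IntervalPartition:
    """Ordered contiguous (start, length) ranges covering 0..n_vars-1.

    Ranges are 0-based and half-open internally: interval k covers columns
    start_k .. start_k + length_k - 1.
    """

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for start, length in self.ranges:
            if start != pos or length < 1:
                raise ValueError("ranges must be contiguous, in order, non-empty")
            pos = start + length
        object.__setattr__(self, "_n_vars", pos)

    @property
    def n_vars(self) -> int:
        return self._n_vars

    @property
    def n_intervals(self) -> int:
        return len(self.ranges)

    def columns(self, k: int) -> np.ndarray:
        start, length = self.ranges[k]
        return np.arange(start, start + length)

    def columns_of(self, intervals) -> np.ndarray:
        """Concatenated column indices of the given interval ids, in order."""
        ids = sorted(intervals)
        if not ids:
            return np.empty(0, dtype=int)
        return np.concatenate([self.columns(k) for k in ids])


def partition(n_vars: int, n_intervals: int = 45) -> IntervalPartition:
    """Split ``n_vars`` columns into ``n_intervals`` contiguous intervals.

    Base size is n_vars // n_intervals; the remainder is distributed one
    extra variable to each of the first n_vars % n_intervals intervals.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if n_vars < n_intervals:
        raise ValueError(f"cannot split {n_vars} variables into {n_intervals} intervals")
    base, rem = divmod(n_vars, n_intervals)
    ranges = []
    pos = 0
    for k in range(n_intervals):
        length = base + (1 if k < rem else 0)
        ranges.append((pos, length))
        pos += length
    return IntervalPartition(tuple(ranges))


@dataclass
class BiPLSRound:
    """Record of one BiPLS round: the model on the surviving variables."""

    round_index: int
    excluded: int | None          # interval excluded entering this round
    surviving: tuple[int, ...]
    n_lv: int
    press: float
    rmse_cv: float


@dataclass
class BiPLSTrace:
    """Full BiPLS run record.

    ``rounds[0]`` is the all-interval starting model. ``best_round`` is the
    index of the round with minimal RMSE_CV (earliest on ties);
    ``selected_intervals`` are that round's survivors and ``nv`` the number
    of spectral variables they contain.
    """

    rounds: list[BiPLSRound]
    best_round: int
    selected_intervals: tuple[int, ...]
    nv: int
    final_cv: CVResult
    partition: IntervalPartition = field(repr=False)


def _candidate_score(X, y, cols, max_lv, p_threshold, n_randomizations, rng,
                     gram=None):
    """(press, n_lv, rmse) for the model on columns ``cols``; inf if degenerate.

    ``gram`` is the full-data XᵀX of all columns of X; the candidate's Gram
    is a gathered submatrix, so no cross-product is recomputed per candidate.
    """
    Xc = X[:, cols]
    if np.all(np.ptp(Xc, axis=0) == 0):
        return np.inf, 0, np.inf
    sub_gram = gram[np.ix_(cols, cols)] if gram is not None else None
    n_lv, press_curve = select_n_lv(
        Xc, y, max_lv=max_lv, p_threshold=p_threshold,
        n_randomizations=n_randomizations, rng=rng, gram=sub_gram,
    )
    press = float(press_curve[n_lv - 1])
    rmse = float(np.sqrt(press / y.size))
    return press, n_lv, rmse


def bipls_run(
    X: np.ndarray,
    y: np.ndarray,
    part: IntervalPartition,
    max_lv: int = 10,
    p_threshold: float = 0.10,
    n_randomizations: int = 1999,
    seed: int | None = 0,
) -> BiPLSTrace:
    """Run backward interval PLS and return the full trace.

    ``seed`` feeds the latent-variable randomization test; with data and
    seed fixed the trace is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != part.n_vars:
        raise ValueError(
            f"X has {X.shape[1]} columns but partition covers {part.n_vars}"
        )
    rng = np.random.default_rng(seed)
    surviving = list(range(part.n_intervals))
    gram = X.T @ X  # shared by every candidate column subset

    press0, lv0, rmse0 = _candidate_score(
        X, y, part.columns_of(surviving), max_lv, p_threshold, n_randomizations,
        rng, gram,
    )
    rounds = [BiPLSRound(0, None, tuple(surviving), lv0, press0, rmse0)]

    r = 1
    while len(surviving) > 1:
        best = None  # (press, interval, n_lv, rmse)
        for k in surviving:  # ascending order; strict '<' keeps the lowest index on ties
            cand = [i for i in surviving if i != k]
            press, n_lv, rmse = _candidate_score(
                X, y, part.columns_of(cand), max_lv, p_threshold,
                n_randomizations, rng, gram,
            )
            if best is None or press < best[0]:
                best = (press, k, n_lv, rmse)
        press, excluded, n_lv, rmse = best
        surviving.remove(excluded)
        rounds.append(BiPLSRound(r, excluded, tuple(surviving), n_lv, press, rmse))
        r += 1

    rmses = np.array([rd.rmse_cv for rd in rounds])
    best_round = int(np.argmin(rmses))  # argmin returns the earliest on ties
    best = rounds[best_round]
    cols = part.columns_of(best.surviving)
    final_cv = loocv(X[:, cols], y, best.n_lv)
    return BiPLSTrace(
        rounds=rounds,
        best_round=best_round,
        selected_intervals=tuple(sorted(best.surviving)),
        nv=int(cols.size),
        final_cv=final_cv,
        partition=part,
    )


@dataclass
class ComparisonResult:
    """Full-spectrum PLS vs best BiPLS model for one trait."""

    trait: str
    pls: CVResult
    bipls: CVResult
    trace: BiPLSTrace = field(repr=False)

    @property
    def delta_r2_cv(self) -> float:
        return self.bipls.r2_cv - self.pls.r2_cv

    @property
    def nv(self) -> int:
        return self.trace.nv


def compare_models(
    X: np.ndarray,
    y: np.ndarray,
    part: IntervalPartition,
    max_lv: int = 10,
    p_threshold: float = 0.10,
    n_randomizations: int = 1999,
    seed: int | None = 0,
    trait: str = "",
) -> ComparisonResult:
    """Fit the full-spectrum PLS model and a BiPLS run with the same settings.

    Both models select their latent-variable count by the same PRESS +
    randomization rule; ΔR²_CV = R²_CV(BiPLS) − R²_CV(PLS).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    pls_lv, _ = select_n_lv(X, y, max_lv=max_lv, p_threshold=p_threshold,
                            n_randomizations=n_randomizations, rng=rng)
    pls_cv = loocv(X, y, pls_lv)
    trace = bipls_run(X, y, part, max_lv=max_lv, p_threshold=p_threshold,
                      n_randomizations=n_randomizations, seed=seed)
    return ComparisonResult(trait=trait, pls=pls_cv, bipls=trace.final_cv, trace=trace)
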
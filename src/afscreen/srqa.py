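"""Symbolic recurrence quantification analysis (SRQA) of RR series.

An RR series {x_t} is delay-embedded (delay 1) into overlapping
m-histories (x_t, ..., x_{t+m-1}).  Each m-history is mapped to its
ordinal pattern: the permutation of time offsets that sorts the values
ascending, ties broken by time order.  E.g. for m = 3 the history
(0.55, 0.65, 0.60) sorts as offsets (0, 2, 1).  Two histories are
recurrent when they share the same pattern, giving the symbolic
recurrence plot (SRP): an N x N matrix whose (t, s) entry is the symbol
code k when patterns t and s coincide with pattern pi_k, else 0.

Because ordinal patterns depend only on the *order* of the values, every
SRQA quantity is exactly invariant under strictly increasing transforms
of the series — in particular under any affine device calibration with
positive slope.  This is what makes the downstream classifier robust to
uncalibrated low-cost sensors.

Line-based statistics follow standard recurrence quantification
conventions: the line of identity (main diagonal) is excluded, and the
minimum line length is 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import RRSeries, as_rr

__all__ = [
    "SymbolSequence",
    "alphabet",
    "embed",
    "symbolize",
    "symbolize_series",
    "build_srp",
    "recurrence_rates",
    "diagonal_measures",
    "vertical_measures",
    "symbol_entropy",
    "distribution_stats",
    "feature_vector",
    "FEATURE_NAMES",
    "plot_srp",
]

#: fixed ordering of the default 9-covariate feature vector
FEATURE_NAMES = (
    "det",
    "lam",
    "l_max",
    "l_mean",
    "symbol_entropy",
    "rr_mean",
    "rr_median",
    "rr_cv",
    "rr_cv_med",
)


def alphabet(m: int) -> List[Tuple[int, ...]]:
    """The m! ordinal patterns of order m in lexicographic (canonical) order."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return list(permutations(range(m)))


@dataclass(frozen=True)
class SymbolSequence:
    """Ordinal-pattern codes of an embedded series.

    ``symbols`` holds 0-based indices into the lexicographic alphabet of
    the m! permutations; length is T - m + 1 for a source of length T.
    """

    symbols: np.ndarray
    m: int

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=int)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("symbols must be a non-empty 1-D array")
        if s.min() < 0 or s.max() >= factorial(self.m):
            raise ValueError("symbol codes must index the m! alphabet")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def patterns(self) -> List[Tuple[int, ...]]:
        """The symbols as permutation tuples."""
        alpha = alphabet(self.m)
        return [alpha[k] for k in self.symbols]


def embed(x: RRSeries | Sequence[float], m: int = 3) -> np.ndarray:
    """Delay embedding (delay 1): T - m + 1 overlapping m-histories."""
    values = x.values if isinstance(x, RRSeries) else np.asarray(x, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if values.size < m:
        raise ValueError(f"series of length {values.size} is shorter than m={m}")
    return np.lib.stride_tricks.sliding_window_view(values, m)


def symbolize(history: Sequence[float]) -> Tuple[int, ...]:
    """Ordinal pattern of one m-history.

    Returns the tuple of time offsets 0..m-1 sorted by ascending value;
    ties are broken by ascending offset (stable sort), e.g.
    (0.55, 0.65, 0.60) -> (0, 2, 1) and (1, 1, 1) -> (0, 1, 2).
    """
    h = np.asarray(history, dtype=float)
    return tuple(int(i) for i in np.argsort(h, kind="stable"))


def symbolize_series(x: RRSeries | Sequence[float], m: int = 3) -> SymbolSequence:
    """Symbolize every m-history of a series into alphabet codes."""
    histories = embed(x, m)
    alpha = {p: k for k, p in enumerate(alphabet(m))}
    codes = np.fromiter(
        (alpha[symbolize(h)] for h in histories), dtype=int, count=histories.shape[0]
    )
    return SymbolSequence(codes, m)


def build_srp(symbols: SymbolSequence) -> np.ndarray:
    """Symbolic recurrence plot: N x N integer matrix.

    Entry (t, s) is k+1 (1-based symbol id in the canonical alphabet)
    when symbols t and s coincide with pattern pi_k, else 0.  The matrix
    is symmetric and its main diagonal is fully non-zero
    (self-recurrence).
    """
    s = symbols.symbols
    equal = s[:, None] == s[None, :]
    return np.where(equal, s[None, :] + 1, 0)


def recurrence_rates(symbols: SymbolSequence) -> np.ndarray:
    """Per-symbol off-diagonal recurrence rates.

    rate_k = (# ordered off-diagonal recurrent pairs with symbol k)
    / (N (N-1)); the line of identity is excluded.  The rates sum to the
    global off-diagonal recurrence rate.
    """
    s = symbols.symbols
    n = s.size
    if n < 2:
        raise ValueError("need at least two symbols")
    n_sym = len(alphabet(symbols.m))
    counts = np.bincount(s, minlength=n_sym).astype(float)
    return counts * (counts - 1) / (n * (n - 1))


def _runs(values: np.ndarray) -> List[int]:
    """Lengths of maximal runs of True in a boolean vector."""
    lengths: List[int] = []
    count = 0
    for v in values:
        if v:
            count += 1
        elif count:
            lengths.append(count)
            count = 0
    if count:
        lengths.append(count)
    return lengths


def diagonal_measures(srp: np.ndarray, l_min: int = 2) -> Dict[str, float]:
    """Determinism and diagonal-line statistics of an SRP.

    Runs of consecutive recurrent points are enumerated along every
    diagonal of the upper triangle (the line of identity is excluded);
    by symmetry the lower triangle contributes identically.

    Returns ``det`` (fraction of recurrent points lying on diagonal runs
    of length >= l_min), ``l_max`` (longest run) and ``l_mean`` (mean
    length of runs >= l_min); all zero when there are no recurrent
    points.
    """
    n = srp.shape[0]
    if n < 2:
        raise ValueError("SRP must be at least 2 x 2")
    rec = srp != 0
    total = 0
    in_lines = 0
    all_runs: List[int] = []
    for off in range(1, n):
        d = np.diagonal(rec, offset=off)
        total += int(d.sum())
        for run in _runs(d):
            all_runs.append(run)
            if run >= l_min:
                in_lines += run
    long_runs = [r for r in all_runs if r >= l_min]
    return {
        "det": in_lines / total if total else 0.0,
        "l_max": float(max(all_runs)) if all_runs else 0.0,
        "l_mean": float(np.mean(long_runs)) if long_runs else 0.0,
    }


def vertical_measures(srp: np.ndarray, v_min: int = 2) -> Dict[str, float]:
    """Laminarity and trapping time from vertical lines of an SRP.

    Runs are enumerated down every column with the main-diagonal cell
    masked out.  ``lam`` is the fraction of off-diagonal recurrent points
    lying on vertical runs of length >= v_min; ``tt`` (trapping time) is
    the mean length of those runs.
    """
    n = srp.shape[0]
    if n < 2:
        raise ValueError("SRP must be at least 2 x 2")
    rec = srp != 0
    np.fill_diagonal(rec := rec.copy(), False)
    total = int(rec.sum())
    in_lines = 0
    long_runs: List[int] = []
    for col in range(n):
        for run in _runs(rec[:, col]):
            if run >= v_min:
                in_lines += run
                long_runs.append(run)
    return {
        "lam": in_lines / total if total else 0.0,
        "tt": float(np.mean(long_runs)) if long_runs else 0.0,
    }


def symbol_entropy(symbols: SymbolSequence) -> float:
    """Shannon entropy (nats) of the per-symbol recurrence-rate distribution.

    Rates are normalized to a probability vector; the entropy lies in
    [0, log m!] and is 0 for a constant-symbol series.
    """
    rates = recurrence_rates(symbols)
    tot = rates.sum()
    if tot == 0:
        return 0.0
    p = rates[rates > 0] / tot
    return float(-np.sum(p * np.log(p)))


def distribution_stats(rr: RRSeries | Sequence[float]) -> Dict[str, float]:
    """Distribution covariates of the raw RR values.

    Mean; median; Pearson coefficient of variation (sample sd, ddof 1,
    over mean); robust CV of the median (median absolute deviation over
    median).
    """
    values = as_rr(rr).values
    if values.size < 2:
        raise ValueError("need at least two intervals")
    mean = float(np.mean(values))
    median = float(np.median(values))
    if mean == 0 or median == 0:
        raise ValueError("zero mean/median — CV undefined")
    return {
        "rr_mean": mean,
        "rr_median": median,
        "rr_cv": float(np.std(values, ddof=1) / mean),
        "rr_cv_med": float(np.median(np.abs(values - median)) / median),
    }


def feature_vector(
    rr: RRSeries | Sequence[float],
    m: int = 3,
    features: Sequence[str] = FEATURE_NAMES,
) -> Dict[str, float]:
    """Compute the covariate vector of one RR window.

    The default nine covariates combine the symbolic-recurrence group
    (det, lam, l_max, l_mean, symbol_entropy) with the RR-distribution
    group (rr_mean, rr_median, rr_cv, rr_cv_med), in the fixed order of
    :data:`FEATURE_NAMES`.
    """
    rr = as_rr(rr)
    if len(rr) < m + 1:
        raise ValueError(f"window of {len(rr)} intervals too short for m={m}")
    symbols = symbolize_series(rr, m)
    srp = build_srp(symbols)
    pool: Dict[str, float] = {}
    pool.update(diagonal_measures(srp))
    pool.update(vertical_measures(srp))
    pool["symbol_entropy"] = symbol_entropy(symbols)
    pool.update(distribution_stats(rr))
    unknown = [f for f in features if f not in pool]
    if unknown:
        raise KeyError(f"unknown features: {unknown}")
    return {name: pool[name] for name in features}


def plot_srp(srp: np.ndarray, m: int = 3, ax=None, title: str | None = None):
    """Render an SRP as a colored dot plot (one color per symbol)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    n_sym = len(alphabet(m))
    cmap = plt.get_cmap("tab10", n_sym)
    for k in range(1, n_sym + 1):
        t, s = np.nonzero(srp == k)
        if t.size:
            ax.scatter(t, s, s=4, color=cmap(k - 1), label=str(alphabet(m)[k - 1]))
    ax.set_xlabel("t")
    ax.set_ylabel("s")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, markerscale=2, loc="upper right")
    return ax
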
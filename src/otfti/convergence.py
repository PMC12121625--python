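"""Jensen-Shannon convergence test on a decorrelated gradient series.

The decorrelated series is split in half chronologically, each half is
binned into equally spaced bins spanning the pooled range, and the
Jensen-Shannon distance — the square root of the symmetrized,
smoothed Kullback-Leibler divergence, computed with base-2 logarithms
so that it is bounded in [0, 1] — between the two histograms decides
whether the window has converged. The base-2 convention matters: it
fixes the scale on which the 0.1 threshold operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import GradientSeries, ProtocolConfig
from .equilibration import detect_equilibration, subsample

__all__ = [
    "Decision",
    "ConvergenceReport",
    "split_halves",
    "histogram_pair",
    "js_distance",
    "decide",
    "assess",
]


class Decision(str, Enum):
    CONVERGED = "converged"
    EXTEND = "extend"
    SOFT_CAP_STOP = "soft_cap_stop"
    HARD_CAP_STOP = "hard_cap_stop"


@dataclass(frozen=True)
class ConvergenceReport:
    """One convergence assessment of a window's gradient series.

    ``js_distance`` is NaN when fewer than two decorrelated samples
    were available to split. ``degenerate_range`` flags a pooled data
    range of zero width (all mass forced into one bin, P = Q).
    """

    js_distance: float
    n_decorrelated: int
    bin_edges: np.ndarray
    first_half_probs: np.ndarray
    second_half_probs: np.ndarray
    decision: Decision
    threshold_used: float
    total_time: float
    degenerate_range: bool = False

    def to_dict(self) -> dict:
        js = self.js_distance
        return {
            "js_distance": None if math.isnan(js) else js,
            "n_decorrelated": self.n_decorrelated,
            "bin_edges": list(map(float, self.bin_edges)),
            "first_half_probs": list(map(float, self.first_half_probs)),
            "second_half_probs": list(map(float, self.second_half_probs)),
            "decision": self.decision.value,
            "threshold_used": self.threshold_used,
            "total_time": self.total_time,
            "degenerate_range": self.degenerate_range,
        }


def split_halves(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a sequence in half chronologically.

    For odd length the second half keeps the extra sample.
    """
    x = np.asarray(values)
    if x.size < 2:
        raise ValueError("need at least 2 samples to split in half")
    mid = x.size // 2
    return x[:mid], x[mid:]


def histogram_pair(
    first: np.ndarray, second: np.ndarray, n_bins: int = 7
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Histogram both halves on shared equally spaced bins.

    Bin edges span the pooled [min, max] of both halves so the two
    probability vectors are comparable; the rightmost bin is closed.
    Returns (edges, P, Q, degenerate) where ``degenerate`` marks a
    zero-width pooled range (P = Q with all mass in one bin).
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both halves must be nonempty")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        edges = lo + np.arange(n_bins + 1, dtype=float)  # placeholder width-1 bins
        p = np.zeros(n_bins)
        q = np.zeros(n_bins)
        p[0] = q[0] = 1.0
        return edges, p, q, True
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    return edges, p / a.size, q / b.size, False


def js_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon distance between two discrete distributions.

    sqrt( (D(P||M) + D(Q||M)) / 2 ) with M = (P + Q)/2, KL divergences
    in bits (base-2 logarithms), so the result lies in [0, 1]. Terms
    with P_i = 0 contribute zero.
    """
    p = np.asarray(P, dtype=float)
    q = np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be nonnegative")
    if not (math.isclose(p.sum(), 1.0, abs_tol=1e-9) and math.isclose(q.sum(), 1.0, abs_tol=1e-9)):
        raise ValueError("P and Q must each sum to 1")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    jsd = 0.5 * (_kl(p) + _kl(q))
    return math.sqrt(max(jsd, 0.0))


def decide(js: float, n_decorrelated: int, total_time: float, cfg: ProtocolConfig) -> Decision:
    """Stopping decision from the three convergence predicates.

    Precedence: converged (js <= threshold, a tie counts, with at
    least min_decorrelated samples) > soft cap (total_time >= soft_cap
    with strictly more than min_decorrelated samples) > hard cap
    (total_time >= hard_cap) > extend. A NaN js fails the convergence
    predicate.
    """
    if not math.isnan(js) and js <= cfg.js_threshold and n_decorrelated >= cfg.min_decorrelated:
        return Decision.CONVERGED
    if total_time >= cfg.soft_cap and n_decorrelated > cfg.min_decorrelated:
        return Decision.SOFT_CAP_STOP
    if total_time >= cfg.hard_cap:
        return Decision.HARD_CAP_STOP
    return Decision.EXTEND


def assess(series: GradientSeries, cfg: ProtocolConfig, total_time: float) -> ConvergenceReport:
    """Run the full convergence test on a raw window series.

    Pipeline: equilibration detection -> decorrelation -> chronological
    halving -> shared-bin histograms -> Jensen-Shannon distance.
    Decision logic, in order of precedence:

    * converged    — JS <= threshold and n_decorrelated >= min_decorrelated
    * soft cap     — total_time >= soft_cap and n_decorrelated > min_decorrelated
    * hard cap     — total_time >= hard_cap
    * extend       — otherwise

    A tie at the threshold counts as converged. When fewer than two
    decorrelated samples exist the JS distance is reported as NaN (it
    fails the convergence predicate, so only the hard cap can stop such
    a window).
    """
    eq = detect_equilibration(series)
    dec = subsample(series, eq)
    n_dec = len(dec)

    if n_dec < 2:
        js = math.nan
        edges = np.array([])
        p = np.array([])
        q = np.array([])
        degenerate = False
    else:
        first, second = split_halves(dec.values)
        edges, p, q, degenerate = histogram_pair(first, second, cfg.n_bins)
        js = js_distance(p, q)

    decision = decide(js, n_dec, total_time, cfg)

    return ConvergenceReport(
        js_distance=js,
        n_decorrelated=n_dec,
        bin_edges=edges,
        first_half_probs=p,
        second_half_probs=q,
        decision=decision,
        threshold_used=cfg.js_threshold,
        total_time=total_time,
        degenerate_range=degenerate,
    )
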
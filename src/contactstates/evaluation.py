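"""Scoring categorizations against time order, K histograms, and per-K
maximum-posterior parameter extraction.

The synthetic benchmarks carry an intrinsic ground truth: frames are
time-ordered and the underlying motion is monotone, so a good
categorization is a concatenation of contiguous label runs.  Perfection
needs exactly K − 1 label transitions; every extra transition marks a
mis-categorized frame.

Two scores per categorization z:

* ``left_pct``  = 100 · (1 − (T − (K_used − 1)) / N) — the raw
  excess-transition penalty, with T the number of adjacent label changes.
* ``right_pct`` — the same after excusing boundary oscillation: adjacent-
  transition counts form a weighted graph over labels; transitions along
  the maximum-weight simple path visiting every label (the "most likely
  path" through the motion) are excused, so only genuinely out-of-sequence
  transitions count as errors.

Both are invariant under relabeling of categories.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import log_resp_matrix

_EXACT_PATH_LIMIT = 12


@dataclass
class AccuracyReport:
    left_pct: float
    right_pct: float
    n_transitions: int
    k_used: int


@dataclass
class KHistogram:
    """Counts of non-empty-category numbers across posterior samples."""

    counts: dict

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def mode(self) -> int:
        return max(self.counts, key=lambda k: (self.counts[k], -k))

    @property
    def mean(self) -> float:
        return sum(k * c for k, c in self.counts.items()) / self.total


def _max_weight_path(labels, weights):
    """Edge set of the maximum-weight simple path visiting every label.

    Exact (Held-Karp subset DP) up to 12 labels; greedy edge insertion
    (heaviest edges first, keeping degrees <= 2 and acyclicity) beyond.
    """
    k = len(labels)
    if k <= 1:
        return set()
    if k <= _EXACT_PATH_LIMIT:
        # exact Held-Karp DP over label subsets: dp[mask][last] = best weight
        # of a simple path covering `mask` that ends at `last`
        w = [[weights.get(frozenset((a, b)), 0) for b in labels] for a in labels]
        full = (1 << k) - 1
        dp = {(1 << i, i): (0, None) for i in range(k)}
        for mask in range(1, full + 1):
            for last in range(k):
                cur = dp.get((mask, last))
                if cur is None or not (mask >> last) & 1:
                    continue
                for nxt in range(k):
                    if (mask >> nxt) & 1:
                        continue
                    nm = mask | (1 << nxt)
                    cand = cur[0] + w[last][nxt]
                    if cand > dp.get((nm, nxt), (-1, None))[0]:
                        dp[(nm, nxt)] = (cand, (mask, last))
        end = max(range(k), key=lambda i: dp.get((full, i), (-1, None))[0])
        edges, key = set(), (full, end)
        while dp[key][1] is not None:
            pmask, plast = dp[key][1]
            edges.add(frozenset((labels[key[1]], labels[plast])))
            key = (pmask, plast)
        return edges
    # greedy fallback for very large K
    degree = {l: 0 for l in labels}
    comp = {l: l for l in labels}

    def find(a):
        while comp[a] != a:
            comp[a] = comp[comp[a]]
            a = comp[a]
        return a

    chosen = set()
    for edge, _w in sorted(weights.items(), key=lambda kv: -kv[1]):
        a, b = tuple(edge)
        if degree[a] >= 2 or degree[b] >= 2 or find(a) == find(b):
            continue
        chosen.add(edge)
        degree[a] += 1
        degree[b] += 1
        comp[find(a)] = find(b)
        if len(chosen) == k - 1:
            break
    return chosen


def time_order_accuracy(z) -> AccuracyReport:
    """Score one categorization against the frame order (see module docs)."""
    z = np.asarray(z)
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 frames to count transitions")
    changes = z[1:] != z[:-1]
    T = int(changes.sum())
    labels = np.unique(z)
    k_used = labels.size
    left = 100.0 * (1.0 - (T - (k_used - 1)) / n)
    weights = Counter(frozenset((int(a), int(b)))
                      for a, b in zip(z[:-1][changes], z[1:][changes]))
    path = _max_weight_path([int(l) for l in labels], weights)
    excused = sum(c for e, c in weights.items() if e in path)
    right = 100.0 * (1.0 - (T - excused) / n)
    return AccuracyReport(left_pct=float(left), right_pct=float(right),
                          n_transitions=T, k_used=k_used)


def summarize_accuracy(samples) -> dict:
    """Mean and interquartile range of both scores over pooled samples."""
    reports = [time_order_accuracy(s.z) for s in samples]
    lefts = np.array([r.left_pct for r in reports])
    rights = np.array([r.right_pct for r in reports])
    q = lambda v: [float(np.percentile(v, 25)), float(np.percentile(v, 75))]
    return {
        "mean_left_pct": float(lefts.mean()),
        "mean_right_pct": float(rights.mean()),
        "iqr_left_pct": q(lefts),
        "iqr_right_pct": q(rights),
        "n_samples": len(reports),
    }


def k_histogram(samples) -> KHistogram:
    """Histogram of the number of occupied categories per retained sample."""
    if not samples:
        raise ValueError("no samples to histogram")
    return KHistogram(counts=dict(Counter(s.k_nonempty for s in samples)))


def best_theta_per_k(samples) -> dict:
    """For each observed K, the sample with the largest log posterior
    (ties broken by earliest chain then step)."""
    best = {}
    for s in sorted(samples, key=lambda s: (s.chain_id, s.step)):
        k = s.k_nonempty
        if k not in best or s.log_post > best[k].log_post:
            best[k] = s
    return best


def representative_frames(fm, theta) -> dict:
    """Frame index maximizing each category's responsibility (ties -> lowest
    frame index).  A category that is never any frame's argmax still gets
    its own maximizing frame."""
    ll = log_resp_matrix(fm, theta)
    return {k: int(np.argmax(ll[:, k])) for k in range(theta.n_categories)}
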
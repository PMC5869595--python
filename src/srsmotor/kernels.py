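"""Shared stochastic primitives: the discretised sliding kernel and the
reflecting boundary map.

Both the Monte Carlo engine and the exact transition-matrix oracle use the
same probability mass function and the same fold, so oracle tests exercise
the simulator's semantics rather than an independent re-derivation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def slide_magnitude_pmf(mean: float, sd: float, tail: float = 1e-12):
    """PMF of the sliding-step magnitude in bp.

    The magnitude is |X| rounded to the nearest non-negative integer where X
    is drawn from Normal(mean, sd) truncated to X >= 0 (negative draws are
    resampled).  Returns ``(support, pmf)`` with support ``0..kmax``.
    """
    if sd < 0 or mean < 0:
        raise ValueError("sliding mean and sd must be >= 0")
    if sd == 0:
        k = int(round(mean))
        support = np.arange(k + 1)
        pmf = np.zeros(k + 1)
        pmf[k] = 1.0
        return support, pmf
    dist = norm(mean, sd)
    kmax = int(np.ceil(mean + sd * norm.isf(tail)))
    edges = np.concatenate(([0.0], np.arange(kmax + 1) + 0.5))
    pmf = np.diff(dist.cdf(edges))
    total = pmf.sum()
    if total <= 0:
        raise ValueError("degenerate sliding kernel (no mass at X >= 0)")
    return np.arange(kmax + 1), pmf / total


def sample_slide_steps(pmf: np.ndarray, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Signed sliding displacements: magnitude from ``pmf``, sign +/-1 with
    equal probability."""
    mags = rng.choice(len(pmf), size=size, p=pmf)
    signs = rng.integers(0, 2, size=size) * 2 - 1
    return mags * signs


def srs_neighbor_tables(is_srs: np.ndarray):
    """Per-site lookup of the nearest SRS site at or beyond each position.

    Returns ``(next_left, next_right)``: ``next_right[i]`` is the smallest
    ``j >= i`` with ``is_srs[j]`` (or ``n`` when none), ``next_left[i]`` the
    largest ``j <= i`` (or ``-1``).  Used to find the first SRS site a
    sliding motor scans across.
    """
    n = is_srs.size
    idx = np.arange(n)
    nr = np.where(is_srs, idx, n)
    next_right = np.minimum.accumulate(nr[::-1])[::-1]
    nl = np.where(is_srs, idx, -1)
    next_left = np.maximum.accumulate(nl)
    return next_left, next_right


def slide_destinations(start: np.ndarray, steps: np.ndarray, n: int,
                       next_left: np.ndarray | None = None,
                       next_right: np.ndarray | None = None) -> np.ndarray:
    """Destination of a sliding step with boundary reflection and SRS capture.

    The motor scans every site between its origin (exclusive) and the step
    endpoint (inclusive), reflecting off the lattice ends; it stops at the
    first SRS site it crosses.  With ``next_left``/``next_right`` omitted
    the step is a plain reflected jump (any magnitude).  With capture
    tables, |step| must be <= n-1 so the scanned path bounces at most once.
    """
    start = np.asarray(start)
    steps = np.asarray(steps)
    raw = start + steps
    dest = reflect_positions(raw, n)
    if next_left is None:
        return dest
    if steps.size and np.abs(steps).max() > n - 1:
        raise ValueError("SRS-capture sliding limited to |step| <= n-1; "
                         "the sliding kernel reach exceeds the lattice")
    moving = steps != 0
    pos_dir = moving & (steps > 0)
    neg_dir = moving & (steps < 0)
    out = dest.copy()

    # segment 1: origin (exclusive) to the endpoint or boundary
    seg1_end = np.clip(raw, 0, n - 1)
    from1 = np.clip(start + np.sign(steps), 0, n - 1)
    cap_r = next_right[from1]
    hit_r = pos_dir & (start + 1 <= seg1_end) & (cap_r <= seg1_end)
    cap_l = next_left[from1]
    hit_l = neg_dir & (start - 1 >= seg1_end) & (cap_l >= seg1_end)

    # segment 2: after one reflection, scanning back from the boundary
    bounced_r = pos_dir & (raw > n - 1) & ~hit_r
    bounced_l = neg_dir & (raw < 0) & ~hit_l
    cap2_l = next_left[np.clip(n - 2, 0, n - 1)]
    hit2_r = bounced_r & (cap2_l >= dest) & (n >= 2)
    cap2_r = next_right[np.clip(1, 0, n - 1)]
    hit2_l = bounced_l & (cap2_r <= dest) & (n >= 2)

    out = np.where(hit_r, cap_r, out)
    out = np.where(hit_l, cap_l, out)
    out = np.where(hit2_r & ~(hit_r | hit_l), cap2_l, out)
    out = np.where(hit2_l & ~(hit_r | hit_l), cap2_r, out)
    return out


def reflect_positions(pos, n: int):
    """Fold positions into [0, n-1] by reflection at both boundaries."""
    pos = np.asarray(pos)
    if n == 1:
        return np.zeros_like(pos)
    period = 2 * (n - 1)
    x = np.mod(pos, period)
    return np.where(x > n - 1, period - x, x)
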
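"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (quadratic scans, exhaustive
enumeration) and share no code with the package's detectors.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from gazereach.simulate import CohortParams


def idt_oracle(x, y, min_samples: int, threshold: float) -> list[tuple[int, int]]:
    """Brute-force I-DT: recompute the window dispersion from scratch at
    every step.  Returns (start_index, end_index) pairs (inclusive)."""
    x = list(map(float, x))
    y = list(map(float, y))
    m = len(x)
    out = []
    i = 0
    while i + min_samples <= m:
        j = i + min_samples
        wx, wy = x[i:j], y[i:j]
        if (max(wx) - min(wx)) + (max(wy) - min(wy)) > threshold:
            i += 1
            continue
        while j < m:
            wx, wy = x[i : j + 1], y[i : j + 1]
            if (max(wx) - min(wx)) + (max(wy) - min(wy)) > threshold:
                break
            j += 1
        out.append((i, j - 1))
        i = j
    return out


def wilcoxon_oracle(d) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank by enumerating all 2^n sign assignments.

    Returns (W, p) where W is the smaller of the two signed-rank sums and p
    the exact two-sided probability.  Requires tie-free, zero-free |d|.
    """
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))  # average ranks on ties
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    w_obs = min(w_plus, total - w_plus)
    # null distribution of W+ over all sign assignments
    dist: dict[float, int] = {}
    for signs in product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        dist[w] = dist.get(w, 0) + 1
    count = 2**n
    p_le = sum(c for w, c in dist.items() if w <= w_plus) / count
    p_ge = sum(c for w, c in dist.items() if w >= w_plus) / count
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_obs, p


def minimum_jerk_speed(t, extent: float, duration: float):
    """Closed-form minimum-jerk speed profile (cm/s) for a reach of the
    given extent and duration starting at t = 0."""
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    return 30.0 * extent / duration * tau**2 * (1.0 - tau) ** 2


@pytest.fixture
def noise_free_params() -> CohortParams:
    p = CohortParams(
        fixation_jitter_sd=0.0,
        hand_noise_sd=0.0,
        exclusion_rate=0.0,
        n_participants=4,
    )
    return p


@pytest.fixture(scope="session")
def small_cohort_trials():
    """A 6-participant cohort run through the full pipeline once per session."""
    from gazereach.pipeline import analyze_cohort

    return analyze_cohort(CohortParams(n_participants=6), design_seed=11)
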
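"""Analyzable-cell-count model shared by both simulators.

The screen's imaging read-out detected on average 795 cells per well with a
standard deviation of 345. Detected counts are non-negative, so the model is
a truncated normal on [0, inf). The underlying (pre-truncation) location and
scale are calibrated numerically so that the *observed* distribution — the
thing the defaults describe — has exactly the target mean and SD; plugging
795/345 in directly would bias the observed mean upward by ~1.2% because the
truncation clips the lower tail.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .errors import InputError

#: Mean analyzable cells per well (screen-wide calibration target).
DEFAULT_MEAN = 795.0
#: Standard deviation of analyzable cells per well.
DEFAULT_SD = 345.0


@lru_cache(maxsize=32)
def truncated_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (loc, scale) of a [0, inf)-truncated normal whose
    truncated mean and SD equal ``mean`` and ``sd``.

    Solved with a root finder on the analytic truncated moments.
    """
    if mean <= 0 or sd <= 0:
        raise InputError(f"mean and sd must be positive, got {mean}, {sd}")

    def residual(x):
        loc, scale = x
        scale = abs(scale)
        a = -loc / scale
        m, v = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale,
                                     moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(residual, x0=[mean, sd], full_output=False)
    loc, scale = float(sol[0]), float(abs(sol[1]))
    check = residual([loc, scale])
    if max(abs(check[0]), abs(check[1])) > 1e-6 * max(mean, sd):
        raise RuntimeError(
            f"truncated-normal calibration did not converge for "
            f"mean={mean}, sd={sd}")
    return loc, scale


def sample_cell_counts(
    n: int,
    rng: np.random.Generator,
    mean: float = DEFAULT_MEAN,
    sd: float = DEFAULT_SD,
) -> np.ndarray:
    """Draw ``n`` integer per-well analyzable cell counts.

    Counts follow the calibrated truncated normal and are rounded to the
    nearest integer (rounding is mean-preserving at this scale).
    """
    if n < 0:
        raise InputError(f"n must be >= 0, got {n}")
    loc, scale = truncated_normal_params(mean, sd)
    a = -loc / scale
    draws = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n,
                                random_state=rng)
    return np.rint(draws).astype(np.int64)
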
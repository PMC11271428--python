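"""Scott-Knott clustering of treatment means into non-overlapping groups.

Means are sorted and recursively split at the contiguous partition that
maximizes the between-group sum of squares B0.  A split is accepted when

    lambda = pi / (2 * (pi - 2)) * B0 / sigma0^2

exceeds the chi-square critical value at nu0 = g / (pi - 2) degrees of
freedom, where sigma0^2 is the maximum-likelihood estimate of the variance
of a treatment mean pooled with the experimental error:

    sigma0^2 = (1 / (g + nu)) * (sum_i (ybar_i - ybar)^2 + nu * s2y)

with s2y = ms_error / reps and nu the error degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ValidationError

_PI = np.pi


@dataclass(frozen=True)
class ScottKnottGrouping:
    """Ordered partition of labels (highest-mean group first) plus letter codes."""

    groups: list[list[str]]
    letters: dict[str, str]
    alpha: float


def _best_contiguous_split(y: np.ndarray) -> tuple[float, int]:
    """Max between-group SS over contiguous splits of sorted means.

    Returns (B0, cut) where the left group is y[:cut].
    """
    n = len(y)
    total = y.sum()
    best_b0, best_cut = -np.inf, 1
    csum = np.cumsum(y)
    for cut in range(1, n):
        t1, k1 = csum[cut - 1], cut
        t2, k2 = total - t1, n - cut
        b0 = t1**2 / k1 + t2**2 / k2 - total**2 / n
        if b0 > best_b0 + 1e-12:
            best_b0, best_cut = b0, cut
    return float(best_b0), best_cut


def _lambda_stat(y: np.ndarray, b0: float, s2y: float, nu: int) -> tuple[float, float]:
    g = len(y)
    sigma0_sq = (np.sum((y - y.mean()) ** 2) + nu * s2y) / (g + nu)
    if sigma0_sq <= 0:
        return np.inf if b0 > 0 else 0.0, g / (_PI - 2)
    lam = _PI / (2 * (_PI - 2)) * b0 / sigma0_sq
    return float(lam), g / (_PI - 2)


def scott_knott(
    means: Mapping[str, float],
    ms_error: float,
    df_error: int,
    reps_per_mean: int,
    alpha: float = 0.05,
) -> ScottKnottGrouping:
    """Group treatment means by the Scott-Knott likelihood-ratio procedure."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if ms_error <= 0:
        raise ValidationError("ms_error must be positive")
    if len(means) < 2:
        raise ValidationError("need at least two means")
    labels = list(means)
    values = np.array([means[lab] for lab in labels], dtype=float)
    order = np.argsort(-values, kind="stable")  # descending: group 'a' = highest
    sorted_labels = [labels[i] for i in order]
    sorted_values = values[order]
    s2y = ms_error / reps_per_mean

    groups: list[list[str]] = []

    def recurse(lo: int, hi: int) -> None:
        y = sorted_values[lo:hi]
        if len(y) < 2 or np.ptp(y) == 0:
            groups.append(sorted_labels[lo:hi])
            return
        b0, cut = _best_contiguous_split(y)
        # never separate identical means across the boundary
        if y[cut - 1] == y[cut]:
            groups.append(sorted_labels[lo:hi])
            return
        lam, nu0 = _lambda_stat(y, b0, s2y, df_error)
        crit = stats.chi2.ppf(1 - alpha, nu0)
        if lam > crit:
            recurse(lo, lo + cut)
            recurse(lo + cut, hi)
        else:
            groups.append(sorted_labels[lo:hi])

    recurse(0, len(sorted_values))

    letters: dict[str, str] = {}
    for gi, group in enumerate(groups):
        code = _letter_code(gi)
        for lab in group:
            letters[lab] = code
    return ScottKnottGrouping(groups, letters, alpha)


def _letter_code(i: int) -> str:
    code = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        code = chr(ord("a") + rem) + code
    return code
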
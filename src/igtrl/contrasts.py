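"""Group contrasts of posterior parameter estimates via highest-density intervals.

A parameter differs "significantly" between two independently fitted groups
when the 95% HDI of the posterior difference of their group-level means
(constrained scale) excludes zero. Because the fits are independent, the
difference distribution is formed by index-pairing seeded shuffles of the
two chains' draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from zlib import crc32

import numpy as np
import pandas as pd

from .task import ValidationError


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * S)`` samples.

    Sliding-window minimum-width scan over the sorted draws; ties broken
    toward the earlier (lower) window. With mass -> 1 this returns the
    sample range.
    """
    if not 0.0 < mass < 1.0:
        raise ValidationError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    S = x.size
    if S < 2:
        raise ValidationError("need at least 2 samples for an HDI")
    m = int(np.ceil(mass * S))
    if m >= S:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: S - m + 1]
    j = int(np.argmin(widths))  # argmin takes the first minimum: earlier window
    return float(x[j]), float(x[j + m - 1])


@dataclass(frozen=True)
class DiffResult:
    """Posterior contrast of one parameter between two groups (A - B)."""

    parameter: str
    group_a: str
    group_b: str
    diff_draws: np.ndarray
    hdi_low: float
    hdi_high: float
    hdi_mean: float
    significant: bool

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "pair": f"{self.group_a}-{self.group_b}",
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "hdi_mean": self.hdi_mean,
            "significant": self.significant,
        }


def compare_groups(
    fit_a,
    fit_b,
    parameter: str,
    mass: float = 0.95,
    seed: int = 0,
) -> DiffResult:
    """Contrast one group-level mean between two fits (A - B).

    Draws are shuffled with a seeded generator, truncated to the shorter
    chain and paired by index; any pairing of independent fits yields the
    correct difference distribution, and shuffling removes accidental
    autocorrelation alignment. The significance flag is the
    exclusion-of-zero rule on the HDI.
    """
    for fit in (fit_a, fit_b):
        if parameter not in fit.param_names:
            raise ValidationError(f"parameter {parameter!r} absent from fit of {fit.group}")
    a = fit_a.mu_constrained_flat(parameter)
    b = fit_b.mu_constrained_flat(parameter)
    # each fit's permutation is derived from (seed, its group label), so the
    # pairing is reproducible, identical fits difference to exactly zero, and
    # compare_groups(B, A) is the exact negation of compare_groups(A, B)
    a = np.random.default_rng([seed, crc32(fit_a.group.encode())]).permutation(a)
    b = np.random.default_rng([seed, crc32(fit_b.group.encode())]).permutation(b)
    s = min(a.size, b.size)
    diff = a[:s] - b[:s]
    lo, hi = hdi(diff, mass=mass)
    return DiffResult(
        parameter=parameter,
        group_a=fit_a.group,
        group_b=fit_b.group,
        diff_draws=diff,
        hdi_low=lo,
        hdi_high=hi,
        hdi_mean=float(diff.mean()),
        significant=bool(lo > 0.0 or hi < 0.0),
    )


def contrast_table(fits: dict[str, object], mass: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """All pairwise contrasts x all parameters of the fitted model.

    ``fits`` maps group label -> PosteriorFit (same model). No multiplicity
    correction is applied; the full table is reported so readers can judge
    multiplicity themselves.
    """
    labels = list(fits)
    rows = []
    for la, lb in combinations(labels, 2):
        for parameter in fits[la].param_names:
            rows.append(compare_groups(fits[la], fits[lb], parameter, mass=mass, seed=seed).as_row())
    return pd.DataFrame(rows)
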
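"""WAIC model comparison with the participant as the pointwise unit.

Because IGT choices are sequentially dependent within a subject, the
pointwise log-likelihood is the *summed* log-likelihood of a participant's
whole choice sequence, not of individual trials. WAIC is then

    lppd   = sum_i log( mean_s exp(ll[s, i]) )
    p_waic = sum_i var_s( ll[s, i] )            (sample variance, S - 1)
    waic   = -2 * (lppd - p_waic)

over posterior draws s and participants i; smaller WAIC means better fit.
Overall fit of a model is the sum of its per-group WAICs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .task import ValidationError


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray

    @property
    def n_participants(self) -> int:
        return len(self.pointwise_lppd)


def waic(log_lik: np.ndarray) -> WaicResult:
    """WAIC from a (draws, participants) pointwise log-likelihood matrix."""
    ll = np.asarray(log_lik, dtype=float)
    if ll.ndim != 2:
        raise ValidationError("log_lik must be 2-D (draws x participants)")
    S = ll.shape[0]
    if S < 2:
        raise ValidationError("WAIC needs at least 2 posterior draws")
    if not np.isfinite(ll).all():
        raise ValidationError("log_lik contains non-finite entries")
    pointwise_lppd = logsumexp(ll, axis=0) - np.log(S)
    pointwise_p = ll.var(axis=0, ddof=1)
    lppd = float(pointwise_lppd.sum())
    p_w = float(pointwise_p.sum())
    return WaicResult(
        lppd=lppd,
        p_waic=p_w,
        waic=-2.0 * (lppd - p_w),
        pointwise_lppd=pointwise_lppd,
        pointwise_p=pointwise_p,
    )


def waic_from_fit(fit) -> WaicResult:
    """WAIC of a :class:`~igtrl.inference.PosteriorFit`."""
    return waic(fit.loglik_matrix())


def total_waic(per_group: Mapping[str, Mapping[str, WaicResult]]) -> pd.DataFrame:
    """Group-summed model comparison table.

    ``per_group[model][group]`` is that fit's WaicResult. Returns a long
    table with one row per (model, group) plus the model totals, ranked
    ascending by total WAIC; ties in the total are flagged in the ``tie``
    column of every tied model's rows.
    """
    rows = []
    totals: dict[str, float] = {}
    for model, groups in per_group.items():
        for group, res in groups.items():
            rows.append(
                {
                    "model": model,
                    "group": group,
                    "lppd": res.lppd,
                    "p_waic": res.p_waic,
                    "waic": res.waic,
                }
            )
        totals[model] = float(sum(res.waic for res in groups.values()))
    df = pd.DataFrame(rows)
    df["total"] = df["model"].map(totals)
    best = min(totals.values())
    tied = {m for m, t in totals.items() if np.isclose(t, best, rtol=0, atol=1e-9)}
    df["winner"] = df["model"].isin(tied)
    df["tie"] = df["model"].isin(tied) & (len(tied) > 1)
    return df.sort_values(["total", "model", "group"], kind="stable").reset_index(drop=True)


def winning_model(table: pd.DataFrame) -> str:
    """Model with the smallest summed WAIC (first alphabetically on a tie)."""
    return str(table.loc[table["winner"], "model"].iloc[0])
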
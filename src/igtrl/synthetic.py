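"""Synthetic IGT cohorts with the hierarchical structure the analysis assumes.

Generates groups of simulated agents whose parameters are drawn from
group-level distributions on the constrained scale, plus parameter- and
model-recovery harnesses. The default presets emulate the three study
cohorts — typically developing controls, ASD and OCD adolescents
(n = 20/24/20) — using the published VPP group means and SDs as
between-subject distributions, with 80-trial sessions on the standard
payoff schedule.

Bounded parameters are realized as probit-squashed normals: the raw-scale
location and scale are found numerically so that the squashed variable's
mean and SD match the requested constrained-scale values (moment matching);
the unbounded perseverance increments are plain normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal, spearmanr

from .models import (
    PARAM_UPPER,
    ModelParameters,
    model_param_names,
    simulate_agent,
)
from .task import GroupDataset, PayoffSchedule, TrialRecord, ValidationError


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic group.

    Means and SDs are on the constrained (interpretable) scale. A
    ``contamination`` rate > 0 randomly converts that fraction of trials to
    premature or omitted responses, to exercise the validity filters.
    """

    label: str
    n_subjects: int
    model: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    schedule: PayoffSchedule = field(default_factory=PayoffSchedule)
    n_trials: int = 80
    seed: int = 0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        names = model_param_names(self.model)
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for name in names:
            if name not in self.means or name not in self.sds:
                raise ValidationError(f"missing mean/SD for parameter {name!r}")
            upper = PARAM_UPPER[name]
            m, s = self.means[name], self.sds[name]
            if s < 0:
                raise ValidationError(f"{name}: SD must be nonnegative")
            if upper is not None and not 0.0 <= m <= upper:
                raise ValidationError(f"{name}: mean {m} outside [0, {upper}]")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_subjects": self.n_subjects,
            "model": self.model,
            "means": dict(self.means),
            "sds": dict(self.sds),
            "schedule": self.schedule.to_dict(),
            "n_trials": self.n_trials,
            "seed": self.seed,
            "contamination": self.contamination,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "schedule" in d:
            d["schedule"] = PayoffSchedule.from_dict(d["schedule"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: published VPP group estimates used as generator presets (mean, SD),
#: constrained scale; group sizes 20 / 24 / 20
_PRESET_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "A": (0.01, 0.01), "alpha": (0.14, 0.06), "c": (3.16, 0.33), "lam": (0.22, 0.08),
        "ep": (-1.38, 0.87), "en": (-0.84, 1.33), "k": (0.42, 0.08), "w": (0.94, 0.01),
    },
    "ASD": {
        "A": (0.44, 0.22), "alpha": (0.61, 0.13), "c": (0.72, 0.07), "lam": (4.70, 1.65),
        "ep": (-1.69, 2.97), "en": (-0.76, 2.75), "k": (0.63, 0.17), "w": (0.25, 0.13),
    },
    "OCD": {
        "A": (0.24, 0.15), "alpha": (0.96, 0.43), "c": (0.66, 0.02), "lam": (4.91, 2.27),
        "ep": (-1.80, 1.16), "en": (-1.07, 2.16), "k": (0.44, 0.16), "w": (0.26, 0.08),
    },
}

_PRESET_N = {"control": 20, "ASD": 24, "OCD": 20}


def default_presets(seed: int = 0) -> dict[str, CohortSpec]:
    """The three study-cohort presets (control / ASD / OCD, n = 20/24/20)."""
    presets = {}
    for i, (label, table) in enumerate(_PRESET_TABLE.items()):
        presets[label] = CohortSpec(
            label=label,
            n_subjects=_PRESET_N[label],
            model="vpp",
            means={k: v[0] for k, v in table.items()},
            sds={k: v[1] for k, v in table.items()},
            seed=seed + i,
        )
    return presets


def squashed_normal_moments(mu: float, sigma: float, upper: float) -> tuple[float, float]:
    """Mean and SD of Phi(mu + sigma * Z) * upper (Z standard normal).

    Closed forms: E[Phi(mu + sigma Z)] = Phi(mu / sqrt(1 + sigma^2)) and
    E[Phi(mu + sigma Z)^2] is a bivariate normal orthant probability with
    correlation sigma^2 / (1 + sigma^2).
    """
    t = mu / np.sqrt(1.0 + sigma**2)
    mean = ndtr(t)
    if sigma == 0.0:
        return float(mean * upper), 0.0
    rho = sigma**2 / (1.0 + sigma**2)
    e2 = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t, t])
    var = max(float(e2 - mean**2), 0.0)
    return float(mean * upper), float(np.sqrt(var) * upper)


def match_squashed_normal(mean: float, sd: float, upper: float) -> tuple[float, float]:
    """Raw-scale (mu, sigma) whose squashed distribution has the given
    constrained-scale mean and SD (numerical moment matching)."""
    q = mean / upper
    if not 0.0 < q < 1.0:
        if sd > 0:
            raise ValidationError(f"mean {mean} on the bound with positive SD is infeasible")
        return float(ndtri(np.clip(q, 1e-12, 1 - 1e-12))), 0.0
    if sd == 0.0:
        return float(ndtri(q)), 0.0
    max_sd = np.sqrt(q * (1.0 - q)) * upper
    if sd >= max_sd:
        raise ValidationError(
            f"requested SD {sd} unattainable for mean {mean} on (0, {upper}); max {max_sd:.4g}"
        )

    def gap(sigma: float) -> float:
        mu = ndtri(q) * np.sqrt(1.0 + sigma**2)
        return squashed_normal_moments(mu, sigma, upper)[1] - sd

    sigma = brentq(gap, 1e-9, 60.0, xtol=1e-10)
    mu = ndtri(q) * np.sqrt(1.0 + sigma**2)
    return float(mu), float(sigma)


def draw_subject_parameters(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample each subject's parameter vector from the group distributions."""
    names = model_param_names(spec.model)
    cols: dict[str, np.ndarray] = {}
    for name in names:
        m, s = spec.means[name], spec.sds[name]
        upper = PARAM_UPPER[name]
        z = rng.standard_normal(spec.n_subjects)
        if upper is None:
            cols[name] = m + s * z
        else:
            mu, sigma = match_squashed_normal(m, s, upper)
            cols[name] = ndtr(mu + sigma * z) * upper
    df = pd.DataFrame(cols)
    df.insert(0, "subjID", [f"{spec.label}{i + 1:03d}" for i in range(spec.n_subjects)])
    return df


def _contaminate(subject, rate: float, rng: np.random.Generator):
    trials = []
    for t in subject.trials:
        if rng.random() < rate:
            if rng.random() < 0.5:
                t = TrialRecord(trial=t.trial, choice=None)
            else:
                t = replace(t, rt=float(rng.uniform(50.0, 195.0)))
        trials.append(t)
    return replace(subject, trials=trials)


def generate_cohort(spec: CohortSpec) -> tuple[GroupDataset, pd.DataFrame]:
    """Generate one group of simulated agents plus its ground-truth table.

    Deterministic in ``spec.seed``. Returns the GroupDataset and a
    DataFrame with one row per subject holding the true parameters.
    """
    rng = np.random.default_rng(spec.seed)
    truth = draw_subject_parameters(spec, rng)
    subjects = []
    for _, row in truth.iterrows():
        params = ModelParameters.from_dict(
            {k: row[k] for k in model_param_names(spec.model)}
        )
        subj = simulate_agent(
            spec.model,
            params,
            spec.schedule,
            rng,
            n_trials=spec.n_trials,
            subject_id=str(row["subjID"]),
            group=spec.label,
        )
        if spec.contamination > 0:
            subj = _contaminate(subj, spec.contamination, rng)
        subjects.append(subj)
    truth.insert(1, "group", spec.label)
    return GroupDataset(label=spec.label, subjects=subjects), truth


@dataclass
class RecoveryReport:
    """Outcome of a generate -> fit -> compare validation round."""

    group: str
    model: str
    params: pd.DataFrame  # per parameter: truth, posterior, interval, coverage, rank corr
    waic_table: pd.DataFrame | None = None

    @property
    def n_covered(self) -> int:
        return int(self.params["covered"].sum())


def recovery_experiment(
    spec: CohortSpec,
    config=None,
    fit_models: Sequence[str] | None = None,
    interval_mass: float = 0.95,
) -> RecoveryReport:
    """Generate a cohort, refit it, and score parameter recovery.

    Coverage is whether the generating group mean lies inside the central
    credible interval of the group-level mean (constrained scale); the rank
    correlation is Spearman's rho between true and posterior-mean
    subject-level parameters. With ``fit_models`` given, all listed models
    are fitted and a WAIC comparison table is attached (model recovery).
    """
    from .inference import McmcConfig, fit_group
    from .selection import total_waic, waic_from_fit

    if config is None:
        config = McmcConfig()
    group, truth = generate_cohort(spec)
    fit = fit_group(spec.model, group, config=config)

    lo_q, hi_q = (1 - interval_mass) / 2, 1 - (1 - interval_mass) / 2
    rows = []
    names = fit.param_names
    for j, name in enumerate(names):
        draws = fit.mu_constrained[:, :, j].reshape(-1)
        lo, hi = np.quantile(draws, [lo_q, hi_q])
        true_mean = float(spec.means[name])
        post_subject = fit.subject_params[:, :, :, j].mean(axis=(0, 1))
        rho = spearmanr(truth[name].to_numpy(), post_subject).statistic
        rows.append(
            {
                "parameter": name,
                "true_mean": true_mean,
                "post_mean": float(draws.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "covered": bool(lo <= true_mean <= hi),
                "rank_corr": float(rho) if np.isfinite(rho) else np.nan,
            }
        )
    report = RecoveryReport(group=spec.label, model=spec.model, params=pd.DataFrame(rows))

    if fit_models:
        per_group: dict[str, dict] = {}
        for model in fit_models:
            mfit = fit if model == spec.model else fit_group(model, group, config=config)
            per_group[model] = {spec.label: waic_from_fit(mfit)}
        report.waic_table = total_waic(per_group)
    return report
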
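"""Hierarchical Bayesian estimation of model parameters for one group.

Each group is fitted independently. For every model parameter p there is a
group-level location mu_p and scale sigma_p on an unconstrained scale, and a
per-subject standard-normal deviate z_ip (non-centered parameterization).
Bounded parameters are mapped to their support through a probit link,
value = Phi(mu_p + sigma_p * z_ip) * upper; the perseverance increments
ep/en use the identity link. Priors: mu_p ~ Normal(0, 1), sigma_p ~
HalfNormal(1), z_ip ~ Normal(0, 1).

Sampling uses an adaptive Metropolis-within-Gibbs scheme: per sweep, every
subject-level deviate is updated with a componentwise random-walk proposal
(vectorized across subjects, which are conditionally independent given the
group-level parameters), then each group-level scalar is updated by
random-walk Metropolis against the full-cohort likelihood. Proposal scales
adapt during warmup toward an acceptance rate of 0.44 and are frozen
afterwards. Convergence is judged by split-R-hat and effective sample size
computed with ArviZ across chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .models import (
    PARAM_NAMES,
    PARAM_UPPER,
    cohort_arrays,
    cohort_log_likelihood,
    model_param_names,
)
from .task import GroupDataset, ValidationError

RHAT_THRESHOLD = 1.1
ESS_PER_CHAIN_THRESHOLD = 100.0


def squash(raw, upper: float):
    """Map an unconstrained real to (0, upper) via the probit link
    Phi(raw) * upper; strictly increasing, with limits 0 and upper."""
    return ndtr(np.asarray(raw, dtype=float)) * upper


def unsquash(value, upper: float):
    """Inverse of :func:`squash`."""
    return ndtri(np.asarray(value, dtype=float) / upper)


@dataclass(frozen=True)
class HierarchicalSpec:
    """Priors and links of the hierarchical model.

    ``mu_scale`` is the SD of the normal prior on group locations,
    ``sigma_scale`` the scale of the half-normal prior on group scales.
    Links are fixed by the parameter bounds (probit-squash for bounded
    parameters, identity for ep/en).
    """

    model: str
    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 1.0

    @property
    def param_names(self) -> tuple[str, ...]:
        return model_param_names(self.model)

    def upper(self, name: str) -> float | None:
        return PARAM_UPPER[name]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. ``chains >= 2`` is required for split-R-hat.

    One iteration is one full Gibbs sweep: ``subject_substeps`` componentwise
    passes over the subject-level deviates, a componentwise pass over the
    group-level scalars, and ``group_substeps`` joint adaptive-covariance
    proposals on the whole group-level vector. Proposal scales and the joint
    covariance adapt only during warmup.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.44
    subject_substeps: int = 2
    group_substeps: int = 4

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("chains must be >= 2 for convergence diagnostics")
        if self.warmup <= 0 or self.draws <= 0:
            raise ValidationError("warmup and draws must be positive")


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one (group, model) fit.

    Draw arrays have leading dimensions (chains, draws). ``mu_constrained``
    holds the group-level means mapped to the constrained scale (the scale
    Table-style summaries and group contrasts use); ``subject_params`` holds
    each subject's constrained parameters; ``log_lik`` the per-draw summed
    log-likelihood of each subject's choice sequence.
    """

    group: str
    model: str
    param_names: tuple[str, ...]
    subject_ids: list[str]
    mu_raw: np.ndarray  # (chains, draws, P)
    sigma: np.ndarray  # (chains, draws, P)
    mu_constrained: np.ndarray  # (chains, draws, P)
    subject_params: np.ndarray  # (chains, draws, n, P)
    log_lik: np.ndarray  # (chains, draws, n)
    diagnostics: dict = field(default_factory=dict)
    config: McmcConfig | None = None

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def mu_constrained_flat(self, parameter: str) -> np.ndarray:
        """All chains' draws of one group-level mean, constrained scale."""
        j = self.param_names.index(parameter)
        return self.mu_constrained[:, :, j].reshape(-1)

    def loglik_matrix(self) -> np.ndarray:
        """(draws_total, n_subjects) pointwise log-likelihood matrix."""
        c, d, n = self.log_lik.shape
        return self.log_lik.reshape(c * d, n)

    def save(self, stem: str | Path) -> None:
        """Write draws to ``<stem>_draws.csv`` and diagnostics to
        ``<stem>_diagnostics.json``."""
        stem = Path(stem)
        c, d, P = self.mu_constrained.shape
        cols = {"chain": np.repeat(np.arange(c), d), "draw": np.tile(np.arange(d), c)}
        for j, name in enumerate(self.param_names):
            cols[f"mu_{name}"] = self.mu_constrained[:, :, j].reshape(-1)
            cols[f"mu_raw_{name}"] = self.mu_raw[:, :, j].reshape(-1)
            cols[f"sigma_{name}"] = self.sigma[:, :, j].reshape(-1)
        for i, sid in enumerate(self.subject_ids):
            cols[f"log_lik_{sid}"] = self.log_lik[:, :, i].reshape(-1)
        pd.DataFrame(cols).to_csv(stem.with_name(stem.name + "_draws.csv"), index=False)
        diag = dict(self.diagnostics)
        diag.update(group=self.group, model=self.model)
        stem.with_name(stem.name + "_diagnostics.json").write_text(
            json.dumps(diag, indent=2, default=float)
        )


def _map_pooled(loglik, P: int, n: int, uppers: np.ndarray, bounded: np.ndarray,
                spec: "HierarchicalSpec", seed: int = 0, n_starts: int = 10) -> np.ndarray:
    """Rough pooled MAP of the group locations (all subjects share
    squash(mu)); used only to initialize the chains near the posterior.

    The pooled surface is multimodal (e.g. a perseverance-dominated mode can
    mimic an RL-dominated one), so the optimizer is restarted from several
    random points and the best optimum wins.
    """
    from scipy.optimize import minimize

    z0 = np.zeros((n, P))
    sig0 = np.zeros(P)

    def objective(mu: np.ndarray) -> float:
        theta = _constrain(mu, sig0, z0, uppers, bounded)
        lp = -0.5 * np.sum((mu - spec.mu_loc) ** 2) / spec.mu_scale**2
        return -(float(loglik(theta).sum()) + lp)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
    best_val, best_x = np.inf, np.zeros(P)
    for i in range(n_starts):
        x0 = np.zeros(P) if i == 0 else rng.standard_normal(P)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 400 * P, "xatol": 1e-3, "fatol": 1e-3})
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.asarray(res.x, dtype=float)
    return best_x


def _slice_1d(logp, x0: float, rng: np.random.Generator, width: float = 1.0,
              max_steps: int = 20) -> float:
    """Univariate slice sampling with stepping-out (Neal 2003)."""
    y = logp(x0) + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += width
    for _ in range(100):
        x = lo + (hi - lo) * rng.random()
        if logp(x) > y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0  # pragma: no cover - shrinkage essentially always succeeds


def _constrain(mu: np.ndarray, sigma: np.ndarray, z: np.ndarray, uppers: np.ndarray,
               bounded: np.ndarray) -> np.ndarray:
    """Subject-level constrained parameters from group state, shape (n, P)."""
    raw = mu[None, :] + sigma[None, :] * z
    out = np.empty_like(raw)
    out[:, bounded] = ndtr(raw[:, bounded]) * uppers[bounded]
    out[:, ~bounded] = raw[:, ~bounded]
    return out


def _theta_full(theta_model: np.ndarray, param_names: tuple[str, ...]) -> np.ndarray:
    """Embed model parameters into the canonical 8-column layout."""
    n = theta_model.shape[0]
    full = np.zeros((n, len(PARAM_NAMES)))
    full[:, 7] = 1.0  # w defaults to 1 so PVL value = EV
    for j, name in enumerate(param_names):
        full[:, PARAM_NAMES.index(name)] = theta_model[:, j]
    return full


def fit_group(
    model: str,
    group: GroupDataset,
    spec: HierarchicalSpec | None = None,
    config: McmcConfig | None = None,
) -> PosteriorFit:
    """Fit one model to one group hierarchically; returns posterior draws.

    Groups are always fitted independently of each other (model comparison
    sums WAIC over per-group fits). Non-convergence (split-R-hat above 1.1
    or effective sample size below 100 per chain on any group-level
    quantity) is flagged in ``diagnostics``, never silently ignored.
    """
    if spec is None:
        spec = HierarchicalSpec(model=model)
    if spec.model != model:
        raise ValidationError("spec.model disagrees with model argument")
    if config is None:
        config = McmcConfig()
    for subj in group.subjects:
        if not any(t.is_valid for t in subj.trials):
            raise ValidationError(f"subject {subj.subject_id}: no valid trials")

    names = spec.param_names
    P = len(names)
    n = len(group.subjects)
    uppers = np.array([spec.upper(nm) if spec.upper(nm) is not None else np.nan for nm in names])
    bounded = ~np.isnan(uppers)
    choices, nets = cohort_arrays(group.subjects)

    def loglik(theta_model: np.ndarray) -> np.ndarray:
        return cohort_log_likelihood(model, _theta_full(theta_model, names), choices, nets)

    total = config.warmup + config.draws
    mu_store = np.empty((config.chains, config.draws, P))
    sig_store = np.empty((config.chains, config.draws, P))
    subj_store = np.empty((config.chains, config.draws, n, P))
    ll_store = np.empty((config.chains, config.draws, n))

    # group-level prior on the unconstrained vector g = (mu, log sigma):
    # normal locations, half-normal scales sampled on the log scale (the
    # trailing + log sigma term is the Jacobian of that reparameterization)
    def log_prior_group(g: np.ndarray) -> float:
        mu_g, ls_g = g[:P], g[P:]
        lp = -0.5 * np.sum((mu_g - spec.mu_loc) ** 2) / spec.mu_scale**2
        lp += np.sum(-0.5 * np.exp(2 * ls_g) / spec.sigma_scale**2 + ls_g)
        return float(lp)

    mu_map = _map_pooled(loglik, P, n, uppers, bounded, spec, seed=config.seed)

    root = np.random.SeedSequence(config.seed)
    for chain, ss in enumerate(root.spawn(config.chains)):
        rng = np.random.default_rng(ss)
        mu = mu_map + 0.1 * rng.standard_normal(P)
        log_sigma = np.log(0.2) + 0.2 * rng.standard_normal(P)
        z = 0.1 * rng.standard_normal((n, P))
        z_step = np.full((n, P), 0.5)
        g_step = np.full(2 * P, 0.15)
        joint_scale = 2.38 / np.sqrt(2 * P)
        chol = np.eye(2 * P) * 0.05
        history = np.empty((total, 2 * P))

        sigma = np.exp(log_sigma)
        theta = _constrain(mu, sigma, z, uppers, bounded)
        ll = loglik(theta)

        for it in range(total):
            adapt = it < config.warmup
            gamma = (it + 1) ** -0.6 if adapt else 0.0

            # subject-level deviates, one parameter column at a time,
            # all subjects in parallel (conditionally independent)
            for _ in range(config.subject_substeps):
                for p in range(P):
                    z_prop = z.copy()
                    z_prop[:, p] = z[:, p] + z_step[:, p] * rng.standard_normal(n)
                    theta_prop = _constrain(mu, sigma, z_prop, uppers, bounded)
                    ll_prop = loglik(theta_prop)
                    log_r = ll_prop - ll - 0.5 * (z_prop[:, p] ** 2 - z[:, p] ** 2)
                    accept = np.log(rng.random(n)) < log_r
                    z[accept, p] = z_prop[accept, p]
                    ll[accept] = ll_prop[accept]
                    if adapt:
                        z_step[:, p] *= np.exp(
                            gamma * (accept.astype(float) - config.target_accept)
                        )
                        np.clip(z_step[:, p], 1e-3, 10.0, out=z_step[:, p])

            g = np.concatenate([mu, log_sigma])
            lp = log_prior_group(g)

            # componentwise random-walk pass over group-level scalars
            for p in range(2 * P):
                g_prop = g.copy()
                g_prop[p] += g_step[p] * rng.standard_normal()
                theta_prop = _constrain(g_prop[:P], np.exp(g_prop[P:]), z, uppers, bounded)
                ll_prop = loglik(theta_prop)
                lp_prop = log_prior_group(g_prop)
                accepted = np.log(rng.random()) < ll_prop.sum() - ll.sum() + lp_prop - lp
                if accepted:
                    g, theta, ll, lp = g_prop, theta_prop, ll_prop, lp_prop
                if adapt:
                    g_step[p] = np.clip(
                        g_step[p] * np.exp(gamma * (float(accepted) - config.target_accept)),
                        1e-3,
                        5.0,
                    )

            # joint adaptive-covariance proposals on the whole group vector
            for _ in range(config.group_substeps):
                g_prop = g + joint_scale * (chol @ rng.standard_normal(2 * P))
                theta_prop = _constrain(g_prop[:P], np.exp(g_prop[P:]), z, uppers, bounded)
                ll_prop = loglik(theta_prop)
                lp_prop = log_prior_group(g_prop)
                accepted = np.log(rng.random()) < ll_prop.sum() - ll.sum() + lp_prop - lp
                if accepted:
                    g, theta, ll, lp = g_prop, theta_prop, ll_prop, lp_prop
                if adapt:
                    joint_scale = float(
                        np.clip(joint_scale * np.exp(gamma * (float(accepted) - 0.234)), 1e-4, 5.0)
                    )

            mu, log_sigma = g[:P].copy(), g[P:].copy()
            sigma = np.exp(log_sigma)

            # interweaved centered step (ASIS): holding each subject's raw
            # value y_ip = mu_p + sigma_p z_ip fixed (so theta and the
            # likelihood are unchanged), mu_p has a conjugate normal
            # conditional and log sigma_p a cheap 1-D conditional sampled by
            # slice sampling. This restores mixing for parameters whose
            # subject-level values the data pin down tightly.
            y = mu[None, :] + sigma[None, :] * z
            for p in range(P):
                yp = y[:, p]
                prec = n / sigma[p] ** 2 + 1.0 / spec.mu_scale**2
                mean = (yp.sum() / sigma[p] ** 2 + spec.mu_loc / spec.mu_scale**2) / prec
                mu[p] = mean + rng.standard_normal() / np.sqrt(prec)
                resid2 = float(((yp - mu[p]) ** 2).sum())

                def logp_ls(ls: float) -> float:
                    return (
                        -n * ls
                        - 0.5 * resid2 * np.exp(-2 * ls)
                        - 0.5 * np.exp(2 * ls) / spec.sigma_scale**2
                        + ls
                    )

                log_sigma[p] = float(
                    np.clip(_slice_1d(logp_ls, log_sigma[p], rng), -12.0, 5.0)
                )
            sigma = np.exp(log_sigma)
            z = (y - mu[None, :]) / sigma[None, :]
            g = np.concatenate([mu, log_sigma])
            history[it] = g
            if adapt and it >= 50 and it % 25 == 0:
                window = history[max(0, it - 500) : it + 1]
                cov = np.cov(window.T) + 1e-8 * np.eye(2 * P)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:  # pragma: no cover - cov is PD by construction
                    pass

            if not adapt:
                d = it - config.warmup
                mu_store[chain, d] = mu
                sig_store[chain, d] = sigma
                subj_store[chain, d] = theta
                ll_store[chain, d] = ll

    mu_con = np.empty_like(mu_store)
    mu_con[:, :, bounded] = ndtr(mu_store[:, :, bounded]) * uppers[bounded]
    mu_con[:, :, ~bounded] = mu_store[:, :, ~bounded]

    diagnostics = _diagnose(names, mu_con, sig_store, config)
    return PosteriorFit(
        group=group.label,
        model=model,
        param_names=names,
        subject_ids=[s.subject_id for s in group.subjects],
        mu_raw=mu_store,
        sigma=sig_store,
        mu_constrained=mu_con,
        subject_params=subj_store,
        log_lik=ll_store,
        diagnostics=diagnostics,
        config=config,
    )


def _diagnose(names, mu_con: np.ndarray, sigma: np.ndarray, config: McmcConfig) -> dict:
    """Split-R-hat and bulk ESS per group-level quantity, via ArviZ."""
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for j, name in enumerate(names):
        for label, arr in ((f"mu_{name}", mu_con[:, :, j]), (f"sigma_{name}", sigma[:, :, j])):
            ds = az.convert_to_dataset(np.ascontiguousarray(arr))
            rhat[label] = float(np.asarray(az.rhat(ds)["x"].values).item())
            ess[label] = float(np.asarray(az.ess(ds)["x"].values).item())
    max_rhat = max(rhat.values())
    min_ess = min(ess.values())
    return {
        "rhat": rhat,
        "ess": ess,
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "converged": bool(
            max_rhat < RHAT_THRESHOLD and min_ess >= ESS_PER_CHAIN_THRESHOLD * config.chains / 4
        ),
    }


def summarize(fit: PosteriorFit, hdi_mass: float = 0.95) -> pd.DataFrame:
    """Posterior summary table of group-level means, constrained scale.

    One row per model parameter: posterior mean, SD, central interval,
    highest-density interval, split-R-hat and ESS.
    """
    from .contrasts import hdi

    rows = []
    for j, name in enumerate(fit.param_names):
        draws = fit.mu_constrained[:, :, j].reshape(-1)
        lo, hi = np.quantile(draws, [(1 - hdi_mass) / 2, 1 - (1 - hdi_mass) / 2])
        h_lo, h_hi = hdi(draws, mass=hdi_mass)
        rows.append(
            {
                "parameter": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)) if draws.std(ddof=1) > 0 else 0.0,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "hdi_low": float(h_lo),
                "hdi_high": float(h_hi),
                "rhat": fit.diagnostics["rhat"][f"mu_{name}"],
                "ess": fit.diagnostics["ess"][f"mu_{name}"],
            }
        )
    return pd.DataFrame(rows)
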
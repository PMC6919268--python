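"""Prospect-valence-learning models of IGT choice.

Three models of trial-by-trial deck choice:

* **PVL-Decay** — prospect-theoretic utility of the net outcome feeds a decay
  learning rule in which every deck's expectancy is discounted each trial and
  the chosen deck additionally absorbs the utility.
* **PVL-Delta** — same utility, delta learning rule: only the chosen deck's
  expectancy moves, toward the utility, at rate A.
* **VPP** (value-plus-perseverance) — PVL-Delta augmented with a decaying
  perseverance strength per deck, incremented after each outcome by ε_p (wins)
  or ε_n (losses), mixed with expectancies through the RL weight ω.

Choice follows a softmax over deck values with sensitivity θ = 3^c − 1, so
c = 0 gives uniform random choice.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .task import DECKS, PayoffSchedule, SubjectDataset, TrialRecord, ValidationError

MODELS: tuple[str, ...] = ("pvl_decay", "pvl_delta", "vpp")

#: canonical parameter order; PVL models use the first four
PARAM_NAMES: tuple[str, ...] = ("A", "alpha", "c", "lam", "ep", "en", "k", "w")

#: upper bound of each probit-squashed parameter; None = unbounded (identity link)
PARAM_UPPER: dict[str, float | None] = {
    "A": 1.0,
    "alpha": 2.0,
    "c": 5.0,
    "lam": 10.0,
    "ep": None,
    "en": None,
    "k": 1.0,
    "w": 1.0,
}

PVL_PARAMS: tuple[str, ...] = PARAM_NAMES[:4]


def model_param_names(model: str) -> tuple[str, ...]:
    """Free parameters of a model, in canonical order."""
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    return PARAM_NAMES if model == "vpp" else PVL_PARAMS


@dataclass(frozen=True)
class ModelParameters:
    """Per-subject parameter vector.

    A: learning/decay rate in [0,1]; alpha: feedback-sensitivity shape in
    [0,2]; c: choice consistency in [0,5]; lam: loss aversion in [0,10];
    ep/en: perseverance increments after nonnegative/negative net outcomes
    (unbounded); k: perseverance decay in [0,1]; w: RL weight in [0,1].
    """

    A: float
    alpha: float
    c: float
    lam: float
    ep: float = 0.0
    en: float = 0.0
    k: float = 0.0
    w: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            upper = PARAM_UPPER[name]
            value = getattr(self, name)
            if upper is not None and not 0.0 <= value <= upper:
                raise ValidationError(f"{name}={value} outside [0, {upper}]")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items() if k in PARAM_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)


def prospect_utility(x, alpha: float, lam: float):
    """Prospect-theoretic power utility of a signed net outcome.

    u(x) = x**alpha for x >= 0, and -lam * |x|**alpha for x < 0. Gains and
    losses share the curvature alpha; losses are scaled by loss aversion lam.
    """
    x = np.asarray(x, dtype=float)
    u = np.where(x >= 0, np.abs(x) ** alpha, -lam * np.abs(x) ** alpha)
    return u if u.ndim else float(u)


def update_decay(ev: np.ndarray, chosen: int, u: float, A: float) -> np.ndarray:
    """Decay rule: every expectancy is discounted by A, then the chosen deck
    absorbs the full utility."""
    ev = A * np.asarray(ev, dtype=float)
    ev[chosen] += u
    return ev


def update_delta(ev: np.ndarray, chosen: int, u: float, A: float) -> np.ndarray:
    """Delta rule: only the chosen deck's expectancy moves, toward u at rate A."""
    ev = np.array(ev, dtype=float)
    ev[chosen] += A * (u - ev[chosen])
    return ev


def update_perseverance(
    p: np.ndarray, chosen: int, net: float, k: float, ep: float, en: float
) -> np.ndarray:
    """All perseverance strengths decay by k; the chosen deck then gains ep
    after a nonnegative net outcome, en after a negative one."""
    p = k * np.asarray(p, dtype=float)
    p[chosen] += ep if net >= 0 else en
    return p


def sensitivity(c: float) -> float:
    """Softmax sensitivity θ = 3^c − 1 (zero at c = 0: random choice)."""
    return 3.0**c - 1.0


def log_choice_probabilities(values: np.ndarray, c: float) -> np.ndarray:
    """Log softmax choice probabilities (log-sum-exp stabilized); finite even
    where the probabilities themselves underflow double precision."""
    s = sensitivity(c) * np.asarray(values, dtype=float)
    return s - logsumexp(s)


def choice_probabilities(values: np.ndarray, c: float) -> np.ndarray:
    """Softmax choice probabilities over deck values with sensitivity 3^c − 1."""
    return np.exp(log_choice_probabilities(values, c))


def deck_values(ev: np.ndarray, p: np.ndarray, model: str, w: float) -> np.ndarray:
    """Combined deck values: V = ω·EV + (1−ω)·P for VPP, V = EV otherwise."""
    if model == "vpp":
        return w * np.asarray(ev) + (1.0 - w) * np.asarray(p)
    return np.asarray(ev, dtype=float)


def subject_log_likelihood(
    model: str,
    params: ModelParameters,
    subject: SubjectDataset,
    update_on_invalid: bool = False,
) -> float:
    """Sequential log-likelihood of a subject's valid choices under a model.

    Expectancies and perseverance strengths start at zero. Each valid trial
    contributes the log softmax probability of its choice and then updates
    the latent state with the choice's outcome. Premature/omitted trials
    contribute no likelihood term; by default they also trigger no state
    update (``update_on_invalid=True`` applies the outcome update anyway for
    trials that do record a choice).
    """
    model_param_names(model)  # validates the model identifier
    ev = np.zeros(len(DECKS))
    p = np.zeros(len(DECKS))
    loglik = 0.0
    n_valid = 0
    for t in subject.trials:
        if t.choice is None:
            continue
        j = DECKS.index(t.choice)
        if t.is_valid:
            values = deck_values(ev, p, model, params.w)
            loglik += float(log_choice_probabilities(values, params.c)[j])
            n_valid += 1
        elif not update_on_invalid:
            continue
        u = prospect_utility(t.net, params.alpha, params.lam)
        if model == "pvl_decay":
            ev = update_decay(ev, j, u, params.A)
        else:
            ev = update_delta(ev, j, u, params.A)
        if model == "vpp":
            p = update_perseverance(p, j, t.net, params.k, params.ep, params.en)
    if n_valid == 0:
        raise ValidationError(f"subject {subject.subject_id}: no valid trials")
    return loglik


def simulate_agent(
    model: str,
    params: ModelParameters,
    schedule: PayoffSchedule,
    rng: np.random.Generator,
    n_trials: int | None = None,
    subject_id: str = "sim",
    group: str = "sim",
) -> SubjectDataset:
    """Forward-simulate one agent: sample a deck from the model's choice
    probabilities, draw its outcome from the payoff schedule, update state."""
    from .task import sample_outcome

    model_param_names(model)
    if n_trials is None:
        n_trials = schedule.n_trials
    ev = np.zeros(len(DECKS))
    p = np.zeros(len(DECKS))
    trials: list[TrialRecord] = []
    for t in range(1, n_trials + 1):
        values = deck_values(ev, p, model, params.w)
        probs = choice_probabilities(values, params.c)
        j = int(rng.choice(len(DECKS), p=probs))
        gain, loss = sample_outcome(DECKS[j], schedule, rng)
        trials.append(TrialRecord(trial=t, choice=DECKS[j], gain=gain, loss=loss))
        u = prospect_utility(gain - loss, params.alpha, params.lam)
        if model == "pvl_decay":
            ev = update_decay(ev, j, u, params.A)
        else:
            ev = update_delta(ev, j, u, params.A)
        if model == "vpp":
            p = update_perseverance(p, j, gain - loss, params.k, params.ep, params.en)
    return SubjectDataset(subject_id=subject_id, group=group, trials=trials)


# ---------------------------------------------------------------------------
# vectorized cohort likelihood (sampler hot path)
# ---------------------------------------------------------------------------

def cohort_arrays(subjects) -> tuple[np.ndarray, np.ndarray]:
    """Pack subjects into (choices, nets) arrays of shape (n_subjects, T).

    Choices are deck indices 0..3, with -1 marking premature/omitted slots
    (no likelihood term, no state update). Rows are padded with -1 to the
    longest subject.
    """
    T = max(len(s.trials) for s in subjects)
    n = len(subjects)
    choices = np.full((n, T), -1, dtype=np.int64)
    nets = np.zeros((n, T), dtype=float)
    for i, subj in enumerate(subjects):
        for t_pos, t in enumerate(subj.trials):
            if t.is_valid:
                choices[i, t_pos] = DECKS.index(t.choice)
                nets[i, t_pos] = t.net
    return choices, nets


def cohort_log_likelihood(
    model: str, theta: np.ndarray, choices: np.ndarray, nets: np.ndarray
) -> np.ndarray:
    """Per-subject log-likelihoods for a whole cohort at once.

    ``theta`` has shape (n_subjects, 8) in canonical parameter order (PVL
    models ignore ep/en/k and take w = 1). Matches subject_log_likelihood to
    floating-point accuracy; exists because the sampler evaluates it tens of
    thousands of times. Uses a compiled kernel when numba is available,
    otherwise a vectorized numpy path.
    """
    from ._kernels import HAVE_NUMBA, MODEL_IDS, ll_kernel

    model_param_names(model)
    if HAVE_NUMBA:
        theta = np.ascontiguousarray(np.asarray(theta, dtype=float))
        if model != "vpp":
            theta = theta.copy()
            theta[:, 7] = 1.0  # w = 1 makes V = EV; ep/en/k columns inert
        return ll_kernel(
            MODEL_IDS[model],
            theta,
            np.ascontiguousarray(choices),
            np.ascontiguousarray(nets),
        )
    return _cohort_log_likelihood_numpy(model, theta, choices, nets)


def _cohort_log_likelihood_numpy(
    model: str, theta: np.ndarray, choices: np.ndarray, nets: np.ndarray
) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    n, T = choices.shape
    A = theta[:, 0]
    alpha = theta[:, 1]
    lam = theta[:, 3]
    theta_sens = 3.0 ** theta[:, 2] - 1.0
    is_vpp = model == "vpp"
    if is_vpp:
        ep, en, k, w = theta[:, 4], theta[:, 5], theta[:, 6], theta[:, 7]
    ev = np.zeros((n, 4))
    pstr = np.zeros((n, 4))
    ll = np.zeros(n)
    rows = np.arange(n)
    for t in range(T):
        ch = choices[:, t]
        act = ch >= 0
        if not act.any():
            continue
        idx = rows[act]
        chosen = ch[act]
        if is_vpp:
            values = w[:, None] * ev + (1.0 - w[:, None]) * pstr
        else:
            values = ev
        s = theta_sens[idx, None] * values[idx]
        m = s.max(axis=1)
        lse = m + np.log(np.exp(s - m[:, None]).sum(axis=1))
        ll[idx] += s[np.arange(len(idx)), chosen] - lse
        x = nets[idx, t]
        absx = np.abs(x)
        u = np.where(x >= 0, absx ** alpha[idx], -lam[idx] * absx ** alpha[idx])
        if model == "pvl_decay":
            ev[idx] *= A[idx, None]
            ev[idx, chosen] += u
        else:
            ev[idx, chosen] += A[idx] * (u - ev[idx, chosen])
        if is_vpp:
            pstr[idx] *= k[idx, None]
            pstr[idx, chosen] += np.where(x >= 0, ep[idx], en[idx])
    return ll
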
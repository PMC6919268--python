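import numpy as np
import pytest
from hypothesis import settings

from igtrl import (
    GroupDataset,
    McmcConfig,
    ModelParameters,
    PayoffSchedule,
    PosteriorFit,
    SubjectDataset,
    TrialRecord,
    fit_group,
    simulate_agent,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule() -> PayoffSchedule:
    return PayoffSchedule()


@pytest.fixture(scope="session")
def small_cohort(schedule) -> GroupDataset:
    """Six PVL-Delta agents, 60 trials each, mild parameter spread."""
    rng = np.random.default_rng(2024)
    subjects = []
    for i in range(6):
        params = ModelParameters(
            A=0.3 + 0.05 * rng.standard_normal(),
            alpha=0.5 + 0.05 * rng.standard_normal(),
            c=1.0 + 0.1 * rng.standard_normal(),
            lam=2.0 + 0.2 * rng.standard_normal(),
        )
        subjects.append(
            simulate_agent(
                "pvl_delta", params, schedule, rng, n_trials=60,
                subject_id=f"s{i}", group="sim",
            )
        )
    return GroupDataset(label="sim", subjects=subjects)


@pytest.fixture(scope="session")
def small_fit(small_cohort) -> PosteriorFit:
    """One reduced PVL-Delta fit shared by inference/selection/contrast tests."""
    cfg = McmcConfig(chains=2, warmup=250, draws=250, seed=77)
    return fit_group("pvl_delta", small_cohort, config=cfg)


def make_synthetic_fit(
    group: str,
    draws_by_param: dict[str, np.ndarray],
    chains: int = 2,
    model: str = "vpp",
) -> PosteriorFit:
    """PosteriorFit stub with prescribed group-level mean draws (constrained
    scale); used to test contrast machinery against analytic distributions.
    Marked synthetic: no sampler was run to produce it."""
    names = tuple(draws_by_param)
    first = next(iter(draws_by_param.values()))
    total = first.size
    d = total // chains
    P = len(names)
    mu = np.stack([draws_by_param[n].reshape(chains, d) for n in names], axis=-1)
    n_subj = 1
    return PosteriorFit(
        group=group,
        model=model,
        param_names=names,
        subject_ids=["s0"],
        mu_raw=np.zeros_like(mu),
        sigma=np.full_like(mu, 1e-6),
        mu_constrained=mu,
        subject_params=np.broadcast_to(mu[:, :, None, :], (chains, d, n_subj, P)).copy(),
        log_lik=np.zeros((chains, d, n_subj)),
        diagnostics={"rhat": {f"mu_{n}": 1.0 for n in names},
                     "ess": {f"mu_{n}": float(total) for n in names},
                     "max_rhat": 1.0, "min_ess": float(total), "converged": True},
    )


def make_subject(choices, nets=None, rts=None, subject_id="s", group="g") -> SubjectDataset:
    """Build a subject from deck letters (None = omission) and net outcomes."""
    trials = []
    n = len(choices)
    nets = nets if nets is not None else [100] * n
    for t in range(n):
        ch = choices[t]
        rt = None if rts is None else rts[t]
        if ch is None:
            trials.append(TrialRecord(trial=t + 1, choice=None))
        else:
            x = nets[t]
            gain, loss = (x, 0) if x >= 0 else (0, -x)
            trials.append(TrialRecord(trial=t + 1, choice=ch, gain=gain, loss=loss, rt=rt))
    return SubjectDataset(subject_id=subject_id, group=group, trials=trials)
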
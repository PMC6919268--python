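"""Iowa Gambling Task data model, payoff environment, I/O and behavioral summaries.

The task presents four card decks. Two "risky" decks (A, B) pay large gains
but even larger losses and are disadvantageous in the long run; two "safe"
decks (C, D) pay small gains and smaller losses and are advantageous. Each
draw is a win or a loss with equal probability. Performance is summarized by
the preference ratio: the fraction of valid choices taken from the safe decks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DECKS: tuple[str, ...] = ("A", "B", "C", "D")
SAFE_DECKS: frozenset[str] = frozenset({"C", "D"})

#: choices with reaction time below this many milliseconds are premature
PREMATURE_RT_MS: float = 200.0


class IgtError(Exception):
    """Base class for task-layer errors."""


class ParseError(IgtError):
    """A trial file row could not be parsed."""


class ValidationError(IgtError):
    """Parsed data violate a task invariant."""


@dataclass(frozen=True)
class PayoffSchedule:
    """Gain/loss menus and win probability defining the task environment.

    Money is integer pounds. Each trial on a deck is either a win (a gain
    drawn uniformly from the deck's gain menu, zero loss) or a loss (a loss
    drawn uniformly from the loss menu, zero gain), with ``win_prob``
    probability of the win branch.
    """

    gains: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "A": (190, 200, 210),
            "B": (190, 200, 210),
            "C": (90, 100, 110),
            "D": (90, 100, 110),
        }
    )
    losses: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "A": (240, 250, 260),
            "B": (240, 250, 260),
            "C": (40, 50, 60),
            "D": (40, 50, 60),
        }
    )
    win_prob: float = 0.5
    endowment: int = 2000
    n_trials: int = 80

    def __post_init__(self) -> None:
        for menus in (self.gains, self.losses):
            if set(menus) != set(DECKS):
                raise ValidationError(f"menus must cover decks {DECKS}, got {set(menus)}")
            for deck, menu in menus.items():
                if len(menu) == 0 or any(v <= 0 for v in menu):
                    raise ValidationError(f"deck {deck}: menu values must be strictly positive")
        if not 0.0 <= self.win_prob <= 1.0:
            raise ValidationError(f"win_prob must lie in [0, 1], got {self.win_prob}")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be positive")

    def to_dict(self) -> dict:
        return {
            "gains": {d: list(m) for d, m in self.gains.items()},
            "losses": {d: list(m) for d, m in self.losses.items()},
            "win_prob": self.win_prob,
            "endowment": self.endowment,
            "n_trials": self.n_trials,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PayoffSchedule":
        return cls(
            gains={k: tuple(v) for k, v in d["gains"].items()},
            losses={k: tuple(v) for k, v in d["losses"].items()},
            win_prob=float(d.get("win_prob", 0.5)),
            endowment=int(d.get("endowment", 2000)),
            n_trials=int(d.get("n_trials", 80)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PayoffSchedule":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def sample_outcome(
    deck: str, schedule: PayoffSchedule, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one (gain, loss) outcome from a deck.

    With probability ``schedule.win_prob`` the trial is a win: the gain is
    uniform on the deck's gain menu and the loss is zero. Otherwise the loss
    is uniform on the loss menu and the gain is zero.
    """
    if deck not in DECKS:
        raise ValidationError(f"unknown deck {deck!r}")
    if rng.random() < schedule.win_prob:
        return int(rng.choice(schedule.gains[deck])), 0
    return 0, int(rng.choice(schedule.losses[deck]))


@dataclass(frozen=True)
class TrialRecord:
    """One trial: choice, outcome and validity.

    ``choice`` is None on omitted trials. ``validity`` is one of
    ``"valid"``, ``"premature"`` (reaction time under 200 ms) or
    ``"omitted"``; premature and omitted trials are excluded from every
    analysis downstream.
    """

    trial: int
    choice: str | None
    gain: int = 0
    loss: int = 0
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.trial < 1:
            raise ValidationError(f"trial index must be 1-based positive, got {self.trial}")
        if self.choice is not None and self.choice not in DECKS:
            raise ValidationError(f"choice must be one of {DECKS} or omitted, got {self.choice!r}")
        if self.gain < 0 or self.loss < 0:
            raise ValidationError("gain and loss must be nonnegative")

    @property
    def validity(self) -> str:
        if self.choice is None:
            return "omitted"
        if self.rt is not None and self.rt < PREMATURE_RT_MS:
            return "premature"
        return "valid"

    @property
    def is_valid(self) -> bool:
        return self.validity == "valid"

    @property
    def net(self) -> int:
        """Signed net outcome x(t) = gain - loss."""
        return self.gain - self.loss


@dataclass
class SubjectDataset:
    """Ordered trial records for one subject."""

    subject_id: str
    group: str
    trials: list[TrialRecord]

    def __post_init__(self) -> None:
        idx = [t.trial for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"subject {self.subject_id}: trial indices must be strictly increasing"
            )

    @property
    def valid_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_valid]

    def validity_counts(self) -> dict[str, int]:
        counts = {"valid": 0, "premature": 0, "omitted": 0}
        for t in self.trials:
            counts[t.validity] += 1
        return counts


@dataclass
class GroupDataset:
    """All subjects sharing one group label."""

    label: str
    subjects: list[SubjectDataset]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError(f"group {self.label!r} has no subjects")
        bad = [s.subject_id for s in self.subjects if s.group != self.label]
        if bad:
            raise ValidationError(f"subjects {bad} do not carry group label {self.label!r}")

    def __len__(self) -> int:
        return len(self.subjects)


REQUIRED_COLUMNS = ("subjID", "group", "trial", "choice", "gain", "loss")


def load_trials(
    path: str | Path,
    schedule: PayoffSchedule | None = None,
    strict: bool = False,
) -> list[GroupDataset]:
    """Read a long-format trial file into one GroupDataset per group label.

    The file is tab- or comma-delimited with header columns
    ``subjID, group, trial, choice, gain, loss[, rt]``; ``choice`` is a deck
    letter or empty for an omitted trial. In strict mode, gains and losses
    are checked against the schedule menus and a win and a loss on the same
    trial is an error; in lax mode these only raise warnings-free acceptance.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype={"subjID": str, "group": str, "choice": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_rt = "rt" in df.columns

    subjects: dict[tuple[str, str], list[TrialRecord]] = {}
    seen: set[tuple[str, int]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        line = f"{path} line {row_no}"
        try:
            trial = int(row.trial)
            gain = int(row.gain)
            loss = int(row.loss)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{line}: malformed numeric field ({exc})") from exc
        choice = None if pd.isna(row.choice) or row.choice == "" else str(row.choice).strip()
        if choice is not None and choice.upper() == "NA":
            choice = None
        if choice is not None and choice not in DECKS:
            raise ValidationError(f"{line}: choice {choice!r} outside {{A,B,C,D,NA}}")
        key = (str(row.subjID), trial)
        if key in seen:
            raise ValidationError(f"{line}: duplicate (subject, trial) = {key}")
        seen.add(key)
        rt = None
        if has_rt and not pd.isna(row.rt):
            rt = float(row.rt)
        if strict and choice is not None:
            if gain > 0 and loss > 0:
                raise ValidationError(f"{line}: gain and loss both nonzero")
            if schedule is not None:
                if gain > 0 and gain not in schedule.gains[choice]:
                    raise ValidationError(f"{line}: gain {gain} not in deck {choice} menu")
                if loss > 0 and loss not in schedule.losses[choice]:
                    raise ValidationError(f"{line}: loss {loss} not in deck {choice} menu")
        rec = TrialRecord(trial=trial, choice=choice, gain=gain, loss=loss, rt=rt)
        subjects.setdefault((str(row.group), str(row.subjID)), []).append(rec)

    groups: dict[str, list[SubjectDataset]] = {}
    for (group, subj_id), recs in subjects.items():
        recs.sort(key=lambda r: r.trial)
        groups.setdefault(group, []).append(
            SubjectDataset(subject_id=subj_id, group=group, trials=recs)
        )
    return [GroupDataset(label=g, subjects=subs) for g, subs in groups.items()]


def write_trials(groups: Iterable[GroupDataset], path: str | Path, sep: str = "\t") -> None:
    """Write groups back to the long-format trial file (inverse of load_trials)."""
    rows = []
    for group in groups:
        for subj in group.subjects:
            for t in subj.trials:
                rows.append(
                    {
                        "subjID": subj.subject_id,
                        "group": group.label,
                        "trial": t.trial,
                        "choice": t.choice if t.choice is not None else "",
                        "gain": t.gain,
                        "loss": t.loss,
                        "rt": t.rt if t.rt is not None else "",
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def preference_ratio(subject: SubjectDataset) -> float:
    """Safe-deck preference: (C + D choices) / all valid choices.

    Values above 0.5 denote preference for the advantageous decks. Equals an
    affine transform of the classical net score (C + D) - (A + B).
    """
    valid = subject.valid_trials
    if not valid:
        raise ValidationError(f"subject {subject.subject_id}: no valid trials")
    safe = sum(1 for t in valid if t.choice in SAFE_DECKS)
    return safe / len(valid)


def block_summary(subject: SubjectDataset, n_blocks: int = 4, n_trials: int | None = None) -> list[float | None]:
    """Per-block preference ratios over valid trials.

    Blocks partition the original trial index range 1..n_trials into
    ``n_blocks`` equal spans (with 80 trials and 4 blocks: 20 trials each),
    so exclusions shrink a block's denominator but never shift block
    boundaries. Blocks without valid trials are reported as None.
    """
    if n_blocks < 1:
        raise ValidationError("n_blocks must be >= 1")
    if n_trials is None:
        n_trials = max((t.trial for t in subject.trials), default=0)
    span = n_trials / n_blocks
    ratios: list[float | None] = []
    for b in range(1, n_blocks + 1):
        lo, hi = (b - 1) * span, b * span
        in_block = [t for t in subject.valid_trials if lo < t.trial <= hi]
        if not in_block:
            ratios.append(None)
        else:
            safe = sum(1 for t in in_block if t.choice in SAFE_DECKS)
            ratios.append(safe / len(in_block))
    return ratios


def behavioral_table(groups: Sequence[GroupDataset], n_blocks: int = 4, n_trials: int = 80) -> pd.DataFrame:
    """Overall and per-block preference ratios for every subject."""
    rows = []
    for group in groups:
        for subj in group.subjects:
            blocks = block_summary(subj, n_blocks=n_blocks, n_trials=n_trials)
            row = {
                "subjID": subj.subject_id,
                "group": group.label,
                "preference_ratio": preference_ratio(subj),
                "n_valid": len(subj.valid_trials),
            }
            row.update({f"block{b + 1}": r for b, r in enumerate(blocks)})
            rows.append(row)
    return pd.DataFrame(rows)
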
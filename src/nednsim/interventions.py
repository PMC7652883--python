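"""Probiotic- and laxative-like perturbations and scheduled scenarios.

A probiotic-like action adds a fixed abundance increment (e.g. 0.05 for a
"+5%" dose) to one genus and renormalizes the community total to 1. A
laxative-like action multiplies every genus by a retention fraction
(default 0.01, i.e. purging the community to 1% of its mass); the
extinction floor is not applied at dosing time — it re-engages at the next
day's growth step. Scenarios interleave scheduled actions with the daily
floored/normalized update and then run on until the community is static.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import Composition, ModelParams, Trajectory, nedn_step
from .stability import STATIC_THRESHOLD, STATIC_WINDOW, is_static

__all__ = [
    "InterventionAction",
    "InterventionSchedule",
    "ScenarioResult",
    "apply_probiotic",
    "apply_laxative",
    "simulate_scenario",
]

DEFAULT_RETENTION = 0.01  # laxative purges the community to 1% by default


@dataclass(frozen=True)
class InterventionAction:
    """One scheduled perturbation.

    ``kind="probiotic"`` requires a target genus and a positive dose
    (absolute fraction of a unit total); ``kind="laxative"`` requires a
    retention fraction in (0, 1) and no target genus.
    """

    day: int
    kind: str
    magnitude: float
    genus: str | None = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"action day must be >= 1, got {self.day}")
        if self.kind == "probiotic":
            if self.genus is None:
                raise ValueError("a probiotic action requires a target genus")
            if not self.magnitude > 0:
                raise ValueError(
                    f"probiotic dose must be > 0, got {self.magnitude}"
                )
        elif self.kind == "laxative":
            if self.genus is not None:
                raise ValueError("a laxative action acts on all genera at once")
            if not 0 < self.magnitude < 1:
                raise ValueError(
                    f"laxative retention must lie in (0, 1), got {self.magnitude}"
                )
        else:
            raise ValueError(
                f"unknown action kind {self.kind!r}; "
                "expected 'probiotic' or 'laxative'"
            )


@dataclass(frozen=True)
class InterventionSchedule:
    """An ordered list of per-day actions."""

    actions: tuple[InterventionAction, ...] = ()

    def __post_init__(self) -> None:
        actions = tuple(
            sorted(self.actions, key=lambda a: (a.day, a.kind != "laxative"))
        )
        object.__setattr__(self, "actions", actions)

    @property
    def last_day(self) -> int:
        return max((a.day for a in self.actions), default=0)

    def by_day(self) -> dict[int, list[InterventionAction]]:
        """Actions grouped per day, laxative before probiotic within a day."""
        out: dict[int, list[InterventionAction]] = {}
        for a in self.actions:
            out.setdefault(a.day, []).append(a)
        return out

    def validate_genera(self, genera: Sequence[str]) -> None:
        for a in self.actions:
            if a.genus is not None and a.genus not in genera:
                raise ValueError(
                    f"schedule targets unknown genus {a.genus!r}; "
                    f"model genera are {tuple(genera)}"
                )

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "InterventionSchedule":
        actions = []
        for r in records:
            actions.append(
                InterventionAction(
                    day=int(r["day"]),
                    kind=str(r["kind"]),
                    magnitude=float(r["magnitude"]),
                    genus=r.get("genus"),
                )
            )
        return cls(tuple(actions))

    @classmethod
    def from_file(cls, path: str | Path) -> "InterventionSchedule":
        """Load a YAML or JSON list of {day, kind, magnitude[, genus]}."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            records = json.loads(text)
        else:
            records = yaml.safe_load(text)
        if not isinstance(records, list):
            raise ValueError("a schedule file must contain a list of actions")
        return cls.from_records(records)

    @classmethod
    def single_dose(
        cls, genus: str, dose: float, day: int = 50
    ) -> "InterventionSchedule":
        return cls((InterventionAction(day, "probiotic", dose, genus),))

    @classmethod
    def daily_doses(
        cls, genus: str, dose: float, first_day: int = 51, last_day: int = 64
    ) -> "InterventionSchedule":
        return cls(
            tuple(
                InterventionAction(d, "probiotic", dose, genus)
                for d in range(first_day, last_day + 1)
            )
        )

    @classmethod
    def laxative_then_daily(
        cls,
        genus: str,
        dose: float,
        retention: float = DEFAULT_RETENTION,
        laxative_day: int = 50,
        first_dose_day: int = 51,
        last_dose_day: int = 64,
    ) -> "InterventionSchedule":
        """Purge at ``laxative_day`` then dose daily (the sequential regimen)."""
        actions = [InterventionAction(laxative_day, "laxative", retention)]
        actions += [
            InterventionAction(d, "probiotic", dose, genus)
            for d in range(first_dose_day, last_dose_day + 1)
        ]
        return cls(tuple(actions))


def apply_probiotic(x: Composition, genus: str, dose: float) -> Composition:
    """Add ``dose`` (absolute fraction) to one genus, renormalize total to 1."""
    if genus not in x.genera:
        raise ValueError(f"unknown genus {genus!r}; have {x.genera}")
    if not dose > 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    values = x.values.copy()
    values[x.genera.index(genus)] += dose
    return Composition(x.genera, values / values.sum())


def apply_laxative(x: Composition, retention: float = DEFAULT_RETENTION) -> Composition:
    """Multiply every genus by the retention fraction (bowel purge).

    The extinction floor is deliberately not applied here; it re-engages at
    the next day's growth step, so relative proportions are preserved
    exactly at dosing time.
    """
    if not 0 < retention < 1:
        raise ValueError(f"retention must lie in (0, 1), got {retention}")
    return Composition(x.genera, x.values * retention)


def _apply_action(x: Composition, action: InterventionAction) -> Composition:
    if action.kind == "laxative":
        return apply_laxative(x, action.magnitude)
    return apply_probiotic(x, action.genus, action.magnitude)


@dataclass
class ScenarioResult:
    """Outcome of a scheduled-intervention simulation."""

    trajectory: Trajectory
    stable_state: Composition | None

    @property
    def resolved(self) -> bool:
        return self.stable_state is not None


def simulate_scenario(
    x0: Composition,
    params: ModelParams,
    schedule: InterventionSchedule = InterventionSchedule(),
    run_to_stable: bool = True,
    initial_days: int = 400,
    extension_block: int = 100,
    max_days: int = 5000,
    window: int = STATIC_WINDOW,
    threshold: float = STATIC_THRESHOLD,
) -> ScenarioResult:
    """Simulate daily dynamics with scheduled interventions.

    Each day the community first takes its floored/normalized growth step;
    any action scheduled for that day is then applied to the post-step
    state (laxative before probiotic when both fall on one day). With
    ``run_to_stable`` the run continues past the last action until the
    trailing-window staticness criterion is met (checked at
    ``initial_days`` past the last action, then every ``extension_block``
    days) or ``max_days`` elapses; otherwise it stops at ``max_days``.

    With an empty schedule this reproduces
    :func:`nednsim.stability.run_to_stability` exactly, day for day.
    """
    schedule.validate_genera(x0.genera)
    if schedule.last_day > max_days:
        raise ValueError(
            f"schedule runs to day {schedule.last_day} but max_days={max_days}"
        )
    if initial_days < window:
        raise ValueError("initial_days must be >= the staticness window")
    actions_by_day = schedule.by_day()
    first_check = schedule.last_day + initial_days

    k = len(x0.genera)
    values = np.empty((max_days + 1, k))
    values[0] = x0.values
    state = x0
    static_at: int | None = None
    for day in range(1, max_days + 1):
        state = nedn_step(state, params)
        for action in actions_by_day.get(day, ()):
            state = _apply_action(state, action)
        values[day] = state.values
        if run_to_stable and day >= first_check:
            if (day - first_check) % extension_block == 0:
                traj_so_far = Trajectory(
                    x0.genera, np.arange(day + 1), values[: day + 1]
                )
                if is_static(traj_so_far, window=window, threshold=threshold):
                    static_at = day
                    break
    n = static_at if static_at is not None else max_days
    traj = Trajectory(x0.genera, np.arange(n + 1), values[: n + 1])
    stable = traj.final_composition() if static_at is not None else None
    if not run_to_stable:
        stable = None
    return ScenarioResult(trajectory=traj, stable_state=stable)
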
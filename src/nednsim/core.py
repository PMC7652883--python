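"""Daily update rules for faecal-microbiome dynamics.

Two discrete-time models over genus-level relative abundances:

* The floored, defecation-normalized model ("nedn"): each day every genus
  grows logistically with rate ``alpha`` and pairwise interactions ``beta``;
  any genus whose predicted abundance falls below ``FLOOR`` (1e-6) is held at
  the floor (no genus ever goes extinct), and if the community total exceeds
  1 the whole vector is rescaled to 1 (excess biomass leaves with the stool).
* The classical discrete generalized Lotka-Volterra comparator ("glv"):
  the same growth bracket with no floor and no normalization, so abundances
  may go negative or diverge.

States are relative abundances: dimensionless fractions of a unit community
total. The interaction matrix is oriented ``beta[j, i]`` = effect of source
genus *j* on target genus *i*, so the interaction term felt by genus *i* is
``sum_j x[j] * beta[j, i]`` (row vector times matrix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "FLOOR",
    "SIMPLEX_TOL",
    "PARAM_BOX",
    "Composition",
    "RawState",
    "ModelParams",
    "Trajectory",
    "GenusMismatchError",
    "growth_step",
    "defecation_step",
    "nedn_step",
    "glv_step",
    "step",
    "simulate",
]

#: Minimal abundance a genus can reach in the floored model (non-extinction).
FLOOR = 1e-6
#: Tolerance on the unit-simplex bound, absorbing accumulated rounding.
SIMPLEX_TOL = 1e-12
#: Box constraint on every growth-rate and interaction coefficient.
PARAM_BOX = (-3.0, 3.0)

ModelName = Literal["nedn", "glv"]


class GenusMismatchError(ValueError):
    """Raised when two objects disagree on genus labels or their order."""


def _as_labels(genera: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(str(g) for g in genera)
    if len(set(labels)) != len(labels):
        raise ValueError(f"genus labels must be unique, got {labels}")
    return labels


def _check_same_genera(a: Sequence[str], b: Sequence[str]) -> None:
    if tuple(a) != tuple(b):
        raise GenusMismatchError(
            f"genus orderings differ: {tuple(a)} vs {tuple(b)}"
        )


@dataclass(frozen=True)
class Composition:
    """A faecal community state: strictly positive abundances, total <= 1.

    Parameters
    ----------
    genera:
        Ordered, unique genus labels.
    values:
        Relative abundances, one per genus. Every entry must be > 0 and the
        sum must not exceed ``1 + SIMPLEX_TOL``.
    """

    genera: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genera", _as_labels(self.genera))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.shape[0] != len(self.genera):
            raise ValueError(
                f"expected {len(self.genera)} values, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("composition values must be finite")
        if np.any(vals <= 0):
            raise ValueError(
                "composition values must be strictly positive "
                f"(min={vals.min()!r}); apply the 1e-6 floor upstream"
            )
        total = float(vals.sum())
        if total > 1.0 + SIMPLEX_TOL:
            raise ValueError(f"composition total {total} exceeds 1")

    @property
    def k(self) -> int:
        return len(self.genera)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def reorder(self, genera: Sequence[str]) -> "Composition":
        """Return the same state with genus axes permuted to ``genera``."""
        labels = _as_labels(genera)
        if set(labels) != set(self.genera):
            raise GenusMismatchError(
                f"cannot reorder {self.genera} to {labels}"
            )
        idx = [self.genera.index(g) for g in labels]
        return Composition(labels, self.values[idx])

    def asdict(self) -> dict[str, float]:
        return dict(zip(self.genera, map(float, self.values)))


@dataclass(frozen=True)
class RawState:
    """An unconstrained abundance vector (pre-defecation, or a gLV state).

    Values may exceed 1 and, for the gLV comparator, may be negative.
    """

    genera: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genera", _as_labels(self.genera))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.shape[0] != len(self.genera):
            raise ValueError(
                f"expected {len(self.genera)} values, got shape {vals.shape}"
            )

    @property
    def k(self) -> int:
        return len(self.genera)


@dataclass(frozen=True)
class ModelParams:
    """Growth rates and interactions of a k-genus community model.

    Parameters
    ----------
    genera:
        Ordered genus labels (dimension k).
    alpha:
        Inherent per-day growth rate of each genus, within ``PARAM_BOX``.
    beta:
        k x k interaction matrix, ``beta[j, i]`` = effect of genus ``j`` on
        genus ``i``. The diagonal is exactly zero (self-limitation is carried
        by the logistic ``alpha * (1 - x)`` term) and every entry lies within
        ``PARAM_BOX``.
    """

    genera: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genera", _as_labels(self.genera))
        k = len(self.genera)
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        if alpha.shape != (k,):
            raise ValueError(f"alpha must have shape ({k},), got {alpha.shape}")
        if beta.shape != (k, k):
            raise ValueError(f"beta must have shape ({k},{k}), got {beta.shape}")
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
            raise ValueError("parameters must be finite")
        if np.any(np.diag(beta) != 0.0):
            raise ValueError("beta diagonal must be exactly zero")
        lo, hi = PARAM_BOX
        if alpha.min() < lo or alpha.max() > hi or beta.min() < lo or beta.max() > hi:
            raise ValueError(f"all parameters must lie within [{lo}, {hi}]")

    @property
    def k(self) -> int:
        return len(self.genera)

    @property
    def n_free_parameters(self) -> int:
        """Count of free coefficients: k growth rates + k(k-1) off-diagonal
        interactions (the zero diagonal is pinned, not free)."""
        k = self.k
        return k + k * (k - 1)

    def reorder(self, genera: Sequence[str]) -> "ModelParams":
        """Permute the genus axes of alpha and beta to ``genera``."""
        labels = _as_labels(genera)
        if set(labels) != set(self.genera):
            raise GenusMismatchError(
                f"cannot reorder {self.genera} to {labels}"
            )
        idx = np.array([self.genera.index(g) for g in labels])
        return ModelParams(labels, self.alpha[idx], self.beta[np.ix_(idx, idx)])

    # -- serialization ----------------------------------------------------
    # JSON keeps doubles bit-exact (repr round-trip), satisfying the
    # round-trip contract of the parameter-file interface.

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genera": list(self.genera),
            "alpha": [float(a) for a in self.alpha],
            "beta": [[float(b) for b in row] for row in self.beta],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(payload["genera"]),
            np.array(payload["alpha"], dtype=float),
            np.array(payload["beta"], dtype=float),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write a TSV: first row alpha, then beta (row = source genus)."""
        lines = ["genus\talpha\t" + "\t".join(f"beta_to_{g}" for g in self.genera)]
        for j, g in enumerate(self.genera):
            cells = [g, repr(float(self.alpha[j]))]
            cells += [repr(float(b)) for b in self.beta[j]]
            lines.append("\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModelParams":
        lines = Path(path).read_text().strip().split("\n")
        genera, alpha, beta = [], [], []
        for line in lines[1:]:
            cells = line.split("\t")
            genera.append(cells[0])
            alpha.append(float(cells[1]))
            beta.append([float(c) for c in cells[2:]])
        return cls(tuple(genera), np.array(alpha), np.array(beta))


def _check_finite_state(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("state contains non-finite abundances")


def _growth_bracket(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """x * (1 + alpha*(1-x) + x @ beta), the shared gLV growth kernel."""
    return x * (1.0 + params.alpha * (1.0 - x) + x @ params.beta)


def growth_step(x: Composition, params: ModelParams) -> RawState:
    """Biological growth: logistic + interaction update, floored at 1e-6.

    Returns the presumed abundance of each genus before the next defecation,
    ``max(FLOOR, x_i * (1 + alpha_i*(1-x_i) + sum_j x_j*beta[j,i]))``. The
    floor applies to the whole product, so no genus is ever eliminated.
    """
    _check_same_genera(x.genera, params.genera)
    _check_finite_state(x.values)
    g = np.maximum(FLOOR, _growth_bracket(x.values, params))
    return RawState(x.genera, g)


def defecation_step(g: RawState) -> Composition:
    """Normalize the community back onto the unit simplex when it overflows.

    If the total abundance exceeds 1 every genus is divided by the total
    (excess biomass is defecated); otherwise the state passes through
    unchanged. Input entries must be positive (the growth floor guarantees
    this).
    """
    if np.any(g.values <= 0):
        raise ValueError(
            "defecation_step requires strictly positive abundances; "
            "the growth floor was bypassed"
        )
    return Composition(g.genera, g.values / max(1.0, float(g.values.sum())))


def nedn_step(x: Composition, params: ModelParams) -> Composition:
    """One full day of the floored, defecation-normalized model."""
    return defecation_step(growth_step(x, params))


def glv_step(x: RawState | Composition, params: ModelParams) -> RawState:
    """One day of the unconstrained discrete generalized Lotka-Volterra model.

    No floor and no normalization: abundances may go negative or above 1.
    """
    _check_same_genera(x.genera, params.genera)
    _check_finite_state(x.values)
    with np.errstate(over="ignore", invalid="ignore"):
        out = _growth_bracket(np.asarray(x.values, dtype=float), params)
    return RawState(x.genera, out)


def step(
    x: Composition | RawState, params: ModelParams, model: ModelName
) -> Composition | RawState:
    """Dispatch one daily update of the requested model."""
    if model == "nedn":
        if not isinstance(x, Composition):
            x = Composition(x.genera, x.values)
        return nedn_step(x, params)
    if model == "glv":
        return glv_step(x, params)
    raise ValueError(f"unknown model {model!r}; expected 'nedn' or 'glv'")


@dataclass
class Trajectory:
    """A day-indexed sequence of community states.

    ``values[t]`` is the state on day ``days[t]``; day indices are
    consecutive integers starting at 0 and ``values[0]`` is the supplied
    initial state. ``diverged`` marks a gLV run truncated because the state
    left the representable range.
    """

    genera: tuple[str, ...]
    days: np.ndarray
    values: np.ndarray  # (n_days+1, k)
    model: ModelName = "nedn"
    diverged: bool = False

    def __post_init__(self) -> None:
        self.genera = _as_labels(self.genera)
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.days.shape[0], len(self.genera)):
            raise ValueError("days/values/genera shapes are inconsistent")
        if self.days.shape[0] and not np.all(np.diff(self.days) == 1):
            raise ValueError("day indices must increase by exactly 1")

    def __len__(self) -> int:
        return self.days.shape[0]

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]

    def final_composition(self) -> Composition:
        if self.model != "nedn":
            raise ValueError("only floored/normalized states are compositions")
        return Composition(self.genera, self.values[-1])

    def states(self) -> Iterator[Composition | RawState]:
        cls = Composition if self.model == "nedn" else RawState
        for row in self.values:
            yield cls(self.genera, row)

    def to_tsv(self, path: str | Path) -> None:
        """Write day-per-row TSV: first column day index, one per genus."""
        header = "day\t" + "\t".join(self.genera)
        lines = [header]
        for d, row in zip(self.days, self.values):
            lines.append("\t".join([str(int(d))] + [repr(float(v)) for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, model: ModelName = "nedn") -> "Trajectory":
        lines = Path(path).read_text().strip().split("\n")
        genera = tuple(lines[0].split("\t")[1:])
        days, values = [], []
        for line in lines[1:]:
            cells = line.split("\t")
            days.append(int(cells[0]))
            values.append([float(c) for c in cells[1:]])
        return cls(genera, np.array(days), np.array(values), model=model)


def simulate(
    x0: Composition | RawState,
    params: ModelParams,
    n_days: int,
    model: ModelName = "nedn",
) -> Trajectory:
    """Iterate the daily update ``n_days`` times from ``x0``.

    Returns a trajectory of ``n_days + 1`` states (day 0 is the initial
    state). A gLV run whose state becomes non-finite is truncated at the
    last finite day and flagged ``diverged=True`` instead of raising, so
    multi-day prediction scoring can still use the finished prefix.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    _check_same_genera(x0.genera, params.genera)
    k = len(x0.genera)
    values = np.empty((n_days + 1, k), dtype=float)
    values[0] = np.asarray(x0.values, dtype=float)
    diverged = False
    if model == "nedn":
        state: Composition | RawState = Composition(x0.genera, values[0])
    elif model == "glv":
        state = RawState(x0.genera, values[0])
    else:
        raise ValueError(f"unknown model {model!r}; expected 'nedn' or 'glv'")
    n_done = n_days
    for t in range(n_days):
        state = step(state, params, model)
        if not np.all(np.isfinite(state.values)):
            diverged = True
            n_done = t
            break
        values[t + 1] = state.values
    values = values[: n_done + 1]
    return Trajectory(
        x0.genera, np.arange(n_done + 1), values, model=model, diverged=diverged
    )
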
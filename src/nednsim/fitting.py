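"""Fitting growth/interaction parameters to next-day composition pairs.

The training signal is pairs (x_day0, x_day1) of observed compositions one
calendar day apart. The objective is the raw cumulative squared deviation

    L = sum over pairs, sum over genera (predicted_next_day - actual)^2

with the prediction given by one daily update of the chosen model. Fitting
is a box-constrained minimization of L over the k growth rates and the
k(k-1) off-diagonal interaction coefficients, every coefficient within
[-3, 3].

The default optimizer is a seeded multi-start bounded least-squares
refinement: the first start is the closed-form solution of the update rule
linearized in the parameters (exact when neither the extinction floor nor
the overflow normalization engages), and further starts are drawn uniformly
from the box. A controlled-random-search backend (``algorithm="crs2"``,
NLopt GN_CRS2_LM) is available where nlopt is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import (
    FLOOR,
    PARAM_BOX,
    Composition,
    GenusMismatchError,
    ModelName,
    ModelParams,
)

__all__ = [
    "DayPairDataset",
    "FitResult",
    "HorizonErrorSummary",
    "objective_L",
    "fit",
    "horizon_error",
]


@dataclass(frozen=True)
class DayPairDataset:
    """Composition pairs a fixed number of days (the horizon) apart.

    ``starts[p]`` and ``ends[p]`` are the abundance vectors of pair ``p``
    over the shared ``genera`` ordering.
    """

    genera: tuple[str, ...]
    horizon: int
    starts: np.ndarray  # (n_pairs, k)
    ends: np.ndarray  # (n_pairs, k)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genera", tuple(self.genera))
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if starts.ndim != 2 or starts.shape[1] != len(self.genera):
            raise ValueError("starts must be (n_pairs, k)")
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have matching shapes")
        if starts.shape[0] == 0:
            raise ValueError("a day-pair dataset must contain at least one pair")

    @property
    def n_pairs(self) -> int:
        return self.starts.shape[0]

    @property
    def k(self) -> int:
        return len(self.genera)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[Composition, Composition]], horizon: int = 1
    ) -> "DayPairDataset":
        if not pairs:
            raise ValueError("a day-pair dataset must contain at least one pair")
        genera = pairs[0][0].genera
        for a, b in pairs:
            if a.genera != genera or b.genera != genera:
                raise GenusMismatchError("all pairs must share one genus ordering")
        starts = np.stack([a.values for a, _ in pairs])
        ends = np.stack([b.values for _, b in pairs])
        return cls(genera, horizon, starts, ends)

    def pairs(self) -> list[tuple[Composition, Composition]]:
        return [
            (Composition(self.genera, s), Composition(self.genera, e))
            for s, e in zip(self.starts, self.ends)
        ]

    # Long-format TSV: pair_id, role in {start, end}, one column per genus.
    def to_tsv(self, path: str | Path) -> None:
        lines = ["pair_id\thorizon\trole\t" + "\t".join(self.genera)]
        for p in range(self.n_pairs):
            for role, row in (("start", self.starts[p]), ("end", self.ends[p])):
                cells = [str(p), str(self.horizon), role]
                cells += [repr(float(v)) for v in row]
                lines.append("\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DayPairDataset":
        lines = Path(path).read_text().strip().split("\n")
        genera = tuple(lines[0].split("\t")[3:])
        rows: dict[int, dict[str, np.ndarray]] = {}
        horizon = 1
        for line in lines[1:]:
            cells = line.split("\t")
            pid, horizon, role = int(cells[0]), int(cells[1]), cells[2]
            rows.setdefault(pid, {})[role] = np.array(
                [float(c) for c in cells[3:]]
            )
        ids = sorted(rows)
        starts = np.stack([rows[i]["start"] for i in ids])
        ends = np.stack([rows[i]["end"] for i in ids])
        return cls(genera, int(horizon), starts, ends)


def _step_matrix(X: np.ndarray, params: ModelParams, model: ModelName) -> np.ndarray:
    """Apply one daily update to every row of X at once."""
    with np.errstate(over="ignore", invalid="ignore"):
        bracket = X * (1.0 + params.alpha * (1.0 - X) + X @ params.beta)
    if model == "glv":
        return bracket
    if model == "nedn":
        g = np.maximum(FLOOR, bracket)
        return g / np.maximum(1.0, g.sum(axis=1, keepdims=True))
    raise ValueError(f"unknown model {model!r}; expected 'nedn' or 'glv'")


def _predict(
    starts: np.ndarray, params: ModelParams, model: ModelName, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the update ``n_steps`` times; returns (pred, finite_row_mask)."""
    X = starts.copy()
    for _ in range(n_steps):
        X = _step_matrix(X, params, model)
    finite = np.all(np.isfinite(X), axis=1)
    return X, finite


def objective_L(
    params: ModelParams, data: DayPairDataset, model: ModelName = "nedn"
) -> float:
    """Cumulative squared deviation of one-step predictions over all pairs."""
    if tuple(data.genera) != params.genera:
        raise GenusMismatchError(
            f"dataset genera {data.genera} do not match params {params.genera}"
        )
    if data.horizon != 1:
        raise ValueError(
            f"the training objective is defined on horizon-1 pairs, "
            f"got horizon {data.horizon}; use horizon_error for longer horizons"
        )
    pred, finite = _predict(data.starts, params, model, 1)
    if not np.all(finite):
        return float("inf")
    return float(np.sum((pred - data.ends) ** 2))


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    objective_value: float
    n_evaluations: int
    converged: bool
    seed: int
    model: ModelName = "nedn"


def _unpack(theta: np.ndarray, genera: tuple[str, ...]) -> ModelParams:
    k = len(genera)
    alpha = theta[:k]
    beta = np.zeros((k, k))
    off = ~np.eye(k, dtype=bool)
    beta[off] = theta[k:]
    return ModelParams(genera, alpha, beta)


def _pack(params: ModelParams) -> np.ndarray:
    off = ~np.eye(params.k, dtype=bool)
    return np.concatenate([params.alpha, params.beta[off]])


def _linearized_start(data: DayPairDataset, box: tuple[float, float]) -> np.ndarray:
    """Closed-form per-genus least squares, ignoring floor and normalization.

    In the unconstrained regime the predicted abundance is linear in the
    parameters: pred_i = x_i + alpha_i*x_i*(1-x_i) + sum_{j!=i} beta_ji*x_i*x_j,
    so each target genus is an independent linear regression.
    """
    X, Y = data.starts, data.ends
    k = data.k
    alpha = np.zeros(k)
    beta = np.zeros((k, k))
    for i in range(k):
        others = [j for j in range(k) if j != i]
        design = np.column_stack(
            [X[:, i] * (1.0 - X[:, i])] + [X[:, i] * X[:, j] for j in others]
        )
        target = Y[:, i] - X[:, i]
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        alpha[i] = coef[0]
        for c, j in zip(coef[1:], others):
            beta[j, i] = c
    theta = np.concatenate([alpha, beta[~np.eye(k, dtype=bool)]])
    return np.clip(theta, box[0], box[1])


def fit(
    data: DayPairDataset,
    model: ModelName = "nedn",
    box: tuple[float, float] = PARAM_BOX,
    xtol_rel: float = 1e-12,
    ftol_rel: float = 1e-12,
    max_evaluations: int = 100_000,
    seed: int = 0,
    n_starts: int = 3,
    algorithm: Literal["multistart", "crs2"] = "multistart",
) -> FitResult:
    """Estimate growth rates and interactions from horizon-1 pairs.

    Deterministic given ``seed``. ``max_evaluations`` caps the total number
    of objective evaluations across all starts; if it is exhausted before
    the relative tolerances are met the best point found is returned with
    ``converged=False``.
    """
    if data.horizon != 1:
        raise ValueError("training uses horizon-1 pairs only")
    genera = tuple(data.genera)
    k = len(genera)
    n_theta = k + k * (k - 1)

    if algorithm == "crs2":
        return _fit_crs2(
            data, model, box, xtol_rel, ftol_rel, max_evaluations, seed
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = _unpack(theta, genera)
        pred, finite = _predict(data.starts, params, model, 1)
        res = pred - data.ends
        # a diverged row cannot occur in one step from finite inputs, but
        # guard anyway so the optimizer sees a large finite penalty
        res[~finite] = 1e6
        return res.ravel()

    rng = np.random.default_rng(seed)
    start_points = [_linearized_start(data, box)]
    for _ in range(max(0, n_starts - 1)):
        start_points.append(rng.uniform(box[0], box[1], size=n_theta))

    best = None
    n_evals = 0
    converged = False
    for theta0 in start_points:
        budget = max_evaluations - n_evals
        if budget <= 0:
            break
        sol = least_squares(
            residuals,
            theta0,
            bounds=(np.full(n_theta, box[0]), np.full(n_theta, box[1])),
            xtol=xtol_rel,
            ftol=ftol_rel,
            gtol=None,
            max_nfev=budget,
        )
        n_evals += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.status > 0:  # terminated by a tolerance, not the budget
            converged = True
    assert best is not None
    params = _unpack(np.clip(best.x, box[0], box[1]), genera)
    return FitResult(
        params=params,
        objective_value=objective_L(params, data, model),
        n_evaluations=n_evals,
        converged=converged,
        seed=seed,
        model=model,
    )


def _fit_crs2(
    data: DayPairDataset,
    model: ModelName,
    box: tuple[float, float],
    xtol_rel: float,
    ftol_rel: float,
    max_evaluations: int,
    seed: int,
) -> FitResult:
    """Controlled random search with local mutation (NLopt GN_CRS2_LM)."""
    try:
        import nlopt
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "algorithm='crs2' requires the optional nlopt package; "
            "use the default multistart algorithm instead"
        ) from exc
    genera = tuple(data.genera)
    k = len(genera)
    n_theta = k + k * (k - 1)
    n_evals = 0

    def nlopt_objective(theta: np.ndarray, grad: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return objective_L(_unpack(theta, genera), data, model)

    nlopt.srand(seed)
    opt = nlopt.opt(nlopt.GN_CRS2_LM, n_theta)
    opt.set_lower_bounds(np.full(n_theta, box[0]))
    opt.set_upper_bounds(np.full(n_theta, box[1]))
    opt.set_min_objective(nlopt_objective)
    opt.set_xtol_rel(xtol_rel)
    opt.set_ftol_rel(ftol_rel)
    opt.set_maxeval(max_evaluations)
    theta = opt.optimize(_linearized_start(data, box))
    params = _unpack(np.clip(theta, box[0], box[1]), genera)
    return FitResult(
        params=params,
        objective_value=objective_L(params, data, model),
        n_evaluations=n_evals,
        converged=opt.last_optimize_result() in (nlopt.XTOL_REACHED, nlopt.FTOL_REACHED),
        seed=seed,
        model=model,
    )


@dataclass(frozen=True)
class HorizonErrorSummary:
    """Per-pair squared-deviation errors of h-day-ahead predictions.

    ``per_pair`` holds NaN for pairs whose (gLV) prediction diverged before
    the horizon; those pairs are excluded from ``mean`` and counted in
    ``n_excluded``.
    """

    horizon: int
    model: ModelName
    per_pair: np.ndarray
    mean: float
    n_excluded: int


def horizon_error(
    params: ModelParams, data: DayPairDataset, model: ModelName = "nedn"
) -> HorizonErrorSummary:
    """Score ``data.horizon``-day-ahead predictions pair by pair.

    The prediction iterates the daily update ``horizon`` times from each
    start; the error of a pair is the squared deviation summed over genera.
    """
    if tuple(data.genera) != params.genera:
        raise GenusMismatchError(
            f"dataset genera {data.genera} do not match params {params.genera}"
        )
    if data.horizon not in (1, 2, 3):
        raise ValueError(f"horizon must be 1, 2 or 3, got {data.horizon}")
    pred, finite = _predict(data.starts, params, model, data.horizon)
    per_pair = np.full(data.n_pairs, np.nan)
    diff = pred[finite] - data.ends[finite]
    per_pair[finite] = np.sum(diff**2, axis=1)
    n_excluded = int(np.sum(~finite))
    if n_excluded == data.n_pairs:
        mean = float("nan")
    else:
        mean = float(np.nanmean(per_pair))
    return HorizonErrorSummary(
        horizon=data.horizon,
        model=model,
        per_pair=per_pair,
        mean=mean,
        n_excluded=n_excluded,
    )
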